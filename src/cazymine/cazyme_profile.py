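"""Per-species CAZyme profiles, substrate heatmap counts and rankings.

A genome's CAZyme profile counts, per CAZy family, the number of distinct
proteins carrying at least one accepted domain of that family — the counting
unit is the gene, so a protein with two accepted GH5 domains contributes one
GH5, while a protein with GH10 + CBM13 contributes to both families.
Glycosyl transferases (GTs), which are largely biosynthetic, are excluded
from the headline totals used for ranking and tree heat annotation.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .domain_annotation import AnnotatedProtein

__all__ = [
    "CAZY_CLASSES",
    "SUBSTRATE_CATEGORIES",
    "GenomeCazymeProfile",
    "SubstrateMap",
    "family_class",
    "base_family",
    "build_profiles",
    "substrate_counts",
    "rank_species",
    "select_rich_species",
    "export_tree_heat_annotation",
    "profiles_to_frame",
]

CAZY_CLASSES = ("GH", "GT", "PL", "CE", "AA", "CBM")

SUBSTRATE_CATEGORIES = (
    "beta-glucan",
    "cellulose",
    "chitin",
    "lignin",
    "mannan",
    "pectin",
    "starch",
    "xylan",
    "xyloglucan",
)

_FAMILY_RE = re.compile(r"^([A-Z]+)(\d+)(?:_(\d+))?$")


def family_class(family: str) -> str:
    """CAZy class of a family: its letter prefix before the digits.

    ``GH5_7`` -> ``GH``; ``CBM13`` -> ``CBM``.
    """
    m = _FAMILY_RE.match(family)
    if not m or m.group(1) not in CAZY_CLASSES:
        raise ValueError(f"not a recognizable CAZy family name: {family!r}")
    return m.group(1)


def base_family(family: str) -> str:
    """Family without its subfamily suffix: ``GH5_7`` -> ``GH5``."""
    return family.split("_", 1)[0]


@dataclass
class GenomeCazymeProfile:
    """Per-species CAZyme family/class counts with GT-excluded total."""

    species_id: str
    clade: str = "unknown"
    family_counts: dict[str, int] = field(default_factory=dict)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CAZY_CLASSES}
        for fam, n in self.family_counts.items():
            counts[family_class(fam)] += n
        return counts

    @property
    def total_excl_gt(self) -> int:
        return sum(
            n for fam, n in self.family_counts.items() if family_class(fam) != "GT"
        )

    @property
    def total(self) -> int:
        return sum(self.family_counts.values())


@dataclass
class SubstrateMap:
    """Many-to-many map from CAZy family to polysaccharide-substrate categories.

    Lookups are subfamily-aware: if ``GH5_7`` has no entry of its own the
    base family ``GH5`` is consulted.  Categories are restricted to the nine
    polysaccharide-degradation groups in :data:`SUBSTRATE_CATEGORIES`.
    """

    mapping: dict[str, set[str]]

    def __post_init__(self) -> None:
        for fam, cats in self.mapping.items():
            bad = cats - set(SUBSTRATE_CATEGORIES)
            if bad:
                raise ValueError(
                    f"family {fam}: unknown substrate categories {sorted(bad)}"
                )

    def categories(self, family: str) -> set[str]:
        if family in self.mapping:
            return self.mapping[family]
        return self.mapping.get(base_family(family), set())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubstrateMap":
        """Read a two-column TSV: family, comma-separated categories."""
        mapping: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("family\t"):
                    continue
                fam, cats = line.split("\t", 1)
                mapping[fam] = {c.strip() for c in cats.split(",") if c.strip()}
        return cls(mapping=mapping)

    @classmethod
    def default(cls) -> "SubstrateMap":
        """The packaged default family-to-substrate assignment table."""
        ref = resources.files("cazymine.data").joinpath("substrate_map.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("family\tcategories\n")
            for fam in sorted(self.mapping):
                fh.write(f"{fam}\t{','.join(sorted(self.mapping[fam]))}\n")


def build_profiles(
    annotated: list[AnnotatedProtein],
    species_clades: dict[str, str] | None = None,
) -> list[GenomeCazymeProfile]:
    """Aggregate annotated proteins into per-species profiles.

    ``species_clades`` maps species_id to clade; species missing from it are
    labeled ``"unknown"`` with a warning.  The count of a family is the
    number of distinct proteins with >=1 accepted domain of that family.
    """
    species_clades = species_clades or {}
    pairs: dict[str, set[tuple[str, str]]] = {}
    for prot in annotated:
        bucket = pairs.setdefault(prot.species_id, set())
        for fam in prot.families:
            bucket.add((prot.protein_id, fam))
    profiles: list[GenomeCazymeProfile] = []
    for species_id in sorted(set(pairs) | set(species_clades)):
        clade = species_clades.get(species_id)
        if clade is None:
            warnings.warn(
                f"species {species_id!r} missing from metadata; clade set to 'unknown'",
                stacklevel=2,
            )
            clade = "unknown"
        counts: dict[str, int] = {}
        for _, fam in pairs.get(species_id, set()):
            counts[fam] = counts.get(fam, 0) + 1
        profiles.append(
            GenomeCazymeProfile(
                species_id=species_id, clade=clade, family_counts=counts
            )
        )
    return profiles


def substrate_counts(
    profile: GenomeCazymeProfile, substrate_map: SubstrateMap
) -> tuple[dict[str, int], list[str]]:
    """Per-category gene counts for one species' profile.

    A gene is counted once in every category its family maps to (categories
    are not disjoint).  Families absent from the map contribute to no
    category and are returned in the unmapped report.
    """
    counts = {cat: 0 for cat in SUBSTRATE_CATEGORIES}
    unmapped: list[str] = []
    for fam, n in sorted(profile.family_counts.items()):
        cats = substrate_map.categories(fam)
        if not cats:
            unmapped.append(fam)
            continue
        for cat in cats:
            counts[cat] += n
    return counts, unmapped


def rank_species(
    profiles: list[GenomeCazymeProfile],
) -> list[GenomeCazymeProfile]:
    """Order species by GT-excluded total, descending; ties by species id."""
    if not profiles:
        raise ValueError("rank_species requires at least one profile")
    return sorted(profiles, key=lambda p: (-p.total_excl_gt, p.species_id))


def select_rich_species(
    profiles: list[GenomeCazymeProfile],
    top_k: int,
    required_categories: dict[str, int] | None = None,
    substrate_map: SubstrateMap | None = None,
) -> list[GenomeCazymeProfile]:
    """Top-k CAZyme-rich species, optionally filtered by substrate minimums.

    The candidates are the ``top_k`` species of :func:`rank_species`; if
    ``required_categories`` gives per-category minimum gene counts, species
    not meeting every minimum are removed.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    selected = rank_species(profiles)[:top_k]
    if required_categories:
        if substrate_map is None:
            substrate_map = SubstrateMap.default()
        kept = []
        for prof in selected:
            counts, _ = substrate_counts(prof, substrate_map)
            if all(
                counts.get(cat, 0) >= minimum
                for cat, minimum in required_categories.items()
            ):
                kept.append(prof)
        selected = kept
    if not selected:
        warnings.warn("select_rich_species: no species met the criteria", stacklevel=2)
    return selected


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    color = color.lstrip("#")
    return tuple(int(color[i : i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]


def _rgb_to_hex(rgb: tuple[float, float, float]) -> str:
    return "#%02X%02X%02X" % tuple(int(round(v)) for v in rgb)


def _interpolate(palette: list[str], t: float) -> str:
    """Linear color ramp over a list of hex colors, t in [0, 1]."""
    if len(palette) == 1:
        return palette[0]
    t = min(max(t, 0.0), 1.0)
    pos = t * (len(palette) - 1)
    i = min(int(pos), len(palette) - 2)
    frac = pos - i
    lo, hi = _hex_to_rgb(palette[i]), _hex_to_rgb(palette[i + 1])
    return _rgb_to_hex(tuple(l + (h - l) * frac for l, h in zip(lo, hi)))


# light yellow -> dark red, the conventional abundance heat ramp
DEFAULT_PALETTE = ["#FFFFCC", "#FD8D3C", "#8B0000"]
NEUTRAL_COLOR = "#CCCCCC"


def export_tree_heat_annotation(
    leaf_ids: list[str],
    profiles: list[GenomeCazymeProfile],
    palette: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-leaf heat annotation of GT-excluded CAZyme totals.

    The minimum total maps to the lightest palette color and the maximum to
    the darkest, with linear interpolation between.  Leaves without a
    profile get a neutral color and are reported in the mismatch list.
    Returns (annotation frame with columns leaf/value/color, mismatches).
    """
    palette = palette or DEFAULT_PALETTE
    totals = {p.species_id: p.total_excl_gt for p in profiles}
    known = [l for l in leaf_ids if l in totals]
    mismatches = [l for l in leaf_ids if l not in totals]
    if mismatches:
        warnings.warn(
            f"{len(mismatches)} tree leaves missing from profiles: {mismatches[:5]}",
            stacklevel=2,
        )
    values = [totals[l] for l in known]
    rows = []
    if values:
        lo, hi = min(values), max(values)
        if lo == hi:
            warnings.warn(
                "all species totals equal; mapping every leaf to mid-palette",
                stacklevel=2,
            )
    for leaf in leaf_ids:
        if leaf in totals:
            v = totals[leaf]
            t = 0.5 if not values or lo == hi else (v - lo) / (hi - lo)
            rows.append({"leaf": leaf, "value": v, "color": _interpolate(palette, t)})
        else:
            rows.append({"leaf": leaf, "value": None, "color": NEUTRAL_COLOR})
    return pd.DataFrame(rows, columns=["leaf", "value", "color"]), mismatches


def profiles_to_frame(profiles: list[GenomeCazymeProfile]) -> pd.DataFrame:
    """Species x family count matrix (integer, zero-filled)."""
    families = sorted({f for p in profiles for f in p.family_counts})
    data = {
        p.species_id: [p.family_counts.get(f, 0) for f in families] for p in profiles
    }
    return pd.DataFrame(data, index=families).T.astype(int)
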