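"""Seeded synthetic datasets with planted CAZyme structure.

Emulates the shape of a multi-species yeast genome-mining study: per-species
proteome FASTAs, a combined HMMER3 ``--domtblout`` table of CAZyme domain
hits, a SignalP 5 short-format secretion table, species/clade metadata, a
family-to-substrate map and a clade-structured Newick tree — together with a
ground-truth table of intended post-filter counts, so every downstream stage
can be tested without external downloads.

Planted structure: one clade can be made "CAZyme-rich" by boosting its
degradative (non-GT) family counts; a configurable fraction of hits is
planted to *fail* each filter rule (bad E-value, low HMM coverage, or an
overlapping worse-E-value duplicate), and these never appear in the ground
truth.  Identical config + seed reproduces byte-identical files.

Protein sequences are random over the 20 canonical residues; the filter
rules are purely positional/statistical, so no real motifs are needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assay_protein import StandardCurve, reducing_sugar_mM, volumetric_activity
from .cazyme_profile import SubstrateMap, family_class
from .domain_annotation import DomainHit

__all__ = [
    "SyntheticConfig",
    "DatasetManifest",
    "generate_dataset",
    "plant_filter_edge_cases",
    "generate_assay_plate",
    "write_domtblout",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

DEFAULT_FAMILY_POOL = (
    "GH3",
    "GH5_7",
    "GH5_9",
    "GH10",
    "GH11",
    "GH18",
    "GH30_7",
    "GH43_6",
    "GH51",
    "CE1",
    "CE4",
    "CBM13",
    "AA9",
    "PL1",
    "GT2",
    "GT4",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a synthetic genome-mining dataset."""

    n_species: int = 12
    n_clades: int = 4
    proteins_per_species: int = 120
    family_pool: tuple[str, ...] = DEFAULT_FAMILY_POOL
    rich_clade_index: int | None = 0
    rich_boost: float = 3.0
    noise_fraction: float = 0.2
    secreted_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clades < 1 or self.n_species < self.n_clades:
            raise ValueError("require n_species >= n_clades >= 1")
        if self.proteins_per_species < 1:
            raise ValueError("proteins_per_species must be >= 1")
        if not self.family_pool:
            raise ValueError("family_pool must be non-empty")
        for name in ("noise_fraction", "secreted_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rich_boost < 1.0:
            raise ValueError("rich_boost must be >= 1")
        if self.rich_clade_index is not None and not (
            0 <= self.rich_clade_index < self.n_clades
        ):
            raise ValueError("rich_clade_index out of range")
        for fam in self.family_pool:
            family_class(fam)  # validates the name


@dataclass
class DatasetManifest:
    """Paths of generated files plus the in-memory ground truth."""

    out_dir: Path
    fasta_paths: dict[str, Path]
    domtblout_path: Path
    signalp_path: Path
    metadata_path: Path
    substrate_map_path: Path
    tree_path: Path
    ground_truth_path: Path
    ground_truth: pd.DataFrame  # columns: species_id, family, count
    species_clades: dict[str, str]
    secreted_proteins: set[str]


def _species_names(n: int) -> list[str]:
    return [f"species_{i:03d}" for i in range(n)]


def _clade_of(i: int, n_species: int, n_clades: int) -> int:
    # contiguous blocks so clades are monophyletic in the generated tree
    return i * n_clades // n_species


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


# base mean planted gene count per degradative family per species; GT
# families use half this rate (biosynthetic background, never boosted)
_MEAN_DEGRADATIVE = 2.0
_MEAN_GT = 1.0

_HMM_LENGTH = 200  # every synthetic profile HMM has this model length


def _plant_counts(
    rng: np.random.Generator, config: SyntheticConfig, is_rich: bool
) -> dict[str, int]:
    counts: dict[str, int] = {}
    for fam in config.family_pool:
        if family_class(fam) == "GT":
            lam = _MEAN_GT
        else:
            lam = _MEAN_DEGRADATIVE * (config.rich_boost if is_rich else 1.0)
        counts[fam] = int(rng.poisson(lam))
    return counts


def _good_hit(
    rng: np.random.Generator, protein_id: str, family: str, protein_len: int
) -> DomainHit:
    # passes all three rules: E <= 1e-15, coverage >= 0.35, no overlap
    # (one planted hit per protein)
    evalue = 10.0 ** rng.uniform(-60, -16)
    cov_len = int(rng.integers(int(0.4 * _HMM_LENGTH), _HMM_LENGTH + 1))
    hmm_from = int(rng.integers(1, _HMM_LENGTH - cov_len + 2))
    ali_len = min(cov_len, protein_len)
    ali_from = int(rng.integers(1, protein_len - ali_len + 2))
    return DomainHit(
        protein_id=protein_id,
        family_id=family,
        hmm_length=_HMM_LENGTH,
        hmm_from=hmm_from,
        hmm_to=hmm_from + cov_len - 1,
        ali_from=ali_from,
        ali_to=ali_from + ali_len - 1,
        evalue_full=evalue,
        evalue_dom=evalue,
        bitscore=float(np.round(-math.log10(evalue) * 3.3, 1)),
    )


def _noise_hit(
    rng: np.random.Generator,
    protein_id: str,
    family: str,
    protein_len: int,
    mode: str,
    anchor: DomainHit | None = None,
) -> DomainHit:
    """A hit built to fail one filter rule.

    ``bad_evalue``: E-value in (1e-14, 1e-5]; ``low_coverage``: spans < 35%
    of the HMM; ``overlap``: overlaps ``anchor`` by > 20% of the shorter
    span with a worse per-domain E-value (dropped at resolution).
    """
    if mode == "bad_evalue":
        hit = _good_hit(rng, protein_id, family, protein_len)
        evalue = 10.0 ** rng.uniform(-14, -5)
        return DomainHit(
            protein_id=protein_id,
            family_id=family,
            hmm_length=hit.hmm_length,
            hmm_from=hit.hmm_from,
            hmm_to=hit.hmm_to,
            ali_from=hit.ali_from,
            ali_to=hit.ali_to,
            evalue_full=evalue,
            evalue_dom=evalue,
            bitscore=hit.bitscore,
        )
    if mode == "low_coverage":
        hit = _good_hit(rng, protein_id, family, protein_len)
        cov_len = int(rng.integers(10, int(0.35 * _HMM_LENGTH)))  # < 35%
        ali_len = min(cov_len, protein_len)
        return DomainHit(
            protein_id=protein_id,
            family_id=family,
            hmm_length=_HMM_LENGTH,
            hmm_from=1,
            hmm_to=cov_len,
            ali_from=hit.ali_from,
            ali_to=hit.ali_from + ali_len - 1,
            evalue_full=hit.evalue_full,
            evalue_dom=hit.evalue_dom,
            bitscore=hit.bitscore,
        )
    if mode == "overlap":
        assert anchor is not None
        # same span as the anchor (100% overlap), strictly worse i-Evalue,
        # different family so dropping it actually matters for the counts
        evalue = min(anchor.evalue_dom * 1e3, 1e-16)
        return DomainHit(
            protein_id=protein_id,
            family_id=family,
            hmm_length=_HMM_LENGTH,
            hmm_from=anchor.hmm_from,
            hmm_to=anchor.hmm_to,
            ali_from=anchor.ali_from,
            ali_to=anchor.ali_to,
            evalue_full=evalue,
            evalue_dom=evalue,
            bitscore=anchor.bitscore - 5.0,
        )
    raise ValueError(f"unknown noise mode {mode!r}")


def write_domtblout(hits: list[DomainHit], path: str | Path, protein_lengths: dict[str, int] | None = None) -> None:
    """Write hits as a HMMER3 hmmsearch-orientation domtblout table."""
    protein_lengths = protein_lengths or {}
    with open(path, "w") as fh:
        fh.write("#                                                               --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord\n")
        fh.write("# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target\n")
        fh.write("#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------\n")
        for h in hits:
            tlen = protein_lengths.get(h.protein_id, h.ali_to)
            fh.write(
                f"{h.protein_id} - {tlen} {h.family_id}.hmm - {h.hmm_length} "
                f"{h.evalue_full:.6g} {h.bitscore:.1f} 0.0 1 1 "
                f"{h.evalue_dom:.6g} {h.evalue_dom:.6g} {h.bitscore:.1f} 0.0 "
                f"{h.hmm_from} {h.hmm_to} {h.ali_from} {h.ali_to} "
                f"{max(1, h.ali_from - 2)} {h.ali_to + 2} 0.90 -\n"
            )


def _write_signalp(
    path: Path, calls: list[tuple[str, bool]], rng: np.random.Generator
) -> None:
    with open(path, "w") as fh:
        fh.write("# SignalP-5.0\torganism: euk\ttimestamp: -\n")
        fh.write("# ID\tPrediction\tSP(Sec/SPI)\tOTHER\tCS Position\n")
        for pid, secreted in calls:
            if secreted:
                p = float(np.round(rng.uniform(0.80, 0.999), 4))
                pos = int(rng.integers(15, 31))
                fh.write(
                    f"{pid}\tSP(Sec/SPI)\t{p:.4f}\t{1 - p:.4f}\t"
                    f"CS pos: {pos}-{pos + 1}. Pr: {rng.uniform(0.5, 0.99):.4f}\n"
                )
            else:
                p = float(np.round(rng.uniform(0.80, 0.999), 4))
                fh.write(f"{pid}\tOTHER\t{1 - p:.4f}\t{p:.4f}\t\n")


def _newick_for_clades(
    species: list[str], clades: list[int], rng: np.random.Generator
) -> str:
    """A tree whose topology groups each clade into its own subtree."""

    def ladder(labels: list[str]) -> str:
        node = f"{labels[0]}:{rng.uniform(0.01, 0.2):.4f}"
        for label in labels[1:]:
            node = f"({node},{label}:{rng.uniform(0.01, 0.2):.4f}):{rng.uniform(0.01, 0.1):.4f}"
        return node

    subtrees = []
    for c in sorted(set(clades)):
        members = [s for s, cl in zip(species, clades) if cl == c]
        subtrees.append(ladder(members))
    node = subtrees[0]
    for sub in subtrees[1:]:
        node = f"({node},{sub}):{rng.uniform(0.05, 0.3):.4f}"
    return node + ";"


def generate_dataset(config: SyntheticConfig, out_dir: str | Path) -> DatasetManifest:
    """Generate a complete synthetic dataset under ``out_dir``.

    Writes per-species FASTAs, a combined domtblout, a SignalP short table,
    a species/clade TSV, a substrate-map TSV, a clade-grouped Newick tree
    and a ground-truth TSV of intended post-filter (protein, family) counts
    per species.  Deterministic: same config (including seed) gives
    byte-identical files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    rng = np.random.default_rng(config.seed)
    species = _species_names(config.n_species)
    clades = [
        _clade_of(i, config.n_species, config.n_clades)
        for i in range(config.n_species)
    ]
    species_clades = {s: f"clade_{c}" for s, c in zip(species, clades)}

    fasta_paths: dict[str, Path] = {}
    all_hits: list[DomainHit] = []
    protein_lengths: dict[str, int] = {}
    truth_rows: list[dict] = []
    signalp_calls: list[tuple[str, bool]] = []
    secreted_proteins: set[str] = set()

    for sp, clade_idx in zip(species, clades):
        is_rich = (
            config.rich_clade_index is not None
            and clade_idx == config.rich_clade_index
        )
        lengths = rng.integers(250, 601, size=config.proteins_per_species)
        proteins = [
            (f"{sp}|p{j:04d}", int(lengths[j]))
            for j in range(config.proteins_per_species)
        ]
        for pid, length in proteins:
            protein_lengths[pid] = length

        counts = _plant_counts(rng, config, is_rich)
        planted_pairs: list[tuple[str, str]] = []  # (protein_id, family)
        for fam in config.family_pool:
            planted_pairs.extend((fam,) for _ in range(counts[fam]))
        planted_pairs = [p[0] for p in planted_pairs]
        # cap at the number of available proteins (one planted family each)
        if len(planted_pairs) > len(proteins):
            planted_pairs = planted_pairs[: len(proteins)]
            recount: dict[str, int] = {}
            for fam in planted_pairs:
                recount[fam] = recount.get(fam, 0) + 1
            counts = {fam: recount.get(fam, 0) for fam in config.family_pool}

        carrier_idx = rng.choice(
            len(proteins), size=len(planted_pairs), replace=False
        )
        good_hits: list[DomainHit] = []
        for fam, idx in zip(planted_pairs, sorted(carrier_idx)):
            pid, plen = proteins[idx]
            good_hits.append(_good_hit(rng, pid, fam, plen))

        # noise hits: planted to fail, never in the ground truth
        n_noise = int(round(config.noise_fraction * len(good_hits)))
        noise_hits: list[DomainHit] = []
        modes = ["bad_evalue", "low_coverage", "overlap"]
        carriers = {h.protein_id for h in good_hits}
        free = [p for p in proteins if p[0] not in carriers]
        other_families = [
            f for f in config.family_pool if family_class(f) != "GT"
        ] or list(config.family_pool)
        for k in range(n_noise):
            mode = modes[k % len(modes)]
            fam = other_families[int(rng.integers(len(other_families)))]
            if mode == "overlap" and good_hits:
                anchor = good_hits[int(rng.integers(len(good_hits)))]
                overlap_fam = next(
                    f for f in other_families + list(config.family_pool)
                    if f != anchor.family_id
                )
                noise_hits.append(
                    _noise_hit(
                        rng,
                        anchor.protein_id,
                        overlap_fam,
                        protein_lengths[anchor.protein_id],
                        "overlap",
                        anchor=anchor,
                    )
                )
            elif free:
                pid, plen = free[int(rng.integers(len(free)))]
                noise_hits.append(_noise_hit(rng, pid, fam, plen, mode))

        all_hits.extend(good_hits)
        all_hits.extend(noise_hits)

        for fam in config.family_pool:
            truth_rows.append(
                {"species_id": sp, "family": fam, "count": counts[fam]}
            )

        # secretion calls: a fraction of CAZyme carriers are secreted
        for h in good_hits:
            secreted = bool(rng.random() < config.secreted_fraction)
            signalp_calls.append((h.protein_id, secreted))
            if secreted:
                secreted_proteins.add(h.protein_id)

        fasta_path = out_dir / f"{sp}.fasta"
        with open(fasta_path, "w") as fh:
            for pid, length in proteins:
                fh.write(f">{pid} synthetic protein of {sp}\n")
                seq = _random_sequence(rng, length)
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        fasta_paths[sp] = fasta_path

    domtblout_path = out_dir / "hits.domtblout"
    write_domtblout(all_hits, domtblout_path, protein_lengths)

    signalp_path = out_dir / "signalp_short.tsv"
    _write_signalp(signalp_path, signalp_calls, rng)

    metadata_path = out_dir / "species_clades.tsv"
    with open(metadata_path, "w") as fh:
        fh.write("species_id\tclade\n")
        for sp in species:
            fh.write(f"{sp}\t{species_clades[sp]}\n")

    substrate_map_path = out_dir / "substrate_map.tsv"
    SubstrateMap.default().to_tsv(substrate_map_path)

    tree_path = out_dir / "tree.nwk"
    tree_path.write_text(_newick_for_clades(species, clades, rng) + "\n")

    ground_truth = pd.DataFrame(truth_rows)
    ground_truth_path = out_dir / "ground_truth.tsv"
    ground_truth.to_csv(ground_truth_path, sep="\t", index=False)

    return DatasetManifest(
        out_dir=out_dir,
        fasta_paths=fasta_paths,
        domtblout_path=domtblout_path,
        signalp_path=signalp_path,
        metadata_path=metadata_path,
        substrate_map_path=substrate_map_path,
        tree_path=tree_path,
        ground_truth_path=ground_truth_path,
        ground_truth=ground_truth,
        species_clades=species_clades,
        secreted_proteins=secreted_proteins,
    )


def plant_filter_edge_cases(
    protein_id: str = "edge|p0000",
) -> list[tuple[DomainHit, str]]:
    """Domain hits sitting exactly on the filter boundaries, with labels.

    Coverage: 35/100 of the model is kept (inclusive rule), 34/100 removed.
    E-value: exactly 1e-15 is kept (inclusive reporting threshold), just
    above is removed.  Overlap: two hits sharing exactly 20% of the shorter
    span both stand; at 21% the worse-E-value hit is dropped.  Hits are
    placed on disjoint protein regions except the deliberate overlap pairs.
    """
    L = 100

    def hit(family, ali_from, ali_to, ev, hmm_to=L, hmm_from=1, ev_dom=None):
        return DomainHit(
            protein_id=protein_id,
            family_id=family,
            hmm_length=L,
            hmm_from=hmm_from,
            hmm_to=hmm_to,
            ali_from=ali_from,
            ali_to=ali_to,
            evalue_full=ev,
            evalue_dom=ev if ev_dom is None else ev_dom,
            bitscore=50.0,
        )

    cases: list[tuple[DomainHit, str]] = [
        (hit("GH10", 1, 35, 1e-30, hmm_to=35), "keep (coverage boundary 0.35)"),
        (hit("GH11", 41, 74, 1e-30, hmm_to=34), "reject coverage (0.34)"),
        (hit("GH3", 81, 180, 1e-15), "keep (e-value boundary 1e-15)"),
        (hit("GH5_9", 191, 290, 1.01e-15), "reject evalue (just above 1e-15)"),
        # overlap exactly 0.20: spans 301-400 and 381-480 share 20/100
        (hit("CE1", 301, 400, 1e-40), "keep (overlap 0.20 partner)"),
        (hit("CE4", 381, 480, 1e-30), "keep (overlap exactly 0.20)"),
        # overlap 0.21: spans 501-600 and 580-679 share 21/100
        (hit("GH43_6", 501, 600, 1e-40), "keep (overlap 0.21 partner)"),
        (hit("GH51", 580, 679, 1e-30), "reject overlap (0.21, worse e-value)"),
    ]
    return cases


def generate_assay_plate(
    true_activities_U_per_mL: list[float],
    curve: StandardCurve,
    seed: int = 0,
    noise_sd: float = 0.0,
    total_volume_L: float = 200e-6,
    time_min: float = 30.0,
    sample_volume_L: float = 25e-6,
) -> pd.DataFrame:
    """Simulate DNS end-point absorbances for known volumetric activities.

    Inverts the assay arithmetic — activity to mM released to absorbance via
    the standard curve — optionally adding Gaussian absorbance noise.  At
    ``noise_sd=0`` the back-calculation recovers the inputs exactly.
    Returns a frame with columns well, true_activity, absorbance.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i, activity in enumerate(true_activities_U_per_mL):
        if activity < 0:
            raise ValueError(f"well {i}: negative activity {activity}")
        conc_mM = activity * time_min * sample_volume_L / total_volume_L
        absorbance = curve.slope * conc_mM + curve.intercept
        if noise_sd > 0:
            absorbance += rng.normal(0.0, noise_sd)
        rows.append(
            {"well": f"W{i:03d}", "true_activity": activity, "absorbance": absorbance}
        )
    return pd.DataFrame(rows)


def recover_activities(
    plate: pd.DataFrame,
    curve: StandardCurve,
    total_volume_L: float = 200e-6,
    time_min: float = 30.0,
    sample_volume_L: float = 25e-6,
) -> pd.DataFrame:
    """Back-calculate U/mL from plate absorbances via the assay module."""
    out = plate.copy()
    out["recovered_activity"] = [
        volumetric_activity(
            reducing_sugar_mM(a, curve), total_volume_L, time_min, sample_volume_L
        )
        for a in out["absorbance"]
    ]
    return out
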