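"""HMMER3 domtblout parsing and the three-rule CAZyme domain filter.

Proteins are scanned against one profile HMM per CAZyme family (dbCAN-style)
and the per-domain tabular output is filtered in three steps:

1. full-sequence E-value must be <= 1e-15 (inclusive at the boundary, as
   HMMER's ``-E`` reporting threshold is inclusive);
2. the domain must span at least 35% of the profile HMM;
3. where two accepted domains on one protein would overlap by more than 20%
   of the shorter aligned span, only the domain with the better (smaller)
   per-domain independent E-value is retained.

Rules 1 and 2 use the full-sequence E-value; rule 3 resolves ties between
domains and therefore uses the per-domain i-Evalue.  All coordinates are
1-based inclusive, matching the domtblout convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

__all__ = [
    "DomainHit",
    "FilterThresholds",
    "ResolvedAnnotation",
    "AnnotatedProtein",
    "parse_domtblout",
    "hmm_coverage",
    "ali_overlap",
    "filter_hits",
    "resolve_overlaps",
    "annotate_proteome",
    "write_annotation_tsv",
    "read_annotation_tsv",
]

Orientation = Literal["hmmsearch", "hmmscan"]


@dataclass(frozen=True)
class DomainHit:
    """A single profile-HMM-vs-protein domain match.

    ``evalue_full`` is the full-sequence E-value (the statistic HMMER's
    ``-E`` flag thresholds); ``evalue_dom`` is the independent per-domain
    i-Evalue used when resolving overlapping domains.
    """

    protein_id: str
    family_id: str
    hmm_length: int
    hmm_from: int
    hmm_to: int
    ali_from: int
    ali_to: int
    evalue_full: float
    evalue_dom: float
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.hmm_from <= self.hmm_to <= self.hmm_length):
            raise ValueError(
                f"{self.protein_id}/{self.family_id}: invalid HMM coordinates "
                f"{self.hmm_from}-{self.hmm_to} on model of length {self.hmm_length}"
            )
        if not (1 <= self.ali_from <= self.ali_to):
            raise ValueError(
                f"{self.protein_id}/{self.family_id}: invalid alignment "
                f"coordinates {self.ali_from}-{self.ali_to}"
            )
        if self.evalue_full < 0 or self.evalue_dom < 0:
            raise ValueError("E-values must be non-negative")

    @property
    def ali_span(self) -> int:
        return self.ali_to - self.ali_from + 1


@dataclass(frozen=True)
class FilterThresholds:
    """The three filter cutoffs; defaults are the standard pipeline values."""

    evalue_max: float = 1e-15
    coverage_min: float = 0.35
    overlap_max: float = 0.20

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if not (0 < self.coverage_min <= 1):
            raise ValueError("coverage_min must be in (0, 1]")
        if not (0 < self.overlap_max <= 1):
            raise ValueError("overlap_max must be in (0, 1]")


RejectReason = Literal["evalue", "coverage", "overlap"]


@dataclass
class ResolvedAnnotation:
    """Post-filter accepted/rejected hit sets for one protein."""

    protein_id: str
    accepted: list[DomainHit]
    rejected: list[tuple[DomainHit, RejectReason]] = field(default_factory=list)

    @property
    def families(self) -> set[str]:
        return {h.family_id for h in self.accepted}


@dataclass
class AnnotatedProtein:
    """A protein together with its accepted domains and secretion flag."""

    protein_id: str
    species_id: str
    accepted: list[DomainHit]
    secreted: bool = False

    @property
    def families(self) -> set[str]:
        return {h.family_id for h in self.accepted}


def parse_domtblout(
    path: str | Path, orientation: Orientation = "hmmsearch"
) -> list[DomainHit]:
    """Parse a HMMER3 ``--domtblout`` table into :class:`DomainHit` objects.

    ``orientation`` declares which sequence set was the HMMER *target*:
    with ``hmmsearch`` the proteins are targets and the profiles queries;
    with ``hmmscan`` the roles (and hence the name/length columns) swap.
    A trailing ``.hmm`` suffix on the profile name is stripped.
    """
    if orientation not in ("hmmsearch", "hmmscan"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 22:
                raise ValueError(
                    f"{path}:{lineno}: expected >=22 whitespace-delimited "
                    f"columns, found {len(cols)}"
                )
            try:
                if orientation == "hmmsearch":
                    protein_id, family_id = cols[0], cols[3]
                    hmm_length = int(cols[5])
                else:
                    protein_id, family_id = cols[3], cols[0]
                    hmm_length = int(cols[2])
                hit = DomainHit(
                    protein_id=protein_id,
                    family_id=_strip_hmm_suffix(family_id),
                    hmm_length=hmm_length,
                    evalue_full=float(cols[6]),
                    evalue_dom=float(cols[12]),
                    bitscore=float(cols[13]),
                    hmm_from=int(cols[15]),
                    hmm_to=int(cols[16]),
                    ali_from=int(cols[17]),
                    ali_to=int(cols[18]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def _strip_hmm_suffix(name: str) -> str:
    return name[:-4] if name.endswith(".hmm") else name


def hmm_coverage(hit: DomainHit) -> float:
    """Fraction of the profile HMM spanned by the match."""
    return (hit.hmm_to - hit.hmm_from + 1) / hit.hmm_length


def ali_overlap(a: DomainHit, b: DomainHit) -> float:
    """Overlap of two domains on the protein: shared residues / shorter span."""
    shared = min(a.ali_to, b.ali_to) - max(a.ali_from, b.ali_from) + 1
    if shared <= 0:
        return 0.0
    return shared / min(a.ali_span, b.ali_span)


def filter_hits(
    hits: Iterable[DomainHit], thresholds: FilterThresholds = FilterThresholds()
) -> tuple[list[DomainHit], list[tuple[DomainHit, RejectReason]]]:
    """Apply the E-value and HMM-coverage rules.

    A hit passes iff evalue_full <= evalue_max and coverage >= coverage_min;
    the rejection reason records the first failed rule (E-value checked
    first).  Both comparisons are inclusive at the boundary.
    """
    passing: list[DomainHit] = []
    rejected: list[tuple[DomainHit, RejectReason]] = []
    for hit in hits:
        if hit.evalue_full > thresholds.evalue_max:
            rejected.append((hit, "evalue"))
        elif hmm_coverage(hit) < thresholds.coverage_min:
            rejected.append((hit, "coverage"))
        else:
            passing.append(hit)
    return passing, rejected


def _resolution_order_key(hit: DomainHit):
    # better i-Evalue first; ties by higher bitscore, left-most start, family
    return (hit.evalue_dom, -hit.bitscore, hit.ali_from, hit.family_id)


def resolve_overlaps(
    hits: list[DomainHit], overlap_max: float = 0.20
) -> tuple[list[DomainHit], list[tuple[DomainHit, RejectReason]]]:
    """Greedy overlap resolution among one protein's filtered hits.

    Hits are taken best per-domain i-Evalue first; a hit is accepted iff its
    overlap with every already-accepted hit is <= ``overlap_max``.  With
    exactly two conflicting domains this reduces to keeping the one with the
    better E-value.  Accepted hits are returned ordered by ali_from.
    """
    if not hits:
        return [], []
    protein_ids = {h.protein_id for h in hits}
    if len(protein_ids) > 1:
        raise ValueError(
            f"resolve_overlaps takes hits of a single protein, got {sorted(protein_ids)}"
        )
    accepted: list[DomainHit] = []
    dropped: list[tuple[DomainHit, RejectReason]] = []
    for hit in sorted(hits, key=_resolution_order_key):
        if all(ali_overlap(hit, kept) <= overlap_max for kept in accepted):
            accepted.append(hit)
        else:
            dropped.append((hit, "overlap"))
    accepted.sort(key=lambda h: (h.ali_from, h.ali_to, h.family_id))
    return accepted, dropped


def resolve_protein(
    protein_id: str,
    hits: list[DomainHit],
    thresholds: FilterThresholds = FilterThresholds(),
) -> ResolvedAnnotation:
    """Full three-rule filter for one protein's hits."""
    passing, rejected = filter_hits(hits, thresholds)
    accepted, dropped = resolve_overlaps(passing, thresholds.overlap_max)
    return ResolvedAnnotation(
        protein_id=protein_id, accepted=accepted, rejected=rejected + dropped
    )


def annotate_proteome(
    records,
    hits: Iterable[DomainHit],
    secretion_calls=None,
    thresholds: FilterThresholds = FilterThresholds(),
    on_unknown_protein: Literal["warn", "error"] = "warn",
) -> tuple[list[AnnotatedProtein], list[ResolvedAnnotation]]:
    """Filter and resolve all hits of a proteome and join secretion calls.

    ``records`` is a list of :class:`~cazymine.proteome_io.ProteinRecord`;
    ``secretion_calls`` a list of :class:`~cazymine.secretion.SecretionCall`
    (missing entries default to not-secreted).  Returns the annotated
    proteins that carry at least one accepted domain, plus an audit list of
    every protein that had hits, including those whose hits were all
    rejected (with reasons).
    """
    from .secretion import is_secreted  # local import to avoid cycle

    by_id = {r.id: r for r in records}
    secreted_ids: set[str] = set()
    if secretion_calls:
        secreted_ids = {c.protein_id for c in secretion_calls if is_secreted(c)}

    by_protein: dict[str, list[DomainHit]] = {}
    for hit in hits:
        if hit.protein_id not in by_id:
            msg = f"domain hit references unknown protein {hit.protein_id!r}"
            if on_unknown_protein == "error":
                raise ValueError(msg)
            warnings.warn(msg + "; skipped", stacklevel=2)
            continue
        by_protein.setdefault(hit.protein_id, []).append(hit)

    annotated: list[AnnotatedProtein] = []
    audit: list[ResolvedAnnotation] = []
    for pid in sorted(by_protein):
        resolution = resolve_protein(pid, by_protein[pid], thresholds)
        audit.append(resolution)
        if resolution.accepted:
            annotated.append(
                AnnotatedProtein(
                    protein_id=pid,
                    species_id=by_id[pid].species_id,
                    accepted=resolution.accepted,
                    secreted=pid in secreted_ids,
                )
            )
    return annotated, audit


_TSV_COLUMNS = [
    "protein_id",
    "family",
    "hmm_length",
    "hmm_from",
    "hmm_to",
    "ali_from",
    "ali_to",
    "hmm_coverage",
    "evalue_full",
    "evalue_dom",
    "bitscore",
    "secreted",
]


def write_annotation_tsv(annotated: list[AnnotatedProtein], path: str | Path) -> None:
    """Write accepted domains to a TSV, one row per (protein, domain)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for prot in annotated:
            for h in prot.accepted:
                fh.write(
                    "\t".join(
                        [
                            prot.protein_id,
                            h.family_id,
                            str(h.hmm_length),
                            str(h.hmm_from),
                            str(h.hmm_to),
                            str(h.ali_from),
                            str(h.ali_to),
                            repr(hmm_coverage(h)),
                            repr(h.evalue_full),
                            repr(h.evalue_dom),
                            repr(h.bitscore),
                            str(int(prot.secreted)),
                        ]
                    )
                    + "\n"
                )


def read_annotation_tsv(path: str | Path) -> list[tuple[DomainHit, bool]]:
    """Re-read :func:`write_annotation_tsv` output; returns (hit, secreted)."""
    out: list[tuple[DomainHit, bool]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_COLUMNS:
            raise ValueError(f"{path}: unexpected annotation TSV header")
        for line in fh:
            c = dict(zip(_TSV_COLUMNS, line.rstrip("\n").split("\t")))
            hit = DomainHit(
                protein_id=c["protein_id"],
                family_id=c["family"],
                hmm_length=int(c["hmm_length"]),
                hmm_from=int(c["hmm_from"]),
                hmm_to=int(c["hmm_to"]),
                ali_from=int(c["ali_from"]),
                ali_to=int(c["ali_to"]),
                evalue_full=float(c["evalue_full"]),
                evalue_dom=float(c["evalue_dom"]),
                bitscore=float(c["bitscore"]),
            )
            out.append((hit, bool(int(c["secreted"]))))
    return out
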