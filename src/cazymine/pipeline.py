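"""End-to-end convenience: annotation files in, CAZyme profiles out."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cazyme_profile import GenomeCazymeProfile, build_profiles
from .domain_annotation import (
    AnnotatedProtein,
    FilterThresholds,
    annotate_proteome,
    parse_domtblout,
)
from .proteome_io import read_fasta
from .secretion import parse_signalp_short

__all__ = ["profile_dataset", "read_species_clades"]


def read_species_clades(path: str | Path) -> dict[str, str]:
    """Read a two-column species_id/clade TSV into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["species_id"], df["clade"]))


def profile_dataset(
    fasta_paths: dict[str, Path],
    domtblout_path: str | Path,
    signalp_path: str | Path | None = None,
    metadata_path: str | Path | None = None,
    thresholds: FilterThresholds = FilterThresholds(),
    orientation: str = "hmmsearch",
) -> tuple[list[GenomeCazymeProfile], list[AnnotatedProtein]]:
    """Run the full annotation pipeline over a multi-species dataset.

    ``fasta_paths`` maps species_id to its proteome FASTA.  Returns the
    per-species profiles and the flat list of annotated proteins.
    """
    records = []
    for species_id, fasta in fasta_paths.items():
        records.extend(read_fasta(fasta, species_id=species_id))
    hits = parse_domtblout(domtblout_path, orientation=orientation)  # type: ignore[arg-type]
    calls = parse_signalp_short(signalp_path) if signalp_path else None
    annotated, _ = annotate_proteome(records, hits, calls, thresholds)
    clades = read_species_clades(metadata_path) if metadata_path else {}
    # ensure species with zero accepted CAZymes still get an (empty) profile
    for species_id in fasta_paths:
        clades.setdefault(species_id, "unknown")
    return build_profiles(annotated, clades), annotated
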