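"""SignalP 5 "short" output parsing and per-protein secretion calls.

Eukaryote-mode SignalP 5 gives a binary verdict per protein: a classical
Sec/SPI signal peptide (``SP(Sec/SPI)``) or ``OTHER``.  The label column is
authoritative — the probability columns are parsed but never re-thresholded
here.  Proteins without a call default to not-secreted on join.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

__all__ = ["SecretionCall", "parse_signalp_short", "is_secreted"]

_CS_RE = re.compile(r"CS pos:\s*(\d+)-(\d+)")


@dataclass(frozen=True)
class SecretionCall:
    protein_id: str
    prediction: str  # "SP(Sec/SPI)" or "OTHER"
    sp_probability: float
    other_probability: float
    cleavage_site: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if abs(self.sp_probability + self.other_probability - 1.0) > 0.01:
            raise ValueError(
                f"{self.protein_id}: SP and OTHER probabilities must sum to ~1, "
                f"got {self.sp_probability} + {self.other_probability}"
            )
        if self.cleavage_site is not None and self.prediction != "SP(Sec/SPI)":
            raise ValueError(
                f"{self.protein_id}: cleavage site given for non-SP prediction"
            )


def parse_signalp_short(path: str | Path) -> list[SecretionCall]:
    """Parse a SignalP 5 short-format table.

    Layout: ``#`` header lines, then tab-separated columns
    ID, Prediction, SP(Sec/SPI), OTHER, CS Position.  A cleavage-site cell
    like ``CS pos: 18-19. Pr: 0.6838`` parses to ``(18, 19)``.  Duplicate
    ids keep the first call with a warning.
    """
    path = Path(path)
    calls: list[SecretionCall] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                cols = line.split()
            if len(cols) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected >=4 columns, found {len(cols)}"
                )
            pid, prediction = cols[0], cols[1]
            if pid in seen:
                warnings.warn(
                    f"{path}:{lineno}: duplicate protein id {pid!r}; keeping first",
                    stacklevel=2,
                )
                continue
            seen.add(pid)
            try:
                sp_p = float(cols[2])
                other_p = float(cols[3])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: malformed probability: {exc}"
                ) from exc
            cs: tuple[int, int] | None = None
            if len(cols) >= 5 and prediction == "SP(Sec/SPI)":
                m = _CS_RE.search(cols[4])
                if m:
                    cs = (int(m.group(1)), int(m.group(2)))
            calls.append(
                SecretionCall(
                    protein_id=pid,
                    prediction=prediction,
                    sp_probability=sp_p,
                    other_probability=other_p,
                    cleavage_site=cs,
                )
            )
    return calls


def is_secreted(call: SecretionCall | None) -> bool:
    """True iff the call predicts a Sec/SPI signal peptide.

    ``None`` (no call for the protein) is treated as not secreted.
    """
    return call is not None and call.prediction == "SP(Sec/SPI)"
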