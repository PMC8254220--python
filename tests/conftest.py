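import numpy as np
import pytest

from cazymine.domain_annotation import DomainHit
from cazymine.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small noisy synthetic dataset shared across read-only tests."""
    config = SyntheticConfig(
        n_species=6, n_clades=3, proteins_per_species=40, seed=7
    )
    out = tmp_path_factory.mktemp("smalldata")
    return config, generate_dataset(config, out)


def random_hits(rng: np.random.Generator, protein_id: str, n: int) -> list[DomainHit]:
    """Random filtered-quality hits for one protein (overlap-testing input)."""
    hits = []
    for _ in range(n):
        ali_from = int(rng.integers(1, 400))
        ali_len = int(rng.integers(20, 150))
        hmm_len = int(rng.integers(50, 400))
        cov = int(rng.integers(int(0.35 * hmm_len), hmm_len + 1))
        hmm_from = int(rng.integers(1, hmm_len - cov + 2))
        ev = 10.0 ** rng.uniform(-50, -16)
        hits.append(
            DomainHit(
                protein_id=protein_id,
                family_id=f"GH{int(rng.integers(1, 120))}",
                hmm_length=hmm_len,
                hmm_from=hmm_from,
                hmm_to=hmm_from + cov - 1,
                ali_from=ali_from,
                ali_to=ali_from + ali_len - 1,
                evalue_full=ev,
                evalue_dom=ev * float(rng.choice([1.0, 1.0, 10.0])),
                bitscore=float(np.round(rng.uniform(20, 300), 1)),
            )
        )
    return hits


def brute_force_resolution(
    hits: list[DomainHit], overlap_max: float = 0.20
) -> list[DomainHit]:
    """Independent replay of the pairwise-constraint greedy acceptance.

    Re-derives the ordering and the overlap fraction from scratch (explicit
    interval arithmetic, no calls into the package's overlap code) so it can
    serve as an oracle for resolve_overlaps.
    """
    def span(h):
        return h.ali_to - h.ali_from + 1

    def overlap_fraction(a, b):
        lo = max(a.ali_from, b.ali_from)
        hi = min(a.ali_to, b.ali_to)
        shared = hi - lo + 1
        if shared <= 0:
            return 0.0
        return shared / min(span(a), span(b))

    order = sorted(
        hits, key=lambda h: (h.evalue_dom, -h.bitscore, h.ali_from, h.family_id)
    )
    accepted: list[DomainHit] = []
    for h in order:
        if all(overlap_fraction(h, k) <= overlap_max for k in accepted):
            accepted.append(h)
    return sorted(accepted, key=lambda h: (h.ali_from, h.ali_to, h.family_id))
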