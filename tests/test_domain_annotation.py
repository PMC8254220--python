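import numpy as np
import pytest

from cazymine.domain_annotation import (
    DomainHit,
    FilterThresholds,
    ali_overlap,
    annotate_proteome,
    filter_hits,
    hmm_coverage,
    parse_domtblout,
    read_annotation_tsv,
    resolve_overlaps,
    write_annotation_tsv,
)
from cazymine.proteome_io import ProteinRecord
from cazymine.secretion import SecretionCall

from conftest import brute_force_resolution, random_hits

DOMTBL_LINE = (
    "p1 - 412 GH10 - 331 1.2e-45 152.3 0.1 1 1 3.1e-47 1.4e-45 150.9 0.1 "
    "5 320 30 360 25 368 0.95 -\n"
)


def make_hit(
    family="GH1",
    ali=(1, 50),
    ev=1e-30,
    ev_dom=None,
    hmm=(1, 100),
    hmm_len=100,
    bitscore=100.0,
    protein="p1",
):
    return DomainHit(
        protein_id=protein,
        family_id=family,
        hmm_length=hmm_len,
        hmm_from=hmm[0],
        hmm_to=hmm[1],
        ali_from=ali[0],
        ali_to=ali[1],
        evalue_full=ev,
        evalue_dom=ev if ev_dom is None else ev_dom,
        bitscore=bitscore,
    )


class TestParsing:
    def test_hmmsearch_orientation(self, tmp_path):
        p = tmp_path / "t.dom"
        p.write_text("# comment\n" + DOMTBL_LINE)
        (hit,) = parse_domtblout(p, orientation="hmmsearch")
        assert hit.protein_id == "p1"
        assert hit.family_id == "GH10"
        assert hit.hmm_length == 331
        assert hit.evalue_full == 1.2e-45
        assert hit.evalue_dom == 1.4e-45
        assert (hit.hmm_from, hit.hmm_to) == (5, 320)
        assert (hit.ali_from, hit.ali_to) == (30, 360)

    def test_hmmscan_orientation_swaps_roles(self, tmp_path):
        p = tmp_path / "t.dom"
        # in hmmscan orientation the model is the target: name col1, tlen col3
        p.write_text(
            "GH10 - 331 p1 - 412 1.2e-45 152.3 0.1 1 1 3.1e-47 1.4e-45 150.9 0.1 "
            "5 320 30 360 25 368 0.95 -\n"
        )
        (hit,) = parse_domtblout(p, orientation="hmmscan")
        assert hit.protein_id == "p1"
        assert hit.family_id == "GH10"
        assert hit.hmm_length == 331

    def test_hmm_suffix_stripped(self, tmp_path):
        p = tmp_path / "t.dom"
        p.write_text(DOMTBL_LINE.replace(" GH10 ", " GH10.hmm "))
        assert parse_domtblout(p)[0].family_id == "GH10"

    def test_header_only_file_empty(self, tmp_path):
        p = tmp_path / "t.dom"
        p.write_text("# only\n# headers\n")
        assert parse_domtblout(p) == []

    def test_bad_column_count_cites_line(self, tmp_path):
        p = tmp_path / "t.dom"
        p.write_text("# ok\np1 - 412 GH10\n")
        with pytest.raises(ValueError, match=":2"):
            parse_domtblout(p)

    def test_non_numeric_field_errors(self, tmp_path):
        p = tmp_path / "t.dom"
        p.write_text(DOMTBL_LINE.replace("331", "banana"))
        with pytest.raises(ValueError):
            parse_domtblout(p)

    def test_annotation_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        hits = random_hits(rng, "p1", 6)
        from cazymine.domain_annotation import AnnotatedProtein

        annotated = [
            AnnotatedProtein(
                protein_id="p1", species_id="s", accepted=hits, secreted=True
            )
        ]
        path = tmp_path / "ann.tsv"
        write_annotation_tsv(annotated, path)
        back = read_annotation_tsv(path)
        assert [h for h, _ in back] == hits
        assert all(sec for _, sec in back)


class TestCoverageAndFilter:
    @pytest.mark.parametrize(
        "hmm,hmm_len,expected",
        [((5, 320), 331, 316 / 331), ((1, 200), 200, 1.0), ((10, 40), 100, 0.31)],
    )
    def test_hmm_coverage_arithmetic(self, hmm, hmm_len, expected):
        hit = make_hit(hmm=hmm, hmm_len=hmm_len, ali=(1, hmm[1] - hmm[0] + 1))
        assert hmm_coverage(hit) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "ev,cov,kept,reason",
        [
            (1e-20, 0.50, True, None),
            (1e-10, 0.90, False, "evalue"),
            (1e-20, 0.34, False, "coverage"),
            (1e-15, 0.35, True, None),  # both boundaries inclusive
            (1e-10, 0.10, False, "evalue"),  # evalue checked first
        ],
    )
    def test_filter_rules_and_first_reason(self, ev, cov, kept, reason):
        span = int(round(cov * 100))
        hit = make_hit(ev=ev, hmm=(1, span), hmm_len=100, ali=(1, span))
        passing, rejected = filter_hits([hit], FilterThresholds())
        if kept:
            assert passing == [hit] and not rejected
        else:
            assert not passing and rejected[0][1] == reason

    def test_monotonic_in_thresholds(self):
        rng = np.random.default_rng(11)
        hits = []
        for i in range(50):
            ev = 10.0 ** rng.uniform(-30, -5)
            span = int(rng.integers(10, 101))
            hits.append(make_hit(ev=ev, hmm=(1, span), hmm_len=100, ali=(1, span)))
        base, _ = filter_hits(hits, FilterThresholds())
        looser, _ = filter_hits(
            hits, FilterThresholds(evalue_max=1e-10, coverage_min=0.10)
        )
        assert len(looser) >= len(base)
        assert set(h.family_id for h in base) <= set(h.family_id for h in looser)


class TestOverlapResolution:
    def test_worked_three_domain_chain(self):
        # A beats B (overlap 11/50 = 0.22); C survives against A (6/50 = 0.12)
        a = make_hit("GHA", ali=(1, 50), ev=1e-30)
        b = make_hit("GHB", ali=(40, 90), ev=1e-20)
        c = make_hit("GHC", ali=(45, 100), ev=1e-10)
        accepted, dropped = resolve_overlaps([a, b, c])
        assert {h.family_id for h in accepted} == {"GHA", "GHC"}
        assert [h.family_id for h, _ in dropped] == ["GHB"]

    def test_non_overlapping_both_kept(self):
        a, b = make_hit("GHA", ali=(1, 50)), make_hit("GHB", ali=(100, 150))
        accepted, dropped = resolve_overlaps([a, b])
        assert len(accepted) == 2 and not dropped

    def test_identical_spans_best_evalue_wins(self):
        a = make_hit("GHA", ali=(1, 50), ev=1e-40)
        b = make_hit("GHB", ali=(1, 50), ev=1e-16)
        accepted, dropped = resolve_overlaps([a, b])
        assert [h.family_id for h in accepted] == ["GHA"]
        assert dropped[0][0].family_id == "GHB"

    def test_overlap_fraction_uses_shorter_span(self):
        a = make_hit("GHA", ali=(1, 100))
        b = make_hit("GHB", ali=(91, 110))  # shares 10 of b's 20 residues
        assert ali_overlap(a, b) == pytest.approx(0.5)

    def test_mixed_proteins_error(self):
        with pytest.raises(ValueError):
            resolve_overlaps([make_hit(protein="p1"), make_hit(protein="p2")])

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        hits = random_hits(rng, "p1", 8)
        once, _ = resolve_overlaps(hits)
        twice, dropped = resolve_overlaps(once)
        assert twice == once and not dropped

    def test_matches_brute_force_oracle_many_proteins(self):
        """Greedy acceptance equals an independent pairwise-constraint replay."""
        rng = np.random.default_rng(2024)
        for i in range(300):
            hits = random_hits(rng, f"p{i}", int(rng.integers(1, 11)))
            accepted, _ = resolve_overlaps(hits)
            assert accepted == brute_force_resolution(hits)
            # and the accepted set satisfies all pairwise constraints
            for x in accepted:
                for y in accepted:
                    if x is not y:
                        assert ali_overlap(x, y) <= 0.20


class TestAnnotateProteome:
    def test_secretion_join_and_audit(self):
        records = [
            ProteinRecord("p1", "M" * 400, species_id="s1"),
            ProteinRecord("p2", "M" * 400, species_id="s1"),
        ]
        hits = [
            make_hit("GH10", protein="p1", ali=(1, 60), hmm=(1, 60), hmm_len=100),
            make_hit("GH11", protein="p2", ev=1e-5),  # sub-threshold
        ]
        calls = [
            SecretionCall("p1", "SP(Sec/SPI)", 0.97, 0.03, cleavage_site=(18, 19))
        ]
        annotated, audit = annotate_proteome(records, hits, calls)
        assert len(annotated) == 1
        assert annotated[0].protein_id == "p1"
        assert annotated[0].secreted is True
        assert annotated[0].families == {"GH10"}
        # p2 kept in the audit trail with its rejection reason
        p2 = next(a for a in audit if a.protein_id == "p2")
        assert not p2.accepted and p2.rejected[0][1] == "evalue"

    def test_unknown_protein_warns_and_skips(self):
        records = [ProteinRecord("p1", "M" * 100, species_id="s1")]
        hits = [make_hit("GH10", protein="ghost")]
        with pytest.warns(UserWarning, match="ghost"):
            annotated, audit = annotate_proteome(records, hits)
        assert annotated == [] and audit == []

    def test_unknown_protein_error_mode(self):
        records = [ProteinRecord("p1", "M" * 100, species_id="s1")]
        hits = [make_hit("GH10", protein="ghost")]
        with pytest.raises(ValueError, match="ghost"):
            annotate_proteome(records, hits, on_unknown_protein="error")
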