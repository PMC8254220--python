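import hashlib
from pathlib import Path

import numpy as np
import pytest

from cazymine.assay_protein import StandardCurve
from cazymine.cazyme_profile import family_class, rank_species
from cazymine.domain_annotation import resolve_protein
from cazymine.pipeline import profile_dataset
from cazymine.synthetic_data import (
    SyntheticConfig,
    generate_assay_plate,
    generate_dataset,
    plant_filter_edge_cases,
    recover_activities,
)


def tree_digest(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(Path(root).iterdir()):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            (dict(n_species=2, n_clades=3), "n_clades"),
            (dict(noise_fraction=1.5), "noise_fraction"),
            (dict(secreted_fraction=-0.1), "secreted_fraction"),
            (dict(rich_boost=0.5), "rich_boost"),
            (dict(rich_clade_index=9), "rich_clade_index"),
            (dict(family_pool=()), "family_pool"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            SyntheticConfig(**kwargs)


class TestGenerateDataset:
    def test_same_seed_byte_identical(self, tmp_path):
        config = SyntheticConfig(n_species=4, n_clades=2, proteins_per_species=25, seed=1)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_dataset(config, d1)
        generate_dataset(config, d2)
        assert tree_digest(d1) == tree_digest(d2)

    def test_different_seed_differs(self, tmp_path):
        base = dict(n_species=4, n_clades=2, proteins_per_species=25)
        generate_dataset(SyntheticConfig(seed=1, **base), tmp_path / "a")
        generate_dataset(SyntheticConfig(seed=2, **base), tmp_path / "b")
        assert tree_digest(tmp_path / "a") != tree_digest(tmp_path / "b")

    def test_record_conservation(self, small_dataset):
        config, manifest = small_dataset
        from cazymine.proteome_io import read_fasta

        total = sum(
            len(read_fasta(p, species_id=s))
            for s, p in manifest.fasta_paths.items()
        )
        assert total == config.n_species * config.proteins_per_species

    def test_noise_free_counts_equal_ground_truth(self, tmp_path):
        config = SyntheticConfig(
            n_species=5, n_clades=2, proteins_per_species=40,
            noise_fraction=0.0, seed=3,
        )
        manifest = generate_dataset(config, tmp_path / "nf")
        profiles, _ = profile_dataset(
            manifest.fasta_paths,
            manifest.domtblout_path,
            manifest.signalp_path,
            manifest.metadata_path,
        )
        gt = manifest.ground_truth.pivot(
            index="species_id", columns="family", values="count"
        )
        for p in profiles:
            for fam in config.family_pool:
                assert p.family_counts.get(fam, 0) == int(gt.loc[p.species_id, fam])

    def test_noisy_counts_equal_ground_truth(self, small_dataset):
        """Planted failing hits are exactly removed by the filter chain."""
        config, manifest = small_dataset
        profiles, _ = profile_dataset(
            manifest.fasta_paths,
            manifest.domtblout_path,
            manifest.signalp_path,
            manifest.metadata_path,
        )
        gt = manifest.ground_truth.pivot(
            index="species_id", columns="family", values="count"
        )
        for p in profiles:
            for fam in config.family_pool:
                assert p.family_counts.get(fam, 0) == int(gt.loc[p.species_id, fam])

    def test_rich_clade_ground_truth_means(self, tmp_path):
        config = SyntheticConfig(
            n_species=12, n_clades=4, rich_clade_index=0, rich_boost=3.0, seed=5
        )
        manifest = generate_dataset(config, tmp_path / "rich")
        gt = manifest.ground_truth
        degradative = [
            f for f in config.family_pool if family_class(f) != "GT"
        ]
        deg = gt[gt.family.isin(degradative)].groupby("species_id")["count"].sum()
        means = deg.groupby(
            deg.index.map(manifest.species_clades)
        ).mean()
        assert means.idxmax() == "clade_0"
        assert means["clade_0"] > means.drop("clade_0").max()

    def test_tree_leaves_match_species(self, small_dataset):
        from cazymine.phylo_assoc import read_newick

        _, manifest = small_dataset
        tree = read_newick(manifest.tree_path)
        assert sorted(tree.leaf_labels) == sorted(manifest.fasta_paths)

    def test_secreted_fraction_reflected_in_signalp(self, small_dataset):
        from cazymine.secretion import is_secreted, parse_signalp_short

        _, manifest = small_dataset
        calls = parse_signalp_short(manifest.signalp_path)
        secreted = {c.protein_id for c in calls if is_secreted(c)}
        assert secreted == manifest.secreted_proteins

    def test_unwritable_path_errors(self, tmp_path):
        blocker = tmp_path / "blocker"
        blocker.write_text("")  # a file where a directory is needed
        with pytest.raises(OSError):
            generate_dataset(
                SyntheticConfig(n_species=2, n_clades=1), blocker / "out"
            )


class TestFilterEdgeCases:
    def test_boundary_hits_behave_as_labeled(self):
        cases = plant_filter_edge_cases()
        resolution = resolve_protein(
            cases[0][0].protein_id, [h for h, _ in cases]
        )
        outcomes = {h.family_id: "keep" for h in resolution.accepted}
        outcomes.update(
            {h.family_id: f"reject {r}" for h, r in resolution.rejected}
        )
        for hit, label in cases:
            expected = "keep" if label.startswith("keep") else label.split(" (")[0]
            assert outcomes[hit.family_id].startswith(expected.split()[0]), (
                hit.family_id, label, outcomes[hit.family_id]
            )

    def test_coverage_boundary_sides(self):
        cases = dict((label, hit) for hit, label in plant_filter_edge_cases())
        from cazymine.domain_annotation import hmm_coverage

        assert hmm_coverage(cases["keep (coverage boundary 0.35)"]) == 0.35
        assert hmm_coverage(cases["reject coverage (0.34)"]) == 0.34

    def test_overlap_boundary_arithmetic(self):
        from cazymine.domain_annotation import ali_overlap

        cases = dict((label, hit) for hit, label in plant_filter_edge_cases())
        at_20 = ali_overlap(
            cases["keep (overlap 0.20 partner)"], cases["keep (overlap exactly 0.20)"]
        )
        assert at_20 == pytest.approx(0.20)
        at_21 = ali_overlap(
            cases["keep (overlap 0.21 partner)"],
            cases["reject overlap (0.21, worse e-value)"],
        )
        assert at_21 == pytest.approx(0.21)


class TestAssayPlate:
    CURVE = StandardCurve(slope=0.5, intercept=0.08)

    def test_zero_activity_gives_intercept(self):
        plate = generate_assay_plate([0.0, 0.0], self.CURVE)
        assert (plate["absorbance"] == self.CURVE.intercept).all()

    def test_zero_noise_exact_round_trip(self):
        acts = [0.0, 0.1, 0.5, 1.0, 2.5, 4.0]
        plate = generate_assay_plate(acts, self.CURVE)
        rec = recover_activities(plate, self.CURVE)
        err = np.abs(rec["recovered_activity"] - rec["true_activity"])
        rel = err / np.where(rec["true_activity"] > 0, rec["true_activity"], 1.0)
        assert rel.max() <= 1e-9

    def test_noisy_mean_within_three_se(self):
        truth = 1.5
        plate = generate_assay_plate([truth] * 100, self.CURVE, seed=11, noise_sd=0.01)
        rec = recover_activities(plate, self.CURVE)["recovered_activity"]
        se = rec.std(ddof=1) / np.sqrt(len(rec))
        assert abs(rec.mean() - truth) <= 3 * se

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError):
            generate_assay_plate([-1.0], self.CURVE)


class TestPlantedCladeRecovery:
    def test_rich_clade_species_rank_top(self, tmp_path):
        """Planted rich-clade species dominate the GT-excluded ranking."""
        config = SyntheticConfig(
            n_species=12, n_clades=4, rich_clade_index=1, rich_boost=3.0, seed=29
        )
        manifest = generate_dataset(config, tmp_path / "rc")
        profiles, _ = profile_dataset(
            manifest.fasta_paths,
            manifest.domtblout_path,
            manifest.signalp_path,
            manifest.metadata_path,
        )
        clade_size = sum(
            1 for c in manifest.species_clades.values() if c == "clade_1"
        )
        top = rank_species(profiles)[:clade_size]
        assert all(p.clade == "clade_1" for p in top)
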