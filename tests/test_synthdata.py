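"""Synthetic-data generator: determinism, planted truth, generative moments."""

import numpy as np
import pandas as pd
import pytest

from surfsig import (
    SimConfig,
    simulate_annotations,
    simulate_counts,
    simulate_itraq,
    verify_bundle,
    write_fixture_bundle,
)
from surfsig.errors import ConfigError
from surfsig.synthdata import PLASMA_MEMBRANE
from tests.conftest import SUITE_SEED


class TestConfig:
    def test_fraction_out_of_range_names_field(self):
        with pytest.raises(ConfigError, match="frac_deg"):
            SimConfig(frac_deg=1.5)

    def test_negative_sigma_names_field(self):
        with pytest.raises(ConfigError, match="sigma_peptide"):
            SimConfig(sigma_peptide=-0.1)

    def test_category_size_exceeding_proteins(self):
        with pytest.raises(ConfigError, match="category_size_range"):
            SimConfig(n_proteins=20, category_size_range=(5, 50))

    def test_roundtrip_dict(self):
        cfg = SimConfig(seed=3)
        assert SimConfig.from_dict(cfg.to_dict()) == cfg


class TestCounts:
    def test_no_planted_effects_when_frac_deg_zero(self):
        cfg = SimConfig(n_genes=200, n_proteins=100, frac_deg=0.0, n_planted_surface=0, seed=1)
        _, truth = simulate_counts(cfg)
        assert not truth.entities["is_differential"].any()

    def test_determinism(self):
        cfg = SimConfig(n_genes=200, n_proteins=100, n_planted_surface=10, seed=5)
        cm1, t1 = simulate_counts(cfg)
        cm2, t2 = simulate_counts(cfg)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
        pd.testing.assert_frame_equal(t1.entities, t2.entities)

    def test_negative_binomial_moments(self):
        """10,000 replicate draws of one null gene match the NB moments."""
        cfg = SimConfig(
            n_genes=1,
            n_proteins=4,
            n_planted_surface=0,
            n_categories=0,
            n_shifted_categories=0,
            category_size_range=(1, 2),
            frac_deg=0.0,
            groups=(("A", 5000), ("B", 5000)),
            dispersion=0.1,
            seed=SUITE_SEED,
        )
        cm, truth = simulate_counts(cfg)
        draws = cm.counts.iloc[0].to_numpy()
        mu = truth.entities["base_mean"].dropna().iloc[0]
        assert draws.mean() == pytest.approx(mu, rel=0.02)
        assert draws.var() == pytest.approx(mu + 0.1 * mu**2, rel=0.10)

    def test_planted_lfc_recorded_per_comparison(self):
        cfg = SimConfig(n_genes=300, n_proteins=200, n_planted_surface=15, seed=2)
        _, truth = simulate_counts(cfg)
        planted = truth.entities[truth.entities["is_planted_surface"]]
        assert len(planted) == 15
        assert (planted["lfc_CPC_vs_MSC"] == cfg.lfc_scale).all()
        assert (planted["lfc_CPC_vs_HDF"] == cfg.lfc_scale).all()


class TestItraq:
    def test_noise_free_null_ratios_are_zero(self):
        cfg = SimConfig(
            n_genes=100,
            n_proteins=50,
            n_planted_surface=0,
            frac_shifted_proteins=0.0,
            n_shifted_categories=0,
            category_size_range=(5, 10),
            sigma_spectrum=0.0,
            sigma_peptide=0.0,
            sigma_protein=0.0,
            seed=3,
        )
        sq, _ = simulate_itraq(cfg)
        np.testing.assert_allclose(sq["log2_ratio"], 0.0)

    def test_row_count_with_degenerate_ranges(self):
        cfg = SimConfig(
            n_genes=100,
            n_proteins=40,
            n_planted_surface=0,
            n_shifted_categories=0,
            category_size_range=(5, 10),
            peptides_per_protein=(1, 1),
            spectra_per_peptide=(1, 1),
            seed=4,
        )
        sq, _ = simulate_itraq(cfg)
        per_cmp = sq.groupby("comparison").size()
        assert (per_cmp == 40).all()

    def test_shifted_subset_mean_near_truth(self):
        cfg = SimConfig(
            n_genes=600,
            n_proteins=500,
            n_planted_surface=0,
            frac_shifted_proteins=0.1,
            shift_scale=1.0,
            n_shifted_categories=0,
            seed=6,
        )
        sq, truth = simulate_itraq(cfg)
        sub = sq[sq["comparison"] == "CPC_vs_MSC"].copy()
        shift = truth.entities["shift_CPC_vs_MSC"]
        up = set(shift.index[shift == 1.0])
        obs = sub[sub["protein_id"].isin(up)]["log2_ratio"]
        sd = np.sqrt(
            cfg.sigma_protein**2 + cfg.sigma_peptide**2 + cfg.sigma_spectrum**2
        ) / np.sqrt(len(obs))
        # protein/peptide deviations are shared within proteins, so allow
        # the conservative 3-sd band on the naive standard error times ~5
        assert abs(obs.mean() - 1.0) < max(3 * sd * 5, 0.1)

    def test_determinism(self):
        cfg = SimConfig(n_genes=150, n_proteins=120, n_planted_surface=10, seed=8)
        sq1, _ = simulate_itraq(cfg)
        sq2, _ = simulate_itraq(cfg)
        pd.testing.assert_frame_equal(sq1, sq2)


class TestAnnotations:
    def test_all_membrane_boundary(self):
        cfg = SimConfig(n_genes=100, n_proteins=60, n_planted_surface=5, frac_membrane=1.0, seed=9)
        ann, _ = simulate_annotations(cfg)
        assert (ann.compartments == PLASMA_MEMBRANE).all()

    def test_planted_surface_construction_contract(self):
        cfg = SimConfig(n_genes=400, n_proteins=300, n_planted_surface=50, seed=10)
        ann, truth = simulate_annotations(cfg)
        planted = truth.planted_surface
        assert len(planted) == 50
        assert (truth.entities.loc[sorted(planted), "compartment"] == PLASMA_MEMBRANE).all()
        target, *others = [g for g, _ in cfg.groups]
        in_target = planted & (set(ann.whole_extract[target]) | set(ann.membrane_fraction[target]))
        assert in_target == planted
        for o in others:
            assert not planted & set(ann.whole_extract[o])
            assert not planted & set(ann.membrane_fraction[o])

    def test_category_sizes_within_range(self):
        cfg = SimConfig(
            n_genes=300,
            n_proteins=200,
            n_planted_surface=0,
            n_categories=100,
            n_shifted_categories=0,
            category_size_range=(5, 10),
            seed=11,
        )
        ann, _ = simulate_annotations(cfg)
        sizes = [len(m) for m in ann.categories.sets.values()]
        assert len(sizes) == 100
        assert min(sizes) >= 5 and max(sizes) <= 10


class TestBundle:
    def test_manifest_lists_files_with_checksums(self, small_bundle_dir):
        assert not verify_bundle(small_bundle_dir)
        import json

        manifest = json.loads((small_bundle_dir / "manifest.json").read_text())
        assert len(manifest["files"]) >= 5
        assert all(len(c) == 64 for c in manifest["files"].values())

    def test_rewrite_reproduces_checksums(self, tmp_path, small_cfg):
        m1 = write_fixture_bundle(small_cfg, tmp_path / "a")
        m2 = write_fixture_bundle(small_cfg, tmp_path / "b")
        assert m1["files"] == m2["files"]

    def test_corruption_detected(self, tmp_path, small_cfg):
        write_fixture_bundle(small_cfg, tmp_path / "c")
        path = tmp_path / "c" / "compartments.tsv"
        path.write_text(path.read_text() + "EXTRA\tnucleus\n")
        assert verify_bundle(tmp_path / "c") == ["compartments.tsv"]
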