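"""Weighted spectrum -> peptide -> protein -> category integration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from surfsig import (
    CategoryDB,
    category_report,
    category_stats,
    compute_spectrum_ratios,
    integrate_level,
    protein_pipeline,
)
from tests.conftest import SUITE_SEED, make_spectra


class TestIntegrateLevel:
    def test_two_equal_weight_children(self):
        """x=(0,1), w=(1,1): X=0.5, W=2, Z = -+0.5/sqrt(0.5)."""
        res = integrate_level([0.0, 1.0], [1.0, 1.0], ["g", "g"])
        assert res.parents.loc["g", "x"] == pytest.approx(0.5)
        assert res.parents.loc["g", "w"] == pytest.approx(2.0)
        np.testing.assert_allclose(res.child_z, [-0.70710678, 0.70710678], rtol=1e-8)
        assert res.sigma2 == 0.0  # too few residuals for dispersion estimation

    def test_singleton_propagates_value_and_weight(self):
        res = integrate_level([0.7], [3.0], ["p"])
        assert res.parents.loc["p", "x"] == pytest.approx(0.7)
        assert res.parents.loc["p", "w"] == pytest.approx(3.0)
        assert np.isnan(res.child_z[0])

    def test_weight_conservation(self, rng):
        """Parent weights equal the (dispersion-adjusted) child weight sum."""
        x = rng.normal(size=200)
        w = rng.uniform(0.5, 3.0, size=200)
        groups = rng.integers(0, 40, size=200)
        res = integrate_level(x, w, groups)
        expected = (1.0 / (1.0 / w + res.sigma2)).sum()
        assert res.parents["w"].sum() == pytest.approx(expected, rel=1e-12)
        if res.sigma2 == 0.0:
            assert res.parents["w"].sum() == pytest.approx(w.sum(), rel=1e-12)

    def test_null_calibration_of_z(self, rng):
        """x ~ N(0, 1/w): standardized residuals are standard normal."""
        n_groups, per = 2000, 5
        w = rng.uniform(0.5, 2.0, size=n_groups * per)
        x = rng.normal(0.0, 1.0 / np.sqrt(w))
        groups = np.repeat(np.arange(n_groups), per)
        res = integrate_level(x, w, groups)
        z = res.child_z[~np.isnan(res.child_z)]
        assert stats.kstest(z, "norm").pvalue > 0.01
        assert abs(np.median(z)) < 0.05

    def test_empty_input(self):
        res = integrate_level([], [], [])
        assert res.parents.empty and len(res.child_z) == 0

    def test_non_positive_weight_rejected(self):
        with pytest.raises(ValueError, match="non-positive weight"):
            integrate_level([0.0, 1.0], [1.0, 0.0], ["g", "g"])


class TestSpectrumRatios:
    def test_exact_values_and_antisymmetry(self):
        df = pd.DataFrame(
            {
                "spectrum_id": ["s1", "s2", "s3"],
                "peptide_id": ["p1", "p1", "p2"],
                "protein_id": ["P", "P", "P"],
                "intensity_num": [200.0, 150.0, 100.0],
                "intensity_den": [100.0, 150.0, 200.0],
            }
        )
        out, rejected = compute_spectrum_ratios(df)
        assert rejected.empty
        np.testing.assert_allclose(out["log2_ratio"], [1.0, 0.0, -1.0])
        swapped, _ = compute_spectrum_ratios(
            df, numerator="intensity_den", denominator="intensity_num"
        )
        np.testing.assert_allclose(swapped["log2_ratio"], -out["log2_ratio"])

    def test_non_positive_intensity_rejected(self):
        df = pd.DataFrame(
            {
                "spectrum_id": ["s1", "s2"],
                "peptide_id": ["p1", "p2"],
                "protein_id": ["P", "P"],
                "intensity_num": [100.0, 0.0],
                "intensity_den": [100.0, 50.0],
            }
        )
        out, rejected = compute_spectrum_ratios(df)
        assert list(out["spectrum_id"]) == ["s1"]
        assert list(rejected["spectrum_id"]) == ["s2"]


class TestProteinPipeline:
    def test_all_zero_ratios_give_zero_xq_zq(self):
        sq = make_spectra([f"P{i}" for i in range(10)], 4, 2, np.zeros(10))
        pq = protein_pipeline(sq)
        np.testing.assert_allclose(pq.table["Xq"], 0.0)
        np.testing.assert_allclose(pq.table["Zq"], 0.0)

    def test_flat_hierarchy_equals_arithmetic_mean(self, rng):
        """One spectrum per peptide, equal weights: Xq is the plain mean."""
        ratios = rng.normal(size=30)
        rows = []
        for i in range(6):
            for j in range(5):
                rows.append(
                    {
                        "spectrum_id": f"P{i}.p{j}.s0",
                        "peptide_id": f"P{i}.p{j}",
                        "protein_id": f"P{i}",
                        "log2_ratio": ratios[i * 5 + j],
                        "weight": 1.0,
                        "comparison": "A_vs_B",
                    }
                )
        pq = protein_pipeline(pd.DataFrame(rows))
        expected = {f"P{i}": ratios[i * 5 : (i + 1) * 5].mean() for i in range(6)}
        for _, row in pq.table.iterrows():
            assert row["Xq"] == pytest.approx(expected[row["protein"]], rel=1e-10)

    def test_shifted_protein_ranks_first(self, rng):
        ratios = rng.normal(0.0, 0.05, size=200)
        ratios[17] += 1.0
        sq = make_spectra([f"P{i:03d}" for i in range(200)], 4, 2, ratios, weight=400.0)
        pq = protein_pipeline(sq)
        top = pq.table.iloc[0]
        assert top["protein"] == "P017"
        assert top["Zq"] > 0
        assert top["Zq"] == pq.table["Zq"].max()

    def test_min_peptides_exclusion_boundary(self):
        """Three peptides or fewer excluded from category analysis; four kept."""
        rows = make_spectra(["P3"], 3, 1, [0.1]).to_dict("records")
        rows += make_spectra(["P4"], 4, 1, [0.2]).to_dict("records")
        pq = protein_pipeline(pd.DataFrame(rows), min_peptides=4)
        flags = pq.table.set_index("protein")["excluded"]
        assert bool(flags["P3"]) is True
        assert bool(flags["P4"]) is False

    def test_peptide_with_two_proteins_rejected(self):
        sq = make_spectra(["A", "B"], 1, 1, [0.0, 0.0])
        sq.loc[1, "peptide_id"] = sq.loc[0, "peptide_id"]
        with pytest.raises(ValueError, match="multiple proteins"):
            protein_pipeline(sq)

    def test_grand_mean_removed(self, rng):
        """Weighted mean of Xq about the grand mean is zero."""
        ratios = rng.normal(0.3, 0.2, size=50)
        sq = make_spectra([f"P{i}" for i in range(50)], 4, 2, ratios)
        pq = protein_pipeline(sq)
        grand = pq.grand["A_vs_B"]
        resid = (pq.table["Xq"] - grand["X"]) * pq.table["w_grand"]
        assert abs(resid.sum()) < 1e-9 * max(1.0, abs(grand["X"]))


class TestCategoryStats:
    def test_null_category_is_zero(self):
        sq = make_spectra([f"P{i}" for i in range(8)], 4, 1, np.zeros(8))
        pq = protein_pipeline(sq)
        db = CategoryDB({"cat": frozenset({"P0", "P1", "P2", "P3", "P4"})})
        cs = category_stats(pq.table, db)
        assert len(cs) == 1
        assert cs.loc[0, "nc"] == 5
        assert cs.loc[0, "Xc"] == pytest.approx(0.0)
        assert cs.loc[0, "Zc"] == pytest.approx(0.0)

    def test_small_category_omitted(self):
        """A category with four quantified members is below the threshold."""
        sq = make_spectra([f"P{i}" for i in range(8)], 4, 1, np.zeros(8))
        pq = protein_pipeline(sq)
        db = CategoryDB({"small": frozenset({"P0", "P1", "P2", "P3"})})
        assert category_stats(pq.table, db).empty

    def test_excluded_proteins_do_not_count(self):
        """Members below the peptide filter drop a category below min size."""
        rows = make_spectra([f"P{i}" for i in range(4)], 4, 1, np.zeros(4)).to_dict("records")
        rows += make_spectra(["P4"], 2, 1, [0.0]).to_dict("records")  # excluded
        pq = protein_pipeline(pd.DataFrame(rows))
        db = CategoryDB({"cat": frozenset({"P0", "P1", "P2", "P3", "P4"})})
        assert category_stats(pq.table, db).empty

    def test_zc_monotone_in_member_shift(self, rng):
        """Raising every member Zq by delta raises Zc by delta*sqrt(nc)."""
        ratios = rng.normal(size=20)
        sq = make_spectra([f"P{i:02d}" for i in range(20)], 4, 2, ratios)
        pq = protein_pipeline(sq)
        members = frozenset(f"P{i:02d}" for i in range(9))
        db = CategoryDB({"cat": members})
        base = category_stats(pq.table, db)
        delta = 0.8
        shifted = pq.table.copy()
        shifted.loc[shifted["protein"].isin(members), "Zq"] += delta
        after = category_stats(shifted, db)
        nc = base.loc[0, "nc"]
        assert after.loc[0, "Zc"] - base.loc[0, "Zc"] == pytest.approx(delta * np.sqrt(nc))

    def test_null_zc_tail_calibration(self):
        """Random categories over standard-normal Zq reject at ~5%."""
        rng = np.random.default_rng(SUITE_SEED)
        tails = []
        for _ in range(20):
            table = pd.DataFrame(
                {
                    "protein": [f"P{i:04d}" for i in range(2000)],
                    "comparison": "A_vs_B",
                    "Xq": 0.0,
                    "Zq": rng.normal(size=2000),
                    "excluded": False,
                }
            )
            sets = {
                f"C{j}": frozenset(
                    f"P{i:04d}" for i in rng.choice(2000, rng.integers(5, 51), replace=False)
                )
                for j in range(200)
            }
            cs = category_stats(table, CategoryDB(sets))
            tails.append((cs["Zc"].abs() > 1.96).mean())
        assert 0.035 <= np.mean(tails) <= 0.065


class TestCategoryReport:
    def test_heads_and_antisymmetry(self):
        stats_df = pd.DataFrame(
            {
                "category": ["up1", "down1", "mid"],
                "comparison": "A_vs_B",
                "nc": [6, 6, 6],
                "Xc": [0.5, -0.5, 0.0],
                "Zc": [3.0, -3.0, 0.1],
            }
        )
        rep = category_report(stats_df)
        assert rep["up"].iloc[0]["category"] == "up1"
        assert rep["down"].iloc[0]["category"] == "down1"
        flipped = stats_df.assign(Zc=-stats_df["Zc"], Xc=-stats_df["Xc"])
        rep2 = category_report(flipped)
        assert list(rep2["up"]["category"]) == list(rep["down"]["category"])
        assert list(rep2["down"]["category"]) == list(rep["up"]["category"])

    def test_theoretical_quantiles_monotone(self):
        stats_df = pd.DataFrame(
            {
                "category": [f"c{i}" for i in range(30)],
                "comparison": "A_vs_B",
                "nc": 6,
                "Xc": 0.0,
                "Zc": np.linspace(-2, 2, 30),
            }
        )
        rep = category_report(stats_df)
        assert (np.diff(rep["up"]["theoretical_quantile"]) < 0).all()
        assert (np.diff(rep["down"]["theoretical_quantile"]) > 0).all()
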