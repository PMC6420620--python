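"""Weighted hierarchical integration of isobaric-label quantifications.

Reporter-ion ratios are observed per spectrum and integrated upward
through the natural hierarchy spectrum -> peptide -> protein -> category.
At each level the parent value is the inverse-variance weighted mean of
its children and every child receives a standardized residual ``Z``.
Under the model a child value ``x_i`` with declared weight ``w_i``
(variance ``1/w_i``) deviates from its parent by an additional,
level-specific random effect with variance ``sigma2_L``; the effective
weight is therefore ``w*_i = 1/(1/w_i + sigma2_L)`` and

    X_g = sum(w*_i x_i) / sum(w*_i)         (parent value)
    W_g = sum(w*_i)                          (parent weight)
    Z_i = (x_i - X_g) / sqrt(1/w*_i - 1/W_g)

is standard normal under the null.  ``sigma2_L`` is estimated robustly
per level by matching the median of ``Z^2`` to the median of a
chi-square with one degree of freedom (0.4549...), so outlying children
do not inflate the dispersion estimate.  When fewer than
``min_residuals`` informative residuals exist the level variance is
fixed at zero.  A simpler multiplicative variant ("scale"), which keeps
the declared weights and rescales ``Z`` by a single robust factor, is
available for comparison.

Protein-level statistics: the grand standardization of the protein
values against the experiment-wide mean yields ``Zq``, the standardized
log2-ratio reported per protein.  Category statistics: ``Xc`` is the
plain mean of member ``Xq`` and ``Zc = sum(member Zq)/sqrt(nc)``, which
is standard normal under the null by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

log = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 degree of freedom
CHI2_MEDIAN = 0.45493642311957283

SPECTRUM_COLUMNS = ("spectrum_id", "peptide_id", "protein_id", "log2_ratio", "weight", "comparison")


@dataclass
class CategoryDB:
    """Named protein sets (functional categories), GMT-compatible."""

    sets: dict[str, frozenset]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"category {name!r} is empty")
            self.sets[name] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


@dataclass
class LevelResult:
    """Outcome of one integration step.

    ``parents`` is indexed by group id with columns ``x`` (weighted
    mean), ``w`` (accumulated weight) and ``n_children``.  ``child_z``
    aligns with the input children; singleton groups carry ``NaN``.
    """

    parents: pd.DataFrame
    child_z: np.ndarray
    child_group_codes: np.ndarray
    sigma2: float
    scale: float


@dataclass
class ProteinQuantResult:
    """Protein-level table plus the per-level variance estimates."""

    table: pd.DataFrame
    dispersions: dict[str, dict[str, float]]
    grand: dict[str, dict[str, float]]


def integrate_level(
    x: Iterable[float],
    w: Iterable[float],
    groups: Iterable,
    *,
    min_residuals: int = 30,
    variance_model: str = "additive",
) -> LevelResult:
    """Integrate child values into parent groups with standardized residuals.

    Parameters
    ----------
    x, w, groups
        Child log2 values, positive weights (inverse variances) and the
        parent group id of each child.
    min_residuals
        Minimum number of residuals (children in groups of size >= 2)
        required to estimate the level dispersion; below it the level
        variance is zero (``scale`` variant: factor 1).
    variance_model
        ``"additive"`` (default): estimate an additive level variance
        and fold it into the weights.  ``"scale"``: keep declared
        weights, divide the raw residuals by a single robust factor.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    groups = np.asarray(groups)
    if variance_model not in ("additive", "scale"):
        raise ValueError(f"unknown variance_model {variance_model!r}")
    if x.size == 0:
        empty = pd.DataFrame(columns=["x", "w", "n_children"])
        return LevelResult(empty, np.empty(0), np.empty(0, dtype=int), 0.0, 1.0)
    if x.shape != w.shape or x.shape != groups.shape:
        raise ValueError("x, w and groups must have equal length")
    bad = ~(w > 0) | ~np.isfinite(w)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-positive weight for child {i} (group {groups[i]!r})")

    codes, uniq = pd.factorize(groups, sort=True)
    n_groups = len(uniq)
    size = np.bincount(codes, minlength=n_groups)
    multi = size[codes] >= 2
    inv_w = 1.0 / w

    def _moments(s2: float):
        ws = 1.0 / (inv_w + s2)
        W = np.bincount(codes, weights=ws, minlength=n_groups)
        X = np.bincount(codes, weights=ws * x, minlength=n_groups) / W
        v = np.maximum(1.0 / ws - 1.0 / W[codes], 1e-300)
        return ws, W, X, v

    def _median_z2(s2: float) -> float:
        _, _, X, v = _moments(s2)
        z2 = (x - X[codes]) ** 2 / v
        return float(np.median(z2[multi]))

    sigma2 = 0.0
    scale = 1.0
    n_resid = int(multi.sum())
    if variance_model == "additive":
        if n_resid >= min_residuals and _median_z2(0.0) > CHI2_MEDIAN:
            hi = 1.0
            while _median_z2(hi) > CHI2_MEDIAN and hi < 1e6:
                hi *= 2.0
            if _median_z2(hi) > CHI2_MEDIAN:
                sigma2 = hi
            else:
                sigma2 = float(
                    brentq(lambda s: _median_z2(s) - CHI2_MEDIAN, 0.0, hi, xtol=1e-12, rtol=1e-12)
                )
        ws, W, X, v = _moments(sigma2)
        z = np.where(multi, (x - X[codes]) / np.sqrt(v), np.nan)
    else:
        ws, W, X, v = _moments(0.0)
        z_raw = np.where(multi, (x - X[codes]) / np.sqrt(v), np.nan)
        if n_resid >= min_residuals:
            med = float(np.median(z_raw[multi] ** 2))
            if med > 0:
                scale = math.sqrt(med / CHI2_MEDIAN)
        z = z_raw / scale

    parents = pd.DataFrame(
        {"x": X, "w": W, "n_children": size},
        index=pd.Index(uniq, name="group"),
    )
    return LevelResult(parents, z, codes, sigma2, scale)


def compute_spectrum_ratios(
    intensities: pd.DataFrame,
    *,
    numerator: str = "intensity_num",
    denominator: str = "intensity_den",
    sigma: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn two-channel reporter intensities into spectrum log2 ratios.

    Rows with a non-positive intensity in either channel are rejected and
    returned separately (and logged with their spectrum ids).  ``sigma``
    sets the declared per-spectrum standard deviation; when omitted the
    weight column is left ``NaN`` and is estimated downstream from the
    global residual spread.
    """
    required = {"spectrum_id", "peptide_id", "protein_id", numerator, denominator}
    missing = required - set(intensities.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    num = intensities[numerator].to_numpy(dtype=float)
    den = intensities[denominator].to_numpy(dtype=float)
    ok = (num > 0) & (den > 0)
    rejected = intensities.loc[~ok]
    if len(rejected):
        log.warning(
            "rejected %d spectra with non-positive intensities: %s",
            len(rejected),
            ", ".join(map(str, rejected["spectrum_id"].head(10))),
        )
    out = intensities.loc[ok, ["spectrum_id", "peptide_id", "protein_id"]].copy()
    out["log2_ratio"] = np.log2(num[ok] / den[ok])
    out["weight"] = 1.0 / sigma**2 if sigma else np.nan
    if "comparison" in intensities.columns:
        out["comparison"] = intensities.loc[ok, "comparison"]
    else:
        out["comparison"] = "ratio"
    return out.reset_index(drop=True), rejected.reset_index(drop=True)


def estimate_spectrum_sigma2(x: np.ndarray, peptide_codes: np.ndarray) -> float:
    """Robust global spectrum-level variance from within-peptide residuals.

    Uses the bias-corrected squared residual ``r^2/(1 - 1/n)`` of each
    spectrum around its peptide mean, for peptides with >= 2 spectra, and
    matches the median to the chi-square(1) median.
    """
    n_pep = int(peptide_codes.max()) + 1 if len(peptide_codes) else 0
    size = np.bincount(peptide_codes, minlength=n_pep)
    mean = np.bincount(peptide_codes, weights=x, minlength=n_pep) / np.maximum(size, 1)
    m = size[peptide_codes] >= 2
    if m.sum() < 3:
        return max(float(np.var(x)), 1e-12)
    r2 = (x - mean[peptide_codes]) ** 2 / (1.0 - 1.0 / size[peptide_codes])
    return max(float(np.median(r2[m])) / CHI2_MEDIAN, 1e-12)


def protein_pipeline(
    spectra: pd.DataFrame,
    min_peptides: int = 4,
    *,
    variance_model: str = "additive",
    use_weights: bool = True,
) -> ProteinQuantResult:
    """Chain the two integrations and the grand standardization.

    Spectra are integrated to peptides, peptides to proteins, and the
    protein values are standardized against the experiment-wide weighted
    mean to give ``Zq``.  Each comparison label is processed
    independently.  Proteins represented by fewer than ``min_peptides``
    peptides (default: three peptides or less) are flagged
    ``excluded`` — retained in the table but left out of category-level
    analysis downstream.
    """
    if spectra.empty:
        raise ValueError("spectrum table is empty")
    required = {"spectrum_id", "peptide_id", "protein_id", "log2_ratio"}
    missing = required - set(spectra.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = spectra.copy()
    if "comparison" not in df.columns:
        df["comparison"] = "ratio"
    # a peptide must map to exactly one protein
    pep_nprot = df.groupby("peptide_id")["protein_id"].nunique()
    shared = pep_nprot[pep_nprot > 1]
    if len(shared):
        raise ValueError(f"peptides mapped to multiple proteins: {list(shared.index[:5])}")

    tables = []
    dispersions: dict[str, dict[str, float]] = {}
    grand: dict[str, dict[str, float]] = {}
    for cmp_label, sub in df.groupby("comparison", sort=True):
        x = sub["log2_ratio"].to_numpy(dtype=float)
        pep_codes, pep_ids = pd.factorize(sub["peptide_id"].to_numpy(), sort=True)
        if use_weights and "weight" in sub.columns and sub["weight"].notna().all():
            w = sub["weight"].to_numpy(dtype=float)
            sigma2_w = np.nan
        else:
            sigma2_w = estimate_spectrum_sigma2(x, pep_codes)
            w = np.full(len(x), 1.0 / sigma2_w)

        lvl1 = integrate_level(x, w, sub["peptide_id"].to_numpy(), variance_model=variance_model)
        pep = lvl1.parents
        prot_of_pep = (
            sub.drop_duplicates("peptide_id").set_index("peptide_id")["protein_id"].reindex(pep.index)
        )
        lvl2 = integrate_level(
            pep["x"].to_numpy(), pep["w"].to_numpy(), prot_of_pep.to_numpy(), variance_model=variance_model
        )
        prot = lvl2.parents
        n_spectra = (
            pep["n_children"].groupby(prot_of_pep.to_numpy()).sum().reindex(prot.index).astype(int)
        )
        lvl3 = integrate_level(
            prot["x"].to_numpy(),
            prot["w"].to_numpy(),
            np.zeros(len(prot), dtype=int),
            variance_model=variance_model,
        )
        x_grand = float(lvl3.parents["x"].iloc[0])
        w_grand_total = float(lvl3.parents["w"].iloc[0])
        w_grand_child = 1.0 / (1.0 / prot["w"].to_numpy() + lvl3.sigma2)

        out = pd.DataFrame(
            {
                "protein": prot.index,
                "comparison": cmp_label,
                "Xq": prot["x"].to_numpy(),
                "Zq": lvl3.child_z,
                "Wq": prot["w"].to_numpy(),
                "n_peptides": prot["n_children"].to_numpy(),
                "n_spectra": n_spectra.to_numpy(),
                "w_grand": w_grand_child,
            }
        )
        out["excluded"] = out["n_peptides"] <= min_peptides - 1
        tables.append(out)
        dispersions[cmp_label] = {
            "spectrum_weight_sigma2": float(sigma2_w),
            "spectrum": float(lvl1.sigma2),
            "peptide": float(lvl2.sigma2),
            "protein": float(lvl3.sigma2),
        }
        grand[cmp_label] = {"X": x_grand, "W": w_grand_total, "sigma2": float(lvl3.sigma2)}

    table = pd.concat(tables, ignore_index=True)
    table = table.sort_values(
        ["comparison", "Zq", "protein"], ascending=[True, False, True], na_position="last"
    ).reset_index(drop=True)
    return ProteinQuantResult(table, dispersions, grand)


def category_stats(
    protein_table: pd.DataFrame,
    db: CategoryDB,
    min_size: int = 5,
) -> pd.DataFrame:
    """Category-level averaged ratio ``Xc`` and normalized ``Zc``.

    Membership is counted among quantified, non-excluded proteins only;
    categories with fewer than ``min_size`` such members are omitted.
    Database members never seen in the protein table are ignored (their
    total is logged).
    """
    out = []
    unknown: set = set()
    for cmp_label, sub in protein_table.groupby("comparison", sort=True):
        quant = sub.loc[~sub["excluded"] & sub["Zq"].notna()].set_index("protein")
        known = set(sub["protein"])
        for name in sorted(db.sets):
            members = db.sets[name]
            unknown |= members - known
            hit = [m for m in members if m in quant.index]
            nc = len(hit)
            if nc < min_size:
                continue
            xq = quant.loc[hit, "Xq"]
            zq = quant.loc[hit, "Zq"]
            out.append(
                {
                    "category": name,
                    "comparison": cmp_label,
                    "nc": nc,
                    "Xc": float(xq.mean()),
                    "Zc": float(zq.sum() / math.sqrt(nc)),
                }
            )
    if unknown:
        log.info("ignored %d category members absent from the protein table", len(unknown))
    stats_df = pd.DataFrame(out, columns=["category", "comparison", "nc", "Xc", "Zc"])
    return stats_df.sort_values(
        ["comparison", "Zc", "category"], ascending=[True, False, True]
    ).reset_index(drop=True)


def category_report(stats_df: pd.DataFrame, top: int | None = None) -> dict[str, pd.DataFrame]:
    """Ranked up- (Zc+) and down-regulated (Zc-) category lists.

    Each list carries the theoretical standard-normal quantile for its
    rank so the observed ``Zc`` can be plotted against the expected null
    distribution.
    """
    if stats_df.empty:
        raise ValueError("category table is empty")
    n = len(stats_df)
    ranks = np.arange(1, n + 1)
    # expected order statistics of N(0,1), Blom's approximation
    upper = stats.norm.ppf((n - ranks + 1 - 0.375) / (n + 0.25))
    lower = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    up = stats_df.sort_values(["Zc", "category"], ascending=[False, True]).reset_index(drop=True)
    up["rank"] = ranks
    up["theoretical_quantile"] = upper
    down = stats_df.sort_values(["Zc", "category"], ascending=[True, True]).reset_index(drop=True)
    down["rank"] = ranks
    down["theoretical_quantile"] = lower
    if top is not None:
        up, down = up.head(top), down.head(top)
    return {"up": up, "down": down}
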