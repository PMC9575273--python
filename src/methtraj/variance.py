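"""CpG density versus the magnitude and variability of methylation change.

Three related questions are answered here: whether the mean rate of
change correlates (negatively) with local CpG density; whether the
scatter of rates around their density trend grows as density falls
(heteroscedasticity, tested with the studentized Koenker form of the
Breusch-Pagan test plus a Spearman correlation of squared residuals with
the predictor); and how the inter-individual variance of slopes behaves
once its parabolic dependence on the mean methylation level is removed
(equal-count binning on mean beta, subtracting the bin median).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan

__all__ = [
    "correlate_slope_density",
    "breusch_pagan",
    "normalize_slope_variance",
    "residual_density_correlation",
]


def _spearman(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Spearman rho with t-approximation p on n-2 df."""
    rho, _ = stats.spearmanr(a, b)
    n = len(a)
    if not np.isfinite(rho) or abs(rho) >= 1.0:
        return float(rho), 0.0 if abs(rho) == 1.0 and n > 2 else np.nan
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(rho), float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlate_slope_density(
    values: pd.Series,
    density: pd.Series,
    n_bins: int = 20,
    min_probes: int = 100,
) -> dict:
    """Spearman correlation of per-CpG slopes (or any statistic) vs density.

    Also returns equal-count density-bin summaries (median value per bin)
    for plotting. Requires >= ``min_probes`` shared probes and non-constant
    density.
    """
    shared = values.index.intersection(density.index)
    if len(shared) < min_probes:
        raise ValueError(f"need >= {min_probes} shared probes, got {len(shared)}")
    v = values.loc[shared].to_numpy(float)
    d = density.loc[shared].to_numpy(float)
    fin = np.isfinite(v) & np.isfinite(d)
    v, d = v[fin], d[fin]
    if np.ptp(d) == 0:
        raise ValueError("density is constant")
    rho, p = _spearman(v, d)
    order = np.argsort(d, kind="stable")
    groups = np.array_split(order, n_bins)
    bins = pd.DataFrame(
        {
            "bin": range(len(groups)),
            "density_median": [np.median(d[g]) for g in groups],
            "value_median": [np.median(v[g]) for g in groups],
            "n": [len(g) for g in groups],
        }
    )
    return {"rho": rho, "p": p, "n": int(fin.sum()), "bins": bins}


def breusch_pagan(response: pd.Series | np.ndarray, predictor: pd.Series | np.ndarray) -> dict:
    """Studentized (Koenker) Breusch-Pagan heteroscedasticity test.

    Fits response ~ predictor by OLS, then regresses the squared residuals
    on the predictor; the statistic is n * R^2 of that auxiliary
    regression, chi-square(1) under homoscedasticity. The Spearman
    correlation of squared residuals with the predictor is reported
    alongside.
    """
    y = np.asarray(response, float)
    x = np.asarray(predictor, float)
    fin = np.isfinite(y) & np.isfinite(x)
    y, x = y[fin], x[fin]
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 observations")
    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    if np.allclose(resid, 0.0) or np.var(resid**2) == 0:
        return {
            "bp_stat": 0.0,
            "bp_p": 1.0,
            "rho_sq_resid": np.nan,
            "rho_p": np.nan,
            "n": n,
        }
    lm, lm_p, _, _ = het_breuschpagan(resid, X, robust=True)
    rho, rho_p = _spearman(resid**2, x)
    return {
        "bp_stat": float(lm),
        "bp_p": float(lm_p),
        "rho_sq_resid": rho,
        "rho_p": rho_p,
        "n": n,
    }


def normalize_slope_variance(
    slope_var: pd.Series,
    mean_beta: pd.Series,
    n_bins: int = 20,
    equal_width: bool = False,
) -> pd.DataFrame:
    """Remove the mean-beta dependence of inter-individual slope variance.

    Probes are assigned to ``n_bins`` equal-count bins of mean beta (ties
    straddling a bin edge are broken by stable input order; populations
    differ by at most 1). The normalized variance is the raw variance
    minus the bin median. ``equal_width=True`` switches to equal-width
    bins on [min, max] of mean beta.
    """
    shared = slope_var.index.intersection(mean_beta.index)
    v = slope_var.loc[shared].to_numpy(float)
    mb = mean_beta.loc[shared].to_numpy(float)
    fin = np.isfinite(v) & np.isfinite(mb)
    if ((mb[fin] < 0) | (mb[fin] > 1)).any():
        raise ValueError("mean betas must lie in [0, 1]")
    if (v[fin] < 0).any():
        raise ValueError("variances must be >= 0")
    bin_idx = np.full(len(shared), -1)
    if equal_width:
        edges = np.linspace(np.nanmin(mb), np.nanmax(mb), n_bins + 1)
        bin_idx[fin] = np.clip(np.digitize(mb[fin], edges) - 1, 0, n_bins - 1)
    else:
        order = np.flatnonzero(fin)[np.argsort(mb[fin], kind="stable")]
        for b, grp in enumerate(np.array_split(order, n_bins)):
            bin_idx[grp] = b
    med = np.full(n_bins, np.nan)
    norm = np.full(len(shared), np.nan)
    for b in range(n_bins):
        sel = bin_idx == b
        if sel.any():
            med[b] = np.median(v[sel])
            norm[sel] = v[sel] - med[b]
    out = pd.DataFrame(
        {
            "slope_var": v,
            "mean_beta": mb,
            "bin": bin_idx,
            "bin_median": med[np.clip(bin_idx, 0, n_bins - 1)],
            "norm_slope_var": norm,
        },
        index=shared,
    )
    out.loc[bin_idx < 0, "bin_median"] = np.nan
    return out


def residual_density_correlation(
    cross_fits: pd.DataFrame, density: pd.Series, min_probes: int = 100
) -> dict:
    """Spearman of per-CpG summed absolute residuals against CpG density."""
    if "abs_resid" not in cross_fits.columns:
        raise ValueError("cross-sectional fits must carry 'abs_resid'")
    res = cross_fits["abs_resid"]
    if np.ptp(res.to_numpy(float)) == 0:
        raise ValueError("summed absolute residuals are constant")
    return correlate_slope_density(res, density, min_probes=min_probes)
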