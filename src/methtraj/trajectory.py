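"""Per-individual methylation trajectories and per-CpG slope inference.

Each CpG j and individual i with >= ``min_points`` observations gets an
ordinary least-squares fit

    beta_ij(age) = gamma_ij + alpha_ij * (age - age_ref)

whose slope alpha_ij is the individual's rate of methylation change in
beta/year. Per CpG, the mean slope mu_j over individuals is tested against
zero with a one-sample two-sided t-test, Bonferroni-corrected across the
CpGs tested.

A random-intercept linear mixed model

    beta_ij = alpha_j * age_i + gamma_i + eps_ij,  gamma_i ~ N(g, tau^2)

is the standard alternative that pools individuals; it is fitted here per
CpG by profiled REML on the variance ratio lambda = tau^2 / sigma_e^2.
Because each individual contributes only per-individual sufficient
statistics, the REML objective for any lambda reduces to a handful of
per-CpG scalars, which lets thousands of CpGs be fitted simultaneously by
a vectorised golden-section search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import LongitudinalBetaSet, TrajectoryTable

__all__ = [
    "IndividualTrajectoryFitter",
    "MixedTrajectoryFitter",
    "fit_individual_trajectories",
    "test_mean_slopes",
    "fit_mixed_trajectory",
    "compare_slope_estimators",
    "fit_cross_sectional",
    "evaluate_locus_set",
    "compare_cohorts",
]


def _pair_stats(Y: np.ndarray, x: np.ndarray):
    """NaN-aware per-row OLS sufficient statistics for one individual.

    Y is (n_probes, n_obs) with NaN for missing betas; x the matching ages.
    Returns n, Sx, Sxx, Sy, Syy, Sxy with the per-row observed mask applied.
    """
    obs = ~np.isnan(Y)
    Y0 = np.where(obs, Y, 0.0)
    n = obs.sum(axis=1)
    Sx = obs @ x
    Sxx = obs @ (x * x)
    Sy = Y0.sum(axis=1)
    Syy = (Y0 * Y0).sum(axis=1)
    Sxy = Y0 @ x
    return n, Sx, Sxx, Sy, Syy, Sxy


def fit_individual_trajectories(
    bset: LongitudinalBetaSet,
    min_points: int = 3,
    age_ref: float = 0.0,
) -> TrajectoryTable:
    """OLS slope/intercept per (CpG, individual) pair.

    Pairs with fewer than ``min_points`` non-missing observations, or whose
    observed ages are all identical, are skipped (counted in
    ``n_skipped_pairs``). Intercepts are reported at ``age_ref``.
    """
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    probes = bset.betas.index
    frames = []
    n_skipped = 0
    beta_sum = np.zeros(len(probes))
    beta_n = np.zeros(len(probes))
    for ind, sample_ids, ages in bset.groupby_individual():
        Y = bset.betas[sample_ids].to_numpy(float)
        x = ages - age_ref
        n, Sx, Sxx, Sy, Syy, Sxy = _pair_stats(Y, x)
        Vx = Sxx - Sx * Sx / np.where(n > 0, n, 1)
        ok = (n >= min_points) & (Vx > 1e-12)
        n_skipped += int((~ok).sum())
        if not ok.any():
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            slope = (Sxy - Sx * Sy / n) / Vx
            intercept = (Sy - slope * Sx) / n
            rss = Syy - Sy * Sy / n - slope * slope * Vx
        rss = np.maximum(rss, 0.0)
        # sum of absolute residuals needs the residuals themselves
        fitted = intercept[:, None] + slope[:, None] * x[None, :]
        absres = np.nansum(np.abs(Y - fitted), axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": probes[ok],
                    "individual_id": ind,
                    "slope": slope[ok],
                    "intercept": intercept[ok],
                    "rss": rss[ok],
                    "abs_resid": absres[ok],
                    "n_points": n[ok],
                }
            )
        )
        obs = ~np.isnan(Y)
        beta_sum += np.where(obs, Y, 0.0).sum(axis=1)
        beta_n += obs.sum(axis=1)
    if not frames:
        raise ValueError("no (CpG, individual) pair had enough observations")
    fits = pd.concat(frames, ignore_index=True)
    # CpGs with fewer than 2 surviving individuals carry no slope information
    counts = fits.groupby("probe_id")["slope"].size()
    keep = counts.index[counts >= 2]
    dropped = len(counts) - len(keep)
    if dropped:
        warnings.warn(f"{dropped} CpGs excluded (<2 individuals with fits)")
        fits = fits[fits["probe_id"].isin(keep)]
    with np.errstate(invalid="ignore"):
        mean_beta = pd.Series(beta_sum / np.where(beta_n > 0, beta_n, np.nan), index=probes)
    return TrajectoryTable(
        fits=fits.reset_index(drop=True),
        mean_beta=mean_beta,
        age_ref=age_ref,
        n_skipped_pairs=n_skipped,
    )


def test_mean_slopes(
    traj: TrajectoryTable,
    alpha: float = 0.01,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """One-sample t-test of individual slopes against zero, per CpG.

    Returns a DataFrame indexed by probe_id with mean_slope, n, t, p,
    p_bonf (= min(1, p * n_tests)), significant flag at ``p_bonf < alpha``,
    slope_var (variance across individuals), mean_beta, and a
    degenerate flag for zero-variance slope sets.
    """
    g = traj.fits.groupby("probe_id")["slope"]
    mean = g.mean()
    n = g.size()
    sd = g.std(ddof=1)
    if (n < 2).any():
        raise ValueError("every CpG needs >= 2 individuals")
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = pd.Series(
        2.0 * stats.t.sf(np.abs(t.to_numpy()), df=(n - 1).to_numpy()), index=t.index
    )
    # zero spread: nonzero mean is infinitely significant, zero mean is null
    p[degenerate & (mean != 0)] = 0.0
    t[degenerate & (mean == 0)] = 0.0
    p[degenerate & (mean == 0)] = 1.0
    family = n_tests if n_tests is not None else len(mean)
    p_bonf = np.minimum(1.0, p * family)
    out = pd.DataFrame(
        {
            "mean_slope": mean,
            "n": n,
            "t": t,
            "p": p,
            "p_bonf": p_bonf,
            "significant": p_bonf < alpha,
            "slope_var": g.var(ddof=1),
            "degenerate": degenerate,
        }
    )
    out["mean_beta"] = traj.mean_beta.reindex(out.index)
    return out


# ---------------------------------------------------------------------------
# Random-intercept mixed model, profiled REML


@dataclass
class _MixedStats:
    """Per-(CpG, individual) sufficient statistics for the REML profile."""

    n: np.ndarray  # (n_probes, n_ind) observation counts
    Sx: np.ndarray
    Sxx: np.ndarray
    Sy: np.ndarray
    Syy: np.ndarray
    Sxy: np.ndarray


def _collect_mixed_stats(bset: LongitudinalBetaSet, min_points: int) -> tuple:
    inds, blocks = [], []
    for ind, sample_ids, ages in bset.groupby_individual():
        Y = bset.betas[sample_ids].to_numpy(float)
        stats_i = _pair_stats(Y, ages)
        inds.append(ind)
        blocks.append(stats_i)
    arrays = [np.stack([b[k] for b in blocks], axis=1) for k in range(6)]
    st = _MixedStats(*arrays)
    # apply the same per-pair filter as the individual fits
    Vx = st.Sxx - st.Sx * st.Sx / np.where(st.n > 0, st.n, 1)
    drop = (st.n < min_points) | (Vx <= 1e-12)
    for a in (st.n, st.Sx, st.Sxx, st.Sy, st.Syy, st.Sxy):
        a[drop] = 0.0
    st.n[drop] = 0
    return st, inds


def _reml_profile(st: _MixedStats, lam: np.ndarray):
    """Criterion, GLS estimates and error variance at per-CpG lambda.

    For V_i = sigma_e^2 (I + lambda 11'), Sherman-Morrison gives
    V_i^{-1} = sigma_e^{-2} (I - c_i 11') with c_i = lambda/(1 + n_i lambda),
    so the GLS normal equations and the REML determinant terms reduce to
    sums of per-individual statistics weighted by c_i.
    """
    lam = np.asarray(lam, float)[:, None]  # (n_probes, 1)
    n = st.n
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(n > 0, lam / (1.0 + n * lam), 0.0)
    N = n.sum(axis=1)
    # A = sum_i X_i'X_i - c_i (X_i'1)(X_i'1)'  with X_i = [1, age]
    a11 = (n - c * n * n).sum(axis=1)
    a12 = (st.Sx - c * n * st.Sx).sum(axis=1)
    a22 = (st.Sxx - c * st.Sx * st.Sx).sum(axis=1)
    b1 = (st.Sy - c * n * st.Sy).sum(axis=1)
    b2 = (st.Sxy - c * st.Sx * st.Sy).sum(axis=1)
    yy = (st.Syy - c * st.Sy * st.Sy).sum(axis=1)
    det = a11 * a22 - a12 * a12
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (a11 * b2 - a12 * b1) / det
        inter = (a22 * b1 - a12 * b2) / det
    Q = np.maximum(yy - inter * b1 - slope * b2, 1e-300)
    logdetV = np.where(n > 0, np.log1p(n * lam), 0.0).sum(axis=1)
    crit = (N - 2) * np.log(Q) + logdetV + np.log(np.maximum(det, 1e-300))
    sigma_e2 = Q / np.maximum(N - 2, 1)
    return crit, slope, inter, sigma_e2


def fit_mixed_trajectory(
    bset: LongitudinalBetaSet,
    min_points: int = 3,
    tol: float = 1e-8,
    lam_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """REML random-intercept model per CpG, vectorised across CpGs.

    Returns a DataFrame indexed by probe_id with fixed_slope,
    fixed_intercept, var_intercept (tau^2), var_resid (sigma_e^2),
    converged and n_individuals. CpGs with fewer than 2 usable individuals
    get NaN estimates and ``converged=False``.
    """
    st, _ = _collect_mixed_stats(bset, min_points)
    probes = bset.betas.index
    n_probes = len(probes)
    n_ind_used = (st.n > 0).sum(axis=1)
    usable = n_ind_used >= 2

    if lam_grid is None:
        lam_grid = np.concatenate([[0.0], np.logspace(-6.0, 5.0, 56)])
    crits = np.empty((len(lam_grid), n_probes))
    for k, lam in enumerate(lam_grid):
        crits[k], *_ = _reml_profile(st, np.full(n_probes, lam))
    best = np.argmin(crits, axis=0)

    # golden-section refinement on log(lambda) within the bracketing bins;
    # boundary optimum at lambda=0 is kept as-is
    lo_i = np.maximum(best - 1, 0)
    hi_i = np.minimum(best + 1, len(lam_grid) - 1)
    interior = (best > 0) & (best < len(lam_grid) - 1)
    lam_hat = lam_grid[best].astype(float)
    if interior.any():
        a = np.log(np.maximum(lam_grid[lo_i], 1e-12))
        b = np.log(lam_grid[hi_i])
        gr = (np.sqrt(5.0) - 1.0) / 2.0
        for _ in range(60):
            x1 = b - gr * (b - a)
            x2 = a + gr * (b - a)
            f1, *_ = _reml_profile(st, np.exp(x1))
            f2, *_ = _reml_profile(st, np.exp(x2))
            shrink_right = f1 < f2  # minimum lies in [a, x2]
            b = np.where(shrink_right, x2, b)
            a = np.where(shrink_right, a, x1)
            if float(np.max((b - a)[interior], initial=0.0)) < 1e-10:
                break
        mid = np.exp((a + b) / 2.0)
        lam_hat = np.where(interior, mid, lam_hat)
        # accept the boundary if it is still better after refinement
        crit_mid, *_ = _reml_profile(st, lam_hat)
        crit_zero, *_ = _reml_profile(st, np.zeros(n_probes))
        lam_hat = np.where(crit_zero <= crit_mid + tol, 0.0, lam_hat)

    crit, slope, inter, sigma_e2 = _reml_profile(st, lam_hat)
    out = pd.DataFrame(
        {
            "fixed_slope": np.where(usable, slope, np.nan),
            "fixed_intercept": np.where(usable, inter, np.nan),
            "var_intercept": np.where(usable, lam_hat * sigma_e2, np.nan),
            "var_resid": np.where(usable, sigma_e2, np.nan),
            "converged": usable,
            "n_individuals": n_ind_used,
        },
        index=probes,
    )
    return out


def compare_slope_estimators(
    summaries: pd.DataFrame, mixed: pd.DataFrame
) -> dict:
    """Pearson correlation between mean individual slopes and mixed fixed slopes."""
    shared = summaries.index.intersection(mixed.index[mixed["converged"]])
    if len(shared) < 10:
        raise ValueError("need >= 10 shared CpGs")
    a = summaries.loc[shared, "mean_slope"].to_numpy(float)
    b = mixed.loc[shared, "fixed_slope"].to_numpy(float)
    r, p = stats.pearsonr(a, b)
    return {"pearson_r": float(r), "p": float(p), "n_cpgs": int(len(shared))}


def fit_cross_sectional(
    betas: pd.DataFrame,
    ages: pd.Series,
    subset: np.ndarray | None = None,
    min_samples: int = 20,
) -> pd.DataFrame:
    """One pooled OLS of beta on age per CpG across individuals.

    ``subset`` is an optional boolean mask or sample-id list selecting the
    samples (e.g. an age predicate). Returns slope, p and the summed
    absolute residuals per CpG.
    """
    if subset is not None:
        cols = betas.columns[np.asarray(subset)] if np.asarray(subset).dtype == bool else list(subset)
        betas = betas[cols]
    x = ages.reindex(betas.columns).to_numpy(float)
    if betas.shape[1] < min_samples:
        raise ValueError(f"subset leaves {betas.shape[1]} samples (< {min_samples})")
    if np.ptp(x) == 0:
        raise ValueError("age is constant in the subset")
    Y = betas.to_numpy(float)
    n, Sx, Sxx, Sy, Syy, Sxy = _pair_stats(Y, x)
    Vx = Sxx - Sx * Sx / np.where(n > 0, n, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (Sxy - Sx * Sy / n) / Vx
        inter = (Sy - slope * Sx) / n
        rss = np.maximum(Syy - Sy * Sy / n - slope * slope * Vx, 0.0)
        se = np.sqrt(rss / np.maximum(n - 2, 1) / Vx)
        t = slope / se
    p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(n - 2, 1))
    p = np.where(rss == 0, 0.0, p)
    fitted = inter[:, None] + slope[:, None] * x[None, :]
    abs_resid = np.nansum(np.abs(Y - fitted), axis=1)
    return pd.DataFrame(
        {"slope": slope, "p": p, "abs_resid": abs_resid, "n": n}, index=betas.index
    )


def evaluate_locus_set(
    summaries: pd.DataFrame,
    locus_set: pd.Series,
    alpha: float = 0.05,
) -> dict:
    """Fraction of a predefined locus set changing in its predicted direction.

    ``locus_set`` maps probe_id -> expected direction (+1/-1 or "+"/"-").
    Also compares normalized slope variance of the set against the
    background by a one-sided Wilcoxon rank-sum (set < background), using
    ``norm_slope_var`` if present else ``slope_var``.
    """
    if len(locus_set) == 0:
        raise ValueError("locus set is empty")
    dirs = locus_set.map(lambda v: {"+": 1.0, "-": -1.0}.get(v, v)).astype(float)
    known = dirs.index.isin(summaries.index)
    if not known.all():
        warnings.warn(f"{(~known).sum()} locus-set probes not in summaries; dropped")
        dirs = dirs[known]
    if len(dirs) == 0:
        raise ValueError("no locus-set probe found in summaries")
    sub = summaries.loc[dirs.index]
    hit = (sub["p_bonf"] < alpha) & (np.sign(sub["mean_slope"]) == np.sign(dirs))
    var_col = "norm_slope_var" if "norm_slope_var" in summaries.columns else "slope_var"
    bg = summaries.loc[~summaries.index.isin(dirs.index), var_col].dropna()
    sv = sub[var_col].dropna()
    if len(sv) and len(bg):
        wstat, wp = stats.mannwhitneyu(sv, bg, alternative="less")
    else:
        wstat, wp = np.nan, np.nan
    return {
        "n_set": int(len(dirs)),
        "n_significant_in_direction": int(hit.sum()),
        "fraction": float(hit.mean()),
        "wilcoxon_stat": float(wstat),
        "wilcoxon_p": float(wp),
    }


def compare_cohorts(
    summary_a: pd.DataFrame,
    summary_b: pd.DataFrame,
    alpha: float = 0.01,
) -> dict:
    """Replication of cohort A's significant CpGs in cohort B.

    One-sided Wilcoxon rank-sum testing whether cohort-B p-values at
    cohort-A-significant CpGs are shifted low relative to the remaining
    shared CpGs, plus the Spearman correlation of slopes on the shared
    significant set.
    """
    pcol_b = "p" if "p" in summary_b.columns else "p_bonf"
    scol_a = "mean_slope" if "mean_slope" in summary_a.columns else "slope"
    scol_b = "mean_slope" if "mean_slope" in summary_b.columns else "slope"
    shared = summary_a.index.intersection(summary_b.index)
    if len(shared) < 10:
        raise ValueError("need >= 10 shared CpGs")
    sig = summary_a.loc[shared]
    sig_mask = (
        sig["significant"]
        if "significant" in sig.columns
        else sig["p_bonf"] < alpha
    )
    sig_ids = shared[sig_mask.to_numpy(bool)]
    rest_ids = shared[~sig_mask.to_numpy(bool)]
    if len(sig_ids) == 0:
        raise ValueError("cohort A has no significant CpGs among shared probes")
    if len(rest_ids) == 0:
        raise ValueError("no non-significant background CpGs shared")
    wstat, wp = stats.mannwhitneyu(
        summary_b.loc[sig_ids, pcol_b],
        summary_b.loc[rest_ids, pcol_b],
        alternative="less",
    )
    rho, rho_p = stats.spearmanr(
        summary_a.loc[sig_ids, scol_a], summary_b.loc[sig_ids, scol_b]
    )
    return {
        "wilcoxon_stat": float(wstat),
        "wilcoxon_p": float(wp),
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
        "n_significant": int(len(sig_ids)),
        "n_shared": int(len(shared)),
    }


# ---------------------------------------------------------------------------
# Estimator classes


class IndividualTrajectoryFitter(BaseEstimator):
    """Per-individual OLS trajectories with per-CpG mean-slope testing.

    Parameters
    ----------
    min_points : minimum observations per (CpG, individual) pair.
    alpha : Bonferroni-adjusted significance level for mean slopes.
    age_ref : age (years) at which intercepts are parameterised.
    """

    def __init__(self, min_points: int = 3, alpha: float = 0.01, age_ref: float = 0.0):
        self.min_points = min_points
        self.alpha = alpha
        self.age_ref = age_ref

    def fit(self, bset: LongitudinalBetaSet, y=None):
        self.trajectories_ = fit_individual_trajectories(
            bset, min_points=self.min_points, age_ref=self.age_ref
        )
        self.summary_ = test_mean_slopes(self.trajectories_, alpha=self.alpha)
        return self

    @property
    def slopes_(self) -> pd.DataFrame:
        return self.trajectories_.slopes_wide()


class MixedTrajectoryFitter(BaseEstimator):
    """Per-CpG random-intercept mixed model fitted by profiled REML."""

    def __init__(self, min_points: int = 3, tol: float = 1e-8):
        self.min_points = min_points
        self.tol = tol

    def fit(self, bset: LongitudinalBetaSet, y=None):
        self.fits_ = fit_mixed_trajectory(
            bset, min_points=self.min_points, tol=self.tol
        )
        return self
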