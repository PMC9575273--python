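"""Blood cell-composition correction and cell-rate variance explanation.

Betas can be residualised on directly measured white-cell counts
(neutrophils, lymphocytes, monocytes, eosinophils, basophils) or on
reference-based estimated proportions (Houseman-style constrained
projection): per CpG the betas are replaced by the residuals of an OLS of
beta on the count columns, and the corrected matrix feeds straight back
into trajectory fitting.

To quantify how much of the variation in per-individual methylation slopes
is driven by changing blood composition, each cell type's proportion is
itself fitted as a linear function of age per individual, and per CpG the
individual slopes are regressed on those cell-type rates (one cell type
dropped because proportions sum to one).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import MEASURED_CELL_TYPES, LongitudinalBetaSet

__all__ = [
    "CellCompositionResidualizer",
    "ReferenceDeconvolver",
    "residualize_betas",
    "estimate_cell_proportions",
    "fit_cell_rates",
    "explain_slopes_by_cell_rates",
]


def _design_with_intercept(counts: pd.DataFrame) -> tuple[np.ndarray, list]:
    """Design matrix [1, counts]; collinear count columns are dropped."""
    cols = list(counts.columns)
    X = np.column_stack([np.ones(len(counts)), counts.to_numpy(float)])
    # rank-revealing QR: drop trailing columns whose R diagonal collapses
    keep = [0]
    for j in range(1, X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=1e-8 * max(1.0, np.abs(cand).max())) == len(keep) + 1:
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear cell-count column '{cols[j - 1]}'")
    return X[:, keep], [cols[j - 1] for j in keep[1:]]


def residualize_betas(
    betas: pd.DataFrame, cell_counts: pd.DataFrame
) -> pd.DataFrame:
    """Per-CpG residuals of beta on the cell-count columns (with intercept).

    ``cell_counts`` is sample x cell-type, indexed like the beta columns.
    Rows of ``betas`` containing NaN fall back to per-CpG complete-case
    regression. Residualisation is idempotent.
    """
    counts = cell_counts.reindex(betas.columns)
    if counts.isna().any().any():
        raise ValueError("cell counts missing for some samples")
    X, _ = _design_with_intercept(counts)
    Q, _ = np.linalg.qr(X)
    B = betas.to_numpy(float)
    has_nan = np.isnan(B).any(axis=1)
    R = np.empty_like(B)
    if (~has_nan).any():
        Bc = B[~has_nan]
        R[~has_nan] = Bc - (Bc @ Q) @ Q.T
    for i in np.flatnonzero(has_nan):
        obs = ~np.isnan(B[i])
        Qi, _ = np.linalg.qr(X[obs])
        r = np.full(B.shape[1], np.nan)
        y = B[i, obs]
        r[obs] = y - Qi @ (Qi.T @ y)
        R[i] = r
    return pd.DataFrame(R, index=betas.index, columns=betas.columns)


def estimate_cell_proportions(
    betas: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Reference-based cell-proportion estimates by constrained projection.

    Per sample, nonnegative least squares fits the observed betas at the
    reference CpGs as a mixture of the reference profiles; weights are then
    rescaled to sum to one. Returns sample x cell-type proportions.
    """
    if reference.shape[1] < 2:
        raise ValueError("need at least 2 reference cell types")
    shared = betas.index.intersection(reference.index)
    if len(shared) < reference.shape[1]:
        raise ValueError("too few reference CpGs shared with the beta matrix")
    A = reference.loc[shared].to_numpy(float)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("reference profile matrix is rank-deficient")
    B = betas.loc[shared].to_numpy(float)
    out = np.empty((betas.shape[1], reference.shape[1]))
    for s in range(B.shape[1]):
        y = B[:, s]
        obs = ~np.isnan(y)
        w, _ = optimize.nnls(A[obs], y[obs])
        total = w.sum()
        out[s] = w / total if total > 0 else np.full(len(w), 1.0 / len(w))
    return pd.DataFrame(out, index=betas.columns, columns=reference.columns)


def fit_cell_rates(
    samples: pd.DataFrame,
    cell_types: tuple = MEASURED_CELL_TYPES,
    min_points: int = 3,
) -> pd.DataFrame:
    """Per-individual OLS rate of change of each cell-type proportion.

    Counts are converted to within-sample proportions first, so the rates
    sum to ~0 across cell types within an individual. Individuals with
    fewer than ``min_points`` timepoints are excluded.
    """
    missing = [c for c in cell_types if c not in samples.columns]
    if missing:
        raise ValueError(f"sample sheet lacks cell columns: {missing}")
    counts = samples[list(cell_types)].to_numpy(float)
    totals = counts.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("non-positive total cell count")
    props = counts / totals
    rows = {}
    for ind, sub in samples.assign(
        **{c: props[:, k] for k, c in enumerate(cell_types)}
    ).groupby("individual_id"):
        if len(sub) < min_points:
            continue
        x = sub["age_years"].to_numpy(float)
        xc = x - x.mean()
        denom = (xc**2).sum()
        if denom == 0:
            continue
        y = sub[list(cell_types)].to_numpy(float)
        rows[ind] = (xc @ y) / denom
    if not rows:
        raise ValueError("no individual had enough cell-count timepoints")
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(cell_types)).rename_axis(
        "individual_id"
    )


def explain_slopes_by_cell_rates(
    slopes: pd.DataFrame,
    rates: pd.DataFrame,
    drop_cell_type: str = "lymphocytes",
    alpha: float = 0.01,
    vif_warn: float = 10.0,
) -> pd.DataFrame:
    """Regress per-individual slopes on cell-type rates, per CpG.

    ``slopes`` is probe x individual; ``rates`` individual x cell type.
    One cell type (default lymphocytes, the one most collinear with
    neutrophils) is dropped because proportions sum to one. Returns per-CpG
    coefficients, F-test p, Bonferroni-adjusted p and R^2; variance
    inflation factors of the retained rate columns are attached as
    DataFrame attrs.
    """
    if drop_cell_type not in rates.columns:
        raise ValueError(f"unknown cell type to drop: {drop_cell_type}")
    use_cols = [c for c in rates.columns if c != drop_cell_type]
    shared = slopes.columns.intersection(rates.index)
    if len(shared) <= len(use_cols) + 1:
        raise ValueError("too few individuals shared between slopes and rates")
    X0 = rates.loc[shared, use_cols].to_numpy(float)
    X = np.column_stack([np.ones(len(shared)), X0])
    n, k = len(shared), X0.shape[1]

    # VIFs on the rate columns (against each other, with intercept)
    vifs = {}
    for j in range(k):
        others = np.delete(X0, j, axis=1)
        Xo = np.column_stack([np.ones(n), others])
        bo, *_ = np.linalg.lstsq(Xo, X0[:, j], rcond=None)
        res = X0[:, j] - Xo @ bo
        tss = ((X0[:, j] - X0[:, j].mean()) ** 2).sum()
        r2 = 1.0 - (res**2).sum() / tss if tss > 0 else 0.0
        vifs[use_cols[j]] = 1.0 / max(1.0 - r2, 1e-12)
        if vifs[use_cols[j]] > vif_warn:
            warnings.warn(f"VIF {vifs[use_cols[j]]:.1f} for {use_cols[j]} exceeds {vif_warn}")

    Y = slopes[shared].to_numpy(float).T  # individuals x probes
    ok = ~np.isnan(Y).any(axis=0)
    coef = np.full((slopes.shape[0], k + 1), np.nan)
    r2 = np.full(slopes.shape[0], np.nan)
    fp = np.full(slopes.shape[0], np.nan)
    if ok.any():
        Yc = Y[:, ok]
        beta, *_ = np.linalg.lstsq(X, Yc, rcond=None)
        fit = X @ beta
        rss1 = ((Yc - fit) ** 2).sum(axis=0)
        tss = ((Yc - Yc.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2_ok = np.where(tss > 0, 1.0 - rss1 / tss, 0.0)
            F = ((tss - rss1) / k) / (rss1 / (n - k - 1))
        p_ok = stats.f.sf(F, k, n - k - 1)
        p_ok = np.where(rss1 == 0, 0.0, p_ok)
        coef[ok] = beta.T
        r2[ok] = np.clip(r2_ok, 0.0, 1.0)
        fp[ok] = p_ok
    # per-CpG complete-case fallback for probes with missing slopes
    for i in np.flatnonzero(~ok):
        y = Y[:, i]
        obs = ~np.isnan(y)
        if obs.sum() <= k + 1:
            continue
        Xi, yi = X[obs], y[obs]
        b, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
        res = yi - Xi @ b
        tss_i = ((yi - yi.mean()) ** 2).sum()
        rss_i = (res**2).sum()
        coef[i] = b
        r2[i] = np.clip(1.0 - rss_i / tss_i, 0.0, 1.0) if tss_i > 0 else 0.0
        Fi = ((tss_i - rss_i) / k) / (rss_i / (obs.sum() - k - 1))
        fp[i] = stats.f.sf(Fi, k, obs.sum() - k - 1) if rss_i > 0 else 0.0

    out = pd.DataFrame(
        coef,
        index=slopes.index,
        columns=["intercept"] + [f"c_{c}" for c in use_cols],
    )
    out["r2"] = r2
    out["f_p"] = fp
    out["f_p_bonf"] = np.minimum(1.0, fp * len(out))
    out["explained"] = out["f_p_bonf"] < alpha
    out.attrs["vif"] = vifs
    out.attrs["n_individuals"] = int(n)
    out.attrs["dropped_cell_type"] = drop_cell_type
    return out


class CellCompositionResidualizer(BaseEstimator, TransformerMixin):
    """Transformer replacing betas by cell-composition-corrected residuals.

    mode="measured" uses the measured count columns of the sample sheet;
    mode="houseman" estimates proportions from the betas at reference CpGs
    (requires ``reference``) and residualises on those.
    """

    def __init__(self, mode: str = "measured", reference: pd.DataFrame | None = None):
        self.mode = mode
        self.reference = reference

    def fit(self, bset: LongitudinalBetaSet, y=None):
        if self.mode == "measured":
            cols = [c for c in MEASURED_CELL_TYPES if c in bset.samples.columns]
            if not cols:
                raise ValueError("sample sheet has no measured cell-count columns")
            self.counts_ = bset.samples[cols]
        elif self.mode == "houseman":
            if self.reference is None:
                raise ValueError("mode='houseman' requires a reference profile matrix")
            self.counts_ = estimate_cell_proportions(bset.betas, self.reference)
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        return self

    def transform(self, bset: LongitudinalBetaSet) -> LongitudinalBetaSet:
        resid = residualize_betas(bset.betas, self.counts_)
        return bset.with_betas(resid)


class ReferenceDeconvolver(BaseEstimator, TransformerMixin):
    """Constrained-projection estimator of cell-type proportions."""

    def __init__(self, reference: pd.DataFrame | None = None):
        self.reference = reference

    def fit(self, betas: pd.DataFrame, y=None):
        if self.reference is None:
            raise ValueError("a reference profile matrix is required")
        self.cell_types_ = list(self.reference.columns)
        return self

    def transform(self, betas: pd.DataFrame) -> pd.DataFrame:
        return estimate_cell_proportions(betas, self.reference)
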