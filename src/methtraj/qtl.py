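"""Slope-QTL mapping: SNPs associated with methylation rate of change.

Per eligible SNP-CpG pair (cis: within 1 Mb), each individual's
trajectory slope is regressed on additive minor-allele dosage; p-values
are Benjamini-Hochberg corrected across all pairs tested in the mode.
Pairs where genotype instead associates with the dispersion of the
individual fits (the per-individual residual sum) are excluded — such
variance-QTLs can arise from SNPs disrupting probe hybridisation rather
than genuine trajectory effects. Linked SNPs hitting the same CpG are
resolved into independent associations by conditional analysis (lead SNP,
re-test of the rest on lead-model residuals, Bonferroni within CpG,
iterated to convergence), and surviving pairs are validated with a pooled
methylation ~ age x genotype interaction model.

Genotype QC follows standard array conventions: call rate >= 0.98,
MAF >= 0.01 and an exact Hardy-Weinberg test p >= 0.001.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datatypes import GenotypeSet, LongitudinalBetaSet

__all__ = [
    "hwe_exact_test",
    "filter_genotypes",
    "map_slope_qtls",
    "filter_variance_qtls",
    "conditional_analysis",
    "validate_interactions",
    "snp_cpg_proximity",
    "local_effect_profile",
    "SlopeQTLMapper",
]


def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg equilibrium p-value.

    Full enumeration of heterozygote counts at fixed allele counts; the
    p-value sums the probabilities of all configurations no more likely
    than the observed one (the standard exact HWE formulation).
    """
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het
    het_values = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    # log P(het = h | allele counts) up to a constant, via log-factorials
    logfact = np.zeros(2 * n + 1)
    logfact[1:] = np.cumsum(np.log(np.arange(1, 2 * n + 1)))
    hom_min = (n_minor - het_values) // 2
    hom_maj = n - het_values - hom_min
    logp = (
        het_values * np.log(2.0)
        + logfact[n]
        - logfact[het_values]
        - logfact[hom_min]
        - logfact[hom_maj]
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[het_values == n_het][0]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


def filter_genotypes(
    genotypes: GenotypeSet,
    min_call_rate: float = 0.98,
    min_maf: float = 0.01,
    min_hwe_p: float = 0.001,
) -> GenotypeSet:
    """Apply call-rate, MAF and exact-HWE QC; annotate per-SNP metadata.

    Dosages are assumed minor-allele coded 0/1/2 with NaN for missing
    calls; monomorphic SNPs fall out through the MAF filter.
    """
    D = genotypes.dosages.to_numpy(float)
    n_ind = D.shape[1]
    n_called = (~np.isnan(D)).sum(axis=1)
    call_rate = n_called / n_ind
    with np.errstate(invalid="ignore"):
        n2 = np.nansum(D == 2, axis=1)
        n1 = np.nansum(D == 1, axis=1)
        n0 = np.nansum(D == 0, axis=1)
    af = (2 * n2 + n1) / np.maximum(2 * n_called, 1)
    maf = np.minimum(af, 1 - af)
    hwe_p = np.array(
        [hwe_exact_test(int(a), int(b), int(c)) for a, b, c in zip(n2, n1, n0)]
    )
    snps = genotypes.snps.copy()
    snps["call_rate"] = call_rate
    snps["maf"] = maf
    snps["hwe_p"] = hwe_p
    keep = (call_rate >= min_call_rate) & (maf >= min_maf) & (hwe_p >= min_hwe_p)
    return GenotypeSet(dosages=genotypes.dosages.loc[keep], snps=snps.loc[keep])


def _pairwise_scan(
    response: pd.DataFrame,
    genotypes: GenotypeSet,
    cpg_pos: pd.DataFrame,
    mode: str,
    cis_window: int,
    min_individuals: int,
) -> pd.DataFrame:
    """OLS of a per-individual response on dosage for every eligible pair."""
    if mode not in ("cis", "trans"):
        raise ValueError("mode must be 'cis' or 'trans'")
    shared = response.columns.intersection(genotypes.individuals)
    Y = response[shared].to_numpy(float)  # probes x individuals
    G = genotypes.dosages[shared].to_numpy(float)  # snps x individuals
    probes = response.index
    cpg_pos = cpg_pos.loc[probes]
    snp_meta = genotypes.snps
    # fast path for probes with complete responses: their sums do not
    # depend on which individuals a SNP was called in
    row_clean = ~np.isnan(Y).any(axis=1)
    Y0 = np.where(np.isnan(Y), 0.0, Y)
    Sy_all = Y0.sum(axis=1)
    Syy_all = (Y0 * Y0).sum(axis=1)
    rows = []
    chrom_arr = cpg_pos["chrom"].to_numpy()
    pos_arr = cpg_pos["pos"].to_numpy(int)
    for s_i, snp in enumerate(genotypes.dosages.index):
        chrom = snp_meta.at[snp, "chrom"]
        pos = int(snp_meta.at[snp, "pos"])
        if mode == "cis":
            elig = np.flatnonzero(
                (chrom_arr == chrom) & (np.abs(pos_arr - pos) <= cis_window)
            )
        else:
            elig = np.arange(len(probes))
        if elig.size == 0:
            continue
        g = G[s_i]
        g_clean = not np.isnan(g).any()
        if g_clean and row_clean[elig].all():
            n = np.full(elig.size, len(g))
            Sg = np.full(elig.size, g.sum())
            Sgg = np.full(elig.size, g @ g)
            Sy = Sy_all[elig]
            Syy = Syy_all[elig]
            Sgy = Y0[elig] @ g
            ok = n >= min_individuals
        else:
            Ys = Y[elig]
            obs = ~np.isnan(Ys) & ~np.isnan(g)[None, :]
            n = obs.sum(axis=1)
            ok = n >= min_individuals
            if not ok.any():
                continue
            g0 = np.where(np.isnan(g), 0.0, g)
            Sg = obs @ g0
            Sgg = obs @ (g0 * g0)
            Sy = np.where(obs, Ys, 0.0).sum(axis=1)
            Syy = np.where(obs, Ys * Ys, 0.0).sum(axis=1)
            Sgy = np.where(obs, Ys, 0.0) @ g0
        Vg = Sgg - Sg * Sg / np.maximum(n, 1)
        ok &= Vg > 1e-12  # dosage constant after complete-case -> skip
        with np.errstate(divide="ignore", invalid="ignore"):
            eff = (Sgy - Sg * Sy / n) / Vg
            rss = np.maximum(Syy - Sy * Sy / n - eff * eff * Vg, 0.0)
            se = np.sqrt(rss / np.maximum(n - 2, 1) / Vg)
            t = eff / se
        p = 2.0 * stats.t.sf(np.abs(t), df=np.maximum(n - 2, 1))
        p = np.where(rss == 0, 0.0, p)
        kk = np.flatnonzero(ok)
        jj = elig[kk]
        same_chrom = cpg_pos["chrom"].to_numpy()[jj] == chrom
        dists = np.where(
            same_chrom, np.abs(cpg_pos["pos"].to_numpy(int)[jj] - pos), -1
        )
        rows.append(
            pd.DataFrame(
                {
                    "snp_id": snp,
                    "probe_id": probes[jj],
                    "effect": eff[kk],
                    "t": t[kk],
                    "p": p[kk],
                    "distance": dists,
                    "n": n[kk].astype(int),
                }
            )
        )
    if rows:
        return pd.concat(rows, ignore_index=True)
    return pd.DataFrame(
        columns=["snp_id", "probe_id", "effect", "t", "p", "distance", "n"]
    )


def map_slope_qtls(
    slopes: pd.DataFrame,
    genotypes: GenotypeSet,
    cpg_pos: pd.DataFrame,
    mode: str = "cis",
    cis_window: int = 1_000_000,
    fdr: float = 0.05,
    min_individuals: int = 30,
) -> pd.DataFrame:
    """Scan all eligible SNP-CpG pairs for genotype-slope associations.

    ``slopes`` is probe x individual (NaN where an individual had no fit);
    ``cpg_pos`` carries chrom/pos per probe. Returns all tested pairs with
    BH-corrected q-values (family: every pair tested in this mode) and a
    ``significant`` flag at ``q < fdr``.
    """
    out = _pairwise_scan(slopes, genotypes, cpg_pos, mode, cis_window, min_individuals)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["q"] < fdr
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def filter_variance_qtls(
    residual_stat: pd.DataFrame,
    genotypes: GenotypeSet,
    cpg_pos: pd.DataFrame,
    mode: str = "cis",
    cis_window: int = 1_000_000,
    fdr: float = 0.05,
    min_individuals: int = 30,
) -> pd.DataFrame:
    """Flag SNP-CpG pairs where genotype associates with fit dispersion.

    ``residual_stat`` is the probe x individual matrix of per-individual
    residual sums from the trajectory fits (sum of squares by default
    upstream; sum of absolute residuals via ``TrajectoryTable.abs_resid_wide``).
    Returns the flagged (BH q < fdr) pairs to exclude.
    """
    scan = _pairwise_scan(
        residual_stat, genotypes, cpg_pos, mode, cis_window, min_individuals
    )
    if not len(scan):
        return scan.assign(q=pd.Series(dtype=float))
    scan["q"] = multipletests(scan["p"], method="fdr_bh")[1]
    return scan[scan["q"] < fdr][["snp_id", "probe_id", "effect", "p", "q"]]


def exclude_variance_qtls(qtls: pd.DataFrame, flagged: pd.DataFrame) -> pd.DataFrame:
    """Drop flagged variance-QTL pairs from a slope-QTL table."""
    if not len(flagged):
        return qtls.copy()
    key = set(zip(flagged["snp_id"], flagged["probe_id"]))
    mask = [
        (s, p) not in key for s, p in zip(qtls["snp_id"], qtls["probe_id"])
    ]
    return qtls[mask].copy()


def conditional_analysis(
    qtls: pd.DataFrame,
    slopes: pd.DataFrame,
    genotypes: GenotypeSet,
    alpha: float = 0.05,
    max_rounds: int = 10,
    ld_r_cap: float = 0.95,
) -> pd.DataFrame:
    """Resolve significant pairs per CpG into independent lead SNPs.

    The lead SNP is the most significant (ties broken by SNP-CpG distance,
    then lexicographic id). Remaining associated SNPs are re-tested
    against the residuals of the model containing all SNPs selected so
    far; a SNP is added when its Bonferroni-corrected p (family: SNPs
    re-tested for that CpG in that round) is < ``alpha``. Candidates whose
    dosage correlates with any selected SNP at |r| > ``ld_r_cap`` are
    never added (they carry no separable signal). Iterates to convergence.
    """
    sig = qtls[qtls["significant"]] if "significant" in qtls.columns else qtls
    if not len(sig):
        return sig.assign(lead=pd.Series(dtype=bool), round=pd.Series(dtype=int))
    shared = slopes.columns.intersection(genotypes.individuals)
    out_rows = []
    for probe, sub in sig.groupby("probe_id"):
        y_full = slopes.loc[probe, shared].to_numpy(float)
        sub = sub.sort_values(
            ["p", "distance", "snp_id"], ascending=[True, True, True]
        )
        lead = sub.iloc[0]
        selected = [(lead["snp_id"], lead["effect"], lead["p"], 1)]
        remaining = sub.iloc[1:]
        for rnd in range(2, max_rounds + 2):
            if not len(remaining):
                break
            sel_ids = [s[0] for s in selected]
            Gsel = genotypes.dosages.loc[sel_ids, shared].to_numpy(float)
            obs = ~np.isnan(y_full) & ~np.isnan(Gsel).any(axis=0)
            X = np.column_stack([np.ones(obs.sum()), Gsel[:, obs].T])
            y = y_full[obs]
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            best = None
            n_tested = 0
            for _, row in remaining.iterrows():
                g = genotypes.dosages.loc[row["snp_id"], shared].to_numpy(float)[obs]
                if np.nanstd(g) == 0:
                    continue
                r_with_sel = [
                    abs(np.corrcoef(g, Gsel[k, obs])[0, 1]) for k in range(len(sel_ids))
                ]
                if max(r_with_sel) > ld_r_cap:
                    continue
                n_tested += 1
                gm = g - g.mean()
                denom = (gm**2).sum()
                eff = (gm @ resid) / denom
                rss = ((resid - eff * gm) ** 2).sum()
                dfree = obs.sum() - X.shape[1] - 1
                se = np.sqrt(rss / max(dfree, 1) / denom)
                tt = eff / se if se > 0 else np.inf
                p = 2.0 * stats.t.sf(abs(tt), df=max(dfree, 1))
                if best is None or p < best[2]:
                    best = (row["snp_id"], eff, p)
            if best is None or n_tested == 0:
                break
            p_bonf = min(1.0, best[2] * n_tested)
            if p_bonf >= alpha:
                break
            selected.append((best[0], best[1], best[2], rnd))
            remaining = remaining[remaining["snp_id"] != best[0]]
        for k, (snp, eff, p, rnd) in enumerate(selected):
            out_rows.append(
                {
                    "snp_id": snp,
                    "probe_id": probe,
                    "effect": eff,
                    "p": p,
                    "lead": k == 0,
                    "round": rnd,
                }
            )
    out = pd.DataFrame(out_rows)
    dist = sig.set_index(["snp_id", "probe_id"])["distance"]
    out["distance"] = [
        dist.get((s, p), np.nan) for s, p in zip(out["snp_id"], out["probe_id"])
    ]
    return out


def validate_interactions(
    bset: LongitudinalBetaSet,
    genotypes: GenotypeSet,
    pairs: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pooled methylation ~ age + genotype + age:genotype model per pair.

    The interaction coefficient is the population-level analogue of the
    per-individual slope-on-dosage effect; on balanced noise-free data the
    two are identical. Returns the per-pair interaction effect and
    Bonferroni-adjusted p (family: all pairs supplied), plus the Spearman
    correlation between interaction and slope-regression effects in attrs.
    """
    samples = bset.samples
    ind_of_sample = samples["individual_id"]
    age = samples["age_years"].to_numpy(float)
    rows = []
    for _, pair in pairs.iterrows():
        probe, snp = pair["probe_id"], pair["snp_id"]
        y = bset.betas.loc[probe].to_numpy(float)
        g_ind = genotypes.dosages.loc[snp]
        g = g_ind.reindex(ind_of_sample).to_numpy(float)
        obs = ~np.isnan(y) & ~np.isnan(g)
        X = np.column_stack(
            [np.ones(obs.sum()), age[obs], g[obs], age[obs] * g[obs]]
        )
        coef, rss_arr, rank, _ = np.linalg.lstsq(X, y[obs], rcond=None)
        resid = y[obs] - X @ coef
        rss = float((resid**2).sum())
        dfree = obs.sum() - X.shape[1]
        XtX_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(max(rss, 0.0) / max(dfree, 1) * XtX_inv[3, 3])
        tt = coef[3] / se if se > 0 else np.inf
        p = 2.0 * stats.t.sf(abs(tt), df=max(dfree, 1))
        rows.append(
            {
                "snp_id": snp,
                "probe_id": probe,
                "interaction_effect": coef[3],
                "interaction_p": p,
                "n_obs": int(obs.sum()),
            }
        )
    out = pd.DataFrame(rows)
    out["interaction_p_bonf"] = np.minimum(1.0, out["interaction_p"] * len(out))
    out["validated"] = out["interaction_p_bonf"] < alpha
    if "effect" in pairs.columns and len(out) >= 3:
        rho, rho_p = stats.spearmanr(
            pairs["effect"].to_numpy(float), out["interaction_effect"].to_numpy(float)
        )
        out.attrs["spearman_rho"] = float(rho)
        out.attrs["spearman_p"] = float(rho_p)
    return out


def _cg_positions(seq: str) -> np.ndarray:
    return np.array([m.start() for m in re.finditer("CG", seq.upper())], dtype=int)


def snp_cpg_proximity(
    snps: pd.DataFrame,
    lead_ids: pd.Index | list,
    genome,
) -> pd.DataFrame:
    """Distance from each SNP to its nearest genomic CpG dyad.

    Distance is to the closest base of the dyad (0 when the SNP falls on
    the C or the G); a SNP at distance <= 1 directly affects a CpG or an
    adjacent base. Returns per-SNP distances plus a two-sample t-test of
    lead vs non-lead distances and the lead direct-hit fraction in attrs.
    """
    from .annotation import _get_sequence

    rows = []
    for chrom, sub in snps.groupby("chrom", sort=False):
        seq = _get_sequence(genome, chrom)
        cg = _cg_positions(seq)
        for snp, pos in zip(sub.index, sub["pos"].astype(int)):
            if not 0 <= pos < len(seq):
                continue
            if cg.size == 0:
                rows.append((snp, np.inf))
                continue
            k = np.searchsorted(cg, pos)
            cand = cg[max(0, k - 1) : k + 1]
            # distance to the half-open dyad interval [c, c+2)
            d = np.minimum(np.abs(pos - cand), np.abs(pos - (cand + 1))).min()
            if ((cand <= pos) & (pos <= cand + 1)).any():
                d = 0
            rows.append((snp, int(d)))
    out = pd.DataFrame(rows, columns=["snp_id", "distance"]).set_index("snp_id")
    out["lead"] = out.index.isin(pd.Index(lead_ids))
    lead_d = out.loc[out["lead"], "distance"]
    other_d = out.loc[~out["lead"], "distance"]
    if len(lead_d) >= 2 and len(other_d) >= 2:
        t, p = stats.ttest_ind(lead_d, other_d, equal_var=False)
        out.attrs["t"] = float(t)
        out.attrs["p"] = float(p)
    out.attrs["lead_direct_fraction"] = (
        float((lead_d <= 1).mean()) if len(lead_d) else np.nan
    )
    return out


def local_effect_profile(
    lead_pairs: pd.DataFrame,
    slopes: pd.DataFrame,
    genotypes: GenotypeSet,
    cpg_pos: pd.DataFrame,
    span: int = 1000,
    bin_width: int = 50,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Spread of lead-SNP effects onto neighbouring CpG slopes.

    For each lead pair, the lead SNP's effect on every measured CpG within
    +/- ``span`` bp of the paired CpG is computed and normalised by the
    lead-pair effect (so the lead CpG's own bin is 1 by construction);
    normalised effects are averaged in ``bin_width`` bp bins of signed
    distance. The null distribution permutes each genotype vector across
    individuals; the returned frame carries the observed mean per bin, the
    permutation mean and 95% band, and the number of contributing pairs.
    """
    rng = np.random.default_rng(seed)
    shared = slopes.columns.intersection(genotypes.individuals)
    S = slopes[shared].to_numpy(float)
    edges = np.arange(-span, span + bin_width, bin_width)
    n_bins = len(edges) - 1
    obs_sum = np.zeros(n_bins)
    obs_n = np.zeros(n_bins, dtype=int)
    perm_sum = np.zeros((n_permutations, n_bins))
    perm_n = np.zeros((n_permutations, n_bins), dtype=int)

    probe_index = slopes.index
    for _, pair in lead_pairs.iterrows():
        probe, snp = pair["probe_id"], pair["snp_id"]
        chrom = cpg_pos.at[probe, "chrom"]
        pos0 = int(cpg_pos.at[probe, "pos"])
        near = cpg_pos[
            (cpg_pos["chrom"] == chrom) & (np.abs(cpg_pos["pos"] - pos0) <= span)
        ]
        near = near[near.index.isin(probe_index)]
        if not len(near):
            continue
        g = genotypes.dosages.loc[snp, shared].to_numpy(float)
        rows = probe_index.get_indexer(near.index)
        Y = S[rows]
        signed = (near["pos"].to_numpy(int) - pos0).clip(-span, span - 1)
        bins = np.digitize(signed, edges) - 1

        def _effects(gv):
            obs = ~np.isnan(Y) & ~np.isnan(gv)[None, :]
            gm0 = np.where(np.isnan(gv), 0.0, gv)
            n = obs.sum(axis=1)
            Sg = obs @ gm0
            Sgg = obs @ (gm0 * gm0)
            Sy = np.where(obs, Y, 0.0).sum(axis=1)
            Sgy = np.where(obs, Y, 0.0) @ gm0
            Vg = Sgg - Sg * Sg / np.maximum(n, 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(Vg > 0, (Sgy - Sg * Sy / np.maximum(n, 1)) / Vg, np.nan)

        lead_effect = pair["effect"]
        if lead_effect == 0 or not np.isfinite(lead_effect):
            continue
        eff = _effects(g) / lead_effect
        for b, e in zip(bins, eff):
            if np.isfinite(e):
                obs_sum[b] += e
                obs_n[b] += 1
        for r in range(n_permutations):
            gp = g[rng.permutation(len(g))]
            effp = _effects(gp) / lead_effect
            fin = np.isfinite(effp)
            np.add.at(perm_sum[r], bins[fin], effp[fin])
            np.add.at(perm_n[r], bins[fin], 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        obs_mean = np.where(obs_n > 0, obs_sum / obs_n, np.nan)
        perm_mean = np.where(perm_n > 0, perm_sum / perm_n, np.nan)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "observed_mean": obs_mean,
            "n_pairs": obs_n,
            "perm_mean": np.nanmean(perm_mean, axis=0) if n_permutations else np.nan,
            "perm_lo": np.nanpercentile(perm_mean, 2.5, axis=0) if n_permutations else np.nan,
            "perm_hi": np.nanpercentile(perm_mean, 97.5, axis=0) if n_permutations else np.nan,
        }
    )


class SlopeQTLMapper(BaseEstimator):
    """End-to-end slope-QTL scan with variance filter and conditional step.

    Parameters mirror the underlying functions; after ``fit`` the fitted
    attributes are ``candidates_`` (all tested pairs), ``flagged_``
    (variance-QTL exclusions), ``qtls_`` (significant pairs surviving the
    filter) and ``independent_`` (conditional-analysis output).
    """

    def __init__(
        self,
        mode: str = "cis",
        cis_window: int = 1_000_000,
        fdr: float = 0.05,
        min_individuals: int = 30,
        variance_filter: bool = True,
        residual_stat: str = "ss",
    ):
        self.mode = mode
        self.cis_window = cis_window
        self.fdr = fdr
        self.min_individuals = min_individuals
        self.variance_filter = variance_filter
        self.residual_stat = residual_stat

    def fit(self, traj, genotypes: GenotypeSet, cpg_pos: pd.DataFrame):
        slopes = traj.slopes_wide()
        self.candidates_ = map_slope_qtls(
            slopes,
            genotypes,
            cpg_pos,
            mode=self.mode,
            cis_window=self.cis_window,
            fdr=self.fdr,
            min_individuals=self.min_individuals,
        )
        qtls = self.candidates_[self.candidates_["significant"]]
        if self.variance_filter:
            resid = (
                traj.rss_wide() if self.residual_stat == "ss" else traj.abs_resid_wide()
            )
            self.flagged_ = filter_variance_qtls(
                resid,
                genotypes,
                cpg_pos,
                mode=self.mode,
                cis_window=self.cis_window,
                fdr=self.fdr,
                min_individuals=self.min_individuals,
            )
            qtls = exclude_variance_qtls(qtls, self.flagged_)
        else:
            self.flagged_ = pd.DataFrame(columns=["snp_id", "probe_id"])
        self.qtls_ = qtls
        self.independent_ = conditional_analysis(qtls, slopes, genotypes)
        return self
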