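"""Genotype QC, slope-QTL mapping, conditional analysis and validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methtraj import (
    CohortDesign,
    GenotypeSet,
    IndividualTrajectoryFitter,
    SlopeQTLMapper,
    simulate_cohort,
    simulate_truth,
)
from methtraj.qtl import (
    conditional_analysis,
    filter_genotypes,
    filter_variance_qtls,
    hwe_exact_test,
    local_effect_profile,
    map_slope_qtls,
    snp_cpg_proximity,
    validate_interactions,
)

from conftest import SMALL_DESIGN


def _gset(dosage_rows, positions=None, chrom="chr1"):
    snp_ids = [f"rs{i}" for i in range(len(dosage_rows))]
    inds = [f"i{k}" for k in range(len(dosage_rows[0]))]
    dos = pd.DataFrame(dosage_rows, index=pd.Index(snp_ids, name="snp_id"), columns=inds, dtype=float)
    pos = positions if positions is not None else np.arange(len(dosage_rows)) * 1000
    snps = pd.DataFrame({"chrom": chrom, "pos": pos}, index=dos.index)
    return GenotypeSet(dosages=dos, snps=snps)


def _hwe_bruteforce(n2, n1, n0):
    """Direct enumeration oracle using exact rational-ish arithmetic."""
    from math import comb

    n = n2 + n1 + n0
    n_minor = 2 * n2 + n1
    def prob(het):
        hom_min = (n_minor - het) // 2
        hom_maj = n - het - hom_min
        return (
            2**het * comb(n, het) * comb(n - het, hom_min)
        ) / comb(2 * n, n_minor) * comb(n - het - hom_min, hom_maj)

    # normalised probabilities over all feasible het counts
    hets = range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    probs = {h: prob(h) for h in hets}
    total = sum(probs.values())
    probs = {h: p / total for h, p in probs.items()}
    p_obs = probs[n1]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestHWE:
    def test_perfect_proportions_pass(self):
        assert hwe_exact_test(25, 50, 25) > 0.5

    def test_no_heterozygotes_fails(self):
        assert hwe_exact_test(50, 0, 50) < 1e-20

    @pytest.mark.parametrize(
        "counts",
        [(5, 10, 5), (3, 7, 20), (0, 10, 30), (12, 1, 2), (8, 8, 8), (1, 0, 9)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            _hwe_bruteforce(*counts), rel=1e-9
        )

    def test_monomorphic_trivial(self):
        assert hwe_exact_test(0, 0, 100) == 1.0


class TestGenotypeQC:
    def test_hwe_violating_snp_removed(self):
        rng = np.random.default_rng(0)
        good = rng.choice([0, 1, 2], 200, p=[0.25, 0.5, 0.25])
        bad = np.array([0] * 100 + [2] * 100)
        gset = _gset([good, bad])
        out = filter_genotypes(gset)
        assert list(out.dosages.index) == ["rs0"]

    def test_low_call_rate_removed(self):
        rng = np.random.default_rng(1)
        g = rng.choice([0.0, 1.0, 2.0], 200, p=[0.25, 0.5, 0.25])
        g_missing = g.copy()
        g_missing[:6] = np.nan  # call rate 0.97
        out = filter_genotypes(_gset([g, g_missing]))
        assert list(out.dosages.index) == ["rs0"]

    def test_low_maf_removed(self):
        common = np.array([0] * 30 + [1] * 60 + [2] * 30)  # HW at maf 0.5
        rare = np.array([0] * 119 + [1])  # maf ~0.004
        out = filter_genotypes(_gset([common, rare]))
        assert list(out.dosages.index) == ["rs0"]
        assert out.snps.loc["rs0", "maf"] == pytest.approx(0.5)


class TestScan:
    def test_noise_free_effect_recovered(self):
        rng = np.random.default_rng(2)
        g = rng.choice([0.0, 1.0, 2.0], 100, p=[0.49, 0.42, 0.09])
        slopes = pd.DataFrame(
            [0.01 * g], index=pd.Index(["cg0"], name="probe_id"),
            columns=[f"i{k}" for k in range(100)],
        )
        gset = _gset([g], positions=[500])
        pos = pd.DataFrame({"chrom": ["chr1"], "pos": [600]}, index=slopes.index)
        out = map_slope_qtls(slopes, gset, pos)
        assert out.loc[0, "effect"] == pytest.approx(0.01, abs=1e-12)
        assert out.loc[0, "p"] < 1e-30

    def test_t_matches_closed_form_on_toy(self):
        g = np.array([0, 0, 1, 1, 1, 2, 2, 0, 1, 2], float)
        rng = np.random.default_rng(3)
        y = 0.005 * g + rng.normal(0, 0.01, 10)
        slopes = pd.DataFrame([y], index=pd.Index(["cg0"], name="probe_id"),
                              columns=[f"i{k}" for k in range(10)])
        gset = _gset([g], positions=[0])
        pos = pd.DataFrame({"chrom": ["chr1"], "pos": [100]}, index=slopes.index)
        out = map_slope_qtls(slopes, gset, pos, min_individuals=5)
        gm = g - g.mean()
        eff = (gm @ y) / (gm @ gm)
        resid = y - y.mean() - eff * gm
        se = np.sqrt((resid @ resid) / 8 / (gm @ gm))
        assert out.loc[0, "effect"] == pytest.approx(eff, rel=1e-12)
        assert out.loc[0, "t"] == pytest.approx(eff / se, rel=1e-10)

    def test_cis_window_limits_pairs(self):
        rng = np.random.default_rng(4)
        slopes = pd.DataFrame(
            rng.normal(0, 0.01, (3, 50)),
            index=pd.Index(["cg0", "cg1", "cg2"], name="probe_id"),
            columns=[f"i{k}" for k in range(50)],
        )
        g = rng.choice([0.0, 1.0, 2.0], 50)
        gset = _gset([g], positions=[0])
        pos = pd.DataFrame(
            {"chrom": "chr1", "pos": [100, 900_000, 2_000_000]}, index=slopes.index
        )
        out = map_slope_qtls(slopes, gset, pos, min_individuals=10)
        assert set(out["probe_id"]) == {"cg0", "cg1"}
        out_t = map_slope_qtls(slopes, gset, pos, mode="trans", min_individuals=10)
        assert set(out_t["probe_id"]) == {"cg0", "cg1", "cg2"}

    def test_constant_dosage_pair_skipped(self):
        slopes = pd.DataFrame(
            [np.arange(40.0)], index=pd.Index(["cg0"], name="probe_id"),
            columns=[f"i{k}" for k in range(40)],
        )
        gset = _gset([np.ones(40)], positions=[0])
        pos = pd.DataFrame({"chrom": ["chr1"], "pos": [10]}, index=slopes.index)
        out = map_slope_qtls(slopes, gset, pos, min_individuals=10)
        assert len(out) == 0


class TestVarianceFilter:
    def _cohort_with_variance_snp(self, seed=5):
        """One SNP widening slope spread without shifting the mean, one
        SNP with a pure mean effect."""
        rng = np.random.default_rng(seed)
        n = 300
        inds = [f"i{k}" for k in range(n)]
        g_var = rng.choice([0.0, 1.0, 2.0], n, p=[0.25, 0.5, 0.25])
        g_mean = rng.choice([0.0, 1.0, 2.0], n, p=[0.25, 0.5, 0.25])
        rss_var = (0.001 + 0.004 * g_var) * rng.chisquare(2, n)
        rss_null = 0.002 * rng.chisquare(2, n)
        rss = pd.DataFrame(
            [rss_var, rss_null],
            index=pd.Index(["cgV", "cgM"], name="probe_id"), columns=inds
        )
        gset = _gset([g_var, g_mean], positions=[100, 200])
        pos = pd.DataFrame({"chrom": "chr1", "pos": [150, 250]}, index=rss.index)
        return rss, gset, pos

    def test_variance_snp_flagged_mean_snp_not(self):
        rss, gset, pos = self._cohort_with_variance_snp()
        flagged = filter_variance_qtls(rss, gset, pos)
        pairs = set(zip(flagged["snp_id"], flagged["probe_id"]))
        assert ("rs0", "cgV") in pairs
        assert ("rs1", "cgM") not in pairs

    def test_no_genotypes_empty_exclusion(self):
        rss = pd.DataFrame(
            [[0.1, 0.2]], index=pd.Index(["cg0"], name="probe_id"), columns=["i0", "i1"]
        )
        gset = _gset([[0.0, 1.0]], positions=[0])
        gset = GenotypeSet(dosages=gset.dosages.iloc[:0], snps=gset.snps.iloc[:0])
        pos = pd.DataFrame({"chrom": ["chr1"], "pos": [10]}, index=rss.index)
        out = filter_variance_qtls(rss, gset, pos)
        assert len(out) == 0


class TestConditional:
    def _slopes_for(self, effects, n=400, seed=6):
        """effects: list of (dosage_vector, beta) acting on one CpG."""
        rng = np.random.default_rng(seed)
        y = rng.normal(0.0, 0.002, n)
        for g, b in effects:
            y = y + b * g
        inds = [f"i{k}" for k in range(n)]
        return pd.DataFrame([y], index=pd.Index(["cg0"], name="probe_id"), columns=inds)

    def test_perfect_ld_yields_single_independent_pair(self):
        rng = np.random.default_rng(7)
        g = rng.choice([0.0, 1.0, 2.0], 400, p=[0.25, 0.5, 0.25])
        slopes = self._slopes_for([(g, 0.01)])
        gset = _gset([g, g.copy()], positions=[100, 300])
        pos = pd.DataFrame({"chrom": ["chr1"], "pos": [200]}, index=slopes.index)
        qtls = map_slope_qtls(slopes, gset, pos)
        assert qtls["significant"].sum() == 2
        indep = conditional_analysis(qtls, slopes, gset)
        assert len(indep) == 1
        assert indep.iloc[0]["lead"]

    def test_two_unlinked_causal_snps_recovered(self):
        rng = np.random.default_rng(8)
        g1 = rng.choice([0.0, 1.0, 2.0], 400, p=[0.25, 0.5, 0.25])
        g2 = rng.choice([0.0, 1.0, 2.0], 400, p=[0.25, 0.5, 0.25])
        slopes = self._slopes_for([(g1, 0.008), (g2, 0.008)])
        gset = _gset([g1, g2], positions=[100, 5000])
        pos = pd.DataFrame({"chrom": ["chr1"], "pos": [2000]}, index=slopes.index)
        qtls = map_slope_qtls(slopes, gset, pos)
        indep = conditional_analysis(qtls, slopes, gset)
        assert len(indep) == 2
        # independence invariant: selected dosages are not near-collinear
        G = gset.dosages.loc[indep["snp_id"]].to_numpy()
        r = np.corrcoef(G)[0, 1]
        assert abs(r) <= 0.95

    def test_single_snp_is_lead(self):
        rng = np.random.default_rng(9)
        g = rng.choice([0.0, 1.0, 2.0], 400, p=[0.25, 0.5, 0.25])
        slopes = self._slopes_for([(g, 0.01)])
        gset = _gset([g], positions=[100])
        pos = pd.DataFrame({"chrom": ["chr1"], "pos": [200]}, index=slopes.index)
        qtls = map_slope_qtls(slopes, gset, pos)
        indep = conditional_analysis(qtls, slopes, gset)
        assert len(indep) == 1 and indep.iloc[0]["lead"]


class TestInteractions:
    def test_balanced_noise_free_identity(self):
        """On balanced noise-free data the pooled age x genotype
        interaction equals the slope-on-dosage regression effect exactly."""
        from methtraj.datatypes import LongitudinalBetaSet

        ages = np.array([68.0, 72.0, 76.0, 79.0])
        rng = np.random.default_rng(10)
        n = 60
        g = rng.choice([0.0, 1.0, 2.0], n, p=[0.25, 0.5, 0.25])
        beta_eff = 0.004
        rows, sample_rows = [], []
        for i in range(n):
            slope = 0.002 + beta_eff * g[i]
            for w, a in enumerate(ages):
                sample_rows.append(
                    {"sample_id": f"i{i}_w{w}", "individual_id": f"i{i}",
                     "wave": w + 1, "age_years": a, "sex": "F"}
                )
                rows.append(0.3 + slope * (a - 70.0))
        samples = pd.DataFrame(sample_rows).set_index("sample_id")
        betas = pd.DataFrame(
            np.asarray(rows).reshape(n * 4)[None, :],
            index=pd.Index(["cg0"], name="probe_id"), columns=samples.index,
        )
        bset = LongitudinalBetaSet(betas=betas, samples=samples)
        gset = _gset([g], positions=[0])
        pairs = pd.DataFrame(
            {"snp_id": ["rs0"], "probe_id": ["cg0"], "effect": [beta_eff]}
        )
        out = validate_interactions(bset, gset, pairs)
        assert out.loc[0, "interaction_effect"] == pytest.approx(beta_eff, abs=1e-10)

    def test_null_pairs_rarely_validated(self, small_cohort, small_traj):
        rng = np.random.default_rng(11)
        n_ind = len(small_cohort.betas.individuals)
        g = [rng.choice([0.0, 1.0, 2.0], n_ind, p=[0.36, 0.48, 0.16]) for _ in range(30)]
        gset = GenotypeSet(
            dosages=pd.DataFrame(
                g, index=pd.Index([f"rs{i}" for i in range(30)], name="snp_id"),
                columns=small_cohort.betas.individuals,
            ),
            snps=pd.DataFrame(
                {"chrom": "chr1", "pos": np.arange(30) * 100},
                index=pd.Index([f"rs{i}" for i in range(30)], name="snp_id"),
            ),
        )
        pairs = pd.DataFrame(
            {"snp_id": [f"rs{i}" for i in range(30)],
             "probe_id": list(small_cohort.betas.betas.index[:30]),
             "effect": np.zeros(30)}
        )
        out = validate_interactions(small_cohort.betas, gset, pairs)
        assert out["validated"].mean() <= 0.2


class TestProximity:
    def test_snp_on_and_near_dyad(self):
        seq = "A" * 100 + "CG" + "A" * 100
        snps = pd.DataFrame(
            {"chrom": "c", "pos": [100, 101, 99, 103, 150]},
            index=pd.Index([f"rs{i}" for i in range(5)], name="snp_id"),
        )
        out = snp_cpg_proximity(snps, ["rs0"], {"c": seq})
        assert out.loc["rs0", "distance"] == 0  # on the C
        assert out.loc["rs1", "distance"] == 0  # on the G
        assert out.loc["rs2", "distance"] == 1  # adjacent 5'
        assert out.loc["rs3", "distance"] == 2
        assert out.loc["rs4", "distance"] == 49

    def test_matches_bruteforce_nearest_scan(self):
        import re

        rng = np.random.default_rng(12)
        seq = "".join(rng.choice(list("ACGT"), 30000))
        cg = [m.start() for m in re.finditer("CG", seq)]
        pos = rng.integers(0, len(seq), 300)
        snps = pd.DataFrame(
            {"chrom": "c", "pos": pos},
            index=pd.Index([f"rs{i}" for i in range(300)], name="snp_id"),
        )
        out = snp_cpg_proximity(snps, [], {"c": seq})
        for rs, p in zip(snps.index, pos):
            brute = min(min(abs(p - c), abs(p - (c + 1))) for c in cg)
            assert out.loc[rs, "distance"] == brute


class TestLocalEffectProfile:
    def test_lead_bin_is_one_and_neighbors_half(self):
        rng = np.random.default_rng(13)
        n = 300
        inds = [f"i{k}" for k in range(n)]
        g = rng.choice([0.0, 1.0, 2.0], n, p=[0.25, 0.5, 0.25])
        lead_eff = 0.01
        slopes = pd.DataFrame(
            [lead_eff * g + rng.normal(0, 1e-4, n),
             0.5 * lead_eff * g + rng.normal(0, 1e-4, n),
             0.5 * lead_eff * g + rng.normal(0, 1e-4, n)],
            index=pd.Index(["cgL", "cgA", "cgB"], name="probe_id"), columns=inds,
        )
        gset = _gset([g], positions=[5000])
        cpg_pos = pd.DataFrame(
            {"chrom": "chr1", "pos": [5000, 5210, 4490]}, index=slopes.index
        )
        gm = g - g.mean()
        eff = (gm @ slopes.loc["cgL"].to_numpy()) / (gm @ gm)
        pairs = pd.DataFrame({"snp_id": ["rs0"], "probe_id": ["cgL"], "effect": [eff]})
        prof = local_effect_profile(
            pairs, slopes, gset, cpg_pos, n_permutations=50, seed=0
        )
        own = prof[(prof["bin_left"] <= 0) & (prof["bin_right"] > 0)]
        assert own["observed_mean"].iloc[0] == pytest.approx(1.0, abs=0.01)
        right = prof[(prof["bin_left"] == 200)]
        assert right["observed_mean"].iloc[0] == pytest.approx(0.5, abs=0.05)
        # permutation null is centred near zero away from the lead
        null_bins = prof[np.isfinite(prof["perm_mean"]) & (prof["bin_left"] != 0)]
        assert np.abs(null_bins["perm_mean"]).max() < 0.2


class TestMapperEndToEnd:
    def test_recovers_designated_qtls(self):
        rng = np.random.default_rng(14)
        truth = simulate_truth(
            n_cpgs=40, n_snps=80, n_qtls=15, qtl_effect_range=(0.005, 0.01),
            sigma_s=0.002, seed=rng,
        )
        cohort = simulate_cohort(CohortDesign(), truth, seed=rng)
        fit = IndividualTrajectoryFitter(age_ref=70.0).fit(cohort.betas)
        mapper = SlopeQTLMapper().fit(
            fit.trajectories_, cohort.genotypes, truth.cpgs[["chrom", "pos"]]
        )
        true_pairs = set(zip(truth.qtls["snp_id"], truth.qtls["probe_id"]))
        found = set(zip(mapper.qtls_["snp_id"], mapper.qtls_["probe_id"]))
        assert len(true_pairs & found) >= 0.8 * len(true_pairs)
        leads = mapper.independent_[mapper.independent_["lead"]]
        assert len(leads) >= 0.8 * len(true_pairs)
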