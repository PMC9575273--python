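"""Synthetic longitudinal methylation cohort with known ground truth.

Emulates the design of a four-wave birth-cohort methylation study: 600
individuals sampled at mean ages 69.6, 72.6, 76.3 and 79.3 years, 351 of
whom have all four measurements and 249 three. Per CpG the generative
model is

    beta_ijt = clamp(b0_j + u_ij + s_ij * (age_it - age_ref) + c_j . p_it
                     + eps_ijt, 0, 1)

with per-individual random intercepts u_ij ~ N(0, tau_j^2), per-individual
slopes s_ij = m_j + beta_j * G_ij' + N(0, sigma_s_j^2) where G is the
minor-allele dosage at the CpG's designated causal SNP (if any),
cell-loading terms c_j . p_it for the sample's cell-type proportions, and
i.i.d. measurement noise. Genotypes are drawn at Hardy-Weinberg
proportions; cell proportions follow a softmax of linear-in-age latents so
they stay on the simplex while drifting approximately linearly.

All quantities used to generate the data are returned in a
:class:`TruthTable` so downstream estimators can be tested for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import (
    MEASURED_CELL_TYPES,
    AnnotationSet,
    GenotypeSet,
    LongitudinalBetaSet,
)

AGE_REF = 70.0  # years; intercepts are parameterised at study entry

# Softmax latent baselines giving realistic blood proportions
# (~57% neutrophils, ~31% lymphocytes, ~7% monocytes, ~3.5% eos, ~1.3% baso)
_CELL_LATENT_BASE = np.array([3.8, 3.2, 1.7, 1.0, 0.0])


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design of the longitudinal cohort.

    ``missing_wave_counts[w]`` is the number of three-wave individuals whose
    missing measurement is wave ``w``; the default reproduces the per-wave
    observation totals 560/578/551/462 of the emulated study.
    """

    n_individuals: int = 600
    wave_mean_ages: tuple = (69.6, 72.6, 76.3, 79.3)
    wave_age_sd: float = 0.8
    n_four_wave: int = 351
    missing_wave_counts: tuple = (40, 22, 49, 138)
    age_ref: float = AGE_REF

    def validate(self) -> None:
        ages = np.asarray(self.wave_mean_ages, float)
        if ages.ndim != 1 or len(ages) < 3:
            raise ValueError("need at least 3 waves")
        if not np.all(np.diff(ages) > 0):
            raise ValueError("wave_mean_ages must be strictly increasing")
        if not 0 <= self.n_four_wave <= self.n_individuals:
            raise ValueError("n_four_wave out of range")
        n_three = self.n_individuals - self.n_four_wave
        if len(self.missing_wave_counts) != len(ages):
            raise ValueError("missing_wave_counts must have one entry per wave")
        if sum(self.missing_wave_counts) != n_three:
            raise ValueError(
                "missing_wave_counts must sum to the number of 3-wave individuals"
            )
        if self.wave_age_sd < 0:
            raise ValueError("wave_age_sd must be >= 0")

    @property
    def n_waves(self) -> int:
        return len(self.wave_mean_ages)


@dataclass
class TruthTable:
    """Ground-truth parameters of a simulated cohort.

    ``cpgs`` is indexed by probe_id with columns chrom, pos, b0 (baseline
    beta at the reference age), slope (mean beta/year), tau
    (random-intercept sd), sigma_s (slope-noise sd) and one
    ``load_<cell type>`` column per cell type. ``snps`` is indexed by
    snp_id with chrom, pos, maf. ``qtls`` maps causal SNPs to CpGs with a
    per-minor-allele slope effect (beta/year/allele).
    """

    cpgs: pd.DataFrame
    snps: pd.DataFrame
    qtls: pd.DataFrame
    sigma_e: float = 0.01
    cell_types: tuple = MEASURED_CELL_TYPES
    cell_drift_sd: float = 0.02  # sd of per-individual latent drift (per year)
    cell_noise_sd: float = 0.05  # sd of per-sample latent jitter

    def validate(self) -> None:
        for col in ("b0", "slope", "tau", "sigma_s"):
            if col not in self.cpgs.columns:
                raise ValueError(f"truth table missing column {col}")
        if (self.cpgs[["tau", "sigma_s"]].to_numpy() < 0).any():
            raise ValueError("tau and sigma_s must be >= 0")
        if self.sigma_e < 0:
            raise ValueError("sigma_e must be >= 0")
        if ((self.cpgs["b0"] < 0) | (self.cpgs["b0"] > 1)).any():
            raise ValueError("b0 must lie in [0, 1]")
        if len(self.qtls):
            if not self.qtls["probe_id"].isin(self.cpgs.index).all():
                raise ValueError("qtls reference unknown probes")
            if not self.qtls["snp_id"].isin(self.snps.index).all():
                raise ValueError("qtls reference unknown SNPs")
        if len(self.snps):
            maf = self.snps["maf"].to_numpy(float)
            if (maf <= 0).any() or (maf > 0.5).any():
                raise ValueError("MAF must lie in (0, 0.5]")


@dataclass
class SimulatedCohort:
    """Everything a downstream stage can consume, plus the truth."""

    betas: LongitudinalBetaSet
    genotypes: GenotypeSet
    truth: TruthTable
    cell_proportions: pd.DataFrame  # true per-sample simplex proportions
    slopes_true: pd.DataFrame  # probe x individual realised slopes s_ij


def simulate_truth(
    n_cpgs: int = 2000,
    n_snps: int = 0,
    n_qtls: int = 0,
    qtl_effect_range: tuple = (0.002, 0.01),
    qtl_maf_range: tuple = (0.1, 0.4),
    maf_range: tuple = (0.05, 0.5),
    mean_slope_sd: float = 0.003,
    tau: float = 0.03,
    sigma_s: float = 0.002,
    sigma_e: float = 0.01,
    cell_loading_sd: float = 0.0,
    cpg_spacing: int = 5000,
    qtl_max_distance: int = 10_000,
    chrom: str = "chr1",
    seed: int | np.random.Generator = 0,
) -> TruthTable:
    """Draw a ground-truth parameter table on a synthetic chromosome layout.

    CpGs are placed every ``cpg_spacing`` bp on one chromosome. Each of the
    first ``n_qtls`` CpGs gets one designated causal SNP within
    ``qtl_max_distance`` bp; remaining SNPs are scattered between CpGs.
    ``sigma_s`` and ``tau`` may be scalars or per-CpG arrays.
    """
    rng = np.random.default_rng(seed)
    if n_cpgs <= 0:
        raise ValueError("n_cpgs must be positive")
    if n_qtls > n_cpgs or n_qtls > n_snps:
        raise ValueError("n_qtls cannot exceed n_cpgs or n_snps")

    probe_ids = [f"cg{j:08d}" for j in range(n_cpgs)]
    pos = 1000 + cpg_spacing * np.arange(n_cpgs)
    cpgs = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "b0": rng.uniform(0.08, 0.92, n_cpgs),
            "slope": rng.normal(0.0, mean_slope_sd, n_cpgs),
            "tau": np.broadcast_to(np.asarray(tau, float), (n_cpgs,)).copy(),
            "sigma_s": np.broadcast_to(np.asarray(sigma_s, float), (n_cpgs,)).copy(),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    for ct in MEASURED_CELL_TYPES:
        cpgs[f"load_{ct}"] = (
            rng.normal(0.0, cell_loading_sd, n_cpgs) if cell_loading_sd > 0 else 0.0
        )

    snp_ids = [f"rs{k:08d}" for k in range(n_snps)]
    snp_pos = np.empty(n_snps, dtype=int)
    maf = rng.uniform(*maf_range, n_snps)
    qtls = pd.DataFrame(columns=["snp_id", "probe_id", "effect"])
    if n_qtls:
        offs = rng.integers(-qtl_max_distance, qtl_max_distance + 1, n_qtls)
        snp_pos[:n_qtls] = np.maximum(0, pos[:n_qtls] + offs)
        maf[:n_qtls] = rng.uniform(*qtl_maf_range, n_qtls)
        effects = rng.uniform(*qtl_effect_range, n_qtls) * rng.choice(
            [-1.0, 1.0], n_qtls
        )
        qtls = pd.DataFrame(
            {
                "snp_id": snp_ids[:n_qtls],
                "probe_id": probe_ids[:n_qtls],
                "effect": effects,
            }
        )
    if n_snps > n_qtls:
        lo, hi = 0, int(pos[-1]) + cpg_spacing
        snp_pos[n_qtls:] = rng.integers(lo, hi, n_snps - n_qtls)
    snps = pd.DataFrame(
        {"chrom": chrom, "pos": snp_pos, "maf": maf},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    truth = TruthTable(cpgs=cpgs, snps=snps, qtls=qtls, sigma_e=sigma_e)
    truth.validate()
    return truth


def _draw_sample_sheet(design: CohortDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Sample sheet with per-individual strictly increasing wave ages."""
    n = design.n_individuals
    n_waves = design.n_waves
    present = np.ones((n, n_waves), dtype=bool)
    # first n_four_wave individuals keep all waves; the rest drop one wave
    # according to missing_wave_counts (assignment order is deterministic)
    i = design.n_four_wave
    for wave, count in enumerate(design.missing_wave_counts):
        present[i : i + count, wave] = False
        i += count

    means = np.asarray(design.wave_mean_ages, float)
    ages = means[None, :] + rng.normal(0.0, design.wave_age_sd, (n, n_waves))
    # enforce strictly increasing ages within an individual (the means are
    # ~3 years apart so this rarely binds at sd 0.8)
    for w in range(1, n_waves):
        ages[:, w] = np.maximum(ages[:, w], ages[:, w - 1] + 0.05)

    sexes = rng.choice(["F", "M"], n)
    rows = []
    for ind in range(n):
        iid = f"ind{ind:04d}"
        for w in range(n_waves):
            if not present[ind, w]:
                continue
            rows.append(
                {
                    "sample_id": f"{iid}_w{w + 1}",
                    "individual_id": iid,
                    "wave": w + 1,
                    "age_years": round(float(ages[ind, w]), 3),
                    "sex": sexes[ind],
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def _simulate_genotypes(
    snps: pd.DataFrame, individuals: list, rng: np.random.Generator
) -> GenotypeSet:
    """Minor-allele dosages at Hardy-Weinberg proportions for each SNP."""
    n_ind = len(individuals)
    maf = snps["maf"].to_numpy(float)
    # two independent allele draws per individual
    alleles = rng.random((len(maf), n_ind, 2)) < maf[:, None, None]
    dosages = alleles.sum(axis=2).astype(float)
    dos = pd.DataFrame(dosages, index=snps.index, columns=individuals)
    return GenotypeSet(dosages=dos, snps=snps.copy())


def _simulate_cell_proportions(
    samples: pd.DataFrame,
    truth: TruthTable,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simplex-valued proportions drifting linearly with age per individual."""
    k = len(truth.cell_types)
    inds = samples["individual_id"].unique()
    base = _CELL_LATENT_BASE[:k] + rng.normal(0.0, 0.15, (len(inds), k))
    drift = rng.normal(0.0, truth.cell_drift_sd, (len(inds), k))
    base_df = pd.DataFrame(base, index=inds)
    drift_df = pd.DataFrame(drift, index=inds)

    age_c = samples["age_years"].to_numpy(float) - AGE_REF
    z = (
        base_df.loc[samples["individual_id"]].to_numpy()
        + drift_df.loc[samples["individual_id"]].to_numpy() * age_c[:, None]
        + rng.normal(0.0, truth.cell_noise_sd, (len(samples), k))
    )
    ez = np.exp(z - z.max(axis=1, keepdims=True))
    props = ez / ez.sum(axis=1, keepdims=True)
    return pd.DataFrame(props, index=samples.index, columns=list(truth.cell_types))


def simulate_cohort(
    design: CohortDesign,
    truth: TruthTable,
    seed: int | np.random.Generator = 0,
) -> SimulatedCohort:
    """Generate betas, genotypes and cell counts under the truth table.

    Fully reproducible from ``seed``; re-running with the same design,
    truth and seed yields bit-identical outputs.
    """
    design.validate()
    truth.validate()
    rng = np.random.default_rng(seed)

    samples = _draw_sample_sheet(design, rng)
    individuals = list(samples["individual_id"].unique())
    n_ind = len(individuals)
    n_cpgs = len(truth.cpgs)

    genotypes = _simulate_genotypes(truth.snps, individuals, rng)

    tau = truth.cpgs["tau"].to_numpy(float)
    sig_s = truth.cpgs["sigma_s"].to_numpy(float)
    b0 = truth.cpgs["b0"].to_numpy(float)
    m = truth.cpgs["slope"].to_numpy(float)

    # per-(CpG, individual) random intercepts and slopes
    u = rng.normal(0.0, 1.0, (n_cpgs, n_ind)) * tau[:, None]
    s = m[:, None] + rng.normal(0.0, 1.0, (n_cpgs, n_ind)) * sig_s[:, None]
    if len(truth.qtls):
        probe_loc = truth.cpgs.index.get_indexer(truth.qtls["probe_id"])
        dos = genotypes.dosages.loc[truth.qtls["snp_id"], individuals].to_numpy(float)
        s[probe_loc, :] += truth.qtls["effect"].to_numpy(float)[:, None] * dos

    props = _simulate_cell_proportions(samples, truth, rng)
    load = truth.cpgs[[f"load_{ct}" for ct in truth.cell_types]].to_numpy(float)
    cell_term = load @ props.to_numpy(float).T  # n_cpgs x n_samples

    ind_idx = pd.Index(individuals).get_indexer(samples["individual_id"])
    age_c = samples["age_years"].to_numpy(float) - design.age_ref

    betas = (
        b0[:, None]
        + u[:, ind_idx]
        + s[:, ind_idx] * age_c[None, :]
        + cell_term
    )
    if truth.sigma_e > 0:
        betas = betas + rng.normal(0.0, truth.sigma_e, betas.shape)
    np.clip(betas, 0.0, 1.0, out=betas)

    beta_df = pd.DataFrame(betas, index=truth.cpgs.index, columns=samples.index)

    # record measured cell counts (10^9 cells/L) alongside the sample sheet
    total = rng.normal(6.5, 1.2, len(samples)).clip(3.0, 12.0)
    counts = props.to_numpy() * total[:, None]
    sheet = samples.copy()
    for k, ct in enumerate(truth.cell_types):
        sheet[ct] = np.round(counts[:, k], 4)

    slopes_true = pd.DataFrame(s, index=truth.cpgs.index, columns=individuals)
    return SimulatedCohort(
        betas=LongitudinalBetaSet(betas=beta_df, samples=sheet),
        genotypes=genotypes,
        truth=truth,
        cell_proportions=props,
        slopes_true=slopes_true,
    )


# ---------------------------------------------------------------------------
# Synthetic genome + annotation


@dataclass
class SyntheticGenome:
    """A/C/G/T chromosome sequences with a CpG manifest.

    Every manifest position carries a forward-strand "CG" at that 0-based
    offset. Region labels record which positions fall in dense
    (island-like) blocks.
    """

    sequences: dict
    manifest: pd.DataFrame  # probe_id -> chrom, pos (0-based position of the C)
    dense_blocks: pd.DataFrame  # chrom, start, end of island-like blocks

    def validate(self) -> None:
        for probe, row in self.manifest.iterrows():
            seq = self.sequences[row["chrom"]]
            if seq[row["pos"] : row["pos"] + 2] != "CG":
                raise AssertionError(f"{probe}: no CG dyad at {row['chrom']}:{row['pos']}")


def _random_background(length: int, rng: np.random.Generator) -> np.ndarray:
    """CpG-free background sequence (so density is fully controlled)."""
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), length)
    # break any accidental CG dyads
    arr = seq.copy()
    for _ in range(4):
        is_c = arr[:-1] == b"C"
        is_g = arr[1:] == b"G"
        hit = np.flatnonzero(is_c & is_g)
        if not hit.size:
            break
        arr[hit + 1] = b"A"
    return arr


def simulate_genome_annotation(
    n_cpgs: int = 200,
    dense_fraction: float = 0.3,
    dense_spacing: int = 10,
    sparse_spacing: int = 800,
    dense_block_size: int = 30,
    chrom: str = "chr1",
    flank: int = 2000,
    seed: int | np.random.Generator = 0,
) -> tuple[SyntheticGenome, AnnotationSet]:
    """Build a small genome with CpG-dense (island-like) and sparse blocks.

    Dense blocks hold ``dense_block_size`` CpGs spaced ``dense_spacing`` bp
    apart; the remaining CpGs sit isolated ``sparse_spacing`` bp apart in
    otherwise CpG-free sequence, so the true local density of any position
    is computable by exhaustively scanning the returned string. CGI
    intervals cover the dense blocks; simple gene/TSS, PMD/HMD and
    chromatin-state tracks are laid over alternating halves.
    """
    if n_cpgs <= 0:
        raise ValueError("n_cpgs must be positive")
    rng = np.random.default_rng(seed)

    n_dense = int(round(n_cpgs * dense_fraction))
    positions: list[int] = []
    dense_blocks: list[tuple[int, int]] = []
    cursor = flank
    remaining_dense = n_dense
    while remaining_dense > 0:
        take = min(dense_block_size, remaining_dense)
        block_pos = [cursor + dense_spacing * i for i in range(take)]
        positions.extend(block_pos)
        dense_blocks.append((block_pos[0] - 50, block_pos[-1] + 2 + 50))
        cursor = block_pos[-1] + sparse_spacing
        remaining_dense -= take
    for _ in range(n_cpgs - n_dense):
        positions.append(cursor)
        cursor += sparse_spacing
    length = cursor + flank

    arr = _random_background(length, rng)
    pos_arr = np.asarray(positions)
    arr[pos_arr] = b"C"
    arr[pos_arr + 1] = b"G"
    seq = arr.tobytes().decode("ascii")

    manifest = pd.DataFrame(
        {"chrom": chrom, "pos": pos_arr},
        index=pd.Index([f"cg{j:08d}" for j in range(n_cpgs)], name="probe_id"),
    )
    genome = SyntheticGenome(
        sequences={chrom: seq},
        manifest=manifest,
        dense_blocks=pd.DataFrame(
            [(chrom, s, e) for s, e in dense_blocks],
            columns=["chrom", "start", "end"],
        ),
    )

    cgi = genome.dense_blocks.copy()
    cgi["name"] = "CGI"
    half = length // 2
    genes = pd.DataFrame(
        {"chrom": [chrom], "start": [half], "end": [length - flank], "name": ["geneA"]}
    )
    tss = pd.DataFrame(
        {"chrom": [chrom], "start": [half], "end": [half + 1], "name": ["geneA"]}
    )
    pmd = pd.DataFrame(
        {
            "chrom": [chrom, chrom],
            "start": [0, half],
            "end": [half, length],
            "name": ["PMD", "HMD"],
        }
    )
    chromhmm = pd.DataFrame(
        {
            "chrom": [chrom, chrom],
            "start": [0, half],
            "end": [half, length],
            "name": ["Quies", "Tx"],
        }
    )
    ann = AnnotationSet(cgi=cgi, tss=tss, genes=genes, pmd=pmd, chromhmm=chromhmm)
    return genome, ann


def simulate_reference_profiles(
    k_cell_types: int = 6,
    n_cpgs: int = 200,
    n_discriminating: int | None = None,
    n_mixtures: int = 20,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cell-type beta reference profiles plus mixtures of known composition.

    Returns ``(reference, mixtures, weights)``: reference is CpG x cell
    type, mixtures is CpG x sample, weights is sample x cell type (rows on
    the simplex). Discriminating CpGs are near 0/1 in exactly one cell
    type so the profiles are well separated.
    """
    if k_cell_types < 2:
        raise ValueError("need at least 2 cell types")
    rng = np.random.default_rng(seed)
    n_disc = n_discriminating if n_discriminating is not None else n_cpgs // 2
    if n_disc > n_cpgs:
        raise ValueError("n_discriminating cannot exceed n_cpgs")

    probes = pd.Index([f"cg{j:08d}" for j in range(n_cpgs)], name="probe_id")
    cell_names = [f"cell{t}" for t in range(k_cell_types)]
    ref = rng.uniform(0.3, 0.7, (n_cpgs, k_cell_types))
    for j in range(n_disc):
        t = j % k_cell_types
        ref[j, :] = rng.uniform(0.85, 0.98)
        ref[j, t] = rng.uniform(0.02, 0.12)
    reference = pd.DataFrame(ref, index=probes, columns=cell_names)

    w = rng.dirichlet(np.ones(k_cell_types), n_mixtures)
    mix = ref @ w.T
    if noise_sd > 0:
        mix = mix + rng.normal(0.0, noise_sd, mix.shape)
    mix = np.clip(mix, 0.0, 1.0)
    samples = [f"mix{s:03d}" for s in range(n_mixtures)]
    mixtures = pd.DataFrame(mix, index=probes, columns=samples)
    weights = pd.DataFrame(w, index=samples, columns=cell_names)
    return reference, mixtures, weights
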