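"""Core in-memory containers shared across the pipeline.

The unit of all trajectory analysis is a beta-value matrix (CpG probes x
samples, values in [0, 1]) joined to a sample sheet keyed by
(individual, wave, age). Genotypes are an additive minor-allele dosage
matrix (SNP x individual) with per-SNP QC metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: column names required in a sample sheet
SAMPLE_SHEET_COLUMNS = ("individual_id", "wave", "age_years", "sex")

#: directly measured white-blood-cell types (Sysmex-style differential)
MEASURED_CELL_TYPES = (
    "neutrophils",
    "lymphocytes",
    "monocytes",
    "eosinophils",
    "basophils",
)


@dataclass
class LongitudinalBetaSet:
    """Beta matrix plus sample sheet.

    Parameters
    ----------
    betas
        DataFrame indexed by probe_id with one column per sample_id.
        Values are Infinium-style beta values in [0, 1]; missing
        (detection-p masked) values are NaN.
    samples
        DataFrame indexed by sample_id with at least the columns
        ``individual_id``, ``wave``, ``age_years`` and ``sex``; cell-count
        columns are optional.
    """

    betas: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if not self.betas.columns.isin(self.samples.index).all():
            extra = self.betas.columns.difference(self.samples.index)
            raise ValueError(f"beta columns not in sample sheet: {list(extra)[:5]}")
        # keep sample sheet aligned to the beta columns
        self.samples = self.samples.loc[self.betas.columns]

    @property
    def n_probes(self) -> int:
        return self.betas.shape[0]

    @property
    def n_samples(self) -> int:
        return self.betas.shape[1]

    @property
    def individuals(self) -> np.ndarray:
        return self.samples["individual_id"].unique()

    def ages(self) -> pd.Series:
        return self.samples["age_years"]

    def groupby_individual(self):
        """Yield (individual_id, sample_ids, ages) in sample-sheet order."""
        for ind, sub in self.samples.groupby("individual_id", sort=True):
            yield ind, sub.index.to_numpy(), sub["age_years"].to_numpy(float)

    def with_betas(self, betas: pd.DataFrame) -> "LongitudinalBetaSet":
        """Return a copy carrying a replacement beta matrix (same samples)."""
        return LongitudinalBetaSet(betas=betas, samples=self.samples.copy())


@dataclass
class GenotypeSet:
    """SNP x individual additive dosage matrix with per-SNP QC metadata.

    ``dosages`` is indexed by snp_id with one column per individual_id;
    entries count minor alleles (0/1/2) with NaN for missing calls.
    ``snps`` is indexed by snp_id with columns ``chrom``, ``pos`` (0-based),
    ``ref``, ``alt`` and, after QC, ``maf``, ``call_rate``, ``hwe_p``.
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.index.equals(self.snps.index):
            self.snps = self.snps.loc[self.dosages.index]
        arr = self.dosages.to_numpy(float)
        bad = arr[~np.isnan(arr)]
        if bad.size and (bad.min() < 0 or bad.max() > 2):
            raise ValueError("dosages must lie in {0, 1, 2} or NaN")

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[0]

    @property
    def individuals(self) -> pd.Index:
        return self.dosages.columns


@dataclass
class TrajectoryTable:
    """Per-(CpG, individual) linear trajectory fits plus per-CpG summaries.

    ``fits`` is a long DataFrame with columns probe_id, individual_id,
    slope (beta/year), intercept (beta at the reference age), rss,
    abs_resid (sum of absolute residuals) and n_points. ``mean_beta`` is a
    per-probe Series of the mean beta across every observation used.
    """

    fits: pd.DataFrame
    mean_beta: pd.Series
    age_ref: float = 0.0
    n_skipped_pairs: int = 0

    def slopes_wide(self) -> pd.DataFrame:
        """probe x individual matrix of slopes (NaN where pair was dropped)."""
        return self.fits.pivot(index="probe_id", columns="individual_id", values="slope")

    def rss_wide(self) -> pd.DataFrame:
        return self.fits.pivot(index="probe_id", columns="individual_id", values="rss")

    def abs_resid_wide(self) -> pd.DataFrame:
        return self.fits.pivot(
            index="probe_id", columns="individual_id", values="abs_resid"
        )


@dataclass
class AnnotationSet:
    """Half-open genomic interval annotations for CpG characterisation.

    Each attribute is a BED-like DataFrame with columns
    ``chrom``, ``start`` (0-based), ``end`` (exclusive) and, where
    relevant, ``name`` carrying the label (e.g. a ChromHMM state).
    """

    cgi: pd.DataFrame = field(default_factory=pd.DataFrame)
    tss: pd.DataFrame = field(default_factory=pd.DataFrame)
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    pmd: pd.DataFrame = field(default_factory=pd.DataFrame)
    chromhmm: pd.DataFrame = field(default_factory=pd.DataFrame)
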