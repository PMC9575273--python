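"""End-to-end orchestration of the trajectory pipeline from one config.

Stages run in dependency order: simulate (optional) -> fit -> cellcomp
(optional) -> rapidgain -> annotate -> qtl -> variance. Every output
table carries a provenance header (stage, config hash, seed); a rerun
with an identical config and seed is bit-identical. A stage failure
halts the run, leaving earlier outputs plus a machine-readable
``error.json`` in place.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, cellcomp, io, qtl, rapid_gain, trajectory, variance
from .simulate import (
    CohortDesign,
    simulate_cohort,
    simulate_genome_annotation,
    simulate_truth,
)

DEFAULT_THRESHOLDS = {
    "min_points": 3,
    "alpha_slopes": 0.01,
    "alpha_cellmodel": 0.01,
    "bin_width": 0.0005,
    "rapid_gain_threshold": None,
    "density_half_width": 300,
    "cis_window": 1_000_000,
    "qtl_fdr": 0.05,
    "n_permutations": 100,
    "variance_bins": 20,
    "age_ref": 70.0,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-serialisable)."""

    out_dir: str
    seed: int = 0
    stages: dict = field(default_factory=dict)  # stage -> bool
    thresholds: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)  # generator parameters
    inputs: dict = field(default_factory=dict)  # paths when not simulating

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def threshold(self, key):
        if key in self.thresholds:
            return self.thresholds[key]
        return DEFAULT_THRESHOLDS[key]

    def stage_enabled(self, name: str, default: bool = True) -> bool:
        return bool(self.stages.get(name, default))

    def as_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "stages": self.stages,
            "thresholds": self.thresholds,
            "simulate": self.simulate,
            "inputs": self.inputs,
        }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns a report dict (also written
    as ``report.json`` in the run directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.as_dict()
    cfg.pop("out_dir")  # the hash identifies the analysis, not its location
    report: dict = {"seed": config.seed, "thresholds": {}, "stages": {}}
    for key in DEFAULT_THRESHOLDS:
        report["thresholds"][key] = config.threshold(key)
    prov = dict(config=cfg, seed=config.seed)

    try:
        # --- inputs ----------------------------------------------------
        genome = None
        density = None
        cpg_pos = None
        if config.stage_enabled("simulate", default=bool(config.simulate)):
            sim_params = dict(config.simulate)
            design_keys = {
                k: sim_params.pop(k)
                for k in list(sim_params)
                if k in CohortDesign.__dataclass_fields__
            }
            design = CohortDesign(**design_keys)
            rng = np.random.default_rng(config.seed)
            truth = simulate_truth(seed=rng, **sim_params)
            cohort = simulate_cohort(design, truth, seed=rng)
            bset, genotypes = cohort.betas, cohort.genotypes
            genome, ann = simulate_genome_annotation(
                n_cpgs=len(truth.cpgs), seed=np.random.default_rng(config.seed + 1)
            )
            # reuse the layout of the truth table for positions
            cpg_pos = truth.cpgs[["chrom", "pos"]]
            io.write_beta_tsv(bset.betas, out / "betas.tsv", stage="simulate", **prov)
            io.write_sample_sheet(bset.samples, out / "samples.csv")
            io.write_dosage_tsv(genotypes, out / "dosages.tsv", out / "snps.tsv")
            io.write_table(truth.cpgs, out / "truth_cpgs.tsv", stage="simulate", **prov)
            if len(truth.qtls):
                io.write_table(
                    truth.qtls, out / "truth_qtls.tsv", stage="simulate", index=False, **prov
                )
            io.write_fasta(genome.sequences, out / "genome.fa")
            for name in ("cgi", "tss", "genes", "pmd", "chromhmm"):
                annotation.write_bed(getattr(ann, name), out / f"{name}.bed")
            report["stages"]["simulate"] = {
                "n_cpgs": int(bset.n_probes),
                "n_samples": int(bset.n_samples),
                "n_snps": int(genotypes.n_snps),
            }
        else:
            bset = io.load_beta_set(
                config.inputs["betas"],
                config.inputs["samples"],
                config.inputs.get("exclude_probes"),
            )
            genotypes = None
            if "dosages" in config.inputs:
                genotypes = io.read_dosage_tsv(
                    config.inputs["dosages"], config.inputs["snps"]
                )
            elif "vcf" in config.inputs:
                genotypes = io.read_vcf(config.inputs["vcf"])
            if "manifest" in config.inputs:
                cpg_pos = io.read_manifest(config.inputs["manifest"])
            if "genome" in config.inputs:
                genome = config.inputs["genome"]

        # --- cell-composition correction (before fitting, optional) ----
        if config.stage_enabled("cellcomp", default=False):
            resid = cellcomp.CellCompositionResidualizer(mode="measured")
            bset_fit = resid.fit(bset).transform(bset)
            report["stages"]["cellcomp"] = {"mode": "measured"}
        else:
            bset_fit = bset
            report["stages"]["cellcomp"] = {"skipped": True, "note": "downstream stages use raw-beta slopes"}

        # --- trajectory fitting ----------------------------------------
        fitter = trajectory.IndividualTrajectoryFitter(
            min_points=config.threshold("min_points"),
            alpha=config.threshold("alpha_slopes"),
            age_ref=config.threshold("age_ref"),
        ).fit(bset_fit)
        traj, summ = fitter.trajectories_, fitter.summary_
        io.write_table(traj.fits, out / "trajectories.tsv", stage="fit", index=False, **prov)
        io.write_table(summ, out / "summary.tsv", stage="fit", **prov)
        report["stages"]["fit"] = {
            "n_cpgs": int(len(summ)),
            "n_significant": int(summ["significant"].sum()),
            "bonferroni_family": int(len(summ)),
        }

        # --- rapid gain -------------------------------------------------
        if config.stage_enabled("rapidgain"):
            det = rapid_gain.RapidGainDetector(
                bin_width=config.threshold("bin_width"),
                threshold=config.threshold("rapid_gain_threshold"),
            )
            try:
                det.fit(summ)
                io.write_table(
                    det.rapid_gain_, out / "rapid_gain.tsv", stage="rapidgain", **prov
                )
                if det.result_ is not None:
                    io.write_table(
                        det.result_.histogram(),
                        out / "rapid_gain_histogram.tsv",
                        stage="rapidgain",
                        index=False,
                        **prov,
                    )
                report["stages"]["rapidgain"] = {
                    "threshold": det.threshold_,
                    "n_rapid_gain": int(len(det.rapid_gain_)),
                }
            except (rapid_gain.NoValleyError, ValueError) as exc:
                report["stages"]["rapidgain"] = {"error": str(exc)}

        # --- annotation / density --------------------------------------
        if config.stage_enabled("annotate") and genome is not None and cpg_pos is not None:
            manifest = cpg_pos.copy()
            if hasattr(genome, "sequences"):
                seqs = genome.sequences
                manifest = genome.manifest
            else:
                seqs = genome
            density_tbl = annotation.compute_cpg_density(
                seqs, manifest, half_width=config.threshold("density_half_width")
            )
            density = density_tbl["count"]
            io.write_table(density_tbl, out / "cpg_density.tsv", stage="annotate", **prov)
            report["stages"]["annotate"] = {"n_cpgs": int(len(density_tbl))}

        # --- slope-QTL --------------------------------------------------
        if config.stage_enabled("qtl") and genotypes is not None and cpg_pos is not None:
            mapper = qtl.SlopeQTLMapper(
                cis_window=config.threshold("cis_window"),
                fdr=config.threshold("qtl_fdr"),
            ).fit(traj, genotypes, cpg_pos)
            io.write_table(
                mapper.candidates_, out / "qtl_candidates.tsv", stage="qtl", index=False, **prov
            )
            io.write_table(
                mapper.independent_, out / "qtl_independent.tsv", stage="qtl", index=False, **prov
            )
            io.write_table(
                mapper.flagged_, out / "qtl_variance_excluded.tsv", stage="qtl", index=False, **prov
            )
            report["stages"]["qtl"] = {
                "n_tested": int(len(mapper.candidates_)),
                "n_significant": int(len(mapper.qtls_)),
                "n_independent": int(len(mapper.independent_)),
                "n_variance_excluded": int(len(mapper.flagged_)),
            }

        # --- variance / density analyses -------------------------------
        if config.stage_enabled("variance"):
            norm = variance.normalize_slope_variance(
                summ["slope_var"], summ["mean_beta"].clip(0, 1),
                n_bins=config.threshold("variance_bins"),
            )
            io.write_table(norm, out / "slope_variance.tsv", stage="variance", **prov)
            report["stages"]["variance"] = {"n_cpgs": int(len(norm))}
            if density is not None:
                try:
                    corr = variance.correlate_slope_density(summ["mean_slope"], density)
                    shared = density.index.intersection(summ.index)
                    bp = variance.breusch_pagan(
                        summ["mean_slope"].loc[shared], density.loc[shared]
                    )
                    var_corr = variance.correlate_slope_density(
                        norm["norm_slope_var"], density
                    )
                    report["stages"]["variance"].update(
                        {
                            "slope_density_rho": corr["rho"],
                            "slope_density_p": corr["p"],
                            "bp_stat": bp["bp_stat"],
                            "bp_p": bp["bp_p"],
                            "variance_density_rho": var_corr["rho"],
                        }
                    )
                except ValueError as exc:
                    report["stages"]["variance"]["density_note"] = str(exc)
    except Exception as exc:  # pragma: no cover - failure path
        record = {"error": type(exc).__name__, "message": str(exc), "traceback": traceback.format_exc()}
        with open(out / "error.json", "w") as fh:
            json.dump(record, fh, indent=2)
        raise

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
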