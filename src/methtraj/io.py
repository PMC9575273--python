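"""Readers and writers for the pipeline's on-disk formats.

Tables are TSV with optional ``#``-prefixed provenance header lines;
genotypes round-trip either as a dosage TSV + SNP manifest or as VCF 4.2
with GT fields (read via cyvcf2 when available, else a plain-text
fallback).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeSet, LongitudinalBetaSet

__all__ = [
    "read_beta_tsv",
    "write_beta_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_manifest",
    "write_manifest",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "write_vcf",
    "read_vcf",
    "write_fasta",
    "write_table",
    "load_beta_set",
]


def _provenance_lines(stage: str | None, config: dict | None, seed: int | None) -> list[str]:
    if stage is None:
        return []
    h = (
        hashlib.sha1(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]
        if config is not None
        else "none"
    )
    return [f"# stage={stage}", f"# config_sha1={h}", f"# seed={seed}"]


def write_table(
    df: pd.DataFrame,
    path,
    stage: str | None = None,
    config: dict | None = None,
    seed: int | None = None,
    index: bool = True,
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in _provenance_lines(stage, config, seed):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_beta_tsv(betas: pd.DataFrame, path, **prov) -> None:
    write_table(betas.rename_axis("probe_id"), path, **prov)


def read_beta_tsv(path, exclude_probes=None) -> pd.DataFrame:
    betas = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    betas.index.name = "probe_id"
    betas.columns.name = "sample_id"
    if exclude_probes is not None:
        betas = betas[~betas.index.isin(set(exclude_probes))]
    return betas


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.rename_axis("sample_id").to_csv(path)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_manifest(manifest: pd.DataFrame, path, **prov) -> None:
    write_table(manifest.rename_axis("probe_id"), path, **prov)


def read_manifest(path) -> pd.DataFrame:
    return read_table(path)


def read_probe_exclusion(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def load_beta_set(beta_path, sample_path, exclude_path=None) -> LongitudinalBetaSet:
    exclude = read_probe_exclusion(exclude_path) if exclude_path else None
    return LongitudinalBetaSet(
        betas=read_beta_tsv(beta_path, exclude_probes=exclude),
        samples=read_sample_sheet(sample_path),
    )


def write_dosage_tsv(genotypes: GenotypeSet, dosage_path, snp_path) -> None:
    genotypes.dosages.rename_axis("snp_id").to_csv(dosage_path, sep="\t")
    genotypes.snps.rename_axis("snp_id").to_csv(snp_path, sep="\t")


def read_dosage_tsv(dosage_path, snp_path) -> GenotypeSet:
    dos = pd.read_csv(dosage_path, sep="\t", index_col=0)
    snps = pd.read_csv(snp_path, sep="\t", index_col=0)
    return GenotypeSet(dosages=dos, snps=snps)


def write_vcf(genotypes: GenotypeSet, path) -> None:
    """Write dosages as VCF 4.2 with unphased GT genotypes."""
    inds = list(genotypes.individuals)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(genotypes.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(inds) + "\n")
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for snp, row in genotypes.snps.iterrows():
            ref = row.get("ref", "A")
            alt = row.get("alt", "G")
            dos = genotypes.dosages.loc[snp]
            gts = "\t".join(
                gt_map.get(float(d), "./.") if not pd.isna(d) else "./."
                for d in dos
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos']) + 1}\t{snp}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeSet:
    """Read GT genotypes from a VCF into minor-allele dosages.

    Uses cyvcf2 when importable, else a plain-text parser for uncompressed
    VCF. ALT dosage is flipped to minor-allele dosage when ALT frequency
    exceeds 0.5.
    """
    try:
        return _read_vcf_cyvcf2(path)
    except ImportError:
        return _read_vcf_text(path)


def _read_vcf_cyvcf2(path) -> GenotypeSet:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    inds = list(vcf.samples)
    rows, meta, ids = [], [], []
    for var in vcf:
        gt = np.asarray(var.gt_types, dtype=float)  # 0 hom ref, 1 het, 3 hom alt, 2 unknown
        dos = np.where(gt == 3, 2.0, np.where(gt == 2, np.nan, gt))
        rows.append(dos)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        meta.append((var.CHROM, var.POS - 1, var.REF, var.ALT[0] if var.ALT else "."))
    return _finalize_vcf(rows, meta, ids, inds)


def _read_vcf_text(path) -> GenotypeSet:
    rows, meta, ids, inds = [], [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            parts = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                inds = parts[9:]
                continue
            chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            fmt = parts[8].split(":")
            gt_i = fmt.index("GT")
            dos = []
            for field in parts[9:]:
                gt = field.split(":")[gt_i].replace("|", "/")
                if "." in gt:
                    dos.append(np.nan)
                else:
                    dos.append(float(sum(int(a) > 0 for a in gt.split("/"))))
            rows.append(np.array(dos))
            ids.append(vid if vid != "." else f"{chrom}:{pos}")
            meta.append((chrom, pos - 1, ref, alt))
    return _finalize_vcf(rows, meta, ids, inds)


def _finalize_vcf(rows, meta, ids, inds) -> GenotypeSet:
    D = np.vstack(rows) if rows else np.empty((0, len(inds)))
    # flip to minor-allele dosage where ALT is the major allele
    with np.errstate(invalid="ignore"):
        af = np.nanmean(D, axis=1) / 2.0
    flip = af > 0.5
    D[flip] = 2.0 - D[flip]
    snps = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt"], index=pd.Index(ids, name="snp_id"))
    dos = pd.DataFrame(D, index=snps.index, columns=inds)
    return GenotypeSet(dosages=dos, snps=snps)


def write_fasta(sequences: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
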