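"""Local CpG density and genomic annotation of array CpGs.

Coordinates are 0-based half-open throughout; manifest positions are the
0-based position of the C of a forward-strand CpG dyad. Local density is
the number of forward-strand "CG" occurrences whose C lies within
``half_width`` bp of the focal position (the focal dyad counts, so a CpG
inside sequence bounds always has density >= 1).

CpGs are labelled against CpG islands (precedence CGI > shore; shores are
the 2 kb flanks of merged islands, excluding island sequence), against
genes (TSS > gene body > intergenic), and independently against PMD/HMD
methylation domains and ChromHMM chromatin states. Enrichment of a CpG
set against a background universe is a per-label 2x2 Fisher exact test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "read_bed",
    "write_bed",
    "merge_intervals",
    "compute_cpg_density",
    "annotate_cpgs",
    "enrichment_test",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file; malformed lines raise with their line number."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: require 0 <= start < end")
            name = parts[3] if len(parts) > 3 else "."
            rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "name" not in out.columns:
        out["name"] = "."
    out[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly overlapping half-open intervals, per chromosome."""
    if df.empty:
        return df.copy()
    out = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        start = end = None
        for s, e in zip(sub["start"], sub["end"]):
            if start is None:
                start, end = s, e
            elif s <= end:
                end = max(end, e)
            else:
                out.append((chrom, start, end))
                start, end = s, e
        out.append((chrom, start, end))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def _subtract(intervals: pd.DataFrame, holes: pd.DataFrame) -> pd.DataFrame:
    """Set difference of merged interval sets (both merged, half-open)."""
    out = []
    holes_by_chrom = {c: sub for c, sub in holes.groupby("chrom")}
    for _, row in intervals.iterrows():
        s, e = row["start"], row["end"]
        sub = holes_by_chrom.get(row["chrom"])
        if sub is None:
            out.append((row["chrom"], s, e))
            continue
        cur = s
        for hs, he in zip(sub["start"], sub["end"]):
            if he <= cur or hs >= e:
                continue
            if hs > cur:
                out.append((row["chrom"], cur, hs))
            cur = max(cur, he)
            if cur >= e:
                break
        if cur < e:
            out.append((row["chrom"], cur, e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def _get_sequence(genome, chrom: str) -> str:
    """Accept a dict of strings, a pyfaidx.Fasta, or a FASTA path."""
    if isinstance(genome, dict):
        return genome[chrom]
    if isinstance(genome, (str, bytes)) or hasattr(genome, "__fspath__"):
        import pyfaidx

        fa = pyfaidx.Fasta(str(genome))
        return str(fa[chrom][:])
    # pyfaidx.Fasta or similar mapping of records
    return str(genome[chrom][:])


def compute_cpg_density(
    genome,
    manifest: pd.DataFrame,
    half_width: int = 300,
) -> pd.DataFrame:
    """Count CpG dyads within +/- ``half_width`` bp of each manifest CpG.

    A dyad is counted when its C lies in [pos - half_width, pos + half_width];
    the window truncates at chromosome ends. Positions lacking a "CG" in
    the genome are flagged (``has_cg=False``) but still counted over.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    records = []
    for chrom, sub in manifest.groupby("chrom", sort=False):
        seq = _get_sequence(genome, chrom).upper()
        L = len(seq)
        for probe, pos in zip(sub.index, sub["pos"].astype(int)):
            if not 0 <= pos < L:
                raise ValueError(f"{probe}: position {pos} outside {chrom} (len {L})")
            lo = max(0, pos - half_width)
            # C may sit at pos + half_width, needing the G one base further
            hi = min(L, pos + half_width + 2)
            window = seq[lo:hi]
            count = window.count("CG")
            has_cg = seq[pos : pos + 2] == "CG"
            records.append((probe, half_width, count, count / (hi - lo), has_cg))
    out = pd.DataFrame(
        records, columns=["probe_id", "half_width", "count", "density", "has_cg"]
    ).set_index("probe_id")
    n_bad = int((~out["has_cg"]).sum())
    if n_bad:
        warnings.warn(f"{n_bad} manifest positions lack a CG dyad in the genome")
    return out.loc[manifest.index]


def _assign(manifest: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean: does each manifest position fall in any (merged) interval."""
    hit = np.zeros(len(manifest), dtype=bool)
    if intervals.empty:
        return hit
    by_chrom = {c: sub.sort_values("start") for c, sub in intervals.groupby("chrom")}
    pos = manifest["pos"].to_numpy(int)
    for chrom, sub in manifest.groupby("chrom", sort=False):
        iv = by_chrom.get(chrom)
        if iv is None:
            continue
        starts = iv["start"].to_numpy(int)
        ends = iv["end"].to_numpy(int)
        idx = manifest.index.get_indexer(sub.index)
        p = pos[idx]
        k = np.searchsorted(starts, p, side="right") - 1
        ok = (k >= 0) & (p < ends[np.clip(k, 0, len(ends) - 1)])
        hit[idx] = ok
    return hit


def _assign_label(manifest: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Label of the covering interval (intervals assumed non-overlapping)."""
    labels = np.full(len(manifest), None, dtype=object)
    if intervals.empty:
        return labels
    pos = manifest["pos"].to_numpy(int)
    for chrom, iv in intervals.groupby("chrom"):
        iv = iv.sort_values("start")
        starts = iv["start"].to_numpy(int)
        ends = iv["end"].to_numpy(int)
        names = iv["name"].to_numpy(object)
        mask = manifest["chrom"].to_numpy() == chrom
        idx = np.flatnonzero(mask)
        p = pos[idx]
        k = np.searchsorted(starts, p, side="right") - 1
        ok = (k >= 0) & (p < ends[np.clip(k, 0, len(ends) - 1)])
        labels[idx[ok]] = names[k[ok]]
    return labels


def annotate_cpgs(
    manifest: pd.DataFrame,
    cgis: pd.DataFrame | None = None,
    tss: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
    pmds: pd.DataFrame | None = None,
    chromhmm: pd.DataFrame | None = None,
    shore_width: int = 2000,
    tss_flank: int = 0,
) -> pd.DataFrame:
    """Per-CpG annotation labels.

    Overlapping CGIs are merged before shores (``shore_width`` bp flanks,
    island sequence excluded) are built; precedence CGI > shore > open sea.
    Gene annotation: TSS overlap (optionally flanked by ``tss_flank`` bp)
    first, then gene body, else intergenic. PMD/HMD domains and ChromHMM
    states are assigned independently from their ``name`` columns.
    """
    out = pd.DataFrame(index=manifest.index)
    if cgis is not None and len(cgis):
        merged = merge_intervals(cgis)
        flanks = pd.concat(
            [
                merged.assign(
                    start=(merged["start"] - shore_width).clip(lower=0),
                    end=merged["start"],
                ),
                merged.assign(start=merged["end"], end=merged["end"] + shore_width),
            ]
        )
        flanks = flanks[flanks["start"] < flanks["end"]]
        shores = _subtract(merge_intervals(flanks), merged)
        in_cgi = _assign(manifest, merged)
        in_shore = _assign(manifest, shores) & ~in_cgi
        out["cgi_status"] = np.where(in_cgi, "CGI", np.where(in_shore, "shore", "open_sea"))
    if tss is not None and genes is not None:
        t = tss.copy()
        if tss_flank:
            t["start"] = (t["start"] - tss_flank).clip(lower=0)
            t["end"] = t["end"] + tss_flank
        at_tss = _assign(manifest, merge_intervals(t)) if len(t) else np.zeros(len(manifest), bool)
        in_gene = (
            _assign(manifest, merge_intervals(genes))
            if len(genes)
            else np.zeros(len(manifest), bool)
        )
        out["gene_status"] = np.where(
            at_tss, "TSS", np.where(in_gene, "gene_body", "intergenic")
        )
    if pmds is not None and len(pmds):
        out["pmd_status"] = _assign_label(manifest, pmds)
    if chromhmm is not None and len(chromhmm):
        out["chrom_state"] = _assign_label(manifest, chromhmm)
    return out


def enrichment_test(
    query: pd.Index | list,
    background: pd.Index | list,
    labels: pd.Series,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Per-label Fisher exact enrichment of a CpG set vs its background.

    ``background`` is the full universe (must contain the query). For each
    distinct label L the 2x2 table (query & L, query & not L, rest & L,
    rest & not L) is tested; "greater" gives the one-sided enrichment test
    used for chromatin states. Fold change is reported as
    (query fraction / background fraction - 1) x 100.
    """
    query = pd.Index(query).unique()
    background = pd.Index(background).unique()
    if len(query) == 0:
        raise ValueError("query set is empty")
    if not query.isin(background).all():
        raise ValueError("query must be a subset of the background universe")
    labels = labels.reindex(background)
    in_query = labels.index.isin(query)
    rows = []
    for label in sorted(labels.dropna().unique()):
        has = (labels == label).to_numpy()
        a = int((has & in_query).sum())
        b = int((~has & in_query).sum())
        c = int((has & ~in_query).sum())
        d = int((~has & ~in_query).sum())
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        q_frac = a / len(query)
        bg_frac = (a + c) / len(background)
        fold = (q_frac / bg_frac - 1.0) * 100.0 if bg_frac > 0 else np.nan
        rows.append(
            {
                "label": label,
                "query_in": a,
                "query_out": b,
                "bg_in": a + c,
                "bg_out": b + d,
                "odds_ratio": odds,
                "fold_change_pct": fold,
                "p": p,
                "alternative": alternative,
            }
        )
    return pd.DataFrame(rows).set_index("label")
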