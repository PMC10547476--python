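"""SNP-to-gene assignment and candidate-gene nomination.

Glycemic-trait SNPs passing a genome-wide significance filter
(-log10(p) > 8, strict) are assigned to genes two ways:

* window -- the SNP lies inside the gene body or within a +/-100 kbp flank
  extending it (route ``body`` when inside the body proper);
* loop   -- a chromatin loop (promoter-capture HiC) connects an anchor
  overlapping the gene's promoter to a distal anchor containing the SNP.

A gene is nominated when at least one filter-passing SNP reaches it by
either route; routes, traits, and the best -log10(p) are carried per gene.

Coordinates are BED-style 0-based half-open internally; SNP table
positions are 1-based and converted on read.  Genes without an explicit
promoter anchor get TSS +/- 2 kbp derived from strand.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .synthgen import GLYCEMIC_TRAITS

__all__ = [
    "filter_snps",
    "assign_window",
    "assign_loops",
    "nominate",
    "promoter_anchors",
    "read_bed",
    "write_bed",
    "read_snps",
    "write_snps",
    "read_bedpe",
    "write_bedpe",
]

PROMOTER_HALF_WIDTH = 2_000  # bp each side of the TSS


def _validate_snps(snps: pd.DataFrame) -> pd.DataFrame:
    if np.any(snps["pvalue"] <= 0) or np.any(snps["pvalue"] > 1):
        raise ValueError("SNP p-values must lie in (0, 1]")
    unknown = set(snps.get("trait", pd.Series(dtype=str)).unique()) - set(GLYCEMIC_TRAITS)
    if unknown:
        warnings.warn(f"unknown trait labels: {sorted(unknown)}", stacklevel=3)
    return snps


def filter_snps(snps: pd.DataFrame, neg_log10_cutoff: float = 8.0) -> pd.DataFrame:
    """Keep SNPs with -log10(p) strictly greater than the cutoff.

    The boundary case p == 10**-cutoff is excluded.
    """
    _validate_snps(snps)
    keep = -np.log10(snps["pvalue"].to_numpy(float)) > neg_log10_cutoff
    return snps[keep].reset_index(drop=True)


def promoter_anchors(genes: pd.DataFrame) -> pd.DataFrame:
    """Ensure promoter_start/promoter_end columns (TSS +/- 2 kbp default).

    Explicit anchors in the input are preferred and left untouched.
    """
    out = genes.copy()
    if "promoter_start" not in out.columns:
        out["promoter_start"] = np.nan
        out["promoter_end"] = np.nan
    tss = np.where(out["strand"] == "-", out["end"], out["start"])
    fill = out["promoter_start"].isna()
    out.loc[fill, "promoter_start"] = np.maximum(tss[fill] - PROMOTER_HALF_WIDTH, 0)
    out.loc[fill, "promoter_end"] = tss[fill] + PROMOTER_HALF_WIDTH
    out["promoter_start"] = out["promoter_start"].astype(int)
    out["promoter_end"] = out["promoter_end"].astype(int)
    return out


_ASSIGN_COLS = ["gene_id", "rsid", "route", "chrom", "pos", "pvalue", "trait"]


def assign_window(
    snps: pd.DataFrame, genes: pd.DataFrame, window_kbp: float = 100.0
) -> pd.DataFrame:
    """Assign SNPs to genes by body/flank containment.

    A SNP at 1-based position ``pos`` maps to 0-based ``pos - 1`` and is
    assigned iff it shares the gene's chromosome and
    ``start - window <= pos0 < end + window``; the route is ``body`` when
    ``start <= pos0 < end`` and ``window`` otherwise.
    """
    if window_kbp < 0:
        raise ValueError("window must be non-negative")
    w = int(round(window_kbp * 1_000))
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        lo = max(row.start - w, 0)
        hi = row.end + w
        trees.setdefault(row.chrom, IntervalTree()).addi(lo, hi, row)
    rows = []
    for snp in snps.itertuples(index=False):
        pos0 = int(snp.pos) - 1
        tree = trees.get(snp.chrom)
        if tree is None:
            continue
        for iv in sorted(tree[pos0], key=lambda iv: iv.data.gene_id):
            gene = iv.data
            route = "body" if gene.start <= pos0 < gene.end else "window"
            rows.append(
                (gene.gene_id, snp.rsid, route, snp.chrom, snp.pos, snp.pvalue, snp.trait)
            )
    return pd.DataFrame(rows, columns=_ASSIGN_COLS)


def _overlaps(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> bool:
    return a_lo < b_hi and b_lo < a_hi  # half-open intersection


def assign_loops(
    snps: pd.DataFrame, genes: pd.DataFrame, loops: pd.DataFrame
) -> pd.DataFrame:
    """Assign SNPs to genes via promoter-contacting chromatin loops.

    A SNP is assigned to a gene iff some loop has one anchor overlapping
    the gene's promoter anchor and the other anchor containing the SNP
    position (exact containment; half-open intervals).
    """
    genes = promoter_anchors(genes)
    rows = []
    if loops is None or loops.empty:
        return pd.DataFrame(rows, columns=_ASSIGN_COLS)
    for gene in genes.itertuples(index=False):
        distal: list[tuple[str, int, int]] = []
        for lp in loops.itertuples(index=False):
            if lp.chrom_a == gene.chrom and _overlaps(
                lp.start_a, lp.end_a, gene.promoter_start, gene.promoter_end
            ):
                distal.append((lp.chrom_b, lp.start_b, lp.end_b))
            if lp.chrom_b == gene.chrom and _overlaps(
                lp.start_b, lp.end_b, gene.promoter_start, gene.promoter_end
            ):
                distal.append((lp.chrom_a, lp.start_a, lp.end_a))
        if not distal:
            continue
        for snp in snps.itertuples(index=False):
            pos0 = int(snp.pos) - 1
            if any(c == snp.chrom and lo <= pos0 < hi for c, lo, hi in distal):
                rows.append(
                    (gene.gene_id, snp.rsid, "loop", snp.chrom, snp.pos, snp.pvalue, snp.trait)
                )
    return pd.DataFrame(rows, columns=_ASSIGN_COLS)


def nominate(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    loops: pd.DataFrame | None = None,
    neg_log10_cutoff: float = 8.0,
    window_kbp: float = 100.0,
) -> pd.DataFrame:
    """Nominate genes supported by filter-passing SNPs via window or loop.

    One record per gene with the union of supporting SNPs (deduplicated by
    rsid; a SNP reaching a gene by several routes counts once, with all
    routes recorded), the traits hit, and the best -log10(p).
    """
    passing = filter_snps(snps, neg_log10_cutoff)
    parts = [assign_window(passing, genes, window_kbp)]
    if loops is not None and not loops.empty:
        parts.append(assign_loops(passing, genes, loops))
    assigned = pd.concat(parts, ignore_index=True)
    if assigned.empty:
        return pd.DataFrame(
            columns=["gene_id", "n_snps", "routes", "traits", "best_neg_log10_p"]
        )
    assigned = assigned.drop_duplicates(["gene_id", "rsid", "route"])
    rows = []
    for gene_id, grp in assigned.groupby("gene_id", sort=True):
        uniq = grp.drop_duplicates("rsid")
        rows.append(
            {
                "gene_id": gene_id,
                "n_snps": len(uniq),
                "routes": ",".join(sorted(grp["route"].unique())),
                "traits": ",".join(sorted(grp["trait"].unique())),
                "best_neg_log10_p": float(-np.log10(grp["pvalue"]).max()),
            }
        )
    return pd.DataFrame(rows)


# --- plain-text format IO -------------------------------------------------

_BED6 = ["chrom", "start", "end", "gene_id", "score", "strand"]
_SNP_COLS = ["chrom", "pos", "rsid", "pvalue", "trait"]
_BEDPE = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b"]


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(_BED6)]
    df.columns = _BED6[: df.shape[1]]
    if np.any(df["start"] >= df["end"]):
        raise ValueError("BED intervals need start < end")
    return df


def write_bed(genes: pd.DataFrame, path) -> None:
    genes[_BED6].to_csv(path, sep="\t", header=False, index=False)


def read_snps(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_SNP_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"SNP table missing columns: {sorted(missing)}")
    return _validate_snps(df)


def write_snps(snps: pd.DataFrame, path) -> None:
    snps[_SNP_COLS].to_csv(path, sep="\t", index=False)


def read_bedpe(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(_BEDPE)]
    df.columns = _BEDPE
    return df


def write_bedpe(loops: pd.DataFrame, path) -> None:
    loops[_BEDPE].to_csv(path, sep="\t", header=False, index=False)
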