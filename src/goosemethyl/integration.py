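"""Expression classes, differential expression, and methylation integration.

Genes are classed by mean FPKM: high (>= 100), middle (10 <= FPKM < 100),
low (0 < FPKM < 10) and none (exactly 0).  Differential expression between
two replicate groups uses a Welch t-test on log2(FPKM + 1) with BH
adjustment; a DEG requires |log2 FC| >= 1 and FDR <= 0.05.  DEGs are
intersected with DMR-related genes per regulatory region and assigned a
joint expression/methylation quadrant (E+&M+, E+&M-, E-&M+, E-&M-).

The promoter per-site comparison reproduces a pyrosequencing-style
readout: for every CpG dyad in a TSS-relative promoter window covered in
all replicates of both groups, the per-replicate levels (plus and minus
strand reads pooled per dyad) are compared with an unadjusted per-site
Welch t-test.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import bh_adjust
from .io_formats import GeneModel
from .regions import DEFAULT_MIN_DEPTH

EXPRESSION_CLASSES = ("high", "middle", "low", "none")
QUADRANTS = ("E+&M+", "E+&M-", "E-&M+", "E-&M-")


def classify_expression(
    fpkm: pd.DataFrame, samples: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Class each gene from its mean FPKM over ``samples`` (default: all).

    Boundaries are exact: high iff mean >= 100; middle iff 10 <= mean < 100;
    low iff 0 < mean < 10; none iff mean is exactly 0.
    """
    sub = fpkm[list(samples)] if samples is not None else fpkm
    values = sub.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative FPKM value")
    mean = values.mean(axis=1)
    cls = np.where(
        mean >= 100, "high",
        np.where(mean >= 10, "middle", np.where(mean > 0, "low", "none")),
    )
    return pd.DataFrame(
        {"gene_id": fpkm.index, "fpkm_mean": mean, "expr_class": cls}
    ).set_index("gene_id")


def call_degs(
    fpkm_a: pd.DataFrame,
    fpkm_b: pd.DataFrame,
    pseudocount: float = 1.0,
    min_lfc: float = 1.0,
    max_fdr: float = 0.05,
    group_a: str = "a",
    group_b: str = "b",
    return_all: bool = False,
) -> pd.DataFrame:
    """Differentially expressed genes between two replicate groups.

    ``fpkm_a``/``fpkm_b`` are genes x replicates with identical gene order.
    log2_fc = log2((mean_a + pc)/(mean_b + pc)); p from a two-sided Welch
    t-test on log2(FPKM + pc); BH across genes.  direction is E+ when group
    a is higher.
    """
    if fpkm_a.shape[1] < 2 or fpkm_b.shape[1] < 2:
        raise ValueError("call_degs requires >= 2 replicates per group")
    if not fpkm_a.index.equals(fpkm_b.index):
        raise ValueError("call_degs: gene indices differ between groups")
    a = fpkm_a.to_numpy(dtype=float)
    b = fpkm_b.to_numpy(dtype=float)
    lfc = np.log2((a.mean(axis=1) + pseudocount) / (b.mean(axis=1) + pseudocount))
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = stats.ttest_ind(la, lb, axis=1, equal_var=False)
        p = np.asarray(t.pvalue, dtype=float)
    # degenerate rows: zero variance in both groups
    same = np.isnan(p)
    p[same & np.isclose(la.mean(axis=1), lb.mean(axis=1))] = 1.0
    p[same & ~np.isclose(la.mean(axis=1), lb.mean(axis=1))] = 0.0
    fdr = bh_adjust(p)
    df = pd.DataFrame(
        {
            "gene_id": fpkm_a.index,
            "log2_fc": lfc,
            "p_value": p,
            "fdr": fdr,
            "direction": np.where(lfc > 0, "E+", "E-"),
            "is_deg": (np.abs(lfc) >= min_lfc) & (fdr <= max_fdr),
        }
    ).set_index("gene_id")
    df.attrs["group_a"] = group_a
    df.attrs["group_b"] = group_b
    return df if return_all else df[df["is_deg"]]


def intersect_and_classify(
    degs: pd.DataFrame, dmr_genes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intersect DEGs with DMR-related genes and assign quadrants.

    ``degs`` carries direction E+/E- (from :func:`call_degs`), ``dmr_genes``
    carries per-(gene, region_type) direction M+/M-/tie (from
    ``dmr.assign_dmr_genes``).  Both must come from the same orientation of
    the same comparison; mismatched group labels raise.

    Genes with a tied methylation direction are excluded.  Returns
    (records, counts): one record per gene x region type with its
    quadrant, and quadrant counts per region type.
    """
    for key in ("group_a", "group_b"):
        la, lb = degs.attrs.get(key), dmr_genes.attrs.get(key)
        if la is not None and lb is not None and la != lb:
            raise ValueError(
                f"orientation mismatch: DEGs {key}={la!r}, DMR genes {key}={lb!r}"
            )
    if degs.empty or dmr_genes.empty:
        records = pd.DataFrame(columns=["gene_id", "region_type", "quadrant"])
    else:
        deg_dir = degs["direction"]
        merged = dmr_genes[dmr_genes["gene_id"].isin(degs.index)].copy()
        merged = merged[merged["direction"] != "tie"]
        merged["quadrant"] = [
            f"{deg_dir[g]}&{m}" for g, m in zip(merged["gene_id"], merged["direction"])
        ]
        records = merged[["gene_id", "region_type", "quadrant"]].reset_index(drop=True)
    counts = (
        records.groupby(["region_type", "quadrant"])
        .size()
        .rename("n")
        .reset_index()
        if not records.empty
        else pd.DataFrame(columns=["region_type", "quadrant", "n"])
    )
    return records, counts


def promoter_site_comparison(
    calls_a: Sequence[pd.DataFrame],
    calls_b: Sequence[pd.DataFrame],
    gene: GeneModel,
    from_offset: int = -723,
    to_offset: int = -480,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> pd.DataFrame:
    """Per-CpG-site methylation comparison in a TSS-relative promoter window.

    Offsets are in transcription orientation (negative = upstream of the
    TSS) and inclusive at both ends.  Per dyad (plus- and minus-strand
    reads pooled) a site is analysed only when its pooled depth reaches
    ``min_depth`` in every replicate of both groups; each site gets per-
    replicate levels, group means and an unadjusted two-sided Welch t
    p-value.

    Columns: chrom, pos, offset, mean_a, mean_b, diff, p_value.
    """
    if from_offset > to_offset:
        from_offset, to_offset = to_offset, from_offset
    tss = gene.tss
    if gene.strand == "+":
        start, end = tss + from_offset, tss + to_offset + 1
    else:
        start, end = tss - to_offset, tss - from_offset + 1

    def dyad_levels(calls: pd.DataFrame) -> pd.DataFrame:
        cg = calls[
            (calls["context"] == "CG")
            & (calls["chrom"] == gene.chrom)
            & (calls["pos"] >= start)
            & (calls["pos"] < end + 1)  # minus-strand C of an edge dyad
        ].copy()
        # dyad anchor = position of the C on the plus strand
        cg["dyad"] = np.where(cg["strand"] == "+", cg["pos"], cg["pos"] - 1)
        g = cg.groupby("dyad").agg(depth=("depth", "sum"), meth=("meth_count", "sum"))
        return g[(g.index >= start) & (g.index < end)]

    per_rep_a = [dyad_levels(c) for c in calls_a]
    per_rep_b = [dyad_levels(c) for c in calls_b]
    all_reps = per_rep_a + per_rep_b
    common = None
    for g in all_reps:
        idx = set(g[g["depth"] >= min_depth].index)
        common = idx if common is None else (common & idx)
    common = sorted(common or ())
    rows = []
    for dyad in common:
        lv_a = np.array([g.loc[dyad, "meth"] / g.loc[dyad, "depth"] for g in per_rep_a])
        lv_b = np.array([g.loc[dyad, "meth"] / g.loc[dyad, "depth"] for g in per_rep_b])
        diff = float(lv_a.mean() - lv_b.mean())
        if np.ptp(lv_a) == 0 and np.ptp(lv_b) == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            p = float(stats.ttest_ind(lv_a, lv_b, equal_var=False).pvalue)
        offset = (dyad - tss) if gene.strand == "+" else (tss - dyad)
        rows.append(
            {
                "chrom": gene.chrom,
                "pos": int(dyad),
                "offset": int(offset),
                "mean_a": float(lv_a.mean()),
                "mean_b": float(lv_b.mean()),
                "diff": diff,
                "p_value": p,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "offset", "mean_a", "mean_b", "diff", "p_value"]
    )
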