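"""Differentially methylated region (DMR) and gene (DMG) detection.

Two groups are compared by pooling replicate read counts at shared CG
positions (strand-specific sites, pooled depth >= 4 in both groups).
Candidate windows of 5 consecutive CpG sites slide one site at a time;
windows whose neighbouring sites lie more than 1 kb apart are discarded.
Each window's pooled 2x2 count table is tested with a two-sided Fisher's
exact test, p-values are Benjamini-Hochberg adjusted across all tested
windows, and windows passing |delta| >= 0.25 and q <= 0.05 are merged
when overlapping or within 1 kb with the same direction.  Merged regions
are re-scored on their full CpG content and must still satisfy every
threshold, so each reported DMR has >= 5 CpGs, an absolute group
difference of at least 0.25 and an adjusted p of at most 0.05.

A DMG is a gene whose regulatory-region methylation (upstream 2 kb, gene
body or downstream 2 kb) changed by |log2 FC| >= 1 at FDR <= 0.001.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import GeneRegions
from .regions import DEFAULT_MIN_DEPTH

DMR_COLUMNS = [
    "chrom", "start", "end", "n_cpg", "total_depth", "level_a", "level_b",
    "delta", "p_value", "q_value", "direction",
]

DEFAULT_MIN_CPG = 5
DEFAULT_MIN_DELTA = 0.25
DEFAULT_MAX_Q = 0.05
DEFAULT_MAX_GAP = 1000


def test_window(pooled_a: tuple[int, int], pooled_b: tuple[int, int]) -> float:
    """Two-sided Fisher's exact test on pooled (meth, depth) counts.

    The 2x2 table is [[meth_a, depth_a - meth_a], [meth_b, depth_b - meth_b]].
    """
    meth_a, depth_a = pooled_a
    meth_b, depth_b = pooled_b
    if depth_a <= 0 or depth_b <= 0:
        raise ValueError("test_window requires positive depth in both groups")
    table = [[meth_a, depth_a - meth_a], [meth_b, depth_b - meth_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def pool_replicates(calls_list: Sequence[pd.DataFrame], context: str = "CG") -> pd.DataFrame:
    """Sum depth and meth_count per (chrom, pos, strand) over replicates."""
    frames = [c[c["context"] == context] for c in calls_list]
    allc = pd.concat(frames, ignore_index=True)
    pooled = (
        allc.groupby(["chrom", "pos", "strand"], as_index=False)
        .agg(depth=("depth", "sum"), meth=("meth_count", "sum"))
        .sort_values(["chrom", "pos", "strand"])
        .reset_index(drop=True)
    )
    return pooled


def shared_cpg_table(
    calls_a: Sequence[pd.DataFrame],
    calls_b: Sequence[pd.DataFrame],
    min_depth: int = DEFAULT_MIN_DEPTH,
    context: str = "CG",
) -> pd.DataFrame:
    """CG sites covered (pooled depth >= min_depth) in both groups.

    Columns: chrom, pos, strand, depth_a, meth_a, depth_b, meth_b.
    """
    a = pool_replicates(calls_a, context)
    b = pool_replicates(calls_b, context)
    merged = a.merge(b, on=["chrom", "pos", "strand"], suffixes=("_a", "_b"))
    merged = merged[
        (merged["depth_a"] >= min_depth) & (merged["depth_b"] >= min_depth)
    ]
    return (
        merged.rename(columns={"meth_a": "meth_a", "meth_b": "meth_b"})
        .sort_values(["chrom", "pos", "strand"])
        .reset_index(drop=True)
    )


def _fisher_many(meth_a, depth_a, meth_b, depth_b) -> np.ndarray:
    """Row-wise two-sided Fisher p-values, memoised on the count table."""
    cache: dict[tuple[int, int, int, int], float] = {}
    out = np.empty(len(meth_a), dtype=float)
    for i, key in enumerate(zip(meth_a, depth_a, meth_b, depth_b)):
        p = cache.get(key)
        if p is None:
            p = test_window((key[0], key[1]), (key[2], key[3]))
            cache[key] = p
        out[i] = p
    return out


def call_dmrs(
    calls_a: Sequence[pd.DataFrame],
    calls_b: Sequence[pd.DataFrame],
    min_cpg: int = DEFAULT_MIN_CPG,
    min_delta: float = DEFAULT_MIN_DELTA,
    max_q: float = DEFAULT_MAX_Q,
    max_gap: int = DEFAULT_MAX_GAP,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> pd.DataFrame:
    """Detect DMRs between two replicate groups (group a vs group b).

    Returns a DataFrame with one row per reported DMR; ``delta`` is
    level_a - level_b and ``direction`` is ``gain`` (a higher) or ``loss``.
    Swapping the groups negates every delta and flips directions while
    leaving intervals identical.
    """
    shared = shared_cpg_table(calls_a, calls_b, min_depth=min_depth)
    if shared.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)

    windows = []
    for chrom, sub in shared.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        da = sub["depth_a"].to_numpy()
        ma = sub["meth_a"].to_numpy()
        db = sub["depth_b"].to_numpy()
        mb = sub["meth_b"].to_numpy()
        n = len(sub)
        if n < min_cpg:
            continue
        gaps = np.diff(pos)
        w = min_cpg
        # candidate windows of w consecutive sites, valid when every
        # neighbouring gap inside the window is <= max_gap
        csum = np.concatenate([[0], np.cumsum(gaps > max_gap)])
        valid = (csum[w - 1 :] - csum[: n - w + 1]) == 0
        starts = np.flatnonzero(valid)
        if starts.size == 0:
            continue

        def wsum(x):
            c = np.concatenate([[0], np.cumsum(x)])
            return c[w:] - c[:-w]

        wa_d, wa_m = wsum(da)[starts], wsum(ma)[starts]
        wb_d, wb_m = wsum(db)[starts], wsum(mb)[starts]
        delta = wa_m / wa_d - wb_m / wb_d
        windows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": pos[starts],
                    "end": pos[starts + w - 1] + 1,
                    "meth_a": wa_m, "depth_a": wa_d,
                    "meth_b": wb_m, "depth_b": wb_d,
                    "delta": delta,
                }
            )
        )
    if not windows:
        return pd.DataFrame(columns=DMR_COLUMNS)
    win = pd.concat(windows, ignore_index=True)
    win["p_value"] = _fisher_many(
        win["meth_a"].to_numpy(), win["depth_a"].to_numpy(),
        win["meth_b"].to_numpy(), win["depth_b"].to_numpy(),
    )
    win["q_value"] = bh_adjust(win["p_value"])
    passing = win[
        (win["delta"].abs() >= min_delta) & (win["q_value"] <= max_q)
    ].copy()
    if passing.empty:
        return pd.DataFrame(columns=DMR_COLUMNS)
    passing["sign"] = np.sign(passing["delta"]).astype(int)

    # merge same-direction passing windows overlapping or within max_gap
    merged_rows = []
    for (chrom, sign), sub in passing.groupby(["chrom", "sign"], sort=True):
        sub = sub.sort_values("start")
        cur_s, cur_e = None, None
        for r in sub.itertuples():
            if cur_s is None:
                cur_s, cur_e = r.start, r.end
            elif r.start <= cur_e + max_gap:
                cur_e = max(cur_e, r.end)
            else:
                merged_rows.append((chrom, int(cur_s), int(cur_e), sign))
                cur_s, cur_e = r.start, r.end
        merged_rows.append((chrom, int(cur_s), int(cur_e), sign))

    # re-score each merged region on its full CpG content
    records = []
    for chrom, s, e, sign in merged_rows:
        sub = shared[
            (shared["chrom"] == chrom) & (shared["pos"] >= s) & (shared["pos"] < e)
        ]
        da, ma = int(sub["depth_a"].sum()), int(sub["meth_a"].sum())
        db, mb = int(sub["depth_b"].sum()), int(sub["meth_b"].sum())
        level_a, level_b = ma / da, mb / db
        records.append(
            {
                "chrom": chrom, "start": s, "end": e, "n_cpg": len(sub),
                "total_depth": da + db,
                "level_a": level_a, "level_b": level_b,
                "delta": level_a - level_b,
                "p_value": test_window((ma, da), (mb, db)),
            }
        )
    res = pd.DataFrame(records)
    res["q_value"] = bh_adjust(res["p_value"])
    res["direction"] = np.where(res["delta"] > 0, "gain", "loss")
    res = res[
        (res["n_cpg"] >= min_cpg)
        & (res["delta"].abs() >= min_delta)
        & (res["q_value"] <= max_q)
    ]
    return (
        res[DMR_COLUMNS]
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )


def validate_dmrs(
    dmrs: pd.DataFrame,
    calls_a: Sequence[pd.DataFrame],
    calls_b: Sequence[pd.DataFrame],
    min_cpg: int = DEFAULT_MIN_CPG,
    min_delta: float = DEFAULT_MIN_DELTA,
    max_q: float = DEFAULT_MAX_Q,
    max_gap: int = DEFAULT_MAX_GAP,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[str]:
    """Post-hoc validator: recompute every reported DMR from raw calls.

    Returns a list of human-readable violations (empty when all reported
    DMRs satisfy the printed thresholds).
    """
    violations: list[str] = []
    if dmrs.empty:
        return violations
    shared = shared_cpg_table(calls_a, calls_b, min_depth=min_depth)
    for r in dmrs.itertuples():
        sub = shared[
            (shared["chrom"] == r.chrom)
            & (shared["pos"] >= r.start)
            & (shared["pos"] < r.end)
        ].sort_values("pos")
        tag = f"{r.chrom}:{r.start}-{r.end}"
        if len(sub) < min_cpg:
            violations.append(f"{tag}: only {len(sub)} CpG sites (< {min_cpg})")
            continue
        da, ma = sub["depth_a"].sum(), sub["meth_a"].sum()
        db, mb = sub["depth_b"].sum(), sub["meth_b"].sum()
        delta = ma / da - mb / db
        if abs(delta) < min_delta:
            violations.append(f"{tag}: |delta| {abs(delta):.3f} < {min_delta}")
        if not np.isclose(delta, r.delta, atol=1e-9):
            violations.append(f"{tag}: reported delta {r.delta:.3f} != recomputed {delta:.3f}")
        if r.q_value > max_q:
            violations.append(f"{tag}: q {r.q_value:.3g} > {max_q}")
        gaps = np.diff(np.unique(sub["pos"].to_numpy()))
        if gaps.size and gaps.max() > max_gap:
            violations.append(f"{tag}: CpG gap {int(gaps.max())} > {max_gap}")
    return violations


# ---------------------------------------------------------------------------
# DMR-related genes and DMGs
# ---------------------------------------------------------------------------

REGION_TYPES = ("upstream2k", "body", "downstream2k")


def assign_dmr_genes(
    dmrs: pd.DataFrame, gene_regions: Sequence[GeneRegions]
) -> pd.DataFrame:
    """Map DMRs onto gene regulatory regions.

    A gene is DMR-related for a region type iff at least one DMR overlaps
    that region by >= 1 bp.  The gene's net direction per region type is the
    depth-weighted sign of the overlapping DMR deltas; exact ties give
    direction ``tie`` and exclude the gene from quadrant classification.

    Columns: gene_id, region_type, n_dmrs, net_delta, direction (M+/M-/tie).
    """
    rows = []
    for gr in gene_regions:
        sub = dmrs[dmrs["chrom"] == gr.chrom] if not dmrs.empty else dmrs
        for region_type in REGION_TYPES:
            s, e = gr.region(region_type)
            if s >= e or sub.empty:
                continue
            hit = sub[(sub["start"] < e) & (sub["end"] > s)]
            if hit.empty:
                continue
            weight = hit["total_depth"].to_numpy(dtype=float)
            net = float(np.sum(np.sign(hit["delta"].to_numpy()) * weight))
            signed = float(np.sum(hit["delta"].to_numpy()))
            direction = "M+" if net > 0 else ("M-" if net < 0 else "tie")
            rows.append(
                {
                    "gene_id": gr.gene_id,
                    "region_type": region_type,
                    "n_dmrs": len(hit),
                    "net_delta": signed,
                    "direction": direction,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "region_type", "n_dmrs", "net_delta", "direction"]
    )


def call_dmgs(
    calls_a: Sequence[pd.DataFrame],
    calls_b: Sequence[pd.DataFrame],
    gene_regions: Sequence[GeneRegions],
    pseudocount: float = 0.01,
    min_lfc: float = 1.0,
    max_fdr: float = 0.001,
    min_depth: int = DEFAULT_MIN_DEPTH,
    return_all: bool = False,
) -> pd.DataFrame:
    """Differentially methylated genes per regulatory region type.

    Per gene and region type the pooled group levels give
    ``log2_fc = log2((level_a + pc)/(level_b + pc))``; the region's pooled
    counts are Fisher-tested and BH-adjusted across genes within each
    region type.  Reported iff |log2_fc| >= 1 and FDR <= 0.001.
    """
    shared = shared_cpg_table(calls_a, calls_b, min_depth=min_depth)
    rows = []
    for gr in gene_regions:
        sub_chrom = shared[shared["chrom"] == gr.chrom]
        for region_type in REGION_TYPES:
            s, e = gr.region(region_type)
            sub = sub_chrom[(sub_chrom["pos"] >= s) & (sub_chrom["pos"] < e)]
            if sub.empty:
                continue
            da, ma = int(sub["depth_a"].sum()), int(sub["meth_a"].sum())
            db, mb = int(sub["depth_b"].sum()), int(sub["meth_b"].sum())
            level_a, level_b = ma / da, mb / db
            lfc = float(np.log2((level_a + pseudocount) / (level_b + pseudocount)))
            rows.append(
                {
                    "gene_id": gr.gene_id,
                    "region_type": region_type,
                    "level_a": level_a,
                    "level_b": level_b,
                    "log2_fc_methylation": lfc,
                    "p_value": test_window((ma, da), (mb, db)),
                }
            )
    if not rows:
        cols = ["gene_id", "region_type", "level_a", "level_b",
                "log2_fc_methylation", "p_value", "fdr", "direction", "is_dmg"]
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows)
    df["fdr"] = np.nan
    for region_type in REGION_TYPES:
        mask = df["region_type"] == region_type
        if mask.any():
            df.loc[mask, "fdr"] = bh_adjust(df.loc[mask, "p_value"])
    df["direction"] = np.where(df["log2_fc_methylation"] > 0, "M+", "M-")
    df["is_dmg"] = (df["log2_fc_methylation"].abs() >= min_lfc) & (df["fdr"] <= max_fdr)
    df = df.sort_values(["region_type", "gene_id"]).reset_index(drop=True)
    return df if return_all else df[df["is_dmg"]].reset_index(drop=True)
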