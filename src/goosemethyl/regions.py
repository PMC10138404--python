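"""Regional methylation levels, metagene profiles, window matrices, clustering.

The methylation level of a region is the depth-weighted quotient
``sum(meth_count) / sum(depth)`` over qualifying strand-specific sites of
one context inside the half-open interval; sites below the minimum depth
(4 reads by default) never contribute.  A region with no qualifying site
has an undefined (missing) level, not zero.

Metagene profiles pool genes in transcription orientation: 100-bp bins
over a 2-kb flank on each side and percent-of-length bins over the body,
smoothed with a centred 5-bin moving average whose window shrinks at the
series ends.

Genome-wide sample comparisons tile the genome into fixed 10-kb windows,
drop windows insufficiently covered in any sample, and feed the resulting
matrix to Ward hierarchical clustering (Euclidean distance) and PCA.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .io_formats import GeneModel

DEFAULT_MIN_DEPTH = 4


@dataclasses.dataclass(frozen=True)
class RegionLevel:
    """Weighted methylation level of one interval in one context."""

    chrom: str
    start: int
    end: int
    context: str
    level: float  # NaN when no qualifying site
    n_sites: int
    total_depth: int
    total_meth: int

    @property
    def missing(self) -> bool:
        return self.n_sites == 0


def _filter_sites(
    calls: pd.DataFrame, context: str, min_depth: int
) -> pd.DataFrame:
    return calls[(calls["context"] == context) & (calls["depth"] >= min_depth)]


def region_level(
    calls: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    context: str = "CG",
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> RegionLevel:
    """Weighted methylation level over [start, end) on ``chrom``."""
    sites = _filter_sites(calls, context, min_depth)
    sub = sites[
        (sites["chrom"] == chrom) & (sites["pos"] >= start) & (sites["pos"] < end)
    ]
    depth = int(sub["depth"].sum())
    meth = int(sub["meth_count"].sum())
    level = meth / depth if depth > 0 else float("nan")
    return RegionLevel(
        chrom=chrom, start=start, end=end, context=context,
        level=level, n_sites=len(sub), total_depth=depth, total_meth=meth,
    )


def pooled_interval_level(
    calls: pd.DataFrame,
    intervals,
    context: str = "CG",
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> RegionLevel:
    """Weighted level pooled over many (chrom, start, end) intervals.

    ``intervals`` is an iterable of (chrom, start, end) tuples; overlapping
    intervals double-count their shared sites, so callers should pass
    disjoint regions.  Uses per-chromosome prefix sums, so it is fast for
    hundreds of intervals.
    """
    sites = _filter_sites(calls, context, min_depth).sort_values("pos")
    by_chrom = {}
    for chrom, sub in sites.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        cm = np.concatenate([[0], np.cumsum(sub["meth_count"].to_numpy())])
        cd = np.concatenate([[0], np.cumsum(sub["depth"].to_numpy())])
        by_chrom[chrom] = (pos, cm, cd)
    meth = depth = n_sites = 0
    for chrom, start, end in intervals:
        if chrom not in by_chrom:
            continue
        pos, cm, cd = by_chrom[chrom]
        lo, hi = np.searchsorted(pos, [start, end])
        meth += int(cm[hi] - cm[lo])
        depth += int(cd[hi] - cd[lo])
        n_sites += int(hi - lo)
    return RegionLevel(
        chrom="*", start=0, end=0, context=context,
        level=meth / depth if depth else float("nan"),
        n_sites=n_sites, total_depth=depth, total_meth=meth,
    )


def pooled_level(
    calls: pd.DataFrame, context: str = "CG", min_depth: int = DEFAULT_MIN_DEPTH
) -> float:
    """Genome-wide weighted level for one context (NaN if uncovered)."""
    sites = _filter_sites(calls, context, min_depth)
    depth = sites["depth"].sum()
    return float(sites["meth_count"].sum() / depth) if depth > 0 else float("nan")


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class MetageneProfile:
    """Pooled per-bin methylation across genes, raw and smoothed.

    Bins run 5'→3' in transcription orientation: ``n_flank_bins`` upstream,
    ``body_bins`` over the body, ``n_flank_bins`` downstream.
    """

    raw: np.ndarray
    smoothed: np.ndarray
    n_flank_bins: int
    body_bins: int
    bin_depth: np.ndarray
    n_genes: int

    @property
    def n_bins(self) -> int:
        return 2 * self.n_flank_bins + self.body_bins

    @property
    def tss_bin(self) -> int:
        """Index of the first body bin (the TSS boundary)."""
        return self.n_flank_bins

    @property
    def tts_bin(self) -> int:
        return self.n_flank_bins + self.body_bins - 1

    def to_frame(self) -> pd.DataFrame:
        segment = (
            ["upstream"] * self.n_flank_bins
            + ["body"] * self.body_bins
            + ["downstream"] * self.n_flank_bins
        )
        return pd.DataFrame(
            {
                "bin": np.arange(self.n_bins),
                "segment": segment,
                "level": self.raw,
                "smoothed": self.smoothed,
                "total_depth": self.bin_depth,
            }
        )


def moving_average(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Centred moving average; the window shrinks symmetrically at the edges.

    NaN entries are ignored within each window (an all-NaN window stays NaN).
    """
    x = np.asarray(x, dtype=float)
    half = window // 2
    out = np.full_like(x, np.nan)
    for i in range(x.size):
        k = min(half, i, x.size - 1 - i)
        seg = x[i - k : i + k + 1]
        if np.isfinite(seg).any():
            out[i] = np.nanmean(seg)
    return out


def _gene_bin_indices(
    pos: np.ndarray, gene: GeneModel, flank: int, bin_size: int, body_bins: int
) -> np.ndarray:
    """Bin index (or -1) of each genomic position for one gene's metagene axis."""
    n_flank = flank // bin_size
    if gene.strand == "+":
        t = pos - gene.start
    else:
        t = (gene.end - 1) - pos
    idx = np.full(pos.shape, -1, dtype=np.int64)
    length = gene.length
    up = (t >= -flank) & (t < 0)
    idx[up] = (t[up] + flank) // bin_size
    body = (t >= 0) & (t < length)
    idx[body] = n_flank + (t[body] * body_bins) // length
    down = (t >= length) & (t < length + flank)
    idx[down] = n_flank + body_bins + (t[down] - length) // bin_size
    return idx


def metagene_profile(
    calls: pd.DataFrame,
    genes: Sequence[GeneModel],
    flank: int = 2000,
    body_bins: int = 60,
    bin_size: int = 100,
    context: str = "CG",
    min_depth: int = DEFAULT_MIN_DEPTH,
    smooth_window: int = 5,
) -> MetageneProfile:
    """Pooled metagene methylation profile over ``genes``.

    Per bin the level pools methylated and total read counts over all
    qualifying sites of all genes (weighted level), then the series is
    smoothed with a centred ``smooth_window``-bin moving average.
    """
    if not genes:
        raise ValueError("metagene_profile requires at least one gene")
    n_flank = flank // bin_size
    n_bins = 2 * n_flank + body_bins
    meth_sum = np.zeros(n_bins, dtype=np.int64)
    depth_sum = np.zeros(n_bins, dtype=np.int64)

    sites = _filter_sites(calls, context, min_depth)
    by_chrom = {
        chrom: (
            sub["pos"].to_numpy(),
            sub["meth_count"].to_numpy(),
            sub["depth"].to_numpy(),
        )
        for chrom, sub in sites.sort_values("pos").groupby("chrom", sort=False)
    }
    n_used = 0
    for gene in genes:
        if gene.chrom not in by_chrom:
            continue
        pos, meth, depth = by_chrom[gene.chrom]
        lo = np.searchsorted(pos, gene.start - flank)
        hi = np.searchsorted(pos, gene.end + flank)
        if hi <= lo:
            continue
        idx = _gene_bin_indices(pos[lo:hi], gene, flank, bin_size, body_bins)
        keep = idx >= 0
        if not keep.any():
            continue
        np.add.at(meth_sum, idx[keep], meth[lo:hi][keep])
        np.add.at(depth_sum, idx[keep], depth[lo:hi][keep])
        n_used += 1

    with np.errstate(invalid="ignore"):
        raw = np.where(depth_sum > 0, meth_sum / np.maximum(depth_sum, 1), np.nan)
    smoothed = moving_average(raw, smooth_window)
    return MetageneProfile(
        raw=raw,
        smoothed=smoothed,
        n_flank_bins=n_flank,
        body_bins=body_bins,
        bin_depth=depth_sum,
        n_genes=n_used,
    )


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


def compare_group_levels(levels_a, levels_b) -> tuple[float, float]:
    """Welch two-sided t-test on per-replicate region levels.

    Returns (difference of means a-b, p-value).  Identical groups give a
    difference of 0 and p = 1.  Requires >= 2 finite levels per group.
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if a.size < 2 or b.size < 2 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("compare_group_levels requires >= 2 finite levels per group")
    diff = float(a.mean() - b.mean())
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return diff, 1.0 if diff == 0 else 0.0
    t = stats.ttest_ind(a, b, equal_var=False)
    return diff, float(t.pvalue)


# ---------------------------------------------------------------------------
# window matrix / clustering / ordination
# ---------------------------------------------------------------------------


def window_matrix(
    calls_by_sample: Mapping[str, pd.DataFrame],
    chrom_lengths: Mapping[str, int],
    window: int = 10_000,
    min_sites: int = 5,
    context: str = "CG",
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> pd.DataFrame:
    """CG levels per fixed genome tile (rows) per sample (columns).

    Tiles with fewer than ``min_sites`` qualifying sites in any sample are
    dropped so between-sample distances remain comparable.
    """
    if len(calls_by_sample) < 2:
        raise ValueError("window_matrix requires >= 2 samples")
    index = []
    for chrom in sorted(chrom_lengths):
        n_tiles = int(np.ceil(chrom_lengths[chrom] / window))
        index.extend((chrom, i * window) for i in range(n_tiles))
    midx = pd.MultiIndex.from_tuples(index, names=["chrom", "window_start"])
    mat = pd.DataFrame(index=midx, columns=list(calls_by_sample), dtype=float)
    for sample, calls in calls_by_sample.items():
        sites = _filter_sites(calls, context, min_depth)
        if sites.empty:
            continue
        key = pd.MultiIndex.from_arrays(
            [sites["chrom"], (sites["pos"] // window) * window],
            names=["chrom", "window_start"],
        )
        grouped = sites.groupby(key).agg(
            meth=("meth_count", "sum"), depth=("depth", "sum"), n=("pos", "size")
        )
        ok = grouped[grouped["n"] >= min_sites]
        mat.loc[ok.index, sample] = (ok["meth"] / ok["depth"]).to_numpy()
    return mat.dropna(axis=0, how="any")


@dataclasses.dataclass(frozen=True)
class ClusterResult:
    linkage: np.ndarray
    samples: tuple[str, ...]
    pca_scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray

    def cut(self, k: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.samples, (int(x) for x in labels)))


def cluster_and_ordinate(matrix: pd.DataFrame, n_components: int = 2) -> ClusterResult:
    """Ward hierarchical clustering and PCA of samples on window levels.

    Observations are samples (matrix columns); features are genome windows.
    Features are centred before the singular value decomposition.  A
    degenerate (constant) matrix has no defined ordination and raises.
    """
    if matrix.shape[1] < 3:
        raise ValueError("cluster_and_ordinate requires >= 3 samples")
    if matrix.shape[0] < 10:
        raise ValueError("cluster_and_ordinate requires >= 10 windows")
    x = matrix.to_numpy(dtype=float).T  # samples x windows
    centred = x - x.mean(axis=0, keepdims=True)
    total_var = float((centred**2).sum())
    if total_var == 0.0:
        raise ValueError("window matrix is constant: ordination undefined")
    link = hierarchy.linkage(x, method="ward", metric="euclidean")
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    k = min(n_components, s.size)
    scores = u[:, :k] * s[:k]
    evr = (s**2 / (s**2).sum())[:k]
    pcs = pd.DataFrame(
        scores, index=list(matrix.columns),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return ClusterResult(
        linkage=link,
        samples=tuple(matrix.columns),
        pca_scores=pcs,
        explained_variance_ratio=evr,
    )


def linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(link)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.get_left(), node.dist)
        right = render(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"
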