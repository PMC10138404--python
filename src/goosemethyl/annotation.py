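"""CpG island detection and genomic region annotation.

A CpG island is an interval with GC content > 50%, length > 200 bp and
observed/expected CpG ratio > 0.6.  The detector uses a Takai-Jones-style
sliding window: every 201-bp window (step 1) passing all three thresholds
seeds an island, overlapping or adjacent seeds are merged, and each merged
interval is trimmed to its outermost CpG and revalidated so every emitted
island satisfies the printed thresholds.  Windows containing N never seed.

Shores are the 2-kb flanks of an island and shelves the next 2 kb beyond
the shores; where features of neighbouring islands collide, precedence is
island > shore > shelf, so the three kinds partition their covered bases.

Gene regulatory regions are strand-aware: the proximal promoter is the
2-kb region upstream of the TSS, the gene body runs TSS to TTS, and the
downstream region is the 2 kb past the TTS.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel

ISLAND_WINDOW = 201  # smallest integer length satisfying "length > 200 bp"
MIN_LENGTH = 200
MIN_GC = 0.5
MIN_OBS_EXP = 0.6

ISLAND_COLUMNS = ["chrom", "start", "end", "kind", "gc_fraction", "obs_exp_cpg", "n_cpg"]


@dataclasses.dataclass(frozen=True)
class IslandStats:
    gc_fraction: float
    obs_exp_cpg: float
    n_cpg: int
    length: int
    passes: bool


def check_island_thresholds(seq: str) -> IslandStats:
    """Evaluate the three island thresholds on a nucleotide string.

    N bases are excluded from base counts and from the effective length;
    CpG dinucleotides are counted on direct adjacency in the raw sequence.
    gc = (#C + #G)/L and obs/exp = (#CpG * L)/(#C * #G).  With #C or #G
    zero the ratio is undefined and the sequence fails.
    """
    seq = seq.upper()
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cpg = seq.count("CG")
    length = len(seq) - seq.count("N")
    if length == 0 or n_c == 0 or n_g == 0:
        return IslandStats(0.0, float("nan"), n_cpg, length, False)
    gc = (n_c + n_g) / length
    obs_exp = n_cpg * length / (n_c * n_g)
    passes = length > MIN_LENGTH and gc > MIN_GC and obs_exp > MIN_OBS_EXP
    return IslandStats(gc, obs_exp, n_cpg, length, passes)


def _window_pass_mask(seq: str, window: int = ISLAND_WINDOW) -> np.ndarray:
    """Boolean mask over window start positions: does [i, i+window) pass?"""
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    n = arr.size
    if n < window:
        return np.zeros(0, dtype=bool)
    is_c = (arr == b"C").astype(np.int64)
    is_g = (arr == b"G").astype(np.int64)
    is_n = (arr == b"N").astype(np.int64)
    is_cpg = np.zeros(n, dtype=np.int64)
    is_cpg[:-1] = (arr[:-1] == b"C") & (arr[1:] == b"G")

    def wsum(x: np.ndarray) -> np.ndarray:
        c = np.concatenate([[0], np.cumsum(x)])
        return c[window:] - c[:-window]

    n_c = wsum(is_c)
    n_g = wsum(is_g)
    n_n = wsum(is_n)
    # CpG straddling the right window edge does not belong to the window
    n_cpg = wsum(is_cpg) - is_cpg[window - 1 :]

    with np.errstate(divide="ignore", invalid="ignore"):
        gc = (n_c + n_g) / window
        obs_exp = np.where(
            (n_c > 0) & (n_g > 0), n_cpg * window / (n_c * n_g * 1.0), 0.0
        )
    return (n_n == 0) & (gc > MIN_GC) & (obs_exp > MIN_OBS_EXP)


def _trim_to_cpg(seq: str, start: int, end: int) -> tuple[int, int]:
    """Shrink [start, end) so it begins at a CpG C and ends after a CpG G."""
    sub = seq[start:end].upper()
    first = sub.find("CG")
    last = sub.rfind("CG")
    if first == -1:
        return start, start
    return start + first, start + last + 2


def detect_cpg_islands(
    genome: Mapping[str, str], window: int = ISLAND_WINDOW
) -> pd.DataFrame:
    """Detect CpG islands on every chromosome of ``genome``.

    Returns a DataFrame with columns chrom, start, end, kind(=island),
    gc_fraction, obs_exp_cpg, n_cpg.  Deterministic for a given genome and
    invariant to chromosome order (islands are reported per chromosome).
    """
    rows = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        mask = _window_pass_mask(seq, window)
        if mask.size == 0 or not mask.any():
            continue
        starts = np.flatnonzero(mask)
        # merge runs of passing windows into candidate intervals; window i
        # covers [i, i+window), so starts within `window` bp of the current
        # interval end produce overlapping or adjacent coverage
        candidates: list[tuple[int, int]] = []
        cur_s = int(starts[0])
        cur_e = cur_s + window
        for i in starts[1:]:
            i = int(i)
            if i <= cur_e:
                cur_e = i + window
            else:
                candidates.append((cur_s, cur_e))
                cur_s, cur_e = i, i + window
        candidates.append((cur_s, cur_e))

        for s, e in candidates:
            s, e = _trim_to_cpg(seq, s, e)
            stats = check_island_thresholds(seq[s:e]) if e > s else None
            while stats is not None and not stats.passes and e - s > window:
                # the merged interval can dilute below threshold: shrink from
                # whichever end improves composition more, one CpG at a time
                ls, le = _trim_to_cpg(seq, s + 2, e)
                rs, re = _trim_to_cpg(seq, s, e - 2)
                left = check_island_thresholds(seq[ls:le]) if le > ls else None
                right = check_island_thresholds(seq[rs:re]) if re > rs else None

                def score(st: Optional[IslandStats]) -> float:
                    if st is None or np.isnan(st.obs_exp_cpg):
                        return -np.inf
                    return st.gc_fraction + st.obs_exp_cpg

                if score(left) >= score(right):
                    s, e, stats = ls, le, left
                else:
                    s, e, stats = rs, re, right
            if stats is not None and stats.passes:
                rows.append(
                    {
                        "chrom": chrom,
                        "start": s,
                        "end": e,
                        "kind": "island",
                        "gc_fraction": stats.gc_fraction,
                        "obs_exp_cpg": stats.obs_exp_cpg,
                        "n_cpg": stats.n_cpg,
                    }
                )
    if not rows:
        return pd.DataFrame(columns=ISLAND_COLUMNS)
    return pd.DataFrame(rows, columns=ISLAND_COLUMNS).sort_values(
        ["chrom", "start"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# shores and shelves
# ---------------------------------------------------------------------------


def _subtract(intervals: list[tuple[int, int]], blockers: list[tuple[int, int]]):
    """Set difference of two lists of half-open intervals (both may overlap)."""
    out = []
    blockers = sorted(blockers)
    for s, e in sorted(intervals):
        cur = s
        for bs, be in blockers:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, min(bs, e)))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return _union(out)


def _union(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if s >= e:
            continue
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def derive_shores_shelves(
    islands: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    genome: Optional[Mapping[str, str]] = None,
    flank: int = 2000,
) -> pd.DataFrame:
    """Derive CpG shores (±2 kb of islands) and shelves (next ±2 kb).

    Features are clipped at chromosome ends and resolved with precedence
    island > shore > shelf so no base carries two kinds.  Composition
    columns are filled when ``genome`` is provided.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        isl = [
            (int(r.start), int(r.end))
            for r in islands[islands["chrom"] == chrom].itertuples()
        ]
        isl = _union(isl)
        shore_raw = [
            (max(0, s - flank), min(length, e + flank)) for s, e in isl
        ]
        shores = _subtract(shore_raw, isl)
        shelf_raw = [
            (max(0, s - 2 * flank), min(length, e + 2 * flank)) for s, e in isl
        ]
        shelves = _subtract(shelf_raw, isl + shores)
        for kind, feats in (("shore", shores), ("shelf", shelves)):
            for s, e in feats:
                stats = (
                    check_island_thresholds(genome[chrom][s:e])
                    if genome is not None
                    else None
                )
                rows.append(
                    {
                        "chrom": chrom,
                        "start": s,
                        "end": e,
                        "kind": kind,
                        "gc_fraction": stats.gc_fraction if stats else float("nan"),
                        "obs_exp_cpg": stats.obs_exp_cpg if stats else float("nan"),
                        "n_cpg": stats.n_cpg if stats else 0,
                    }
                )
    if not rows:
        return pd.DataFrame(columns=ISLAND_COLUMNS)
    return pd.DataFrame(rows, columns=ISLAND_COLUMNS).sort_values(
        ["chrom", "start"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene regulatory regions
# ---------------------------------------------------------------------------


Interval = tuple[int, int]


@dataclasses.dataclass(frozen=True)
class GeneRegions:
    """Strand-aware regulatory regions of one gene (half-open intervals)."""

    gene_id: str
    chrom: str
    strand: str
    upstream2k: Interval
    body: Interval
    downstream2k: Interval
    exons: tuple[Interval, ...]
    introns: tuple[Interval, ...]
    cds: tuple[Interval, ...]
    utr5: tuple[Interval, ...]
    utr3: tuple[Interval, ...]

    def region(self, region_type: str):
        return getattr(self, region_type)


def derive_gene_regions(
    gene: GeneModel, flank: int = 2000, chrom_length: Optional[int] = None
) -> GeneRegions:
    """Regulatory regions of a gene; "upstream" follows transcription.

    For a minus-strand gene the upstream 2 kb is genomically rightward of
    the TSS.  Regions are clipped to [0, chrom_length) when a length is
    given.
    """
    if flank <= 0:
        raise ValueError(f"flank must be positive, got {flank}")
    hi = chrom_length if chrom_length is not None else np.iinfo(np.int64).max

    def clip(s: int, e: int) -> Interval:
        return (max(0, min(s, hi)), max(0, min(e, hi)))

    if gene.strand == "+":
        upstream = clip(gene.start - flank, gene.start)
        downstream = clip(gene.end, gene.end + flank)
    else:
        upstream = clip(gene.end, gene.end + flank)
        downstream = clip(gene.start - flank, gene.start)
    body = clip(gene.start, gene.end)
    cds = (gene.cds,) if gene.cds is not None else ()
    return GeneRegions(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        upstream2k=upstream,
        body=body,
        downstream2k=downstream,
        exons=gene.exons,
        introns=gene.introns,
        cds=cds,
        utr5=gene.utr5,
        utr3=gene.utr3,
    )


def derive_all_gene_regions(
    genes: Sequence[GeneModel],
    flank: int = 2000,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> list[GeneRegions]:
    return [
        derive_gene_regions(
            g,
            flank=flank,
            chrom_length=chrom_lengths.get(g.chrom) if chrom_lengths else None,
        )
        for g in genes
    ]
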