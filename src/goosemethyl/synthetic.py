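"""Synthetic goose-like WGBS + expression dataset with planted truth.

The generator emulates the statistical structure the analysis assumes,
at a desk scale (two chromosomes of 500 kb, 200 genes, 2 breeds x 3
stages x 3 replicates by default):

* a CpG-depleted background genome with embedded CpG-rich segments that
  each satisfy the island thresholds (recorded as truth islands);
* strand-specific per-cytosine calls with Poisson read depth and binomial
  methylated counts; near-zero non-CG methylation driven only by the
  bisulfite conversion error (0.8% by default, inside the 0.69-0.88%
  range typical of real bird methylomes);
* a CG methylation surface with a methylation dip around the TSS, a gene-
  body plateau, a TTS-proximal elevation coupled to gene activity, breed-
  and stage-specific global offsets (the "STE-like" breed stays high while
  the "WZE-like" breed demethylates towards the latest stage), and planted
  DMRs of known effect size in upstream-2kb/body/downstream-2kb regions;
* FPKM expression spanning the four expression classes, anti-correlated
  with promoter methylation through a coupling coefficient, with a planted
  set of differentially expressed genes and a designated promoter gene
  carrying exactly 13 CpG sites in a fixed TSS-relative window (a
  pyrosequencing-style target).

Everything is regenerated bit-identically from ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io_formats
from .annotation import check_island_thresholds
from .io_formats import GeneModel

_A, _C, _G, _T = 65, 67, 71, 84
_CTX_NAMES = np.array(["CG", "CHG", "CHH"])


def _default_breed_offsets() -> dict:
    return {"WZE": 0.0, "STE": 0.015}


def _default_stage_offsets() -> dict:
    return {
        "WZE": {"E15": 0.0, "E23": -0.02, "P1": -0.05},
        "STE": {"E15": 0.0, "E23": 0.0, "P1": 0.0},
    }


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions of the synthetic dataset.

    Defaults are the package's standard toy scale; offsets encode the
    qualitative breed/stage pattern (the STE-like breed more methylated
    throughout, the WZE-like breed demethylating fastest between the two
    later stages).
    """

    # genome
    n_chrom: int = 2
    chrom_length: int = 500_000
    island_density: float = 2e-5  # islands per bp (10 per 500 kb chromosome)
    island_min_len: int = 400
    island_max_len: int = 800
    gc_background: float = 0.43
    cpg_retention: float = 0.25  # background obs/exp CpG after depletion
    # genes
    n_genes: int = 200
    gene_min_len: int = 1500
    gene_max_len: int = 3000
    # methylome surface
    level_intergenic: float = 0.70
    level_body: float = 0.76
    level_island: float = 0.15
    tss_dip_sd: float = 900.0  # bp, Gaussian half-width of the TSS dip
    tss_dip_min: float = 0.05
    tss_dip_max: float = 0.95
    tts_elev_max: float = 0.18
    tts_frac: float = 0.2  # fraction of the body carrying the TTS ramp
    breed_offsets: dict = dataclasses.field(default_factory=_default_breed_offsets)
    stage_offsets: dict = dataclasses.field(default_factory=_default_stage_offsets)
    # planted DMRs
    n_dmrs: int = 40
    dmr_delta: float = 0.5
    dmr_n_cpg: int = 8
    dmr_low_level: float = 0.2
    dmr_max_span: int = 900
    # designated promoter gene (pyrosequencing-style target)
    promoter_n_cpg: int = 13
    promoter_from: int = -723
    promoter_to: int = -480
    promoter_levels: dict = dataclasses.field(
        default_factory=lambda: {"STE": 0.75, "WZE": 0.35}
    )
    # sequencing
    mean_depth: float = 30.0
    conversion_error: float = 0.008
    # expression
    coupling: float = -12.0  # log2-FPKM units per unit promoter methylation
    dispersion: float = 0.1  # replicate noise sd on log2 FPKM
    log_fpkm_spread: float = 1.7
    fpkm_center: float = 15.0
    frac_silent: float = 0.08
    n_de_genes: int = 30
    de_fold_change: float = 4.0
    # design
    breeds: tuple = ("WZE", "STE")
    stages: tuple = ("E15", "E23", "P1")
    n_replicates: int = 3

    def validate(self) -> None:
        if self.chrom_length < 10_000:
            raise ValueError("chrom_length must be >= 10,000")
        if not 0.0 <= self.conversion_error <= 0.05:
            raise ValueError("conversion_error must be in [0, 0.05]")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")
        if self.coupling > 0:
            raise ValueError("coupling must be <= 0 (anti-correlation)")
        footprint = self.island_max_len + 4000
        if self.island_density * footprint > 1.0:
            raise ValueError("island_density too high: islands would overlap")


def _rng(seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, stream)]))


# ---------------------------------------------------------------------------
# genome and genes
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int, gc: float, cpg_retention: float) -> np.ndarray:
    """i.i.d. sequence at the given GC, then CpG-depleted to ~cpg_retention obs/exp."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=length, p=p)
    arr = np.array([_A, _C, _G, _T], dtype=np.uint8)[codes]
    cg = np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G))
    flip = cg[rng.random(cg.size) > cpg_retention]
    arr[flip + 1] = np.where(rng.random(flip.size) < 0.5, _A, _T).astype(np.uint8)
    return arr


def generate_genome(
    n_chrom: int = 2,
    chrom_length: int = 500_000,
    island_density: float = 2e-5,
    seed: int = 0,
    config: Optional[SimulationConfig] = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Background genome with embedded CpG islands recorded as truth.

    Returns ``(genome, truth_islands)``.  Every truth island satisfies the
    three island thresholds (checked at generation time).
    """
    cfg = config or SimulationConfig(
        n_chrom=n_chrom, chrom_length=chrom_length, island_density=island_density
    )
    cfg.validate()
    genome: dict[str, str] = {}
    rows = []
    for ci in range(cfg.n_chrom):
        chrom = f"chr{ci + 1}"
        rng = _rng(seed, 10, ci)
        arr = _random_seq(rng, cfg.chrom_length, cfg.gc_background, cfg.cpg_retention)
        n_islands = int(round(cfg.island_density * cfg.chrom_length))
        placed: list[tuple[int, int]] = []
        tries = 0
        while len(placed) < n_islands:
            tries += 1
            if tries > 1000 * max(n_islands, 1):
                raise ValueError("island_density too high: cannot place islands")
            length = int(rng.integers(cfg.island_min_len, cfg.island_max_len + 1))
            start = int(rng.integers(3000, cfg.chrom_length - length - 3000))
            if any(start < e + 2000 and start + length > s - 2000 for s, e in placed):
                continue
            for _ in range(20):
                block = _random_seq(rng, length, gc=0.62, cpg_retention=0.85)
                if check_island_thresholds(block.tobytes().decode()).passes:
                    break
            else:  # pragma: no cover - vanishingly unlikely
                continue
            arr[start : start + length] = block
            placed.append((start, start + length))
        for s, e in sorted(placed):
            stats = check_island_thresholds(arr[s:e].tobytes().decode())
            rows.append(
                {
                    "chrom": chrom, "start": s, "end": e,
                    "gc_fraction": stats.gc_fraction,
                    "obs_exp_cpg": stats.obs_exp_cpg,
                    "n_cpg": stats.n_cpg,
                }
            )
        genome[chrom] = arr.tobytes().decode()
    islands = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gc_fraction", "obs_exp_cpg", "n_cpg"]
    )
    return genome, islands


def place_genes(
    genome: Mapping[str, str], config: SimulationConfig, seed: int
) -> list[GeneModel]:
    """Lay out non-overlapping genes along each chromosome."""
    chroms = list(genome)
    quota = [config.n_genes // len(chroms)] * len(chroms)
    quota[0] += config.n_genes - sum(quota)
    genes: list[GeneModel] = []
    gid = 0
    for ci, chrom in enumerate(chroms):
        rng = _rng(seed, 20, ci)
        length = len(genome[chrom])
        cursor = 3000
        placed = 0
        while placed < quota[ci]:
            glen = int(rng.integers(config.gene_min_len, config.gene_max_len + 1))
            gap = int(rng.integers(1000, 3001))
            if cursor + glen + 3000 > length:
                raise ValueError(
                    f"cannot place {config.n_genes} genes: {chrom} too short"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(1, 6))
            grid = np.arange(100, glen - 100, 25)
            if n_ex > 1 and grid.size >= 2 * (n_ex - 1):
                cuts = np.sort(rng.choice(grid, size=2 * (n_ex - 1), replace=False))
                bounds = [0, *cuts.tolist(), glen]
            else:
                bounds = [0, glen]
            exons = tuple(
                (cursor + bounds[i], cursor + bounds[i + 1])
                for i in range(0, len(bounds) - 1, 2)
            )
            cds = (cursor + 150, cursor + glen - 150) if glen >= 600 else None
            gid += 1
            genes.append(
                GeneModel(
                    gene_id=f"g{gid:04d}", chrom=chrom, strand=strand,
                    start=cursor, end=cursor + glen, exons=exons, cds=cds,
                )
            )
            cursor += glen + gap
            placed += 1
    return genes


def _plant_promoter_sites(
    genome: dict[str, str], genes: Sequence[GeneModel], islands: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[str, np.ndarray]:
    """Rewrite one plus-strand gene's promoter window to hold exactly
    ``promoter_n_cpg`` CpG dyads (A/T filler elsewhere).

    Returns (gene_id, dyad positions).
    """
    lo, hi = config.promoter_from, config.promoter_to  # e.g. -723, -480
    span = hi - lo + 1
    spacing = (span - 2) // max(config.promoter_n_cpg - 1, 1)
    for gene in genes:
        if gene.strand != "+" or gene.tss + lo < 0:
            continue
        w_start, w_end = gene.tss + lo, gene.tss + hi + 1
        isl = islands[islands["chrom"] == gene.chrom]
        if ((isl["start"] < w_end) & (isl["end"] > w_start)).any():
            continue
        arr = np.frombuffer(genome[gene.chrom].encode(), dtype=np.uint8).copy()
        block = np.full(span, _A, dtype=np.uint8)
        block[1::2] = _T
        dyads = w_start + spacing * np.arange(config.promoter_n_cpg)
        block[dyads - w_start] = _C
        block[dyads - w_start + 1] = _G
        arr[w_start:w_end] = block
        # the filler must not chain a CpG across the window boundary
        if w_start > 0 and arr[w_start - 1] == _C and arr[w_start] == _G:
            arr[w_start - 1] = _T  # unreachable with A-leading filler; safety
        genome[gene.chrom] = arr.tobytes().decode()
        return gene.gene_id, dyads
    raise ValueError("no suitable plus-strand gene for the promoter target")


# ---------------------------------------------------------------------------
# cytosine site enumeration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CytosineSites:
    """All cytosine positions of one chromosome, both strands, sorted by pos."""

    pos: np.ndarray
    strand: np.ndarray  # "+" / "-"
    ctx_code: np.ndarray  # 0=CG 1=CHG 2=CHH
    dyad_index: np.ndarray  # index into dyad_pos for CG sites, -1 otherwise
    dyad_pos: np.ndarray  # genomic position of the C of each CG dyad


def enumerate_cytosines(seq: str) -> CytosineSites:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = arr.size
    is_c = arr == _C
    is_g = arr == _G
    nxt1 = np.zeros(n, dtype=np.uint8)
    nxt1[:-1] = arr[1:]
    nxt2 = np.zeros(n, dtype=np.uint8)
    nxt2[:-2] = arr[2:]
    prv1 = np.zeros(n, dtype=np.uint8)
    prv1[1:] = arr[:-1]
    prv2 = np.zeros(n, dtype=np.uint8)
    prv2[2:] = arr[:-2]

    pos_p = np.flatnonzero(is_c)
    ctx_p = np.where(nxt1[pos_p] == _G, 0, np.where(nxt2[pos_p] == _G, 1, 2))
    pos_m = np.flatnonzero(is_g)
    ctx_m = np.where(prv1[pos_m] == _C, 0, np.where(prv2[pos_m] == _C, 1, 2))

    dyad_pos = np.flatnonzero(is_c[:-1] & is_g[1:])
    di_p = np.where(ctx_p == 0, np.searchsorted(dyad_pos, pos_p), -1)
    di_m = np.where(ctx_m == 0, np.searchsorted(dyad_pos, pos_m - 1), -1)

    pos = np.concatenate([pos_p, pos_m])
    strand = np.concatenate([np.repeat("+", pos_p.size), np.repeat("-", pos_m.size)])
    ctx = np.concatenate([ctx_p, ctx_m])
    dyad = np.concatenate([di_p, di_m])
    order = np.argsort(pos, kind="stable")
    return CytosineSites(
        pos=pos[order], strand=strand[order], ctx_code=ctx[order],
        dyad_index=dyad[order], dyad_pos=dyad_pos,
    )


# ---------------------------------------------------------------------------
# methylation surface
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MethylationSurface:
    """True CG-dyad methylation probabilities plus planted structure."""

    config: SimulationConfig
    base: dict  # chrom -> per-dyad base probability
    dyad_pos: dict  # chrom -> dyad positions
    overrides: dict  # breed -> chrom -> (dyad indices, absolute levels)
    gene_table: pd.DataFrame  # per-gene latent parameters
    dmrs: pd.DataFrame  # planted truth DMRs
    promoter_gene: str
    promoter_dyads: np.ndarray

    def true_level(self, chrom: str, breed: str, stage: str) -> np.ndarray:
        cfg = self.config
        p = (
            self.base[chrom]
            + cfg.breed_offsets[breed]
            + cfg.stage_offsets[breed][stage]
        )
        idx, levels = self.overrides.get(breed, {}).get(chrom, (None, None))
        if idx is not None:
            p = p.copy()
            p[idx] = levels
        return np.clip(p, 0.0, 1.0)

    def region_mean(self, chrom: str, start: int, end: int, breed: str, stage: str) -> float:
        d = self.dyad_pos[chrom]
        lo, hi = np.searchsorted(d, [start, end])
        if hi <= lo:
            return float("nan")
        return float(self.true_level(chrom, breed, stage)[lo:hi].mean())


def _upstream_interval(gene: GeneModel, flank: int = 2000) -> tuple[int, int]:
    if gene.strand == "+":
        return max(0, gene.start - flank), gene.start
    return gene.end, gene.end + flank


def build_surface(
    genome: dict[str, str],
    genes: Sequence[GeneModel],
    islands: pd.DataFrame,
    config: SimulationConfig,
    seed: int,
    promoter_gene: str,
    promoter_dyads: np.ndarray,
) -> MethylationSurface:
    """Construct the true methylation surface and plant DMRs."""
    rng = _rng(seed, 30)
    dyad_pos = {c: enumerate_cytosines(genome[c]).dyad_pos for c in genome}
    base = {c: np.full(dyad_pos[c].size, config.level_intergenic) for c in genome}

    # islands are lowly methylated
    for r in islands.itertuples():
        d = dyad_pos[r.chrom]
        lo, hi = np.searchsorted(d, [r.start, r.end])
        base[r.chrom][lo:hi] = config.level_island

    n = len(genes)
    dip = rng.uniform(config.tss_dip_min, config.tss_dip_max, size=n)
    b_latent = rng.normal(0.0, config.log_fpkm_spread, size=n)
    activity = np.argsort(np.argsort(b_latent)) / max(n - 1, 1)
    elev = np.where(
        activity <= 0.8,
        config.tts_elev_max * activity,
        config.tts_elev_max * 0.3,
    )

    for gi, gene in enumerate(genes):
        d = dyad_pos[gene.chrom]
        arr = base[gene.chrom]
        lo, hi = np.searchsorted(d, [gene.start, gene.end])
        arr[lo:hi] = config.level_body
        # TSS dip, Gaussian in transcription-oriented distance
        t_lo, t_hi = np.searchsorted(d, [gene.start - 2000, gene.end + 2000])
        pos = d[t_lo:t_hi]
        t = (pos - gene.tss) if gene.strand == "+" else (gene.tss - pos)
        w = np.exp(-(t.astype(float) ** 2) / (2 * config.tss_dip_sd**2))
        inside = np.abs(t) <= 2000
        arr[t_lo:t_hi] = np.where(
            inside, arr[t_lo:t_hi] * (1 - dip[gi] * w), arr[t_lo:t_hi]
        )
        # TTS-proximal elevation over the last fraction of the body
        tb = (pos - gene.start) if gene.strand == "+" else (gene.end - 1 - pos)
        frac = tb / gene.length
        ramp_lo = 1.0 - config.tts_frac
        in_ramp = (frac >= ramp_lo) & (frac < 1.0) & (pos >= gene.start) & (pos < gene.end)
        ramp = np.clip((frac - ramp_lo) / config.tts_frac, 0, 1)
        arr[t_lo:t_hi] = np.where(
            in_ramp, arr[t_lo:t_hi] + elev[gi] * ramp, arr[t_lo:t_hi]
        )

    for c in base:
        np.clip(base[c], 0.01, 0.99, out=base[c])

    # silent genes and planted DE genes
    silent = np.zeros(n, dtype=bool)
    silent[rng.choice(n, size=int(round(config.frac_silent * n)), replace=False)] = True
    prom_idx = next(i for i, g in enumerate(genes) if g.gene_id == promoter_gene)
    silent[prom_idx] = False

    # plant DMRs on expressed genes (region types cycle), never on the
    # designated promoter gene
    candidates = [
        i for i in rng.permutation(n)
        if not silent[i] and i != prom_idx
    ]
    region_types = ("upstream2k", "body", "downstream2k")
    used_dyads: dict[str, set] = {c: set() for c in genome}
    # reserve the designated promoter dyads so no DMR is planted on them
    prom_gene = genes[prom_idx]
    prom_dyad_idx = np.searchsorted(dyad_pos[prom_gene.chrom], promoter_dyads)
    used_dyads[prom_gene.chrom].update(int(x) for x in promoter_dyads)
    dmr_rows = []
    overrides: dict[str, dict[str, dict[int, float]]] = {
        b: {c: {} for c in genome} for b in config.breeds
    }
    dmr_gene_idx: set[int] = set()
    k = 0
    for i in candidates:
        if len(dmr_rows) >= config.n_dmrs:
            break
        gene = genes[i]
        region_type = region_types[k % 3]
        if region_type == "upstream2k":
            s, e = _upstream_interval(gene)
        elif region_type == "body":
            s, e = gene.start, gene.end
        else:
            us, ue = _upstream_interval(gene)
            s, e = (gene.end, gene.end + 2000) if gene.strand == "+" else (
                max(0, gene.start - 2000), gene.start)
        d = dyad_pos[gene.chrom]
        lo, hi = np.searchsorted(d, [s, e])
        window = None
        for j in range(lo, hi - config.dmr_n_cpg + 1):
            cand = d[j : j + config.dmr_n_cpg]
            if cand[-1] - cand[0] > config.dmr_max_span:
                continue
            if any(int(x) in used_dyads[gene.chrom] for x in cand):
                continue
            if gene.gene_id == promoter_gene:
                continue
            window = (j, cand)
            break
        if window is None:
            continue
        j, cand = window
        used_dyads[gene.chrom].update(int(x) for x in cand)
        high_breed = config.breeds[len(dmr_rows) % 2]
        low_level = config.dmr_low_level
        high_level = low_level + config.dmr_delta
        levels = {}
        for breed in config.breeds:
            level = high_level if breed == high_breed else low_level
            levels[breed] = level
            for off in range(config.dmr_n_cpg):
                overrides[breed][gene.chrom][j + off] = level
        dmr_rows.append(
            {
                "chrom": gene.chrom,
                "start": int(cand[0]),
                "end": int(cand[-1]) + 2,
                "gene_id": gene.gene_id,
                "region_type": region_type,
                "n_cpg": config.dmr_n_cpg,
                **{f"level_{b}": levels[b] for b in config.breeds},
            }
        )
        dmr_gene_idx.add(i)
        k += 1

    # designated promoter: breed-specific absolute levels at its 13 dyads
    prom_gene = genes[prom_idx]
    d = dyad_pos[prom_gene.chrom]
    prom_dyad_idx = np.searchsorted(d, promoter_dyads)
    for breed in config.breeds:
        for j in prom_dyad_idx:
            overrides[breed][prom_gene.chrom][int(j)] = config.promoter_levels[breed]

    packed = {
        b: {
            c: (
                np.array(sorted(overrides[b][c]), dtype=np.int64),
                np.array([overrides[b][c][j] for j in sorted(overrides[b][c])]),
            )
            for c in overrides[b]
            if overrides[b][c]
        }
        for b in overrides
    }

    # planted DE genes: expressed, not the promoter target, not DMR-planted,
    # and with a promoter clear of every planted DMR interval — a DMR in a
    # neighbouring gene's flank can fall inside this gene's upstream 2 kb and
    # would couple into its expression, confounding the planted fold change
    dmr_intervals: dict[str, list[tuple[int, int]]] = {}
    for row in dmr_rows:
        dmr_intervals.setdefault(row["chrom"], []).append((row["start"], row["end"]))

    def _promoter_clear(i: int) -> bool:
        s, e = _upstream_interval(genes[i])
        return not any(
            s < de and e > ds
            for ds, de in dmr_intervals.get(genes[i].chrom, ())
        )

    de_sign = np.zeros(n, dtype=int)
    de_candidates = [
        i for i in rng.permutation(n)
        if not silent[i] and i != prom_idx and i not in dmr_gene_idx
        and b_latent[i] > np.median(b_latent) and _promoter_clear(i)
    ]
    for j, i in enumerate(de_candidates[: config.n_de_genes]):
        de_sign[i] = 1 if j % 2 == 0 else -1

    gene_table = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
            "tts": [g.tts for g in genes],
            "dip": dip,
            "log2_base": b_latent,
            "activity": activity,
            "tts_elevation": elev,
            "silent": silent,
            "de_sign": de_sign,
            "has_dmr": [i in dmr_gene_idx for i in range(n)],
        }
    )
    dmrs = pd.DataFrame(
        dmr_rows,
        columns=["chrom", "start", "end", "gene_id", "region_type", "n_cpg"]
        + [f"level_{b}" for b in config.breeds],
    )
    return MethylationSurface(
        config=config,
        base=base,
        dyad_pos=dyad_pos,
        overrides=packed,
        gene_table=gene_table,
        dmrs=dmrs,
        promoter_gene=promoter_gene,
        promoter_dyads=promoter_dyads,
    )


# ---------------------------------------------------------------------------
# methylome and expression simulation
# ---------------------------------------------------------------------------


def simulate_methylome(
    sites_by_chrom: Mapping[str, CytosineSites],
    surface: MethylationSurface,
    breed: str,
    stage: str,
    mean_depth: float,
    conversion_error: float,
    seed: int,
    stream: int = 0,
) -> pd.DataFrame:
    """One sample's strand-specific per-cytosine call table.

    Depth is Poisson(mean_depth); the methylated count is binomial with
    success probability equal to the true CG level (0 at non-CG sites)
    plus symmetric conversion-error leakage: an unmethylated read appears
    methylated with probability ``conversion_error``.  Zero-depth sites
    are not reported (the table holds covered cytosines only).
    """
    if not 0.0 <= conversion_error <= 0.05:
        raise ValueError("conversion_error must be in [0, 0.05]")
    if mean_depth < 1:
        raise ValueError("mean_depth must be >= 1")
    rng = _rng(seed, 40, stream)
    frames = []
    for chrom in sorted(sites_by_chrom):
        sites = sites_by_chrom[chrom]
        p_true = np.zeros(sites.pos.size)
        cg = sites.dyad_index >= 0
        levels = surface.true_level(chrom, breed, stage)
        p_true[cg] = levels[sites.dyad_index[cg]]
        p_eff = p_true + (1.0 - p_true) * conversion_error
        depth = rng.poisson(mean_depth, size=sites.pos.size)
        meth = rng.binomial(depth, p_eff)
        keep = depth > 0
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": sites.pos[keep],
                    "strand": sites.strand[keep],
                    "context": _CTX_NAMES[sites.ctx_code[keep]],
                    "depth": depth[keep],
                    "meth_count": meth[keep],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_expression(
    genes: Sequence[GeneModel],
    surface: MethylationSurface,
    sample_sheet: pd.DataFrame,
    coupling: float,
    dispersion: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM matrix (genes x samples) and truth differential-expression labels.

    Per sample, log2 FPKM = gene base + coupling * true promoter
    (upstream-2kb) methylation of the sample's breed/stage + log-normal
    replicate noise; planted DE genes get a fixed fold change in the
    STE-like breed; silent genes stay at exactly 0.
    """
    if coupling > 0:
        raise ValueError("coupling must be <= 0")
    cfg = surface.config
    gt = surface.gene_table
    n = len(genes)
    prom = {}
    groups = sorted({(r.breed, r.stage) for r in sample_sheet.itertuples()})
    for (breed, stage) in groups:
        vals = np.empty(n)
        for i, gene in enumerate(genes):
            s, e = _upstream_interval(gene)
            vals[i] = surface.region_mean(gene.chrom, s, e, breed, stage)
        prom[(breed, stage)] = np.nan_to_num(vals, nan=cfg.level_intergenic)
    mean_prom = np.mean([v.mean() for v in prom.values()])
    b0 = np.log2(cfg.fpkm_center) - coupling * mean_prom
    base = b0 + gt["log2_base"].to_numpy()

    rng = _rng(seed, 50)
    de_sign = gt["de_sign"].to_numpy()
    silent = gt["silent"].to_numpy()
    log_fc = np.log2(cfg.de_fold_change)
    cols = {}
    for r in sample_sheet.itertuples():
        noise = rng.normal(0.0, dispersion, size=n)
        log2fpkm = base + coupling * prom[(r.breed, r.stage)] + noise
        if r.breed == "STE":
            log2fpkm = log2fpkm + de_sign * log_fc
        fpkm = np.power(2.0, log2fpkm)
        fpkm[silent] = 0.0
        cols[r.sample_id] = fpkm
    fpkm_df = pd.DataFrame(cols, index=[g.gene_id for g in genes])
    fpkm_df.index.name = "gene_id"
    truth_de = pd.DataFrame(
        {
            "gene_id": gt["gene_id"],
            "de_sign": de_sign,
            "log2_fc_STE_vs_WZE": de_sign * log_fc,
        }
    )
    truth_de = truth_de[truth_de["de_sign"] != 0].reset_index(drop=True)
    return fpkm_df, truth_de


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SyntheticDataset:
    config: SimulationConfig
    seed: int
    genome: dict[str, str]
    genes: list[GeneModel]
    islands: pd.DataFrame
    surface: MethylationSurface
    sample_sheet: pd.DataFrame
    calls: dict[str, pd.DataFrame]  # sample_id -> call table
    fpkm: pd.DataFrame
    truth_de: pd.DataFrame

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}

    def samples(self, breed: str, stage: str) -> list[str]:
        sheet = self.sample_sheet
        return list(
            sheet.loc[(sheet["breed"] == breed) & (sheet["stage"] == stage), "sample_id"]
        )

    def group_calls(self, breed: str, stage: str) -> list[pd.DataFrame]:
        return [self.calls[s] for s in self.samples(breed, stage)]

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        (out / "calls").mkdir(parents=True, exist_ok=True)
        (out / "truth").mkdir(exist_ok=True)
        io_formats.write_fasta(self.genome, out / "genome.fa")
        io_formats.write_gene_models_gff3(self.genes, out / "genes.gff3")
        self.sample_sheet.to_csv(out / "samples.tsv", sep="\t", index=False)
        for sample_id, calls in self.calls.items():
            io_formats.write_methylation_table(calls, out / "calls" / f"{sample_id}.tsv")
        io_formats.write_fpkm(self.fpkm, out / "fpkm.tsv")
        self.islands.to_csv(out / "truth" / "islands.tsv", sep="\t", index=False)
        self.surface.dmrs.to_csv(out / "truth" / "dmrs.tsv", sep="\t", index=False)
        self.truth_de.to_csv(out / "truth" / "de_genes.tsv", sep="\t", index=False)
        self.surface.gene_table.to_csv(out / "truth" / "genes.tsv", sep="\t", index=False)
        prom = pd.DataFrame(
            {
                "gene_id": self.surface.promoter_gene,
                "dyad_pos": self.surface.promoter_dyads,
                **{
                    f"level_{b}": self.config.promoter_levels[b]
                    for b in self.config.breeds
                },
            }
        )
        prom.to_csv(out / "truth" / "promoter.tsv", sep="\t", index=False)


def make_sample_sheet(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for breed in config.breeds:
        for stage in config.stages:
            for rep in range(1, config.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{breed}_{stage}_r{rep}",
                        "breed": breed,
                        "stage": stage,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


def generate_dataset(
    config: Optional[SimulationConfig] = None, seed: int = 0
) -> SyntheticDataset:
    """Generate the full synthetic study: genome, genes, 18 methylomes,
    expression matrix and truth tables.  Bit-identical for a given
    ``(config, seed)``."""
    cfg = config or SimulationConfig()
    cfg.validate()
    genome, islands = generate_genome(seed=seed, config=cfg)
    genes = place_genes(genome, cfg, seed)
    promoter_gene, promoter_dyads = _plant_promoter_sites(genome, genes, islands, cfg)
    surface = build_surface(genome, genes, islands, cfg, seed, promoter_gene, promoter_dyads)
    sites = {c: enumerate_cytosines(genome[c]) for c in genome}
    sheet = make_sample_sheet(cfg)
    calls = {}
    for i, r in enumerate(sheet.itertuples()):
        calls[r.sample_id] = simulate_methylome(
            sites, surface, r.breed, r.stage,
            cfg.mean_depth, cfg.conversion_error, seed, stream=i,
        )
    fpkm, truth_de = simulate_expression(
        genes, surface, sheet, cfg.coupling, cfg.dispersion, seed
    )
    return SyntheticDataset(
        config=cfg, seed=seed, genome=genome, genes=genes, islands=islands,
        surface=surface, sample_sheet=sheet, calls=calls, fpkm=fpkm,
        truth_de=truth_de,
    )
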