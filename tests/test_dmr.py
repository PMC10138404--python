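"""DMR calling: Fisher window test, BH adjustment, merging, DMGs."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from goosemethyl import dmr
from goosemethyl.annotation import GeneRegions
from goosemethyl.io_formats import CALL_COLUMNS


def fisher_two_sided_oracle(a, b, c, d) -> float:
    """Exact two-sided Fisher p by hypergeometric enumeration (Fractions)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(k):
        return Fraction(
            math.comb(c1, k) * math.comb(n - c1, r1 - k), math.comb(n, r1)
        )

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum(
        (pk for k in range(lo, hi + 1) if (pk := pmf(k)) <= p_obs), Fraction(0)
    )
    return float(total)


class TestWindowTest:
    def test_identical_tables(self):
        assert dmr.test_window((50, 100), (50, 100)) == pytest.approx(1.0)

    def test_extreme_difference(self):
        assert dmr.test_window((90, 100), (10, 100)) < 1e-10

    def test_zero_depth_is_error(self):
        with pytest.raises(ValueError):
            dmr.test_window((0, 0), (5, 10))

    def test_matches_hypergeometric_enumeration(self):
        depths = [2, 3, 5, 8, 12]
        for da in depths:
            for db in depths:
                for ma in range(da + 1):
                    for mb in range(db + 1):
                        got = dmr.test_window((ma, da), (mb, db))
                        want = fisher_two_sided_oracle(ma, da - ma, mb, db - mb)
                        assert got == pytest.approx(want, rel=1e-9, abs=1e-12), (
                            ma, da, mb, db
                        )


class TestBenjaminiHochberg:
    def bh_oracle(self, p):
        """Hand-written step-up procedure."""
        p = np.asarray(p, dtype=float)
        m = p.size
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        return adj

    def test_matches_reference_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(rng.integers(1, 200))
            np.testing.assert_allclose(dmr.bh_adjust(p), self.bh_oracle(p), atol=1e-12)

    def test_empty(self):
        assert dmr.bh_adjust([]).size == 0


def two_group_calls(
    n_sites=60, spacing=60, depth=30, base=0.5,
    block=(20, 28), delta=0.5, reps=3, seed=0,
):
    """Replicate call tables for two groups with one planted block difference."""
    rng = np.random.default_rng(seed)
    pos = np.arange(n_sites) * spacing + 100
    level_a = np.full(n_sites, base)
    level_b = np.full(n_sites, base)
    level_a[block[0] : block[1]] = base + delta / 2
    level_b[block[0] : block[1]] = base - delta / 2

    def group(levels):
        out = []
        for _ in range(reps):
            d = rng.poisson(depth, n_sites)
            m = rng.binomial(d, levels)
            out.append(
                pd.DataFrame(
                    {"chrom": "c", "pos": pos, "strand": "+", "context": "CG",
                     "depth": d, "meth_count": m}
                )
            )
        return out

    return group(level_a), group(level_b), (int(pos[block[0]]), int(pos[block[1] - 1]) + 1)


class TestCallDmrs:
    def test_planted_block_recovered(self):
        calls_a, calls_b, (s, e) = two_group_calls()
        out = dmr.call_dmrs(calls_a, calls_b)
        assert len(out) == 1
        r = out.iloc[0]
        assert r["start"] < e and r["end"] > s
        assert r["direction"] == "gain" and r["delta"] > 0.25
        assert not dmr.validate_dmrs(out, calls_a, calls_b)

    def test_group_swap_symmetry(self):
        calls_a, calls_b, _ = two_group_calls()
        fwd = dmr.call_dmrs(calls_a, calls_b)
        rev = dmr.call_dmrs(calls_b, calls_a)
        assert fwd[["chrom", "start", "end", "n_cpg"]].equals(
            rev[["chrom", "start", "end", "n_cpg"]]
        )
        np.testing.assert_allclose(fwd["delta"], -rev["delta"], atol=1e-12)
        assert (fwd["direction"] == "gain").equals(rev["direction"] == "loss")

    def test_short_window_never_reported(self):
        # only 4 CpGs differ and the rest are flat: nothing reaches 5 CpGs
        calls_a, calls_b, _ = two_group_calls(n_sites=4, block=(0, 4), spacing=100)
        out = dmr.call_dmrs(calls_a, calls_b)
        assert out.empty

    def test_gap_rule_blocks_spread_out_sites(self):
        # identical strong difference, but neighbouring CpGs 2 kb apart
        calls_a, calls_b, _ = two_group_calls(
            n_sites=12, block=(0, 12), spacing=2000
        )
        assert dmr.call_dmrs(calls_a, calls_b).empty

    def test_no_shared_sites(self):
        calls_a, calls_b, _ = two_group_calls(n_sites=6, block=(0, 6))
        moved = [c.assign(pos=c["pos"] + 10_000) for c in calls_b]
        assert dmr.call_dmrs(calls_a, moved).empty


def make_regions():
    return [
        GeneRegions(
            gene_id="g1", chrom="c", strand="+",
            upstream2k=(3000, 5000), body=(5000, 8000), downstream2k=(8000, 10_000),
            exons=((5000, 8000),), introns=(), cds=(), utr5=(), utr3=(),
        ),
        GeneRegions(
            gene_id="g2", chrom="c", strand="+",
            upstream2k=(5500, 7500), body=(7500, 9500), downstream2k=(9500, 11_500),
            exons=((7500, 9500),), introns=(), cds=(), utr5=(), utr3=(),
        ),
    ]


def dmr_row(start, end, delta, depth=600):
    return {
        "chrom": "c", "start": start, "end": end, "n_cpg": 6,
        "total_depth": depth, "level_a": 0.5 + delta / 2, "level_b": 0.5 - delta / 2,
        "delta": delta, "p_value": 1e-9, "q_value": 1e-8,
        "direction": "gain" if delta > 0 else "loss",
    }


class TestAssignDmrGenes:
    def test_dmr_inside_upstream(self):
        dmrs = pd.DataFrame([dmr_row(3500, 4200, 0.4)])
        out = dmr.assign_dmr_genes(dmrs, make_regions())
        rec = out[(out.gene_id == "g1") & (out.region_type == "upstream2k")]
        assert len(rec) == 1 and rec.iloc[0]["direction"] == "M+"

    def test_dmr_overlapping_two_bodies(self):
        dmrs = pd.DataFrame([dmr_row(7600, 7900, -0.3)])
        out = dmr.assign_dmr_genes(dmrs, make_regions())
        body_hits = out[out.region_type == "body"]["gene_id"].tolist()
        assert body_hits == ["g1", "g2"]

    def test_equal_gain_and_loss_is_tie(self):
        dmrs = pd.DataFrame(
            [dmr_row(5100, 5300, 0.4, depth=500), dmr_row(6100, 6300, -0.3, depth=500)]
        )
        out = dmr.assign_dmr_genes(dmrs, make_regions())
        rec = out[(out.gene_id == "g1") & (out.region_type == "body")]
        assert rec.iloc[0]["direction"] == "tie"


class TestCallDmgs:
    def test_log_fold_change_arithmetic(self):
        # levels 0.8 vs 0.2 at high depth: strong candidate with lfc ~ 1.95
        calls_a, calls_b, _ = two_group_calls(
            n_sites=30, block=(0, 30), base=0.5, delta=0.6, depth=60, spacing=60
        )
        gr = [
            GeneRegions(
                gene_id="g", chrom="c", strand="+",
                upstream2k=(0, 100), body=(100, 4000), downstream2k=(4000, 6000),
                exons=(), introns=(), cds=(), utr5=(), utr3=(),
            )
        ]
        out = dmr.call_dmgs(calls_a, calls_b, gr, return_all=True)
        body = out[out.region_type == "body"].iloc[0]
        expected = np.log2((body.level_a + 0.01) / (body.level_b + 0.01))
        assert body.log2_fc_methylation == pytest.approx(expected)
        assert body.is_dmg and body.direction == "M+"

    def test_equal_levels_never_reported(self):
        calls_a, calls_b, _ = two_group_calls(n_sites=30, block=(0, 1), delta=0.0)
        gr = make_regions()
        out = dmr.call_dmgs(calls_a, calls_b, gr)
        assert out.empty

    def test_zero_level_is_finite_via_pseudocount(self):
        calls_a, calls_b, _ = two_group_calls(
            n_sites=20, block=(0, 20), base=0.25, delta=0.5, depth=80
        )  # group b level ~ 0
        gr = [
            GeneRegions(
                gene_id="g", chrom="c", strand="+",
                upstream2k=(0, 50), body=(50, 3000), downstream2k=(3000, 5000),
                exons=(), introns=(), cds=(), utr5=(), utr3=(),
            )
        ]
        out = dmr.call_dmgs(calls_a, calls_b, gr, return_all=True)
        assert np.isfinite(out["log2_fc_methylation"]).all()
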