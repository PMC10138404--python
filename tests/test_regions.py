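"""Region levels, metagene profiles, window matrices, clustering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from goosemethyl import regions
from goosemethyl.io_formats import CALL_COLUMNS, GeneModel


def calls_frame(rows):
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


class TestRegionLevel:
    def test_weighted_quotient(self):
        calls = calls_frame(
            [("c", 10, "+", "CG", 10, 5), ("c", 20, "-", "CG", 10, 0)]
        )
        rl = regions.region_level(calls, "c", 0, 100)
        assert rl.level == pytest.approx(0.25)
        assert rl.n_sites == 2 and rl.total_depth == 20

    def test_low_depth_sites_are_missing_not_zero(self):
        calls = calls_frame([("c", 10, "+", "CG", 3, 3)])
        rl = regions.region_level(calls, "c", 0, 100)
        assert rl.missing and np.isnan(rl.level)

    def test_uncovered_interval_missing(self):
        calls = calls_frame([("c", 10, "+", "CG", 10, 5)])
        assert regions.region_level(calls, "c", 5000, 6000).missing

    def test_matches_brute_force_on_random_calls(self):
        rng = np.random.default_rng(2)
        depth = rng.integers(0, 40, 300)
        calls = calls_frame(
            [
                ("c", int(p), "+", "CG", int(d), int(rng.integers(0, d + 1)))
                for p, d in zip(rng.choice(10_000, 300, replace=False), depth)
            ]
        )
        rl = regions.region_level(calls, "c", 2000, 7000)
        sub = calls[(calls.pos >= 2000) & (calls.pos < 7000) & (calls.depth >= 4)]
        assert rl.total_meth == sub.meth_count.sum()
        assert rl.level == pytest.approx(sub.meth_count.sum() / sub.depth.sum())

    def test_pooled_interval_level_equals_sum_of_parts(self):
        calls = calls_frame(
            [("c", p, "+", "CG", 10, m) for p, m in [(5, 1), (50, 9), (500, 5)]]
        )
        pooled = regions.pooled_interval_level(calls, [("c", 0, 100), ("c", 400, 600)])
        assert pooled.total_meth == 15 and pooled.total_depth == 30


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        x = np.full(30, 0.6)
        np.testing.assert_allclose(regions.moving_average(x), x)

    def test_edges_shrink_symmetrically(self):
        x = np.arange(10.0)
        out = regions.moving_average(x, window=5)
        assert out[0] == x[0]  # single-element window at the edge
        assert out[1] == pytest.approx(x[:3].mean())
        assert out[5] == pytest.approx(x[3:8].mean())


def uniform_gene_calls(gene, level=0.6, spacing=50, depth=10, flank=2000):
    rows = []
    for pos in range(gene.start - flank, gene.end + flank, spacing):
        if pos >= 0:
            rows.append((gene.chrom, pos, "+", "CG", depth, int(round(level * depth))))
    return calls_frame(rows)


class TestMetagene:
    def test_constant_surface_gives_flat_profile(self):
        gene = GeneModel("g", "c", "+", 10_000, 13_000)
        prof = regions.metagene_profile(uniform_gene_calls(gene), [gene])
        covered = ~np.isnan(prof.raw)
        np.testing.assert_allclose(prof.raw[covered], 0.6, atol=1e-12)
        np.testing.assert_allclose(prof.smoothed[covered], 0.6, atol=1e-12)

    def test_strand_reversal_mirrors_bins(self):
        fwd = GeneModel("g", "c", "+", 10_000, 13_000)
        rev = GeneModel("g", "c", "-", 10_000, 13_000)
        # asymmetric methylation: level rises with genomic position
        rows = []
        for i, pos in enumerate(range(8_000, 15_000, 40)):
            rows.append(("c", pos, "+", "CG", 20, min(i % 21, 20)))
        calls = calls_frame(rows)
        pf = regions.metagene_profile(calls, [fwd], body_bins=30)
        pr = regions.metagene_profile(calls, [rev], body_bins=30)
        np.testing.assert_allclose(pf.raw, pr.raw[::-1], atol=1e-12)

    def test_tss_dip_minimum_near_tss(self, dataset):
        pooled = pd.concat(dataset.group_calls("STE", "E15"), ignore_index=True)
        prof = regions.metagene_profile(pooled, dataset.genes)
        min_bin = int(np.nanargmin(prof.smoothed))
        assert abs(min_bin - prof.tss_bin) <= 2

    def test_body_bins_pool_to_aggregate_body_level(self, dataset):
        calls = dataset.calls["WZE_E15_r1"]
        prof = regions.metagene_profile(calls, dataset.genes)
        body_depth = prof.bin_depth[prof.n_flank_bins : prof.n_flank_bins + prof.body_bins]
        pooled = regions.pooled_interval_level(
            calls, [(g.chrom, g.start, g.end) for g in dataset.genes]
        )
        assert int(body_depth.sum()) == pooled.total_depth

    def test_requires_genes(self):
        with pytest.raises(ValueError):
            regions.metagene_profile(calls_frame([]), [])


class TestGroupComparison:
    def test_identical_groups(self):
        diff, p = regions.compare_group_levels([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert diff == 0.0 and p == 1.0

    def test_separated_groups(self):
        diff, p = regions.compare_group_levels([0.60, 0.61, 0.59], [0.50, 0.51, 0.49])
        assert diff == pytest.approx(0.10)
        assert p < 0.01

    def test_missing_replicate_is_error(self):
        with pytest.raises(ValueError):
            regions.compare_group_levels([0.5], [0.4, 0.5])
        with pytest.raises(ValueError):
            regions.compare_group_levels([0.5, np.nan, 0.5], [0.4, 0.5])


def dense_sample(level, seed, length=500_000, spacing=100):
    rng = np.random.default_rng(seed)
    pos = np.arange(0, length, spacing)
    depth = np.full(pos.size, 20)
    meth = rng.binomial(depth, level)
    return pd.DataFrame(
        {"chrom": "c", "pos": pos, "strand": "+", "context": "CG",
         "depth": depth, "meth_count": meth}
    )


class TestWindowMatrixAndClustering:
    def test_tile_count(self):
        calls = {"s1": dense_sample(0.5, 1), "s2": dense_sample(0.5, 2)}
        mat = regions.window_matrix(calls, {"c": 500_000})
        assert mat.shape == (50, 2)

    def test_empty_sample_drops_everything(self):
        calls = {"s1": dense_sample(0.5, 1), "s2": calls_frame([])}
        assert regions.window_matrix(calls, {"c": 500_000}).empty

    def test_identical_samples_have_zero_distance(self):
        s = dense_sample(0.5, 3)
        calls = {"s1": s, "s2": s.copy(), "s3": dense_sample(0.7, 4)}
        mat = regions.window_matrix(calls, {"c": 500_000})
        result = regions.cluster_and_ordinate(mat)
        # the duplicated pair merges first, at height 0
        assert result.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        labels = result.cut(2)
        assert labels["s1"] == labels["s2"] != labels["s3"]

    def test_pca_invariant_to_window_order(self):
        calls = {f"s{i}": dense_sample(0.4 + 0.05 * i, i) for i in range(4)}
        mat = regions.window_matrix(calls, {"c": 500_000})
        shuffled = mat.sample(frac=1.0, random_state=0)
        a = regions.cluster_and_ordinate(mat).pca_scores
        b = regions.cluster_and_ordinate(shuffled).pca_scores
        np.testing.assert_allclose(np.abs(a.to_numpy()), np.abs(b.to_numpy()), atol=1e-8)

    def test_constant_matrix_is_error(self):
        mat = pd.DataFrame(
            np.full((20, 3), 0.5),
            columns=["a", "b", "c"],
        )
        with pytest.raises(ValueError, match="constant"):
            regions.cluster_and_ordinate(mat)

    def test_breed_offset_separates_first_bipartition(self):
        # two groups of three samples, global offset 0.05, binomial noise
        calls = {}
        for i in range(3):
            calls[f"A_r{i}"] = dense_sample(0.60, 10 + i)
            calls[f"B_r{i}"] = dense_sample(0.65, 20 + i)
        mat = regions.window_matrix(calls, {"c": 500_000})
        labels = regions.cluster_and_ordinate(mat).cut(2)
        groups = {k[0] for k in labels}  # noqa: F841
        a_labels = {v for k, v in labels.items() if k.startswith("A")}
        b_labels = {v for k, v in labels.items() if k.startswith("B")}
        assert len(a_labels) == 1 and len(b_labels) == 1 and a_labels != b_labels

    def test_newick_rendering(self):
        calls = {f"s{i}": dense_sample(0.4 + 0.1 * i, i) for i in range(3)}
        mat = regions.window_matrix(calls, {"c": 500_000})
        result = regions.cluster_and_ordinate(mat)
        nwk = regions.linkage_to_newick(result.linkage, list(result.samples))
        assert nwk.endswith(";") and all(s in nwk for s in result.samples)
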