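"""Expression classes, DEG calling, quadrants, promoter site comparison."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from goosemethyl import integration
from goosemethyl.io_formats import CALL_COLUMNS, GeneModel


class TestClassifyExpression:
    def test_printed_boundaries(self):
        fpkm = pd.DataFrame(
            {"s1": [100.0, 0.0, 9.999, 10.0, 99.999]},
            index=["a", "b", "c", "d", "e"],
        )
        fpkm.index.name = "gene_id"
        out = integration.classify_expression(fpkm)
        assert out.loc["a", "expr_class"] == "high"  # inclusive at 100
        assert out.loc["b", "expr_class"] == "none"  # exactly 0
        assert out.loc["c", "expr_class"] == "low"
        assert out.loc["d", "expr_class"] == "middle"
        assert out.loc["e", "expr_class"] == "middle"

    def test_negative_fpkm_rejected(self):
        fpkm = pd.DataFrame({"s1": [-1.0]}, index=["a"])
        with pytest.raises(ValueError):
            integration.classify_expression(fpkm)


def fpkm_groups(n_genes=200, n_planted=10, fc=4.0, dispersion=0.1, seed=0):
    rng = np.random.default_rng(seed)
    base = np.power(2.0, rng.normal(5.0, 1.5, n_genes))
    planted = np.arange(n_planted)
    signs = np.where(planted % 2 == 0, 1.0, -1.0)

    def group(mult):
        cols = {}
        for r in range(3):
            noise = np.power(2.0, rng.normal(0, dispersion, n_genes))
            cols[f"r{r}"] = base * mult * noise
        return pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])

    mult_a = np.ones(n_genes)
    mult_a[planted] = fc**signs
    fa = group(mult_a)
    fb = group(np.ones(n_genes))
    return fa, fb, planted, signs


class TestCallDegs:
    def test_planted_fold_changes_recovered(self):
        fa, fb, planted, signs = fpkm_groups()
        degs = integration.call_degs(fa, fb)
        hits = 0
        for i, s in zip(planted, signs):
            g = f"g{i}"
            if g in degs.index and degs.loc[g, "direction"] == ("E+" if s > 0 else "E-"):
                hits += 1
        assert hits >= 9  # recall >= 0.9 on 10 planted genes
        # planted log2 ratio ~ +/-2
        ratio = np.log2(fa.loc["g0"].mean() / fb.loc["g0"].mean())
        assert ratio == pytest.approx(2.0, abs=0.35)

    def test_null_comparison_nearly_empty(self):
        fa, fb, *_ = fpkm_groups(n_planted=0, seed=1)
        degs = integration.call_degs(fa, fb)
        assert len(degs) <= 2  # BH keeps false positives near zero

    def test_small_fold_change_never_deg(self):
        fa, fb, *_ = fpkm_groups(n_planted=0, seed=2, dispersion=0.01)
        fa = fa * 1.9  # |log2 1.9| < 1: excluded regardless of p
        out = integration.call_degs(fa, fb, return_all=True)
        assert not out["is_deg"].any()
        assert (out["fdr"] < 0.05).all()  # significant but below the fold floor

    def test_identical_groups_p_is_one(self):
        fa = pd.DataFrame({"r1": [5.0, 0.0], "r2": [5.0, 0.0]}, index=["a", "b"])
        out = integration.call_degs(fa, fa.copy(), return_all=True)
        assert (out["p_value"] == 1.0).all()

    def test_requires_replicates(self):
        fa = pd.DataFrame({"r1": [5.0]}, index=["a"])
        fb = pd.DataFrame({"r1": [5.0], "r2": [6.0]}, index=["a"])
        with pytest.raises(ValueError):
            integration.call_degs(fa, fb)


class TestIntersectAndClassify:
    def degs(self, mapping, group_a="STE_E15", group_b="WZE_E15"):
        df = pd.DataFrame(
            {"direction": list(mapping.values())}, index=list(mapping.keys())
        )
        df.index.name = "gene_id"
        df.attrs["group_a"] = group_a
        df.attrs["group_b"] = group_b
        return df

    def dmr_genes(self, rows, group_a="STE_E15", group_b="WZE_E15"):
        df = pd.DataFrame(rows, columns=["gene_id", "region_type", "n_dmrs",
                                         "net_delta", "direction"])
        df.attrs["group_a"] = group_a
        df.attrs["group_b"] = group_b
        return df

    def test_label_rule(self):
        records, counts = integration.intersect_and_classify(
            self.degs({"g1": "E+"}),
            self.dmr_genes([("g1", "upstream2k", 1, -0.4, "M-")]),
        )
        assert records.iloc[0]["quadrant"] == "E+&M-"
        assert counts.iloc[0]["n"] == 1

    def test_empty_deg_set(self):
        records, counts = integration.intersect_and_classify(
            self.degs({}), self.dmr_genes([("g1", "body", 1, 0.4, "M+")])
        )
        assert records.empty and counts.empty

    def test_ties_excluded(self):
        records, _ = integration.intersect_and_classify(
            self.degs({"g1": "E+"}),
            self.dmr_genes([("g1", "body", 2, 0.0, "tie")]),
        )
        assert records.empty

    def test_orientation_mismatch_is_error(self):
        with pytest.raises(ValueError, match="orientation"):
            integration.intersect_and_classify(
                self.degs({"g1": "E+"}, group_a="STE_E15"),
                self.dmr_genes([("g1", "body", 1, 0.4, "M+")], group_a="STE_E23"),
            )

    def test_counts_sum_to_records(self):
        records, counts = integration.intersect_and_classify(
            self.degs({"g1": "E+", "g2": "E-", "g3": "E+"}),
            self.dmr_genes(
                [
                    ("g1", "upstream2k", 1, 0.3, "M+"),
                    ("g2", "upstream2k", 1, 0.3, "M+"),
                    ("g2", "body", 1, -0.3, "M-"),
                    ("g4", "body", 1, -0.3, "M-"),
                ]
            ),
        )
        assert counts["n"].sum() == len(records) == 3


def promoter_calls(levels_by_rep, dyads, depth=20):
    """Build replicate call tables with both strands of each dyad."""
    out = []
    for levels in levels_by_rep:
        rows = []
        for dyad, level in zip(dyads, levels):
            m = int(round(level * depth))
            rows.append(("c", dyad, "+", "CG", depth, m))
            rows.append(("c", dyad + 1, "-", "CG", depth, m))
        out.append(pd.DataFrame(rows, columns=CALL_COLUMNS))
    return out


class TestPromoterSiteComparison:
    gene = GeneModel("g", "c", "+", 10_000, 12_000)

    def test_sites_and_offsets(self):
        dyads = [10_000 - 700, 10_000 - 600, 10_000 - 500]
        a = promoter_calls([[0.8, 0.7, 0.6]] * 3, dyads)
        b = promoter_calls([[0.3, 0.3, 0.3]] * 3, dyads)
        tab = integration.promoter_site_comparison(a, b, self.gene)
        assert len(tab) == 3
        assert tab["offset"].tolist() == [-700, -600, -500]
        assert (tab["diff"] > 0.2).all()

    def test_identical_groups_zero_difference(self):
        dyads = [10_000 - 700, 10_000 - 600]
        a = promoter_calls([[0.5, 0.5]] * 3, dyads)
        tab = integration.promoter_site_comparison(a, [c.copy() for c in a], self.gene)
        assert (tab["diff"] == 0).all() and (tab["p_value"] == 1.0).all()

    def test_incompletely_covered_site_excluded(self):
        dyads = [10_000 - 700, 10_000 - 600]
        a = promoter_calls([[0.5, 0.5]] * 3, dyads)
        # drop one dyad from one replicate of group b
        b = promoter_calls([[0.5, 0.5]] * 3, dyads)
        b[1] = b[1][b[1]["pos"] < 10_000 - 650]
        tab = integration.promoter_site_comparison(a, b, self.gene)
        assert tab["pos"].tolist() == [10_000 - 700]

    def test_no_covered_sites_empty(self):
        a = promoter_calls([[0.5]] * 3, [15_000])  # outside the window
        tab = integration.promoter_site_comparison(a, a, self.gene)
        assert tab.empty

    def test_planted_promoter_recovered(self, dataset):
        gmap = {g.gene_id: g for g in dataset.genes}
        gene = gmap[dataset.surface.promoter_gene]
        tab = integration.promoter_site_comparison(
            dataset.group_calls("STE", "E15"),
            dataset.group_calls("WZE", "E15"),
            gene,
        )
        assert len(tab) == dataset.config.promoter_n_cpg
        want = (
            dataset.config.promoter_levels["STE"]
            - dataset.config.promoter_levels["WZE"]
        )
        assert tab["diff"].mean() == pytest.approx(want, abs=0.1)
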