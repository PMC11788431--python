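import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from screenhit.counting import CountTable
from screenhit.enrichment import (
    ScreenThresholds,
    aggregate_genes,
    bh_adjust,
    call_guides,
    fdr_plot_table,
    guide_test,
    odds_ratio,
)
from screenhit.errors import InputError
from screenhit.library import CONTROL_GENE


def enumeration_p(a, b, c, d):
    """Independent oracle: exact-integer hypergeometric enumeration."""
    n1, n2, k = a + b, c + d, a + c
    lo, hi = max(0, k - n2), min(k, n1)
    weights = [math.comb(n1, x) * math.comb(n2, k - x) for x in range(lo, hi + 1)]
    obs = weights[a - lo]
    total = math.comb(n1 + n2, k)
    return min(1.0, sum(w for w in weights if w <= obs * (1 + 1e-7)) / total)


class TestGuideTest:
    def test_symmetric_table(self):
        orr, p = guide_test(5, 995, 5, 995)
        assert orr == 1.0
        assert p == 1.0

    def test_enriched_table_against_enumeration(self):
        orr, p = guide_test(20, 980, 5, 995)
        assert orr == pytest.approx(19900 / 4900)
        assert p == pytest.approx(enumeration_p(20, 980, 5, 995), abs=1e-11)

    def test_haldane_correction_only_for_odds_ratio(self):
        orr, p = guide_test(3, 997, 0, 1000)
        assert orr == pytest.approx((3.5 * 1000.5) / (997.5 * 0.5))
        # p stays the uncorrected enumeration value
        assert p == pytest.approx(enumeration_p(3, 997, 0, 1000), abs=1e-11)

    def test_no_correction_when_all_cells_positive(self):
        assert odds_ratio(2, 8, 1, 9) == (2 * 9) / (8 * 1)

    def test_zero_margin_untestable(self):
        with pytest.raises(InputError):
            guide_test(0, 0, 5, 5)

    def test_matches_scipy_fisher_exact(self):
        rng = np.random.default_rng(17)
        for _ in range(150):
            a, b, c, d = (int(x) for x in rng.integers(0, 300, 4))
            if a + b == 0 or c + d == 0:
                continue
            _, p = guide_test(a, b, c, d)
            assert p == pytest.approx(
                fisher_exact([[a, b], [c, d]]).pvalue, abs=1e-11
            )

    def test_depth_scaling_sharpens_an_enriched_table(self):
        """Same odds ratio at greater depth can only lower the p-value."""
        p_prev = 1.0
        for scale in (1, 2, 4, 8):
            _, p = guide_test(20 * scale, 980 * scale, 5 * scale, 995 * scale)
            assert p <= p_prev + 1e-15
            p_prev = p


class TestBHAdjust:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_identity(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_zero_stays_zero(self):
        np.testing.assert_allclose(bh_adjust([0.5, 0.0]), [0.5, 0.0])

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-14)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(InputError):
            bh_adjust([-0.1])

    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=30),
        st.randoms(use_true_random=False),
    )
    def test_monotone_and_permutation_invariant(self, pvals, rnd):
        q = bh_adjust(pvals)
        order = np.argsort(pvals, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()
        shuffled = list(pvals)
        rnd.shuffle(shuffled)
        assert sorted(np.round(bh_adjust(shuffled), 14)) == sorted(np.round(q, 14))


def _table(counts_by_guide, genes):
    guides = [f"g{i}" for i in range(len(genes))]
    return CountTable(
        guides=guides,
        genes=list(genes),
        samples=["unsorted", "sorted"],
        counts=np.array(counts_by_guide),
    )


class TestCallGuides:
    def test_zero_zero_guide_untestable(self):
        t = _table([[0, 0], [100, 100], [100, 100]], ["A", "A", "B"])
        res = call_guides(t, "sorted", "unsorted")
        row = res.iloc[0]
        assert not row.testable
        assert np.isnan(row.p) and np.isnan(row.padj)
        assert not row.enriched

    def test_enrichment_requires_both_criteria(self):
        # guide 0: strong enrichment; guide 1: depleted (small p, OR < 1)
        t = _table([[50, 400], [400, 50], [500, 500], [500, 500]], list("ABCD"))
        res = call_guides(t, "sorted", "unsorted")
        assert res.iloc[0].enriched
        assert res.iloc[1].padj < 0.05 and not res.iloc[1].enriched

    def test_bh_family_excludes_untestable(self):
        t = _table([[0, 0], [50, 400], [500, 500]], list("ABC"))
        res = call_guides(t, "sorted", "unsorted")
        testable_p = res.loc[res.testable, "p"].to_numpy()
        np.testing.assert_allclose(
            res.loc[res.testable, "padj"].to_numpy(), bh_adjust(testable_p)
        )

    def test_padj_never_below_p(self):
        t = _table([[50, 400], [400, 50], [500, 500], [30, 90]], list("ABCD"))
        res = call_guides(t, "sorted", "unsorted")
        ok = res.testable
        assert (res.loc[ok, "padj"] >= res.loc[ok, "p"] - 1e-15).all()

    def test_missing_sample_errors(self):
        t = _table([[1, 1]], ["A"])
        with pytest.raises(InputError):
            call_guides(t, "sorted", "nope")


class TestAggregateGenes:
    def _results(self, enriched_by_gene):
        rows = []
        for gene, flags in enriched_by_gene.items():
            for i, e in enumerate(flags):
                rows.append(
                    {
                        "guide_id": f"{gene}_{i}",
                        "gene": gene,
                        "padj": 0.01 if e else 0.5,
                        "enriched": e,
                        "testable": True,
                    }
                )
        return pd.DataFrame(rows)

    def test_hit_and_candidate_rules(self):
        res = self._results(
            {"FULL": [1, 1, 1, 1], "PAIR": [1, 1, 0, 0], "NONE": [0, 0, 0, 0]}
        )
        g = aggregate_genes(res).set_index("gene")
        assert g.loc["FULL", "hit"] and g.loc["FULL", "candidate_of_interest"]
        assert not g.loc["PAIR", "hit"] and g.loc["PAIR", "candidate_of_interest"]
        assert not g.loc["NONE", "hit"] and not g.loc["NONE", "candidate_of_interest"]

    def test_controls_excluded(self):
        res = self._results({CONTROL_GENE: [1, 1, 1, 1], "X": [0, 0, 0, 0]})
        g = aggregate_genes(res)
        assert list(g.gene) == ["X"]

    def test_deterministic_ranking(self):
        res = self._results({"B": [1, 1, 1, 1], "A": [1, 1, 1, 1], "C": [0, 1, 1, 1]})
        g = aggregate_genes(res)
        # equal best_padj and n_enriched: lexicographic gene order
        assert list(g.gene[:2]) == ["A", "B"]
        assert list(g["rank"]) == [1, 2, 3]

    def test_fdr_plot_table_ordered_by_gene_rank(self):
        res = self._results({"B": [1, 1, 1, 1], "A": [0, 0, 1, 1]})
        g = aggregate_genes(res)
        plot = fdr_plot_table(res, g)
        assert (plot.groupby("gene_rank", sort=True).size() == 4).all()
        assert list(plot.gene_rank) == sorted(plot.gene_rank)

    def test_custom_thresholds(self):
        res = self._results({"X": [1, 1, 1, 0]})
        g = aggregate_genes(res, ScreenThresholds(min_enriched_hit=3))
        assert g.iloc[0].hit
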