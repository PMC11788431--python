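"""Per-guide enrichment testing and gene-level hit calling.

Each guide is tested on a 2x2 contingency table of read counts:

    a = guide reads in the sorted sample      b = all other sorted reads
    c = guide reads in the unsorted sample    d = all other unsorted reads

against the null that guide abundance is independent of sorting, using the
two-tailed Fisher exact test (point-probability method: the p-value sums
hypergeometric point probabilities, margins fixed, over every table whose
point probability is at most the observed one within a ``1 + 1e-7``
relative tolerance). The odds ratio is ``(a*d)/(b*c)``; when any cell is
zero, 0.5 is added to every cell first (Haldane correction) so the ratio
stays finite for thresholding — the correction never touches the p-value.

A guide is *enriched* when its odds ratio is at least ``or_threshold``
(default 2) AND its Benjamini-Hochberg adjusted p-value is below ``alpha``
(default 0.05); enrichment is one-directional (sorted over unsorted), so a
strongly depleted guide can have a small p-value but is never enriched.
A gene is a *hit* when at least ``min_enriched_hit`` (default 4) of its
guides are enriched, and a *candidate of interest* at
``min_enriched_candidate`` (default 2). Counts are tested raw — margins
carry sequencing depth, which the Fisher test conditions on — so no prior
normalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .counting import CountTable
from .errors import InputError
from .library import CONTROL_GENE

#: Relative tolerance when comparing point probabilities (guards float ties).
_REL_TOL = 1.0 + 1e-7


@dataclass(frozen=True)
class ScreenThresholds:
    """Selection rules for guide enrichment and gene hit calling."""

    or_threshold: float = 2.0
    alpha: float = 0.05
    min_enriched_hit: int = 4
    min_enriched_candidate: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise InputError("alpha must be in (0, 1)")
        if self.or_threshold <= 0 or self.min_enriched_hit <= 0:
            raise InputError("thresholds must be positive")


def _log_binom(n, k) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


# log-factorial lookup, grown on demand; shared across batch calls so that
# repeated screens at the same depth pay the gammaln cost once
_LOG_FACT = np.zeros(1)


def _log_fact_table(n_max: int) -> np.ndarray:
    global _LOG_FACT
    if n_max >= _LOG_FACT.size:
        _LOG_FACT = gammaln(np.arange(n_max + 1, dtype=np.float64) + 1.0)
    return _LOG_FACT


@lru_cache(maxsize=4096)
def _family(n1: int, n2: int, k: int):
    """Hypergeometric family for fixed margins (row sums n1, n2; column k).

    Returns (a_min, point probs over the support, probs sorted ascending,
    cumulative sums of the sorted probs). Point probabilities are computed
    from log-binomials in one vectorized pass over the support.
    """
    a_min = max(0, k - n2)
    a_max = min(k, n1)
    a = np.arange(a_min, a_max + 1)
    logp = (
        _log_binom(n1, a)
        + _log_binom(n2, k - a)
        - _log_binom(n1 + n2, k)
    )
    probs = np.exp(logp)
    order = np.argsort(probs, kind="stable")
    sorted_probs = probs[order]
    cum = np.cumsum(sorted_probs)
    return a_min, probs, sorted_probs, cum


def _two_tailed_p(a: int, n1: int, n2: int, k: int) -> float:
    a_min, probs, sorted_probs, cum = _family(n1, n2, k)
    p_obs = probs[a - a_min]
    idx = np.searchsorted(sorted_probs, p_obs * _REL_TOL, side="right")
    if idx == sorted_probs.size:  # every table included: the sum is exactly 1
        return 1.0
    return float(min(1.0, cum[idx - 1]))


def _batch_two_tailed_p(a_obs: np.ndarray, n1: int, n2: int, k: np.ndarray) -> np.ndarray:
    """Two-tailed p for many tables sharing row margins (n1, n2).

    One vectorized log-pmf evaluation over the concatenated supports, then
    a cheap per-table sort/cumsum. Identical by construction to
    :func:`guide_test` on each table.
    """
    a_min = np.maximum(0, k - n2)
    a_max = np.minimum(k, n1)
    lengths = (a_max - a_min + 1).astype(np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    support = np.concatenate(
        [np.arange(lo, hi + 1) for lo, hi in zip(a_min, a_max)]
    )
    k_rep = np.repeat(k, lengths)
    lf = _log_fact_table(n1 + n2)
    logp = (
        (lf[n1] - lf[support] - lf[n1 - support])
        + (lf[n2] - lf[k_rep - support] - lf[n2 - k_rep + support])
        - (lf[n1 + n2] - lf[k_rep] - lf[n1 + n2 - k_rep])
    )
    probs = np.exp(logp)
    out = np.empty(len(k))
    for i in range(len(k)):
        seg = probs[offsets[i] : offsets[i + 1]]
        p_obs = seg[a_obs[i] - a_min[i]]
        s = np.sort(seg)
        idx = np.searchsorted(s, p_obs * _REL_TOL, side="right")
        out[i] = 1.0 if idx == s.size else min(1.0, float(s[:idx].sum()))
    return out


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio ``(a*d)/(b*c)``, Haldane-corrected iff any cell is 0."""
    if min(a, b, c, d) < 0:
        raise InputError("contingency cells must be non-negative")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def guide_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-tailed Fisher exact test of one guide's 2x2 table.

    Returns ``(odds_ratio, p)``. Both row margins must be positive.
    """
    a, b, c, d = int(a), int(b), int(c), int(d)
    if min(a, b, c, d) < 0:
        raise InputError("contingency cells must be non-negative")
    n1, n2 = a + b, c + d
    if n1 == 0 or n2 == 0:
        raise InputError("zero row margin: table is untestable")
    return odds_ratio(a, b, c, d), _two_tailed_p(a, n1, n2, a + c)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in the input order.

    ``q_i = min_{j >= i} (m * p_(j) / j)`` over the ascending order
    statistics, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InputError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_guides(
    counts: CountTable,
    sorted_sample: str,
    unsorted_sample: str,
    thresholds: ScreenThresholds | None = None,
) -> pd.DataFrame:
    """Test every library guide for sorted-vs-unsorted enrichment.

    Guides with zero counts in both samples are untestable (p and padj are
    NaN, never enriched) and are excluded from the BH family; all testable
    guides form a single BH family. Returns one row per guide with columns
    guide_id, gene, a, b, c, d, odds_ratio, p, padj, testable, enriched.
    """
    thresholds = thresholds or ScreenThresholds()
    a = counts.column(sorted_sample).astype(np.int64)
    c = counts.column(unsorted_sample).astype(np.int64)
    total_s, total_u = int(a.sum()), int(c.sum())
    if total_s == 0 or total_u == 0:
        raise InputError("both samples must have positive totals")
    b = total_s - a
    d = total_u - c
    testable = ~((a == 0) & (c == 0))

    n = len(counts.guides)
    ors = np.full(n, np.nan)
    pvals = np.full(n, np.nan)
    idx = np.flatnonzero(testable)
    for i in idx:
        ors[i] = odds_ratio(int(a[i]), int(b[i]), int(c[i]), int(d[i]))
    if idx.size:
        pvals[idx] = _batch_two_tailed_p(
            a[idx], total_s, total_u, (a + c)[idx]
        )
    padj = np.full(n, np.nan)
    if testable.any():
        padj[testable] = bh_adjust(pvals[testable])

    enriched = (
        testable
        & (np.nan_to_num(ors, nan=0.0) >= thresholds.or_threshold)
        & (np.nan_to_num(padj, nan=1.0) < thresholds.alpha)
    )
    return pd.DataFrame(
        {
            "guide_id": counts.guides,
            "gene": counts.genes,
            "a": a,
            "b": b,
            "c": c,
            "d": d,
            "odds_ratio": ors,
            "p": pvals,
            "padj": padj,
            "testable": testable,
            "enriched": enriched,
        }
    )


def aggregate_genes(
    results: pd.DataFrame, thresholds: ScreenThresholds | None = None
) -> pd.DataFrame:
    """Aggregate per-guide results to gene-level hit calls.

    Non-targeting control guides are excluded. Genes are ranked by best
    (minimum) adjusted p-value, then by number of enriched guides
    (descending), then by gene symbol for determinism.
    """
    thresholds = thresholds or ScreenThresholds()
    df = results[results["gene"] != CONTROL_GENE]
    if df.empty:
        raise InputError("no targeting guides to aggregate")
    grouped = df.groupby("gene", sort=False)
    out = grouped.agg(
        n_guides=("guide_id", "size"),
        n_enriched=("enriched", "sum"),
        best_padj=("padj", "min"),
    ).reset_index()
    out["n_enriched"] = out["n_enriched"].astype(int)
    out["hit"] = out["n_enriched"] >= thresholds.min_enriched_hit
    out["candidate_of_interest"] = (
        out["n_enriched"] >= thresholds.min_enriched_candidate
    )
    out = out.sort_values(
        by=["best_padj", "n_enriched", "gene"],
        ascending=[True, False, True],
        na_position="last",
        kind="stable",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out[
        [
            "gene",
            "n_guides",
            "n_enriched",
            "hit",
            "candidate_of_interest",
            "best_padj",
            "rank",
        ]
    ]


def fdr_plot_table(
    results: pd.DataFrame, gene_summary: pd.DataFrame
) -> pd.DataFrame:
    """Long-format table behind an FDR plot: per-gene guides with adjusted p.

    One row per (gene, guide), genes ordered by their rank, guides within a
    gene ordered by adjusted p-value.
    """
    rank = gene_summary.set_index("gene")["rank"]
    df = results[results["gene"].isin(rank.index)].copy()
    df["gene_rank"] = df["gene"].map(rank)
    df = df.sort_values(
        by=["gene_rank", "padj", "guide_id"], na_position="last", kind="stable"
    )
    return df[["gene", "gene_rank", "guide_id", "padj", "enriched"]].reset_index(
        drop=True
    )


def write_results(
    results: pd.DataFrame, gene_summary: pd.DataFrame, outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results.to_csv(outdir / "guide_results.tsv", sep="\t", index=False)
    gene_summary.to_csv(outdir / "gene_summary.tsv", sep="\t", index=False)
    fdr_plot_table(results, gene_summary).to_csv(
        outdir / "fdr_plot.tsv", sep="\t", index=False
    )
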