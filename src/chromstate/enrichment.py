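"""Chromatin-state enrichment of differential-deposition regions.

The statistic: overlap a set of differential histone-deposition regions
with a labeled genome segmentation; a state bin counts as a *hit* when the
regions cover more than half of it; per state i,

    ratio_i = hit_bins_i / total_bins_i

is compared against the genome-wide background rate
(total hits / total bins), and the hit count is tested against the
hypergeometric distribution of drawing ``total_hits`` bins from the genome
at random. Significance tiers mirror the usual star convention
(*** p<0.001, ** p<0.01, * p<0.05).

Exposed both as free functions and as the :class:`StateEnrichment` model
whose :meth:`~StateEnrichment.fit` returns a
:class:`StateEnrichmentResults` object with a ``summary()`` table.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genome import GenomicInterval, StateSegmentation, merge_intervals

TIER_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _covered_prefix(x: np.ndarray, rs: np.ndarray, re: np.ndarray, cum: np.ndarray):
    """Covered bases in [0, x) given merged sorted regions (rs, re)."""
    idx = np.searchsorted(rs, x, side="right")
    out = cum[idx].astype(np.float64)
    inside = idx > 0
    j = idx[inside] - 1
    overhang = np.clip(re[j] - x[inside], 0, re[j] - rs[j])
    out[inside] -= overhang
    return out


def count_hit_bins(
    regions: Sequence[GenomicInterval],
    segmentation: StateSegmentation,
    min_bin_coverage: float = 0.5,
    strict: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-state hit and total bin counts under the bin-coverage rule.

    A bin is a hit when the fraction of its bases covered by the union of
    ``regions`` exceeds ``min_bin_coverage`` (strictly by default, so a bin
    covered exactly 50% is *not* a hit).

    Returns
    -------
    (hit_bins, total_bins) : ndarray of shape (n_states,)
        ``hit_bins[i-1]`` and ``total_bins[i-1]`` for state i.
    """
    merged = merge_intervals(regions)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    S = segmentation.n_states
    hits = np.zeros(S, dtype=np.int64)
    totals = segmentation.state_totals()
    for chrom in segmentation.chroms:
        starts, ends, labels = segmentation.bins_on(chrom)
        regs = by_chrom.get(chrom)
        if not regs:
            continue
        rs = np.array([r.start for r in regs], dtype=np.int64)
        re = np.array([r.end for r in regs], dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(re - rs)])
        cov = _covered_prefix(ends, rs, re, cum) - _covered_prefix(starts, rs, re, cum)
        frac = cov / (ends - starts)
        hit = frac > min_bin_coverage if strict else frac >= min_bin_coverage
        hits += np.bincount(labels[hit] - 1, minlength=S)
    return hits, totals


def hypergeometric_enrichment(
    k: int, n: int, K: int, N: int, tail: str = "upper"
) -> float:
    """Hypergeometric probability for ``k`` hit bins of one state.

    Parameters follow the counting scheme: ``k`` hit bins in the state,
    ``n`` total hit bins genome-wide, ``K`` bins of the state, ``N`` bins
    genome-wide. ``tail="upper"`` gives the enrichment p-value
    P(X >= k) for X ~ Hypergeometric(N, K, n); ``tail="point"`` gives the
    point mass P(X = k) (the literal spreadsheet-function semantics).
    """
    k, n, K, N = int(k), int(n), int(K), int(N)
    if not (0 <= k <= K and 0 <= n <= N and K <= N and k <= n):
        raise ValueError(f"inconsistent hypergeometric arguments k={k} n={n} K={K} N={N}")
    if tail == "upper":
        return float(hypergeom.sf(k - 1, N, K, n))
    if tail == "point":
        return float(hypergeom.pmf(k, N, K, n))
    raise ValueError(f"unknown tail {tail!r}")


def _tier(p: float) -> str:
    for thresh, stars in TIER_THRESHOLDS:
        if p < thresh:
            return stars
    return "ns"


def compute_ratios(hit_counts: np.ndarray, totals: np.ndarray) -> pd.DataFrame:
    """Per-state ratios, background rate, and background-exceeding selection.

    States absent from the segmentation (total 0) get ratio NaN and are
    never selected, but remain in the table.
    """
    hits = np.asarray(hit_counts, dtype=np.int64)
    totals = np.asarray(totals, dtype=np.int64)
    if hits.shape != totals.shape:
        raise ValueError("hit and total arrays differ in length")
    if np.any(hits > totals):
        raise ValueError("hit count exceeds total bins for some state")
    if np.any((totals == 0) & (hits > 0)):
        raise ValueError("hits reported for a state with zero bins")
    total_hits = int(hits.sum())
    total_bins = int(totals.sum())
    background = total_hits / total_bins if total_bins else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(totals > 0, hits / np.maximum(totals, 1), np.nan)
    df = pd.DataFrame(
        {
            "state": np.arange(1, len(hits) + 1),
            "total_bins": totals,
            "hit_bins": hits,
            "ratio": ratio,
            "background_rate": background,
            "selected": (ratio > background) & (totals > 0),
        }
    )
    return df


class StateEnrichment:
    """Enrichment model: differential regions against a state segmentation.

    Parameters
    ----------
    regions : sequence of GenomicInterval
        Differential-deposition regions (merged internally).
    segmentation : StateSegmentation
        Labeled genome bins, typically 36 states.
    min_bin_coverage : float
        Bin-coverage threshold for calling a hit (default 0.5, strict
        "more than" comparison).
    strict : bool
        Use ``>`` (default) or ``>=`` for the coverage rule.
    tail : {"upper", "point"}
        Hypergeometric tail semantics; upper is the enrichment p-value.
    """

    def __init__(
        self,
        regions: Sequence[GenomicInterval],
        segmentation: StateSegmentation,
        min_bin_coverage: float = 0.5,
        strict: bool = True,
        tail: str = "upper",
    ):
        self.regions = list(regions)
        self.segmentation = segmentation
        self.min_bin_coverage = min_bin_coverage
        self.strict = strict
        self.tail = tail

    def fit(self) -> "StateEnrichmentResults":
        hits, totals = count_hit_bins(
            self.regions, self.segmentation, self.min_bin_coverage, self.strict
        )
        table = compute_ratios(hits, totals)
        n = int(hits.sum())
        N = int(totals.sum())
        pvals = np.ones(len(hits))
        for i, (k, K) in enumerate(zip(hits, totals)):
            if K == 0:
                pvals[i] = np.nan
                continue
            pvals[i] = hypergeometric_enrichment(int(k), n, int(K), N, self.tail)
        table["p"] = pvals
        ok = ~np.isnan(pvals)
        q = np.full(len(pvals), np.nan)
        if ok.any():
            q[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        table["q"] = q
        table["tier"] = ["ns" if np.isnan(p) else _tier(p) for p in pvals]
        return StateEnrichmentResults(self, table)


class StateEnrichmentResults:
    """Fitted enrichment result: per-state counts, ratios, p/q, tiers."""

    def __init__(self, model: StateEnrichment, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def total_hits(self) -> int:
        return int(self.table["hit_bins"].sum())

    @property
    def total_bins(self) -> int:
        return int(self.table["total_bins"].sum())

    @property
    def background_rate(self) -> float:
        return float(self.table["background_rate"].iloc[0])

    @property
    def selected_states(self) -> list[int]:
        return self.table.loc[self.table["selected"], "state"].tolist()

    def significant_states(self, alpha: float = 0.05) -> list[int]:
        return self.table.loc[self.table["p"] < alpha, "state"].tolist()

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self) -> str:
        lines = [
            "State enrichment of differential-deposition regions",
            f"  regions: {len(self.model.regions)}  "
            f"bins: {self.total_bins}  hit bins: {self.total_hits}",
            f"  background rate: {self.background_rate:.4f}  "
            f"coverage rule: {'>' if self.model.strict else '>='}"
            f"{self.model.min_bin_coverage:g}  tail: {self.model.tail}",
            "",
            self.table.to_string(
                index=False,
                formatters={
                    "ratio": "{:.4f}".format,
                    "background_rate": "{:.4f}".format,
                    "p": "{:.3g}".format,
                    "q": "{:.3g}".format,
                },
            ),
        ]
        return "\n".join(lines)


def enrich_states(
    regions: Sequence[GenomicInterval],
    segmentation: StateSegmentation,
    min_bin_coverage: float = 0.5,
    strict: bool = True,
    tail: str = "upper",
) -> StateEnrichmentResults:
    """One-call wrapper: build the model and fit it."""
    return StateEnrichment(
        regions, segmentation, min_bin_coverage=min_bin_coverage, strict=strict, tail=tail
    ).fit()
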