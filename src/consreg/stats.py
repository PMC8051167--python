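"""Nonparametric comparisons used by the pipeline.

* Mann-Whitney U on per-gene conservation fractions, pairwise between
  intron groups (two-sided; exact where SciPy supports it, normal
  approximation with tie/continuity correction otherwise);
* Chi-square goodness of fit of each intron's four-class pattern
  distribution against the pooled all-intron class proportions (classes
  with a pooled expected count below 1 collapse SS into TFBS-SS first);
* Wilcoxon signed-rank on paired conserved-vs-control element counts
  (zero differences dropped, two-sided).

P-values are annotated with the conventional star scale:
ns, * < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .classify import PatternClass
from .patterns import ConservedPattern

log = logging.getLogger(__name__)

STAR_CUTPOINTS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p_value: float) -> str:
    """Significance stars for a p-value (ns at or above 0.05)."""
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p-value out of [0, 1]: {p_value}")
    for cut, mark in STAR_CUTPOINTS:
        if p_value < cut:
            return mark
    return "ns"


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    @property
    def stars(self) -> str:
        return stars(self.p_value)


def mannwhitney_conservation(
    groups: Mapping[object, Sequence[float]],
) -> dict[tuple[object, object], TestResult]:
    """Pairwise two-sided Mann-Whitney U tests between value groups.

    Returns a symmetric mapping keyed by ordered group-label pairs.  Two
    groups whose pooled values are all identical are reported as U =
    n1*n2/2, p = 1 (no evidence of a shift, and the rank statistic is
    degenerate there).
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for lab in labels:
        if len(groups[lab]) < 1:
            raise ValueError(f"group {lab!r} is empty")
    out: dict[tuple[object, object], TestResult] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            x, y = np.asarray(groups[a], float), np.asarray(groups[b], float)
            if np.unique(np.concatenate([x, y])).size == 1:
                res = TestResult("mannwhitneyu", len(x) * len(y) / 2.0, 1.0, (len(x), len(y)))
            else:
                r = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
                res = TestResult("mannwhitneyu", float(r.statistic), float(r.pvalue), (len(x), len(y)))
            out[(a, b)] = res
            out[(b, a)] = res
    return out


#: class display order used for chi-square cell vectors
CLASS_ORDER = (
    PatternClass.TFBS,
    PatternClass.TFBS_SS,
    PatternClass.SS,
    PatternClass.NOT_IDENTIFIED,
)


def chisq_class_distribution(
    observed: Mapping[object, Mapping[PatternClass, int]],
) -> dict[object, TestResult]:
    """Chi-square test of each group's class counts against pooled proportions.

    Expected cell counts come from the pooled class proportions across all
    groups, scaled to each group's total.  If any class's pooled expected
    count (at the smallest group size) falls below 1, SS is collapsed into
    TFBS-SS with a warning before testing; a class with zero pooled
    probability after collapsing is an error.
    """
    if not observed:
        raise ValueError("no observed groups")
    classes = list(CLASS_ORDER)
    table = {
        g: np.array([counts.get(c, 0) for c in classes], dtype=float)
        for g, counts in observed.items()
    }
    pooled = np.sum(list(table.values()), axis=0)
    if pooled.sum() == 0:
        raise ValueError("all observed counts are zero")
    props = pooled / pooled.sum()
    min_total = min(v.sum() for v in table.values())
    if np.any(props * min_total < 1.0):
        log.warning("expected class count < 1; collapsing SS into TFBS-SS")
        i_ss = classes.index(PatternClass.SS)
        i_both = classes.index(PatternClass.TFBS_SS)
        for g in table:
            table[g][i_both] += table[g][i_ss]
        classes = [c for c in classes if c is not PatternClass.SS]
        table = {g: np.delete(v, i_ss) for g, v in table.items()}
        pooled = np.sum(list(table.values()), axis=0)
        props = pooled / pooled.sum()
    if np.any(props == 0):
        raise ValueError("a class has zero expected frequency after collapsing")
    return {g: chisq_goodness_of_fit(obs, props) for g, obs in table.items()}


def chisq_goodness_of_fit(
    observed_counts: Sequence[float], expected_props: Sequence[float]
) -> TestResult:
    """Pearson chi-square of one count vector against expected proportions."""
    obs = np.asarray(observed_counts, dtype=float)
    props = np.asarray(expected_props, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed and expected shapes differ")
    if np.any(props <= 0):
        raise ValueError("expected proportions must be positive")
    expected = props / props.sum() * obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    p = float(sps.chi2.sf(chi2, df))
    return TestResult("chisquare", chi2, p, (int(obs.sum()),))


def wilcoxon_paired_counts(
    conserved_counts: Sequence[float],
    control_counts: Sequence[float],
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired element counts.

    Pairs with zero difference are dropped; if every difference is zero
    the statistic is undefined and an error is raised.
    """
    a = np.asarray(conserved_counts, dtype=float)
    b = np.asarray(control_counts, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if np.all(a == b):
        raise ValueError("all paired differences are zero; signed-rank test undefined")
    n_nonzero = int(np.sum(a != b))
    method = "exact" if n_nonzero <= 25 else "auto"
    r = sps.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided", method=method)
    return TestResult("wilcoxon", float(r.statistic), float(r.pvalue), (len(a),))


# ---------------------------------------------------------------------------
# data wrangling helpers for the pipeline


def conservation_fractions(
    patterns: Iterable[ConservedPattern],
    region_lengths: Mapping[tuple[str, int], int],
) -> dict[int, list[float]]:
    """Per-ordinal lists of per-gene conserved fractions.

    The unit of observation is the gene: for every region in
    ``region_lengths`` (keyed (gene_id, ordinal)), the fraction of its
    alignment columns covered by conserved patterns (0.0 when none).
    """
    covered: dict[tuple[str, int], int] = {}
    for p in patterns:
        covered[(p.gene_id, p.ordinal)] = covered.get((p.gene_id, p.ordinal), 0) + len(p)
    groups: dict[int, list[float]] = {}
    for (gene, ordinal), length in sorted(region_lengths.items()):
        if length <= 0:
            raise ValueError(f"non-positive region length for {gene} ordinal {ordinal}")
        groups.setdefault(ordinal, []).append(covered.get((gene, ordinal), 0) / length)
    return groups


def paired_region_counts(
    conserved_hits: Iterable,
    control_hits: Iterable,
    regions: Sequence[tuple[str, int]],
) -> tuple[list[int], list[int]]:
    """Per-region element counts for conserved and control patterns, paired."""
    def tally(hits):
        t: dict[tuple[str, int], int] = {}
        for h in hits:
            gene, _, rest = h.pattern_id.partition("|")
            region = rest.partition("|")[0]
            kind = region.rstrip("0123456789")
            key = (gene, int(region[len(kind):]))
            t[key] = t.get(key, 0) + 1
        return t

    ta, tb = tally(conserved_hits), tally(control_hits)
    return [ta.get(r, 0) for r in regions], [tb.get(r, 0) for r in regions]
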