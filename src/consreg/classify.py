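"""Pattern classification and summary tables.

Every pattern falls into exactly one of four classes according to the
regulatory elements found inside it: TFBS only, splice site only, both
(TFBS-SS), or neither (not identified).  Summaries report, per intron/exon
ordinal, the pattern count, how many patterns contain at least one TFBS or
splice site, and those counts as integer percentages of the pattern count
(half-up rounding).  Family tallies count binding sites per DNA-binding-
domain family; nuclear-receptor cluster reports list, per gene region, the
receptors whose motifs hit its patterns.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .patterns import ConservedPattern

DEFAULT_NR_FAMILY_LABELS = frozenset({"Nuclear receptor"})


class PatternClass(Enum):
    TFBS = "TFBS"
    TFBS_SS = "TFBS-SS"
    SS = "SS"
    NOT_IDENTIFIED = "Not identified"

    @property
    def label(self) -> str:
        return self.value

    @property
    def has_tfbs(self) -> bool:
        return self in (PatternClass.TFBS, PatternClass.TFBS_SS)

    @property
    def has_ss(self) -> bool:
        return self in (PatternClass.SS, PatternClass.TFBS_SS)


def round_half_up_pct(numerator: int, denominator: int) -> int:
    """Integer percent of numerator/denominator, exact half-up rounding."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return (200 * numerator + denominator) // (2 * denominator)


def _hit_pattern_ids(hits: Iterable) -> set[str]:
    return {getattr(h, "pattern_id", h) for h in hits}


def classify_patterns(
    patterns: Sequence[ConservedPattern],
    tfbs_hits: Iterable,
    splice_hits: Iterable,
) -> dict[str, PatternClass]:
    """Assign each pattern its class from the hits referencing it.

    ``tfbs_hits`` / ``splice_hits`` are hit objects (or bare pattern ids);
    a hit referencing an unknown pattern is an error.
    """
    known = {p.pattern_id for p in patterns}
    with_tfbs = _hit_pattern_ids(tfbs_hits)
    with_ss = _hit_pattern_ids(splice_hits)
    dangling = (with_tfbs | with_ss) - known
    if dangling:
        raise ValueError(f"hits reference unknown patterns: {sorted(dangling)[:5]}")
    out = {}
    for p in patterns:
        t, s = p.pattern_id in with_tfbs, p.pattern_id in with_ss
        if t and s:
            cls = PatternClass.TFBS_SS
        elif t:
            cls = PatternClass.TFBS
        elif s:
            cls = PatternClass.SS
        else:
            cls = PatternClass.NOT_IDENTIFIED
        out[p.pattern_id] = cls
    return out


SUMMARY_COLUMNS = [
    "ordinal",
    "n_patterns",
    "n_tfbs_patterns",
    "n_ss_patterns",
    "n_class_tfbs",
    "n_class_tfbs_ss",
    "n_class_ss",
    "n_class_not_identified",
    "pct_tfbs",
    "pct_ss",
]


def summarize_counts(
    n_patterns: Mapping[int, int],
    n_tfbs_patterns: Mapping[int, int],
    n_ss_patterns: Mapping[int, int],
    class_counts: Mapping[int, Mapping[PatternClass, int]] | None = None,
) -> pd.DataFrame:
    """Build the per-ordinal frequency table from plain counts.

    One row per ordinal plus a ``Total`` row; percentage columns are the
    TFBS-containing and SS-containing pattern counts as half-up-rounded
    integer percentages of the pattern count.
    """
    rows = []
    for ordinal in sorted(n_patterns):
        n = n_patterns[ordinal]
        nt = n_tfbs_patterns.get(ordinal, 0)
        ns = n_ss_patterns.get(ordinal, 0)
        cc = (class_counts or {}).get(ordinal, {})
        rows.append(
            {
                "ordinal": str(ordinal),
                "n_patterns": n,
                "n_tfbs_patterns": nt,
                "n_ss_patterns": ns,
                "n_class_tfbs": cc.get(PatternClass.TFBS, 0),
                "n_class_tfbs_ss": cc.get(PatternClass.TFBS_SS, 0),
                "n_class_ss": cc.get(PatternClass.SS, 0),
                "n_class_not_identified": cc.get(PatternClass.NOT_IDENTIFIED, 0),
                "pct_tfbs": round_half_up_pct(nt, n) if n else 0,
                "pct_ss": round_half_up_pct(ns, n) if n else 0,
            }
        )
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    totals = df.drop(columns=["ordinal", "pct_tfbs", "pct_ss"]).sum()
    total_n = int(totals["n_patterns"])
    total_row = {"ordinal": "Total", **{k: int(v) for k, v in totals.items()}}
    total_row["pct_tfbs"] = round_half_up_pct(int(totals["n_tfbs_patterns"]), total_n) if total_n else 0
    total_row["pct_ss"] = round_half_up_pct(int(totals["n_ss_patterns"]), total_n) if total_n else 0
    return pd.concat([df, pd.DataFrame([total_row])], ignore_index=True)


def build_summary(
    groups: Mapping[int, Sequence[ConservedPattern]],
    classes: Mapping[str, PatternClass],
) -> pd.DataFrame:
    """Per-ordinal frequency table from grouped patterns and their classes.

    A pattern counts as TFBS-containing when its class is TFBS or TFBS-SS,
    and as SS-containing when its class is SS or TFBS-SS, so the class
    counts per ordinal always partition the pattern count.
    """
    n_patterns: dict[int, int] = {}
    n_tfbs: dict[int, int] = {}
    n_ss: dict[int, int] = {}
    class_counts: dict[int, Counter] = {}
    for ordinal, patterns in groups.items():
        n_patterns[ordinal] = len(patterns)
        cc = Counter(classes[p.pattern_id] for p in patterns)
        class_counts[ordinal] = cc
        n_tfbs[ordinal] = sum(v for k, v in cc.items() if k.has_tfbs)
        n_ss[ordinal] = sum(v for k, v in cc.items() if k.has_ss)
    return summarize_counts(n_patterns, n_tfbs, n_ss, class_counts)


@dataclass
class FamilyTally:
    """Binding-site counts per DNA-binding-domain family."""

    counts: dict[str, int] = field(default_factory=dict)
    k: int = 10

    @property
    def top(self) -> list[tuple[str, int]]:
        """The ``k`` most numerous families; ties broken alphabetically."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))[: self.k]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(rows, columns=["family", "n_tfbs"])


def tally_families(tfbs_hits: Iterable, k: int = 10) -> FamilyTally:
    """Count TFBS per family; each hit (one motif/offset/strand site) counts once."""
    counts = Counter(h.family for h in tfbs_hits)
    return FamilyTally(dict(counts), k=k)


def nr_cluster_report(
    tfbs_hits: Iterable,
    nr_family_labels: Iterable[str] = DEFAULT_NR_FAMILY_LABELS,
) -> pd.DataFrame:
    """Per gene region, the nuclear receptors whose motifs hit its patterns.

    Membership is defined by the motif library's family column, so the
    report follows whatever library version was scanned.  Output columns:
    gene, location ("Intron 1", ...), receptors (sorted, comma-joined).
    """
    labels = set(nr_family_labels)
    clusters: dict[tuple[str, str], set[str]] = {}
    order: dict[tuple[str, str], tuple] = {}
    for h in tfbs_hits:
        if h.family not in labels:
            continue
        gene, _, rest = h.pattern_id.partition("|")
        region, _, _ = rest.partition("|")
        kind = region.rstrip("0123456789")
        ordinal = int(region[len(kind):])
        key = (gene, f"{kind.capitalize()} {ordinal}")
        clusters.setdefault(key, set()).update(h.tf_names)
        order[key] = (gene, kind, ordinal)
    rows = [
        {"gene": gene, "location": loc, "receptors": ", ".join(sorted(clusters[(gene, loc)]))}
        for (gene, loc) in sorted(clusters, key=lambda key: order[key])
    ]
    return pd.DataFrame(rows, columns=["gene", "location", "receptors"])
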