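"""Extraction of fully conserved patterns and matched non-conserved controls.

A pattern is a maximal run of alignment columns in which every row carries
the same nucleotide (no gap, no N, no substitution), kept only when the run
spans at least ``min_len`` columns (default 15, which suppresses runs
expected by chance and is long enough to hold a binding site).  Controls
are random, equally long windows drawn from the complementary, less-than-
fully-conserved columns of the same alignments.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import Pssm
from .io_formats import GAP, MsaBlock

log = logging.getLogger(__name__)

DEFAULT_MIN_PATTERN_LEN = 15


@dataclass
class ConservedPattern:
    """A maximal 100%-conserved alignment run (0-based half-open columns)."""

    gene_id: str
    region_kind: str
    ordinal: int
    aln_start: int
    aln_end: int
    sequence: str
    per_species_coords: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return self.aln_end - self.aln_start

    @property
    def pattern_id(self) -> str:
        # 1-based inclusive in the id so it matches the written tables
        return f"{self.gene_id}|{self.region_kind}{self.ordinal}|{self.aln_start + 1}-{self.aln_end}"

    @property
    def region_label(self) -> str:
        return f"{self.region_kind.capitalize()} {self.ordinal}"


@dataclass
class ControlPattern(ConservedPattern):
    """A non-conserved window sampled as a matched control."""

    rng_seed: int = 0


def conserved_mask(pssm: Pssm) -> np.ndarray:
    """True where a single nucleotide (not gap/N) occupies every row."""
    return pssm.counts[:, :4].max(axis=1) == pssm.n_rows


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as 0-based half-open (start, end) pairs."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def _ungapped_start(row: str, aln_start: int) -> int:
    return aln_start - row.count(GAP, 0, aln_start)


def extract_conserved_patterns(
    pssm: Pssm,
    msa: MsaBlock,
    min_len: int = DEFAULT_MIN_PATTERN_LEN,
) -> list[ConservedPattern]:
    """Extract maximal fully conserved runs of at least ``min_len`` columns.

    Returned patterns are sorted by alignment start and are pairwise
    disjoint (maximality separates them by at least one non-conserved
    column).  The pattern sequence can be read off any row because
    conserved columns contain no gaps.
    """
    if pssm.length != msa.length:
        raise ValueError("PSSM and alignment lengths differ")
    mask = conserved_mask(pssm)
    first_row = next(iter(msa.rows.values()))
    patterns = []
    for start, end in _runs(mask):
        if end - start < min_len:
            continue
        coords = {sp: _ungapped_start(row, start) for sp, row in msa.rows.items()}
        patterns.append(
            ConservedPattern(
                gene_id=msa.gene_id,
                region_kind=msa.region_kind,
                ordinal=msa.ordinal,
                aln_start=start,
                aln_end=end,
                sequence=first_row[start:end],
                per_species_coords=coords,
            )
        )
    return patterns


def extract_nonconserved_controls(
    pssm: Pssm,
    msa: MsaBlock,
    n: int,
    min_len: int = DEFAULT_MIN_PATTERN_LEN,
    seed: int = 0,
) -> list[ControlPattern]:
    """Sample ``n`` non-conserved windows of at least ``min_len`` columns.

    Candidate columns are those that are not 100% conserved, are gap-free
    in the reference (first) species, and hold at least one nucleotide.
    Maximal runs of candidates at least ``min_len`` long are sampled
    without replacement with probability proportional to run length; each
    selected run contributes one uniformly placed sub-window of uniformly
    drawn length.  The control sequence reads the per-column majority
    nucleotide (ties broken alphabetically).  Fully reproducible under
    ``seed``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if pssm.length != msa.length:
        raise ValueError("PSSM and alignment lengths differ")
    ref_sp, ref_row = next(iter(msa.rows.items()))
    ref_arr = np.frombuffer(ref_row.encode("ascii"), dtype=np.uint8)
    eligible = (
        ~conserved_mask(pssm)
        & (ref_arr != ord(GAP))
        & (pssm.counts[:, :4].sum(axis=1) > 0)
    )
    runs = [(s, e) for s, e in _runs(eligible) if e - s >= min_len]
    rng = np.random.default_rng(seed)
    k = min(n, len(runs))
    if k < n:
        log.warning(
            "%s %s%d: only %d non-conserved runs of >=%d columns for %d requested controls",
            msa.gene_id, msa.region_kind, msa.ordinal, len(runs), min_len, n,
        )
    if k == 0:
        return []
    lengths = np.array([e - s for s, e in runs], dtype=float)
    chosen = rng.choice(len(runs), size=k, replace=False, p=lengths / lengths.sum())
    majority = pssm.counts[:, :4].argmax(axis=1)  # argmax ties resolve alphabetically
    controls = []
    for idx in chosen:
        s, e = runs[int(idx)]
        run_len = e - s
        w = int(rng.integers(min_len, run_len + 1))
        start = s + int(rng.integers(0, run_len - w + 1))
        end = start + w
        seq = "".join("ACGT"[majority[i]] for i in range(start, end))
        coords = {sp: _ungapped_start(row, start) for sp, row in msa.rows.items()}
        controls.append(
            ControlPattern(
                gene_id=msa.gene_id,
                region_kind=msa.region_kind,
                ordinal=msa.ordinal,
                aln_start=start,
                aln_end=end,
                sequence=seq,
                per_species_coords=coords,
                rng_seed=seed,
            )
        )
    controls.sort(key=lambda c: c.aln_start)
    return controls


def group_by_ordinal(patterns: Iterable[ConservedPattern]) -> dict[int, list[ConservedPattern]]:
    """Partition patterns by intron/exon ordinal (1-based position in gene)."""
    groups: dict[int, list[ConservedPattern]] = {}
    for p in patterns:
        groups.setdefault(p.ordinal, []).append(p)
    return dict(sorted(groups.items()))


def normalize_counts(
    groups: Mapping[int, Sequence | int],
    genes_per_ordinal: Mapping[int, int],
    length_per_ordinal: Mapping[int, float],
) -> pd.DataFrame:
    """Normalize per-ordinal pattern counts to gene number and sequence length.

    ``groups`` maps ordinal to a pattern list or a plain count.  Output has
    one row per ordinal with the raw count, count per gene carrying the
    ordinal, and count per kilobase of total sequence; ordinals lacking a
    denominator are omitted with a warning.
    """
    rows = []
    for ordinal in sorted(groups):
        val = groups[ordinal]
        count = val if isinstance(val, int) else len(val)
        genes = genes_per_ordinal.get(ordinal)
        length = length_per_ordinal.get(ordinal)
        if not genes or not length:
            log.warning("ordinal %d: missing gene-count or length denominator, omitted", ordinal)
            continue
        rows.append(
            {
                "ordinal": ordinal,
                "n_patterns": count,
                "per_gene": count / genes,
                "per_kb": count / (length / 1000.0),
            }
        )
    return pd.DataFrame(rows, columns=["ordinal", "n_patterns", "per_gene", "per_kb"])
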