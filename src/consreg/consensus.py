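"""Alignment profile and position score matrix.

The profile is a per-column majority-rule ("dumb") consensus: a column
contributes its most common nucleotide when that nucleotide's fraction of
rows strictly exceeds the threshold (default 0.7), and the ambiguity
character ``X`` otherwise.  Gaps and N are tallied in the position score
matrix but are never emitted as consensus characters, which keeps the
extracted patterns free of gaps.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MsaBlock

#: tally categories, in column order of ``Pssm.counts``
CATEGORIES = "ACGT-N"
AMBIGUOUS = "X"
DEFAULT_CONSENSUS_THRESHOLD = 0.7


@dataclass
class Pssm:
    """Per-alignment-column occurrence counts of A, C, G, T, gap and N."""

    counts: np.ndarray  # shape (length, 6), integer counts in CATEGORIES order
    n_rows: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[1] != len(CATEGORIES):
            raise ValueError(f"counts must be (length, {len(CATEGORIES)})")
        if not np.all(c.sum(axis=1) == self.n_rows):
            raise ValueError("per-column counts must sum to the number of rows")
        self.counts = c

    @property
    def length(self) -> int:
        return int(self.counts.shape[0])

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.n_rows


@dataclass
class ConsensusProfile:
    profile: str
    threshold: float = DEFAULT_CONSENSUS_THRESHOLD

    def __len__(self) -> int:
        return len(self.profile)


def build_pssm(msa: MsaBlock) -> Pssm:
    """Tally nucleotide, gap and N occurrences for every alignment column."""
    arr = np.array(
        [np.frombuffer(row.encode("ascii"), dtype=np.uint8) for row in msa.rows.values()]
    )
    counts = np.stack([(arr == ord(c)).sum(axis=0) for c in CATEGORIES], axis=1)
    return Pssm(counts.astype(np.int64), msa.n_rows)


def dumb_consensus(pssm: Pssm, threshold: float = DEFAULT_CONSENSUS_THRESHOLD) -> ConsensusProfile:
    """Majority-rule consensus with a strict fraction threshold.

    A column's character is its most common nucleotide when that
    nucleotide's fraction strictly exceeds ``threshold``; ties for the most
    common nucleotide, gap-majority columns and everything at or below the
    threshold give ``X``.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    fractions = pssm.fractions
    nuc = fractions[:, :4]
    best = nuc.argmax(axis=1)
    best_frac = nuc.max(axis=1)
    tied = (nuc == best_frac[:, None]).sum(axis=1) > 1
    # gap- or N-majority columns never yield a consensus nucleotide
    nonnuc_frac = fractions[:, 4:].max(axis=1)
    keep = (best_frac > threshold) & ~tied & (best_frac > nonnuc_frac)
    chars = [
        CATEGORIES[b] if ok else AMBIGUOUS
        for b, ok in zip(best, keep)
    ]
    return ConsensusProfile("".join(chars), threshold)
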