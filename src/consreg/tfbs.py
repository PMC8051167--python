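"""PWM log-odds scanning of pattern sequences against a motif library.

Each motif's position probabilities are turned into per-position log-odds
in bits against a background (uniform by default), with a small pseudocount
mixed in proportionally to the background:

    score(i, b) = log2( (p_ib + c * bg_b) / ((1 + c) * bg_b) )

A window is a hit when its summed score reaches the score threshold
(default 10 bits) and the motif spans at least ``min_width`` nucleotides
(default 10), which drops sparse short matches.  Both strands are scanned
by default; reverse-strand windows are scored on the reverse complement
and reported in forward coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import MotifModel, NUCLEOTIDES
from .patterns import ConservedPattern

DEFAULT_LOGODDS_THRESHOLD = 10.0
DEFAULT_MIN_MOTIF_WIDTH = 10
DEFAULT_PSEUDOCOUNT = 0.01

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(NUCLEOTIDES):
    _CODE[ord(_b)] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class LogOddsMatrix:
    motif_id: str
    scores: np.ndarray  # (width, 4) log-odds in bits, columns A C G T
    tf_names: list[str] = field(default_factory=list)
    family: str = ""

    @property
    def width(self) -> int:
        return int(self.scores.shape[0])

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())


@dataclass
class TfbsHit:
    pattern_id: str
    gene_id: str
    motif_id: str
    tf_names: list[str]
    family: str
    offset: int  # 0-based start within the pattern sequence, forward strand
    strand: str  # '+' or '-'
    score: float


def pwm_to_logodds(
    motif: MotifModel,
    background: Sequence[float] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> LogOddsMatrix:
    """Convert a position-probability matrix to per-position log-odds (bits)."""
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-6:
        raise ValueError("background must be four positive fractions summing to 1")
    scores = np.log2((motif.matrix + pseudocount * bg) / ((1.0 + pseudocount) * bg))
    return LogOddsMatrix(motif.motif_id, scores, list(motif.tf_names), motif.family)


def window_score(seq: str, lom: LogOddsMatrix, offset: int) -> float:
    """Score of the width-long window at ``offset`` (forward strand)."""
    codes = _CODE[np.frombuffer(seq[offset : offset + lom.width].encode("ascii"), dtype=np.uint8)]
    if np.any(codes < 0):
        return float("-inf")
    return float(lom.scores[np.arange(lom.width), codes].sum())


def scan_pattern(
    seq: str,
    lom: LogOddsMatrix,
    threshold: float = DEFAULT_LOGODDS_THRESHOLD,
    min_width: int = DEFAULT_MIN_MOTIF_WIDTH,
    strands: str = "both",
    pattern_id: str = "",
    gene_id: str = "",
) -> list[TfbsHit]:
    """Score every window of the motif's width on the requested strands.

    Windows containing a character outside A/C/G/T never match.  Hits may
    overlap.  Reverse-strand windows are scored on the reverse complement
    and reported with forward-strand offsets.
    """
    if strands not in ("+", "-", "both"):
        raise ValueError(f"strands must be '+', '-' or 'both', got {strands!r}")
    w = lom.width
    n = len(seq)
    if w < min_width or n < w:
        return []
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    hits = []
    do_fwd = strands in ("+", "both")
    do_rev = strands in ("-", "both")
    pos_idx = np.arange(w)
    valid = codes >= 0
    rc_codes = None
    if do_rev:
        rc_codes = _CODE[np.frombuffer(reverse_complement(seq).encode("ascii"), dtype=np.uint8)]
    for off in range(n - w + 1):
        if do_fwd and valid[off : off + w].all():
            s = float(lom.scores[pos_idx, codes[off : off + w]].sum())
            if s >= threshold:
                hits.append(
                    TfbsHit(pattern_id, gene_id, lom.motif_id, lom.tf_names, lom.family, off, "+", s)
                )
        if do_rev:
            rc_off = n - w - off
            win = rc_codes[rc_off : rc_off + w]
            if (win >= 0).all():
                s = float(lom.scores[pos_idx, win].sum())
                if s >= threshold:
                    hits.append(
                        TfbsHit(pattern_id, gene_id, lom.motif_id, lom.tf_names, lom.family, off, "-", s)
                    )
    hits.sort(key=lambda h: (h.offset, h.motif_id, h.strand))
    return hits


def scan_all(
    patterns: Iterable[ConservedPattern],
    library: Iterable[MotifModel],
    threshold: float = DEFAULT_LOGODDS_THRESHOLD,
    min_width: int = DEFAULT_MIN_MOTIF_WIDTH,
    strands: str = "both",
    background: Sequence[float] | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[TfbsHit]:
    """Scan every pattern against every library motif.

    Output is deterministically ordered by (pattern, offset, motif, strand).
    One (motif, offset, strand) triple counts as one TFBS; motifs mapped to
    several TFs multiply TF-level tallies downstream, not site-level ones.
    """
    loms = [
        pwm_to_logodds(m, background=background, pseudocount=pseudocount)
        for m in library
        if m.width >= min_width
    ]
    hits: list[TfbsHit] = []
    for p in patterns:
        per_pattern: list[TfbsHit] = []
        for lom in loms:
            per_pattern.extend(
                scan_pattern(
                    p.sequence,
                    lom,
                    threshold=threshold,
                    min_width=min_width,
                    strands=strands,
                    pattern_id=p.pattern_id,
                    gene_id=p.gene_id,
                )
            )
        per_pattern.sort(key=lambda h: (h.offset, h.motif_id, h.strand))
        hits.extend(per_pattern)
    return hits
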