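"""Splice-site detection inside patterns.

Two scorers are supported:

* a consensus-value (CV) scorer: the per-position frequencies of a window
  are summed and min-max normalized to a 0-100 scale,

      CV = 100 * (t - t_min) / (t_max - t_min),  t = sum_i freq_i(window_i),

  where t_min / t_max sum the per-position minima / maxima.  A window is
  called a splice site at CV >= 75 by default.
* an optional maximum-entropy scorer defined entirely by score-table files
  (a direct k-mer table, or several factored sub-tables whose signed scores
  are summed in log2 units).  A window is called at a score >= 3 bits by
  default.  Without model tables the pipeline runs in CV-only mode.

The packaged default frequency matrices are synthetic: they are built from
the classical mammalian splice-consensus base frequencies (donor width 9,
acceptor width 14) and are user-replaceable files, not the matrices of any
particular web service.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np

from .patterns import ConservedPattern

log = logging.getLogger(__name__)

SITE_TYPES = ("donor", "acceptor")
DEFAULT_CV_THRESHOLD = 75.0
DEFAULT_MAXENT_THRESHOLD = 3.0

_CODE = {b: i for i, b in enumerate("ACGT")}


@dataclass
class SpliceMatrix:
    """Per-position nucleotide frequencies of a splice-site consensus."""

    site_type: str
    freq: np.ndarray  # (width, 4), columns A C G T
    source: str = ""

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"site_type must be one of {SITE_TYPES}")
        f = np.asarray(self.freq, dtype=float)
        if f.ndim != 2 or f.shape[1] != 4 or f.shape[0] < 1:
            raise ValueError("freq must be (width>=1, 4)")
        if np.any(f < 0):
            raise ValueError("negative frequencies")
        sums = f.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError("a position has zero total frequency")
        # rows are stored normalized; CV is invariant to a global rescale
        self.freq = f / sums[:, None]

    @property
    def width(self) -> int:
        return int(self.freq.shape[0])


@dataclass
class SpliceHit:
    pattern_id: str
    gene_id: str
    site_type: str
    offset: int  # 0-based start of the scored window within the pattern
    cv: float | None
    maxent: float | None
    called_by: set[str] = field(default_factory=set)


def load_splice_matrix(path: str | Path, site_type: str) -> SpliceMatrix:
    """Load a frequency matrix TSV (columns pos, A, C, G, T; '#' comments)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"A", "C", "G", "T"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: splice matrix needs columns A C G T")
    return SpliceMatrix(site_type, df[["A", "C", "G", "T"]].to_numpy(dtype=float), source=str(path))


def default_donor_matrix() -> SpliceMatrix:
    with resources.as_file(resources.files("consreg.data") / "donor_freq_synthetic.tsv") as p:
        mat = load_splice_matrix(p, "donor")
    mat.source = "packaged synthetic donor consensus"
    return mat


def default_acceptor_matrix() -> SpliceMatrix:
    with resources.as_file(resources.files("consreg.data") / "acceptor_freq_synthetic.tsv") as p:
        mat = load_splice_matrix(p, "acceptor")
    mat.source = "packaged synthetic acceptor consensus"
    return mat


def consensus_value(window: str, mat: SpliceMatrix) -> float:
    """Min-max normalized frequency sum of ``window``, on a 0-100 scale."""
    if len(window) != mat.width:
        raise ValueError(f"window length {len(window)} != matrix width {mat.width}")
    try:
        idx = [_CODE[b] for b in window]
    except KeyError as exc:
        raise ValueError(f"window contains non-ACGT character {exc}") from exc
    t = float(mat.freq[np.arange(mat.width), idx].sum())
    t_min = float(mat.freq.min(axis=1).sum())
    t_max = float(mat.freq.max(axis=1).sum())
    if t_max == t_min:  # fully uninformative matrix
        return 0.0
    return 100.0 * (t - t_min) / (t_max - t_min)


# ---------------------------------------------------------------------------
# maximum-entropy scorer (pluggable, defined by its model files)


@dataclass
class _SubTable:
    positions: tuple[int, ...]  # 0-based positions within the window
    sign: int
    scores: dict[str, float]


@dataclass
class MaxEntModel:
    """Score tables for one or both site types.

    Model directory contract: one or more ``.tsv`` files whose names start
    with ``donor`` or ``acceptor``.  Each file holds header comment lines

        # site_type: donor
        # positions: 0,1,2,...   (0-based within the scored window)
        # sign: 1                (optional, +1 or -1; default +1)

    followed by tab-separated ``kmer<TAB>score`` rows with scores in log2
    units.  A site type's score is the signed sum of its sub-table lookups
    (the log-space form of a product/quotient of factored marginals); any
    missing k-mer makes the window unscorable (-inf, never called).
    """

    tables: dict[str, list[_SubTable]] = field(default_factory=dict)

    def has(self, site_type: str) -> bool:
        return bool(self.tables.get(site_type))

    def window_width(self, site_type: str) -> int:
        return max(max(t.positions) for t in self.tables[site_type]) + 1

    def score(self, window: str, site_type: str) -> float:
        if not self.has(site_type):
            raise ValueError(f"no {site_type} tables loaded")
        if len(window) != self.window_width(site_type):
            raise ValueError(
                f"window length {len(window)} != model width {self.window_width(site_type)}"
            )
        total = 0.0
        for tab in self.tables[site_type]:
            kmer = "".join(window[i] for i in tab.positions)
            if kmer not in tab.scores:
                return float("-inf")
            total += tab.sign * tab.scores[kmer]
        return total


def maxent_score(window: str, model: MaxEntModel, site_type: str) -> float:
    """Score a window with the loaded maximum-entropy tables (log2 units)."""
    return model.score(window, site_type)


def load_maxent_model(model_dir: str | Path) -> MaxEntModel:
    model_dir = Path(model_dir)
    model = MaxEntModel()
    for path in sorted(model_dir.glob("*.tsv")):
        site_type = None
        positions: tuple[int, ...] | None = None
        sign = 1
        scores: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line.lstrip("# ").partition(":")
                    key = key.strip().lower()
                    if key == "site_type":
                        site_type = val.strip()
                    elif key == "positions":
                        positions = tuple(int(x) for x in val.replace(" ", "").split(","))
                    elif key == "sign":
                        sign = int(val)
                    continue
                kmer, _, score = line.partition("\t")
                scores[kmer.strip().upper()] = float(score)
        if site_type not in SITE_TYPES:
            raise ValueError(f"{path}: missing or invalid '# site_type:' header")
        if positions is None:
            width = len(next(iter(scores)))
            positions = tuple(range(width))
        model.tables.setdefault(site_type, []).append(_SubTable(positions, sign, scores))
    if not model.tables:
        raise ValueError(f"no model tables found in {model_dir}")
    return model


# ---------------------------------------------------------------------------
# scanning


def scan_splice(
    pattern: ConservedPattern,
    donor: SpliceMatrix | None = None,
    acceptor: SpliceMatrix | None = None,
    model: MaxEntModel | None = None,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
    maxent_threshold: float = DEFAULT_MAXENT_THRESHOLD,
    ss_rule: str = "any",
) -> list[SpliceHit]:
    """Test every window of the pattern for donor and acceptor signals.

    For each site type every CV-matrix-width window is scored; where
    maximum-entropy tables of the same width exist, the window gets both
    scores and ``called_by`` records which scorers exceeded their
    thresholds.  Model widths different from the CV width are scanned
    separately (their hits carry no CV).  ``ss_rule='any'`` keeps hits
    called by at least one scorer; ``'all'`` keeps only windows called by
    both.  Windows containing N are skipped.
    """
    if ss_rule not in ("any", "all"):
        raise ValueError("ss_rule must be 'any' or 'all'")
    matrices = {"donor": donor, "acceptor": acceptor}
    hits: list[SpliceHit] = []
    seq = pattern.sequence
    for site_type in SITE_TYPES:
        mat = matrices[site_type]
        model_ok = model is not None and model.has(site_type)
        model_w = model.window_width(site_type) if model_ok else None
        if mat is not None:
            for off in range(len(seq) - mat.width + 1):
                window = seq[off : off + mat.width]
                if "N" in window:
                    continue
                cv = consensus_value(window, mat)
                me = None
                called = set()
                if cv >= cv_threshold:
                    called.add("HSF")
                if model_ok and model_w == mat.width:
                    me = model.score(window, site_type)
                    if me >= maxent_threshold:
                        called.add("MaxEnt")
                if called:
                    hits.append(
                        SpliceHit(pattern.pattern_id, pattern.gene_id, site_type, off, cv, me, called)
                    )
        if model_ok and (mat is None or model_w != mat.width):
            for off in range(len(seq) - model_w + 1):
                window = seq[off : off + model_w]
                if "N" in window:
                    continue
                me = model.score(window, site_type)
                if me >= maxent_threshold:
                    hits.append(
                        SpliceHit(
                            pattern.pattern_id, pattern.gene_id, site_type, off, None, me, {"MaxEnt"}
                        )
                    )
    if ss_rule == "all":
        hits = [h for h in hits if {"HSF", "MaxEnt"} <= h.called_by]
    hits.sort(key=lambda h: (h.site_type, h.offset))
    return hits


def scan_all_splice(
    patterns: Iterable[ConservedPattern],
    donor: SpliceMatrix | None = None,
    acceptor: SpliceMatrix | None = None,
    model: MaxEntModel | None = None,
    cv_threshold: float = DEFAULT_CV_THRESHOLD,
    maxent_threshold: float = DEFAULT_MAXENT_THRESHOLD,
    ss_rule: str = "any",
) -> list[SpliceHit]:
    hits: list[SpliceHit] = []
    for p in patterns:
        hits.extend(
            scan_splice(
                p,
                donor=donor,
                acceptor=acceptor,
                model=model,
                cv_threshold=cv_threshold,
                maxent_threshold=maxent_threshold,
                ss_rule=ss_rule,
            )
        )
    return hits
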