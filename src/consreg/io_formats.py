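"""Readers and writers for the external formats the pipeline consumes and emits.

Formats handled here:

* FASTA files holding one gene region (one record per species), unaligned
  or pre-aligned;
* CIS-BP-style motif dumps: a ``TF_Information``-like TSV plus one plain-text
  position-probability matrix per motif;
* the TSV tables written by the pipeline (patterns, hits, summaries).

Coordinate convention: every in-memory interval is 0-based half-open.
Every written table uses 1-based inclusive coordinates and states so in a
leading ``#`` comment line.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
ALPHABET = frozenset("ACGTN")
GAP = "-"
REGION_KINDS = ("intron", "exon")

#: canonical CIS-BP TF_Information column names
CISBP_MOTIF_COL = "Motif_ID"
CISBP_TF_COL = "TF_Name"
CISBP_FAMILY_COL = "Family_Name"
CISBP_STATUS_COL = "TF_Status"


@dataclass
class OrthologSet:
    """One gene region's orthologous sequences across species.

    ``sequences`` maps species id to an ungapped DNA string over {A,C,G,T,N};
    insertion order is preserved and meaningful (the first species is the
    reference used for ungapped output coordinates).
    """

    gene_id: str
    region_kind: str
    ordinal: int
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if self.region_kind not in REGION_KINDS:
            raise ValueError(f"region_kind must be one of {REGION_KINDS}, got {self.region_kind!r}")
        if self.ordinal < 1:
            raise ValueError(f"ordinal must be >= 1, got {self.ordinal}")
        if len(self.sequences) < 2:
            raise ValueError("an OrthologSet needs at least two species")
        for sp, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for species {sp!r}")
            bad = set(seq) - ALPHABET
            if bad:
                raise ValueError(
                    f"non-nucleotide characters {sorted(bad)} in species {sp!r} "
                    f"of {self.gene_id} {self.region_kind} {self.ordinal}"
                )

    @property
    def species(self) -> list[str]:
        return list(self.sequences)

    @property
    def region_label(self) -> str:
        return f"{self.region_kind.capitalize()} {self.ordinal}"


@dataclass
class MsaBlock:
    """A multiple alignment of one gene region: equal-length gapped rows."""

    rows: dict[str, str]
    gene_id: str = ""
    region_kind: str = "intron"
    ordinal: int = 1
    source: OrthologSet | None = None

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least two rows")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment rows (lengths {sorted(lengths)})")
        allowed = ALPHABET | {GAP}
        for sp, row in self.rows.items():
            bad = set(row) - allowed
            if bad:
                raise ValueError(f"invalid characters {sorted(bad)} in aligned row {sp!r}")
        if self.source is not None:
            for sp, row in self.rows.items():
                if row.replace(GAP, "") != self.source.sequences.get(sp):
                    raise ValueError(f"degapped row {sp!r} does not match its source sequence")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def degap(self, species: str) -> str:
        return self.rows[species].replace(GAP, "")

    def to_ortholog_set(self) -> OrthologSet:
        return OrthologSet(
            self.gene_id or "unknown",
            self.region_kind,
            self.ordinal,
            {sp: self.degap(sp) for sp in self.rows},
        )

    @classmethod
    def from_ortholog_set(cls, oset: OrthologSet) -> "MsaBlock":
        """Treat equal-length ungapped sequences as a (trivial) alignment."""
        lengths = {len(s) for s in oset.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(
                "sequences differ in length; align them first (e.g. with an external aligner)"
            )
        return cls(
            dict(oset.sequences),
            gene_id=oset.gene_id,
            region_kind=oset.region_kind,
            ordinal=oset.ordinal,
            source=oset,
        )


@dataclass
class MotifModel:
    """A position-probability matrix with its TF attribution.

    ``matrix`` has shape (width, 4) with columns A, C, G, T; each row sums to
    one (rows off by at most 1e-3 are renormalized, anything worse is
    rejected). ``tf_names`` carries every TF mapped to the motif, direct or
    inferred, and ``family`` is the DNA-binding-domain family label.
    """

    motif_id: str
    tf_names: list[str]
    family: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError(f"motif {self.motif_id}: matrix must be (width>=1, 4)")
        if np.any(m < 0):
            raise ValueError(f"motif {self.motif_id}: negative probabilities")
        sums = m.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"motif {self.motif_id}: matrix row {bad} sums to {sums[bad]:.4g}, not 1"
            )
        self.matrix = m / sums[:, None]

    @property
    def width(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def consensus(self) -> str:
        return "".join(NUCLEOTIDES[i] for i in self.matrix.argmax(axis=1))


# ---------------------------------------------------------------------------
# FASTA


def read_ortholog_fasta(path: str | Path, gene_id: str, region_kind: str, ordinal: int) -> OrthologSet:
    """Read one gene region's FASTA (record ids are species ids)."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        sp = rec.id
        if sp in sequences:
            raise ValueError(f"duplicate species id {sp!r} in {path}")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty record {sp!r} in {path}")
        sequences[sp] = seq
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return OrthologSet(gene_id, region_kind, ordinal, sequences)


def write_ortholog_fasta(oset: OrthologSet, path: str | Path) -> Path:
    path = Path(path)
    records = [SeqRecord(Seq(seq), id=sp, description="") for sp, seq in oset.sequences.items()]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_msa_fasta(
    path: str | Path,
    gene_id: str = "",
    region_kind: str = "intron",
    ordinal: int = 1,
) -> MsaBlock:
    """Read a pre-aligned FASTA into an MsaBlock (rows must be equal length)."""
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise ValueError(f"duplicate species id {rec.id!r} in {path}")
        rows[rec.id] = str(rec.seq).upper().replace("U", "T")
    if len(rows) < 2:
        raise ValueError(f"alignment {path} has fewer than two rows")
    return MsaBlock(rows, gene_id=gene_id, region_kind=region_kind, ordinal=ordinal)


def parse_region_filename(path: str | Path) -> tuple[str, str, int]:
    """Parse ``<gene>_<intron|exon><N>`` out of a region file name.

    Returns (gene_id, region_kind, ordinal).
    """
    import re

    stem = Path(path).stem
    m = re.fullmatch(r"(?P<gene>.+)_(?P<kind>intron|exon)(?P<ord>\d+)", stem)
    if not m:
        raise ValueError(
            f"cannot parse region from file name {stem!r}; expected <gene>_intron<N> or <gene>_exon<N>"
        )
    return m["gene"], m["kind"], int(m["ord"])


# ---------------------------------------------------------------------------
# CIS-BP motif library


def read_cisbp_library(info_path: str | Path, pwm_dir: str | Path) -> list[MotifModel]:
    """Read a CIS-BP-style dump: TF info TSV + one PPM text file per motif.

    Both direct and inferred TF->motif rows are kept; every TF mapped to a
    motif is attributed to its hits.  Motifs whose matrix file is missing or
    empty are skipped with a warning; a malformed matrix row is an error.
    """
    pwm_dir = Path(pwm_dir)
    info = pd.read_csv(info_path, sep="\t", dtype=str)
    missing = [c for c in (CISBP_MOTIF_COL, CISBP_TF_COL, CISBP_FAMILY_COL) if c not in info.columns]
    if missing:
        raise ValueError(f"{info_path}: missing required columns {missing}")
    info = info.dropna(subset=[CISBP_MOTIF_COL])

    motifs: list[MotifModel] = []
    for motif_id, grp in info.groupby(CISBP_MOTIF_COL, sort=True):
        tf_names = sorted({t for t in grp[CISBP_TF_COL].dropna() if t})
        family = str(grp[CISBP_FAMILY_COL].dropna().iloc[0]) if grp[CISBP_FAMILY_COL].notna().any() else ""
        mat_path = pwm_dir / f"{motif_id}.txt"
        if not mat_path.exists() or mat_path.stat().st_size == 0:
            log.warning("motif %s: matrix file missing or empty, skipping", motif_id)
            continue
        matrix = _read_pwm_file(mat_path, motif_id)
        if matrix is None:
            log.warning("motif %s: matrix file has no data rows, skipping", motif_id)
            continue
        motifs.append(MotifModel(str(motif_id), tf_names, family, matrix))
    return motifs


def _read_pwm_file(path: Path, motif_id: str) -> np.ndarray | None:
    df = pd.read_csv(path, sep="\t")
    expected = {"Pos", "A", "C", "G", "T"}
    if not expected.issubset(df.columns):
        raise ValueError(f"motif {motif_id}: matrix file {path} lacks columns {sorted(expected)}")
    if df.empty:
        return None
    df = df.sort_values("Pos")
    try:
        mat = df[["A", "C", "G", "T"]].to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"motif {motif_id}: malformed matrix row in {path}: {exc}") from exc
    if np.isnan(mat).any():
        raise ValueError(f"motif {motif_id}: malformed matrix row (missing value) in {path}")
    return mat


def write_cisbp_library(motifs: Iterable[MotifModel], info_path: str | Path, pwm_dir: str | Path) -> None:
    """Write motifs back out in the same dump layout ``read_cisbp_library`` reads."""
    pwm_dir = Path(pwm_dir)
    pwm_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for m in motifs:
        for i, tf in enumerate(m.tf_names):
            rows.append(
                {
                    CISBP_MOTIF_COL: m.motif_id,
                    CISBP_TF_COL: tf,
                    CISBP_STATUS_COL: "D" if i == 0 else "I",
                    CISBP_FAMILY_COL: m.family,
                }
            )
        df = pd.DataFrame(m.matrix, columns=list("ACGT"))
        df.insert(0, "Pos", np.arange(1, m.width + 1))
        df.to_csv(pwm_dir / f"{m.motif_id}.txt", sep="\t", index=False, float_format="%.6f")
    pd.DataFrame(rows).to_csv(info_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pattern / hit tables

PATTERN_COLUMNS = [
    "gene",
    "region_kind",
    "ordinal",
    "aln_start",
    "aln_end",
    "length",
    "sequence",
    "class",
    "n_tfbs",
    "n_ss",
]
_COORD_HEADER = "# coordinates: 1-based inclusive alignment columns\n"


def write_pattern_table(
    patterns: Iterable,
    path: str | Path,
    tfbs_hits: Iterable | None = None,
    splice_hits: Iterable | None = None,
    classes: Mapping[str, object] | None = None,
) -> Path:
    """Write the pattern table (one row per conserved or control pattern).

    ``classes`` maps pattern id to a PatternClass (or any object with a
    ``label``); hits are counted per pattern id.  Coordinates are converted
    to 1-based inclusive.
    """
    from collections import Counter

    n_tfbs = Counter(h.pattern_id for h in (tfbs_hits or []))
    n_ss = Counter(h.pattern_id for h in (splice_hits or []))
    rows = []
    for p in patterns:
        cls = (classes or {}).get(p.pattern_id)
        label = getattr(cls, "label", cls) if cls is not None else "unclassified"
        rows.append(
            {
                "gene": p.gene_id,
                "region_kind": p.region_kind,
                "ordinal": p.ordinal,
                "aln_start": p.aln_start + 1,
                "aln_end": p.aln_end,
                "length": p.aln_end - p.aln_start,
                "sequence": p.sequence,
                "class": label,
                "n_tfbs": n_tfbs.get(p.pattern_id, 0),
                "n_ss": n_ss.get(p.pattern_id, 0),
            }
        )
    df = pd.DataFrame(rows, columns=PATTERN_COLUMNS)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_COORD_HEADER)
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_pattern_table(path: str | Path):
    """Read a pattern table back into pattern records (0-based internally)."""
    from .patterns import ConservedPattern

    df = pd.read_csv(path, sep="\t", comment="#")
    patterns = []
    for row in df.itertuples(index=False):
        patterns.append(
            ConservedPattern(
                gene_id=str(row.gene),
                region_kind=str(row.region_kind),
                ordinal=int(row.ordinal),
                aln_start=int(row.aln_start) - 1,
                aln_end=int(row.aln_end),
                sequence=str(row.sequence),
                per_species_coords={},
            )
        )
    return patterns, df


def write_tfbs_table(hits: Iterable, path: str | Path) -> Path:
    rows = [
        {
            "pattern_id": h.pattern_id,
            "gene": h.gene_id,
            "motif_id": h.motif_id,
            "tf_names": ",".join(h.tf_names),
            "family": h.family,
            "offset": h.offset + 1,
            "strand": h.strand,
            "score": h.score,
        }
        for h in hits
    ]
    df = pd.DataFrame(
        rows,
        columns=["pattern_id", "gene", "motif_id", "tf_names", "family", "offset", "strand", "score"],
    )
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based offset within the pattern sequence\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.4f")
    return path


def write_splice_table(hits: Iterable, path: str | Path) -> Path:
    rows = [
        {
            "pattern_id": h.pattern_id,
            "gene": h.gene_id,
            "site_type": h.site_type,
            "offset": h.offset + 1,
            "cv": "" if h.cv is None else f"{h.cv:.2f}",
            "maxent": "" if h.maxent is None else f"{h.maxent:.3f}",
            "called_by": ",".join(sorted(h.called_by)),
        }
        for h in hits
    ]
    df = pd.DataFrame(
        rows, columns=["pattern_id", "gene", "site_type", "offset", "cv", "maxent", "called_by"]
    )
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based offset within the pattern sequence\n")
        df.to_csv(fh, sep="\t", index=False)
    return path
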