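"""Synthetic orthologous gene regions and toy motif libraries.

The simulator emulates the pipeline's inputs end to end with known truth:
for each gene region an ancestral sequence is drawn uniformly, and each
species copy is mutated independently per column (star phylogeny, no rate
variation) except inside planted blocks, which are copied verbatim and are
therefore exactly the fully conserved runs a correct extractor must
recover.  Planted blocks may embed a motif consensus or a canonical donor
or acceptor site, giving ground truth for the downstream scans and the
four-way classification.  Everything is deterministic under the spec seed.

Defaults reflect the intended study conditions: five mammalian species,
25 genes of three 600-nt introns, a 0.3 per-column substitution
probability in the background (well past the point where chance 15-nt
conserved runs are negligible), indels off (conserved patterns are
gap-free by construction; an indel mode exists to exercise gap handling),
and 40 planted blocks of 20 nt - 20 embedding a motif consensus, 10 a
canonical donor site, 10 plain.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import MotifModel, OrthologSet, write_cisbp_library, write_ortholog_fasta

DEFAULT_SPECIES = (
    "Homo_sapiens",
    "Gorilla_gorilla",
    "Pan_troglodytes",
    "Mus_musculus",
    "Rattus_norvegicus",
)

#: the ten DNA-binding-domain families the toy library covers
TOY_FAMILIES = (
    "Homeodomain",
    "Forkhead",
    "Homeodomain POU",
    "C2H2 ZF",
    "bZIP",
    "Nuclear receptor",
    "bHLH",
    "Ets",
    "Sox",
    "GATA",
)

#: canonical splice signals planted into blocks (consensus instantiations)
CANONICAL_DONOR = "CAGGTAAGT"
CANONICAL_ACCEPTOR = "TTTTTTTTTTCCAG"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PlantedBlock:
    gene_id: str
    ordinal: int
    offset: int  # 0-based within the region
    length: int
    element: str  # "none", "donor", "acceptor" or "motif:<motif_id>"

    def __post_init__(self) -> None:
        if self.length < 15:
            raise ValueError("planted blocks must be at least 15 nt")
        if self.element not in ("none", "donor", "acceptor") and not self.element.startswith("motif:"):
            raise ValueError(f"unknown element {self.element!r}")


@dataclass
class SimulationSpec:
    n_genes: int = 25
    introns_per_gene: int = 3
    intron_length: int = 600
    n_species: int = 5
    substitution_prob: float = 0.3
    indel_prob: float = 0.0
    planted_blocks: list[PlantedBlock] = field(default_factory=list)
    motif_consensus: dict[str, str] = field(default_factory=dict)
    region_kind: str = "intron"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_prob <= 1 or not 0 <= self.indel_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_species < 2 or self.n_species > len(DEFAULT_SPECIES):
            raise ValueError(f"n_species must be in [2, {len(DEFAULT_SPECIES)}]")
        by_region: dict[tuple[str, int], list[PlantedBlock]] = {}
        for b in self.planted_blocks:
            if b.offset < 0 or b.offset + b.length > self.intron_length:
                raise ValueError(f"block {b} exceeds its {self.intron_length}-nt region")
            by_region.setdefault((b.gene_id, b.ordinal), []).append(b)
        for blocks in by_region.values():
            blocks = sorted(blocks, key=lambda b: b.offset)
            for prev, nxt in zip(blocks, blocks[1:]):
                if prev.offset + prev.length > nxt.offset:
                    raise ValueError(f"planted blocks overlap: {prev} / {nxt}")

    @property
    def gene_ids(self) -> list[str]:
        return [f"GENE{i:02d}" for i in range(1, self.n_genes + 1)]

    @property
    def species(self) -> tuple[str, ...]:
        return DEFAULT_SPECIES[: self.n_species]


@dataclass
class ToyLibrarySpec:
    families: tuple[str, ...] = TOY_FAMILIES
    motif_width: int = 12
    sharpness: float = 0.97  # probability mass on the consensus base
    nr_tf_names: tuple[str, ...] = ("RARA", "RARB", "RARG")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.25 < self.sharpness <= 1.0:
            raise ValueError("sharpness must exceed the uniform 0.25")
        if self.motif_width < 1:
            raise ValueError("motif_width must be >= 1")


def simulate_toy_library(spec: ToyLibrarySpec) -> tuple[list[MotifModel], pd.DataFrame]:
    """Build one sharp motif per family; returns models plus a truth table.

    The nuclear-receptor motif is mapped to several receptor gene symbols
    (direct + inferred rows in the written dump) so TF-level reports can be
    exercised; every other motif maps to a single synthetic TF name.
    """
    rng = np.random.default_rng(spec.seed)
    motifs = []
    truth_rows = []
    off = (1.0 - spec.sharpness) / 3.0
    for i, family in enumerate(spec.families, start=1):
        motif_id = f"M{i:03d}_toy"
        consensus_idx = rng.integers(0, 4, size=spec.motif_width)
        matrix = np.full((spec.motif_width, 4), off)
        matrix[np.arange(spec.motif_width), consensus_idx] = spec.sharpness
        if family == "Nuclear receptor":
            tf_names = list(spec.nr_tf_names)
        else:
            tf_names = [family.replace(" ", "_").upper() + "_TF"]
        motif = MotifModel(motif_id, tf_names, family, matrix)
        motifs.append(motif)
        truth_rows.append(
            {"motif_id": motif_id, "family": family, "consensus": motif.consensus,
             "tf_names": ",".join(tf_names)}
        )
    return motifs, pd.DataFrame(truth_rows)


def default_planted_blocks(
    spec_like: SimulationSpec,
    motif_consensus: dict[str, str],
    rng: np.random.Generator,
    n_motif: int = 20,
    n_donor: int = 10,
    n_none: int = 10,
    block_len: int = 20,
) -> list[PlantedBlock]:
    """Place one block in each of ``n_motif+n_donor+n_none`` distinct regions."""
    regions = [
        (g, k)
        for g in spec_like.gene_ids
        for k in range(1, spec_like.introns_per_gene + 1)
    ]
    total = n_motif + n_donor + n_none
    if total > len(regions):
        raise ValueError(f"{total} blocks requested but only {len(regions)} regions")
    chosen = rng.choice(len(regions), size=total, replace=False)
    motif_ids = sorted(motif_consensus)
    elements = (
        [f"motif:{motif_ids[i % len(motif_ids)]}" for i in range(n_motif)]
        + ["donor"] * n_donor
        + ["none"] * n_none
    )
    blocks = []
    margin = 5  # keep blocks away from region edges
    for idx, element in zip(chosen, elements):
        gene, ordinal = regions[int(idx)]
        offset = int(rng.integers(margin, spec_like.intron_length - block_len - margin + 1))
        blocks.append(PlantedBlock(gene, ordinal, offset, block_len, element))
    return blocks


def default_simulation_spec(seed: int = 0) -> tuple[SimulationSpec, list[MotifModel], pd.DataFrame]:
    """The standard end-to-end fixture: spec + toy library + library truth."""
    lib_spec = ToyLibrarySpec(seed=seed)
    motifs, lib_truth = simulate_toy_library(lib_spec)
    consensus = {m.motif_id: m.consensus for m in motifs}
    base = SimulationSpec(seed=seed, motif_consensus=consensus)
    rng = np.random.default_rng(seed + 101)
    blocks = default_planted_blocks(base, consensus, rng)
    spec = SimulationSpec(seed=seed, motif_consensus=consensus, planted_blocks=blocks)
    return spec, motifs, lib_truth


def _element_sequence(block: PlantedBlock, motif_consensus: dict[str, str]) -> str | None:
    if block.element == "none":
        return None
    if block.element == "donor":
        return CANONICAL_DONOR
    if block.element == "acceptor":
        return CANONICAL_ACCEPTOR
    motif_id = block.element.split(":", 1)[1]
    if motif_id not in motif_consensus:
        raise ValueError(f"unknown motif id {motif_id!r} in planted block")
    return motif_consensus[motif_id]


def simulate_ortholog_sets(spec: SimulationSpec) -> tuple[list[OrthologSet], pd.DataFrame]:
    """Generate all gene regions plus the planted-block truth table.

    Truth columns: gene, ordinal, offset, length (the block, 0-based
    half-open within the human/ancestral region), element, element_offset
    (absolute 0-based start of the embedded element, or -1), element_seq.
    """
    rng = np.random.default_rng(spec.seed)
    blocks_by_region: dict[tuple[str, int], list[PlantedBlock]] = {}
    for b in spec.planted_blocks:
        blocks_by_region.setdefault((b.gene_id, b.ordinal), []).append(b)

    sets: list[OrthologSet] = []
    truth_rows = []
    for gene in spec.gene_ids:
        for ordinal in range(1, spec.introns_per_gene + 1):
            anc = _BASES[rng.integers(0, 4, size=spec.intron_length)].copy()
            protected = np.zeros(spec.intron_length, dtype=bool)
            for b in sorted(blocks_by_region.get((gene, ordinal), []), key=lambda b: b.offset):
                protected[b.offset : b.offset + b.length] = True
                elem = _element_sequence(b, spec.motif_consensus)
                elem_off = -1
                if elem is not None:
                    if len(elem) > b.length:
                        raise ValueError(f"element longer than its block: {b}")
                    elem_off = b.offset + int(rng.integers(0, b.length - len(elem) + 1))
                    anc[elem_off : elem_off + len(elem)] = np.frombuffer(
                        elem.encode("ascii"), dtype=np.uint8
                    )
                truth_rows.append(
                    {
                        "gene": gene,
                        "ordinal": ordinal,
                        "offset": b.offset,
                        "length": b.length,
                        "element": b.element,
                        "element_offset": elem_off,
                        "element_seq": elem or "",
                    }
                )
            sequences = {}
            for sp in spec.species:
                seq = anc.copy()
                if spec.substitution_prob > 0:
                    mutate = (rng.random(spec.intron_length) < spec.substitution_prob) & ~protected
                    if mutate.any():
                        # substitute with a uniformly chosen *different* base
                        shifts = rng.integers(1, 4, size=int(mutate.sum()))
                        cur = np.searchsorted(_BASES, seq[mutate])
                        seq[mutate] = _BASES[(cur + shifts) % 4]
                if spec.indel_prob > 0:
                    seq = _apply_indels(seq, protected, spec.indel_prob, rng)
                sequences[sp] = seq.tobytes().decode("ascii")
            sets.append(OrthologSet(gene, spec.region_kind, ordinal, sequences))
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene", "ordinal", "offset", "length", "element", "element_offset", "element_seq"],
    )
    return sets, truth


def _apply_indels(
    seq: np.ndarray, protected: np.ndarray, indel_prob: float, rng: np.random.Generator
) -> np.ndarray:
    out = []
    for i, base in enumerate(seq):
        if not protected[i] and rng.random() < indel_prob:
            if rng.random() < 0.5:
                continue  # deletion
            out.append(base)
            out.append(_BASES[rng.integers(0, 4)])  # insertion after i
        else:
            out.append(base)
    return np.array(out, dtype=np.uint8)


def write_simulation(
    sets: list[OrthologSet],
    truth: pd.DataFrame,
    motifs: list[MotifModel],
    lib_truth: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write regions, library and truth tables in the formats the pipeline reads."""
    out_dir = Path(out_dir)
    regions_dir = out_dir / "regions"
    regions_dir.mkdir(parents=True, exist_ok=True)
    for oset in sets:
        write_ortholog_fasta(
            oset, regions_dir / f"{oset.gene_id}_{oset.region_kind}{oset.ordinal}.fasta"
        )
    lib_dir = out_dir / "library"
    info_path = lib_dir / "TF_Information.txt"
    pwm_dir = lib_dir / "pwms"
    lib_dir.mkdir(parents=True, exist_ok=True)
    write_cisbp_library(motifs, info_path, pwm_dir)
    truth_path = out_dir / "truth_blocks.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    lib_truth_path = out_dir / "truth_library.tsv"
    lib_truth.to_csv(lib_truth_path, sep="\t", index=False)
    return {
        "regions_dir": regions_dir,
        "library_info": info_path,
        "pwm_dir": pwm_dir,
        "truth_blocks": truth_path,
        "truth_library": lib_truth_path,
    }
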