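"""End-to-end driver: regions in, annotated pattern tables and stats out.

Runs the whole analysis on a directory of per-region FASTA files (named
``<gene>_<intron|exon><N>.fasta``, pre-aligned or equal-length) against a
motif library: conserved-pattern extraction, matched control sampling,
TFBS and splice-site scans of both sets, four-way classification, the
per-ordinal frequency summary, normalized pattern densities, family
tallies, nuclear-receptor cluster reports and the nonparametric
comparisons.  All results are written as TSV plus a JSON run manifest.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import (
    build_summary,
    classify_patterns,
    nr_cluster_report,
    tally_families,
)
from .config import RunConfig
from .consensus import build_pssm
from .io_formats import (
    MsaBlock,
    parse_region_filename,
    read_cisbp_library,
    read_msa_fasta,
    write_pattern_table,
    write_splice_table,
    write_tfbs_table,
)
from .patterns import (
    extract_conserved_patterns,
    extract_nonconserved_controls,
    group_by_ordinal,
    normalize_counts,
)
from .splice import (
    default_acceptor_matrix,
    default_donor_matrix,
    load_maxent_model,
    load_splice_matrix,
    scan_all_splice,
)
from .stats import (
    chisq_class_distribution,
    conservation_fractions,
    mannwhitney_conservation,
    paired_region_counts,
    wilcoxon_paired_counts,
)
from .tfbs import scan_all

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    patterns: list = field(default_factory=list)
    controls: list = field(default_factory=list)
    tfbs_hits: list = field(default_factory=list)
    splice_hits: list = field(default_factory=list)
    control_tfbs_hits: list = field(default_factory=list)
    control_splice_hits: list = field(default_factory=list)
    classes: dict = field(default_factory=dict)
    summary: pd.DataFrame | None = None
    outputs: dict[str, Path] = field(default_factory=dict)


def load_alignments(input_dir: str | Path) -> list[MsaBlock]:
    input_dir = Path(input_dir)
    files = sorted(input_dir.glob("*.fasta")) + sorted(input_dir.glob("*.fa"))
    if not files:
        raise FileNotFoundError(f"no FASTA files in {input_dir}")
    blocks = []
    for path in files:
        gene, kind, ordinal = parse_region_filename(path)
        blocks.append(read_msa_fasta(path, gene_id=gene, region_kind=kind, ordinal=ordinal))
    return blocks


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res = PipelineResult()

    blocks = load_alignments(cfg.input_dir)
    library = read_cisbp_library(cfg.library_info, cfg.pwm_dir)
    donor = (
        load_splice_matrix(cfg.donor_matrix, "donor") if cfg.donor_matrix else default_donor_matrix()
    )
    acceptor = (
        load_splice_matrix(cfg.acceptor_matrix, "acceptor")
        if cfg.acceptor_matrix
        else default_acceptor_matrix()
    )
    model = load_maxent_model(cfg.maxent_dir) if cfg.maxent_dir else None

    region_lengths: dict[tuple[str, int], int] = {}
    for i, msa in enumerate(blocks):
        pssm = build_pssm(msa)
        pats = extract_conserved_patterns(pssm, msa, min_len=cfg.min_pattern_len)
        res.patterns.extend(pats)
        n_ctrl = cfg.n_controls if cfg.n_controls is not None else len(pats)
        res.controls.extend(
            extract_nonconserved_controls(
                pssm, msa, n=n_ctrl, min_len=cfg.min_pattern_len, seed=cfg.seed + i
            )
        )
        region_lengths[(msa.gene_id, msa.ordinal)] = msa.length

    scan_kwargs = dict(
        threshold=cfg.logodds_threshold,
        min_width=cfg.min_motif_width,
        strands=cfg.strands,
        pseudocount=cfg.pseudocount,
    )
    res.tfbs_hits = scan_all(res.patterns, library, **scan_kwargs)
    res.control_tfbs_hits = scan_all(res.controls, library, **scan_kwargs)
    ss_kwargs = dict(
        donor=donor,
        acceptor=acceptor,
        model=model,
        cv_threshold=cfg.cv_threshold,
        maxent_threshold=cfg.maxent_threshold,
        ss_rule=cfg.ss_rule,
    )
    res.splice_hits = scan_all_splice(res.patterns, **ss_kwargs)
    res.control_splice_hits = scan_all_splice(res.controls, **ss_kwargs)

    res.classes = classify_patterns(res.patterns, res.tfbs_hits, res.splice_hits)
    groups = group_by_ordinal(res.patterns)
    res.summary = build_summary(groups, res.classes)

    genes_per_ordinal: dict[int, int] = {}
    length_per_ordinal: dict[int, float] = {}
    for (gene, ordinal), length in region_lengths.items():
        genes_per_ordinal[ordinal] = genes_per_ordinal.get(ordinal, 0) + 1
        length_per_ordinal[ordinal] = length_per_ordinal.get(ordinal, 0) + length
    normalized = normalize_counts(groups, genes_per_ordinal, length_per_ordinal)

    # ---- outputs
    res.outputs["patterns"] = write_pattern_table(
        res.patterns,
        out_dir / "patterns.tsv",
        tfbs_hits=res.tfbs_hits,
        splice_hits=res.splice_hits,
        classes=res.classes,
    )
    ctrl_classes = {c.pattern_id: "control" for c in res.controls}
    res.outputs["controls"] = write_pattern_table(
        res.controls,
        out_dir / "controls.tsv",
        tfbs_hits=res.control_tfbs_hits,
        splice_hits=res.control_splice_hits,
        classes=ctrl_classes,
    )
    res.outputs["tfbs_hits"] = write_tfbs_table(res.tfbs_hits, out_dir / "tfbs_hits.tsv")
    res.outputs["splice_hits"] = write_splice_table(res.splice_hits, out_dir / "splice_hits.tsv")
    res.outputs["control_tfbs_hits"] = write_tfbs_table(
        res.control_tfbs_hits, out_dir / "control_tfbs_hits.tsv"
    )
    res.outputs["control_splice_hits"] = write_splice_table(
        res.control_splice_hits, out_dir / "control_splice_hits.tsv"
    )
    summary_path = out_dir / "summary.tsv"
    res.summary.to_csv(summary_path, sep="\t", index=False)
    res.outputs["summary"] = summary_path
    norm_path = out_dir / "normalized_counts.tsv"
    normalized.to_csv(norm_path, sep="\t", index=False, float_format="%.4f")
    res.outputs["normalized_counts"] = norm_path

    fam_path = out_dir / "family_tally.tsv"
    tally_families(res.tfbs_hits).to_frame().to_csv(fam_path, sep="\t", index=False)
    res.outputs["family_tally"] = fam_path
    ctrl_fam_path = out_dir / "control_family_tally.tsv"
    tally_families(res.control_tfbs_hits).to_frame().to_csv(ctrl_fam_path, sep="\t", index=False)
    res.outputs["control_family_tally"] = ctrl_fam_path
    nr_path = out_dir / "nr_clusters.tsv"
    nr_cluster_report(res.tfbs_hits).to_csv(nr_path, sep="\t", index=False)
    res.outputs["nr_clusters"] = nr_path

    res.outputs["stats"] = _write_stats(res, region_lengths, groups, out_dir / "stats.tsv")
    res.outputs["manifest"] = _write_manifest(cfg, out_dir / "manifest.json")
    return res


def _write_stats(res: PipelineResult, region_lengths, groups, path: Path) -> Path:
    rows = []
    # conservation shift between intron groups
    fractions = conservation_fractions(res.patterns, region_lengths)
    fractions = {k: v for k, v in fractions.items() if len(v) >= 1}
    if len(fractions) >= 2:
        mwu = mannwhitney_conservation(fractions)
        for (a, b), r in sorted(mwu.items()):
            if a < b:
                rows.append(
                    {
                        "test": "mannwhitneyu_conservation",
                        "comparison": f"intron{a}_vs_intron{b}",
                        "statistic": r.statistic,
                        "p_value": r.p_value,
                        "stars": r.stars,
                    }
                )
    # class distribution per ordinal against pooled proportions
    from collections import Counter

    observed = {
        ordinal: Counter(res.classes[p.pattern_id] for p in pats)
        for ordinal, pats in groups.items()
    }
    observed = {k: v for k, v in observed.items() if sum(v.values()) > 0}
    if observed:
        try:
            chis = chisq_class_distribution(observed)
            for ordinal, r in sorted(chis.items()):
                rows.append(
                    {
                        "test": "chisq_class_distribution",
                        "comparison": f"intron{ordinal}_vs_pooled",
                        "statistic": r.statistic,
                        "p_value": r.p_value,
                        "stars": r.stars,
                    }
                )
        except ValueError as exc:
            log.warning("chi-square skipped: %s", exc)
    # paired conserved-vs-control element counts per region
    regions = sorted(region_lengths)
    for name, cons_hits, ctrl_hits in (
        ("wilcoxon_tfbs_counts", res.tfbs_hits, res.control_tfbs_hits),
        ("wilcoxon_ss_counts", res.splice_hits, res.control_splice_hits),
    ):
        a, b = paired_region_counts(cons_hits, ctrl_hits, regions)
        try:
            r = wilcoxon_paired_counts(a, b)
            rows.append(
                {
                    "test": name,
                    "comparison": "conserved_vs_control",
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "stars": r.stars,
                }
            )
        except ValueError as exc:
            log.warning("%s skipped: %s", name, exc)
    df = pd.DataFrame(rows, columns=["test", "comparison", "statistic", "p_value", "stars"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def _write_manifest(cfg: RunConfig, path: Path) -> Path:
    manifest = {
        "package": "consreg",
        "version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
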