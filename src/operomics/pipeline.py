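"""End-to-end annotation pipeline.

Stages run in a fixed order: candidate selection → evidence filtering →
physicochemical profiling → topology → confidence scoring → categorization
→ neighborhood detection → summary. Every stage logs its input/output
cardinalities to stderr; results go to files only. Float columns are
printed with fixed 4-decimal formatting and rows are sorted on stable
keys, so re-running on identical inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from . import categorize as cat
from . import evidence as ev
from . import io as oio
from . import neighborhood as nb
from . import physchem as pc
from . import topology as topo

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    Defaults are the pipeline's standard operating point: e-value cutoff
    1e-5 (inclusive) with DUF removal, per-component retention minimum 3,
    instability threshold 40, TM window 19 / threshold 1.6 / min length
    15, neighborhood max gap 200 bp / min size 2 / same strand.
    """

    fasta: Path
    evidence: Path
    literature: Path
    outdir: Path
    layout: Optional[Path] = None
    synonyms: Optional[Path] = None
    keywords: Sequence[str] = oio.DEFAULT_HP_KEYWORDS
    e_cutoff: float = ev.DEFAULT_E_CUTOFF
    drop_duf: bool = True
    tm_window: int = 19
    tm_threshold: float = 1.6
    tm_min_len: int = 15
    max_gap: int = 200
    min_size: int = 2
    require_same_strand: bool = True
    seed: Optional[int] = None  # passthrough for provenance in the summary


def _fmt(v: float) -> str:
    return f"{v:.4f}"


def _write_tsv(path: Path, header: List[str], rows: List[List[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Run every stage and write the six output files; returns the summary dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    synonyms = oio.load_synonyms(config.synonyms) if config.synonyms else None

    records = oio.read_fasta(config.fasta)
    selected = oio.select_hypothetical(records, config.keywords)
    log.info("select: %d records in, %d candidates out", len(records), len(selected))
    tags = [r.locus_tag for r in selected]

    raw_evidence = oio.read_evidence_table(config.evidence)
    filtered = ev.filter_evidence(raw_evidence, config.e_cutoff, config.drop_duf)
    log.info("filter: %d evidence rows in, %d kept", len(raw_evidence), len(filtered))
    literature = oio.read_literature_table(config.literature)
    log.info("literature: %d rows", len(literature))

    signal_by_tag: Dict[str, bool] = {}
    for rec in raw_evidence:
        if rec.signal_peptide:
            signal_by_tag[rec.locus_tag] = True

    prop_rows, topo_rows = [], []
    topologies = []
    for r in selected:
        p = pc.profile(r.sequence)
        prop_rows.append(
            [
                r.locus_tag,
                _fmt(p.molecular_weight),
                _fmt(p.theoretical_pi),
                _fmt(p.instability_index),
                _fmt(p.aliphatic_index),
                _fmt(p.gravy),
                p.stability_class,
            ]
        )
        t = topo.profile_topology(
            r.sequence,
            signal_peptide=signal_by_tag.get(r.locus_tag, False),
            window=config.tm_window,
            threshold=config.tm_threshold,
            min_len=config.tm_min_len,
        )
        topologies.append(t)
        topo_rows.append(
            [
                r.locus_tag,
                str(t.tm_count),
                ";".join(f"{s}-{e}" for s, e in t.tm_segments),
                t.localization_class,
            ]
        )
    log.info("physchem+topology: %d profiles", len(selected))

    scored = ev.score_all(filtered, literature, tags, synonyms)
    n_retained = sum(s.confidence.retained for s in scored)
    log.info("score: %d proteins, %d retained", len(scored), n_retained)
    score_rows = [
        [
            s.locus_tag,
            s.winning_label,
            str(s.confidence.prediction_component),
            str(s.confidence.literature_component),
            str(s.confidence.combined),
            "retained" if s.confidence.retained else "rejected",
        ]
        for s in scored
    ]

    subsystem_map = cat.default_subsystem_map()
    assignments = [
        cat.assign_category(
            s.locus_tag, s.winning_label, s.confidence, subsystem_map=subsystem_map
        )
        for s in scored
        if s.confidence.retained
    ]
    log.info("categorize: %d assignments", len(assignments))
    assign_rows = [
        [
            a.locus_tag,
            a.assigned_function,
            a.category,
            a.subsystem or "",
            str(a.confidence.combined),
        ]
        for a in assignments
    ]

    cluster_rows = []
    n_clusters = 0
    if config.layout is not None:
        loci = oio.read_gene_layout(config.layout)
        clusters = nb.detect_clusters(
            loci,
            max_gap=config.max_gap,
            min_size=config.min_size,
            require_same_strand=config.require_same_strand,
        )
        n_clusters = len(clusters)
        log.info("neighborhood: %d loci, %d clusters", len(loci), n_clusters)
        for i, c in enumerate(clusters, start=1):
            cluster_rows.append(
                [
                    str(i),
                    c.cluster_label,
                    ",".join(m.locus_tag for m in c.members),
                    f"{c.span[0]}-{c.span[1]}",
                ]
            )

    report = cat.summarize(assignments, topologies)
    summary = {
        "n_input_records": len(records),
        "n_candidates": len(selected),
        "n_evidence_rows": len(raw_evidence),
        "n_evidence_kept": len(filtered),
        "n_retained": n_retained,
        "n_rejected": len(scored) - n_retained,
        "annotation_rate_percent": cat.annotation_rate(n_retained, len(selected))
        if selected
        else 0.0,
        "n_clusters": n_clusters,
        "category_axis": [list(x) for x in report.category_axis],
        "subsystem_axis": [list(x) for x in report.subsystem_axis],
        "topology_axis": [list(x) for x in report.topology_axis],
        "seed": config.seed,
    }

    _write_tsv(
        outdir / "properties.tsv",
        ["locus_tag", "molecular_weight", "theoretical_pi", "instability_index",
         "aliphatic_index", "gravy", "stability_class"],
        prop_rows,
    )
    _write_tsv(
        outdir / "topology.tsv",
        ["locus_tag", "tm_count", "segments", "localization_class"],
        topo_rows,
    )
    _write_tsv(
        outdir / "scores.tsv",
        ["locus_tag", "winning_label", "pred_component", "lit_component",
         "combined", "status"],
        score_rows,
    )
    _write_tsv(
        outdir / "assignments.tsv",
        ["locus_tag", "assigned_function", "category", "subsystem", "combined"],
        assign_rows,
    )
    _write_tsv(
        outdir / "clusters.tsv",
        ["cluster_id", "label", "members", "span"],
        cluster_rows,
    )
    with open(outdir / "summary.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
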