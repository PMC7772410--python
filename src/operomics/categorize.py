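"""Functional categorization and summary reporting.

Retained proteins are binned into six coarse categories by an ordered rule
list (an EC number is the strongest signal and always wins, then keyword
rules for regulators, transporters, binding proteins, and cell-division
proteins, with ``other`` as fallback). Metabolic enzymes additionally get
a subsystem code from a controlled 16-code vocabulary (amino-acid
biosynthesis, aminoacyl-tRNA charging, carbohydrate biosynthesis, ...);
the default label→subsystem map is seeded from the bundled metabolic
annotation table's section headings and is user-extensible via TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

from .errors import ValidationError
from .evidence import ConfidenceScore, normalize_label
from .topology import TopologyProfile

CATEGORIES = (
    "metabolic_enzyme",
    "transcriptional_regulator",
    "transporter",
    "binding_protein",
    "cell_division",
    "other",
)

#: controlled subsystem vocabulary (figure-legend codes)
SUBSYSTEM_CODES = {
    "AAB": "Amino acid biosynthesis",
    "AAT": "Aminoacyl-tRNA charging metabolic clusters",
    "ACD": "Aromatic compounds degradation",
    "C1UA": "C1 Compounds utilization and assimilation",
    "CHB": "Carbohydrates biosynthesis",
    "CSB": "Cell structures biosynthesis",
    "CPEB": "Cofactors, prosthetic groups, electron carriers biosynthesis",
    "FALB": "Fatty acid and lipid biosynthesis",
    "GPME": "Generation of precursor metabolites and energy",
    "INM": "Inorganic nutrients metabolism",
    "NNB": "Nucleosides and nucleotides biosynthesis",
    "PMR": "Protein-modification reactions",
    "RR": "RNA-reactions",
    "SMD": "Secondary metabolites degradation",
    "tRR": "tRNA reactions",
    "OTR": "Other reactions",
}

#: section headings of the bundled metabolic table → subsystem codes;
#: headings without a dedicated code fall into OTR
SECTION_TO_SUBSYSTEM = {
    "Amino acids biosynthesis": "AAB",
    "Aminoacyl-tRNA charging metabolic clusters": "AAT",
    "Carbohydrates and Cell structures biosynthesis": "CHB",
    "Cell structures biosynthesis": "CSB",
    "Cofactors, Prosthetic groups, Electron carriers biosynthesis": "CPEB",
    "Fatty acid and lipid biosynthesis": "FALB",
    "Metabolic regulators biosynthesis": "OTR",
    "Nucleosides and nucleotides biosynthesis": "NNB",
    "Alcohols degradation": "OTR",
    "Amino acids degradation": "OTR",
    "Aromatic compounds degradation": "ACD",
    "C1 Compounds utilization and assimilation": "C1UA",
    "Inorganic nutrients metabolism": "INM",
    "Secondary metabolites degradation": "SMD",
    "Macromolecule modification": "OTR",
    "Small molecule reactions": "OTR",
    "Protein-modification reactions": "PMR",
    "Generation of precursor metabolites and energy": "GPME",
}

_REGULATOR_KEYWORDS = ("regulator", "repressor", "transcription factor", "transcriptional")
_TRANSPORTER_KEYWORDS = ("transporter", "permease", "antiporter", "translocase", "transport")
_BINDING_KEYWORDS = ("binding",)
_CELL_DIVISION_KEYWORDS = ("cell division", "cell cycle", "septum", "chromosome")


@dataclass(frozen=True)
class FunctionAssignment:
    """A retained protein's final functional call."""

    locus_tag: str
    assigned_function: str
    category: str
    confidence: ConfidenceScore
    gene_symbol: Optional[str] = None
    ec_number: Optional[str] = None
    subsystem: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category!r}")
        if self.subsystem is not None and self.category != "metabolic_enzyme":
            raise ValidationError("subsystem only applies to metabolic enzymes")
        if not self.confidence.retained:
            raise ValidationError(
                f"{self.locus_tag}: assignments exist only for retained proteins"
            )


def default_subsystem_map() -> Dict[str, str]:
    """Canonical label → subsystem code, seeded from the bundled metabolic table."""
    from .io import load_paper_tables

    out: Dict[str, str] = {}
    for row in load_paper_tables(("table3",)):
        code = SECTION_TO_SUBSYSTEM.get(row.section_label, "OTR")
        out.setdefault(normalize_label(row.assigned_function), code)
    return out


def _contains_any(label: str, keywords: Sequence[str]) -> bool:
    folded = label.casefold()
    return any(k in folded for k in keywords)


def assign_category(
    locus_tag: str,
    winning_label: str,
    confidence: ConfidenceScore,
    ec_number: Optional[str] = None,
    gene_symbol: Optional[str] = None,
    subsystem_map: Optional[Mapping[str, str]] = None,
) -> FunctionAssignment:
    """Categorize one retained protein by the ordered rule list.

    EC number present → metabolic enzyme (with subsystem looked up from
    the label map, OTR when unmapped); otherwise the first matching
    keyword family wins; ``other`` is the fallback.
    """
    if ec_number:
        category = "metabolic_enzyme"
        lookup = subsystem_map if subsystem_map is not None else default_subsystem_map()
        subsystem = lookup.get(normalize_label(winning_label), "OTR")
    elif _contains_any(winning_label, _REGULATOR_KEYWORDS):
        category, subsystem = "transcriptional_regulator", None
    elif _contains_any(winning_label, _TRANSPORTER_KEYWORDS):
        category, subsystem = "transporter", None
    elif _contains_any(winning_label, _BINDING_KEYWORDS):
        category, subsystem = "binding_protein", None
    elif _contains_any(winning_label, _CELL_DIVISION_KEYWORDS):
        category, subsystem = "cell_division", None
    else:
        category, subsystem = "other", None
    return FunctionAssignment(
        locus_tag=locus_tag,
        assigned_function=winning_label,
        category=category,
        confidence=confidence,
        gene_symbol=gene_symbol,
        ec_number=ec_number,
        subsystem=subsystem,
    )


@dataclass(frozen=True)
class SummaryReport:
    """Counts and percentages per axis, each axis summing to its total."""

    category_axis: Tuple[Tuple[str, int, float], ...]
    subsystem_axis: Tuple[Tuple[str, int, float], ...]
    fold_axis: Tuple[Tuple[str, int, float], ...]
    topology_axis: Tuple[Tuple[str, int, float], ...]
    n_assignments: int
    n_topologies: int


def _axis(counts: Dict[str, int]) -> Tuple[Tuple[str, int, float], ...]:
    total = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return tuple(
        (label, n, round(100.0 * n / total, 1) if total else 0.0) for label, n in ordered
    )


def summarize(
    assignments: Sequence[FunctionAssignment],
    topologies: Sequence[TopologyProfile] = (),
    folds: Sequence[str] = (),
) -> SummaryReport:
    """Tally assignments per category/subsystem (plus optional fold and topology axes)."""
    cat: Dict[str, int] = {}
    sub: Dict[str, int] = {}
    for a in assignments:
        cat[a.category] = cat.get(a.category, 0) + 1
        if a.subsystem:
            sub[a.subsystem] = sub.get(a.subsystem, 0) + 1
    fold_counts: Dict[str, int] = {}
    for f in folds:
        fold_counts[f] = fold_counts.get(f, 0) + 1
    topo: Dict[str, int] = {}
    for t in topologies:
        topo[t.localization_class] = topo.get(t.localization_class, 0) + 1
    return SummaryReport(
        category_axis=_axis(cat),
        subsystem_axis=_axis(sub),
        fold_axis=_axis(fold_counts),
        topology_axis=_axis(topo),
        n_assignments=len(assignments),
        n_topologies=len(topologies),
    )


def annotation_rate(n_assigned: int, n_candidates: int) -> float:
    """Percentage of candidate proteins that received a retained function call."""
    if n_candidates <= 0:
        raise ValidationError("n_candidates must be positive")
    if not 0 <= n_assigned <= n_candidates:
        raise ValidationError("n_assigned must be between 0 and n_candidates")
    return round(100.0 * n_assigned / n_candidates, 1)
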