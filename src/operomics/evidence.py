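"""Evidence integration and the 12-level confidence scheme.

Six prediction channels (motif, domain, structure, evolutionary trace,
physicochemical, localization) each contribute at most one vote per
protein toward a candidate function label. The prediction component of
the confidence score is the number of distinct channels supporting the
winning label (0–6); the literature component is the best taxonomic
provenance level of a matching literature record on a fixed 6-level scale
(6 = same organism, 5 = phylogenetic neighbors, 4 = methanogens,
3 = archaea, 2 = bacteria, 1 = eukaryotes). A predicted function is
retained only when *both* components reach 3; the combined score is their
sum, at most 12.

Also provided: the evidence filter (e-value cutoff 1e-5, inclusive, plus
removal of DUF "domain of unknown function" hits), the noisy-OR
probability combination used by phylogenomic function prediction
(``1 - prod(1 - s_i)``), and the structural-model composite scores
(QMEAN5 linear combination and the QMEAN-weighted GDT_TS average) used to
rank homology-model candidates.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .errors import ValidationError

#: the six controlled evidence channels
CHANNELS = ("motif", "domain", "structure", "evolutionary", "physchem", "localization")

#: channels that may win on their own; the two supporting channels
#: (physchem, localization) never outvote these alone
CORE_CHANNELS = frozenset({"motif", "domain", "structure", "evolutionary"})

#: taxonomic provenance scale for literature evidence
PROVENANCE_LEVELS: Mapping[str, int] = {
    "same_organism": 6,
    "phylogenetic_neighbors": 5,
    "methanogens": 4,
    "archaea": 3,
    "bacteria": 2,
    "eukaryotes": 1,
}

#: minimum per-component score for a function to be retained
RETENTION_MINIMUM = 3

#: default e-value cutoff for evidence filtering
DEFAULT_E_CUTOFF = 1e-5

_DUF_RE = re.compile(r"\bDUF\d+\b", re.IGNORECASE)
_TOKEN_RE = re.compile(r"[^0-9a-z]+")

#: QMEAN5 component coefficients as used throughout this package
#: (torsion, pairwise, solvation, SSE agreement, ACC agreement)
QMEAN5_COEFFICIENTS = (0.3, 0.17, 0.7, 80.0, 45.0)


@dataclass(frozen=True)
class EvidenceRecord:
    """One prediction hit from one channel."""

    locus_tag: str
    channel: str
    function_label: str
    identifier: str
    evalue: float
    source: str = ""
    signal_peptide: Optional[bool] = None
    fold: Optional[str] = None

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValidationError(
                f"unknown channel {self.channel!r}; expected one of {CHANNELS}"
            )
        if not (self.evalue >= 0):
            raise ValidationError(f"evalue must be nonnegative, got {self.evalue!r}")


@dataclass(frozen=True)
class LiteratureEvidence:
    """A function label with a taxonomic-provenance level from the literature."""

    locus_tag: str
    function_label: str
    provenance_level: int
    reference: str = ""

    def __post_init__(self) -> None:
        if self.provenance_level not in range(1, 7):
            raise ValidationError(
                f"provenance_level must be in 1..6, got {self.provenance_level}"
            )


@dataclass(frozen=True)
class ConfidenceScore:
    """Per-protein confidence: prediction and literature components, 0–6 each."""

    prediction_component: int
    literature_component: int

    def __post_init__(self) -> None:
        for name in ("prediction_component", "literature_component"):
            v = getattr(self, name)
            if not isinstance(v, int) or not 0 <= v <= 6:
                raise ValidationError(f"{name} must be an integer in 0..6, got {v!r}")

    @property
    def combined(self) -> int:
        return self.prediction_component + self.literature_component

    @property
    def retained(self) -> bool:
        return (
            self.prediction_component >= RETENTION_MINIMUM
            and self.literature_component >= RETENTION_MINIMUM
        )


@dataclass(frozen=True)
class ModelScore:
    """Component scores of one structural model plus composites."""

    score_torsion: float
    score_pairwise: float
    score_solvation: float
    score_sse: float
    score_acc: float


def filter_evidence(
    records: Iterable[EvidenceRecord],
    e_cutoff: float = DEFAULT_E_CUTOFF,
    drop_duf: bool = True,
) -> List[EvidenceRecord]:
    """Keep hits with evalue <= cutoff; drop DUF hits; preserve order.

    The cutoff is inclusive: a hit exactly at the cutoff survives. DUF
    matching is ``\\bDUF\\d+\\b``, case-insensitive, on either the function
    label or the identifier.
    """
    if not e_cutoff > 0:
        raise ValidationError("e_cutoff must be positive")
    kept = []
    for rec in records:
        if rec.evalue > e_cutoff:
            continue
        if drop_duf and (
            _DUF_RE.search(rec.function_label) or _DUF_RE.search(rec.identifier)
        ):
            continue
        kept.append(rec)
    return kept


def normalize_label(label: str, synonyms: Optional[Mapping[str, str]] = None) -> str:
    """Canonicalize a free-text function label.

    Casefold, strip punctuation, sort tokens, then apply the synonym map
    (whose keys and values are themselves normalized before lookup).
    Labels empty after normalization become the sentinel ``"unassigned"``.
    """
    tokens = sorted(t for t in _TOKEN_RE.split(label.casefold()) if t)
    canonical = " ".join(tokens)
    if not canonical:
        return "unassigned"
    if synonyms:
        norm_map = {
            " ".join(sorted(t for t in _TOKEN_RE.split(k.casefold()) if t)): v
            for k, v in synonyms.items()
        }
        if canonical in norm_map:
            return normalize_label(norm_map[canonical])
    return canonical


def prediction_agreement_score(
    evidence: Sequence[EvidenceRecord],
    synonyms: Optional[Mapping[str, str]] = None,
) -> Tuple[str, int]:
    """Winning canonical label and its distinct-channel support count (0–6).

    Multiple hits in one channel count once. Ties are broken by lowest
    best e-value, then lexicographically. Labels supported only by the
    physchem/localization channels are eligible to win only when no label
    has support from a core channel (motif/domain/structure/evolutionary).
    """
    if not evidence:
        return "unassigned", 0
    channels: Dict[str, set] = {}
    best_e: Dict[str, float] = {}
    for rec in evidence:
        canon = normalize_label(rec.function_label, synonyms)
        channels.setdefault(canon, set()).add(rec.channel)
        best_e[canon] = min(best_e.get(canon, math.inf), rec.evalue)
    candidates = list(channels)
    if any(channels[c] & CORE_CHANNELS for c in candidates):
        candidates = [c for c in candidates if channels[c] & CORE_CHANNELS]
    winner = min(candidates, key=lambda c: (-len(channels[c]), best_e[c], c))
    return winner, len(channels[winner])


def literature_score(
    evidence: Sequence[LiteratureEvidence],
    winning_label: str,
    synonyms: Optional[Mapping[str, str]] = None,
) -> int:
    """Maximum provenance level among records matching the winning label; else 0."""
    levels = [
        rec.provenance_level
        for rec in evidence
        if normalize_label(rec.function_label, synonyms) == winning_label
    ]
    return max(levels, default=0)


def combined_confidence(pred: int, lit: int) -> ConfidenceScore:
    """Combine the two components; retained iff both reach the minimum of 3."""
    return ConfidenceScore(prediction_component=pred, literature_component=lit)


def sifter_combine(scores: Sequence[float]) -> float:
    """Noisy-OR combination of per-source probabilities: 1 - prod(1 - s)."""
    out = 1.0
    for s in scores:
        if not 0.0 <= s <= 1.0:
            raise ValidationError(f"probability outside [0, 1]: {s!r}")
        out *= 1.0 - s
    return 1.0 - out


def qmean5(
    components: ModelScore,
    coefficients: Tuple[float, float, float, float, float] = QMEAN5_COEFFICIENTS,
) -> float:
    """Linear composite of the five model-quality component scores.

    The default coefficients are the ones this pipeline standardizes on;
    pass a different 5-tuple to substitute another weighting.
    """
    values = (
        components.score_torsion,
        components.score_pairwise,
        components.score_solvation,
        components.score_sse,
        components.score_acc,
    )
    if any(v is None or not math.isfinite(v) for v in values):
        raise ValidationError("all five component scores must be finite")
    return sum(c * v for c, v in zip(coefficients, values))


def weighted_model_average(
    gdt_ts: Sequence[float], qmean: Sequence[float]
) -> float:
    """QMEAN-weighted mean of per-model GDT_TS scores."""
    if not gdt_ts or len(gdt_ts) != len(qmean):
        raise ValidationError("gdt_ts and qmean must be equal-length nonempty lists")
    total = sum(qmean)
    if total == 0:
        raise ValidationError("degenerate input: QMEAN weights sum to zero")
    return sum(g * q for g, q in zip(gdt_ts, qmean)) / total


@dataclass(frozen=True)
class ScoredProtein:
    """Final scoring result for one protein."""

    locus_tag: str
    winning_label: str
    confidence: ConfidenceScore


def score_protein(
    locus_tag: str,
    evidence: Sequence[EvidenceRecord],
    literature: Sequence[LiteratureEvidence],
    synonyms: Optional[Mapping[str, str]] = None,
) -> ScoredProtein:
    """Score one protein from its (already filtered) evidence and literature."""
    label, pred = prediction_agreement_score(evidence, synonyms)
    lit = literature_score(literature, label, synonyms)
    return ScoredProtein(locus_tag, label, combined_confidence(pred, lit))


def score_all(
    evidence: Iterable[EvidenceRecord],
    literature: Iterable[LiteratureEvidence],
    locus_tags: Sequence[str],
    synonyms: Optional[Mapping[str, str]] = None,
) -> List[ScoredProtein]:
    """Score every protein in ``locus_tags`` (proteins without evidence score 0)."""
    ev_by_tag: Dict[str, List[EvidenceRecord]] = {}
    for rec in evidence:
        ev_by_tag.setdefault(rec.locus_tag, []).append(rec)
    lit_by_tag: Dict[str, List[LiteratureEvidence]] = {}
    for rec in literature:
        lit_by_tag.setdefault(rec.locus_tag, []).append(rec)
    return [
        score_protein(tag, ev_by_tag.get(tag, []), lit_by_tag.get(tag, []), synonyms)
        for tag in locus_tags
    ]
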