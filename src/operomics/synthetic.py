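"""Synthetic study inputs with planted ground truth.

Generates a proteome of hypothetical proteins, six-channel prediction
evidence with a controllable per-channel agreement probability, literature
records over the 6-level taxonomic provenance scale, and genome layouts
with planted operon-like clusters — everything the pipeline consumes,
with the truth recorded so recovery can be checked exactly.

Defaults emulate the study conditions: 756 hypothetical proteins, six
prediction channels, and six planted gene clusters totalling 32 genes.
Decoy labels live in a per-(protein, channel) namespace by default so the
planted label's support count is unambiguous; e-values are drawn inside
the filtering cutoff and DUF identifiers are attached only to decoy
records, so filtering never erodes planted support and retention truth
stays exact. All draws go through independent numpy generator streams
spawned from the single mandatory seed, so each ``gen_*`` call is
deterministic regardless of call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import GenerationError, ValidationError
from .evidence import CHANNELS, EvidenceRecord, LiteratureEvidence
from .io import DEFAULT_HP_KEYWORDS, ProteinRecord
from .neighborhood import GeneLocus

_AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: stream indices for the per-operation child generators
_STREAMS = {"proteome": 0, "evidence": 1, "literature": 2, "layout": 3}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic-data generator (seed is mandatory).

    ``literature_level_probs`` is a categorical over levels 0..6 where 0
    means "no literature record". ``cluster_spec`` is a list of
    (size, intra-cluster gap bp) pairs for planted operon-like clusters.
    """

    seed: int
    n_proteins: int = 756
    length_range: Tuple[int, int] = (60, 600)
    composition: Optional[Sequence[float]] = None  # 20 probs, alphabetical; None=uniform
    hp_keyword_fraction: float = 1.0
    channel_agreement: float = 0.5
    literature_level_probs: Tuple[float, ...] = (1 / 7,) * 7
    evalue_bounds: Tuple[float, float] = (1e-30, 1e-6)
    fraction_duf: float = 0.1
    colliding_decoys: bool = False
    evalue_signal: bool = False
    cluster_spec: Tuple[Tuple[int, int], ...] = ((5, 50), (4, 50), (5, 50), (4, 50), (6, 50), (8, 50))
    intercluster_gap: int = 2000
    filler_genes: bool = True

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        if not 0.0 <= self.channel_agreement <= 1.0:
            raise ValidationError("channel_agreement must be a probability")
        if not 0.0 <= self.hp_keyword_fraction <= 1.0:
            raise ValidationError("hp_keyword_fraction must be a probability")
        if not 0.0 <= self.fraction_duf <= 1.0:
            raise ValidationError("fraction_duf must be a probability")
        if len(self.literature_level_probs) != 7 or not math.isclose(
            sum(self.literature_level_probs), 1.0, abs_tol=1e-9
        ):
            raise ValidationError("literature_level_probs must be 7 values summing to 1")
        if self.composition is not None and (
            len(self.composition) != 20
            or not math.isclose(sum(self.composition), 1.0, abs_tol=1e-9)
        ):
            raise ValidationError("composition must be 20 probabilities summing to 1")
        lo, hi = self.evalue_bounds
        if not (0 < lo <= hi):
            raise ValidationError("evalue_bounds must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth for one synthetic protein."""

    locus_tag: str
    planted_label: str
    supporting_channels: Tuple[str, ...]

    @property
    def channel_count(self) -> int:
        return len(self.supporting_channels)


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


def _tag(i: int) -> str:
    return f"mru_{i + 1:04d}"


def planted_label_for(tag: str) -> str:
    """The deterministic planted function label of a synthetic protein."""
    return f"planted function {tag}"


_NON_HP_DESCRIPTIONS = (
    "methyl-coenzyme M reductase subunit",
    "formate dehydrogenase alpha chain",
    "ribosomal protein L2",
)


def gen_proteome(config: GeneratorConfig) -> List[ProteinRecord]:
    """Residue-i.i.d. protein sequences with HP-keyword descriptions.

    A ``hp_keyword_fraction`` of the descriptions contain one of the four
    candidate-selection keywords (cycled deterministically); the rest get
    named-function descriptions so selection has something to reject.
    """
    rng = _rng(config, "proteome")
    lo, hi = config.length_range
    probs = None if config.composition is None else np.asarray(config.composition)
    records = []
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(_AMINO_ACIDS, size=length, p=probs))
        if rng.random() < config.hp_keyword_fraction:
            keyword = DEFAULT_HP_KEYWORDS[i % len(DEFAULT_HP_KEYWORDS)]
            desc = f"conserved {keyword}" if "protein" in keyword else f"{keyword} protein"
        else:
            desc = _NON_HP_DESCRIPTIONS[i % len(_NON_HP_DESCRIPTIONS)]
        records.append(ProteinRecord(_tag(i), desc, seq))
    return records


_DECOY_POOL = tuple(f"decoy pool label {k}" for k in range(5))


def gen_evidence(
    proteome: Sequence[ProteinRecord], config: GeneratorConfig
) -> Tuple[List[EvidenceRecord], Dict[str, PlantedTruth]]:
    """Six-channel evidence with a planted true label per protein.

    Each channel independently reports the planted label with probability
    ``channel_agreement``; otherwise it reports a decoy (unique per
    protein and channel, or drawn from a small shared pool in
    ``colliding_decoys`` mode for stress tests). E-values are log-uniform
    within ``evalue_bounds``; in ``evalue_signal`` mode true-label records
    get the lower half of the range so e-value tie-breaks favour truth.
    """
    rng = _rng(config, "evidence")
    log_lo, log_hi = (math.log10(b) for b in config.evalue_bounds)
    log_mid = 0.5 * (log_lo + log_hi)
    records: List[EvidenceRecord] = []
    truth: Dict[str, PlantedTruth] = {}
    for rec in proteome:
        planted = planted_label_for(rec.locus_tag)
        supporting = []
        for channel in CHANNELS:
            is_true = bool(rng.random() < config.channel_agreement)
            if is_true:
                label = planted
                supporting.append(channel)
            elif config.colliding_decoys:
                label = _DECOY_POOL[int(rng.integers(len(_DECOY_POOL)))]
            else:
                label = f"decoy {rec.locus_tag} {channel}"
            if config.evalue_signal:
                lo, hi = (log_lo, log_mid) if is_true else (log_mid, log_hi)
            else:
                lo, hi = log_lo, log_hi
            evalue = float(10.0 ** rng.uniform(lo, hi))
            if not is_true and rng.random() < config.fraction_duf:
                identifier = f"DUF{int(rng.integers(1000, 10000))}"
            else:
                identifier = f"SYN{int(rng.integers(10000, 100000))}"
            records.append(
                EvidenceRecord(
                    locus_tag=rec.locus_tag,
                    channel=channel,
                    function_label=label,
                    identifier=identifier,
                    evalue=evalue,
                    source="synthetic",
                )
            )
        truth[rec.locus_tag] = PlantedTruth(rec.locus_tag, planted, tuple(supporting))
    return records, truth


def gen_literature(
    proteome: Sequence[ProteinRecord], config: GeneratorConfig
) -> List[LiteratureEvidence]:
    """One literature record per protein for its planted label, at a sampled
    provenance level (level 0 = no record emitted)."""
    rng = _rng(config, "literature")
    levels = rng.choice(7, size=len(proteome), p=config.literature_level_probs)
    out = []
    for rec, level in zip(proteome, levels):
        if level > 0:
            out.append(
                LiteratureEvidence(
                    locus_tag=rec.locus_tag,
                    function_label=planted_label_for(rec.locus_tag),
                    provenance_level=int(level),
                    reference="synthetic",
                )
            )
    return out


def literature_levels(
    literature: Sequence[LiteratureEvidence],
) -> Dict[str, int]:
    """Best provenance level per locus tag (helper for recovery checks)."""
    out: Dict[str, int] = {}
    for rec in literature:
        out[rec.locus_tag] = max(out.get(rec.locus_tag, 0), rec.provenance_level)
    return out


def gen_genome_layout(config: GeneratorConfig) -> List[GeneLocus]:
    """Plant the configured operon-like clusters on a linear genome.

    Clusters are laid out left to right with intra-cluster gaps as
    specified and inter-cluster separations of ``intercluster_gap`` bp
    (which must exceed any detection gap in use); optional single
    known-function filler genes sit midway between clusters.
    """
    rng = _rng(config, "layout")
    loci: List[GeneLocus] = []
    pos = 1000
    for ci, (size, gap) in enumerate(config.cluster_spec):
        if size < 1 or gap < 0:
            raise GenerationError(f"bad cluster spec ({size}, {gap})")
        strand = "+" if ci % 2 == 0 else "-"
        last_end = pos - 1
        for gi in range(size):
            length = int(rng.integers(600, 1201))
            loci.append(
                GeneLocus(
                    f"syn_c{ci:02d}_{gi:02d}", pos, pos + length - 1,
                    strand, is_hp=True, label=f"planted cluster {ci}",
                )
            )
            last_end = pos + length - 1
            pos = last_end + 1 + gap
        if config.filler_genes and ci + 1 < len(config.cluster_spec):
            # known-function gene roughly midway between consecutive clusters
            filler_len = int(rng.integers(300, 900))
            margin = (config.intercluster_gap - filler_len) // 2
            filler_start = last_end + 1 + margin
            loci.append(
                GeneLocus(
                    f"syn_f{ci:02d}", filler_start, filler_start + filler_len - 1,
                    "+", is_hp=False, label="known function gene",
                )
            )
        pos = last_end + 1 + config.intercluster_gap
    ordered = sorted(loci, key=lambda g: g.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise GenerationError(
                f"planted spans overlap: {a.locus_tag} and {b.locus_tag}"
            )
    return ordered


def gen_bundle(config: GeneratorConfig):
    """Generate every input at once: (proteome, evidence, truth, literature, layout)."""
    proteome = gen_proteome(config)
    evidence, truth = gen_evidence(proteome, config)
    literature = gen_literature(proteome, config)
    layout = gen_genome_layout(config)
    return proteome, evidence, truth, literature, layout
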