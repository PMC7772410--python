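"""Operon-like gene-neighborhood detection.

Prokaryotic genes that are co-transcribed tend to sit adjacent on the same
strand with short intergenic gaps. A single linear scan over start-sorted
loci groups hypothetical-protein genes into runs; a run breaks when the
intergenic gap exceeds ``max_gap``, the strand flips (when required), or a
gene of known function intervenes. Runs of at least ``min_size`` genes are
reported as operon-like clusters labelled by their dominant member label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

from .errors import ValidationError


@dataclass(frozen=True)
class GeneLocus:
    """One gene on the genome, 1-based inclusive coordinates."""

    locus_tag: str
    start: int
    end: int
    strand: str
    is_hp: bool = True
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"{self.locus_tag}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.locus_tag}: strand must be '+' or '-'")


@dataclass(frozen=True)
class GeneCluster:
    """A detected operon-like run of adjacent HP genes."""

    members: tuple
    cluster_label: str

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def span(self) -> tuple:
        return (self.members[0].start, self.members[-1].end)


def label_cluster(members: Sequence[GeneLocus]) -> str:
    """Most frequent member label; ties go to the earliest gene; all-None → "unlabeled"."""
    if not members:
        raise ValidationError("cannot label an empty cluster")
    counts: dict = {}
    first_pos: dict = {}
    for locus in members:
        if locus.label is None or locus.label == "":
            continue
        counts[locus.label] = counts.get(locus.label, 0) + 1
        first_pos.setdefault(locus.label, locus.start)
    if not counts:
        return "unlabeled"
    return min(counts, key=lambda lb: (-counts[lb], first_pos[lb]))


def detect_clusters(
    loci: Sequence[GeneLocus],
    max_gap: int = 200,
    min_size: int = 2,
    require_same_strand: bool = True,
    break_on_non_hp: bool = True,
) -> List[GeneCluster]:
    """Group HP genes into operon-like clusters by a linear scan.

    ``max_gap`` is the largest allowed intergenic gap in bp (``next.start -
    prev.end - 1``); clusters smaller than ``min_size`` are discarded.
    Genes of known function (``is_hp=False``) never join a cluster and, by
    default, break a run they interrupt.
    """
    if max_gap < 0:
        raise ValidationError("max_gap must be nonnegative")
    if min_size < 2:
        raise ValidationError("min_size must be at least 2")
    ordered = sorted(loci, key=lambda g: (g.start, g.end, g.locus_tag))
    clusters: List[GeneCluster] = []
    run: List[GeneLocus] = []
    interrupted = False

    def flush() -> None:
        nonlocal run
        if len(run) >= min_size:
            clusters.append(GeneCluster(tuple(run), label_cluster(run)))
        run = []

    for locus in ordered:
        if not locus.is_hp:
            if break_on_non_hp:
                interrupted = True
            continue
        if run:
            prev = run[-1]
            gap = locus.start - prev.end - 1
            if (
                interrupted
                or gap > max_gap
                or (require_same_strand and locus.strand != prev.strand)
            ):
                flush()
        run.append(locus)
        interrupted = False
    flush()
    return clusters
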