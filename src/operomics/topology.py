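"""Hydropathy-window transmembrane calling and coarse localization.

A sliding Kyte–Doolittle window (classic TM heuristics: window 19,
threshold 1.6, minimum segment length 15) marks candidate membrane-spanning
stretches. Signal peptides are never predicted here — they arrive as
ingested evidence — and localization is a three-way rule:
membrane if any TM segment, secreted if signal peptide and no TM,
otherwise cytoplasmic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Tuple

from .errors import ValidationError
from .physchem import PhyschemConfig, default_config

log = logging.getLogger(__name__)

LOCALIZATION_CLASSES = ("cytoplasmic", "membrane", "secreted", "unknown")


@dataclass(frozen=True)
class TopologyProfile:
    """Transmembrane topology summary for one protein.

    ``tm_segments`` are 1-based inclusive residue intervals, sorted and
    non-overlapping; ``signal_peptide`` is ingested evidence, not a
    prediction.
    """

    tm_segments: Tuple[Tuple[int, int], ...]
    signal_peptide: bool = False
    localization_class: str = "unknown"

    @property
    def tm_count(self) -> int:
        return len(self.tm_segments)

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.tm_segments:
            if start <= prev_end:
                raise ValidationError("TM segments must be sorted and non-overlapping")
            if end < start:
                raise ValidationError("TM segment end before start")
            prev_end = end


def predict_tm_segments(
    sequence: str,
    window: int = 19,
    threshold: float = 1.6,
    min_len: int = 15,
    config: PhyschemConfig | None = None,
) -> List[Tuple[int, int]]:
    """Call transmembrane segments from sliding-window mean hydropathy.

    The window mean is evaluated at every position where the window fits;
    maximal runs of centers above ``threshold`` are extended to the window
    bounds, overlapping extensions merged, and segments shorter than
    ``min_len`` dropped. Returns 1-based inclusive intervals.
    """
    if window < 5 or window % 2 == 0:
        raise ValidationError("window must be an odd integer >= 5")
    config = config or default_config()
    seq = sequence.upper()
    n = len(seq)
    if n < window:
        log.warning("sequence length %d shorter than window %d; no TM call", n, window)
        return []
    scale = config.hydropathy_scale
    values = [scale[r] for r in seq]
    half = (window - 1) // 2
    # exactly-rounded window sums so threshold ties are decided reproducibly
    above = [
        math.fsum(values[center - half : center + half + 1]) / window > threshold
        for center in range(half, n - half)
    ]
    # maximal runs of above-threshold centers, extended to window bounds
    segments: List[Tuple[int, int]] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            start = (i + half) - half  # 0-based residue start of first window
            end = (j + half) + half  # 0-based residue end of last window
            if segments and start <= segments[-1][1] + 1:
                segments[-1] = (segments[-1][0], end)
            else:
                segments.append((start, end))
            i = j + 1
        else:
            i += 1
    return [(s + 1, e + 1) for s, e in segments if e - s + 1 >= min_len]


def classify_localization(profile: TopologyProfile) -> str:
    """membrane if any TM segment; secreted if signal-only; else cytoplasmic."""
    if profile.tm_count >= 1:
        return "membrane"
    if profile.signal_peptide:
        return "secreted"
    return "cytoplasmic"


def profile_topology(
    sequence: str,
    signal_peptide: bool = False,
    window: int = 19,
    threshold: float = 1.6,
    min_len: int = 15,
    config: PhyschemConfig | None = None,
) -> TopologyProfile:
    """Convenience: call segments then classify in one step."""
    segments = tuple(predict_tm_segments(sequence, window, threshold, min_len, config))
    prof = TopologyProfile(tm_segments=segments, signal_peptide=signal_peptide)
    return TopologyProfile(
        tm_segments=segments,
        signal_peptide=signal_peptide,
        localization_class=classify_localization(prof),
    )
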