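"""Sequence-derived physicochemical properties of proteins.

Implements the classical ProtParam-style descriptor set for a protein
sequence over the 20 standard residues:

* **instability index** (II) — the dipeptide-weight statistic
  ``II = (10/L) * sum_{i=1}^{L-1} DIWV(x[i] x[i+1])`` over the published
  400-entry dipeptide instability weight table; a protein with II below a
  threshold (40 by convention) is predicted stable *in vitro*, at or above
  it unstable.
* **aliphatic index** — the relative volume occupied by aliphatic side
  chains, ``X(Ala) + a*X(Val) + b*(X(Ile)+X(Leu))`` with X in mole percent
  and Ikai's volume coefficients a=2.9, b=3.9.
* **GRAVY** — grand average of hydropathicity: the mean Kyte–Doolittle
  hydropathy over all residues.
* **molecular weight** — sum of average residue masses plus one water.
* **theoretical pI** — the pH at which the Henderson–Hasselbalch net
  charge over the termini and ionizable side chains (EMBOSS pKa set by
  default) vanishes, located by bisection.

The dipeptide weights are the published Guruprasad table (loaded from
Biopython's copy); the hydropathy scale, pKa set, and residue masses ship
as TSV data files and are swappable through :class:`PhyschemConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Mapping, Tuple

from .errors import ResidueError, UndefinedPropertyError, ValidationError

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: mass of one water molecule (average isotopic composition), daltons
WATER_MASS = 18.01524


def _read_table(name: str) -> Dict[str, float]:
    text = resources.files("operomics.data").joinpath(name).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    out: Dict[str, float] = {}
    for ln in lines[1:]:  # skip header
        key, value = ln.split("\t")[:2]
        out[key] = float(value)
    return out


def _load_diwv() -> Dict[str, float]:
    # published 20x20 dipeptide instability weight table, via Biopython's copy
    from Bio.SeqUtils.ProtParamData import DIWV

    flat = {a + b: float(w) for a, row in DIWV.items() for b, w in row.items()}
    if len(flat) != 400:
        raise ValidationError(f"dipeptide weight table has {len(flat)} entries, expected 400")
    return flat


def _load_pka() -> Dict[str, Tuple[float, int]]:
    text = resources.files("operomics.data").joinpath("pka_emboss.tsv").read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    out: Dict[str, Tuple[float, int]] = {}
    for ln in lines[1:]:
        group, pka, charge = ln.split("\t")
        out[group] = (float(pka), +1 if charge == "positive" else -1)
    return out


@dataclass(frozen=True)
class PhyschemConfig:
    """Constants behind the physicochemical formulas.

    Attributes
    ----------
    diwv_table : 400-entry dipeptide → instability weight map.
    hydropathy_scale : residue → hydropathy value (Kyte–Doolittle default).
    aliphatic_a, aliphatic_b : side-chain volume coefficients for Val and
        Ile+Leu relative to Ala (defaults 2.9 and 3.9).
    residue_masses : residue → average mass in daltons.
    pka_set : ionizable group → (pKa, sign); groups are the one-letter
        residue codes plus "Nterm"/"Cterm".
    stability_threshold : II boundary; values strictly below are stable.
    permissive : when True, residues outside the 20 standard codes are
        silently excluded from property sums instead of raising.
    """

    diwv_table: Mapping[str, float] = field(default_factory=_load_diwv)
    hydropathy_scale: Mapping[str, float] = field(
        default_factory=lambda: _read_table("hydropathy_kd.tsv")
    )
    aliphatic_a: float = 2.9
    aliphatic_b: float = 3.9
    residue_masses: Mapping[str, float] = field(
        default_factory=lambda: _read_table("residue_masses.tsv")
    )
    pka_set: Mapping[str, Tuple[float, int]] = field(default_factory=_load_pka)
    stability_threshold: float = 40.0
    permissive: bool = False

    def __post_init__(self) -> None:
        if self.aliphatic_a <= 0 or self.aliphatic_b <= 0:
            raise ValidationError("aliphatic coefficients must be positive")
        missing = {a + b for a in STANDARD_RESIDUES for b in STANDARD_RESIDUES} - set(
            self.diwv_table
        )
        if missing:
            raise ValidationError(f"dipeptide table missing {len(missing)} entries")


_DEFAULT: PhyschemConfig | None = None


def default_config() -> PhyschemConfig:
    """Shared default configuration (built lazily, tables loaded once)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = PhyschemConfig()
    return _DEFAULT


@dataclass(frozen=True)
class PhyschemProfile:
    """Per-protein physicochemical descriptor vector."""

    molecular_weight: float
    theoretical_pi: float
    instability_index: float
    aliphatic_index: float
    gravy: float
    stability_class: str  # "stable" | "unstable"


def _clean(sequence: str, config: PhyschemConfig) -> str:
    seq = sequence.upper()
    bad = set(seq) - STANDARD_RESIDUES
    if not bad:
        return seq
    if config.permissive:
        return "".join(r for r in seq if r in STANDARD_RESIDUES)
    raise ResidueError(f"nonstandard residue(s) {sorted(bad)} in sequence")


def instability_index(sequence: str, config: PhyschemConfig | None = None) -> float:
    """Guruprasad instability index: (10/L) times the sum of dipeptide weights."""
    config = config or default_config()
    seq = _clean(sequence, config)
    length = len(seq)
    if length < 2:
        raise UndefinedPropertyError("instability index undefined for length < 2")
    total = sum(config.diwv_table[seq[i : i + 2]] for i in range(length - 1))
    return (10.0 / length) * total


def classify_stability(ii: float, config: PhyschemConfig | None = None) -> str:
    """``stable`` iff II < threshold; the exact boundary classifies unstable."""
    config = config or default_config()
    if not math.isfinite(ii):
        raise ValidationError("instability index must be finite")
    return "stable" if ii < config.stability_threshold else "unstable"


def aliphatic_index(sequence: str, config: PhyschemConfig | None = None) -> float:
    """X(Ala) + a*X(Val) + b*(X(Ile)+X(Leu)), X in mole percent of the full length."""
    config = config or default_config()
    seq = _clean(sequence, config)
    if not seq:
        raise UndefinedPropertyError("aliphatic index undefined for empty sequence")
    length = len(seq)
    mole_pct = lambda r: 100.0 * seq.count(r) / length
    return (
        mole_pct("A")
        + config.aliphatic_a * mole_pct("V")
        + config.aliphatic_b * (mole_pct("I") + mole_pct("L"))
    )


def gravy(sequence: str, config: PhyschemConfig | None = None) -> float:
    """Grand average of hydropathicity: mean per-residue hydropathy."""
    config = config or default_config()
    seq = _clean(sequence, config)
    if not seq:
        raise UndefinedPropertyError("GRAVY undefined for empty sequence")
    scale = config.hydropathy_scale
    return sum(scale[r] for r in seq) / len(seq)


def molecular_weight(sequence: str, config: PhyschemConfig | None = None) -> float:
    """Average molecular mass: sum of residue masses plus one water, daltons."""
    config = config or default_config()
    seq = _clean(sequence, config)
    if not seq:
        raise UndefinedPropertyError("molecular weight undefined for empty sequence")
    return sum(config.residue_masses[r] for r in seq) + WATER_MASS


def net_charge(sequence: str, ph: float, config: PhyschemConfig | None = None) -> float:
    """Henderson–Hasselbalch net charge of the sequence at the given pH.

    Positive groups contribute ``n / (1 + 10**(pH - pKa))``, negative groups
    ``-n / (1 + 10**(pKa - pH))``; the two termini always contribute.
    """
    config = config or default_config()
    seq = _clean(sequence, config)
    if not seq:
        raise UndefinedPropertyError("net charge undefined for empty sequence")
    counts = {"Nterm": 1, "Cterm": 1}
    for group in config.pka_set:
        if len(group) == 1:
            counts[group] = seq.count(group)
    charge = 0.0
    for group, n in counts.items():
        if n == 0:
            continue
        pka, sign = config.pka_set[group]
        if sign > 0:
            charge += n / (1.0 + 10.0 ** (ph - pka))
        else:
            charge -= n / (1.0 + 10.0 ** (pka - ph))
    return charge


def theoretical_pi(
    sequence: str, config: PhyschemConfig | None = None, tol: float = 1e-4
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    Net charge is strictly decreasing in pH, so the root is unique.
    """
    config = config or default_config()
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, config) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def profile(sequence: str, config: PhyschemConfig | None = None) -> PhyschemProfile:
    """Compute the full descriptor vector for one sequence."""
    config = config or default_config()
    ii = instability_index(sequence, config)
    return PhyschemProfile(
        molecular_weight=molecular_weight(sequence, config),
        theoretical_pi=theoretical_pi(sequence, config),
        instability_index=ii,
        aliphatic_index=aliphatic_index(sequence, config),
        gravy=gravy(sequence, config),
        stability_class=classify_stability(ii, config),
    )
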