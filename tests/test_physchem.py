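"""Physicochemical formulas against closed forms and independent oracles."""

import math
import random

import pytest
from hypothesis import given, strategies as st

from operomics.errors import ResidueError, UndefinedPropertyError
from operomics.physchem import (
    STANDARD_RESIDUES,
    WATER_MASS,
    PhyschemConfig,
    aliphatic_index,
    classify_stability,
    gravy,
    instability_index,
    molecular_weight,
    net_charge,
    theoretical_pi,
)

AA = sorted(STANDARD_RESIDUES)
seq_strategy = st.text(alphabet=AA, min_size=2, max_size=80)


# -- independent brute-force oracles (plain loops, no shared code path) -------

def oracle_instability(seq, diwv):
    weights = 0.0
    for i in range(len(seq) - 1):
        weights += diwv[seq[i] + seq[i + 1]]
    return 10.0 * weights / len(seq)


def oracle_gravy(seq, scale):
    return sum(scale[c] for c in seq) / len(seq)


def oracle_aliphatic(seq):
    n = len(seq)
    return 100.0 * (
        seq.count("A") + 2.9 * seq.count("V") + 3.9 * (seq.count("I") + seq.count("L"))
    ) / n


def oracle_mw(seq, masses):
    return sum(masses[c] for c in seq) + WATER_MASS


def oracle_pi_grid(seq, config, step=0.001):
    """Dense pH-grid scan for the zero crossing of the net charge."""
    ph = 0.0
    while ph < 14.0:
        if net_charge(seq, ph, config) <= 0:
            return ph
        ph += step
    return 14.0


class TestInstabilityIndex:
    def test_homopolymer_closed_form(self, physchem_config):
        diwv = physchem_config.diwv_table
        for residue, length in [("A", 5), ("W", 17), ("L", 2)]:
            seq = residue * length
            expected = 10.0 * (length - 1) / length * diwv[residue * 2]
            assert instability_index(seq) == pytest.approx(expected)

    def test_length_two_is_five_times_weight(self, physchem_config):
        assert instability_index("MK") == pytest.approx(
            5.0 * physchem_config.diwv_table["MK"]
        )

    def test_reference_peptide_matches_dipeptide_sum_oracle(self, physchem_config):
        seq = "MKWVTFISLLLLFSSAYS"
        assert instability_index(seq) == pytest.approx(
            oracle_instability(seq, physchem_config.diwv_table)
        )

    def test_undefined_below_length_two(self):
        with pytest.raises(UndefinedPropertyError):
            instability_index("M")

    def test_not_permutation_invariant_in_general(self):
        # order matters for a dipeptide statistic
        assert instability_index("ACDEFGHIKL") != pytest.approx(
            instability_index("LKIHGFEDCA")
        )


class TestStabilityClassification:
    @pytest.mark.parametrize(
        "ii,expected",
        [(39.99, "stable"), (40.01, "unstable"), (40.0, "unstable"), (0.0, "stable")],
    )
    def test_threshold_semantics(self, ii, expected):
        assert classify_stability(ii) == expected


class TestAliphaticIndex:
    def test_poly_ala_is_100(self):
        assert aliphatic_index("AAAA") == pytest.approx(100.0)

    def test_poly_gly_is_0(self):
        assert aliphatic_index("GGGG") == pytest.approx(0.0)

    def test_poly_val_uses_coefficient_a(self):
        assert aliphatic_index("VVVVV") == pytest.approx(290.0)

    def test_poly_ile_and_leu_use_coefficient_b(self):
        assert aliphatic_index("IL") == pytest.approx(390.0)

    @given(seq_strategy)
    def test_permutation_invariant(self, seq):
        shuffled = "".join(sorted(seq))
        assert aliphatic_index(seq) == pytest.approx(aliphatic_index(shuffled))


class TestGravy:
    def test_homopolymer_equals_scale_value(self, physchem_config):
        for r in "AIWD":
            assert gravy(r * 7) == pytest.approx(physchem_config.hydropathy_scale[r])

    @given(seq_strategy, seq_strategy)
    def test_mean_decomposition_over_concatenation(self, s1, s2):
        combined = gravy(s1 + s2)
        expected = (len(s1) * gravy(s1) + len(s2) * gravy(s2)) / (len(s1) + len(s2))
        assert combined == pytest.approx(expected)

    def test_bounded_by_scale_extremes(self, physchem_config, random_sequences):
        lo = min(physchem_config.hydropathy_scale.values())
        hi = max(physchem_config.hydropathy_scale.values())
        for seq in random_sequences[:30]:
            assert lo <= gravy(seq) <= hi


class TestMolecularWeight:
    def test_single_glycine_is_free_glycine(self, physchem_config):
        expected = physchem_config.residue_masses["G"] + WATER_MASS
        assert molecular_weight("G") == pytest.approx(expected)
        assert molecular_weight("G") == pytest.approx(75.067, abs=0.01)

    def test_dipeptide_bookkeeping(self, physchem_config):
        masses = physchem_config.residue_masses
        assert molecular_weight("GA") == pytest.approx(
            masses["G"] + masses["A"] + WATER_MASS
        )

    def test_empty_sequence_errors(self):
        with pytest.raises(UndefinedPropertyError):
            molecular_weight("")


class TestTheoreticalPi:
    def test_net_charge_at_pi_is_negligible(self):
        for seq in ["MKWVTFISLLLLFSSAYS", "KKKDDDEEHH", "ACDEFGHIKLMNPQRSTVWY"]:
            assert abs(net_charge(seq, theoretical_pi(seq))) < 1e-3

    def test_basic_above_acidic(self):
        assert theoretical_pi("KKKKKK") > theoretical_pi("DDDDDD")

    def test_net_charge_strictly_decreasing_in_ph(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        grid = [net_charge(seq, 0.5 * k) for k in range(29)]
        assert all(a > b for a, b in zip(grid, grid[1:]))

    def test_bisection_agrees_with_grid_scan(self, physchem_config, random_sequences):
        for seq in random_sequences[:20]:
            assert theoretical_pi(seq) == pytest.approx(
                oracle_pi_grid(seq, physchem_config), abs=0.01
            )


class TestOracleAgreementSuite:
    """All properties vs independent brute-force oracles on 100 random sequences."""

    def test_all_properties_match_oracles(self, physchem_config, random_sequences):
        cfg = physchem_config
        for seq in random_sequences:
            assert instability_index(seq) == pytest.approx(
                oracle_instability(seq, cfg.diwv_table)
            )
            assert gravy(seq) == pytest.approx(oracle_gravy(seq, cfg.hydropathy_scale))
            assert aliphatic_index(seq) == pytest.approx(oracle_aliphatic(seq))
            assert molecular_weight(seq) == pytest.approx(
                oracle_mw(seq, cfg.residue_masses)
            )

    def test_instability_and_gravy_match_reference_implementation(
        self, random_sequences
    ):
        """Cross-check against an established third-party implementation."""
        from Bio.SeqUtils.ProtParam import ProteinAnalysis

        for seq in random_sequences[:40]:
            pa = ProteinAnalysis(seq)
            assert instability_index(seq) == pytest.approx(
                pa.instability_index(), abs=0.01
            )
            assert gravy(seq) == pytest.approx(pa.gravy(), abs=1e-9)
            assert molecular_weight(seq) == pytest.approx(
                pa.molecular_weight(), rel=1e-4
            )


class TestResidueHandling:
    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ResidueError):
            gravy("MKXV")

    def test_permissive_mode_excludes_from_sums(self, physchem_config):
        permissive = PhyschemConfig(
            diwv_table=physchem_config.diwv_table,
            hydropathy_scale=physchem_config.hydropathy_scale,
            residue_masses=physchem_config.residue_masses,
            pka_set=physchem_config.pka_set,
            permissive=True,
        )
        assert gravy("MKXV", permissive) == pytest.approx(gravy("MKV"))
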