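"""The 12-level confidence scheme, filtering, and combination formulas."""

import itertools
import math

import pytest
from hypothesis import given, strategies as st

from operomics.errors import ValidationError
from operomics.evidence import (
    CHANNELS,
    DEFAULT_E_CUTOFF,
    PROVENANCE_LEVELS,
    ConfidenceScore,
    EvidenceRecord,
    LiteratureEvidence,
    ModelScore,
    combined_confidence,
    filter_evidence,
    literature_score,
    normalize_label,
    prediction_agreement_score,
    qmean5,
    score_protein,
    sifter_combine,
    weighted_model_average,
)


def ev(channel, label, evalue=1e-10, tag="mru_0001", identifier="ID1"):
    return EvidenceRecord(tag, channel, label, identifier, evalue)


class TestFilterEvidence:
    def test_cutoff_inclusive(self):
        records = [ev("motif", "x", e) for e in (1e-6, 1e-4, 1e-5)]
        kept = filter_evidence(records)
        assert [r.evalue for r in kept] == [1e-6, 1e-5]

    def test_duf_removed_by_label_or_identifier(self):
        records = [
            ev("domain", "DUF1234 family protein"),
            ev("domain", "kinase", identifier="DUF99"),
            ev("domain", "kinase", identifier="PF00001"),
        ]
        kept = filter_evidence(records)
        assert [r.identifier for r in kept] == ["PF00001"]
        assert len(filter_evidence(records, drop_duf=False)) == 3

    def test_order_preserved(self):
        records = [ev("motif", f"label {i}", 1e-10) for i in range(5)]
        assert filter_evidence(records) == records


class TestNormalizeLabel:
    def test_casefold_and_punctuation(self):
        assert normalize_label("AAA+ ATPase") == normalize_label("aaa ATPase")

    def test_token_order_insensitive(self):
        assert normalize_label("cell division inhibitor") == normalize_label(
            "inhibitor, cell division"
        )

    def test_synonym_map_applied(self):
        syns = {"Methionine—tRNA ligase": "Methionyl-tRNA synthetase"}
        assert normalize_label("methionine—trna ligase", syns) == normalize_label(
            "Methionyl-tRNA synthetase"
        )

    def test_empty_becomes_unassigned(self):
        assert normalize_label("+++") == "unassigned"


class TestPredictionAgreement:
    def test_all_six_channels_score_six(self):
        records = [ev(c, "AAA+ ATPase") for c in CHANNELS]
        label, score = prediction_agreement_score(records)
        assert score == 6 and label == normalize_label("AAA+ ATPase")

    def test_no_evidence_scores_zero(self):
        assert prediction_agreement_score([]) == ("unassigned", 0)

    def test_distinct_channel_counting(self):
        records = [ev(c, "label A") for c in ("motif", "domain", "structure")] + [
            ev("evolutionary", "label B")
        ]
        label, score = prediction_agreement_score(records)
        assert label == normalize_label("label A") and score == 3

    def test_multiple_hits_in_one_channel_count_once(self):
        records = [ev("motif", "label A", 1e-20), ev("motif", "label A", 1e-8)]
        assert prediction_agreement_score(records)[1] == 1

    def test_tie_broken_by_lowest_evalue_then_label(self):
        records = [ev("motif", "bbb", 1e-20), ev("domain", "aaa", 1e-10)]
        assert prediction_agreement_score(records)[0] == "bbb"
        records = [ev("motif", "bbb", 1e-10), ev("domain", "aaa", 1e-10)]
        assert prediction_agreement_score(records)[0] == "aaa"

    def test_support_channels_never_outvote_core(self):
        records = [
            ev("physchem", "membrane transport candidate"),
            ev("localization", "membrane transport candidate"),
            ev("motif", "kinase"),
        ]
        label, score = prediction_agreement_score(records)
        assert label == normalize_label("kinase") and score == 1

    def test_support_channels_can_win_without_core_competition(self):
        records = [
            ev("physchem", "membrane transport candidate"),
            ev("localization", "membrane transport candidate"),
        ]
        assert prediction_agreement_score(records)[1] == 2


class TestLiteratureScore:
    def test_same_organism_is_six(self):
        assert PROVENANCE_LEVELS["same_organism"] == 6
        lit = [LiteratureEvidence("t", "kinase", 6)]
        assert literature_score(lit, normalize_label("kinase")) == 6

    def test_maximum_rule(self):
        lit = [
            LiteratureEvidence("t", "kinase", 2),
            LiteratureEvidence("t", "kinase", 4),
        ]
        assert literature_score(lit, normalize_label("kinase")) == 4

    def test_no_match_is_zero(self):
        lit = [LiteratureEvidence("t", "other function", 6)]
        assert literature_score(lit, normalize_label("kinase")) == 0


class TestCombinedConfidence:
    @pytest.mark.parametrize(
        "pred,lit,combined,retained",
        [(6, 6, 12, True), (2, 6, 8, False), (3, 3, 6, True), (6, 2, 8, False),
         (0, 0, 0, False)],
    )
    def test_examples(self, pred, lit, combined, retained):
        score = combined_confidence(pred, lit)
        assert score.combined == combined and score.retained is retained

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            combined_confidence(7, 0)
        with pytest.raises(ValidationError):
            combined_confidence(3, -1)

    def test_monotone_in_both_components(self):
        for p, l in itertools.product(range(6), range(6)):
            base = combined_confidence(p, l)
            up_p = combined_confidence(p + 1, l)
            up_l = combined_confidence(p, l + 1)
            assert up_p.combined >= base.combined and up_l.combined >= base.combined
            if base.retained:
                assert up_p.retained and up_l.retained


def oracle_inclusion_exclusion(scores):
    total = 0.0
    for r in range(1, len(scores) + 1):
        for subset in itertools.combinations(scores, r):
            total += (-1) ** (r + 1) * math.prod(subset)
    return total


class TestSifterCombine:
    @pytest.mark.parametrize(
        "scores,expected",
        [([0.5, 0.5], 0.75), ([1.0, 0.2], 1.0), ([0.3], 0.3), ([], 0.0)],
    )
    def test_closed_forms(self, scores, expected):
        assert sifter_combine(scores) == pytest.approx(expected)

    @given(st.lists(st.floats(0, 1), min_size=0, max_size=4))
    def test_matches_inclusion_exclusion_oracle(self, scores):
        assert sifter_combine(scores) == pytest.approx(
            oracle_inclusion_exclusion(scores), abs=1e-9
        )

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    def test_permutation_invariant_bounded_and_dominates_max(self, scores):
        combined = sifter_combine(scores)
        assert 0.0 <= combined <= 1.0 + 1e-12
        assert combined >= max(scores) - 1e-12
        assert sifter_combine(list(reversed(scores))) == pytest.approx(combined)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            sifter_combine([0.5, 1.2])


class TestModelScores:
    def test_qmean5_coefficients(self):
        zero = ModelScore(0, 0, 0, 0, 0)
        assert qmean5(zero) == 0.0
        assert qmean5(ModelScore(1, 0, 0, 0, 0)) == pytest.approx(0.3)
        assert qmean5(ModelScore(0, 1, 0, 0, 0)) == pytest.approx(0.17)
        assert qmean5(ModelScore(0, 0, 1, 0, 0)) == pytest.approx(0.7)
        assert qmean5(ModelScore(0, 0, 0, 1, 0)) == pytest.approx(80.0)
        assert qmean5(ModelScore(0, 0, 0, 0, 1)) == pytest.approx(45.0)

    def test_qmean5_rejects_nonfinite(self):
        with pytest.raises(ValidationError):
            qmean5(ModelScore(float("nan"), 0, 0, 0, 0))

    def test_qmean5_alternative_coefficients(self):
        assert qmean5(ModelScore(1, 1, 1, 1, 1), (1, 1, 1, 1, 1)) == pytest.approx(5.0)

    def test_weighted_average(self):
        assert weighted_model_average([0.4, 0.8], [1, 3]) == pytest.approx(0.7)
        assert weighted_model_average([0.55], [2.0]) == pytest.approx(0.55)
        assert weighted_model_average([0.2, 0.8], [1, 1]) == pytest.approx(0.5)

    def test_weighted_average_degenerate(self):
        with pytest.raises(ValidationError):
            weighted_model_average([0.5, 0.5], [0, 0])
        with pytest.raises(ValidationError):
            weighted_model_average([], [])


def test_score_protein_end_to_end():
    records = [ev(c, "cell division protein SepF", tag="mru_0647") for c in CHANNELS[:4]]
    lit = [LiteratureEvidence("mru_0647", "SepF, cell division protein", 5)]
    scored = score_protein("mru_0647", records, lit)
    assert scored.confidence.prediction_component == 4
    assert scored.confidence.literature_component == 5
    assert scored.confidence.combined == 9 and scored.confidence.retained
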