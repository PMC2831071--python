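"""Proof checking: justifications, linearity, discharge, theorem extraction."""

import pytest

from zsyntax.derivation import (
    AndE,
    AndI,
    ArrowE,
    ArrowI,
    BAD_COMBINE,
    BAD_DISCHARGE,
    BAD_EXTRACTION,
    BAD_MODUS_PONENS,
    BAD_REF,
    Derivation,
    DerivationLine,
    EVF_NOT_IN_KB,
    EvfRef,
    IA,
    LINEARITY,
    check_derivation,
    dump_derivation,
    extract_theorem,
    loads_derivation,
    render_derivation,
)
from zsyntax.formula import Multiset, Sequent, parse_aggregate, parse_formula
from zsyntax.kb import KnowledgeBase, loads_kb


def _codes(report):
    return {v.code for v in report.violations}


class TestWorkedDerivations:
    def test_glycolysis_detailed_valid(self, glycolysis_kb, glycolysis_derivation):
        report = check_derivation(glycolysis_derivation, glycolysis_kb)
        assert report.valid, report.violations
        assert len(glycolysis_derivation) == 33
        # the premise is discharged, so the theorem needs no initial aggregate
        assert report.theorem.premises.is_empty()
        assert report.theorem.conclusion == parse_formula(
            "(Glc & HK & GPI & PFK & ATP & ATP) -> F1,6P"
        )

    def test_tp53_loop_detailed_valid(self, tp53_loop_kb, tp53_loop_derivation):
        report = check_derivation(tp53_loop_derivation, tp53_loop_kb)
        assert report.valid, report.violations
        assert len(tp53_loop_derivation) == 27

    def test_ffl_detailed_valid(self, ffl_kb, ffl_derivation):
        report = check_derivation(ffl_derivation, ffl_kb)
        assert report.valid, report.violations
        assert len(ffl_derivation) == 35


class TestReflexivity:
    def test_single_premise_line(self):
        d = Derivation([DerivationLine(1, parse_formula("A"), IA())])
        report = check_derivation(d, KnowledgeBase())
        assert report.valid
        assert report.theorem == Sequent(parse_aggregate("A"), parse_formula("A"))

    def test_aggregate_premise_line(self):
        f = parse_formula("A & A & B")
        d = Derivation([DerivationLine(1, f, IA())])
        theorem = extract_theorem(d, KnowledgeBase())
        assert theorem.premises == parse_aggregate("A & A & B")
        assert theorem.conclusion == f


class TestMutations:
    """Single-point corruptions of the glycolysis proof must fail precisely."""

    def test_double_consumption_fails_linearity(self, glycolysis_kb, glycolysis_derivation):
        # make line 27 steal line 5 (the ATP already consumed at line 9)
        lines = list(glycolysis_derivation.lines)
        lines[26] = DerivationLine(27, lines[26].formula, AndI(5, 26))
        report = check_derivation(Derivation(lines), glycolysis_kb)
        assert not report.valid
        assert _codes(report) == {LINEARITY}
        assert report.violations[0].line == 27

    def test_missing_evf_fails(self, glycolysis_kb, glycolysis_derivation):
        for evf_id in [e.id for e in glycolysis_kb]:
            smaller = glycolysis_kb.without(evf_id)
            report = check_derivation(glycolysis_derivation, smaller)
            assert not report.valid
            assert EVF_NOT_IN_KB in _codes(report)

    def test_over_extraction_fails(self, glycolysis_kb, glycolysis_derivation):
        # a third ATP extraction from line 1 exceeds its bag of two
        lines = list(glycolysis_derivation.lines)[:6]
        lines.append(DerivationLine(7, parse_formula("ATP"), AndE(1)))
        report = check_derivation(Derivation(lines), glycolysis_kb)
        assert BAD_EXTRACTION in _codes(report)

    def test_forward_reference_fails(self):
        d = Derivation([DerivationLine(1, parse_formula("A"), AndE(2))])
        report = check_derivation(d, KnowledgeBase())
        assert BAD_REF in _codes(report)

    def test_wrong_modus_ponens_consequent_fails(self):
        kb = loads_kb("r1\tA & B -> A*B")
        d = loads_derivation(
            "1\tA & B\tIA\n"
            "2\tA & B -> A*B\tEVF:r1\n"
            "3\tB*A\tArrowE:2,1\n"
        )
        report = check_derivation(d, kb)
        assert _codes(report) == {BAD_MODUS_PONENS}

    def test_bad_combination_fails(self):
        d = loads_derivation(
            "1\tA\tIA\n2\tB\tIA\n3\tA & A\tAndI:1,2\n"
        )
        assert _codes(check_derivation(d, KnowledgeBase())) == {BAD_COMBINE}

    def test_discharge_must_match_premise(self):
        d = loads_derivation(
            "1\tA\tIA\n2\tB -> A\tArrowI:1,1-1\n"
        )
        assert _codes(check_derivation(d, KnowledgeBase())) == {BAD_DISCHARGE}

    def test_consumed_line_cannot_feed_extraction(self):
        kb = loads_kb("r1\tA & B -> A*B")
        d = loads_derivation(
            "1\tA & B\tIA\n"
            "2\tA & B -> A*B\tEVF:r1\n"
            "3\tA*B\tArrowE:2,1\n"
            "4\tA\tAndE:1\n"
        )
        assert LINEARITY in _codes(check_derivation(d, kb))


class TestTheoremExtraction:
    def test_degradation_theorem(self, tp53_degradation_kb):
        text = (
            "1\tTP53 & MDM2 & U & P\tIA\n"
            "2\tMDM2\tAndE:1\n"
            "3\tTP53\tAndE:1\n"
            "4\tU\tAndE:1\n"
            "5\tP\tAndE:1\n"
            "6\tMDM2 & TP53\tAndI:2,3\n"
            "7\tMDM2 & TP53 -> MDM2*TP53\tEVF:deg1\n"
            "8\tMDM2*TP53\tArrowE:7,6\n"
            "9\t(MDM2*TP53) & U\tAndI:4,8\n"
            "10\t(MDM2*TP53) & U -> (MDM2*TP53)*U\tEVF:deg2\n"
            "11\t(MDM2*TP53)*U\tArrowE:10,9\n"
            "12\t(MDM2*TP53)*U -> MDM2 & (TP53*U)\tEVF:deg3\n"
            "13\tMDM2 & (TP53*U)\tArrowE:12,11\n"
            "14\tTP53*U\tAndE:13\n"
            "15\t(TP53*U) & P\tAndI:5,14\n"
            "16\t(TP53*U) & P -> (TP53*U)*P\tEVF:deg4\n"
            "17\t(TP53*U)*P\tArrowE:16,15\n"
            "18\t(TP53*U)*P -> d(TP53) & U & P\tEVF:deg5\n"
            "19\td(TP53) & U & P\tArrowE:18,17\n"
            "20\td(TP53)\tAndE:19\n"
        )
        theorem = extract_theorem(loads_derivation(text), tp53_degradation_kb)
        assert theorem.premises == parse_aggregate("TP53 & MDM2 & U & P")
        assert theorem.conclusion == parse_formula("d(TP53)")

    def test_ffl_theorem_after_discharge(self, ffl_kb, ffl_derivation):
        theorem = extract_theorem(ffl_derivation, ffl_kb)
        assert theorem.premises.is_empty()
        assert theorem.conclusion == parse_formula(
            "(A_gene & A_gene & B_gene & C_gene & RA & RA & RB) -> C"
        )

    def test_invalid_derivation_rejected(self):
        d = loads_derivation("1\tA\tAndE:1\n")
        with pytest.raises(ValueError, match="invalid"):
            extract_theorem(d, KnowledgeBase())


class TestSerialization:
    def test_zdx_roundtrip(self, glycolysis_derivation):
        again = loads_derivation(dump_derivation(glycolysis_derivation))
        assert again.lines == glycolysis_derivation.lines

    def test_label_column(self):
        d = loads_derivation("1\tA\tIA\t0.05\n")
        assert d[1].label == "0.05"
        assert "0.05" in dump_derivation(d)

    def test_inline_label(self):
        d = loads_derivation("1\tA : 0.05\tIA\n")
        assert d[1].label == "0.05"

    def test_render_mentions_rules(self, glycolysis_derivation):
        table = render_derivation(glycolysis_derivation)
        assert "From 2,7 by ->E" in table
        assert "From 1-32 by ->I" in table

    def test_line_numbers_must_be_consecutive(self):
        with pytest.raises(ValueError, match="consecutive"):
            loads_derivation("1\tA\tIA\n3\tB\tIA\n")
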