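"""Rule-expression parsing and the family presence call engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rcdprofiler import (
    DetectionMode,
    Evidence,
    EvidenceUnavailableError,
    ExprSyntaxError,
    GeneFamilyRule,
    Category,
    DomainHit,
    RuleExpr,
    call_family,
    evaluate_protein,
    format_rule_expr,
    parse_rule_expr,
)


class TestParseExpr:
    def test_conjunction(self):
        expr = parse_rule_expr("PF00565 + PF00567")
        assert expr.alternatives == (frozenset({"PF00565", "PF00567"}),)

    def test_disjunction(self):
        expr = parse_rule_expr("PF02265 / PF01223 / PF03265")
        assert len(expr.alternatives) == 3
        assert all(len(a) == 1 for a in expr.alternatives)

    def test_plus_binds_tighter_than_slash(self):
        expr = parse_rule_expr("PF13365 + PF00595 / PF12812")
        assert set(expr.alternatives) == {
            frozenset({"PF13365", "PF00595"}), frozenset({"PF12812"})
        }

    def test_version_suffixes_normalized(self):
        expr = parse_rule_expr("PF00656.22")
        assert expr.alternatives == (frozenset({"PF00656"}),)

    @pytest.mark.parametrize(
        "bad", ["PF00565 +", "+ PF00565", "PF00565 / / PF00567",
                "PF00565 NOTPF", "", "PF00565 + banana"]
    )
    def test_syntax_errors(self, bad):
        with pytest.raises(ExprSyntaxError):
            parse_rule_expr(bad)

    def test_error_carries_position(self):
        with pytest.raises(ExprSyntaxError) as exc:
            parse_rule_expr("PF00565 + banana")
        assert exc.value.position == 10


accession = st.from_regex(r"PF\d{5}", fullmatch=True)
conjunction = st.frozensets(accession, min_size=1, max_size=3)
expr_strategy = st.builds(
    RuleExpr, st.lists(conjunction, min_size=1, max_size=4).map(tuple)
)


class TestEvaluate:
    def test_partial_conjunction_false(self):
        tsn = parse_rule_expr("PF00565 + PF00567")
        assert not evaluate_protein(tsn, {"PF00565"})

    def test_superset_satisfies_conjunction(self):
        tsn = parse_rule_expr("PF00565 + PF00567")
        assert evaluate_protein(tsn, {"PF00565", "PF00567", "PF00001"})

    @settings(max_examples=200, deadline=None)
    @given(expr=expr_strategy, domains=st.frozensets(accession, max_size=6))
    def test_matches_truth_table(self, expr, domains):
        brute = any(
            all(acc in domains for acc in alt) for alt in expr.alternatives
        )
        assert evaluate_protein(expr, domains) == brute

    @settings(max_examples=100, deadline=None)
    @given(expr=expr_strategy, domains=st.frozensets(accession, max_size=5),
           extra=accession)
    def test_monotone_in_domain_set(self, expr, domains, extra):
        if evaluate_protein(expr, domains):
            assert evaluate_protein(expr, domains | {extra})

    @settings(max_examples=200, deadline=None)
    @given(expr=expr_strategy)
    def test_parse_print_parse_identity(self, expr):
        again = parse_rule_expr(format_rule_expr(expr))
        assert set(again.alternatives) == set(expr.alternatives)


def _rule(mode, expr_text=None, fam="FAM"):
    return GeneFamilyRule(
        family_id=fam,
        category=Category.APOPTOSIS,
        detection_mode=mode,
        domain_expr=parse_rule_expr(expr_text) if expr_text else None,
    )


def dhit(prot, acc):
    return DomainHit(protein_id=prot, pfam_acc=acc, env_start=1,
                     env_end=100, e_value=1e-10)


class TestCallFamily:
    def test_metacaspase_domain_presence(self):
        rule = _rule(DetectionMode.COMBINED, "PF00656", "METACASPASE")
        call = call_family(rule, "SP1", [dhit("p1", "PF00656")], set())
        assert call.present and call.evidence is Evidence.DOMAIN
        assert call.supporting_proteins == {"p1"}

    def test_homology_only_absent_with_empty_set(self):
        rule = _rule(DetectionMode.HOMOLOGY_ONLY, None, "AIF_AMID")
        call = call_family(rule, "SP1", [], set())
        assert not call.present and call.evidence is None

    def test_homology_only_without_input_raises(self):
        rule = _rule(DetectionMode.HOMOLOGY_ONLY, None, "AIF_AMID")
        with pytest.raises(EvidenceUnavailableError, match="AIF_AMID"):
            call_family(rule, "SP1", [], None)

    def test_combined_mode_homology_alone_suffices(self):
        rule = _rule(DetectionMode.COMBINED, "PF00656")
        call = call_family(rule, "SP1", [], {"h1"})
        assert call.present and call.evidence is Evidence.HOMOLOGY

    def test_combined_mode_both_evidence_kinds(self):
        rule = _rule(DetectionMode.COMBINED, "PF00656")
        call = call_family(rule, "SP1", [dhit("p1", "PF00656")], {"h1"})
        assert call.evidence is Evidence.BOTH
        assert call.supporting_proteins == {"p1", "h1"}

    def test_domain_only_ignores_homologs(self):
        rule = _rule(DetectionMode.DOMAIN_ONLY, "PF00656")
        call = call_family(rule, "SP1", [], {"h1"})
        assert not call.present

    def test_conjunction_requires_same_protein(self):
        rule = _rule(DetectionMode.DOMAIN_ONLY, "PF00565 + PF00567", "TSN")
        split = [dhit("p1", "PF00565"), dhit("p2", "PF00567")]
        assert not call_family(rule, "SP1", split, None).present
        joint = [dhit("p1", "PF00565"), dhit("p1", "PF00567")]
        assert call_family(rule, "SP1", joint, None).present

    def test_invariant_under_order_and_duplication(self):
        rule = _rule(DetectionMode.DOMAIN_ONLY, "PF00565 + PF00567")
        hits = [dhit("p1", "PF00565"), dhit("p1", "PF00567")]
        rng = np.random.default_rng(0)
        base = call_family(rule, "SP1", hits, None)
        for _ in range(5):
            shuffled = list(hits) + [hits[int(rng.integers(2))]]
            rng.shuffle(shuffled)
            assert call_family(rule, "SP1", shuffled, None) == base

    def test_optional_evalue_ceiling(self):
        rule = _rule(DetectionMode.DOMAIN_ONLY, "PF00656")
        weak = [DomainHit("p1", "PF00656", 1, 50, 0.5)]
        assert call_family(rule, "SP1", weak, None).present
        assert not call_family(
            rule, "SP1", weak, None, domain_e_max=1e-3
        ).present
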