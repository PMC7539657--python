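"""Domain-architecture rule engine.

Gene-family formulas are written with the field's shorthand: ``+`` joins
Pfam domains that must co-occur on the same protein (conserved domain
association), ``/`` separates alternative architectures.  ``+`` binds
tighter than ``/``, so ``PF13365 + PF00595 / PF12812`` reads as
``(PF13365 AND PF00595) OR PF12812``.
"""

from __future__ import annotations

import re
from collections import defaultdict
from typing import Iterable, Mapping, Optional

from .model import (
    DetectionMode,
    DomainHit,
    Evidence,
    EvidenceUnavailableError,
    ExprSyntaxError,
    GeneFamilyRule,
    PresenceCall,
    RuleExpr,
    normalize_pfam,
)

_TOKEN_RE = re.compile(r"\S+")


def parse_rule_expr(text: str) -> RuleExpr:
    """Parse a formula string into a disjunction of conjunctions.

    Raises :class:`ExprSyntaxError` (with character position) on dangling
    operators or tokens that are not Pfam accessions.
    """
    tokens = [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(text)]
    if not tokens:
        raise ExprSyntaxError("empty rule expression", 0)

    alternatives: list[frozenset[str]] = []
    current: set[str] = set()
    expect_acc = True
    for tok, pos in tokens:
        if tok in ("+", "/"):
            if expect_acc:
                raise ExprSyntaxError(f"dangling operator {tok!r} at {pos}", pos)
            if tok == "/":
                alternatives.append(frozenset(current))
                current = set()
            expect_acc = True
        else:
            if not expect_acc:
                raise ExprSyntaxError(
                    f"missing operator before {tok!r} at {pos}", pos
                )
            try:
                current.add(normalize_pfam(tok))
            except ExprSyntaxError as exc:
                raise ExprSyntaxError(f"{exc} at {pos}", pos) from None
            expect_acc = False
    if expect_acc:
        _, pos = tokens[-1]
        raise ExprSyntaxError(f"dangling operator at end of expression", pos)
    alternatives.append(frozenset(current))
    return RuleExpr(tuple(alternatives))


def format_rule_expr(expr: RuleExpr) -> str:
    """Canonical text form; ``parse_rule_expr(format_rule_expr(e))`` is
    the identity on the set of alternatives."""
    return str(expr)


def evaluate_protein(expr: RuleExpr, domains_of_protein: Iterable[str]) -> bool:
    """True iff some alternative's accessions all occur on the protein.

    Monotone in the domain set: adding accessions never flips True->False.
    """
    accs = frozenset(domains_of_protein)
    return any(alt <= accs for alt in expr.alternatives)


def domains_by_protein(
    hits: Iterable[DomainHit], e_max: Optional[float] = None
) -> dict[str, frozenset[str]]:
    """Collapse domain intervals to per-protein accession sets, optionally
    applying an E-value ceiling (off by default: scan output is assumed
    already thresholded)."""
    acc: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        if e_max is not None and h.e_value > e_max:
            continue
        acc[h.protein_id].add(h.pfam_acc)
    return {p: frozenset(s) for p, s in acc.items()}


def call_family(
    rule: GeneFamilyRule,
    species_id: str,
    domain_hits: Iterable[DomainHit] = (),
    homolog_proteins: Optional[Iterable[str]] = None,
    domain_e_max: Optional[float] = None,
) -> PresenceCall:
    """Presence call for one family in one species.

    domain_only: present iff some protein satisfies the formula.
    homology_only: present iff the screened-homolog set is non-empty;
    passing ``homolog_proteins=None`` (no homology input at all) raises
    :class:`EvidenceUnavailableError` rather than silently calling absence.
    combined: union (OR) of both evidence kinds; the evidence field records
    which kind(s) supported the call.
    """
    mode = rule.detection_mode
    dom_support: set[str] = set()
    if mode is not DetectionMode.HOMOLOGY_ONLY:
        assert rule.domain_expr is not None
        per_protein = domains_by_protein(domain_hits, e_max=domain_e_max)
        dom_support = {
            p for p, accs in per_protein.items()
            if evaluate_protein(rule.domain_expr, accs)
        }

    hom_support: set[str] = set()
    if mode is not DetectionMode.DOMAIN_ONLY:
        if homolog_proteins is None:
            if mode is DetectionMode.HOMOLOGY_ONLY:
                raise EvidenceUnavailableError(
                    f"family {rule.family_id} ({species_id}): homology-only "
                    f"detection but no homolog evidence supplied"
                )
            # combined mode degrades gracefully to domain evidence alone
        else:
            hom_support = set(homolog_proteins)

    supporting = frozenset(dom_support | hom_support)
    if dom_support and hom_support:
        evidence: Optional[Evidence] = Evidence.BOTH
    elif dom_support:
        evidence = Evidence.DOMAIN
    elif hom_support:
        evidence = Evidence.HOMOLOGY
    else:
        evidence = None
    return PresenceCall(
        species_id=species_id,
        family_id=rule.family_id,
        present=bool(supporting),
        supporting_proteins=supporting,
        evidence=evidence,
    )


def call_all(
    rules: Iterable[GeneFamilyRule],
    species_ids: Iterable[str],
    domain_hits_by_species: Mapping[str, Iterable[DomainHit]],
    homologs_by_species_family: Optional[
        Mapping[tuple[str, str], set[str]]
    ] = None,
    domain_e_max: Optional[float] = None,
) -> list[PresenceCall]:
    """Call every (species, family) pair.

    ``homologs_by_species_family`` maps (species_id, family_id) to the set
    of screened homolog protein ids; ``None`` means no homology input was
    provided at all (homology-only families then raise).
    """
    calls = []
    for sp in species_ids:
        dh = list(domain_hits_by_species.get(sp, ()))
        for rule in rules:
            if homologs_by_species_family is None:
                homs: Optional[set[str]] = None
            else:
                homs = homologs_by_species_family.get((sp, rule.family_id), set())
            calls.append(
                call_family(rule, sp, dh, homs, domain_e_max=domain_e_max)
            )
    return calls
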