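"""Largest-ortholog-group reduction of homolog-based presence calls.

For each gene family the retrieved (screened) proteins are matched against
an externally supplied ortholog-group table.  The candidate groups are
those containing at least one retrieved protein; the largest candidate
(total protein members; ties to the lexicographically smallest group id)
is selected, and a species is called present at the ortholog level iff it
contributes at least one member to a selected group.  Families whose
proteins fall in no group are reported as *unassigned*, which is distinct
from absence.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .model import (
    FamilyGroupSelection,
    OrthologGroupTable,
    RcdError,
)


def select_largest_group(
    groups: OrthologGroupTable,
    retrieved: Iterable[tuple[str, str]],
    family_id: str,
) -> FamilyGroupSelection:
    """Pick the largest ortholog group containing a retrieved protein.

    ``retrieved`` is the set of (species_id, protein_id) pairs recovered
    for one family.  Group size is the total member count.  Returns an
    unassigned selection (selected_group_id None) when no group contains
    any retrieved protein.
    """
    retrieved = set(retrieved)
    if not retrieved:
        raise RcdError(f"family {family_id}: empty retrieved protein set")
    candidates = sorted(
        (
            (gid, len(members))
            for gid, members in groups.groups.items()
            if members & retrieved
        ),
        key=lambda t: t[0],
    )
    if not candidates:
        return FamilyGroupSelection(
            family_id=family_id,
            selected_group_id=None,
            group_size=0,
            candidate_groups=(),
        )
    best_gid, best_size = min(candidates, key=lambda t: (-t[1], t[0]))
    return FamilyGroupSelection(
        family_id=family_id,
        selected_group_id=best_gid,
        group_size=best_size,
        candidate_groups=tuple(candidates),
    )


def ortholog_presence(
    selections: Sequence[FamilyGroupSelection],
    groups: OrthologGroupTable,
    species_id: str,
) -> int:
    """1 iff the species contributes a member to ANY selected group.

    Multiple selections cover composite families whose subfamilies were
    reduced separately; presence of at least one ortholog suffices.
    """
    for sel in selections:
        if sel.selected_group_id is None:
            continue
        members = groups.groups[sel.selected_group_id]
        if any(sp == species_id for sp, _ in members):
            return 1
    return 0


def reduce_family_calls(
    groups: OrthologGroupTable,
    retrieved_by_family: Mapping[str, set[tuple[str, str]]],
    species_ids: Sequence[str],
) -> tuple[dict[str, FamilyGroupSelection], dict[tuple[str, str], int]]:
    """Run the reduction for every family with retrieved proteins.

    Returns the per-family selection and a dense (species, family) -> 0/1
    presence mapping over ``species_ids``.
    """
    selections: dict[str, FamilyGroupSelection] = {}
    presence: dict[tuple[str, str], int] = {}
    for fam in sorted(retrieved_by_family):
        retrieved = retrieved_by_family[fam]
        if not retrieved:
            continue
        sel = select_largest_group(groups, retrieved, fam)
        selections[fam] = sel
        for sp in species_ids:
            presence[(sp, fam)] = ortholog_presence([sel], groups, sp)
    return selections, presence
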