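"""Core domain types for the regulated-cell-death (RCD) gene inventory.

The pipeline profiles gene families associated with apoptosis, autophagic
cell death and regulated necrosis across unicellular eukaryote proteomes.
Each species is described by a :class:`SpeciesRecord`; each gene family by a
:class:`GeneFamilyRule` whose :class:`RuleExpr` encodes the Pfam
domain-architecture formula (a disjunction of same-protein co-occurrence
requirements).  Presence/absence calls are collected in a
:class:`PresenceMatrix` keyed by species and family.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# errors

class RcdError(Exception):
    """Base class for all package errors."""


class ManifestError(RcdError):
    """Invalid species manifest content (bad enum, duplicate id, ...)."""


class FormatError(RcdError):
    """Malformed tabular input; message carries file and line number."""


class ConfigError(RcdError):
    """Invalid gene-family rule configuration."""


class ExprSyntaxError(ConfigError):
    """Syntax error in a domain-architecture formula."""

    def __init__(self, message: str, position: int = -1):
        super().__init__(message)
        self.position = position


class EvidenceUnavailableError(RcdError):
    """A detection mode requires evidence that was not supplied."""


class SearchError(RcdError):
    """An injected homology-search callable failed."""


# ---------------------------------------------------------------------------
# enumerations

class Superphylum(str, Enum):
    AMO = "AMO"     # Amorphea
    SAR = "SAR"     # Stramenopiles-Alveolates-Rhizaria
    ARC = "ARC"     # Archaeplastida
    EXC = "EXC"     # Excavata
    HAP = "HAP"     # Haptophyta
    CRYP = "CRYP"   # Cryptista


class MitoClass(str, Enum):
    """Mitochondrial phenotype classes, from fully aerobic organelles down
    to complete secondary loss (amitochondriate)."""

    AEROBIC = "aerobic"
    ANAEROBIC = "anaerobic"
    HYDROGEN_PRODUCING = "hydrogen_producing"
    HYDROGENOSOME = "hydrogenosome"
    MITOSOME = "mitosome"
    AMITOCHONDRIATE = "amitochondriate"

    @property
    def is_diverged(self) -> bool:
        """True for every phenotype other than fully aerobic mitochondria."""
        return self is not MitoClass.AEROBIC


class Lifestyle(str, Enum):
    P = "P"  # parasitic
    S = "S"  # (ecto)symbiotic
    F = "F"  # free-living
    M = "M"  # transiently multicellular


class Category(str, Enum):
    APOPTOSIS = "apoptosis"
    AUTOPHAGY = "autophagy"
    NECROSIS = "necrosis"


class DetectionMode(str, Enum):
    HOMOLOGY_ONLY = "homology_only"
    DOMAIN_ONLY = "domain_only"
    COMBINED = "combined"


class Evidence(str, Enum):
    DOMAIN = "domain"
    HOMOLOGY = "homology"
    BOTH = "both"


# ---------------------------------------------------------------------------
# Pfam accession handling

_PFAM_RE = re.compile(r"^PF\d{5}$")


def normalize_pfam(token: str) -> str:
    """Strip a version suffix (``PF00656.22`` -> ``PF00656``) and validate.

    Raises :class:`ExprSyntaxError` if the result is not ``PF`` + 5 digits.
    """
    acc = token.split(".", 1)[0].strip()
    if not _PFAM_RE.match(acc):
        raise ExprSyntaxError(f"not a Pfam accession: {token!r}")
    return acc


def is_pfam(token: str) -> bool:
    return bool(_PFAM_RE.match(token.split(".", 1)[0].strip()))


# ---------------------------------------------------------------------------
# species / evidence records

@dataclass(frozen=True)
class SpeciesRecord:
    """One protist taxon with its phenotype and lifestyle labels."""

    species_id: str
    taxon_name: str
    superphylum: Superphylum
    mito_class: MitoClass
    lifestyle: Lifestyle
    proteome_path: Optional[str] = None


@dataclass(frozen=True)
class HomologyHit:
    """One row of 12-column tabular protein homology output
    (qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore); coordinates 1-based inclusive."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatch: int
    gapopen: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    def __post_init__(self):
        if self.q_start > self.q_end:
            raise ValueError(f"q_start > q_end for {self.query_id}")
        if self.s_start > self.s_end:
            raise ValueError(f"s_start > s_end for {self.query_id}")
        if self.e_value < 0:
            raise ValueError(f"negative e-value for {self.query_id}")


@dataclass(frozen=True)
class DomainHit:
    """One Pfam domain interval on a protein (envelope coordinates,
    1-based inclusive); accession stored without version suffix."""

    protein_id: str
    pfam_acc: str
    env_start: int
    env_end: int
    e_value: float

    def __post_init__(self):
        if not _PFAM_RE.match(self.pfam_acc):
            raise ValueError(f"non-normalized Pfam accession {self.pfam_acc!r}")
        if self.e_value < 0:
            raise ValueError(f"negative e-value on {self.protein_id}")


# ---------------------------------------------------------------------------
# rule expressions and family rules

@dataclass(frozen=True)
class RuleExpr:
    """Domain-architecture formula: a disjunction of conjunctions.

    Each conjunction (alternative) is a non-empty frozenset of Pfam
    accessions that must co-occur on the same protein.
    """

    alternatives: tuple[frozenset[str], ...]

    def __post_init__(self):
        if not self.alternatives:
            raise ValueError("RuleExpr needs at least one alternative")
        for alt in self.alternatives:
            if not alt:
                raise ValueError("empty conjunction in RuleExpr")
            for acc in alt:
                if not _PFAM_RE.match(acc):
                    raise ValueError(f"non-normalized accession {acc!r}")

    @property
    def accessions(self) -> frozenset[str]:
        out: set[str] = set()
        for alt in self.alternatives:
            out |= alt
        return frozenset(out)

    def __str__(self) -> str:
        return " / ".join(
            " + ".join(sorted(alt)) for alt in self.alternatives
        )


@dataclass(frozen=True)
class GeneFamilyRule:
    """Definition of one RCD gene family: how presence is detected."""

    family_id: str
    category: Category
    detection_mode: DetectionMode
    domain_expr: Optional[RuleExpr] = None
    pathway_group: Optional[str] = None
    bait_set_id: Optional[str] = None

    def __post_init__(self):
        if (self.domain_expr is None) != (
            self.detection_mode is DetectionMode.HOMOLOGY_ONLY
        ):
            raise ConfigError(
                f"family {self.family_id}: domain expression must be empty "
                f"iff detection mode is homology_only"
            )


# ---------------------------------------------------------------------------
# presence calls and matrix

@dataclass(frozen=True)
class PresenceCall:
    """Presence/absence of one family in one species, with provenance."""

    species_id: str
    family_id: str
    present: bool
    supporting_proteins: frozenset[str] = frozenset()
    evidence: Optional[Evidence] = None

    def __post_init__(self):
        if self.present != bool(self.supporting_proteins):
            raise ValueError(
                f"{self.species_id}/{self.family_id}: present flag must match "
                f"non-emptiness of supporting proteins"
            )
        if self.present and self.evidence is None:
            raise ValueError(
                f"{self.species_id}/{self.family_id}: present call needs evidence"
            )


@dataclass
class PresenceMatrix:
    """Species x family binary matrix with per-call provenance.

    ``data`` is an int8 DataFrame (rows = species, columns = families);
    ``provenance`` maps (species_id, family_id) of every 1-cell to its
    supporting protein set; ``categories`` maps family_id -> Category.
    """

    data: pd.DataFrame
    provenance: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    categories: dict[str, Category] = field(default_factory=dict)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def family_ids(self) -> list[str]:
        return list(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.int8)

    def __eq__(self, other) -> bool:  # matrix content equality
        if not isinstance(other, PresenceMatrix):
            return NotImplemented
        return self.data.equals(other.data)


# ---------------------------------------------------------------------------
# ortholog groups

@dataclass
class OrthologGroupTable:
    """Mapping group_id -> set of (species_id, protein_id) members.

    A member pair may belong to at most one group (validated on read).
    """

    groups: dict[str, frozenset[tuple[str, str]]]

    def __len__(self) -> int:
        return len(self.groups)

    def group_of(self, species_id: str, protein_id: str) -> Optional[str]:
        for gid, members in self.groups.items():
            if (species_id, protein_id) in members:
                return gid
        return None

    def size(self, group_id: str) -> int:
        return len(self.groups[group_id])


@dataclass(frozen=True)
class FamilyGroupSelection:
    """Result of the largest-ortholog-group reduction for one family."""

    family_id: str
    selected_group_id: Optional[str]
    group_size: int
    candidate_groups: tuple[tuple[str, int], ...]

    @property
    def unassigned(self) -> bool:
        """No ortholog group contained any retrieved protein."""
        return self.selected_group_id is None


# ---------------------------------------------------------------------------
# statistics containers

@dataclass(frozen=True)
class GroupComparison:
    """Two-sample Mann-Whitney comparison of gene-count vectors.

    ``U`` is the rank-sum statistic of group a; ``sd_*`` are sample
    standard deviations (n-1 denominator), reported as 0.0 with a note
    for single-member groups.
    """

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    U: float
    p_two_tailed: float
    method: str  # "exact" | "normal_approx"
    notes: str = ""


# ---------------------------------------------------------------------------
# linkage tree

@dataclass(frozen=True)
class Merge:
    node_a: int
    node_b: int
    height: float
    size: int


@dataclass
class LinkageTree:
    """Agglomerative merge history in scipy convention: leaves are
    0..n-1, the cluster created at step t gets id n+t."""

    merges: list[Merge]
    n_leaves: int

    def to_scipy(self) -> np.ndarray:
        """Return an (n-1, 4) linkage array compatible with
        scipy.cluster.hierarchy."""
        return np.array(
            [[m.node_a, m.node_b, m.height, m.size] for m in self.merges],
            dtype=float,
        )

    def heights(self) -> np.ndarray:
        return np.array([m.height for m in self.merges])

    def cut(self, k: int) -> np.ndarray:
        """Flat labels (1..k) obtained by replaying the first n-k merges.

        Guarantees exactly k clusters for 1 <= k <= n; labels are numbered
        by first appearance in leaf order.
        """
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError(f"k must be in 1..{n}, got {k}")
        parent = list(range(2 * n - 1))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for t, m in enumerate(self.merges[: n - k]):
            new_id = n + t
            parent[find(m.node_a)] = new_id
            parent[find(m.node_b)] = new_id

        labels = np.empty(n, dtype=int)
        seen: dict[int, int] = {}
        for leaf in range(n):
            root = find(leaf)
            if root not in seen:
                seen[root] = len(seen) + 1
            labels[leaf] = seen[root]
        return labels

    def leaf_order(self) -> list[int]:
        """Dendrogram display order of the leaves."""
        from scipy.cluster.hierarchy import leaves_list

        if self.n_leaves == 1:
            return [0]
        return [int(i) for i in leaves_list(self.to_scipy())]


# ---------------------------------------------------------------------------
# helpers

PROTEIN_ID_SEP = "|"


def make_protein_id(species_id: str, protein: str) -> str:
    """Globally unique protein token ``SPECIES|protein``."""
    return f"{species_id}{PROTEIN_ID_SEP}{protein}"


def split_protein_id(token: str) -> tuple[str, str]:
    """Split a ``SPECIES|protein`` token; raises on missing separator."""
    if PROTEIN_ID_SEP not in token:
        raise FormatError(f"protein id {token!r} lacks '{PROTEIN_ID_SEP}' separator")
    sp, prot = token.split(PROTEIN_ID_SEP, 1)
    return sp, prot


def species_of_members(
    members: Iterable[tuple[str, str]],
) -> frozenset[str]:
    return frozenset(sp for sp, _ in members)
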