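"""Synthetic study generator: planted truth plus self-consistent evidence.

The generator plants a binary presence/absence truth matrix over groups of
species (each group has a mitochondrial phenotype, a lifestyle and
per-category presence probabilities), then fabricates exactly the evidence
files the pipeline consumes — a species manifest, a domain-scan table, a
12-column homology-hit table, an ortholog-group membership table and a
bait FASTA — such that running the pipeline over the bundle recovers the
truth matrix exactly.  Evidence is minimal-sufficient: one satisfying
protein per planted presence, plus decoy proteins whose domains satisfy no
rule and decoy hits that fail the screening thresholds.

The default cohort emulates the study conditions of the protist survey:
67 species, group sizes matching the published marginals (31 free-living,
15 transiently multicellular, 17 parasitic, 4 symbiotic; 51 aerobic, 16
with diverged mitochondria including one amitochondriate), and per-group
presence probabilities matching the published per-group mean gene counts.
All randomness flows through one NumPy generator seeded from the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    write_domain_scan,
    write_ortholog_groups,
    write_species_manifest,
    write_tabular_hits,
)
from .model import (
    Category,
    DetectionMode,
    DomainHit,
    GeneFamilyRule,
    HomologyHit,
    Lifestyle,
    MitoClass,
    OrthologGroupTable,
    RcdError,
    SpeciesRecord,
    Superphylum,
    make_protein_id,
)

BAIT_LENGTH = 100  # residues; fabricated hits align 90/100 of the bait
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class GroupSpec:
    """One species group: size, labels and per-category presence rates."""

    n_species: int
    mito_class: MitoClass
    lifestyle: Lifestyle
    superphylum: Superphylum
    presence_prob: Mapping[str, float]  # category value -> probability

    def __post_init__(self):
        for cat, p in self.presence_prob.items():
            Category(cat)
            if not 0 <= p <= 1:
                raise ValueError(f"presence_prob[{cat}]={p} outside [0,1]")


@dataclass(frozen=True)
class SimConfig:
    """Full simulation design; the seed is mandatory."""

    groups: Mapping[str, GroupSpec]
    seed: int
    flip_noise: float = 0.0
    decoy_domains_per_proteome: int = 5

    def __post_init__(self):
        if not 0 <= self.flip_noise <= 1:
            raise ValueError("flip_noise outside [0,1]")
        if not self.groups:
            raise ValueError("no species groups configured")


def default_sim_config(seed: int, flip_noise: float = 0.0) -> SimConfig:
    """The 67-species default cohort (see module docstring)."""
    g = {
        "MAER": GroupSpec(15, MitoClass.AEROBIC, Lifestyle.M, Superphylum.AMO,
                          {"apoptosis": 0.80, "autophagy": 0.91, "necrosis": 0.0}),
        "FAER": GroupSpec(30, MitoClass.AEROBIC, Lifestyle.F, Superphylum.SAR,
                          {"apoptosis": 0.66, "autophagy": 0.66, "necrosis": 0.0}),
        "SAER": GroupSpec(4, MitoClass.AEROBIC, Lifestyle.S, Superphylum.AMO,
                          {"apoptosis": 0.70, "autophagy": 0.80, "necrosis": 0.0}),
        "PAER": GroupSpec(2, MitoClass.AEROBIC, Lifestyle.P, Superphylum.SAR,
                          {"apoptosis": 0.55, "autophagy": 0.38, "necrosis": 0.0}),
        "PANA": GroupSpec(2, MitoClass.ANAEROBIC, Lifestyle.P, Superphylum.SAR,
                          {"apoptosis": 0.80, "autophagy": 0.38, "necrosis": 0.0}),
        "PHYD": GroupSpec(2, MitoClass.HYDROGEN_PRODUCING, Lifestyle.P,
                          Superphylum.EXC,
                          {"apoptosis": 0.55, "autophagy": 0.38, "necrosis": 0.0}),
        "PHGS": GroupSpec(6, MitoClass.HYDROGENOSOME, Lifestyle.P,
                          Superphylum.EXC,
                          {"apoptosis": 0.33, "autophagy": 0.38, "necrosis": 0.0}),
        "PMIT": GroupSpec(5, MitoClass.MITOSOME, Lifestyle.P, Superphylum.AMO,
                          {"apoptosis": 0.20, "autophagy": 0.38, "necrosis": 0.0}),
        "FAMI": GroupSpec(1, MitoClass.AMITOCHONDRIATE, Lifestyle.F,
                          Superphylum.EXC,
                          {"apoptosis": 0.20, "autophagy": 0.75, "necrosis": 0.0}),
    }
    return SimConfig(groups=g, seed=seed, flip_noise=flip_noise)


def two_group_config(
    seed: int,
    n_per_group: int = 15,
    p_high: float = 0.9,
    p_low: float = 0.2,
    flip_noise: float = 0.0,
    categories: Sequence[str] = ("apoptosis",),
) -> SimConfig:
    """Planted two-block design used for recovery and power studies."""
    probs_hi = {c: p_high for c in categories}
    probs_lo = {c: p_low for c in categories}
    return SimConfig(
        groups={
            "HI": GroupSpec(n_per_group, MitoClass.AEROBIC, Lifestyle.M,
                            Superphylum.AMO, probs_hi),
            "LO": GroupSpec(n_per_group, MitoClass.MITOSOME, Lifestyle.P,
                            Superphylum.EXC, probs_lo),
        },
        seed=seed,
        flip_noise=flip_noise,
    )


# ---------------------------------------------------------------------------
# truth simulation

@dataclass
class SimTruth:
    truth: pd.DataFrame                  # species x family, int8
    records: list[SpeciesRecord]
    group_of: dict[str, str]             # species_id -> group label


def simulate_truth(
    config: SimConfig,
    rules: Sequence[GeneFamilyRule],
    rng: Optional[np.random.Generator] = None,
) -> SimTruth:
    """Draw the planted truth matrix: Bernoulli(presence_prob[group,
    category]) per cell, then flipped with probability flip_noise.
    Deterministic given the config seed."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    records: list[SpeciesRecord] = []
    group_of: dict[str, str] = {}
    rows: list[np.ndarray] = []
    fam_ids = [r.family_id for r in rules]
    for label, spec in config.groups.items():
        for i in range(1, spec.n_species + 1):
            sp_id = f"{label}{i:02d}"
            records.append(
                SpeciesRecord(
                    species_id=sp_id,
                    taxon_name=f"Synthetica {label.lower()} {i}",
                    superphylum=spec.superphylum,
                    mito_class=spec.mito_class,
                    lifestyle=spec.lifestyle,
                )
            )
            group_of[sp_id] = label
            row = np.zeros(len(fam_ids), dtype=np.int8)
            for j, rule in enumerate(rules):
                p = spec.presence_prob.get(rule.category.value, 0.0)
                present = rng.random() < p
                if config.flip_noise and rng.random() < config.flip_noise:
                    present = not present
                row[j] = int(present)
            rows.append(row)
    truth = pd.DataFrame(
        np.vstack(rows), index=[r.species_id for r in records], columns=fam_ids
    ).astype("int8")
    return SimTruth(truth=truth, records=records, group_of=group_of)


# ---------------------------------------------------------------------------
# evidence fabrication

@dataclass
class EvidenceBundle:
    directory: Path
    manifest: Path
    domains: Path
    hits: Path
    orthogroups: Path
    baits_fasta: Path
    truth: Path


def _decoy_pool(rules: Sequence[GeneFamilyRule], size: int = 40) -> list[str]:
    used = set()
    for r in rules:
        if r.domain_expr is not None:
            used |= r.domain_expr.accessions
    pool = [f"PF9{i:04d}" for i in range(9000, 9000 + size + len(used))]
    return [a for a in pool if a not in used][:size]


def emit_evidence(
    sim: SimTruth,
    rules: Sequence[GeneFamilyRule],
    config: SimConfig,
    out_dir: Path | str,
    rng: Optional[np.random.Generator] = None,
) -> EvidenceBundle:
    """Write the full evidence bundle consistent with the planted truth.

    For every planted presence one protein is fabricated that satisfies
    the family's detection mode: the full domain conjunction of one
    randomly chosen alternative (unless homology-only), a homology hit
    clearing every screening threshold (unless domain-only), and
    membership in the family's ortholog group.  Absences emit nothing.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rule_by_id = {r.family_id: r for r in rules}

    domains: list[DomainHit] = []
    hits: list[HomologyHit] = []
    members: dict[str, set[tuple[str, str]]] = {}
    hom_families = [
        r.family_id for r in rules
        if r.detection_mode is not DetectionMode.DOMAIN_ONLY
    ]

    for sp_id in sim.truth.index:
        for fam in sim.truth.columns:
            if not sim.truth.at[sp_id, fam]:
                continue
            rule = rule_by_id[fam]
            prot = make_protein_id(sp_id, f"{fam}_p1")
            if rule.detection_mode is not DetectionMode.HOMOLOGY_ONLY:
                alts = rule.domain_expr.alternatives
                alt = alts[int(rng.integers(len(alts)))]
                pos = 1
                for acc in sorted(alt):
                    length = int(rng.integers(50, 150))
                    domains.append(
                        DomainHit(
                            protein_id=prot,
                            pfam_acc=acc,
                            env_start=pos,
                            env_end=pos + length,
                            e_value=float(10.0 ** -rng.uniform(6, 40)),
                        )
                    )
                    pos += length + 10
            if rule.detection_mode is not DetectionMode.DOMAIN_ONLY:
                hits.append(
                    _make_hit(rng, f"{fam}:bait1", prot, passing=True)
                )
            # group membership uses species-local protein names, matching
            # how the pipeline splits SPECIES|protein provenance tokens
            members.setdefault(f"OG_{fam}", set()).add((sp_id, f"{fam}_p1"))

        # decoys: domains satisfying no rule, hits failing the screen
        pool = _decoy_pool(rules)
        for i in range(config.decoy_domains_per_proteome):
            acc = pool[int(rng.integers(len(pool)))]
            prot = make_protein_id(sp_id, f"decoy{i + 1}")
            start = int(rng.integers(1, 200))
            domains.append(
                DomainHit(
                    protein_id=prot,
                    pfam_acc=acc,
                    env_start=start,
                    env_end=start + int(rng.integers(40, 120)),
                    e_value=float(10.0 ** -rng.uniform(3, 20)),
                )
            )
        if hom_families:
            fam = hom_families[int(rng.integers(len(hom_families)))]
            hits.append(
                _make_hit(
                    rng, f"{fam}:bait1",
                    make_protein_id(sp_id, "decoy_hom"), passing=False,
                )
            )

    bundle = EvidenceBundle(
        directory=out_dir,
        manifest=out_dir / "manifest.tsv",
        domains=out_dir / "domains.tsv",
        hits=out_dir / "hits.tsv",
        orthogroups=out_dir / "orthogroups.tsv",
        baits_fasta=out_dir / "baits.fasta",
        truth=out_dir / "truth.tsv",
    )
    write_species_manifest(sim.records, bundle.manifest)
    write_domain_scan(domains, bundle.domains)
    write_tabular_hits(hits, bundle.hits)
    write_ortholog_groups(
        OrthologGroupTable({g: frozenset(m) for g, m in members.items()}),
        bundle.orthogroups,
    )
    _write_baits(rules, rng, bundle.baits_fasta)
    sim.truth.to_csv(bundle.truth, sep="\t", index_label="species_id")
    return bundle


def _make_hit(
    rng: np.random.Generator, bait: str, subject: str, passing: bool
) -> HomologyHit:
    if passing:
        pident = round(float(rng.uniform(35, 95)), 1)   # clears >=30
        span = 90                                       # coverage 0.9 >= 0.8
        evalue = float(10.0 ** -rng.uniform(10, 60))    # < 1e-5
    else:
        pident = round(float(rng.uniform(5, 25)), 1)    # fails identity
        span = 90
        evalue = float(10.0 ** -rng.uniform(10, 60))
    mism = int(round(span * (100 - pident) / 100))
    return HomologyHit(
        query_id=bait,
        subject_id=subject,
        pct_identity=pident,
        aln_length=span,
        mismatch=mism,
        gapopen=0,
        q_start=1,
        q_end=span,
        s_start=1,
        s_end=span,
        e_value=evalue,
        bit_score=round(float(rng.uniform(80, 400)), 1),
    )


def _write_baits(
    rules: Sequence[GeneFamilyRule], rng: np.random.Generator, path: Path
) -> None:
    with open(path, "w") as fh:
        for r in rules:
            if r.detection_mode is DetectionMode.DOMAIN_ONLY:
                continue
            seq = "".join(rng.choice(_AA, size=BAIT_LENGTH))
            fh.write(f">{r.family_id}:bait1\n{seq}\n")


def simulate_bundle(
    config: SimConfig,
    rules: Sequence[GeneFamilyRule],
    out_dir: Path | str,
) -> tuple[SimTruth, EvidenceBundle]:
    """Truth plus evidence from one RNG stream seeded by the config."""
    rng = np.random.default_rng(config.seed)
    sim = simulate_truth(config, rules, rng)
    bundle = emit_evidence(sim, rules, config, out_dir, rng)
    return sim, bundle
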