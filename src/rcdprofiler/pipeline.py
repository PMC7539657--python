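"""End-to-end orchestration: screen -> call -> reduce -> profile -> stats.

``run_all`` consumes an evidence bundle (manifest, domain scan, homology
hits + bait FASTA, optional ortholog groups), produces the homolog-based
and ortholog-based presence matrices, clusters species per gene category,
computes the standard group comparisons, writes every artifact as TSV and
a machine-readable JSON run report with file checksums.  Runs with
identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .io import (
    parse_rules_config,
    read_domain_scan,
    read_fasta_lengths,
    read_ortholog_groups,
    read_species_manifest,
    read_tabular_hits,
    write_calls,
    write_presence_matrix,
)
from .model import (
    Category,
    DetectionMode,
    DomainHit,
    GeneFamilyRule,
    PresenceCall,
    PresenceMatrix,
    RcdError,
    SpeciesRecord,
    split_protein_id,
)
from .orthology import reduce_family_calls
from .profiles import binary_distance, build_matrix, category_counts
from .cluster import select_k, ward_linkage
from .rules import call_all
from .screen import ScreenParams, filter_hits
from .stats import comparisons_frame, group_report

logger = logging.getLogger("rcdprofiler")


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    version: str
    config: dict
    stage_counts: dict = field(default_factory=dict)
    group_stats: dict = field(default_factory=dict)
    comparisons: list = field(default_factory=list)
    cluster_selection: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # filename -> sha256

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str):
    logger.info("stage %s", name)
    return time.perf_counter()


# ---------------------------------------------------------------------------
# stage helpers (library surface reused by the CLI and tests)

def screen_stage(
    hits_path: Path,
    baits_fasta: Path,
    params: ScreenParams,
) -> dict[tuple[str, str], set[str]]:
    """Screen homology hits; returns (species, family) -> kept protein ids.

    Family is taken from the bait query id prefix (``FAMILY:bait``);
    species from the ``SPECIES|protein`` subject id.
    """
    hits = read_tabular_hits(hits_path)
    lengths = read_fasta_lengths(baits_fasta)
    kept = filter_hits(hits, lengths, params)
    homolog_sets: dict[tuple[str, str], set[str]] = {}
    for h in kept:
        if ":" not in h.query_id:
            raise RcdError(
                f"bait id {h.query_id!r} lacks 'FAMILY:' prefix"
            )
        fam = h.query_id.split(":", 1)[0]
        sp, _ = split_protein_id(h.subject_id)
        homolog_sets.setdefault((sp, fam), set()).add(h.subject_id)
    return homolog_sets


def domains_by_species(
    domain_hits: Sequence[DomainHit],
) -> dict[str, list[DomainHit]]:
    """Group global-id domain hits by their species prefix."""
    by_sp: dict[str, list[DomainHit]] = {}
    for d in domain_hits:
        sp, _ = split_protein_id(d.protein_id)
        by_sp.setdefault(sp, []).append(d)
    return by_sp


def cluster_category(
    matrix: PresenceMatrix, category: Category
) -> Optional[dict]:
    """Ward-cluster species on one category's columns; returns linkage,
    selection table and flat labels (None when <2 informative columns)."""
    fams = [f for f in matrix.family_ids
            if matrix.categories.get(f) == category]
    if len(fams) < 2 or len(matrix.species_ids) < 3:
        return None
    sub = PresenceMatrix(
        data=matrix.data[fams],
        categories={f: category for f in fams},
    )
    tree = ward_linkage(binary_distance(sub))
    sel = select_k(tree, sub)
    return {"tree": tree, "selection": sel, "families": fams}


# ---------------------------------------------------------------------------
# run_all

def run_all(
    manifest_path: Path | str,
    evidence_dir: Path | str,
    out_dir: Path | str,
    rules_path: Optional[Path | str] = None,
    params: ScreenParams = ScreenParams(),
    with_orthologs: bool = True,
    domain_e_max: Optional[float] = None,
) -> RunReport:
    """Run every stage over an evidence directory.

    The directory must contain ``domains.tsv``; ``hits.tsv`` plus
    ``baits.fasta`` enable homology evidence and ``orthogroups.tsv``
    enables the ortholog-based matrix (skipped with a notice otherwise).
    Stage failures abort with the stage name and offending file.
    """
    evidence_dir = Path(evidence_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        version=__version__,
        config={
            "manifest": str(manifest_path),
            "evidence_dir": str(evidence_dir),
            "rules": str(rules_path) if rules_path else "default",
            "e_max": params.e_max,
            "id_min": params.id_min,
            "cov_min": params.cov_min,
            "with_orthologs": with_orthologs,
        },
    )

    def fail(stage: str, path, exc) -> RcdError:
        return RcdError(f"stage {stage!r} failed on {path}: {exc}")

    # --- load
    _stage("load")
    try:
        records = read_species_manifest(manifest_path)
    except (OSError, RcdError) as exc:
        raise fail("load-manifest", manifest_path, exc) from exc
    try:
        rules = parse_rules_config(rules_path)
    except (OSError, RcdError) as exc:
        raise fail("load-rules", rules_path or "default", exc) from exc
    species_ids = [r.species_id for r in records]
    categories = {r.family_id: r.category for r in rules}
    report.stage_counts["species"] = len(records)
    report.stage_counts["families"] = len(rules)

    domains_path = evidence_dir / "domains.tsv"
    try:
        domain_hits = read_domain_scan(domains_path)
    except (OSError, RcdError) as exc:
        raise fail("load-domains", domains_path, exc) from exc
    report.stage_counts["domain_hits"] = len(domain_hits)

    # --- screen
    _stage("screen")
    hits_path = evidence_dir / "hits.tsv"
    baits_path = evidence_dir / "baits.fasta"
    homolog_sets: Optional[dict[tuple[str, str], set[str]]] = None
    if hits_path.exists() and baits_path.exists():
        try:
            homolog_sets = screen_stage(hits_path, baits_path, params)
        except (OSError, RcdError) as exc:
            raise fail("screen", hits_path, exc) from exc
        report.stage_counts["screened_pairs"] = len(homolog_sets)
    else:
        needs_hom = [r.family_id for r in rules
                     if r.detection_mode is DetectionMode.HOMOLOGY_ONLY]
        if needs_hom:
            raise fail(
                "screen", hits_path,
                f"no homology evidence but homology-only families {needs_hom}",
            )
        logger.info("no hits.tsv/baits.fasta; homology evidence skipped")

    # --- call
    _stage("call")
    by_sp = domains_by_species(domain_hits)
    calls = call_all(
        rules, species_ids, by_sp, homolog_sets, domain_e_max=domain_e_max
    )
    report.stage_counts["calls_present"] = sum(c.present for c in calls)
    calls_path = out_dir / "calls.tsv"
    write_calls(calls, calls_path)

    # --- homolog-based matrix
    _stage("profile")
    fam_ids = [r.family_id for r in rules]
    matrix_hom = build_matrix(calls, species_ids, fam_ids, categories)
    hom_path = out_dir / "matrix_homologs.tsv"
    write_presence_matrix(matrix_hom, hom_path)

    # --- ortholog reduction
    matrix_ort: Optional[PresenceMatrix] = None
    groups_path = evidence_dir / "orthogroups.tsv"
    if with_orthologs and groups_path.exists():
        _stage("reduce")
        try:
            groups = read_ortholog_groups(groups_path)
        except (OSError, RcdError) as exc:
            raise fail("reduce", groups_path, exc) from exc
        retrieved: dict[str, set[tuple[str, str]]] = {}
        for c in calls:
            if not c.present:
                continue
            for prot in c.supporting_proteins:
                retrieved.setdefault(c.family_id, set()).add(
                    split_protein_id(prot)
                )
        selections, presence = reduce_family_calls(
            groups, retrieved, species_ids
        )
        report.stage_counts["ortholog_selections"] = len(selections)
        ort_calls: list[PresenceCall] = []
        cells = {
            (sp, fam): presence.get((sp, fam), 0)
            for sp in species_ids
            for fam in fam_ids
        }
        data = pd.DataFrame(
            [[cells[(sp, fam)] for fam in fam_ids] for sp in species_ids],
            index=species_ids, columns=fam_ids,
        ).astype("int8")
        matrix_ort = PresenceMatrix(data=data, categories=categories)
        write_presence_matrix(matrix_ort, out_dir / "matrix_orthologs.tsv")
        sel_rows = [
            {
                "family_id": s.family_id,
                "selected_group_id": s.selected_group_id or "",
                "group_size": s.group_size,
                "n_candidates": len(s.candidate_groups),
            }
            for s in selections.values()
        ]
        pd.DataFrame(sel_rows).to_csv(
            out_dir / "group_selections.tsv", sep="\t", index=False
        )
    elif with_orthologs:
        logger.info("no orthogroups.tsv; ortholog-based outputs skipped")

    # --- cluster + stats per category, per matrix flavor
    _stage("cluster/stats")
    all_comparisons = []
    flavors = [("homologs", matrix_hom)]
    if matrix_ort is not None:
        flavors.append(("orthologs", matrix_ort))
    for flavor, matrix in flavors:
        for category in Category:
            fams = [f for f in fam_ids if categories[f] == category]
            if not fams:
                continue
            counts = category_counts(matrix, category)
            for grouping in ("mito_class", "lifestyle"):
                summary, comps = group_report(counts, records, grouping)
                key = f"{flavor}.{category.value}.{grouping}"
                report.group_stats[key] = json.loads(
                    summary.to_json(orient="index")
                )
                for c in comps:
                    row = {
                        "matrix": flavor, "category": category.value,
                        "grouping": grouping,
                    }
                    row.update(comparisons_frame([c]).iloc[0].to_dict())
                    all_comparisons.append(row)
            clust = cluster_category(matrix, category)
            if clust is not None:
                sel = clust["selection"]
                report.cluster_selection[f"{flavor}.{category.value}"] = {
                    "k_best": sel.k_best,
                    "indices": json.loads(sel.table.to_json(orient="index"))
                    if not sel.table.empty else {},
                }
                tree = clust["tree"]
                pd.DataFrame(
                    [
                        {"node_a": m.node_a, "node_b": m.node_b,
                         "height": m.height, "size": m.size}
                        for m in tree.merges
                    ]
                ).to_csv(
                    out_dir / f"linkage_{flavor}_{category.value}.tsv",
                    sep="\t", index=False,
                )
                labels = sel.labels[sel.k_best]
                pd.DataFrame(
                    {"species_id": species_ids, "cluster": labels}
                ).to_csv(
                    out_dir / f"clusters_{flavor}_{category.value}.tsv",
                    sep="\t", index=False,
                )

    comp_df = pd.DataFrame(all_comparisons)
    comp_df.to_csv(out_dir / "comparisons.tsv", sep="\t", index=False)
    report.comparisons = json.loads(comp_df.to_json(orient="records"))

    # --- checksums + report
    for p in sorted(out_dir.glob("*.tsv")):
        report.outputs[p.name] = _sha256(p)
    (out_dir / "report.json").write_text(report.to_json())
    return report


def configure_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
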