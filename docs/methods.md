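# Methods

## Scope and model

`rcdprofiler` implements a comparative inventory of regulated-cell-death
(RCD) gene families across protist proteomes as a five-stage pipeline:
homology screening, rule-based presence calling from Pfam domain
architectures, largest-ortholog-group reduction, binary-profile
clustering, and nonparametric group comparison. The package does not
infer homology or orthology itself: DIAMOND/BLAST tabular hits, domain
scans and Broccoli-style ortholog membership tables are consumed as
inputs, and the library is deliberately agnostic about which scanner
produced them (the domain-scan reader takes a declared column mapping
rather than guessing a dialect).

## Screening thresholds

A homology hit is kept iff all three conditions hold: E-value < `e_max`
(default 10⁻⁵, strict), percent identity ≥ `id_min` (default 30,
inclusive), and query coverage ≥ `cov_min` (default 0.80, inclusive).
Coverage is computed on the **query** (bait) as
`(q_end − q_start + 1) / query_length`; bait-based retrieval conventionally
thresholds the bait span, and the aligned span of the subject is not a
reliable proxy for domain completeness of the bait. Iterative search
re-runs an injected search callable with the grown bait set until no new
subjects are kept or `max_rounds` (default 3) is reached; the cap
guarantees termination when the underlying homology graph keeps growing.

## Presence rules

A family formula is a disjunction of conjunctions over Pfam accessions
(versions stripped, `PF` + five digits). `+` binds tighter than `/`, so
`PF13365 + PF00595 / PF12812` is `(PF13365 ∧ PF00595) ∨ PF12812` — the
reading under which single-domain alternatives remain meaningful.
Conjunctions require co-occurrence on the **same protein** (domain
architecture, order-insensitive), not across the proteome.

Detection modes: `domain_only` (some protein satisfies the formula),
`homology_only` (non-empty screened-homolog set; absent homology *input*
raises an explicit evidence-unavailable error instead of silently calling
absence), `combined` (union of both evidence kinds — both are positive
evidence, homology catching remote members and domain parsing catching
non-homologous carriers). When homology input is omitted entirely,
combined families degrade to domain evidence alone; only homology-only
families refuse to be called. Domain-scan E-values are assumed already
thresholded by the scanner; an optional per-call ceiling is exposed but
off by default. The Tor family is marked `combined` in the shipped
configuration: its definition mixes a specific domain with homolog
language, and combined mode is the permissive reading consistent with
both.

## Ortholog reduction

For each family, candidate ortholog groups are those containing at least
one retrieved (screened/supporting) protein; the selected group is the
largest by **total protein member count**, with ties broken by smallest
group id — species count would be a defensible alternative, but member
count is the more direct reading of "largest group" and the tie-break
makes runs reproducible. Proteins in no group are ignored (orthology
pipelines leave singletons unassigned); a family whose proteins all fall
outside the table is reported *unassigned*, distinct from absent. A
species is present at the ortholog level iff it contributes a member to
any selected group of the family. When groups are built from the
retrieved proteins themselves, this reduction can only remove presence,
never create it — asserted on synthetic data.

## Clustering

Distances are Euclidean on the 0/1 profiles (√Hamming), the default
pairing with Ward linkage in standard tooling. Ward is computed with the
Lance–Williams recurrence on squared heights,

    d²(k, i∪j) = [(nᵢ+nₖ)d²(i,k) + (nⱼ+nₖ)d²(j,k) − nₖd²(i,j)] / (nᵢ+nⱼ+nₖ),

so a merge height equals √(2·ΔESS), the increase in within-cluster sum of
squares. Costs within 10⁻⁹ of the minimum are treated as ties and broken
by the lexicographically smallest (i, j) cluster-id pair; the tolerance
keeps the merge order stable between algebraically equivalent ways of
computing the same cost, and the rule makes runs bit-for-bit
reproducible. Flat labels are obtained by replaying the first n−k merges
with union-find, which guarantees exactly k clusters (threshold-based
cutting can merge tied heights).

The cluster number is a majority vote of three indices over k in
2..min(8, n−1): Calinski–Harabasz (max), mean silhouette (max), and a
within-cluster-sum-of-squares elbow (maximum second difference). This is
a deterministic desk-scale stand-in for a full multi-index vote across
~30 indices; the per-index table is emitted so users can inspect
disagreement, and no claim of index-level fidelity to any particular
multi-index tool is made. All-identical profiles short-circuit to k = 1
with a warning. Vote ties go to the smallest k.

## Group statistics

Counts are compared with the two-tailed Mann–Whitney U test on midranks.
For tie-free samples with n_a·n_b ≤ 400 the p-value is exact: the null
distribution of U is built by the standard counting recursion
f(n,m,u) = f(n−1,m,u−m) + f(n,m−1,u) (mathematically identical to
enumerating all rank assignments), and p = 2·min(P(U≤u), P(U≥u)) capped
at 1. Otherwise a normal approximation with tie correction and a 0.5
continuity correction is used; the two routes agree within 0.01 at the
crossover size. Group summaries report the sample SD (n−1 denominator);
a single-member group's SD is reported as 0 with an explicit note.
P-values are reported, never used to gate pipeline behaviour.

The standard contrasts are: diverged (all non-aerobic mitochondrial
phenotypes pooled) vs aerobic; parasitic vs non-parasitic; transiently
multicellular vs free-living. Custom partitions yield all pairwise
comparisons.

## Synthetic data

The generator plants a truth matrix — per species in group g and family
of category c, presence ~ Bernoulli(p[g,c]), then flipped with
probability `flip_noise` — and fabricates minimal-sufficient evidence:
exactly one satisfying protein per planted presence (the full conjunction
of one randomly chosen alternative on a single protein, a homology hit
clearing every screening threshold with 90/100 bait coverage, membership
in the family's ortholog group), plus per-species decoys (domains from a
pool disjoint from every rule, hits failing the identity threshold).
Absences emit nothing, so the pipeline round-trips the bundle to the
truth matrix exactly. One NumPy generator seeded from the config drives
all randomness.

The default cohort fixes the study conditions: 67 species in seven
lifestyle × mitochondrial-phenotype groups with marginals 31 free-living,
15 transiently multicellular, 17 parasitic, 4 symbiotic and 51 aerobic,
2 anaerobic, 2 hydrogen-producing, 6 hydrogenosome, 5 mitosome,
1 amitochondriate; per-group presence probabilities are set so expected
per-group mean gene counts match the published survey (e.g. apoptosis
0.80 for multicellular aerobes, 0.20 for mitosome parasites; necrosis 0
everywhere, as no necrosis regulator homologs were found in protists).
Default `flip_noise` is 0 and 5 decoy domains per proteome.

What the generator does **not** emulate: real sequence evolution (hits
are fabricated records, not alignments), correlated gene loss within
pathways, paralog inflation, incomplete proteome assemblies, or
domain-scan false positives that partially satisfy a conjunction. Passing
tests therefore demonstrate correctness of the pipeline's logic under
clean evidence and calibrated noise — not robustness to annotation error
in real proteomes.

## Problem sizes

The test suite and the acceptance script use desk-scale designs chosen as
representative of the cohort: 30-species two-block bundles for
round-trip and recovery studies (100 replicates for cluster recovery,
1000 for type-I calibration, 200 for power), 25 seeds for end-to-end
identity, 10,000 randomized cases for the rule-engine and screening
oracles, and brute-force Ward verification at n ≤ 7 where exhaustive
recomputation is cheap.

## Known limitations

- The boolean rule engine carries no domain order, copy-number or
  inter-domain distance constraints.
- Cluster-number selection is a 3-index vote; on weakly structured data
  the indices can disagree and the smallest-k tie-break is conservative.
- Ward on binary data inherits the usual caveat that one genuinely
  intermediate profile can be attached to the "wrong" branch even when it
  is marginally closer to its own group centroid; with planted two-block
  designs this affects roughly one replicate in ten.
- The ortholog reduction trusts the input membership table; no
  reconciliation or reciprocal-best-hit fallback is attempted.
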