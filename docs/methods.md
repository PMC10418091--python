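# Methods

## Scope and design

`mgcscan` re-implements, as a tested pipeline, a comparative-genomics
analysis built around four genomic-context rules for *mlp* gene clusters
(MGCs), SSN-based Mlp subfamily typing, Zn-site triad classification,
selenium-trait co-occurrence, and a substrate-inhibition kinetic fit.
The package is organised as one module per stage with plain functions;
the kinetics stage — the one genuinely model-fitting step — follows the
statsmodels Model/Results pattern (`SubstrateInhibitionModel.fit()`
returning a `KineticsResults` with `params`, `bse`, `summary()`).

## Coordinates and gap arithmetic

All coordinates are 1-based inclusive (GenBank convention); GFF3 input
is converted on read. Compound (`join`) locations are collapsed to
their envelope: the cluster rules reason about gene extents, not exons.
Intergenic gaps are strictly intergenic DNA, `start(downstream) −
end(upstream) − 1`, clamped to 0 for overlapping or abutting genes
(the source analysis does not state how overlaps were measured; clamping
is our choice). Origin-spanning features on circular contigs are
rejected with a clear error. CDS without translations participate in
strand and intervening-gene checks but never receive homology roles.

## Homology and statistics

Local alignments are optimal Smith–Waterman alignments under affine
gaps, BLOSUM62, with the NCBI "11/1" convention (a gap of length L costs
11 + L). Percent identity is identities over alignment columns
including gaps (BLAST convention). The aligner is Biopython's
`PairwiseAligner`; a quadratic-time Gotoh dynamic program written
independently in the test suite serves as its oracle.

E-values follow Karlin–Altschul statistics with the standard length
adjustment `l = ln(K·m·n)/H`, using the published gapped constants for
this scoring regime (λ = 0.267, K = 0.041, H = 0.14). Because E-values
scale with database size, the pipeline thresholds on **bit score**
(default ≥ 50 bits) when no effective database size is configured, and
on E-value (default < 1e-10) when one is, or when hits are imported
from a real BLAST tabular file. Two E-value thresholds circulate for
this analysis (1e-09 and 1e-10); we default to the stricter 1e-10 and
expose it as configuration. We do not attempt to reproduce NCBI
E-values bit-exactly (no composition-based statistics).

The 50-bit default sits far above the expected best local score of
unrelated ~300-aa proteins (≈20 bits under these statistics) and far
below any homolog at ≥30% identity over most of its length, so role
calls are insensitive to its exact value over a wide range.

## Cluster rules

`find_mgc_candidates` reports every *maximal* run of same-strand
core-role genes (Mlp, corrinoid protein, Ram/RACE) satisfying:

1. composition ≥ {2×Mlp, 1×corrinoid, 1×Ram/RACE};
2. no opposite-strand annotated gene overlapping the core span
   (opposite-strand genes flanking the cluster are allowed; tRNA/rRNA
   features are ignored unless `include_rna=True`);
3. at most 2,000 bp of intergenic DNA between adjacent core members,
   where base pairs covered by other annotated genes sitting inside the
   cluster do not count as intergenic DNA — so same-strand non-core
   genes may sit inside a cluster;
4. no H4folate-methylase homolog within 20,000 bp nearest-edge distance
   of any core member, measured on the same contig.

Whether the 2-kb rule was originally applied between adjacent core
genes or across the whole envelope is not stated; we chose adjacent
pairs. Overlapping qualifying windows are merged (their union always
qualifies), which is why reported candidates are maximal and mutually
non-nested. `brute_force_candidates` re-checks the four criteria
literally on every contiguous window, counting intergenic positions one
by one; equality with the fast path over thousands of random genomes is
the core correctness argument. `diagnose_window` reports which criteria
an arbitrary set of core genes fails, which is how decoy rejections are
audited.

## SSN dialect

The network stage replaces a webserver-based step with a documented
in-package dialect. Sequences are filtered to the 200–470 aa window,
dropped for internal stops or ≥10-residue X runs, collapsed into
representative nodes at ≥50% global identity by greedy single linkage
(representative = longest member; canonical (length desc, id) order
makes the result input-order invariant), and connected all-vs-all. The
edge statistic is an EFI-EST-style alignment score AS = −log₁₀(E)
computed from our own E-value with a fixed effective database size of
10⁷ residues; edges require AS ≥ 40. Repnode global identity is
`1 − edit_distance / max(len)` via edlib — exact for the
substitution-only variants the generator produces, a conservative lower
bound otherwise. Connected components define clusters; members inherit
the subfamily (Mlp1/2/3) of their cluster's references when those are
unanimous, otherwise stay unassigned, with an optional
nearest-reference fallback for sequences the filter dropped. This
preserves the thresholding semantics, not the exact scores, of the
original tool; reports flag the dialect. Reproducing the original
superfamily-wide network would require an InterPro snapshot and is out
of scope.

## Zn-site triads

The triad classifier is a pure function of three residues: (H, C, C) →
S/Se-type; H at the His site with ≥1 Asp/Glu at a Cys site →
carboxylate O-type; anything else non-coordinating (we deliberately do
not invent an O-type call for a mutated His site); a triad column that
maps to a gap, or a query with no positive-scoring alignment, →
undetermined. Queries are mapped by local alignment onto an annotated
reference (sequence + three 1-based columns, supplied as YAML). The
original triad residue numbers are not published, so the shipped
annotation is a curator-supplied synthetic example, and the pipeline's
built-in profiles are the three synthetic Mlp seeds (real analyses
should supply a characterized reference such as MtaA, which aligns to
all Mlps — the synthetic seed families are mutually unrelated, hence
one profile each).

## Selenium traits

Genome-level booleans for selA, selB, selD and glycine reductase come
from role presence anywhere in the genome; selC (tRNA-Sec) cannot be
found with protein seeds and is taken from RNA product text when
annotations carry it, but never keys the classification:
`full_machinery` = selA ∧ selB ∧ selD, `selD_only` = selD without
(selA ∧ selB), else `none`. Co-occurrence is the fraction of
type-1-positive genomes with any selenium trait; whether the published
co-occurrence statistic counted full machinery or any trait is
ambiguous, so a `full_machinery_only` switch is provided. MarHDK
proximity is reported as annotation only, never used for
classification.

## Kinetics

The substrate-inhibition form v/E₀ = k_cat·S/(K_M + S + S²/K_I) is the
standard three-parameter model consistent with reporting (k_cat, K_M,
K_I); the source does not print the equation. The fit minimises
(optionally proportionally-weighted) squared residuals over
log-parameters — enforcing positivity and taming the ill-conditioning
that appears when K_I ≫ max(S) — via Levenberg–Marquardt with 10 seeded
multiplicative restarts around a heuristic start (k_cat₀ = 1.2·max v,
K_M₀ from the rising limb, K_I₀ = 10·max S). Standard errors come from
the Jacobian covariance with a delta-method transform back to the
natural scale. `no_inhibition_detected` is flagged when fitted
K_I > 100·max(S). Default weighting is unweighted least squares (the
original weighting is unstated); fits run on relative rates — absolute
turnover would need the Δε₅₂₅ of the methylcob(III)alamin→cob(II)alamin
conversion, which must be supplied by the user. Initial rates are OLS
slopes of A₅₂₅ vs time over a window (≥5 points); isosbestic drift is
max |ΔA₄₈₅| from the initial value, a QC statistic with a
user-chosen pass threshold; fold-changes are ratios of absolute rates.

## Synthetic data: what it emulates and what it does not

The generator plants clusters with controlled gene order, strand,
intergenic gaps and per-protein identity to deterministic synthetic
seed proteins (point substitutions at seeded positions, Zn-triad
columns protected and then set to a requested triple), decoys violating
exactly one criterion each (recorded in a truth table), and background
genes with seed-pool residue composition but no seed homology. Planted
units are spaced 25 kb apart so one unit's H4folate decoy cannot veto a
neighbour. A permuted-gene-order mode checks that detection is
synteny-independent. Everything is a pure function of (spec, seed);
identical inputs give byte-identical GenBank/TSV/FASTA output.

Default study conditions used by tests and the acceptance script: 20
genomes (10 positives, 10 single-criterion decoys), identity to seed
0.6, 12 background genes per genome; kinetic design of 12 substrate
levels spanning 20–3,500 μM, 3 replicates, 3% proportional noise; 1,000
random role-annotated genomes of 20–200 genes for the rule-engine
oracle. These sizes make the whole suite run in a couple of minutes on
one CPU.

What passing these tests does **not** show about real data: synthetic
proteins evolve by uniform point substitution (no indels, no
phylogenetic correlation, no composition bias), background genes are
compositionally realistic but structurally random, and the synthetic
seed families are mutually unrelated — real Mlp subfamilies share
superfamily-level similarity, so real networks have borderline edges
the synthetic corpus does not exercise. Corpus-scale published numbers
(cluster counts across a database snapshot, superfamily network
fractions, the phylum composition) depend on database snapshots and
manual curation and are intentionally not reproduced.

## Numerical choices and degenerate inputs

Ties in role assignment break by higher percent identity, then
lexicographic seed id. Cluster candidates sort by (contig, span); SSN
cluster indices by (size desc, smallest member id). Empty inputs:
empty genome lists give empty reports; an all-dropped SSN input is
refused rather than silently empty; a zero control rate flags an
infinite fold-change. The brute-force oracle refuses genomes above 500
features. Fits raise a ConvergenceError carrying the best attempt
rather than returning silently bad parameters.

## Known limitations

No HMM/profile search, no six-frame translation, no operon prediction
beyond the stated rules, no selenoprotein (in-frame TGA) prediction, no
phylogenetic tree building, and no nucleotide-level analysis. The SSN
alignment score is a surrogate, documented above. The worked
percent-identity examples against real proteins require the user to
download two sequences (`data/reference/README.md`).
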