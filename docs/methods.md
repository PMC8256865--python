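# Methods

## The model

`fusiongrn` analyses transcriptional control in leukemias driven by a
chromosomal fusion protein (the motivating system is KMT2A-AFF1 B-cell
acute lymphoblastic leukemia). The central object is a *root-centred gene
regulatory network* (GRN): a simple directed graph whose root is the
fusion protein, whose non-root nodes are genes that respond to knockdown
(KD) of the root, and whose edges are regulator→target relations
supported either by direct binding or by a curated TF-interaction
catalog.

Construction proceeds in four steps:

1. **Regulatory scope.** Genes differentially expressed after root KD at
   FDR strictly below 0.05 define the universe of admissible nodes. The
   threshold is strict and configurable.
2. **Direct layer.** ChIP-seq peaks for the root are annotated to the
   nearest promoter (unsigned distance from the peak midpoint to the TSS,
   ties broken by lexicographically smallest gene id); each bound gene in
   scope receives a `direct` edge from the root. For an intermediate-TF
   root the regulator's peaks are first restricted to operational
   enhancers — H3K27ac peaks overlapping H3K4me1 by ≥ 1 bp — under a
   config switch; the fusion-root build uses all peaks. All coordinates
   are BED-style 0-based half-open, and "overlap" always means a
   non-empty half-open intersection (≥ 1 bp).
3. **Catalog expansion with pruning.** Catalog edges are admitted when
   both endpoints lie in scope, and the graph is then restricted to the
   nodes reachable from the root. This realizes "keep only interactions
   that explain connectivity between the root and its targets" in its
   minimal reading: since every non-root node is itself a KD-responsive
   gene, every reachable node is a genuine downstream target, and
   dead-end interior TFs cannot arise. The root participates only through
   its ChIP-derived edges; an edge supported both directly and by the
   catalog keeps the `direct` label.
4. **Annotation.** Nodes carry their KD logFC/FDR and a CRISPR
   essentiality category; edges carry a sign inferred from the
   regulator's own KD: targets that fall on KD (logFC < 0) are activated
   (`+`), targets that rise are repressed (`-`), and edges whose
   regulator has no KD table stay `unsigned`.

Peak-level normalizations follow standard ChIP practice: tag counts are
scaled to tags per 10 million, and exogenous spike-in normalization uses
α = (spike/host)input / (spike/host)IP so that equal spike:host ratios in
input and IP imply no adjustment. The exact arithmetic of spike-in
scaling is a modelling choice (only the ratio principle is standard); α
is defined so that it is scale-invariant in the raw counts.

## Centrality and in-silico deletion

Degree centrality is total degree (in + out). Stress centrality is the
Shimbel stress: for node v, the number of shortest directed s→t paths
(over all ordered pairs with s ≠ v ≠ t) whose interior contains v, each
co-optimal path counted once. It is computed by a Brandes-style
accumulation (one BFS per source, O(V·E) total) and is cross-checked in
the test suite against an exhaustive all-shortest-paths enumeration.

In-silico deletion removes a node and its incident edges *without*
re-pruning reachability, so downstream nodes remain and their stress
change is measurable. The per-gene stress fold change is

    FC(g) = log2((stress_after(g) + 1) / (stress_before(g) + 1)),

a log ratio with pseudocount 1 (both base and pseudocount are exposed);
the pseudocount keeps zero-stress genes comparable and makes the measure
symmetric around 0, matching the ±0.1 gain/loss classification
thresholds. A node's overall impact is the mean |FC| over all other
genes. Two consequences worth noting: a terminal node adjacent to the
root has zero impact, but deleting a *deeper* leaf removes multi-hop
pairs that passed through its ancestors and therefore lowers upstream
stress — "leaves are inert" holds only at depth 1.

## Motif classification

Two GRNs — fusion root A and intermediate TF B, with A binding and
activating B — are unioned. For each downstream target T: edges A→T and
B→T form a feed-forward loop; B→T alone forms a cascade; A→T alone is
excluded (tallied in diagnostics). With the A→B edge fixed as activating,
the quadrant of (logFC under A KD, logFC under B KD) determines the FFL
subtype: (−,−)→C1, (+,+)→C3, (−,+)→I1, (+,−)→I3, following the standard
FFL nomenclature with a positive X→Y edge; the map is an explicit
argument and can be overridden if a different diagram convention is
wanted. Cascades are coherent iff the two KD responses share a sign —
exactly the C1∪C3 half-plane, so the two rules are mutually consistent.
Targets that are DEGs in only one KD carry no two-regulator sign evidence
and are excluded from percentages (reported in a diagnostics bucket).
Coherence percentages are reported to one decimal and are *undefined*
(None), not zero, for an empty class.

## Patient subnetworks

A cohort expression matrix (TPM, genes × samples, each sample labelled
with its data set: ALL, AML or normal fetal bone marrow) induces one
subnetwork per sample: the GRN build is re-run with scope restricted to
the genes expressed in that sample. "Expressed" means
log2(TPM + 1) strictly above the grand mean of log2(TPM + 1) over all
entries of that sample's data set (per-data-set thresholds accommodate
scale differences between cohorts; a per-sample-mean alternative is
available by flag). The pseudocount of 1 handles zero TPM. A gene can
drop out of a subnetwork either by falling below threshold or by losing
its only path from the root; subnetwork node sets are monotone in the
expressed set.

Node presence across subnetworks gives a binary activity matrix;
per-cohort conservation is the percentage of a cohort's samples
containing the node. Activity rows are clustered with k-means (k = 5,
Euclidean, 10 restarts, fixed seed; labels renumbered by descending
cluster size for stability). Clustering operates on the raw binary
matrix; the 2-D UMAP embedding is produced for visualization only.
Always-inactive nodes are clustered with the rest and naturally form the
silent cluster.

## The synthetic study system

The generator plants: an intermediate TF B bound and activated by root
A; FFL targets per subtype (defaults C1 70, C3 46, I1 27, I3 19 — 162
FFLs, 71.6% coherent, C1 the most common subtype); B-only cascade targets
(99 coherent + 38 incoherent) plus 3 secondary "chain" TFs below B, which
are themselves coherent cascade intermediates, giving 140 cascades with
72.9% coherent / 27.1% incoherent; 45 chain-TF targets adding third-level
depth; 80 directly-bound-only targets; 30 orphan DEGs and 150 background
genes. Genes sit on synthetic chromosomes at 10 kb spacing with peaks
jittered ±300 bp around the intended TSS, so nearest-promoter annotation
is unambiguous by construction.

Every filtering stage gets nontrivial work: the root assay is generated
as a split-epitope pair (N- and C-terminal pulldowns) whose 1-bp
intersection defines root peaks, with single-assay decoy peaks that the
intersection removes; the B assay includes enhancer-free decoy peaks that
the H3K27ac∩H3K4me1 rule removes and enhancer-backed peaks at
out-of-scope genes that the scope rule removes; the catalog includes
edges from orphan DEGs (in scope but unreachable — removed by pruning)
and edges between background genes (removed by scope).

Knockdown tables give each planted target |logFC| ~ |N(μ, μ/3)| with
μ = 1.5 log2 units and the planted sign, flipped independently with
probability ε (default 0.05); DEG FDRs are U(0, 0.049), non-DEG FDRs
U(0.05, 1). Under sign-flip noise a motif is *observed* coherent iff both
signs survive or both flip, so the expected observed coherent fraction is
q = p(1−ε)² + pε² + (1−p)·2ε(1−ε); the acceptance suite checks the pooled
recovered fraction against q to 3 binomial standard errors.

The expression cohort realizes five activity programs over GRN nodes —
constitutive, leukemia-only (ALL+AML), ALL-only, AML-only, silent — with
proportions (0.25, 0.25, 0.15, 0.15, 0.20); active entries draw
log2(TPM+1) ~ N(7, 0.5) and inactive ~ N(0.5, 0.3), far enough apart that
the per-cohort grand-mean threshold separates them for any realized
active fraction. Cohort sizes default to ALL 30 / AML 40 / FBM 3 — the
small normal-marrow cohort mirrors the intended application. Dropout
silences an active entry with probability 0.05; the regulator tiers (B
and chain TFs) are exempt so that a target's activity reflects its own
expression rather than a correlated upstream disconnection, which would
otherwise couple whole-column noise across every indirect target.
Essentiality calls use two leukemia lines (MOLM-13, MV4-11) and two
non-leukemia lines (HT-29, HT-1080); flags are drawn consistently with
each gene's planted category (classification precedence: essential in any
non-leukemia line → nonspecific; else any leukemia line →
leukemia-specific; else nonessential), and B is always planted
leukemia-specific.

What the synthetic system does *not* emulate: read-level data, realistic
peak shapes and widths, overlapping/ambiguous promoter assignment,
continuous expression gradients (activity is bimodal by design), batch
effects, and correlated noise between the two KD experiments. Passing
tests therefore demonstrate correctness of the pipeline's logic and its
statistical behaviour under the stated noise models, not performance on
real sequencing data.

## Numerical and degenerate-input choices

- Strict inequalities throughout (FDR < threshold, log2 expression >
  mean), so boundary values are excluded deterministically.
- Promoter ties broken by lexicographic gene id; motif and report
  orderings sorted by target id; k-means labels renumbered by cluster
  size — all outputs are deterministic given a seed.
- logFC = 0 for a supposed DEG raises rather than guessing a sign.
- A peak on a chromosome with no promoters is recorded unannotated, not
  an error; a gene absent from essentiality calls is nonessential with a
  warning; a node absent from the DEG table during annotation is an error
  (scope-invariant violation).
- Zero spike-in or library counts raise: the normalization is undefined.
- Percentages over empty motif classes are None (undefined), never 0.

## Problem sizes

Default synthetic runs use a ~430-node, ~590-edge root GRN and a
73-sample cohort; the full test suite and the acceptance script each run
in well under a minute on one core. Stress centrality is O(V·E) per
graph and the exhaustive oracles used in tests are restricted to ≤ 12
nodes (enumeration) and ≤ 50 (closed form), sizes at which brute force is
exact and instant.

## Known limitations

- The spike-in α and the stress-FC formula are principled choices where
  only the intent (ratio adjustment; signed fold change with symmetric
  thresholds) is fixed externally; both are config-exposed.
- Pruning is pure root-reachability; alternative readings (e.g. also
  requiring paths to terminate at bound targets) would remove nothing
  under this construction but could differ on exotic inputs.
- Gene identifiers are plain case-sensitive symbols; alias resolution is
  the caller's job.
- The nearest-promoter scan is O(peaks × promoters) per chromosome,
  vectorised; adequate to ~10^5 × 10^5 but not optimised beyond that.
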