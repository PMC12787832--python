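# Methods

## Scope and model

`camnet` implements the statistical and graph-theoretic core of a
three-group multi-omics integration analysis: layer-specific differential
feature calling, the metabolomics QC/normalization cascade, enrichment
statistics, and the contraction of a differential interaction network into
a functional-module quotient graph ranked by connectivity. It deliberately
starts *after* primary quantification: inputs are feature-by-sample
matrices, an edge list, and GMT pathway annotations. Read alignment,
peptide search and peak picking are out of scope.

## Synthetic data generator

The generator emulates the study design the package targets, and its
defaults are the study conditions:

- three groups (a control and two treatment levels), n = 3 biological
  replicates per group for the transcript and protein layers, n = 6 for
  metabolites plus pooled-QC injections;
- transcript counts drawn from a negative binomial with mean/dispersion
  parameterization (var = μ + aμ²); protein and metabolite intensities
  from a mean-preserving log-normal with stated CV. The pipeline default
  dispersion a = 0.04 corresponds to ≈ 20 % biological CV at high
  abundance, matching the 0.2 CV used for the other layers;
- planted differential features carry a signed log2 effect (default ±2)
  applied multiplicatively to the test group's mean;
- QC injections are technical replicates of the pooled grand mean with a
  small CV (default 0.05); a planted "unstable" class carries a large QC
  CV (default 0.8 for general use);
- metabolite missingness is intensity-dependent: an entry's dropout
  probability decreases linearly with its fractional intensity rank,
  scaled so the overall rate matches the requested value (default 0.15).
  This makes minimum-imputation a meaningful operation rather than a
  no-op;
- the interaction network draws each feature pair independently with
  probability `intra_density` if the two features share a pathway and
  `inter_density` otherwise; edges touching the planted hub module have
  their inter-module probability multiplied by `hub_factor` (default 3);
- hub-module members are always included in every contrast's planted DE
  set, and remaining DE features are sampled with 3× weight on module
  members. Without this, the differential subnetwork would contain almost
  no annotated structure and the module network would be empty — the
  planted hub could never be recovered downstream.

What the generator does **not** emulate: correlated features (all features
are independent given their group means), batch effects and injection-order
drift, shared transcript–protein noise (the two layers are drawn
independently even though they share planted effects), compositionality of
real peak intensities, or realistic pathway overlap (generated modules are
disjoint; the contraction itself supports multi-pathway membership and is
tested on random overlapping assignments). Passing recovery tests
therefore demonstrate correctness of the *procedures* under controlled
conditions, not performance on real data.

## Metabolomics cascade

Stages are ordered and the order is enforced through a stage tag on the
matrix (raw → filtered → imputed → normalized → qc_filtered → logged);
running an operation out of order raises instead of silently reordering.
Numerical conventions:

- "detected" = non-missing and strictly positive;
- the 80 % presence boundary is inclusive (detected in exactly 80 % of
  samples is kept);
- minimum imputation is per-feature by default (global scope available) —
  the protocol phrase "the minimum value" is ambiguous, and per-feature is
  the common reading in peak-table pipelines;
- sum normalization targets a column total of 1.0 (any positive constant
  is equivalent up to the later log shift);
- QC RSD uses the sample standard deviation (n−1), the metabolomics-QC
  convention, computed after normalization and before the log; RSD exactly
  at the 0.30 threshold is retained (exclusion is strictly "> 30 %");
- log10 requires strictly positive values and fails loudly otherwise.

## PLS-DA VIP

Metabolite significance combines a two-sample t-test with a variable
importance in projection score. The model is PLS1 fitted by NIPALS on
mean-centered, unit-variance (autoscaled, ddof = 1) features against a
centered ±1 group code, with

VIP_j = sqrt( p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a ),

where SSY_a = q_a² t_aᵀt_a is the response sum of squares captured by
component a. mean(VIP²) = 1 holds identically over fitted features;
constant features are excluded from scaling and assigned VIP 0 with a
warning. The original protocol used OPLS-DA; for a two-class contrast the
VIP *ranking* from PLS-DA is the analysis-relevant output, so plain PLS-DA
is the default (2 components; an orthogonal pre-step would change scores,
not the top-ranked separating features, and is intentionally not silently
assumed). Default n_components = 2, bounded by min(samples−1, features).

## Differential rules

Per contrast (test vs reference):

| layer | rule | boundary |
|---|---|---|
| transcript | \|log2FC\| ≥ 1 and BH FDR < 0.05 | fold inclusive |
| protein | \|log2FC\| ≥ 1 and raw p < 0.05 | fold inclusive |
| metabolite | VIP > 1 and p < 0.05 | VIP strict |

log2FC = log2((mean_test + c)/(mean_ref + c)) with pseudocount c = 1 for
counts and 0 for intensities; on log10 matrices it is the difference of
group means divided by log10(2). The transcript layer runs a Welch t-test
(pooled-variance Student selectable) on log2(count+1) — a deliberate,
documented stand-in for a negative-binomial GLM, whose reimplementation is
out of scope; at n = 3 this test is conservative, and transcript recall is
correspondingly lower than what shrinkage-based count models report.
Degenerate features (zero variance in both groups, equal means) get p = 1
by convention. BH is the step-up rule fdr_(i) = min_{j≥i} m·p_(j)/j capped
at 1, computed within each layer × contrast; it is the single shared
implementation used by the enrichment module as well.

## Enrichment

Over-representation: upper-tail hypergeometric p with the universe defined
as all features present in the layer's matrix after preprocessing (the
conservative convention), sets intersected with the universe before
testing, BH across sets. GSEA: pre-ranked weighted running sum (hit
increment |s|^w normalized over members, miss decrement 1/(N−K)), ES = the
signed maximum deviation; significance by gene-label permutation,
p = (1 + #{|ES*| ≥ |ES|})/(1 + n_perm). Phenotype permutation would require
per-sample recomputation of the ranking and is not the default at this
scale. No multiple-testing correction is applied across GSEA sets by
default. Default ranking metric: log2FC.

## Module contraction and ranking

Nodes are assigned "to a specific functional module" — read as unique
assignment by default, with `unique_lexicographic` (deterministic smallest
pathway ID), `unique_smallest_set`, and `multi` policies. Contraction:
each node edge increments the weight of the module pair it spans (multi
mode: once per distinct unordered pathway pair), or the module's
self-support when both endpoints share the module; redundant (parallel)
module edges thereby collapse, and self-loops are excluded from the
displayed network but reported as self-support. Edges touching unannotated
nodes are dropped and counted, never silently lost. In unique mode the
edge mass is conserved: Σ weights + Σ self-support + dropped = node edges.

Ranking is by degree (distinct neighboring modules, the default reading of
"connectivity degree") with a weighted variant (sum of incident weights).
One consequence matters for recovery experiments: at the recovery-test
densities (8 modules × 12 nodes, inter-module density 0.05) a module pair
is connected with probability 1 − 0.95^144 ≈ 0.9994, so the contracted
graph is complete almost surely and the unweighted degree is the constant
7 for every module — it carries no hub signal at all. The planted-hub
recovery checks therefore rank by weighted degree, where the hub's ≈ 3×
cross-module support dominates robustly. On sparser inputs (such as the
differential subnetworks the pipeline actually produces) the unweighted
degree is informative and remains the default.

A brute-force pairwise-enumeration oracle (`contraction_oracle`)
recomputes the module network by scanning all node pairs per module pair;
the test suite requires exact equality on randomized instances (edges,
weights, self-support, dropped count, degrees) under both unique and multi
policies.

## Pipeline and determinism

The `camnet run` pipeline executes simulate → preprocess → differential →
enrich → network → contract with a single YAML-configurable `RunConfig`
whose defaults are the rules above. All randomness flows from one seed
through `numpy.random.SeedSequence`; artifacts are TSV/GMT/JSON with fixed
float formatting and sorted keys, so identical config + seed reproduces
byte-identical trees. Each stage writes a provenance sidecar (parameters,
feature counts, removed features); the report echoes the config and its
hash. Desk-scale default sizes (1200 transcripts, 600 proteins, 400
metabolites, 8 × 12 module structure) keep a full run in seconds while
leaving every stage's statistics non-trivial.

## Known limitations

- The transcript test is not a count model; its power at n = 3 is well
  below DESeq2-style shrinkage estimators (by design, documented above).
- VIP is computed from plain PLS-DA, not OPLS-DA; scores differ even
  though two-class rankings agree in practice.
- The RSD filter's removed set is not purely the planted unstable class
  when missingness is high: minimum-imputed QC entries can legitimately
  inflate (or deflate) a feature's QC RSD. With four QC injections the RSD
  estimator itself misclassifies borderline features; recovery experiments
  should plant the unstable class well above the threshold.
- Identifier mapping between transcript and protein layers is an explicit
  two-column table (identity by default); no orthology or isoform
  handling.
- GO DAG topology, KEGG hierarchy roll-ups, and network visualization are
  out of scope.
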