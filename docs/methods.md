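# Methods

## Scope and data model

`omicnet` analyzes paired feature-by-sample matrices — gene counts and
metabolite peak heights — from a two-level phenotype (reference level `NP`,
nonpregnant; other level `AI-P`, pregnant after artificial insemination, in
the motivating design). The `FeatureMatrix` container enforces unique
feature/sample IDs, a phenotype label per sample, and ≥ 2 samples per level;
correlation stages require ≥ 3 samples per group.

## Quality control

**Genes.** CPM(i, j) = count(i, j) / library_size(j) × 10⁶, with library
sizes taken as column sums of the *unfiltered* matrix (standard CPM
practice: filtering must not change the scale). Three filters run in order,
each removal attributed to the first failing rule: (i) all counts zero;
(ii) mean CPM < 1; (iii) "present" (CPM ≥ 1) in fewer than 50% of samples.
"Present" is not otherwise defined for rule (iii); CPM ≥ 1 is used for
consistency with rule (ii), and the threshold is configurable. The retained
set equals the intersection of the three rules, so the order affects only
the report. The filter is idempotent and order-preserving.

**Metabolites.** Per group, RSD = sd/mean (ddof = 1) of raw peak heights; a
metabolite is retained *for that group's network* when RSD ≤ 0.15
(boundary included). Retained sets may differ between groups and are kept as
group masks over one matrix. Values are natural-log transformed; peaks must
be positive (an optional +1 pseudocount accommodates zero-containing
tables). RSD is scale-free, so retention is invariant to positive rescaling.
The RSD filter is a *network-stage* stability criterion: differential
abundance and the integration stage operate on the full log-normalized
table (`metabolite_universe="pre_qc"`, the default; `"qc"` restricts
integration to the RSD-retained union).

## Differential expression

The built-in caller is a Welch two-sample t-test on log2(CPM+1) for genes
and on log2-converted abundances for metabolites, with log2FC = difference
of group means on the log2 scale. It is deliberately transparent rather than
a count-model fit; externally computed lists (edgeR/DESeq2 output, published
metabolite calls) can be loaded instead and flow through the identical
downstream contracts. Significance uses raw p ≤ 0.05 and |log2FC| ≥ 0.5
(boundaries included); a BH-FDR column is emitted for reference but not used
in calling. Sign convention: the reference (NP) group is the log2FC
numerator — positive log2FC and direction "up" mean higher expression in
NP — with `fc_direction="other-minus-reference"` to flip. Features with zero
variance in both groups get p = 1.

## PCIT network inference

For a group's samples, Pearson correlation is computed on the log-scale
matrix (log2(CPM+1) genes; log metabolites), dropping zero-variance features
with a warning. For every trio (x, y, z):

    r_xy·z = (r_xy − r_xz r_yz) / sqrt((1 − r_xz²)(1 − r_yz²))
    ε      = 1/3 (r_xy·z / r_xy + r_xz·y / r_xz + r_yz·x / r_yz)

and the edge (x, y) is **eliminated** if |r_xy| < |ε r_xz| and
|r_xy| < |ε r_yz| for some conditioning z. Numerical policy: ratio terms
whose direct correlation has |r| < 1e−12 are dropped from the ε average
(guarding division by zero); if all three terms are degenerate, or any
conditioning correlation has |r| = 1 (undefined partial), the trio is
skipped; elimination uses strict "<", so ties retain the edge; edges with
r exactly 0 are never significant. The production implementation vectorizes
over all (x, y) panels for each z (O(n³) time, O(n²) memory); a naive
triple-loop reference with identical guards is kept in the package and the
two are asserted equal on hundreds of random instances.

Behavioral note: the tolerance is an *average* of partial/direct ratios and
in practice sits near 0.5 for transitive trios, so an indirect edge is
eliminated only when it is clearly weaker than the path explaining it
(r_xz ≲ ε·r_xy). A chain with r_xy = r_yz = 0.5 and r_xz = 0.25 loses the
transitive edge; a chain with r = 0.9 and r_xz = 0.81 does not — no ε built
from these ratios can exceed r_xz/r_xy = 0.9. PCIT's advantage over plain
marginal thresholding (higher F1 at matched edge count against a known
graph) correspondingly shows in regimes with moderate partial correlations
and appreciable transitive fill-in (the regime exercised in the tests:
30-node Gaussian graphical models, precision weights 0.2–0.4, density 0.15,
200 samples); with few, very strong edges the two selections coincide.

Published-threshold filtering keeps PCIT-significant edges with |r| ≥ 0.99
(genes) or ≥ 0.90 (metabolites) that have at least one differentially
expressed endpoint; anchoring can be disabled (`require_de_anchor=False`).
Groups are analyzed separately by subsetting samples before correlation.

## Topology and differential connectivity

Degree and betweenness come from networkx on the unweighted graph of
significant edges; betweenness is Brandes' exact algorithm, unnormalized by
default (a flag divides by (N−1)(N−2)/2 for comparability with normalized
viewer output). Hub calling offers the published rule (degree ≥ 1,
betweenness ≥ 0 — which admits every non-isolated node) as `mode="paper"`,
and a practical default `mode="practical"` requiring betweenness > 0, plus a
deterministic `top_k`. The published rule as stated cannot yield the small
hub sets it reportedly produced; both modes are shipped rather than guessing
the unstated cut.

The union ("central reference") network takes the union of nodes and edges
of the two group networks, annotating each with membership ∈
{A-only, B-only, shared}. Differential connectivity is computed over the
union node set: DK_i = K_ref(i) − K_other(i) with degree 0 for nodes absent
from a network, z_i = (DK_i − μ)/σ with μ, σ the mean and population sd of
DK over all union nodes, and calls at |z| ≥ 1.96 (the two-sided 5% standard
normal point; configurable). "Gain" means more connected in the reference
(NP) network. When all DK are equal, σ = 0 and no calls are made (explicit
warning). The statistic is exactly antisymmetric under swapping the inputs.
Because z standardizes across nodes, a rewired module is detectable only
against a background of nodes present in both networks — a property worth
remembering when interpreting small networks, and the reason the synthetic
scenarios plant stable "housekeeping" modules alongside gated ones.

## Gene–metabolite integration

Targets per group are hubs ∪ differentially connected features (gain calls
are reference-group targets, loss calls other-group targets);
group-exclusive targets are the set differences. The combined-layer network
stacks log2(CPM+1) genes with log metabolites, runs PCIT on the stacked
correlation matrix per group, and keeps cross-layer edges with |r| ≥ 0.75
anchored on a group-exclusive target.

The interaction model is fit per (gene, metabolite) pair over all samples
jointly, phenotype coded 0 = reference: m = b₁ + b₂g + b₃p + b₄(g:p) + e,
by ordinary least squares with a two-sided t-test on b₄ at n − 4 residual
df. The scan shares the design matrix across all metabolites of a gene
(one batched solve per gene); singular designs (a gene constant within a
level, condition number > 1e12) are skipped with a reason. Before the scan,
genes in the lowest 5% of variance are excluded (ties at the cut retained).
The candidate grid defaults to (DE ∪ network ∪ target) genes × (DE ∪
network ∪ target) metabolites, configurable to the full matrices. The
within-group Spearman difference r_AIP − r_NP and its absolute value are
emitted per pair; selection uses the b₄ p-value (raw p ≤ 0.05, as in the
published analysis; BH column emitted), with the Spearman difference kept
descriptive. The final list is the overlap of the two routes
(evidence = "both"), with per-group sign annotated from the PCIT r.

## Enrichment

Over-representation uses the exact hypergeometric upper tail
P[X ≥ k] with X ~ Hypergeom(N, K, n) (scipy), the universe defaulting to all
features surviving QC in the relevant layer. Multiple testing uses Holm's
Bonferroni step-down: sort ascending, adjusted_(i) = max_{j≤i}
min(1, (m−j+1) p_(j)). Joint gene+metabolite pathway evidence is combined by
Fisher's method, −2(ln p_g + ln p_m) ~ χ²(4), with a missing layer
contributing p = 1 (the combination can only weaken single-layer evidence in
that case). Term clustering and topology-weighted variants of web tools are
out of scope; annotation sets are user-supplied GMT.

## Synthetic data

The generator draws gene counts through a Gaussian copula: each feature's
latent value is Σ_k λ_k f_k + √(1 − Σ λ²)·ε with shared standard-normal
module factors f_k, mapped through the negative-binomial quantile function
(size = dispersion, mean per feature/group), so marginals are exactly NB
while within-module correlation ≈ λ² on the latent scale. A module gated to
one group has its factor replaced by independent noise in the other group's
samples — rewiring without differential expression. Planted DE multiplies
the NB mean by 2^(±lfc/2) per group (log2FC positive = higher in NP).
Metabolites are log-normal: log peak = baseline + lfc·ln2 shift +
within-group sd × latent, with within-group log-sd 0.08 (RSD ≈ 8%, passing
the 0.15 filter) unless the metabolite is a planted interaction partner, in
which case log peak = b₁ + b₂·g_c + b₄·g_c·p + N(0, sd²) with g_c the
gene's centered log2 counts. Randomness is organized as named streams
spawned from one seed (`SeedSequence(seed, spawn_key=(k,))`), so adding a
downstream draw never shifts earlier ones; output is bit-reproducible.

**Default study conditions.** `planted_scenario` fixes the conditions used
throughout the tests: 300 genes, 30 metabolites; ten both-group gene modules
of eight (network background), one six-gene module gated to each group
(planted rewiring, DK = ±5 against ~80 stable nodes gives |z| ≈ 2.6);
module loading 0.95 (within-module r ≈ 0.90 — hence the scenario's network
cutoff r = 0.8 rather than the published 0.99, which belongs to the
10,832-gene, n = 6 design it came from); |log2FC| = 1 planted on module
members (so DE anchoring keeps their edges) and eight singleton genes; four
unexpressed and four near-zero genes to exercise the count filters; two
both-group and two gated metabolite modules; three gene–metabolite pairs
with b₂ = 0.5, b₄ = 1.5, noise sd 0.5 linking AI-P-gated module genes to
otherwise unstructured metabolites. NB dispersion (size) is 10 and baseline
means ~150 counts — bulk-RNA-like moderate overdispersion. Sample sizes:
n = 50/group for power-bearing checks, n = 6/group for paper-scale smoke
tests. Scoring reports TP/FP/FN, precision, recall per stage, with NaN
precision for empty predictions.

**What the generator does not emulate:** library-size variation and
composition effects, batch effects, count zero-inflation beyond NB,
GC-TOF-MS peak artifacts, missing metabolite values, and realistic bovine
expression distributions. Passing tests demonstrate the pipeline's
statistical machinery recovers planted structure under clean conditions;
they do not certify performance on real data with those artifacts.

## Numerical and reproducibility choices

Correlations are clipped to [−1, 1]; PCIT guards are described above. The
DK z-score uses the population sd (ddof = 0) so z has exactly unit sd.
Holm and BH are computed with stable sorts; hub top-k ties break by degree,
then betweenness, then node ID. All TSV output uses `%.10g` floats and
deterministic row orderings, making reruns with the same config and seed
byte-identical (asserted in the tests). Validation sizes were chosen to keep
the full suite and the acceptance script comfortably within a few minutes
on one CPU: 200 random instances (n ∈ [3, 30]) for PCIT oracle equivalence,
200 graphs ≤ 10 nodes for betweenness, 2000 null / 500 alternative fits for
interaction-model calibration, and 20 seeded end-to-end simulations.

## Known limitations

- The all-trio PCIT loop is O(n³); ~10⁴ features is hours-scale. Block
  processing keeps memory at O(n²).
- The built-in DE caller is not a count-model fit; for real RNA-Seq, supply
  edgeR/DESeq2 calls via `load_external_calls`.
- The DK z-score assumes an approximately homogeneous background; with few
  union nodes, or symmetric rewiring dominating the union, σ inflates and
  sensitivity drops.
- At n = 6 per group, correlation estimates are extremely noisy; the
  published-scale thresholds (r ≥ 0.99) are then acting as ranking cutoffs
  rather than consistency guarantees. The paper-scale smoke tests assert
  mechanics, not recovery, at that size.
- IntLIM-style scanning at raw p ≤ 0.05 over thousands of pairs admits ~5%
  false positives by construction; the PCIT overlap is what controls the
  final list.
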