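# Methods

`symbionet` implements the statistical core of a tripartite gene-expression
interaction analysis: a mite host and two bacterial symbionts — SOL, a
facultative *Solitalea*-like gut symbiont, and cTPut, an intracellular
*Cardinium* present in only some host cultures — observed as three
gene-by-sample count compartments over a 2×2×7 design (two cTPut-positive
cultures, two cTPut-negative cultures, seven replicates each).  This note
documents the models, the numerical choices, and what the synthetic
generator does and does not emulate.

## Permutation-Spearman edge calling

For each cross-compartment gene pair, rho is the Pearson correlation of
average-ranked values.  The two-sided p-value is

* exact for n ≤ 7 samples: the proportion of all n! rank permutations with
  |rho*| ≥ |rho| (the observed arrangement is one of them, so p ≥ 1/n!);
* Monte Carlo otherwise: p = (1 + #extreme)/(1 + n_perm), the standard
  positively biased estimator that is valid at any n_perm and never zero.

All pairs in a matrix share one stream of sample permutations.  Each
pair's test remains exactly valid (the null distribution per pair is
unchanged); only the *joint* distribution across pairs is coupled, which
is irrelevant for per-edge calling and makes the all-pairs scan a few
matrix products per permutation.  Edges are kept at p < α (default 0.05)
within an optional |rho| window; the hub analysis uses 0.75 ≤ |rho| ≤ 1.
Zero-variance genes are skipped with a warning rather than failing the
run — real count matrices contain all-zero genes.  Edge-level multiple
testing is deliberately *not* corrected by default (the motivating
analysis filters on raw permutation p); a BH switch exists as a clearly
labelled extension.

## Hub scores: N, S_type, S_strength

Per focal gene: `N` is the number of distinct partner genes.  In
`pathway_instance` mode every edge is expanded into one counted instance
per pathway membership of the catalog-covered endpoint — the convention
of network views that draw one node per (gene, pathway) instance — so
`S_strength` is the instance count and `S_type` the signed (+1/−1)
instance sum.  The covered endpoint is the partner when the catalog
contains it, else the focal gene, else the edge counts once (warned).
In `abs_rho` mode counted edges are distinct partners, `S_strength` is
Σ|rho| (so rho_min·edges ≤ S_strength ≤ edges), and `S_type` the signed
partner sum.  Hubs are genes with S_strength strictly greater than the
threshold (default 100).  `pathway_instance` is the default because
observed hub tables show S_strength/N ratios of 4–8, consistent with
multiplicity counting and impossible for Σ|rho| under a 0.75 cutoff.

## Distances

* **Bray–Curtis** d(i,j) = Σ|x−y| / Σ(x+y), computed on count columns; a
  semi-metric (its Gower-centred matrix can have negative eigenvalues).
* **Robust Aitchison**: Euclidean distance on robust-clr transformed
  samples, rclr(x)ᵢ = ln xᵢ − mean(ln over the sample's positive entries)
  for xᵢ > 0 and 0 for xᵢ = 0.  Zeros are excluded from the geometric
  mean and left at zero after centring — a deliberate simplification of
  matrix-completion-based robust Aitchison; it keeps the transform exact,
  deterministic and cheap, at the cost of treating zeros as "at the
  sample mean".

For per-pathway models the rclr transform is computed on the **full**
host composition and then restricted to the pathway's genes.  Applying
rclr to a pathway submatrix would re-centre every sample by the pathway
mean and cancel any coordinated same-direction pathway response — the
composition is the whole transcriptome; a pathway is a projection of it.

## dbRDA

Given a sample distance matrix D and predictor table X (centred, aliased
columns dropped with a warning):

1. Gower-centre: G = −½ J (D∘D) J.
2. Eigendecompose G; the positive-eigenvalue axes Y (classical principal
   coordinates) carry the real ordination; negative eigenvalues are
   reported separately (no Lingoes/Cailliez correction by default).
3. Project: with hat matrix H of X, constrained inertia = ‖HY‖²;
   **R = constrained / total positive inertia** ∈ [0, 1].
4. **Pseudo-F uses the trace partition of G itself** (SS_model =
   tr(HG), SS_total = tr(G)), i.e. the McArdle–Anderson sums-of-squares
   decomposition, so with one factor the F equals the classical
   PERMANOVA statistic exactly, negative eigenvalues included.  R and F
   therefore use slightly different inertia accountings when D is
   semi-metric; on Euclidean distances they coincide and R equals the
   multivariate least-squares R² to machine precision.
5. p by permuting sample rows of the predictors (equivalently permuting
   G's rows and columns), seeded; exact enumeration of all n!
   arrangements when n ≤ 7.  Since tr(G) is permutation-invariant,
   comparing SS_model suffices.
6. Site scores (CAP axes) are the principal axes of the fitted values HY.

df_model + df_residual = n − 1 always.  A saturated model (n − 1
independent predictors) is allowed at the boundary: R = 1, F undefined
(reported as inf), no permutation test.

## Forward selection

Greedy forward selection on the partial pseudo-F, permuting sample rows;
ties break toward larger marginal R, then input order; duplicated
(aliased) candidates can never enter; selection is forward-only, which
keeps it deterministic and testable.  The entry rule needs care:
requiring the best candidate's p < α per step lets noise predictors
in with probability ≈ 1 − (1−α)^k per step (≈ 87% for k = 40 candidates),
which badly overfits small-n models and distorts between-condition R
comparisons.  The default therefore applies a Šidák correction — entry
requires p below 1 − (1−α)^(1/k) for the k candidates screened that step
— which holds the familywise entry error at α per step; on pure noise the
selected set is then empty in ≈ 95% of runs.  Uncorrected entry is
available as `correction="none"`.  n_perm must resolve the corrected
level (1/(n_perm+1) below it), otherwise nothing can enter and a warning
is logged; the pathway ledger defaults to n_perm = 999, sufficient for a
40-gene candidate pool.

## Pathway ledger (dR)

For each host pathway, fit dbRDA(pathway expression distance ~
forward-selected symbiont genes) separately in cTPut-positive and
cTPut-negative samples and report R, F, df per condition plus
dR = R_with − R_without, sorted descending.  An empty selection yields
R = 0 with df_model = 0 and F undefined.  Pathways with fewer than two
genes present, or whose submatrix leaves a sample with no counts, are
skipped with a warning.  The symbiont candidate pool is an explicit
argument (default: all genes); analyses here use a fixed pool of the
first 40 SOL genes, large enough to contain signal and null candidates
while keeping the per-step screen well-posed at n = 14.

## ANOSIM, Mann–Whitney, paired t

* ANOSIM: R = (mean between-group rank − mean within-group rank)/(M/2)
  over the M = n(n−1)/2 pairwise distances, average ranks for ties;
  one-sided p by label permutation, exact over distinct labelings for
  n ≤ 7.
* Mann–Whitney: U = min(U₁, U₂); z uses the tie-corrected variance and a
  0.5 continuity correction; two-sided p exact by enumerating all
  C(n₁+n₂, n₁) group assignments when n₁+n₂ ≤ 12 (using the symmetry of
  U₁ about its mean), normal approximation otherwise.
* Between-condition comparison of per-gene correlation counts: paired t
  on genes present in both conditions (unpaired genes excluded, count
  logged), run separately for positive and negative counts.  Zero-variance
  differences return t = 0 (identical counts) or an infinite-t degenerate
  flag (constant nonzero shift) instead of failing.

## Contrasts and FDR

Per-gene condition contrasts use Mann–Whitney by default (Welch's t
optional), BH step-up q-values (q₍ᵢ₎ = min_{j≥i} p₍ⱼ₎·m/j, capped at 1)
and log2FC = log₂((mean_pos + pc)/(mean_neg + pc)) with pseudocount 1 on
standardized values.  Pathway-level contrasts sum member-gene expression
per sample first and correct across pathways.  The test used is recorded
in the result's metadata.

## Normalization

"Standardized to N reads" is implemented both ways the phrase can be
read: deterministic per-sample scaling to the target total (default —
reproducible and proportion-preserving) and seeded multinomial
downsampling (rarefaction).  The method tag travels with the matrix.
Note that per-sample scaling with unequal library sizes is *not* a
rank-preserving transform across samples, so Spearman correlations can
change under standardization; what is preserved exactly is every
sample's internal proportions.  Shannon diversity defaults to natural
log (comparisons downstream are rank-based, hence base-invariant); the
qPCR helper censors values below the detection limit (default 10 copies)
to zero before log10(x+1).

## Synthetic generator

The generator emulates the study design, not the organisms: 4 cultures
(2 cTPut-positive: 5L, 5S; 2 negative: 5Pi, 5Tk) × 7 replicates; default
compartment sizes 500 host / 200 SOL / 150 cTPut genes (scaled down from
5,838 / 1,273 to keep full runs fast; full size is a config change).
Counts come from a latent-factor Gaussian copula with negative-binomial
marginals: per sample one standard-normal factor per planted block; a
block gene's latent value is sign·λ·factor + √(1−λ²)·noise, mapped
through the NB quantile at its mean (baseline 50 reads × log-normal
library size, σ = 0.3; dispersion r = 0.5).  Two block genes with
loading λ have latent correlation λ², so Spearman-level effect sizes are
controllable; λ = 0.9 gives pair correlation ≈ 0.8.

Default planted structure: a positive host–SOL block (80×10 genes), a
negative host–SOL block (80×10), a positive host–cTPut block (40×10),
and a condition-specific positive host–SOL block (60×8) whose coupling
exists only in cTPut-positive samples.  cTPut columns are emitted only
for positive samples — structural absence, matching the study design.
SOL library sizes are multiplied by 0.6 in cTPut-positive samples (the
abundance-suppression effect; the magnitude is a free parameter, chosen
once as a plainly detectable but not extreme shift).  Host pathways are
clean 25-gene chunks plus four large "umbrella" pathways; every gene
joins two umbrellas, giving multiplicity 3 — the shape of KEGG catalogs,
where a gene has one specific pathway and several broad signalling
umbrellas.  Block and catalog sizes were fixed from a power analysis at
n = 14 (≈ 59% of planted pairs clear |rho| ≥ 0.75, so planted SOL hubs
expect S_strength ≈ 140 > 100 while null genes stay near zero).

What the generator does **not** emulate: real KEGG gene content or
annotations (pathways are synthetic partitions), overdispersion
heterogeneity across genes, compositional closure effects of deep
sequencing, batch effects, or mean-expression condition shifts beyond
the SOL library multiplier.  Passing recovery tests therefore shows the
pipeline detects controlled rank-correlation structure and
condition-specific coupling at realistic n — not that it would recover
any particular biological network.

## Reproducibility and problem sizes

Every stochastic step takes a seed; the pipeline derives per-stage child
seeds deterministically from one global seed (seed·1000003 + crc32(stage),
mod 2³¹), so full runs are byte-identical.  Test and verification runs
use the scaled-down defaults: 28 samples, 500×200 gene scans at
n_perm = 999, 10-seed recovery batches, 50-seed null batches — sizes
chosen so the whole verification suite completes in minutes on one CPU
while keeping binomial standard errors small against the bounds checked.

## Known limitations

* rclr zero handling is the simplified convention described above, not
  matrix completion; distances between very sparse samples are
  compressed.
* The permutation schemes permute raw sample rows (no residualization);
  with nuisance covariates this is only approximate.
* Forward selection p-values are entry-stage screening values, not
  post-selection inference; the reported per-model permutation p for the
  final fitted model does not account for the selection step.
* The paired-t comparison of correlation counts treats counts as
  exchangeable paired observations; heavy zero-inflation would call for
  a sign-flip test instead.
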