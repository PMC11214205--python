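# Methods

This note documents the models, algorithms and numerical choices behind
`holosel`, and what the synthetic-data generators do and do not emulate.

## Abundance processing

Rarefaction subsamples each sample's counts **without replacement** to a
common depth (multivariate hypergeometric draw), the standard way to remove
sequencing-depth differences before diversity and distance computations.
Samples below the target depth are dropped, never rescaled, and reported.
The default depth of 7000 reads/sample is the working depth typical of
genus-level 16S profiles in post-weaning pig studies.

Alpha diversity is observed richness (taxa with count > 0 after
rarefaction) and the Shannon index in **nats**; the log base is a
convention and we state ours explicitly since downstream heritability
estimates are scale-free either way.

Relative abundances are expressed in percent. The log transformation used
before genetic analyses is elementwise `ln(x + 0.01)`: the pseudo-count of
0.01 percentage points removes zeros. We deliberately do **not** use a CLR
transform by default — the pseudo-count is defined on the abundance scale
and per-taxon animal models do not require subcompositional coherence — but
the function is a one-liner to swap.

Genus filtering keeps taxa with mean relative abundance > 0.1% across
samples (interpreted as the mean of per-sample percentages; for equal-depth
rarefied tables this ranks identically to taxon-total over grand-total) and
optionally taxa with a zero fraction strictly below 50%. The 0.1% filter is
applied before the zero filter by default; the order is configurable and
immaterial for the synthetic tables we generate.

Composite selection criteria: Prevotella = Prevotella_9 + Prevotella_7 +
Prevotella; Ruminococcus = Ruminococcus + the gnavus, torques and
gauvreauii group labels. Missing member columns contribute zero and are
logged rather than raised, since annotation versions differ in which
sub-labels they emit.

## Enterotyping

The sample-to-sample distance is the square root of the Jensen–Shannon
divergence (natural log), a true metric bounded by √ln 2. Zeros are
replaced by a 1e-12 pseudo-count and the vector renormalized; this
perturbs distances far below every tolerance used in tests while keeping
Kullback–Leibler terms finite.

Clustering is partitioning around medoids implemented directly on the
distance matrix: a greedy BUILD phase followed by best-improvement SWAP
moves until no swap lowers the total within-cluster distance. The SWAP
phase never increases the objective, and for n ≤ 6 the result is verified
against exhaustive search over all medoid sets in the test suite. The
cluster number is chosen by a Calinski–Harabasz (pseudo-F) profile computed
from the distance matrix via the sum-of-squares identity
`SS = Σ_{i<j} d²_ij / n`, so no embedding is needed; a silhouette profile
would rank the same on well-separated data but CH is the index customarily
used with enterotype PAM clustering.

The stability filter repeats 2-cluster PAM (default 100×) from **random
medoid initializations** — the minimal stochastic element of the procedure,
since BUILD+SWAP is otherwise deterministic; re-drawing the rarefaction is
available as an alternative randomization. In each run the cluster with the
higher mean Prevotella(+sub-genera) + Mitsuokella abundance is labelled PM,
the other RT; a sample is "stable" when its label never changes. Ties in
the anchor comparison label cluster 1 PM (logged; never observed off
degenerate inputs).

Ordination is classical metric multidimensional scaling (PCoA, Gower
centering + eigendecomposition) via scikit-bio; negative eigenvalues are
reported, and requesting more axes than the positive spectrum truncates
with a warning.

## Pedigree and variance components

The additive relationship matrix uses the tabular method
(`a_ii = 1 + ½ a(s,d)`, `a_ij = ½ (a(j,s) + a(j,d))`), with unknown parents
treated as unrelated non-inbred founders; unknown-parent groups are not
implemented. Construction validates acyclicity and sorts
parents-before-offspring with a stable topological order. The
implementation is tested against an independent recursive
coefficient-of-coancestry oracle on random pedigrees up to 12 animals.

The univariate animal model is
`y = Xb + Z_a u + Z_c l + e`, `u ~ N(0, σ²_a A)`, `l ~ N(0, σ²_c I)`,
`e ~ N(0, σ²_e I)`, with fixed effects of sex and batch as full-rank
treatment contrasts (reference = lexicographically first level).
Restricted maximum likelihood is maximized with **average-information
updates**: at each iterate we form `P = V⁻¹ − V⁻¹X(X'V⁻¹X)⁻¹X'V⁻¹`, the
score `−½[tr(PG_i) − y'PG_iPy]` and the AI matrix `½ y'PG_iPG_jPy`. The AI
step is safeguarded to keep the restricted log-likelihood monotone: steps
are halved when they would decrease it, parameters pinned at the lower
bound (1e-10 of the phenotypic variance) with negative gradients are frozen
out of the Newton system (active set), and an EM step is the fallback.
Convergence requires at least 3 iterations and either a log-likelihood
change < 1e-8 or a relative parameter change < 1e-6; 200 iterations is the
budget, with non-convergence raised as an error carrying the likelihood
trace. Standard errors come from the inverse AI matrix, with the delta
method for `h² = σ²_a/σ²_p` and `c² = σ²_c/σ²_p`. Traits are standardized
internally and results rescaled, so estimates are exactly invariant to
affine trait rescaling. On balanced one-way designs the estimator
reproduces the closed-form ANOVA estimator, which the tests exploit as an
independent oracle.

Bivariate fits without a litter effect use an eigendecomposition of the
phenotyped-animal relationship matrix: rotating by its eigenvectors turns
the two-trait model into independent 2×2 blocks `V_j = d_j Σ_a + Σ_e`, so
the restricted likelihood costs O(n) per evaluation after one O(n³)
decomposition and is maximized directly (L-BFGS on log-Cholesky–
parametrized Σ_a, Σ_e). The genetic correlation is
`r_G = Σ_a[0,1]/√(Σ_a[0,0]Σ_a[1,1])`, clipped to [−1, 1] with a boundary
flag; its SE comes from a finite-difference Hessian on the (co)variance
scale plus the delta method. A generic dense AI-REML path over the stacked
2n system supports per-trait litter effects; the two paths agree to
numerical precision on litter-free data (tested). Bivariate fits are done
pairwise; no higher-dimensional multi-trait model is attempted.

The 0/1 enterotype label is analyzed on the observed scale with the same
linear animal model — the pragmatic treatment of a binary trait in
selection studies — and the Dempster–Lerner conversion
`h²_liab = h²_obs · p(1−p)/z²` is reported as supplementary output.

Batch precorrection for selection criteria is the residual of a
fixed-effects-only OLS fit on batch; it is used only by the simulator's
selection rules, mirroring how selection candidates are ranked in practice.

## Selection-scheme simulator

The study design: 30 founder sires × 30 founder dams produce a 316-piglet
base generation in 30 litters; each subsequent generation per line has 6
sires, 30 dams, 30 litters, with phenotyped totals 272 (133/139), 228
(114/114) and 251 (126/125) across the two lines — 1067 phenotyped animals,
matched exactly (litter sizes are a multinomial split of the
generation total).

Six traits are simulated: the four selection-criterion taxa (composite
Prevotella, Mitsuokella, Treponema, composite Ruminococcus), the enterotype
liability, and post-weaning daily gain. Genetic correlations come from a
**one-factor structure**: each trait loads on a latent PM-vs-RT axis
(defaults +0.95, +0.75, −0.95, −0.75, +0.95, +0.5) and
`r_G(i,j) = λ_i λ_j`, which is positive-semidefinite by construction, makes
opposite-enterotype primary taxa correlate at −0.90 (the ">0.9 in absolute
value" band), puts the growth–taxon correlations at ±0.375…0.475 (inside
the study's 0.32–0.52 band) and ties the liability tightly to the taxa —
justified a priori because the enterotype label is computed *from* the
composition, so its liability cannot be loosely coupled to the keystone
taxa. Default heritabilities are 0.3 for taxa and liability, 0.2 for
growth; litter fractions 0.05; sex effect 0.1 SD; four batches per
generation with effect SD 0.3, shared by both lines within a generation
(batches are rearing groups, which is also what makes the line contrast
estimable).

Breeding values follow the standard recursion: founders are multivariate
normal with covariance Σ_a; offspring get the midparent average plus a
Mendelian-sampling deviation with covariance `½Σ_a(1 − (F_s + F_d)/2)`,
with parental inbreeding tracked by an incrementally grown relationship
matrix. The enterotype is PM when the liability phenotype exceeds a
threshold fixed at the base generation's median (≈ the 50% point; the
observed 53/47 base split is sampling noise around it).

Selection follows the stated rules exactly: males ranked intra-sire-family
on the batch-precorrected primary taxon, top three kept (all, if fewer),
the best on the secondary taxon picked, one boar per sire, best six
families' picks retained; females selected litter-capped (≤2/litter,
best-per-litter first) in the first round and by mass selection later;
matings balanced (5 dams/sire) with fullsib/halfsib avoidance implemented
as "no shared parent", resolved by randomized backtracking. Both lines draw
their founders from the same base generation (HPM first, HRT from the
remainder — with opposite criteria the overlap is negligible).

**Known, deliberate property:** with this symmetric architecture the two
lines respond symmetrically, reaching ≈ 79–80% prevalence of their target
enterotype at G3 over 50 replicates (cumulative liability shift ≈ 0.8 SD,
as truncation-selection theory predicts for 6-sire within-family male
selection plus 30-of-~65 female selection at h² = 0.3). An asymmetric
realized response (one line overshooting to ~87%, the other at ~70%) is
within the between-replicate spread of single realizations but is not the
expectation of any symmetric parameterization; a per-line
selection-accuracy knob exists in the architecture (via per-line loadings)
but no asymmetric default is asserted. Non-genetic dam-to-offspring
microbiota transmission, which could amplify one line's response, is
intentionally not modelled.

## Response contrasts

Per feature, an OLS fit of
`value ~ sex + batch(generation) + generation × line` on the standardized
variable (centered-standardized and rank variants available); the
per-generation HPM−HRT difference is the line-contrast coefficient, with a
t-test on residual degrees of freedom and a Tukey adjustment using the
studentized range with the number of generation×line cells as family size.
With a balanced design and no nuisance effects the contrast reduces to the
raw difference of line means over the pooled SD (closed-form test). G3
differences sorted descending give the response ranking.

## Shotgun layer

Gene counts are normalized by gene length in kilobases; no library-size
factor is applied because group comparisons use rank tests on per-sample
**relative** profiles (each sample's normalized vector over its total),
which removes depth effects; the raw-normalized mode is also exposed. An
MGS's abundance is the mean of its (default 100) marker genes **including
zeros**, nulled when fewer than 10% of markers have a nonzero raw count —
"found" means any read, as no detection threshold is defined beyond
presence. Taxon abundances are sums of member MGS; KO abundances sums of
member genes.

Differential abundance: two-sided Wilcoxon–Mann–Whitney (exact when both
groups ≤ 8 and untied, otherwise the tie- and continuity-corrected normal
approximation), Benjamini–Hochberg q-values computed separately for the MGS
and KO analyses, Cliff's Delta `δ = (#[x>y] − #[x<y])/(nm)` as the effect
size, and a feature called enriched when q < 0.1 and |δ| > 0.7, in the
group with the larger values. Pathway over-representation is the
hypergeometric upper tail with the tested KOs as the background universe,
reported below p = 0.05.

## Synthetic-data generators

The genus-table generator draws, per sample, a multiplicative log-normal
factor per focal genus group (shared across that group's sub-genus columns
so the study's group-level SDs are matched: Prevotella 44.9±8.3 in PM vs
25.7±10.0 in RT; Mitsuokella 1.2±1.2 / 0.4±0.5; Ruminococcus 0.5±0.5 /
1.3±0.8; Treponema 1.2±1.4 / 8.7±6.5; Rikenellaceae RC9 1.8±1.1 /
5.0±2.3 — "±" values treated as across-animal SDs), independent log-normal
noise for 120 background genera whose power-law mean profile fills the
remaining mass, renormalization, and a multinomial count draw at a uniform
random depth (10k–30k). The RT background tail is flatter (exponent 1.0 vs
1.6), which realizes the higher RT alpha diversity. Renormalization biases
the realized mean of a noisy large component slightly upward (~+2
percentage points for Prevotella at its configured dispersion); this is an
inherent property of compositional noise, left uncorrected and covered by
the test tolerances. Independent per-group noise means no within-enterotype
taxon covariance beyond the compositional constraint — co-abundance network
structure is *not* emulated, so network-based analyses cannot be validated
against these tables.

The shotgun fixture plants fold-changes (default 4×) in designated PM- and
RT-enriched MGS, multiplies truth abundance × length × depth × per-gene
efficiency (log-normal) into Poisson marker counts with Bernoulli dropout,
and annotates planted MGS genes into dedicated pathways so KO and pathway
recovery are testable end to end.

`generate_study_phenotypes` is the selection simulator with selection
switched off (random one-boar-per-family sires, random dams, same mating
constraints): the recovery loop — simulate with known parameters, re-estimate
with REML — is the package's principal end-to-end test. What passing it
shows: the estimator is unbiased at the study's size and structure, with
replicate SDs of ≈0.07 for h² and ≈0.17 for r_G (taxon×growth pair). What
it does not show: anything about real-data properties the generators omit —
compositional zero inflation, taxon covariance networks, non-genetic
maternal transmission, or genotype-by-environment interaction.

## Pipeline

`holosel run` executes synth → rarefy/diversity → enterotype → quantgen →
simulate → respond → shotgun, each stage communicating through TSV files
only, and writes a JSON manifest (config snapshot, seed, SHA-256 per
artifact). Re-running with the same config and seed reproduces identical
checksums; the pipeline stops at the first stage error with a non-zero
exit.

## Limitations

* Read-level processing (primer trimming, denoising, taxonomy assignment,
  read mapping, catalog construction) is upstream and out of scope.
* The liability-threshold + one-factor correlation model is a deliberate
  simplification of "the label is a clustering of the composition"; it
  reproduces expected response directions and magnitudes, not the full
  classification geometry.
* Bivariate REML standard errors use a numerical Hessian; near-boundary
  fits (|r_G| → 1, variances → 0) report clipped estimates with a flag
  rather than profile-likelihood intervals.
* The pedigree carries only the study generations plus founders; deeper
  ancestor layers would slightly sharpen relationship resolution but are
  not reconstructible from the study design.
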