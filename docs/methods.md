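# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic generators do and do not emulate.

## Core-lipid registry

The registry catalogues 13 structures: the diethers DGD, macrocyclic DGD
and the C20/C25- and C25/C25-chain diethers, and the tetraethers GTGT-0/1,
GDGT-0…4 and GMGT-0/1. Masses are nominal [M+H]+ values at unit
resolution, anchored at DGD 653.5, GDGT-0 1302.5, GMGT-0 1300.5 and
GTGT-0 1302.5, with each cyclopentane ring removing exactly 2.0 Da (two
hydrogens). GTGT-0 is registered at the same observed m/z as GDGT-0 even
though its formula suggests a 2 Da offset; the pair — like every other
isobaric group the −2 Da/ring rule creates (GTGT-1/GDGT-1/GMGT-0 at
1300.5, GDGT-2/GMGT-1 at 1298.5) — is resolved purely by retention time,
with the class elution order DGD < GTGT < GDGT < GMGT.

Retention times in the registry are configuration, not chemistry: any
values preserving the class order are valid, and the defaults space
co-eluting isobars by ≥ 4 peak widths so identification is decided by the
assignment logic, not by luck. Macrocyclic DGD and the C25-chain diethers
carry nominal masses but appear at zero abundance in all shipped data;
they exist so the identification layer knows about them.

Response factors are per-class: 1.0 for every tetraether and 0.1 for every
diether, i.e. a response factor of 1 is assumed *within* each class and a
10-fold gap between classes, as calibrated by a 2:1 molar DGD/GDGT-0
standard.

## Quantification

Peak detection smooths each channel with a 9-point moving average for apex
finding (integration always uses the raw trace). Baseline is the raw-trace
median and noise its scaled MAD (1.4826·MAD); apexes must clear
`baseline + min_snr·noise` (default min_snr 3) in *smoothed* intensity,
which suppresses single-sample spikes because smoothing shrinks noise
roughly threefold while leaving genuine peaks (tens of samples wide)
intact. A minimum apex separation of the smoothing window merges noisy
double-tops, and a prominence requirement equal to the height threshold
rejects bumps riding on the shoulders of larger peaks. Integration is
trapezoidal between valley boundaries tightened to the first samples back
inside the noise band; on a noiseless Gaussian this recovers the
closed-form area to well under 0.5%.

Identification matches each peak's channel m/z to the registry within
`mz_tol` (default 0.5 Da, unit-resolution ion trap). Within an isobaric
group, peaks and candidate structures are matched by a small dynamic
program that preserves both elution orders while minimising the summed
|apex − nominal RT| discrepancy; more peaks than candidates on one channel
is an unresolved co-elution and raises. Unassignable peaks are returned,
never dropped.

Correction divides each area by its response factor and closes to 100%.
Detection states: no peak on a species' channel ⇒ ND; a corrected
abundance below `trace_cutoff` (default 0.05% — the literature reports
"traces" without a number, so this is our convention) ⇒ TRACE, removed
from the closure; the rest re-close to 100% as QUANT. Replicate
aggregation reports mean and sample sd (ddof 1) per species, counts TRACE
as 0 in the mean but keeps the TRACE label if any replicate was TRACE, and
marks a species ND only when ND in every replicate — also a convention,
chosen so that a sporadically detected species is never silently promoted
to a hard zero.

End-to-end, a noiseless simulate→quantify round trip reproduces any closed
composition to well under 1% absolute per component, and to under ~0.5% at
signal-to-noise 50 (tested at 3%).

## Ring Index and class totals

RI is evaluated exactly as defined in the README, with ND/TRACE terms as
zero; a profile with no quantified tetraethers has no RI (error, or a
missing value in tables). Class totals pool cyclic and acyclic variants
into dgd/gdgt/gmgt/gtgt; all diether skeletons pool into the dgd total.
PCA and clustering operate on raw proportions (matching common practice in
this literature); no log-ratio transform is applied by default, and the
closure-induced singularity of the four class totals is handled where it
matters (CCA ridge, eigenspace-aware generators) rather than hidden.

The packaged 51-strain table transcribes a published composition table
verbatim, including three rows whose printed values close only to
97.5–102.3 rather than 100 ± 0.5; the fixture loader therefore validates
closure at ±2.5, while pipeline-produced profiles are held to ±0.5. The
file's sha256 is checked at load time.

## Imputation

`impute_iterative_pca` is mean-initialised iterative PCA: missing cells
start at the column mean and are repeatedly replaced by a rank-k SVD
reconstruction about the running column means (k = 5 by default, the
component count conventionally selected for tables of this shape).
Initialisation by column means rather than random draws makes runs
reproducible without a seed. By default the retained singular values are
shrunk by the residual variance of the discarded ones
(s → (s² − σ̂²)/s, σ̂² the mean discarded eigenvalue) — regularized
iterative PCA — which stops the fit chasing noise directions; on exactly
low-rank data the shrinkage vanishes and the unregularized and regularized
variants coincide (a masked cell of a rank-1 matrix is recovered to 1e-6
and better). Convergence is declared when the imputed cells change by less
than `tol` in relative L2 norm (default 1e-4, the point at which imputed
values are stable far below any downstream sensitivity; tighten it for
exact-recovery work). Hitting `max_iter` raises an explicit
non-convergence error that carries the last iterate. In the unregularized
variant the observed-cell squared reconstruction error is provably
non-increasing and is recorded per iteration.

`multiple_impute` perturbs the observed cells with Gaussian noise of a
chosen scale, re-imputes, and reports the across-draw standard deviation
per originally-missing cell — a direct measure of how much each prediction
leans on the observed data. Data are not column-scaled before imputation.

## Canonical correlation analysis

Columns of both blocks are standardized; the canonical correlations and
weights come from the SVD of Σxx^(−1/2) Σxy Σyy^(−1/2), equivalent to the
generalized eigenproblem of the between-block covariance (the tests check
this against a brute-force eigendecomposition of Σxx⁻¹ Σxy Σyy⁻¹ Σyx to
1e-8). A singular within-block covariance raises with a suggestion to pass
`ridge` (ridge·I added to both block covariances); closed compositional
blocks always need it, and 1e-8 is ample. The reported correlation table
is the plain Pearson cross-correlation of each lipid variable
(dgd/gdgt/gmgt/gtgt/ri) with each environment variable — not the canonical
structure coefficients, which are also derivable from the returned
weights — starred by a two-sided t-test at p < 0.05 (*), < 0.01 (**) and,
as the natural extension of that ladder, < 0.001 (***). No
multiple-testing correction is applied.

## Clustering and tree congruence

Composition trees use Euclidean distance on class-total percentages with
average linkage (defaults chosen as the most conventional pairing; both
are configurable), rows sorted lexicographically first so ties break
deterministically, and branch lengths of half the merge-height difference
(ultrametric output). Tree congruence is the Robinson–Foulds symmetric
difference normalized by the total number of non-trivial bipartitions in
the two (unrooted) trees, so 0 = identical topology, 1 = no shared
internal split.

## Trait inference

The parsimony rule upgrades *unknown* to *assumed* within a rank group
containing at least one *observed* producer of the same lipid class;
*absent* and *observed* are never modified, making the rule monotone and
idempotent. The rank is caller-chosen (genus default, order available) —
the coarser application covers cases where evidence sits in a sister
genus. Membrane categories from compositions use a 1% diether threshold
for "trace amounts" (the literature gives no number); from ability flags,
observed/assumed counts as present. Category medians are standard midpoint
medians with per-variable NaN skipping. Ancestral composition averages the
dgd and pooled-tetraether totals over a caller-supplied basal-species
list; nearest-ten rounding is half-away-from-zero.

## Synthetic data: what it emulates, what it does not

* **Chromatograms** — Gaussian peaks of configurable width on the
  species' m/z channels over a scan range of m/z 600–2200, peak area =
  molar fraction × response factor × total signal, plus (optionally) a
  constant detector offset of 5·noise_sd and additive Gaussian noise
  clipped at zero. Not emulated: retention-time drift between runs,
  tailing/fronting peak shapes, correlated (1/f) detector noise, ion
  suppression, isotope envelopes. Passing round-trip tests therefore shows
  the integration/assignment logic is correct, not that real instrument
  drift is handled (RT alignment is explicitly out of scope).
* **Replicates** — logistic-normal compositional noise (perturb logs,
  re-close); published per-strain sds constrain magnitude but not the
  noise law, so the law is a modelling choice.
* **Environment/lipid blocks** — `simulate_env_lipid` plants shared
  latents so the *population* canonical correlations equal the requested
  values exactly; `attach_env_columns` builds growth/environment variables
  around an existing lipid matrix with requested Pearson correlations
  (default targets: optimal temperature vs dgd −0.46, gdgt +0.34, ri
  +0.23; depth vs dgd +0.20; in-situ temperature vs gmgt −0.41; optimal
  NaCl vs gmgt −0.54; pH and the ion columns Sr/Fe/Mn/H2S free). Because
  class totals are closed, a full arbitrary correlation vector is
  infeasible — only the listed pairs are controlled and the rest follow
  from the compositional geometry. Missingness is MCAR on the environment
  block only; real missingness is structural (whole vents unmeasured), so
  MCAR results bound, not reproduce, that situation.
* **Survey** — 440 species in three membrane categories with growth
  optima drawn symmetrically around the category medians
  (tetraether-dominant 80 °C / pH 3.6 / 0% NaCl; mixed 80 / 7.0 / 2.3;
  diether-only 38 / 7.3 / 20.0). The diether-only count (255) pools the
  halophiles with the few diether-only methanogens and *A. pernix*; the
  140/45 split of the remaining mixed-lipid species between the mixed and
  tetraether-dominant categories is our choice — only the total (185) is
  constrained by the surveyed literature.
* **Cohorts** — `simulate_thermococcales_cohort` bootstraps the packaged
  51-strain class totals with logistic-normal jitter (dispersion 0.15), so
  synthetic cohorts inherit the real marginal distribution, including the
  strong dgd/gdgt trade-off, at any sample size (acceptance runs use
  n = 1000 with five replicate cohorts, sized to hold Monte-Carlo error on
  a correlation near ±0.02 while staying fast).

## Known limitations

* No absolute quantification (per cell mass) and no retention-time
  alignment across injections.
* The Pearson-vs-canonical-structure ambiguity in how lipid–environment
  correlation tables are conventionally presented is resolved in favour of
  Pearson; both are computable from the returned object.
* Imputation quality degrades, as for any low-rank method, when columns
  are nearly independent; the multiple-imputation sd is the honest report
  of that uncertainty.
* The genus-level parsimony rule is a heuristic: it encodes taxonomic
  conservatism of lipid biosynthesis, not pathway genomics.
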