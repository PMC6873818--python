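# Methods

## Model and procedure

The package compares a protein's elution profile between a control and an
RNase-treated size-exclusion separation. Profiles are PSM counts over N
fractions, on a fraction grid that must match exactly between conditions:
the score is a fraction-by-fraction comparison and no cross-grid
resampling is defined (resampling would silently change every score).
Counts are accepted as non-negative reals so normalized matrices flow
through the same path. A protein detected in only one condition keeps an
all-zero profile in the other and attains the maximal score of 2; such
proteins belong to the abundance-gain/loss signal classes and must stay in
the analysis.

**Score.** D_p = Σᵢ|X_pᵢ − Y_pᵢ| and D_p^norm = 2·D_p/(ΣX + ΣY). The
normalization maps onto [0, 2] with 2 attained exactly on disjoint
support. Proteins with zero total abundance in both conditions are flagged
undefined and excluded downstream rather than raising. No smoothing or
noise filtering is applied to profiles before scoring.

**Empirical null.** D^norm shrinks with abundance (Poisson counting noise
is relatively larger for low-count proteins), so a global null would be
badly miscalibrated. Each protein is therefore tested against the scores
of proteins at neighboring abundance ranks. The pool is every protein with
a defined score and no prior literature RNA annotation, ordered by mean
abundance (mean of the two condition totals) descending, ties broken by
protein ID for determinism. The window spans pool ranks [r − s, r + s]
(s is a half-width, default 100, so 201 members); at the pool edges the
window extends inward to preserve its width, and a pool smaller than
2s + 1 degenerates to the whole pool. A protein in the pool occupies its
own rank and its own score is excluded from its window (an extreme scorer
must not inflate its own null); an annotated protein is slotted at the
rank its abundance would give it.

**Mixture model and selection.** The window's scores are modelled as a
mixture of a non-RNA-associated bulk and a possible RNA-associated tail.
Both a one- and a two-component Gaussian mixture are fitted; the
two-component model is accepted only when its BIC is no worse, the
lowest-mean component carries the largest weight, and that weight reaches
t_weight. t_weight estimates the fraction of non-RNA-binders in the
proteome; practice puts it between 0.6 and 0.75 and the default is the
midpoint 0.7. When accepted, the lowest-mean component is the null;
otherwise the single Gaussian is.

**Calling.** Z = (D^norm − μ)/σ, p from the standard-normal survival
function, Benjamini–Hochberg correction across all proteins with defined
p, and `significant ⇔ q < alpha` (default 0.05, strict inequality).
Within one fitted window, p is strictly decreasing in D^norm, so rankings
are preserved.

**Shift classification.** The elution position is the PSM-weighted mean
fraction index (1-based). shift = w_control − w_treated: SEC elutes large
assemblies first, so movement to later fractions (loss of apparent
molecular weight) is negative. d_abundance = (ΣY − ΣX)/(ΣY + ΣX) ∈ [−1, 1],
positive for a solubility gain on treatment. Signs map to the four signal
classes; exact zeros are kept as their own "none" label rather than being
folded into a side, because exact ties occur in integer count data and are
worth tracking. By default only significant proteins are classified, with
a flag to classify everything.

**Complex calls.** Curated and computational complex sets are merged
non-redundantly: only complexes with identical membership (Jaccard
coefficient exactly 1.0) are collapsed, curated (CORUM) representative
kept; near-duplicates both survive. A complex is an RNP when strictly more
than half its subunits carry evidence from the union of three sources
(significant differential call, high-throughput annotation, low-throughput
annotation) — exactly half fails. RNP Select additionally requires mean
pairwise Pearson r > 0.75 among detected subunits in the control sample
and a strict subunit majority at a relaxed threshold, applied to the
FDR-corrected p-value (q < 0.5) for consistency with the headline 5%
cutoff; the inequality direction is exposed as a switch
(`relaxed_is_upper_bound`) because a lower-bound reading also circulates.
Subunits absent from the elution data are excluded from the co-elution
mean but stay in the denominator of every majority rule: the rules are
about the complex's full subunit list.

## Tunable parameters

| name | default | unit | meaning |
|---|---|---|---|
| `s` | 100 | pool ranks | abundance-window half-width (window = 2s+1) |
| `t_weight` | 0.7 | — | minimum weight of the null component for two-component acceptance |
| `alpha` | 0.05 | — | FDR threshold for significance calls |
| `r_min` | 0.75 | — | co-elution gate (mean pairwise Pearson r) for RNP Select |
| `p_relaxed` | 0.5 | — | relaxed per-subunit q threshold for RNP Select |
| `min_mean_abundance` | 10 | PSMs | abundance filter for set-overlap reporting |
| `n_restarts` | 3 | — | EM restarts per window |
| `seed` | 0 | — | seed for all stochastic fitting |

## Numerical choices

The windowed fits are the runtime bottleneck (thousands of windows of
~200 points each), so the one-dimensional EM is authored here and
vectorized across all windows at once: windows are padded and masked into
a (windows × restarts, window-size) batch, and a single EM loop iterates
all of them, dropping converged rows from the working set. The
one-component fit is closed-form. Initialization uses a deterministic
quantile start (component means at the window's 25th/75th percentiles)
plus random window members for the remaining restarts; restarts follow a
short-run EM scheme — every restart gets a 50-iteration burn-in and only
the best-likelihood restart per window continues to convergence
(tolerance 1e-6 on the mean per-point log-likelihood, 500 iterations
total cap). With the quantile start, additional restarts essentially
never change a call in one dimension, so the default is 3. Variances are
regularized by 1e-6 in every M-step (matching common practice) and BIC
uses 3K − 1 free parameters for K components; the fits agree with
scikit-learn's `GaussianMixture` to optimizer tolerance, which the test
suite checks as an independent cross-reference. Zero-variance windows are
flagged degenerate (undefined p) and σ is floored at 1e-6 everywhere so
Z stays finite. BH correction is delegated to statsmodels and verified
against a brute-force step-up oracle in tests.

Pearson correlations for co-elution skip pairs where either profile is
constant (correlation undefined); a complex with fewer than two detected,
variable subunits has undefined co-elution and cannot enter RNP Select.
Molecular-weight calibration fits log10(kDa) against fraction position by
least squares; non-monotonic standards warn but still fit.

## The simulator

`simulate_pair` emulates a 50-fraction SEC separation of a few thousand
proteins: per-protein total abundance is log-normal (log-mean 3.5, log-sd
1.0; median ≈ 33 PSMs with a heavy right tail), elution peaks are
Gaussians with centers uniform over the gradient and widths uniform in
[1.5, 4] fractions, truncated at the grid edges with mass renormalized so
every protein keeps its drawn abundance in expectation. Observed counts
are Poisson draws (optionally gamma-Poisson via an overdispersion knob,
since real spectral counts are overdispersed). A configurable fraction of
proteins (default 10%) is truly RNA-associated: their treated peak moves
by U(10, 15) fractions, 80% of the time toward later fractions (the
dominant direction — RNA loss mostly shrinks assemblies), and their
treated abundance is rescaled by a log-normal(0, 0.25) multiplier. A
small per-condition jitter on the peak center with sd 2/√abundance makes
low-abundance nulls noisier than abundant ones — precisely the abundance
dependence the windowed background exists to absorb.

Planted complexes occupy disjoint blocks of proteins that share one
elution template (center noise sd 0.25 fractions) and, when flagged as
true RNPs, shift coherently. Planted subunits get an abundance floor of
50 PSMs: the planted complex emulates a detectably co-eluting curated
complex (curated databases skew toward abundant proteins), and two
Poisson profiles sharing a template at 10 PSMs correlate at only r ≈ 0.5 —
no analysis could see such a complex co-elute. The floor applies equally
to true-RNP and decoy complexes.

What the simulator does **not** emulate: chromatographic carryover between
fractions, peptide-level identification noise and protein inference
ambiguity, multi-peak elution (proteins in several assemblies), RNA
species identity, and correlated abundances between conditions beyond the
shared peak. Passing calibration and power tests on these simulations
therefore shows that the statistical machinery behaves as designed under
its own assumptions — not that real experiments meet those assumptions.

## Problem sizes used in the checks

Calibration and power checks run at 2,000 proteins × 50 fractions over 20
fixed seeds (tests) or seed-derived replicates (acceptance script, 5–10
replicates per quantity); complex-recovery checks run at 600 proteins with
twelve planted complexes (six true, six decoys) per seed. These sizes give
stable rates while keeping a full run of the suite in a few minutes.

## Known limitations

- The empirical null is estimation-noisy: on 10%-true simulations the
  realized false-discovery proportion at alpha = 0.05 averages ≈ 0.06 over
  seeds, but single seeds occasionally reach ≈ 0.19 when a window's
  mixture fit underestimates the null spread. The q-values should be read
  as calibrated on average, not per-experiment guarantees.
- With very small pools (fewer than ~50 unannotated proteins) every window
  degenerates to the whole pool and the abundance conditioning is lost.
- The two-component null assumes the window's non-RNA bulk is
  approximately Gaussian on the D^norm scale; heavy-tailed nulls inflate
  significance and are only partially absorbed by the tail component.
- Complex-level calls inherit the completeness and granularity of the
  input complex definitions; no de novo complex discovery is attempted.
- The apo-stable / structural / compositional taxonomy of RNP complexes is
  descriptive (derivable per subunit from the shift table), not an
  automated classifier.
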