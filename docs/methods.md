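# Methods

## Synthetic data model

Each subject's scan in each condition is drawn as `n_timepoints`
independent samples from a zero-mean multivariate normal over the atlas
nodes. The correlation matrix has `rho_within` (default 0.3) inside each
network and `rho_between` (default 0.05) across networks — values typical of
parcellated resting-state data after denoising. The DMN is split into two
hidden sub-communities; in the drug condition each (sub-community, target
network) pair in the effect map has its cross-block correlations shifted by
a subject-specific delta drawn from N(delta, sigma_delta²). The shifted
matrix is projected to the nearest positive semi-definite correlation matrix
by eigenvalue clipping at 1e-10 followed by re-normalisation to unit
diagonal; clipping (rather than rejection) keeps the generator total and
deterministic. A tiny ridge (1e-9 on the diagonal) then guarantees the
Cholesky factorisation used for sampling.

Two presets ship:

| preset | nodes | networks | DMN split | subjects | timepoints | planted deltas |
|--------|-------|----------|-----------|----------|-----------|----------------|
| `toy`  | 60    | 5 (incl. 4 unassigned) | 20 = 8 + 12 | 12 | 120 | −0.3 on sub1×{TargetA, TargetB}, +0.3 on sub2×TargetC |
| `paper`| 300   | 14 (incl. 12 unassigned) | 65 = 28 + 37 | 55 | 234 | −0.15 on sub1×{somatomotor-dorsal, cinguloopercular, auditory}, +0.15 on sub2×parietomedial |

The `paper` preset mirrors the geometry of a published 300-ROI atlas study
(TR 2 s, 55 participants); the community sizes are used purely as a size
template. Because effect sizes in correlation units are not reported for
such designs, the deltas were chosen once for reliable desk-scale recovery:
at 234 timepoints band-passed to ~78 effective degrees of freedom, a 0.15
shift gives edge-level paired *t* around 6, comfortably above the FDR
threshold without being trivial.

**Between-subject heterogeneity.** `sigma_delta` defaults to 0.1 — two
thirds of the mean effect. The choice is forced by self-consistency: the
per-subject change score carries irreducible single-session measurement
noise of roughly 0.06–0.09 Fisher-Z units (shared node-signal noise across
a block of edges), so a scenario in which individual differences in drug
response are observable at all — which the emulated design's brain–behavior
correlations presuppose — requires subject-level spread at least comparable
to that noise floor.

**Behavioral coupling.** BIS-11 totals are generated as
`intercept + beta · (delta_i − mean delta) + N(0, noise_sd)`, rounded and
clipped to [30, 120], then partitioned into the attentional (8 items),
motor (11) and non-planning (11) subscales by largest-remainder rounding so
the subscales sum exactly to the total. `behavior_beta_for_correlation`
converts a target generating correlation into the slope; the presets use
r = −0.4 (higher impulsivity ↔ stronger connectivity decrease), matching
the magnitude such studies report at n ≈ 55. Noise SD defaults to 6 score
points, a plausible residual spread for a 30-item questionnaire.

**Temporal structure.** Timepoints are i.i.d. by default; an optional AR(1)
flag (`ar_coefficient`) adds smoothness. The analysis consumes only
correlations, so white series keep the generator exactly analysable. The
cost of this simplification is that band-pass filtering, which on real data
removes drift and physiological noise, here only discards information: the
0.008–0.09 Hz band at TR 2 s retains ~⅓ of the spectrum, shrinking the
effective sample per correlation from ~231 to ~78. The end-to-end pipeline
checks (fractionation, stability, sign recovery) keep the full chain
including the filter; the module-level behavioral-coupling recovery check
runs without it, since on white series the filter is a pure information
sink and the check targets the coupling estimator, not the filter.
Consequently, passing tests demonstrate recovery under idealised noise; they
do not speak to motion artifacts, hemodynamic confounds or scanner drift,
which are out of scope.

## Preprocessing

Order: confound regression → linear detrend → band-pass, all linear maps.
Confound regression takes least-squares residuals on [intercept |
confounds], raising a rank-deficiency error that names collinear columns; a
helper supplies backward-difference derivative regressors (first element 0).
The band-pass is an ideal boxcar on the discrete Fourier spectrum —
frequencies strictly above the low edge and up to (inclusive) the high edge
are kept, DC and Nyquist always removed. A boxcar was chosen over e.g.
Butterworth because downstream correlations are phase-insensitive and the
boxcar is exactly testable (in-band sinusoids preserved to ≥99% power,
out-of-band suppressed to ≤1%); any linear filter honouring the band would
be equally valid.

## Connectivity

Pearson correlations over assigned (non-unassigned) nodes, Fisher-Z
transformed with |r| clamped to 1 − 1e-7 so degenerate correlations stay
finite. The diagonal is stored as 0 and masked undefined; zero-variance node
series have their edges masked (with a logged warning) rather than dropped,
preserving matrix shape across subjects.

## Group statistics

Edge-wise paired *t* uses the closed form `t = mean(d) / (sd(d)/sqrt(n))`
with an n − 1 denominator in the SD and two-sided p-values from the
t-distribution (cross-checked against `scipy.stats.ttest_rel` to 1e-10).
Zero-variance differences are flagged undefined and excluded from the FDR
family. BH-FDR (via `statsmodels.multipletests`, validated against a
literal step-up implementation) is applied once, jointly, across all
DMN × other cells. Network-wise, overall and sub-network tests are
one-sample *t*-tests on the surviving per-edge **mean differences**
(df = edge count − 1), matching the degrees of freedom such analyses
report; testing per-edge *t*-values instead is available behind
`use_t_values`. The Bonferroni factor is always computed from the
parcellation (target networks, × sub-network count for sub-network tests),
never hard-coded.

A caveat worth stating: one-sample tests on FDR-selected edges inherit
selection bias — surviving edges have inflated, same-signed means, so
networks with a handful of spurious survivors can show extreme *t*-values.
The pipeline reports surviving-edge counts alongside every test so such
cases are visible; on the synthetic scenarios the planted networks dominate
by two orders of magnitude of edge count.

## DMN fractionation

**Graph construction.** Each DMN node's profile is its row of paired *t*
statistics with non-surviving cells zeroed (profile source and masking are
configurable). Node similarity is the **uncentered cosine** of the two
profiles. Cosine rather than centered (Pearson) similarity is essential to
the structure being sought: the two sub-communities respond on *disjoint*
target-network column sets, and centering links disjoint-support profiles of
opposite mean sign positively (cov = −x̄·ȳ > 0), collapsing the graph into
a single positive block whose optimal partition is one community. Cosine
gives ~0 weight to disjoint responses and negative weight to genuinely
opposite ones, which is exactly the signed structure modularity can split.
Pearson similarity remains available (`similarity="pearson"`).

**Quality function.** The signed modularity treats positive and negative
weights asymmetrically: Q = Q⁺ − (v⁻/(v⁺+v⁻))·Q⁻, each part a Newman
modularity of the corresponding weight layer with resolution γ (sums include
i = j; for all-positive weights this reduces exactly to Newman weighted
modularity). Internally the optimizer works on the modularity matrix B with
Q(partition) = Σ same-community B<sub>ij</sub>; B aggregates exactly under
block summation, which raw signed weights do not (their positive and
negative parts mix).

**Optimizer.** A seeded Louvain-style procedure: greedy single-node moves in
random order (candidate targets are all occupied communities plus one empty
community, so splits are reachable; ties break to the lowest label),
alternating with community-level moves on the aggregated matrix, a
best-first Kernighan–Lin refinement (force the best move of each node at
most once, backtrack to the best prefix), and randomised forced sweeps that
cross barriers the deterministic pass cannot. `louvain_signed` returns the
best of 4 internally derived restarts; the whole procedure is deterministic
given its seed. Against an exhaustive set-partition oracle on random signed
graphs of ≤ 8 nodes it attained the global optimum in 400/400 instances
during development; the suite asserts ≥ 49/50.

**Stability.** `stability_analysis` repeats the optimisation with distinct
derived seeds, computes all pairwise NMI values
(NMI = 2·I(A;B)/(H(A)+H(B)), natural logs, defined as 1 when both
partitions are single-community) and returns the highest-Q partition as
consensus (first found wins ties). On planted structure every run agrees
(min NMI = 1); on i.i.d.-noise graphs runs disagree, which is what makes
the probe informative. The γ-sweep runs one optimisation per resolution on
a 0–10 grid (step 0.1 by convention) and reports NMI against the γ = 1
partition and the community count without asserting any threshold; γ = 0
degenerate all-in-one outcomes are reported, not suppressed.

## Brain–behavior correlation

Change scores average the per-subject Fisher-Z difference over the
FDR-surviving edges of each (node set, target network) pair — whole DMN and
each sub-network; averaging over surviving edges only is the default, all
edges being the obvious alternative. Pearson r with two-sided
t-approximation p (df = n − 2) is computed against the BIS-11 total and each
subscale; uncorrected p and BH q across the reported family are emitted side
by side, and by default the correlations are restricted to the networks the
group-level tests flagged significant. Estimated coupling is attenuated
relative to the generating correlation by the measurement-noise factor
σ_δ/√(σ_δ² + σ_m²) ≈ 0.8–0.9 at study scale — visible in the recovery
metrics as `behavior_r_estimated` vs `behavior_r_generating`.

## Pipeline and determinism

One master seed; per-stage seeds are derived by SHA-256 of
`"{seed}:{stage}"` reduced mod 2³¹, so stochastic stages are isolated.
Reports are JSON with sorted keys; identical config + seed reproduces them
byte for byte. Stage inputs are validated up front (fail fast with the full
list of missing items), and all on-disk formats are TSV/JSON with floats at
17 significant digits, so write→read round-trips are exact.

## Problem sizes in the test suite

The suite exercises the toy preset for unit-level checks and the `paper`
preset for the end-to-end ones: one full study-scale run with 100 stability
iterations, 20 seeds of planted-partition/sign recovery, and 50 seeds of
behavioral-coupling recovery; the oracle-equivalence check uses 50 random
graphs of ≤ 8 nodes and the FDR checks 1000 random vectors plus 200
full-null replicates. The 1000-iteration stability convention is a config
knob (`iterations`); 100 is used in tests and the acceptance script.

## Known limitations

- The generator omits hemodynamics, temporal autocorrelation (unless the
  AR(1) flag is set), motion, and scanner noise; recovery results bound
  what the pipeline can do under idealised conditions only.
- PSD projection of the shifted correlation matrix slightly perturbs
  off-target blocks, so a handful of non-planted edges carry real but tiny
  effects; at the default scenario these survive FDR occasionally and are
  visible as small extra networks in the network-wise table.
- The row-profile-similarity graph is one defensible reading of how a
  rectangular difference matrix becomes a square graph; alternatives
  (e.g. similarity on unmasked profiles or mean differences) are exposed as
  options but not separately validated.
- Sub-network inference reuses edges selected by the whole-matrix FDR step;
  p-values are conditional on that selection.
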