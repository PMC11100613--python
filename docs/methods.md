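# Methods note

This note records the models, parameter defaults (with units and rationale),
the scope of the synthetic generator, numerical choices, and known
limitations. Every quantitative statement here is either a model definition
or a value computed by the test suite / acceptance script.

## 1. Natural-abundance correction (`metamech.isotopes`)

**Model.** For a metabolite with `n` correctable atoms of the tracer element,
the observed mass-shift spectrum is `raw = M x`, where `x` is the true mass
isotopologue distribution (MID) and column `i` of `M` is the distribution of
observed shifts for a molecule carrying `i` tracer-derived labels: binomial
label *loss* with probability `1 − π` over the `i` nominally labeled
positions, convolved with binomial natural-abundance *gain* with probability
`p` over the `n − i` unlabeled positions.

| parameter | default | units | rationale |
|---|---|---|---|
| `p` (natural abundance) | 0.0107 for ¹³C, 0.000115 for ²H | probability/atom | standard isotope abundances of the tracer element |
| `π` (tracer purity) | 1.0 in correction; 0.99 typical commercial tracers | probability/position | purity certificates of U-¹³C tracers |
| residual flag threshold | 0.05 | relative L2 misfit | spectra outside the feasible cone usually indicate a wrong atom count or a co-eluting contaminant |
| negative clamp | 1 % of spectrum max | — | baseline-subtraction artifacts are clamped with a warning; larger negatives are rejected as corrupt |

Only the tracer element is corrected; heavy isotopes of other elements are
assumed resolved away by high-resolution MS. `M` is inverted by non-negative
least squares (`scipy.optimize.nnls`) and the solution renormalized to sum 1.
NNLS rather than a direct solve keeps fractions non-negative under noise; the
two coincide whenever the unconstrained solution is feasible (verified on
1000 random MIDs, `n ∈ [1, 30]`, round-trip L1 ≤ 1e−6). Note that `M` is
lower-triangular only at `π = 1`; purity loss puts mass above the diagonal.

**Labeling summaries.** `fractional_enrichment` is the atom-level labeled
fraction `Σ i·f_i / n`; `labeled_fraction` is the molecule-level `1 − f₀`.
Complementation sums use fractional enrichment (a per-atom, tracer-additive
quantity); this choice is declared here because the two differ for partially
labeled pools.

## 2. Tracing indicators (`metamech.tracing`)

* **Anaplerosis**: `f₃/(f₂+f₃)` of 4-carbon malate from U-¹³C₆-glucose
  (M+2 via pyruvate dehydrogenase + citrate synthase, M+3 via pyruvate
  carboxylation / malic enzyme). The undefined case `f₂+f₃ = 0` is flagged,
  not NaN-propagated.
* **Reductive carboxylation**: citrate M+5 from U-¹³C₅-glutamine, with
  malate/aspartate M+3 as re-entry markers. Requires the glutamine tracer.
* **Complementation**: per-metabolite FE from glucose and glutamine tracers;
  "fully compensated" when the treated-vs-control FE-sum difference is within
  0.05 (an absolute tolerance on a [0, 1] quantity, chosen as roughly the
  replicate-level FE noise at the generator's 5 % spectrum CV).
* **Acetyl deconvolution**: citrate modeled as acetyl (2C) ⊗ OAA (4C), with
  the measured aspartate MID as the OAA proxy. The acetyl MID minimizes the
  L2 misfit over the probability simplex (SLSQP, uniform start, `ftol`
  1e−14); 500 random forward-model pairs are recovered with L1 ≤ 1e−6.
  Residual > 0.1 flags a model violation. *Limitation:* aspartate is used as
  the OAA proxy without modeling symmetry scrambling at fumarate, and the
  citrate pool is assumed to be a single well-mixed condensation product.

## 3. Differential signatures (`metamech.signature`)

Fold-changes are ratios of geometric means (treated over vehicle); tests are
Welch's unequal-variance t on log intensities; q-values are
Benjamini–Hochberg across the features of a profile (statsmodels). Zero
variance is guarded: identical constant groups give t = 0, p = 1; constant
but different groups give a capped statistic with a note. Non-positive
intensities are floored at half the smallest positive intensity
(detection-limit convention) and counted.

**Classifier.** `fasn_inhibition` requires, for each of malonate (≥10×),
succinate (≥2×), malonyl-CoA (≥2×), succinyl-CoA (≥1.2×): top-dose fold above
threshold, q < 0.05, and a positive Spearman dose trend. The fold thresholds
sit roughly an order of magnitude below the effects the generator encodes, so
the call is robust to sampling noise without being trivial.
`complex_i_like` requires the mean expected-direction log2 effect over a
13-marker panel (NADH/NAD+, G3P, lactate, pyruvate up; TCA pools and CoA
esters down) to exceed 0.5 (≈1.4-fold average move) while malonate stays
below 2×(the veto that separates the two mechanisms). Everything else —
including profiles missing markers — is `indeterminate`. Null calibration:
over 200 vehicle seeds the q < 0.05 rate stays within 2 MC-SE of 0.05 and
the classifier is indeterminate in ≥ 99 % of seeds (acceptance criterion 8).

Profile similarity is Pearson correlation over shared finite features (≥ 10
required); clustering is average linkage on `1 − r` with labels sorted for
determinism.

## 4. Kinetics (`metamech.kinetics`)

**Exometabolomic flux.** Under exponential growth `N(t) = N₀ e^{μt}` and a
constant per-cell flux `J` (fmol/cell/h), the medium amount (μmol) follows
`M(t) = M₀ ∓ J N₀ (e^{μt} − 1)/μ` (linear limit at μ = 0). The default
estimator inverts this per replicate from the first-to-last difference
("endpoint"); a regression variant fits all time points against the growth
integral. `μ` comes from a log-linear fit to the paired cell counts. The
fold/stoichiometry summary suppresses the Δ-ratio when the excess glucose
flux is not resolved from zero (|ΔJ| < 3 SE).

Flux-scenario defaults (`fasnall_24h`): control (J_glc, J_lac) =
(100, 94.1), treated (900, 1694.1) fmol/cell/h; μ = ln2/30 h⁻¹ control,
ln2/60 h⁻¹ treated (treatment slows growth); N₀ = 10⁶ cells; 50 μmol glucose
per dish. The baselines are chosen so that the treated/control folds are
exactly 9 (glucose) and 18.003 (lactate) while the *excess* fluxes obey the
1 glucose : 2 lactate carbon balance, `J_lac,ctrl = 0.941 J_glc,ctrl`; the
config validates this identity. Note the raw ΔM ratio differs from the flux
ratio because the two conditions grow at different rates — the estimator's
growth normalization is what recovers the 18-fold figure.

**Pharmacokinetics.** `C(t) = C_ref · 2^{−(t−t₀)/t_half}` fitted log-linearly
from the first sampled time `t₀ = 15` min onward; the absorption phase is not
modeled, and earlier times are rejected by the generator. A non-negative
slope is reported as "no measurable elimination" rather than a negative
half-life. Tissue defaults (C at 15 min, μM; t½, min): liver (9.2, 48),
heart (3.75, 85), brain (3.75, 85), plasma (0.8, 88). Heart and brain share
one concentration midpoint and the 85-min half-life because the source data
do not resolve the two tissues separately.

**Plate kinetics.** The reference channel (A750) is subtracted point-by-point
to remove shared baseline drift. The "initial linear part" is formalized as
the longest prefix of 4–12 points whose linear fit has R² ≥ 0.98 (ties to
more points); if none qualifies, the first 4 points are used and the result
is quality-flagged. *Known bias:* on a noise-free saturating trace (rate
0.02 AU/min, plateau 1.0 AU) the exponential's curvature makes the windowed
slope at 5-min sampling ~14 % low even for the minimal window; the 10 %
recovery property therefore holds (and is tested) at sub-minute sampling of
the early phase, and estimated rates at 5-min sampling should be read as
slightly conservative. Group comparisons are Welch + BH across the substrates
of a plate, requiring ≥ 3 replicates.

**Tumor volumes.** `0.5 · L · W²` (mm³) with L ≥ W enforced (swap with
warning); endpoint arms compared by Welch's t with ≥ 3 animals per arm.

## 5. Synthetic generator (`metamech.synthetic`)

**Noise model.** All intensity-like noise is multiplicative log-normal and
mean-preserving: `ε ~ N(−σ²/2, σ²)` with `σ² = ln(1 + cv²)`, so expected
intensities follow the clean model exactly. Defaults: cv = 0.20 for peak
intensities and medium amounts (0.25 for pooled zebrafish embryos, a noisier
matrix), 0.15 for tissue concentrations, 0.05 for isotopologue spectra and
cell counts, 0.002 AU additive for plate absorbances. For medium time
courses the noise multiplies the *cumulative consumed/secreted amount*, not
the total medium amount: a 20 % error on a 50-μmol baseline would swamp the
~3-μmol control-condition change and make control fluxes unidentifiable,
whereas rate-level variability is what replicate cultures actually show.

**Dose response.** `intensity = baseline × (1 + (fold − 1)·d^h/(d^h+EC50^h))`
with Hill slope h = 2 and EC50 at the second dose of the (0.1, 0.3, 1.0,
3.0) μM grid, so the top dose realizes ~99 % of the scenario fold (e.g.
990.1 of the 1000-fold malonate effect). Baselines are drawn log-uniformly
over 10⁴–10⁷ counts. Fold defaults encode the published effect sizes:
malonate 1000×, succinate 10×, malonyl-CoA 20×, succinyl-CoA 2×, acetyl-CoA
1.75× for the FASN scenario; NADH/NAD+ 3×, G3P 5×, lactate 3×, TCA pools
0.35–0.5× for the Complex-I scenarios. The zebrafish scenario uses
whole-embryo lactate folds of 15 (rotenone) and 4 (test drug) — single
saturating exposures, no dose grid.

**Profiles.** Two drugs sharing a mechanism get log2 fold-change vectors
`x = s + ε` with a common latent signature `s ~ N(0, σ_s²)`, σ_s = 1, and
independent noise with `σ_ε = σ_s √((1−ρ)/ρ)`, ρ = 0.56, giving expected
Pearson correlation 0.56 over 208 features. The measured mean of the 20-seed
average is 0.562 ± 0.010 (SD of the mean), comfortably above the 0.54
acceptance bound.

**Replicates.** The profiling default is `n_reps = 10`: a power analysis of
the weakest signature component (succinyl-CoA, true fold 2, gate q < 0.05
under BH across 208 features at cv = 0.2) gives ≈ 75 % power at n = 6 and
≥ 95 % at n = 10. Fold-recovery targets use the 3-replicate design stated in
their setup.

**Determinism.** Every table derives its generator from
`SeedSequence([master_seed, crc32(scenario/label)])`, so tables are
independent streams, byte-identical across reruns, and all derived seeds are
below 2³¹.

**Scope.** The generator emulates statistical structure only: log-normal
intensities, Hill dose responses, natural-abundance-convolved spectra,
exponential growth and decay, saturating plate traces. Raw spectra,
chromatography, matrix effects, batch drift, metabolite identification, and
absorption-phase pharmacokinetics are out of scope.

## 6. Pipeline and IO (`metamech.io`, CLI)

Tidy CSVs (UTF-8, comma, header, "." decimal) with fixed schemas; validation
reports column presence, numeric types, key uniqueness, replicate counts,
vehicle presence, and propagation of the isotope clamp rule, citing 1-based
line numbers. Each run writes one `manifest.json` with the pipeline version,
a SHA-256 config hash, the master seed, per-stage timings, deduplicated
warnings, and SHA-256 digests of every output; identical config + seed
reproduces identical digests (tested).

## 7. Tolerances

* Exact algebra (matrix columns, closed-form fluxes, PK round trips):
  relative 1e−6 to 1e−12, set by float64 and `nnls`/SLSQP convergence.
* Oracle round trips: L1 ≤ 1e−6 (criteria 6–7).
* Monte-Carlo recoveries: 10 % relative on means over 20–100 seeds, several
  times the standard error of each estimate.
* Null calibration: 2 Monte-Carlo SE above the nominal 0.05.

## 8. Limitations

* The classifier's marker panel and thresholds are tuned to the two
  mechanisms modeled; drugs with mixed or novel mechanisms will be called
  `indeterminate` rather than characterized.
* The endpoint flux estimator assumes constant per-cell flux and pure
  exponential growth over the window; death phases or lag phases bias it.
* Initial-rate estimates at coarse plate sampling are biased low (see §4).
* Acetyl deconvolution ignores fumarate symmetry scrambling and pool
  compartmentation; its residual flag detects only gross violations.
* The generator's noise is independent across features; correlated batch
  structure, which real studies must model, is absent.
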