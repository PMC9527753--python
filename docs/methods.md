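# Methods

## Model

kinsense fits the pseudo-first-order 1:1 interaction model for real-time
fluorescence sensorgrams. During association (analyte at concentration
`c` flowing over the chip, `t_a ≤ t ≤ t_d`):

    F(t) = y0 + A · (1 − exp(−k_obs · (t − t_a))),   k_obs = k_a·c + k_d

During dissociation (buffer only, `t ≥ t_d`):

    F(t) = y0 + A_d · (f_res + (1 − f_res) · exp(−k_d · (t − t_d)))

Assumptions: the analyte is in large excess over the surface ligand
(pseudo-first-order), transport to the surface is fast relative to binding
(no mass-transport limitation), one binding mode per analyte, and rates
constant over a trace. Signal before `t_a` is constant at `y0`. The
dissociation amplitude `A_d` is pinned to the association value at `t_d`
by default (the instrument records one continuous curve); an untied
per-trace `A_d` is available for truncated traces
(`ModelSpec(tie_dissociation_amplitude=False)`).

The residual bound fraction `f_res ∈ [0, 1]` models incomplete
dissociation: a fraction of the complex that buffer flow does not remove
on the experimental timescale, leaving a plateau at `y0 + A_d·f_res`.
`f_res = 0` recovers the complete-dissociation model exactly. This plateau
form is one defensible parameterization of incomplete dissociation (a
slow second dissociation phase would be an alternative); it adds a single
bounded parameter and nests the simpler model, which is what the AICc
comparison in `select_dissociation_model` exploits.

Equilibrium constants are derived from the fitted rates, `K_A = k_a/k_d`
and `K_D = k_d/k_a`; they are reciprocal by construction and the package
never reports constants inconsistent with the rates.

## Global fitting

All traces of a concentration series are fitted simultaneously with
shared `k_a`, `k_d` (and `f_res`) and per-trace `A`, `y0`. Sharing across
≥ 2 distinct concentrations is what separates `k_a` from `k_d`; a single
trace determines only `k_obs`, and the fitter raises an identifiability
error rather than returning an arbitrary split. Blanks are excluded from
fitting — they feed blank correction.

Numerics: bounded trust-region least squares (lmfit/`least_squares`,
`x_scale="jac"` so the wildly different parameter scales — `k_a` up to
10⁷ M⁻¹s⁻¹ against `k_d` down to 10⁻³ s⁻¹ — are equilibrated from the
Jacobian), tolerances `ftol = xtol = 1e-14` so that noise-free data are
recovered to better than 10⁻⁶ relative error across that whole magnitude
range. Rates are bounded below by 10⁻¹⁵, `f_res` to [0, 1]. Optional
seeded multi-start (`n_starts`) perturbs the initial rates log-normally
and keeps the lowest cost; the default single start is sufficient when
the initial guesses below are usable.

Initial guesses come from classical linearizations: `y0` from the
pre-association window mean; the dissociation plateau from the tail mean
and `k_d` from log-linear regression of `ln(F − plateau)` (points above
2 % of the initial decay amplitude, amplitude-weighted across traces);
per-trace `k_obs` from the linearized association
`ln(1 − (F − y0)/A_plateau)`; `k_a` from the least-squares slope of
`k_obs` versus `c`, floored at a small positive value. On noise-free,
fully decayed traces these guesses are exact to ~10⁻⁹; on noisy or
plateau-truncated data they are only starting values and the optimizer
does the work. A post-fit guard warns when `max(k_obs)·t_assoc < 1`
(association plateau not reached), the regime where rate estimates
degrade.

Weighting is uniform by default. `inverse_variance` weights each trace by
the reciprocal noise SD estimated from its pre-association window
(falling back to uniform when that window is flat), useful when traces
have visibly different noise.

Uncertainties: `curvature` takes standard errors of the shared parameters
from the covariance at the optimum (marked unavailable on singular
curvature); `bootstrap` resamples residuals within each trace with a
seeded generator and refits. Replicate experiments are combined by
`aggregate_replicates` as arithmetic mean ± sample SD per parameter, with
K_A/K_D summarized from the per-replicate constants — the mean of ratios,
not the ratio of means, which differ whenever replicates are unequal.

## Synthetic data

The generator emulates: mono-exponential association at `k_a·c + k_d`,
exponential dissociation at `k_d` with optional `f_res`, per-trace
amplitude and baseline, additive homoscedastic Gaussian noise scaled as a
percentage of the series' maximum noise-free amplitude, optional linear
baseline drift, and blanks recorded before and after the ladder. Default
designs mirror the published protocols: five-concentration factor-2
ladder from 1×10⁻⁶ M with 60 s/300 s phases (standard static method),
30 s/60 s (weak-binder method), and 2×10⁻⁴ M down by factor 2 with
240 s/480 s for slow, incompletely dissociating binders; 10 Hz sampling
and a 10 s pre-association baseline throughout. Amplitudes follow the
equilibrium saturation law `A(c) = A_max·c/(c + K_D)` (a free-amplitude
option draws them instead), with `A_max = 30 %` and `y0 = 0` as the
reference scale so the ladder spans roughly 3–20 % responses — inside the
2–30 % range reported as favorable; the absolute fluorescence scale of a
real instrument is arbitrary and so is this one.

Not emulated: nanolever actuation (dynamic mode), photobleaching,
flow-rate artifacts, mass-transport limitation, heteroscedastic or
correlated noise, chip regeneration. Passing recovery tests therefore
demonstrate correctness of the estimator under the stated noise model,
not robustness to every instrument artifact.

Simulation sizes in the test suite are chosen to keep the full run in a
few seconds (e.g. the noise-free recovery grid uses 200 samples per
association window and 4 concentrations per grid point); the acceptance
designs use the full 10 Hz protocols (≈ 18 500 and 29 000 fitted points).

## Quality checks

Blank correction subtracts the pointwise mean of all blanks, linearly
interpolated onto each analyte trace's grid (the mean of the pre- and
post-series blanks is used because both are recorded; it is idempotent
once blanks are removed). `percent_change` reports the peak absolute
deviation from the pre-association baseline over the association window
and flags responses under 1 % as unreliable — below that level the
derived rate constants carry high scatter. `linearity_check` is ordinary
least squares of response on concentration with R²; it is descriptive
only (near and above `K_D` the saturation law bends, so a high R² over a
limited ladder does not imply global linearity — see limitations).
Kinetic tables render `(value ± SD) × 10^n` at three significant figures,
plain decimals for decades −1…2, matching the conventional layout.

## Docking post-analysis

Pose sets (centroid + binding-energy magnitude; negative ΔG input is
converted to magnitude on read) are partitioned by single-linkage
clustering at a Euclidean cutoff, default 3.5 Å — a deterministic,
parameter-light stand-in for engine-internal clustering, configurable per
call. Ranking returns the most populous cluster ("most popular site",
ties broken by best energy then list order) and the cluster containing
the single best pose ("most strongly bonded site"); the two may coincide.
Groove assignment needs the receptor structure and is out of scope;
clusters live in coordinate space with optional user labels.

## Degenerate inputs and tie-breaks

Flat traces fail initial guessing with diagnostics rather than producing
rates; constant responses make `linearity_check` return R² = 0 with a
degenerate flag; an empty pose set clusters to an empty list, while an
energy fraction over an empty set is an error; AICc ties select the
complete (simpler) dissociation model; blank correction with no blanks is
an identity transform with an explicit warning.

## Known limitations

- The 1:1 model cannot represent bivalent or heterogeneous binding, nor
  mass-transport-limited kinetics; systematic misfit shows up in the
  residuals, not in the standard errors.
- `f_res` is phenomenological; it does not distinguish a truly
  non-dissociating subpopulation from dissociation much slower than the
  observation window.
- Curvature standard errors assume independent homoscedastic residuals;
  with correlated instrument noise they understate uncertainty — prefer
  replicate SDs (`aggregate_replicates`) for reporting.
- Per-temperature constants only; no Arrhenius/van 't Hoff analysis.
- The observed concentration–response linearity over a factor-16 ladder
  coexists with the saturation amplitude law; `linearity_check` makes no
  attempt to reconcile the two and should be read as a QC indicator.
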