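# Methods

## The mixing model

Each rate surface is the full second-order bivariate polynomial in agarose
concentration *G* and salt concentration *N*,

R(G, N) = c1 + c2·G + c3·G² + c4·N + c5·N² + c6·G·N + c7·G²·N + c8·G·N² + c9·G²·N²,

evaluated term by term in double precision (no Horner re-association). The
physical reading: c1 is the solvent (deionized-water) rate, c2–c3 the
agarose gel contribution, c4–c5 the dopant relaxivity terms, and c6–c9
cross terms capturing how the gel matrix modulates the dopant's
effectiveness. Nonnegativity of every coefficient encodes that both levers
can only accelerate relaxation, which makes each surface nondecreasing in
both concentrations and the water point (0, 0) the global minimum rate —
properties the inversion and fallback logic rely on.

**Units.** Agarose is percent weight/volume; salt is millimolar; rates are
s⁻¹; field strength is tesla. The packaged model files carry these units as
explicit metadata so an alternative convention changes labels, not code.
With these units the packaged salt coefficients c4 correspond to the usual
relaxivities (e.g. ≈ 15.6 s⁻¹ mM⁻¹ for Gd-EDTA at 0.064 T, ≈ 0.57 s⁻¹ mM⁻¹
for NiCl2).

**Packaged data.** Twelve models (CuSO4, GdCl3-EDTA, MnCl2, NiCl2 × 0.0065,
0.064, 0.55 T) ship as JSON inside the package. The water/agarose
coefficients c1–c3 are shared across the four salts at each field, because
they derive from the same salt-free measurements. A second, independent
transcription lives in the test suite and is string-compared against the
packaged values. Models are immutable after construction; refitting
produces new objects, which keeps provenance unambiguous.

## Staged fitting

Coefficients are estimated in four conditioned stages, mirroring how the
calibration samples are built:

1. **water**: c1 = mean measured rate over water records;
2. **agarose-only**: nonnegative least squares of (rate − c1) on [G, G²];
3. **salt-only**: likewise on [N, N²];
4. **full**: with c1–c5 fixed, nonnegative least squares of the remaining
   residual on the four interaction terms.

Rate-domain loss is the default because the model is linear in the
coefficients there, making every stage a bounded linear problem
(`scipy.optimize.nnls`) with a deterministic solution — fitting twice on
the same data gives identical coefficients. A time-domain loss option
refines the rate-domain solution with a bounded nonlinear pass for users
who prefer residuals in the measured quantity. Nonnegativity is enforced by
the solver, not by clipping, so residuals are minimized subject to the
constraint. After each stage, coefficients below the zeroing threshold
(default 1×10⁻⁴ in rate units) are set to zero without refitting; the
threshold exists because such terms are physically negligible and
numerically unstable. Weighting is uniform by default (a config hook
accepts alternatives).

**Replicate handling.** Before fitting, records are reduced to one per
composition: only the temperature(s) nearest the 20 °C target are kept
(both retained when equidistant — no information is discarded where the
tie rule is arbitrary), and retained replicates are averaged in the time
domain, since the measurements are times; a rate-domain averaging switch is
provided because the two conventions differ at second order. Records
missing one relaxation time participate only in the other kind's fit.

## Recipe inversion

Given targets (T1, T2), the solver finds (G, N) ≥ 0 inside configured
bounds with R1(G, N) = 1/T1 and R2(G, N) = 1/T2. The 2×2 polynomial system
is solved numerically: the relative rate residual is evaluated on a coarse
21×21 grid, a Newton-type iteration (`scipy.optimize.root`, hybrid Powell,
analytic Jacobian) is started from every local minimum of that surface plus
the globally best grid points, and converged roots are accepted at a
relative rate tolerance of 1×10⁻⁸. Starting from every basin matters: for
the MnCl2 model at 0.55 T a small fraction of targets (~3%) genuinely admit
two distinct in-bounds compositions. When several roots exist the recipe
with minimal salt concentration is returned (ties: minimal agarose) and
flagged `multiple_roots` — less dopant means cheaper, safer samples and
smaller sensitivity to weighing error.

**Fallback ladder.** If no joint root exists in bounds: match T1 alone,
then T2 alone (single-target solutions prefer the salt-only axis, the more
precisely dispensable lever, then agarose-only — each is a quadratic in one
variable, bracketed and solved with Brent's method); if the target relaxes
more slowly than water (both target rates at or below the intercepts), the
status is `water_fallback` with plain water as the recommendation — this is
exactly the body-temperature-CSF situation, unreachable by any doped gel at
laboratory temperature; otherwise `infeasible`. Every returned recipe's
predicted times are computed by the forward model on its composition, so
predictions are consistent bit for bit.

**Concentration limits** are configuration, not constants: defaults are
G ∈ [0, 4] % w/v for all salts and salt-specific maxima (CuSO4 10 mM,
GdCl3-EDTA 2 mM, MnCl2 1 mM, NiCl2 25 mM) scaled inversely to relaxivity so
each salt's attainable (T1, T2) cloud covers sub-second tissue targets.
`feasible_region` samples that cloud on a grid and offers a convex-hull
membership test; the hull is a superset of the (non-convex) attainable set,
so it serves as a quick pre-check, not a proof of feasibility.

## Dispersion targets

Tissue relaxation times depend on B0, so targets for an arbitrary field are
interpolated from a fitted dispersion curve. Two built-in families:

* **power law** T = A·B0^β, fitted on times — two parameters, adequate for
  the roughly log-linear T1 rise of most tissues over 0.002–1 T;
* **Lorentzian sum** R = B + Σᵢ Cᵢ·τᵢ / (1 + (ω·τᵢ)²), ω = γ·B0 (proton
  angular Larmor frequency), fitted on rates — a spectral-density form with
  physically interpretable correlation times τᵢ (two terms by default).

The form is pluggable and neither is claimed canonical; target tables can
also be supplied literally, bypassing fitting. Fits are bounded nonlinear
least squares (lmfit). Because the Lorentzian parameters span many decades
(Cᵢ ~ 10⁹ s⁻², τᵢ ~ 10⁻⁹ s), that family is optimized over log10-parameters
with relative rate residuals, which conditions the problem without changing
the model. Evaluating a fitted curve outside its fitted field range warns
but returns the value — extrapolation is the user's call.

`band_coverage` reports the maximal contiguous field intervals where a
measured mimic dispersion stays within a fractional tolerance (default 10%)
of a tissue curve; band crossings between samples are located by linear
interpolation of the relative deviation in log-field, matching the
logarithmic spacing of dispersion data.

## Evaluation metrics

Mimic accuracy is the signed percent error 100·(measured − target)/target,
per relaxation kind. `fraction_within` counts error values with magnitude
*strictly* below the threshold; "datapoint" mode counts each T1 and T2
error individually (default), "sample" mode counts a mimic once and
requires all its present errors inside — both are exposed because the
natural counting unit is a modelling choice. Variability uses deviations
normalized to each sample's mean, 100·(v − mean)/mean, pooled per condition
(repeatability / protocol / temperature): the summary reports the mean
absolute deviation, extreme signed deviations, and the count of samples
whose worst absolute deviation exceeds the ±10% acceptability band
(strictly greater).

## Synthetic data

The generator emulates a calibration study: water, agarose-only, salt-only
and mixed compositions on a configurable grid, times forward-computed from
a known model and perturbed by multiplicative log-normal noise (default
σ = 0.02, the few-percent scale typical of multi-site relaxometry
variability). Temperature jitter labels records only — there is no physical
temperature model — which suffices to exercise replicate selection. All
randomness is seeded; generation is deterministic given the design.

What this does *not* emulate: acquisition (inversion-recovery /
spin-echo fitting and its biases), multi-exponential T2, magnetization
transfer, inter-site protocol differences beyond iid noise, or
temperature dependence of relaxation. Passing recovery tests therefore
demonstrates the estimator and solver are correct under the stated noise
model, not that real multi-site data meet the same tolerances.

## Problem sizes and numerical choices

* Parameter-recovery studies use a 49-composition design (water + 6
  agarose-only + 6 salt-only + 36 mixed, agarose up to 4 % w/v, salt up to
  10 mM) with 12 replicates at σ = 0.01; replication is sized so coefficient
  standard errors sit well inside the 5% recovery tolerance across seeds.
* Inversion round-trips use 100 random in-bounds compositions per packaged
  model (1200 total), tolerance 1×10⁻⁶ relative on concentrations; a dense
  301×301 grid serves as an independent root-selection oracle in tests.
* Inversion accepts roots at 1×10⁻⁸ relative rate residual; concentrations
  within 10⁻⁹ of zero from the unconstrained Newton step are snapped to 0.
* Degenerate inputs: all-zero surfaces are rejected before inversion;
  single-point feasible regions fall back to a nearest-sample membership
  test; empty measurement sets yield empty selections, not errors.

## Known limitations

* The 0.0475 and 0.05 T use case relies on the 0.064 T models as proxies;
  the package does not interpolate mixing models between fields.
* The convex-hull feasibility pre-check can report points feasible that lie
  in concavities of the attainable set; `solve_recipe` resolves these
  truthfully via the fallback ladder.
* Published coefficient tables are point estimates; no uncertainty is
  propagated from model coefficients into recipes.
* Single-exponential relaxation throughout; no magnetization-transfer or
  chemical-shift modelling.
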