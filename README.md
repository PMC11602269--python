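# phantomgel

Mixing models and recipe inversion for doped-agarose MRI/NMR relaxation
phantoms, aimed at low magnetic field strengths (≤ 0.55 T).

Tissue-mimicking reference phantoms are essential for developing and
validating MRI sequences, and because tissue relaxation times vary strongly
with field strength, phantoms designed for 1.5–3 T are poor mimics at the
low fields (0.0065–0.55 T) of emerging portable scanners. `phantomgel` is
for physicists and engineers who need gel samples with *specific* T1 and T2
at a given B0: it models, fits, inverts and scores the relationship between
gel composition and relaxation.

## The model

For a gel of agarose concentration *G* (% w/v) doped with a paramagnetic
salt at concentration *N* (mM), each relaxation rate at one field strength
is a second-order bivariate polynomial:

```
R1 = 1/T1 = a1 + a2·G + a3·G² + a4·N + a5·N² + a6·G·N + a7·G²·N + a8·G·N² + a9·G²·N²
R2 = 1/T2 = b1 + b2·G + b3·G² + b4·N + b5·N² + b6·G·N + b7·G²·N + b8·G·N² + b9·G²·N²
```

All coefficients are constrained nonnegative (doping and gelling only speed
up relaxation), and fitted values below 1×10⁻⁴ are set to zero. The
intercepts a1, b1 are the deionized-water rates; a4, b4 are the salt
relaxivities r1, r2 (s⁻¹ mM⁻¹).

The package ships published coefficient tables for four salts — CuSO4,
GdCl3-EDTA, MnCl2, NiCl2 — at 0.0065, 0.064 and 0.55 T (twelve models),
and provides:

* **forward prediction** — T1/T2 from composition (`predict_times`);
* **staged constrained fitting** — water → agarose-only → salt-only → full
  interaction terms, by nonnegative least squares on rates
  (`fit_mixing_model`), with replicate selection at the 20 °C target
  temperature;
* **recipe inversion** — solve the 2×2 polynomial system for (G, N) given
  target (T1, T2), with a fallback ladder (T1-only → T2-only → plain water →
  infeasible) for unreachable targets (`solve_recipe`);
* **dispersion targets** — fit parametric T(B0) curves (power law or a
  Lorentzian-sum rate form) to tissue relaxometry data and interpolate
  targets at any field (`fit_dispersion`, `target_at_field`,
  `band_coverage`);
* **evaluation** — signed percent errors of mimics against targets,
  fraction within a ±10% acceptability band, and normalized-deviation
  variability summaries (`mimic_errors`, `fraction_within`,
  `normalized_deviations`);
* **synthetic data** — seeded generators for measurement tables and
  dispersion curves with known ground truth (`generate_measurements`,
  `generate_dispersion`).

## Worked example

Solve white-matter mimic recipes at 0.064 T for every salt
(`examples/02_make_tissue_recipe.py`):

```
Target WM @ 0.064 T: T1 = 0.35 s, T2 = 0.08 s
  CuSO4       status=exact    agarose 1.119% w/v, salt 0.841 mM  ->  T1 0.350 s, T2 0.080 s
  GdCl3-EDTA  status=exact    agarose 1.210% w/v, salt 0.143 mM  ->  T1 0.350 s, T2 0.080 s
  MnCl2       status=exact    agarose 1.108% w/v, salt 0.124 mM  ->  T1 0.350 s, T2 0.080 s
  NiCl2       status=exact    agarose 1.386% w/v, salt 3.857 mM  ->  T1 0.350 s, T2 0.080 s

Target CSF @ 0.064 T: status = water_fallback (water gives T1 2.43 s, T2 2.16 s)
```

Each line is a recipe: mix that agarose and salt concentration and the
model predicts the target T1/T2 exactly (`status=exact`). The agarose
lever sets mostly T2, the salt lever mostly T1; the required salt
concentration scales inversely with the salt's relaxivity (NiCl2 is the
weakest relaxer, hence needs ~4 mM). The CSF target relaxes more slowly
than water at laboratory temperature — no doped gel can reach it, so the
solver falls back to recommending plain deionized water.

The other scripts in `examples/` walk through forward prediction, model
fitting from measurement tables, dispersion-target interpolation, and
mimic scoring. A thin CLI mirrors these entry points:

```bash
phantomgel make-recipe --salt NiCl2 --field 0.064 --t1 0.35 --t2 0.08
phantomgel simulate --salt NiCl2 --field 0.064 --seed 1 --out meas.csv
phantomgel fit-model --measurements meas.csv --salt NiCl2 --field 0.064 --out model.json
```

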