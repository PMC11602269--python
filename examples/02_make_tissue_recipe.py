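"""Solve gel recipes that mimic tissue relaxation times.

Inverts each salt's mixing model at 0.064 T for white-matter-like targets,
and shows the fallback behaviour for a CSF-like target that no gel can
reach at laboratory temperature.
"""

from phantomgel import SALTS, TargetSpec, load_published_models, solve_recipe

models = load_published_models()

wm = TargetSpec(t1_s=0.35, t2_s=0.08, field_T=0.064, label="WM @ 0.064 T")
print(f"Target {wm.label}: T1 = {wm.t1_s} s, T2 = {wm.t2_s} s")
for salt in SALTS:
    r = solve_recipe(models[(salt, 0.064)], wm)
    if r.conc is not None:
        print(f"  {salt:<11} status={r.status:<8} agarose {r.conc.agarose:.3f}% w/v, "
              f"salt {r.conc.salt:.3f} mM  ->  T1 {r.predicted_t1_s:.3f} s, "
              f"T2 {r.predicted_t2_s:.3f} s")
    else:
        print(f"  {salt:<11} status={r.status}")

# A body-temperature CSF target relaxes more slowly than water at lab
# temperature; doping can only shorten relaxation, so the solver recommends
# plain deionized water.
csf = TargetSpec(t1_s=4.0, t2_s=2.6, field_T=0.064, label="CSF @ 0.064 T")
r = solve_recipe(models[("NiCl2", 0.064)], csf)
print(f"\nTarget {csf.label}: status = {r.status} "
      f"(water gives T1 {r.predicted_t1_s:.2f} s, T2 {r.predicted_t2_s:.2f} s)")
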