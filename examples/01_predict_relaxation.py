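"""Predict T1 and T2 of a doped agarose gel from its composition.

Loads the packaged mixing models and forward-evaluates the polynomial rate
surfaces for one gel recipe at each of the three modelled field strengths.
"""

from phantomgel import ConcentrationPair, load_published_models, predict_times

models = load_published_models()

# 1% w/v agarose doped with 5 mM nickel chloride
gel = ConcentrationPair(agarose=1.0, salt=5.0)

print(f"NiCl2 gel, agarose {gel.agarose}% w/v, salt {gel.salt} mM")
for field in (0.0065, 0.064, 0.55):
    t1, t2 = predict_times(models[("NiCl2", field)], gel)
    print(f"  B0 = {field:<7} T:  T1 = {t1 * 1e3:7.1f} ms   T2 = {t2 * 1e3:6.1f} ms")

# The same composition relaxes faster at lower field for T1 (agarose and Ni
# relaxivity terms are larger there), while T2 is dominated by the agarose
# term at every field.
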