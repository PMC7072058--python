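"""Expected viable/dead ratios for volumetric mixtures of pure suspensions.

A harshly killed dead suspension loses events to cell disintegration, so a
volumetric 80/20 viable/dead mixture contains more than 80 % viable events.
The expectation follows from the measured pure-suspension counts; the yield
factor r = N_PI_D100 / N_FDA_V100 summarises the effect.
"""

from cytogate import (
    MixtureDesignPoint,
    PureSuspensionCounts,
    expected_ratio_for_mixture,
    fit_yield_factor,
    qc_particle_load,
)

for label, n_pi_d100 in [("harshly killed (r = 0.51)", 510.0),
                         ("gently killed  (r = 0.96)", 960.0)]:
    pure = PureSuspensionCounts(n_fda_v100=1000.0, n_pi_d100=n_pi_d100)
    row = []
    for p in (100, 80, 60, 50, 40, 20, 0):
        point = MixtureDesignPoint(p_viable=p, p_dead=100 - p)
        row.append(expected_ratio_for_mixture(pure, point).rounded()[0] if p else 0)
    print(f"{label}: expected viable % for 100/80/60/50/40/20/0 -> {row}")

# recover the yield factor back from a reported expected row
row = [(80.0, 89.0), (60.0, 75.0), (50.0, 66.0), (40.0, 57.0), (20.0, 33.0)]
r = fit_yield_factor(row)
print(f"yield factor fitted from the integer row {row}: r = {r:.3f}")

# sample QC: the method needs < 1e6 particles/mL in the measured sample
for conc in (5e5, 3e7):
    v = qc_particle_load(conc)
    print(f"QC at {conc:.0e} particles/mL: pass={v.passed}, "
          f"recommended extra dilution {v.recommended_dilution}x")
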