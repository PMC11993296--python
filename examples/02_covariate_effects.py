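"""Covariate effects on platelet reconstitution: ATG, donor relation, TP.

Simulates the typical patient under four scenarios and prints the nadir and
day-30 counts, showing that ATG crashes platelets during treatment (nadir
before day 0), a related donor triples the day-+1 boost, and a persistently
low total protein slows the graft recovery.
"""

import numpy as np

from pltrecon import (
    CovariateSeries,
    PopulationParameters,
    TreatmentRegimen,
    simulate_individual,
)

pop = PopulationParameters()
scenarios = {
    "reference (unrelated, no ATG)": (TreatmentRegimen(), None),
    "ATG 800 mg/day, days -4..-2": (
        TreatmentRegimen(atg_doses=((-4, 800.0), (-3, 800.0), (-2, 800.0))),
        None,
    ),
    "related donor": (TreatmentRegimen(donor_relation="related"), None),
    "low total protein (4.2 g/dL)": (
        TreatmentRegimen(),
        CovariateSeries([-30.0], [4.2]),
    ),
}

print(f"{'scenario':32s} {'nadir':>14s} {'day +1':>7s} {'day +30':>8s} {'day +180':>9s}")
for name, (regimen, covariates) in scenarios.items():
    traj = simulate_individual(pop, regimen, covariates)
    window = traj.t >= -6.0
    tt, vv = traj.t[window], traj.plt_total[window]
    nadir = f"{vv.min():5.1f} @ {tt[np.argmin(vv)]:+5.1f}"
    d1, d30, d180 = traj.at([1.0, 30.0, 180.0])
    print(f"{name:32s} {nadir:>14s} {d1:7.1f} {d30:8.1f} {d180:9.1f}")
# Counts are in 1e9/L.  The ATG nadir precedes the transplant; the related-
# donor boost only shifts the first post-HCT days; low TP scales the graft
# production down by (4.2/5.43)^0.197 ~ 0.95 and lowers the late plateau.
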