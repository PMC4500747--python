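"""Conduction velocity under named interventions.

Builds a small myocyte sheet with the default (polarized) sodium-channel
distribution and measures longitudinal/transverse conduction velocity for
the control condition and two interventions: interstitial edema (raised
extracellular conductivities) and gap-junction uncoupling (halved g_j).

A 9x10-cell sheet keeps the runtime to roughly half a minute; the test
suite uses a 20x10 sheet for the full trend matrix.
"""

from dataclasses import replace

from perinexus import (ModelConfig, SheetLayout, SolverConfig,
                       StimulusConfig, apply_interventions, run_protocol,
                       cv_from_simulation, AIE, GJ_UNCOUPLING)

base = ModelConfig().with_updates(
    layout=SheetLayout(9, 10),
    solver=SolverConfig(dt=0.005, duration=25.0))

conditions = {
    "control": [],
    "edema (AIE)": [AIE],
    "GJ uncoupling": [GJ_UNCOUPLING],
}

print(f"{'condition':<16}{'CV_L (cm/s)':>12}{'CV_T (cm/s)':>12}{'AR':>8}")
for name, interventions in conditions.items():
    cfg = apply_interventions(base, interventions)
    cv = {}
    for direction, edge in (("longitudinal", "left"),
                            ("transverse", "bottom")):
        c = cfg.with_updates(solver=replace(
            cfg.solver, stimulus=StimulusConfig(edge=edge, amplitude=0.01)))
        _, system = c.build(junctional_subdivisions=5)
        cv[direction] = cv_from_simulation(run_protocol(system, c.solver),
                                           direction)
    ar = cv["longitudinal"] / cv["transverse"]
    print(f"{name:<16}{cv['longitudinal']:>12.2f}"
          f"{cv['transverse']:>12.2f}{ar:>8.2f}")
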