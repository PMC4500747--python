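"""Named interventions and the parameter sweeps behind the model panels.

Interventions are applied as functional updates of a
:class:`~perinexus.config.ModelConfig`:

``AIE``
    acute interstitial edema — raises both effective extracellular
    conductivities additively (lateral +44.4, junctional +45.0 mS/cm,
    i.e. 159.1 -> 203.5 and 17.8 -> 62.8 at nominal).
``GJ_uncoupling``
    halves the gap-junctional coupling (100 -> 50 mS/cm^2 at nominal).
``INa_inhibition``
    scales the sodium conductance to 86 % of its current value
    (flecainide-like).

Composition is commutative: the three interventions touch disjoint
parameters with offsets/scale factors.

:func:`run_sweep` evaluates CV_L, CV_T and AR over a grid of extracellular
conductivity offsets, gap-junction conductances and sodium-conductance
scale factors for one or both channel-distribution models, one
longitudinal and one transverse pacing run per grid point.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import ModelConfig, MODEL_FRACTIONS
from .geometry import ConfigurationError, SheetLayout
from .solver import run_protocol, NumericalError, StimulusConfig
from .wavefront import cv_from_simulation, EstimationError

AIE = "AIE"
GJ_UNCOUPLING = "GJ_uncoupling"
INA_INHIBITION = "INa_inhibition"

AIE_SIGMA_LATERAL_OFFSET = 44.4     # mS/cm: 159.1 -> 203.5
AIE_SIGMA_JUNCTIONAL_OFFSET = 45.0  # mS/cm: 17.8 -> 62.8
GJ_UNCOUPLING_FACTOR = 0.5          # 100 -> 50 mS/cm^2
INA_INHIBITION_FACTOR = 0.86        # g_Na at 86 % of nominal

_KNOWN = (AIE, GJ_UNCOUPLING, INA_INHIBITION)


def apply_interventions(base: ModelConfig, interventions) -> ModelConfig:
    """Return a new configuration with the named interventions applied.

    ``interventions`` is any iterable of intervention names; order is
    irrelevant and an empty iterable returns a configuration equal to
    ``base``.  Unknown names raise :class:`ConfigurationError`.
    """
    flags = list(interventions)
    for name in flags:
        if name not in _KNOWN:
            raise ConfigurationError(
                f"unknown intervention {name!r}; known: {_KNOWN}")
    cfg = base
    if AIE in flags:
        ex = cfg.extracellular
        cfg = cfg.with_updates(extracellular=replace(
            ex,
            sigma_eff_lateral=ex.sigma_eff_lateral + AIE_SIGMA_LATERAL_OFFSET,
            sigma_eff_junctional=(ex.sigma_eff_junctional
                                  + AIE_SIGMA_JUNCTIONAL_OFFSET)))
    if GJ_UNCOUPLING in flags:
        cfg = cfg.with_updates(g_j_bar=cfg.g_j_bar * GJ_UNCOUPLING_FACTOR)
    if INA_INHIBITION in flags:
        cfg = cfg.with_updates(
            g_na_scale=cfg.g_na_scale * INA_INHIBITION_FACTOR)
    return cfg


@dataclass(frozen=True)
class InterventionSet:
    """Sweep specification: channel models and parameter grids.

    ``sigma_e_offsets`` are additive offsets (mS/cm) applied to both
    effective extracellular conductivities, ``g_j_values`` are absolute
    gap-junction conductances (mS/cm^2), ``g_na_scales`` multiply the
    nominal sodium conductance.
    """

    models: tuple = ("uniform", "polarized")
    sigma_e_offsets: tuple = (0.0,)
    g_j_values: tuple = (100.0,)
    g_na_scales: tuple = (1.0,)

    def __post_init__(self):
        for m in self.models:
            if m not in MODEL_FRACTIONS:
                raise ConfigurationError(f"unknown channel model {m!r}")
        if not (self.models and self.sigma_e_offsets and self.g_j_values
                and self.g_na_scales):
            raise ConfigurationError("sweep grids must be non-empty")
        if any(g < 0 for g in self.g_j_values):
            raise ConfigurationError("g_j values must be >= 0")
        if any(s <= 0 for s in self.g_na_scales):
            raise ConfigurationError("g_na scales must be > 0")


def _measure_direction(cfg: ModelConfig, direction: str,
                       junctional_subdivisions: int) -> float:
    edge = "left" if direction == "longitudinal" else "bottom"
    cfg = cfg.with_updates(solver=replace(
        cfg.solver, stimulus=replace(cfg.solver.stimulus, edge=edge)))
    _, system = cfg.build(junctional_subdivisions=junctional_subdivisions)
    result = run_protocol(system, cfg.solver)
    return cv_from_simulation(result, direction)


def run_sweep(base: ModelConfig, sweep: InterventionSet,
              sheet: tuple[int, int] = (10, 20), *,
              junctional_subdivisions: int = 5) -> pd.DataFrame:
    """Evaluate CV_L, CV_T and AR over the sweep grid.

    ``sheet`` is (n_rows, n_cols); the default 10x20 (a 20x10-cell sheet
    with 20 cells along the fiber axis) is the smallest size at which the
    on-axis ray fits are stable.  Returns a tidy DataFrame with one row
    per grid point and columns (model, sigma_e_lateral, sigma_e_junctional,
    g_j_bar, g_na_scale, cv_l, cv_t, ar, blocked).  Conduction block or a
    failed solve is recorded per row (NaN velocities, ``blocked=True``)
    and the sweep continues.
    """
    base = base.with_updates(layout=SheetLayout(
        sheet[0], sheet[1], base.layout.transverse_offset,
        base.layout.longitudinal_offset))
    rows = []
    grid = itertools.product(sweep.models, sweep.sigma_e_offsets,
                             sweep.g_j_values, sweep.g_na_scales)
    for model, ds, gj, gs in grid:
        ex = base.extracellular
        cfg = base.with_updates(
            channel_model=model,
            extracellular=replace(
                ex, sigma_eff_lateral=ex.sigma_eff_lateral + ds,
                sigma_eff_junctional=ex.sigma_eff_junctional + ds),
            g_j_bar=gj, g_na_scale=gs)
        cv = {}
        blocked = False
        for direction in ("longitudinal", "transverse"):
            try:
                cv[direction] = _measure_direction(
                    cfg, direction, junctional_subdivisions)
            except (NumericalError, EstimationError):
                cv[direction] = float("nan")
                blocked = True
        cv_l, cv_t = cv["longitudinal"], cv["transverse"]
        rows.append({
            "model": model,
            "sigma_e_lateral": cfg.extracellular.sigma_eff_lateral,
            "sigma_e_junctional": cfg.extracellular.sigma_eff_junctional,
            "g_j_bar": gj,
            "g_na_scale": gs,
            "cv_l": cv_l,
            "cv_t": cv_t,
            "ar": cv_l / cv_t if not blocked else float("nan"),
            "blocked": blocked,
        })
    return pd.DataFrame(rows)
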