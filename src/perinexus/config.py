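"""Model configuration: one serializable bundle of every model parameter.

:class:`ModelConfig` gathers the geometric, extracellular, gap-junctional,
membrane, ionic and solver parameters plus the sodium-channel distribution,
with nominal defaults.  Configurations serialize to/from YAML or JSON with
explicit parameter names and physical units in the keys.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import yaml

from .geometry import (CellShape, SheetLayout, ExtracellularParams,
                       GapJunctionParams, ConfigurationError, build_sheet)
from .membrane import (MembraneParams, IonicModelParams, ChannelDistribution,
                       SodiumPotassiumModel, partition_channels,
                       UNIFORM_FRACTION, POLARIZED_FRACTION)
from .solver import SolverConfig, StimulusConfig, DiscreteSystem, assemble_system

MODEL_FRACTIONS = {"uniform": UNIFORM_FRACTION, "polarized": POLARIZED_FRACTION}


@dataclass(frozen=True)
class ModelConfig:
    """Complete parameterization of a tissue-sheet simulation."""

    cell: CellShape = field(default_factory=CellShape)
    layout: SheetLayout = field(default_factory=lambda: SheetLayout(10, 20))
    extracellular: ExtracellularParams = field(default_factory=ExtracellularParams)
    g_j_bar: float = 100.0
    membrane: MembraneParams = field(default_factory=MembraneParams)
    ionic: IonicModelParams = field(default_factory=IonicModelParams)
    g_na_scale: float = 1.0
    channel_model: str = "polarized"
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self):
        if self.g_j_bar < 0:
            raise ConfigurationError("g_j_bar must be >= 0")
        if self.g_na_scale < 0:
            raise ConfigurationError("g_na_scale must be >= 0")
        if self.channel_model not in MODEL_FRACTIONS:
            raise ConfigurationError(
                f"channel_model must be one of {sorted(MODEL_FRACTIONS)}")

    @property
    def junctional_fraction(self) -> float:
        return MODEL_FRACTIONS[self.channel_model]

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        stim = self.solver.stimulus
        return {
            "cell_um": {"length": self.cell.length, "width": self.cell.width,
                        "depth": self.cell.depth},
            "layout": {"n_rows": self.layout.n_rows,
                       "n_cols": self.layout.n_cols,
                       "transverse_offset": self.layout.transverse_offset,
                       "longitudinal_offset": self.layout.longitudinal_offset},
            "extracellular": {
                "junctional_width_nm": self.extracellular.junctional_width_nm,
                "lateral_width_um": self.extracellular.lateral_width_um,
                "sigma_eff_lateral_mS_per_cm":
                    self.extracellular.sigma_eff_lateral,
                "sigma_eff_junctional_mS_per_cm":
                    self.extracellular.sigma_eff_junctional},
            "gap_junction": {"g_j_bar_mS_per_cm2": self.g_j_bar},
            "membrane": {"c_m_uF_per_cm2": self.membrane.c_m,
                         "sigma_i_mS_per_cm": self.membrane.sigma_i},
            "ionic": {"g_na_mS_per_cm2": self.ionic.g_na,
                      "g_k_mS_per_cm2": self.ionic.g_k,
                      "e_na_mV": self.ionic.e_na,
                      "e_k_mV": self.ionic.e_k,
                      "g_na_scale": self.g_na_scale},
            "channel_model": self.channel_model,
            "solver": {"dt_ms": self.solver.dt,
                       "duration_ms": self.solver.duration,
                       "sample_dt_ms": self.solver.sample_dt,
                       "linear_tol": self.solver.linear_tol,
                       "stimulus": {"edge": stim.edge,
                                    "amplitude_uA": stim.amplitude,
                                    "width_ms": stim.width_ms,
                                    "start_ms": stim.start_ms}},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        try:
            cell = d["cell_um"]
            lay = d["layout"]
            ex = d["extracellular"]
            ion = d["ionic"]
            sol = d["solver"]
            stim = sol["stimulus"]
            return cls(
                cell=CellShape(cell["length"], cell["width"], cell["depth"]),
                layout=SheetLayout(lay["n_rows"], lay["n_cols"],
                                   lay["transverse_offset"],
                                   lay["longitudinal_offset"]),
                extracellular=ExtracellularParams(
                    ex["junctional_width_nm"], ex["lateral_width_um"],
                    ex["sigma_eff_lateral_mS_per_cm"],
                    ex["sigma_eff_junctional_mS_per_cm"]),
                g_j_bar=d["gap_junction"]["g_j_bar_mS_per_cm2"],
                membrane=MembraneParams(d["membrane"]["c_m_uF_per_cm2"],
                                        d["membrane"]["sigma_i_mS_per_cm"]),
                ionic=IonicModelParams(ion["g_na_mS_per_cm2"],
                                       ion["g_k_mS_per_cm2"],
                                       ion["e_na_mV"], ion["e_k_mV"]),
                g_na_scale=ion.get("g_na_scale", 1.0),
                channel_model=d["channel_model"],
                solver=SolverConfig(
                    dt=sol["dt_ms"], duration=sol["duration_ms"],
                    sample_dt=sol["sample_dt_ms"],
                    linear_tol=sol["linear_tol"],
                    stimulus=StimulusConfig(edge=stim["edge"],
                                            amplitude=stim["amplitude_uA"],
                                            width_ms=stim["width_ms"],
                                            start_ms=stim["start_ms"])),
            )
        except KeyError as exc:
            raise ConfigurationError(f"missing configuration key: {exc}") from exc

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ModelConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh.read())
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        if not isinstance(data, dict):
            raise ConfigurationError("configuration source is not a mapping")
        return cls.from_dict(data)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    # -- convenience ------------------------------------------------------

    def with_updates(self, **kwargs) -> "ModelConfig":
        """Functional update returning a new configuration."""
        return replace(self, **kwargs)

    def build(self, junctional_subdivisions: int = 5):
        """Construct the mesh and assembled discrete system.

        Returns ``(mesh, system)`` ready for
        :func:`~perinexus.solver.run_protocol`.
        """
        mesh = build_sheet(self.cell, self.layout, self.extracellular,
                           GapJunctionParams(self.g_j_bar),
                           junctional_subdivisions=junctional_subdivisions)
        ionic = SodiumPotassiumModel(
            replace(self.ionic, g_na=self.ionic.g_na * self.g_na_scale))
        g_na_patch = partition_channels(
            mesh, ChannelDistribution(self.junctional_fraction), ionic.params)
        system = assemble_system(mesh, self.membrane, ionic, g_na_patch)
        return mesh, system
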