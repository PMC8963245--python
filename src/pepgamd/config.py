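"""Run configuration: strict YAML schema with lossless round-tripping.

Defaults encode the standard analysis settings of the workflow: bin size
1 coordinate unit, 500-frame bin/cluster cutoff, top-10 structural
clusters, three production replicas, statistics refresh every 50 steps.
Unknown keys are rejected with the offending key path.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .engine import ProtocolSpec
from .errors import ConfigError, UnknownKeyError

__all__ = [
    "RunConfig",
    "SystemConfig",
    "ProtocolConfig",
    "BoostConfig",
    "ReweightConfig",
    "AnalysisConfig",
    "load_config",
    "save_config",
]

KB_KCAL_PER_MOL_K = 0.0019872041  # Boltzmann constant, kcal/mol/K


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SystemConfig(_Strict):
    kind: Literal["double_well", "three_state", "peptide"] = "double_well"
    # double well
    barrier_height: float = 5.0
    well_separation: float = 2.0
    # three-state landscape (activation-coordinate wells near 8.6/11.1/15.3)
    minima: tuple[tuple[float, float], ...] = ((8.6, 10.0), (11.1, 10.0), (15.3, 10.0))
    depths: tuple[float, ...] = (5.0, 4.4, 4.6)
    widths: tuple[float, ...] = (0.9, 0.9, 0.9)
    # toy peptide
    n_peptide_beads: int = 4

    def build(self, seed: int):
        from . import toy_systems as ts

        if self.kind == "double_well":
            return ts.make_double_well(self.barrier_height, self.well_separation)
        if self.kind == "three_state":
            return ts.make_three_state_landscape(
                list(self.minima), list(self.depths), list(self.widths)
            )
        return ts.make_toy_peptide_system(self.n_peptide_beads, seed)


class ProtocolConfig(_Strict):
    n_cmd_steps: int = 2000
    n_equil_steps: int = 5000
    n_prod_steps: int = 20000
    n_replicas: int = 3
    dt: float = 0.02
    friction: float = 1.0
    temperature: float = 1.0
    update_interval: int = 50
    sample_interval: int = 10

    def to_spec(self, seed: int) -> ProtocolSpec:
        return ProtocolSpec(seed=seed, **self.model_dump())


class BoostConfig(_Strict):
    sigma0_peptide: float = 10.0  # user limit on sigma_dV, k_B T units
    sigma0_rest: float = 10.0
    bound_mode: Literal["lower", "upper"] = "lower"


class ReweightConfig(_Strict):
    bin_width: float = 1.0
    cutoff_frames: int = 500
    units: Literal["reduced", "kcal/mol"] = "reduced"
    beta: float = 1.0            # used in reduced-units mode
    temperature_K: float = 310.0  # used in kcal/mol mode

    @property
    def effective_beta(self) -> float:
        if self.units == "reduced":
            return self.beta
        return 1.0 / (KB_KCAL_PER_MOL_K * self.temperature_K)


class DistanceConfig(_Strict):
    label: str
    selection_a: tuple[int, ...]
    selection_b: tuple[int, ...]
    mode: Literal["single", "centroid"] = "single"


class StateBandConfig(_Strict):
    name: str
    lower: float
    upper: Optional[float] = None  # None = open upper end


class AnalysisConfig(_Strict):
    n_clusters: int = 10
    stride: int = 1
    depth_threshold: float = 3.0
    state_bands: tuple[StateBandConfig, ...] = (
        StateBandConfig(name="Inactive", lower=0.0, upper=10.0),
        StateBandConfig(name="Intermediate", lower=10.0, upper=13.0),
        StateBandConfig(name="Active", lower=13.0, upper=None),
    )
    distances: tuple[DistanceConfig, ...] = ()

    def build_bands(self):
        from .analysis import StateBands

        return StateBands(
            bands=tuple(
                (b.name, b.lower, float("inf") if b.upper is None else b.upper)
                for b in self.state_bands
            )
        )


class RunConfig(_Strict):
    system: SystemConfig = SystemConfig()
    protocol: ProtocolConfig = ProtocolConfig()
    boost: BoostConfig = BoostConfig()
    reweight: ReweightConfig = ReweightConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    output_prefix: str = "pepgamd_run"
    seed: int = 1


def _format_validation_error(exc: ValidationError) -> ConfigError:
    unknown = []
    msgs = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"])
        if err["type"] == "extra_forbidden":
            unknown.append(loc)
        msgs.append(f"{loc}: {err['msg']}")
    if unknown:
        return UnknownKeyError(f"unknown configuration key(s): {', '.join(unknown)}")
    return ConfigError("invalid configuration: " + "; ".join(msgs))


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise _format_validation_error(exc) from exc


def save_config(cfg: RunConfig, path) -> None:
    """Write a configuration so that ``load_config(save_config(x)) == x``."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(mode="json"), fh, sort_keys=False)
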