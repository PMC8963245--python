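"""Langevin dynamics with Gaussian-accelerated boosting.

The boost law: when the (selected) potential energy V is below a threshold
E, a harmonic boost dV = 1/2 k (E - V)^2 is added, smoothing the energy
surface while preserving the relative order of potential values.  The two
parameters are fixed by three principles: (i) order preservation and (ii)
barrier smoothing bracket the threshold as Vmax <= E <= Vmin + 1/k, with
k = k0 / (Vmax - Vmin) and 0 < k0 <= 1; (iii) the standard deviation of the
boost, sigma_dV = k (E - Vavg) sigma_V, must stay below a user limit
sigma_0 so second-order cumulant reweighting remains accurate.  With E at
its lower bound (E = Vmax),

    k0 = min(1, (sigma_0 / sigma_V) * (Vmax - Vmin) / (Vmax - Vavg)),

and with E at its upper bound (E = Vmin + 1/k),

    k0'' = (1 - sigma_0 / sigma_V) * (Vmax - Vmin) / (Vavg - Vmin),

used when 0 < k0'' <= 1 and otherwise falling back to the lower-bound
formula.

The dual-boost peptide variant applies one boost to the essential peptide
energy V_L (bonded + all peptide-involving nonbonded terms) and a second,
independent boost to the remainder V_D of the system energy; the total
boost of a frame is dV = dV_L + dV_D.

Integration uses BAOAB Langevin splitting with a fixed time step.  The
staged protocol mirrors enhanced-sampling practice: a short conventional-MD
stage collects energy statistics, an equilibration stage applies the boost
while refreshing parameters every ``update_interval`` steps, and production
runs (``n_replicas`` independent repeats differing only in the noise seed)
use frozen parameters, which keeps reweighting well-defined.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateStatisticsError,
    IntegrationInstabilityError,
    InvalidParameterError,
)
from .toy_systems import PotentialSurface, ToyPeptideSystem

__all__ = [
    "GaMDParams",
    "DualBoostParams",
    "ProtocolSpec",
    "TrajectoryRecord",
    "Trajectory",
    "GaMDResult",
    "PepGaMDResult",
    "boost_potential",
    "boosted_force_scale",
    "k0_lower_bound",
    "k0_upper_bound",
    "update_statistics",
    "run_cmd",
    "run_gamd",
    "run_pep_gamd",
]

logger = logging.getLogger(__name__)

_ENERGY_GUARD = 1e10


# --------------------------------------------------------------------------
# Boost parameters
# --------------------------------------------------------------------------

def k0_lower_bound(v_max, v_min, v_avg, sigma_v, sigma_0) -> float:
    """Force-constant factor k0 for the lower-bound threshold E = Vmax."""
    _check_stats(v_max, v_min, v_avg, sigma_v, sigma_0, need_avg_above_min=False)
    if v_max <= v_avg:
        raise DegenerateStatisticsError("v_max must exceed v_avg")
    return min(1.0, (sigma_0 / sigma_v) * (v_max - v_min) / (v_max - v_avg))


def k0_upper_bound(v_max, v_min, v_avg, sigma_v, sigma_0) -> tuple[float, str]:
    """k0 for the upper-bound threshold E = Vmin + 1/k.

    Returns ``(k0, branch)``: branch ``"upper"`` when the upper-bound
    formula yields a value in (0, 1], otherwise ``"lower_fallback"`` with
    the lower-bound value.
    """
    _check_stats(v_max, v_min, v_avg, sigma_v, sigma_0, need_avg_above_min=True)
    k0pp = (1.0 - sigma_0 / sigma_v) * (v_max - v_min) / (v_avg - v_min)
    if 0.0 < k0pp <= 1.0:
        return k0pp, "upper"
    return k0_lower_bound(v_max, v_min, v_avg, sigma_v, sigma_0), "lower_fallback"


def _check_stats(v_max, v_min, v_avg, sigma_v, sigma_0, need_avg_above_min):
    if sigma_0 < 0:
        raise InvalidParameterError("sigma_0 must be >= 0")
    if not (v_max > v_min):
        raise DegenerateStatisticsError("v_max must exceed v_min")
    if sigma_v <= 0:
        raise DegenerateStatisticsError("sigma_v must be > 0")
    if not (v_min <= v_avg <= v_max):
        raise DegenerateStatisticsError("v_avg must lie within [v_min, v_max]")
    if need_avg_above_min and not (v_avg > v_min):
        raise DegenerateStatisticsError("v_avg must exceed v_min")


@dataclass
class GaMDParams:
    """Boost-potential state for one boosted energy term.

    Running potential-energy statistics (min/max and Welford mean/variance,
    population convention) together with the derived boost parameters.
    ``finalize`` recomputes (k0, k, E) from the current statistics; until
    the statistics can support that (fewer than 2 samples, or a degenerate
    spread) the boost stays inactive and evaluates to zero.
    """

    sigma_0: float
    bound_mode: str = "lower"
    label: str = "V"
    n_samples: int = 0
    v_min: float = math.inf
    v_max: float = -math.inf
    _mean: float = 0.0
    _m2: float = 0.0
    k0: float | None = None
    k: float = 0.0
    threshold_E: float | None = None
    k0_branch: str | None = None

    def __post_init__(self):
        if self.bound_mode not in ("lower", "upper"):
            raise InvalidParameterError("bound_mode must be 'lower' or 'upper'")
        if self.sigma_0 < 0:
            raise InvalidParameterError("sigma_0 must be >= 0")

    # -- statistics --------------------------------------------------------

    def update(self, v: float) -> None:
        v = float(v)
        self.n_samples += 1
        if v < self.v_min:
            self.v_min = v
        if v > self.v_max:
            self.v_max = v
        delta = v - self._mean
        self._mean += delta / self.n_samples
        self._m2 += delta * (v - self._mean)

    @property
    def v_avg(self) -> float:
        return self._mean if self.n_samples else math.nan

    @property
    def sigma_v(self) -> float:
        if self.n_samples < 2:
            return 0.0
        return math.sqrt(self._m2 / self.n_samples)  # population SD

    @property
    def ready(self) -> bool:
        return (
            self.n_samples >= 2
            and self.v_max > self.v_min
            and self.sigma_v > 0
            and self.v_max > self.v_avg
            and (self.bound_mode == "lower" or self.v_avg > self.v_min)
        )

    def finalize(self) -> "GaMDParams":
        """Recompute (k0, k, E) from the collected statistics."""
        if self.sigma_0 == 0.0:
            # zero-boost limit: degenerate to conventional dynamics
            self.k0, self.k, self.k0_branch = 0.0, 0.0, "zero"
            self.threshold_E = self.v_max if self.n_samples else None
            return self
        if not self.ready:
            self.k0, self.k, self.threshold_E, self.k0_branch = None, 0.0, None, None
            return self
        if self.bound_mode == "lower":
            self.k0 = k0_lower_bound(
                self.v_max, self.v_min, self.v_avg, self.sigma_v, self.sigma_0
            )
            self.k0_branch = "lower"
            self.k = self.k0 / (self.v_max - self.v_min)
            self.threshold_E = self.v_max
        else:
            self.k0, self.k0_branch = k0_upper_bound(
                self.v_max, self.v_min, self.v_avg, self.sigma_v, self.sigma_0
            )
            self.k = self.k0 / (self.v_max - self.v_min)
            if self.k0_branch == "upper":
                self.threshold_E = self.v_min + 1.0 / self.k
            else:
                self.threshold_E = self.v_max
        return self

    @property
    def active(self) -> bool:
        return self.k0 is not None and self.k0 > 0.0 and self.k > 0.0

    @property
    def sigma_dv(self) -> float:
        """Gaussian-approximation SD of the boost: k (E - Vavg) sigma_V."""
        if not self.active:
            return 0.0
        return self.k * (self.threshold_E - self.v_avg) * self.sigma_v

    # -- boost evaluation --------------------------------------------------

    def boost(self, v: float) -> float:
        if not self.active or v >= self.threshold_E:
            return 0.0
        return 0.5 * self.k * (self.threshold_E - v) ** 2

    def force_scale(self, v: float) -> float:
        if not self.active or v >= self.threshold_E:
            return 1.0
        return 1.0 - self.k * (self.threshold_E - v)

    def copy(self) -> "GaMDParams":
        return copy.deepcopy(self)

    def summary(self) -> str:
        return (
            f"[{self.label}] n={self.n_samples} Vmax={self.v_max:.6f} "
            f"Vmin={self.v_min:.6f} Vavg={self.v_avg:.6f} sigmaV={self.sigma_v:.6f} "
            f"k0={self.k0 if self.k0 is not None else float('nan'):.6f} "
            f"E={self.threshold_E if self.threshold_E is not None else float('nan'):.6f}"
        )


@dataclass
class DualBoostParams:
    """Independent boost parameters for the peptide (V_L) and rest (V_D) terms."""

    peptide: GaMDParams
    rest: GaMDParams

    def copy(self) -> "DualBoostParams":
        return DualBoostParams(self.peptide.copy(), self.rest.copy())


def boost_potential(v: float, params: GaMDParams) -> float:
    """dV(v) = 1/2 k (E - v)^2 for v < E, else 0."""
    return params.boost(v)


def boosted_force_scale(v: float, params: GaMDParams) -> float:
    """d(v + dV)/dv = 1 - k (E - v) for v < E, else 1."""
    return params.force_scale(v)


def update_statistics(params: GaMDParams, v: float) -> GaMDParams:
    """Fold one potential-energy sample into the running statistics."""
    params.update(v)
    params.finalize()
    return params


# --------------------------------------------------------------------------
# Protocol and trajectory containers
# --------------------------------------------------------------------------

@dataclass
class ProtocolSpec:
    """Staged simulation protocol, in integrator steps.

    Mirrors the production recipe (short conventional stage, boosted
    equilibration with statistics refreshed every ``update_interval``
    steps, then ``n_replicas`` independent frozen-parameter production
    runs) scaled to desk size.
    """

    n_cmd_steps: int = 2000
    n_equil_steps: int = 5000
    n_prod_steps: int = 20000
    n_replicas: int = 3
    dt: float = 0.02
    friction: float = 1.0
    temperature: float = 1.0  # k_B T in energy units
    seed: int = 1
    update_interval: int = 50
    sample_interval: int = 10

    def __post_init__(self):
        for name in ("n_cmd_steps", "n_equil_steps", "n_prod_steps"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.n_replicas < 1:
            raise InvalidParameterError("n_replicas must be >= 1")
        if self.dt <= 0:
            raise InvalidParameterError("dt must be > 0")
        if self.friction <= 0:
            raise InvalidParameterError(
                "friction must be > 0 (pure NVE is not supported)"
            )
        if self.temperature <= 0:
            raise InvalidParameterError("temperature must be > 0")
        if self.update_interval < 1 or self.sample_interval < 1:
            raise InvalidParameterError("intervals must be >= 1")


@dataclass
class TrajectoryRecord:
    """One recorded frame: time, configuration, energy terms, boosts."""

    time: float
    coords: np.ndarray
    v_total: float
    v_peptide: float
    v_rest: float
    dv_peptide: float
    dv_rest: float

    @property
    def dv_total(self) -> float:
        return self.dv_peptide + self.dv_rest


class Trajectory:
    """A sequence of :class:`TrajectoryRecord`, stored as arrays.

    For single-boost (or plain) runs on analytic surfaces the boosted term
    occupies the ``v_peptide`` slot and ``v_rest`` is zero, so the record
    layout is uniform across run types.
    """

    def __init__(self, times, coords, v_peptide, v_rest, dv_peptide, dv_rest):
        self.times = np.asarray(times, dtype=float)
        self.coords = np.asarray(coords, dtype=float)
        self.v_peptide = np.asarray(v_peptide, dtype=float)
        self.v_rest = np.asarray(v_rest, dtype=float)
        self.dv_peptide = np.asarray(dv_peptide, dtype=float)
        self.dv_rest = np.asarray(dv_rest, dtype=float)

    @property
    def v_total(self) -> np.ndarray:
        return self.v_peptide + self.v_rest

    @property
    def dv_total(self) -> np.ndarray:
        return self.dv_peptide + self.dv_rest

    def __len__(self) -> int:
        return len(self.times)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Trajectory(
                self.times[i], self.coords[i], self.v_peptide[i],
                self.v_rest[i], self.dv_peptide[i], self.dv_rest[i],
            )
        return TrajectoryRecord(
            time=float(self.times[i]),
            coords=self.coords[i],
            v_total=float(self.v_peptide[i] + self.v_rest[i]),
            v_peptide=float(self.v_peptide[i]),
            v_rest=float(self.v_rest[i]),
            dv_peptide=float(self.dv_peptide[i]),
            dv_rest=float(self.dv_rest[i]),
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    @staticmethod
    def concatenate(trajs: list["Trajectory"]) -> "Trajectory":
        return Trajectory(
            np.concatenate([t.times for t in trajs]),
            np.concatenate([t.coords for t in trajs]),
            np.concatenate([t.v_peptide for t in trajs]),
            np.concatenate([t.v_rest for t in trajs]),
            np.concatenate([t.dv_peptide for t in trajs]),
            np.concatenate([t.dv_rest for t in trajs]),
        )


@dataclass
class GaMDResult:
    """Staged single-boost run: stage trajectories plus frozen parameters."""

    cmd: Trajectory
    equilibration: Trajectory
    production: list[Trajectory]
    params: GaMDParams
    vmax_exceeded: list[int] = field(default_factory=list)


@dataclass
class PepGaMDResult:
    """Staged dual-boost run."""

    cmd: Trajectory
    equilibration: Trajectory
    production: list[Trajectory]
    params: DualBoostParams
    vmax_exceeded: list[int] = field(default_factory=list)


# --------------------------------------------------------------------------
# Integrator
# --------------------------------------------------------------------------

class _Recorder:
    def __init__(self):
        self.t, self.x = [], []
        self.vp, self.vr, self.dvp, self.dvr = [], [], [], []

    def add(self, t, x, vp, vr, dvp, dvr):
        self.t.append(t)
        self.x.append(np.array(x, copy=True))
        self.vp.append(vp)
        self.vr.append(vr)
        self.dvp.append(dvp)
        self.dvr.append(dvr)

    def trajectory(self) -> Trajectory:
        return Trajectory(self.t, self.x, self.vp, self.vr, self.dvp, self.dvr)


def _surface_eval(surface: PotentialSurface):
    energy, gradient = surface.energy, surface.gradient

    def eval_fn(x):
        return float(energy(x)), 0.0, -gradient(x), 0.0

    return eval_fn


def _integrate(
    eval_fn,
    x,
    p,
    masses,
    n_steps,
    dt,
    friction,
    kbt,
    rng,
    params_L: GaMDParams | None = None,
    params_D: GaMDParams | None = None,
    collect: bool = False,
    refinalize_every: int = 0,
    record_every: int = 0,
    time_offset: float = 0.0,
):
    """BAOAB Langevin loop; returns (x, p, recorder, n_vmax_exceeded).

    The boost (if any) is applied through per-term force scales; statistics
    collection and periodic parameter refresh happen in-loop so the
    equilibration stage sees up-to-date (k0, k, E) every
    ``refinalize_every`` steps.
    """
    x = np.array(x, dtype=float, copy=True)
    p = np.array(p, dtype=float, copy=True)
    inv_m = 1.0 / masses
    sqrt_m_kbt = np.sqrt(masses * kbt)
    half_dt = 0.5 * dt
    c1 = math.exp(-friction * dt)
    c2 = math.sqrt(1.0 - c1 * c1)
    rec = _Recorder() if record_every else None
    n_exceed = 0

    vL, vD, fL, fD = eval_fn(x)
    sL = params_L.force_scale(vL) if params_L is not None else 1.0
    sD = params_D.force_scale(vD) if params_D is not None else 1.0

    chunk = 8192
    s = 0
    while s < n_steps:
        m = min(chunk, n_steps - s)
        noise = rng.standard_normal((m,) + x.shape)
        for i in range(m):
            s += 1
            p += half_dt * (fL * sL + fD * sD)
            x += half_dt * p * inv_m
            p *= c1
            p += c2 * sqrt_m_kbt * noise[i]
            x += half_dt * p * inv_m
            vL, vD, fL, fD = eval_fn(x)
            vt = vL + vD
            if not (-_ENERGY_GUARD < vt < _ENERGY_GUARD):  # also catches NaN
                raise IntegrationInstabilityError(s)
            if params_L is not None:
                sL = params_L.force_scale(vL)
                if collect:
                    params_L.update(vL)
                elif params_L.active and vL > params_L.v_max:
                    n_exceed += 1
            if params_D is not None:
                sD = params_D.force_scale(vD)
                if collect:
                    params_D.update(vD)
                elif params_D.active and vD > params_D.v_max:
                    n_exceed += 1
            p += half_dt * (fL * sL + fD * sD)
            if collect and refinalize_every and s % refinalize_every == 0:
                if params_L is not None:
                    params_L.finalize()
                if params_D is not None:
                    params_D.finalize()
            if record_every and s % record_every == 0:
                dvp = params_L.boost(vL) if params_L is not None else 0.0
                dvr = params_D.boost(vD) if params_D is not None else 0.0
                rec.add(time_offset + s * dt, x, vL, vD, dvp, dvr)
    return x, p, rec, n_exceed


def _prepare(system, protocol):
    """Initial state, masses and evaluation closure for either system kind."""
    if isinstance(system, PotentialSurface):
        if "minima" in system.metadata:
            x0 = np.array(system.metadata["minima"][0], dtype=float)
        else:
            x0 = np.array(
                [0.5 * (lo + hi) for lo, hi in system.domain_bounds], dtype=float
            )
        masses = np.ones_like(x0)
        eval_fn = _surface_eval(system)
    elif isinstance(system, ToyPeptideSystem):
        x0 = system.initial_mobile_coords()
        masses = system.masses[:, None]
        eval_fn = system.energy_forces
    else:
        raise InvalidParameterError(f"unsupported system type {type(system)!r}")
    return x0, masses, eval_fn


def _rng(seed: int) -> np.random.Generator:
    # counter-based generator: independent replica streams from small keys
    return np.random.Generator(np.random.Philox(key=seed & 0x7FFFFFFF))


def _initial_momenta(rng, masses, shape, kbt):
    return np.sqrt(np.broadcast_to(masses, shape) * kbt) * rng.standard_normal(shape)


def run_cmd(system, protocol: ProtocolSpec) -> Trajectory:
    """Conventional (unboosted) Langevin dynamics for ``n_prod_steps``.

    Deterministic for a given seed; all dv columns are zero.
    """
    x0, masses, eval_fn = _prepare(system, protocol)
    rng = _rng(protocol.seed)
    p0 = _initial_momenta(rng, masses, x0.shape, protocol.temperature)
    _, _, rec, _ = _integrate(
        eval_fn, x0, p0, masses, protocol.n_prod_steps, protocol.dt,
        protocol.friction, protocol.temperature, rng,
        record_every=protocol.sample_interval,
    )
    return rec.trajectory()


def _staged_run(
    system,
    protocol: ProtocolSpec,
    params_L: GaMDParams,
    params_D: GaMDParams | None,
    include_cmd_statistics: bool = True,
):
    x, masses, eval_fn = _prepare(system, protocol)
    rng = _rng(protocol.seed)
    p = _initial_momenta(rng, masses, x.shape, protocol.temperature)

    # Stage 1: conventional dynamics, statistics only (no boost active yet:
    # k0 stays None until finalize).
    x, p, rec_cmd, _ = _integrate(
        eval_fn, x, p, masses, protocol.n_cmd_steps, protocol.dt,
        protocol.friction, protocol.temperature, rng,
        params_L=params_L if include_cmd_statistics else None,
        params_D=params_D if include_cmd_statistics else None,
        collect=True, refinalize_every=0,
        record_every=protocol.sample_interval,
    )
    if not include_cmd_statistics:
        # still need a first pass of statistics before boosting; reuse the
        # conventional stage trajectory energies would be biased-free, but
        # the stage above ran without params, so warm up from the current
        # configuration over a short unboosted window.
        x, p, _, _ = _integrate(
            eval_fn, x, p, masses, max(protocol.update_interval, 2), protocol.dt,
            protocol.friction, protocol.temperature, rng,
            params_L=params_L, params_D=params_D, collect=True,
        )
    params_L.finalize()
    if params_D is not None:
        params_D.finalize()

    # Stage 2: boosted equilibration with periodic parameter refresh.
    t0 = protocol.n_cmd_steps * protocol.dt
    x, p, rec_eq, _ = _integrate(
        eval_fn, x, p, masses, protocol.n_equil_steps, protocol.dt,
        protocol.friction, protocol.temperature, rng,
        params_L=params_L, params_D=params_D,
        collect=True, refinalize_every=protocol.update_interval,
        record_every=protocol.sample_interval, time_offset=t0,
    )
    params_L.finalize()
    if params_D is not None:
        params_D.finalize()
    logger.info("equilibration end: %s", params_L.summary())
    if params_D is not None:
        logger.info("equilibration end: %s", params_D.summary())

    # Stage 3: frozen-parameter production, independent replicas.
    t1 = t0 + protocol.n_equil_steps * protocol.dt
    production, exceeded = [], []
    for r in range(protocol.n_replicas):
        rng_r = _rng(protocol.seed + r + 1)
        _, _, rec_p, n_ex = _integrate(
            eval_fn, x, p, masses, protocol.n_prod_steps, protocol.dt,
            protocol.friction, protocol.temperature, rng_r,
            params_L=params_L, params_D=params_D,
            collect=False, record_every=protocol.sample_interval, time_offset=t1,
        )
        production.append(rec_p.trajectory())
        exceeded.append(n_ex)
    return rec_cmd.trajectory(), rec_eq.trajectory(), production, exceeded


def run_gamd(
    system,
    protocol: ProtocolSpec,
    sigma_0: float,
    bound_mode: str = "lower",
    include_cmd_statistics: bool = True,
) -> GaMDResult:
    """Staged single-boost run (boost on the total potential energy)."""
    params = GaMDParams(sigma_0=sigma_0, bound_mode=bound_mode, label="V")
    cmd, eq, prod, exceeded = _staged_run(
        system, protocol, params, None, include_cmd_statistics
    )
    return GaMDResult(cmd=cmd, equilibration=eq, production=prod,
                      params=params, vmax_exceeded=exceeded)


def run_pep_gamd(
    system: ToyPeptideSystem,
    protocol: ProtocolSpec,
    sigma_0_L: float,
    sigma_0_D: float,
    bound_mode: str = "lower",
    include_cmd_statistics: bool = True,
) -> PepGaMDResult:
    """Staged dual-boost run on the toy peptide system.

    One boost acts on the essential peptide energy V_L, the other on the
    remainder V_D; per-frame records carry both boost components so that
    dv_total = dv_peptide + dv_rest drives reweighting.
    """
    if not isinstance(system, ToyPeptideSystem):
        raise InvalidParameterError("run_pep_gamd requires a ToyPeptideSystem")
    if protocol.n_prod_steps <= 0 or protocol.n_equil_steps <= 0:
        raise InvalidParameterError("protocol step counts must be > 0")
    params = DualBoostParams(
        peptide=GaMDParams(sigma_0=sigma_0_L, bound_mode=bound_mode, label="V_L"),
        rest=GaMDParams(sigma_0=sigma_0_D, bound_mode=bound_mode, label="V_D"),
    )
    cmd, eq, prod, exceeded = _staged_run(
        system, protocol, params.peptide, params.rest, include_cmd_statistics
    )
    return PepGaMDResult(cmd=cmd, equilibration=eq, production=prod,
                         params=params, vmax_exceeded=exceeded)
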