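"""Work-loop and isometric protocols.

A work loop drives the half sarcomere with a sinusoidal strain (t = 0 at
maximum length, i.e. the start of shortening), a once-per-cycle activation
pulse at phase phi, and a prescribed lattice-spacing trajectory, then scores
the net mass-specific mechanical work from the area of the stress-strain loop
(positive = motor-like, negative = brake-like).

Lattice-spacing modes
---------------------
isolattice   constant face spacing LS0 throughout the cycle.
poisson      d10 follows axial strain with Poisson ratio nu:
             d10(t) = d10_0 * (1 + dL/L)^(-nu); nu = 0.5 is isovolumetric
             (d10^2 * L constant), nu = 0 reduces to isolattice.
prescribed   a periodic table of d10 offsets (nm) added to the baseline, e.g.
             the synthetic in-vivo-like trace from :func:`make_invivo_trace`.

Stress scaling: the simulated supercell reports force per thick filament; the
areal density of thick filaments in the hexagonal lattice, sqrt(3)/(2 d10^2),
converts it to stress, and work is normalized by muscle density to J/kg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import mechanics
from .activation import ActivationParams, PhasedActivation, periodic_permissiveness
from .crossbridge_kinetics import (RateParams, SpringParams, step_states,
                                   thermal_diffuse)
from .lattice_geometry import (FilamentParams, GeometryConfig,
                               HalfSarcomereState, LatticeState,
                               apply_axial_strain, build_half_sarcomere,
                               d10_to_face_spacing, face_spacing_to_d10,
                               set_lattice_spacing)
from .mechanics import SolverConfig, TitinParams, balance, net_axial_force

__all__ = [
    "ModelParams",
    "WorkloopProtocol",
    "ScalingParams",
    "PrescribedTrace",
    "WorkloopResult",
    "strain_waveform",
    "lattice_trajectory",
    "make_invivo_trace",
    "isovolumetric_fundamental",
    "run_workloop",
    "run_isometric",
    "net_work_per_cycle",
    "phase_sweep",
    "lattice_sweep",
    "stiffness_sweep",
    "titin_sweep",
]


@dataclass(frozen=True)
class ModelParams:
    """Kinetic and mechanical constants bundled for the protocol drivers."""

    springs: SpringParams = SpringParams()
    rates: RateParams = RateParams()
    titin: TitinParams = TitinParams()
    solver: SolverConfig = SolverConfig()


@dataclass(frozen=True)
class PrescribedTrace:
    """Periodic d10 offset table: time (ms) vs delta-d10 (nm)."""

    time: np.ndarray
    dd10: np.ndarray
    period: float

    def __post_init__(self) -> None:
        if self.time.size != self.dd10.size or self.time.size < 2:
            raise ValueError("trace needs matching time/dd10 arrays, length >= 2")
        if abs(self.dd10[0] - self.dd10[-1]) > 0.05 + 1e-9:
            raise ValueError("prescribed trace must be periodic "
                             "(endpoints differ by more than 0.05 nm)")

    def at(self, t) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float) % self.period,
                         self.time, self.dd10)


@dataclass(frozen=True)
class WorkloopProtocol:
    """Strain/activation/lattice program of one work-loop trial.

    n_cycles counts all simulated cycles; the first warmup_cycles are
    discarded (activation transient), so n_cycles - warmup_cycles works are
    recorded.  Defaults record 16 cycles at the in-vivo-like 25 Hz, 10%
    peak-to-peak strain.
    """

    frequency: float = 25.0           # Hz
    peak_to_peak_strain: float = 0.10
    phi: float = 0.0                  # activation phase, cycle fraction
    n_cycles: int = 17
    warmup_cycles: int = 1
    dt: float = 1.0                   # ms
    lattice_mode: str = "isolattice"  # isolattice | poisson | prescribed
    nu: float = 0.0                   # Poisson ratio for 'poisson' mode
    base_face_spacing: float = 15.0   # nm, LS0 at mean strain
    prescribed_trace: PrescribedTrace | None = None
    lattice_class: str = "invertebrate_flight"

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.dt <= 0:
            raise ValueError("frequency and dt must be > 0")
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError("nu must be in [0, 0.5]")
        if self.lattice_mode not in ("isolattice", "poisson", "prescribed"):
            raise ValueError("lattice_mode must be isolattice|poisson|prescribed")
        if self.lattice_mode == "prescribed" and self.prescribed_trace is None:
            raise ValueError("prescribed lattice_mode requires prescribed_trace")
        if self.warmup_cycles >= self.n_cycles:
            raise ValueError("warmup_cycles must be < n_cycles")
        spc = self.period / self.dt
        if abs(spc - round(spc)) > 1e-6:
            raise ValueError("dt must divide the period 1000/frequency")

    @property
    def period(self) -> float:
        """Cycle period, ms."""
        return 1000.0 / self.frequency

    @property
    def steps_per_cycle(self) -> int:
        return round(self.period / self.dt)

    @property
    def base_d10(self) -> float:
        return face_spacing_to_d10(self.base_face_spacing, self.lattice_class)


@dataclass(frozen=True)
class ScalingParams:
    """Force -> stress -> mass-specific work conversions.

    thick_per_m2, if given, overrides the hexagonal-lattice density
    sqrt(3) / (2 d10^2) computed from the protocol's baseline d10.
    """

    muscle_density: float = 1060.0    # kg/m^3
    thick_per_m2: float | None = None

    def __post_init__(self) -> None:
        if self.muscle_density <= 0:
            raise ValueError("muscle_density must be > 0")

    def filament_density(self, d10_nm: float) -> float:
        if self.thick_per_m2 is not None:
            return self.thick_per_m2
        return math.sqrt(3.0) / (2.0 * (d10_nm * 1e-9) ** 2)

    def stress_mN_mm2(self, force_per_thick_pN, d10_nm: float):
        """Stress (mN/mm^2 = kPa) from per-thick-filament force (pN)."""
        pa = np.asarray(force_per_thick_pN) * 1e-12 * self.filament_density(d10_nm)
        return pa / 1e3


@dataclass
class WorkloopResult:
    """Per-timestep traces plus per-cycle net work statistics."""

    time: np.ndarray            # ms
    strain: np.ndarray
    stress: np.ndarray          # mN/mm^2
    permissiveness: np.ndarray
    face_spacing: np.ndarray    # nm
    net_force: np.ndarray       # pN, whole supercell (4 thick filaments)
    n_bound: np.ndarray         # bound heads (weak + strong)
    n_strong: np.ndarray        # strongly bound heads
    per_cycle_work: np.ndarray  # J/kg, recorded cycles only

    @property
    def work_mean(self) -> float:
        return float(np.mean(self.per_cycle_work))

    @property
    def work_sd(self) -> float:
        return float(np.std(self.per_cycle_work, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.time, "strain": self.strain, "stress": self.stress,
            "permissiveness": self.permissiveness,
            "face_spacing": self.face_spacing, "net_force": self.net_force,
            "n_bound": self.n_bound, "n_strong": self.n_strong,
        })


def strain_waveform(t, protocol: WorkloopProtocol):
    """eps(t) = (p2p/2) * cos(2 pi f t): maximum length at t = 0."""
    t = np.asarray(t, dtype=float)
    amp = 0.5 * protocol.peak_to_peak_strain
    out = amp * np.cos(2.0 * math.pi * protocol.frequency * t / 1000.0)
    return out if out.ndim else float(out)


def lattice_trajectory(t, strain, protocol: WorkloopProtocol):
    """Face spacing (nm) at time t given the protocol's lattice mode."""
    strain = np.asarray(strain, dtype=float)
    gf = d10_to_face_spacing(1.0, protocol.lattice_class, r_sum=0.0)
    if protocol.lattice_mode == "isolattice":
        out = np.full_like(strain, protocol.base_face_spacing)
    elif protocol.lattice_mode == "poisson":
        # face spacing tracks the d10 excursion: dLS = gf * dd10
        dd10 = protocol.base_d10 * ((1.0 + strain) ** (-protocol.nu) - 1.0)
        out = protocol.base_face_spacing + gf * dd10
    else:
        out = protocol.base_face_spacing + gf * protocol.prescribed_trace.at(t)
    return out if out.ndim else float(out)


def isovolumetric_fundamental(protocol: WorkloopProtocol, n: int = 512):
    """(amplitude nm, phase rad) of the fundamental of the nu=0.5 d10 trace."""
    t = np.arange(n) / n * protocol.period
    eps = strain_waveform(t, protocol)
    dd10 = protocol.base_d10 * ((1.0 + eps) ** -0.5 - 1.0)
    c = np.fft.rfft(dd10)[1] * 2.0 / n
    return float(np.abs(c)), float(np.angle(c))


def make_invivo_trace(amplitude: float, phase_lead: float,
                      n_harmonics: int = 1,
                      protocol: WorkloopProtocol | None = None,
                      n: int = 512) -> PrescribedTrace:
    """Synthetic in-vivo-like periodic d10 trace (a labeled stand-in).

    Takes the Fourier harmonics of the isovolumetric (nu = 0.5) trajectory,
    rescales them so the fundamental has the requested amplitude (nm of d10),
    and advances every harmonic by phase_lead cycles.  With amplitude matched
    to the isovolumetric fundamental and zero lead, the trace reproduces the
    isovolumetric trajectory to first harmonic exactly.  This emulates the
    measured hawkmoth lattice dynamics qualitatively - phase-advanced relative
    to isovolumetric, with smaller peak excursion - and is synthetic, not
    experimental data.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    protocol = protocol or WorkloopProtocol()
    t = np.arange(n + 1) / n * protocol.period
    eps = strain_waveform(t[:-1], protocol)
    dd10_iso = protocol.base_d10 * ((1.0 + eps) ** -0.5 - 1.0)
    coef = np.fft.rfft(dd10_iso) / n
    a1 = 2.0 * np.abs(coef[1])
    scale = 0.0 if a1 == 0 else amplitude / a1
    out = np.zeros_like(t)
    for k in range(1, min(n_harmonics, len(coef) - 1) + 1):
        ck = 2.0 * coef[k] * scale
        out += np.abs(ck) * np.cos(2.0 * math.pi * k * (t / protocol.period
                                                        + phase_lead)
                                   + np.angle(ck))
    return PrescribedTrace(time=t, dd10=out, period=protocol.period)


def net_work_per_cycle(stress, strain, rho: float = 1060.0,
                       closure_tol: float = 1e-6) -> float:
    """Mass-specific net work (J/kg) of one closed stress-strain loop.

    W = -closed-loop integral of sigma d-eps / rho (trapezoidal); positive
    when stress is higher during shortening (motor-like).  stress in mN/mm^2,
    rho in kg/m^3.  The strain trace must close on itself.
    """
    stress = np.asarray(stress, dtype=float)
    strain = np.asarray(strain, dtype=float)
    if stress.shape != strain.shape or stress.ndim != 1 or stress.size < 3:
        raise ValueError("stress and strain must be matching 1-D traces")
    if abs(strain[0] - strain[-1]) > closure_tol:
        raise ValueError(
            f"strain trajectory is not closed: endpoints differ by "
            f"{abs(strain[0] - strain[-1]):.3g}")
    pa = stress * 1e3
    loop = np.trapezoid(pa, strain)
    return float(-loop / rho)


# ---------------------------------------------------------------------------
# drivers

def _simulate(state: HalfSarcomereState, model: ModelParams, dt: float,
              n_steps: int, rng: np.random.Generator,
              strain_fn, spacing_fn, perm_fn):
    """Shared timestep loop: boundary -> diffuse -> transitions -> balance."""
    nt = n_steps + 1
    rec = {k: np.empty(nt) for k in
           ("time", "strain", "permissiveness", "face_spacing", "net_force",
            "n_bound", "n_strong")}
    for i in range(nt):
        t = i * dt
        eps = strain_fn(t)
        perm = perm_fn(t)
        apply_axial_strain(state, eps)
        set_lattice_spacing(state, spacing_fn(t, eps))
        if i > 0:  # record the initial balanced state before any kinetics
            thermal_diffuse(state, model.springs, model.rates, rng)
            step_states(state, model.springs, model.rates, perm, dt, rng)
        balance(state, model.springs, model.titin, model.solver)
        state.time = t
        rec["time"][i] = t
        rec["strain"][i] = eps
        rec["permissiveness"][i] = perm
        rec["face_spacing"][i] = state.lattice.face_spacing
        rec["net_force"][i] = net_axial_force(state)
        rec["n_bound"][i] = int(np.count_nonzero(state.head_state > 0))
        rec["n_strong"][i] = int(np.count_nonzero(state.head_state == 2))
    return rec


def run_workloop(state: HalfSarcomereState, protocol: WorkloopProtocol,
                 activation: ActivationParams, scaling: ScalingParams,
                 rng: np.random.Generator | int,
                 model: ModelParams | None = None) -> WorkloopResult:
    """Simulate one work-loop trial and score per-cycle net work.

    Per timestep: impose boundary strain and lattice spacing, thermally
    diffuse unbound heads, draw stochastic state transitions at the current
    permissiveness, rebalance the lattice, record net force.  Per-cycle works
    are computed for every cycle after the warmup.
    """
    model = model or ModelParams()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    phased = PhasedActivation(phi=protocol.phi, period=protocol.period,
                              params=activation)
    spc = protocol.steps_per_cycle
    n_steps = spc * protocol.n_cycles

    rec = _simulate(
        state, model, protocol.dt, n_steps, rng,
        strain_fn=lambda t: strain_waveform(t, protocol),
        spacing_fn=lambda t, eps: lattice_trajectory(t, eps, protocol),
        perm_fn=lambda t: periodic_permissiveness(t, phased))

    stress = scaling.stress_mN_mm2(rec["net_force"] / state.config.n_thick,
                                   protocol.base_d10)
    works = []
    for c in range(protocol.warmup_cycles, protocol.n_cycles):
        sl = slice(c * spc, (c + 1) * spc + 1)
        works.append(net_work_per_cycle(stress[sl], rec["strain"][sl],
                                        scaling.muscle_density))
    return WorkloopResult(
        time=rec["time"], strain=rec["strain"], stress=stress,
        permissiveness=rec["permissiveness"],
        face_spacing=rec["face_spacing"], net_force=rec["net_force"],
        n_bound=rec["n_bound"], n_strong=rec["n_strong"],
        per_cycle_work=np.asarray(works))


def run_isometric(state: HalfSarcomereState, duration: float,
                  activation_fn, scaling: ScalingParams,
                  rng: np.random.Generator | int,
                  model: ModelParams | None = None, dt: float = 1.0,
                  face_spacing: float | None = None) -> pd.DataFrame:
    """Fixed-length simulation (twitch, tetanus) returning per-step traces.

    activation_fn maps time (ms) to permissiveness in [0, 1]; pass
    ``lambda t: 1.0`` for a saturating tetanus.
    """
    model = model or ModelParams()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    ls = face_spacing if face_spacing is not None else state.lattice.face_spacing
    n_steps = round(duration / dt)
    rec = _simulate(state, model, dt, n_steps, rng,
                    strain_fn=lambda t: 0.0,
                    spacing_fn=lambda t, eps: ls,
                    perm_fn=lambda t: float(activation_fn(t)))
    d10 = face_spacing_to_d10(ls, state.lattice.lattice_class,
                              state.lattice.r_sum)
    df = pd.DataFrame(rec)
    df["stress"] = scaling.stress_mN_mm2(df["net_force"] / state.config.n_thick,
                                         d10)
    return df


# ---------------------------------------------------------------------------
# sweeps

def _fresh_state(protocol: WorkloopProtocol,
                 geometry: GeometryConfig | None,
                 filaments: FilamentParams | None) -> HalfSarcomereState:
    lattice = LatticeState(face_spacing=protocol.base_face_spacing,
                           lattice_class=protocol.lattice_class)
    return build_half_sarcomere(geometry, filaments, lattice)


def _spawn_seeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def phase_sweep(phis, protocol: WorkloopProtocol, activation: ActivationParams,
                scaling: ScalingParams, seed: int,
                model: ModelParams | None = None,
                geometry: GeometryConfig | None = None,
                filaments: FilamentParams | None = None) -> pd.DataFrame:
    """Independent work-loop trials over activation phases."""
    rows = []
    for phi, rng in zip(phis, _spawn_seeds(seed, len(phis))):
        p = replace(protocol, phi=float(phi))
        res = run_workloop(_fresh_state(p, geometry, filaments), p, activation,
                           scaling, rng, model)
        rows.append({"phi": float(phi), "work_mean": res.work_mean,
                     "work_sd": res.work_sd,
                     "n_cycles": res.per_cycle_work.size})
    return pd.DataFrame(rows)


def lattice_sweep(spacings, protocol: WorkloopProtocol,
                  activation: ActivationParams, scaling: ScalingParams,
                  seed: int, model: ModelParams | None = None,
                  geometry: GeometryConfig | None = None,
                  filaments: FilamentParams | None = None) -> pd.DataFrame:
    """Work-loop trials over baseline face spacings at fixed phase."""
    if np.any(np.asarray(spacings, dtype=float) <= 0):
        raise ValueError("spacings must be > 0")
    rows = []
    for ls, rng in zip(spacings, _spawn_seeds(seed, len(spacings))):
        p = replace(protocol, base_face_spacing=float(ls))
        res = run_workloop(_fresh_state(p, geometry, filaments), p, activation,
                           scaling, rng, model)
        rows.append({"face_spacing": float(ls), "work_mean": res.work_mean,
                     "work_sd": res.work_sd,
                     "n_cycles": res.per_cycle_work.size})
    return pd.DataFrame(rows)


def stiffness_sweep(protocol: WorkloopProtocol, activation: ActivationParams,
                    scaling: ScalingParams, seed: int,
                    phis=(0.0,), spacings=(15.0,),
                    factors=((("k_r",), 0.5), (("k_r",), 1.5),
                             (("k_theta",), 0.5), (("k_theta",), 1.5)),
                    model: ModelParams | None = None,
                    geometry: GeometryConfig | None = None,
                    filaments: FilamentParams | None = None) -> pd.DataFrame:
    """Grid of net work under scaled head-spring stiffnesses.

    Each factor entry is (fields, factor): the named SpringParams fields are
    multiplied by factor.  Results are reported alongside the default-
    stiffness grid as dwork = work - work_default at the same (phi, LS).
    """
    model = model or ModelParams()
    conditions = [((), 1.0)] + [tuple(f) for f in factors]
    grid = [(phi, ls) for phi in phis for ls in spacings]
    seeds = _spawn_seeds(seed, len(conditions) * len(grid))
    rows = []
    i = 0
    for fields, factor in conditions:
        springs = model.springs
        for name in fields:
            springs = replace(springs, **{name: getattr(springs, name) * factor})
        m = replace(model, springs=springs)
        for phi, ls in grid:
            p = replace(protocol, phi=float(phi), base_face_spacing=float(ls))
            res = run_workloop(_fresh_state(p, geometry, filaments), p,
                               activation, scaling, seeds[i], m)
            rows.append({"fields": "+".join(fields) or "default",
                         "factor": factor, "phi": float(phi),
                         "face_spacing": float(ls),
                         "work_mean": res.work_mean, "work_sd": res.work_sd})
            i += 1
    df = pd.DataFrame(rows)
    base = df[df["fields"] == "default"].set_index(["phi", "face_spacing"])
    df["dwork"] = [
        row.work_mean - base.loc[(row.phi, row.face_spacing), "work_mean"]
        for row in df.itertuples()]
    return df


def titin_sweep(b_values, protocol: WorkloopProtocol,
                activation: ActivationParams, scaling: ScalingParams,
                seed: int, phis=(0.0,), model: ModelParams | None = None,
                geometry: GeometryConfig | None = None,
                filaments: FilamentParams | None = None) -> pd.DataFrame:
    """Work vs phase for a range of titin exponential stiffnesses b (1/um)."""
    model = model or ModelParams()
    seeds = _spawn_seeds(seed, len(list(b_values)) * len(phis))
    rows = []
    i = 0
    for b in b_values:
        m = replace(model, titin=replace(model.titin, b=float(b)))
        for phi in phis:
            p = replace(protocol, phi=float(phi))
            res = run_workloop(_fresh_state(p, geometry, filaments), p,
                               activation, scaling, seeds[i], m)
            rows.append({"titin_b": float(b), "phi": float(phi),
                         "work_mean": res.work_mean, "work_sd": res.work_sd})
            i += 1
    return pd.DataFrame(rows)
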