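"""Two-spring myosin head energetics and three-state stochastic kinetics.

Each myosin head is a torsional spring at its base (stiffness k_theta, rest
angle r_theta) in series with a linear spring along the arm (stiffness k_r,
rest length r_r).  The power stroke (weak -> strong transition) shifts both
equilibria: the head's tip equilibrium swings ~8.8 nm toward the M-line.

Kinetic states: 0 unbound, 1 weakly bound, 2 strongly bound.  Forward rates
(per ms, distances in nm)::

    r12 = tau * exp(-d^2) + baseline        d: axial diffused-tip-to-site distance
    r23 = A * (1 + tanh(C + D*(U1 - U2)))
    r31 = max(0, G*U2 + H)                  r13 = 0 (ATP-driven, irreversible)

Reverse rates follow detailed balance, so a strained bound head unbinds at a
rate that grows without bound with its elastic energy::

    r21 = r12 * exp(U1 - U0)
    r32 = r23 * exp(U2 - U1)

The small baseline in r12 keeps r21 from collapsing at extreme strain (it
enforces an "infinite well": far from the site, r12 floors at `baseline` while
exp(U1) explodes), which is what lets the model survive rapid in-vivo-scale
length oscillations.

Free energies are U0 = 0 for the unbound reference and
U_i = alpha_i + E_i / energy_scale for the bound states, with E_i the spring
distortion energy at that state's equilibria (pN nm), alpha_i the chemistry
baseline offsets (binding for state 1, post-hydrolysis for state 2) and
``energy_scale`` the energy normalization of the rate equations.  alpha_1,
alpha_2 and energy_scale are calibration constants (see docs/methods.md): they
are frozen so that the mean steady-state crossbridge force during an isometric
tetanus lands at 8-10 pN.  Thermal motion of unbound heads always uses the
physical kT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lattice_geometry import HalfSarcomereState

__all__ = [
    "SpringParams",
    "RateParams",
    "MyosinHead",
    "head_energy",
    "free_energy",
    "thermal_diffuse",
    "rate_r12",
    "rate_r21",
    "rate_r23",
    "rate_r32",
    "rate_r31",
    "transition_probability",
    "step_states",
    "bound_axial_offset",
    "bound_configuration",
]

#: thermal energy at ~25 C, pN nm
KT = 4.11


@dataclass(frozen=True)
class SpringParams:
    """Stiffnesses and pre/post-power-stroke equilibria of the head springs.

    Angles are stored in radians; the config layer accepts degrees.
    """

    k_theta: float = 4000.0                       # pN nm / rad
    k_r: float = 16.0                             # pN / nm
    r_theta_pre: float = math.radians(47.16)      # rad
    r_theta_post: float = math.radians(73.20)     # rad
    r_r_pre: float = 19.96                        # nm
    r_r_post: float = 16.47                       # nm

    def __post_init__(self) -> None:
        if self.k_theta <= 0 or self.k_r <= 0:
            raise ValueError("spring stiffnesses must be > 0")

    def equilibria(self, stroke_state: str) -> tuple[float, float]:
        """(rest arm length, rest base angle) for 'pre' or 'post' stroke."""
        if stroke_state == "pre":
            return self.r_r_pre, self.r_theta_pre
        if stroke_state == "post":
            return self.r_r_post, self.r_theta_post
        raise ValueError("stroke_state must be 'pre' or 'post'")

    def tip_rest(self, stroke_state: str) -> tuple[float, float]:
        """Rest tip position (axial, radial) relative to the head base, nm."""
        r, th = self.equilibria(stroke_state)
        return r * math.cos(th), r * math.sin(th)


@dataclass(frozen=True)
class RateParams:
    """Rate constants of the three-state scheme plus energy normalization."""

    tau: float = 72.0        # 1/ms, binding prefactor
    baseline: float = 0.005  # 1/ms, distance-independent binding floor
    A: float = 0.8           # 1/ms, power-stroke prefactor
    C: float = 6.0           # dimensionless, power-stroke gate offset
    D: float = 0.2           # dimensionless, power-stroke gate gain
    G: float = 0.6           # 1/ms per free-energy unit, ATPase detachment gain
    H: float = 0.02          # 1/ms, ATPase detachment floor
    kT: float = KT           # pN nm, thermal energy for head diffusion
    energy_scale: float = 17.5   # pN nm per free-energy unit in the rates
    alpha1: float = -2.0     # binding free-energy drop, state 1 offset
    alpha2: float = -19.5    # post-hydrolysis offset, state 2
    d_scale: float = 1.0     # nm, length scale of the exponent in r12

    def __post_init__(self) -> None:
        for name in ("tau", "baseline", "A", "G", "H"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.kT <= 0 or self.energy_scale <= 0 or self.d_scale <= 0:
            raise ValueError("kT, energy_scale and d_scale must be > 0")


@dataclass
class MyosinHead:
    """Scalar view of one motor (the simulator itself uses flat arrays)."""

    state: int = 0           # 0 unbound, 1 weakly bound, 2 strongly bound
    theta: float = 0.0       # rad
    r: float = 0.0           # nm
    bound_site: int | None = None

    def __post_init__(self) -> None:
        if (self.bound_site is None) != (self.state == 0):
            raise ValueError("bound_site must be set iff the head is bound")


# ---------------------------------------------------------------------------
# energetics

def head_energy(r, theta, springs: SpringParams, stroke_state: str):
    """Spring distortion energy (pN nm) at configuration (r, theta)."""
    r_eq, th_eq = springs.equilibria(stroke_state)
    return 0.5 * springs.k_r * (np.asarray(r) - r_eq) ** 2 + \
        0.5 * springs.k_theta * (np.asarray(theta) - th_eq) ** 2


def free_energy(r, theta, springs: SpringParams, rates: RateParams,
                state_index: int):
    """Free energy U_i of a head configuration, in rate-equation units."""
    if state_index == 0:
        return np.zeros_like(np.asarray(r, dtype=float))
    stroke = "pre" if state_index == 1 else "post"
    alpha = rates.alpha1 if state_index == 1 else rates.alpha2
    return alpha + head_energy(r, theta, springs, stroke) / rates.energy_scale


def thermal_diffuse(state: HalfSarcomereState, springs: SpringParams,
                    rates: RateParams, rng: np.random.Generator) -> HalfSarcomereState:
    """Resample every unbound head's (r, theta) from its Boltzmann distribution.

    Each quadratic spring gives a Gaussian centered on the pre-stroke rest
    value with variance kT/k.
    """
    unbound = np.nonzero(state.head_state == 0)[0]
    n = unbound.size
    if n == 0:
        return state
    sd_r = math.sqrt(rates.kT / springs.k_r)
    sd_th = math.sqrt(rates.kT / springs.k_theta)
    state.head_r[unbound] = rng.normal(springs.r_r_pre, sd_r, n)
    state.head_theta[unbound] = rng.normal(springs.r_theta_pre, sd_th, n)
    return state


# ---------------------------------------------------------------------------
# rate functions

def rate_r12(d, params: RateParams):
    """Binding rate (1/ms) at axial tip-to-site distance d (nm)."""
    d = np.asarray(d, dtype=float)
    return params.tau * np.exp(-((d / params.d_scale) ** 2)) + params.baseline


def rate_r21(r12, delta_u1):
    """Unbinding rate: r12 * exp(U1 - U0).

    delta_u1 is the weakly-bound free energy in excess of the unbound state.
    Because r12 never falls below its baseline, r21 grows without bound as the
    bound head is strained (delta_u1 -> +inf) instead of collapsing to zero.
    """
    return np.asarray(r12) * np.exp(delta_u1)


def rate_r23(delta_u12, params: RateParams):
    """Power-stroke rate A*(1 + tanh(C + D*(U1 - U2)))."""
    return params.A * (1.0 + np.tanh(params.C + params.D * np.asarray(delta_u12)))


def rate_r32(r23, delta_u21):
    """Reverse power stroke: r23 * exp(U2 - U1) (detailed balance)."""
    return np.asarray(r23) * np.exp(delta_u21)


def rate_r31(u2, params: RateParams):
    """ATP-driven detachment from the strong state: max(0, G*U2 + H)."""
    return np.maximum(0.0, params.G * np.asarray(u2) + params.H)


def transition_probability(rate, dt: float):
    """p = 1 - exp(-rate * dt) for a Poisson transition in a step of dt ms."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be >= 0")
    return 1.0 - np.exp(-rate * dt)


# ---------------------------------------------------------------------------
# bound-head geometry

def bound_axial_offset(state: HalfSarcomereState, heads: np.ndarray) -> np.ndarray:
    """Axial offset b = x_site - x_base for bound heads."""
    base = state.thick_x[state.head_thick[heads], state.head_crown[heads]]
    return state.site_x(state.head_site[heads]) - base


def bound_configuration(b, face_spacing: float):
    """(r, theta) of a bound head spanning axial offset b and the face gap."""
    b = np.asarray(b, dtype=float)
    r = np.hypot(b, face_spacing)
    theta = np.arctan2(face_spacing, b)
    return r, theta


def _bound_energies(state: HalfSarcomereState, springs: SpringParams,
                    rates: RateParams, heads: np.ndarray):
    """U1, U2 and the rest-tip distance d for currently bound heads."""
    ls = state.lattice.face_spacing
    b = bound_axial_offset(state, heads)
    r, th = bound_configuration(b, ls)
    u1 = rates.alpha1 + head_energy(r, th, springs, "pre") / rates.energy_scale
    u2 = rates.alpha2 + head_energy(r, th, springs, "post") / rates.energy_scale
    ax, rad = springs.tip_rest("pre")
    # distance of the site from the pre-stroke rest tip: axial distortion
    # plus the radial reach deficit (see step_states)
    d_rest = np.hypot(b - ax, max(0.0, ls - rad))
    return u1, u2, d_rest


# ---------------------------------------------------------------------------
# stochastic stepping

def _binding_candidates(state: HalfSarcomereState, springs: SpringParams):
    """For each unbound head: nearest free site on its facing filament.

    Returns (heads, flat site index, tip axial offset to site, radial tip
    position); heads with no eligible site are dropped.
    """
    cfg = state.config
    unbound = np.nonzero(state.head_state == 0)[0]
    if unbound.size == 0:
        return (np.empty(0, dtype=int),) * 2 + (np.empty(0),) * 2

    base = state.thick_x[state.head_thick[unbound], state.head_crown[unbound]]
    tip_ax = base + state.head_r[unbound] * np.cos(state.head_theta[unbound])
    tip_rad = state.head_r[unbound] * np.sin(state.head_theta[unbound])
    fil = state.head_thin[unbound]

    ns = cfg.thin_sites_per_filament
    site_idx = np.empty(unbound.size, dtype=np.int64)
    for f in np.unique(fil):
        m = fil == f
        xs = state.thin_x[f]
        j = np.searchsorted(xs, tip_ax[m])
        j0 = np.clip(j - 1, 0, ns - 1)
        j1 = np.clip(j, 0, ns - 1)
        pick_hi = np.abs(xs[j1] - tip_ax[m]) < np.abs(xs[j0] - tip_ax[m])
        site_idx[m] = np.where(pick_hi, j1, j0)

    flat = fil * ns + site_idx
    dx = state.site_x(flat) - tip_ax
    ok = (np.abs(dx) <= cfg.binding_window) & (state.site_occupant[flat] < 0)
    return unbound[ok], flat[ok], dx[ok], tip_rad[ok]


def step_states(state: HalfSarcomereState, springs: SpringParams,
                rates: RateParams, permissiveness: float, dt: float,
                rng: np.random.Generator) -> HalfSarcomereState:
    """One stochastic kinetics step: each head makes at most one transition.

    Unbound heads bind with probability permissiveness * (1 - exp(-r12*dt))
    to their nearest eligible site (one head per site; conflicts resolved by a
    random priority order, losers refused).  Bound heads choose among their
    outgoing transitions by a single uniform draw partitioned proportionally
    to the competing rates, so total per-step transition probability is
    1 - exp(-sum(r)*dt) <= 1 even at saturating rates.
    """
    if not 0.0 <= permissiveness <= 1.0:
        raise ValueError("permissiveness must be in [0, 1]")
    ls = state.lattice.face_spacing

    # --- draw all transitions against the start-of-step configuration
    heads_b, sites_b, dx_b, tip_rad_b = _binding_candidates(state, springs)
    # d combines the axial tip-to-site offset with the radial reach deficit:
    # a head whose thermally displaced tip falls short of the site's radial
    # plane is penalized by the shortfall, while a closer-than-reach plane
    # costs nothing (the arm folds compliantly), so binding falls off
    # monotonically as the lattice spacing grows.  The bound free energies
    # carry the rest of the lattice-spacing dependence.
    d = np.hypot(dx_b, np.maximum(0.0, ls - tip_rad_b))
    p_bind = permissiveness * transition_probability(rate_r12(d, rates), dt)
    want = rng.random(heads_b.size) < p_bind
    heads_b, sites_b = heads_b[want], sites_b[want]
    # site exclusivity: random priority, first claim wins
    if heads_b.size:
        order = rng.permutation(heads_b.size)
        _, first = np.unique(sites_b[order], return_index=True)
        keep = order[first]
        heads_b, sites_b = heads_b[keep], sites_b[keep]

    weak = np.nonzero(state.head_state == 1)[0]
    strong = np.nonzero(state.head_state == 2)[0]

    weak_dest = np.empty(0, dtype=int)
    if weak.size:
        u1, u2, d_rest = _bound_energies(state, springs, rates, weak)
        r21 = rate_r21(rate_r12(d_rest, rates), u1)
        r23 = rate_r23(u1 - u2, rates)
        weak_dest = _competing_draw(np.stack([r21, r23]), dt, rng)

    strong_dest = np.empty(0, dtype=int)
    if strong.size:
        u1, u2, _ = _bound_energies(state, springs, rates, strong)
        r32 = rate_r32(rate_r23(u1 - u2, rates), u2 - u1)
        r31 = rate_r31(u2, rates)
        strong_dest = _competing_draw(np.stack([r32, r31]), dt, rng)

    # --- apply
    if heads_b.size:
        state.head_state[heads_b] = 1
        state.head_site[heads_b] = sites_b
        state.site_occupant[sites_b] = heads_b

    if weak.size:
        unbind = weak[weak_dest == 0]
        stroke = weak[weak_dest == 1]
        _release(state, unbind, springs)
        state.head_state[stroke] = 2

    if strong.size:
        revert = strong[strong_dest == 0]
        detach = strong[strong_dest == 1]
        state.head_state[revert] = 1
        _release(state, detach, springs)

    state.balanced = False
    return state


def _release(state: HalfSarcomereState, heads: np.ndarray,
             springs: SpringParams) -> None:
    if heads.size == 0:
        return
    state.site_occupant[state.head_site[heads]] = -1
    state.head_site[heads] = -1
    state.head_state[heads] = 0
    # released heads relax to rest; next thermal_diffuse resamples them
    state.head_r[heads] = springs.r_r_pre
    state.head_theta[heads] = springs.r_theta_pre


def _competing_draw(rate_rows: np.ndarray, dt: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Competing-risks selection: -1 for no transition, else the row index.

    P(any transition) = 1 - exp(-total*dt); the winning channel is chosen
    proportionally to its rate.
    """
    total = rate_rows.sum(axis=0)
    n = rate_rows.shape[1]
    dest = np.full(n, -1, dtype=int)
    p_any = 1.0 - np.exp(-total * dt)
    u = rng.random(n)
    go = u < p_any
    if not np.any(go):
        return dest
    # partition [0, p_any) proportionally to the channel rates
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, u / np.where(p_any > 0, p_any, 1.0), 1.0)
    cum = np.cumsum(rate_rows, axis=0) / np.where(total > 0, total, 1.0)
    for k in range(rate_rows.shape[0]):
        pick = go & (dest == -1) & (frac <= cum[k])
        dest[pick] = k
    return dest
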