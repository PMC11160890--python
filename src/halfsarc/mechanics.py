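"""Force laws and the axial equilibrium solver.

Every node of the filament lattice must carry zero net axial force at the end
of each timestep: filament backbone springs, attached crossbridges, and titin
(an exponential spring tying each thick filament's Z-ward tip to the Z-disk,
F = a*exp(b*dL) with dL the half-sarcomere length change) all contribute.  The
solver is a block Newton/fixed-point sweep: each filament is a tridiagonal
chain solved exactly with the crossbridge loads linearized at the current
configuration, iterated filament-by-filament until the largest per-node
residual is below tolerance.  The net axial force of the half sarcomere is the
tension in the M-line anchoring segment of each thick filament (positive =
contractile, pulling the M-line toward the Z-disk).

Lattice spacing is prescribed, so crossbridge radial force components are
computed (and reported) but have no degree of freedom to act on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .crossbridge_kinetics import SpringParams, bound_axial_offset
from .lattice_geometry import HalfSarcomereState

__all__ = [
    "TitinParams",
    "SolverConfig",
    "SolverError",
    "crossbridge_force",
    "xb_axial_force_stiffness",
    "titin_force",
    "assemble_node_forces",
    "balance",
    "net_axial_force",
]


@dataclass(frozen=True)
class TitinParams:
    """Exponential titin spring F = a * exp(b * dL), dL in um from rest."""

    a: float = 260.0   # pN
    b: float = 4.0     # 1/um, swept 4-10

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("titin a and b must be > 0")


@dataclass(frozen=True)
class SolverConfig:
    tolerance: float = 1e-3        # pN residual per node
    max_iterations: int = 10_000
    relaxation: float = 1.0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


class SolverError(RuntimeError):
    """Equilibrium relaxation failed to converge; carries the residual."""

    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(
            f"force balance did not converge: residual {residual:.3g} pN "
            f"after {iterations} iterations")


def titin_force(delta_L: float, params: TitinParams) -> float:
    """Titin tension (pN) at half-sarcomere length change delta_L (um)."""
    return params.a * math.exp(params.b * delta_L)


def xb_axial_force_stiffness(b, face_spacing: float, springs: SpringParams,
                             stroke_state: str):
    """Axial crossbridge force on the bound site, and its stiffness.

    A bound head spans axial offset b (site minus base) and the radial face
    gap, so its configuration is r = hypot(b, LS), theta = atan2(LS, b).  The
    force on the site is -dE/db (negative pulls the site toward the M-line,
    i.e. contractile for a post-stroke head at large b); the reaction +dE/db
    acts on the base node.  Also returns d2E/db2 for solver linearization.
    """
    b = np.asarray(b, dtype=float)
    ls = face_spacing
    r = np.hypot(b, ls)
    theta = np.arctan2(ls, b)
    r_eq, th_eq = springs.equilibria(stroke_state)
    dr, dth = r - r_eq, theta - th_eq
    drdb, dthdb = b / r, -ls / r ** 2
    e_prime = springs.k_r * dr * drdb + springs.k_theta * dth * dthdb
    e_second = (springs.k_r * (drdb ** 2 + dr * ls ** 2 / r ** 3)
                + springs.k_theta * (dthdb ** 2 + dth * 2.0 * ls * b / r ** 4))
    return -e_prime, e_second


def crossbridge_force(state: HalfSarcomereState, head: int,
                      springs: SpringParams) -> tuple[float, float]:
    """(axial, radial) force a bound head exerts on its binding site, pN.

    Restoring force of the two-spring system at the head's current (r, theta)
    relative to its state's equilibria (pre-stroke for weak, post for strong).
    The radial component is informational only: the lattice spacing is
    prescribed.
    """
    if state.head_state[head] == 0:
        raise ValueError(f"head {head} is unbound; crossbridge force undefined")
    stroke = "pre" if state.head_state[head] == 1 else "post"
    ls = state.lattice.face_spacing
    b = float(bound_axial_offset(state, np.array([head]))[0])
    r = math.hypot(b, ls)
    theta = math.atan2(ls, b)
    r_eq, th_eq = springs.equilibria(stroke)
    dr, dth = r - r_eq, theta - th_eq
    f_ax = -(springs.k_r * dr * (b / r) + springs.k_theta * dth * (-ls / r ** 2))
    f_rad = -(springs.k_r * dr * (ls / r) + springs.k_theta * dth * (b / r ** 2))
    return f_ax, f_rad


def _xb_loads(state: HalfSarcomereState, springs: SpringParams):
    """Per-bound-head site force/stiffness plus index arrays.

    Returns (heads, base filament, base crown, site filament, site index,
    force-on-site, stiffness>=0 clipped for solver SPD-ness).
    """
    heads = state.bound_heads()
    if heads.size == 0:
        z = np.empty(0)
        zi = np.empty(0, dtype=int)
        return zi, zi, zi, zi, zi, z, z
    ls = state.lattice.face_spacing
    b = bound_axial_offset(state, heads)
    stroke = np.where(state.head_state[heads] == 1, 0, 1)
    f_site = np.empty(heads.size)
    k_lin = np.empty(heads.size)
    for s, name in enumerate(("pre", "post")):
        m = stroke == s
        if np.any(m):
            f, k = xb_axial_force_stiffness(b[m], ls, springs, name)
            f_site[m] = f
            k_lin[m] = np.maximum(k, 0.0)
    ns = state.config.thin_sites_per_filament
    flat = state.head_site[heads]
    return (heads, state.head_thick[heads], state.head_crown[heads],
            flat // ns, flat % ns, f_site, k_lin)


def assemble_node_forces(state: HalfSarcomereState, springs: SpringParams,
                         titin: TitinParams):
    """Net axial force on every node: (thick (nT,nc), thin (nA,ns)) in pN.

    Thick node 0 hangs from the M-line by one backbone segment; the last
    thick node carries titin tension (toward the Z-disk).  Thin filaments
    anchor at the moving Z-disk on their last node's far side.
    """
    cfg = state.config
    kT_, kA = state.filaments.k_thick, state.filaments.k_thin

    # backbone spring forces, thick: anchor at x=0
    x = state.thick_x
    left = np.concatenate([np.zeros((cfg.n_thick, 1)), x[:, :-1]], axis=1)
    ext_lo = x - left - cfg.crown_spacing          # extension of segment below node
    f_lo = -kT_ * ext_lo                            # pulls node toward M-line if stretched
    f_hi = np.concatenate([kT_ * ext_lo[:, 1:], np.zeros((cfg.n_thick, 1))], axis=1)
    thick_f = f_lo + f_hi
    dl_um = (state.length - state.rest_length) / 1000.0
    thick_f[:, -1] += titin_force(dl_um, titin)

    # thin: anchor at x=L beyond the last node
    y = state.thin_x
    right = np.concatenate([y[:, 1:], np.full((cfg.n_thin, 1), state.length)], axis=1)
    ext_hi = right - y - cfg.site_spacing          # extension of segment above node
    f_hi2 = kA * ext_hi
    f_lo2 = np.concatenate([np.zeros((cfg.n_thin, 1)), -kA * ext_hi[:, :-1]], axis=1)
    thin_f = f_hi2 + f_lo2

    _, btf, btc, stf, sti, f_site, _ = _xb_loads(state, springs)
    if f_site.size:
        np.add.at(thin_f, (stf, sti), f_site)
        np.add.at(thick_f, (btf, btc), -f_site)
    return thick_f, thin_f


def balance(state: HalfSarcomereState, springs: SpringParams,
            titin: TitinParams, solver: SolverConfig | None = None
            ) -> HalfSarcomereState:
    """Relax all node positions until every axial residual <= tolerance.

    Gauss-Seidel fixed-point over the crossbridge coupling; exact tridiagonal
    Newton solve per filament chain (crossbridge loads linearized at the
    current offsets, stiffness clipped at zero).  Converges in a few sweeps
    because crossbridge stiffness is small against the filament backbone.
    The inner loop runs in a numba kernel; :func:`assemble_node_forces` is the
    pure-python reference the kernel is tested against.
    """
    from ._solver import balance_kernel

    solver = solver or SolverConfig()
    heads = state.bound_heads()
    ns = state.config.thin_sites_per_filament
    flat = state.head_site[heads]
    dl_um = (state.length - state.rest_length) / 1000.0
    resid, _its = balance_kernel(
        state.thick_x, state.thin_x, state.length,
        float(state.filaments.k_thick), float(state.filaments.k_thin),
        float(state.config.crown_spacing), float(state.config.site_spacing),
        float(titin_force(dl_um, titin)),
        state.head_thick[heads], state.head_crown[heads],
        flat // ns, flat % ns,
        (state.head_state[heads] == 2).astype(np.bool_),
        float(state.lattice.face_spacing),
        float(springs.k_r), float(springs.k_theta),
        float(springs.r_r_pre), float(springs.r_theta_pre),
        float(springs.r_r_post), float(springs.r_theta_post),
        float(solver.tolerance), int(solver.max_iterations),
        float(solver.relaxation))
    if resid > solver.tolerance:
        raise SolverError(float(resid), solver.max_iterations)
    state.balanced = True
    return state


def net_axial_force(state: HalfSarcomereState) -> float:
    """Net contractile force (pN): summed M-line anchor-segment tension.

    The force each thick filament's M-line-proximal node exerts on the M-line
    is the tension of its anchoring backbone segment.  Positive pulls the
    M-line toward the Z-disk.
    """
    if not state.balanced:
        raise RuntimeError("state is not balanced; call mechanics.balance first")
    ext = state.thick_x[:, 0] - state.config.crown_spacing
    return float(np.sum(state.filaments.k_thick * ext))
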