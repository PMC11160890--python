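"""Half-sarcomere lattice geometry.

The contractile unit is modeled as a 3-D spring lattice: 4 myosin-containing
thick filaments and 8 actin-containing thin filaments (the 2:1 vertebrate-style
arrangement, one thin filament equidistant between three thick) in a
transversely periodic supercell, so that every thick filament interacts with 6
thin filaments.  Thick filaments carry crowns of 3 myosin heads every 14.3 nm
(azimuthally 120 deg apart, adjacent crowns rotated 60 deg); thin filaments
carry binding sites every 38.7 nm.  The 42.9 nm helical repeat of the crowns is
deliberately out of register with the 38.7 nm site repeat.

Radial geometry is prescribed, not dynamic: the single face spacing (the
surface-to-surface actin-myosin distance, ``LS``) enters every head-to-site
distance computation.  The crystallographic d10 spacing measured by x-ray
diffraction converts to face spacing via a muscle-class geometry factor:
center-to-center actin-myosin distance is (2/3) d10 in vertebrate muscle and
(1/sqrt 3) d10 in invertebrate flight muscle; the combined filament radii are
subtracted to give the face spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GeometryConfig",
    "FilamentParams",
    "LatticeState",
    "HalfSarcomereState",
    "GEOMETRY_FACTORS",
    "build_half_sarcomere",
    "d10_to_face_spacing",
    "face_spacing_to_d10",
    "apply_axial_strain",
    "set_lattice_spacing",
    "head_to_site_distance",
]

#: center-to-center actin-myosin distance as a fraction of d10
GEOMETRY_FACTORS = {
    "vertebrate": 2.0 / 3.0,
    "invertebrate_flight": 1.0 / math.sqrt(3.0),
}

#: combined thick + thin filament radii, nm.  Reproduces the standard printed
#: conversion pairs (47.5 nm d10 -> 15 nm LS and 45.9 -> 14 in invertebrate
#: flight muscle; 38 nm d10 -> 12.8 nm LS in vertebrate muscle) within 0.1 nm.
DEFAULT_R_SUM = 12.5


class ConfigurationError(ValueError):
    """Invalid geometry/lattice configuration; message names the field."""


@dataclass(frozen=True)
class GeometryConfig:
    """Counts and spacings of the filament lattice.

    Defaults give a physiological-length thick filament (60 crowns x 14.3 nm =
    858 nm) in a 1250 nm half sarcomere (2.5 um sarcomere), 720 heads total.
    """

    n_thick: int = 4
    n_thin: int = 8
    crowns_per_thick: int = 60
    thin_sites_per_filament: int = 28
    crown_spacing: float = 14.3         # nm, thick-filament node repeat
    site_spacing: float = 38.7          # nm, thin-filament binding-site repeat
    rest_hs_length: float = 1250.0      # nm, half-sarcomere rest length L0
    r_thick_plus_r_thin: float = DEFAULT_R_SUM   # nm
    lattice_class: str = "invertebrate_flight"
    binding_window: float = 16.0        # nm, axial search window for eligible sites

    def __post_init__(self) -> None:
        if self.n_thick < 1:
            raise ConfigurationError("n_thick must be >= 1")
        if self.n_thin != 2 * self.n_thick:
            raise ConfigurationError("n_thin must equal 2 * n_thick")
        for name in ("crown_spacing", "site_spacing", "rest_hs_length",
                     "binding_window"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.crowns_per_thick < 1:
            raise ConfigurationError("crowns_per_thick must be >= 1")
        if self.thin_sites_per_filament < 1:
            raise ConfigurationError("thin_sites_per_filament must be >= 1")
        if self.lattice_class not in GEOMETRY_FACTORS:
            raise ConfigurationError(
                f"lattice_class must be one of {sorted(GEOMETRY_FACTORS)}")
        span = self.crown_spacing * self.crowns_per_thick
        if span >= self.rest_hs_length:
            raise ConfigurationError(
                "crowns_per_thick * crown_spacing must fit inside rest_hs_length")

    @property
    def heads_per_crown(self) -> int:
        return 3

    @property
    def n_heads(self) -> int:
        return self.n_thick * self.crowns_per_thick * self.heads_per_crown


@dataclass(frozen=True)
class FilamentParams:
    """Series-spring stiffness of the filament backbones.

    Stiffnesses are per segment (one crown repeat for thick, one site repeat
    for thin); rest lengths are the corresponding repeats.
    """

    k_thick: float = 2020.0   # pN/nm per 14.3 nm segment
    k_thin: float = 1760.0    # pN/nm per 38.7 nm segment

    def __post_init__(self) -> None:
        if self.k_thick <= 0:
            raise ConfigurationError("k_thick must be > 0")
        if self.k_thin <= 0:
            raise ConfigurationError("k_thin must be > 0")


def d10_to_face_spacing(d10: float, lattice_class: str = "invertebrate_flight",
                        r_sum: float = DEFAULT_R_SUM) -> float:
    """Convert crystallographic d10 spacing to actin-myosin face spacing (nm).

    face = geometry_factor * d10 - r_sum, where the geometry factor is the
    muscle-class-specific ratio of actin-myosin center distance to d10.
    """
    if d10 <= 0:
        raise ValueError("d10 must be > 0")
    face = GEOMETRY_FACTORS[lattice_class] * d10 - r_sum
    if face <= 0:
        raise ValueError(
            f"d10 = {d10} nm gives non-positive face spacing {face:.3f} nm")
    return face


def face_spacing_to_d10(face_spacing: float,
                        lattice_class: str = "invertebrate_flight",
                        r_sum: float = DEFAULT_R_SUM) -> float:
    """Inverse of :func:`d10_to_face_spacing`."""
    if face_spacing <= 0:
        raise ValueError("face_spacing must be > 0")
    return (face_spacing + r_sum) / GEOMETRY_FACTORS[lattice_class]


@dataclass(frozen=True)
class LatticeState:
    """Prescribed radial geometry of the myofilament lattice."""

    face_spacing: float = 15.0               # nm, actin-myosin surface-to-surface
    lattice_class: str = "invertebrate_flight"
    r_sum: float = DEFAULT_R_SUM             # nm, combined filament radii

    def __post_init__(self) -> None:
        if self.face_spacing <= 0:
            raise ValueError("face_spacing must be > 0")

    @property
    def geometry_factor(self) -> float:
        return GEOMETRY_FACTORS[self.lattice_class]

    @property
    def d10(self) -> float:
        return face_spacing_to_d10(self.face_spacing, self.lattice_class,
                                   self.r_sum)


def _neighbor_maps(config: GeometryConfig):
    """Transverse supercell geometry: thick/thin positions and facing maps.

    Thick filaments sit on a hexagonal lattice (supercell 2x2 primitive cells,
    periodic); thin filaments occupy the two trigonal interstices per cell.
    Returns (thick_neighbors, head_facing) where thick_neighbors[t] is the
    sorted array of the 6 distinct thin filaments around thick t, and
    head_facing maps (thick, azimuth-slot 0..5) -> thin filament index.
    """
    a = 1.0  # nearest thick-thick distance; map is purely combinatorial
    a1 = np.array([a, 0.0])
    a2 = np.array([0.5 * a, 0.5 * math.sqrt(3.0) * a])
    A1, A2 = 2 * a1, 2 * a2  # supercell vectors

    cells = [(0, 0), (1, 0), (0, 1), (1, 1)]
    thick_xy = np.array([i * a1 + j * a2 for i, j in cells])
    thin_xy = np.array(
        [i * a1 + j * a2 + (a1 + a2) * frac
         for i, j in cells for frac in (1.0 / 3.0, 2.0 / 3.0)])

    # periodic images of thin filaments
    shifts = [m * A1 + n * A2 for m in (-1, 0, 1) for n in (-1, 0, 1)]
    # head azimuth slots: 30 + 60*k degrees, aligned with the six trigonal
    # directions so each head faces exactly one thin filament
    slot_angles = np.deg2rad(30 + 60 * np.arange(6))

    thick_neighbors = []
    head_facing = np.empty((len(thick_xy), 6), dtype=int)
    for t, txy in enumerate(thick_xy):
        for k, ang in enumerate(slot_angles):
            direction = np.array([math.cos(ang), math.sin(ang)])
            best, best_d = -1, np.inf
            for s in range(len(thin_xy)):
                for sh in shifts:
                    rel = thin_xy[s] + sh - txy
                    d = np.linalg.norm(rel)
                    if d < 1e-9:
                        continue
                    # must lie along the slot direction
                    if np.dot(rel, direction) / d > 0.999 and d < best_d:
                        best, best_d = s, d
            if best < 0:  # pragma: no cover - geometry is fixed
                raise ConfigurationError("no facing thin filament for slot")
            head_facing[t, k] = best
        thick_neighbors.append(np.unique(head_facing[t]))
    return thick_neighbors, head_facing


@dataclass
class HalfSarcomereState:
    """Full spatial state of the half sarcomere.

    Axial coordinate x runs from the M-line (x = 0) to the Z-disk (x = L).
    Thick filaments anchor at the M-line; thin filaments anchor at the Z-disk
    and point back toward the M-line.  Head kinetic state: 0 unbound, 1 weakly
    bound, 2 strongly bound.
    """

    config: GeometryConfig
    filaments: FilamentParams
    lattice: LatticeState
    # node axial positions, nm
    thick_x: np.ndarray          # (n_thick, crowns_per_thick)
    thin_x: np.ndarray           # (n_thin, thin_sites_per_filament), ascending
    # per-head arrays, flat ordering: (thick, crown, head-in-crown)
    head_state: np.ndarray       # (n_heads,) int in {0, 1, 2}
    head_site: np.ndarray        # (n_heads,) flat site index, -1 if unbound
    head_r: np.ndarray           # (n_heads,) arm length of unbound diffused head
    head_theta: np.ndarray       # (n_heads,) base angle of unbound diffused head
    # static maps
    head_thick: np.ndarray       # (n_heads,) thick filament index
    head_crown: np.ndarray       # (n_heads,) crown index on that filament
    head_thin: np.ndarray        # (n_heads,) facing thin filament index
    thick_neighbors: list        # per thick filament: array of 6 thin indices
    site_occupant: np.ndarray    # (n_thin * sites,) head index, -1 if free
    length: float = 0.0          # nm, current L
    rest_length: float = 0.0     # nm, L0
    time: float = 0.0            # ms
    balanced: bool = False       # set by mechanics.balance, cleared on any change

    @property
    def strain(self) -> float:
        return self.length / self.rest_length - 1.0

    @property
    def n_heads(self) -> int:
        return self.head_state.size

    def site_flat(self, fil: np.ndarray, idx: np.ndarray) -> np.ndarray:
        """Flat index of site ``idx`` on thin filament ``fil``."""
        return fil * self.config.thin_sites_per_filament + idx

    def site_x(self, flat: np.ndarray) -> np.ndarray:
        """Axial position of sites given flat indices."""
        n = self.config.thin_sites_per_filament
        return self.thin_x[flat // n, flat % n]

    def bound_heads(self) -> np.ndarray:
        return np.nonzero(self.head_state > 0)[0]

    def copy(self) -> "HalfSarcomereState":
        return replace(
            self,
            thick_x=self.thick_x.copy(),
            thin_x=self.thin_x.copy(),
            head_state=self.head_state.copy(),
            head_site=self.head_site.copy(),
            head_r=self.head_r.copy(),
            head_theta=self.head_theta.copy(),
            site_occupant=self.site_occupant.copy(),
        )


def build_half_sarcomere(config: GeometryConfig | None = None,
                         filaments: FilamentParams | None = None,
                         lattice: LatticeState | None = None,
                         ) -> HalfSarcomereState:
    """Construct the rest-state spring lattice.

    All heads start unbound at their pre-stroke rest configuration (the rest
    arm length / base angle are filled in by the kinetics module on first
    diffusion; initialized here to zeros), all filament springs at rest and
    node positions at their unstrained repeats.
    """
    config = config or GeometryConfig()
    filaments = filaments or FilamentParams()
    lattice = lattice or LatticeState()

    nT, nA = config.n_thick, config.n_thin
    nc, ns = config.crowns_per_thick, config.thin_sites_per_filament
    L0 = config.rest_hs_length

    # thick node i at (i+1) * crown_spacing: node 0 hangs off the M-line by
    # one rest segment (that anchoring segment transmits the net force)
    thick_x = np.tile((np.arange(1, nc + 1) * config.crown_spacing), (nT, 1))
    # thin site j at L - (ns - j) * site_spacing, ascending in x; the last
    # (j = ns-1) is one rest segment from the Z-disk anchor
    thin_x = np.tile(L0 - (ns - np.arange(ns)) * config.site_spacing, (nA, 1))
    if thin_x[0, 0] <= 0:
        raise ConfigurationError(
            "thin_sites_per_filament * site_spacing exceeds rest_hs_length")

    thick_neighbors, head_facing = _neighbor_maps(config)

    n_heads = config.n_heads
    head_thick = np.repeat(np.arange(nT), nc * 3)
    head_crown = np.tile(np.repeat(np.arange(nc), 3), nT)
    # azimuth slot: crown c holds slots (0,2,4) shifted by 1 on odd crowns
    # (120 deg within a crown, 60 deg rotation between adjacent crowns)
    head_in_crown = np.tile(np.arange(3), nT * nc)
    slot = (2 * head_in_crown + (head_crown % 2)) % 6
    head_thin = head_facing[head_thick, slot]

    return HalfSarcomereState(
        config=config,
        filaments=filaments,
        lattice=lattice,
        thick_x=thick_x.astype(float),
        thin_x=thin_x.astype(float),
        head_state=np.zeros(n_heads, dtype=np.int8),
        head_site=np.full(n_heads, -1, dtype=np.int64),
        head_r=np.zeros(n_heads),
        head_theta=np.zeros(n_heads),
        head_thick=head_thick,
        head_crown=head_crown,
        head_thin=head_thin,
        thick_neighbors=thick_neighbors,
        site_occupant=np.full(nA * ns, -1, dtype=np.int64),
        length=L0,
        rest_length=L0,
        time=0.0,
    )


def apply_axial_strain(state: HalfSarcomereState, strain: float) -> HalfSarcomereState:
    """Move the Z-disk boundary to L0*(1+strain) (absolute, not cumulative).

    Thin filaments translate rigidly with the Z-disk (their anchor); internal
    equilibration is the balance solver's job.  Thick filaments stay (they
    anchor at the fixed M-line).
    """
    if abs(strain) >= 0.5:
        raise ValueError("strain magnitude must be < 0.5")
    new_len = state.rest_length * (1.0 + strain)
    state.thin_x += new_len - state.length
    state.length = new_len
    state.balanced = False
    return state


def set_lattice_spacing(state: HalfSarcomereState, face_spacing: float) -> HalfSarcomereState:
    """Prescribe the radial face spacing used by all head-site distances."""
    if face_spacing <= 0:
        raise ValueError("face_spacing must be > 0")
    state.lattice = replace(state.lattice, face_spacing=face_spacing)
    state.balanced = False
    return state


def head_to_site_distance(state: HalfSarcomereState, head: int, site_flat: int) -> float:
    """Euclidean distance from a head's tip axial station to a binding site.

    Combines the axial offset between the head's current tip position and the
    site with the prescribed radial face spacing.  The site must be on the
    head's facing (periodic-neighbor) thin filament.
    """
    ns = state.config.thin_sites_per_filament
    fil = site_flat // ns
    if fil != state.head_thin[head]:
        raise LookupError(
            f"site {site_flat} is on thin filament {fil}, not the facing "
            f"filament {state.head_thin[head]} of head {head}")
    base = state.thick_x[state.head_thick[head], state.head_crown[head]]
    tip_ax = base + state.head_r[head] * math.cos(state.head_theta[head])
    dx = state.thin_x[fil, site_flat % ns] - tip_ax
    return math.hypot(dx, state.lattice.face_spacing)
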