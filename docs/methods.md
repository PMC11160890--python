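# Methods

## Scope and model family

`halfsarc` implements a spatially explicit half-sarcomere model in the
multifilament spring-lattice tradition: filaments are chains of linear
springs, myosin heads are discrete two-spring mechanisms with three kinetic
states, activation is a scalar actin permissiveness, and the radial
actin-myosin spacing is a prescribed input rather than a dynamical degree of
freedom. The package's purpose is to quantify how work-loop output (net
mass-specific work under sinusoidal strain with periodic activation) depends
on the myofilament lattice spacing and its trajectory within the cycle.

## Geometry

* 4 thick / 8 thin filaments in a transversely periodic supercell; thick
  filaments on a hexagonal lattice, thin filaments at the trigonal
  interstices, so each thick filament interacts with 6 thin filaments and
  each thin filament serves 3. The facing map is constructed from the actual
  2-D supercell geometry at build time.
* Thick filaments carry 60 crowns at 14.3 nm (858 nm, a physiological
  filament length), 3 heads per crown, 120° apart, adjacent crowns rotated
  60°; head azimuth slots are aligned with the six trigonal directions so
  every head faces exactly one thin filament. Thin filaments carry 28
  binding sites at 38.7 nm. With the default 1250 nm half-sarcomere rest
  length (2.5 µm sarcomere), the filament overlap engages ~48 crowns.
  We deliberately simulate a full-length filament rather than a reduced one:
  net force is reported per thick filament and converted to stress with the
  real hexagonal filament density, so a shortened filament would understate
  stress and work roughly in proportion to the missing overlap.
* d10 conversions: center-to-center actin-myosin distance is (2/3)·d10
  (vertebrate) or d10/√3 (invertebrate flight); face spacing subtracts the
  combined filament radii, default 12.5 nm, chosen because it reproduces the
  standard printed conversion pairs (47.5 → 15 nm, 45.9 → 14 nm invertebrate
  flight; 38 → 12.8 nm vertebrate) within 0.1 nm. Simulations are centered
  on a face spacing of 15 nm (d10 ≈ 47.6 nm in flight-muscle packing).

## Mechanics

Backbone stiffnesses are per segment: 2020 pN/nm (thick, 14.3 nm repeat) and
1760 pN/nm (thin, 38.7 nm repeat). Titin is one exponential spring per thick
filament, F = a·e^(b·ΔL) with a = 260 pN, b = 4 µm⁻¹ (swept 4–10), ΔL the
half-sarcomere length change in µm from rest; the 260 pN pre-load at rest is
retained and appears as a constant passive offset (~100 mN/mm² of stress)
that cancels exactly in net work because titin is conservative and the
lattice spacing it might act on radially is prescribed.

Equilibration: after every kinetics step each node's axial position is
relaxed until the largest net node force is ≤ 10⁻³ pN (Gauss–Seidel over
filaments; each filament chain solved exactly as a tridiagonal Newton system
with crossbridge loads linearized at the current offsets and their stiffness
clipped at zero for definiteness; deterministic sweep order thick-then-thin).
The inner loop is a numba kernel; the pure-python force assembly is kept as
the reference implementation and the tests assert the kernel against it and
against an independent `scipy.optimize.root` solution on small instances.
Thick filaments pin to the M-line through one anchoring backbone segment
whose tension, summed over filaments, is the reported net force; thin
filaments pin to the (moving) Z-disk.

## Crossbridge energetics and rates

A bound head spanning axial offset b and face gap LS has arm length
r = √(b² + LS²) and base angle θ = atan2(LS, b). State free energies are

    U0 = 0,   U1 = α1 + E_pre/ε,   U2 = α2 + E_post/ε

with E the two-spring distortion energy at the pre- or post-stroke
equilibria, ε the rate-equation energy normalization, and α1, α2 chemistry
offsets. Three of these constants — ε, α1, α2 — are not printed constants of
this model family and are calibration artifacts (below). Thermal motion of
unbound heads always uses the physical kT = 4.11 pN·nm: each spring's
coordinate is resampled every step from its Boltzmann Gaussian (variance
kT/k), which the tests verify to 3 s.e. at 10⁵ draws and by a KS test.

Why ε is not kT: with the stiffened springs (k_θ = 4000 pN·nm/rad,
k_r = 16 pN/nm) the pre→post equilibrium shift at the binding position costs
~500 pN·nm ≈ 120 kT. If U were normalized by physical kT, the power-stroke
gate tanh(C + D(U1−U2)) could never open anywhere a weakly bound head
survives, and the model would produce essentially no force or work. The rate
equations therefore run on an effective energy unit ε ≈ 4 kT, which restores
the soft-spring energetics the rate constants were originally shaped for
while forces keep the stiff springs.

Reverse rates follow detailed balance, r21 = r12·e^(U1−U0) and
r32 = r23·e^(U2−U1), so equilibrium favors the lower free-energy state and a
strained bound head unbinds at an exploding rate (the r12 baseline of
0.005 ms⁻¹ guarantees r21 never collapses far from the site). The binding
distance d in r12 combines the axial offset of the thermally displaced tip
from the site with the radial *reach deficit* max(0, LS − y_tip): a site
plane closer than the tip's thermal reach costs nothing (the arm folds
compliantly), while falling short of a wide lattice is Gaussian-penalized.
This one-sided convention is a deliberate design choice: it makes binding
monotonically less likely as lattice spacing grows, which together with the
bound-state energetics produces the observed phenomenology — compressed,
drag-dominated (brake-like) behavior at 12–14 nm, motor-like output at
15–16 nm, and a falloff beyond.

Transitions are per-step Bernoulli draws, p = 1 − e^(−r·dt); competing exits
from a state are resolved by one uniform draw partitioned proportionally to
the rates, so the total per-step transition probability never exceeds
1 − e^(−Σr·dt). Binding probability is multiplied by the actin
permissiveness; one head per site, conflicts resolved by a random priority
order each step.

## The timestep is part of the model definition

dt defaults to 1 ms (the rates are stated per ms, and transition
probabilities per step). This is not an innocent numerical choice: the
stochastic state machine has an explicit minimum one-step state residence,
and at 25 Hz the filaments slide up to ~10 nm per millisecond. As dt → 0
this rate family is provably brake-like at every phase and spacing — heads
bind at the weak-state energy minimum, so every weak excursion is
dissipative, and the linear detachment gate r31 = G·U2 + H releases strong
heads at the same elastic energy level they entered, so strong-state transit
extracts no net work in continuous time (we verified this numerically down
to dt = 0.03 ms: net work decreases monotonically with dt toward large
negative values, the failure mode this model family was modified to escape).
The motor behavior lives in the 1-ms discretized process. Consequently the
package treats dt = 1 ms as part of the model definition, ships a
self-convergence test that documents the residual dt dependence (expected to
fail between 0.5 and 0.25 ms), and makes no claim that work output is a
timestep-converged quantity.

## Activation

Permissiveness is a product-of-exponentials pulse: saturating rise
(τ_rise = 4 ms) during a 13 ms stimulus window — so peak permissiveness is
13 ms after onset — then exponential decay with half-life 3 ms. For work
loops the pulse recurs once per cycle with onset at phase ϕ of the strain
cycle (ϕ = 0 at the start of shortening); tails are summed across cycle
boundaries and clipped at the ceiling. The time constants are calibration
artifacts tuned so that isometric twitch force rises over ~20 ms and the
phase sweep shows the expected motor/brake alternation; they are not
literature constants. `fit_twitch` exposes a descriptor-matching optimizer
(time-to-peak, half-relaxation, peak fraction of tetanus) for re-fitting.
One caveat: at strictly isometric conditions a residual force plateau
remains after a twitch, because strongly bound heads near their energy
minimum have r31 = 0 and nothing slides them away; any length change clears
them. Twitch descriptors are therefore measured against the late-time floor.

## Work loops and scaling

Strain is ε(t) = (p2p/2)·cos(2πft), f = 25 Hz, peak-to-peak 0.10. Lattice
modes: isolattice (constant), poisson (d10 ∝ (1+ΔL/L)^−ν; ν = 0.5
isovolumetric, d10²·L invariant to machine precision), prescribed (periodic
Δd10 table). The synthetic in-vivo-like trace rescales the isovolumetric
Fourier fundamental to 0.75× amplitude and advances it by 0.1 cycle,
matching the qualitative description of measured hawkmoth lattice dynamics
(phase-advanced, smaller excursion); it is clearly a synthetic stand-in, not
data. Stress = force per thick filament × √3/(2·d10²) (hexagonal areal
density, ~3.8×10¹⁴ m⁻² at d10 = 47.6 nm); work per cycle W = −∮σ dε / ρ with
ρ = 1060 kg/m³; per-trial statistics are mean ± s.d. across recorded cycles
(default 16, first cycle discarded as activation transient).

## Calibration of (ε, α1, α2) and what it can and cannot deliver

The three free-energy constants were frozen by grid scan
(`scripts/calibrate.py`) against the model's grounding behaviors: a
sustained isometric tetanus; positive work at face spacing 15 nm near
ϕ = 0 and maximal around ϕ = 0.8 with brake-like output near ϕ = 0.5;
monotone work increase across 12 → 16 nm with the sign changing between 14
and 15 nm. Final defaults: ε = 17.5 pN·nm, α1 = −2, α2 = −19.5. At this
point (128-cycle precision): W ≈ −0.76 (12 nm), −0.12 (14), +0.10 (15),
+0.24 (16) J/kg at ϕ = 0; −1.0 at ϕ = 0.5; +1.4 at ϕ = 0.8; mean active
force per bound crossbridge at tetanus ≈ 24 pN.

Known limitations, stated plainly:

* The 1-nm sign switch exists (the zero crossing sits between 14 and 15 nm)
  but the contrast per nanometer (~0.25 J/kg) is several-fold weaker than
  the reference behavior of this model family, so resolving both signs needs
  long trials (~100+ cycles), and 16-cycle means at 14/15 nm are dominated
  by cycle noise.
* Brake-side magnitudes are small: the discrete recording misses drag
  impulses shorter than one step, so strongly negative conditions (low
  spacing, mid-cycle activation) come out a factor of ~3–5 weaker than the
  family's reference values.
* Mean force per bound crossbridge at tetanus (~24 pN) exceeds the nominal
  8–10 pN single-molecule stroke scale; within this rate family we found no
  parameterization that meets 8–10 pN while preserving the work-loop sign
  structure, and we prioritized the latter.
* The phase of peak negative work falls near ϕ ≈ 0.2–0.3 rather than
  ϕ ≈ 0.4–0.5; the isovolumetric-vs-constant-lattice enhancement at ϕ = 0.2
  (~+0.2 J/kg averaged over 14–18 nm) therefore rides on a negative rather
  than positive baseline at 15 nm.

## What the synthetic inputs do and do not emulate

All inputs are generated: there is no experimental data in the package. The
synthetic lattice trajectories reproduce amplitude, phase and periodicity of
the lattice-spacing signal class, not any measured trace; passing tests
therefore demonstrate internal consistency of the model and its documented
phenomenology, not agreement with any particular muscle. Real muscle
additionally has passive elasticity far above the model's, activation-
dependent titin, emergent (force-coupled) lattice spacing, and inter-
sarcomere heterogeneity, all explicitly out of scope.

## Numerical choices

* Solver tolerance 10⁻³ pN per node, max 10⁴ sweeps (typically 3–6);
  crossbridge stiffness clipped at ≥0 in the Jacobian only.
* RNG: one numpy PCG64 generator per trial, consumed in a fixed vectorized
  order; sweeps derive per-condition generators from a root SeedSequence, so
  any (config, seed) pair reproduces bit for bit.
* Binding search window ±16 nm around the tip (at most one candidate site at
  the 38.7 nm site repeat); ties cannot occur, site conflicts are refused
  against a per-step random priority.
* Degenerate inputs (non-positive spacings, open loop integrals, aperiodic
  prescribed traces, over-strained boundaries) raise typed errors early.
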