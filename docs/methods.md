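# Methods

`perisim` couples a particle model of a fluid-filled contractile tube to
an online Q-learning agent that must discover peristaltic coordination.
This note documents the model, its numerical choices, the reduced-scale
presets, and what the test suite does and does not demonstrate.

## Physical model

**Geometry.** A cylinder of length L (periodic along the axis, x) and
diameter D, filled with fluid particles and wrapped in a membrane of
solid particles. The membrane is partitioned into `n_slices = 10` equal
axial sections — the contraction units. The reference scale is
L = 0.6 m, D = 5 mm, 12,078 fluid + 2,500 membrane particles.

**Fluid (weakly-compressible SPH).** Summation density
ρ_i = Σ_j m_j W(r_ij, h) over fluid neighbours (self term included),
with a cubic-spline kernel of support 2h and h = 9 mm. Pressure from
the Tait equation of state

    P = (c0² ρ0 / 7) [(ρ/ρ0)⁷ − 1],

with ρ0 = 1000 kg/m³. A variant with prefactor c0·ρ0/7 is selectable
(`tait_prefactor_mode="as_printed"`); it is not dimensionally a pressure
and is provided for strict comparability only — the squared form is the
default. c0 is a *numerical* sound speed: it is chosen per run so that
flow speeds stay below ~c0/10 (weak-compressibility rule); the default
c0 = 1 m/s comfortably covers the ~1 cm/s flows this system develops,
and keeps the acoustic CFL limit (≈ 0.25 h/c0 = 2.25 ms) above the
fixed time step.

Viscosity is the Monaghan-type pair term

    Π_ij = −a h (c0/ρ_ij) (v_ij · r_ij) / (r_ij² + b h²),

with ρ_ij = ρ_i + ρ_j, b = 0.01, applied for all pair velocities (no
approach-only gating). The coefficient `a` is derived from the physical
kinematic viscosity ν = μ/ρ0 = 10⁻⁴ m²/s through the standard
correspondence ν ≈ a·h·c0 / (2(d+2)), d = 3
(`perisim.core.viscosity_coefficient`); with the defaults a ≈ 0.111.
The momentum equation is the symmetric SPH form
F_i = −Σ m_i m_j (P_i/ρ_i² + P_j/ρ_j² + Π_ij) ∇_i W, which conserves
momentum pair by pair.

**Membrane (lattice springs).** Hookean bonds F = k(r − r_rest) with
k = 9×10⁻² N/m between wall particles within 1.1× the largest lattice
spacing at build time; rest lengths are the as-built pair distances
(nominal spacing r0 = 6 mm at full scale). Each wall particle is
tethered to its build position with a weak spring k′ = 5×10⁻⁴ N/m that
restores the shape after contractions. Contraction of a section applies
a constant force f0 = 4×10⁻⁴ N to each of its particles, directed
radially at the axis; the actuation is purely transverse (its summed
axial component is identically zero), switching on/off instantaneously
at action boundaries.

**Interface.** Fluid and wall exchange (i) the same pair-viscosity term
as the fluid interior — the no-slip approximation — with wall particles
entering at the constant density ρ0, and (ii) a repulsive barrier
U = A[1 + cos(π r/r0_rep)] for r < r0_rep, A = 2×10⁻⁶ J, that prevents
compenetration. Both act on fluid–solid pairs only.

*Repulsion range.* The barrier's nominal range equals the membrane bond
spacing (6 mm) in the reference parameter set, which exceeds the tube
radius (2.5 mm): taken literally, every fluid particle repels every
wall particle at all times and the membrane balloons to more than twice
the stated diameter, destroying the geometry the model is supposed to
have. `perisim` therefore reads the repulsion as what its role implies —
a *contact* barrier — and the presets set `r0_repulsive` to the fluid
lattice contact scale (≈ one lattice spacing: 0.9 mm at full/desk3d
resolution, 1.5 mm for the coarse `tiny` preset). The config default
retains 6 mm for strict comparability; the knob is independent of the
bond spacing.

**Integration.** Velocity Verlet with Δt = 10⁻³ s, forces re-evaluated
at the new positions each step; neighbour lists (linked cells along the
axis, minimum image) are rebuilt every step. Periodicity applies along
the axis only; winding counts make unwrapped axial coordinates — and
hence the reward — continuous across boundary crossings. Non-finite
forces abort with the offending particle and step index.

## Presets and particle mass

| preset  | L (m) | particles        | purpose                          |
|---------|-------|------------------|----------------------------------|
| full    | 0.6   | 12,078 + 2,500   | reference-scale geometry/counts  |
| desk3d  | 0.06  | 1,206 + 250      | desk-scale physics checks        |
| tiny    | 0.06  | 200 + 100        | CI-scale episodes and training   |

All physical constants are identical across presets; only the lattice is
coarsened. The full preset reproduces the reference particle budget
exactly (671 axial fluid layers of 18 = 6 + 12 particles on two rings;
500 membrane rings of 5); the ring decomposition itself is a
reconstruction, as only the totals are fixed by the published counts.

With summation density, particle mass and ρ0 are not independent: in a
tube narrower than the kernel, the kernel sum is dominated by the axial
neighbourhood and the nominal mass of 2.5×10⁻⁴ kg would imply densities
far above ρ0. The desk presets therefore *calibrate* the (common)
particle mass so that the initial summation density averages ρ0; the
full preset keeps the nominal mass. After assembly the desk presets are
settled by damped dynamics (400–1000 steps, velocities then zeroed) so
that the stored initial state is force balanced: free evolution over
0.1 s moves no particle by more than 5% of a lattice spacing. Tether
anchors remain at the as-placed lattice positions.

## Environment, reward and R*

The state is the 10-component binary activation vector; in single-action
mode the agent contracts exactly one section per decision interval
ΔT = 1 s (1000 physics steps). The general 2¹⁰-pattern action space is
retained in the types (`ActionSpec(mode="general")`) but untrained by
default. The reward of an action is the mass-weighted displacement of
the fluid centre of mass along +x over its interval, measured on
unwrapped coordinates. Episodes are 20 actions by default, start from
the settled build state with zero activation, and end only by length.

The **dimensionless cumulative reward** R* of an episode is

    R* = V_forward / V_squeezed,
    V_forward  = Δx_total · V_lumen / L,
    V_squeezed = Σ_actions Σ_{active s} max(0, V_rest(s) − min_t V_s(t)),

where slice volumes are estimated as π r̄² · (L/10) from the mean
membrane radius r̄ per slice, V_rest uses the settled state and the
minimum is tracked over the action's physics steps. V_lumen is the rest
lumen volume π r̄_rest² L — the geometric choice consistent with the
slice-volume estimate (the mass-based volume Σm/ρ0 is not geometric
under the calibrated masses). R* ≈ 1 means the squeezed volume was
transported forward; 0 means symmetric splitting; negative means net
retrograde flow. With no contraction in an entire episode R* is
undefined and reported as absent.

## Agent

A dense 10–50–50–10 network (relu, relu, linear) maps states to the 10
action values. Training is plain online TD learning: per transition one
Adam step (step size 10⁻³, the optimiser family's conventional default)
on the squared error between the taken action's output and
r + γ max_a′ Q(s′, a′), γ = 0.5; the other outputs carry no error
(masked loss). The episode's final transition is treated as terminal by
default (`bootstrap_final` flips this). No replay buffer and no target
network by default; both exist behind config flags. Weights initialise
uniformly within ±(fan_in)^(−1/2), seeded. Exploration is ε-greedy with
ε decaying linearly 1.0 → 0.1; the reference schedule spans 30,000
episodes, and the trainer by default rescales the decay horizon to the
run's own episode count (so a 30,000-episode run reproduces the
reference schedule exactly, and shorter desk runs traverse the same
exploration profile). Argmax ties break toward the lowest index.

Training logs record both the *exploring* episode reward and a cheap
*greedy evaluation* reward per episode (surrogate environment only);
with an ε floor of 0.1 the exploring reward saturates ~15% below the
optimum by construction, so policy quality is read from the greedy
column.

## Surrogate environment

A physics-free environment with the identical reset/step interface for
fast agent tests: contracting the section after the previous one earns
+1, repeating the previous section 0, anything else −0.5, and all
actions from the initial zero state 0. Its optimal policy is the
travelling wave, and its optimal action values follow from value
iteration (a γ-contraction with a unique fixed point, provided in
`surrogate_value_iteration`). The surrogate shares the tube
environment's alphabet and reward sign conventions but none of its
dynamics: inertia, slosh-back, volume bookkeeping and divergence modes
are absent, so surrogate results validate the *learning machinery*, not
the physics task.

## What the desk-scale tests show — and what they do not

Force laws are validated against exhaustive double-loop references and
printed-value arithmetic; conservation, wrapping and reward invariants
are exact-tolerance properties. The no-slip coupling is validated in a
planar channel at a *resolved* smoothing length (h = 1.5 lattice
spacings, densities pinned — unidirectional shear is incompressible),
because at the tube's own h = 9 mm the kernel spans the entire lumen
and sub-gap shear is unresolvable by construction; at tube scale the
coupling manifests as bulk drag and as the seal formed by near-complete
occlusion during contraction, which is the mechanism peristalsis
actually uses here.

The short desk tube differs from the reference scale in one important
way: the fluid slug is light and weakly damped, so momentum persists
across decision intervals and even arbitrary fixed contraction patterns
can transport fluid. Desk-scale rewards are therefore noisier and less
action-determined than at full scale, which limits how sharply a short
training run can separate itself from baselines. Learning-at-scale
claims (training curves over tens of thousands of episodes, R* → 1,
wave speeds) are full-scale properties and are not reproduced at desk
scale; the desk suite checks the machinery and the qualitative physics.

## Problem sizes used by the test suite and acceptance script

Physics rollouts use the `tiny` preset (300 particles) with 5–20
actions per episode; desk3d (1,456 particles) is built once for
geometry/force-balance checks. The scaled-down physics learning run is
40 episodes of 5 actions on `tiny` with the ε horizon rescaled to the
run. Surrogate training uses 2,000 episodes of 20 actions. The full
preset is built (not simulated) for the particle-budget checks.
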