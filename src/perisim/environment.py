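"""Reinforcement-learning environment over the contractile tube.

The membrane is partitioned into 10 axial sections.  The *state* is the
10-component binary activation vector (1 = section currently
contracting); the *action* chooses the section(s) to contract over the
next decision interval (default 1 s, i.e. 1000 physics steps at
dt = 1 ms).  The *reward* of an action is the displacement of the fluid
centre of mass along the axis over that interval, measured on unwrapped
(winding-corrected) coordinates so periodic crossings do not corrupt it.

An episode of N actions also records a dimensionless cumulative reward
R*: the ratio of the fluid volume transported forward (plug-flow
equivalent of the total centre-of-mass displacement) to the total volume
squeezed out of the contracting sections.  R* near 1 means nearly all
squeezed volume went forward; 0 means symmetric splitting; negative
means net retrograde flow.

A physics-free surrogate environment with the same reset/step interface
provides a fast, exactly solvable testbed for the learning agent: the
optimal policy is the travelling contraction wave and the optimal value
function is computable by value iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .builder import TubeModel
from .core import unwrapped_axial
from .forces import run_steps

__all__ = [
    "N_SLICES",
    "MembraneState",
    "ActionSpec",
    "Transition",
    "EpisodeLog",
    "encode_state",
    "decode_state",
    "compute_reward",
    "dimensionless_cumulative_reward",
    "TubeEnvironment",
    "SurrogateEnvironment",
    "surrogate_value_iteration",
    "enumerate_general_actions",
]

N_SLICES = 10


@dataclass(frozen=True)
class MembraneState:
    """10-component binary activation vector."""

    activation: tuple

    def __post_init__(self) -> None:
        if len(self.activation) != N_SLICES:
            raise ValueError(f"activation must have {N_SLICES} components")
        if any(v not in (0, 1) for v in self.activation):
            raise ValueError("activation components must be 0 or 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.activation, dtype=np.float64)

    @property
    def active_slices(self) -> frozenset:
        return frozenset(i for i, v in enumerate(self.activation) if v)


ZERO_STATE = MembraneState(activation=(0,) * N_SLICES)


@dataclass(frozen=True)
class ActionSpec:
    """Either a single contracting section (index 0-9) or a general
    10-bit contraction pattern (2^10 possibilities)."""

    mode: str            # "single" | "general"
    value: int

    def __post_init__(self) -> None:
        if self.mode == "single":
            if not 0 <= self.value < N_SLICES:
                raise ValueError("single-mode action index must be in [0, 10)")
        elif self.mode == "general":
            if not 0 <= self.value < 2 ** N_SLICES:
                raise ValueError("general-mode pattern must be < 2^10")
        else:
            raise ValueError("mode must be 'single' or 'general'")

    @property
    def active_slices(self) -> frozenset:
        if self.mode == "single":
            return frozenset((self.value,))
        return frozenset(i for i in range(N_SLICES) if self.value >> i & 1)

    def to_state(self) -> MembraneState:
        act = [0] * N_SLICES
        for s in self.active_slices:
            act[s] = 1
        return MembraneState(activation=tuple(act))


def enumerate_general_actions() -> list:
    """All 2^10 = 1024 general contraction patterns."""
    return [ActionSpec(mode="general", value=v) for v in range(2 ** N_SLICES)]


def encode_state(active_slices: Iterable[int]) -> MembraneState:
    act = [0] * N_SLICES
    for s in active_slices:
        if not 0 <= int(s) < N_SLICES:
            raise ValueError(f"slice index {s} out of range")
        act[int(s)] = 1
    return MembraneState(activation=tuple(act))


def decode_state(state: MembraneState) -> frozenset:
    return state.active_slices


@dataclass(frozen=True)
class Transition:
    s: MembraneState
    a: ActionSpec
    r: float
    s_next: MembraneState
    terminal: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.r):
            raise ValueError("reward must be finite")


@dataclass
class EpisodeLog:
    """Per-episode bookkeeping: transitions, per-action displacements,
    squeezed volumes and the dimensionless cumulative reward."""

    transitions: list = field(default_factory=list)
    dx: list = field(default_factory=list)              # m per action
    squeezed_volume: list = field(default_factory=list)  # m^3 per action
    r_star: float | None = None

    @property
    def cumulative_reward(self) -> float:
        return float(sum(self.dx))

    @property
    def n_actions(self) -> int:
        return len(self.dx)


def compute_reward(x_before: np.ndarray, x_after: np.ndarray,
                   masses: np.ndarray) -> float:
    """Mass-weighted mean axial displacement of the fluid, after - before.

    Coordinates must be unwrapped; forward (+x) motion gives a positive
    reward.
    """
    x_before = np.asarray(x_before, dtype=np.float64)
    x_after = np.asarray(x_after, dtype=np.float64)
    masses = np.asarray(masses, dtype=np.float64)
    if not (len(x_before) == len(x_after) == len(masses)):
        raise ValueError("position and mass arrays must have equal length")
    total = masses.sum()
    return float(np.dot(masses, x_after - x_before) / total)


def dimensionless_cumulative_reward(total_dx: float,
                                    squeezed_volumes: Sequence[float],
                                    fluid_volume: float,
                                    tube_length: float) -> float | None:
    """R* = V_forward / V_squeezed.

    V_forward converts the total centre-of-mass displacement into a
    transported volume under plug-flow equivalence, total_dx * V_fluid / L.
    V_squeezed sums, per action, the rest-to-minimum volume change of the
    contracting sections.  Undefined (None) when nothing contracted.
    """
    v_squeezed = float(np.sum(squeezed_volumes))
    if v_squeezed <= 0.0:
        return None
    v_forward = total_dx * fluid_volume / tube_length
    return v_forward / v_squeezed


class TubeEnvironment:
    """reset()/step(action) interface over the particle model.

    Each step holds the chosen contraction for ``delta_t`` seconds of
    physics (round(delta_t/dt) velocity-Verlet steps), accumulates the
    reward and tracks the minimum volume of the contracting sections for
    the dimensionless cumulative reward.
    """

    def __init__(self, model: TubeModel, delta_t: float = 1.0,
                 actions_per_episode: int = 20, action_mode: str = "single"):
        if round(delta_t / model.config.dt) < 1:
            raise ValueError("delta_t must cover at least one physics step")
        self.model = model
        self.delta_t = delta_t
        self.actions_per_episode = actions_per_episode
        self.action_mode = action_mode
        self.n_substeps = int(round(delta_t / model.config.dt))
        self._rest_radii = model.slice_mean_radii(model.initial)
        self.state = ZERO_STATE
        self.log = EpisodeLog()
        self._n_done = 0
        #: optional callable(step, system) invoked after every physics step
        self.frame_observer = None

    # -- helpers -----------------------------------------------------

    def _slice_volume(self, radii: np.ndarray) -> np.ndarray:
        return np.pi * radii ** 2 * self.model.geometry.slice_thickness

    @property
    def rest_slice_volumes(self) -> np.ndarray:
        return self._slice_volume(self._rest_radii)

    def observation(self) -> dict:
        """JSON-serialisable snapshot of the decision-level state."""
        return {
            "activation": list(self.state.activation),
            "actions_done": self._n_done,
            "cumulative_reward_m": self.log.cumulative_reward,
        }

    # -- environment API ---------------------------------------------

    def reset(self) -> MembraneState:
        self.model.reset()
        self.state = ZERO_STATE
        self.log = EpisodeLog()
        self._n_done = 0
        return self.state

    def step(self, action: ActionSpec):
        active = sorted(action.active_slices)
        sys_ = self.model.system
        fluid = sys_.fluid_mask
        x_before = unwrapped_axial(sys_, self.model.box)[fluid]
        min_radii = {s: np.inf for s in active}

        def observer(step, system):
            if active:
                radii = self.model.slice_mean_radii(system)
                for s in active:
                    if radii[s] < min_radii[s]:
                        min_radii[s] = radii[s]
            if self.frame_observer is not None:
                self.frame_observer(step, system)

        use_observer = bool(active) or self.frame_observer is not None
        run_steps(sys_, self.model.box, self.model.config, self.model.bonds,
                  self.model.tethers, self.n_substeps, active_slices=active,
                  observer=observer if use_observer else None)
        x_after = unwrapped_axial(sys_, self.model.box)[fluid]
        reward = compute_reward(x_before, x_after, sys_.masses[fluid])

        rest_v = self.rest_slice_volumes
        squeezed = 0.0
        for s in active:
            v_min = self._slice_volume(np.asarray(min_radii[s]))
            squeezed += max(0.0, float(rest_v[s] - v_min))

        s_prev = self.state
        self.state = action.to_state()
        self._n_done += 1
        done = self._n_done >= self.actions_per_episode
        self.log.dx.append(reward)
        self.log.squeezed_volume.append(squeezed)
        self.log.transitions.append(
            Transition(s=s_prev, a=action, r=reward, s_next=self.state,
                       terminal=done))
        if done:
            self.log.r_star = dimensionless_cumulative_reward(
                self.log.cumulative_reward, self.log.squeezed_volume,
                self.model.fluid_volume, self.model.geometry.length)
        return self.state, reward, done, {"active_slices": active}


class SurrogateEnvironment:
    """Physics-free stand-in with the tube environment's interface.

    Deterministic toy dynamics on the same 10-section alphabet:
    contracting the section after the previous one (mod 10) rewards +1,
    repeating the previous section rewards 0, anything else -0.5; from
    the initial all-zero state every action rewards 0.  The optimal
    policy is the travelling wave and the optimal action values follow
    from value iteration.
    """

    REWARD_WAVE = 1.0
    REWARD_REPEAT = 0.0
    REWARD_OTHER = -0.5

    def __init__(self, actions_per_episode: int = 20):
        self.actions_per_episode = actions_per_episode
        self.state = ZERO_STATE
        self.log = EpisodeLog()
        self._n_done = 0

    @staticmethod
    def reward_of(state: MembraneState, action: ActionSpec) -> float:
        active = state.active_slices
        if not active:
            return 0.0
        prev = next(iter(active))
        a = action.value
        if a == (prev + 1) % N_SLICES:
            return SurrogateEnvironment.REWARD_WAVE
        if a == prev:
            return SurrogateEnvironment.REWARD_REPEAT
        return SurrogateEnvironment.REWARD_OTHER

    def reset(self) -> MembraneState:
        self.state = ZERO_STATE
        self.log = EpisodeLog()
        self._n_done = 0
        return self.state

    def step(self, action: ActionSpec):
        if action.mode != "single":
            raise ValueError("surrogate environment is single-action only")
        reward = self.reward_of(self.state, action)
        s_prev = self.state
        self.state = action.to_state()
        self._n_done += 1
        done = self._n_done >= self.actions_per_episode
        self.log.dx.append(reward)
        self.log.squeezed_volume.append(0.0)
        self.log.transitions.append(
            Transition(s=s_prev, a=action, r=reward, s_next=self.state,
                       terminal=done))
        return self.state, reward, done, {}


def surrogate_state_index(state: MembraneState) -> int:
    """0 for the all-zero state, 1 + slice index for single-slice states."""
    active = state.active_slices
    if not active:
        return 0
    if len(active) != 1:
        raise ValueError("surrogate states have at most one active section")
    return 1 + next(iter(active))


def surrogate_value_iteration(gamma: float, tol: float = 1e-12,
                              max_iter: int = 10_000) -> np.ndarray:
    """Optimal Q table of the surrogate dynamics, shape (11, 10).

    Row 0 is the all-zero state, rows 1..10 the single-slice states.
    Bellman iteration on the deterministic transitions; gamma < 1 makes
    the operator a sup-norm contraction with a unique fixed point.
    """
    n_states = N_SLICES + 1
    q = np.zeros((n_states, N_SLICES))
    rewards = np.zeros((n_states, N_SLICES))
    for s in range(1, n_states):
        prev = s - 1
        rewards[s, :] = SurrogateEnvironment.REWARD_OTHER
        rewards[s, prev] = SurrogateEnvironment.REWARD_REPEAT
        rewards[s, (prev + 1) % N_SLICES] = SurrogateEnvironment.REWARD_WAVE
    for _ in range(max_iter):
        v_next = q.max(axis=1)          # value of landing in state 1+a
        new_q = rewards + gamma * v_next[1 + np.arange(N_SLICES)][None, :]
        if np.max(np.abs(new_q - q)) < tol:
            return new_q
        q = new_q
    raise RuntimeError("value iteration failed to converge")
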