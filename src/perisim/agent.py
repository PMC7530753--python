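"""Online deep Q-learning agent.

A compact dense value network maps the 10-component membrane state to
the 10 action values Q*(s, a): layers 10-50-50-10 with relu hidden
activations and a linear output.  Training is plain online temporal-
difference learning: after every transition one Adam step is taken on
the squared error between the taken action's output and the bootstrap
target r + gamma * max_a' Q*(s', a') (just r on terminal transitions).
Only the taken action's output carries error — the masked realisation of
the scalar TD loss for a vector-output network.

Exploration is epsilon-greedy with epsilon decaying linearly from 1.0 to
0.1 over the configured number of episodes (the published schedule runs
over 30,000 episodes).

No replay buffer and no target network are used by default; both exist
behind config flags.  A tabular variant of the same update rule is
provided as the exactly analysable limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .environment import N_SLICES, MembraneState, Transition

__all__ = [
    "LAYER_SIZES",
    "AgentConfig",
    "QNetwork",
    "q_forward",
    "q_target",
    "td_loss",
    "epsilon_schedule",
    "select_action",
    "QAgent",
    "TabularQ",
]

LAYER_SIZES = (10, 50, 50, 10)


@dataclass(frozen=True)
class AgentConfig:
    gamma: float = 0.5
    epsilon_start: float = 1.0
    epsilon_end: float = 0.1
    epsilon_decay_episodes: int = 30_000
    learning_rate: float = 1.0e-3     # Adam step size
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1.0e-8
    seed: int = 0
    replay_buffer_size: int = 0       # 0 disables replay
    replay_batch: int = 16
    target_network_update: int = 0    # 0 disables the target network
    bootstrap_final: bool = False     # treat the episode's last action as terminal

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must be in [0, 1)")
        if not 0.0 <= self.epsilon_end <= self.epsilon_start <= 1.0:
            raise ValueError("need 0 <= epsilon_end <= epsilon_start <= 1")

    def with_overrides(self, **kwargs) -> "AgentConfig":
        return replace(self, **kwargs)


class QNetwork:
    """Dense 10-50-50-10 value network (relu, relu, linear).

    Weights are initialised uniformly in +-sqrt(1/fan_in), seeded.
    """

    def __init__(self, seed: int = 0, layer_sizes: Sequence[int] = LAYER_SIZES):
        self.layer_sizes = tuple(layer_sizes)
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.weights = []
        self.biases = []
        for fan_in, fan_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
            bound = np.sqrt(1.0 / fan_in)
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def forward(self, x: np.ndarray, keep: bool = False):
        """Action values for input vector x; with ``keep`` also returns
        the per-layer activations needed for backprop."""
        x = np.asarray(x, dtype=np.float64)
        if x.shape != (self.layer_sizes[0],):
            raise ValueError(
                f"input must have shape ({self.layer_sizes[0]},), got {x.shape}")
        acts = [x]
        for li in range(self.n_layers):
            z = acts[-1] @ self.weights[li] + self.biases[li]
            if li < self.n_layers - 1:
                z = np.maximum(z, 0.0)
            acts.append(z)
        return (acts[-1], acts) if keep else acts[-1]

    def gradients(self, acts, action: int, dq: float):
        """Backprop of dL/dq through the masked output."""
        grads_w = [None] * self.n_layers
        grads_b = [None] * self.n_layers
        delta = np.zeros(self.layer_sizes[-1])
        delta[action] = dq
        for li in range(self.n_layers - 1, -1, -1):
            grads_w[li] = np.outer(acts[li], delta)
            grads_b[li] = delta.copy()
            if li > 0:
                delta = (self.weights[li] @ delta) * (acts[li] > 0.0)
        return grads_w, grads_b

    def state_dict(self) -> dict:
        out = {"layer_sizes": np.asarray(self.layer_sizes), "seed": np.asarray(self.seed)}
        for li in range(self.n_layers):
            out[f"W{li}"] = self.weights[li]
            out[f"b{li}"] = self.biases[li]
        return out

    @classmethod
    def from_state_dict(cls, d: dict) -> "QNetwork":
        net = cls(seed=int(d["seed"]), layer_sizes=tuple(int(v) for v in d["layer_sizes"]))
        for li in range(net.n_layers):
            net.weights[li] = np.asarray(d[f"W{li}"], dtype=np.float64).copy()
            net.biases[li] = np.asarray(d[f"b{li}"], dtype=np.float64).copy()
        return net

    def copy(self) -> "QNetwork":
        return QNetwork.from_state_dict(self.state_dict())


def q_forward(network: QNetwork, state: MembraneState) -> np.ndarray:
    """Deterministic action values for a membrane state (length 10)."""
    out = network.forward(state.as_array())
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite Q values")
    return out


def q_target(r: float, gamma: float, next_q_values: np.ndarray,
             terminal: bool) -> float:
    """Bootstrap target r + gamma * max_a' Q(s', a'); just r if terminal."""
    if terminal:
        return float(r)
    next_q_values = np.asarray(next_q_values, dtype=np.float64)
    if next_q_values.shape != (N_SLICES,):
        raise ValueError(f"next_q_values must have length {N_SLICES}")
    return float(r + gamma * np.max(next_q_values))


def td_loss(predicted_q: float, target: float) -> float:
    """Squared TD error (target - prediction)^2."""
    return float((target - predicted_q) ** 2)


def epsilon_schedule(episode: int, config: AgentConfig) -> float:
    """Linear decay from epsilon_start to epsilon_end, then constant."""
    if episode < 0:
        raise ValueError("episode must be non-negative")
    n = config.epsilon_decay_episodes
    if n <= 0 or episode >= n:
        return config.epsilon_end
    frac = episode / n
    return config.epsilon_start + frac * (config.epsilon_end - config.epsilon_start)


def select_action(q_values: np.ndarray, alpha: float,
                  rng: np.random.Generator) -> int:
    """Epsilon-greedy: random with probability alpha, else argmax with
    ties broken toward the lowest index."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if alpha > 0.0 and rng.random() < alpha:
        return int(rng.integers(N_SLICES))
    q_values = np.asarray(q_values, dtype=np.float64)
    return int(np.argmax(q_values))   # np.argmax returns the first maximum


class _Adam:
    def __init__(self, network: QNetwork, config: AgentConfig):
        self.cfg = config
        self.t = 0
        self.m_w = [np.zeros_like(w) for w in network.weights]
        self.v_w = [np.zeros_like(w) for w in network.weights]
        self.m_b = [np.zeros_like(b) for b in network.biases]
        self.v_b = [np.zeros_like(b) for b in network.biases]

    def step(self, network: QNetwork, grads_w, grads_b) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.adam_beta1 ** self.t
        bc2 = 1.0 - c.adam_beta2 ** self.t
        for li in range(network.n_layers):
            for m, v, g, p in ((self.m_w[li], self.v_w[li], grads_w[li], network.weights[li]),
                               (self.m_b[li], self.v_b[li], grads_b[li], network.biases[li])):
                m *= c.adam_beta1
                m += (1.0 - c.adam_beta1) * g
                v *= c.adam_beta2
                v += (1.0 - c.adam_beta2) * g * g
                p -= c.learning_rate * (m / bc1) / (np.sqrt(v / bc2) + c.adam_eps)

    def state_dict(self) -> dict:
        out = {"t": np.asarray(self.t)}
        for li in range(len(self.m_w)):
            out[f"m_w{li}"] = self.m_w[li]
            out[f"v_w{li}"] = self.v_w[li]
            out[f"m_b{li}"] = self.m_b[li]
            out[f"v_b{li}"] = self.v_b[li]
        return out

    def load_state_dict(self, d: dict) -> None:
        self.t = int(d["t"])
        for li in range(len(self.m_w)):
            self.m_w[li] = np.asarray(d[f"m_w{li}"], dtype=np.float64).copy()
            self.v_w[li] = np.asarray(d[f"v_w{li}"], dtype=np.float64).copy()
            self.m_b[li] = np.asarray(d[f"m_b{li}"], dtype=np.float64).copy()
            self.v_b[li] = np.asarray(d[f"v_b{li}"], dtype=np.float64).copy()


class QAgent:
    """Network + optimiser + optional replay/target-network machinery."""

    def __init__(self, config: AgentConfig | None = None):
        self.config = config or AgentConfig()
        self.network = QNetwork(seed=self.config.seed)
        self.opt = _Adam(self.network, self.config)
        self._target_net = None
        self._replay: list = []
        self._updates = 0
        if self.config.target_network_update > 0:
            self._target_net = self.network.copy()

    # -- acting ------------------------------------------------------

    def act(self, state: MembraneState, alpha: float,
            rng: np.random.Generator) -> int:
        return select_action(q_forward(self.network, state), alpha, rng)

    def greedy_action(self, state: MembraneState) -> int:
        return select_action(q_forward(self.network, state), 0.0,
                             np.random.default_rng(0))

    # -- learning ----------------------------------------------------

    def _bootstrap_net(self) -> QNetwork:
        return self._target_net if self._target_net is not None else self.network

    def _fit_one(self, transition: Transition) -> float:
        terminal = transition.terminal and not self.config.bootstrap_final
        next_q = q_forward(self._bootstrap_net(), transition.s_next)
        target = q_target(transition.r, self.config.gamma, next_q, terminal)
        action = self._action_index(transition)
        pred, acts = self.network.forward(transition.s.as_array(), keep=True)
        loss = td_loss(pred[action], target)
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite TD loss")
        # dL/dq = -2 (target - q)
        grads_w, grads_b = self.network.gradients(
            acts, action, -2.0 * (target - pred[action]))
        self.opt.step(self.network, grads_w, grads_b)
        return loss

    @staticmethod
    def _action_index(transition: Transition) -> int:
        if transition.a.mode != "single":
            raise ValueError("the 10-output network trains on single-section actions")
        return transition.a.value

    def train_step(self, transition: Transition,
                   rng: np.random.Generator | None = None) -> float:
        """One online update; with replay enabled, also a replayed batch."""
        loss = self._fit_one(transition)
        if self.config.replay_buffer_size > 0:
            self._replay.append(transition)
            if len(self._replay) > self.config.replay_buffer_size:
                self._replay.pop(0)
            if rng is not None and len(self._replay) >= self.config.replay_batch:
                idx = rng.integers(len(self._replay), size=self.config.replay_batch)
                for k in idx:
                    self._fit_one(self._replay[int(k)])
        self._updates += 1
        if (self._target_net is not None
                and self._updates % self.config.target_network_update == 0):
            self._target_net = self.network.copy()
        return loss

    # -- persistence -------------------------------------------------

    def state_dict(self) -> dict:
        out = {f"net_{k}": v for k, v in self.network.state_dict().items()}
        out.update({f"opt_{k}": v for k, v in self.opt.state_dict().items()})
        out["updates"] = np.asarray(self._updates)
        return out

    def load_state_dict(self, d: dict) -> None:
        self.network = QNetwork.from_state_dict(
            {k[4:]: v for k, v in d.items() if k.startswith("net_")})
        self.opt = _Adam(self.network, self.config)
        self.opt.load_state_dict(
            {k[4:]: v for k, v in d.items() if k.startswith("opt_")})
        self._updates = int(d["updates"])
        if self.config.target_network_update > 0:
            self._target_net = self.network.copy()


class TabularQ:
    """Lookup-table agent running the same TD update rule.

    The exactly analysable limit of the network agent: on the surrogate
    dynamics its table converges to the value-iteration fixed point.
    States are indexed 0 (all-zero) and 1..10 (single-slice).
    """

    def __init__(self, n_states: int = N_SLICES + 1, gamma: float = 0.5,
                 learning_rate: float = 0.5):
        self.q = np.zeros((n_states, N_SLICES))
        self.gamma = gamma
        self.lr = learning_rate

    def update(self, s: int, a: int, r: float, s_next: int,
               terminal: bool = False) -> float:
        target = q_target(r, self.gamma, self.q[s_next], terminal)
        loss = td_loss(self.q[s, a], target)
        self.q[s, a] += self.lr * (target - self.q[s, a])
        return loss
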