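"""Training orchestration: seeded episode loop, logging, checkpointing,
greedy rollout and trajectory export.

Randomness discipline: one base seed is split into named streams (agent
initialisation, exploration) so that toggling logging or dumping never
perturbs trajectories.  The epsilon schedule decays over the run's own
episode count by default (the full-scale configuration of 30,000
episodes then reproduces the published schedule); set
``scale_epsilon_to_run=False`` to pin the decay horizon independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .agent import AgentConfig, QAgent, epsilon_schedule, q_forward
from .builder import PRESETS, build_tube, get_preset
from .core import SimulationConfig
from .environment import (ActionSpec, EpisodeLog, SurrogateEnvironment,
                          TubeEnvironment)
from .io import Frame, config_hash, write_trajectory

__all__ = ["RunConfig", "TrainingResult", "run_training", "rollout",
           "greedy_episode_reward", "episode_logs_to_csv"]

LOG_COLUMNS = ["episode", "epsilon", "cumulative_reward", "r_star",
               "mean_loss", "greedy_reward"]


@dataclass(frozen=True)
class RunConfig:
    environment: str = "surrogate"      # "surrogate" | "tube"
    preset: str = "tiny"                # tube geometry preset
    episodes: int = 2000
    actions_per_episode: int = 20
    delta_t: float = 1.0
    seed: int = 0
    agent: AgentConfig = field(default_factory=AgentConfig)
    sim_overrides: dict = field(default_factory=dict)
    scale_epsilon_to_run: bool = True
    outdir: str | None = None
    checkpoint_every: int = 0           # episodes; 0 = only final
    log_greedy_eval: bool = True        # cheap greedy evaluation per episode (surrogate)

    def __post_init__(self) -> None:
        if self.episodes < 1:
            raise ValueError("episodes must be >= 1")
        if self.environment not in ("surrogate", "tube"):
            raise ValueError("environment must be 'surrogate' or 'tube'")
        if self.environment == "tube" and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")

    def effective_agent_config(self) -> AgentConfig:
        cfg = self.agent
        if self.scale_epsilon_to_run:
            cfg = cfg.with_overrides(epsilon_decay_episodes=self.episodes)
        return cfg

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("environment", "preset", "episodes", "actions_per_episode",
              "delta_t", "seed", "scale_epsilon_to_run", "checkpoint_every")}
        d["agent"] = self.agent.__dict__
        d["sim_overrides"] = dict(self.sim_overrides)
        return d


@dataclass
class TrainingResult:
    log: pd.DataFrame
    agent: QAgent
    env: object
    config: RunConfig
    cfg_hash: str


def _make_env(cfg: RunConfig):
    if cfg.environment == "surrogate":
        return SurrogateEnvironment(actions_per_episode=cfg.actions_per_episode)
    sim = SimulationConfig(**cfg.sim_overrides) if cfg.sim_overrides \
        else SimulationConfig()
    model = build_tube(get_preset(cfg.preset), sim)
    return TubeEnvironment(model, delta_t=cfg.delta_t,
                           actions_per_episode=cfg.actions_per_episode)


def greedy_episode_reward(agent: QAgent, env, n_actions: int | None = None) -> float:
    """Cumulative reward of one fully greedy episode."""
    n = n_actions or env.actions_per_episode
    state = env.reset()
    total = 0.0
    for _ in range(n):
        a = agent.greedy_action(state)
        state, r, done, _ = env.step(ActionSpec(mode="single", value=a))
        total += r
        if done:
            break
    return total


def _write_log(df: pd.DataFrame, path: Path, cfg_hash: str, seed: int) -> None:
    with path.open("w") as fh:
        fh.write(f"# config_hash={cfg_hash} seed={seed}\n")
        df.to_csv(fh, index=False)


def episode_logs_to_csv(logs: Sequence, path, seed: int | None = None,
                        cfg_hash: str | None = None) -> pd.DataFrame:
    """Write one CSV row per episode: index, action sequence, per-action
    displacement series (space-separated) and R*."""
    rows = []
    for k, log in enumerate(logs):
        rows.append({
            "episode": k,
            "actions": " ".join(str(t.a.value) for t in log.transitions),
            "dx_series": " ".join(f"{dx:.8e}" for dx in log.dx),
            "cumulative_reward": log.cumulative_reward,
            "r_star": np.nan if log.r_star is None else log.r_star,
        })
    df = pd.DataFrame(rows)
    with Path(path).open("w") as fh:
        if seed is not None or cfg_hash is not None:
            fh.write(f"# config_hash={cfg_hash} seed={seed}\n")
        df.to_csv(fh, index=False)
    return df


def run_training(run_config: RunConfig, resume_from=None) -> TrainingResult:
    """Train the agent for ``episodes`` episodes; one online update per
    transition.  Fully reproducible for a given seed; resuming from a
    checkpoint continues the exact uninterrupted trajectory."""
    cfg = run_config
    agent_cfg = cfg.effective_agent_config()
    cfg_h = config_hash(cfg.to_dict())
    ss = np.random.SeedSequence(cfg.seed)
    init_ss, explore_ss = ss.spawn(2)
    agent_seed = int(init_ss.generate_state(1)[0] % (2 ** 31))
    explore_rng = np.random.default_rng(explore_ss)

    agent = QAgent(agent_cfg.with_overrides(seed=agent_seed))
    env = _make_env(cfg)
    rows: list = []
    start_episode = 0

    if resume_from is not None:
        with np.load(resume_from, allow_pickle=False) as data:
            meta = json.loads(bytes(data["meta_json"]).decode())
            if meta.get("cfg_hash") != cfg_h:
                raise ValueError("checkpoint does not match this run configuration")
            agent.load_state_dict({k: data[k] for k in data.files
                                   if k != "meta_json"})
            explore_rng.bit_generator.state = meta["rng_state"]
            start_episode = int(meta["episode"])
            rows = meta["rows"]

    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def save_checkpoint(episode: int, tag: str) -> None:
        if not outdir:
            return
        meta = {"cfg_hash": cfg_h, "seed": cfg.seed, "episode": episode,
                "rng_state": explore_rng.bit_generator.state,
                "rows": [list(r) for r in rows]}
        arrays = dict(agent.state_dict())
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta, default=str).encode(), dtype=np.uint8)
        np.savez(outdir / f"checkpoint_{tag}.npz", **arrays)

    for episode in range(start_episode, cfg.episodes):
        eps = epsilon_schedule(episode, agent_cfg)
        state = env.reset()
        losses = []
        try:
            for _ in range(cfg.actions_per_episode):
                a = agent.act(state, eps, explore_rng)
                state, r, done, _ = env.step(ActionSpec(mode="single", value=a))
                loss = agent.train_step(env.log.transitions[-1], explore_rng)
                losses.append(loss)
                if done:
                    break
        except FloatingPointError:
            save_checkpoint(episode, "last_good")
            raise
        train_reward = env.log.cumulative_reward
        r_star = getattr(env.log, "r_star", None)
        greedy = np.nan
        if cfg.log_greedy_eval and isinstance(env, SurrogateEnvironment):
            greedy = greedy_episode_reward(agent, env)
        rows.append([episode, eps, train_reward,
                     np.nan if r_star is None else r_star,
                     float(np.mean(losses)), greedy])
        if cfg.checkpoint_every and (episode + 1) % cfg.checkpoint_every == 0:
            save_checkpoint(episode + 1, f"ep{episode + 1:06d}")

    df = pd.DataFrame(rows, columns=LOG_COLUMNS)
    if outdir:
        _write_log(df, outdir / "training_log.csv", cfg_h, cfg.seed)
        save_checkpoint(cfg.episodes, "final")
    return TrainingResult(log=df, agent=agent, env=env, config=cfg,
                          cfg_hash=cfg_h)


def rollout(agent: QAgent, env, n_episodes: int = 1, greedy: bool = True,
            epsilon: float = 0.0, seed: int = 0,
            dump_path=None, dump_every: int = 0) -> list:
    """Run episodes with a fixed policy; returns the episode logs.

    With ``greedy`` the exploration probability is forced to 0 and the
    action sequence is deterministic.  For tube environments a dump
    cadence k writes a trajectory frame every k physics steps (plus the
    initial frame)."""
    rng = np.random.default_rng(seed)
    eps = 0.0 if greedy else epsilon
    frames: list = []
    is_tube = isinstance(env, TubeEnvironment)
    if is_tube and dump_path and dump_every:
        counter = {"n": 0}
        dt = env.model.config.dt

        def frame_observer(step, system):
            counter["n"] += 1
            if counter["n"] % dump_every == 0:
                frames.append(Frame(step=counter["n"],
                                    time=counter["n"] * dt,
                                    positions=system.positions.copy(),
                                    phase=system.phase.copy(),
                                    slice_index=system.slice_index.copy()))
        env.frame_observer = frame_observer
    logs = []
    for _ in range(n_episodes):
        state = env.reset()
        if is_tube and dump_path and dump_every and not frames:
            sys_ = env.model.system
            frames.append(Frame(step=0, time=0.0,
                                positions=sys_.positions.copy(),
                                phase=sys_.phase.copy(),
                                slice_index=sys_.slice_index.copy()))
        done = False
        while not done:
            a = agent.act(state, eps, rng)
            state, _, done, _ = env.step(ActionSpec(mode="single", value=a))
        logs.append(env.log)
    if is_tube:
        env.frame_observer = None
        if dump_path and frames:
            write_trajectory(frames, dump_path, seed=seed)
    return logs
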