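"""Runs agents through the task and performs the parametric sweep.

Two simulation paths share the same model:

* :func:`run_agent` — one agent, full per-trial log, used for audited runs
  and the rejection fitter (the log retains raw currency; the learning rule
  sees normalized payoffs).
* :func:`simulate_block_preferences` — many agents at one parameter set,
  vectorized across agents, returning only block preferences. This is the
  workhorse for the grid sweep and the simulation-based fit objective.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .agent import (
    DEFAULT_VALUE_FLOOR,
    INITIAL_VALUE,
    AgentParams,
    ParameterError,
    matching_probabilities,
    softmax_probabilities,
)
from .task import ConfigError, TaskConfig, default_task

__all__ = [
    "TrialRecord",
    "SimulationResult",
    "SweepCombo",
    "SweepResult",
    "run_agent",
    "relative_preference",
    "simulate_block_preferences",
    "parameter_sweep",
    "default_grid",
    "trials_to_frame",
]

#: Default sweep grid: 0.1 .. 0.9 in steps of 0.1 for each parameter.
DEFAULT_GRID = tuple(np.round(np.arange(1, 10) * 0.1, 10))


@dataclass(frozen=True)
class TrialRecord:
    """One trial of one agent.

    ``gain`` and ``loss`` are raw currency; ``net_gain`` is the subjective
    net gain actually fed to the value update (normalized payoffs by
    default). ``values_after`` is the value vector after the update,
    ``probabilities_used`` the choice distribution the draw came from.
    """

    trial: int
    deck: str
    gain: float
    loss: float
    net_gain: float
    values_after: tuple[float, ...]
    probabilities_used: tuple[float, ...]


@dataclass
class SimulationResult:
    """Trial log plus block-wise relative preference for one agent run."""

    params: AgentParams
    seed: int | None
    trials: list[TrialRecord]
    block_preferences: np.ndarray

    @property
    def overall_preference(self) -> float:
        return float(np.mean(self.block_preferences))

    @property
    def accumulated_money(self) -> float:
        return float(sum(t.gain - t.loss for t in self.trials))

    def to_frame(self) -> pd.DataFrame:
        return trials_to_frame(self.trials)


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    """Trial log as a data frame with the canonical CSV column layout."""
    k = len(trials[0].values_after) if trials else 4
    rows = []
    for t in trials:
        row = {
            "trial": t.trial,
            "deck": t.deck,
            "gain": t.gain,
            "loss": t.loss,
            "net_gain": t.net_gain,
        }
        for i, label in enumerate("ABCD"[:k]):
            row[f"v{label}"] = t.values_after[i]
        for i, label in enumerate("ABCD"[:k]):
            row[f"p{label}"] = t.probabilities_used[i]
        rows.append(row)
    return pd.DataFrame(rows)


def _deck_arrays(
    task: TaskConfig, normalize: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    decks = task.normalized_decks() if normalize else task.decks
    gains = np.array([d.gain for d in decks])
    losses = np.array([d.loss_magnitude for d in decks])
    probs = np.array([d.loss_prob for d in decks])
    return gains, losses, probs


def _choice_probs(
    values: np.ndarray, rule: str, floor: float, temperature: float
) -> np.ndarray:
    if rule == "matching":
        return matching_probabilities(values, floor)
    if rule == "softmax":
        return softmax_probabilities(values, temperature)
    raise ParameterError(f"unknown decision rule {rule!r}")


def run_agent(
    params: AgentParams,
    task: TaskConfig | None = None,
    seed: int | None = None,
    *,
    decision_rule: str = "matching",
    temperature: float = 1.0,
    value_floor: float = DEFAULT_VALUE_FLOOR,
    lapse: float = 0.0,
    normalize: bool = True,
    record: bool = True,
) -> SimulationResult:
    """Simulate one agent over the full task, deterministically given ``seed``.

    Each trial runs the choose -> draw-outcome -> net-gain -> update cycle;
    only the chosen alternative's value is updated. With ``lapse`` > 0 the
    sampled choice is replaced by a uniformly random deck with that
    probability (used by the synthetic-cohort generator; 0 leaves the
    random stream untouched). ``record=False`` skips the per-trial log and
    returns only block preferences, which the rejection fitter exploits.
    """
    if task is None:
        task = default_task()
    if not 0.0 <= lapse <= 1.0:
        raise ParameterError(f"lapse must be in [0, 1], got {lapse}")
    rng = np.random.default_rng(seed)
    gains_raw = np.array([d.gain for d in task.decks])
    losses_raw = np.array([d.loss_magnitude for d in task.decks])
    gains, losses, loss_probs = _deck_arrays(task, normalize)
    k = task.n_decks
    m = params.memory
    gs = params.gain_sensitivity
    ls = params.loss_sensitivity
    labels = task.labels

    values = np.full(k, INITIAL_VALUE)
    choices = np.empty(task.n_trials, dtype=np.intp)
    trials: list[TrialRecord] = []
    for t in range(task.n_trials):
        probs = _choice_probs(values, decision_rule, value_floor, temperature)
        cum = np.cumsum(probs)
        c = min(int(np.searchsorted(cum, rng.random(), side="right")), k - 1)
        if lapse > 0.0 and rng.random() < lapse:
            c = int(rng.integers(k))
        punished = rng.random() < loss_probs[c]
        loss = losses[c] if punished else 0.0
        gn = gains[c] * gs - loss * ls
        values[c] = m * values[c] + (1.0 - m) * gn
        choices[t] = c
        if record:
            trials.append(
                TrialRecord(
                    trial=t + 1,
                    deck=labels[c],
                    gain=float(gains_raw[c]),
                    loss=float(losses_raw[c]) if punished else 0.0,
                    net_gain=float(gn),
                    values_after=tuple(values),
                    probabilities_used=tuple(probs),
                )
            )

    adv = np.zeros(k, dtype=bool)
    adv[list(task.advantageous_indices)] = True
    block_prefs = (
        adv[choices].reshape(task.n_blocks, task.block_size).mean(axis=1)
    )
    return SimulationResult(
        params=params, seed=seed, trials=trials, block_preferences=block_prefs
    )


def relative_preference(
    trials: Sequence[TrialRecord | str],
    block_size: int,
    advantageous: Sequence[str] = ("A", "B"),
) -> np.ndarray:
    """Per-block proportion of advantageous choices: (#A + #B) / block_size.

    Accepts a trial log or a bare sequence of deck labels.
    """
    labels = [t.deck if isinstance(t, TrialRecord) else t for t in trials]
    n = len(labels)
    if block_size <= 0 or n % block_size != 0:
        raise ConfigError(
            f"trial count {n} not divisible by block_size {block_size}"
        )
    adv = set(advantageous)
    flags = np.array([label in adv for label in labels], dtype=float)
    return flags.reshape(n // block_size, block_size).mean(axis=1)


def simulate_block_preferences(
    params: AgentParams,
    task: TaskConfig | None = None,
    n_agents: int = 50,
    rng: np.random.Generator | int | None = None,
    *,
    decision_rule: str = "matching",
    temperature: float = 1.0,
    value_floor: float = DEFAULT_VALUE_FLOOR,
    lapse: float = 0.0,
    normalize: bool = True,
) -> np.ndarray:
    """Block preferences for ``n_agents`` independent agents, shape
    ``(n_agents, n_blocks)``.

    Vectorized across agents (one random stream drives the whole batch), so
    it is fast enough for the full grid sweep, but its trajectories are not
    draw-for-draw identical to a sequence of :func:`run_agent` calls.
    """
    if task is None:
        task = default_task()
    if n_agents <= 0:
        raise ParameterError(f"n_agents must be positive, got {n_agents}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    gains, losses, loss_probs = _deck_arrays(task, normalize)
    k = task.n_decks
    m = params.memory
    gs = params.gain_sensitivity
    ls = params.loss_sensitivity

    values = np.full((n_agents, k), INITIAL_VALUE)
    choices = np.empty((n_agents, task.n_trials), dtype=np.intp)
    rows = np.arange(n_agents)
    for t in range(task.n_trials):
        if decision_rule == "matching":
            rect = np.maximum(values, value_floor)
            probs = rect / rect.sum(axis=1, keepdims=True)
        elif decision_rule == "softmax":
            z = values / temperature
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            probs = e / e.sum(axis=1, keepdims=True)
        else:
            raise ParameterError(f"unknown decision rule {decision_rule!r}")
        cum = np.cumsum(probs, axis=1)
        u = rng.random(n_agents)
        c = np.minimum((cum <= u[:, None]).sum(axis=1), k - 1)
        if lapse > 0.0:
            lapse_mask = rng.random(n_agents) < lapse
            c = np.where(lapse_mask, rng.integers(k, size=n_agents), c)
        punished = rng.random(n_agents) < loss_probs[c]
        loss = np.where(punished, losses[c], 0.0)
        gn = gains[c] * gs - loss * ls
        values[rows, c] = m * values[rows, c] + (1.0 - m) * gn
        choices[:, t] = c

    adv = np.zeros(k, dtype=bool)
    adv[list(task.advantageous_indices)] = True
    return (
        adv[choices]
        .reshape(n_agents, task.n_blocks, task.block_size)
        .mean(axis=2)
    )


@dataclass(frozen=True)
class SweepCombo:
    """One grid point of the sweep with its mean preference over agents."""

    memory: float
    gain_sensitivity: float
    loss_sensitivity: float
    mean_preference: float


@dataclass
class SweepResult:
    """Full sweep table plus the extreme and most-typical grid points.

    ``grand_mean_combo`` is the grid point whose mean preference is closest
    to the grand mean over all grid points.
    """

    table: pd.DataFrame
    argmax_combo: SweepCombo
    argmin_combo: SweepCombo
    grand_mean_combo: SweepCombo
    n_agents: int
    seed: int | None

    @property
    def grand_mean(self) -> float:
        return float(self.table["mean_preference"].mean())


def default_grid() -> tuple[float, ...]:
    return DEFAULT_GRID


def _combo(row: pd.Series) -> SweepCombo:
    return SweepCombo(
        memory=float(row["M"]),
        gain_sensitivity=float(row["Gs"]),
        loss_sensitivity=float(row["Ls"]),
        mean_preference=float(row["mean_preference"]),
    )


def parameter_sweep(
    m_grid: Sequence[float] | None = None,
    gs_grid: Sequence[float] | None = None,
    ls_grid: Sequence[float] | None = None,
    n_agents: int = 50,
    task: TaskConfig | None = None,
    seed: int | None = None,
    **sim_kwargs,
) -> SweepResult:
    """Grid sweep over (M, Gs, Ls); ``n_agents`` independent agents per combo.

    Each combination records the mean and SD over agents of the overall
    (all-trials) relative preference for advantageous decks. Per-combination
    seeds are spawned from ``seed`` by grid index, so any single combination
    can be reproduced in isolation.
    """
    m_grid = tuple(m_grid) if m_grid is not None else DEFAULT_GRID
    gs_grid = tuple(gs_grid) if gs_grid is not None else DEFAULT_GRID
    ls_grid = tuple(ls_grid) if ls_grid is not None else DEFAULT_GRID
    if not (m_grid and gs_grid and ls_grid):
        raise ParameterError("all three grids must be non-empty")
    if task is None:
        task = default_task()

    combos = list(itertools.product(m_grid, gs_grid, ls_grid))
    children = np.random.SeedSequence(seed).spawn(len(combos))
    rows = []
    for (m, gs, ls), child in zip(combos, children):
        params = AgentParams(memory=m, gain_sensitivity=gs, loss_sensitivity=ls)
        prefs = simulate_block_preferences(
            params,
            task,
            n_agents=n_agents,
            rng=np.random.default_rng(child),
            **sim_kwargs,
        ).mean(axis=1)
        rows.append(
            {
                "M": m,
                "Gs": gs,
                "Ls": ls,
                "mean_preference": float(prefs.mean()),
                "sd_preference": float(prefs.std(ddof=1)) if n_agents > 1 else 0.0,
                "n_agents": n_agents,
            }
        )
    table = pd.DataFrame(rows)
    argmax = _combo(table.loc[table["mean_preference"].idxmax()])
    argmin = _combo(table.loc[table["mean_preference"].idxmin()])
    grand = float(table["mean_preference"].mean())
    nearest = _combo(table.loc[(table["mean_preference"] - grand).abs().idxmin()])
    return SweepResult(
        table=table,
        argmax_combo=argmax,
        argmin_combo=argmin,
        grand_mean_combo=nearest,
        n_agents=n_agents,
        seed=seed,
    )


def sweep_figure(result: SweepResult, path: str) -> None:
    """Heat-grid of mean preference, one panel per memory-factor value."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = result.table
    m_values = sorted(table["M"].unique())
    ncol = min(3, len(m_values))
    nrow = -(-len(m_values) // ncol)
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(3.2 * ncol, 2.8 * nrow), squeeze=False
    )
    for ax in axes.flat:
        ax.set_visible(False)
    for ax, m in zip(axes.flat, m_values):
        ax.set_visible(True)
        sub = table[table["M"] == m].pivot(
            index="Ls", columns="Gs", values="mean_preference"
        )
        im = ax.imshow(
            sub.values,
            origin="lower",
            vmin=0,
            vmax=1,
            cmap="coolwarm",
            extent=(
                sub.columns.min(),
                sub.columns.max(),
                sub.index.min(),
                sub.index.max(),
            ),
            aspect="auto",
        )
        ax.set_title(f"M = {m:g}")
        ax.set_xlabel("Gs")
        ax.set_ylabel("Ls")
    fig.colorbar(im, ax=axes, label="mean preference (A+B)", shrink=0.8)
    fig.savefig(path, dpi=150)
    plt.close(fig)
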