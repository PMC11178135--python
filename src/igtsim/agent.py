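"""Agent valuation and choice rules.

The agent weighs gains and losses by separate sensitivities to form a
subjective net gain, updates the chosen option's value with a linear-operator
(exponentially weighted) rule, and converts values into choice probabilities
with either the matching rule (default) or softmax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "AgentParams",
    "AgentConfig",
    "ParameterError",
    "INITIAL_VALUE",
    "DEFAULT_VALUE_FLOOR",
    "net_gain",
    "update_value",
    "matching_probabilities",
    "softmax_probabilities",
    "choose",
    "initial_values",
]

#: Starting value assigned to every alternative.
INITIAL_VALUE = 0.25

#: Rectification floor used by the matching rule when values go negative.
DEFAULT_VALUE_FLOOR = 1e-3


class ParameterError(ValueError):
    """Raised for out-of-range agent parameters or inputs."""


@dataclass(frozen=True)
class AgentParams:
    """The agent's three traits.

    ``memory`` weighs an alternative's previous value in the update (1 keeps
    the old value forever, 0 replaces it with the latest net gain).
    ``gain_sensitivity`` and ``loss_sensitivity`` multiplicatively weigh
    gains and loss magnitudes in the subjective net gain.
    """

    memory: float
    gain_sensitivity: float
    loss_sensitivity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.memory <= 1.0:
            raise ParameterError(f"memory must be in [0, 1], got {self.memory}")
        if not 0.0 < self.gain_sensitivity <= 1.0:
            raise ParameterError(
                f"gain_sensitivity must be in (0, 1], got {self.gain_sensitivity}"
            )
        if not 0.0 < self.loss_sensitivity <= 1.0:
            raise ParameterError(
                f"loss_sensitivity must be in (0, 1], got {self.loss_sensitivity}"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.memory, self.gain_sensitivity, self.loss_sensitivity)


def net_gain(gain: float, loss: float, params: AgentParams) -> float:
    """Subjective net gain: ``gain * Gs - loss * Ls``.

    ``loss`` is a positive magnitude; the result may be negative.
    """
    if gain < 0 or loss < 0:
        raise ParameterError(
            f"gain and loss must be non-negative magnitudes, got ({gain}, {loss})"
        )
    return gain * params.gain_sensitivity - loss * params.loss_sensitivity


def update_value(v_prev: float, params: AgentParams, gn: float) -> float:
    """Linear-operator update: ``M * v_prev + (1 - M) * gn``.

    A convex combination, so the result lies between ``v_prev`` and ``gn``
    and the update contracts toward ``gn`` at rate ``M``.
    """
    m = params.memory
    return m * v_prev + (1.0 - m) * gn


def matching_probabilities(
    values: np.ndarray, floor: float = DEFAULT_VALUE_FLOOR
) -> np.ndarray:
    """Choice probabilities proportional to value: ``p_i = v_i / sum(v)``.

    The ratio rule is undefined for non-positive values, which the learning
    rule readily produces, so each value is rectified to ``max(v, floor)``
    before dividing. The floor guarantees a proper distribution and keeps
    every alternative explorable; when all rectified values are equal the
    result is uniform. Stored values are never modified.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ParameterError("values vector must be non-empty")
    if floor <= 0:
        raise ParameterError(f"floor must be > 0, got {floor}")
    rectified = np.maximum(values, floor)
    return rectified / rectified.sum()


def softmax_probabilities(values: np.ndarray, temperature: float = 1.0) -> np.ndarray:
    """Softmax choice probabilities ``exp(v/tau) / sum(exp(v/tau))``.

    Computed with max-subtraction for overflow safety.
    """
    if temperature <= 0:
        raise ParameterError(f"temperature must be > 0, got {temperature}")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ParameterError("values vector must be non-empty")
    z = values / temperature
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def choose(probs: np.ndarray, rng: np.random.Generator) -> int:
    """Sample an index from a probability vector.

    A uniform draw on [0, 1) is placed in the half-open cumulative interval
    ``[c_{i-1}, c_i)``; the interval's index is returned.
    """
    probs = np.asarray(probs, dtype=float)
    total = probs.sum()
    if abs(total - 1.0) > 1e-9:
        raise ParameterError(f"probabilities must sum to 1 within 1e-9, got {total}")
    cum = np.cumsum(probs)
    u = rng.random()
    idx = int(np.searchsorted(cum, u, side="right"))
    return min(idx, probs.size - 1)  # guard the u == 1.0 - eps edge on float cumsums


def initial_values(n_decks: int) -> np.ndarray:
    """Fresh value vector for a new simulation: every alternative at 0.25."""
    if n_decks <= 0:
        raise ParameterError(f"n_decks must be positive, got {n_decks}")
    return np.full(n_decks, INITIAL_VALUE)


@dataclass(frozen=True)
class AgentConfig:
    """Agent parameters plus the decision-rule settings.

    ``decision_rule`` is ``"matching"`` (default) or ``"softmax"``;
    ``temperature`` only applies to softmax, ``value_floor`` only to
    matching.
    """

    params: AgentParams
    decision_rule: str = "matching"
    temperature: float = 1.0
    value_floor: float = DEFAULT_VALUE_FLOOR

    def __post_init__(self) -> None:
        if self.decision_rule not in ("matching", "softmax"):
            raise ParameterError(
                f"decision_rule must be 'matching' or 'softmax', got {self.decision_rule!r}"
            )
        if self.temperature <= 0:
            raise ParameterError(f"temperature must be > 0, got {self.temperature}")
        if self.value_floor <= 0:
            raise ParameterError(f"value_floor must be > 0, got {self.value_floor}")


def config_to_dict(config: AgentConfig) -> dict:
    return {
        "memory": config.params.memory,
        "gain_sensitivity": config.params.gain_sensitivity,
        "loss_sensitivity": config.params.loss_sensitivity,
        "decision_rule": config.decision_rule,
        "temperature": config.temperature,
        "value_floor": config.value_floor,
    }


def config_from_dict(data: dict) -> AgentConfig:
    params = AgentParams(
        memory=float(data["memory"]),
        gain_sensitivity=float(data["gain_sensitivity"]),
        loss_sensitivity=float(data["loss_sensitivity"]),
    )
    return AgentConfig(
        params=params,
        decision_rule=data.get("decision_rule", "matching"),
        temperature=float(data.get("temperature", 1.0)),
        value_floor=float(data.get("value_floor", DEFAULT_VALUE_FLOOR)),
    )


def load_agent_config(path: str | Path) -> AgentConfig:
    """Read an agent configuration from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return config_from_dict(data)
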