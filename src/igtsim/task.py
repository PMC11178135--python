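"""IGT payoff environment: deck definitions, outcome sampling, normalization.

The task is described by four card decks that differ in gain per card, loss
magnitude per punished card, and the probability that a card is punished.
Losses are stored as positive magnitudes; outcome sampling returns the loss
as a magnitude as well, and downstream code subtracts it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "DeckSpec",
    "TaskConfig",
    "standard_decks",
    "normalize_deck",
    "draw_outcome",
    "default_task",
    "load_task",
    "dump_task",
    "task_from_dict",
    "task_to_dict",
]

DECK_LABELS = ("A", "B", "C", "D")


class ConfigError(ValueError):
    """Raised for invalid deck or task configurations."""


@dataclass(frozen=True)
class DeckSpec:
    """One card deck: fixed gain, probabilistic loss, long-term label.

    Parameters
    ----------
    label
        Deck name, conventionally one of ``A``-``D``.
    gain
        Currency units delivered on every draw (> 0).
    loss_magnitude
        Currency units taken when a card is punished, stored as a
        positive magnitude (>= 0).
    loss_prob
        Probability that a drawn card is punished, in [0, 1].
    advantageous
        Long-term label of the deck.
    """

    label: str
    gain: float
    loss_magnitude: float
    loss_prob: float
    advantageous: bool

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ConfigError(f"deck {self.label!r}: gain must be > 0, got {self.gain}")
        if self.loss_magnitude < 0:
            raise ConfigError(
                f"deck {self.label!r}: loss_magnitude must be >= 0 "
                f"(losses are stored as magnitudes), got {self.loss_magnitude}"
            )
        if not 0.0 <= self.loss_prob <= 1.0:
            raise ConfigError(
                f"deck {self.label!r}: loss_prob must be in [0, 1], got {self.loss_prob}"
            )

    @property
    def expected_net(self) -> float:
        """Expected raw currency outcome per draw: gain - loss_prob * loss_magnitude."""
        return self.gain - self.loss_prob * self.loss_magnitude


def standard_decks() -> list[DeckSpec]:
    """The four standard decks.

    A and B carry the large $100 gain (A with rare large losses, B with
    frequent moderate losses) and are labelled advantageous; C and D carry
    the $50 gain and are labelled disadvantageous.
    """
    return [
        DeckSpec("A", 100.0, 1250.0, 0.1, advantageous=True),
        DeckSpec("B", 100.0, 250.0, 0.5, advantageous=True),
        DeckSpec("C", 50.0, 50.0, 0.5, advantageous=False),
        DeckSpec("D", 50.0, 250.0, 0.1, advantageous=False),
    ]


def normalize_deck(deck: DeckSpec, normalizer: float) -> DeckSpec:
    """Rescale a deck's gain and loss magnitude by ``normalizer``.

    The loss probability is unchanged. Normalizing by ``c`` then by ``d``
    equals normalizing by ``c * d``.
    """
    if normalizer <= 0:
        raise ConfigError(f"normalizer must be > 0, got {normalizer}")
    return replace(
        deck,
        gain=deck.gain / normalizer,
        loss_magnitude=deck.loss_magnitude / normalizer,
    )


def draw_outcome(deck: DeckSpec, rng: np.random.Generator) -> tuple[float, float]:
    """Sample one card: ``(gain, loss_magnitude)``.

    The gain is delivered on every draw; the loss co-occurs with the gain
    on punished cards (Bernoulli with probability ``loss_prob``) and is 0
    otherwise.
    """
    loss = deck.loss_magnitude if rng.random() < deck.loss_prob else 0.0
    return deck.gain, loss


@dataclass(frozen=True)
class TaskConfig:
    """Full task configuration: decks plus trial structure.

    ``normalizer`` defaults to the maximum deck gain; payoffs handed to the
    learning rule are divided by it (trial logs keep raw currency).
    """

    decks: tuple[DeckSpec, ...] = field(default_factory=lambda: tuple(standard_decks()))
    n_trials: int = 100
    block_size: int = 20
    normalizer: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "decks", tuple(self.decks))
        if not self.decks:
            raise ConfigError("task needs at least one deck")
        if self.n_trials <= 0 or self.block_size <= 0:
            raise ConfigError("n_trials and block_size must be positive")
        if self.n_trials % self.block_size != 0:
            raise ConfigError(
                f"n_trials ({self.n_trials}) must be divisible by "
                f"block_size ({self.block_size})"
            )
        if self.normalizer is None:
            object.__setattr__(self, "normalizer", max(d.gain for d in self.decks))
        if self.normalizer <= 0:
            raise ConfigError(f"normalizer must be > 0, got {self.normalizer}")

    @property
    def n_decks(self) -> int:
        return len(self.decks)

    @property
    def n_blocks(self) -> int:
        return self.n_trials // self.block_size

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(d.label for d in self.decks)

    @property
    def advantageous_indices(self) -> tuple[int, ...]:
        return tuple(i for i, d in enumerate(self.decks) if d.advantageous)

    def normalized_decks(self) -> tuple[DeckSpec, ...]:
        return tuple(normalize_deck(d, self.normalizer) for d in self.decks)


def task_to_dict(task: TaskConfig) -> dict:
    return {
        "decks": [
            {
                "label": d.label,
                "gain": d.gain,
                "loss_magnitude": d.loss_magnitude,
                "loss_prob": d.loss_prob,
                "advantageous": d.advantageous,
            }
            for d in task.decks
        ],
        "n_trials": task.n_trials,
        "block_size": task.block_size,
        "normalizer": task.normalizer,
    }


def task_from_dict(data: dict) -> TaskConfig:
    try:
        decks = tuple(DeckSpec(**d) for d in data["decks"])
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed task dictionary: {exc}") from exc
    return TaskConfig(
        decks=decks,
        n_trials=int(data.get("n_trials", 100)),
        block_size=int(data.get("block_size", 20)),
        normalizer=data.get("normalizer"),
    )


def load_task(path: str | Path) -> TaskConfig:
    """Read a task configuration from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return task_from_dict(data)


def dump_task(task: TaskConfig, path: str | Path) -> None:
    """Write a task configuration as JSON (or YAML for .yaml/.yml paths)."""
    path = Path(path)
    data = task_to_dict(task)
    if path.suffix.lower() in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2) + "\n")


def default_task() -> TaskConfig:
    """The bundled default task: standard decks, 100 trials, 5 blocks of 20."""
    with resources.files("igtsim.data").joinpath("default_task.json").open() as fh:
        return task_from_dict(json.load(fh))
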