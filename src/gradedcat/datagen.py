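"""Synthetic item banks, latent traits, and graded response matrices.

The generator emulates the structure of a short 3-scale screening
questionnaire: by default 3 scales of 7 polytomous items with 4 response
categories, latent traits drawn from Normal(0, 1), and responses drawn from
graded-response-model category probabilities.  Item thresholds default to
positive offsets (scales are "peaked", most informative above the population
mean), mirroring how symptom inventories behave in non-clinical samples.

Negative-control injections (a duplicated item, a threshold shift for one
group) are provided so that downstream local-dependence and DIF checks can be
validated against data that violate their assumptions on purpose.

One global seed is split into independent substreams for traits, bank, and
responses, so e.g. changing the number of respondents never perturbs the
generated bank.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _em
from .bank import (
    InvalidConfigError,
    InvalidInputError,
    ItemBank,
    ItemParameters,
    ResponseMatrix,
)

__all__ = [
    "TrueTheta",
    "GenerationConfig",
    "generate_thetas",
    "generate_item_bank",
    "simulate_responses",
    "simulate_item_column",
    "inject_dependence",
    "generate_dataset",
]

_SCALE_NAMES = ("depression", "anxiety", "stress")
_MIN_GAP = 0.05


@dataclass(frozen=True)
class TrueTheta:
    """Known generating latent traits for a simulated cohort."""

    values: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class GenerationConfig:
    """Study-condition defaults: 3 scales x 7 items, 4 categories, N(0,1) traits.

    ``discrimination_range`` bounds the log-uniform item discriminations;
    ``threshold_spread`` scales the dispersion of threshold draws around
    scale-specific offsets centered at ``threshold_center`` (+1 by default:
    peaked scales).  ``injections`` holds optional (kind, params) negative
    controls applied by :func:`generate_dataset`.
    """

    n_respondents: int = 10_000
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    n_scales: int = 3
    items_per_scale: int = 7
    n_categories: int = 4
    discrimination_range: tuple[float, float] = (0.8, 2.5)
    threshold_spread: float = 1.0
    threshold_center: float = 1.0
    seed: int = 0
    injections: tuple[tuple[str, dict], ...] = ()

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise InvalidConfigError("n_respondents must be >= 1")
        if self.theta_sd <= 0:
            raise InvalidConfigError("theta_sd must be positive")
        if self.n_scales < 1 or self.items_per_scale < 1:
            raise InvalidConfigError("need at least one scale and one item per scale")
        if self.n_categories < 2:
            raise InvalidConfigError("n_categories must be >= 2")
        lo, hi = self.discrimination_range
        if not (0 < lo <= hi):
            raise InvalidConfigError("discrimination_range must satisfy 0 < low <= high")
        if self.threshold_spread <= 0:
            raise InvalidConfigError("threshold_spread must be positive")
        object.__setattr__(self, "injections", tuple(self.injections))


def _substream(seed: int, purpose: str) -> np.random.Generator:
    """Independent substream per purpose from one global seed."""
    order = {"theta": 0, "bank": 1, "responses": 2, "injection": 3}
    ss = np.random.SeedSequence(seed)
    return np.random.default_rng(ss.spawn(4)[order[purpose]])


def generate_thetas(config: GenerationConfig) -> TrueTheta:
    """Draw i.i.d. Normal(theta_mean, theta_sd^2) latent traits."""
    rng = _substream(config.seed, "theta")
    values = rng.normal(config.theta_mean, config.theta_sd, size=config.n_respondents)
    return TrueTheta(values=values, seed=config.seed)


def _scale_names(n: int) -> list[str]:
    if n <= len(_SCALE_NAMES):
        return list(_SCALE_NAMES[:n])
    return list(_SCALE_NAMES) + [f"scale{i+1}" for i in range(len(_SCALE_NAMES), n)]


def generate_item_bank(config: GenerationConfig) -> ItemBank:
    """Random GRM item bank with the configured scale structure.

    Discriminations are log-uniform on ``discrimination_range``; each item's
    thresholds are sorted Normal(offset, spread) draws with a minimum gap of
    0.05, where the scale offsets straddle ``threshold_center``.  Strictly
    increasing thresholds hold by construction.
    """
    rng = _substream(config.seed, "bank")
    names = _scale_names(config.n_scales)
    if config.n_scales > 1:
        offsets = config.threshold_center + np.linspace(-0.3, 0.3, config.n_scales)
    else:
        offsets = np.array([config.threshold_center])
    lo, hi = config.discrimination_range
    items = []
    for s, scale in enumerate(names):
        prefix = scale[:3]
        for j in range(config.items_per_scale):
            a = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            raw = np.sort(
                rng.normal(offsets[s], config.threshold_spread, size=config.n_categories - 1)
            )
            b = [raw[0]]
            for v in raw[1:]:
                b.append(max(v, b[-1] + _MIN_GAP))
            items.append(
                ItemParameters(id=f"{prefix}{j+1}", a=a, b=tuple(b), scale=scale)
            )
    return ItemBank(items=tuple(items), name="synthetic", n_categories=config.n_categories)


def simulate_item_column(
    item: ItemParameters, thetas: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw one item's responses from GRM category probabilities."""
    thetas = np.asarray(thetas, dtype=float)
    if not np.all(np.isfinite(thetas)):
        raise InvalidInputError("theta values must be finite")
    pstar = 1.0 / (1.0 + np.exp(-item.a * (thetas[:, None] - np.asarray(item.b)[None, :])))
    u = rng.uniform(size=(len(thetas), 1))
    return (u < pstar).sum(axis=1).astype(np.int64)


def simulate_responses(
    bank: ItemBank, thetas: TrueTheta | np.ndarray, seed: int
) -> ResponseMatrix:
    """Simulate a full respondents x items category matrix from the GRM."""
    if len(bank) == 0:
        raise InvalidInputError("item bank is empty")
    theta_values = thetas.values if isinstance(thetas, TrueTheta) else np.asarray(thetas, float)
    if len(theta_values) == 0:
        raise InvalidInputError("no respondents to simulate")
    if not np.all(np.isfinite(theta_values)):
        raise InvalidInputError("theta values must be finite")
    rng = _substream(seed, "responses")
    cols = {
        it.id: simulate_item_column(it, theta_values, rng) for it in bank.items
    }
    return ResponseMatrix(data=pd.DataFrame(cols), true_theta=theta_values.copy())


def inject_dependence(
    matrix: ResponseMatrix,
    kind: str,
    params: dict,
    bank: ItemBank | None = None,
    seed: int = 0,
) -> ResponseMatrix:
    """Apply a negative-control violation to a simulated response matrix.

    ``duplicate_item`` appends a copy of ``params["item"]``'s column under a
    new id (``params.get("noise", 0.0)`` is the per-cell probability of a
    +-1 category jitter), creating a locally dependent pair for Q3 checks.

    ``dif_shift`` re-simulates ``params["item"]`` for respondents whose group
    label equals ``params["group"]`` with thresholds shifted by
    ``params["shift"]`` (harder items for positive shifts), creating uniform
    DIF; requires ``bank`` and the matrix's ``true_theta``.
    """
    rng = _substream(seed, "injection")
    if kind == "duplicate_item":
        item_id = params["item"]
        if item_id not in matrix.item_ids:
            raise InvalidConfigError(f"unknown item {item_id!r}")
        noise = float(params.get("noise", 0.0))
        new_id = params.get("new_id", f"{item_id}_dup")
        col = matrix.data[item_id].to_numpy().copy()
        if noise > 0:
            jitter = rng.uniform(size=len(col)) < noise
            col[jitter] += rng.choice([-1, 1], size=jitter.sum())
            kmax = int(matrix.data.to_numpy().max())
            col = np.clip(col, 0, kmax)
        data = matrix.data.copy()
        data[new_id] = col
        return ResponseMatrix(data=data, group=matrix.group, true_theta=matrix.true_theta)

    if kind == "dif_shift":
        if bank is None:
            raise InvalidConfigError("dif_shift needs the generating item bank")
        if matrix.true_theta is None:
            raise InvalidConfigError("dif_shift needs known true thetas")
        if matrix.group is None:
            raise InvalidConfigError("dif_shift needs group labels")
        item = bank[params["item"]]
        shift = float(params["shift"])
        target = params["group"]
        rows = np.where(matrix.group == target)[0]
        shifted = ItemParameters(
            id=item.id, a=item.a, b=tuple(np.asarray(item.b) + shift), scale=item.scale
        )
        data = matrix.data.copy()
        if shift != 0.0:
            col = data[item.id].to_numpy().copy()
            col[rows] = simulate_item_column(shifted, matrix.true_theta[rows], rng)
            data[item.id] = col
        return ResponseMatrix(data=data, group=matrix.group, true_theta=matrix.true_theta)

    raise InvalidConfigError(f"unknown injection kind {kind!r}")


def generate_dataset(
    config: GenerationConfig, groups: Sequence | None = None
) -> tuple[ItemBank, TrueTheta, ResponseMatrix]:
    """End-to-end generation: bank, traits, responses, then any injections.

    ``groups`` (optional per-respondent labels) is attached before injections
    so ``dif_shift`` controls can target a subgroup.  With no explicit groups
    and a ``dif_shift`` injection, respondents are split A/B alternately.
    """
    bank = generate_item_bank(config)
    thetas = generate_thetas(config)
    matrix = simulate_responses(bank, thetas, config.seed)
    if groups is None and any(kind == "dif_shift" for kind, _p in config.injections):
        groups = np.where(np.arange(config.n_respondents) % 2 == 0, "A", "B")
    if groups is not None:
        matrix = ResponseMatrix(
            data=matrix.data, group=np.asarray(groups), true_theta=matrix.true_theta
        )
    for kind, params in config.injections:
        matrix = inject_dependence(matrix, kind, params, bank=bank, seed=config.seed)
    return bank, thetas, matrix
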