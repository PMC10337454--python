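"""Core containers: item parameters, item banks, response matrices, quadrature.

The graded response model (GRM) describes an ordinal item with ``K`` response
categories through a discrimination ``a > 0`` and ``K - 1`` strictly increasing
thresholds ``b_1 < ... < b_{K-1}`` on the latent-trait (theta) scale.  An item
bank is an ordered collection of such items partitioned into named scales
(e.g. the depression / anxiety / stress scales of a 21-item screening
instrument).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InvalidConfigError",
    "InvalidInputError",
    "SchemaError",
    "ItemParameters",
    "ItemBank",
    "ResponseMatrix",
    "ThetaEstimate",
    "QuadratureGrid",
    "make_grid",
]


class InvalidConfigError(ValueError):
    """A configuration value violates its contract."""


class InvalidInputError(ValueError):
    """Data passed to an operation violates its preconditions."""


class SchemaError(ValueError):
    """A serialized artifact does not match the documented schema."""


MIN_THRESHOLD_GAP = 1e-8


@dataclass(frozen=True)
class ItemParameters:
    """A single graded item: discrimination ``a`` and ordered thresholds ``b``.

    ``b[k-1]`` is the theta at which the probability of responding in
    category ``k`` or above equals one half.  ``scale`` names the subscale
    the item belongs to.
    """

    id: str
    a: float
    b: tuple[float, ...]
    scale: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "b", tuple(float(x) for x in self.b))
        object.__setattr__(self, "a", float(self.a))
        if not np.isfinite(self.a) or self.a < 0:
            raise SchemaError(f"item {self.id!r}: discrimination a={self.a} must be finite and >= 0")
        if len(self.b) < 1:
            raise SchemaError(f"item {self.id!r}: needs at least one threshold")
        if not all(np.isfinite(self.b)):
            raise SchemaError(f"item {self.id!r}: thresholds must be finite, got {self.b}")
        if any(hi - lo < MIN_THRESHOLD_GAP for lo, hi in zip(self.b, self.b[1:])):
            raise SchemaError(
                f"item {self.id!r}: thresholds must be strictly increasing, got {self.b}"
            )

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1


@dataclass(frozen=True)
class ItemBank:
    """Ordered item collection partitioned into scales."""

    items: tuple[ItemParameters, ...]
    name: str = "bank"
    n_categories: int = 0

    def __post_init__(self) -> None:
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        ids = [it.id for it in items]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate item ids: {dup}")
        if self.n_categories == 0 and items:
            object.__setattr__(
                self, "n_categories", max(it.n_categories for it in items)
            )

    @property
    def item_ids(self) -> list[str]:
        return [it.id for it in self.items]

    @property
    def scales(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for it in self.items:
            out.setdefault(it.scale, []).append(it.id)
        return out

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, item_id: str) -> ItemParameters:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)

    def subset(self, scale: str) -> "ItemBank":
        """The sub-bank holding one scale's items (order preserved)."""
        items = tuple(it for it in self.items if it.scale == scale)
        if not items:
            raise KeyError(f"no items in scale {scale!r}")
        return ItemBank(items=items, name=f"{self.name}:{scale}", n_categories=self.n_categories)

    def scale_items(self, scale: str | None) -> tuple[ItemParameters, ...]:
        if scale is None:
            return self.items
        return self.subset(scale).items


@dataclass
class ResponseMatrix:
    """Respondents x items integer categories, with optional metadata.

    ``data`` holds one column per item id with categories in
    ``{0, ..., n_categories-1}``.  ``group`` (labels for DIF) and
    ``true_theta`` (known generating traits, for simulations) are optional
    per-respondent columns.
    """

    data: pd.DataFrame
    group: np.ndarray | None = None
    true_theta: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        if self.group is not None:
            self.group = np.asarray(self.group)
            if len(self.group) != len(self.data):
                raise InvalidInputError("group labels length != number of respondents")
        if self.true_theta is not None:
            self.true_theta = np.asarray(self.true_theta, dtype=float)
            if len(self.true_theta) != len(self.data):
                raise InvalidInputError("true_theta length != number of respondents")

    @property
    def item_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_respondents(self) -> int:
        return len(self.data)

    def values(self, item_ids: Sequence[str] | None = None) -> np.ndarray:
        cols = list(item_ids) if item_ids is not None else self.item_ids
        return self.data[cols].to_numpy(dtype=np.int64)

    def subset(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        return ResponseMatrix(
            data=self.data[list(item_ids)].copy(),
            group=None if self.group is None else self.group.copy(),
            true_theta=None if self.true_theta is None else self.true_theta.copy(),
        )


@dataclass(frozen=True)
class ThetaEstimate:
    """A latent-trait estimate: posterior mean, posterior SD, method tag."""

    theta: float
    se: float
    method: str = "EAP"
    n_items_used: int = 0

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise InvalidInputError(f"standard error must be positive, got {self.se}")


@dataclass(frozen=True)
class QuadratureGrid:
    """Theta nodes and normalized prior weights for EAP / EM integrals."""

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        wts = np.asarray(self.weights, dtype=float)
        if pts.ndim != 1 or pts.shape != wts.shape:
            raise InvalidConfigError("points and weights must be 1-d and equal length")
        if np.any(np.diff(pts) <= 0):
            raise InvalidConfigError("quadrature points must be strictly increasing")
        if np.any(wts < 0) or wts.sum() <= 0:
            raise InvalidConfigError("weights must be nonnegative with positive sum")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", wts / wts.sum())

    def __len__(self) -> int:
        return len(self.points)


def make_grid(
    n_points: int = 61,
    theta_range: tuple[float, float] = (-6.0, 6.0),
    prior_mean: float = 0.0,
    prior_sd: float = 1.0,
) -> QuadratureGrid:
    """Equally spaced theta nodes with renormalized Normal(prior) weights."""
    if n_points < 3:
        raise InvalidConfigError("need at least 3 quadrature points")
    if prior_sd <= 0:
        raise InvalidConfigError("prior sd must be positive")
    pts = np.linspace(theta_range[0], theta_range[1], n_points)
    z = (pts - prior_mean) / prior_sd
    w = np.exp(-0.5 * z * z)
    return QuadratureGrid(points=pts, weights=w)
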