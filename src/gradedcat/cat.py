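"""The adaptive administration loop.

A computer-adaptive test (CAT) over a calibrated graded-response item bank:
items are selected by maximum posterior-weighted information (the expected
Fisher information of a candidate under the respondent's current theta
posterior), the trait is re-estimated by EAP after every response, and
administration stops when the posterior SD falls below a SEM threshold, when
no remaining item offers enough information (optional combination rule), or
when the bank / item cap is exhausted.

Both a per-respondent loop (:func:`run_cat`, full trace) and a vectorized
batch runner (:func:`run_cat_batch`, used by the simulation study) are
provided; they implement identical semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from . import _em
from .bank import (
    InvalidConfigError,
    InvalidInputError,
    ItemBank,
    ItemParameters,
    QuadratureGrid,
    ThetaEstimate,
    make_grid,
)
from .grm import item_information

__all__ = [
    "ExhaustedBankError",
    "CatConfig",
    "CatState",
    "CatRecord",
    "new_state",
    "posterior_weighted_information",
    "select_next_item",
    "update_state",
    "check_stop",
    "run_cat",
    "run_cat_batch",
    "simulated_source",
    "recorded_source",
]


class ExhaustedBankError(RuntimeError):
    """No unadministered item remains."""


@dataclass(frozen=True)
class CatConfig:
    """Administration rules for one CAT run.

    ``stop_sem = 0`` never triggers the SEM rule (the posterior SD is always
    positive), so the test runs to ``max_items``.  ``min_information``, when
    set, stops the test once no remaining candidate's posterior-weighted
    information reaches it (the combination rule for small peaked banks).
    """

    selection: str = "posterior_weighted_information"
    estimation: str = "EAP"
    prior: tuple[float, float] = (0.0, 1.0)
    stop_sem: float = 0.0
    min_items: int = 1
    max_items: int | None = None
    min_information: float | None = None
    seed: int = 0
    n_quadrature: int = 61
    theta_range: tuple[float, float] = (-6.0, 6.0)
    sem_rule: str = "posterior_sd"  # or "expected_information"

    def __post_init__(self) -> None:
        if self.selection != "posterior_weighted_information":
            raise InvalidConfigError(f"unknown selection rule {self.selection!r}")
        if self.estimation != "EAP":
            raise InvalidConfigError(f"unknown estimation method {self.estimation!r}")
        if self.stop_sem < 0:
            raise InvalidConfigError("stop_sem must be >= 0")
        if self.min_items < 1:
            raise InvalidConfigError("min_items must be >= 1")
        if self.max_items is not None and self.min_items > self.max_items:
            raise InvalidConfigError("min_items must not exceed max_items")
        if self.min_information is not None and self.min_information <= 0:
            raise InvalidConfigError("min_information must be positive when set")
        if self.sem_rule not in ("posterior_sd", "expected_information"):
            raise InvalidConfigError(f"unknown sem_rule {self.sem_rule!r}")

    def resolve_max_items(self, bank_size: int) -> int:
        return bank_size if self.max_items is None else min(self.max_items, bank_size)

    def grid(self) -> QuadratureGrid:
        return make_grid(self.n_quadrature, self.theta_range, *self.prior)


@dataclass
class CatState:
    """Mutable administration state: answered items and the theta posterior."""

    grid: QuadratureGrid
    administered: list[str] = field(default_factory=list)
    responses: list[int] = field(default_factory=list)
    posterior: np.ndarray = None  # type: ignore[assignment]
    current: ThetaEstimate = None  # type: ignore[assignment]

    def copy(self) -> "CatState":
        return CatState(
            grid=self.grid,
            administered=list(self.administered),
            responses=list(self.responses),
            posterior=self.posterior.copy(),
            current=self.current,
        )


def _posterior_moments(grid: QuadratureGrid, posterior: np.ndarray) -> tuple[float, float]:
    w = posterior / posterior.sum()
    mean = float(w @ grid.points)
    var = float(w @ (grid.points - mean) ** 2)
    return mean, float(np.sqrt(max(var, 1e-300)))


def new_state(config: CatConfig) -> CatState:
    grid = config.grid()
    post = grid.weights.copy()
    theta, se = _posterior_moments(grid, post)
    return CatState(
        grid=grid,
        posterior=post,
        current=ThetaEstimate(theta=theta, se=se, method="EAP", n_items_used=0),
    )


def posterior_weighted_information(state: CatState, candidate: ItemParameters) -> float:
    """Expected information of a candidate under the current theta posterior.

    ``sum_q posterior(theta_q) * I_item(theta_q)``; invariant to posterior
    scaling (the posterior is renormalized internally).
    """
    if candidate.id in state.administered:
        raise InvalidInputError(f"item {candidate.id!r} already administered")
    w = state.posterior / state.posterior.sum()
    return float(w @ item_information(candidate, state.grid.points))


def _candidates(state: CatState, items: Sequence[ItemParameters]) -> list[ItemParameters]:
    return [it for it in items if it.id not in state.administered]


def select_next_item(
    state: CatState, items: Sequence[ItemParameters] | ItemBank, config: CatConfig
) -> str:
    """Argmax of posterior-weighted information; ties go to the lowest index."""
    if isinstance(items, ItemBank):
        items = items.items
    cands = _candidates(state, items)
    if not cands:
        raise ExhaustedBankError("no unadministered items remain")
    crits = [posterior_weighted_information(state, it) for it in cands]
    return cands[int(np.argmax(crits))].id


def update_state(
    state: CatState, item: ItemParameters, response: int,
    grid: QuadratureGrid | None = None,
) -> CatState:
    """Multiply the posterior by the item's category likelihood; renormalize.

    Sequential updates reproduce batch EAP on the same pattern exactly (the
    likelihood factorizes over items).
    """
    if not (0 <= int(response) < item.n_categories):
        raise InvalidInputError(
            f"category {response} invalid for item {item.id!r} "
            f"({item.n_categories} categories)"
        )
    g = grid if grid is not None else state.grid
    like = _em.grm_probs(item.a, np.asarray(item.b), g.points)[:, int(response)]
    post = state.posterior * np.maximum(like, 1e-300)
    post = post / post.sum()
    theta, se = _posterior_moments(g, post)
    new = state.copy()
    new.administered.append(item.id)
    new.responses.append(int(response))
    new.posterior = post
    new.current = ThetaEstimate(
        theta=theta, se=se, method="EAP", n_items_used=len(new.administered)
    )
    return new


def _stop_sem_value(
    state: CatState, config: CatConfig, items: Sequence[ItemParameters]
) -> float:
    if config.sem_rule == "posterior_sd":
        return state.current.se
    administered = [it for it in items if it.id in state.administered]
    info = sum(item_information(it, state.current.theta) for it in administered)
    prior_info = 1.0 / config.prior[1] ** 2
    return float(1.0 / np.sqrt(info + prior_info))


def check_stop(
    state: CatState,
    config: CatConfig,
    items: Sequence[ItemParameters] | ItemBank | None = None,
) -> tuple[bool, str | None]:
    """Stop decision: SEM rule, optional minimum-information rule, item cap."""
    if isinstance(items, ItemBank):
        items = items.items
    n = len(state.administered)
    max_items = config.resolve_max_items(len(items) if items is not None else n)
    if n >= config.min_items:
        sem = _stop_sem_value(state, config, items or [])
        if config.stop_sem > 0 and sem <= config.stop_sem:
            return True, "sem_met"
    if n >= max_items:
        return True, "max_items"
    if n >= config.min_items and config.min_information is not None:
        if items is None:
            raise InvalidInputError("min_information rule needs the item bank")
        cands = _candidates(state, items)
        if not cands or max(
            posterior_weighted_information(state, it) for it in cands
        ) < config.min_information:
            return True, "min_information"
    return False, None


@dataclass
class CatRecord:
    """One respondent's administration trace and final estimate."""

    respondent: int | str
    items: list[str]
    responses: list[int]
    trace: list[tuple[float, float]]
    final: ThetaEstimate
    stop_reason: str
    aborted: bool = False

    @property
    def n_items(self) -> int:
        return len(self.items)


def simulated_source(
    theta: float, items: Sequence[ItemParameters] | ItemBank, seed: int = 0
) -> Callable[[str], int]:
    """Response source drawing each requested item from the GRM at ``theta``."""
    if isinstance(items, ItemBank):
        items = items.items
    if not np.isfinite(theta):
        raise InvalidInputError("theta must be finite")
    by_id = {it.id: it for it in items}
    rng = np.random.default_rng(seed)

    def source(item_id: str) -> int:
        it = by_id[item_id]
        pstar = 1.0 / (1.0 + np.exp(-it.a * (theta - np.asarray(it.b))))
        return int((rng.uniform() < pstar).sum())

    return source


def recorded_source(row: Mapping[str, int]) -> Callable[[str], int]:
    """Response source replaying a recorded response pattern."""

    def source(item_id: str) -> int:
        return int(row[item_id])

    return source


def run_cat(
    items: Sequence[ItemParameters] | ItemBank,
    response_source: Callable[[str], int] | Mapping[str, int] | float,
    config: CatConfig,
    respondent: int | str = 0,
) -> CatRecord:
    """Select -> elicit -> update -> check loop for one respondent.

    ``response_source`` may be a callable mapping item id to category, a
    recorded response row (mapping), or a scalar true theta (responses are
    then simulated with ``config.seed``).  A failing source aborts the
    administration and flags the partial record.
    """
    if isinstance(items, ItemBank):
        items = items.items
    if isinstance(response_source, Mapping):
        source = recorded_source(response_source)
    elif callable(response_source):
        source = response_source
    else:
        source = simulated_source(float(response_source), items, seed=config.seed)

    state = new_state(config)
    trace: list[tuple[float, float]] = []
    stop, reason = check_stop(state, config, items)
    aborted = False
    while not stop:
        item_id = select_next_item(state, items, config)
        item = next(it for it in items if it.id == item_id)
        try:
            response = source(item_id)
        except Exception:
            reason, aborted = "aborted", True
            break
        state = update_state(state, item, response)
        trace.append((state.current.theta, state.current.se))
        stop, reason = check_stop(state, config, items)
    return CatRecord(
        respondent=respondent,
        items=list(state.administered),
        responses=list(state.responses),
        trace=trace,
        final=state.current,
        stop_reason=reason or "max_items",
        aborted=aborted,
    )


def run_cat_batch(
    items: Sequence[ItemParameters] | ItemBank,
    responses: np.ndarray,
    config: CatConfig,
) -> dict[str, np.ndarray]:
    """Vectorized CAT over a pre-drawn (n, m) response matrix.

    Semantically identical to looping :func:`run_cat` with recorded sources
    (a simulated respondent's answers can be pre-drawn because, given theta,
    responses are independent across items).  Returns arrays ``theta``,
    ``se``, ``n_items``, ``stop_reason``, and the (n, max_items) item-index
    ``sequence`` (-1 padding).
    """
    if isinstance(items, ItemBank):
        items = items.items
    x = np.asarray(responses, dtype=np.int64)
    n, m = x.shape
    if m != len(items):
        raise InvalidInputError("response matrix does not match the item list")
    grid = config.grid()
    nodes, prior_w = grid.points, grid.weights
    q = len(nodes)
    max_items = config.resolve_max_items(m)

    p_tensor = _em.prob_tensor(
        np.array([it.a for it in items]), [np.asarray(it.b) for it in items], nodes
    )  # (m, q, K)
    info = np.stack([item_information(it, nodes) for it in items])  # (m, q)

    post = np.tile(prior_w, (n, 1))
    administered = np.zeros((n, m), dtype=bool)
    sequence = np.full((n, max_items), -1, dtype=np.int64)
    n_admin = np.zeros(n, dtype=np.int64)
    theta = np.full(n, float(prior_w @ nodes))
    var0 = float(prior_w @ nodes**2) - theta[0] ** 2
    se = np.full(n, np.sqrt(max(var0, 1e-300)))
    active = np.ones(n, dtype=bool)
    stop_reason = np.full(n, "", dtype=object)

    def sem_values(rows: np.ndarray) -> np.ndarray:
        if config.sem_rule == "posterior_sd":
            return se[rows]
        prior_info = 1.0 / config.prior[1] ** 2
        out = np.empty(len(rows))
        for pos, r in enumerate(rows):
            idx = np.where(administered[r])[0]
            tinfo = sum(
                float(item_information(items[i], theta[r])) for i in idx
            )
            out[pos] = 1.0 / np.sqrt(tinfo + prior_info)
        return out

    for _step in range(max_items):
        rows = np.where(active)[0]
        if len(rows) == 0:
            break
        pwi = (post[rows] / post[rows].sum(axis=1, keepdims=True)) @ info.T  # (r, m)
        pwi[administered[rows]] = -np.inf
        # min-information rule applies before selecting the next item
        if config.min_information is not None:
            eligible = n_admin[rows] >= config.min_items
            weak = eligible & (pwi.max(axis=1) < config.min_information)
            if weak.any():
                stop_reason[rows[weak]] = "min_information"
                active[rows[weak]] = False
                keepers = ~weak
                rows = rows[keepers]
                pwi = pwi[keepers]
                if len(rows) == 0:
                    break
        sel = np.argmax(pwi, axis=1)
        sequence[rows, n_admin[rows]] = sel
        administered[rows, sel] = True
        n_admin[rows] += 1
        resp = x[rows, sel]
        like = p_tensor[sel, :, resp]  # (r, q)
        post[rows] = post[rows] * np.maximum(like, 1e-300)
        post[rows] /= post[rows].sum(axis=1, keepdims=True)
        theta[rows] = post[rows] @ nodes
        se[rows] = np.sqrt(
            np.maximum(post[rows] @ nodes**2 - theta[rows] ** 2, 1e-300)
        )
        can_stop = n_admin[rows] >= config.min_items
        if config.stop_sem > 0:
            sem_now = sem_values(rows)
            met = can_stop & (sem_now <= config.stop_sem)
            stop_reason[rows[met]] = "sem_met"
            active[rows[met]] = False
        done = active[rows] & (n_admin[rows] >= max_items)
        stop_reason[rows[done]] = "max_items"
        active[rows[done]] = False

    stop_reason[stop_reason == ""] = "max_items"
    return {
        "theta": theta,
        "se": se,
        "n_items": n_admin,
        "stop_reason": stop_reason.astype(str),
        "sequence": sequence,
    }
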