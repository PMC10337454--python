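"""The graded response model: probabilities, information, calibration, scoring.

Samejima's graded response model (GRM) treats an ordinal item with ``K``
categories through cumulative logistic curves

    P(X >= k | theta) = 1 / (1 + exp(-a (theta - b_k))),   k = 1..K-1,

with category probabilities as adjacent differences.  The logistic metric is
used without the historical 1.7 scaling constant.  This module provides

* closed-form category probabilities and Fisher information,
* EAP (expected a posteriori) trait scoring on a quadrature grid,
* :class:`GradedResponseModel`, a scikit-learn style estimator performing
  marginal-maximum-likelihood calibration via EM,
* marginal reliability and the reliability <-> SEM correspondence used when
  translating CAT stop rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import _em
from .bank import (
    InvalidInputError,
    ItemBank,
    ItemParameters,
    QuadratureGrid,
    ResponseMatrix,
    ThetaEstimate,
    make_grid,
)

__all__ = [
    "category_probabilities",
    "item_information",
    "test_information_and_sem",
    "reliability_sem_conversion",
    "sem_to_reliability",
    "eap_score",
    "eap_score_matrix",
    "marginal_reliability",
    "check_threshold_ordering",
    "GradedResponseModel",
    "CalibrationResult",
    "calibrate_grm",
]


def category_probabilities(item: ItemParameters, theta) -> np.ndarray:
    """GRM category probabilities at ``theta``.

    Returns shape ``(K,)`` for scalar theta, ``(len(theta), K)`` otherwise.
    """
    theta_arr = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta_arr)):
        raise InvalidInputError("theta must be finite")
    p = _em.grm_probs(item.a, np.asarray(item.b), np.atleast_1d(theta_arr))
    return p[0] if theta_arr.ndim == 0 else p


def item_information(item: ItemParameters, theta) -> np.ndarray | float:
    """Fisher information of one graded item, ``sum_k P'_k(theta)^2 / P_k``."""
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    b = np.asarray(item.b)
    pstar = 1.0 / (1.0 + np.exp(-item.a * (theta_arr[:, None] - b[None, :])))
    w = pstar * (1.0 - pstar)
    wfull = np.concatenate(
        [np.zeros((len(theta_arr), 1)), w, np.zeros((len(theta_arr), 1))], axis=1
    )
    dp = item.a * (wfull[:, :-1] - wfull[:, 1:])  # P'_k, (n, K)
    p = _em.grm_probs(item.a, b, theta_arr)
    info = np.where(p > 1e-12, dp**2 / np.maximum(p, 1e-12), 0.0).sum(axis=1)
    return float(info[0]) if np.asarray(theta).ndim == 0 else info


def test_information_and_sem(
    items: Sequence[ItemParameters] | ItemBank, theta
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Scale information (sum over items) and SEM(theta) = information^(-1/2).

    Zero total information yields an infinite SEM sentinel.
    """
    if isinstance(items, ItemBank):
        items = items.items
    if len(items) == 0:
        raise InvalidInputError("need at least one item")
    scalar = np.asarray(theta).ndim == 0
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    info = np.zeros(len(theta_arr))
    for it in items:
        info += item_information(it, theta_arr)
    with np.errstate(divide="ignore"):
        sem = np.where(info > 0, 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.inf)
    if scalar:
        return float(info[0]), float(sem[0])
    return info, sem


def reliability_sem_conversion(reliability: float) -> float:
    """SEM implied by a reliability target under a unit-variance trait.

    ``sem = sqrt(1 - reliability)``; e.g. 0.80 -> 0.447, 0.90 -> 0.316, the
    correspondence used to translate reliability levels into CAT stop rules.
    """
    if not (0.0 < reliability <= 1.0):
        raise InvalidInputError(f"reliability must be in (0, 1], got {reliability}")
    return float(np.sqrt(1.0 - reliability))


def sem_to_reliability(sem: float) -> float:
    """Inverse of :func:`reliability_sem_conversion`: ``1 - sem**2``."""
    if sem < 0 or sem > 1:
        raise InvalidInputError(f"sem must be in [0, 1], got {sem}")
    return float(1.0 - sem**2)


def _resolve_responses(
    items: Sequence[ItemParameters],
    responses: Mapping[str, int] | Sequence[int | None],
) -> list[tuple[ItemParameters, int]]:
    pairs: list[tuple[ItemParameters, int]] = []
    if isinstance(responses, Mapping):
        by_id = {it.id: it for it in items}
        for item_id, cat in responses.items():
            if item_id not in by_id:
                raise InvalidInputError(f"response references unknown item {item_id!r}")
            pairs.append((by_id[item_id], int(cat)))
    else:
        if len(responses) != len(items):
            raise InvalidInputError("aligned response sequence must match item count")
        for it, cat in zip(items, responses):
            if cat is None:
                continue
            pairs.append((it, int(cat)))
    for it, cat in pairs:
        if not (0 <= cat < it.n_categories):
            raise InvalidInputError(
                f"category {cat} out of range for item {it.id!r} "
                f"with {it.n_categories} categories"
            )
    return pairs


def eap_score(
    items: Sequence[ItemParameters] | ItemBank,
    responses: Mapping[str, int] | Sequence[int | None],
    grid: QuadratureGrid | None = None,
    prior: tuple[float, float] = (0.0, 1.0),
) -> ThetaEstimate:
    """Expected a posteriori trait estimate for one (possibly partial) pattern.

    The posterior over the grid combines a Normal(prior) with the GRM
    likelihood of the answered items; the estimate is the posterior mean and
    the standard error is the posterior SD.  With no responses the prior
    moments are returned (within quadrature error).
    """
    if isinstance(items, ItemBank):
        items = items.items
    if grid is None:
        grid = make_grid(prior_mean=prior[0], prior_sd=prior[1])
    pairs = _resolve_responses(items, responses)
    logpost = np.log(grid.weights)
    for it, cat in pairs:
        p = _em.grm_probs(it.a, np.asarray(it.b), grid.points)[:, cat]
        logpost += np.log(np.maximum(p, 1e-300))
    logpost -= logpost.max()
    post = np.exp(logpost)
    post /= post.sum()
    mean = float(post @ grid.points)
    var = float(post @ (grid.points - mean) ** 2)
    return ThetaEstimate(
        theta=mean, se=float(np.sqrt(max(var, 1e-300))), method="EAP",
        n_items_used=len(pairs),
    )


def eap_score_matrix(
    items: Sequence[ItemParameters] | ItemBank,
    x: np.ndarray,
    grid: QuadratureGrid | None = None,
    prior: tuple[float, float] = (0.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized EAP over a complete (n, m) response matrix.

    Returns (theta, se) arrays of length n.
    """
    if isinstance(items, ItemBank):
        items = items.items
    if grid is None:
        grid = make_grid(prior_mean=prior[0], prior_sd=prior[1])
    x = np.asarray(x, dtype=np.int64)
    probs = [_em.grm_probs(it.a, np.asarray(it.b), grid.points) for it in items]
    ll = _em._loglik_matrix(x, probs)  # (n, q)
    joint = ll + np.log(grid.weights)[None, :]
    joint -= joint.max(axis=1, keepdims=True)
    post = np.exp(joint)
    post /= post.sum(axis=1, keepdims=True)
    theta = post @ grid.points
    var = post @ (grid.points**2) - theta**2
    return theta, np.sqrt(np.maximum(var, 1e-300))


def marginal_reliability(
    items: Sequence[ItemParameters] | ItemBank,
    grid: QuadratureGrid | None = None,
    prior: tuple[float, float] = (0.0, 1.0),
) -> float:
    """Prior-averaged reliability of a scale, in [0, 1).

    Defined as ``1 - E_theta[(I(theta) + 1/sigma^2)^-1] / sigma^2`` under the
    trait prior: the expected posterior error variance (test information plus
    prior information, a Laplace approximation of the EAP posterior variance)
    relative to the prior variance.  Information-free scales give 0; very
    informative scales approach 1.
    """
    if isinstance(items, ItemBank):
        items = items.items
    if len(items) == 0:
        raise InvalidInputError("need at least one item")
    if grid is None:
        grid = make_grid(prior_mean=prior[0], prior_sd=prior[1])
    info, _ = test_information_and_sem(items, grid.points)
    prior_var = prior[1] ** 2
    post_var = 1.0 / (np.asarray(info) + 1.0 / prior_var)
    expected = float(grid.weights @ post_var)
    return float(1.0 - expected / prior_var)


def check_threshold_ordering(
    calibration_or_items, responses: ResponseMatrix | None = None,
    theta_range: tuple[float, float] = (-6.0, 6.0), n_points: int = 1201,
) -> list[dict]:
    """Empirical category-usage check behind "ordered thresholds".

    GRM structural thresholds are ordered by construction, so the meaningful
    check is on the category response curves: an item is well ordered when
    every category is the modal response over some theta interval.  Items
    whose intermediate categories are never modal are flagged.
    Returns one report dict per item.
    """
    if isinstance(calibration_or_items, CalibrationResult):
        items = calibration_or_items.bank.items
    elif isinstance(calibration_or_items, ItemBank):
        items = calibration_or_items.items
    else:
        items = tuple(calibration_or_items)
    grid = np.linspace(theta_range[0], theta_range[1], n_points)
    report = []
    for it in items:
        p = category_probabilities(it, grid)
        modal = set(np.unique(np.argmax(p, axis=1)).tolist())
        missing = sorted(set(range(it.n_categories)) - modal)
        report.append(
            {"item": it.id, "ordered": not missing, "non_modal_categories": missing}
        )
    return report


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Output of a marginal-maximum-likelihood GRM calibration."""

    bank: ItemBank
    standard_errors: dict[str, dict]
    log_likelihood: float
    ll_trace: list[float]
    n_cycles: int
    converged: bool
    category_collapse_map: dict[str, dict[int, int]] = field(default_factory=dict)


class GradedResponseModel(BaseEstimator):
    """Marginal-maximum-likelihood GRM calibration with EAP scoring.

    Fits a unidimensional graded response model to an integer response matrix
    by an EM algorithm: the E-step places each respondent's posterior over a
    fixed theta quadrature grid, the M-step maximizes each item's expected
    complete-data log-likelihood with thresholds kept ordered through a
    (log a, b_1, log-gap) reparameterization.  The marginal log-likelihood is
    non-decreasing across cycles.

    Parameters
    ----------
    n_quadrature : number of equally spaced theta nodes.
    theta_range : node range on the latent scale.
    prior_mean, prior_sd : Normal prior used for the latent distribution.
    tol : EM stops when the largest absolute parameter change falls below it.
    max_cycles : EM cycle cap; exceeding it flags ``converged_ = False``.
    se_method : "xpd" (cross-product of per-respondent scores, default),
        "observed" (finite-difference observed information), "bootstrap",
        or "none".  Non-positive-definite information falls back to bootstrap.
    n_bootstrap : resamples for bootstrap standard errors.
    min_category_count : categories observed fewer times trigger a warning.
    scale_name : label given to the fitted items' scale.

    Attributes (after ``fit``)
    --------------------------
    item_ids_, discrimination_, thresholds_, bank_, log_likelihood_,
    ll_trace_, n_cycles_, converged_, standard_errors_,
    category_collapse_map_, result_.
    """

    def __init__(
        self,
        n_quadrature: int = 61,
        theta_range: tuple[float, float] = (-6.0, 6.0),
        prior_mean: float = 0.0,
        prior_sd: float = 1.0,
        tol: float = 1e-4,
        max_cycles: int = 500,
        se_method: str = "xpd",
        n_bootstrap: int = 200,
        min_category_count: int = 5,
        scale_name: str = "scale",
        random_state: int | None = 0,
    ):
        self.n_quadrature = n_quadrature
        self.theta_range = theta_range
        self.prior_mean = prior_mean
        self.prior_sd = prior_sd
        self.tol = tol
        self.max_cycles = max_cycles
        self.se_method = se_method
        self.n_bootstrap = n_bootstrap
        self.min_category_count = min_category_count
        self.scale_name = scale_name
        self.random_state = random_state

    # -- helpers ------------------------------------------------------------

    def _coerce(self, X) -> tuple[np.ndarray, list[str]]:
        if isinstance(X, ResponseMatrix):
            return X.values(), X.item_ids
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=np.int64), [str(c) for c in X.columns]
        arr = np.asarray(X)
        if arr.ndim != 2:
            raise InvalidInputError("response matrix must be 2-dimensional")
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise InvalidInputError("responses must be integer categories")
        return arr.astype(np.int64), [f"item{i+1}" for i in range(arr.shape[1])]

    def _grid(self) -> QuadratureGrid:
        return make_grid(self.n_quadrature, self.theta_range, self.prior_mean, self.prior_sd)

    # -- estimator API -------------------------------------------------------

    def fit(self, X, y=None) -> "GradedResponseModel":
        x, ids = self._coerce(X)
        n, m = x.shape
        if m < 2:
            raise InvalidInputError("calibration needs at least 2 items")
        if np.any(x < 0):
            raise InvalidInputError("negative response category found")

        # collapse never-observed categories to a contiguous 0..K_obs-1 range
        collapse: dict[str, dict[int, int]] = {}
        n_cats = np.zeros(m, dtype=np.int64)
        xw = x.copy()
        for i in range(m):
            observed, counts = np.unique(x[:, i], return_counts=True)
            if len(observed) < 2:
                raise InvalidInputError(
                    f"item {ids[i]!r} has a degenerate observed category distribution"
                )
            small = observed[counts < self.min_category_count]
            if len(small):
                warnings.warn(
                    f"item {ids[i]!r}: categories {small.tolist()} observed fewer "
                    f"than {self.min_category_count} times",
                    stacklevel=2,
                )
            mapping = {int(c): k for k, c in enumerate(observed)}
            if any(orig != new for orig, new in mapping.items()):
                collapse[ids[i]] = mapping
                xw[:, i] = np.searchsorted(observed, x[:, i])
            n_cats[i] = len(observed)

        grid = self._grid()
        res = _em.fit_grm(
            xw, n_cats, grid.points,
            prior=(self.prior_mean, self.prior_sd),
            tol=self.tol, max_cycles=self.max_cycles,
        )

        self.item_ids_ = list(ids)
        self.n_categories_ = n_cats.copy()
        self.discrimination_ = res.a.copy()
        self.thresholds_ = [bb.copy() for bb in res.b]
        self.log_likelihood_ = res.log_likelihood
        self.ll_trace_ = list(res.ll_trace)
        self.n_cycles_ = res.n_cycles
        self.converged_ = res.converged
        self.category_collapse_map_ = collapse
        self.grid_ = grid
        self._x_fit = xw

        self.bank_ = ItemBank(
            items=tuple(
                ItemParameters(id=ids[i], a=float(res.a[i]), b=tuple(res.b[i]),
                               scale=self.scale_name)
                for i in range(m)
            ),
            name=self.scale_name,
        )
        self.standard_errors_ = self._standard_errors(xw, grid)
        self.result_ = CalibrationResult(
            bank=self.bank_,
            standard_errors=self.standard_errors_,
            log_likelihood=self.log_likelihood_,
            ll_trace=self.ll_trace_,
            n_cycles=self.n_cycles_,
            converged=self.converged_,
            category_collapse_map=collapse,
        )
        return self

    def _standard_errors(self, xw: np.ndarray, grid: QuadratureGrid) -> dict[str, dict]:
        m = len(self.item_ids_)
        if self.se_method == "none":
            return {}
        se = None
        ok = False
        if self.se_method in ("xpd", "observed"):
            fn = (_em.xpd_standard_errors if self.se_method == "xpd"
                  else _em.observed_info_standard_errors)
            se, ok = fn(xw, self.discrimination_, self.thresholds_, grid.points,
                        prior=(self.prior_mean, self.prior_sd))
        if not ok:
            se = self._bootstrap_se(xw, grid)
        out: dict[str, dict] = {}
        pos = 0
        for i in range(m):
            k = len(self.thresholds_[i]) + 1
            out[self.item_ids_[i]] = {
                "a": float(se[pos]),
                "b": [float(v) for v in se[pos + 1 : pos + k]],
            }
            pos += k
        return out

    def _bootstrap_se(self, xw: np.ndarray, grid: QuadratureGrid) -> np.ndarray:
        rng = np.random.default_rng(self.random_state)
        n = xw.shape[0]
        draws = []
        start = (self.discrimination_.copy(), [b.copy() for b in self.thresholds_])
        for _ in range(self.n_bootstrap):
            rows = rng.integers(0, n, size=n)
            res = _em.fit_grm(
                xw[rows], self.n_categories_, grid.points,
                prior=(self.prior_mean, self.prior_sd),
                start=start, tol=self.tol, max_cycles=self.max_cycles,
            )
            draws.append(np.concatenate([[res.a[i], *res.b[i]] for i in range(len(res.a))]))
        return np.std(np.asarray(draws), axis=0, ddof=1)

    def predict(self, X) -> np.ndarray:
        """EAP theta estimates for each row of ``X``."""
        return self.transform(X)[:, 0]

    def transform(self, X) -> np.ndarray:
        """Columns (theta, se): EAP estimate and posterior SD per respondent."""
        check_is_fitted(self, "bank_")
        x, ids = self._coerce(X)
        if ids != self.item_ids_ and set(ids) == set(self.item_ids_):
            order = [ids.index(i) for i in self.item_ids_]
            x = x[:, order]
        x = self._apply_collapse(x)
        theta, se = eap_score_matrix(
            self.bank_.items, x, self.grid_, (self.prior_mean, self.prior_sd)
        )
        return np.column_stack([theta, se])

    def _apply_collapse(self, x: np.ndarray) -> np.ndarray:
        if not self.category_collapse_map_:
            return x
        x = x.copy()
        for i, item_id in enumerate(self.item_ids_):
            mapping = self.category_collapse_map_.get(item_id)
            if mapping:
                lut = np.zeros(max(mapping) + 1, dtype=np.int64)
                for orig, new in mapping.items():
                    lut[orig] = new
                x[:, i] = lut[np.clip(x[:, i], 0, len(lut) - 1)]
        return x

    def score(self, X, y=None) -> float:
        """Mean marginal log-likelihood per respondent."""
        check_is_fitted(self, "bank_")
        x, _ = self._coerce(X)
        x = self._apply_collapse(x)
        probs = [
            _em.grm_probs(self.discrimination_[i], self.thresholds_[i], self.grid_.points)
            for i in range(len(self.item_ids_))
        ]
        ll = _em._loglik_matrix(x, probs) + np.log(self.grid_.weights)[None, :]
        from scipy.special import logsumexp

        return float(logsumexp(ll, axis=1).mean())


def calibrate_grm(
    responses: ResponseMatrix | pd.DataFrame | np.ndarray,
    scale: str | Sequence[str] | None = None,
    bank: ItemBank | None = None,
    **settings,
) -> CalibrationResult:
    """Calibrate one scale's GRM from responses (thin estimator wrapper).

    ``scale`` may be a scale name (resolved through ``bank``), an explicit
    sequence of item ids, or None to use every column.
    """
    if isinstance(scale, str):
        item_ids = bank.scales[scale] if bank is not None else None
        settings.setdefault("scale_name", scale)
    elif scale is not None:
        item_ids = list(scale)
    else:
        item_ids = None

    if item_ids is not None:
        if isinstance(responses, ResponseMatrix):
            responses = responses.subset(item_ids)
        elif isinstance(responses, pd.DataFrame):
            responses = responses[item_ids]
        else:
            raise InvalidInputError("item-id selection needs labelled responses")
    model = GradedResponseModel(**settings)
    model.fit(responses)
    return model.result_
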