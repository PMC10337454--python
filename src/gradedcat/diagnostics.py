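"""Scale diagnostics preceding IRT use and CAT deployment.

Classical and nonparametric checks on an ordinal scale:

* Cronbach alpha (internal consistency),
* Mokken scale analysis — polytomous Loevinger H coefficients, bootstrap
  standard errors, the automated item selection procedure (AISP), and a
  rest-score monotonicity check,
* Yen's Q3 residual correlations (local independence),
* the S-X2 item-fit statistic (observed vs. model-expected category
  frequencies conditional on the rest summed score, expected frequencies via
  the Lord-Wingersky recursion),
* a likelihood-ratio test of differential item functioning (DIF) between two
  groups, with Benjamini-Hochberg adjustment across items.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _em
from .bank import (
    InvalidInputError,
    ItemBank,
    QuadratureGrid,
    ResponseMatrix,
    make_grid,
)
from .grm import CalibrationResult, eap_score_matrix

__all__ = [
    "MokkenResult",
    "Q3Result",
    "DifResult",
    "cronbach_alpha",
    "loevinger_pair_matrix",
    "mokken_analysis",
    "automated_item_selection",
    "monotonicity_check",
    "yen_q3",
    "lord_wingersky",
    "s_x2_item_fit",
    "dif_likelihood_ratio",
]


def _as_array(responses, item_ids: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
    if isinstance(responses, ResponseMatrix):
        ids = list(item_ids) if item_ids is not None else responses.item_ids
        return responses.values(ids), ids
    if isinstance(responses, pd.DataFrame):
        df = responses[list(item_ids)] if item_ids is not None else responses
        return df.to_numpy(dtype=np.int64), [str(c) for c in df.columns]
    arr = np.asarray(responses, dtype=np.int64)
    ids = list(item_ids) if item_ids is not None else [f"item{i+1}" for i in range(arr.shape[1])]
    return arr, ids


# ---------------------------------------------------------------------------
# Cronbach alpha
# ---------------------------------------------------------------------------

def cronbach_alpha(responses, item_ids: Sequence[str] | None = None) -> float:
    """Cronbach alpha: ``k/(k-1) * (1 - sum(item variances) / total variance)``."""
    x, _ids = _as_array(responses, item_ids)
    n, k = x.shape
    if k < 2:
        raise InvalidInputError("alpha needs at least 2 items")
    if n < 3:
        raise InvalidInputError("alpha needs at least 3 respondents")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise InvalidInputError("total-score variance is zero; alpha undefined")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


# ---------------------------------------------------------------------------
# Mokken scaling
# ---------------------------------------------------------------------------

@dataclass
class MokkenResult:
    """Loevinger scalability coefficients for one scale."""

    H_pairs: pd.DataFrame
    H_items: dict[str, float]
    H_scale: float
    se_scale: float
    accuracy_labels: dict[str, str]
    n_bootstrap: int = 0


def _accuracy_label(h: float) -> str:
    if h < 0.3:
        return "inaccurate"
    if h < 0.4:
        return "low"
    if h < 0.5:
        return "moderate"
    return "good"


def _cov_and_covmax(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise covariances and their maxima given the item marginals.

    The maximum covariance attainable for fixed marginal category frequencies
    is achieved by the comonotone coupling, i.e. pairing both items' sorted
    values.  Population (1/n) normalization is used consistently.
    """
    n, m = x.shape
    means = x.mean(axis=0)
    xc = x - means
    cov = (xc.T @ xc) / n
    xs = np.sort(x, axis=0)
    covmax = (xs.T.astype(float) @ xs) / n - np.outer(means, means)
    return cov, covmax


def loevinger_pair_matrix(x: np.ndarray) -> np.ndarray:
    """Item-pair Loevinger coefficients ``H_ij = cov / cov_max`` (diag = nan)."""
    cov, covmax = _cov_and_covmax(x)
    if np.any(np.diag(covmax) <= 0):
        bad = int(np.argmin(np.diag(covmax)))
        raise InvalidInputError(f"item column {bad} has zero variance")
    h = cov / np.where(np.abs(covmax) > 1e-12, covmax, np.nan)
    np.fill_diagonal(h, np.nan)
    return h


def _aggregate_h(cov: np.ndarray, covmax: np.ndarray) -> tuple[np.ndarray, float]:
    m = cov.shape[0]
    off = ~np.eye(m, dtype=bool)
    h_items = np.array(
        [cov[i, off[i]].sum() / covmax[i, off[i]].sum() for i in range(m)]
    )
    iu = np.triu_indices(m, 1)
    h_scale = cov[iu].sum() / covmax[iu].sum()
    return h_items, float(h_scale)


def mokken_analysis(
    responses,
    item_ids: Sequence[str] | None = None,
    lower_bound: float = 0.3,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> MokkenResult:
    """Polytomous Mokken scalability analysis of one scale.

    Computes item-pair, per-item, and scale Loevinger H coefficients with a
    bootstrap standard error for the scale coefficient, and labels each item
    by the conventional cut points (<0.3 inaccurate, 0.3-0.4 low, 0.4-0.5
    moderate, >0.5 good).  Warns below 250 respondents, where the procedure
    becomes unstable.
    """
    x, ids = _as_array(responses, item_ids)
    n, m = x.shape
    if n < 50:
        raise InvalidInputError("Mokken analysis needs at least 50 respondents")
    if n < 250:
        warnings.warn("Mokken analysis below n=250 may be unstable", stacklevel=2)
    cov, covmax = _cov_and_covmax(x)
    if np.any(np.diag(covmax) <= 0):
        bad = ids[int(np.argmin(np.diag(covmax)))]
        raise InvalidInputError(f"item {bad!r} has zero variance")
    h_pairs = loevinger_pair_matrix(x)
    h_items, h_scale = _aggregate_h(cov, covmax)

    se = float("nan")
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        draws = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            rows = rng.integers(0, n, size=n)
            cb, cmb = _cov_and_covmax(x[rows])
            iu = np.triu_indices(m, 1)
            draws[b] = cb[iu].sum() / cmb[iu].sum()
        se = float(np.std(draws, ddof=1))

    return MokkenResult(
        H_pairs=pd.DataFrame(h_pairs, index=ids, columns=ids),
        H_items={ids[i]: float(h_items[i]) for i in range(m)},
        H_scale=h_scale,
        se_scale=se,
        accuracy_labels={ids[i]: _accuracy_label(h_items[i]) for i in range(m)},
        n_bootstrap=n_bootstrap,
    )


def _pair_significance(x: np.ndarray, alpha: float) -> np.ndarray:
    """One-sided test of positive association per item pair (True = significant)."""
    m = x.shape[1]
    sig = np.zeros((m, m), dtype=bool)
    for i in range(m):
        for j in range(i + 1, m):
            r, p = stats.pearsonr(x[:, i], x[:, j])
            ok = (r > 0) and (p / 2 < alpha)
            sig[i, j] = sig[j, i] = ok
    return sig


def automated_item_selection(
    responses,
    item_ids: Sequence[str] | None = None,
    lower_bound: float = 0.3,
    alpha: float = 0.05,
) -> dict:
    """Greedy AISP: partition items into Mokken scales plus an unscalable set.

    Each scale is seeded with the highest significantly-positive item-pair H
    meeting the bound; items are then added one at a time, choosing the item
    that maximizes the provisional scale H among those whose item coefficient
    against the current scale stays >= ``lower_bound`` and significantly
    positive.  The procedure repeats on the leftovers.
    """
    x, ids = _as_array(responses, item_ids)
    n, m = x.shape
    if m < 3:
        raise InvalidInputError("AISP needs at least 3 items")
    cov, covmax = _cov_and_covmax(x)
    with np.errstate(invalid="ignore", divide="ignore"):
        h = cov / covmax
    sig = _pair_significance(x, alpha)

    remaining = list(range(m))
    scales: list[list[int]] = []
    while len(remaining) >= 2:
        best_pair, best_h = None, -np.inf
        for ai in range(len(remaining)):
            for aj in range(ai + 1, len(remaining)):
                i, j = remaining[ai], remaining[aj]
                if sig[i, j] and h[i, j] >= lower_bound and h[i, j] > best_h:
                    best_pair, best_h = (i, j), h[i, j]
        if best_pair is None:
            break
        scale = list(best_pair)
        pool = [k for k in remaining if k not in scale]
        while pool:
            best_k, best_scale_h = None, -np.inf
            for k in pool:
                cand = scale + [k]
                hk = cov[k, scale].sum() / covmax[k, scale].sum()
                sig_ok = all(sig[k, s] for s in scale)
                if hk >= lower_bound and sig_ok:
                    iu = np.ix_(cand, cand)
                    cc, mm_ = cov[iu], covmax[iu]
                    tri = np.triu_indices(len(cand), 1)
                    sh = cc[tri].sum() / mm_[tri].sum()
                    if sh > best_scale_h:
                        best_k, best_scale_h = k, sh
            if best_k is None:
                break
            scale.append(best_k)
            pool.remove(best_k)
        scales.append(sorted(scale))
        remaining = [k for k in remaining if k not in scale]

    return {
        "scales": [[ids[k] for k in sc] for sc in scales],
        "unscalable": [ids[k] for k in remaining],
    }


def monotonicity_check(
    responses,
    item_ids: Sequence[str] | None = None,
    min_bin: int | None = None,
    alpha: float = 0.05,
    min_violation: float = 0.03,
) -> list[dict]:
    """Rest-score monotonicity: count significant decreases per item.

    For each item, respondents are grouped by binned rest score (scale total
    minus the item; bins merged until each holds >= ``min_bin`` respondents,
    default n/10 with a floor of 50, the convention of Mokken software).  For
    each cumulative category proportion P(X >= k), a decrease of at least
    ``min_violation`` across adjacent bins that is significant by a one-sided
    two-proportion z test counts as a violation.
    """
    x, ids = _as_array(responses, item_ids)
    n, m = x.shape
    if m < 3:
        raise InvalidInputError("monotonicity check needs at least 3 items")
    if min_bin is None:
        min_bin = max(50, n // 10)
    out = []
    total = x.sum(axis=1)
    for i in range(m):
        rest = total - x[:, i]
        order = np.argsort(rest, kind="stable")
        sorted_rest = rest[order]
        # greedy bins of >= min_bin respondents along increasing rest score,
        # never splitting ties
        bins: list[np.ndarray] = []
        start = 0
        while start < n:
            end = min(start + min_bin, n)
            while end < n and sorted_rest[end] == sorted_rest[end - 1]:
                end += 1
            bins.append(order[start:end])
            start = end
        merged = 0
        if len(bins) > 1 and len(bins[-1]) < min_bin:
            bins[-2] = np.concatenate([bins[-2], bins[-1]])
            bins.pop()
            merged = 1
        kmax = int(x[:, i].max())
        violations = 0
        n_tests = 0
        for k in range(1, kmax + 1):
            geq = (x[:, i] >= k).astype(float)
            props = np.array([geq[bidx].mean() for bidx in bins])
            sizes = np.array([len(bidx) for bidx in bins], dtype=float)
            for bnum in range(len(bins) - 1):
                p1, p2 = props[bnum], props[bnum + 1]
                n1, n2 = sizes[bnum], sizes[bnum + 1]
                n_tests += 1
                if p1 - p2 < min_violation:
                    continue
                pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
                se = np.sqrt(max(pooled * (1 - pooled), 1e-12) * (1 / n1 + 1 / n2))
                z = (p1 - p2) / se
                if stats.norm.sf(z) < alpha:
                    violations += 1
        out.append(
            {"item": ids[i], "n_violations": violations, "n_tests": n_tests,
             "n_bins": len(bins), "bins_merged": merged}
        )
    return out


def _bank_and_collapse(calibrated) -> tuple[ItemBank, dict[str, dict[int, int]]]:
    """Accept an ItemBank or a CalibrationResult (with its collapse map)."""
    if isinstance(calibrated, CalibrationResult):
        return calibrated.bank, calibrated.category_collapse_map
    return calibrated, {}


def _apply_collapse(x: np.ndarray, ids: Sequence[str],
                    collapse: dict[str, dict[int, int]]) -> np.ndarray:
    if not collapse:
        return x
    x = x.copy()
    for col, item_id in enumerate(ids):
        mapping = collapse.get(item_id)
        if mapping:
            lut = np.zeros(max(mapping) + 1, dtype=np.int64)
            for orig, new in mapping.items():
                lut[orig] = new
            x[:, col] = lut[np.clip(x[:, col], 0, len(lut) - 1)]
    return x


# ---------------------------------------------------------------------------
# Yen's Q3 local dependence
# ---------------------------------------------------------------------------

@dataclass
class Q3Result:
    """Residual item correlations after conditioning on the EAP trait."""

    residual_correlations: pd.DataFrame
    flagged_pairs: list[tuple[str, str, float]]
    threshold: float = 0.20
    theta_source: str = "EAP"
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)


def yen_q3(
    responses,
    calibrated_bank: ItemBank,
    item_ids: Sequence[str] | None = None,
    threshold: float = 0.20,
    grid: QuadratureGrid | None = None,
    prior: tuple[float, float] = (0.0, 1.0),
    two_sided: bool = False,
) -> Q3Result:
    """Yen's Q3: correlations of residuals ``x - E[X | theta_hat]``.

    ``theta_hat`` is the EAP estimate from the calibrated scale (the residuals
    are estimator-dependent, so the source is recorded in the result).  Pairs
    with Q3 above ``threshold`` are flagged: positive residual correlation is
    the signature of local dependence.  Under local independence Q3 centers
    slightly below zero (roughly -1/(m-1), a compensatory artifact of
    conditioning on an estimated trait), so negative values are not flagged
    unless ``two_sided`` is set.
    """
    calibrated_bank, collapse = _bank_and_collapse(calibrated_bank)
    ids = list(item_ids) if item_ids is not None else [it.id for it in calibrated_bank.items]
    items = [calibrated_bank[i] for i in ids]
    x, _ = _as_array(responses, ids)
    x = _apply_collapse(x, ids, collapse)
    if grid is None:
        grid = make_grid(prior_mean=prior[0], prior_sd=prior[1])
    theta, _se = eap_score_matrix(items, x, grid, prior)
    resid = np.empty_like(x, dtype=float)
    for col, it in enumerate(items):
        p = _em.grm_probs(it.a, np.asarray(it.b), theta)  # (n, K)
        expected = p @ np.arange(p.shape[1])
        resid[:, col] = x[:, col] - expected
    sd = resid.std(axis=0)
    undefined = [ids[i] for i in np.where(sd <= 1e-12)[0]]
    with np.errstate(invalid="ignore", divide="ignore"):
        q3 = np.corrcoef(resid, rowvar=False)
    np.fill_diagonal(q3, 1.0)
    flagged, undef_pairs = [], []
    m = len(ids)
    for i in range(m):
        for j in range(i + 1, m):
            if ids[i] in undefined or ids[j] in undefined or not np.isfinite(q3[i, j]):
                undef_pairs.append((ids[i], ids[j]))
            else:
                value = abs(q3[i, j]) if two_sided else q3[i, j]
                if value > threshold:
                    flagged.append((ids[i], ids[j], float(q3[i, j])))
    return Q3Result(
        residual_correlations=pd.DataFrame(q3, index=ids, columns=ids),
        flagged_pairs=flagged,
        threshold=threshold,
        undefined_pairs=undef_pairs,
    )


# ---------------------------------------------------------------------------
# S-X2 item fit
# ---------------------------------------------------------------------------

def lord_wingersky(probs: list[np.ndarray]) -> np.ndarray:
    """Summed-score distribution over quadrature nodes, shape (q, max_score+1).

    Generalized Lord-Wingersky recursion for polytomous items: convolve the
    per-node category distributions item by item.  Each row sums to 1.
    """
    q = probs[0].shape[0]
    dist = np.ones((q, 1))
    for p in probs:
        k = p.shape[1]
        new = np.zeros((q, dist.shape[1] + k - 1))
        for c in range(k):
            new[:, c : c + dist.shape[1]] += dist * p[:, c : c + 1]
        dist = new
    return dist


def s_x2_item_fit(
    responses,
    calibrated_bank: ItemBank,
    item_ids: Sequence[str] | None = None,
    grid: QuadratureGrid | None = None,
    prior: tuple[float, float] = (0.0, 1.0),
    min_expected: float = 1.0,
) -> pd.DataFrame:
    """S-X2 item fit: observed vs expected categories given the rest score.

    For each item, model-expected category frequencies conditional on the
    rest summed score are obtained from the Lord-Wingersky recursion over the
    remaining items; adjacent rest-score rows (and, within rows, adjacent
    category cells) are collapsed until every expected cell reaches
    ``min_expected``.  Returns one row per item with the Pearson statistic,
    degrees of freedom (free cells minus item-parameter count), p-value, and
    an RMSEA-style misfit magnitude ``sqrt(max(X2-df, 0) / (df * n))``.
    """
    calibrated_bank, collapse = _bank_and_collapse(calibrated_bank)
    ids = list(item_ids) if item_ids is not None else [it.id for it in calibrated_bank.items]
    items = [calibrated_bank[i] for i in ids]
    x, _ = _as_array(responses, ids)
    x = _apply_collapse(x, ids, collapse)
    n, m = x.shape
    if grid is None:
        grid = make_grid(prior_mean=prior[0], prior_sd=prior[1])
    probs = [_em.grm_probs(it.a, np.asarray(it.b), grid.points) for it in items]
    total = x.sum(axis=1)
    rows_out = []
    for i in range(m):
        k = probs[i].shape[1]
        rest_probs = [probs[j] for j in range(m) if j != i]
        srest = lord_wingersky(rest_probs)  # (q, S+1)
        joint = np.einsum("q,qk,qs->sk", grid.weights, probs[i], srest)  # (S+1, K)
        rest_obs = total - x[:, i]
        smax = srest.shape[1] - 1
        observed = np.zeros((smax + 1, k))
        for s, cat in zip(rest_obs, x[:, i]):
            observed[s, cat] += 1
        n_s = observed.sum(axis=1)
        marg = joint.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = np.where(marg[:, None] > 0, joint / np.maximum(marg[:, None], 1e-300), 0.0)
        expected = n_s[:, None] * cond

        keep = n_s > 0
        obs_rows = [observed[s] for s in range(smax + 1) if keep[s]]
        exp_rows = [expected[s] for s in range(smax + 1) if keep[s]]
        # collapse adjacent rest-score rows until min expected cell is reached
        def worst(rows_e):
            return min((r.min(), idx) for idx, r in enumerate(rows_e))
        while len(exp_rows) > 1:
            wmin, widx = worst(exp_rows)
            if wmin >= min_expected:
                break
            nb = widx - 1 if widx == len(exp_rows) - 1 else widx + 1
            if widx > 0 and widx < len(exp_rows) - 1:
                nb = widx - 1 if exp_rows[widx - 1].sum() < exp_rows[widx + 1].sum() else widx + 1
            lo, hi = min(widx, nb), max(widx, nb)
            exp_rows[lo] = exp_rows[lo] + exp_rows[hi]
            obs_rows[lo] = obs_rows[lo] + obs_rows[hi]
            del exp_rows[hi], obs_rows[hi]
        # within-row category collapsing
        x2 = 0.0
        free_cells = 0
        testable = True
        for o_row, e_row in zip(obs_rows, exp_rows):
            o_c, e_c = list(o_row), list(e_row)
            while len(e_c) > 1 and min(e_c) < min_expected:
                j = int(np.argmin(e_c))
                nb = j - 1 if j == len(e_c) - 1 else j + 1
                lo, hi = min(j, nb), max(j, nb)
                e_c[lo] += e_c[hi]
                o_c[lo] += o_c[hi]
                del e_c[hi], o_c[hi]
            if len(e_c) < 2:
                continue
            free_cells += len(e_c) - 1
            x2 += sum((o - e) ** 2 / e for o, e in zip(o_c, e_c))
        n_params = 1 + (k - 1)
        df = free_cells - n_params
        if df <= 0 or not testable:
            rows_out.append(
                {"item": ids[i], "statistic": np.nan, "df": int(max(df, 0)),
                 "p": np.nan, "rmsea": np.nan, "testable": False}
            )
            continue
        p_val = float(stats.chi2.sf(x2, df))
        rmsea = float(np.sqrt(max(x2 - df, 0.0) / (df * n)))
        rows_out.append(
            {"item": ids[i], "statistic": float(x2), "df": int(df), "p": p_val,
             "rmsea": rmsea, "testable": True}
        )
    return pd.DataFrame(rows_out)


# ---------------------------------------------------------------------------
# likelihood-ratio DIF
# ---------------------------------------------------------------------------

@dataclass
class DifResult:
    """Per-item likelihood-ratio DIF tests between two groups."""

    table: pd.DataFrame
    flagged: list[str]
    skipped: list[str]
    baseline_log_likelihood: float
    focal_mean: float
    focal_sd: float
    groups: tuple = ()


def dif_likelihood_ratio(
    responses,
    groups: np.ndarray | None = None,
    item_ids: Sequence[str] | None = None,
    alpha: float = 0.05,
    grid: QuadratureGrid | None = None,
    prior: tuple[float, float] = (0.0, 1.0),
    tol: float = 3e-4,
    max_cycles: int = 500,
) -> DifResult:
    """Likelihood-ratio DIF with all-other-items anchors, one item at a time.

    The baseline multigroup GRM constrains every item equal across the two
    groups while freeing the focal group's latent mean and SD (the reference
    group anchors the metric at the prior).  For each candidate item, a model
    freeing that item's parameters is fit from the baseline solution; twice
    the log-likelihood gain is referred to chi-square with one degree of
    freedom per freed parameter.  P-values are Benjamini-Hochberg adjusted
    across items; adjusted p < ``alpha`` flags the item.

    Items for which one group never uses an observed category are skipped
    with a warning (their freed fit would be degenerate).  The default EM
    tolerance is looser than for calibration because the statistic is a
    log-likelihood difference, which converges well before the parameters do.
    """
    if isinstance(responses, ResponseMatrix) and groups is None:
        groups = responses.group
    if groups is None:
        raise InvalidInputError("DIF needs group labels")
    x, ids = _as_array(responses, item_ids)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    if len(labels) != 2:
        raise InvalidInputError(f"DIF needs exactly 2 groups, got {labels}")
    codes = (groups == labels[1]).astype(np.int64)
    n, m = x.shape
    if min((codes == 0).sum(), (codes == 1).sum()) < 100:
        warnings.warn("fewer than 100 respondents in a group; DIF may be unstable",
                      stacklevel=2)

    # contiguous categories pooled; skip items with group-missing categories
    n_cats = np.zeros(m, dtype=np.int64)
    xw = x.copy()
    skipped: list[str] = []
    for i in range(m):
        observed = np.unique(x[:, i])
        xw[:, i] = np.searchsorted(observed, x[:, i])
        n_cats[i] = len(observed)
        for g in (0, 1):
            if len(np.unique(xw[codes == g, i])) < n_cats[i]:
                skipped.append(ids[i])
                warnings.warn(
                    f"item {ids[i]!r} skipped: group {labels[g]!r} is missing "
                    "response categories", stacklevel=2,
                )
                break

    if grid is None:
        grid = make_grid(prior_mean=prior[0], prior_sd=prior[1])
    nodes = grid.points
    base = _em.fit_grm(
        xw, n_cats, nodes, prior=prior, groups=codes, tol=tol, max_cycles=max_cycles
    )
    start = (
        np.array([base.item_params(i)[0] for i in range(m)]),
        [base.item_params(i)[1] for i in range(m)],
    )

    rows = []
    pvals = []
    tested = []
    for i in range(m):
        if ids[i] in skipped:
            continue
        free = _em.fit_grm(
            xw, n_cats, nodes, prior=prior, groups=codes, free_items={i},
            start=start, focal_start=(base.focal_mean, base.focal_sd),
            tol=tol, max_cycles=max_cycles,
        )
        lr = max(2.0 * (free.log_likelihood - base.log_likelihood), 0.0)
        df = int(n_cats[i])  # one discrimination + K-1 thresholds
        p = float(stats.chi2.sf(lr, df))
        rows.append({"item": ids[i], "lr": lr, "df": df, "p": p})
        pvals.append(p)
        tested.append(ids[i])

    if pvals:
        from statsmodels.stats.multitest import multipletests

        _rej, p_adj, _a, _b = multipletests(pvals, alpha=alpha, method="fdr_bh")
    else:
        p_adj = np.array([])
    for row, pa in zip(rows, p_adj):
        row["p_adj"] = float(pa)
    flagged = [row["item"] for row in rows if row["p_adj"] < alpha]
    return DifResult(
        table=pd.DataFrame(rows),
        flagged=flagged,
        skipped=skipped,
        baseline_log_likelihood=base.log_likelihood,
        focal_mean=base.focal_mean,
        focal_sd=base.focal_sd,
        groups=tuple(labels),
    )
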