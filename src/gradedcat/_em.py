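"""Marginal-maximum-likelihood fitting of the graded response model by EM.

Internal module.  Supports a single-group fit and a two-group fit with
per-item parameters either shared across groups or freed (the building block
of the likelihood-ratio DIF test).  The E-step places a posterior over a
fixed theta quadrature grid; the M-step maximizes each item's expected
complete-data log-likelihood by a damped Newton iteration on the
reparameterization (log a, b_1, log gaps), which keeps thresholds ordered by
construction.  Steps are only accepted when they improve the objective, so
the marginal log-likelihood is non-decreasing across cycles (a generalized
EM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

_PMIN = 1e-12
_GAP_FLOOR = 1e-4


def grm_probs(a: float, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Category probabilities of one graded item; returns (len(theta), K)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    b = np.asarray(b, dtype=float)
    pstar = expit(a * (theta[:, None] - b[None, :]))
    n = theta.shape[0]
    upper = np.concatenate([np.ones((n, 1)), pstar], axis=1)
    lower = np.concatenate([pstar, np.zeros((n, 1))], axis=1)
    return np.clip(upper - lower, 0.0, 1.0)


def prob_tensor(a: np.ndarray, b_list: list[np.ndarray], nodes: np.ndarray) -> np.ndarray:
    """Stacked category probabilities, shape (n_items, n_nodes, K_max).

    Items with fewer categories are zero-padded on the right.
    """
    kmax = max(len(b) + 1 for b in b_list)
    out = np.zeros((len(b_list), len(nodes), kmax))
    for i, (ai, bi) in enumerate(zip(a, b_list)):
        p = grm_probs(ai, bi, nodes)
        out[i, :, : p.shape[1]] = p
    return out


# ---------------------------------------------------------------------------
# reparameterization: t = (log a, b_1, log(gap_2), ..., log(gap_{K-1}))
# ---------------------------------------------------------------------------

def nat_to_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batched (B,) a and (B, K-1) b -> (B, K) unconstrained params."""
    gaps = np.diff(b, axis=1)
    gaps = np.maximum(gaps, _GAP_FLOOR + 1e-8)
    return np.concatenate(
        [np.log(a)[:, None], b[:, :1], np.log(gaps - _GAP_FLOOR + 1e-12)], axis=1
    )


def t_to_nat(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.exp(t[:, 0])
    gaps = _GAP_FLOOR + np.exp(t[:, 2:])
    b = t[:, 1:2] + np.concatenate(
        [np.zeros_like(t[:, :1]), np.cumsum(gaps, axis=1)], axis=1
    )
    return a, b


def _batch_probs(a: np.ndarray, b: np.ndarray, nodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(B,) a, (B, K-1) b -> (pstar (B, q, K-1), probs (B, q, K))."""
    z = a[:, None, None] * (nodes[None, :, None] - b[:, None, :])
    pstar = expit(z)
    bsz, q, km1 = pstar.shape
    upper = np.concatenate([np.ones((bsz, q, 1)), pstar], axis=2)
    lower = np.concatenate([pstar, np.zeros((bsz, q, 1))], axis=2)
    return pstar, np.clip(upper - lower, 0.0, 1.0)


def _objective(t: np.ndarray, r: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Negative expected complete-data log-likelihood per block, shape (B,)."""
    a, b = t_to_nat(t)
    _, p = _batch_probs(a, b, nodes)
    return -(r * np.log(np.maximum(p, _PMIN))).sum(axis=(1, 2))


def _gradient(t: np.ndarray, r: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Analytic gradient of `_objective` w.r.t. t, shape (B, K)."""
    a, b = t_to_nat(t)
    pstar, p = _batch_probs(a, b, nodes)  # (B,q,K-1), (B,q,K)
    c = r / np.maximum(p, _PMIN)  # (B, q, K)
    # coefficient on dP*_j: appears +1 in P_j, -1 in P_{j-1}
    d = c[:, :, 1:] - c[:, :, :-1]  # (B, q, K-1), index j-1 <-> threshold j
    w = pstar * (1.0 - pstar)  # (B, q, K-1)
    theta_minus_b = nodes[None, :, None] - b[:, None, :]
    df_da = -(d * w * theta_minus_b).sum(axis=1).sum(axis=1)  # (B,)
    df_db = a[:, None] * (d * w).sum(axis=1)  # (B, K-1)
    # chain rule to t
    g = np.empty_like(t)
    g[:, 0] = a * df_da
    g[:, 1] = df_db.sum(axis=1)
    if t.shape[1] > 2:
        # reverse cumulative sums over thresholds j >= l
        rev = np.cumsum(df_db[:, ::-1], axis=1)[:, ::-1]
        g[:, 2:] = np.exp(t[:, 2:]) * rev[:, 1:]
    return g


def _mstep(t: np.ndarray, r: np.ndarray, nodes: np.ndarray, n_iter: int = 1) -> np.ndarray:
    """Damped-Newton ascent on the expected complete-data log-likelihood.

    Accepts a step only when it improves the objective, so the outer EM stays
    monotone even when the Newton direction is poor.
    """
    h = 1e-5
    t = t.copy()
    bsz, p = t.shape
    f = _objective(t, r, nodes)
    for _ in range(n_iter):
        g = _gradient(t, r, nodes)
        hess = np.empty((bsz, p, p))
        for d in range(p):
            td = t.copy()
            td[:, d] += h
            hess[:, :, d] = (_gradient(td, r, nodes) - g) / h
        hess = 0.5 * (hess + np.transpose(hess, (0, 2, 1)))
        # ridge for non-PD blocks
        step = np.zeros_like(t)
        for i in range(bsz):
            hi = hess[i]
            lam = 0.0
            for _try in range(4):
                try:
                    step[i] = np.linalg.solve(hi + lam * np.eye(p), -g[i])
                    if np.all(np.isfinite(step[i])):
                        break
                except np.linalg.LinAlgError:
                    pass
                lam = max(lam * 10.0, 1e-2 * (1.0 + np.abs(np.diag(hi)).max()))
            else:
                step[i] = -g[i]
        # backtracking, per block
        improved = np.zeros(bsz, dtype=bool)
        alpha = 1.0
        t_new = t.copy()
        f_new = f.copy()
        for _bt in range(6):
            cand = t.copy()
            cand[~improved] = t[~improved] + alpha * step[~improved]
            cand[:, 0] = np.clip(cand[:, 0], -6.0, 6.0)   # a in [e^-6, e^6]
            cand[:, 1] = np.clip(cand[:, 1], -20.0, 20.0)
            if p > 2:
                cand[:, 2:] = np.clip(cand[:, 2:], -20.0, 6.0)
            fc = _objective(cand, r, nodes)
            better = (~improved) & (fc < f_new - 1e-12)
            t_new[better] = cand[better]
            f_new[better] = fc[better]
            improved |= better
            if improved.all():
                break
            alpha *= 0.5
        # fall back to a small gradient step for blocks Newton failed on
        if not improved.all():
            idx = ~improved
            gn = np.maximum(np.linalg.norm(g[idx], axis=1, keepdims=True), 1e-12)
            for alpha in (0.1, 0.01, 0.001):
                cand = t[idx] - alpha * g[idx] / gn
                fc = _objective(cand, r[idx], nodes)
                upd = fc < f_new[idx] - 1e-12
                sub = np.where(idx)[0][upd]
                t_new[sub] = cand[upd]
                f_new[sub] = fc[upd]
                idx2 = idx.copy()
                idx2[sub] = False
                idx = idx2
                if not idx.any():
                    break
        t, f = t_new, f_new
        if np.max(np.abs(g)) < 1e-8:
            break
    return t


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------

@dataclass
class EMResult:
    a: np.ndarray                      # per item (shared) or per (item, group)
    b: list[np.ndarray]
    blocks: list[tuple[int, int | None]]  # (item index, group or None)
    log_likelihood: float
    ll_trace: list[float] = field(default_factory=list)
    n_cycles: int = 0
    converged: bool = False
    focal_mean: float = 0.0
    focal_sd: float = 1.0

    def item_params(self, item: int, group: int | None = None) -> tuple[float, np.ndarray]:
        for j, (i, g) in enumerate(self.blocks):
            if i == item and (g is None or group is None or g == group):
                return float(self.a[j]), self.b[j]
        raise KeyError((item, group))


def _start_values(x: np.ndarray, n_cats: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Heuristic starts: a = 1.2, thresholds from empirical cumulative rates."""
    m = x.shape[1]
    a0 = np.full(m, 1.2)
    b0 = []
    for i in range(m):
        k = int(n_cats[i])
        p = np.array([(x[:, i] >= c).mean() for c in range(1, k)])
        p = np.clip(p, 0.02, 0.98)
        b = -np.log(p / (1.0 - p))
        # enforce strict increase
        for j in range(1, len(b)):
            b[j] = max(b[j], b[j - 1] + 0.1)
        b0.append(b)
    return a0, b0


def _normal_logweights(nodes: np.ndarray, mean: float, sd: float) -> np.ndarray:
    z = (nodes - mean) / sd
    lw = -0.5 * z * z
    return lw - logsumexp(lw)


def _loglik_matrix(x: np.ndarray, probs: list[np.ndarray]) -> np.ndarray:
    """Sum over items of log P_i(x_i | theta_q); returns (n, q)."""
    n = x.shape[0]
    q = probs[0].shape[0]
    ll = np.zeros((n, q))
    for i, p in enumerate(probs):
        lp = np.log(np.maximum(p, _PMIN))  # (q, K_i)
        ll += lp[:, x[:, i]].T
    return ll


def fit_grm(
    x: np.ndarray,
    n_cats: np.ndarray,
    nodes: np.ndarray,
    prior: tuple[float, float] = (0.0, 1.0),
    groups: np.ndarray | None = None,
    free_items: frozenset[int] | set[int] = frozenset(),
    estimate_focal_moments: bool = True,
    start: tuple[np.ndarray, list[np.ndarray]] | None = None,
    focal_start: tuple[float, float] | None = None,
    tol: float = 1e-4,
    max_cycles: int = 500,
) -> EMResult:
    """EM fit of the GRM; two-group support with optionally freed items.

    `x` is (n, m) integer categories with per-item counts `n_cats` (values
    must already be contiguous 0..K_i-1).  With `groups` given (codes 0 =
    reference, 1 = focal), items in `free_items` get separate parameters per
    group; the focal group's latent mean/SD are estimated (reference fixed to
    the prior) for identification.
    """
    x = np.asarray(x, dtype=np.int64)
    n, m = x.shape
    nodes = np.asarray(nodes, dtype=float)
    q = len(nodes)

    if groups is None:
        group_codes = np.zeros(n, dtype=np.int64)
        n_groups = 1
        free_items = frozenset()
    else:
        group_codes = np.asarray(groups, dtype=np.int64)
        n_groups = 2

    blocks: list[tuple[int, int | None]] = []
    for i in range(m):
        if i in free_items:
            blocks.extend([(i, 0), (i, 1)])
        else:
            blocks.append((i, None))

    if start is None:
        a0, b0 = _start_values(x, n_cats)
    else:
        a0, b0 = start
    a = np.array([a0[i] for i, _g in blocks], dtype=float)
    b = [np.asarray(b0[i], dtype=float).copy() for i, _g in blocks]

    focal_mean, focal_sd = focal_start if focal_start is not None else prior
    ref_logw = _normal_logweights(nodes, prior[0], prior[1])

    group_rows = [np.where(group_codes == g)[0] for g in range(n_groups)]

    def block_params_for_group(g: int) -> tuple[np.ndarray, list[np.ndarray]]:
        ag = np.empty(m)
        bg: list[np.ndarray] = [None] * m  # type: ignore[list-item]
        for j, (i, bg_grp) in enumerate(blocks):
            if bg_grp is None or bg_grp == g:
                ag[i] = a[j]
                bg[i] = b[j]
        return ag, bg

    def marginal_ll_and_posteriors() -> tuple[float, list[np.ndarray], list[np.ndarray]]:
        total = 0.0
        posts, lls = [], []
        for g in range(n_groups):
            rows = group_rows[g]
            if len(rows) == 0:
                posts.append(np.zeros((0, q)))
                lls.append(np.zeros(0))
                continue
            ag, bg = block_params_for_group(g)
            probs = [grm_probs(ag[i], bg[i], nodes) for i in range(m)]
            ll = _loglik_matrix(x[rows], probs)  # (n_g, q)
            logw = ref_logw if g == 0 else _normal_logweights(nodes, focal_mean, focal_sd)
            joint = ll + logw[None, :]
            marg = logsumexp(joint, axis=1)
            posts.append(np.exp(joint - marg[:, None]))
            lls.append(marg)
            total += marg.sum()
        return total, posts, lls

    ll_trace: list[float] = []
    converged = False
    cycle = 0
    ll, posts, _ = marginal_ll_and_posteriors()
    for cycle in range(1, max_cycles + 1):
        ll_trace.append(ll)
        # expected counts per block
        r_blocks = []
        for j, (i, g) in enumerate(blocks):
            k = int(n_cats[i])
            r = np.zeros((q, k))
            use_groups = range(n_groups) if g is None else [g]
            for gg in use_groups:
                rows = group_rows[gg]
                if len(rows) == 0:
                    continue
                xg = x[rows, i]
                w = posts[gg]
                for c in range(k):
                    mask = xg == c
                    if mask.any():
                        r[:, c] += w[mask].sum(axis=0)
            r_blocks.append(r)

        a_old = a.copy()
        b_old = [bb.copy() for bb in b]

        # M-step, batched by category count
        kvals = sorted({r.shape[1] for r in r_blocks})
        for kv in kvals:
            idx = [j for j, r in enumerate(r_blocks) if r.shape[1] == kv]
            tj = nat_to_t(a[idx], np.stack([b[j] for j in idx]))
            rj = np.stack([r_blocks[j] for j in idx])
            tj = _mstep(tj, rj, nodes)
            aj, bj = t_to_nat(tj)
            for pos, j in enumerate(idx):
                a[j] = aj[pos]
                b[j] = bj[pos]

        # focal latent moments (reference fixed for identification)
        if n_groups == 2 and estimate_focal_moments and len(group_rows[1]) > 0:
            w1 = posts[1]
            mu = float((w1 @ nodes).mean())
            var = float((w1 @ (nodes**2)).mean() - mu * mu)
            old_moments = (focal_mean, focal_sd)
            focal_mean, focal_sd = mu, float(np.sqrt(max(var, 1e-4)))
            ll_new, posts_new, _ = marginal_ll_and_posteriors()
            if ll_new < ll - 1e-9:
                focal_mean, focal_sd = old_moments
                ll_new, posts_new, _ = marginal_ll_and_posteriors()
        else:
            ll_new, posts_new, _ = marginal_ll_and_posteriors()

        if ll_new < ll - 1e-7:  # guard: GEM should never decrease
            a, b = a_old, b_old
            ll_new, posts_new, _ = marginal_ll_and_posteriors()
            ll, posts = ll_new, posts_new
            converged = True
            break
        delta = max(
            float(np.max(np.abs(a - a_old))),
            max(float(np.max(np.abs(bb - bo))) for bb, bo in zip(b, b_old)),
        )
        ll, posts = ll_new, posts_new
        if delta < tol:
            converged = True
            break
    ll_trace.append(ll)

    return EMResult(
        a=a,
        b=b,
        blocks=blocks,
        log_likelihood=float(ll),
        ll_trace=ll_trace,
        n_cycles=cycle,
        converged=converged,
        focal_mean=float(focal_mean),
        focal_sd=float(focal_sd),
    )


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------

def score_vectors(
    x: np.ndarray,
    a: np.ndarray,
    b: list[np.ndarray],
    nodes: np.ndarray,
    prior: tuple[float, float] = (0.0, 1.0),
) -> np.ndarray:
    """Per-respondent score of the marginal log-likelihood, (n, n_params).

    Parameters are ordered item-by-item as (a_i, b_i1, ..., b_i,K-1).  Used
    for cross-product ("XPD") standard errors.
    """
    x = np.asarray(x, dtype=np.int64)
    n, m = x.shape
    q = len(nodes)
    logw = _normal_logweights(nodes, *prior)
    probs = [grm_probs(a[i], b[i], nodes) for i in range(m)]
    ll = _loglik_matrix(x, probs)
    joint = ll + logw[None, :]
    post = np.exp(joint - logsumexp(joint, axis=1)[:, None])  # (n, q)

    cols = []
    for i in range(m):
        k = probs[i].shape[1]
        bi = b[i]
        pstar = expit(a[i] * (nodes[:, None] - bi[None, :]))  # (q, k-1)
        w = pstar * (1 - pstar)
        wfull = np.concatenate([np.zeros((q, 1)), w, np.zeros((q, 1))], axis=1)
        tmb = np.concatenate(
            [np.zeros((q, 1)), nodes[:, None] - bi[None, :], np.zeros((q, 1))], axis=1
        )
        p = np.maximum(probs[i], _PMIN)
        # d log P_k / d a and / d b_j, laid out (q, k, 1 + (k-1))
        grad = np.zeros((q, k, k))
        grad[:, :, 0] = (wfull[:, :-1] * tmb[:, :-1] - wfull[:, 1:] * tmb[:, 1:]) / p
        for j in range(1, k):
            dj = np.zeros((q, k))
            dj[:, j - 1] += a[i] * wfull[:, j]    # P_{j-1} gains +P*_j
            dj[:, j] -= a[i] * wfull[:, j]        # P_j loses P*_j ... sign: dP_j/db_j = -a w_j
            grad[:, :, j] = dj / p
        sel = grad[:, x[:, i], :]  # (q, n, k)
        cols.append(np.einsum("nq,qnp->np", post, sel))
    return np.concatenate(cols, axis=1)


def xpd_standard_errors(
    x: np.ndarray,
    a: np.ndarray,
    b: list[np.ndarray],
    nodes: np.ndarray,
    prior: tuple[float, float] = (0.0, 1.0),
) -> tuple[np.ndarray, bool]:
    """Cross-product SEs; returns (se vector, ok flag)."""
    s = score_vectors(x, a, b, nodes, prior)
    fisher = s.T @ s
    try:
        cov = np.linalg.inv(fisher)
        diag = np.diag(cov)
        if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
            return np.full(fisher.shape[0], np.nan), False
        return np.sqrt(diag), True
    except np.linalg.LinAlgError:
        return np.full(fisher.shape[0], np.nan), False


def observed_info_standard_errors(
    x: np.ndarray,
    a: np.ndarray,
    b: list[np.ndarray],
    nodes: np.ndarray,
    prior: tuple[float, float] = (0.0, 1.0),
    h: float = 1e-4,
) -> tuple[np.ndarray, bool]:
    """Finite-difference observed-information SEs of the marginal likelihood."""
    logw = _normal_logweights(nodes, *prior)

    def pack() -> np.ndarray:
        return np.concatenate([[a[i], *b[i]] for i in range(len(a))])

    def unpack(v: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        av, bv, pos = [], [], 0
        for i in range(len(a)):
            k = len(b[i]) + 1
            av.append(v[pos])
            bv.append(v[pos + 1 : pos + k])
            pos += k
        return np.array(av), bv

    def nll(v: np.ndarray) -> float:
        av, bv = unpack(v)
        probs = [grm_probs(av[i], bv[i], nodes) for i in range(len(av))]
        ll = _loglik_matrix(x, probs) + logw[None, :]
        return -float(logsumexp(ll, axis=1).sum())

    v0 = pack()
    p = len(v0)
    hess = np.zeros((p, p))
    f0 = nll(v0)
    fp = np.zeros(p)
    fm = np.zeros(p)
    for i in range(p):
        vp, vm = v0.copy(), v0.copy()
        vp[i] += h
        vm[i] -= h
        fp[i], fm[i] = nll(vp), nll(vm)
        hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(p):
        for j in range(i + 1, p):
            vpp = v0.copy()
            vpp[[i, j]] += h
            fpp = nll(vpp)
            hess[i, j] = hess[j, i] = (fpp - fp[i] - fp[j] + f0) / h**2
    try:
        eigs = np.linalg.eigvalsh(hess)
        if eigs.min() <= 0:
            return np.full(p, np.nan), False
        cov = np.linalg.inv(hess)
        return np.sqrt(np.diag(cov)), True
    except np.linalg.LinAlgError:
        return np.full(p, np.nan), False
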