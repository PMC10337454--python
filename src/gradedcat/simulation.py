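"""Batch CAT simulation and its evaluation metrics.

Runs the adaptive test over a grid of reliability-targeted SEM stop rules
(default {1.0, 0.9, 0.8, 0.7, 0.6, 0.5}, translated through
``sem = sqrt(1 - reliability)``) in one of two modes:

* simulated mode — responses are drawn from the bank at known generating
  thetas, and the "true theta" is the generating value;
* recorded-response mode (validation-style) — an observed response matrix is
  re-administered adaptively, and the reference theta is the full-bank EAP
  score, so that a SEM stop rule of 0 (all items administered) reproduces the
  reference exactly and r = 1 identically.

Reported per scale x stop level: average items administered, Pearson
correlation of the CAT theta with the reference, bias (mean estimate minus
reference), and n.  A theta-stratified breakdown uses width-0.6 bins from
-3.0 to 3.0 plus open tails.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .bank import InvalidInputError, ItemBank, ResponseMatrix
from .cat import CatConfig, run_cat_batch
from .datagen import TrueTheta, simulate_responses
from .grm import eap_score_matrix, reliability_sem_conversion

__all__ = [
    "DEFAULT_RELIABILITY_GRID",
    "THETA_BIN_EDGES",
    "run_simulation_grid",
    "theta_group_breakdown",
    "percent_reduction",
    "bias",
]

DEFAULT_RELIABILITY_GRID: tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5)

# width-0.6 strata from -3.0 to 3.0 plus open tails
THETA_BIN_EDGES: np.ndarray = np.round(np.arange(-3.0, 3.0 + 1e-9, 0.6), 10)


def bias(theta_hat: np.ndarray, reference: np.ndarray) -> float:
    """Mean (estimate - reference); positive values mean overestimation."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if theta_hat.shape != reference.shape:
        raise InvalidInputError("estimates and references must align")
    return float(np.mean(theta_hat - reference))


def percent_reduction(avg_items: float, bank_size: int) -> float:
    """Percent of items saved relative to linear administration."""
    if not (0 < avg_items <= bank_size):
        raise InvalidInputError(
            f"avg_items must lie in (0, {bank_size}], got {avg_items}"
        )
    return float(100.0 * (bank_size - avg_items) / bank_size)


def _mode_and_inputs(
    bank: ItemBank,
    thetas_or_responses,
    seed: int,
) -> tuple[str, ResponseMatrix, np.ndarray | None]:
    """Resolve simulated vs recorded-response mode."""
    if isinstance(thetas_or_responses, ResponseMatrix):
        return "recorded", thetas_or_responses, None
    if isinstance(thetas_or_responses, TrueTheta):
        values = thetas_or_responses.values
    else:
        values = np.asarray(thetas_or_responses, dtype=float)
    if values.size == 0:
        raise InvalidInputError("no respondents supplied")
    matrix = simulate_responses(bank, values, seed)
    return "simulated", matrix, values


def run_simulation_grid(
    bank: ItemBank,
    thetas_or_responses,
    reliability_levels: Sequence[float] = DEFAULT_RELIABILITY_GRID,
    config: CatConfig | None = None,
    seed: int = 0,
    scales: Sequence[str] | None = None,
    return_records: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """CAT metrics per (scale x reliability stop level).

    ``thetas_or_responses`` is either known generating thetas (simulated mode;
    one response matrix is drawn once and reused across stop levels, so the
    levels are compared on paired data) or a recorded :class:`ResponseMatrix`
    (validation-style mode; the reference theta is the full-bank EAP).

    Returns a tidy frame with columns scale, reliability, stop_sem, avg_items,
    r, bias, n (plus per-respondent records keyed by (scale, reliability)
    when ``return_records``).
    """
    levels = [float(r) for r in reliability_levels]
    if not levels or any(not (0 < r <= 1) for r in levels):
        raise InvalidInputError("reliability levels must lie in (0, 1]")
    base = config if config is not None else CatConfig()
    mode, matrix, true_theta = _mode_and_inputs(bank, thetas_or_responses, seed)

    scale_names = list(scales) if scales is not None else list(bank.scales)
    rows = []
    records: dict[tuple[str, float], dict] = {}
    for scale in scale_names:
        sub = bank.subset(scale)
        ids = sub.item_ids
        x = matrix.values(ids)
        if mode == "simulated":
            reference = true_theta
        else:
            reference, _ = eap_score_matrix(
                sub.items, x,
                base.grid(), base.prior,
            )
        for rel in levels:
            stop_sem = reliability_sem_conversion(rel)
            cfg = replace(base, stop_sem=float(stop_sem))
            out = run_cat_batch(sub.items, x, cfg)
            r = float(np.corrcoef(reference, out["theta"])[0, 1])
            rows.append(
                {
                    "scale": scale,
                    "reliability": rel,
                    "stop_sem": float(stop_sem),
                    "avg_items": float(out["n_items"].mean()),
                    "r": r,
                    "bias": bias(out["theta"], reference),
                    "n": len(reference),
                    "mode": mode,
                }
            )
            if return_records:
                records[(scale, rel)] = {**out, "reference": reference}
    frame = pd.DataFrame(rows)
    if return_records:
        return frame, records
    return frame


def theta_group_breakdown(
    n_items: np.ndarray, thetas: np.ndarray
) -> pd.DataFrame:
    """Average items administered per theta stratum.

    Strata: below -3.0, ten width-0.6 bins from -3.0 to 3.0, and above 3.0.  Empty strata are kept with ``applicable = False`` (printed as
    not-applicable).  Bin counts sum to the total n by construction.
    """
    n_items = np.asarray(n_items, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    if n_items.shape != thetas.shape:
        raise InvalidInputError("records and thetas must align")
    edges = np.concatenate([[-np.inf], THETA_BIN_EDGES, [np.inf]])
    labels = (
        ["Below -3.0"]
        + [f"{lo:g} to {hi:g}" for lo, hi in zip(THETA_BIN_EDGES[:-1], THETA_BIN_EDGES[1:])]
        + ["Above 3.0"]
    )
    idx = np.digitize(thetas, edges[1:-1], right=False)
    rows = []
    for b, label in enumerate(labels):
        mask = idx == b
        count = int(mask.sum())
        rows.append(
            {
                "bin": label,
                "lower": float(edges[b]),
                "upper": float(edges[b + 1]),
                "n": count,
                "avg_items": float(n_items[mask].mean()) if count else np.nan,
                "applicable": count > 0,
            }
        )
    return pd.DataFrame(rows)
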