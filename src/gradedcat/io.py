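"""File formats: item-bank / calibration JSON and response-matrix CSV.

Bank JSON schema::

    {"name": ..., "n_categories": ...,
     "scales": [{"name": ..., "items": [{"id": ..., "a": ..., "b": [...]}]}]}

Calibration JSON mirrors the bank schema plus per-item ``se`` blocks and the
fit metadata (``log_likelihood``, ``n_cycles``, ``converged``,
``category_collapse_map``).  Response CSV has one column per item id plus
optional ``group`` and ``true_theta`` columns, one row per respondent.
All round-trips are lossless.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bank import ItemBank, ItemParameters, ResponseMatrix, SchemaError
from .grm import CalibrationResult

__all__ = [
    "read_item_bank",
    "write_item_bank",
    "read_responses",
    "write_responses",
    "read_calibration",
    "write_calibration",
    "write_cat_records",
]

_META_COLUMNS = ("group", "true_theta")


def _bank_payload(bank: ItemBank) -> dict:
    scales = []
    for scale, ids in bank.scales.items():
        scales.append(
            {
                "name": scale,
                "items": [
                    {"id": it.id, "a": it.a, "b": list(it.b)}
                    for it in bank.items
                    if it.id in ids
                ],
            }
        )
    return {"name": bank.name, "n_categories": bank.n_categories, "scales": scales}


def write_item_bank(path: str | Path, bank: ItemBank) -> None:
    Path(path).write_text(json.dumps(_bank_payload(bank), indent=2) + "\n")


def _items_from_payload(payload: dict) -> list[ItemParameters]:
    items: list[ItemParameters] = []
    for scale_block in payload.get("scales", []):
        if "name" not in scale_block or "items" not in scale_block:
            raise SchemaError("each scale needs 'name' and 'items'")
        for entry in scale_block["items"]:
            for key in ("id", "a", "b"):
                if key not in entry:
                    raise SchemaError(
                        f"item entry {entry.get('id', '?')!r} missing field {key!r}"
                    )
            items.append(
                ItemParameters(
                    id=str(entry["id"]),
                    a=float(entry["a"]),
                    b=tuple(float(v) for v in entry["b"]),
                    scale=str(scale_block["name"]),
                )
            )
    return items


def read_item_bank(path: str | Path) -> ItemBank:
    payload = json.loads(Path(path).read_text())
    if "scales" not in payload:
        raise SchemaError("bank JSON missing 'scales'")
    items = _items_from_payload(payload)
    if not items:
        raise SchemaError("bank contains no items")
    return ItemBank(
        items=tuple(items),
        name=str(payload.get("name", "bank")),
        n_categories=int(payload.get("n_categories", 0)),
    )


def write_responses(path: str | Path, matrix: ResponseMatrix) -> None:
    df = matrix.data.copy()
    if matrix.group is not None:
        df["group"] = matrix.group
    if matrix.true_theta is not None:
        df["true_theta"] = matrix.true_theta
    df.to_csv(path, index=False)


def read_responses(
    path: str | Path, n_categories: int | None = None
) -> ResponseMatrix:
    df = pd.read_csv(path)
    item_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if not item_cols:
        raise SchemaError("response CSV has no item columns")
    group = df["group"].to_numpy() if "group" in df.columns else None
    true_theta = df["true_theta"].to_numpy(dtype=float) if "true_theta" in df.columns else None
    data = df[item_cols]
    for col in item_cols:
        vals = data[col]
        as_float = pd.to_numeric(vals, errors="coerce")
        bad = as_float.isna() | (np.mod(as_float.fillna(0), 1) != 0)
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise SchemaError(
                f"non-integer response at row {row}, column {col!r}: {vals.iloc[row]!r}"
            )
        if n_categories is not None:
            out_of_range = (as_float < 0) | (as_float >= n_categories)
            if out_of_range.any():
                row = int(np.where(out_of_range)[0][0])
                raise SchemaError(
                    f"category {vals.iloc[row]} out of range [0, {n_categories - 1}] "
                    f"at row {row}, column {col!r}"
                )
    return ResponseMatrix(
        data=data.astype(np.int64), group=group, true_theta=true_theta
    )


def write_cat_records(
    path: str | Path,
    batch: dict[str, np.ndarray],
    item_ids: list[str],
) -> None:
    """JSON-lines administration records, one per respondent.

    ``batch`` is the output of :func:`gradedcat.run_cat_batch`; each line
    holds the item sequence (ids), final theta and SE, item count, and stop
    reason.
    """
    lines = []
    n = len(batch["theta"])
    for row in range(n):
        seq = [item_ids[s] for s in batch["sequence"][row] if s >= 0]
        lines.append(
            json.dumps(
                {
                    "respondent": row,
                    "items": seq,
                    "theta": float(batch["theta"][row]),
                    "se": float(batch["se"][row]),
                    "n_items": int(batch["n_items"][row]),
                    "stop_reason": str(batch["stop_reason"][row]),
                }
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_calibration(path: str | Path, result: CalibrationResult) -> None:
    payload = _bank_payload(result.bank)
    for scale_block in payload["scales"]:
        for entry in scale_block["items"]:
            entry["se"] = result.standard_errors.get(entry["id"], {})
    payload.update(
        {
            "log_likelihood": result.log_likelihood,
            "n_cycles": result.n_cycles,
            "converged": result.converged,
            "category_collapse_map": {
                item: {str(k): v for k, v in mapping.items()}
                for item, mapping in result.category_collapse_map.items()
            },
        }
    )
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_calibration(path: str | Path) -> CalibrationResult:
    payload = json.loads(Path(path).read_text())
    items = _items_from_payload(payload)
    se: dict[str, dict] = {}
    for scale_block in payload.get("scales", []):
        for entry in scale_block["items"]:
            if "se" in entry:
                se[str(entry["id"])] = entry["se"]
    bank = ItemBank(
        items=tuple(items),
        name=str(payload.get("name", "bank")),
        n_categories=int(payload.get("n_categories", 0)),
    )
    return CalibrationResult(
        bank=bank,
        standard_errors=se,
        log_likelihood=float(payload.get("log_likelihood", np.nan)),
        ll_trace=[],
        n_cycles=int(payload.get("n_cycles", 0)),
        converged=bool(payload.get("converged", False)),
        category_collapse_map={
            item: {int(k): int(v) for k, v in mapping.items()}
            for item, mapping in payload.get("category_collapse_map", {}).items()
        },
    )
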