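"""Reading and writing the package's standard file formats.

Responses travel as CSV with a person-id first column and one column per
item; an empty cell or ``NA`` is a missing response, never a zero.
Parameter tables are CSV with columns ``item_id, slope, b1..bm`` (or an
equivalent JSON list); information curves are CSV with a theta column,
one column per item, the total, and the SE.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._likelihood import MISSING
from .calibrate import CalibrationResult, ResponseMatrix
from .errors import SchemaError
from .model import InformationCurve, ItemParameters, ScaleParameters


def read_responses(path, n_categories: int = 6) -> ResponseMatrix:
    """Read a response CSV; malformed codes raise with row/column context."""
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    codes = np.full(df.shape, MISSING, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            text = raw.strip()
            if text == "" or text.upper() in ("NA", "NAN"):
                continue
            try:
                value = int(text)
            except ValueError as exc:
                raise SchemaError(
                    f"{path}: non-integer code {raw!r} at row {df.index[i]!r}, "
                    f"column {col!r}"
                ) from exc
            if not 0 <= value < n_categories:
                raise SchemaError(
                    f"{path}: code {value} out of range 0..{n_categories - 1} "
                    f"at row {df.index[i]!r}, column {col!r}"
                )
            codes[i, j] = value
    return ResponseMatrix(
        tuple(df.index.astype(str)), tuple(df.columns.astype(str)), codes, n_categories
    )


def write_responses(responses: ResponseMatrix, path) -> None:
    df = responses.to_dataframe()
    out = df.astype("Int64")
    out.to_csv(path, na_rep="")


def read_groups(path) -> pd.DataFrame:
    """Group labels CSV: person-id first column, one column per variable."""
    df = pd.read_csv(path, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return df


def write_groups(groups: pd.DataFrame, path) -> None:
    groups.to_csv(path)


def scale_to_frame(scale: ScaleParameters) -> pd.DataFrame:
    m = max(it.thresholds.size for it in scale.items)
    rows = []
    for it in scale.items:
        row = {"item_id": it.item_id, "slope": it.slope}
        for k in range(m):
            row[f"b{k + 1}"] = it.thresholds[k] if k < it.thresholds.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_parameters(scale: ScaleParameters, path) -> None:
    scale_to_frame(scale).to_csv(path, index=False)


def read_parameters(path, dimension_name: str | None = None) -> ScaleParameters:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        items = tuple(
            ItemParameters(r["item_id"], r["slope"], np.asarray(r["thresholds"], dtype=float))
            for r in payload["items"]
        )
        return ScaleParameters(dimension_name or payload.get("dimension_name", "scale"), items)
    df = pd.read_csv(path)
    b_cols = sorted(
        (c for c in df.columns if c.startswith("b") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    items = []
    for _, row in df.iterrows():
        b = row[b_cols].to_numpy(dtype=float)
        b = b[~np.isnan(b)]
        items.append(ItemParameters(str(row["item_id"]), float(row["slope"]), b))
    return ScaleParameters(dimension_name or "scale", tuple(items))


def write_parameters_json(scale: ScaleParameters, path) -> None:
    payload = {
        "dimension_name": scale.dimension_name,
        "items": [
            {
                "item_id": it.item_id,
                "slope": it.slope,
                "thresholds": it.thresholds.tolist(),
            }
            for it in scale.items
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_information_curve(curve: InformationCurve, path) -> None:
    data = {"theta": curve.theta}
    for i, item_id in enumerate(curve.item_ids):
        data[item_id] = curve.item_information[i]
    data["total"] = curve.total_information
    data["se"] = curve.standard_error
    pd.DataFrame(data).to_csv(path, index=False)


def calibration_run_record(result: CalibrationResult, seed=None) -> dict:
    return {
        "seed": seed,
        "grid": {
            "points": [float(result.grid.points[0]), float(result.grid.points[-1])],
            "n": int(result.grid.points.size),
        },
        "log_likelihood": result.log_likelihood,
        "n_iterations": result.n_iterations,
        "converged": result.converged,
        "category_maps": {k: {str(a): b for a, b in v.items()}
                          for k, v in result.category_maps.items()},
    }
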