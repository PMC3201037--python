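"""Synthetic response data with the structure the analysis assumes.

The generator draws graded-response data under a standard-normal latent
trait, with a two-group population (reference and focal), controllable
impact (focal prior mean/SD), injectable uniform DIF (a constant — or
per-threshold — shift of the focal thresholds) and non-uniform DIF (a
multiplicative edit of the focal slope), plus missing-completely-at-
random item non-response.  Defaults mirror the study conditions the
package targets: 296 respondents on 6-category Likert items scored 0-5,
roughly 4.5% item non-response, and a 61.8% focal-group share (the
female share of the LVQOL sample).

The module also carries the published LVQOL re-calibration parameters
(21 items in four dimensions) and the published two-group DIF parameter
rows, which serve as reference fixtures throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._likelihood import MISSING
from .calibrate import ResponseMatrix
from .dif import SubgroupSpec
from .errors import ConfigurationError
from .model import ItemParameters, ScaleParameters, boundary_probs


@dataclass(frozen=True)
class DifEdit:
    """One injected DIF effect on the focal group's copy of an item."""

    item_id: str
    kind: str  # "uniform" (threshold shift) or "non-uniform" (slope multiplier)
    magnitude: float | tuple

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "non-uniform"):
            raise ConfigurationError(f"unknown DIF kind {self.kind!r}")


@dataclass(frozen=True)
class SimulationDesign:
    scale: ScaleParameters
    n_persons: int = 296
    group_fraction: float = 0.618  # focal share; study default is the female share
    focal_mean: float = 0.0
    focal_sd: float = 1.0
    dif_edits: tuple = ()
    missing_rate: float = 0.045
    seed: int = 0
    variable_name: str = "group"
    reference_label: str = "reference"
    focal_label: str = "focal"

    def __post_init__(self) -> None:
        if not 0.0 <= self.group_fraction <= 1.0:
            raise ConfigurationError("group_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1]")
        if self.focal_sd <= 0:
            raise ConfigurationError("focal_sd must be positive")
        if self.n_persons < 2:
            raise ConfigurationError("need at least 2 persons")
        ids = set(self.scale.item_ids)
        for e in self.dif_edits:
            if e.item_id not in ids:
                raise ConfigurationError(f"DIF edit references unknown item {e.item_id!r}")
        object.__setattr__(self, "dif_edits", tuple(self.dif_edits))


def _apply_edits(scale: ScaleParameters, edits) -> ScaleParameters:
    by_item = {}
    for e in edits:
        by_item.setdefault(e.item_id, []).append(e)
    items = []
    for it in scale.items:
        slope, b = it.slope, it.thresholds.copy()
        for e in by_item.get(it.item_id, []):
            if e.kind == "uniform":
                shift = np.asarray(e.magnitude, dtype=float)
                if shift.ndim == 0:
                    b = b + float(shift)
                else:
                    if shift.size != b.size:
                        raise ConfigurationError(
                            f"per-threshold shift for {it.item_id!r} has wrong length"
                        )
                    b = b + shift
            else:
                slope = slope * float(e.magnitude)
        items.append(ItemParameters(it.item_id, slope, np.sort(b)))
    return ScaleParameters(scale.dimension_name, tuple(items))


def simulate_responses(design: SimulationDesign):
    """Draw (ResponseMatrix, SubgroupSpec, truth record) for a design.

    Identical designs (including the seed) reproduce identical output.
    The truth record retains the generating trait values, the group-wise
    parameters and the injected edits.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_persons
    n_focal = int(round(design.group_fraction * n))
    focal = np.zeros(n, dtype=bool)
    focal[rng.choice(n, size=n_focal, replace=False)] = True

    theta = np.where(
        focal,
        design.focal_mean + design.focal_sd * rng.standard_normal(n),
        rng.standard_normal(n),
    )
    ref_scale = design.scale
    foc_scale = _apply_edits(design.scale, design.dif_edits)

    n_items = len(ref_scale)
    codes = np.empty((n, n_items), dtype=np.int64)
    u = rng.random((n, n_items))
    for i in range(n_items):
        # P(X >= j) thresholds per person; count of exceeded boundaries = code
        for scale_g, mask in ((ref_scale, ~focal), (foc_scale, focal)):
            if not mask.any():
                continue
            pstar = boundary_probs(scale_g.items[i], theta[mask])
            codes[mask, i] = (u[mask, i][:, None] < pstar).sum(axis=1)

    miss = rng.random((n, n_items)) < design.missing_rate
    codes[miss] = MISSING

    persons = tuple(f"p{k + 1:04d}" for k in range(n))
    n_categories = max(it.n_categories for it in ref_scale.items)
    responses = ResponseMatrix(persons, tuple(ref_scale.item_ids), codes, n_categories)
    labels = tuple(
        design.focal_label if f else design.reference_label for f in focal
    )
    # a one-group design (fraction 0 or 1) has no subgroup structure
    if 2 <= n_focal <= n - 2:
        subgroup = SubgroupSpec(design.variable_name, labels, design.reference_label)
    else:
        subgroup = None
    truth = {
        "theta": theta,
        "focal": focal,
        "reference_scale": ref_scale,
        "focal_scale": foc_scale,
        "edits": design.dif_edits,
        "seed": design.seed,
    }
    return responses, subgroup, truth


# --------------------------------------------------------------------------
# Published LVQOL reference parameters (re-calibrated 21-item instrument).
# Four unidimensional subscales of 6-category items scored 0-5.
# --------------------------------------------------------------------------

_RECALIBRATED = {
    "Basic aspects": [
        ("item6", "Seeing moving objects", 2.06, (-1.21, -0.66, 0.13, 0.66, 2.55)),
        ("item7", "Eyes getting tired", 2.61, (-1.25, -0.96, -0.29, 0.25, 2.10)),
        ("item8", "Seeing the television", 2.18, (-1.69, -1.18, -0.34, 0.21, 1.98)),
        ("item9", "Glare (dazzled by lights)", 1.81, (-2.17, -1.80, -1.20, -0.51, 1.76)),
        ("item10", "Getting right amount light", 2.12, (-1.83, -1.26, -0.37, 0.22, 2.32)),
    ],
    "Mobility": [
        ("item2", "Night vision inside house", 1.66, (-1.42, -0.88, 0.32, 0.85, 3.16)),
        ("item3", "Seeing steps or curbs", 3.56, (-1.04, -0.68, -0.09, 0.17, 1.55)),
        ("item4", "Depth/distance perception", 2.41, (-0.80, -0.45, 0.09, 0.51, 1.98)),
        ("item15", "Getting around outdoors", 5.26, (-1.07, -0.75, -0.14, 0.22, 1.72)),
        ("item16", "Crossing a road with traffic", 3.35, (-1.11, -0.69, -0.25, 0.12, 1.52)),
    ],
    "Adjustment": [
        ("item11", "Understand eye condition", 1.26, (-0.94, -0.47, 0.22, 0.68, 3.48)),
        ("item12", "Unhappy situation in life", 3.23, (-0.63, -0.37, 0.51, 0.93, 3.22)),
        ("item13", "Frustration with doing tasks", 3.41, (-1.06, -0.69, 0.02, 0.38, 2.44)),
        ("item14", "Visiting friends and family", 1.37, (-0.44, -0.13, 0.52, 0.89, 2.99)),
    ],
    "Reading and fine work": [
        ("item17", "Reading large print", 2.14, (-0.14, 0.19, 0.85, 1.17, 2.10)),
        ("item18", "Reading newspaper/books", 3.98, (-1.42, -1.06, -0.61, -0.26, 0.92)),
        ("item19", "Reading labels", 3.50, (-1.79, -1.44, -0.94, -0.54, 0.79)),
        ("item20", "Reading letters and mail", 5.02, (-1.28, -0.93, -0.36, 0.02, 0.98)),
        ("item21", "Finding out the time", 1.91, (-0.50, -0.16, 0.59, 1.13, 2.27)),
        ("item22", "Writing", 3.55, (-1.04, -0.71, -0.17, 0.17, 1.06)),
        ("item23", "Reading own handwriting", 3.17, (-0.81, -0.41, 0.11, 0.51, 1.31)),
    ],
}

ITEM_CONTENT = {
    item_id: content
    for rows in _RECALIBRATED.values()
    for item_id, content, _, _ in rows
}


def lvqol_reference_scales() -> dict:
    """The re-calibrated 21-item LVQOL parameters, by dimension."""
    return {
        dim: ScaleParameters(
            dim,
            tuple(ItemParameters(item_id, slope, np.array(b))
                  for item_id, _, slope, b in rows),
        )
        for dim, rows in _RECALIBRATED.items()
    }


@dataclass(frozen=True)
class PublishedDifRow:
    """One published two-group DIF parameter row (first-listed group first)."""

    item_id: str
    dimension: str
    variable: str
    group_first: str
    group_second: str
    params_first: ItemParameters
    params_second: ItemParameters
    g2: float
    df: int
    p_value: float
    es_delta_max: float
    theta_at_max: float


def _dif_row(item_id, dim, var, g1, a1, b1, g2name, a2, b2, g2, df, p, es, th):
    return PublishedDifRow(
        item_id, dim, var, g1, g2name,
        ItemParameters(item_id, a1, np.array(b1)),
        ItemParameters(item_id, a2, np.array(b2)),
        g2, df, p, es, th,
    )


def lvqol_dif_rows() -> list:
    """Published two-group parameters for the items that showed DIF."""
    return [
        _dif_row("item7", "Basic aspects", "visual_acuity",
                 "low_vision", 2.50, (-0.93, -0.65, -0.10, 0.32, 2.13),
                 "moderate_vision_loss", 2.50, (-1.37, -1.23, -0.54, 0.10, 1.86),
                 15.7, 5, 0.008, -0.80, -0.80),
        _dif_row("item3", "Mobility", "visual_acuity",
                 "low_vision", 2.38, (-0.97, -0.61, -0.01, 0.21, 1.56),
                 "moderate_vision_loss", 5.76, (-0.96, -0.71, -0.26, -0.02, 1.68),
                 14.2, 1, 0.0005, -0.74, 0.20),
        _dif_row("item1", "Adjustment", "administration",
                 "self", 1.99, (-1.98, -1.44, -0.14, 0.38, 2.33),
                 "assisted", 1.99, (-2.47, -2.30, -0.56, -0.09, 2.33),
                 19.4, 5, 0.002, -0.70, -2.00),
        _dif_row("item1", "Adjustment", "gender",
                 "male", 2.08, (-2.05, -1.44, 0.04, 0.40, 1.95),
                 "female", 2.08, (-1.83, -1.57, -0.27, 0.24, 3.37),
                 17.9, 5, 0.003, 0.62, 2.60),
        _dif_row("item12", "Adjustment", "gender",
                 "male", 3.27, (-0.74, -0.31, 0.56, 1.03, 3.06),
                 "female", 3.27, (-0.39, -0.27, 0.51, 0.88, 7.57),
                 15.4, 5, 0.009, 1.00, 5.40),
        _dif_row("item19", "Reading and fine work", "eye_condition",
                 "amd", 3.77, (-1.34, -1.21, -0.94, -0.46, 0.68),
                 "other", 3.77, (-1.48, -1.16, -0.63, -0.51, 0.68),
                 17.8, 5, 0.003, 0.24, -0.80),
        _dif_row("item24", "Reading and fine work", "gender",
                 "male", 1.83, (-1.22, -0.92, -0.38, -0.15, 1.13),
                 "female", 1.83, (-1.80, -1.58, -1.39, -0.94, 1.05),
                 35.2, 5, 0.0005, -1.22, -1.00),
    ]
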