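"""Graded response model (GRM) primitives.

Samejima's graded response model describes the probability that a person
with latent trait level ``theta`` responds in ordered category ``j`` of a
polytomous item.  Each item carries one slope (discrimination) ``alpha``
and ``m`` ordered thresholds ``b_1 <= ... <= b_m`` (one fewer than the
number of response categories).  The cumulative probability of responding
in category ``j`` *or higher* is a two-parameter logistic,

    P*_j(theta) = logistic(alpha * (theta - b_j)),

with the conventions ``P*_0 = 1`` and ``P*_{m+1} = 0``; category
probabilities are differences of adjacent cumulative curves,
``P_j = P*_j - P*_{j+1}``.

This module contains only the pure mathematics: category probabilities,
expected item scores, Fisher information, and test-information curves.
Estimation lives in :mod:`grmkit.calibrate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit


class InvalidParameterError(ValueError):
    """Raised when GRM parameters or inputs violate their invariants."""


def _as_float_array(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError("non-finite value encountered")
    return arr


@dataclass(frozen=True)
class ItemParameters:
    """One item's slope and ordered difficulty thresholds.

    Parameters
    ----------
    item_id:
        Label for the item (e.g. ``"item24"``).
    slope:
        Discrimination ``alpha`` (> 0), in logit units per trait unit.
    thresholds:
        Ordered thresholds ``b_1 <= ... <= b_m`` on the latent-trait scale.
        The item has ``m + 1`` response categories coded ``0..m``.
    """

    item_id: str
    slope: float
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and self.slope > 0):
            raise InvalidParameterError(
                f"item {self.item_id!r}: slope must be finite and > 0, got {self.slope}"
            )
        b = _as_float_array(self.thresholds)
        if b.ndim != 1 or b.size < 1:
            raise InvalidParameterError(
                f"item {self.item_id!r}: thresholds must be a 1-d sequence"
            )
        if np.any(np.diff(b) < 0):
            raise InvalidParameterError(
                f"item {self.item_id!r}: thresholds must be non-decreasing, got {b}"
            )
        object.__setattr__(self, "thresholds", b)
        object.__setattr__(self, "slope", float(self.slope))

    @property
    def n_categories(self) -> int:
        return self.thresholds.size + 1


@dataclass(frozen=True)
class ScaleParameters:
    """An ordered collection of items forming one unidimensional scale."""

    dimension_name: str
    items: tuple

    def __post_init__(self) -> None:
        items = tuple(self.items)
        if not items:
            raise InvalidParameterError("scale must contain at least one item")
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            raise InvalidParameterError(f"duplicate item ids in scale: {ids}")
        object.__setattr__(self, "items", items)

    @property
    def item_ids(self) -> list:
        return [it.item_id for it in self.items]

    def __len__(self) -> int:
        return len(self.items)

    def item(self, item_id: str) -> ItemParameters:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def drop(self, item_ids) -> "ScaleParameters":
        """Return a copy of the scale without the given items."""
        drop = set(item_ids)
        kept = tuple(it for it in self.items if it.item_id not in drop)
        return ScaleParameters(self.dimension_name, kept)


@dataclass(frozen=True)
class AbilityGrid:
    """Quadrature grid for the latent trait with prior mass at each point."""

    points: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        pts = _as_float_array(self.points)
        w = _as_float_array(self.weights)
        if pts.ndim != 1 or pts.size < 2 or np.any(np.diff(pts) <= 0):
            raise InvalidParameterError("grid points must be strictly increasing")
        if w.shape != pts.shape or np.any(w <= 0):
            raise InvalidParameterError("weights must be positive, one per point")
        if abs(w.sum() - 1.0) > 1e-10:
            raise InvalidParameterError("weights must sum to 1 within 1e-10")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w)

    @classmethod
    def standard_normal(cls, lo: float = -6.0, hi: float = 6.0, n: int = 61) -> "AbilityGrid":
        """Equally spaced points with renormalized N(0, 1) mass (the default prior)."""
        pts = np.linspace(lo, hi, n)
        w = np.exp(-0.5 * pts**2)
        return cls(pts, w / w.sum())

    @classmethod
    def normal(cls, mean: float, sd: float, lo: float = -6.0, hi: float = 6.0, n: int = 61) -> "AbilityGrid":
        pts = np.linspace(lo, hi, n)
        w = np.exp(-0.5 * ((pts - mean) / sd) ** 2)
        return cls(pts, w / w.sum())


def cumulative_prob(slope: float, threshold: float, theta):
    """P(response >= category) for one boundary: logistic(slope * (theta - threshold)).

    Accepts scalar or array ``theta``; strictly increasing in ``theta``.
    """
    if not (np.isfinite(slope) and slope > 0):
        raise InvalidParameterError(f"slope must be finite and > 0, got {slope}")
    th = _as_float_array(theta)
    _as_float_array(threshold)
    out = expit(slope * (th - threshold))
    return float(out) if np.isscalar(theta) else out


def boundary_probs(item: ItemParameters, theta) -> np.ndarray:
    """Cumulative curves P*_j for j = 1..m, shape (..., m)."""
    th = np.atleast_1d(_as_float_array(theta))
    return expit(item.slope * (th[..., None] - item.thresholds[None, :]))


def category_probs(item: ItemParameters, theta) -> np.ndarray:
    """Category probabilities P_j = P*_j - P*_{j+1}, shape (..., m+1); rows sum to 1."""
    pstar = boundary_probs(item, theta)
    ones = np.ones(pstar.shape[:-1] + (1,))
    zeros = np.zeros_like(ones)
    padded = np.concatenate([ones, pstar, zeros], axis=-1)
    probs = padded[..., :-1] - padded[..., 1:]
    out = np.clip(probs, 0.0, 1.0)
    if np.isscalar(theta):
        return out[0]
    return out


def expected_item_score(item: ItemParameters, theta):
    """Expected score E[X | theta] = sum_j j * P_j = sum_j P*_j, on the 0..m scale."""
    es = boundary_probs(item, theta).sum(axis=-1)
    return float(es[0]) if np.isscalar(theta) else es


def item_information(item: ItemParameters, theta):
    """Fisher information of one graded item at theta.

    Uses the boundary-weight closed form
    ``alpha^2 * sum_j (w_j - w_{j+1})^2 / P_j`` with ``w = P*(1 - P*)``,
    which equals the generic score-function form ``sum_j (dP_j/dtheta)^2 / P_j``.
    """
    th = np.atleast_1d(_as_float_array(theta))
    pstar = boundary_probs(item, th)
    ones = np.ones((th.size, 1))
    zeros = np.zeros((th.size, 1))
    padded = np.concatenate([ones, pstar, zeros], axis=-1)
    w = padded * (1.0 - padded)
    num = (w[:, :-1] - w[:, 1:]) ** 2
    den = padded[:, :-1] - padded[:, 1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(den > 1e-300, num / np.maximum(den, 1e-300), 0.0)
    info = item.slope**2 * terms.sum(axis=-1)
    return float(info[0]) if np.isscalar(theta) else info


@dataclass(frozen=True)
class InformationCurve:
    """Test information and SE(theta) on a grid, optionally including the prior.

    ``total_information[t] = sum_i item_information[i, t] (+ 1 if prior_included)``
    and ``standard_error = 1 / sqrt(total_information)``.  The unit prior term
    is the information of the standard-normal population prior, which
    marginal-estimation software includes in reported test information.
    """

    theta: np.ndarray
    item_ids: tuple
    item_information: np.ndarray  # (n_items, n_theta)
    total_information: np.ndarray
    prior_included: bool
    standard_error: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        se = 1.0 / np.sqrt(self.total_information)
        object.__setattr__(self, "standard_error", se)
        expected = self.item_information.sum(axis=0) + (1.0 if self.prior_included else 0.0)
        if not np.allclose(expected, self.total_information, atol=1e-9):
            raise InvalidParameterError("total information inconsistent with item sum")

    @property
    def max_information(self) -> float:
        return float(self.total_information.max())

    @property
    def theta_at_max(self) -> float:
        return float(self.theta[int(np.argmax(self.total_information))])


def scale_information(
    scale: ScaleParameters,
    theta_grid,
    prior_included: bool = True,
) -> InformationCurve:
    """Test information curve for a scale on a strictly increasing theta grid."""
    th = _as_float_array(theta_grid)
    if th.ndim != 1 or th.size == 0:
        raise InvalidParameterError("theta grid must be a non-empty 1-d array")
    if th.size > 1 and np.any(np.diff(th) <= 0):
        raise InvalidParameterError("theta grid must be strictly increasing")
    per_item = np.vstack([item_information(it, th) for it in scale.items])
    total = per_item.sum(axis=0) + (1.0 if prior_included else 0.0)
    return InformationCurve(
        theta=th,
        item_ids=tuple(scale.item_ids),
        item_information=per_item,
        total_information=total,
        prior_included=prior_included,
    )


DEFAULT_INFO_GRID = np.round(np.arange(-4.0, 4.0 + 1e-9, 0.1), 10)
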