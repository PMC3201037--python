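"""Marginal-maximum-likelihood calibration of the graded response model.

Estimation follows the Bock–Aitkin EM scheme with a fixed standard-normal
population prior discretized on an equally spaced quadrature grid: the
E-step computes each person's posterior mass over grid points and
aggregates posterior expected category counts per item; the M-step
maximizes each item's expected complete-data log-likelihood by
quasi-Newton search in a transformed parameterization (log slope, first
threshold, log threshold increments) that keeps every iterate valid.
Missing responses are treated as ignorable and simply skipped in the
likelihood products.

Person scoring is expected a posteriori (EAP): the posterior mean and SD
of the trait given the person's responses.  Reliability is summarized by
the index of subject separation, the empirical-reliability ratio
``var(EAP) / (var(EAP) + mean(posterior variance))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _likelihood as lk
from ._likelihood import MISSING
from .errors import (
    DegenerateItemError,
    InsufficientDataError,
    SchemaError,
    UndefinedReliabilityError,
)
from .model import AbilityGrid, ItemParameters, ScaleParameters


@dataclass(frozen=True)
class ResponseMatrix:
    """Persons x items ordinal codes with explicit missingness.

    ``codes`` holds integers in ``0..n_categories-1`` or ``-1`` for a
    missing response.  Missingness is never an in-range code.
    """

    persons: tuple
    items: tuple
    codes: np.ndarray
    n_categories: int = 6

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        persons = tuple(str(p) for p in self.persons)
        items = tuple(str(i) for i in self.items)
        if codes.shape != (len(persons), len(items)):
            raise SchemaError(
                f"codes shape {codes.shape} does not match "
                f"{len(persons)} persons x {len(items)} items"
            )
        bad = (codes != MISSING) & ((codes < 0) | (codes >= self.n_categories))
        if bad.any():
            s, i = np.argwhere(bad)[0]
            raise SchemaError(
                f"code {codes[s, i]} out of range 0..{self.n_categories - 1} "
                f"at person {persons[s]!r}, item {items[i]!r}"
            )
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "persons", persons)
        object.__setattr__(self, "items", items)

    @property
    def n_persons(self) -> int:
        return len(self.persons)

    def subset(self, item_ids) -> "ResponseMatrix":
        idx = [self.items.index(i) for i in item_ids]
        return ResponseMatrix(self.persons, tuple(item_ids), self.codes[:, idx], self.n_categories)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes.astype(float), index=list(self.persons), columns=list(self.items))
        df[df == MISSING] = np.nan
        df.index.name = "person_id"
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_categories: int = 6) -> "ResponseMatrix":
        codes = df.to_numpy(dtype=float)
        filled = np.where(np.isnan(codes), MISSING, codes)
        if not np.allclose(filled, np.round(filled)):
            raise SchemaError("response codes must be integers")
        return cls(tuple(df.index.astype(str)), tuple(df.columns.astype(str)),
                   filled.astype(np.int64), n_categories)


@dataclass(frozen=True)
class PersonPosterior:
    person: str
    eap_mean: float
    posterior_sd: float
    n_items_observed: int


@dataclass
class CalibrationResult:
    """Fitted scale with standard errors and the optimization record."""

    scale: ScaleParameters
    standard_errors: dict
    log_likelihood: float
    n_iterations: int
    converged: bool
    grid: AbilityGrid
    category_maps: dict = field(default_factory=dict)
    ll_history: list = field(default_factory=list)


def _match_items(responses: ResponseMatrix, scale: ScaleParameters) -> None:
    if list(responses.items) != list(scale.item_ids):
        raise SchemaError(
            f"response columns {list(responses.items)} do not match "
            f"scale items {list(scale.item_ids)}"
        )


def _log_tables(scale: ScaleParameters, points: np.ndarray) -> list:
    return [lk.log_prob_table(it.slope, it.thresholds, points) for it in scale.items]


def marginal_log_likelihood(
    responses: ResponseMatrix, scale: ScaleParameters, grid: AbilityGrid
) -> float:
    """Sum over persons of log sum over grid of prior mass x response likelihood."""
    _match_items(responses, scale)
    _, ll, _ = lk.posterior_weights(
        responses.codes, _log_tables(scale, grid.points), np.log(grid.weights)
    )
    return ll


def _collapse_categories(codes: np.ndarray, n_categories: int):
    """Rank-recode each item onto its observed categories.

    An unobserved category is merged with its lower neighbor, which for
    integer codes amounts to mapping observed codes onto consecutive ranks.
    Returns the recoded matrix, per-item category counts, and the mapping
    per item (original code -> recoded category).
    """
    recoded = codes.copy()
    n_cats = []
    maps = []
    for i in range(codes.shape[1]):
        col = codes[:, i]
        observed = np.unique(col[col != MISSING])
        if observed.size < 2:
            raise DegenerateItemError(
                f"item column {i} has {observed.size} observed category(ies); "
                "at least 2 are required"
            )
        mapping = {int(orig): rank for rank, orig in enumerate(observed)}
        if observed.size < np.ptp(observed) + 1 or observed[0] != 0:
            lut = np.full(n_categories, MISSING, dtype=np.int64)
            for orig, rank in mapping.items():
                lut[orig] = rank
            obs = col != MISSING
            recoded[obs, i] = lut[col[obs]]
        n_cats.append(observed.size)
        maps.append(mapping)
    return recoded, n_cats, maps


def apply_category_maps(responses: ResponseMatrix, category_maps: dict) -> ResponseMatrix:
    """Recode a response matrix with a calibration's category-collapse maps.

    Needed before computing item fit or DIF statistics against a fitted
    scale whose rare categories were merged during calibration.
    """
    codes = responses.codes.copy()
    for i, item_id in enumerate(responses.items):
        mapping = category_maps.get(item_id)
        if not mapping:
            continue
        lut = np.full(responses.n_categories, MISSING, dtype=np.int64)
        for orig, rank in mapping.items():
            lut[int(orig)] = rank
        obs = codes[:, i] != MISSING
        codes[obs, i] = lut[codes[obs, i]]
    return ResponseMatrix(responses.persons, responses.items, codes, responses.n_categories)


def _initial_item(col: np.ndarray, n_cat: int) -> tuple:
    """Start values from marginal cumulative proportions at unit slope."""
    obs = col[col != MISSING]
    b = []
    for j in range(1, n_cat):
        p = np.clip(np.mean(obs >= j), 1e-3, 1 - 1e-3)
        b.append(-np.log(p / (1 - p)))
    b = np.asarray(b)
    # enforce a strictly increasing start
    for j in range(1, b.size):
        b[j] = max(b[j], b[j - 1] + 1e-3)
    return 1.0, np.clip(b, -4.5, 4.5)


def _mstep_item(r: np.ndarray, alpha: float, b: np.ndarray, points: np.ndarray):
    raw0 = lk.to_raw(alpha, b)

    def fun(raw):
        a, bb = lk.from_raw(raw)
        f = -lk.item_expected_loglik(r, a, bb, points)
        ga, gb = lk.item_natural_grad(r, a, bb, points)
        return f, -lk.chain_to_raw(raw, ga, gb)

    res = minimize(fun, raw0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 100, "ftol": 1e-12, "gtol": 1e-9})
    # EM only needs the expected log-likelihood not to decrease
    if res.fun > -lk.item_expected_loglik(r, alpha, b, points) + 1e-12:
        return alpha, b
    return lk.from_raw(res.x)


def fit_grm(
    responses: ResponseMatrix,
    grid: AbilityGrid | None = None,
    tol: float = 1e-5,
    param_tol: float = 1e-4,
    max_iter: int = 500,
    compute_se: bool = True,
    dimension_name: str | None = None,
    start: ScaleParameters | None = None,
) -> CalibrationResult:
    """Calibrate a scale by marginal maximum likelihood (Bock–Aitkin EM).

    Convergence requires both an absolute log-likelihood change below
    ``tol`` and a maximum absolute parameter change below ``param_tol``;
    non-convergence within ``max_iter`` is flagged, not raised.
    """
    if grid is None:
        grid = AbilityGrid.standard_normal()
    points, logw = grid.points, np.log(grid.weights)
    codes, n_cats, cat_maps = _collapse_categories(responses.codes, responses.n_categories)
    n_items = len(responses.items)

    alphas, bs = [], []
    if start is not None:
        for i, item_id in enumerate(responses.items):
            it = start.item(item_id)
            if it.n_categories != n_cats[i]:
                raise SchemaError(
                    f"start values for {item_id!r} have {it.n_categories} categories, "
                    f"data (after collapsing) has {n_cats[i]}"
                )
            alphas.append(it.slope)
            bs.append(it.thresholds.copy())
    else:
        for i in range(n_items):
            a0, b0 = _initial_item(codes[:, i], n_cats[i])
            alphas.append(a0)
            bs.append(b0)

    ll_old = -np.inf
    ll_history: list = []
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        log_tables = [lk.log_prob_table(alphas[i], bs[i], points) for i in range(n_items)]
        post, ll, _ = lk.posterior_weights(codes, log_tables, logw)
        if ll < ll_old - 1e-8:
            raise RuntimeError(
                f"EM log-likelihood decreased at iteration {iteration}: {ll_old} -> {ll}"
            )
        ll_history.append(ll)
        delta_param = 0.0
        new_alphas, new_bs = [], []
        for i in range(n_items):
            r = lk.expected_counts(post, codes[:, i], n_cats[i])
            a_new, b_new = _mstep_item(r, alphas[i], bs[i], points)
            delta_param = max(delta_param, abs(a_new - alphas[i]),
                              float(np.max(np.abs(b_new - bs[i]))))
            new_alphas.append(a_new)
            new_bs.append(b_new)
        if abs(ll - ll_old) < tol and delta_param < param_tol:
            converged = True
            break
        alphas, bs = new_alphas, new_bs
        ll_old = ll

    items = tuple(
        ItemParameters(responses.items[i], alphas[i], bs[i]) for i in range(n_items)
    )
    scale = ScaleParameters(dimension_name or "scale", items)
    ses: dict = {}
    if compute_se:
        ses = parameter_standard_errors(
            ResponseMatrix(responses.persons, responses.items, codes,
                           max(n_cats)),
            scale, grid)
    return CalibrationResult(
        scale=scale,
        standard_errors=ses,
        log_likelihood=ll_history[-1],
        n_iterations=iteration,
        converged=converged,
        grid=grid,
        category_maps={responses.items[i]: cat_maps[i] for i in range(n_items)},
        ll_history=ll_history,
    )


def _full_natural_grad(codes, scale, points, logw) -> np.ndarray:
    log_tables = _log_tables(scale, points)
    post, _, _ = lk.posterior_weights(codes, log_tables, logw)
    grads = []
    for i, it in enumerate(scale.items):
        r = lk.expected_counts(post, codes[:, i], it.n_categories)
        ga, gb = lk.item_natural_grad(r, it.slope, it.thresholds, points)
        grads.append(np.concatenate([[ga], gb]))
    return np.concatenate(grads)


def parameter_standard_errors(
    responses: ResponseMatrix, scale: ScaleParameters, grid: AbilityGrid,
    step: float = 1e-4,
) -> dict:
    """Per-parameter SEs from a finite-difference observed-information matrix.

    The Hessian of the marginal log-likelihood is built by central
    differences of the analytic score at the solution; SEs are square roots
    of the diagonal of the inverse negative Hessian (NaN where the
    information matrix is not positive on that coordinate).
    """
    _match_items(responses, scale)
    points, logw = grid.points, np.log(grid.weights)
    x0 = np.concatenate([np.concatenate([[it.slope], it.thresholds]) for it in scale.items])
    sizes = [1 + it.thresholds.size for it in scale.items]

    def rebuild(x):
        items = []
        pos = 0
        for it, size in zip(scale.items, sizes):
            block = x[pos:pos + size]
            pos += size
            b = np.sort(block[1:])  # keep valid under perturbation
            items.append(ItemParameters(it.item_id, max(block[0], 1e-6), b))
        return ScaleParameters(scale.dimension_name, tuple(items))

    p = x0.size
    hess = np.zeros((p, p))
    for k in range(p):
        h = step * (1.0 + abs(x0[k]))
        xp, xm = x0.copy(), x0.copy()
        xp[k] += h
        xm[k] -= h
        gp = _full_natural_grad(responses.codes, rebuild(xp), points, logw)
        gm = _full_natural_grad(responses.codes, rebuild(xm), points, logw)
        hess[:, k] = (gp - gm) / (2 * h)
    hess = 0.5 * (hess + hess.T)
    cov = np.linalg.pinv(-hess)
    diag = np.diag(cov)
    se = np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)
    out: dict = {}
    pos = 0
    for it, size in zip(scale.items, sizes):
        out[it.item_id] = se[pos:pos + size].copy()
        pos += size
    return out


def eap_scores(
    responses: ResponseMatrix, scale: ScaleParameters, grid: AbilityGrid | None = None
) -> list:
    """Expected a posteriori trait estimates, one per person in input order.

    A person with no observed responses carries the (discretized) prior
    mean and SD.
    """
    if grid is None:
        grid = AbilityGrid.standard_normal()
    _match_items(responses, scale)
    points, logw = grid.points, np.log(grid.weights)
    post, _, _ = lk.posterior_weights(responses.codes, _log_tables(scale, points), logw)
    means = post @ points
    second = post @ points**2
    sds = np.sqrt(np.maximum(second - means**2, 0.0))
    n_obs = (responses.codes != MISSING).sum(axis=1)
    return [
        PersonPosterior(responses.persons[s], float(means[s]), float(sds[s]), int(n_obs[s]))
        for s in range(responses.n_persons)
    ]


def subject_separation(posteriors) -> float:
    """Empirical reliability: var(EAP) / (var(EAP) + mean posterior variance).

    Persons with no observed responses are excluded; at least two scored
    persons are required.
    """
    scored = [p for p in posteriors if p.n_items_observed > 0]
    if len(scored) < 2:
        raise InsufficientDataError("need at least 2 persons with observed responses")
    means = np.array([p.eap_mean for p in scored])
    variances = np.array([p.posterior_sd**2 for p in scored])
    var_means = float(np.var(means, ddof=1))
    total = var_means + float(variances.mean())
    if total <= 0:
        raise UndefinedReliabilityError("zero total variance in person estimates")
    return var_means / total
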