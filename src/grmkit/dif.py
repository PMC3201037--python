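"""Two-group likelihood-ratio tests for differential item functioning (DIF).

The testing scheme compares nested two-group GRM models in which all
anchor items (every other item of the dimension) are constrained equal
across groups, the reference group's trait prior is fixed at N(0, 1), and
the focal group's prior mean and SD are free — so true group differences
in the trait ("impact") are absorbed by the focal prior rather than
mistaken for DIF.  For the studied item three constraint levels are
fitted:

* ``equal``        — slope and thresholds equal across groups,
* ``slope_equal``  — shared slope, free thresholds,
* ``free``         — slope and thresholds both free.

The slope (non-uniform DIF) test is G^2 = 2 * (LL_free - LL_slope_equal)
on 1 df; only when it is non-significant is the threshold (uniform DIF)
test G^2 = 2 * (LL_slope_equal - LL_equal) on m df carried out — the
hierarchical structure of the IRT likelihood-ratio DIF procedure.

DIF magnitude is summarized by the expected-score difference curve
between groups and its signed maximum (ES_dmax), on the 0..m raw-score
scale of the item.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import chi2, norm

from . import _likelihood as lk
from ._likelihood import MISSING
from .calibrate import ResponseMatrix
from .errors import ConfigurationError, InsufficientDataError
from .model import (
    AbilityGrid,
    InvalidParameterError,
    ItemParameters,
    ScaleParameters,
    expected_item_score,
)

DEFAULT_ES_GRID = np.round(np.arange(-8.0, 8.0 + 1e-9, 0.01), 10)

CONSTRAINTS = ("equal", "slope_equal", "free")


@dataclass(frozen=True)
class SubgroupSpec:
    """Binary subgroup membership aligned with a ResponseMatrix's persons."""

    variable_name: str
    group_labels: tuple
    reference_group: str

    def __post_init__(self) -> None:
        labels = tuple(str(g) for g in self.group_labels)
        distinct = sorted(set(labels))
        if len(distinct) != 2:
            raise ConfigurationError(
                f"{self.variable_name!r}: exactly two group labels required, got {distinct}"
            )
        if self.reference_group not in distinct:
            raise ConfigurationError(
                f"{self.variable_name!r}: reference group {self.reference_group!r} "
                f"not among labels {distinct}"
            )
        for g in distinct:
            if labels.count(g) < 2:
                raise ConfigurationError(
                    f"{self.variable_name!r}: group {g!r} has fewer than 2 persons"
                )
        object.__setattr__(self, "group_labels", labels)

    @property
    def focal_group(self) -> str:
        return next(g for g in sorted(set(self.group_labels)) if g != self.reference_group)

    def focal_mask(self) -> np.ndarray:
        return np.array([g == self.focal_group for g in self.group_labels])

    def swapped(self) -> "SubgroupSpec":
        return SubgroupSpec(self.variable_name, self.group_labels, self.focal_group)


@dataclass(frozen=True)
class GroupedItemParameters:
    """The studied item's parameters in both groups under a constraint level."""

    item_id: str
    group_a: ItemParameters  # reference
    group_b: ItemParameters  # focal
    constraint: str

    def __post_init__(self) -> None:
        if self.constraint not in CONSTRAINTS:
            raise ConfigurationError(f"unknown constraint {self.constraint!r}")
        if self.group_a.n_categories != self.group_b.n_categories:
            raise InvalidParameterError("category counts differ between groups")
        if self.constraint in ("equal", "slope_equal") and not np.isclose(
            self.group_a.slope, self.group_b.slope
        ):
            raise InvalidParameterError("slopes must match under a shared-slope constraint")


@dataclass
class TwoGroupFit:
    grouped_item: GroupedItemParameters
    anchors: ScaleParameters
    log_likelihood: float
    focal_mean: float
    focal_sd: float
    converged: bool
    n_evaluations: int


@dataclass
class DIFResult:
    """One item x one grouping variable: hierarchical G^2 tests and ES magnitude."""

    item_id: str
    variable_name: str
    g2_slope: float
    df_slope: int
    p_slope: float
    g2_thresholds: float | None
    df_thresholds: int | None
    p_thresholds: float | None
    classification: str  # none | uniform | non-uniform
    es_theta: np.ndarray
    es_curve: np.ndarray
    es_delta_max: float
    theta_at_max: float
    focal_mean: float
    focal_sd: float
    group_parameters: GroupedItemParameters = None

    def __post_init__(self) -> None:
        if self.classification not in ("none", "uniform", "non-uniform"):
            raise ConfigurationError(f"bad classification {self.classification!r}")


@dataclass
class RemovalDecision:
    item_id: str
    remove: bool
    reasons: list = field(default_factory=list)


class _TwoGroupObjective:
    """Negative marginal log-likelihood and analytic gradient for the
    constrained two-group model, over an unconstrained packed vector."""

    def __init__(self, codes, focal_mask, n_cats, studied_idx, constraint, points):
        self.codes_ref = codes[~focal_mask]
        self.codes_foc = codes[focal_mask]
        self.n_cats = list(n_cats)
        self.studied = studied_idx
        self.constraint = constraint
        self.points = points
        logw = -0.5 * points**2
        self.logw_ref = logw - logsumexp(logw)
        self.n_items = codes.shape[1]

    # --- packing ------------------------------------------------------------

    def pack(self, scale: ScaleParameters, studied_focal: ItemParameters | None,
             mu: float, sigma: float) -> np.ndarray:
        parts = []
        for i, it in enumerate(scale.items):
            raw = lk.to_raw(it.slope, it.thresholds)
            if i != self.studied or self.constraint == "equal":
                parts.append(raw)
            elif self.constraint == "slope_equal":
                foc = studied_focal if studied_focal is not None else it
                parts.append(raw[:1])
                parts.append(raw[1:])
                parts.append(lk.to_raw(foc.slope, foc.thresholds)[1:])
            else:  # free
                foc = studied_focal if studied_focal is not None else it
                parts.append(raw)
                parts.append(lk.to_raw(foc.slope, foc.thresholds))
        parts.append([mu, np.log(sigma)])
        return np.concatenate(parts)

    def unpack(self, x):
        ref_params, foc_params = [], []
        pos = 0
        for i in range(self.n_items):
            m = self.n_cats[i] - 1
            if i != self.studied or self.constraint == "equal":
                a, b = lk.from_raw(x[pos:pos + 1 + m])
                pos += 1 + m
                ref_params.append((a, b))
                foc_params.append((a, b))
            elif self.constraint == "slope_equal":
                u = x[pos]
                pos += 1
                a, b_ref = lk.from_raw(np.concatenate([[u], x[pos:pos + m]]))
                pos += m
                _, b_foc = lk.from_raw(np.concatenate([[u], x[pos:pos + m]]))
                pos += m
                ref_params.append((a, b_ref))
                foc_params.append((a, b_foc))
            else:
                a_r, b_r = lk.from_raw(x[pos:pos + 1 + m])
                pos += 1 + m
                a_f, b_f = lk.from_raw(x[pos:pos + 1 + m])
                pos += 1 + m
                ref_params.append((a_r, b_r))
                foc_params.append((a_f, b_f))
        mu, log_sigma = x[pos], x[pos + 1]
        return ref_params, foc_params, float(mu), float(np.exp(np.clip(log_sigma, -5, 3)))

    # --- objective ----------------------------------------------------------

    def __call__(self, x):
        ref_params, foc_params, mu, sigma = self.unpack(x)
        pts = self.points
        v = -0.5 * ((pts - mu) / sigma) ** 2
        logw_foc = v - logsumexp(v)

        lt_ref = [lk.log_prob_table(a, b, pts) for a, b in ref_params]
        lt_foc = [lk.log_prob_table(a, b, pts) for a, b in foc_params]
        post_r, ll_r, _ = lk.posterior_weights(self.codes_ref, lt_ref, self.logw_ref)
        post_f, ll_f, _ = lk.posterior_weights(self.codes_foc, lt_foc, logw_foc)

        grads = []
        pos = 0
        for i in range(self.n_items):
            m = self.n_cats[i] - 1
            r_ref = lk.expected_counts(post_r, self.codes_ref[:, i], self.n_cats[i])
            r_foc = lk.expected_counts(post_f, self.codes_foc[:, i], self.n_cats[i])
            if i != self.studied or self.constraint == "equal":
                a, b = ref_params[i]
                ga, gb = lk.item_natural_grad(r_ref + r_foc, a, b, pts)
                raw = x[pos:pos + 1 + m]
                pos += 1 + m
                grads.append(lk.chain_to_raw(raw, ga, gb))
            elif self.constraint == "slope_equal":
                a, b_ref = ref_params[i]
                _, b_foc = foc_params[i]
                ga_r, gb_r = lk.item_natural_grad(r_ref, a, b_ref, pts)
                ga_f, gb_f = lk.item_natural_grad(r_foc, a, b_foc, pts)
                raw_r = np.concatenate([[x[pos]], x[pos + 1:pos + 1 + m]])
                raw_f = np.concatenate([[x[pos]], x[pos + 1 + m:pos + 1 + 2 * m]])
                g_r = lk.chain_to_raw(raw_r, ga_r, gb_r)
                g_f = lk.chain_to_raw(raw_f, ga_f, gb_f)
                grads.append(np.concatenate([[g_r[0] + g_f[0]], g_r[1:], g_f[1:]]))
                pos += 1 + 2 * m
            else:
                a_r, b_r = ref_params[i]
                a_f, b_f = foc_params[i]
                ga_r, gb_r = lk.item_natural_grad(r_ref, a_r, b_r, pts)
                ga_f, gb_f = lk.item_natural_grad(r_foc, a_f, b_f, pts)
                grads.append(lk.chain_to_raw(x[pos:pos + 1 + m], ga_r, gb_r))
                pos += 1 + m
                grads.append(lk.chain_to_raw(x[pos:pos + 1 + m], ga_f, gb_f))
                pos += 1 + m

        # focal prior mean / log-sd gradients
        big_r = post_f.sum(axis=0)
        n_f = self.codes_foc.shape[0]
        w_foc = np.exp(logw_foc)
        dv_mu = (pts - mu) / sigma**2
        dv_ls = ((pts - mu) / sigma) ** 2 - 1.0
        g_mu = float(((big_r - n_f * w_foc) * dv_mu).sum())
        g_ls = float(((big_r - n_f * w_foc) * dv_ls).sum())
        grads.append([g_mu, g_ls])

        grad = np.concatenate(grads)
        return -(ll_r + ll_f), -grad


def _validate_two_group(responses, subgroup, scale, studied_item):
    if len(subgroup.group_labels) != responses.n_persons:
        raise ConfigurationError("subgroup labels do not align with response rows")
    if studied_item not in scale.item_ids:
        raise ConfigurationError(f"studied item {studied_item!r} not in scale")
    if len(scale) < 2:
        raise ConfigurationError("anchor set is empty: scale must contain other items")
    idx = scale.item_ids.index(studied_item)
    focal = subgroup.focal_mask()
    col = responses.codes[:, idx]
    for mask, name in ((~focal, subgroup.reference_group), (focal, subgroup.focal_group)):
        if (col[mask] != MISSING).sum() == 0:
            raise InsufficientDataError(
                f"group {name!r} has no observed responses on {studied_item!r}"
            )
    return idx, focal


def fit_two_group(
    responses: ResponseMatrix,
    subgroup: SubgroupSpec,
    scale: ScaleParameters,
    studied_item: str,
    constraint: str,
    grid: AbilityGrid | None = None,
    start: np.ndarray | None = None,
) -> TwoGroupFit:
    """Fit the constrained two-group model by direct quasi-Newton MML.

    ``scale`` supplies starting values (typically the pooled single-group
    calibration); anchors are constrained equal across groups and the
    focal prior mean/SD are estimated.
    """
    if constraint not in CONSTRAINTS:
        raise ConfigurationError(f"unknown constraint {constraint!r}")
    if grid is None:
        grid = AbilityGrid.standard_normal()
    idx, focal = _validate_two_group(responses, subgroup, scale, studied_item)
    n_cats = [it.n_categories for it in scale.items]
    obj = _TwoGroupObjective(responses.codes, focal, n_cats, idx, constraint, grid.points)
    x0 = start if start is not None else obj.pack(scale, None, 0.0, 1.0)
    res = minimize(obj, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7})
    ref_params, foc_params, mu, sigma = obj.unpack(res.x)
    items_ref = [
        ItemParameters(it.item_id, *ref_params[i]) for i, it in enumerate(scale.items)
    ]
    grouped = GroupedItemParameters(
        studied_item,
        items_ref[idx],
        ItemParameters(studied_item, *foc_params[idx]),
        constraint,
    )
    anchors = ScaleParameters(
        scale.dimension_name,
        tuple(it for i, it in enumerate(items_ref) if i != idx),
    )
    fit = TwoGroupFit(
        grouped_item=grouped,
        anchors=anchors,
        log_likelihood=-float(res.fun),
        focal_mean=mu,
        focal_sd=sigma,
        converged=bool(res.success),
        n_evaluations=int(res.nfev),
    )
    fit._solution = res.x  # warm start for the next (less constrained) model
    fit._objective = obj
    return fit


def _expand_start(fit: TwoGroupFit, scale: ScaleParameters, studied_item: str,
                  obj_new: _TwoGroupObjective) -> np.ndarray:
    """Re-pack a fitted solution as the start of a less constrained model."""
    idx = scale.item_ids.index(studied_item)
    items = list(fit.anchors.items)
    items.insert(idx, fit.grouped_item.group_a)
    full = ScaleParameters(scale.dimension_name, tuple(items))
    return obj_new.pack(full, fit.grouped_item.group_b, fit.focal_mean, fit.focal_sd)


def expected_score_dif(
    group_a: ItemParameters, group_b: ItemParameters, theta_grid=None
):
    """Expected-score difference curve (group_a minus group_b) and its
    signed maximum-magnitude value with location (smallest theta on ties)."""
    if theta_grid is None:
        theta_grid = DEFAULT_ES_GRID
    th = np.asarray(theta_grid, dtype=float)
    if th.ndim != 1 or (th.size > 1 and np.any(np.diff(th) <= 0)):
        raise InvalidParameterError("theta grid must be strictly increasing")
    if group_a.n_categories != group_b.n_categories:
        raise InvalidParameterError("category counts differ between groups")
    es = expected_item_score(group_a, th) - expected_item_score(group_b, th)
    i = int(np.argmax(np.abs(es)))
    return es, float(es[i]), float(th[i])


def hierarchical_dif_test(
    responses: ResponseMatrix,
    subgroup: SubgroupSpec,
    scale: ScaleParameters,
    studied_item: str,
    grid: AbilityGrid | None = None,
    alpha: float = 0.01,
    es_grid=None,
) -> DIFResult:
    """Hierarchical slope-then-thresholds likelihood-ratio DIF test for one item."""
    if grid is None:
        grid = AbilityGrid.standard_normal()
    if es_grid is None:
        es_grid = DEFAULT_ES_GRID
    idx = scale.item_ids.index(studied_item) if studied_item in scale.item_ids else None
    if idx is None:
        raise ConfigurationError(f"studied item {studied_item!r} not in scale")
    m = scale.items[idx].thresholds.size

    fit_eq = fit_two_group(responses, subgroup, scale, studied_item, "equal", grid)
    obj_se = _TwoGroupObjective(
        responses.codes, subgroup.focal_mask(),
        [it.n_categories for it in scale.items], idx, "slope_equal", grid.points)
    fit_se = fit_two_group(
        responses, subgroup, scale, studied_item, "slope_equal", grid,
        start=_expand_start(fit_eq, scale, studied_item, obj_se))
    obj_fr = _TwoGroupObjective(
        responses.codes, subgroup.focal_mask(),
        [it.n_categories for it in scale.items], idx, "free", grid.points)
    fit_fr = fit_two_group(
        responses, subgroup, scale, studied_item, "free", grid,
        start=_expand_start(fit_se, scale, studied_item, obj_fr))

    g2_slope = max(0.0, 2.0 * (fit_fr.log_likelihood - fit_se.log_likelihood))
    p_slope = float(chi2.sf(g2_slope, 1))

    if p_slope < alpha:
        classification = "non-uniform"
        g2_thr = df_thr = p_thr = None
        used = fit_fr
    else:
        g2_thr = max(0.0, 2.0 * (fit_se.log_likelihood - fit_eq.log_likelihood))
        df_thr = m
        p_thr = float(chi2.sf(g2_thr, df_thr))
        classification = "uniform" if p_thr < alpha else "none"
        used = fit_se

    es, es_max, th_max = expected_score_dif(
        used.grouped_item.group_a, used.grouped_item.group_b, es_grid)
    return DIFResult(
        item_id=studied_item,
        variable_name=subgroup.variable_name,
        g2_slope=g2_slope,
        df_slope=1,
        p_slope=p_slope,
        g2_thresholds=g2_thr,
        df_thresholds=df_thr,
        p_thresholds=p_thr,
        classification=classification,
        es_theta=np.asarray(es_grid, dtype=float),
        es_curve=es,
        es_delta_max=es_max,
        theta_at_max=th_max,
        focal_mean=used.focal_mean,
        focal_sd=used.focal_sd,
        group_parameters=used.grouped_item,
    )


def removal_decision(
    results,
    es_threshold: float = 1.0,
    min_variables: int = 2,
    extent_es: float = 0.5,
    extent_mass: float = 0.5,
) -> RemovalDecision:
    """Decide whether to drop an item given its DIF results across variables.

    The item is removed if (a) any signed maximum expected-score difference
    exceeds ``es_threshold`` in magnitude, (b) significant DIF occurs on at
    least ``min_variables`` grouping variables, or (c) for any significant
    result the expected-score difference exceeds ``extent_es`` over a trait
    region carrying at least ``extent_mass`` of the standard-normal
    population — DIF over a large part of the disability continuum.
    """
    results = list(results)
    if not results:
        raise ConfigurationError("removal_decision requires at least one DIF result")
    ids = {r.item_id for r in results}
    if len(ids) != 1:
        raise ConfigurationError(f"results refer to multiple items: {sorted(ids)}")
    item_id = results[0].item_id
    reasons = []

    significant = [r for r in results if r.classification != "none"]
    for r in significant:
        if abs(r.es_delta_max) > es_threshold:
            reasons.append(
                f"|ES_dmax| = {abs(r.es_delta_max):.2f} > {es_threshold:g} "
                f"on {r.variable_name!r}"
            )
    if len(significant) >= min_variables:
        names = sorted(r.variable_name for r in significant)
        reasons.append(
            f"significant DIF on {len(significant)} variables (>= {min_variables}): {names}"
        )
    for r in significant:
        step = np.diff(r.es_theta).mean() if r.es_theta.size > 1 else 0.0
        mass = float((norm.pdf(r.es_theta)[np.abs(r.es_curve) > extent_es]).sum() * step)
        if mass >= extent_mass:
            reasons.append(
                f"|ES| > {extent_es:g} over {100 * mass:.0f}% of the trait "
                f"distribution (>= {100 * extent_mass:.0f}%) on {r.variable_name!r}"
            )
    return RemovalDecision(item_id=item_id, remove=bool(reasons), reasons=reasons)
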