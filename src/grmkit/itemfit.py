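"""S-X^2-type goodness-of-fit for graded items, and a local-dependence screen.

The S-X^2 construction compares observed item-category counts with
model-expected counts conditional on the rest score (the scale total
excluding the studied item).  Expected cell proportions come from the
rest-score distribution, built by the generalized Lord–Wingersky
recursion over the anchor items' category probabilities and integrated
against the trait prior.  Sparse groups are collapsed — adjacent
rest-score groups merged toward the nearer tail until each holds a
minimum number of persons, then category cells within a group merged
until each expected count reaches a configurable floor — and the
statistic is the usual Pearson sum over retained cells against a
chi-square reference whose degrees of freedom subtract the studied
item's free parameters.

Local dependence is screened through pairwise correlations of
person-level residuals (observed code minus model-expected score at the
person's EAP estimate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import _likelihood as lk
from ._likelihood import MISSING
from .calibrate import ResponseMatrix
from .errors import InsufficientDataError
from .model import AbilityGrid, ScaleParameters, expected_item_score


@dataclass(frozen=True)
class ScoreDistribution:
    """P(summed score = s | theta) over a quadrature grid."""

    score_support: np.ndarray
    mass_given_theta: np.ndarray  # (n_theta, n_scores)

    def __post_init__(self) -> None:
        sums = self.mass_given_theta.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-10):
            raise ValueError("each theta row must sum to 1 within 1e-10")


@dataclass
class FitStatistic:
    item_id: str
    statistic: float
    df: int
    p_value: float
    misfit: bool
    collapsed_table: list  # per retained score group: list of (observed, expected)
    n_persons_used: int


def _score_recursion(prob_tables: list) -> np.ndarray:
    """Generalized Lord–Wingersky recursion: convolve category distributions."""
    dist = np.ones((prob_tables[0].shape[0], 1))
    for table in prob_tables:
        n_cat = table.shape[1]
        new = np.zeros((dist.shape[0], dist.shape[1] + n_cat - 1))
        for j in range(n_cat):
            new[:, j:j + dist.shape[1]] += dist * table[:, j:j + 1]
        dist = new
    return dist


def summed_score_distribution(
    items: ScaleParameters, grid: AbilityGrid
) -> ScoreDistribution:
    """Distribution of the scale's summed score at every grid point."""
    tables = [lk.prob_table(it.slope, it.thresholds, grid.points) for it in items.items]
    mass = _score_recursion(tables)
    # guard against accumulated round-off before validating the simplex
    mass = mass / mass.sum(axis=1, keepdims=True)
    return ScoreDistribution(np.arange(mass.shape[1]), mass)


def _collapse_rows(O: np.ndarray, E: np.ndarray, counts: np.ndarray, min_row_count: float):
    """Merge adjacent rest-score groups (toward the nearer tail) until every
    retained group holds at least ``min_row_count`` persons.

    Sparse category cells within a group are handled afterwards by
    :func:`_collapse_categories_in_row`; merging rows on their person
    counts (rather than on every category cell) keeps many score groups,
    which is what makes the chi-square reference behave.
    """
    O, E, counts = O.copy(), E.copy(), counts.copy()
    while O.shape[0] > 1 and counts.min() < min_row_count:
        r = int(np.argmin(counts))
        n_rows = O.shape[0]
        if r == 0:
            tgt = 1
        elif r == n_rows - 1:
            tgt = n_rows - 2
        else:
            tgt = r - 1 if r < n_rows / 2 else r + 1
        lo, hi = min(r, tgt), max(r, tgt)
        O[lo] += O[hi]
        E[lo] += E[hi]
        counts[lo] += counts[hi]
        O = np.delete(O, hi, axis=0)
        E = np.delete(E, hi, axis=0)
        counts = np.delete(counts, hi)
    return O, E, counts


def _collapse_categories_in_row(o_row: np.ndarray, e_row: np.ndarray, min_expected: float):
    """Merge adjacent category cells until each merged cell has expected
    count >= min_expected (a trailing sparse cell joins its neighbor)."""
    cells = []
    acc_o = acc_e = 0.0
    for o, e in zip(o_row, e_row):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            cells.append((acc_o, acc_e))
            acc_o = acc_e = 0.0
    if acc_e > 0 or acc_o > 0:
        if cells:
            last_o, last_e = cells.pop()
            cells.append((last_o + acc_o, last_e + acc_e))
        else:
            cells.append((acc_o, acc_e))
    return cells


def s_x2_item_fit(
    responses: ResponseMatrix,
    scale: ScaleParameters,
    item_id: str,
    grid: AbilityGrid | None = None,
    alpha: float = 0.01,
    min_expected: float = 1.0,
    min_rest_fraction: float = 1.0,
    min_row_count: float = 10.0,
) -> FitStatistic:
    """S-X^2 goodness-of-fit for one item of a calibrated scale.

    Rows missing the studied item are dropped; by default only rows with a
    complete rest score are used.  Lowering ``min_rest_fraction`` admits
    rows with partially observed rest items, whose rest scores use the
    items actually observed (expected proportions are computed per
    observed-item pattern, so observed and expected tables stay calibrated
    against each other).
    """
    if grid is None:
        grid = AbilityGrid.standard_normal()
    idx = scale.item_ids.index(item_id)
    item = scale.items[idx]
    rest_idx = [i for i in range(len(scale)) if i != idx]
    if not rest_idx:
        raise InsufficientDataError("S-X^2 requires at least one other item in the scale")
    codes = responses.codes
    observed_item = codes[:, idx] != MISSING
    rest_obs = codes[:, rest_idx] != MISSING
    enough_rest = rest_obs.mean(axis=1) >= min_rest_fraction
    keep = observed_item & enough_rest & (rest_obs.sum(axis=1) > 0)
    if keep.sum() < 3:
        raise InsufficientDataError(
            f"only {int(keep.sum())} usable rows for item {item_id!r}"
        )

    w = grid.weights
    tables = [lk.prob_table(it.slope, it.thresholds, grid.points) for it in scale.items]
    item_table = tables[idx]  # (Q, K)
    n_cat = item.n_categories
    max_rest = sum(scale.items[i].thresholds.size for i in rest_idx)

    O = np.zeros((max_rest + 1, n_cat))
    E = np.zeros((max_rest + 1, n_cat))
    counts = np.zeros(max_rest + 1)

    rows = np.where(keep)[0]
    patterns: dict = {}
    for s in rows:
        pat = tuple(i for i in rest_idx if codes[s, i] != MISSING)
        patterns.setdefault(pat, []).append(s)

    for pat, members in patterns.items():
        rest_mass = _score_recursion([tables[i] for i in pat])  # (Q, S_p + 1)
        denom = w @ rest_mass  # (S_p + 1,)
        numer = (w[:, None] * item_table).T @ rest_mass  # (K, S_p + 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            eprob = np.where(denom[None, :] > 0, numer / denom[None, :], 0.0)  # (K, S)
        member_scores = np.array(
            [int(codes[s, list(pat)].sum()) for s in members]
        )
        member_codes = codes[members, idx]
        for s_val, code in zip(member_scores, member_codes):
            O[s_val, code] += 1
        for s_val in np.unique(member_scores):
            n_here = int((member_scores == s_val).sum())
            E[s_val] += n_here * eprob[:, s_val]
            counts[s_val] += n_here

    nonempty = counts > 0
    O, E, counts = O[nonempty], E[nonempty], counts[nonempty]
    O, E, counts = _collapse_rows(O, E, counts, min_row_count)

    statistic = 0.0
    n_cells = 0
    table = []
    for r in range(O.shape[0]):
        cells = _collapse_categories_in_row(O[r], E[r], min_expected)
        table.append(cells)
        if len(cells) < 2:
            continue
        for o, e in cells:
            if e > 0:
                statistic += (o - e) ** 2 / e
        n_cells += len(cells) - 1  # row totals are fixed

    n_free = 1 + item.thresholds.size
    df = max(n_cells - n_free, 1)
    p = float(chi2.sf(statistic, df))
    return FitStatistic(
        item_id=item_id,
        statistic=float(statistic),
        df=int(df),
        p_value=p,
        misfit=bool(p < alpha),
        collapsed_table=table,
        n_persons_used=int(keep.sum()),
    )


@dataclass
class ResidualScreen:
    correlations: pd.DataFrame
    flagged: list = field(default_factory=list)
    threshold: float = 0.10


def model_implied_correlations(scale: ScaleParameters, grid: AbilityGrid) -> np.ndarray:
    """Pearson correlations between item scores implied by the fitted model.

    Computed by quadrature against the trait prior: the common trait is the
    only source of between-item covariance under local independence.
    """
    w = grid.weights
    means_given_theta = np.vstack(
        [expected_item_score(it, grid.points) for it in scale.items]
    )  # (k, Q)
    second_given_theta = np.vstack(
        [
            (lk.prob_table(it.slope, it.thresholds, grid.points)
             * np.arange(it.n_categories)[None, :] ** 2).sum(axis=1)
            for it in scale.items
        ]
    )
    m = means_given_theta @ w
    cov = (means_given_theta * w[None, :]) @ means_given_theta.T - np.outer(m, m)
    var = second_given_theta @ w - m**2
    np.fill_diagonal(cov, var)
    d = np.sqrt(np.maximum(var, 1e-12))
    return cov / np.outer(d, d)


def residual_correlation_screen(
    responses: ResponseMatrix,
    scale: ScaleParameters,
    grid: AbilityGrid | None = None,
    threshold: float = 0.10,
) -> ResidualScreen:
    """Excess item-pair correlation beyond what the common trait explains.

    For each pair the residual correlation is the observed Pearson
    correlation of the two items' codes minus the model-implied
    correlation through the latent trait; under local independence it is
    near zero.  Pairs with fewer than 3 pairwise-complete persons are
    reported as NaN; pairs at or above ``threshold`` in magnitude are
    flagged.
    """
    if grid is None:
        grid = AbilityGrid.standard_normal()
    codes = responses.codes.astype(float)
    codes[responses.codes == MISSING] = np.nan
    frame = pd.DataFrame(codes, columns=list(responses.items))
    observed = frame.corr(min_periods=3)
    implied = model_implied_correlations(scale, grid)
    corr = (observed - implied).clip(-1.0, 1.0)
    np.fill_diagonal(corr.values, 1.0)
    flagged = []
    ids = list(responses.items)
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            r = corr.iloc[a, b]
            if np.isfinite(r) and abs(r) >= threshold:
                flagged.append((ids[a], ids[b], float(r)))
    return ResidualScreen(correlations=corr, flagged=flagged, threshold=threshold)
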