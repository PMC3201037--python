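"""End-to-end questionnaire re-evaluation.

For each configured dimension the pipeline calibrates the graded
response model, tests every item's S-X^2 fit, runs hierarchical
likelihood-ratio DIF tests for every item x grouping variable, applies
the removal rule (large expected-score difference, DIF on multiple
variables, or DIF over a large part of the trait continuum), re-calibrates
dimensions that lost items and repeats their DIF tests, and finally
reports test-information curves and subject-separation reliability for
the retained item set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import io as gio
from .calibrate import (
    ResponseMatrix,
    apply_category_maps,
    eap_scores,
    fit_grm,
    subject_separation,
)
from .dif import SubgroupSpec, hierarchical_dif_test, removal_decision
from .errors import ConfigurationError
from .itemfit import s_x2_item_fit
from .model import AbilityGrid, scale_information


@dataclass(frozen=True)
class PipelineConfig:
    dimensions: dict  # dimension name -> ordered item ids
    dif_variables: tuple = ()
    reference_groups: dict = field(default_factory=dict)  # variable -> reference label
    alpha_dif: float = 0.01
    alpha_fit: float = 0.01
    es_removal_threshold: float = 1.0
    min_variables_for_removal: int = 2
    extent_es: float = 0.5
    extent_mass: float = 0.5
    grid_lo: float = -6.0
    grid_hi: float = 6.0
    grid_n: int = 61
    info_grid_lo: float = -4.0
    info_grid_hi: float = 4.0
    info_grid_step: float = 0.1
    es_grid_lo: float = -8.0
    es_grid_hi: float = 8.0
    es_grid_step: float = 0.01
    min_expected: float = 1.0
    compute_se: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dimensions:
            raise ConfigurationError("at least one dimension must be configured")
        seen: dict = {}
        for dim, items in self.dimensions.items():
            for it in items:
                if it in seen:
                    raise ConfigurationError(
                        f"item {it!r} assigned to both {seen[it]!r} and {dim!r}"
                    )
                seen[it] = dim
        for a, name in ((self.alpha_dif, "alpha_dif"), (self.alpha_fit, "alpha_fit")):
            if not 0 < a < 1:
                raise ConfigurationError(f"{name} must be in (0, 1)")
        object.__setattr__(self, "dif_variables", tuple(self.dif_variables))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yml", ".yaml"):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return cls(**payload)

    def grid(self) -> AbilityGrid:
        return AbilityGrid.standard_normal(self.grid_lo, self.grid_hi, self.grid_n)

    def info_grid(self) -> np.ndarray:
        return np.round(
            np.arange(self.info_grid_lo, self.info_grid_hi + 1e-9, self.info_grid_step), 10
        )

    def es_grid(self) -> np.ndarray:
        return np.round(
            np.arange(self.es_grid_lo, self.es_grid_hi + 1e-9, self.es_grid_step), 10
        )


@dataclass
class DimensionReport:
    dimension: str
    initial_calibration: object
    initial_fit: list
    initial_dif: list
    removals: list
    removed_items: list
    final_calibration: object
    final_dif: list
    information: object
    subject_separation: float
    errors: list = field(default_factory=list)


@dataclass
class PipelineReport:
    dimensions: dict
    metadata: dict


def _subgroups(groups: pd.DataFrame, responses: ResponseMatrix, config: PipelineConfig):
    specs = {}
    aligned = groups.loc[list(responses.persons)]
    for var in config.dif_variables:
        if var not in aligned.columns:
            raise ConfigurationError(f"grouping variable {var!r} not in groups table")
        labels = tuple(aligned[var].astype(str))
        ref = config.reference_groups.get(var) or sorted(set(labels))[0]
        specs[var] = SubgroupSpec(var, labels, ref)
    return specs


def _dif_pass(sub, specs, scale, grid, alpha, es_grid, errors, stage):
    results = []
    for var, spec in specs.items():
        for item_id in scale.item_ids:
            try:
                results.append(
                    hierarchical_dif_test(sub, spec, scale, item_id, grid, alpha, es_grid)
                )
            except Exception as exc:  # recorded, not fatal to other cells
                errors.append(f"{stage} DIF {item_id} x {var}: {exc}")
    return results


def run_full_reevaluation(
    responses: ResponseMatrix,
    groups: pd.DataFrame | None,
    config: PipelineConfig,
) -> PipelineReport:
    """Execute calibration, item fit, DIF testing, removal and re-calibration.

    ``groups`` may be None when no DIF variables are configured.  The run
    is deterministic given the same inputs and configuration.
    """
    grid = config.grid()
    es_grid = config.es_grid()
    info_grid = config.info_grid()
    specs = _subgroups(groups, responses, config) if config.dif_variables else {}

    reports: dict = {}
    for dim, item_ids in config.dimensions.items():
        errors: list = []
        sub = responses.subset(item_ids)
        calib = fit_grm(sub, grid, compute_se=config.compute_se, dimension_name=dim)
        recoded = apply_category_maps(sub, calib.category_maps)

        fit_stats = []
        for item_id in item_ids:
            try:
                fit_stats.append(
                    s_x2_item_fit(recoded, calib.scale, item_id, grid,
                                  config.alpha_fit, config.min_expected)
                )
            except Exception as exc:
                errors.append(f"item fit {item_id}: {exc}")

        dif_results = _dif_pass(recoded, specs, calib.scale, grid,
                                config.alpha_dif, es_grid, errors, "initial")

        removals = []
        removed = []
        for item_id in item_ids:
            per_item = [r for r in dif_results if r.item_id == item_id]
            if not per_item:
                continue
            decision = removal_decision(
                per_item,
                es_threshold=config.es_removal_threshold,
                min_variables=config.min_variables_for_removal,
                extent_es=config.extent_es,
                extent_mass=config.extent_mass,
            )
            removals.append(decision)
            if decision.remove:
                removed.append(item_id)

        if removed:
            kept = [i for i in item_ids if i not in removed]
            if len(kept) < 2:
                errors.append(f"dimension {dim}: too few items left after removal")
                final_calib, final_dif, final_recoded = calib, [], recoded
            else:
                final_sub = responses.subset(kept)
                final_calib = fit_grm(final_sub, grid,
                                      compute_se=config.compute_se, dimension_name=dim)
                final_recoded = apply_category_maps(final_sub, final_calib.category_maps)
                final_dif = _dif_pass(final_recoded, specs, final_calib.scale, grid,
                                      config.alpha_dif, es_grid, errors, "final")
        else:
            final_calib, final_dif, final_recoded = calib, [], recoded

        info = scale_information(final_calib.scale, info_grid, prior_included=True)
        final_items = final_calib.scale.item_ids
        posteriors = eap_scores(
            final_recoded.subset(final_items), final_calib.scale, grid)
        separation = subject_separation(posteriors)

        reports[dim] = DimensionReport(
            dimension=dim,
            initial_calibration=calib,
            initial_fit=fit_stats,
            initial_dif=dif_results,
            removals=removals,
            removed_items=removed,
            final_calibration=final_calib,
            final_dif=final_dif,
            information=info,
            subject_separation=separation,
            errors=errors,
        )

    config_hash = hashlib.sha256(
        json.dumps(_config_payload(config), sort_keys=True).encode()
    ).hexdigest()[:16]
    metadata = {
        "seed": config.seed,
        "config_hash": config_hash,
        "grmkit_version": _version,
    }
    return PipelineReport(dimensions=reports, metadata=metadata)


def _config_payload(config: PipelineConfig) -> dict:
    payload = asdict(config)
    payload["dimensions"] = {k: list(v) for k, v in payload["dimensions"].items()}
    payload["dif_variables"] = list(payload["dif_variables"])
    return payload


# --------------------------------------------------------------------------
# report serialization
# --------------------------------------------------------------------------


def _fit_row(f) -> dict:
    return {
        "item_id": f.item_id,
        "statistic": round(float(f.statistic), 6),
        "df": int(f.df),
        "p_value": round(float(f.p_value), 6),
        "misfit": bool(f.misfit),
        "n_persons_used": int(f.n_persons_used),
    }


def _dif_row(r) -> dict:
    g = r.group_parameters
    return {
        "item_id": r.item_id,
        "variable": r.variable_name,
        "g2_slope": round(float(r.g2_slope), 6),
        "df_slope": r.df_slope,
        "p_slope": round(float(r.p_slope), 6),
        "g2_thresholds": None if r.g2_thresholds is None else round(float(r.g2_thresholds), 6),
        "df_thresholds": r.df_thresholds,
        "p_thresholds": None if r.p_thresholds is None else round(float(r.p_thresholds), 6),
        "classification": r.classification,
        "es_delta_max": round(float(r.es_delta_max), 6),
        "theta_at_max": round(float(r.theta_at_max), 6),
        "focal_mean": round(float(r.focal_mean), 6),
        "focal_sd": round(float(r.focal_sd), 6),
        "slope_reference": round(float(g.group_a.slope), 6),
        "slope_focal": round(float(g.group_b.slope), 6),
        "thresholds_reference": [round(float(x), 6) for x in g.group_a.thresholds],
        "thresholds_focal": [round(float(x), 6) for x in g.group_b.thresholds],
        "constraint": g.constraint,
    }


def _calib_payload(c) -> dict:
    return {
        "dimension": c.scale.dimension_name,
        "items": [
            {
                "item_id": it.item_id,
                "slope": round(float(it.slope), 6),
                "thresholds": [round(float(b), 6) for b in it.thresholds],
            }
            for it in c.scale.items
        ],
        "log_likelihood": round(float(c.log_likelihood), 6),
        "n_iterations": int(c.n_iterations),
        "converged": bool(c.converged),
    }


def report_payload(report: PipelineReport) -> dict:
    dims = {}
    for dim, r in report.dimensions.items():
        dims[dim] = {
            "initial_calibration": _calib_payload(r.initial_calibration),
            "initial_fit": [_fit_row(f) for f in r.initial_fit],
            "initial_dif": [_dif_row(d) for d in r.initial_dif],
            "removals": [
                {"item_id": d.item_id, "remove": d.remove, "reasons": d.reasons}
                for d in r.removals
            ],
            "removed_items": list(r.removed_items),
            "final_calibration": _calib_payload(r.final_calibration),
            "final_dif": [_dif_row(d) for d in r.final_dif],
            "information_max": round(float(r.information.max_information), 6),
            "information_theta_at_max": round(float(r.information.theta_at_max), 6),
            "se_min": round(float(r.information.standard_error.min()), 6),
            "subject_separation": round(float(r.subject_separation), 6),
            "errors": list(r.errors),
        }
    return {"dimensions": dims, "metadata": report.metadata}


def write_report(report: PipelineReport, outdir) -> None:
    """Emit report.json plus per-dimension CSV tables and a run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = report_payload(report)
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    log_lines = [f"grmkit {_version} seed={report.metadata['seed']} "
                 f"config_hash={report.metadata['config_hash']}"]
    for dim, r in report.dimensions.items():
        safe = dim.replace(" ", "_").lower()
        gio.write_parameters(r.final_calibration.scale, outdir / f"params_{safe}.csv")
        if r.initial_fit:
            pd.DataFrame([_fit_row(f) for f in r.initial_fit]).to_csv(
                outdir / f"fit_{safe}.csv", index=False)
        dif_rows = [_dif_row(d) for d in r.initial_dif + r.final_dif]
        if dif_rows:
            pd.DataFrame(dif_rows).to_csv(outdir / f"dif_{safe}.csv", index=False)
        gio.write_information_curve(r.information, outdir / f"info_{safe}.csv")
        for d in r.removals:
            if d.remove:
                log_lines.append(f"{dim}: removed {d.item_id}: " + "; ".join(d.reasons))
        for err in r.errors:
            log_lines.append(f"{dim}: WARNING {err}")
    (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")
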