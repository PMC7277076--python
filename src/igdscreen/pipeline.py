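"""End-to-end orchestration: simulate -> estimate -> reduce -> score -> screen.

``run_validation`` executes the full validation analysis on a dataset
(simulated by default, or read from CSV): polychoric correlations and the
second-order CFA of the 34-item form, one-factor comparison, top-3 item
reduction, 27-item CFA, reliability and criterion-validity statistics,
ROC/AUC, the cutoff scan against the DSM-5 reference, the optimal-cutoff
selection, and between-group contrasts at the selected cutoff.  Every
stage is deterministic given the seed; results serialize to CSV/JSON.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cfa import (CFAResult, MeasurementModel, fit_independence_baseline,
                  fit_indices, fit_model)
from .items import ScaleDefinition, select_top_items, sum_score
from .polychoric import polychoric_matrix
from .reference import FACTOR_MAP
from .screening import (classify, roc_auc, round_half_up, scan_cutoffs,
                        select_optimal_cutoff)
from .synthetic import (GeneratorConfig, ItemResponseMatrix, SyntheticDataset,
                        generate_dataset)
from .validity import (chi_square_independence, cronbach_alpha, kr20,
                       mann_whitney_u, pearson_r, two_sample_t)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ValidationReport", "read_responses", "run_validation"]

_ITEM_PREFIXES = tuple(FACTOR_MAP)   # F1..F9
_DSM_COLS = [f"dsm_{k}" for k in range(1, 10)]
DSM_CUTOFF = 5


@dataclass
class PipelineConfig:
    """Everything a full run needs; mirrors the CLI flags."""

    n_persons: int = 464
    seed: int = 7
    responses_csv: str | None = None      # if set, load instead of simulating
    output_dir: str | None = None
    estimator: str = "dwls"
    top_k: int = 3
    scan_min: int = 1
    scan_max: int = 54
    min_sens: float = 75.0
    min_spec: float = 75.0
    percent_digits: int = 1
    coef_digits: int = 2

    def __post_init__(self) -> None:
        if self.scan_max < self.scan_min:
            raise ValueError("empty cutoff scan range")
        if self.responses_csv is not None and not Path(self.responses_csv).exists():
            raise FileNotFoundError(self.responses_csv)


@dataclass
class ValidationReport:
    """All result tables of one run, serializable to CSV and JSON."""

    cfa_table: pd.DataFrame            # item/loading layout, 34- and 27-item
    fit_table: pd.DataFrame            # fit indices per model
    reliability_table: pd.DataFrame    # construct correlations, alpha diagonal
    scan_table: pd.DataFrame           # per-cutoff efficacy rows
    selection: dict                    # audit trail and selected cutoff
    contrast_table: pd.DataFrame       # between-group statistics
    summary: dict                      # scalar headline numbers
    run_info: dict

    def to_json(self) -> str:
        payload = {
            "run_info": self.run_info,
            "summary": self.summary,
            "cfa": self.cfa_table.to_dict(orient="records"),
            "fit": self.fit_table.to_dict(orient="records"),
            "reliability": self.reliability_table.to_dict(orient="records"),
            "scan": self.scan_table.to_dict(orient="records"),
            "selection": self.selection,
            "contrasts": self.contrast_table.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cfa_table.to_csv(out / "cfa_loadings.csv", index=False)
        self.fit_table.to_csv(out / "fit_indices.csv", index=False)
        self.reliability_table.to_csv(out / "reliability_validity.csv", index=False)
        self.scan_table.to_csv(out / "cutoff_scan.csv", index=False)
        self.contrast_table.to_csv(out / "group_contrasts.csv", index=False)
        (out / "report.json").write_text(self.to_json(), encoding="utf-8")
        with open(out / "run.log", "w", encoding="utf-8") as fh:
            for key, val in self.run_info.items():
                fh.write(f"{key}: {val}\n")


def read_responses(path):
    """Load a generator-format CSV back into responses plus criteria.

    Validates item codes (0/1/2) and DSM codes (0/1), naming the offending
    row and column on failure; rows with missing item responses are logged
    and dropped (listwise).
    """
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    item_cols = [c for c in frame.columns
                 if c.split("_")[0] in _ITEM_PREFIXES and not c.startswith("dsm")]
    if not item_cols:
        raise ValueError(f"{path}: no item columns found")
    unknown = [c for c in frame.columns
               if c not in item_cols + _DSM_COLS
               + ["person_id", "ia", "dep", "freq", "spend", "device"]]
    if unknown:
        raise ValueError(f"{path}: unknown columns {unknown}")

    missing = frame[item_cols].isna().any(axis=1)
    if missing.any():
        logger.warning("dropping %d rows with missing item responses (listwise)",
                       int(missing.sum()))
        frame = frame.loc[~missing].reset_index(drop=True)
    if frame.empty:
        raise ValueError(f"{path}: all rows dropped")

    for col in item_cols + [c for c in _DSM_COLS if c in frame.columns]:
        allowed = (0, 1, 2) if col in item_cols else (0, 1)
        vals = frame[col]
        bad = ~vals.isin(allowed)
        if bad.any():
            row = int(frame.index[bad][0])
            raise ValueError(
                f"{path}: out-of-range code {vals[bad].iloc[0]!r} in "
                f"column {col!r}, row {row}")

    factor_map = {f: [c for c in item_cols if c.startswith(f + "_")]
                  for f in _ITEM_PREFIXES}
    factor_map = {f: items for f, items in factor_map.items() if items}
    responses = ItemResponseMatrix(data=frame[item_cols].astype(np.int8),
                                   factor_map=factor_map)
    criteria = frame.drop(columns=item_cols)
    return responses, criteria


def _round_frame(frame: pd.DataFrame, digits: int = 3) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(digits)
    return out


def _fit_battery(pm, factor_map, estimator, n):
    spec = MeasurementModel(factor_map=factor_map)
    second = fit_model(pm, spec, estimator=estimator)
    onef = fit_model(pm, MeasurementModel(factor_map=factor_map,
                                          model_kind="one_factor"),
                     estimator=estimator)
    base = fit_independence_baseline(pm, estimator=estimator)
    return {
        "second_order": (second, fit_indices(second, base, n)),
        "one_factor": (onef, fit_indices(onef, base, n)),
    }


def _reliability_block(data: pd.DataFrame, scale: ScaleDefinition,
                       criteria: pd.DataFrame, score: pd.Series) -> pd.DataFrame:
    """Construct x construct correlations with alpha on the diagonal."""
    subs = {f: data[items].sum(axis=1) for f, items in scale.items_by_factor.items()}
    cols = {"total": score, **subs}
    rows = []
    names = list(cols)
    for i, a in enumerate(names):
        rec = {"construct": a,
               "alpha": cronbach_alpha(data[scale.items if a == "total"
                                            else scale.items_by_factor[a]])}
        for b in names[:i]:
            rec[b] = pearson_r(cols[a], cols[b])
        rows.append(rec)
    for crit, series in (("dsm_sum", criteria[_DSM_COLS].sum(axis=1)),
                         ("ia", criteria["ia"]), ("freq", criteria["freq"]),
                         ("dep", criteria["dep"])):
        rec = {"construct": crit, "alpha": np.nan}
        for b in names:
            rec[b] = pearson_r(cols[b], series)
        rows.append(rec)
    return pd.DataFrame(rows)


def _contrasts(score, criteria: pd.DataFrame, cutoff: int) -> pd.DataFrame:
    labels, sizes = classify(score, cutoff)
    pos, neg = labels == 1, labels == 0
    recs = []
    for name in ("ia", "dep"):
        t = two_sample_t(criteria[name][pos], criteria[name][neg])
        recs.append({"variable": name, "test": "t",
                     "mean_positive": float(criteria[name][pos].mean()),
                     "mean_negative": float(criteria[name][neg].mean()),
                     "statistic": t.statistic, "df": t.df, "pvalue": t.pvalue})
    dsm_sum = criteria[_DSM_COLS].sum(axis=1)
    t = two_sample_t(dsm_sum[pos], dsm_sum[neg])
    recs.append({"variable": "dsm_sum", "test": "t",
                 "mean_positive": float(dsm_sum[pos].mean()),
                 "mean_negative": float(dsm_sum[neg].mean()),
                 "statistic": t.statistic, "df": t.df, "pvalue": t.pvalue})
    for name in ("freq", "spend"):
        u = mann_whitney_u(criteria[name][pos], criteria[name][neg])
        recs.append({"variable": name, "test": "U",
                     "statistic": u.u_first, "statistic_other": u.u_second,
                     "pvalue": u.pvalue})
    table = pd.crosstab(labels, criteria["device"])
    chi = chi_square_independence(table.to_numpy())
    recs.append({"variable": "device", "test": "chi2",
                 "statistic": chi.statistic, "df": chi.df, "pvalue": chi.pvalue})
    return pd.DataFrame(recs)


def run_validation(config: PipelineConfig | None = None) -> ValidationReport:
    """Run the full validation pipeline; deterministic given the seed."""
    config = config if config is not None else PipelineConfig()

    if config.responses_csv is not None:
        responses, criteria = read_responses(config.responses_csv)
        dataset = None
    else:
        dataset = generate_dataset(GeneratorConfig(n_persons=config.n_persons,
                                                   seed=config.seed))
        responses = dataset.responses
        criteria = pd.concat([dataset.dsm_items,
                              dataset.ia_score.rename("ia"),
                              dataset.depression_score.rename("dep"),
                              dataset.gameplay_frequency.rename("freq"),
                              dataset.expenditure_band.rename("spend"),
                              dataset.device.rename("device")], axis=1)
    n = responses.n_persons

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    pm_full = stage("polychoric_34", polychoric_matrix, responses)
    fits_full = stage("cfa_34", _fit_battery, pm_full, responses.factor_map,
                      config.estimator, n)
    scale = stage("reduce", select_top_items, fits_full["second_order"][0],
                  config.top_k)
    reduced = ItemResponseMatrix(data=responses.data[scale.items],
                                 factor_map=scale.items_by_factor)
    pm_27 = stage("polychoric_reduced", polychoric_matrix, reduced)
    fits_27 = stage("cfa_reduced", _fit_battery, pm_27, scale.items_by_factor,
                    config.estimator, n)
    score = stage("score", sum_score, responses, scale)

    reliability = stage("reliability", _reliability_block, responses.data,
                        scale, criteria, score)
    kr = kr20(criteria[_DSM_COLS])

    reference = (criteria[_DSM_COLS].sum(axis=1) >= DSM_CUTOFF).astype(int)
    auc, _ = stage("roc", roc_auc, score, reference)
    scan = stage("scan", scan_cutoffs, score, reference,
                 range(config.scan_min, config.scan_max + 1))
    selection = stage("select", select_optimal_cutoff, scan,
                      config.min_sens, config.min_spec)

    if selection.selected is not None:
        contrasts = stage("contrasts", _contrasts, score, criteria,
                          selection.selected)
        _, sizes = classify(score, selection.selected)
        positive_pct = round_half_up(100.0 * sizes["positive"] / n, 1)
    else:
        contrasts = pd.DataFrame()
        positive_pct = np.nan

    cfa_rows = []
    for tag, fits in (("34-item", fits_full), ("27-item", fits_27)):
        tab = fits["second_order"][0].model.to_table()
        tab.insert(0, "scale", tag)
        cfa_rows.append(tab)
    cfa_table = _round_frame(pd.concat(cfa_rows, ignore_index=True))

    fit_rows = []
    for tag, fits in (("34-item", fits_full), ("27-item", fits_27)):
        for kind, (res, fi) in fits.items():
            fit_rows.append({"scale": tag, "model": kind,
                             "chi_square": fi.chi_square, "df": fi.df,
                             "cfi": fi.cfi, "tli": fi.tli, "rmsea": fi.rmsea,
                             "rmsea_lo": fi.rmsea_ci[0], "rmsea_hi": fi.rmsea_ci[1],
                             "srmr": fi.srmr, "converged": res.converged})
    fit_table = _round_frame(pd.DataFrame(fit_rows))

    selection_payload = {
        "selected_cutoff": selection.selected,
        "candidates": selection.candidates,
        "kappa_max_set": selection.kappa_max_set,
        "audit": selection.audit,
        "no_admissible_cutoff": selection.selected is None,
    }
    summary = {
        "n_persons": int(n),
        "n_items_full": len(responses.items),
        "n_items_reduced": scale.n_items,
        "alpha_total": round(float(reliability.iloc[0]["alpha"]),
                             config.coef_digits + 1),
        "kr20_dsm": round(float(kr), config.coef_digits + 1),
        "auc": round(float(auc), config.coef_digits + 1),
        "dsm_prevalence_pct": round_half_up(100.0 * reference.mean(), 1),
        "selected_cutoff": selection.selected,
        "positive_proportion_pct": positive_pct,
    }
    run_info = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "estimator": config.estimator,
        "n_persons": int(n),
        "scan_range": f"{config.scan_min}-{config.scan_max}",
        "min_sens": config.min_sens,
        "min_spec": config.min_spec,
        "collapsed_items": list(pm_full.thresholds.collapsed),
    }
    report = ValidationReport(
        cfa_table=cfa_table, fit_table=fit_table,
        reliability_table=_round_frame(pd.DataFrame(reliability)),
        scan_table=scan.to_frame(),
        selection=selection_payload,
        contrast_table=_round_frame(contrasts),
        summary=summary, run_info=run_info)
    if config.output_dir is not None:
        report.write(config.output_dir)
    if dataset is not None and config.output_dir is not None:
        dataset.write_csv(Path(config.output_dir) / "dataset.csv")
    return report
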