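"""Bootstrap model-stability assessment.

For one experimental setting the engine draws B with-replacement resamples
of the prepared cohort; within each resample it reruns collinearity
filtering and feature selection, fits the clinical / radiomics / combined
Cox models, and evaluates every model both on the resample ("apparent")
and on the original cohort ("test") — the test evaluation is the
optimism-adjusted value.  Stability statistics summarise the resample
distribution: per-metric means with percentile 95% confidence intervals,
the feature co-occurrence percentage (how often the modal feature set was
selected), and the family of 1-year calibration curves.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import BIN_COUNTS, FeatureTable
from .ist import IST_NAMES
from .metrics import METRIC_NAMES, calibration_curve_1yr, evaluate_model
from .selection import (FS_METHODS, build_design, collinearity_filter,
                        fit_model, select_features)

MBS_VALUES = (5, 10, 15)
DEFAULT_B = 1000
MIN_SUCCESSFUL_RESAMPLES = 10


@dataclass(frozen=True)
class ExperimentSetting:
    """One cell of the IST x bin-count x ComBat x MBS grid (96 cells)."""

    ist: str
    bin_count: int
    combat: bool
    mbs: int

    def __post_init__(self):
        if self.ist not in IST_NAMES:
            raise ValueError(f"unknown IST {self.ist!r}")
        if self.bin_count not in BIN_COUNTS:
            raise ValueError(f"unknown bin count {self.bin_count}")
        if self.mbs not in MBS_VALUES:
            raise ValueError(f"unknown minimum batch size {self.mbs}")

    @property
    def label(self) -> str:
        cb = "combat" if self.combat else "nocombat"
        return f"{self.ist}_bin{self.bin_count}_{cb}_mbs{self.mbs}"


@dataclass
class BootstrapSummary:
    """Aggregated stability statistics for one setting."""

    setting: ExperimentSetting | None
    n_resamples: int
    n_failures: int
    metrics: pd.DataFrame        # rows (model_type, fs_method, metric)
    cooccurrence: dict           # fs_method -> percentage
    curves: dict = field(default_factory=dict)

    def ci_width(self, model_type: str, fs_method: str, metric: str) -> float:
        row = self.metrics.loc[(model_type, fs_method, metric)]
        return float(row["hi"] - row["lo"])


# --------------------------------------------------------------------------

def _eval_pair(model, design_fit, surv_fit, design_orig, surv_orig,
               store_curve: bool, evaluate_apparent: bool = True):
    """Apparent and test MetricSets (plus optional test calibration curve)."""
    cols = model.predictor_names
    apparent = None
    if evaluate_apparent:
        apparent = evaluate_model(model, design_fit[cols].to_numpy(float),
                                  surv_fit["time"], surv_fit["event"])
    test = evaluate_model(model, design_orig[cols].to_numpy(float),
                          surv_orig["time"], surv_orig["event"])
    curve = None
    if store_curve:
        curve = calibration_curve_1yr(
            model, design_orig[cols].to_numpy(float),
            surv_orig["time"], surv_orig["event"])
    return apparent, test, curve


def bootstrap_run(
    features: FeatureTable,
    clinical_design: pd.DataFrame,
    survival: pd.DataFrame,
    B: int = 100,
    seed: int = 0,
    fs_methods=FS_METHODS,
    collinearity_threshold: float = 0.7,
    rsf_trees: int = 100,
    store_curves: bool = True,
    include_original: bool = True,
    evaluate_apparent: bool = True,
    model_types: tuple = ("radiomics", "combined"),
    max_redraws: int = 100,
) -> list[dict]:
    """Run the bootstrap for one prepared cohort.

    ``features``, ``clinical_design`` and ``survival`` must already be
    aligned on the same patients (post-IST, extraction, ICC and MBS
    filtering and — if the setting asks for it — ComBat adjustment).
    Resamples with zero events are redrawn (counted in the record).  A
    model whose fit fails is recorded as failed, never silently dropped.

    Returns one record per resample plus, if ``include_original``, a
    record with ``resample_id == "original"`` holding the full-data fits.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    ids = list(features.patient_ids)
    if list(clinical_design.index) != ids or list(survival.index) != ids:
        raise ValueError("inputs not aligned on the same patients")
    rng = np.random.default_rng(seed)
    n = len(ids)
    records: list[dict] = []

    def run_one(res_ids, surv_fit, resample_id):
        feat_fit = features.subset(patient_ids=res_ids)
        feat_fit.values.index = pd.RangeIndex(len(res_ids))
        clin_fit = clinical_design.loc[res_ids].set_axis(
            pd.RangeIndex(len(res_ids)))
        surv_fit = surv_fit.set_axis(pd.RangeIndex(len(res_ids)))
        rec: dict = {"resample_id": resample_id, "failures": [],
                     "models": {}, "selected": {}}
        # clinical-only model, shared by all selection strategies
        try:
            m_clin = fit_model(clin_fit, surv_fit["time"], surv_fit["event"])
            app, tst, curve = _eval_pair(m_clin, clin_fit, surv_fit,
                                         clinical_design, survival,
                                         store_curves, evaluate_apparent)
            rec["models"][("clinical", None)] = {
                "apparent": app, "test": tst, "curve": curve,
                "n_predictors": m_clin.k_parameters}
        except Exception as exc:  # noqa: BLE001 - recorded, not hidden
            rec["failures"].append(("clinical", None, str(exc)))
        try:
            filt = collinearity_filter(feat_fit, collinearity_threshold)
        except Exception as exc:  # noqa: BLE001
            rec["failures"].append(("collinearity", None, str(exc)))
            records.append(rec)
            return
        for fs in fs_methods:
            try:
                sel = select_features(filt, surv_fit["time"],
                                      surv_fit["event"], fs,
                                      rsf_trees=rsf_trees, seed=seed)
            except Exception as exc:  # noqa: BLE001
                rec["failures"].append((fs, "selection", str(exc)))
                continue
            rec["selected"][fs] = frozenset(sel)
            for model_type in model_types:
                if not sel and model_type == "radiomics":
                    rec["failures"].append((fs, "radiomics", "empty selection"))
                    continue
                try:
                    design_fit = build_design(model_type, clin_fit,
                                              feat_fit, sel)
                    m = fit_model(design_fit, surv_fit["time"],
                                  surv_fit["event"])
                    design_orig = build_design(model_type, clinical_design,
                                               features, sel)
                    app, tst, curve = _eval_pair(
                        m, design_fit, surv_fit, design_orig, survival,
                        store_curves and model_type == "combined",
                        evaluate_apparent)
                    rec["models"][(model_type, fs)] = {
                        "apparent": app, "test": tst, "curve": curve,
                        "n_predictors": m.k_parameters}
                except Exception as exc:  # noqa: BLE001
                    rec["failures"].append((fs, model_type, str(exc)))
        records.append(rec)

    if include_original:
        run_one(ids, survival.copy(), "original")
    for b in range(B):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            res_ids = [ids[i] for i in idx]
            surv_fit = survival.iloc[idx]
            if surv_fit["event"].sum() > 0:
                break
        else:
            raise RuntimeError("could not draw a resample with events")
        rec_before = len(records)
        run_one(res_ids, surv_fit.copy(), b)
        records[rec_before]["n_redraws"] = attempt
    return records


# --------------------------------------------------------------------------
# summaries

def feature_cooccurrence(selected_sets) -> float:
    """Percentage of non-empty selections equal to the modal feature set."""
    non_empty = [frozenset(s) for s in selected_sets if s]
    if not non_empty:
        raise ValueError("all selections empty")
    _, count = Counter(non_empty).most_common(1)[0]
    return 100.0 * count / len(non_empty)


def summarise(records, setting: ExperimentSetting | None = None,
              which: str = "test") -> BootstrapSummary:
    """Aggregate bootstrap records into means, 95% CIs and co-occurrence.

    ``which`` selects the evaluation used for the metric summaries:
    "test" (fit on resample, evaluated on the original cohort — the
    optimism-adjusted value) or "apparent".
    """
    boot = [r for r in records if r["resample_id"] != "original"]
    n_fail = sum(len(r["failures"]) > 0 for r in boot)
    ok = boot
    n_success = len([r for r in boot if r["models"]])
    if n_success < MIN_SUCCESSFUL_RESAMPLES:
        raise ValueError(
            f"only {n_success} successful resamples (< {MIN_SUCCESSFUL_RESAMPLES})")
    rows = []
    keys = sorted({k for r in ok for k in r["models"]},
                  key=lambda k: (k[0], k[1] or ""))
    for key in keys:
        model_type, fs = key
        for metric in METRIC_NAMES:
            vals = np.array([
                getattr(r["models"][key][which], metric)
                for r in ok if key in r["models"]
            ], dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                continue
            lo, hi = np.percentile(vals, [2.5, 97.5])
            rows.append({
                "model_type": model_type, "fs_method": fs or "none",
                "metric": metric, "mean": vals.mean(),
                "lo": lo, "hi": hi, "n": len(vals),
            })
    metrics = pd.DataFrame(rows).set_index(["model_type", "fs_method", "metric"])
    cooc = {}
    for fs in {fs for r in ok for fs in r.get("selected", {})}:
        sets = [r["selected"][fs] for r in ok if fs in r.get("selected", {})]
        try:
            cooc[fs] = feature_cooccurrence(sets)
        except ValueError:
            cooc[fs] = np.nan
    curves: dict = {}
    for key in keys:
        fam = [r["models"][key]["curve"] for r in boot
               if key in r["models"] and r["models"][key]["curve"] is not None]
        orig = next(
            (r["models"][key]["curve"] for r in records
             if r["resample_id"] == "original" and key in r["models"]
             and r["models"][key]["curve"] is not None), None)
        if fam or orig is not None:
            curves[key] = {"resamples": fam, "original": orig}
    return BootstrapSummary(
        setting=setting, n_resamples=len(boot), n_failures=n_fail,
        metrics=metrics, cooccurrence=cooc, curves=curves,
    )


def tidy_metrics(summary: BootstrapSummary) -> pd.DataFrame:
    """One row per model x fs_method x metric, with the setting label."""
    df = summary.metrics.reset_index()
    if summary.setting is not None:
        for f in ("ist", "bin_count", "combat", "mbs"):
            df.insert(0, f, getattr(summary.setting, f))
    return df


# --------------------------------------------------------------------------
# clinical-centred scaled heatmap transform

def scale_relative(metric_values: pd.DataFrame,
                   clinical_reference: pd.Series) -> pd.DataFrame:
    """Centre on the clinical model and scale by the across-model SD.

    ``metric_values`` has one row per model and one column per
    experimental setting; ``clinical_reference`` gives the clinical-only
    value per setting.  Each column is transformed to
    (value - clinical) / SD(models in that column) (sample SD, ddof=1),
    so the clinical model itself maps to 0 and values are comparable
    across settings.  Columns with zero SD are returned unscaled and
    flagged in ``.attrs["zero_sd_settings"]``.
    """
    if metric_values.shape[0] < 2:
        raise ValueError("need >= 2 models per setting to define the SD")
    out = {}
    zero_sd = []
    for col in metric_values.columns:
        v = metric_values[col].astype(float)
        sd = v.std(ddof=1)
        centred = v - float(clinical_reference[col])
        if sd == 0 or not np.isfinite(sd):
            zero_sd.append(col)
            out[col] = centred
        else:
            out[col] = centred / sd
    res = pd.DataFrame(out)
    res.attrs["zero_sd_settings"] = zero_sd
    return res


def curve_spread(curve_family, grid_points=None) -> float:
    """Calibration instability: mean inter-resample SD of observed risk.

    Curves are interpolated onto a common predicted-risk grid (the central
    80% of the pooled predictions by default) and the SD of the observed
    values across resamples is averaged over the grid.
    """
    curves = [c for c in curve_family if c is not None and not c["flags"]]
    if len(curves) < 2:
        raise ValueError("need >= 2 curves")
    if grid_points is None:
        allp = np.concatenate([c["predicted"] for c in curves])
        grid_points = np.linspace(*np.quantile(allp, [0.1, 0.9]), 25)
    obs = np.stack([
        np.interp(grid_points, c["predicted"], c["observed"])
        for c in curves
    ])
    return float(obs.std(axis=0, ddof=1).mean())
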