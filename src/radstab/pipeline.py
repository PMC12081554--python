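"""End-to-end orchestration over the experimental-setting grid.

The full grid crosses four intensity standardisation techniques, four bin
counts, ComBat on/off and three minimum batch sizes — 96 settings.  For
each requested setting the pipeline runs, in order: IST -> feature
extraction at the setting's bin count -> ICC segmentation-robustness
filter -> minimum-batch-size filter -> optional ComBat -> bootstrap ->
summaries, and writes tidy CSV results plus a manifest recording the
configuration hash, seeds and per-stage patient counts.

Two cohort modes exist.  ``image`` mode starts from phantom volumes and
exercises every stage.  ``feature`` mode starts from a simulated feature
table (the location-scale batch-effect generator); the IST and bin-count
axes then only label the settings, since no images exist to standardise —
this is the mode used for the harmonisation / stability experiments,
where image processing is not the quantity under study.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .combat import batch_covariate_screen, combat_adjust_by_sequence, filter_by_mbs
from .features import BIN_COUNTS, SEQUENCES, FeatureTable, extract_cohort, icc_filter
from .ist import IST_NAMES, apply_ist
from .selection import FS_METHODS
from .stability import (MBS_VALUES, BootstrapSummary, ExperimentSetting,
                        bootstrap_run, summarise, tidy_metrics)
from .synthetic import CohortConfig, clinical_design, generate_feature_cohort, generate_phantom_volumes

log = logging.getLogger("radstab")


@dataclass
class RunConfig:
    """Configuration of one experiment run."""

    mode: str = "feature"                  # "feature" or "image"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    settings: list[ExperimentSetting] | None = None   # None = full grid
    B: int = 100
    seed: int = 0
    out_dir: str | None = None
    fs_methods: tuple = FS_METHODS
    rsf_trees: int = 100
    icc_threshold: float = 0.8
    collinearity_threshold: float = 0.7
    covariate_alpha: float = 0.05          # screen for including age
    store_curves: bool = True
    evaluate_apparent: bool = True
    model_types: tuple = ("radiomics", "combined")
    bootstrap_sequences: tuple | None = None   # restrict modelling features

    def __post_init__(self):
        if self.mode not in ("feature", "image"):
            raise ValueError("mode must be 'feature' or 'image'")

    def config_hash(self) -> str:
        payload = json.dumps({
            "mode": self.mode,
            "cohort": {k: v for k, v in vars(self.cohort).items()},
            "settings": [s.label for s in (self.settings or [])] or "all",
            "B": self.B, "seed": self.seed,
            "fs_methods": list(self.fs_methods),
            "rsf_trees": self.rsf_trees,
            "icc_threshold": self.icc_threshold,
            "collinearity_threshold": self.collinearity_threshold,
        }, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def enumerate_grid(settings=None) -> list[ExperimentSetting]:
    """The deterministic setting grid: (ist, bin, combat, mbs) order.

    With no argument, the full 96-cell grid.  A provided subset is
    validated, deduplicated and returned in grid order.
    """
    full = [
        ExperimentSetting(ist, b, cb, mbs)
        for ist in IST_NAMES
        for b in BIN_COUNTS
        for cb in (False, True)
        for mbs in MBS_VALUES
    ]
    if settings is None:
        return full
    requested = set()
    for s in settings:
        if not isinstance(s, ExperimentSetting):
            s = ExperimentSetting(**s)
        requested.add(s)
    return [s for s in full if s in requested]


def _setting_seed(root_seed: int, setting: ExperimentSetting) -> int:
    """Stable per-setting seed derived from the root seed, so results are
    identical no matter which subset of settings runs or in what order."""
    h = hashlib.sha256(f"{root_seed}:{setting.label}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def prepare_setting(
    setting: ExperimentSetting,
    features: FeatureTable,
    batch_maps: dict,
    clinical: pd.DataFrame,
    survival: pd.DataFrame,
    covariate_alpha: float = 0.05,
):
    """MBS filter and optional ComBat for one setting.

    Returns (features, clinical_design, survival, stage_info).
    """
    retained, info = filter_by_mbs(batch_maps, setting.mbs)
    feats = features.subset(patient_ids=retained)
    clin = clinical.loc[retained]
    surv = survival.loc[retained]
    maps = {seq: bm.subset(retained) for seq, bm in batch_maps.items()}
    stage = {"n_after_mbs": len(retained), "retention": info}
    if setting.combat:
        p_age, _ = batch_covariate_screen(clin["age"], maps[SEQUENCES[0]])
        cov = pd.DataFrame({"age": clin["age"]}) if p_age < covariate_alpha else None
        stage["age_batch_p"] = p_age
        stage["age_covariate_included"] = cov is not None
        feats, _ = combat_adjust_by_sequence(feats, maps, cov)
    return feats, clinical_design(clin), surv, stage


def _image_mode_features(volume_sets, setting: ExperimentSetting,
                         icc_threshold: float):
    """IST -> extraction (two segmentations) -> ICC filter."""
    standardised = []
    by_seq = {seq: apply_ist(setting.ist, volume_sets, seq)
              for seq in SEQUENCES}
    for i, vs in enumerate(volume_sets):
        new = type(vs)(vs.patient_id,
                       {seq: by_seq[seq][i] for seq in SEQUENCES},
                       vs.masks, vs.spacing)
        standardised.append(new)
    table_a = extract_cohort(standardised, setting.bin_count)
    vs_b = [type(vs)(vs.patient_id, vs.volumes,
                     {**vs.masks, "wtv": vs.masks["wtv_b"]}, vs.spacing)
            for vs in standardised]
    table_b = extract_cohort(vs_b, setting.bin_count)
    retained = icc_filter(table_a, table_b, icc_threshold)
    return table_a.subset(feature_names=retained), len(table_a.feature_names)


def run_experiment(config: RunConfig) -> dict:
    """Execute the pipeline over the requested settings.

    Returns {"summaries": {label: BootstrapSummary}, "manifest": dict,
    "results": tidy DataFrame}; if ``config.out_dir`` is set, the results
    CSV and manifest JSON are also written there.  A failing setting is
    logged and recorded in the manifest; the remaining settings continue.
    """
    settings = config.settings or enumerate_grid()
    settings = enumerate_grid(settings)
    cohort_cfg = config.cohort
    features = None
    volume_sets = None
    if config.mode == "feature":
        features, batch_maps, clinical, survival, truth = \
            generate_feature_cohort(cohort_cfg)
    else:
        volume_sets = generate_phantom_volumes(cohort_cfg)
        from .synthetic import assign_batches
        batch_maps = assign_batches(cohort_cfg)
        rng = np.random.default_rng(cohort_cfg.seed)
        from .synthetic import _clinical_table
        clinical = _clinical_table(cohort_cfg, rng,
                                   batch_maps[SEQUENCES[0]].assignments)
        # survival driven by tumour burden in image mode
        eta = 0.3 * (np.log(clinical["wtv_cm3"])
                     - np.log(clinical["wtv_cm3"]).mean())
        from .synthetic import simulate_survival
        survival, _ = simulate_survival(
            pd.Series(eta.to_numpy(), index=clinical.index), cohort_cfg,
            rng=np.random.default_rng(cohort_cfg.seed + 2))
        truth = None

    manifest = {
        "config_hash": config.config_hash(),
        "root_seed": config.seed,
        "version": __version__,
        "mode": config.mode,
        "n_patients": cohort_cfg.n_patients,
        "settings": {},
    }
    summaries: dict[str, BootstrapSummary] = {}
    tidy_rows = []
    for setting in settings:
        label = setting.label
        try:
            if config.mode == "image":
                feats, n_before_icc = _image_mode_features(
                    volume_sets, setting, config.icc_threshold)
                icc_info = {"n_features_before_icc": n_before_icc,
                            "n_features_after_icc": len(feats.feature_names)}
            else:
                feats = features
                icc_info = {}
            feats_s, clin_s, surv_s, stage = prepare_setting(
                setting, feats, batch_maps, clinical, survival,
                config.covariate_alpha)
            stage.update(icc_info)
            if config.bootstrap_sequences is not None:
                cols = [c for c in feats_s.feature_names
                        if c.split("_")[0] in config.bootstrap_sequences]
                feats_s = feats_s.subset(feature_names=cols)
            records = bootstrap_run(
                feats_s, clin_s, surv_s, B=config.B,
                seed=_setting_seed(config.seed, setting),
                fs_methods=config.fs_methods,
                collinearity_threshold=config.collinearity_threshold,
                rsf_trees=config.rsf_trees,
                store_curves=config.store_curves,
                evaluate_apparent=config.evaluate_apparent,
                model_types=config.model_types,
            )
            summary = summarise(records, setting)
            summaries[label] = summary
            df = tidy_metrics(summary)
            tidy_rows.append(df)
            stage["n_resamples"] = summary.n_resamples
            stage["n_failures"] = summary.n_failures
            stage["cooccurrence"] = summary.cooccurrence
            manifest["settings"][label] = stage
            log.info("setting %s done (n=%d)", label, stage["n_after_mbs"])
        except Exception as exc:  # noqa: BLE001 - setting isolation
            manifest["settings"][label] = {"error": str(exc)}
            log.warning("setting %s aborted: %s", label, exc)
    results = (pd.concat(tidy_rows, ignore_index=True)
               if tidy_rows else pd.DataFrame())
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        results.to_csv(os.path.join(config.out_dir, "results.csv"), index=False)
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, default=float)
    return {"summaries": summaries, "manifest": manifest, "results": results}


def run_mbs_trend_study(n_seeds: int = 15, B: int = 100, root_seed: int = 0,
                        ist: str = "ZS", bin_count: int = 32,
                        n_features: int = 5) -> pd.DataFrame:
    """Replicated minimum-batch-size stability experiment.

    For each of ``n_seeds`` independent synthetic cohorts (default study
    conditions: 195 patients, 15 unequal batches, simulated batch
    effects; 15 replicate seeds keep the Monte-Carlo error of the
    seed-averaged statistics well below the trend step sizes), runs the bootstrap (B resamples, forward selection on one
    sequence's feature block, combined clinical-radiomic models) over the
    six settings crossing ComBat on/off with minimum batch sizes 5/10/15,
    and averages over seeds the three stability statistics: feature
    co-occurrence, the 95% CI width of the test C-index, and the mean test
    C-index.

    Returns a DataFrame indexed by (combat, mbs) with columns
    ``cooccurrence``, ``ci_width_c``, ``mean_c``, each averaged over seeds.
    """
    settings = [ExperimentSetting(ist, bin_count, cb, mbs)
                for cb in (False, True) for mbs in MBS_VALUES]
    rows = []
    for k in range(n_seeds):
        seed = (root_seed + 7919 * (k + 1)) % (2**31 - 1)
        cfg = RunConfig(
            cohort=CohortConfig(seed=seed, n_features=n_features),
            settings=settings, B=B, seed=seed, fs_methods=("forward",),
            store_curves=False, evaluate_apparent=False,
            model_types=("combined",), bootstrap_sequences=("T1W",),
        )
        out = run_experiment(cfg)
        for setting in settings:
            s = out["summaries"][setting.label]
            rows.append({
                "seed": k, "combat": setting.combat, "mbs": setting.mbs,
                "cooccurrence": s.cooccurrence["forward"],
                "ci_width_c": s.ci_width("combined", "forward", "c_index"),
                "mean_c": float(
                    s.metrics.loc[("combined", "forward", "c_index"), "mean"]),
            })
    df = pd.DataFrame(rows)
    return df.groupby(["combat", "mbs"])[
        ["cooccurrence", "ci_width_c", "mean_c"]].mean()
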