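"""End-to-end run configuration, orchestration and manifest.

``run_pipeline`` ties the stages together: simulate (or ingest) a dataset,
assemble and split the data matrix, calibrate the UPLS model with
venetian-blinds cross-validation, predict, aggregate per dose, and run the
accordance statistics against the MTT reference.  Every artifact is a
plain-text file re-readable by this package's own readers, and the manifest
records the configuration, content hashes and stage log so a run is fully
reproducible from (config, seed).

Config files are flat key–value YAML with units embedded in the key names
(``ex_step_nm``, ``mtt_sd_pct``, ...).  Note that bare ``off`` is a YAML
boolean; quote the ``medium_mode`` value (the loader tolerates the
unquoted form and maps ``false`` back to ``"off"``).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accordance import (
    ViabilitySample,
    correlate_methods,
    pairwise_discrimination,
    per_timepoint_accordance,
)
from .calibration import (
    SplitSpec,
    aggregate_by_dose,
    assemble_matrix,
    dose_mean_response,
    fit_upls,
    linear_fit_diagnostics,
    per_replicate_response,
    split_train_test,
)
from .eem import AcquisitionGeometry
from .io import save_model, write_eem_long, write_viability_csv
from .synthetic import SyntheticConfig, simulate_dataset

logger = logging.getLogger("eemviab")


@dataclass
class RunConfig:
    """Validated configuration of one end-to-end run."""

    seed: int = 1
    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    train_fraction: float = 0.75
    n_cv_splits: int = 10
    max_lv: int | None = None
    response: str = "dose_mean"
    alpha: float = 0.05
    t_variant: str = "pooled"
    out_dir: str = "eemviab_run"

    def __post_init__(self) -> None:
        # the run seed and geometry are the single source of truth
        import dataclasses

        if self.synthetic.seed != self.seed or self.synthetic.geometry != self.geometry:
            self.synthetic = dataclasses.replace(
                self.synthetic, seed=self.seed, geometry=self.geometry
            )
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if self.n_cv_splits < 2:
            raise ValueError("n_cv_splits must be >= 2")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie strictly between 0 and 1")
        if self.response not in ("dose_mean", "per_replicate"):
            raise ValueError(f"unknown response mode {self.response!r}")
        if self.t_variant not in ("pooled", "welch"):
            raise ValueError(f"unknown t-test variant {self.t_variant!r}")


_GEOMETRY_KEYS = {
    "ex_start_nm": "ex_start", "ex_stop_nm": "ex_stop", "ex_step_nm": "ex_step",
    "em_stop_nm": "em_stop", "em_step_nm": "em_step", "em_floor_nm": "em_floor",
    "ex_cutoff_nm": "ex_cutoff", "scatter_offset_nm": "scatter_offset",
}
_SYNTH_KEYS = {
    "doses_min": "doses", "n_eem_reps": "n_eem_reps", "n_mtt_reps": "n_mtt_reps",
    "mtt_sd_pct": "mtt_sd", "bio_sd_pct": "bio_sd", "medium_mode": "medium_mode",
}
_RUN_KEYS = {
    "seed": "seed", "train_fraction": "train_fraction", "n_cv_splits": "n_cv_splits",
    "max_lv": "max_lv", "response": "response", "alpha": "alpha",
    "t_variant": "t_variant", "out_dir": "out_dir",
}


def load_config(path: str | Path) -> RunConfig:
    """Load a flat-key YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    known = set(_GEOMETRY_KEYS) | set(_SYNTH_KEYS) | set(_RUN_KEYS)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {unknown}")
    geom_kwargs = {v: int(raw[k]) for k, v in _GEOMETRY_KEYS.items() if k in raw}
    geometry = AcquisitionGeometry(**geom_kwargs)
    synth_kwargs: dict = {}
    for k, v in _SYNTH_KEYS.items():
        if k in raw:
            val = raw[k]
            if k == "medium_mode" and val is False:  # YAML 1.1 parses `off` as False
                val = "off"
            if k == "doses_min":
                val = tuple(float(d) for d in val)
            synth_kwargs[v] = val
    run_kwargs = {v: raw[k] for k, v in _RUN_KEYS.items() if k in raw}
    seed = int(run_kwargs.get("seed", 1))
    synthetic = SyntheticConfig(geometry=geometry, seed=seed, **synth_kwargs)
    return RunConfig(geometry=geometry, synthetic=synthetic, **run_kwargs)


def config_to_dict(config: RunConfig) -> dict:
    """Flat-key echo of the configuration (for manifests and config files)."""
    out = {k: getattr(config.geometry, v) for k, v in _GEOMETRY_KEYS.items()}
    s = config.synthetic
    out.update(
        {
            "doses_min": list(s.doses), "n_eem_reps": s.n_eem_reps,
            "n_mtt_reps": s.n_mtt_reps, "mtt_sd_pct": s.mtt_sd,
            "bio_sd_pct": s.bio_sd, "medium_mode": s.medium_mode,
        }
    )
    out.update({k: getattr(config, v) for k, v in _RUN_KEYS.items()})
    return out


@dataclass
class RunManifest:
    config: dict
    version: str
    confounded: bool
    artifacts: dict[str, str]  # relative path -> sha256
    stages: list[str]
    started: str
    finished: str


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute simulate → fit → predict → aggregate → accordance end to end."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    stages: list[str] = []
    confounded = config.synthetic.medium_mode == "confound"
    if confounded:
        logger.warning(
            "medium_mode=confound: dataset carries a dose-correlated medium "
            "signal; apparent model quality does not reflect cellular viability"
        )

    def stage(name: str) -> None:
        stages.append(name)
        logger.info("stage %s (seed=%d)", name, config.seed)

    try:
        stage("simulate")
        dataset = simulate_dataset(config.synthetic)
        write_eem_long(dataset.eems, out / "eem_dataset.csv")
        dataset.mtt_table.to_csv(out / "mtt.csv", index=False)
        logger.info("simulated %d EEMs, %d MTT replicates",
                    len(dataset.eems), len(dataset.mtt_table))

        stage("assemble")
        matrix = assemble_matrix(dataset.eems)

        stage("split")
        split_spec = SplitSpec(train_fraction=config.train_fraction, seed=config.seed)
        split = split_train_test(matrix, split_spec)

        stage("fit")
        response_fn = (
            dose_mean_response if config.response == "dose_mean" else per_replicate_response
        )
        y_train = response_fn(split.train, dataset.mtt_table)
        y_test = response_fn(split.test, dataset.mtt_table)
        model = fit_upls(
            split.train, y_train, split=split_spec,
            max_lv=config.max_lv, n_splits=config.n_cv_splits,
            response_mode=config.response,
        )
        save_model(model, out / "model.json")
        logger.info("chosen %d latent variable(s); RMSECV %.3f%%",
                    model.cv.n_lv, model.cv.rmsecv[model.cv.n_lv])

        stage("predict")
        pred_train = model.predict_values(split.train.values)
        pred_test = model.predict_values(split.test.values)
        preds = pd.concat(
            [
                split.train.meta.assign(subset="train", predicted_viability_pct=pred_train),
                split.test.meta.assign(subset="test", predicted_viability_pct=pred_test),
            ],
            ignore_index=True,
        )
        preds.to_csv(out / "predictions.csv", index=False)

        stage("aggregate")
        dose_summary = pd.concat(
            [
                aggregate_by_dose(pred_train, split.train.meta["dose_min"]).assign(subset="train"),
                aggregate_by_dose(pred_test, split.test.meta["dose_min"]).assign(subset="test"),
                aggregate_by_dose(
                    preds["predicted_viability_pct"], preds["dose_min"]
                ).assign(subset="all"),
            ],
            ignore_index=True,
        )
        dose_summary.to_csv(out / "dose_summary.csv", index=False)

        train_fit = linear_fit_diagnostics(pred_train, y_train)
        test_fit = linear_fit_diagnostics(pred_test, y_test)
        test_dose = dose_summary[dose_summary["subset"] == "test"]
        mtt_means = dataset.mtt_table.groupby("dose_min")["viability_pct"].mean()
        test_dose_fit = linear_fit_diagnostics(
            test_dose["mean"].to_numpy(), mtt_means.loc[test_dose["dose_min"]].to_numpy()
        )

        stage("accordance")
        mtt_samples = [
            ViabilitySample("MTT", dose, dataset.mtt_values(dose))
            for dose in sorted(dataset.true_viability)
        ]
        eem_samples = [
            ViabilitySample(
                "EEM_all", dose,
                preds.loc[preds["dose_min"] == dose, "predicted_viability_pct"].to_numpy(),
            )
            for dose in sorted(dataset.true_viability)
        ]
        write_viability_csv(mtt_samples + eem_samples, out / "viability_samples.csv")
        table = per_timepoint_accordance(
            mtt_samples, eem_samples, alpha=config.alpha, t_variant=config.t_variant
        )
        table.table.to_csv(out / "accordance_table.csv", index=False)
        for label, samples in (("mtt", mtt_samples), ("eem", eem_samples)):
            disc = pairwise_discrimination(samples, alpha=config.alpha,
                                           t_variant=config.t_variant)
            pd.DataFrame(disc.p_values, index=disc.doses, columns=disc.doses).to_csv(
                out / f"discrimination_{label}.csv"
            )
        eem_means = (
            preds.groupby("dose_min")["predicted_viability_pct"].mean().sort_index()
        )
        corr = correlate_methods(
            mtt_means.sort_index().to_numpy(), eem_means.to_numpy(), alpha=config.alpha
        )
        report = {
            "confounded": confounded,
            "note": (
                "CONFOUNDED RUN: spectra carry a dose-correlated medium "
                "photodegradation signal; correlations here do not demonstrate "
                "a viability response"
            ) if confounded else "",
            "chosen_n_lv": model.cv.n_lv,
            "rmsecv": model.cv.rmsecv.tolist(),
            "train_fit": vars(train_fit),
            "test_fit": vars(test_fit),
            "test_dose_mean_fit": vars(test_dose_fit),
            "accordance_unflagged_doses": table.n_unflagged,
            "correlation": {
                **corr.diagnostics,
                "contains_ideal_slope": corr.contains_ideal_slope,
                "contains_ideal_intercept": corr.contains_ideal_intercept,
            },
        }
        (out / "diagnostics.json").write_text(
            json.dumps(report, indent=2), encoding="utf-8"
        )
    except Exception as exc:
        failed = stages[-1] if stages else "setup"
        (out / "INCOMPLETE").write_text(
            f"failed at stage {failed}: {exc}\n", encoding="utf-8"
        )
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    artifact_names = [
        "eem_dataset.csv", "mtt.csv", "model.json", "predictions.csv",
        "dose_summary.csv", "accordance_table.csv", "discrimination_mtt.csv",
        "discrimination_eem.csv", "viability_samples.csv", "diagnostics.json",
    ]
    manifest = RunManifest(
        config=config_to_dict(config),
        version=__version__,
        confounded=confounded,
        artifacts={name: _sha256(out / name) for name in artifact_names},
        stages=stages,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    (out / "manifest.json").write_text(
        json.dumps(asdict(manifest), indent=2), encoding="utf-8"
    )
    return manifest
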