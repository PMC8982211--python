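"""Plain-text file formats for EEM datasets, viability tables and models.

Wide EEM CSV: first header row lists the emission wavelengths (nm), the
first column the excitation wavelengths (nm); scatter-masked cells are
written as empty fields and must stay empty on read.  Long dataset CSV:
one row per (sample, λex, λem) valid cell.  Viability CSV: one row per
(method, dose, replicate).  Models serialize to a self-describing JSON
document.  All files are UTF-8 with period decimal separators; wavelengths
are integers in nm.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .accordance import ViabilitySample
from .calibration import (
    CVResult,
    PLSCore,
    ScalingParams,
    SplitSpec,
    UPLSModel,
)
from .eem import (
    AcquisitionGeometry,
    ExcitationEmissionMatrix,
    build_mask,
)


class ParseError(ValueError):
    """Raised for malformed input files, with a file location."""


# ---------------------------------------------------------------- wide EEM


def write_eem_wide(eem: ExcitationEmissionMatrix, path: str | Path) -> None:
    """Write one EEM as a wide CSV; masked cells become empty fields."""
    g = eem.geometry
    mask = build_mask(g)
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        header = ",".join(["ex_nm/em_nm"] + [str(int(w)) for w in g.em_wavelengths])
        fh.write(header + "\n")
        for i, ex in enumerate(g.ex_wavelengths):
            cells = [
                repr(float(eem.intensities[i, j])) if mask.grid[i, j] else ""
                for j in range(g.n_em)
            ]
            fh.write(",".join([str(int(ex))] + cells) + "\n")


def read_eem_wide(
    path: str | Path,
    geometry: AcquisitionGeometry | None = None,
    **metadata,
) -> ExcitationEmissionMatrix:
    """Read a wide EEM CSV, inferring the geometry from the header if needed.

    Raises :class:`ParseError` for off-grid wavelengths or a value in a
    masked cell, naming the offending (λex, λem).
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise ParseError(f"{path}: no data rows")
    header = lines[0].split(",")
    try:
        ems = np.array([int(tok) for tok in header[1:]])
    except ValueError as exc:
        raise ParseError(f"{path}: malformed emission header: {exc}") from exc
    if np.any(np.diff(ems) <= 0):
        raise ParseError(f"{path}: emission wavelengths are not strictly increasing")
    exs, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        toks = line.split(",")
        if len(toks) != len(ems) + 1:
            raise ParseError(f"{path}:{lineno}: expected {len(ems) + 1} fields")
        exs.append(int(toks[0]))
        rows.append([float(t) if t != "" else np.nan for t in toks[1:]])
    exs = np.array(exs)
    if geometry is None:
        em_steps = np.unique(np.diff(ems))
        ex_steps = np.unique(np.diff(exs))
        if len(em_steps) != 1 or len(ex_steps) != 1:
            raise ParseError(f"{path}: wavelength grids are not uniform")
        geometry = AcquisitionGeometry(
            ex_start=int(exs[0]),
            ex_stop=int(exs[-1]),
            ex_step=int(ex_steps[0]),
            em_stop=int(ems[-1]),
            em_step=int(em_steps[0]),
            em_floor=int(ems[0]),
        )
    if not np.array_equal(exs, geometry.ex_wavelengths) or not np.array_equal(
        ems, geometry.em_wavelengths
    ):
        raise ParseError(f"{path}: wavelength grids do not match the geometry")
    intensities = np.array(rows)
    mask = build_mask(geometry)
    misplaced = np.argwhere(~mask.grid & np.isfinite(intensities))
    if len(misplaced):
        i, j = misplaced[0]
        raise ParseError(
            f"{path}: intensity present at masked cell "
            f"λex={int(exs[i])} nm, λem={int(ems[j])} nm"
        )
    missing = np.argwhere(mask.grid & ~np.isfinite(intensities))
    if len(missing):
        i, j = missing[0]
        raise ParseError(
            f"{path}: missing intensity at valid cell "
            f"λex={int(exs[i])} nm, λem={int(ems[j])} nm"
        )
    return ExcitationEmissionMatrix(geometry=geometry, intensities=intensities, **metadata)


# ---------------------------------------------------------------- long CSV

LONG_COLUMNS = ["sample_id", "dose_min", "replicate", "lambda_ex", "lambda_em", "intensity"]


def write_eem_long(eems: list[ExcitationEmissionMatrix], path: str | Path) -> None:
    """Write a dataset of EEMs as a long CSV (masked cells absent)."""
    frames = []
    for eem in eems:
        mask = build_mask(eem.geometry)
        im = mask.index_map
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": eem.sample_id,
                    "dose_min": eem.dose_min,
                    "replicate": eem.replicate,
                    "lambda_ex": eem.geometry.ex_wavelengths[im[:, 0]],
                    "lambda_em": eem.geometry.em_wavelengths[im[:, 1]],
                    "intensity": eem.intensities[im[:, 0], im[:, 1]],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    # repr round-trips float64 exactly; pandas' default float formatting does not
    df["intensity"] = [repr(float(v)) for v in df["intensity"]]
    df.to_csv(path, index=False)


def read_eem_long(
    path: str | Path, geometry: AcquisitionGeometry | None = None
) -> list[ExcitationEmissionMatrix]:
    """Read a long-CSV dataset back into per-sample EEMs."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    if geometry is None:
        geometry = AcquisitionGeometry()
    mask = build_mask(geometry)
    ex_index = {int(w): i for i, w in enumerate(geometry.ex_wavelengths)}
    em_index = {int(w): j for j, w in enumerate(geometry.em_wavelengths)}
    eems = []
    for (sample_id, dose, rep), grp in df.groupby(
        ["sample_id", "dose_min", "replicate"], sort=False
    ):
        grid = np.full(geometry.shape, np.nan)
        try:
            ii = [ex_index[int(w)] for w in grp["lambda_ex"]]
            jj = [em_index[int(w)] for w in grp["lambda_em"]]
        except KeyError as exc:
            raise ParseError(f"{path}: off-grid wavelength {exc}") from exc
        grid[ii, jj] = grp["intensity"].to_numpy()
        if np.any(np.isfinite(grid[~mask.grid])):
            raise ParseError(
                f"{path}: sample {sample_id!r} has intensity in a masked cell"
            )
        eems.append(
            ExcitationEmissionMatrix(
                geometry=geometry,
                intensities=grid,
                sample_id=str(sample_id),
                dose_min=float(dose),
                replicate=int(rep),
            )
        )
    if not eems:
        raise ParseError(f"{path}: no samples found")
    return eems


# ---------------------------------------------------------------- viability


def write_viability_csv(samples: list[ViabilitySample], path: str | Path) -> None:
    rows = [
        {
            "method": s.method,
            "dose_min": s.dose_min,
            "replicate": r,
            "viability_pct": float(v),
        }
        for s in samples
        for r, v in enumerate(s.values)
    ]
    pd.DataFrame(rows, columns=["method", "dose_min", "replicate", "viability_pct"]).to_csv(
        path, index=False
    )


def read_viability_csv(path: str | Path) -> list[ViabilitySample]:
    """Read (method, dose, replicate, viability) rows into grouped samples."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    required = ["dose_min", "viability_pct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    if (df["viability_pct"] < 0).any():
        raise ParseError(f"{path}: negative viability value")
    if "method" not in df.columns:
        df["method"] = "unknown"
    return [
        ViabilitySample(
            method=str(method), dose_min=float(dose),
            values=grp["viability_pct"].to_numpy()
        )
        for (method, dose), grp in df.groupby(["method", "dose_min"], sort=True)
    ]


# ---------------------------------------------------------------- model JSON


def save_model(model: UPLSModel, path: str | Path) -> None:
    """Serialize a fitted model to a self-describing JSON document."""
    g = model.geometry
    doc = {
        "format": "eemviab-upls-model",
        "version": 1,
        "geometry": {
            "ex_start": g.ex_start, "ex_stop": g.ex_stop, "ex_step": g.ex_step,
            "em_stop": g.em_stop, "em_step": g.em_step, "em_floor": g.em_floor,
            "ex_cutoff": g.ex_cutoff, "scatter_offset": g.scatter_offset,
        },
        "scaling": {
            "mean": model.scaling.mean.tolist(),
            "sd": model.scaling.sd.tolist(),
            "zero_variance": model.scaling.zero_variance.tolist(),
        },
        "y_mean": model.y_mean,
        "pls": {
            "weights": model.core.weights.tolist(),
            "x_loadings": model.core.x_loadings.tolist(),
            "y_loadings": model.core.y_loadings.tolist(),
            "coef": model.core.coef.tolist(),
            "n_lv": model.core.n_lv,
        },
        "cv": {
            "lv_counts": model.cv.lv_counts.tolist(),
            "rmsecv": model.cv.rmsecv.tolist(),
            "n_lv": model.cv.n_lv,
            "n_splits": model.cv.n_splits,
        },
        "split": {"train_fraction": model.split.train_fraction, "seed": model.split.seed},
        "response_mode": model.response_mode,
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def load_model(path: str | Path) -> UPLSModel:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("format") != "eemviab-upls-model":
        raise ParseError(f"{path}: not an eemviab model file")
    geometry = AcquisitionGeometry(**doc["geometry"])
    scaling = ScalingParams(
        mean=np.array(doc["scaling"]["mean"]),
        sd=np.array(doc["scaling"]["sd"]),
        zero_variance=np.array(doc["scaling"]["zero_variance"], dtype=bool),
    )
    pls = doc["pls"]
    core = PLSCore(
        weights=np.array(pls["weights"]).reshape(len(scaling.mean), -1),
        x_loadings=np.array(pls["x_loadings"]).reshape(len(scaling.mean), -1),
        y_loadings=np.array(pls["y_loadings"]),
        scores=np.zeros((0, pls["n_lv"])),  # training scores are not persisted
        coef=np.array(pls["coef"]),
        n_lv=int(pls["n_lv"]),
    )
    cv = CVResult(
        lv_counts=np.array(doc["cv"]["lv_counts"]),
        rmsecv=np.array(doc["cv"]["rmsecv"]),
        n_lv=int(doc["cv"]["n_lv"]),
        n_splits=int(doc["cv"]["n_splits"]),
    )
    return UPLSModel(
        scaling=scaling,
        y_mean=float(doc["y_mean"]),
        core=core,
        cv=cv,
        geometry=geometry,
        split=SplitSpec(**doc["split"]),
        response_mode=doc.get("response_mode", "dose_mean"),
    )
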