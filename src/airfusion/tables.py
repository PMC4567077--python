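"""Site and grid tables: schemas, validation, CSV readers/writers.

Two plain tables drive the whole pipeline:

* **site table** — one row per measurement location (automatic monitor or
  diffusion tube) with coordinates in metres, a source label, a local
  environment class and an annual-mean NO2 concentration in ug/m3.
* **grid table** — one row per cell of a regular prediction grid with the
  cell-centre coordinates, the dispersion-model ("modelled-PCM") background
  NO2 value and an urban/rural flag.

Coordinates are stored in metres everywhere on disk and in the tables;
they are converted to kilometres at a single internal boundary (the
distance-matrix computation in :mod:`airfusion.covariance`).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOURCES = ("monitor", "tube")
ENVIRONMENTS = ("kerbside", "roadside", "urban_background", "rural", "special")

SITE_COLUMNS = ["site_id", "easting_m", "northing_m", "source", "environment",
                "pcm_no2_ugm3", "no2_ugm3"]
GRID_COLUMNS = ["cell_id", "easting_m", "northing_m", "pcm_no2_ugm3", "urban"]


class TableError(ValueError):
    """A site or grid table violates its schema."""


def _normalize_label(value: str) -> str:
    return str(value).strip().lower().replace(" ", "_").replace("-", "_")


def validate_sites(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a site table, returning a clean copy.

    Labels are case-folded ("Roadside" -> "roadside", "urban background" ->
    "urban_background"); unknown labels and non-positive concentrations raise
    :class:`TableError` naming the offending row.
    """
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise TableError(f"site table missing columns: {missing}")
    out = df.copy().reset_index(drop=True)
    for col, vocab in [("source", SOURCES), ("environment", ENVIRONMENTS)]:
        raw = out[col].astype(str)
        norm = raw.map(_normalize_label)
        changed = (norm != raw).sum()
        if changed:
            logger.info("normalized %d %s labels by case-folding", changed, col)
        bad = ~norm.isin(vocab)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableError(
                f"unknown {col} label {raw.iloc[row]!r} in row {row}")
        out[col] = norm
    for col in ("easting_m", "northing_m", "pcm_no2_ugm3", "no2_ugm3"):
        out[col] = pd.to_numeric(out[col], errors="raise")
        if not np.isfinite(out[col]).all():
            row = int(np.flatnonzero(~np.isfinite(out[col].to_numpy()))[0])
            raise TableError(f"non-finite {col} in row {row}")
    for col in ("pcm_no2_ugm3", "no2_ugm3"):
        bad = out[col].to_numpy() <= 0
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise TableError(
                f"non-positive {col} ({out[col].iloc[row]}) in row {row}; "
                "concentrations must be strictly positive for the log transform")
    logger.info("site table: %d rows (%s)", len(out),
                ", ".join(f"{k}={v}" for k, v in
                          out["source"].value_counts().items()))
    return out


def validate_grid(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a grid table; warns (does not fail) if cells are off-lattice."""
    missing = [c for c in GRID_COLUMNS if c not in df.columns]
    if missing:
        raise TableError(f"grid table missing columns: {missing}")
    out = df.copy().reset_index(drop=True)
    if out["cell_id"].duplicated().any():
        dup = out.loc[out["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise TableError(f"duplicated cell_id {dup!r}")
    for col in ("easting_m", "northing_m", "pcm_no2_ugm3"):
        out[col] = pd.to_numeric(out[col], errors="raise")
    if (out["pcm_no2_ugm3"].to_numpy() <= 0).any():
        row = int(np.flatnonzero(out["pcm_no2_ugm3"].to_numpy() <= 0)[0])
        raise TableError(f"non-positive pcm_no2_ugm3 in row {row}")
    out["urban"] = out["urban"].astype(bool)
    for col in ("easting_m", "northing_m"):
        vals = np.sort(out[col].unique())
        if len(vals) > 2:
            steps = np.diff(vals)
            if not np.allclose(steps, steps[0], rtol=1e-6):
                logger.warning("grid %s values are not on a regular lattice", col)
    return out


def read_sites(path) -> pd.DataFrame:
    """Read and validate a site CSV."""
    return validate_sites(pd.read_csv(path))


def read_grid(path) -> pd.DataFrame:
    """Read and validate a grid CSV."""
    return validate_grid(pd.read_csv(path))


def write_sites(df: pd.DataFrame, path) -> None:
    validate_sites(df).to_csv(path, index=False)


def write_grid(df: pd.DataFrame, path) -> None:
    validate_grid(df).to_csv(path, index=False)
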