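"""Delimited-text readers and writers for every pipeline artifact.

All formats are plain TSV so cohorts are diffable and portable:

* time series — first column ``region_id``, then one column per frame;
* motion — columns ``trans_x trans_y trans_z rot_x rot_y rot_z``
  (mm and radians);
* nuisance — columns ``ventricle white_matter global``;
* partition — columns ``region_id network``;
* cohort metadata — ``subject_id age gender cesd_01..cesd_20`` and
  optionally ``hand_01..hand_11``;
* manifest — ``subject_id timeseries_path motion_path nuisance_path`` with
  paths relative to the manifest's directory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import FCMatrix, NetworkPartition
from .preprocess import MOTION_COLUMNS, ParcellatedTimeSeries

FLOAT_FORMAT = "%.10g"

NUISANCE_COLUMNS = ("ventricle", "white_matter", "global")


def write_timeseries(path: str | Path, ts: ParcellatedTimeSeries) -> None:
    df = pd.DataFrame(
        ts.data, columns=[f"f{i:05d}" for i in range(ts.n_frames)]
    )
    df.insert(0, "region_id", list(ts.region_ids))
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_timeseries(
    path: str | Path, tr: float, subject_id: str | None = None
) -> ParcellatedTimeSeries:
    df = pd.read_csv(path, sep="\t")
    if "region_id" not in df.columns:
        raise ValueError(f"{path}: missing region_id column")
    region_ids = tuple(df["region_id"])
    data = df.drop(columns="region_id").to_numpy(dtype=float)
    sid = subject_id or Path(path).stem
    return ParcellatedTimeSeries(sid, data, tr, region_ids)


def write_motion(path: str | Path, motion: np.ndarray) -> None:
    pd.DataFrame(np.asarray(motion, dtype=float), columns=list(MOTION_COLUMNS)).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def read_motion(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    missing = set(MOTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing motion columns {sorted(missing)}")
    return df[list(MOTION_COLUMNS)].to_numpy(dtype=float)


def write_nuisance(path: str | Path, nuisance: pd.DataFrame) -> None:
    missing = set(NUISANCE_COLUMNS) - set(nuisance.columns)
    if missing:
        raise ValueError(f"nuisance table missing columns {sorted(missing)}")
    nuisance[list(NUISANCE_COLUMNS)].to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )


def read_nuisance(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(NUISANCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing nuisance columns {sorted(missing)}")
    return df[list(NUISANCE_COLUMNS)]


def write_partition(path: str | Path, partition: NetworkPartition) -> None:
    partition.to_frame().to_csv(path, sep="\t", index=False)


def read_partition(path: str | Path) -> NetworkPartition:
    return NetworkPartition.from_frame(pd.read_csv(path, sep="\t"))


def write_metadata(path: str | Path, metadata: pd.DataFrame) -> None:
    metadata.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"subject_id", "age", "gender"} | {
        f"cesd_{i:02d}" for i in range(1, 21)
    }
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"subject_id", "timeseries_path", "motion_path", "nuisance_path"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing manifest columns {sorted(missing)}")
    return df


def write_fc_matrix(path: str | Path, fc: FCMatrix) -> None:
    df = pd.DataFrame(fc.values, index=list(fc.region_ids), columns=list(fc.region_ids))
    df.to_csv(path, sep="\t", index_label="region_id", float_format=FLOAT_FORMAT)


def read_fc_matrix(path: str | Path) -> FCMatrix:
    df = pd.read_csv(path, sep="\t", index_col="region_id")
    return FCMatrix(df.to_numpy(dtype=float), tuple(df.index))
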