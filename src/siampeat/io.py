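"""Readers and writers for the canonical delimited-text table formats.

All tables are comma-separated UTF-8 with a mandatory header row and "."
decimal separator, matching the supplementary-table convention of
metabolomics feature exports.  The flux table carries its unit string in a
``# unit:`` comment line above the header.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .design import SampleDesign, design_from_frame, design_to_frame
from .flux import FLUX_UNIT, FluxObservation
from .tables import FeatureTable, parse_feature_id

MASS_TOL = 1e-5  # id prints 5 decimals
RT_TOL = 1e-3    # id prints 3 decimals


# ----------------------------------------------------------------------
# Feature tables
# ----------------------------------------------------------------------
def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature table CSV, validating ids against explicit columns.

    Feature ids of the form ``MW_<mass>@RT_<rt>`` are parsed into mass and
    RT; when explicit ``neutral_mass`` / ``rt_min`` columns are present they
    must agree with the id within print precision, otherwise they are
    derived from the id.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if "feature_id" not in df.columns:
        raise ValueError(f"{path}: missing feature_id column")
    masses, rts = [], []
    for i, fid in enumerate(df["feature_id"]):
        try:
            m, r = parse_feature_id(str(fid))
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
        masses.append(m)
        rts.append(r)
    if "neutral_mass" in df.columns:
        bad = np.abs(df["neutral_mass"].to_numpy(float) - np.array(masses)) > MASS_TOL
        if bad.any():
            row = int(np.nonzero(bad)[0][0])
            raise ValueError(
                f"{path}: row {row}: neutral_mass column disagrees with id "
                f"beyond print precision"
            )
    else:
        df["neutral_mass"] = masses
    if "rt_min" in df.columns:
        bad = np.abs(df["rt_min"].to_numpy(float) - np.array(rts)) > RT_TOL
        if bad.any():
            row = int(np.nonzero(bad)[0][0])
            raise ValueError(
                f"{path}: row {row}: rt_min column disagrees with id "
                f"beyond print precision"
            )
    else:
        df["rt_min"] = rts
    if "snr" not in df.columns:
        raise ValueError(f"{path}: missing snr column")
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False)
    return path


# ----------------------------------------------------------------------
# Metadata
# ----------------------------------------------------------------------
def write_metadata(design: list[SampleDesign], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    design_to_frame(design).to_csv(path, index=False)
    return path


def read_metadata(path: str | Path) -> list[SampleDesign]:
    return design_from_frame(pd.read_csv(path))


# ----------------------------------------------------------------------
# NMR-style concentration tables
# ----------------------------------------------------------------------
def write_nmr_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def read_nmr_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if "metabolite_id" not in df.columns:
        raise ValueError(f"{path}: missing metabolite_id column")
    if df["metabolite_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate metabolite ids")
    return df


# ----------------------------------------------------------------------
# Flux tables
# ----------------------------------------------------------------------
def write_flux_table(
    observations: list[FluxObservation], path: str | Path, unit: str = FLUX_UNIT
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        [
            {
                "jar_id": o.jar_id,
                "treatment": o.treatment,
                "label_status": o.label_status,
                "day": o.day,
                "f_net": o.f_net,
                "r_net": o.r_net,
            }
            for o in observations
        ]
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# unit: {unit}\n")
        df.to_csv(fh, index=False)
    return path


def read_flux_table(path: str | Path) -> tuple[list[FluxObservation], str]:
    """Read a flux table; returns observations and the declared unit string."""
    unit = FLUX_UNIT
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# unit:"):
            unit = first.split(":", 1)[1].strip()
            df = pd.read_csv(fh, float_precision="round_trip")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, float_precision="round_trip")
    obs = [
        FluxObservation(
            jar_id=str(r["jar_id"]),
            treatment=str(r["treatment"]),
            label_status=str(r["label_status"]),
            day=float(r["day"]),
            f_net=float(r["f_net"]),
            r_net=float(r["r_net"]),
        )
        for _, r in df.iterrows()
    ]
    return obs, unit


# ----------------------------------------------------------------------
# Helpers
# ----------------------------------------------------------------------
def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
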