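"""The LC-MS feature table: the pipeline's central data container.

A feature table has one row per detected feature and four metadata columns
(``feature_id``, ``neutral_mass`` in Da, ``rt_min`` in minutes, ``snr``)
followed by one non-negative intensity column per sample.  Feature ids carry
their own mass and retention time in the conventional ``MW_<mass>@RT_<rt>``
form (mass printed to 5 decimals, RT to 3), and the explicit columns must
agree with the id within print precision.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLUMNS = ["feature_id", "neutral_mass", "rt_min", "snr"]

MASS_DECIMALS = 5
RT_DECIMALS = 3

_ID_RE = re.compile(r"^MW_(\d+(?:\.\d+)?)@RT_(\d+(?:\.\d+)?)$")


def format_feature_id(neutral_mass: float, rt: float) -> str:
    """Render the canonical ``MW_<mass>@RT_<rt>`` feature id."""
    return f"MW_{neutral_mass:.{MASS_DECIMALS}f}@RT_{rt:.{RT_DECIMALS}f}"


def parse_feature_id(feature_id: str) -> tuple[float, float]:
    """Parse a ``MW_<mass>@RT_<rt>`` id into (neutral mass in Da, RT in min)."""
    m = _ID_RE.match(feature_id)
    if m is None:
        raise ValueError(f"malformed feature id: {feature_id!r}")
    return float(m.group(1)), float(m.group(2))


@dataclass
class FeatureRecord:
    """A single LC-MS feature with its per-sample intensities."""

    feature_id: str
    neutral_mass: float
    rt: float
    snr: float
    intensities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError("neutral_mass must be positive")
        if self.rt < 0:
            raise ValueError("rt must be non-negative")


class FeatureTable:
    """Features x samples intensity table with mass/RT/SNR metadata.

    Thin wrapper around a :class:`pandas.DataFrame` in the canonical column
    order; all pipeline stages read and write this object.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        sample_cols = [c for c in df.columns if c not in META_COLUMNS]
        df = df[META_COLUMNS + sample_cols].reset_index(drop=True)
        if df["feature_id"].duplicated().any():
            dupes = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        vals = df[sample_cols].to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ValueError("negative intensities in feature table")
        self.df = df
        self.sample_ids: list[str] = sample_cols

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def feature_ids(self) -> list[str]:
        return self.df["feature_id"].tolist()

    @property
    def intensities(self) -> pd.DataFrame:
        """Intensity block indexed by feature id (features x samples)."""
        block = self.df[self.sample_ids].copy()
        block.index = self.df["feature_id"]
        return block

    def records(self) -> list[FeatureRecord]:
        out = []
        for _, row in self.df.iterrows():
            out.append(
                FeatureRecord(
                    feature_id=row["feature_id"],
                    neutral_mass=float(row["neutral_mass"]),
                    rt=float(row["rt_min"]),
                    snr=float(row["snr"]),
                    intensities={s: float(row[s]) for s in self.sample_ids},
                )
            )
        return out

    # ------------------------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        neutral_mass: np.ndarray,
        rt: np.ndarray,
        snr: np.ndarray,
        intensities: np.ndarray,
        sample_ids: list[str],
    ) -> "FeatureTable":
        """Build a table, deriving feature ids from mass and RT.

        The stored mass/RT columns are rounded to id print precision so the
        id remains the authoritative identity of the feature.
        """
        mass = np.round(np.asarray(neutral_mass, dtype=float), MASS_DECIMALS)
        rtv = np.round(np.asarray(rt, dtype=float), RT_DECIMALS)
        ids = [format_feature_id(m, r) for m, r in zip(mass, rtv)]
        df = pd.DataFrame(
            {
                "feature_id": ids,
                "neutral_mass": mass,
                "rt_min": rtv,
                "snr": np.asarray(snr, dtype=float),
            }
        )
        inten = pd.DataFrame(np.asarray(intensities, dtype=float), columns=sample_ids)
        return cls(pd.concat([df, inten], axis=1))

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.df.copy())
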