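"""Incubation sample design: treatments, label status, timepoints, replicates.

The experimental design modelled here is an oxic peat incubation with three
treatments — litter only (LO), peat only (PO), and peat amended with litter
(PL) — destructively harvested at four timepoints T0-T3 (days 0, 7, 18 and
40).  Litter-amended and litter-only material exists in a ``labeled``
(isotopically enriched) and an ``unlabeled`` (natural-abundance control)
variant; peat-only jars are always unlabeled.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

TREATMENTS = ("LO", "PO", "PL")
LABEL_STATUSES = ("labeled", "unlabeled")
TIMEPOINTS = ("T0", "T1", "T2", "T3")

#: Single place where timepoint labels map to incubation days.
TIMEPOINT_DAYS = {"T0": 0, "T1": 7, "T2": 18, "T3": 40}

# Which timepoints and label statuses each treatment admits.  Litter-only
# material is the T0 amendment itself and never incubates; peat-only jars
# receive no litter and therefore no label.
_ALLOWED_TIMEPOINTS = {
    "LO": ("T0",),
    "PO": TIMEPOINTS,
    "PL": TIMEPOINTS,
}

# Timepoints actually harvested per treatment: amended jars are
# destructively harvested at days 7, 18 and 40 only; the time-zero state is
# characterized through the peat-only and litter-only T0 samples.
_HARVEST_TIMEPOINTS = {
    "LO": ("T0",),
    "PO": TIMEPOINTS,
    "PL": ("T1", "T2", "T3"),
}
_ALLOWED_LABELS = {
    "LO": ("labeled", "unlabeled"),
    "PO": ("unlabeled",),
    "PL": ("labeled", "unlabeled"),
}


@dataclass(frozen=True)
class SampleDesign:
    """One sample (jar harvest) in the incubation design."""

    sample_id: str
    treatment: str
    label_status: str
    timepoint: str
    replicate: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.label_status not in LABEL_STATUSES:
            raise ValueError(f"unknown label status {self.label_status!r}")
        if self.timepoint not in TIMEPOINT_DAYS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.timepoint not in _ALLOWED_TIMEPOINTS[self.treatment]:
            raise ValueError(
                f"{self.treatment} samples cannot exist at {self.timepoint}"
            )
        if self.label_status not in _ALLOWED_LABELS[self.treatment]:
            raise ValueError(
                f"{self.treatment} samples cannot be {self.label_status}"
            )

    @property
    def day(self) -> int:
        """Days since the start of the incubation."""
        return TIMEPOINT_DAYS[self.timepoint]


def build_design(replicates: int = 2) -> list[SampleDesign]:
    """Build the full factorial design the incubation study uses.

    Every admissible treatment x timepoint x label-status cell receives
    ``replicates`` samples (default 2, matching the two destructively
    harvested jars per cell).

    Sample ids look like ``PL-T1-lab-1``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    design: list[SampleDesign] = []
    for treatment in TREATMENTS:
        for timepoint in _HARVEST_TIMEPOINTS[treatment]:
            for label in _ALLOWED_LABELS[treatment]:
                for rep in range(1, replicates + 1):
                    short = "lab" if label == "labeled" else "unl"
                    design.append(
                        SampleDesign(
                            sample_id=f"{treatment}-{timepoint}-{short}-{rep}",
                            treatment=treatment,
                            label_status=label,
                            timepoint=timepoint,
                            replicate=rep,
                        )
                    )
    return design


def design_to_frame(design: list[SampleDesign]) -> pd.DataFrame:
    """Render a design as the canonical metadata table (one row per sample)."""
    rows = []
    for s in design:
        d = asdict(s)
        d["day"] = s.day
        rows.append(d)
    return pd.DataFrame(rows)


def design_from_frame(frame: pd.DataFrame) -> list[SampleDesign]:
    """Parse the canonical metadata table back into design objects.

    The ``day`` column, if present, is cross-checked against the timepoint
    codec rather than trusted.
    """
    required = {"sample_id", "treatment", "label_status", "timepoint", "replicate"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    design = []
    for _, row in frame.iterrows():
        s = SampleDesign(
            sample_id=str(row["sample_id"]),
            treatment=str(row["treatment"]),
            label_status=str(row["label_status"]),
            timepoint=str(row["timepoint"]),
            replicate=int(row["replicate"]),
        )
        if "day" in frame.columns and int(row["day"]) != s.day:
            raise ValueError(
                f"sample {s.sample_id}: day {row['day']} inconsistent with "
                f"timepoint {s.timepoint} (expected {s.day})"
            )
        design.append(s)
    if len({s.sample_id for s in design}) != len(design):
        raise ValueError("duplicate sample ids in metadata table")
    return design
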