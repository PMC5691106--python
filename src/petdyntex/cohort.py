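"""Paired dual-time-point cohort container.

A :class:`PairedCohort` holds one feature vector per (patient, timepoint),
with both the standard (~60 min, ``PET1``) and delayed (~3 h, ``PET2``)
acquisition present for every included patient.  It is the input to all
cohort statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import FEATURE_COLUMNS, TIMEPOINTS

__all__ = ["PairedCohort"]


class PairedCohort:
    """Per-patient PET-1/PET-2 feature-vector pairs.

    Parameters
    ----------
    frame : pandas.DataFrame
        Long-format table with columns ``patient_id``, ``timepoint``
        (``"PET1"``/``"PET2"``) and one column per feature.  Every patient
        must appear exactly once per timepoint.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if "patient_id" not in frame.columns or "timepoint" not in frame.columns:
            raise ValueError("cohort frame needs patient_id and timepoint columns")
        bad_tp = set(frame["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoint labels: {sorted(bad_tp)}")
        if frame[["patient_id", "timepoint"]].duplicated().any():
            raise ValueError("duplicated (patient, timepoint) rows")
        if len(frame):
            counts = frame.groupby("patient_id")["timepoint"].nunique()
            incomplete = counts.index[counts < 2].tolist()
            if incomplete:
                raise ValueError(f"patients missing a timepoint: {sorted(incomplete)}")
        self.frame = frame.sort_values(["patient_id", "timepoint"]).reset_index(drop=True)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(cls, records) -> "PairedCohort":
        """Build from an iterable of dicts (each with patient_id, timepoint, features)."""
        return cls(pd.DataFrame(list(records)))

    @classmethod
    def empty(cls) -> "PairedCohort":
        cols = ["patient_id", "timepoint"] + FEATURE_COLUMNS
        return cls(pd.DataFrame(columns=cols))

    # -- accessors -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def patients(self) -> list:
        return sorted(self.frame["patient_id"].unique().tolist())

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("patient_id", "timepoint")]

    def values(self, variable: str, timepoint: str) -> np.ndarray:
        """Values of one variable at one timepoint, ordered by patient id."""
        sub = self.frame[self.frame["timepoint"] == timepoint]
        sub = sub.set_index("patient_id").loc[self.patients]
        return sub[variable].to_numpy(dtype=float)

    def pair_values(self, variable: str) -> tuple[np.ndarray, np.ndarray]:
        """Patient-aligned (PET1, PET2) arrays for one variable."""
        return self.values(variable, "PET1"), self.values(variable, "PET2")

    def subset(self, patient_ids) -> "PairedCohort":
        keep = self.frame["patient_id"].isin(set(patient_ids))
        return PairedCohort(self.frame[keep])
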