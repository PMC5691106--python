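"""Model/results interface over the paired cohort statistics.

`DualTimePointModel` wraps a :class:`~petdyntex.cohort.PairedCohort` and
its :meth:`fit` runs the full dual-time-point analysis: one paired test
per variable (t or Wilcoxon, chosen by normality of the differences) plus
Spearman texture-volume associations, returned as a
:class:`DualTimePointResults` with a printable summary.
"""

from __future__ import annotations

import pandas as pd

from .cohort import PairedCohort
from .stats import (
    compare_timepoints,
    results_to_frame,
    stratify_by_mtv,
    texture_volume_table,
)

__all__ = ["DualTimePointModel", "DualTimePointResults"]


class DualTimePointModel:
    """Paired PET-1/PET-2 analysis of a feature cohort.

    Parameters
    ----------
    cohort : PairedCohort
        Complete per-patient PET-1/PET-2 feature pairs.
    """

    def __init__(self, cohort: PairedCohort):
        if len(cohort) < 3:
            raise ValueError("at least 3 complete patient pairs are required")
        self.cohort = cohort

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DualTimePointModel":
        """Build from a long-format DataFrame (patient_id, timepoint, features)."""
        return cls(PairedCohort(frame))

    @classmethod
    def from_csv(cls, path) -> "DualTimePointModel":
        """Build from a feature CSV written by :func:`petdyntex.io.save_feature_table`."""
        from .io import load_feature_table

        return cls(load_feature_table(path))

    def fit(self, alpha: float = 0.05, correction: str | None = None) -> "DualTimePointResults":
        """Run the paired comparisons and return a results object."""
        tests = compare_timepoints(self.cohort, alpha=alpha, correction=correction)
        return DualTimePointResults(self, tests, alpha=alpha, correction=correction)


class DualTimePointResults:
    """Estimates and tests from a fitted :class:`DualTimePointModel`."""

    def __init__(self, model, tests, alpha, correction):
        self.model = model
        self.cohort = model.cohort
        self.tests = tests
        self.alpha = alpha
        self.correction = correction

    @property
    def frame(self) -> pd.DataFrame:
        """Per-variable means, SDs, test used, signed statistic, p, flag."""
        return results_to_frame(self.tests)

    def texture_volume_correlations(self) -> pd.DataFrame:
        """Spearman r of every textural variable with MTV and TLG."""
        return texture_volume_table(self.cohort)

    def stratified_correlations(
        self, cutoff_cm3: float = 10.0, timepoint: str = "PET1"
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Texture-volume tables within the MTV <= cutoff and > cutoff strata."""
        g1, g2 = stratify_by_mtv(self.cohort, cutoff_cm3=cutoff_cm3, timepoint=timepoint)
        return texture_volume_table(g1), texture_volume_table(g2)

    def summary(self) -> str:
        """Human-readable report of the paired comparisons."""
        df = self.frame.copy()
        df["mean±SD PET1"] = df.apply(lambda r: f"{r.mean_pet1:.3g} ± {r.sd_pet1:.3g}", axis=1)
        df["mean±SD PET2"] = df.apply(lambda r: f"{r.mean_pet2:.3g} ± {r.sd_pet2:.3g}", axis=1)
        cols = ["variable", "mean±SD PET1", "mean±SD PET2", "test", "statistic", "p_value", "significant"]
        out = df[cols].copy()
        out["statistic"] = out["statistic"].map(lambda v: f"{v:.2f}")
        out["p_value"] = out["p_value"].map(lambda v: f"{v:.4f}")
        n = self.tests[0].n if self.tests else 0
        header = (
            f"Dual-time-point paired comparison (n = {n} patients, "
            f"alpha = {self.alpha}, correction = {self.correction or 'none'})\n"
            "A negative statistic means the PET-1 value was lower than PET-2.\n"
        )
        return header + out.to_string(index=False)
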