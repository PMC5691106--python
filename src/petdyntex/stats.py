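"""Paired dual-time-point cohort statistics.

For every variable, the standard (PET-1) and delayed (PET-2) acquisitions
are compared with a paired test: Student's t for dependent samples when
the paired differences pass Shapiro-Wilk normality (alpha = 0.05), the
Wilcoxon signed-rank test otherwise.  The signed statistic follows the
convention that a negative value means the PET-1 value was lower than its
PET-2 counterpart.

Associations between textural and volume-based variables (MTV, TLG) use
Spearman's rank correlation; |r| > 0.75 is flagged as a strong
correlation, and cohorts can be stratified at MTV = 10 cm^3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import PairedCohort
from .io import FEATURE_COLUMNS, TEXTURE_COLUMNS

__all__ = [
    "TestResult",
    "CorrelationResult",
    "DegenerateTestError",
    "paired_compare",
    "spearman",
    "compare_timepoints",
    "results_to_frame",
    "texture_volume_table",
    "stratify_by_mtv",
]

STRONG_CORRELATION = 0.75


class DegenerateTestError(ValueError):
    """The paired test is undefined (e.g. all differences are zero)."""


@dataclass(frozen=True)
class TestResult:
    """Paired comparison of one variable between PET-1 and PET-2."""

    variable: str
    n: int
    mean_pet1: float
    sd_pet1: float
    mean_pet2: float
    sd_pet2: float
    test: str  # "paired-t" | "wilcoxon"
    statistic: float  # negative <=> PET-1 lower than PET-2
    p_value: float
    alpha: float = 0.05
    p_adjusted: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")

    @property
    def effective_p(self) -> float:
        return self.p_value if self.p_adjusted is None else self.p_adjusted

    @property
    def significant(self) -> bool:
        return bool(self.effective_p < self.alpha)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman association between two variables."""

    variable_x: str
    variable_y: str
    r: float
    p_value: float

    def __post_init__(self):
        if not (np.isnan(self.r) or -1.0 <= self.r <= 1.0):
            raise ValueError("correlation outside [-1, 1]")

    @property
    def strong(self) -> bool:
        return bool(not np.isnan(self.r) and abs(self.r) > STRONG_CORRELATION)


def _signed_wilcoxon(d: np.ndarray) -> tuple[float, float]:
    """Wilcoxon signed-rank Z and two-sided p, tie-corrected normal approximation.

    Zero differences are discarded.  Z is built from the positive-rank sum
    of d = PET1 - PET2, so mostly-negative differences (PET-1 lower) give a
    negative Z, matching the reporting convention.
    """
    nz = d[d != 0]
    n = nz.size
    if n == 0:
        raise DegenerateTestError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(np.abs(nz), return_counts=True)
    var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
    if var <= 0:
        raise DegenerateTestError("zero variance in signed ranks")
    z = (w_plus - mu) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return z, min(1.0, p)


def paired_compare(cohort: PairedCohort, variable: str, alpha: float = 0.05) -> TestResult:
    """Paired PET-1 vs PET-2 comparison of one variable.

    Normality of the paired differences is decided by Shapiro-Wilk at
    alpha = 0.05: paired t when normal, Wilcoxon signed-rank otherwise
    (constant nonzero differences, whose normality is undefined, also take
    the Wilcoxon branch).
    """
    x1, x2 = cohort.pair_values(variable)
    n = x1.size
    if n < 3:
        raise ValueError("at least 3 complete pairs are required")
    d = x1 - x2
    if np.all(d == 0):
        raise DegenerateTestError(
            f"all paired differences of {variable!r} are zero; the test is degenerate"
        )
    if np.ptp(d) > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # shapiro warns for n > 5000
            normal = sps.shapiro(d).pvalue > 0.05
    else:
        normal = False  # constant nonzero differences: undefined variance path
    if normal:
        res = sps.ttest_rel(x1, x2)
        test, stat, p = "paired-t", float(res.statistic), float(res.pvalue)
    else:
        z, p = _signed_wilcoxon(d)
        test, stat = "wilcoxon", float(z)
    return TestResult(
        variable=variable,
        n=int(n),
        mean_pet1=float(x1.mean()),
        sd_pet1=float(x1.std(ddof=1)),
        mean_pet2=float(x2.mean()),
        sd_pet2=float(x2.std(ddof=1)),
        test=test,
        statistic=stat,
        p_value=p,
        alpha=alpha,
    )


def spearman(x, y, variable_x: str = "x", variable_y: str = "y") -> CorrelationResult:
    """Spearman rank correlation with midranks for ties.

    Degenerate inputs (either argument constant) yield r = NaN with a
    warning rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn(
            f"Spearman correlation undefined for constant input "
            f"({variable_x!r} vs {variable_y!r}); returning NaN",
            stacklevel=2,
        )
        return CorrelationResult(variable_x, variable_y, float("nan"), float("nan"))
    res = sps.spearmanr(x, y)
    return CorrelationResult(variable_x, variable_y, float(res.statistic), float(res.pvalue))


def compare_timepoints(
    cohort: PairedCohort,
    alpha: float = 0.05,
    correction: str | None = None,
) -> list[TestResult]:
    """One paired TestResult per variable (5 metabolic + 18 textural).

    ``correction`` in {None, "holm", "bonferroni"} adjusts the p column
    for multiplicity; the significance flag then uses adjusted p-values.
    """
    if correction not in (None, "none", "holm", "bonferroni"):
        raise ValueError("correction must be None, 'holm' or 'bonferroni'")
    variables = [v for v in FEATURE_COLUMNS if v in cohort.feature_names]
    results = [paired_compare(cohort, v, alpha=alpha) for v in variables]
    if correction in ("holm", "bonferroni"):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([r.p_value for r in results], alpha=alpha, method=correction)[1]
        results = [
            TestResult(**{**r.__dict__, "p_adjusted": float(pa)})
            for r, pa in zip(results, adj)
        ]
    return results


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    """Tabulate TestResults, one row per variable."""
    rows = []
    for r in results:
        rows.append(
            {
                "variable": r.variable,
                "n": r.n,
                "mean_pet1": r.mean_pet1,
                "sd_pet1": r.sd_pet1,
                "mean_pet2": r.mean_pet2,
                "sd_pet2": r.sd_pet2,
                "test": r.test,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)


def texture_volume_table(cohort: PairedCohort) -> pd.DataFrame:
    """Spearman associations of textural features with MTV and TLG.

    Rows: each textural variable at each timepoint; columns: r, p and
    strong flag against MTV and TLG at each timepoint.
    """
    rows = []
    for tex in TEXTURE_COLUMNS:
        for tex_tp in ("PET1", "PET2"):
            xv = cohort.values(tex, tex_tp)
            row: dict = {"texture": tex, "texture_timepoint": tex_tp}
            for vol_var in ("mtv_cm3", "tlg"):
                for vol_tp in ("PET1", "PET2"):
                    yv = cohort.values(vol_var, vol_tp)
                    c = spearman(xv, yv, f"{tex}({tex_tp})", f"{vol_var}({vol_tp})")
                    key = f"{vol_var}_{vol_tp}"
                    row[f"r_{key}"] = c.r
                    row[f"p_{key}"] = c.p_value
                    row[f"strong_{key}"] = c.strong
            rows.append(row)
    return pd.DataFrame(rows)


def stratify_by_mtv(
    cohort: PairedCohort,
    cutoff_cm3: float = 10.0,
    timepoint: str = "PET1",
) -> tuple[PairedCohort, PairedCohort]:
    """Split into group I (MTV <= cutoff) and group II (MTV > cutoff).

    The boundary value goes to group I.  An empty group triggers a warning.
    """
    mtv = cohort.values("mtv_cm3", timepoint)
    patients = np.asarray(cohort.patients, dtype=object)
    group1 = cohort.subset(patients[mtv <= cutoff_cm3])
    group2 = cohort.subset(patients[mtv > cutoff_cm3])
    for name, g in (("I (MTV <= cutoff)", group1), ("II (MTV > cutoff)", group2)):
        if len(g) == 0:
            warnings.warn(f"MTV stratum {name} is empty", stacklevel=2)
    return group1, group2
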