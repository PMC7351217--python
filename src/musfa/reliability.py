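"""Agreement and reliability statistics for subjects x raters designs.

Implements the two-way ANOVA decomposition with one observation per
cell, single-rater ICCs (consistency and absolute agreement, each with
an F-based 95% CI), the Sorensen-Dice mask overlap, SEM and SEM%, paired
t-tests, and an ICC hypothesis-test sample-size calculation.

The ICC point estimators are the standard single-rater forms::

    consistency        (MSR - MSE) / (MSR + (k-1) MSE)
    absolute agreement (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

and confidence intervals follow the McGraw-Wong constructions. Note the
consistency/absolute-agreement distinction is orthogonal to the
random/mixed model choice for single-rater point estimates; results
carry an explicit ``model_label`` rather than an ambiguous numeric tag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .image_io import ROIMask

#: ICC reliability bands; an estimate exactly at an edge takes the higher band.
BAND_EDGES = (0.5, 0.75, 0.9)
BAND_NAMES = ("poor", "moderate", "good", "excellent")


@dataclass(frozen=True)
class RatingsTable:
    """Complete n_subjects x k_raters grid of one parameter's measurements."""

    values: np.ndarray
    subject_ids: list[str] | None = None
    rater_ids: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValidationError("ratings must form a 2D subjects x raters grid")
        n, k = v.shape
        if n < 2 or k < 2:
            raise ValidationError(f"need >= 2 subjects and >= 2 raters, got {n}x{k}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("ratings table has missing or non-finite cells")
        object.__setattr__(self, "values", v)
        if self.subject_ids is None:
            object.__setattr__(self, "subject_ids", [f"S{i+1}" for i in range(n)])
        elif len(self.subject_ids) != n:
            raise ValidationError("subject_ids length mismatch")
        if self.rater_ids is None:
            object.__setattr__(self, "rater_ids", [f"R{j+1}" for j in range(k)])
        elif len(self.rater_ids) != k:
            raise ValidationError("rater_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k_raters(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class MeanSquares:
    ms_rows: float
    ms_cols: float
    ms_error: float
    df_rows: int
    df_cols: int
    df_error: int


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    model_label: str
    reliability_band: str
    degenerate: bool = False


def two_way_anova(table: RatingsTable) -> MeanSquares:
    """Two-way subjects x raters decomposition, one observation per cell."""
    y = table.values
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    # Residual form (not SS_total minus the others): exact zeros survive
    # instead of turning into cancellation noise.
    resid = y - row_means[:, None] - col_means[None, :] + grand
    ss_error = float(np.sum(resid**2))
    return MeanSquares(
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1),
        ms_error=ss_error / ((n - 1) * (k - 1)),
        df_rows=n - 1,
        df_cols=k - 1,
        df_error=(n - 1) * (k - 1),
    )


def reliability_band(estimate: float) -> str:
    """Map an ICC estimate to poor/moderate/good/excellent (0.5/0.75/0.9)."""
    idx = sum(estimate >= edge for edge in BAND_EDGES)
    return BAND_NAMES[idx]


def _consistency_ci(msr, mse, n, k, alpha):
    f_obs = msr / mse
    df1, df2 = n - 1, (n - 1) * (k - 1)
    fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    return (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)


def _agreement_ci(msr, msc, mse, n, k, alpha, est):
    # McGraw & Wong A,1 interval via Satterthwaite df.
    a = (k * est) / (n * (1 - est)) if est < 1 else np.inf
    b = 1 + (k * est * (n - 1)) / (n * (1 - est)) if est < 1 else np.inf
    if not np.isfinite(a):
        return 1.0, 1.0
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else 1.0
    f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
    with np.errstate(invalid="ignore", over="ignore"):
        lower = n * (msr - f_low * mse) / (
            f_low * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f_up * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_up * msr
        )
    # Tiny Satterthwaite df can push the F quantiles to infinity; take the
    # corresponding limits of the bound expressions instead of NaN.
    if not np.isfinite(lower):
        denom_limit = k * msc + (k * n - k - n) * mse
        lower = -n * mse / denom_limit if denom_limit > 0 else -1.0
    if not np.isfinite(upper):
        upper = 1.0
    return lower, upper


def icc(
    table: RatingsTable,
    form: str = "consistency",
    model: str = "two_way_mixed",
    alpha: float = 0.05,
) -> ICCResult:
    """Single-rater two-way ICC with a 95% (or ``1 - alpha``) CI.

    ``form`` is ``"consistency"`` or ``"absolute_agreement"``; ``model``
    (``"two_way_random"`` / ``"two_way_mixed"``) is recorded in the label
    (the single-rater point estimates coincide across the two models).
    """
    if form not in ("consistency", "absolute_agreement"):
        raise ValidationError(f"unknown ICC form {form!r}")
    if model not in ("two_way_random", "two_way_mixed"):
        raise ValidationError(f"unknown ICC model {model!r}")
    ms = two_way_anova(table)
    n, k = table.n_subjects, table.k_raters
    label = f"{model}:{form}:single"
    total_var = ms.ms_rows + ms.ms_cols + ms.ms_error
    if total_var <= 0:
        return ICCResult(
            estimate=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            model_label=label, reliability_band="undefined", degenerate=True,
        )
    if form == "consistency":
        denom = ms.ms_rows + (k - 1) * ms.ms_error
        est = (ms.ms_rows - ms.ms_error) / denom if denom > 0 else float("nan")
        if ms.ms_error == 0:
            low, high = est, est
        else:
            low, high = _consistency_ci(ms.ms_rows, ms.ms_error, n, k, alpha)
    else:
        denom = ms.ms_rows + (k - 1) * ms.ms_error + (k / n) * (ms.ms_cols - ms.ms_error)
        est = (ms.ms_rows - ms.ms_error) / denom if denom > 0 else float("nan")
        low, high = _agreement_ci(ms.ms_rows, ms.ms_cols, ms.ms_error, n, k, alpha, est)
    if not math.isfinite(est):
        return ICCResult(
            estimate=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            model_label=label, reliability_band="undefined", degenerate=True,
        )
    low = min(low, est)
    high = min(max(high, est), 1.0)
    return ICCResult(
        estimate=float(est), ci_low=float(low), ci_high=float(high),
        model_label=label, reliability_band=reliability_band(est),
    )


def dice_coefficient(a: ROIMask, b: ROIMask) -> float:
    """Sorensen-Dice overlap 2|A&B| / (|A| + |B|) between two masks."""
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    size_a = int(a.mask.sum())
    size_b = int(b.mask.sum())
    if size_a + size_b == 0:
        warnings.warn("both masks empty; Dice defined as 1.0", stacklevel=2)
        return 1.0
    inter = int(np.logical_and(a.mask, b.mask).sum())
    return 2.0 * inter / (size_a + size_b)


def sem(table: RatingsTable) -> tuple[float, float]:
    """(SEM, SEM%) where SEM = sqrt(MS_error) of the two-way ANOVA and
    SEM% = 100 * SEM / grand mean of all cells."""
    ms = two_way_anova(table)
    sem_value = math.sqrt(ms.ms_error)
    grand = float(table.values.mean())
    if grand == 0:
        warnings.warn("grand mean is 0; SEM%% undefined", stacklevel=2)
        return sem_value, float("nan")
    return sem_value, 100.0 * sem_value / grand


def paired_t_test(x, y) -> tuple[float, float]:
    """Classical paired t-test on differences, df = n - 1, two-sided p.

    All-zero differences give (0, 1). Zero-variance nonzero differences
    give (+/-inf, 0) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValidationError("paired samples must be equal-length 1D arrays with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        warnings.warn("zero variance of nonzero differences; t is infinite", stacklevel=2)
        return math.copysign(math.inf, d.mean()), 0.0
    t = d.mean() / (sd / math.sqrt(len(d)))
    p = 2 * stats.t.sf(abs(t), df=len(d) - 1)
    return float(t), float(p)


def icc_sample_size(
    rho_alt: float,
    rho_null: float,
    alpha: float = 0.05,
    power: float = 0.80,
    k: int = 2,
) -> int:
    """Subjects needed to reject ICC = rho_null when truly rho_alt.

    Uses the ANOVA-F / log-ratio construction (Walter-Eliasziw-Donner,
    the basis of Zou's ICC planning methodology) with two-sided alpha::

        n = 1 + 2k (z_{1-a/2} + z_{power})^2 / ((k-1) (ln C0)^2)
        C0 = (1 + k r0/(1-r0)) / (1 + k r1/(1-r1))

    rounded up to an integer.
    """
    if not (0 < rho_alt < 1):
        raise ValidationError("rho_alt must be in (0, 1)")
    if not (0 <= rho_null < 1):
        raise ValidationError("rho_null must be in [0, 1)")
    if rho_alt <= rho_null:
        raise ValidationError("rho_alt must exceed rho_null")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValidationError("alpha and power must be in (0, 1)")
    if k < 2:
        raise ValidationError("k must be >= 2 raters")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    c0 = (1 + k * rho_null / (1 - rho_null)) / (1 + k * rho_alt / (1 - rho_alt))
    n = 1 + 2 * k * z**2 / ((k - 1) * math.log(c0) ** 2)
    return math.ceil(n - 1e-12)


def kernel_count_diff(count_a: float, count_b: float) -> float:
    """Absolute kernel-count difference as a percent of the pair mean."""
    if count_a < 0 or count_b < 0:
        raise ValidationError("kernel counts must be >= 0")
    mean = (count_a + count_b) / 2.0
    if mean == 0:
        raise ValidationError("kernel count difference undefined when both counts are 0")
    return 100.0 * abs(count_a - count_b) / mean
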