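"""Validation metrics and normality-gated paired comparisons.

Sensor validation: per-participant RMSE between device-estimated and
motion-capture-measured step lengths, expressed as a percent of that
participant's mean measured step length, reported as mean +/- sd
across participants; plus Pearson's R over all participants' steps
pooled, with the conventional strength bands (0.7-0.9 "strong").

Condition comparisons: paired differences are first checked for
normality with a Lilliefors-corrected Kolmogorov-Smirnov test (the
correction is required when the null parameters are estimated from the
sample); if normality is not rejected at 0.05 a paired two-tailed
t-test is used, otherwise a Wilcoxon signed-rank test (Pratt handling
of zero differences).  Significance at alpha <= 0.05, no
multiple-comparison correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "ValidationReport",
    "ComparisonResult",
    "step_length_rmse_pct",
    "pooled_pearson",
    "correlation_strength",
    "compare_conditions",
    "build_validation_report",
]

ALPHA = 0.05


def step_length_rmse_pct(
    estimates: np.ndarray, measured: np.ndarray
) -> float:
    """RMSE of (estimated - measured) step length as a percent of the
    mean measured step length, for one participant."""
    est = np.asarray(estimates, dtype=float)
    meas = np.asarray(measured, dtype=float)
    if est.shape != meas.shape:
        raise ValueError(
            f"unpaired series: {est.shape} estimates vs {meas.shape} measured"
        )
    if est.size == 0:
        raise ValueError("empty step series")
    denom = float(np.mean(meas))
    if denom <= 0:
        raise ValueError("mean measured step length must be positive")
    rmse = float(np.sqrt(np.mean((est - meas) ** 2)))
    return 100.0 * rmse / denom


def correlation_strength(r: float) -> str:
    """Conventional label: 0.7-0.9 strong, above 0.9 very strong."""
    a = abs(r)
    if a >= 0.9:
        return "very strong"
    if a >= 0.7:
        return "strong"
    if a >= 0.5:
        return "moderate"
    return "weak"


def pooled_pearson(
    estimates: np.ndarray, measured: np.ndarray
) -> tuple[float, float, str]:
    """Pearson R over all pooled step pairs, with p-value and strength
    label.  Requires at least 3 pairs and nonzero variance on both
    sides."""
    est = np.asarray(estimates, dtype=float).ravel()
    meas = np.asarray(measured, dtype=float).ravel()
    if est.shape != meas.shape:
        raise ValueError("pooled series must be paired")
    if est.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(est) == 0 or np.std(meas) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(est, meas)
    r = float(res.statistic)
    return r, float(res.pvalue), correlation_strength(r)


@dataclass(frozen=True)
class ValidationReport:
    """Step-length validation across a cohort."""

    rmse_pct: dict[str, float]
    rmse_pct_mean: float
    rmse_pct_sd: float
    pearson_r: float
    pearson_p: float
    r_strength: str
    n_steps: int

    def as_dict(self) -> dict:
        return asdict(self)


def build_validation_report(
    per_participant: dict[str, tuple[np.ndarray, np.ndarray]]
) -> ValidationReport:
    """Validation report from ``{participant: (estimates, measured)}``.

    RMSE% is computed per participant and summarized mean +/- sd;
    Pearson R is computed over all steps pooled.
    """
    rmse = {
        pid: step_length_rmse_pct(est, meas)
        for pid, (est, meas) in per_participant.items()
    }
    pooled_est = np.concatenate([np.asarray(e) for e, _ in per_participant.values()])
    pooled_meas = np.concatenate([np.asarray(m) for _, m in per_participant.values()])
    r, p, strength = pooled_pearson(pooled_est, pooled_meas)
    vals = np.array(list(rmse.values()))
    return ValidationReport(
        rmse_pct=rmse,
        rmse_pct_mean=float(vals.mean()),
        rmse_pct_sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        pearson_r=r,
        pearson_p=p,
        r_strength=strength,
        n_steps=int(pooled_est.size),
    )


@dataclass(frozen=True)
class ComparisonResult:
    """One paired condition comparison for one outcome."""

    outcome: str
    pair: tuple[str, str]
    differences: tuple[float, ...]
    normality_p: float
    test_used: str  # "t" | "wilcoxon"
    statistic: float
    p_value: float
    mean_change_pct: float
    sd_change_pct: float
    significant: bool
    alpha: float = ALPHA
    notes: str = ""

    def as_dict(self) -> dict:
        d = asdict(self)
        d["pair"] = list(self.pair)
        d["differences"] = list(self.differences)
        return d


def compare_conditions(
    means_a: np.ndarray,
    means_b: np.ndarray,
    outcome: str = "",
    pair: tuple[str, str] = ("A", "B"),
) -> ComparisonResult:
    """Paired comparison of per-participant means between conditions.

    Differences ``b - a`` are tested for normality (Lilliefors); the
    paired two-tailed t-test is used unless normality is rejected at
    0.05, in which case the Wilcoxon signed-rank test (Pratt
    zero-handling) is used.  Percent change is per-participant
    ``(b - a) / a * 100``, reported mean +/- sd.
    """
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    n = a.size
    if n < 3:
        raise ValueError(f"need at least 3 participants, got {n}")
    diffs = b - a
    pct = 100.0 * diffs / a
    mean_pct = float(np.mean(pct))
    sd_pct = float(np.std(pct, ddof=1))

    if np.all(diffs == 0):
        # identical conditions: no evidence against the null by convention
        return ComparisonResult(
            outcome=outcome, pair=pair, differences=tuple(diffs),
            normality_p=1.0, test_used="t", statistic=0.0, p_value=1.0,
            mean_change_pct=mean_pct, sd_change_pct=sd_pct,
            significant=False, notes="all paired differences zero",
        )

    if n < 4:
        # too few pairs to test normality; fall back to the t branch
        res = sps.ttest_rel(b, a)
        return ComparisonResult(
            outcome=outcome, pair=pair, differences=tuple(diffs),
            normality_p=float("nan"), test_used="t",
            statistic=float(res.statistic), p_value=float(res.pvalue),
            mean_change_pct=mean_pct, sd_change_pct=sd_pct,
            significant=bool(res.pvalue <= ALPHA),
            notes="n < 4: normality gate not applicable",
        )

    _, norm_p = lilliefors(diffs, dist="norm")
    norm_p = float(norm_p)
    if norm_p < ALPHA:
        method = "exact" if n <= 25 and not np.any(diffs == 0) else "auto"
        res = sps.wilcoxon(diffs, zero_method="pratt", method=method)
        test_used = "wilcoxon"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        res = sps.ttest_rel(b, a)
        test_used = "t"
        stat, p = float(res.statistic), float(res.pvalue)

    return ComparisonResult(
        outcome=outcome, pair=pair, differences=tuple(diffs),
        normality_p=norm_p, test_used=test_used, statistic=stat,
        p_value=p, mean_change_pct=mean_pct, sd_change_pct=sd_pct,
        significant=bool(p <= ALPHA),
    )
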