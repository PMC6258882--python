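"""Intersite agreement and inference statistics for paired ROI means.

Implements the small-sample-corrected coefficient of variation, Pearson
correlation with its t-transform p-value, the paired t-test, the TOST
equivalence procedure, Bland-Altman agreement analysis, a noncentral-t
power/sample-size calculation for paired designs, and a cohort-level
report assembling all of them per ROI.

Conventions: sample SDs use the n-1 denominator throughout; paired
differences are site1 - site2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "TostResult",
    "BlandAltmanResult",
    "PowerSpec",
    "PairedTResult",
    "corrected_cov",
    "pearson_r_p",
    "pearson_p_from_r",
    "paired_t",
    "p_from_t",
    "tost",
    "bland_altman",
    "paired_power",
    "required_sample_size",
    "cohort_report",
    "ReproReport",
]


@dataclass(frozen=True)
class PairedSample:
    """Per-participant values measured at two sites (same units, no gaps)."""

    participants: np.ndarray
    site1: np.ndarray
    site2: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.participants)
        s1 = np.asarray(self.site1, dtype=float)
        s2 = np.asarray(self.site2, dtype=float)
        if not (p.size == s1.size == s2.size):
            raise ValueError("participants, site1 and site2 must have equal length")
        if s1.size < 2:
            raise ValueError("need at least two pairs")
        if not (np.all(np.isfinite(s1)) and np.all(np.isfinite(s2))):
            raise ValueError("paired samples must not contain missing values")
        object.__setattr__(self, "participants", p)
        object.__setattr__(self, "site1", s1)
        object.__setattr__(self, "site2", s2)

    @property
    def n(self) -> int:
        return self.site1.size

    @property
    def differences(self) -> np.ndarray:
        return self.site1 - self.site2


def corrected_cov(values: np.ndarray) -> float:
    """Small-sample-corrected coefficient of variation, in percent.

    ``100 * (SD / mean) * (1 + 1/(4n))`` with the n-1 SD denominator.  At
    n = 2 the correction factor is 1.125.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values for a COV")
    mean = v.mean()
    if mean <= 0:
        raise ValueError(f"COV undefined for non-positive mean ({mean})")
    sd = float(np.std(v, ddof=1))
    return 100.0 * (sd / mean) * (1.0 + 1.0 / (4.0 * v.size))


def cov_correction_factor(n: int) -> float:
    """The small-sample COV bias-correction multiplier ``1 + 1/(4n)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1.0 + 1.0 / (4.0 * n)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via the t-transform with n-2 df."""
    if n < 3:
        raise ValueError("need n >= 3")
    if not (-1 <= r <= 1):
        raise ValueError(f"r must be in [-1, 1], got {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def pearson_r_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation and its two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson r undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, pearson_p_from_r(r, x.size)


@dataclass(frozen=True)
class PairedTResult:
    mean_diff: float
    se: float
    t: float
    df: int
    p: float
    ci95: tuple[float, float]


def p_from_t(t: float, df: int) -> float:
    """Two-sided tail probability of a central t statistic."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(2.0 * sps.t.sf(abs(t), df))


def paired_t(sample: PairedSample) -> PairedTResult:
    """Paired t-test on site1 - site2 with 95% CI of the mean difference."""
    d = sample.differences
    n = sample.n
    mean_diff = float(d.mean())
    sd = float(np.std(d, ddof=1))
    se = sd / np.sqrt(n)
    df = n - 1
    if se == 0.0:
        t_stat = 0.0 if mean_diff == 0.0 else np.inf * np.sign(mean_diff)
        p = 1.0 if mean_diff == 0.0 else 0.0
        return PairedTResult(mean_diff, 0.0, float(t_stat), df, p, (mean_diff, mean_diff))
    t_stat = mean_diff / se
    p = p_from_t(t_stat, df)
    tq = float(sps.t.ppf(0.975, df))
    ci = (mean_diff - tq * se, mean_diff + tq * se)
    return PairedTResult(mean_diff, float(se), float(t_stat), df, p, ci)


@dataclass(frozen=True)
class TostResult:
    mean_diff: float
    se: float
    df: int
    bound: float
    p_lower: float  # H0: diff <= -bound
    p_upper: float  # H0: diff >= +bound
    p: float  # max of the two one-sided p-values
    ci90: tuple[float, float]

    @property
    def equivalent_at(self) -> float:
        """Largest alpha grid value is up to the caller; compare ``p < alpha``."""
        return self.p


def tost(
    sample: PairedSample | None = None,
    bound: float = 0.005,
    *,
    summary: tuple[float, float, int] | None = None,
) -> TostResult:
    """Two one-sided tests of equivalence against symmetric bounds.

    Accepts either raw paired data or a printed summary ``(mean_diff, se,
    df)`` so published results can be verified without raw values.  The
    overall p is the larger of the two one-sided p-values; equivalence is
    declared when it falls below the chosen alpha.
    """
    if bound <= 0:
        raise ValueError(f"equivalence bound must be > 0, got {bound}")
    if (sample is None) == (summary is None):
        raise ValueError("provide exactly one of sample or summary")
    if sample is not None:
        res = paired_t(sample)
        mean_diff, se, df = res.mean_diff, res.se, res.df
    else:
        mean_diff, se, df = summary
        df = int(df)
    if se <= 0:
        raise ValueError(f"standard error must be > 0, got {se}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")

    t_lower = (mean_diff + bound) / se
    t_upper = (mean_diff - bound) / se
    p_lower = float(sps.t.sf(t_lower, df))  # reject when diff > -bound
    p_upper = float(sps.t.cdf(t_upper, df))  # reject when diff < +bound
    tq = float(sps.t.ppf(0.95, df))
    ci90 = (mean_diff - tq * se, mean_diff + tq * se)
    return TostResult(
        mean_diff=float(mean_diff),
        se=float(se),
        df=df,
        bound=float(bound),
        p_lower=p_lower,
        p_upper=p_upper,
        p=max(p_lower, p_upper),
        ci90=ci90,
    )


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    slope: float  # OLS slope of differences vs pair means; NaN if degenerate
    slope_p: float

    @property
    def loa(self) -> tuple[float, float]:
        return (self.loa_lower, self.loa_upper)


def bland_altman(sample: PairedSample) -> BlandAltmanResult:
    """Bland-Altman agreement: bias, +/-1.96 SD limits, proportional-bias slope."""
    d = sample.differences
    means = 0.5 * (sample.site1 + sample.site2)
    bias = float(d.mean())
    sd = float(np.std(d, ddof=1))
    loa_lo, loa_hi = bias - 1.96 * sd, bias + 1.96 * sd
    slope = slope_p = float("nan")
    if sample.n >= 3 and np.std(means) > 0:
        if np.std(d) == 0:
            slope, slope_p = 0.0, 1.0
        else:
            fit = sps.linregress(means, d)
            slope, slope_p = float(fit.slope), float(fit.pvalue)
    return BlandAltmanResult(bias, sd, float(loa_lo), float(loa_hi), slope, slope_p)


@dataclass(frozen=True)
class PowerSpec:
    """Design of a paired t-test power calculation."""

    effect_size: float  # Cohen's d of the paired differences
    alpha: float = 0.05  # two-sided
    power: float = 0.90

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if not (0 < self.alpha < 1) or not (0 < self.power < 1):
            raise ValueError("alpha and power must be in (0, 1)")


def paired_power(d: float, n: int, alpha: float = 0.05) -> float:
    """Power of a two-sided paired t-test at effect size d and n pairs,
    from the noncentral t distribution with ncp = d*sqrt(n)."""
    if n < 2:
        return 0.0
    df = n - 1
    ncp = d * np.sqrt(n)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def required_sample_size(spec: PowerSpec, n_max: int = 100_000) -> int:
    """Smallest n with paired-t power >= the target at the given design."""
    for n in range(2, n_max + 1):
        if paired_power(spec.effect_size, n, spec.alpha) >= spec.power:
            return n
    raise ValueError(
        f"power {spec.power} unreachable for d={spec.effect_size} within n<={n_max}"
    )


@dataclass(frozen=True)
class ReproReport:
    """Per-ROI reproducibility statistics of a two-site cohort."""

    covs: pd.DataFrame  # columns: roi, participant, cov_percent
    mean_covs: pd.DataFrame  # columns: roi, mean_cov_percent, n_participants
    agreement: pd.DataFrame  # per-roi Pearson/paired-t/TOST/Bland-Altman

    def summary_text(self) -> str:
        lines = ["Intersite reproducibility report", "=" * 32, ""]
        lines.append("Mean corrected COV per ROI (%):")
        for _, row in self.mean_covs.iterrows():
            lines.append(f"  {row['roi']}: {row['mean_cov_percent']:.2f}")
        lines.append("")
        for _, row in self.agreement.iterrows():
            lines.append(
                f"{row['roi']}: r={row['pearson_r']:.2f} (p={row['pearson_p']:.3g}), "
                f"paired t={row['t']:.3f} (p={row['t_p']:.3g}), "
                f"bias={row['bias']:.4g}, LoA=({row['loa_lower']:.4g}, "
                f"{row['loa_upper']:.4g}), TOST p={row['tost_p']:.3g}"
            )
        return "\n".join(lines)


def cohort_report(
    roi_table: pd.DataFrame,
    tost_bound: float = 0.005,
) -> ReproReport:
    """Assemble all intersite statistics from a long-format ROI table.

    ``roi_table`` columns: participant, site, roi, mean_mwf (the CSV schema
    written by the ROI stage).  Exactly two sites are expected and every
    (participant, roi) must be present at both; missing pairs raise with
    the offending participants listed.
    """
    required = {"participant", "site", "roi", "mean_mwf"}
    missing = required - set(roi_table.columns)
    if missing:
        raise ValueError(f"roi table lacks columns: {sorted(missing)}")
    sites = sorted(roi_table["site"].unique())
    if len(sites) != 2:
        raise ValueError(f"expected exactly 2 sites, found {sites}")

    wide = roi_table.pivot_table(
        index=["roi", "participant"], columns="site", values="mean_mwf"
    )
    unmatched = wide[wide.isna().any(axis=1)]
    if len(unmatched):
        raise ValueError(
            "participants missing at one site: "
            + ", ".join(f"{roi}/{p}" for roi, p in unmatched.index)
        )

    cov_rows = []
    agree_rows = []
    for roi, grp in wide.groupby(level="roi"):
        s1 = grp[sites[0]].to_numpy()
        s2 = grp[sites[1]].to_numpy()
        participants = grp.index.get_level_values("participant")
        for pid, a, b in zip(participants, s1, s2):
            cov_rows.append(
                {
                    "roi": roi,
                    "participant": pid,
                    "cov_percent": corrected_cov(np.array([a, b])),
                }
            )
        sample = PairedSample(np.asarray(participants), s1, s2)
        t_res = paired_t(sample)
        ba = bland_altman(sample)
        if sample.n >= 3 and np.std(s1) > 0 and np.std(s2) > 0:
            r, r_p = pearson_r_p(s1, s2)
        else:
            r, r_p = float("nan"), float("nan")
        if t_res.se > 0:
            tost_res = tost(sample, bound=tost_bound)
            tost_p = tost_res.p
        else:
            tost_p = 0.0 if abs(t_res.mean_diff) < tost_bound else 1.0
        agree_rows.append(
            {
                "roi": roi,
                "n": sample.n,
                "pearson_r": r,
                "pearson_p": r_p,
                "mean_diff": t_res.mean_diff,
                "se": t_res.se,
                "t": t_res.t,
                "t_p": t_res.p,
                "ci95_lower": t_res.ci95[0],
                "ci95_upper": t_res.ci95[1],
                "tost_p": tost_p,
                "bias": ba.bias,
                "loa_lower": ba.loa_lower,
                "loa_upper": ba.loa_upper,
                "ba_slope": ba.slope,
                "ba_slope_p": ba.slope_p,
            }
        )

    covs = pd.DataFrame(cov_rows)
    mean_covs = (
        covs.groupby("roi", as_index=False)
        .agg(mean_cov_percent=("cov_percent", "mean"), n_participants=("cov_percent", "size"))
    )
    return ReproReport(covs, mean_covs, pd.DataFrame(agree_rows))
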