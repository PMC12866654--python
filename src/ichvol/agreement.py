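"""Method-comparison statistics for paired volume measurements.

Implements the agreement workflow used in clinical method-comparison
studies of haematoma volumetry:

1. restrict to complete cases (both methods measured);
2. Bland-Altman limits of agreement (LoA), mean difference +/- 1.96 SD, on
   absolute (mL) or percent differences;
3. a heteroscedasticity screen — Kendall's tau-b between absolute
   differences and pairwise means; tau above a threshold (default 0.1)
   triggers a log transformation, retained only if it reduces tau;
4. back-transformation of log-scale LoA to mean-dependent limits of the
   form ``slope * X`` where X is the pairwise mean;
5. one-way random-effects ICC for inter-observer variability (unbalanced
   designs allowed), paired t-tests and Shapiro-Wilk normality checks;
6. subgroup analyses (IVH presence, location, 40 mL volume split) and a
   clinical-acceptability rule: percent LoA within +/-10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedSample",
    "LogBranch",
    "BlandAltmanResult",
    "ICCResult",
    "TestResult",
    "paired_complete_cases",
    "differences",
    "bland_altman_limits",
    "kendall_tau_het",
    "back_transform_loa",
    "slope_to_ratio",
    "adaptive_log_loa",
    "icc_oneway",
    "paired_t_test",
    "shapiro_wilk",
    "subgroup_agreement",
    "acceptance_check",
]

Z_LOA = 1.96  # multiplier defining the 95% limits of agreement


@dataclass(frozen=True)
class PairedSample:
    """Aligned complete-case measurements of the same cases by two methods."""

    case_ids: tuple[str, ...]
    m1: np.ndarray
    m2: np.ndarray
    method1: str = "m1"
    method2: str = "m2"

    def __post_init__(self) -> None:
        if not (len(self.case_ids) == len(self.m1) == len(self.m2)):
            raise ValueError("case_ids, m1 and m2 must be aligned")
        if len(self.m1) < 2:
            raise ValueError("a paired sample needs at least 2 complete pairs")
        if np.any(~np.isfinite(self.m1)) or np.any(~np.isfinite(self.m2)):
            raise ValueError("paired samples must be complete (no missing values)")

    @property
    def n(self) -> int:
        return len(self.m1)


@dataclass(frozen=True)
class LogBranch:
    """Log-scale quantities of a heteroscedasticity-adapted analysis."""

    tau_log: float
    mean_log_diff: float
    sd_log_diff: float
    loa_log_low: float
    loa_log_high: float
    ratio_low: float
    ratio_high: float
    slope_low: float
    slope_high: float


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland-Altman summary for one method pair (one mode, one stratum)."""

    n: int
    mode: str  # "absolute" | "percent"
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    tau_raw: float
    heteroscedastic: bool
    log_branch: LogBranch | None = None
    estimable: bool = True


@dataclass(frozen=True)
class ICCResult:
    """One-way random-effects, single-measurement intraclass correlation."""

    icc: float
    ms_between: float
    ms_within: float
    n_subjects: int
    mean_raters_per_subject: float


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    name: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value must lie in [0, 1]")


# ---------------------------------------------------------------------------
# pairing and differences
# ---------------------------------------------------------------------------

def paired_complete_cases(records: pd.DataFrame, method1: str,
                          method2: str) -> PairedSample:
    """Complete-case intersection of two methods, order-stable by case_id.

    When a method has several readings per case (repeat ABC/2 readers) the
    first row wins — matching the convention that only the first reading
    enters between-method comparisons.
    """
    for m in (method1, method2):
        if m not in set(records["method"]):
            raise ValueError(f"method {m!r} absent from the measurement table")

    def per_case(method: str) -> pd.Series:
        sub = records[records["method"] == method]
        sub = sub.drop_duplicates(subset="case_id", keep="first")
        sub = sub[~sub["missed"].astype(bool) & sub["volume_mL"].notna()]
        return sub.set_index("case_id")["volume_mL"]

    v1, v2 = per_case(method1), per_case(method2)
    common = sorted(set(v1.index) & set(v2.index))
    if len(common) < 2:
        raise ValueError(
            f"fewer than 2 complete pairs for {method1} vs {method2}"
        )
    return PairedSample(
        case_ids=tuple(common),
        m1=v1.loc[common].to_numpy(dtype=float),
        m2=v2.loc[common].to_numpy(dtype=float),
        method1=method1, method2=method2,
    )


def differences(paired: PairedSample, mode: str = "absolute"
                ) -> tuple[np.ndarray, np.ndarray]:
    """Paired differences (method1 - method2) and pairwise means.

    ``absolute`` returns mL differences; ``percent`` returns
    ``100 * (m1 - m2) / ((m1 + m2) / 2)``.
    """
    means = (paired.m1 + paired.m2) / 2.0
    if mode == "absolute":
        d = paired.m1 - paired.m2
    elif mode == "percent":
        if np.any(paired.m1 + paired.m2 == 0):
            raise ValueError("percent differences undefined when m1 + m2 == 0")
        d = 100.0 * (paired.m1 - paired.m2) / means
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return d, means


def bland_altman_limits(diffs: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, SD, LoA_low, LoA_high) with LoA = mean +/- 1.96 SD (n-1 SD)."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return mean, sd, mean - Z_LOA * sd, mean + Z_LOA * sd


def kendall_tau_het(diffs: np.ndarray, means: np.ndarray) -> float:
    """Kendall tau-b between |differences| and pairwise means.

    The standard screen for heteroscedasticity in a Bland-Altman analysis:
    a positive association says the disagreement grows with the measured
    volume.
    """
    d = np.abs(np.asarray(diffs, dtype=float))
    x = np.asarray(means, dtype=float)
    if d.size != x.size or d.size < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if np.all(d == d[0]) or np.all(x == x[0]):
        raise ValueError("Kendall tau undefined for all-tied input")
    tau = stats.kendalltau(d, x).statistic
    return float(tau)


def back_transform_loa(log_limit: float) -> float:
    """Slope of a mean-dependent limit from a log-scale LoA.

    A limit ``l`` on the scale of ``ln m1 - ln m2`` maps back to the
    original scale as the line ``slope * X`` through the Bland-Altman plot,
    with ``slope = 2 (e^l - 1) / (e^l + 1)``.
    """
    if not np.isfinite(log_limit):
        raise ValueError("log limit must be finite")
    r = np.exp(log_limit)
    return float(2.0 * (r - 1.0) / (r + 1.0))


def slope_to_ratio(slope: float) -> float:
    """Invert ``back_transform_loa``: the ratio limit whose slope is given."""
    if not -2 < slope < 2:
        raise ValueError("a back-transformed slope must lie in (-2, 2)")
    return float((2.0 + slope) / (2.0 - slope))


def adaptive_log_loa(paired: PairedSample, mode: str = "absolute",
                     tau_threshold: float = 0.1) -> BlandAltmanResult:
    """Bland-Altman analysis with the heteroscedasticity-adaptive log branch.

    Computes raw-scale limits of agreement; if Kendall's tau between
    |differences| and means exceeds ``tau_threshold`` the volumes are
    log-transformed and tau recomputed.  If the transformation reduces tau,
    the log-scale LoA are retained and back-transformed into mean-dependent
    limits ``slope * X``.

    Degenerate samples in which tau is undefined (all differences or all
    means tied, e.g. an error-free method pair) are treated as showing no
    heteroscedasticity.
    """
    d, means = differences(paired, mode)
    mean, sd, lo, hi = bland_altman_limits(d)
    try:
        tau_raw = kendall_tau_het(d, means)
    except ValueError:
        tau_raw = 0.0
    heteroscedastic = tau_raw > tau_threshold

    log_branch = None
    if heteroscedastic:
        if np.any(paired.m1 <= 0) or np.any(paired.m2 <= 0):
            bad = np.asarray(paired.case_ids)[
                (paired.m1 <= 0) | (paired.m2 <= 0)
            ]
            raise ValueError(
                f"log transform requires positive volumes; offending cases: "
                f"{bad[:5].tolist()}"
            )
        dlog = np.log(paired.m1) - np.log(paired.m2)
        try:
            tau_log = kendall_tau_het(dlog, means)
        except ValueError:
            tau_log = 0.0
        if tau_log < tau_raw:
            mlog, sdlog, llo, lhi = bland_altman_limits(dlog)
            log_branch = LogBranch(
                tau_log=tau_log,
                mean_log_diff=mlog, sd_log_diff=sdlog,
                loa_log_low=llo, loa_log_high=lhi,
                ratio_low=float(np.exp(llo)), ratio_high=float(np.exp(lhi)),
                slope_low=back_transform_loa(llo),
                slope_high=back_transform_loa(lhi),
            )
    return BlandAltmanResult(
        n=paired.n, mode=mode, mean_diff=mean, sd_diff=sd,
        loa_low=lo, loa_high=hi, tau_raw=tau_raw,
        heteroscedastic=heteroscedastic, log_branch=log_branch,
    )


# ---------------------------------------------------------------------------
# ICC, t-test, normality
# ---------------------------------------------------------------------------

def icc_oneway(ratings: pd.DataFrame) -> ICCResult:
    """One-way random-effects, single-measurement ICC from an unbalanced table.

    ``ratings`` needs columns case_id, reader_id, volume.  Uses the one-way
    ANOVA decomposition with the unbalanced average group size
    ``k_bar = (N - sum(k_i^2) / N) / (n - 1)`` and
    ``ICC = (MSB - MSW) / (MSB + (k_bar - 1) * MSW)``.
    """
    df = ratings.dropna(subset=["volume"])
    groups = df.groupby("case_id")["volume"]
    k = groups.size()
    n = len(k)
    N = int(k.sum())
    if n < 2 or N == n:
        raise ValueError("ICC needs >= 2 cases and at least one case with >= 2 readings")
    grand = df["volume"].mean()
    means = groups.mean()
    ssb = float((k * (means - grand) ** 2).sum())
    ssw = float(((df["volume"] - means.loc[df["case_id"]].to_numpy()) ** 2).sum())
    msb = ssb / (n - 1)
    msw = ssw / (N - n)
    k_bar = (N - float((k**2).sum()) / N) / (n - 1)
    icc = (msb - msw) / (msb + (k_bar - 1) * msw)
    return ICCResult(
        icc=float(icc), ms_between=msb, ms_within=msw,
        n_subjects=n, mean_raters_per_subject=float(k_bar),
    )


def paired_t_test(diffs: np.ndarray) -> TestResult:
    """Two-sided one-sample t-test on paired differences."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 differences")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("t-test undefined for zero-variance differences")
    t = d.mean() / (sd / np.sqrt(d.size))
    p = 2.0 * stats.t.sf(abs(t), d.size - 1)
    return TestResult(statistic=float(t), p_value=float(p), name="paired t-test")


def shapiro_wilk(x: np.ndarray) -> TestResult:
    """Shapiro-Wilk normality test (Royston algorithm, 3 <= n <= 5000)."""
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant sample")
    res = stats.shapiro(x)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      name="Shapiro-Wilk")


# ---------------------------------------------------------------------------
# subgroups and acceptability
# ---------------------------------------------------------------------------

STRATIFIERS = ("ivh", "location", "volume_40")


def _strata(stratifier: str, truth: pd.DataFrame,
            reference_volumes: pd.Series | None) -> dict[str, set[str]]:
    t = truth.set_index("case_id")
    if stratifier == "ivh":
        flags = t["ivh_present"].astype(bool)
        return {"ivh": set(t.index[flags]), "no_ivh": set(t.index[~flags])}
    if stratifier == "location":
        loc = t["location"]
        return {
            "lobar": set(t.index[loc == "lobar"]),
            "basal_ganglia_thalamus": set(t.index[loc == "basal_ganglia_thalamus"]),
        }
    if stratifier == "volume_40":
        if reference_volumes is None:
            raise ValueError("volume_40 stratifier needs reference-method volumes")
        small = reference_volumes < 40.0
        return {
            "lt_40_mL": set(reference_volumes.index[small]),
            "ge_40_mL": set(reference_volumes.index[~small]),
        }
    raise ValueError(f"unknown stratifier {stratifier!r}; one of {STRATIFIERS}")


def subgroup_agreement(
    records: pd.DataFrame,
    truth: pd.DataFrame,
    stratifier: str,
    pair: tuple[str, str],
    mode: str = "absolute",
    tau_threshold: float = 0.1,
    reference_method: str = "reference_voxel",
) -> dict[str, BlandAltmanResult]:
    """Adaptive Bland-Altman analysis within each stratum of a stratifier.

    Strata with fewer than 3 complete pairs are reported as not estimable
    rather than raising.  The 40 mL split uses the reference method's
    measured volumes.
    """
    ref_vols = None
    if stratifier == "volume_40":
        sub = records[records["method"] == reference_method]
        sub = sub.drop_duplicates(subset="case_id", keep="first")
        sub = sub[~sub["missed"].astype(bool) & sub["volume_mL"].notna()]
        ref_vols = sub.set_index("case_id")["volume_mL"]
    strata = _strata(stratifier, truth, ref_vols)

    out: dict[str, BlandAltmanResult] = {}
    for name, case_ids in strata.items():
        sub = records[records["case_id"].isin(case_ids)]
        try:
            paired = paired_complete_cases(sub, *pair)
            if paired.n < 3:
                raise ValueError("stratum too small")
            out[name] = adaptive_log_loa(paired, mode=mode,
                                         tau_threshold=tau_threshold)
        except ValueError:
            out[name] = BlandAltmanResult(
                n=0, mode=mode, mean_diff=float("nan"), sd_diff=float("nan"),
                loa_low=float("nan"), loa_high=float("nan"),
                tau_raw=float("nan"), heteroscedastic=False, estimable=False,
            )
    return out


def acceptance_check(result: BlandAltmanResult, limit_pct: float = 10.0) -> bool:
    """Clinical acceptability: percent LoA entirely within +/- limit_pct.

    Boundary inclusive — a deviation of exactly the limit still counts as
    acceptable ("10% or less").
    """
    if result.mode != "percent":
        raise ValueError("acceptance_check requires a percent-mode result")
    if not result.estimable:
        raise ValueError("acceptance_check requires an estimable result")
    return bool(result.loa_low >= -limit_pct and result.loa_high <= limit_pct)
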