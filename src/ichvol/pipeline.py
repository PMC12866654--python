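"""End-to-end study orchestration: cohort -> measurements -> agreement report.

``run_study`` reproduces the structure of a three-method volumetry agreement
study on a synthetic cohort: every case is measured by the voxel reference,
by ABC/2 readers (with a repeat-reading subsample for inter-observer ICC)
and by the simulated automated segmenter; the agreement analyses (adaptive
Bland-Altman in absolute and percent mode, subgroups, paired t-test,
normality check, ICC, the 10% acceptability rule) are then run for every
requested method pair and the whole result is serialized as a JSON report
that validates against the shipped schema.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel

from . import agreement as ag
from . import phantoms as ph
from . import volumetry as vm

__all__ = [
    "StudyConfig",
    "AgreementReport",
    "run_study",
    "summarize_cohort",
    "write_report",
    "make_ba_plot",
]

logger = logging.getLogger("ichvol")

DEFAULT_PAIRS = [
    ("auto_sim", "reference_voxel"),
    ("auto_sim", "abc2"),
    ("abc2", "reference_voxel"),
]


@dataclass
class StudyConfig:
    """Everything needed for one reproducible synthetic agreement study."""

    cohort: ph.CohortConfig = field(default_factory=ph.CohortConfig)
    error_model: vm.AutoSegErrorModel = field(default_factory=vm.AutoSegErrorModel)
    #: log-scale SD of ABC/2 reader noise on the A and B diameters
    reader_sd: float = 0.10
    #: fraction of cases read by two extra ABC/2 readers (ICC subsample)
    repeat_fraction: float = 0.10
    n_readers: int = 5
    c_rule: str = "kothari_weighted"
    pairs: list[tuple[str, str]] | None = None
    stratifiers: list[str] = field(default_factory=lambda: list(ag.STRATIFIERS))
    acceptance_limit_pct: float = 10.0
    tau_threshold: float = 0.1
    seed: int = 0
    out_dir: str | None = None
    make_plots: bool = False
    #: with False, masks are not rasterized: the reference equals the exact
    #: ground truth and ABC/2 is unavailable (fast, purely parametric mode)
    generate_masks: bool = True

    def __post_init__(self) -> None:
        if self.acceptance_limit_pct <= 0:
            raise ValueError("acceptance_limit_pct must be positive")
        if not 0 <= self.repeat_fraction <= 1:
            raise ValueError("repeat_fraction must lie in [0, 1]")
        if self.pairs is not None:
            known = {"reference_voxel", "abc2", "auto_sim"}
            for p in self.pairs:
                if set(p) - known:
                    raise ValueError(f"unknown method in pair {p}")

    def resolved_pairs(self) -> list[tuple[str, str]]:
        if self.pairs is not None:
            return [tuple(p) for p in self.pairs]
        if self.generate_masks:
            return list(DEFAULT_PAIRS)
        return [("auto_sim", "reference_voxel")]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohort" in raw:
            c = dict(raw["cohort"])
            for key in ("volume_iqr_mL", "irregularity_range",
                        "ivh_fraction_range", "spacing_mm", "grid_shape"):
                if key in c and c[key] is not None:
                    c[key] = tuple(c[key])
            raw["cohort"] = ph.CohortConfig(**c)
        if "error_model" in raw:
            m = dict(raw["error_model"])
            for key in ("partial_fraction_range", "distractor_volume_mL_range"):
                if key in m and m[key] is not None:
                    m[key] = tuple(m[key])
            raw["error_model"] = vm.AutoSegErrorModel(**m)
        if "pairs" in raw and raw["pairs"] is not None:
            raw["pairs"] = [tuple(p) for p in raw["pairs"]]
        return cls(**raw)


# ---------------------------------------------------------------------------
# report schema (pydantic models; the JSON schema file is generated from these)
# ---------------------------------------------------------------------------

class LogBranchModel(BaseModel):
    tau_log: float
    mean_log_diff: float
    sd_log_diff: float
    loa_log_low: float
    loa_log_high: float
    ratio_low: float
    ratio_high: float
    slope_low: float
    slope_high: float


class BAModel(BaseModel):
    n: int
    mode: str
    estimable: bool
    mean_diff: float | None = None
    sd_diff: float | None = None
    loa_low: float | None = None
    loa_high: float | None = None
    tau_raw: float | None = None
    heteroscedastic: bool = False
    log_branch: LogBranchModel | None = None


class TestModel(BaseModel):
    statistic: float
    p_value: float
    name: str


class ICCModel(BaseModel):
    icc: float
    ms_between: float
    ms_within: float
    n_subjects: int
    mean_raters_per_subject: float


class SummaryRow(BaseModel):
    method: str
    subset: str
    n: int
    mean: float | None = None
    median: float | None = None
    q25: float | None = None
    q75: float | None = None


class PairReport(BaseModel):
    method1: str
    method2: str
    n_complete: int
    t_test: TestModel | None = None
    shapiro: TestModel | None = None
    modes: dict[str, dict[str, BAModel]]  # mode -> stratum -> result
    acceptable: bool | None = None


class AgreementReport(BaseModel):
    n_cases: int
    n_missed_auto: int
    n_complete: int
    event_counts: dict[str, int]
    acceptance_limit_pct: float
    seed: int
    cohort_summary: list[SummaryRow]
    icc: ICCModel | None = None
    pairs: dict[str, PairReport]


def _ba_to_model(r: ag.BlandAltmanResult) -> BAModel:
    if not r.estimable:
        return BAModel(n=r.n, mode=r.mode, estimable=False)
    lb = None
    if r.log_branch is not None:
        lb = LogBranchModel(**r.log_branch.__dict__)
    return BAModel(
        n=r.n, mode=r.mode, estimable=True, mean_diff=r.mean_diff,
        sd_diff=r.sd_diff, loa_low=r.loa_low, loa_high=r.loa_high,
        tau_raw=r.tau_raw, heteroscedastic=r.heteroscedastic, log_branch=lb,
    )


# ---------------------------------------------------------------------------
# measurement stage
# ---------------------------------------------------------------------------

def _measure_cohort(config: StudyConfig,
                    cases: list[tuple[ph.LabeledVolume | None, ph.PhantomRecord]],
                    ) -> pd.DataFrame:
    rng = np.random.default_rng(config.seed)
    n = len(cases)
    auto_seeds = rng.integers(0, 2**31 - 1, size=n)
    reader_seeds = rng.integers(0, 2**31 - 1, size=(n, 3))
    repeat = rng.random(n) < config.repeat_fraction
    readers = [f"reader_{i + 1}" for i in range(config.n_readers)]

    records: list[vm.MeasurementRecord] = []
    for i, (vol, rec) in enumerate(cases):
        auto = vm.simulate_auto_segmentation(vol, rec, config.error_model,
                                             int(auto_seeds[i]))
        records.append(auto)
        if auto.missed:
            logger.info("%s: automated segmentation missed the haematoma", rec.case_id)
        elif auto.ivh_included or auto.partial or auto.distractor_included:
            logger.info(
                "%s: automated segmentation events ivh=%s partial=%s distractor=%s",
                rec.case_id, auto.ivh_included, auto.partial,
                auto.distractor_included,
            )
        if config.generate_masks:
            if vol is None:
                raise ValueError(f"{rec.case_id}: mask missing in mask mode")
            scan = ph.reslice_axial(vol, rec.slice_thickness_mm)
            records.append(vm.measure_reference(scan, rec.case_id))
            base = vm.abc2_measure(scan, c_rule=config.c_rule)
            case_readers = [readers[i % config.n_readers]]
            if repeat[i]:
                extra = [r for r in readers if r not in case_readers]
                case_readers += extra[:2]
            for j, reader in enumerate(case_readers):
                records.append(
                    vm.simulate_abc2_reader(
                        base, config.reader_sd, int(reader_seeds[i, j]),
                        case_id=rec.case_id, reader_id=reader,
                    )
                )
        else:
            records.append(
                vm.MeasurementRecord(
                    case_id=rec.case_id, method="reference_voxel",
                    volume_mL=rec.true_ich_volume_mL,
                )
            )
    return vm.records_to_frame(records)


# ---------------------------------------------------------------------------
# cohort summary (the measurement-table analog)
# ---------------------------------------------------------------------------

def _quantiles(v: pd.Series) -> tuple[float, float, float, float]:
    # type-7 (linear interpolation) quantiles, the R default
    return (float(v.mean()), float(v.median()),
            float(v.quantile(0.25)), float(v.quantile(0.75)))


def summarize_cohort(records: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-method volume summaries in the layout of a study measurement table.

    Rows cover, per method: all cases; complete cases (measured by every
    method present); cases missed by the automated method; and the same for
    the no-IVH subgroup.  Medians and IQRs use linear (type-7) interpolation.
    """
    if records.empty:
        raise ValueError("no measurement records to summarize")
    firsts = records.drop_duplicates(subset=["case_id", "method"], keep="first")
    methods = sorted(firsts["method"].unique())
    measured = {
        m: set(firsts[(firsts["method"] == m) & firsts["volume_mL"].notna()]["case_id"])
        for m in methods
    }
    all_cases = set(truth["case_id"])
    complete = set.intersection(*measured.values()) if methods else set()
    missed_auto = (all_cases - measured["auto_sim"]) if "auto_sim" in measured else set()
    no_ivh = set(truth[~truth["ivh_present"].astype(bool)]["case_id"])

    subsets = {
        "all": all_cases,
        "complete": complete,
        "missed_auto": missed_auto,
        "no_ivh_all": no_ivh,
        "no_ivh_complete": no_ivh & complete,
    }
    rows = []
    for method in methods:
        sub = firsts[(firsts["method"] == method) & firsts["volume_mL"].notna()]
        by_case = sub.set_index("case_id")["volume_mL"]
        for name, ids in subsets.items():
            v = by_case[by_case.index.isin(ids)]
            if len(v) == 0:
                rows.append(dict(method=method, subset=name, n=0, mean=None,
                                 median=None, q25=None, q75=None))
            else:
                mean, med, q25, q75 = _quantiles(v)
                rows.append(dict(method=method, subset=name, n=len(v),
                                 mean=mean, median=med, q25=q25, q75=q75))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the study driver
# ---------------------------------------------------------------------------

def _analyse_pair(config: StudyConfig, records: pd.DataFrame,
                  truth: pd.DataFrame, pair: tuple[str, str]) -> PairReport:
    m1, m2 = pair
    paired = ag.paired_complete_cases(records, m1, m2)
    d_abs, _ = ag.differences(paired, "absolute")

    t_test = shapiro = None
    try:
        t = ag.paired_t_test(d_abs)
        t_test = TestModel(statistic=t.statistic, p_value=t.p_value, name=t.name)
    except ValueError:
        pass
    try:
        s = ag.shapiro_wilk(d_abs)
        shapiro = TestModel(statistic=s.statistic, p_value=s.p_value, name=s.name)
    except ValueError:
        pass

    modes: dict[str, dict[str, BAModel]] = {}
    acceptable = None
    for mode in ("absolute", "percent"):
        strata: dict[str, BAModel] = {}
        overall = ag.adaptive_log_loa(paired, mode=mode,
                                      tau_threshold=config.tau_threshold)
        strata["all"] = _ba_to_model(overall)
        if mode == "percent":
            acceptable = ag.acceptance_check(overall, config.acceptance_limit_pct)
        for strat in config.stratifiers:
            per = ag.subgroup_agreement(
                records, truth, strat, pair, mode=mode,
                tau_threshold=config.tau_threshold,
            )
            for name, res in per.items():
                strata[f"{strat}:{name}"] = _ba_to_model(res)
        modes[mode] = strata
    return PairReport(
        method1=m1, method2=m2, n_complete=paired.n,
        t_test=t_test, shapiro=shapiro, modes=modes, acceptable=acceptable,
    )


def run_study(config: StudyConfig) -> AgreementReport:
    """Run the full synthetic agreement study; write outputs if configured."""
    cases, truth = ph.sample_cohort(config.cohort,
                                    build_masks=config.generate_masks)
    records = _measure_cohort(config, cases)
    pairs = config.resolved_pairs()

    auto = records[records["method"] == "auto_sim"]
    n_missed = int(auto["missed"].sum())
    event_counts = {
        flag: int(auto[flag].sum())
        for flag in ("missed", "partial", "ivh_included", "distractor_included")
    }

    pair_reports: dict[str, PairReport] = {}
    n_complete = len(truth)
    for pair in pairs:
        rep = _analyse_pair(config, records, truth, pair)
        pair_reports[f"{pair[0]}_vs_{pair[1]}"] = rep
        n_complete = min(n_complete, rep.n_complete)

    icc_model = None
    abc2 = records[records["method"] == "abc2"]
    if not abc2.empty:
        counts = abc2.groupby("case_id").size()
        if (counts >= 2).any():
            ratings = abc2.rename(columns={"volume_mL": "volume"})[
                ["case_id", "reader_id", "volume"]
            ]
            r = ag.icc_oneway(ratings)
            icc_model = ICCModel(**r.__dict__)

    summary = summarize_cohort(records, truth)
    summary_rows = [
        {k: (None if isinstance(v, float) and np.isnan(v) else v)
         for k, v in row.items()}
        for row in summary.to_dict("records")
    ]
    report = AgreementReport(
        n_cases=len(truth),
        n_missed_auto=n_missed,
        n_complete=n_complete,
        event_counts=event_counts,
        acceptance_limit_pct=config.acceptance_limit_pct,
        seed=config.seed,
        cohort_summary=[SummaryRow(**row) for row in summary_rows],
        icc=icc_model,
        pairs=pair_reports,
    )
    logger.info(
        "study complete: %d cases, %d missed by automated segmentation, "
        "%d complete for all pairs", len(truth), n_missed, n_complete,
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        truth.to_csv(out / "truth.csv", index=False)
        vm.write_measurements_csv(records, out / "measurements.csv")
        write_report(report, out / "report.json")
        if config.make_plots:
            for pair in pairs:
                paired = ag.paired_complete_cases(records, *pair)
                res = ag.adaptive_log_loa(paired, mode="absolute",
                                          tau_threshold=config.tau_threshold)
                make_ba_plot(res, *ag.differences(paired, "absolute"),
                             out / f"ba_{pair[0]}_vs_{pair[1]}.png",
                             title=f"{pair[0]} vs {pair[1]}")
    return report


def write_report(report: AgreementReport, path: str | Path) -> None:
    """Deterministic JSON serialization (sorted keys, no NaN)."""
    payload = json.dumps(report.model_dump(mode="json"), indent=2,
                         sort_keys=True, allow_nan=False)
    Path(path).write_text(payload + "\n")


def make_ba_plot(result: ag.BlandAltmanResult, diffs: np.ndarray,
                 means: np.ndarray, path: str | Path, title: str = "") -> None:
    """Conventional Bland-Altman plot with the four-line layout.

    Mean-difference line, flat LoA, regression of difference on mean, and —
    when the log branch was retained — the back-transformed mean-dependent
    limits ``slope * X``.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(means, diffs, s=12, alpha=0.6, color="0.3")
    ax.axhline(result.mean_diff, color="red", lw=1.5, label="mean difference")
    ax.axhline(result.loa_low, color="red", ls=":", lw=1.2, label="LoA")
    ax.axhline(result.loa_high, color="red", ls=":", lw=1.2)
    coeffs = np.polyfit(means, diffs, 1)
    xs = np.linspace(float(np.min(means)), float(np.max(means)), 50)
    ax.plot(xs, np.polyval(coeffs, xs), color="blue", lw=1.2, label="regression")
    if result.log_branch is not None:
        ax.plot(xs, result.log_branch.slope_low * xs, color="green", ls="--",
                lw=1.2, label="back-transformed LoA")
        ax.plot(xs, result.log_branch.slope_high * xs, color="green", ls="--",
                lw=1.2)
    ax.set_xlabel("mean of paired measurements (mL)")
    ax.set_ylabel("difference (mL)" if result.mode == "absolute"
                  else "difference (%)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
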