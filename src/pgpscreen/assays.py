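"""Assay analysis: MTT re-sensitization, LC-MS/MS substrate calls, DAU accumulation.

Three readouts decide whether a screening hit behaves like a useful
efflux-pump inhibitor in cells:

* **MTT viability.**  Percent survival of each well is 100 × its
  background-corrected absorbance (570 nm) over the mean absorbance of
  vehicle-treated control wells.  A compound *re-sensitizes* resistant cells
  to a chemotherapeutic when survival under compound+chemo drops at least 30
  percentage points below survival under chemo alone.

* **LC-MS/MS intracellular accumulation.**  For each sample the analyte peak
  area is divided by the internal-standard (IS) peak area and normalized by
  lysate protein content (mg/mL).  Comparing the mean normalized ratio with
  and without the reference pump inhibitor tariquidar (TQR) by a
  pooled-variance two-sample t-test asks whether blocking the pump makes the
  compound accumulate: a significant *increase* with TQR marks the compound
  as a likely transport substrate.

* **Daunorubicin (DAU) fluorescence.**  Fold change of intrinsic DAU
  fluorescence with vs without a compound reports whether the compound
  blocks DAU efflux.

All t-tests are Student's (pooled variance, df = n₁+n₂−2) and two-sided;
they can be computed from raw replicates or from (mean, SD, n) summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlateReading",
    "SurvivalResult",
    "AccumulationSample",
    "TrialTest",
    "SubstrateCall",
    "FluorescenceResult",
    "percent_survival",
    "resensitization_call",
    "mtt_resensitization",
    "normalized_ratio",
    "mean_ratio",
    "substrate_ttest",
    "classify_substrate",
    "substrate_calls",
    "substrate_calls_from_summary",
    "dau_fold_change",
    "hit_rate",
    "read_plate_csv",
    "read_lcms_csv",
    "read_summary_csv",
]

RESENSITIZATION_THRESHOLD_PP = 30.0  # percentage points, inclusive
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class PlateReading:
    """One background-corrected absorbance reading at 570 nm."""

    well_id: str
    cell_line: str
    treatment: str  # vehicle | chemo-only | compound-only | compound+chemo
    compound_id: str | None
    absorbance: float


@dataclass
class SurvivalResult:
    """Re-sensitization call for one compound."""

    compound_id: str
    pct_survival_compound_chemo: float
    pct_survival_chemo_only: float
    decrease: float  # percentage points
    resensitizer: bool
    n_compound_chemo: int = 0
    sd_compound_chemo: float = float("nan")
    n_chemo_only: int = 0
    sd_chemo_only: float = float("nan")


@dataclass(frozen=True)
class AccumulationSample:
    """One LC-MS/MS sample: peak areas, lysate content, ±TQR condition."""

    compound_id: str
    condition: str  # minus_TQR | plus_TQR
    trial: int
    analyte_peak: float  # counts
    is_peak: float       # internal-standard counts
    lysate: float        # mg/mL

    def __post_init__(self):
        if self.analyte_peak < 0:
            raise ValueError(f"{self.compound_id}: negative analyte peak")


@dataclass
class TrialTest:
    """Per-trial ±TQR comparison for one compound."""

    trial: int
    mean_minus: float
    sd_minus: float
    mean_plus: float
    sd_plus: float
    n_per_group: int
    t_statistic: float
    p_two_sided: float
    significant: bool
    direction_up: bool  # mean_plus > mean_minus
    indeterminate: bool = False


@dataclass
class SubstrateCall:
    """Substrate classification: any trial with p < α and +TQR increase."""

    compound_id: str
    per_trial: list[TrialTest] = field(default_factory=list)
    substrate: bool = False
    indeterminate: bool = False  # no measurable analyte in any trial


@dataclass
class FluorescenceResult:
    """DAU accumulation fold change with significance."""

    compound_id: str
    fold_change: float
    p_two_sided: float
    significant: bool
    n_compound: int
    n_dau_alone: int


# --- MTT -------------------------------------------------------------------

def _readings_frame(readings) -> pd.DataFrame:
    if isinstance(readings, pd.DataFrame):
        return readings.copy()
    return pd.DataFrame([vars(r) for r in readings])


def percent_survival(readings, control_group: str = "vehicle",
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-well percent survival relative to the control group's mean.

    ``readings`` is a sequence of :class:`PlateReading` or a DataFrame with
    columns well_id, cell_line, treatment, compound_id, absorbance (one cell
    line per call).  Returns (per_well, summary): per_well adds a
    ``pct_survival`` column; summary holds mean/SD/n per
    (treatment, compound_id) group.
    """
    df = _readings_frame(readings)
    control = df[df["treatment"] == control_group]
    if control.empty:
        raise ValueError(f"no readings in control group {control_group!r}")
    denom = control["absorbance"].mean()
    if denom <= 0:
        raise ValueError(f"non-positive control mean absorbance {denom}")
    df["pct_survival"] = 100.0 * df["absorbance"] / denom
    summary = (df.fillna({"compound_id": ""})
               .groupby(["treatment", "compound_id"])["pct_survival"]
               .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
               .reset_index())
    return df, summary


def resensitization_call(pct_chemo_only: float, pct_compound_chemo: float,
                         threshold: float = RESENSITIZATION_THRESHOLD_PP,
                         ) -> tuple[bool, float]:
    """Re-sensitization rule: decrease ≥ threshold percentage points (inclusive).

    Both percentages must be computed against the same vehicle control.
    Returns (call, decrease).
    """
    decrease = pct_chemo_only - pct_compound_chemo
    return decrease >= threshold, decrease


def mtt_resensitization(readings, control_group: str = "vehicle",
                        threshold: float = RESENSITIZATION_THRESHOLD_PP,
                        ) -> list[SurvivalResult]:
    """Full MTT analysis: survival percentages then per-compound calls."""
    per_well, _ = percent_survival(readings, control_group)
    chemo = per_well[per_well["treatment"] == "chemo-only"]["pct_survival"]
    if chemo.empty:
        raise ValueError("no chemo-only readings")
    results = []
    cc = per_well[per_well["treatment"] == "compound+chemo"]
    for cid, grp in cc.groupby("compound_id", sort=True):
        call, decrease = resensitization_call(chemo.mean(),
                                              grp["pct_survival"].mean(),
                                              threshold)
        results.append(SurvivalResult(
            compound_id=cid,
            pct_survival_compound_chemo=grp["pct_survival"].mean(),
            pct_survival_chemo_only=chemo.mean(),
            decrease=decrease, resensitizer=call,
            n_compound_chemo=len(grp),
            sd_compound_chemo=grp["pct_survival"].std(ddof=1),
            n_chemo_only=len(chemo),
            sd_chemo_only=chemo.std(ddof=1)))
    return results


# --- LC-MS/MS --------------------------------------------------------------

def normalized_ratio(sample: AccumulationSample) -> float:
    """(analyte peak / IS peak) / lysate content, (counts/counts)/(mg/mL)."""
    if sample.is_peak <= 0:
        raise ValueError(f"sample {sample.compound_id} trial {sample.trial} "
                         f"({sample.condition}): non-positive IS peak")
    if sample.lysate <= 0:
        raise ValueError(f"sample {sample.compound_id} trial {sample.trial} "
                         f"({sample.condition}): non-positive lysate content")
    return (sample.analyte_peak / sample.is_peak) / sample.lysate


def mean_ratio(samples: Sequence[AccumulationSample]) -> tuple[float, float]:
    """Mean and sample SD (n−1) of normalized ratios for one group."""
    if not samples:
        raise ValueError("empty sample set")
    ratios = np.array([normalized_ratio(s) for s in samples])
    sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else float("nan")
    return float(ratios.mean()), sd


def substrate_ttest(mean_minus: float, sd_minus: float, n_minus: int,
                    mean_plus: float, sd_plus: float, n_plus: int,
                    ) -> tuple[float, float]:
    """Pooled-variance two-sample Student's t-test from summary statistics.

    t = (mean_plus − mean_minus) / (s_p·√(1/n₁+1/n₂)) with
    s_p² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2); two-sided p from the t
    distribution with df = n₁+n₂−2, capped at 1.0.  Degenerate inputs:
    both SDs zero with equal means → (0, 1); with unequal means →
    (±inf, 0) with a warning.
    """
    if n_minus < 2 or n_plus < 2:
        raise ValueError("each group needs n ≥ 2")
    if sd_minus < 0 or sd_plus < 0:
        raise ValueError("negative SD")
    df = n_minus + n_plus - 2
    sp2 = ((n_minus - 1) * sd_minus**2 + (n_plus - 1) * sd_plus**2) / df
    diff = mean_plus - mean_minus
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means; "
                      "t is infinite", stacklevel=2)
        return math.copysign(math.inf, diff), 0.0
    t = diff / math.sqrt(sp2 * (1.0 / n_minus + 1.0 / n_plus))
    p = min(1.0, float(2.0 * stats.t.sf(abs(t), df)))
    return float(t), p


def classify_substrate(compound_id: str, trials: Sequence[TrialTest],
                       ) -> SubstrateCall:
    """Substrate iff any determinate trial has p < α and a +TQR increase.

    Trials flagged indeterminate (analyte below quantification in both
    conditions) are recorded but never trigger a substrate call.
    """
    if not trials:
        raise ValueError(f"{compound_id}: no trials")
    determinate = [t for t in trials if not t.indeterminate]
    substrate = any(t.significant and t.direction_up for t in determinate)
    return SubstrateCall(compound_id, list(trials), substrate,
                         indeterminate=not determinate)


def _trial_test(trial: int, mean_minus, sd_minus, mean_plus, sd_plus, n,
                alpha: float, indeterminate: bool = False) -> TrialTest:
    if indeterminate:
        return TrialTest(trial, mean_minus, sd_minus, mean_plus, sd_plus, n,
                         float("nan"), float("nan"), False,
                         mean_plus > mean_minus, True)
    t, p = substrate_ttest(mean_minus, sd_minus, n, mean_plus, sd_plus, n)
    return TrialTest(trial, mean_minus, sd_minus, mean_plus, sd_plus, n,
                     t, p, p < alpha, mean_plus > mean_minus, False)


def substrate_calls(samples: Sequence[AccumulationSample],
                    alpha: float = DEFAULT_ALPHA,
                    loq: float | None = None) -> list[SubstrateCall]:
    """Substrate classification from raw LC-MS/MS samples.

    Samples are grouped by (compound, trial); each trial compares the
    minus_TQR and plus_TQR normalized-ratio means by pooled t-test.  When
    ``loq`` is given, a trial whose group means both fall at or below it is
    indeterminate (analyte below quantification).
    """
    by_comp: dict[str, dict[int, dict[str, list[AccumulationSample]]]] = {}
    for s in samples:
        by_comp.setdefault(s.compound_id, {}) \
               .setdefault(s.trial, {}) \
               .setdefault(s.condition, []).append(s)
    calls = []
    for cid in sorted(by_comp):
        trials = []
        for trial in sorted(by_comp[cid]):
            groups = by_comp[cid][trial]
            if "minus_TQR" not in groups or "plus_TQR" not in groups:
                raise ValueError(f"{cid} trial {trial}: needs both ±TQR "
                                 "conditions")
            m_minus, s_minus = mean_ratio(groups["minus_TQR"])
            m_plus, s_plus = mean_ratio(groups["plus_TQR"])
            n = min(len(groups["minus_TQR"]), len(groups["plus_TQR"]))
            indet = (loq is not None and m_minus <= loq and m_plus <= loq)
            trials.append(_trial_test(trial, m_minus, s_minus, m_plus,
                                      s_plus, n, alpha, indet))
        calls.append(classify_substrate(cid, trials))
    return calls


def substrate_calls_from_summary(summary: pd.DataFrame,
                                 alpha: float = DEFAULT_ALPHA,
                                 ) -> list[SubstrateCall]:
    """Substrate classification from (mean, SD, n) summary statistics.

    ``summary`` columns: compound_id, trial, mean_minus, sd_minus,
    mean_plus, sd_plus, n, and optionally ``indeterminate`` (truthy for
    below-quantification trials).
    """
    calls = []
    for cid, grp in summary.groupby("compound_id", sort=True):
        trials = []
        for _, row in grp.sort_values("trial").iterrows():
            indet = bool(row.get("indeterminate", False))
            trials.append(_trial_test(
                int(row["trial"]), float(row["mean_minus"]),
                float(row["sd_minus"]), float(row["mean_plus"]),
                float(row["sd_plus"]), int(row["n"]), alpha, indet))
        calls.append(classify_substrate(str(cid), trials))
    return calls


# --- daunorubicin accumulation ---------------------------------------------

def dau_fold_change(fluor_compound_plus_dau: Sequence[float],
                    fluor_dau_alone: Sequence[float],
                    compound_id: str = "",
                    alpha: float = DEFAULT_ALPHA,
                    blank: float = 0.0) -> FluorescenceResult:
    """DAU fluorescence fold change and two-sided pooled t-test vs DAU alone.

    ``blank`` is an optional background fluorescence subtracted from every
    reading before analysis (0 when background correction was already done).
    """
    comp = np.asarray(fluor_compound_plus_dau, dtype=float) - blank
    dau = np.asarray(fluor_dau_alone, dtype=float) - blank
    if comp.size == 0 or dau.size == 0:
        raise ValueError("both fluorescence groups must be non-empty")
    if dau.mean() <= 0:
        raise ValueError("non-positive DAU-alone mean fluorescence")
    fold = float(comp.mean() / dau.mean())
    t, p = substrate_ttest(dau.mean(), dau.std(ddof=1), dau.size,
                           comp.mean(), comp.std(ddof=1), comp.size)
    return FluorescenceResult(compound_id, fold, p, p < alpha,
                              comp.size, dau.size)


# --- reporting -------------------------------------------------------------

def hit_rate(n_tested: int, n_hits: int, ndigits: int = 1) -> float:
    """Screening hit rate as a percentage, rounded for reporting.

    E.g. 9 validated re-sensitizers out of 67 docking-selected compounds
    tested in cells → 13.4.
    """
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    if not 0 <= n_hits <= n_tested:
        raise ValueError("n_hits must be between 0 and n_tested")
    return round(100.0 * n_hits / n_tested, ndigits)


# --- file readers ----------------------------------------------------------

def read_plate_csv(path) -> pd.DataFrame:
    """Plate CSV: well_id, cell_line, treatment, compound_id, absorbance."""
    df = pd.read_csv(path, comment="#", dtype={"compound_id": str},
                     float_precision="round_trip")
    required = {"well_id", "cell_line", "treatment", "compound_id",
                "absorbance"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns "
                         f"{sorted(required - set(df.columns))}")
    return df


def read_lcms_csv(path) -> list[AccumulationSample]:
    """LC-MS/MS CSV: compound_id, condition, trial, analyte_peak, is_peak,
    lysate_mg_per_ml."""
    df = pd.read_csv(path, comment="#", dtype={"compound_id": str},
                     float_precision="round_trip")
    return [AccumulationSample(str(r.compound_id), str(r.condition),
                               int(r.trial), float(r.analyte_peak),
                               float(r.is_peak), float(r.lysate_mg_per_ml))
            for r in df.itertuples()]


def read_summary_csv(path) -> pd.DataFrame:
    """Summary-stats CSV: compound_id, trial, mean_minus, sd_minus,
    mean_plus, sd_plus, n [, indeterminate, printed_p]."""
    df = pd.read_csv(path, comment="#", dtype={"compound_id": str},
                     float_precision="round_trip")
    required = {"compound_id", "trial", "mean_minus", "sd_minus",
                "mean_plus", "sd_plus", "n"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns "
                         f"{sorted(required - set(df.columns))}")
    if "indeterminate" in df.columns:
        df["indeterminate"] = df["indeterminate"].fillna(0).astype(bool)
    return df
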