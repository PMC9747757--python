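"""Subject-level analysis chain and cohort-level statistics.

``analyze_subject`` chains binarization -> avalanche extraction ->
exponent fits -> activity statistics for one continuous recording;
``run_cohort`` applies it across subjects, fits the cohort scaling line,
assigns positions, and computes the correlation / group-contrast table.
No multiple-comparisons correction is applied to the table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import events as ev
from .activity import (
    activity_density,
    avalanche_size_variance,
    branching_mr,
    branching_naive,
    ltf,
    susceptibility,
)
from .avalanches import AvalancheCatalog, ExponentPair, extract_avalanches, fit_exponent_pair
from .errors import QuasicritError
from .events import Recording
from .scaling import fit_scaling_line, position_on_line

logger = logging.getLogger("quasicrit")

__all__ = [
    "AnalysisParams",
    "SubjectMetrics",
    "SubjectResult",
    "CohortResults",
    "analyze_subject",
    "run_cohort",
    "cohort_statistics",
]


@dataclass(frozen=True)
class AnalysisParams:
    """Knobs of the per-subject analysis chain."""

    threshold_sd: float = 3.0
    bin_width: int | None = None  # None -> mean inter-event interval
    fit_method: str = "mle"
    n_boot: int = 0  # bootstrap resamples for exponent stderr (0 = analytic)
    min_gamma_count: int = 10
    mr_k_max: int = 40
    seed: int = 0


@dataclass
class SubjectMetrics:
    """Per-subject activity statistics."""

    mean_rate: float
    chi: float
    ltf: float
    var_s: float
    sigma_naive: float
    sigma_mr: float
    bin_width: int
    n_avalanches: int
    position: float = float("nan")  # filled in at cohort level


@dataclass
class SubjectResult:
    subject_id: str
    metrics: SubjectMetrics | None
    exponents: ExponentPair | None
    excluded: bool = False
    exclusion_reason: str | None = None
    age: float | None = None
    gender: str | None = None


def analyze_subject(
    recording: Recording,
    params: AnalysisParams = AnalysisParams(),
    subject_id: str = "sub-000",
) -> SubjectResult:
    """Run the full per-subject chain; failures mark the subject excluded."""
    try:
        z = ev.zscore(recording)
        trains = ev.detect_events(z, threshold_sd=params.threshold_sd)
        bin_width = params.bin_width or ev.auto_bin_width(trains)
        raster = ev.bin_events(trains, bin_width, sampling_rate=recording.sampling_rate)
        catalog = extract_avalanches(
            raster,
            provenance={"threshold_sd": params.threshold_sd, "subject_id": subject_id},
        )
        pair = fit_exponent_pair(
            catalog,
            method=params.fit_method,
            n_boot=params.n_boot,
            min_count=params.min_gamma_count,
            seed=params.seed,
            system_size=raster.n_rows,
        )
        metrics = _metrics(raster, catalog, bin_width, params)
    except QuasicritError as exc:
        logger.warning("subject %s excluded: %s", subject_id, exc)
        return SubjectResult(
            subject_id=subject_id,
            metrics=None,
            exponents=None,
            excluded=True,
            exclusion_reason=f"{type(exc).__name__}: {exc}",
        )
    return SubjectResult(subject_id=subject_id, metrics=metrics, exponents=pair)


def _metrics(raster, catalog: AvalancheCatalog, bin_width: int, params: AnalysisParams):
    series = activity_density(raster)
    chi = susceptibility(series)
    try:
        sigma_naive = branching_naive(catalog)
    except QuasicritError:
        sigma_naive = float("nan")
    try:
        sigma_mr = branching_mr(series, k_max=params.mr_k_max)
    except QuasicritError:
        sigma_mr = float("nan")
    return SubjectMetrics(
        mean_rate=series.mean_rate,
        chi=chi,
        ltf=ltf(series),
        var_s=avalanche_size_variance(catalog),
        sigma_naive=sigma_naive,
        sigma_mr=sigma_mr,
        bin_width=bin_width,
        n_avalanches=len(catalog),
    )


@dataclass
class CohortResults:
    table: pd.DataFrame  # one row per subject (included and excluded)
    scaling_line: object
    statistics: pd.DataFrame
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out_dir / "cohort_results.csv", index=False)
        self.statistics.to_csv(out_dir / "statistics.csv", index=False)
        line = self.scaling_line
        with open(out_dir / "scaling_line.json", "w") as fh:
            json.dump(
                {
                    "slope": line.slope,
                    "intercept": line.intercept,
                    "slope_stderr": line.slope_stderr,
                    "n_pairs": line.n_pairs,
                    "excluded": [
                        {"subject_id": s, "reason": r} for s, r in self.excluded
                    ],
                },
                fh,
                indent=2,
            )


def run_cohort(
    subjects,
    params: AnalysisParams = AnalysisParams(),
) -> CohortResults:
    """Analyze a cohort of subjects (``SyntheticSubject`` or (id, age, gender,
    Recording) tuples), fit the scaling line and compute cohort statistics."""
    results: list[SubjectResult] = []
    for sub in subjects:
        if hasattr(sub, "recording"):
            sid, age, gender, rec = sub.subject_id, sub.age, sub.gender, sub.recording
        else:
            sid, age, gender, rec = sub
        res = analyze_subject(rec, params, subject_id=sid)
        res.age, res.gender = age, gender
        results.append(res)

    included = [r for r in results if not r.excluded]
    excluded = [(r.subject_id, r.exclusion_reason) for r in results if r.excluded]
    for sid, reason in excluded:
        logger.info("excluded %s: %s", sid, reason)
    pairs = np.array(
        [(r.exponents.tau_S.exponent, r.exponents.tau_T.exponent) for r in included]
    )
    line = fit_scaling_line(pairs)
    positions = position_on_line(pairs, line)
    for r, pos in zip(included, positions):
        r.metrics.position = float(pos)

    table = pd.DataFrame([_row(r) for r in results])
    statistics = cohort_statistics(table)
    return CohortResults(
        table=table, scaling_line=line, statistics=statistics, excluded=excluded
    )


def _row(r: SubjectResult) -> dict:
    row = {
        "subject_id": r.subject_id,
        "age": r.age,
        "gender": r.gender,
        "excluded": r.excluded,
        "exclusion_reason": r.exclusion_reason,
    }
    if not r.excluded:
        row.update(
            {
                "tau_S": r.exponents.tau_S.exponent,
                "tau_S_err": r.exponents.tau_S.stderr,
                "tau_T": r.exponents.tau_T.exponent,
                "tau_T_err": r.exponents.tau_T.stderr,
                "gamma_fit": r.exponents.gamma_fit,
                "fraction": r.exponents.fraction,
                "dcc": r.exponents.dcc,
            }
        )
        row.update(dataclasses.asdict(r.metrics))
    return row


#: variable pairs correlated across the cohort (log10 var(S) per convention)
_CORRELATION_PAIRS = [
    ("age", "position"),
    ("age", "chi"),
    ("position", "chi"),
    ("age", "mean_rate"),
    ("age", "ltf"),
    ("age", "log_var_s"),
    ("chi", "log_var_s"),
    ("age", "sigma_naive"),
    ("age", "sigma_mr"),
]


def cohort_statistics(table: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """Pearson correlations plus a Welch t-test of position by gender.

    Rows with missing values are dropped per statistic; statistics with
    fewer than ``min_n`` usable subjects are omitted (logged).
    """
    df = table[~table["excluded"]].copy()
    if "var_s" in df:
        df["log_var_s"] = np.log10(df["var_s"].where(df["var_s"] > 0))
    rows = []
    for x, y in _CORRELATION_PAIRS:
        if x not in df or y not in df:
            continue
        sub = df[[x, y]].dropna()
        if len(sub) < min_n:
            logger.info("statistic (%s, %s) omitted: n=%d", x, y, len(sub))
            continue
        if sub[x].nunique() < 2 or sub[y].nunique() < 2:
            logger.info("statistic (%s, %s) omitted: constant input", x, y)
            continue
        r, p = stats.pearsonr(sub[x], sub[y])
        rows.append(
            {"statistic": "pearson", "x": x, "y": y, "value": r, "p": p, "n": len(sub)}
        )
    by_gender = df.dropna(subset=["position"]).groupby("gender")["position"]
    if by_gender.ngroups == 2 and by_gender.size().min() >= min_n:
        (g1, a), (g2, b) = list(by_gender)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "statistic": f"welch_t_position_{g1}_vs_{g2}",
                "x": "gender",
                "y": "position",
                "value": t,
                "p": p,
                "n": len(a) + len(b),
            }
        )
    return pd.DataFrame(rows)
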