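"""Longitudinal analysis of shunt response.

Phase binning of follow-up scans, absolute/relative change computation,
cohort summary tables (mean +/- SD per measure, phase and stratum) and the
nonparametric comparisons: Wilcoxon signed-rank against the pre-shunt scan,
Wilcoxon rank-sum between strata, and Fisher's exact test for proportions.

Sign convention: changes are stored as follow-up minus baseline, so a
shrinking ventricle has a negative change; renderers are free to print
magnitudes with direction words. No multiplicity correction is applied by
default (each comparison is reported at the nominal level); Holm adjustment
is available via ``holm=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .volume_model import COMPARTMENT_ROLES, ParameterError

__all__ = [
    "MEASURES",
    "VOLUME_MEASURES",
    "assign_phase",
    "compute_changes",
    "signed_rank_test",
    "rank_sum_test",
    "fisher_exact",
    "summarize",
    "SummaryResult",
]

#: Measures analysed longitudinally: the six indices plus all volumes.
INDEX_MEASURES: tuple[str, ...] = (
    "evans",
    "z_evans",
    "callosal_angle",
    "bvr_ac",
    "bvr_pc",
    "cvr",
)
VOLUME_MEASURES: tuple[str, ...] = COMPARTMENT_ROLES + (
    "total_ventricles",
    "total_sas",
    "total_csf",
)
MEASURES: tuple[str, ...] = INDEX_MEASURES + VOLUME_MEASURES


# ---------------------------------------------------------------------------
# Phase binning


def assign_phase(days_since_shunt: int) -> str:
    """Bin a scan by time from shunt surgery.

    Negative days are pre-shunt; [0, 30) days is early; [30, 365] is mid;
    beyond one year is late. The observed visit windows never touch the
    boundary days, so the convention at 30/365 is safe either way; this one
    is fixed here.
    """
    d = int(days_since_shunt)
    if d < 0:
        return "pre"
    if d < 30:
        return "early"
    if d <= 365:
        return "mid"
    return "late"


PHASE_ORDER: tuple[str, ...] = ("pre", "early", "mid", "late")


# ---------------------------------------------------------------------------
# Changes


def compute_changes(
    records: pd.DataFrame, measures: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-scan changes from baseline, one row per measure per follow-up.

    ``absolute_change`` is follow-up minus baseline in measure units;
    ``relative_change`` is the absolute change as a percentage of baseline
    (NaN when the baseline is 0). Follow-ups of patients without a baseline
    record are skipped with a warning.
    """
    measures = list(measures) if measures is not None else [
        m for m in MEASURES if m in records.columns
    ]
    base = records[records.phase == "pre"]
    dup = base.patient_id.duplicated()
    if dup.any():
        raise ParameterError(
            f"patients with multiple baseline records: "
            f"{sorted(base.patient_id[dup].unique().tolist())}"
        )
    base = base.set_index("patient_id")
    follow = records[records.phase != "pre"]
    missing = set(follow.patient_id) - set(base.index)
    if missing:
        warnings.warn(
            f"skipping follow-ups of patients without baseline: {sorted(missing)}",
            stacklevel=2,
        )
        follow = follow[~follow.patient_id.isin(missing)]

    long = follow.melt(
        id_vars=["patient_id", "phase", "days_since_shunt"],
        value_vars=measures,
        var_name="measure",
        value_name="followup",
    )
    base_long = (
        base[measures]
        .reset_index()
        .melt(id_vars="patient_id", var_name="measure", value_name="baseline")
    )
    out = long.merge(base_long, on=["patient_id", "measure"], how="left")
    out["absolute_change"] = out.followup - out.baseline
    zero = out.baseline == 0
    if zero.any():
        warnings.warn(
            f"baseline is 0 for {int(zero.sum())} measure/patient pairs; "
            "relative change undefined there",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["relative_change"] = np.where(
            zero, np.nan, out.absolute_change / out.baseline * 100.0
        )
    return out[
        [
            "patient_id",
            "measure",
            "phase",
            "days_since_shunt",
            "baseline",
            "followup",
            "absolute_change",
            "relative_change",
        ]
    ]


# ---------------------------------------------------------------------------
# Nonparametric tests (scipy-backed; enumeration oracles live in the tests)


def signed_rank_test(differences: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired differences.

    Zeros are dropped (Wilcoxon's original treatment). The exact null
    distribution is used for n <= 25 without tied magnitudes; otherwise the
    normal approximation with continuity and tie correction.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all differences are zero; p = 1", stacklevel=2)
        return 1.0
    ties = np.unique(np.abs(d)).size < d.size
    if d.size <= 25 and not ties:
        return float(_st.wilcoxon(d, method="exact").pvalue)
    return float(_st.wilcoxon(d, method="approx", correction=True).pvalue)


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact when the smaller group has <= 10 observations and there are no
    ties across the pooled sample; otherwise the tie-corrected normal
    approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    if min(a.size, b.size) <= 10 and not ties:
        return float(_st.mannwhitneyu(a, b, method="exact").pvalue)
    return float(
        _st.mannwhitneyu(a, b, method="asymptotic", use_continuity=True).pvalue
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table
    (hypergeometric tail summation over tables at most as probable)."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ParameterError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ParameterError("counts must be nonnegative integers")
    return float(_st.fisher_exact(t).pvalue)


# ---------------------------------------------------------------------------
# Summary tables


@dataclass
class SummaryResult:
    """``table``: mean +/- SD per stratum x measure x phase;
    ``tests``: paired and between-stratum test results."""

    table: pd.DataFrame
    tests: pd.DataFrame


def _dedup_earliest(records: pd.DataFrame) -> pd.DataFrame:
    """Keep the earliest scan when a patient has several in one phase."""
    return (
        records.sort_values("days_since_shunt")
        .groupby(["patient_id", "phase"], as_index=False)
        .first()
    )


def summarize(
    records: pd.DataFrame,
    stratifier: str = "none",
    alpha: float = 0.05,
    holm: bool = False,
    measures: Sequence[str] | None = None,
) -> SummaryResult:
    """Cohort summary and the analysis-plan tests.

    Means and SDs per measure x phase (x stratum); volume measures also get
    the mean volume ratio in percent of TIV. Each post-shunt phase is
    compared to pre-shunt by the signed-rank test on patients observed in
    both; with a stratifier, the two largest strata are compared at each
    phase by the rank-sum test. ``significant`` flags p < alpha; no
    multiplicity correction unless ``holm=True`` (adds ``p_adj``).
    """
    if stratifier not in ("none", "outcome", "ad_status"):
        raise ParameterError(f"unknown stratifier {stratifier!r}")
    measures = list(measures) if measures is not None else [
        m for m in MEASURES if m in records.columns
    ]
    recs = _dedup_earliest(records)
    if stratifier == "none":
        recs = recs.assign(stratum="all")
    elif stratifier == "outcome":
        recs = recs.assign(stratum=recs.outcome)
    else:
        recs = recs.assign(
            stratum=np.where(recs.ad_comorbid, "inph_ad", "pure_inph")
        )

    table_rows = []
    for (stratum, phase), grp in recs.groupby(["stratum", "phase"], sort=False):
        for m in measures:
            vals = grp[m].to_numpy(dtype=float)
            n = len(vals)
            if n == 0:
                continue
            if n < 2:
                warnings.warn(
                    f"single record for {m} in {stratum}/{phase}; SD undefined",
                    stacklevel=2,
                )
            row = {
                "stratum": stratum,
                "measure": m,
                "phase": phase,
                "n": n,
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if n >= 2 else np.nan,
            }
            if m in VOLUME_MEASURES and "tiv" in grp.columns:
                row["mean_vr_pct"] = float(
                    np.mean(vals / grp["tiv"].to_numpy(dtype=float)) * 100.0
                )
            else:
                row["mean_vr_pct"] = np.nan
            table_rows.append(row)
    table = pd.DataFrame(table_rows)
    table["phase"] = pd.Categorical(table["phase"], PHASE_ORDER, ordered=True)
    table = table.sort_values(["stratum", "measure", "phase"]).reset_index(drop=True)

    test_rows = []
    wide = {
        m: recs.pivot_table(
            index="patient_id", columns="phase", values=m, aggfunc="first"
        )
        for m in measures
    }
    strata = recs.groupby("stratum").patient_id.nunique().sort_values(ascending=False)
    for stratum in strata.index:
        pids = recs.loc[recs.stratum == stratum, "patient_id"].unique()
        for m in measures:
            w = wide[m].reindex(pids)
            if "pre" not in w.columns:
                continue
            for phase in ("early", "mid", "late"):
                if phase not in w.columns:
                    continue
                paired = w[["pre", phase]].dropna()
                if len(paired) == 0:
                    continue
                diffs = paired[phase] - paired["pre"]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = signed_rank_test(diffs.to_numpy())
                test_rows.append(
                    {
                        "test": "signed_rank_vs_pre",
                        "stratum": stratum,
                        "measure": m,
                        "phase": phase,
                        "n": len(paired),
                        "p": p,
                    }
                )
    if stratifier != "none" and len(strata) >= 2:
        # baseline values are compared directly; post-shunt phases are
        # compared on relative changes from baseline (the response, not the
        # patient's absolute anatomy)
        g1, g2 = strata.index[:2]
        stratum_of = recs.drop_duplicates("patient_id").set_index("patient_id").stratum
        for m in measures:
            w = wide[m]
            for phase in PHASE_ORDER:
                if phase == "pre":
                    series = w["pre"] if "pre" in w.columns else None
                elif phase in w.columns and "pre" in w.columns:
                    series = (w[phase] - w["pre"]) / w["pre"] * 100.0
                else:
                    series = None
                if series is None:
                    continue
                series = series.dropna()
                a = series[stratum_of.reindex(series.index) == g1]
                b = series[stratum_of.reindex(series.index) == g2]
                if len(a) == 0 or len(b) == 0:
                    continue
                test_rows.append(
                    {
                        "test": f"rank_sum_{g1}_vs_{g2}",
                        "stratum": f"{g1}|{g2}",
                        "measure": m,
                        "phase": phase,
                        "n": len(a) + len(b),
                        "p": rank_sum_test(a.to_numpy(), b.to_numpy()),
                    }
                )
    tests = pd.DataFrame(
        test_rows, columns=["test", "stratum", "measure", "phase", "n", "p"]
    )
    if holm and len(tests):
        from statsmodels.stats.multitest import multipletests

        tests["p_adj"] = multipletests(tests["p"], method="holm")[1]
        tests["significant"] = tests["p_adj"] < alpha
    else:
        tests["significant"] = tests["p"] < alpha
    return SummaryResult(table=table, tests=tests)
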