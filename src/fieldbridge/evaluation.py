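"""Aggregation, anchor-point and pairwise-comparison logic.

The atom of all aggregation is a *metric record*: one value of one metric
(and ψ threshold, for IDP) for one subject/slice/comparison.  Records live in
a pandas ``DataFrame`` with columns::

    subject_id, vendor, comparison, metric, psi, level, slice_index, value

``comparison`` names what was scored against the high-field reference:
``"orig_low"`` (the realigned low-field scan — the first clinical anchor's
baseline), a method name (``"bicubic"``, ``"espcn"``, ...), or
``"repeat_low"`` (two repeat low-field scans against each other — the second
anchor).  Averaging is hierarchical and unweighted: slice values are averaged
within subject, subject values are averaged across the cohort (optionally per
vendor).

Pairwise method differences come with 95% confidence intervals and two-sided
p-values from either a paired t-test on subject-level values or a
subject-clustered robust (sandwich) estimator on slice-level values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .metrics import QuantizedPair, idp

RECORD_COLUMNS = [
    "subject_id", "vendor", "comparison", "metric", "psi",
    "level", "slice_index", "value",
]

#: metrics where smaller values mean a closer match to the reference
LOWER_IS_BETTER = {"idp": True, "perceptual": True, "psnr": False, "ssim": False}

BASELINE_COMPARISON = "orig_low"
REPEAT_COMPARISON = "repeat_low"


def make_record(
    subject_id: str, vendor: str, comparison: str, metric: str, value: float,
    psi: Optional[float] = None, level: str = "slice",
    slice_index: Optional[int] = None,
) -> Dict:
    return {
        "subject_id": subject_id, "vendor": vendor, "comparison": comparison,
        "metric": metric, "psi": psi, "level": level,
        "slice_index": slice_index, "value": float(value),
    }


def records_frame(records: Sequence[Dict]) -> pd.DataFrame:
    df = pd.DataFrame(list(records), columns=RECORD_COLUMNS)
    return df


def _one_group(df: pd.DataFrame) -> None:
    if df.empty:
        raise ValueError("no records to aggregate")
    metrics = df["metric"].unique()
    if len(metrics) != 1:
        raise ValueError(f"mixed metrics in one aggregation call: {sorted(metrics)}")
    psis = df["psi"].fillna(-1).unique()
    if len(psis) != 1:
        raise ValueError("mixed psi thresholds in one aggregation call")


def aggregate(slice_records: pd.DataFrame) -> pd.DataFrame:
    """Slice → subject → cohort averaging for one metric/ψ combination.

    Returns subject-level records plus cohort-level records overall
    (vendor ``"all"``) and per vendor, for each comparison present.
    """
    df = slice_records
    _one_group(df)
    if not (df["level"] == "slice").all():
        raise ValueError("aggregate expects slice-level records")
    out: List[Dict] = []
    metric = df["metric"].iloc[0]
    psi = df["psi"].iloc[0]
    subj = (
        df.groupby(["comparison", "subject_id", "vendor"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    for _, row in subj.iterrows():
        out.append(
            make_record(row["subject_id"], row["vendor"], row["comparison"],
                        metric, row["value"], psi=psi, level="subject")
        )
    for comparison, grp in subj.groupby("comparison"):
        out.append(
            make_record("cohort", "all", comparison, metric,
                        grp["value"].mean(), psi=psi, level="cohort")
        )
        for vendor, vgrp in grp.groupby("vendor"):
            out.append(
                make_record("cohort", vendor, comparison, metric,
                            vgrp["value"].mean(), psi=psi, level="cohort")
            )
    return records_frame(out)


def aggregate_all(slice_records: pd.DataFrame) -> pd.DataFrame:
    """Run :func:`aggregate` for every (metric, ψ) combination present."""
    frames = [
        aggregate(grp)
        for _, grp in slice_records.groupby(
            ["metric", slice_records["psi"].fillna(-1)], sort=True
        )
    ]
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class PairwiseComparison:
    metric: str
    psi: Optional[float]
    method_a: str
    method_b: str
    mean_difference: float
    ci95: Tuple[float, float]
    p_value: float
    n_subjects: int
    stat_method: str = "paired_t"

    def __post_init__(self):
        lo, hi = self.ci95
        if not (lo <= self.mean_difference <= hi):
            raise ValueError("CI does not bracket the mean difference")


def _subject_means(df: pd.DataFrame, comparison: str) -> pd.Series:
    sub = df[df["comparison"] == comparison]
    if (sub["level"] == "slice").any():
        return sub.groupby("subject_id")["value"].mean()
    return sub.set_index("subject_id")["value"]


def compare_pairwise(
    records: pd.DataFrame,
    comparison_a: str,
    comparison_b: str,
    method: str = "paired_t",
    alpha: float = 0.05,
) -> PairwiseComparison:
    """Paired difference (a − b) between two comparisons on shared subjects.

    ``paired_t``: t-test on subject-level differences with the analytic
    t-based CI.  ``cluster_robust``: intercept-only least squares on
    slice-level differences with subject-clustered sandwich standard errors
    and a t reference distribution on (clusters − 1) degrees of freedom.
    """
    _one_group(records)
    metric = records["metric"].iloc[0]
    psi = records["psi"].iloc[0]
    if method not in ("paired_t", "cluster_robust"):
        raise ValueError(f"unknown method {method!r}")

    a = _subject_means(records, comparison_a)
    b = _subject_means(records, comparison_b)
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError(
            f"no shared subjects between {comparison_a!r} and {comparison_b!r}"
        )
    n = len(shared)

    if method == "paired_t":
        d = (a.loc[shared] - b.loc[shared]).to_numpy(dtype=float)
        mean = float(d.mean())
        sd = float(d.std(ddof=1)) if n > 1 else 0.0
        if sd == 0.0:
            p = 1.0 if mean == 0.0 else 0.0
            ci = (mean, mean)
        else:
            se = sd / np.sqrt(n)
            tstat = mean / se
            p = float(2 * stats.t.sf(abs(tstat), df=n - 1))
            tcrit = stats.t.ppf(1 - alpha / 2, df=n - 1)
            ci = (mean - tcrit * se, mean + tcrit * se)
    else:
        sl = records[records["level"] == "slice"]
        da = sl[sl["comparison"] == comparison_a].set_index(
            ["subject_id", "slice_index"])["value"]
        db = sl[sl["comparison"] == comparison_b].set_index(
            ["subject_id", "slice_index"])["value"]
        joined = pd.concat({"a": da, "b": db}, axis=1).dropna()
        if joined.empty:
            raise ValueError("cluster_robust requires slice-level records")
        diff = (joined["a"] - joined["b"]).to_numpy(dtype=float)
        groups = joined.index.get_level_values("subject_id")
        n = groups.nunique()
        if np.allclose(diff.std(), 0.0):
            mean = float(diff.mean())
            p = 1.0 if mean == 0.0 else 0.0
            ci = (mean, mean)
        else:
            model = sm.OLS(diff, np.ones_like(diff)).fit(
                cov_type="cluster",
                cov_kwds={"groups": groups.to_numpy()},
                use_t=True,
            )
            mean = float(model.params[0])
            p = float(model.pvalues[0])
            lo, hi = model.conf_int(alpha=alpha)[0]
            ci = (float(lo), float(hi))

    return PairwiseComparison(
        metric=metric, psi=None if pd.isna(psi) else float(psi),
        method_a=comparison_a, method_b=comparison_b,
        mean_difference=mean, ci95=ci, p_value=p, n_subjects=int(n),
        stat_method=method,
    )


def holm_adjust(p_values: Sequence[float]) -> List[float]:
    """Holm step-down adjustment of raw p-values."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()


@dataclass
class MethodVerdict:
    method: str
    metric: str
    psi: Optional[float]
    beats_baseline: bool
    p_vs_baseline: float
    mean_difference: float
    gap_to_repeat_baseline: Optional[float] = None
    below_repeat_floor: Optional[bool] = None


@dataclass
class AnchorReport:
    """Clinical-significance anchors.

    Anchor 1: a method must score statistically significantly *better* than
    the realigned original low-field scan against the reference.  Anchor 2:
    a method's cohort IDP is expected to sit above the repeat-scan IDP
    (measurement-error floor); the signed gap is reported, smaller is better,
    and a gap below the floor is flagged.
    """

    baseline_subject_values: Dict[str, pd.Series]
    repeat_scan_idp: Optional[pd.Series]
    verdicts: List[MethodVerdict] = field(default_factory=list)


def anchor_analysis(
    records: pd.DataFrame,
    alpha: float = 0.001,
    stat_method: str = "paired_t",
    idp_psi_for_anchor2: float = 0.0,
) -> AnchorReport:
    """Evaluate every method against the two anchors.

    ``records`` holds slice- or subject-level records including the
    ``orig_low`` baseline and, for anchor 2, ``repeat_low`` IDP records.
    """
    methods = sorted(
        set(records["comparison"]) - {BASELINE_COMPARISON, REPEAT_COMPARISON}
    )
    if BASELINE_COMPARISON not in set(records["comparison"]):
        raise ValueError("records lack the orig_low baseline comparison")

    rep = records[
        (records["comparison"] == REPEAT_COMPARISON)
        & (records["metric"] == "idp")
        & (records["psi"] == idp_psi_for_anchor2)
    ]
    repeat_idp = None
    if not rep.empty:
        repeat_idp = rep.groupby("subject_id")["value"].mean()
        if repeat_idp.size < 2:
            raise ValueError("repeat-scan records must cover >= 2 subjects")

    baselines: Dict[str, pd.Series] = {}
    verdicts: List[MethodVerdict] = []
    for (metric, psi), grp in records.groupby(
        ["metric", records["psi"].fillna(-1)], sort=True
    ):
        psi_val = None if psi == -1 else float(psi)
        main = grp[grp["comparison"] != REPEAT_COMPARISON]
        key = metric if psi_val is None else f"{metric}@{psi_val:g}"
        baselines[key] = _subject_means(main, BASELINE_COMPARISON)
        lower_better = LOWER_IS_BETTER.get(metric, True)
        for m in methods:
            if m not in set(main["comparison"]):
                continue
            cmp = compare_pairwise(main, m, BASELINE_COMPARISON, method=stat_method)
            better = (
                cmp.mean_difference < 0 if lower_better else cmp.mean_difference > 0
            )
            v = MethodVerdict(
                method=m, metric=metric, psi=psi_val,
                beats_baseline=bool(better and cmp.p_value < alpha),
                p_vs_baseline=cmp.p_value,
                mean_difference=cmp.mean_difference,
            )
            if (
                metric == "idp"
                and psi_val == idp_psi_for_anchor2
                and repeat_idp is not None
            ):
                method_cohort = float(_subject_means(main, m).mean())
                floor = float(repeat_idp.mean())
                v.gap_to_repeat_baseline = method_cohort - floor
                v.below_repeat_floor = bool(method_cohort < floor)
            verdicts.append(v)

    return AnchorReport(
        baseline_subject_values=baselines,
        repeat_scan_idp=repeat_idp,
        verdicts=verdicts,
    )


@dataclass(frozen=True)
class MethodRanking:
    metric: str
    psi: Optional[float]
    ordered: List[Tuple[str, float]]
    has_ties: bool


def rank_methods(
    records: pd.DataFrame, metric: str, psi: Optional[float] = None
) -> MethodRanking:
    """Order methods by cohort mean: ascending where lower is better (IDP,
    perceptual), descending otherwise (PSNR, SSIM).  Exact ties are broken
    alphabetically and flagged."""
    if metric not in LOWER_IS_BETTER:
        raise ValueError(f"unknown metric {metric!r}")
    sel = records[records["metric"] == metric]
    if psi is not None:
        sel = sel[sel["psi"] == psi]
    sel = sel[sel["comparison"] != REPEAT_COMPARISON]
    methods = sorted(set(sel["comparison"]))
    if len(methods) < 2:
        raise ValueError("ranking needs at least two comparisons")
    means = {m: float(_subject_means(sel, m).mean()) for m in methods}
    reverse = not LOWER_IS_BETTER[metric]
    ordered = sorted(means.items(), key=lambda kv: (-kv[1] if reverse else kv[1], kv[0]))
    values = [v for _, v in ordered]
    has_ties = len(set(values)) < len(values)
    return MethodRanking(metric=metric, psi=psi, ordered=ordered, has_ties=has_ties)


def difference_overlay(
    reference: np.ndarray, candidate: np.ndarray
) -> Tuple[np.ndarray, int]:
    """Mark every pixel with at least one quantized gray level of difference.

    Returns an RGB overlay (grayscale base with qualifying pixels in cyan)
    and the qualifying-pixel count, which equals ``idp(ψ=0).n_qualifying``
    by shared definition.  Symmetric in the two inputs up to the base image.
    """
    from .metrics import make_pair

    pair = make_pair(np.asarray(reference, float), np.asarray(candidate, float))
    res = idp(pair, 0.0)
    mask = _qualify_mask(pair)
    base = pair.reference.astype(float) / pair.max_f
    rgb = np.stack([base, base, base], axis=-1)
    rgb[mask] = [0.0, 1.0, 1.0]
    return rgb, res.n_qualifying


def _qualify_mask(pair: QuantizedPair) -> np.ndarray:
    from .metrics import _qualifying

    q, _ = _qualifying(pair, 0.0, "flag_nonzero")
    return q
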