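"""Threshold statistics: subgroup comparisons and ROC/Youden cut-point analysis.

The unit of analysis is the *slice* (one of the 25 slabs of one patient),
carrying its ΔArea% and the patient-level antero-posterior displacement of
each jaw.  A slice is "positive" at a given cutoff when its ΔArea% reaches
that percentage increase (+30, +50 or +100 %); sweeping a displacement
threshold over the patient scores yields an ROC curve whose maximal Youden
index J = sensitivity + specificity − 1 locates the skeletal displacement
threshold.  Slices of one patient share a score, a deliberate
pseudo-replication mirroring the clinical analysis; a patient-averaged
sensitivity mode is available.

Group comparisons use one-way ANOVA with a Games–Howell post hoc test
(unequal variances, studentized-range reference distribution) for ΔArea%,
and a Mann–Whitney test for ΔVolume%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import StatisticsError
from .metrics import REGION_NAMES, DeltaTable

__all__ = [
    "SliceDataset",
    "ROCResult",
    "build_slice_dataset",
    "subgroup_split",
    "anova_oneway",
    "games_howell",
    "mann_whitney",
    "roc_threshold",
    "youden_peaks",
    "logistic_combined_roc",
    "summarize_reports",
    "format_threshold_cell",
]

DEFAULT_CUTOFFS = (30.0, 50.0, 100.0)
DEFAULT_SUBGROUP_CUT = 5.0  # mm


# ---------------------------------------------------------------------------
# Dataset


@dataclass
class SliceDataset:
    """Long per-slice table plus per-case volume changes and provenance."""

    slices: pd.DataFrame  # patient, group, maxilla_ap, mandible_ap, slab, region, delta_area_pct
    volumes: pd.DataFrame  # patient, group, maxilla_ap, mandible_ap, delta_volume_pct
    n_excluded: int = 0

    def region_slices(self, region: str) -> pd.DataFrame:
        if region not in REGION_NAMES:
            raise ValueError(f"unknown region {region!r}")
        return self.slices[self.slices.region == region]

    def scores(self, segment: str) -> pd.Series:
        col = {"maxilla": "maxilla_ap", "mandible": "mandible_ap"}.get(segment)
        if col is None:
            raise ValueError(f"segment must be maxilla or mandible, got {segment!r}")
        return self.slices[col]


def build_slice_dataset(
    delta_tables: Mapping[str, DeltaTable],
    displacement_records: Iterable,
    groups: Mapping[str, str],
) -> SliceDataset:
    """Join per-case ΔArea tables with the bone-displacement records.

    Every patient must contribute a maxilla and a mandible record; slabs
    flagged invalid are omitted from the long table but counted.
    """
    ap = {}
    for rec in displacement_records:
        ap.setdefault(rec.patient, {})[rec.segment] = rec.ap
    rows, vol_rows, excluded = [], [], 0
    for patient, table in delta_tables.items():
        seg = ap.get(patient, {})
        missing = [s for s in ("maxilla", "mandible") if s not in seg]
        if missing:
            raise StatisticsError(
                f"patient {patient}: missing displacement record(s) for "
                + ", ".join(missing)
            )
        group = groups[patient]
        for slab, region, delta, valid in zip(
            table.slab_index, table.region, table.delta_area_pct, table.valid
        ):
            if not valid:
                excluded += 1
                continue
            rows.append(
                {
                    "patient": patient,
                    "group": group,
                    "maxilla_ap": seg["maxilla"],
                    "mandible_ap": seg["mandible"],
                    "slab": slab,
                    "region": region,
                    "delta_area_pct": delta,
                }
            )
        vol_rows.append(
            {
                "patient": patient,
                "group": group,
                "maxilla_ap": seg["maxilla"],
                "mandible_ap": seg["mandible"],
                "delta_volume_pct": table.delta_volume_pct,
            }
        )
    return SliceDataset(
        slices=pd.DataFrame(rows),
        volumes=pd.DataFrame(vol_rows),
        n_excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Subgroups


@dataclass(frozen=True)
class SubgroupSplit:
    segment: str
    cut: float
    #: region -> {"MAMS": array, "MMA_below": array, "MMA_at_or_above": array}
    by_region: dict
    empty: tuple  # (region, name) pairs flagged empty


def subgroup_split(
    ds: SliceDataset, segment: str, cut: float = DEFAULT_SUBGROUP_CUT
) -> SubgroupSplit:
    """Split slices into MAMS vs MMA-below-cut vs MMA-at-or-above-cut.

    The boundary is inclusive on the upper side: a displacement of exactly
    ``cut`` lands in the "at or above" subgroup.
    """
    score_col = {"maxilla": "maxilla_ap", "mandible": "mandible_ap"}[segment]
    by_region, empty = {}, []
    for region in REGION_NAMES:
        sl = ds.region_slices(region)
        parts = {
            "MAMS": sl[sl.group == "MAMS"],
            "MMA_below": sl[(sl.group == "MMA") & (sl[score_col] < cut)],
            "MMA_at_or_above": sl[(sl.group == "MMA") & (sl[score_col] >= cut)],
        }
        by_region[region] = {
            k: v.delta_area_pct.to_numpy() for k, v in parts.items()
        }
        for k, v in parts.items():
            if len(v) == 0:
                warnings.warn(f"empty subgroup {k} in {region}; comparison skipped")
                empty.append((region, k))
    return SubgroupSplit(segment=segment, cut=cut, by_region=by_region, empty=tuple(empty))


# ---------------------------------------------------------------------------
# Classical tests


def anova_oneway(groups: Sequence[np.ndarray]) -> tuple:
    """One-way fixed-effects ANOVA; returns (F, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise StatisticsError("ANOVA needs >= 2 groups with n >= 2 each")
    if all(np.var(g) == 0 for g in groups):
        raise StatisticsError("all groups have zero within-group variance")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def games_howell(
    groups: Sequence[np.ndarray],
    labels: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    with_ci: bool = True,
) -> pd.DataFrame:
    """Games–Howell pairwise comparisons for unequal variances.

    For each pair: Welch t statistic, Welch–Satterthwaite degrees of
    freedom, and the p-value of q = |t|·√2 under the studentized-range
    distribution with k groups.  Confidence intervals use the same
    reference distribution at the requested family-wise level.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 3 for g in groups):
        raise StatisticsError("Games-Howell requires n >= 3 in every group")
    k = len(groups)
    if k < 2:
        raise StatisticsError("need at least two groups")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(k)]
    m = [g.mean() for g in groups]
    v = [g.var(ddof=1) for g in groups]
    n = [len(g) for g in groups]
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            se2 = v[i] / n[i] + v[j] / n[j]
            se = np.sqrt(se2)
            diff = m[i] - m[j]
            if se == 0:
                t = 0.0 if diff == 0 else np.inf
                df = n[i] + n[j] - 2.0
            else:
                t = diff / se
                df = se2**2 / (
                    (v[i] / n[i]) ** 2 / (n[i] - 1) + (v[j] / n[j]) ** 2 / (n[j] - 1)
                )
            q = abs(t) * np.sqrt(2.0)
            p = float(sps.studentized_range.sf(q, k, df))
            if with_ci:
                q_crit = float(sps.studentized_range.ppf(1 - alpha, k, df))
                half = q_crit / np.sqrt(2.0) * se
            else:
                half = float("nan")
            rows.append(
                {
                    "group_i": labels[i],
                    "group_j": labels[j],
                    "mean_diff": diff,
                    "se": se,
                    "t": t,
                    "df": df,
                    "p_adj": min(p, 1.0),
                    "ci_lo": diff - half,
                    "ci_hi": diff + half,
                }
            )
    return pd.DataFrame(rows)


def mann_whitney(x, y) -> tuple:
    """Two-tailed Mann–Whitney U; exact for small tie-free samples, normal
    approximation with tie correction otherwise.  Returns (U, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise StatisticsError("Mann-Whitney requires non-empty samples")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# ROC / Youden


@dataclass(frozen=True)
class ROCResult:
    """ROC over candidate displacement thresholds for one analysis cell."""

    cutoff_pct: float
    segment: str  # maxilla | mandible | combined
    region: str
    thresholds: tuple  # candidate score thresholds, ascending
    sensitivity: tuple
    specificity: tuple
    youden: tuple
    auc: float
    n_pos: int
    n_neg: int
    primary_threshold: float
    secondary_thresholds: tuple = ()
    separation_flag: bool = field(default=False, compare=False)
    params: tuple = field(default=(), compare=False)  # logistic fit coefficients

    def __post_init__(self):
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC out of [0, 1]")

    @property
    def j_max(self) -> float:
        return max(self.youden)

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "youden_j": self.youden,
            }
        )


def _roc_from_scores(scores: np.ndarray, labels: np.ndarray):
    """Candidate thresholds (midpoints of sorted unique scores), sens/spec
    arrays, and trapezoidal AUC.  Positive prediction: score >= threshold."""
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise StatisticsError("need at least two distinct scores")
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    sens = np.array([(scores[labels] >= t).mean() for t in mids])
    spec = np.array([(scores[~labels] < t).mean() for t in mids])
    # full curve for AUC includes the degenerate end thresholds
    all_t = np.concatenate([[uniq[0] - 1], mids, [uniq[-1] + 1]])
    tpr = np.array([(scores[labels] >= t).mean() for t in all_t])
    fpr = np.array([(scores[~labels] >= t).mean() for t in all_t])
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return mids, sens, spec, auc, n_pos, n_neg


def roc_threshold(
    ds: SliceDataset,
    segment: str,
    region: str,
    cutoff_pct: float,
    group: Optional[str] = None,
    patient_average: bool = False,
    peak_window: float = 0.05,
) -> ROCResult:
    """ROC of slice positivity (ΔArea% >= cutoff) against segment AP score.

    ``group`` restricts to one surgical procedure (default: pooled).
    ``patient_average`` collapses each patient's slices of the region to
    their mean ΔArea% first (sensitivity analysis for the pseudo-
    replication of slice-level scoring).
    """
    sl = ds.region_slices(region)
    if group is not None:
        sl = sl[sl.group == group]
    score_col = {"maxilla": "maxilla_ap", "mandible": "mandible_ap"}[segment]
    if patient_average:
        sl = (
            sl.groupby("patient", as_index=False)
            .agg({score_col: "first", "delta_area_pct": "mean"})
        )
    scores = sl[score_col].to_numpy(dtype=float)
    labels = sl.delta_area_pct.to_numpy(dtype=float) >= cutoff_pct
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise StatisticsError(
            f"single-class labels in {region} at +{cutoff_pct:g}% "
            f"({n_pos} positive, {n_neg} negative slices)"
        )
    mids, sens, spec, auc, n_pos, n_neg = _roc_from_scores(scores, labels)
    youden = sens + spec - 1.0
    result = ROCResult(
        cutoff_pct=float(cutoff_pct),
        segment=segment,
        region=region,
        thresholds=tuple(mids),
        sensitivity=tuple(sens),
        specificity=tuple(spec),
        youden=tuple(youden),
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
        primary_threshold=float("nan"),
    )
    primary, secondaries = youden_peaks(result, peak_window)
    return _with_peaks(result, primary, secondaries)


def _with_peaks(roc: ROCResult, primary: float, secondaries: tuple) -> ROCResult:
    from dataclasses import replace

    return replace(
        roc, primary_threshold=float(primary), secondary_thresholds=tuple(secondaries)
    )


def youden_peaks(roc: ROCResult, peak_window: float = 0.05) -> tuple:
    """Primary and secondary displacement thresholds from the J profile.

    Primary: candidate threshold maximising J (ties resolved toward the
    smaller displacement — clinically conservative).  Secondaries: other
    local maxima of J within ``peak_window`` of the maximum, reported in
    ascending order; a dual peak signals a possible double threshold.
    """
    j = np.asarray(roc.youden, dtype=float)
    t = np.asarray(roc.thresholds, dtype=float)
    if len(j) == 0:
        raise StatisticsError("degenerate ROC: no candidate thresholds")
    j_max = j.max()
    primary = float(t[np.argmax(j)])  # argmax returns first == smallest threshold
    secondaries = []
    for i in range(len(j)):
        left = j[i - 1] if i > 0 else -np.inf
        right = j[i + 1] if i < len(j) - 1 else -np.inf
        if j[i] >= max(left, right) and j[i] >= j_max - peak_window:
            # plateau: only the first index of a run counts
            if i > 0 and j[i] == j[i - 1]:
                continue
            if t[i] != primary:
                secondaries.append(float(t[i]))
    return primary, tuple(secondaries)


def format_threshold_cell(roc: ROCResult, ndigits: int = 1) -> str:
    """Render "(secondary) primary" in the reporting convention."""
    prim = f"{roc.primary_threshold:.{ndigits}f}"
    if roc.secondary_thresholds:
        secs = " ".join(f"({s:.{ndigits}f})" for s in roc.secondary_thresholds)
        return f"{secs} {prim}"
    return prim


# ---------------------------------------------------------------------------
# Combined logistic ROC


def logistic_combined_roc(
    ds: SliceDataset,
    region: str,
    cutoff_pct: float = 30.0,
    group: Optional[str] = None,
    peak_window: float = 0.05,
) -> ROCResult:
    """Multivariate ROC: logit of slice positivity on both jaw displacements.

    The fitted probability is the score; with complete separation the fit
    is flagged and a lightly ridge-penalised fit supplies the separating
    score instead.
    """
    sl = ds.region_slices(region)
    if group is not None:
        sl = sl[sl.group == group]
    y = (sl.delta_area_pct.to_numpy(dtype=float) >= cutoff_pct).astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise StatisticsError("single-class labels for combined ROC")
    x = sm.add_constant(sl[["maxilla_ap", "mandible_ap"]].to_numpy(dtype=float))
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(y, x).fit(disp=False)
        scores = fit.predict(x)
        params = fit.params
    except (Exception,):
        separation = True
        fit = sm.Logit(y, x).fit_regularized(alpha=1e-4, disp=False, maxiter=500)
        scores = fit.predict(x)
        params = fit.params
    labels = y.astype(bool)
    mids, sens, spec, auc, n_pos, n_neg = _roc_from_scores(np.asarray(scores), labels)
    youden = sens + spec - 1.0
    roc = ROCResult(
        cutoff_pct=float(cutoff_pct),
        segment="combined",
        region=region,
        thresholds=tuple(mids),
        sensitivity=tuple(sens),
        specificity=tuple(spec),
        youden=tuple(youden),
        auc=auc,
        n_pos=n_pos,
        n_neg=n_neg,
        primary_threshold=float("nan"),
        separation_flag=separation,
        params=tuple(np.asarray(params)),  # (const, b_maxilla, b_mandible)
    )
    primary, secondaries = youden_peaks(roc, peak_window)
    return _with_peaks(roc, primary, secondaries)


# ---------------------------------------------------------------------------
# Report tables


def _descr(values: np.ndarray) -> dict:
    if len(values) == 0:
        return {k: float("nan") for k in ("N", "max", "min", "mean", "sd", "median", "iqr")}
    q75, q25 = np.percentile(values, [75, 25])
    return {
        "N": len(values),
        "max": float(np.max(values)),
        "min": float(np.min(values)),
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        "median": float(np.median(values)),
        "iqr": float(q75 - q25),
    }


def _patient_frame(ds: SliceDataset) -> pd.DataFrame:
    return ds.volumes[["patient", "group", "maxilla_ap", "mandible_ap"]]


def _subgroup_masks(pf: pd.DataFrame, cut: float) -> dict:
    return {
        "MAMS": pf.group == "MAMS",
        "MMA": pf.group == "MMA",
        f"MMA—MX < {cut:g}": (pf.group == "MMA") & (pf.maxilla_ap < cut),
        f"MMA—MX ≥ {cut:g}": (pf.group == "MMA") & (pf.maxilla_ap >= cut),
        f"MMA—MD < {cut:g}": (pf.group == "MMA") & (pf.mandible_ap < cut),
        f"MMA—MD ≥ {cut:g}": (pf.group == "MMA") & (pf.mandible_ap >= cut),
    }


def table1_displacements(ds: SliceDataset, cut: float = DEFAULT_SUBGROUP_CUT) -> pd.DataFrame:
    """Descriptive statistics of AP displacement by subgroup and segment."""
    pf = _patient_frame(ds)
    rows = []
    for name, mask in _subgroup_masks(pf, cut).items():
        sub = pf[mask]
        if len(sub) == 0:
            warnings.warn(f"empty subgroup {name} in displacement table")
        for segment, col in (("maxilla", "maxilla_ap"), ("mandible", "mandible_ap")):
            rows.append(
                {"subgroup": name, "segment": segment, **_descr(sub[col].to_numpy())}
            )
    return pd.DataFrame(rows)


def table2_delta_area(ds: SliceDataset, cut: float = DEFAULT_SUBGROUP_CUT) -> pd.DataFrame:
    """ΔArea% mean/SD/min/max by pharyngeal region and subgroup."""
    pf = _patient_frame(ds)
    rows = []
    for name, mask in _subgroup_masks(pf, cut).items():
        patients = set(pf[mask].patient)
        sub = ds.slices[ds.slices.patient.isin(patients)]
        row = {"subgroup": name, "n_patients": len(patients)}
        for region in REGION_NAMES:
            vals = sub[sub.region == region].delta_area_pct.to_numpy()
            if len(vals):
                row.update(
                    {
                        f"{region}_mean": float(vals.mean()),
                        f"{region}_sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                        f"{region}_min": float(vals.min()),
                        f"{region}_max": float(vals.max()),
                    }
                )
            else:
                row.update({f"{region}_{s}": float("nan") for s in ("mean", "sd", "min", "max")})
        rows.append(row)
    return pd.DataFrame(rows)


def table3_thresholds(
    ds: SliceDataset,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    peak_window: float = 0.05,
) -> pd.DataFrame:
    """Displacement threshold, Youden J and AUC per segment x cutoff x region."""
    rows = []
    for segment in ("maxilla", "mandible"):
        for cutoff in cutoffs:
            for region in REGION_NAMES:
                try:
                    roc = roc_threshold(ds, segment, region, cutoff, peak_window=peak_window)
                    rows.append(
                        {
                            "segment": segment,
                            "cutoff_pct": cutoff,
                            "region": region,
                            "threshold_mm": roc.primary_threshold,
                            "secondary_mm": ";".join(
                                f"{s:.2f}" for s in roc.secondary_thresholds
                            ),
                            "youden_j": roc.j_max,
                            "auc": roc.auc,
                            "n_pos": roc.n_pos,
                            "n_neg": roc.n_neg,
                            "cell": format_threshold_cell(roc),
                        }
                    )
                except StatisticsError as exc:
                    warnings.warn(f"{segment}/{cutoff}/{region}: {exc}")
                    rows.append(
                        {
                            "segment": segment,
                            "cutoff_pct": cutoff,
                            "region": region,
                            "threshold_mm": float("nan"),
                            "secondary_mm": "",
                            "youden_j": float("nan"),
                            "auc": float("nan"),
                            "n_pos": 0,
                            "n_neg": 0,
                            "cell": "NA",
                        }
                    )
    return pd.DataFrame(rows)


def summarize_reports(
    ds: SliceDataset,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
    cut: float = DEFAULT_SUBGROUP_CUT,
) -> dict:
    """Bundle the three report tables plus subgroup test results."""
    tests = []
    for segment in ("maxilla", "mandible"):
        split = subgroup_split(ds, segment, cut)
        for region in REGION_NAMES:
            g = split.by_region[region]
            for mma_arm in ("MMA_below", "MMA_at_or_above"):
                a, b = g["MAMS"], g[mma_arm]
                if len(a) >= 3 and len(b) >= 3:
                    gh = games_howell([a, b], labels=["MAMS", mma_arm])
                    p = float(gh.p_adj.iloc[0])
                else:
                    p = float("nan")
                tests.append(
                    {
                        "segment": segment,
                        "region": region,
                        "comparison": f"MAMS vs {mma_arm}",
                        "p_games_howell": p,
                    }
                )
    # volume comparisons (Mann-Whitney) on the same subgroup logic
    vol_tests = []
    vols = ds.volumes
    for segment, col in (("maxilla", "maxilla_ap"), ("mandible", "mandible_ap")):
        mams = vols[vols.group == "MAMS"].delta_volume_pct.to_numpy()
        for name, mask in (
            ("MMA_below", (vols.group == "MMA") & (vols[col] < cut)),
            ("MMA_at_or_above", (vols.group == "MMA") & (vols[col] >= cut)),
        ):
            arm = vols[mask].delta_volume_pct.to_numpy()
            if len(mams) and len(arm):
                u, p = mann_whitney(mams, arm)
            else:
                u, p = float("nan"), float("nan")
            vol_tests.append(
                {
                    "segment": segment,
                    "comparison": f"MAMS vs {name}",
                    "U": u,
                    "p": p,
                }
            )
    return {
        "table1": table1_displacements(ds, cut),
        "table2": table2_delta_area(ds, cut),
        "table3": table3_thresholds(ds, cutoffs),
        "games_howell": pd.DataFrame(tests),
        "mann_whitney_volume": pd.DataFrame(vol_tests),
    }
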