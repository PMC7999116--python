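from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from airwaymorph.errors import StatisticsError
from airwaymorph.metrics import DeltaTable, N_SLABS, SLAB_REGIONS
from airwaymorph.registration import DisplacementRecord
from airwaymorph.stats import (
    ROCResult,
    SliceDataset,
    anova_oneway,
    build_slice_dataset,
    format_threshold_cell,
    games_howell,
    logistic_combined_roc,
    mann_whitney,
    roc_threshold,
    subgroup_split,
    summarize_reports,
    table1_displacements,
    table3_thresholds,
    youden_peaks,
)


def _delta_table(patient, deltas=None, invalid=()):
    deltas = deltas if deltas is not None else np.zeros(N_SLABS)
    valid = [i + 1 not in invalid for i in range(N_SLABS)]
    return DeltaTable(
        patient=patient,
        slab_index=tuple(range(1, N_SLABS + 1)),
        region=SLAB_REGIONS,
        area_pre=tuple(100.0 for _ in range(N_SLABS)),
        area_post=tuple(100.0 + d for d in deltas),
        delta_area_pct=tuple(
            d if v else float("nan") for d, v in zip(deltas, valid)
        ),
        valid=tuple(valid),
        volume_pre=10000.0,
        volume_post=11000.0,
    )


def _record(patient, segment, ap):
    return DisplacementRecord(patient=patient, segment=segment, tx=0, ty=ap, tz=0,
                              pitch=0, roll=0, yaw=0)


def _dataset(aps, deltas_by_patient=None, groups=None):
    """aps: {patient: (mx, md)}; deltas default 0."""
    tables = {
        p: _delta_table(p, None if deltas_by_patient is None else deltas_by_patient[p])
        for p in aps
    }
    records = [
        r for p, (mx, md) in aps.items()
        for r in (_record(p, "maxilla", mx), _record(p, "mandible", md))
    ]
    groups = groups or {p: "MMA" for p in aps}
    return build_slice_dataset(tables, records, groups)


class TestBuildDataset:
    def test_two_patients_fifty_rows(self):
        ds = _dataset({"a": (1, 2), "b": (3, 4)})
        assert len(ds.slices) == 50
        assert ds.n_excluded == 0

    def test_invalid_slab_excluded_and_counted(self):
        tables = {"a": _delta_table("a", invalid={7}), "b": _delta_table("b")}
        records = [_record("a", "maxilla", 1), _record("a", "mandible", 1),
                   _record("b", "maxilla", 1), _record("b", "mandible", 1)]
        ds = build_slice_dataset(tables, records, {"a": "MMA", "b": "MAMS"})
        assert len(ds.slices) == 49
        assert ds.n_excluded == 1

    def test_region_row_counts_per_patient(self):
        ds = _dataset({"a": (1, 2)})
        counts = ds.slices.groupby("region").size()
        assert counts["nasopharynx"] == 5
        assert counts["oropharynx"] == 9
        assert counts["hypopharynx"] == 11

    def test_missing_segment_record_raises(self):
        tables = {"a": _delta_table("a")}
        with pytest.raises(StatisticsError, match="mandible"):
            build_slice_dataset(tables, [_record("a", "maxilla", 1)], {"a": "MMA"})


class TestSubgroupSplit:
    def test_membership_matches_enumeration(self):
        aps = {"a": (2.0, 1.0), "b": (7.0, 2.0), "c": (4.0, 9.0), "d": (3.0, -2.0)}
        groups = {"a": "MMA", "b": "MMA", "c": "MMA", "d": "MAMS"}
        ds = _dataset(aps, groups=groups)
        split = subgroup_split(ds, "maxilla", 5.0)
        for region, g in split.by_region.items():
            n_region = {"nasopharynx": 5, "oropharynx": 9, "hypopharynx": 11}[region]
            assert len(g["MAMS"]) == 1 * n_region
            assert len(g["MMA_below"]) == 2 * n_region  # a, c
            assert len(g["MMA_at_or_above"]) == 1 * n_region  # b

    def test_boundary_exactly_five_goes_to_upper_group(self):
        ds = _dataset({"a": (5.0, 0.0)}, groups={"a": "MMA"})
        split = subgroup_split(ds, "maxilla", 5.0)
        assert len(split.by_region["oropharynx"]["MMA_at_or_above"]) == 9
        assert len(split.by_region["oropharynx"]["MMA_below"]) == 0

    def test_empty_subgroup_flagged(self):
        ds = _dataset({"a": (2.0, 1.0)}, groups={"a": "MMA"})
        with pytest.warns(UserWarning, match="empty subgroup"):
            split = subgroup_split(ds, "maxilla", 5.0)
        assert ("oropharynx", "MAMS") in split.empty


class TestAnova:
    def test_identical_groups(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        f, p = anova_oneway([g, g, g])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_f(self):
        groups = [np.array([1.0, 2, 3]), np.array([2.0, 4, 6]), np.array([5.0, 5, 8])]
        f, p = anova_oneway(groups)
        all_v = np.concatenate(groups)
        grand = all_v.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_hand = (ss_between / 2) / (ss_within / (len(all_v) - 3))
        assert f == pytest.approx(f_hand, rel=1e-12)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(23)
        rej = 0
        reps = 2000
        for _ in range(reps):
            _, p = anova_oneway([rng.normal(size=10) for _ in range(3)])
            rej += p < 0.05
        assert 0.03 <= rej / reps <= 0.07

    def test_degenerate_inputs(self):
        with pytest.raises(StatisticsError):
            anova_oneway([np.array([1.0, 2.0])])
        with pytest.raises(StatisticsError):
            anova_oneway([np.array([1.0, 1.0]), np.array([2.0, 2.0])])


class TestGamesHowell:
    def test_identical_groups_p_near_one(self):
        g = np.array([1.0, 2, 3, 4, 5])
        out = games_howell([g, g + 1e-12, g - 1e-12])
        assert (out.p_adj > 0.999).all()

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        g1, g2, g3 = rng.normal(0, 1, 20), rng.normal(1, 3, 15), rng.normal(0.5, 0.5, 30)
        mine = games_howell([g1, g2, g3], labels=["a", "b", "c"])
        df = pd.DataFrame(
            {"v": np.concatenate([g1, g2, g3]), "g": ["a"] * 20 + ["b"] * 15 + ["c"] * 30}
        )
        ref = pg.pairwise_gameshowell(data=df, dv="v", between="g")
        assert np.abs(mine.p_adj.to_numpy() - ref.pval.to_numpy()).max() < 1e-3

    def test_reduces_to_tukey_for_equal_variances(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(8)
        groups = [rng.normal(i * 0.1, 1.0, 1000) for i in range(3)]
        mine = games_howell(groups, labels=["0", "1", "2"])
        data = np.concatenate(groups)
        labels = np.repeat(["0", "1", "2"], 1000)
        tk = pairwise_tukeyhsd(data, labels)
        assert np.abs(mine.p_adj.to_numpy() - tk.pvalues).max() < 0.01

    def test_null_familywise_error_rate(self):
        rng = np.random.default_rng(31)
        reps = 2000
        rej = 0
        for _ in range(reps):
            out = games_howell(
                [rng.normal(size=10) for _ in range(3)], with_ci=False
            )
            rej += (out.p_adj < 0.05).any()
        assert 0.03 <= rej / reps <= 0.07

    def test_small_group_rejected(self):
        with pytest.raises(StatisticsError):
            games_howell([np.array([1.0, 2.0]), np.array([1.0, 2, 3])])


class TestMannWhitney:
    def test_identical_samples_p_near_one(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        _, p = mann_whitney(x, x.copy())
        assert p > 0.9

    def test_exact_p_equals_enumeration(self):
        x = np.array([1.2, 3.4, 0.5, 2.2, 5.1])
        y = np.array([2.9, 4.4, 6.1, 0.1, 3.3])
        u, p = mann_whitney(x, y)
        n, m = len(x), len(y)
        ranks = sps.rankdata(np.concatenate([x, y]))
        u_obs = ranks[:n].sum() - n * (n + 1) / 2
        u_min_obs = min(u_obs, n * m - u_obs)
        count = total = 0
        all_ranks = np.arange(1, n + m + 1)
        for idx in combinations(range(n + m), n):
            rx = all_ranks[list(idx)].sum()
            uu = rx - n * (n + 1) / 2
            if min(uu, n * m - uu) <= u_min_obs:
                count += 1
            total += 1
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_power_for_shifted_normals(self):
        rng = np.random.default_rng(12)
        rejections = 0
        for _ in range(500):
            x = rng.normal(0, 1, 30)
            y = rng.normal(2, 1, 30)
            _, p = mann_whitney(x, y)
            rejections += p < 0.05
        assert rejections / 500 > 0.9

    def test_empty_input_rejected(self):
        with pytest.raises(StatisticsError):
            mann_whitney([], [1.0])


def _roc_dataset(scores, deltas, groups=None):
    n = len(scores)
    pats = [f"p{i}" for i in range(n)]
    sl = pd.DataFrame(
        {
            "patient": pats,
            "group": groups if groups is not None else ["MMA"] * n,
            "maxilla_ap": scores,
            "mandible_ap": np.asarray(scores) * 0.5,
            "slab": 1,
            "region": "oropharynx",
            "delta_area_pct": deltas,
        }
    )
    vols = sl.rename(columns={"delta_area_pct": "delta_volume_pct"})[
        ["patient", "group", "maxilla_ap", "mandible_ap", "delta_volume_pct"]
    ]
    return SliceDataset(slices=sl, volumes=vols)


class TestROC:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2, 3, 4, 10, 11, 12, 13])
        deltas = np.where(scores > 5, 100.0, 0.0)
        roc = roc_threshold(_roc_dataset(scores, deltas), "maxilla", "oropharynx", 50.0)
        assert roc.auc == 1.0
        assert 4.0 < roc.primary_threshold < 10.0

    def test_auc_equals_mann_whitney_identity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            scores = np.round(rng.normal(5, 2, 30), 1)  # rounding creates ties
            deltas = rng.normal(40, 30, 30)
            ds = _roc_dataset(scores, deltas)
            roc = roc_threshold(ds, "maxilla", "oropharynx", 30.0)
            lab = deltas >= 30.0
            u = sps.mannwhitneyu(scores[lab], scores[~lab], alternative="greater").statistic
            assert roc.auc == pytest.approx(u / (lab.sum() * (~lab).sum()), abs=1e-12)

    def test_permuted_labels_auc_half(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(5, 2, 40)
        deltas = np.where(np.arange(40) < 15, 80.0, 0.0)
        aucs = []
        for _ in range(500):
            ds = _roc_dataset(scores, rng.permutation(deltas))
            aucs.append(
                roc_threshold(ds, "maxilla", "oropharynx", 50.0).auc
            )
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_single_class_reports_counts(self):
        ds = _roc_dataset(np.arange(5.0), np.zeros(5))
        with pytest.raises(StatisticsError, match="0 positive"):
            roc_threshold(ds, "maxilla", "oropharynx", 50.0)

    def test_monotone_curve(self):
        rng = np.random.default_rng(10)
        ds = _roc_dataset(rng.normal(5, 2, 50), rng.normal(40, 40, 50))
        roc = roc_threshold(ds, "maxilla", "oropharynx", 50.0)
        sens = np.asarray(roc.sensitivity)
        spec = np.asarray(roc.specificity)
        assert (np.diff(sens) <= 1e-12).all()  # sens falls as threshold rises
        assert (np.diff(spec) >= -1e-12).all()


class TestYoudenPeaks:
    @staticmethod
    def _mk(thresholds, youden):
        n = len(thresholds)
        return ROCResult(
            cutoff_pct=50.0, segment="mandible", region="nasopharynx",
            thresholds=tuple(thresholds), sensitivity=(0.5,) * n,
            specificity=(0.5,) * n, youden=tuple(youden), auc=0.5,
            n_pos=10, n_neg=10, primary_threshold=float("nan"),
        )

    def test_unimodal_no_secondaries(self):
        roc = self._mk([1, 2, 3, 4, 5], [0.1, 0.3, 0.6, 0.4, 0.2])
        primary, secondaries = youden_peaks(roc)
        assert primary == 3.0 and secondaries == ()

    def test_dual_peak_reported(self):
        roc = self._mk([0.5, 1.4, 3.0, 5.2, 6.0], [0.30, 0.52, 0.20, 0.55, 0.30])
        primary, secondaries = youden_peaks(roc)
        assert primary == 5.2
        assert secondaries == (1.4,)
        assert format_threshold_cell(
            roc.__class__(**{**roc.__dict__, "primary_threshold": primary,
                             "secondary_thresholds": secondaries})
        ) == "(1.4) 5.2"

    def test_tie_goes_to_smaller_threshold(self):
        roc = self._mk([1.0, 2.0, 4.0], [0.5, 0.1, 0.5])
        primary, secondaries = youden_peaks(roc)
        assert primary == 1.0
        assert secondaries == (4.0,)

    def test_end_to_end_dual_peak_from_data(self):
        # two clusters of responders produce two J peaks
        scores = np.array([0.8, 1.0, 1.8, 2.0, 3.0, 3.2, 4.8, 5.0, 5.6, 5.8])
        deltas = np.array([0, 0, 80, 80, 0, 0, 0, 0, 80, 80.0])
        ds = _roc_dataset(scores, deltas)
        roc = roc_threshold(ds, "maxilla", "oropharynx", 50.0, peak_window=0.5)
        assert len(roc.secondary_thresholds) >= 1


class TestLogisticCombined:
    def test_maxilla_only_dependence_matches_univariate(self):
        rng = np.random.default_rng(3)
        n = 400
        mx = rng.normal(5, 3, n)
        md = rng.normal(3, 3, n)
        pr = 1 / (1 + np.exp(-(-3 + 0.8 * mx)))
        deltas = np.where(rng.uniform(size=n) < pr, 60.0, 0.0)
        sl = pd.DataFrame(
            {
                "patient": [f"p{i}" for i in range(n)], "group": "MMA",
                "maxilla_ap": mx, "mandible_ap": md, "slab": 1,
                "region": "nasopharynx", "delta_area_pct": deltas,
            }
        )
        ds = SliceDataset(slices=sl, volumes=sl.rename(
            columns={"delta_area_pct": "delta_volume_pct"}))
        combined = logistic_combined_roc(ds, "nasopharynx", 30.0)
        uni = roc_threshold(ds, "maxilla", "nasopharynx", 30.0)
        assert combined.auc == pytest.approx(uni.auc, abs=0.01)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(14)
        n = 1000
        mx = rng.normal(5, 3, n)
        md = rng.normal(3, 3, n)
        lin = -4 + 0.6 * mx + 0.3 * md
        deltas = np.where(rng.uniform(size=n) < 1 / (1 + np.exp(-lin)), 60.0, 0.0)
        sl = pd.DataFrame(
            {
                "patient": [f"p{i}" for i in range(n)], "group": "MMA",
                "maxilla_ap": mx, "mandible_ap": md, "slab": 1,
                "region": "oropharynx", "delta_area_pct": deltas,
            }
        )
        ds = SliceDataset(slices=sl, volumes=sl.rename(
            columns={"delta_area_pct": "delta_volume_pct"}))
        roc = logistic_combined_roc(ds, "oropharynx", 30.0)
        est = np.asarray(roc.params)
        assert np.abs((est - [-4, 0.6, 0.3]) / np.array([-4, 0.6, 0.3])).max() < 0.15

    def test_separable_data_flagged_auc_one(self):
        mx = np.array([0.0, 1, 2, 3, 10, 11, 12, 13])
        deltas = np.where(mx > 5, 60.0, 0.0)
        sl = pd.DataFrame(
            {
                "patient": [f"p{i}" for i in range(8)], "group": "MMA",
                "maxilla_ap": mx, "mandible_ap": mx * 0.1, "slab": 1,
                "region": "hypopharynx", "delta_area_pct": deltas,
            }
        )
        ds = SliceDataset(slices=sl, volumes=sl.rename(
            columns={"delta_area_pct": "delta_volume_pct"}))
        roc = logistic_combined_roc(ds, "hypopharynx", 30.0)
        assert roc.separation_flag
        assert roc.auc == 1.0


class TestReports:
    @staticmethod
    def _cohort_ds(seed=0):
        rng = np.random.default_rng(seed)
        aps, groups, deltas = {}, {}, {}
        for i in range(12):
            p = f"p{i}"
            g = "MMA" if i < 8 else "MAMS"
            mx = float(rng.uniform(0, 10))
            md = float(rng.uniform(0, 10) if g == "MMA" else rng.uniform(-5, 0))
            aps[p] = (mx, md)
            groups[p] = g
            deltas[p] = rng.normal(20, 30, N_SLABS)
        return _dataset(aps, deltas, groups), aps, groups

    def test_table1_medians_equal_direct_computation(self):
        ds, aps, groups = self._cohort_ds()
        t1 = table1_displacements(ds)
        mams_mx = np.median([v[0] for p, v in aps.items() if groups[p] == "MAMS"])
        row = t1[(t1.subgroup == "MAMS") & (t1.segment == "maxilla")].iloc[0]
        assert row["median"] == pytest.approx(mams_mx)
        assert row["N"] == 4

    def test_table3_has_18_threshold_cells(self):
        ds, _, _ = self._cohort_ds()
        t3 = table3_thresholds(ds)
        assert len(t3) == 18
        assert set(t3.segment) == {"maxilla", "mandible"}

    def test_summarize_bundle_keys_and_empty_subgroup_handling(self):
        ds, _, _ = self._cohort_ds()
        with pytest.warns(UserWarning):
            # +100% cutoff has very few positives in this small cohort
            reports = summarize_reports(ds)
        assert set(reports) == {
            "table1", "table2", "table3", "games_howell", "mann_whitney_volume"
        }
        assert len(reports["games_howell"]) == 12
        assert len(reports["mann_whitney_volume"]) == 4
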