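"""UAR/LAR arithmetic, national aggregation, decomposition conservation,
and recovery scoring against ground truth."""

import numpy as np
import pandas as pd
import pytest

from salesgap.anomalies import (
    aggregate_national,
    compute_lar,
    compute_uar,
    decompose_uar,
    grouping_from_truth,
    quantify_anomalies,
    recovery_report,
)


@pytest.mark.parametrize(
    "observed, p_u, expected",
    [(150.0, 100.0, 0.5), (100.0, 100.0, 0.0), (290.0, 100.0, 1.9)],
)
def test_upper_anomaly_ratio_formula(observed, p_u, expected):
    assert compute_uar(observed, p_u) == pytest.approx(expected)


@pytest.mark.parametrize(
    "observed, p_l, expected",
    [(80.0, 100.0, -0.2), (100.0, 100.0, 0.0), (65.0, 100.0, -0.35)],
)
def test_lower_anomaly_ratio_formula(observed, p_l, expected):
    assert compute_lar(observed, p_l) == pytest.approx(expected)


def test_nonpositive_bound_rejected():
    with pytest.raises(ValueError, match="positive"):
        compute_uar(100.0, 0.0)
    with pytest.raises(ValueError, match="positive"):
        compute_lar(100.0, -1.0)


def test_quantified_records_have_sign_correct_ratios(toy_classified):
    records = quantify_anomalies(toy_classified)
    assert (records.loc[records["status"] == "upper", "ratio"] > 0).all()
    assert (records.loc[records["status"] == "lower", "ratio"] < 0).all()
    assert records.loc[records["status"] == "none", "ratio"].isna().all()
    # UAR of observed 280 against p_u 200
    assert records.set_index("province").loc["A", "ratio"] == pytest.approx(0.4)


def _records(rows):
    return pd.DataFrame(rows, columns=["province", "year", "status", "ratio"])


def test_national_average_over_anomalous_provinces_only():
    records = _records([
        ("A", 2002, "upper", 0.4),
        ("B", 2002, "upper", 0.6),
        ("C", 2002, "none", np.nan),
    ])
    nat = aggregate_national(records)
    assert nat.loc[0, "avg_uar"] == pytest.approx(0.5)
    assert nat.loc[0, "avg_abslar"] == 0.0
    assert nat.loc[0, "n_upper"] == 2 and nat.loc[0, "n_lower"] == 0


def test_year_with_no_anomalies_contributes_zero():
    records = _records([("A", 2002, "none", np.nan), ("B", 2002, "none", np.nan)])
    nat = aggregate_national(records)
    assert nat.loc[0, "avg_uar"] == 0.0 and nat.loc[0, "avg_abslar"] == 0.0
    assert nat.loc[0, "n_upper"] == 0 and nat.loc[0, "n_lower"] == 0


def test_years_aggregate_independently():
    records = _records([
        ("A", 2002, "upper", 0.4),
        ("B", 2003, "lower", -0.2),
        ("A", 2003, "none", np.nan),
    ])
    nat = aggregate_national(records).set_index("year")
    assert nat.loc[2002, "avg_uar"] == pytest.approx(0.4)
    assert nat.loc[2002, "avg_abslar"] == 0.0
    assert nat.loc[2003, "avg_uar"] == 0.0
    assert nat.loc[2003, "avg_abslar"] == pytest.approx(0.2)


def test_all_provinces_denominator_convention():
    records = _records([
        ("A", 2002, "upper", 0.4),
        ("B", 2002, "none", np.nan),
        ("C", 2002, "none", np.nan),
        ("D", 2002, "none", np.nan),
    ])
    nat = aggregate_national(records, denominator="all")
    assert nat.loc[0, "avg_uar"] == pytest.approx(0.1)


def test_empty_records_rejected():
    with pytest.raises(ValueError, match="at least one year"):
        aggregate_national(_records([]))


def test_decomposition_sums_back_to_average_uar():
    rng = np.random.default_rng(0)
    provinces = [f"P{i}" for i in range(12)]
    grouping = {p: ("cross_border" if i < 4 else "tourism" if i < 8 else "other")
                for i, p in enumerate(provinces)}
    rows = []
    for year in (2002, 2003, 2004):
        for p in provinces:
            status = rng.choice(["upper", "lower", "none"], p=[0.3, 0.2, 0.5])
            ratio = rng.uniform(0.1, 2.0) if status == "upper" else (
                -rng.uniform(0.1, 0.5) if status == "lower" else np.nan)
            rows.append((p, year, status, ratio))
    records = _records(rows)
    comp = decompose_uar(records, grouping).set_index("year")
    nat = aggregate_national(records).set_index("year")
    for year in (2002, 2003, 2004):
        # brute-force per-record sum oracle
        up = records[(records["year"] == year) & (records["status"] == "upper")]
        brute = {g: up.loc[up["province"].map(grouping) == g, "ratio"].sum() / len(up)
                 for g in ("cross_border", "tourism", "other")}
        for g, v in brute.items():
            assert comp.loc[year, f"uar_{g}"] == pytest.approx(v, abs=1e-15)
        assert comp.loc[year].sum() == pytest.approx(nat.loc[year, "avg_uar"], abs=1e-12)


def test_single_group_decomposition_leaves_others_zero():
    records = _records([("A", 2002, "upper", 0.5), ("B", 2002, "upper", 0.3)])
    comp = decompose_uar(records, {"A": "cross_border", "B": "cross_border"})
    assert comp.loc[0, "uar_cross_border"] == pytest.approx(0.4)


def test_grouping_must_cover_all_provinces():
    records = _records([("A", 2002, "upper", 0.5), ("B", 2002, "none", np.nan)])
    with pytest.raises(ValueError, match="B"):
        decompose_uar(records, {"A": "tourism"})


def test_scaling_an_upper_anomaly_weakly_increases_avg_uar(toy_classified):
    records = quantify_anomalies(toy_classified)
    base = aggregate_national(records).loc[0, "avg_uar"]
    boosted = toy_classified.copy()
    boosted.loc[boosted["province"] == "A", "observed"] *= 1.5
    boosted_avg = aggregate_national(quantify_anomalies(boosted)).loc[0, "avg_uar"]
    assert boosted_avg >= base


def _truth(rows):
    return pd.DataFrame(
        rows, columns=["province", "year", "true_multiplier", "true_label", "group_label"]
    )


def test_perfect_detector_scores_unit_precision_and_recall():
    records = _records([("A", 2002, "upper", 0.6), ("B", 2002, "lower", -0.3),
                        ("C", 2002, "none", np.nan)])
    truth = _truth([("A", 2002, 1.6, "upper", "tourism"),
                    ("B", 2002, 0.7, "lower", "deficit_border"),
                    ("C", 2002, 1.0, "none", "")])
    rep = recovery_report(records, truth)
    assert rep["upper"]["precision"] == 1.0 and rep["upper"]["recall"] == 1.0
    assert rep["lower"]["precision"] == 1.0 and rep["lower"]["recall"] == 1.0
    assert rep["upper"]["magnitude_rmse"] == pytest.approx(0.0)


def test_silent_detector_reports_zero_recall_nan_precision():
    records = _records([("A", 2002, "none", np.nan), ("B", 2002, "none", np.nan),
                        ("C", 2002, "none", np.nan)])
    truth = _truth([("A", 2002, 1.6, "upper", "tourism"),
                    ("B", 2002, 0.7, "lower", ""),
                    ("C", 2002, 1.0, "none", "")])
    rep = recovery_report(records, truth)
    assert rep["upper"]["recall"] == 0.0 and rep["lower"]["recall"] == 0.0
    assert np.isnan(rep["upper"]["precision"]) and np.isnan(rep["lower"]["precision"])


def test_random_detector_recall_approximates_flag_rate():
    """Independent random flags recover truth at about the flag rate."""
    rng = np.random.default_rng(7)
    n = 4000
    flag_rate = 0.25
    provinces = [f"P{i}" for i in range(n)]
    status = rng.choice(["upper", "none"], size=n, p=[flag_rate, 1 - flag_rate])
    records = _records([
        (p, 2002, s, 0.5 if s == "upper" else np.nan) for p, s in zip(provinces, status)
    ])
    labels = rng.choice(["upper", "none"], size=n, p=[0.5, 0.5])
    truth = _truth([
        (p, 2002, 1.5 if l == "upper" else 1.0, l, "") for p, l in zip(provinces, labels)
    ])
    rep = recovery_report(records, truth)
    se = np.sqrt(flag_rate * (1 - flag_rate) / (0.5 * n))
    assert abs(rep["upper"]["recall"] - flag_rate) < 3 * se


def test_key_mismatch_rejected():
    records = _records([("A", 2002, "none", np.nan)])
    truth = _truth([("A", 2003, 1.0, "none", "")])
    with pytest.raises(ValueError, match="keys"):
        recovery_report(records, truth)


def test_grouping_derived_from_truth_labels():
    truth = _truth([("A", 2002, 1.6, "upper", "tourism"),
                    ("B", 2002, 1.0, "none", ""),
                    ("C", 2002, 0.7, "lower", "deficit_border")])
    mapping = grouping_from_truth(truth)
    assert mapping == {"A": "tourism", "B": "other", "C": "deficit_border"}
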