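import numpy as np
import pandas as pd
import pytest

from pollenx.expression import (
    ExpressionStudy,
    call_dex,
    call_specificity,
    condition_mean_rpm,
    filter_low_counts,
    median_ratio_size_factors,
    nb_wald_test,
    rpm_normalize,
)


def _study(counts, library_sizes, conditions=None, dataset="D", tissue="pollen"):
    samples = pd.DataFrame({
        "dataset": dataset,
        "sample": list(counts.columns),
        "condition": conditions or ["control"] * len(counts.columns),
        "replicate": range(1, len(counts.columns) + 1),
        "library_size": library_sizes,
        "tissue": tissue,
    })
    return ExpressionStudy(counts, samples)


def test_rpm_uses_sheet_library_size_not_column_sum():
    counts = pd.DataFrame({"s1": [10, 0], "s2": [5, 5]}, index=["a", "b"])
    study = _study(counts, [1_000_000, 500_000])
    rpm = rpm_normalize(study)
    assert rpm.loc["a", "s1"] == 10.0
    assert rpm.loc["a", "s2"] == 10.0  # 5 / 0.5e6 * 1e6
    # column sum would give 10/10*1e6 = 1e6 — very different
    assert rpm.loc["a", "s1"] != pytest.approx(1e6)


def test_rpm_rejects_bad_library():
    counts = pd.DataFrame({"s1": [1]}, index=["a"])
    with pytest.raises(ValueError):
        rpm_normalize(_study(counts, [0]))


def test_filter_low_counts_any_sample_rule():
    counts = pd.DataFrame(
        {"s1": [10, 9, 0], "s2": [0, 9, 3]}, index=["keep", "drop", "drop2"]
    )
    kept = filter_low_counts(_study(counts, [1e6, 1e6]), min_count=10)
    assert list(kept.counts.index) == ["keep"]


def test_median_ratio_hand_example():
    # two samples differing by exactly 2x -> factors (1/sqrt(2), sqrt(2))
    counts = pd.DataFrame({"s1": [10, 100, 40], "s2": [20, 200, 80]})
    sf = median_ratio_size_factors(counts)
    assert sf["s1"] == pytest.approx(1 / np.sqrt(2))
    assert sf["s2"] == pytest.approx(np.sqrt(2))
    # ratio of normalized counts is exactly 1 after scaling
    norm = counts / sf
    assert np.allclose(norm["s1"], norm["s2"])


def test_median_ratio_requires_all_positive_row():
    counts = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]})
    with pytest.raises(ValueError, match="pseudo-reference"):
        median_ratio_size_factors(counts)


def test_condition_mean_rpm_grouping():
    counts = pd.DataFrame(
        {"c1": [2], "c2": [4], "h1": [8], "h2": [16]}, index=["a"]
    )
    study = _study(counts, [1e6] * 4, conditions=["control", "control", "HS", "HS"])
    mean = condition_mean_rpm(study)
    assert mean.loc["a", ("D", "control")] == 3.0
    assert mean.loc["a", ("D", "HS")] == 12.0


# ---------------------------------------------------------------- NB Wald

def _two_condition_study(rng, n_loci, mu_ctl, mu_hs, dispersion=0.05, n_rep=3, lib=2_000_000):
    cols, conds = [], []
    data = {}
    for cond, mu in (("control", mu_ctl), ("HS", mu_hs)):
        for r in range(n_rep):
            name = f"{cond}{r}"
            shape = 1.0 / dispersion
            lam = rng.gamma(shape, np.asarray(mu) / shape)
            data[name] = rng.poisson(lam)
            cols.append(name)
            conds.append(cond)
    counts = pd.DataFrame(data, index=[f"L{i}" for i in range(n_loci)])
    return _study(counts, [lib] * len(cols), conditions=conds)


def test_nb_wald_detects_planted_change():
    rng = np.random.default_rng(5)
    mu = np.full(400, 200.0)
    mu_hs = mu.copy()
    mu_hs[:50] *= 4  # planted LFC = 2
    study = _two_condition_study(rng, 400, mu, mu_hs)
    res = nb_wald_test(study)
    dex = res.table.dex.to_numpy()
    assert dex[:50].mean() >= 0.9
    assert dex[50:].mean() <= 0.02


def test_nb_wald_sensitivity_and_fdr_at_lfc3():
    rng = np.random.default_rng(11)
    mu = np.full(2000, 250.0)
    mu_hs = mu.copy()
    mu_hs[:100] *= 8.0   # planted LFC = +3
    mu_hs[100:200] /= 8.0  # planted LFC = -3
    study = _two_condition_study(rng, 2000, mu, mu_hs)
    dex = nb_wald_test(study).table.dex.to_numpy()
    assert dex[:200].mean() >= 0.9
    n_false = dex[200:].sum()
    assert n_false / max(dex.sum(), 1) <= 0.1  # realized FDR


def test_size_factor_scales_with_sample_depth():
    rng = np.random.default_rng(13)
    base = rng.poisson(100.0, size=(50, 3)).astype(float) + 1
    counts = pd.DataFrame(base, columns=["s1", "s2", "s3"])
    sf = median_ratio_size_factors(counts)
    for c in (2.0, 5.0):
        scaled = counts.copy()
        scaled["s2"] = counts["s2"] * c
        sf2 = median_ratio_size_factors(scaled)
        # multiplying one sample by c multiplies its factor by c (up to the
        # shared geometric-mean renormalization, c^(1/3) here)
        ratio = (sf2 / sf).to_numpy()
        assert ratio[1] / ratio[0] == pytest.approx(c)
        assert ratio[2] == pytest.approx(ratio[0])


def test_counts_cannot_exceed_library_size():
    counts = pd.DataFrame({"s1": [600, 600]}, index=["a", "b"])
    with pytest.raises(ValueError, match="exceed library size"):
        _study(counts, [1000])


def test_nb_wald_requires_replicates():
    counts = pd.DataFrame({"c1": [5], "h1": [5]}, index=["a"])
    study = _study(counts, [1e6, 1e6], conditions=["control", "HS"])
    with pytest.raises(ValueError, match="replicates"):
        nb_wald_test(study)


def test_bh_adjustment_monotone_in_p():
    rng = np.random.default_rng(9)
    mu = rng.uniform(50, 500, size=200)
    study = _two_condition_study(rng, 200, mu, mu)
    tab = nb_wald_test(study).table.sort_values("wald_p")
    # BH-adjusted p is a monotone transform of raw p
    assert (np.diff(tab.padj.to_numpy()) >= -1e-12).all()
    assert (tab.padj >= tab.wald_p - 1e-12).all()


def test_call_dex_rule():
    assert call_dex(1.0, 0.049)
    assert not call_dex(0.99, 0.049)
    assert not call_dex(1.5, 0.05)  # padj must be strictly below
    assert call_dex(-1.2, 0.01)
    assert not call_dex(np.nan, 0.01)


# ---------------------------------------------------------------- specificity

def _mean_rpm(rows):
    cols = pd.MultiIndex.from_tuples(
        [("MP", "control"), ("MP", "HS"), ("leaf", "control"), ("leaf", "HS")],
        names=["dataset", "condition"],
    )
    return pd.DataFrame(rows, columns=cols, index=[f"L{i}" for i in range(len(rows))])


def test_specificity_rules():
    mean = _mean_rpm([
        [5.0, 0.0, 0.0, 0.0],   # PEX + PSX
        [12.0, 0.0, 0.5, 0.9],  # hPEX, sporophyte below 1 -> PSX
        [5.0, 0.0, 1.5, 0.0],   # PEX but leaf >= 1 -> not PSX
        [1.0, 1.0, 0.0, 0.0],   # exactly 1 RPM: PEX needs strictly > 1
        [0.04, 0.0, 0.0, 0.0],  # below presence floor
    ])
    out = call_specificity(mean, ["MP"], ["leaf"]).table
    assert list(out.pex) == [True, True, True, False, False]
    assert list(out.hpex) == [False, True, False, False, False]
    assert list(out.psx) == [True, True, False, False, False]
    assert list(out.present_MP) == [True, True, True, True, False]


def test_specificity_presence_boundary_inclusive():
    mean = _mean_rpm([[0.05, 0.0, 0.0, 0.0]])
    out = call_specificity(mean, ["MP"], ["leaf"]).table
    assert bool(out.present_MP.iloc[0])


def test_pollen_dataset_detection_via_tissue():
    counts = pd.DataFrame({"p1": [1], "l1": [1]}, index=["a"])
    samples = pd.DataFrame({
        "dataset": ["MP", "leaf"], "sample": ["p1", "l1"],
        "condition": ["control", "control"], "replicate": [1, 1],
        "library_size": [1e6, 1e6], "tissue": ["pollen", "sporophyte"],
    })
    study = ExpressionStudy(counts, samples)
    assert study.pollen_datasets() == ["MP"]
    assert study.sporophytic_datasets() == ["leaf"]
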