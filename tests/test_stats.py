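"""LLD substitution, ROI averaging, and Spearman correlation."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ejpnet import (
    HormoneRecord,
    average_rois,
    correlate_cohort,
    spearman,
    substitute_lld,
)


def _rec(phase, e=100.0, p=1.0, e_below=False, p_below=False):
    return HormoneRecord("s1", phase, e, p, e_below, p_below)


@pytest.mark.parametrize(
    "phase,field,expected",
    [
        ("FOL", "estradiol_pg_ml", 22.0),
        ("LUT", "estradiol_pg_ml", 10.0),
        ("FOL", "progesterone_ng_ml", 0.05),
        ("LUT", "progesterone_ng_ml", 0.05),
    ],
)
def test_below_lld_substitution_values(phase, field, expected):
    flags = {
        "e_below": field.startswith("estradiol"),
        "p_below": field.startswith("progesterone"),
    }
    out = substitute_lld(_rec(phase, **flags))
    assert getattr(out, field) == expected


def test_detected_values_pass_through_unchanged():
    out = substitute_lld(_rec("FOL", e=94.0))
    assert out.estradiol_pg_ml == 94.0
    assert out.progesterone_ng_ml == 1.0


def test_substitution_is_idempotent():
    once = substitute_lld(_rec("LUT", e_below=True, p_below=True))
    twice = substitute_lld(once)
    assert once == twice


def test_unknown_phase_rejected():
    with pytest.raises(ValueError, match="phase"):
        substitute_lld(_rec("OVU"))


def test_roi_averaging():
    df = pd.DataFrame(
        {
            "sample_id": ["a", "a", "a", "b"],
            "roi_id": ["r0", "r1", "r2", "r0"],
            "height_um": [10.0, 20.0, 30.0, 7.0],
            "pct_intact": [50.0, 60.0, 70.0, 80.0],
        }
    )
    out = average_rois(df).set_index("sample_id")
    assert out.loc["a", "height_um"] == 20.0
    assert out.loc["a", "n_rois"] == 3
    assert out.loc["b", "height_um"] == 7.0  # single ROI unchanged
    # brute-force oracle on random table
    rng = np.random.default_rng(8)
    big = pd.DataFrame(
        {
            "sample_id": np.repeat([f"s{i}" for i in range(5)], 4),
            "pct_intact": rng.random(20) * 100,
        }
    )
    out2 = average_rois(big).set_index("sample_id")
    for i in range(5):
        vals = big[big["sample_id"] == f"s{i}"]["pct_intact"].to_numpy()
        assert out2.loc[f"s{i}", "pct_intact"] == pytest.approx(sum(vals) / len(vals))


def test_missing_metric_averaged_over_available_rois():
    df = pd.DataFrame(
        {
            "sample_id": ["a", "a"],
            "height_um": [10.0, np.nan],
        }
    )
    with pytest.warns(UserWarning, match="missing"):
        out = average_rois(df)
    assert out["height_um"].iloc[0] == 10.0


def test_perfect_monotone_correlations():
    x = np.arange(10.0)
    assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)
    assert spearman(x, -(x**3)).rho == pytest.approx(-1.0)


def test_exact_permutation_p_matches_exhaustive_enumeration():
    rng = np.random.default_rng(13)
    for _ in range(3):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        res = spearman(x, y, p_method="exact_permutation")
        # oracle: scipy spearman rho on every one of the 120 orderings
        obs = abs(sps.spearmanr(x, y)[0])
        count = sum(
            1
            for perm in permutations(y)
            if abs(sps.spearmanr(x, perm)[0]) >= obs - 1e-12
        )
        assert res.p_value == pytest.approx(count / math.factorial(5))


def test_rho_matches_scipy_with_and_without_ties():
    rng = np.random.default_rng(1)
    x = rng.normal(size=30)
    y = rng.normal(size=30)
    assert spearman(x, y).rho == pytest.approx(sps.spearmanr(x, y)[0])
    # heavy ties from mass LLD substitution
    xt = np.concatenate([np.full(15, 0.05), rng.random(15)])
    assert spearman(xt, y).rho == pytest.approx(sps.spearmanr(xt, y)[0])
    assert spearman(x, y, p_method="large_sample").p_value == pytest.approx(
        sps.spearmanr(x, y)[1], rel=1e-6
    )


def test_permutation_and_t_approximation_agree_at_n9():
    rng = np.random.default_rng(5)
    x = rng.normal(size=9)
    y = 0.5 * x + rng.normal(size=9)
    pe = spearman(x, y, p_method="exact_permutation").p_value
    pt = spearman(x, y, p_method="large_sample").p_value
    assert abs(pe - pt) <= 0.02


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_rho_invariant_under_monotone_transforms(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    base = spearman(x, y).rho
    assert spearman(np.exp(x), y).rho == pytest.approx(base)
    assert spearman(x, 3 * y + 7).rho == pytest.approx(base)
    assert spearman(x, -y).rho == pytest.approx(-base)


def test_constant_input_rejected():
    with pytest.raises(ValueError):
        spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


def test_correlate_cohort_skips_underpowered_pairs():
    df = pd.DataFrame(
        {
            "estradiol_pg_ml": [10.0, 20.0, np.nan, np.nan],
            "pct_intact": [1.0, 2.0, 3.0, 4.0],
        }
    )
    with pytest.warns(UserWarning, match="complete pairs"):
        out = correlate_cohort(df, hormones=("estradiol_pg_ml",), metrics=("pct_intact",))
    assert out.empty


def test_correlate_cohort_pairwise_deletion():
    df = pd.DataFrame(
        {
            "estradiol_pg_ml": [1.0, 2.0, 3.0, 4.0, np.nan],
            "pct_intact": [2.0, 3.0, 1.0, 5.0, 9.0],
            "height_um": [5.0, 4.0, 3.0, np.nan, 1.0],
        }
    )
    out = correlate_cohort(df, hormones=("estradiol_pg_ml",)).set_index("metric")
    assert out.loc["pct_intact", "n"] == 4
    assert out.loc["height_um", "n"] == 3
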