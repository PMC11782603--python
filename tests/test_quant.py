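"""Fold changes, response groups, summed-abundance ratios, profile correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secmx.model import AssemblyState, ElutionMatrix, Peak, PTMAnnotation, ValidationError
from secmx.quant import (
    classify_response_group,
    phospho_fold_changes,
    profile_correlation,
    response_group_table,
    state_fold_change,
    state_fold_changes,
    total_abundance_ratio,
)


def _state(heights, sid="P1~s1"):
    members = {
        c: Peak("P1", "global", c, 20, h, h * 0.9, 2.0) for c, h in heights.items()
    }
    return AssemblyState("P1", sid, members, 20.0, 1.0)


def test_state_fold_change_hand_computed():
    fc = state_fold_change(_state({"A": 100.0, "B": 350.0}), "A", "B")
    assert fc.log2_ratio == pytest.approx(np.log2(3.5))  # ~1.807, 'up in B'
    assert state_fold_change(_state({"A": 100.0, "B": 100.0}), "A", "B").log2_ratio == 0.0
    # states missing a condition are excluded
    assert state_fold_change(_state({"A": 100.0}), "A", "B") is None


def test_fold_change_antisymmetry():
    rng = np.random.default_rng(0)
    for _ in range(50):
        ha, hb = rng.uniform(1e3, 1e5, 2)
        st_ = _state({"A": ha, "B": hb})
        ab = state_fold_change(st_, "A", "B").log2_ratio
        ba = state_fold_change(st_, "B", "A").log2_ratio
        assert ab == pytest.approx(-ba)


@pytest.mark.parametrize(
    "g, p, group",
    [
        (0.2, 1.4, "B"),      # global NS, phospho up in B
        (0.0, 0.0, "E"),      # center cell
        (-1.0, 0.0, "E"),     # exactly at cutoff -> NS (strict inequality)
        (1.5, 1.5, "C"),
        (-1.5, 1.5, "A"),
        (1.5, 0.0, "F"),
        (-1.5, 0.0, "D"),
        (0.0, -1.5, "H"),     # global NS, phospho up in A
        (-1.5, -1.5, "G"),
        (1.5, -1.5, "I"),
        (None, 1.5, None),    # absent dimension excluded from the grid
        (1.5, None, None),
    ],
)
def test_response_group_grid(g, p, group):
    assert classify_response_group(g, p, fold_cutoff=2.0) == group


def test_response_group_table_counts():
    g_fcs = state_fold_changes(
        [_state({"A": 100.0, "B": 100.0}, "P1~s1"), _state({"A": 100.0, "B": 500.0}, "P1~s2")],
        "A", "B")
    anns = []
    for pep, sid, ha, hb in [("pep1", "P1~s1", 100, 500), ("pep2", "P1~s1", 100, 90),
                             ("pep3", "P1~s2", 100, 100), ("pep4", "P9~s9", 10, 10)]:
        for cond, h in (("A", ha), ("B", hb)):
            anns.append(PTMAnnotation(pep, "P1", cond, 20, "mapped", sid, 20, 0,
                                      phospho_height=float(h)))
    p_fcs = phospho_fold_changes(anns, "A", "B")
    table = response_group_table(g_fcs, p_fcs)
    # pep4's state has no global fold change -> excluded; grid covers the rest
    assert len(table) == 3
    assert set(table["group"]) == {"B", "E", "F"}
    assert table["group"].notna().all()


def test_phospho_fold_change_requires_same_state_both_conditions():
    anns = [
        PTMAnnotation("pep1", "P1", "A", 20, "mapped", "P1~s1", 20, 0, phospho_height=100.0),
        PTMAnnotation("pep1", "P1", "B", 24, "mapped", "P1~s2", 25, 1, phospho_height=300.0),
    ]
    assert phospho_fold_changes(anns, "A", "B") == []  # different states: dropped
    anns[1] = PTMAnnotation("pep1", "P1", "B", 21, "mapped", "P1~s1", 20, 1,
                            phospho_height=300.0)
    fcs = phospho_fold_changes(anns, "A", "B")
    assert len(fcs) == 1
    assert fcs[0].log2_ratio == pytest.approx(np.log2(3.0))


def _em(d, condition="A", replicate="r1"):
    return ElutionMatrix(pd.DataFrame(d).T, condition=condition, replicate=replicate)


def test_total_abundance_ratio():
    a = [_em({"P1": [5.0, 5.0], "P2": [1.0, 1.0]}),
         _em({"P1": [4.0, 6.0]}, replicate="r2")]
    b = [_em({"P1": [10.0, 10.0], "P3": [9.0, 9.0]}, condition="B"),
         _em({"P1": [15.0, 25.0]}, condition="B", replicate="r2")]
    out = total_abundance_ratio(a, b)
    # P1: mean(10, 10) = 10 vs mean(20, 40) = 30 -> ratio 3; P2/P3 not shared
    assert list(out.index) == ["P1"]
    assert out.loc["P1", "ratio"] == pytest.approx(3.0)
    # identical matrices -> all ratios 1
    same = total_abundance_ratio(a, a)
    assert np.allclose(same["ratio"], 1.0)
    # invariant to fraction permutation
    perm = [ElutionMatrix(m.data[m.data.columns[::-1]].set_axis(m.data.columns, axis=1),
                          condition=m.condition, replicate=m.replicate) for m in b]
    assert np.allclose(total_abundance_ratio(a, perm)["ratio"], out["ratio"])


def test_profile_correlation():
    x = np.array([0.0, 1.0, 4.0, 2.0, 0.5])
    assert profile_correlation(x, x) == pytest.approx(1.0)
    assert profile_correlation(x, -x) == pytest.approx(-1.0)
    # matches the direct covariance formula for an asymmetric profile pair
    y = x[::-1].copy()
    want = np.cov(x, y)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
    assert profile_correlation(x, y) == pytest.approx(want)
    assert np.isnan(profile_correlation(x, np.full(5, 2.0)))
    with pytest.raises(ValidationError):
        profile_correlation(x, x[:3])


@settings(max_examples=100, deadline=None)
@given(st.floats(0.01, 100), st.floats(0.01, 100))
def test_classification_antisymmetric_under_condition_swap(ha, hb):
    st_ = _state({"A": ha, "B": hb})
    ab = state_fold_change(st_, "A", "B").log2_ratio
    ba = state_fold_change(st_, "B", "A").log2_ratio
    assert ab == pytest.approx(-ba, abs=1e-9)
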