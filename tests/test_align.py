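"""Path algebra and greedy state selection, checked against hand-worked values
and an independent brute-force implementation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secmx.align import (
    align_conditions,
    enumerate_paths,
    map_ptm_peaks,
    path_mean,
    path_score,
    path_variance,
    select_paths,
    threshold_evaluation,
)
from secmx.model import AssemblyState, Peak, ValidationError

from oracles import bf_enumerate, bf_select, bf_stats


# ---------------------------------------------------------------------------
# worked examples (hand-derived)


@pytest.mark.parametrize(
    "elements, mean, var, score",
    [
        ((10.0, 12.0), 11.0, 1.0, 0.5),
        ((10.0, None), 10.0, 4.5, 1 / 5.5),
        ((7.0, 7.0, 7.0), 7.0, 0.0, 1.0),
        ((5.0,), 5.0, 0.0, 1.0),
    ],
)
def test_path_statistics_hand_worked(elements, mean, var, score):
    assert path_mean(elements) == pytest.approx(mean)
    assert path_variance(elements, 3.0) == pytest.approx(var)
    assert path_score(elements, 3.0) == pytest.approx(score)


def test_enumerate_counts_product_of_augmented_lengths():
    paths = enumerate_paths([[10.0, 30.0], [11.0, 29.0, 40.0]], 3.0)
    # (2+1)*(3+1) = 12 including the all-missing path, 11 without it
    assert len(paths) == 11
    with pytest.raises(ValidationError):
        enumerate_paths([], 3.0)
    single = enumerate_paths([[10.0]], 3.0)
    assert [p.elements for p in single] == [(10.0,)]


def _key(elements):
    return tuple(math.inf if e is None else e for e in elements)


def test_select_pairs_close_apexes_and_splits_distant_ones():
    # close peaks pair up (score 0.8 each)...
    sel = select_paths([[10.0, 30.0], [11.0, 29.0]], 3.0)
    partitions = sorted((p.elements for p in sel), key=_key)
    assert partitions == [(10.0, 11.0), (30.0, 29.0)]
    assert all(p.score == pytest.approx(0.8) for p in sel)
    # ...while peaks 10 apart score worse together (1/26) than solo (1/5.5 each)
    sel = select_paths([[10.0], [20.0]], 3.0)
    assert sorted((p.elements for p in sel), key=_key) == [(10.0, None), (None, 20.0)]
    # a single sample yields singleton states
    sel = select_paths([[10.0, 20.0]], 3.0)
    assert [p.elements for p in sel] == [(10.0,), (20.0,)]


def test_missing_vs_distant_crossover_for_two_samples():
    """For n=2: joint variance g^2/4 vs solo variance T^2/2, so the solo
    option wins exactly when the apex gap exceeds T*sqrt(2)."""
    thr = 3.0
    cross = thr * math.sqrt(2)
    for gap in (cross - 0.3, cross, cross + 0.3):
        joint = path_score((10.0, 10.0 + gap), thr)
        solo = path_score((10.0, None), thr)
        if gap < cross:
            assert joint > solo
        elif gap > cross:
            assert joint < solo
        else:
            assert joint == pytest.approx(solo)


# ---------------------------------------------------------------------------
# brute-force equivalence and the partition property


def _instances(domain=(2.0, 5.0, 8.0, 11.0), max_peaks=3, max_samples=3):
    lists = []
    for k in range(1, max_peaks + 1):
        lists.extend(itertools.combinations(domain, k))
    for n in range(1, max_samples + 1):
        for combo in itertools.product(lists, repeat=n):
            yield [list(l) for l in combo]


def test_exhaustive_bruteforce_equivalence():
    """Enumerate/score/select agree with the independent brute force on every
    instance with <= 3 samples and <= 3 peaks per sample over a 4-apex domain."""
    thr = 3.0
    n_checked = 0
    for lists in _instances():
        paths = enumerate_paths(lists, thr)
        expected = bf_enumerate(lists)
        assert len(paths) == len(expected) == np.prod([len(l) + 1 for l in lists]) - 1
        for p in paths:
            mean, var, score = bf_stats(p.elements, thr)
            assert p.mean == pytest.approx(mean)
            assert p.variance == pytest.approx(var)
            assert p.score == pytest.approx(score)
        sel = select_paths(lists, thr)
        assert sorted((p.elements for p in sel), key=_key) == sorted(
            bf_select(lists, thr), key=_key)
        n_checked += 1
    assert n_checked > 2900


def test_partition_property_random_instances():
    """After selection every input peak belongs to exactly one state."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n = rng.integers(1, 4)
        lists = []
        for _ in range(n):
            k = int(rng.integers(0, 5))
            apexes = np.sort(rng.choice(np.arange(1, 55), size=k, replace=False))
            lists.append([float(a) for a in apexes])
        if not any(lists):
            continue
        sel = select_paths(lists, 3.0)
        used = [(i, e) for p in sel for i, e in enumerate(p.elements) if e is not None]
        everything = [(i, a) for i, lst in enumerate(lists) for a in lst]
        assert sorted(used) == sorted(everything)  # each peak exactly once


@settings(max_examples=200, deadline=None)
@given(
    apexes=st.lists(st.floats(1, 60).map(lambda x: round(x, 2)), min_size=1, max_size=4),
    missing=st.integers(0, 3),
    thr=st.floats(0.5, 10),
)
def test_score_bounds_property(apexes, missing, thr):
    elements = tuple(apexes) + (None,) * missing
    s = path_score(elements, thr)
    assert 0 < s <= 1
    # score 1 iff nothing missing and all apexes equal
    assert (s == 1) == (missing == 0 and len(set(apexes)) == 1)


@settings(max_examples=200, deadline=None)
@given(
    apexes=st.lists(st.floats(1, 60), min_size=2, max_size=4),
    idx=st.integers(0, 3),
    shift=st.floats(0.1, 20),
)
def test_dispersion_never_raises_score(apexes, idx, shift):
    idx = idx % len(apexes)
    base = list(apexes)
    mu = path_mean(base)
    moved = list(base)
    moved[idx] = moved[idx] + shift if moved[idx] >= mu else moved[idx] - shift
    assert path_score(tuple(moved), 3.0) <= path_score(tuple(base), 3.0) + 1e-12


# ---------------------------------------------------------------------------
# condition alignment and PTM mapping


def _peak(entity, cond, apex, height=5000.0):
    return Peak(entity, "global", cond, apex, height, height * 0.9, 2.0)


def test_align_conditions_consensus_and_presence():
    peaks = {
        "A": {"P1": [_peak("P1", "A", 24)], "P2": [_peak("P2", "A", 10)]},
        "B": {"P1": [_peak("P1", "B", 25)]},
    }
    states = align_conditions(peaks, 3.0)
    by_entity = {s.entity_id: s for s in states}
    assert by_entity["P1"].consensus_apex == pytest.approx(24.5)
    assert by_entity["P1"].presence == "mutual"
    # P2 has peaks only in A — single-sample alignment, flagged as such
    assert by_entity["P2"].presence.endswith("-only")
    # distant apexes split into exclusive states
    peaks = {
        "A": {"P3": [_peak("P3", "A", 10)]},
        "B": {"P3": [_peak("P3", "B", 20)]},
    }
    states = align_conditions(peaks, 3.0)
    assert len(states) == 2
    assert all(len(s.members) == 1 for s in states)


def _state(protein, apexes_by_cond, sid="s1"):
    members = {
        c: Peak(protein, "global", c, a, 5000.0, 4500.0, 2.0)
        for c, a in apexes_by_cond.items()
    }
    return AssemblyState(protein, f"{protein}~{sid}", members,
                         float(np.mean(list(apexes_by_cond.values()))), 1.0)


@pytest.mark.parametrize("dist, status", [(0, "mapped"), (1, "mapped"), (2, "mapped"),
                                          (3, "mapped"), (4, "unmatched")])
def test_ptm_mapping_distance_boundary(dist, status):
    states = [_state("P1", {"A": 20}), _state("P1", {"A": 40}, sid="s2")]
    ph = {"A": {"pep1": [Peak("pep1", "phospho", "A", 20 + dist, 3000.0, 2800.0, 2.0)]}}
    anns = map_ptm_peaks(ph, states, {"pep1": "P1"}, max_dist=3)
    assert len(anns) == 1
    assert anns[0].status == status
    if status == "mapped":
        assert anns[0].global_apex == 20  # annotation adopts the global apex
        assert anns[0].distance == dist


def test_ptm_mapping_many_to_one_and_orphans():
    states = [_state("P1", {"A": 20})]
    ph = {"A": {
        "pep1": [Peak("pep1", "phospho", "A", 19, 3000.0, 2800.0, 2.0)],
        "pep2": [Peak("pep2", "phospho", "A", 22, 3000.0, 2800.0, 2.0)],
        "pep3": [Peak("pep3", "phospho", "A", 21, 3000.0, 2800.0, 2.0)],
    }}
    anns = map_ptm_peaks(ph, states, {"pep1": "P1", "pep2": "P1", "pep3": "ZZZ"}, 3)
    by_pep = {a.peptide_id: a for a in anns}
    assert by_pep["pep1"].state_id == by_pep["pep2"].state_id == "P1~s1"
    assert by_pep["pep3"].status == "orphan"


def test_ptm_mapping_picks_nearest_global_peak():
    states = [_state("P1", {"A": 20}), _state("P1", {"A": 26}, sid="s2")]
    ph = {"A": {"pep1": [Peak("pep1", "phospho", "A", 22, 3000.0, 2800.0, 2.0)]}}
    anns = map_ptm_peaks(ph, states, {"pep1": "P1"}, 3)
    assert anns[0].global_apex == 20


# ---------------------------------------------------------------------------
# replicate threshold diagnostics


def test_threshold_evaluation_identical_and_jittered_replicates():
    rng = np.random.default_rng(5)
    rep1 = {}
    rep2 = {}
    for i in range(60):
        apex = int(rng.integers(5, 50))
        rep1[f"P{i}"] = [_peak(f"P{i}", "r1", apex)]
        jitter = int(rng.integers(-1, 2))
        rep2[f"P{i}"] = [_peak(f"P{i}", "r2", apex + jitter)]
    table = threshold_evaluation(rep1, rep2, max_difference=8, rng=np.random.default_rng(1))
    # real-pair excess confined to d <= 1 for +/-1-fraction jitter
    assert table.loc[table["difference"] <= 1, "real_pairs"].sum() == 60
    assert table.loc[table["difference"] > 1, "real_pairs"].sum() == 0
    # random pairs are spread out well beyond d = 1
    assert table.loc[table["difference"] > 1, "random_pairs"].sum() > 20
    # identical replicates: everything at d = 0
    table = threshold_evaluation(rep1, rep1, max_difference=8, rng=np.random.default_rng(1))
    assert table.loc[0, "real_pairs"] == 60
    assert table.loc[1:, "real_pairs"].sum() == 0
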