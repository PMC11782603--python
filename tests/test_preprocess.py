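"""Signal-processing stages: filtering, MS1 normalization, batch correction,
condition normalization, replicate averaging, smoothing, collapsing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secmx.model import DesignEntry, ElutionMatrix, ExperimentDesign, ValidationError
from secmx.preprocess import (
    NormalizationReport,
    assign_representative_id,
    average_replicates,
    batch_correct_mixes,
    build_fraction_matrix,
    collapse_to_protein,
    filter_records,
    minmax_normalize,
    ms1_normalize,
    normalize_between_conditions,
    phospho_enrichment_efficiency,
    smooth_profile,
)


def _records(rows):
    base = {
        "protein_ids": "P1", "peptide_seq": "PEP", "modified_seq": "PEP",
        "is_phospho": False, "site_probs": "", "is_decoy": False, "is_proteotypic": True,
        "mix": "m1", "channel": "c01", "reporter_intensity": 1.0, "ms1_intensity": 1.0,
        "condition": "A", "replicate": "r1", "fraction": 1,
    }
    return pd.DataFrame([{**base, **r} for r in rows])


def test_filter_records_flags():
    df = _records(
        [{}] * 7 + [{"is_decoy": True}] * 2 + [{"is_proteotypic": False}]
    )
    assert len(filter_records(df)) == 7
    assert len(filter_records(df[df["is_decoy"]])) == 0
    clean = _records([{}] * 3)
    assert filter_records(clean).equals(clean)


def test_representative_id_deterministic():
    df = _records([
        {"protein_ids": "P2;P1"}, {"protein_ids": "P1;P2"}, {"protein_ids": "P9"},
        {"protein_ids": ""},
    ])
    out = assign_representative_id(df)
    assert list(out["entity_id"]) == ["P1", "P1", "P9"]  # empty group dropped


def test_ms1_normalize_fractional_scaling():
    df = _records([
        {"channel": "c01", "reporter_intensity": 100.0, "ms1_intensity": 800.0},
        {"channel": "c02", "reporter_intensity": 300.0, "ms1_intensity": 800.0},
        {"modified_seq": "OTHER", "reporter_intensity": 50.0, "ms1_intensity": 500.0},
        {"modified_seq": "ZERO", "reporter_intensity": 0.0, "ms1_intensity": 100.0},
    ])
    out = ms1_normalize(df)
    assert list(out["reporter_intensity"]) == pytest.approx([200.0, 600.0, 500.0, 0.0])
    with pytest.raises(ValidationError):
        ms1_normalize(_records([{"ms1_intensity": -5.0}]))


def _overlap_design(n_mix=2, width=6, stride=3, condition="A"):
    entries = []
    for m in range(n_mix):
        lo = 1 + m * stride
        for ch, f in enumerate(range(lo, lo + width), start=1):
            entries.append(DesignEntry(f"m{m + 1}", f"c{ch:02d}", condition, "r1", f))
    return ExperimentDesign(entries)


def _mix_records(design, values):
    """values: {(mix, fraction): {peptide: intensity}}"""
    rows = []
    for (mix, f), peps in values.items():
        sel = design.frame[(design.frame["mix"] == mix) & (design.frame["fraction"] == f)]
        ch = sel["channel"].iloc[0]
        for pep, v in peps.items():
            rows.append({"peptide_seq": pep, "modified_seq": pep, "mix": mix,
                         "channel": ch, "fraction": f, "reporter_intensity": v})
    return _records(rows)


def test_build_matrix_zero_fill_and_sum_aggregation():
    design = _overlap_design(n_mix=1)
    df = _records([
        {"fraction": 1, "channel": "c01", "reporter_intensity": 10.0},
        {"fraction": 3, "channel": "c03", "reporter_intensity": 5.0},
        {"fraction": 2, "channel": "c02", "reporter_intensity": 4.0},
        {"fraction": 2, "channel": "c02", "reporter_intensity": 6.0},  # duplicate PSM
    ])
    df["entity_id"] = "PEP"
    frame = build_fraction_matrix(df, design, "A", "r1")
    vec = frame.loc["PEP"].to_numpy()
    assert list(vec[:3]) == [10.0, 10.0, 5.0]  # duplicates summed, gaps zero
    assert frame.shape[1] == 6
    # entity absent from the condition has no row at all
    assert "OTHER" not in frame.index


def test_batch_correction_recovers_planted_factor():
    design = _overlap_design()
    peps = {f"pep{i}": 100.0 * (i + 1) for i in range(9)}
    values = {}
    for m, (mix, scale) in enumerate((("m1", 1.0), ("m2", 2.0))):
        lo = 1 + m * 3
        for f in range(lo, lo + 6):
            values[(mix, f)] = {p: v * scale for p, v in peps.items()}
    df = _mix_records(design, values)
    df["entity_id"] = df["peptide_seq"]
    frame = build_fraction_matrix(df, design, "A", "r1", entity_col="peptide_seq")
    matrix, report = batch_correct_mixes(frame, design, "A", "r1")
    assert report.batch_factors[("A", "r1", "m1", "m2")] == pytest.approx(2.0)
    # after correction the overlap average equals the mix-1 value
    for f in (4, 5, 6):
        assert matrix.data[f]["pep0"] == pytest.approx(100.0)
    # identical mixes: factor 1, matrix unchanged by correction
    values_id = {k: dict(peps) for k in values}
    df = _mix_records(design, values_id)
    frame = build_fraction_matrix(df, design, "A", "r1", entity_col="peptide_seq")
    matrix, report = batch_correct_mixes(frame, design, "A", "r1")
    assert report.batch_factors[("A", "r1", "m1", "m2")] == pytest.approx(1.0)
    assert np.allclose(matrix.data.loc["pep3"].to_numpy(), 400.0)


def test_batch_correction_median_is_outlier_robust():
    design = _overlap_design()
    values = {}
    for m, (mix, scale) in enumerate((("m1", 1.0), ("m2", 2.0))):
        lo = 1 + m * 3
        for f in range(lo, lo + 6):
            values[(mix, f)] = {f"pep{i}": 100.0 * scale for i in range(9)}
    # one wild peptide at ratio 100 in every overlap fraction
    for f in (4, 5, 6):
        values[("m1", f)]["wild"] = 10.0
        values[("m2", f)]["wild"] = 1000.0
    df = _mix_records(design, values)
    frame = build_fraction_matrix(df, design, "A", "r1", entity_col="peptide_seq")
    _, report = batch_correct_mixes(frame, design, "A", "r1")
    assert report.batch_factors[("A", "r1", "m1", "m2")] == pytest.approx(2.0)


def test_batch_correction_errors_without_usable_overlap():
    design = _overlap_design()
    values = {("m1", f): {"pep": 10.0} for f in range(1, 4)}  # nothing in overlap
    values.update({("m2", f): {"pep2": 10.0} for f in range(7, 10)})
    df = _mix_records(design, values)
    frame = build_fraction_matrix(df, design, "A", "r1", entity_col="peptide_seq")
    with pytest.raises(ValidationError, match="m1.*m2"):
        batch_correct_mixes(frame, design, "A", "r1")


def _matrix(rows, condition="A", replicate="r1", **kw):
    df = pd.DataFrame(rows).T if isinstance(rows, dict) else rows
    return ElutionMatrix(df, condition=condition, replicate=replicate, **kw)


def test_condition_normalization_median_ratio():
    a = _matrix({"p1": [10.0, 0, 30], "p2": [0, 20.0, 40]})
    b = _matrix({"p1": [30.0, 0, 90], "p2": [0, 60.0, 120]}, condition="B")
    a2, b2, rep = normalize_between_conditions(a, b)
    assert rep.condition_factors[("global", "r1")] == pytest.approx(3.0)
    assert np.allclose(b2.data.to_numpy(), a.data.to_numpy())  # B scaled back onto A
    assert a2.data.equals(a.data)
    # zeros do not drag the median: padding B with zero cells changes nothing
    b_pad = _matrix({"p1": [30.0, 0, 90], "p2": [0, 60.0, 120], "p3": [0, 0, 0]},
                    condition="B")
    _, b3, rep = normalize_between_conditions(a, b_pad)
    assert rep.condition_factors[("global", "r1")] == pytest.approx(3.0)
    with pytest.raises(ValidationError):
        normalize_between_conditions(a, _matrix({"p": [0.0, 0, 0]}))


def test_union_replicate_averaging():
    r1 = _matrix({"p1": [10.0, 0.0], "p2": [4.0, 4.0]})
    r2 = _matrix({"p1": [20.0, 2.0]}, replicate="r2")
    avg = average_replicates([r1, r2])
    assert avg.replicate == "averaged"
    assert set(avg.entities) == {"p1", "p2"}
    assert list(avg.profile("p1")) == [15.0, 1.0]
    # entity seen in one replicate keeps that replicate's values undiluted
    assert list(avg.profile("p2")) == [4.0, 4.0]
    # no entity gains signal where all replicates were zero
    assert avg.profile("p1")[1] <= max(r1.profile("p1")[1], r2.profile("p1")[1])
    single = average_replicates([r1])
    assert single.data.equals(r1.data)


def test_smoothing_kernel_and_boundaries():
    imp = np.zeros(9)
    imp[4] = 1.0
    out = smooth_profile(imp)
    assert out[3:6] == pytest.approx([0.25, 0.5, 0.25])
    # unit DC gain on constants, zero-phase on symmetric input
    assert smooth_profile(np.full(20, 7.0)) == pytest.approx(np.full(20, 7.0))
    sym = np.exp(-0.5 * ((np.arange(21) - 10) / 2.0) ** 2)
    sm = smooth_profile(sym)
    assert sm == pytest.approx(sm[::-1])
    assert np.argmax(sm) == 10
    assert (smooth_profile(np.array([5.0])) == [5.0]).all()  # too short: unchanged


@settings(max_examples=100, deadline=None)
@given(st.lists(st.floats(0, 1e5), min_size=8, max_size=40))
def test_smoothing_preserves_interior_mass_and_nonnegativity(vals):
    x = np.zeros(len(vals) + 8)
    x[4:-4] = vals  # interior support: boundary extension cannot leak mass
    y = smooth_profile(x)
    assert (y >= 0).all()
    assert np.sum(y) == pytest.approx(np.sum(x), rel=1e-9, abs=1e-6)


def test_collapse_to_protein_top3():
    df = pd.DataFrame(
        {
            "pep1": [100.0, 0], "pep2": [90.0, 0], "pep3": [80.0, 0],
            "pep4": [70.0, 0], "pep5": [60.0, 0], "pepX": [5.0, 5.0],
        }
    ).T
    m = ElutionMatrix(df)
    parents = {f"pep{i}": "P1" for i in (1, 2, 3, 4, 5)}
    parents["pepX"] = "P2"
    out = collapse_to_protein(m, parents)
    assert out.level == "protein"
    assert out.profile("P1")[0] == pytest.approx(270.0)  # only top-3 contribute
    assert out.profile("P2")[0] == pytest.approx(5.0)    # <= 3 peptides: plain sum
    # invariant to row order
    out2 = collapse_to_protein(ElutionMatrix(df.iloc[::-1]), parents)
    assert out2.data.equals(out.data)


def test_minmax_normalize():
    assert minmax_normalize(np.array([0.0, 5.0, 10.0])) == pytest.approx([0, 0.5, 1.0])
    assert (minmax_normalize(np.zeros(4)) == 0).all()
    x = np.random.default_rng(0).uniform(1, 9, 10)
    assert minmax_normalize(x).max() == 1.0


def test_phospho_enrichment_efficiency_counts_stripped_sequences():
    df = _records([
        {"modified_seq": "AAAS[ph]K", "is_phospho": True},
        {"modified_seq": "AAA[ph]SK", "is_phospho": True},   # same stripped sequence
        {"modified_seq": "CCCK", "is_phospho": False},
        {"modified_seq": "DDDK", "is_phospho": True, "mix": "m2"},
    ])
    eff = phospho_enrichment_efficiency(df)
    assert eff["m1"] == pytest.approx(0.5)  # {AAASK(ph)} over {AAASK, CCCK}
    assert eff["m2"] == pytest.approx(1.0)
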