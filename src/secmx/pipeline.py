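"""End-to-end orchestration: records -> matrices -> peaks -> states -> differentials.

`run_pipeline` wires the stages together for a two-condition experiment:

1.  filter / representative-ID / MS1-normalize the records;
2.  per (dataset, condition, replicate): pivot to a per-mix fraction frame,
    batch-correct full-overlap mixes (or just merge), giving peptide-level
    elution matrices;
3.  scale the comparison condition onto the reference per replicate
    (nonzero-median ratio), then union-average replicates;
4.  collapse the global dataset to protein level (top-3 peptide sum) and
    smooth; smooth the phospho peptide-level matrices;
5.  fit the MW calibration, detect peaks, align peaks across conditions
    into assembly states, classify them monomer/complexed;
6.  map phosphopeptide peaks onto global states and compute peak-height
    fold changes and response groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import align as _align
from . import calibration as _cal
from . import peaks as _peaks
from . import preprocess as _pre
from . import quant as _quant
from .model import (
    AssemblyState,
    ElutionMatrix,
    ExperimentDesign,
    PTMAnnotation,
    ValidationError,
    stripped_sequence,
)

log = logging.getLogger("secmx")

__all__ = ["PipelineParams", "PipelineResult", "PreprocessResult",
           "preprocess_records", "analyze_profiles", "run_pipeline"]


@dataclass(frozen=True)
class PipelineParams:
    """All tunable thresholds, at their standard defaults."""

    prominence_frac: float = 0.05
    min_distance: int = 3
    min_height: float = 1000.0
    threshold: float = 3.0          # alignment threshold, fractions
    ptm_max_dist: int = 3           # phospho -> global mapping cutoff, fractions
    fold_cutoff: float = 2.0        # response-group cutoff (linear fold)
    monomer_multiplier: float = 1.5
    smoothing_padlen: int = 3
    reference_condition: str | None = None  # default: first condition in the design

    def peak_params(self) -> _peaks.PeakParams:
        return _peaks.PeakParams(self.prominence_frac, self.min_distance, self.min_height)


@dataclass
class PipelineResult:
    conditions: list[str]
    params: PipelineParams
    matrices: dict[tuple[str, str, str], ElutionMatrix]  # (dataset, condition, replicate)
    averaged: dict[tuple[str, str], ElutionMatrix]       # (dataset, condition), peptide level
    smoothed: dict[tuple[str, str], ElutionMatrix]       # protein level (global) / peptide (phospho)
    peaksets: dict[tuple[str, str], dict[str, list]]     # (dataset, condition) -> entity -> peaks
    global_states: list[AssemblyState]
    ptm_annotations: list[PTMAnnotation]
    global_fold_changes: list[_quant.StateFoldChange]
    phospho_fold_changes: list[_quant.StateFoldChange]
    response_groups: pd.DataFrame
    total_abundance: pd.DataFrame
    report: _pre.NormalizationReport
    calibration: _cal.CalibrationModel | None
    peptide_to_protein: dict[str, str]

    def states_frame(self) -> pd.DataFrame:
        """Assembly-states result table (one row per state)."""
        rows = []
        for st in self.global_states:
            row = {
                "entity_id": st.entity_id,
                "state_id": st.state_id,
                "consensus_apex": st.consensus_apex,
                "classification": st.classification,
                "presence": st.presence,
                "score": st.score,
            }
            for cond, pk in st.members.items():
                row[f"apex_{cond}"] = pk.apex
                row[f"height_{cond}"] = pk.height
            rows.append(row)
        return pd.DataFrame(rows)

    def ptm_frame(self) -> pd.DataFrame:
        rows = [
            {
                "peptide_id": a.peptide_id, "protein_id": a.protein_id,
                "condition": a.condition, "phospho_apex": a.phospho_apex,
                "status": a.status, "state_id": a.state_id,
                "global_apex": a.global_apex, "distance": a.distance,
                "phospho_height": a.phospho_height, "site_probs": a.site_probs,
            }
            for a in self.ptm_annotations
        ]
        return pd.DataFrame(rows, columns=[
            "peptide_id", "protein_id", "condition", "phospho_apex", "status",
            "state_id", "global_apex", "distance", "phospho_height", "site_probs"])


@dataclass
class PreprocessResult:
    """Output of the signal-processing phase (everything before peak calling)."""

    conditions: list[str]
    matrices: dict[tuple[str, str, str], ElutionMatrix]
    averaged: dict[tuple[str, str], ElutionMatrix]
    smoothed: dict[tuple[str, str], ElutionMatrix]
    peptide_to_protein: dict[str, str]
    report: _pre.NormalizationReport


def _peptide_matrices(
    records: pd.DataFrame,
    design: ExperimentDesign,
    dataset: str,
    report: _pre.NormalizationReport,
) -> dict[tuple[str, str], ElutionMatrix]:
    """Per (condition, replicate) peptide-level matrices, batch-corrected and merged."""
    out: dict[tuple[str, str], ElutionMatrix] = {}
    for cond in records["condition"].unique():
        for rep in records.loc[records["condition"] == cond, "replicate"].unique():
            frame = _pre.build_fraction_matrix(records, design, cond, rep, entity_col="pep_entity")
            if frame.empty:
                continue
            matrix, _ = _pre.batch_correct_mixes(
                frame, design, cond, rep, dataset=dataset, level="peptide", report=report
            )
            out[(cond, rep)] = matrix
    return out


def preprocess_records(
    records: pd.DataFrame,
    design: ExperimentDesign,
    params: PipelineParams = PipelineParams(),
) -> PreprocessResult:
    """Signal-processing phase: records -> smoothed, normalized elution matrices.

    ``records`` must carry the canonical schema plus resolved ``condition``,
    ``replicate`` and ``fraction`` columns (as produced by
    :func:`secmx.io.read_quant_report` or the simulator).
    """
    report = _pre.NormalizationReport()
    report.counts["records_in"] = len(records)

    recs = _pre.filter_records(records)
    recs = _pre.assign_representative_id(recs)
    recs = _pre.ms1_normalize(recs)
    recs["pep_entity"] = recs["modified_seq"].map(stripped_sequence)
    report.counts["records_filtered"] = len(recs)

    conditions = [c for c in design.condition_order if c in set(recs["condition"])]
    if len(conditions) != 2:
        raise ValidationError(f"pipeline expects exactly 2 conditions, got {conditions}")
    ref = params.reference_condition or conditions[0]
    other = [c for c in conditions if c != ref]
    if len(other) != 1:
        raise ValidationError(f"reference condition {ref!r} not among {conditions}")
    cond_a, cond_b = ref, other[0]

    datasets = {"global": recs[~recs["is_phospho"]], "phospho": recs[recs["is_phospho"]]}
    datasets = {k: v for k, v in datasets.items() if len(v)}

    # peptide -> representative protein map, per dataset scope
    pep_parent = (
        recs.groupby("pep_entity")["entity_id"].agg(lambda s: min(s)).to_dict()
    )

    matrices: dict[tuple[str, str, str], ElutionMatrix] = {}
    averaged: dict[tuple[str, str], ElutionMatrix] = {}
    for ds, sub in datasets.items():
        per_rep = _peptide_matrices(sub, design, ds, report)
        reps = sorted({r for (_, r) in per_rep})
        # condition normalization per replicate: B scaled onto A
        for rep in reps:
            ma, mb = per_rep.get((cond_a, rep)), per_rep.get((cond_b, rep))
            if ma is None or mb is None:
                continue
            ma, mb, _ = _pre.normalize_between_conditions(ma, mb, report)
            per_rep[(cond_a, rep)], per_rep[(cond_b, rep)] = ma, mb
        for (cond, rep), m in per_rep.items():
            matrices[(ds, cond, rep)] = m
        for cond in (cond_a, cond_b):
            group = [per_rep[(cond, r)] for r in reps if (cond, r) in per_rep]
            if group:
                averaged[(ds, cond)] = _pre.average_replicates(group)

    # collapse global to protein level, smooth everything
    smoothed: dict[tuple[str, str], ElutionMatrix] = {}
    for (ds, cond), m in averaged.items():
        if ds == "global":
            m = _pre.collapse_to_protein(m, pep_parent)
        smoothed[(ds, cond)] = _pre.smooth_matrix(m, params.smoothing_padlen)

    return PreprocessResult(
        conditions=[cond_a, cond_b],
        matrices=matrices,
        averaged=averaged,
        smoothed=smoothed,
        peptide_to_protein=pep_parent,
        report=report,
    )


def analyze_profiles(
    pre: PreprocessResult,
    standard: _cal.CalibrationStandard | None = None,
    monomer_masses: Mapping[str, float] | None = None,
    params: PipelineParams = PipelineParams(),
) -> PipelineResult:
    """Analysis phase: peak calling, alignment, classification, differentials."""
    cond_a, cond_b = pre.conditions
    smoothed = pre.smoothed
    matrices = pre.matrices
    pep_parent = pre.peptide_to_protein
    report = pre.report

    # calibration
    model = None
    if standard is not None:
        model = _cal.fit_mw_calibration(standard, params.monomer_multiplier)

    # peak detection
    pk_params = params.peak_params()
    peaksets: dict[tuple[str, str], dict[str, list]] = {}
    for key, m in smoothed.items():
        peaksets[key] = _peaks.drop_empty(_peaks.detect_peaks_matrix(m, pk_params))

    # condition alignment of the global dataset
    g_by_cond = {cond: peaksets.get(("global", cond), {}) for cond in (cond_a, cond_b)}
    states = _align.align_conditions(g_by_cond, params.threshold)
    if model is not None and monomer_masses:
        for st in states:
            st.classification = _cal.classify_apex(
                model, monomer_masses.get(st.entity_id), st.consensus_apex
            )

    # phospho -> global mapping (per condition), then differentials
    ph_by_cond = {cond: peaksets.get(("phospho", cond), {}) for cond in (cond_a, cond_b)}
    ph_parent = {
        pep: pep_parent.get(pep, "")
        for cond in ph_by_cond for pep in ph_by_cond[cond]
    }
    annotations = _align.map_ptm_peaks(
        ph_by_cond, states, ph_parent, params.ptm_max_dist
    ) if any(ph_by_cond.values()) else []

    g_fc = _quant.state_fold_changes(states, cond_a, cond_b, "global")
    p_fc = _quant.phospho_fold_changes(annotations, cond_a, cond_b)
    groups = _quant.response_group_table(g_fc, p_fc, params.fold_cutoff)

    # fraction-summed abundance ratios at protein level, per replicate
    reps = sorted({r for (ds, c, r) in matrices if ds == "global"})
    coll_a = [
        _pre.collapse_to_protein(matrices[("global", cond_a, r)], pep_parent)
        for r in reps if ("global", cond_a, r) in matrices
    ]
    coll_b = [
        _pre.collapse_to_protein(matrices[("global", cond_b, r)], pep_parent)
        for r in reps if ("global", cond_b, r) in matrices
    ]
    totals = (
        _quant.total_abundance_ratio(coll_a, coll_b)
        if coll_a and coll_b else pd.DataFrame(columns=["sum_a", "sum_b", "ratio"])
    )

    return PipelineResult(
        conditions=[cond_a, cond_b],
        params=params,
        matrices=matrices,
        averaged=pre.averaged,
        smoothed=smoothed,
        peaksets=peaksets,
        global_states=states,
        ptm_annotations=annotations,
        global_fold_changes=g_fc,
        phospho_fold_changes=p_fc,
        response_groups=groups,
        total_abundance=totals,
        report=report,
        calibration=model,
        peptide_to_protein=pep_parent,
    )


def run_pipeline(
    records: pd.DataFrame,
    design: ExperimentDesign,
    standard: _cal.CalibrationStandard | None = None,
    monomer_masses: Mapping[str, float] | None = None,
    params: PipelineParams = PipelineParams(),
) -> PipelineResult:
    """Full analysis: :func:`preprocess_records` then :func:`analyze_profiles`."""
    pre = preprocess_records(records, design, params)
    return analyze_profiles(pre, standard, monomer_masses, params)
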