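"""Differential statistics on aligned assembly states.

Fold changes between two conditions (reference A, comparison B) are
computed per assembly state as log2 of the ratio of peak heights read from
the smoothed, replicate-averaged profiles — each condition at its own member
apex.  Phosphopeptide fold changes are computed per peptide, and only for
peptides whose phospho peak mapped to the *same* global state in both
conditions.  Crossing the global and phospho calls at a +/-2-fold cutoff
yields the 3x3 grid of response groups (letters A..I; E is the
doubly-unchanged center cell).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import PTMAnnotation
from .model import AssemblyState, ElutionMatrix, ValidationError

log = logging.getLogger("secmx")

__all__ = [
    "StateFoldChange",
    "state_fold_change",
    "state_fold_changes",
    "phospho_fold_changes",
    "classify_response_group",
    "response_group_table",
    "total_abundance_ratio",
    "profile_correlation",
]

UP_IN_B = "up_in_B"
UP_IN_A = "up_in_A"
NS = "NS"

# Row-major 3x3 grid: rows = phospho call (up_in_B, NS, up_in_A),
# columns = global call (up_in_A, NS, up_in_B).  Fixes B = (global NS,
# phospho up in B), E = (NS, NS), H = (global NS, phospho up in A).
_GRID = {
    (UP_IN_B, UP_IN_A): "A", (UP_IN_B, NS): "B", (UP_IN_B, UP_IN_B): "C",
    (NS, UP_IN_A): "D", (NS, NS): "E", (NS, UP_IN_B): "F",
    (UP_IN_A, UP_IN_A): "G", (UP_IN_A, NS): "H", (UP_IN_A, UP_IN_B): "I",
}


@dataclass
class StateFoldChange:
    entity_id: str
    state_id: str
    dataset: str
    height_a: float
    height_b: float
    log2_ratio: float
    peptide_id: str | None = None   # set for per-phosphopeptide ratios


def state_fold_change(
    state: AssemblyState, condition_a: str, condition_b: str, dataset: str = "global"
) -> StateFoldChange | None:
    """log2(B/A) peak-height ratio for a state aligned in both conditions.

    Heights are the member peaks' (smoothed, replicate-averaged) apex
    intensities, each condition at its own apex.  States missing either
    condition, or with a zero height, return ``None`` (flagged upstream).
    """
    pa = state.members.get(condition_a)
    pb = state.members.get(condition_b)
    if pa is None or pb is None:
        return None
    if pa.height <= 0 or pb.height <= 0:
        log.warning("state %s has zero peak height; excluded from ratios", state.state_id)
        return None
    return StateFoldChange(
        entity_id=state.entity_id,
        state_id=state.state_id,
        dataset=dataset,
        height_a=pa.height,
        height_b=pb.height,
        log2_ratio=float(np.log2(pb.height / pa.height)),
    )


def state_fold_changes(
    states: Sequence[AssemblyState], condition_a: str, condition_b: str, dataset: str = "global"
) -> list[StateFoldChange]:
    out = []
    for st in states:
        fc = state_fold_change(st, condition_a, condition_b, dataset)
        if fc is not None:
            out.append(fc)
    return out


def phospho_fold_changes(
    annotations: Sequence[PTMAnnotation], condition_a: str, condition_b: str
) -> list[StateFoldChange]:
    """Per-phosphopeptide log2(B/A) ratios for peaks mapped to one global state.

    A peptide contributes a ratio only when its phospho peak mapped to the
    same global assembly state in both conditions; the heights are the
    phosphopeptide peak heights.
    """
    mapped: dict[tuple[str, str], dict[str, PTMAnnotation]] = {}
    for ann in annotations:
        if ann.status != "mapped":
            continue
        mapped.setdefault((ann.peptide_id, ann.state_id), {})[ann.condition] = ann
    out = []
    for (pep, state_id), by_cond in sorted(mapped.items()):
        a, b = by_cond.get(condition_a), by_cond.get(condition_b)
        if a is None or b is None:
            continue
        if a.phospho_height <= 0 or b.phospho_height <= 0:
            continue
        out.append(
            StateFoldChange(
                entity_id=a.protein_id,
                state_id=state_id,
                dataset="phospho",
                height_a=a.phospho_height,
                height_b=b.phospho_height,
                log2_ratio=float(np.log2(b.phospho_height / a.phospho_height)),
                peptide_id=pep,
            )
        )
    return out


def _call(log2_ratio: float | None, cutoff_log2: float) -> str | None:
    if log2_ratio is None or np.isnan(log2_ratio):
        return None
    if log2_ratio > cutoff_log2:
        return UP_IN_B
    if log2_ratio < -cutoff_log2:
        return UP_IN_A
    return NS


def classify_response_group(
    global_log2: float | None,
    phospho_log2: float | None,
    fold_cutoff: float = 2.0,
) -> str | None:
    """Letter of the 3x3 response-group grid, or None if a dimension is absent.

    Calls use strict inequalities at the cutoff (|log2 fc| exactly at the
    boundary is not significant).  Pairs missing either the global or the
    phospho fold change are excluded from the grid.
    """
    cut = float(np.log2(fold_cutoff))
    g = _call(global_log2, cut)
    p = _call(phospho_log2, cut)
    if g is None or p is None:
        return None
    return _GRID[(p, g)]


def response_group_table(
    global_fcs: Sequence[StateFoldChange],
    phospho_fcs: Sequence[StateFoldChange],
    fold_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Cross global-state and phosphopeptide fold changes into response groups.

    One row per (state, phosphopeptide) pair where both fold changes exist.
    Proteins with several assembly states or phosphopeptides appear in
    several rows (and possibly several groups); deduplicated protein-level
    counting is up to the consumer of this table.
    """
    g_by_state = {fc.state_id: fc for fc in global_fcs}
    rows = []
    for pfc in phospho_fcs:
        gfc = g_by_state.get(pfc.state_id)
        if gfc is None:
            continue
        group = classify_response_group(gfc.log2_ratio, pfc.log2_ratio, fold_cutoff)
        rows.append(
            {
                "entity_id": gfc.entity_id,
                "state_id": pfc.state_id,
                "peptide_id": pfc.peptide_id,
                "global_log2fc": gfc.log2_ratio,
                "phospho_log2fc": pfc.log2_ratio,
                "group": group,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["entity_id", "state_id", "peptide_id", "global_log2fc", "phospho_log2fc", "group"],
    )


def total_abundance_ratio(
    matrices_a: Sequence[ElutionMatrix], matrices_b: Sequence[ElutionMatrix]
) -> pd.DataFrame:
    """Fraction-summed abundance ratio B/A per entity (replicate-averaged sums).

    The SEC dimension is collapsed first: per entity, intensities are summed
    over all measured fractions, the sums averaged over replicates, and a
    single ratio computed on the entities present in both conditions.
    Entities with a zero denominator are excluded (logged).
    """
    def summed(mats: Sequence[ElutionMatrix]) -> pd.Series:
        sums = [m.data.sum(axis=1) for m in mats]
        return pd.concat(sums, axis=1).mean(axis=1, skipna=True)

    sa, sb = summed(matrices_a), summed(matrices_b)
    shared = sa.index.intersection(sb.index)
    sa, sb = sa.loc[shared], sb.loc[shared]
    ok = sa > 0
    if (~ok).any():
        log.info("total_abundance_ratio: excluded %d entities with zero reference sum", int((~ok).sum()))
    return pd.DataFrame(
        {"sum_a": sa[ok], "sum_b": sb[ok], "ratio": sb[ok] / sa[ok]}
    ).rename_axis("entity_id")


def profile_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two elution profiles; NaN for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"profile length mismatch: {x.shape} vs {y.shape}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])
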