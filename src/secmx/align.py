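"""Cross-sample peak alignment by variance-scored paths.

Peaks of one entity detected in *n* samples (e.g. two conditions) are
matched by enumerating *alignment paths*: each sample contributes either one
of its peak apexes or a missing marker, every combination forming one
candidate path (the all-missing path is excluded).  A path is scored by a
threshold-penalized variance:

    mean  = (sum of non-missing apexes) / m          (m = non-missing count)
    var   = (1/n) * [ sum_present (apex - mean)^2  +  (n - m) * T^2 ]
    score = 1 / (var + 1)

where T is the alignment threshold (default 3 fractions).  A peak that sits
further than T from the path mean therefore costs more than leaving that
sample unmatched, so distant peaks fall out into their own states.  Paths
are selected greedily: the best-scoring path becomes an assembly state, all
paths sharing any of its concrete peaks are discarded, and the process
repeats until every peak is covered — a partition of the peak set.

Phosphopeptide peaks are mapped onto the selected global (protein-level)
states by nearest apex within a cutoff (default 3 fractions); the
annotation adopts the global peak's apex, so many phosphopeptides can share
one global assembly state.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import AlignmentPath, AssemblyState, Peak, PTMAnnotation, ValidationError

log = logging.getLogger("secmx")

__all__ = [
    "enumerate_paths",
    "path_mean",
    "path_variance",
    "path_score",
    "select_paths",
    "align_conditions",
    "map_ptm_peaks",
    "threshold_evaluation",
]

DEFAULT_THRESHOLD = 3.0


# ---------------------------------------------------------------------------
# path algebra


def path_mean(elements: Sequence[float | None]) -> float:
    """Mean of the non-missing apexes (missing contributes nothing)."""
    present = [e for e in elements if e is not None]
    if not present:
        raise ValidationError("path has no non-missing element")
    return sum(present) / len(present)


def path_variance(elements: Sequence[float | None], threshold: float = DEFAULT_THRESHOLD) -> float:
    """Threshold-penalized variance over all n samples."""
    mu = path_mean(elements)
    n = len(elements)
    ss = sum((e - mu) ** 2 if e is not None else threshold**2 for e in elements)
    return ss / n


def path_score(elements: Sequence[float | None], threshold: float = DEFAULT_THRESHOLD) -> float:
    """Score in (0, 1]; 1 iff nothing is missing and all apexes coincide."""
    return 1.0 / (path_variance(elements, threshold) + 1.0)


def enumerate_paths(
    peak_lists: Sequence[Sequence[float]], threshold: float = DEFAULT_THRESHOLD
) -> list[AlignmentPath]:
    """All alignment paths over the missing-augmented peak lists.

    Each sample's list is augmented with one missing marker; the Cartesian
    product, minus the all-missing path, is returned.  The pre-exclusion
    count is the product of the augmented list lengths.
    """
    if len(peak_lists) == 0:
        raise ValidationError("enumerate_paths needs at least one sample")
    for lst in peak_lists:
        if any(b <= a for a, b in zip(lst, lst[1:])):
            raise ValidationError("peak apexes must be strictly increasing per sample")
    augmented = [list(lst) + [None] for lst in peak_lists]
    paths = []
    for combo in itertools.product(*augmented):
        if all(e is None for e in combo):
            continue
        paths.append(AlignmentPath(tuple(combo), threshold))
    return paths


def _tiebreak_key(p: AlignmentPath) -> tuple:
    # highest score; then more matched peaks; then smaller mean; then
    # lexicographic elements (missing sorts last).  Fully deterministic.
    elems = tuple(math.inf if e is None else e for e in p.elements)
    return (-p.score, -p.m, p.mean, elems)


def select_paths(
    peak_lists: Sequence[Sequence[float]], threshold: float = DEFAULT_THRESHOLD
) -> list[AlignmentPath]:
    """Greedy non-redundant path selection: a partition of all input peaks.

    Iteratively take the best-scoring remaining path, drop every path that
    shares a concrete peak with it, and repeat until all peaks of all
    samples are covered.  Peaks that align with nothing end up in
    single-peak paths (their only remaining candidates).
    """
    candidates = enumerate_paths(peak_lists, threshold)
    remaining = {(i, apex) for i, lst in enumerate(peak_lists) for apex in lst}
    selected: list[AlignmentPath] = []
    while remaining and candidates:
        best = min(candidates, key=_tiebreak_key)
        selected.append(best)
        used = {(i, e) for i, e in enumerate(best.elements) if e is not None}
        remaining -= used
        candidates = [
            p for p in candidates
            if not used & {(i, e) for i, e in enumerate(p.elements) if e is not None}
        ]
    assert not remaining, "greedy selection failed to cover all peaks"
    return selected


# ---------------------------------------------------------------------------
# condition alignment -> assembly states


def align_conditions(
    peaks_by_condition: Mapping[str, Mapping[str, Sequence[Peak]]],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[AssemblyState]:
    """Align each entity's peaks across conditions into assembly states.

    ``peaks_by_condition`` maps condition -> entity -> peak list.  Only
    conditions in which the entity has peaks participate (an entity absent
    everywhere is skipped).  The consensus apex is the mean of the member
    apexes; states are flagged ``mutual`` when every participating condition
    contributed a peak, else ``<condition>-only`` style.
    """
    conditions = sorted(peaks_by_condition)
    entities = sorted({e for c in conditions for e in peaks_by_condition[c]})
    states: list[AssemblyState] = []
    for entity in entities:
        present = [c for c in conditions if peaks_by_condition[c].get(entity)]
        if not present:
            continue
        by_cond = {c: sorted(peaks_by_condition[c][entity], key=lambda p: p.apex) for c in present}
        lists = [[float(p.apex) for p in by_cond[c]] for c in present]
        for k, path in enumerate(select_paths(lists, threshold)):
            members: dict[str, Peak] = {}
            for ci, e in enumerate(path.elements):
                if e is None:
                    continue
                cond = present[ci]
                members[cond] = next(p for p in by_cond[cond] if p.apex == e)
            in_conds = sorted(members)
            presence = "mutual" if len(in_conds) == len(conditions) else "+".join(in_conds) + "-only"
            states.append(
                AssemblyState(
                    entity_id=entity,
                    state_id=f"{entity}~s{k + 1}",
                    members=members,
                    consensus_apex=path.mean,
                    score=path.score,
                    presence=presence,
                )
            )
    return states


# ---------------------------------------------------------------------------
# phosphopeptide -> global state mapping


def map_ptm_peaks(
    phospho_peaksets: Mapping[str, Mapping[str, Sequence[Peak]]],
    global_states: Sequence[AssemblyState],
    parent_of: Mapping[str, str],
    max_dist: int = 3,
    site_probs: Mapping[str, str] | None = None,
) -> list[PTMAnnotation]:
    """Map phosphopeptide elution peaks onto global assembly states.

    ``phospho_peaksets`` maps condition -> peptide entity -> peaks;
    ``parent_of`` maps peptide entity -> protein accession.  Each phospho
    peak is assigned to the nearest same-condition member peak of its parent
    protein's states with |apex difference| <= ``max_dist``; ties go to the
    taller global peak.  The annotation adopts the global peak's apex.
    Unassignable peaks are flagged ``unmatched``; peptides whose parent has
    no global states are flagged ``orphan``.
    """
    site_probs = site_probs or {}
    # (protein, condition) -> [(apex, height, state_id)]
    index: dict[tuple[str, str], list[tuple[int, float, str]]] = {}
    for st in global_states:
        for cond, peak in st.members.items():
            index.setdefault((st.entity_id, cond), []).append(
                (peak.apex, peak.height, st.state_id)
            )
    annotations: list[PTMAnnotation] = []
    for cond in sorted(phospho_peaksets):
        for pep in sorted(phospho_peaksets[cond]):
            protein = parent_of.get(pep, "")
            for pk in phospho_peaksets[cond][pep]:
                cands = index.get((protein, cond))
                if not cands:
                    annotations.append(PTMAnnotation(
                        pep, protein, cond, pk.apex, "orphan",
                        phospho_height=pk.height, site_probs=site_probs.get(pep, "")))
                    continue
                # nearest apex; ties -> taller global peak, then earlier apex
                best = min(cands, key=lambda t: (abs(t[0] - pk.apex), -t[1], t[0]))
                dist = abs(best[0] - pk.apex)
                if dist <= max_dist:
                    annotations.append(PTMAnnotation(
                        pep, protein, cond, pk.apex, "mapped",
                        state_id=best[2], global_apex=best[0], distance=dist,
                        phospho_height=pk.height, site_probs=site_probs.get(pep, "")))
                else:
                    annotations.append(PTMAnnotation(
                        pep, protein, cond, pk.apex, "unmatched",
                        phospho_height=pk.height, site_probs=site_probs.get(pep, "")))
    return annotations


# ---------------------------------------------------------------------------
# threshold diagnostics


def threshold_evaluation(
    peaks_rep1: Mapping[str, Sequence[Peak]],
    peaks_rep2: Mapping[str, Sequence[Peak]],
    max_difference: int = 10,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Apex-difference distribution of real vs randomly paired entities.

    For every entity detected in both replicates, each replicate-1 peak is
    matched to the nearest replicate-2 peak of the same entity and the
    absolute apex difference tallied (capped at ``max_difference``).  The
    same tally over a random entity pairing gives the decoy distribution the
    alignment threshold is judged against: real pairs pile up at small
    differences, random pairs are spread out.
    """
    rng = rng or np.random.default_rng(0)
    shared = sorted(set(peaks_rep1) & set(peaks_rep2))
    if len(shared) < 2:
        raise ValidationError("threshold_evaluation needs >= 2 shared entities")

    def tally(pairing: Iterable[tuple[str, str]]) -> np.ndarray:
        counts = np.zeros(max_difference + 1, dtype=int)
        for e1, e2 in pairing:
            apex2 = [p.apex for p in peaks_rep2[e2]]
            if not apex2:
                continue
            for p in peaks_rep1[e1]:
                d = min(abs(p.apex - a) for a in apex2)
                counts[min(d, max_difference)] += 1
        return counts

    real = tally((e, e) for e in shared)
    perm = rng.permutation(len(shared))
    # avoid fixed points so 'random' never silently matches an entity to itself
    for i in range(len(perm)):
        if perm[i] == i:
            j = (i + 1) % len(perm)
            perm[i], perm[j] = perm[j], perm[i]
    random = tally((shared[i], shared[perm[i]]) for i in range(len(shared)))
    return pd.DataFrame(
        {"difference": np.arange(max_difference + 1), "real_pairs": real, "random_pairs": random}
    )
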