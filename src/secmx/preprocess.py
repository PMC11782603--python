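"""Signal processing: from raw reporter measurements to clean elution matrices.

The stages mirror how multiplexed SEC co-fractionation data are prepared for
peak analysis:

1. filter to proteotypic, non-decoy peptides;
2. assign one representative protein accession per peptide;
3. normalize reporter intensities to the precursor (MS1) intensity;
4. pivot to entity x fraction matrices (missing -> 0), per mix;
5. correct TMT batch effects via the fractions shared by adjacent mixes
   (full-overlap designs) and average the duplicated overlap measurements;
6. scale condition B onto reference condition A by the ratio of nonzero
   intensity medians;
7. union-average biological replicates;
8. smooth profiles with a zero-phase width-2 moving-average filter;
9. optionally collapse peptides to protein level by top-3 summation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import filtfilt

from .model import ElutionMatrix, ExperimentDesign, ValidationError, stripped_sequence

log = logging.getLogger("secmx")

__all__ = [
    "NormalizationReport",
    "filter_records",
    "assign_representative_id",
    "ms1_normalize",
    "build_fraction_matrix",
    "batch_correct_mixes",
    "merge_mixes",
    "normalize_between_conditions",
    "average_replicates",
    "smooth_profile",
    "smooth_matrix",
    "collapse_to_protein",
    "minmax_normalize",
    "phospho_enrichment_efficiency",
]


@dataclass
class NormalizationReport:
    """Deterministic record of every normalization factor applied.

    ``batch_factors`` maps (condition, replicate, mix_n, mix_n+1) to the
    median-of-ratios factor by which mix n+1 was divided; ``condition_factors``
    maps (dataset, replicate) to the median-ratio factor applied to the
    non-reference condition; ``counts`` holds entity counts per stage.
    """

    batch_factors: dict[tuple[str, str, str, str], float] = field(default_factory=dict)
    condition_factors: dict[tuple[str, str], float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def batch_frame(self) -> pd.DataFrame:
        rows = [
            {"condition": c, "replicate": r, "mix_from": a, "mix_to": b, "factor": f}
            for (c, r, a, b), f in sorted(self.batch_factors.items())
        ]
        return pd.DataFrame(rows, columns=["condition", "replicate", "mix_from", "mix_to", "factor"])

    def to_tsv(self, path) -> None:
        rows = self.batch_frame()
        rows.insert(0, "kind", "batch")
        cond = pd.DataFrame(
            [
                {"kind": "condition", "condition": d, "replicate": r, "mix_from": "", "mix_to": "", "factor": f}
                for (d, r), f in sorted(self.condition_factors.items())
            ]
        )
        pd.concat([rows, cond], ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# record-level operations


def filter_records(records: pd.DataFrame) -> pd.DataFrame:
    """Keep proteotypic, non-decoy records."""
    out = records[records["is_proteotypic"] & ~records["is_decoy"]].copy()
    log.info("filter_records: %d -> %d rows", len(records), len(out))
    return out


def assign_representative_id(records: pd.DataFrame) -> pd.DataFrame:
    """Assign one protein accession per peptide: lexicographically first of the group.

    Deterministic and stable regardless of how the search engine ordered the
    group.  Records with an empty accession list are dropped with a warning.
    """
    out = records.copy()
    ids = out["protein_ids"].astype(str)
    empty = ids.str.strip().isin(("", "nan"))
    if empty.any():
        log.warning("assign_representative_id: dropping %d records with no accession", int(empty.sum()))
        out = out[~empty]
        ids = ids[~empty]
    out["entity_id"] = [min(s.split(";")) for s in ids.str.strip()]
    return out


def ms1_normalize(records: pd.DataFrame) -> pd.DataFrame:
    """Distribute each spectrum's MS1 intensity over its reporter channels.

    A TMT spectrum (one precursor of one peptide in one mix) carries one
    reporter value per channel; the normalized value is the channel's share
    of the summed reporters times the precursor intensity:
    ``reporter_c / sum_c(reporter) * ms1``.  Spectra whose reporters sum to
    zero yield zeros.  Missing reporters are treated as zero share.
    """
    if (records["ms1_intensity"].dropna() < 0).any():
        raise ValidationError("negative MS1 intensity")
    out = records.copy()
    rep = out["reporter_intensity"].fillna(0.0)
    total = rep.groupby([out["mix"], out["modified_seq"]]).transform("sum")
    share = np.where(total > 0, rep / total.replace(0, np.nan), 0.0)
    out["reporter_intensity"] = np.nan_to_num(share) * out["ms1_intensity"].fillna(0.0)
    return out


# ---------------------------------------------------------------------------
# matrix construction and batch correction


def build_fraction_matrix(
    records: pd.DataFrame,
    design: ExperimentDesign,
    condition: str,
    replicate: str,
    entity_col: str = "entity_id",
) -> pd.DataFrame:
    """Pivot records of one (condition, replicate) to an entity x (mix, fraction) frame.

    Cells are summed over duplicate spectra; unobserved cells are zero.  The
    mix level is kept because full-overlap designs measure each interior
    fraction twice (once per adjacent mix); :func:`batch_correct_mixes` or
    :func:`merge_mixes` collapses it to a plain fraction-indexed matrix.
    """
    sub = records[(records["condition"] == condition) & (records["replicate"] == replicate)]
    if sub.empty:
        return pd.DataFrame()
    wide = (
        sub.assign(intensity=sub["reporter_intensity"].fillna(0.0))
        .pivot_table(
            index=entity_col,
            columns=["mix", "fraction"],
            values="intensity",
            aggfunc="sum",
            fill_value=0.0,
        )
        .astype(float)
    )
    # zero-fill the unobserved cells of every observed mix's design fractions
    grp = design.frame[
        (design.frame["condition"] == condition) & (design.frame["replicate"] == replicate)
    ]
    observed = set(wide.columns.get_level_values(0))
    full_cols = pd.MultiIndex.from_frame(
        grp.loc[grp["mix"].isin(observed), ["mix", "fraction"]].drop_duplicates()
        .sort_values(["mix", "fraction"])
    )
    return wide.reindex(columns=full_cols, fill_value=0.0)


def batch_correct_mixes(
    mix_frame: pd.DataFrame,
    design: ExperimentDesign,
    condition: str,
    replicate: str,
    dataset: str = "global",
    level: str = "peptide",
    report: NormalizationReport | None = None,
) -> tuple[ElutionMatrix, NormalizationReport]:
    """Chain-correct TMT batch effects using overlap fractions, then merge mixes.

    For each adjacent mix pair (n, n+1): per overlapping fraction, take the
    median over peptides (nonzero in both mixes) of the intensity ratio
    mix[n+1]/mix[n]; the pair's factor is the mean of those per-fraction
    medians; all mix n+1 intensities are divided by it.  Division (rather
    than the multiplication a literal reading of the protocol would suggest)
    makes the post-correction overlap ratios converge to 1.  Corrections
    chain left-to-right, anchored on the first mix.  Finally the duplicated
    overlap measurements are averaged (over nonzero measurements, so a value
    missing from one mix is not halved).
    """
    report = report or NormalizationReport()
    present = set(mix_frame.columns.get_level_values(0))
    mixes = [m for m in design.mix_chain_for(condition, replicate) if m in present]
    grp = design.frame[
        (design.frame["condition"] == condition) & (design.frame["replicate"] == replicate)
    ]
    fr_sets = {m: set(grp.loc[grp["mix"] == m, "fraction"]) for m in mixes}
    corrected = mix_frame.copy()
    for a, b in zip(mixes, mixes[1:]):
        overlap = sorted(fr_sets[a] & fr_sets[b])
        if not overlap:
            continue
        per_fraction = []
        for f in overlap:
            if (a, f) not in corrected.columns or (b, f) not in corrected.columns:
                continue
            va, vb = corrected[(a, f)], corrected[(b, f)]
            both = (va > 0) & (vb > 0)
            if both.any():
                per_fraction.append(float((vb[both] / va[both]).median()))
        if not per_fraction:
            raise ValidationError(
                f"no usable overlap peptides between mixes {a!r} and {b!r}"
            )
        factor = float(np.mean(per_fraction))
        bcols = [c for c in corrected.columns if c[0] == b]
        corrected[bcols] = corrected[bcols] / factor
        report.batch_factors[(condition, replicate, a, b)] = factor
    matrix = merge_mixes(corrected, dataset, condition, replicate, level)
    return matrix, report


def merge_mixes(
    mix_frame: pd.DataFrame,
    dataset: str = "global",
    condition: str = "",
    replicate: str = "",
    level: str = "peptide",
) -> ElutionMatrix:
    """Collapse the mix level: per fraction, average the nonzero measurements."""
    vals = mix_frame.to_numpy(dtype=float)
    fracs = mix_frame.columns.get_level_values(1).to_numpy()
    uniq = np.unique(fracs)
    out = np.zeros((vals.shape[0], len(uniq)))
    for j, f in enumerate(uniq):
        cols = vals[:, fracs == f]
        nz = (cols > 0).sum(axis=1)
        out[:, j] = np.where(nz > 0, cols.sum(axis=1) / np.maximum(nz, 1), 0.0)
    df = pd.DataFrame(out, index=mix_frame.index, columns=[int(f) for f in uniq])
    df.index = df.index.astype(str)
    return ElutionMatrix(df, dataset=dataset, condition=condition, replicate=replicate, level=level)


# ---------------------------------------------------------------------------
# between-sample normalization and replicate averaging


def normalize_between_conditions(
    matrix_a: ElutionMatrix,
    matrix_b: ElutionMatrix,
    report: NormalizationReport | None = None,
) -> tuple[ElutionMatrix, ElutionMatrix, NormalizationReport]:
    """Scale condition B onto reference condition A by the nonzero-median ratio.

    factor = median(nonzero B) / median(nonzero A); B is divided by it, A is
    untouched.  Medians are over nonzero cells only — zero-filled missing
    cells would otherwise dominate.
    """
    report = report or NormalizationReport()
    va = matrix_a.data.to_numpy(dtype=float)
    vb = matrix_b.data.to_numpy(dtype=float)
    if not (va > 0).any() or not (vb > 0).any():
        raise ValidationError("cannot normalize: a condition matrix is all zero")
    factor = float(np.median(vb[vb > 0]) / np.median(va[va > 0]))
    out_b = ElutionMatrix(
        matrix_b.data / factor,
        dataset=matrix_b.dataset,
        condition=matrix_b.condition,
        replicate=matrix_b.replicate,
        level=matrix_b.level,
    )
    report.condition_factors[(matrix_b.dataset, matrix_b.replicate)] = factor
    return matrix_a, out_b, report


def average_replicates(matrices: Sequence[ElutionMatrix]) -> ElutionMatrix:
    """Union-based replicate averaging.

    The output row set is the union of the inputs' rows; each cell is the
    mean over the replicates in which the entity was identified at all, so an
    entity seen in a single replicate keeps that replicate's values instead
    of being diluted by zeros from replicates that never measured it.
    """
    if not matrices:
        raise ValidationError("average_replicates needs at least one matrix")
    first = matrices[0]
    if len(matrices) == 1:
        return ElutionMatrix(first.data, dataset=first.dataset,
                             condition=first.condition, replicate="averaged", level=first.level)
    all_fracs = sorted({f for m in matrices for f in m.fractions})
    frames = [m.data.reindex(columns=all_fracs, fill_value=0.0) for m in matrices]
    total = None
    count = None
    union_index = frames[0].index
    for df in frames[1:]:
        union_index = union_index.union(df.index)
    union_index = union_index.sort_values()
    for df in frames:
        aligned = df.reindex(index=union_index, fill_value=0.0)
        present = df.index
        pres_vec = union_index.isin(present).astype(float)[:, None]
        total = aligned.to_numpy() if total is None else total + aligned.to_numpy()
        count = pres_vec if count is None else count + pres_vec
    avg = total / count
    out = pd.DataFrame(avg, index=union_index, columns=all_fracs)
    return ElutionMatrix(out, dataset=first.dataset, condition=first.condition,
                         replicate="averaged", level=first.level)


# ---------------------------------------------------------------------------
# smoothing, collapsing, scaling


def smooth_profile(vector: np.ndarray, padlen: int = 3) -> np.ndarray:
    """Zero-phase two-pass moving average of width 2 (b = [1/2, 1/2], a = [1]).

    Forward-backward filtering makes the effective interior kernel
    [0.25, 0.5, 0.25] with unit DC gain and no phase shift, so symmetric
    peaks keep their apex.  Boundaries use odd (antisymmetric) signal
    extension; tiny negative boundary artifacts are clipped to zero.
    """
    x = np.asarray(vector, dtype=float)
    if x.size < 2:
        log.warning("smooth_profile: vector of length %d returned unchanged", x.size)
        return x.copy()
    pl = min(padlen, x.size - 1)
    y = filtfilt([0.5, 0.5], [1.0], x, padtype="odd", padlen=pl)
    return np.clip(y, 0.0, None)


def smooth_matrix(m: ElutionMatrix, padlen: int = 3) -> ElutionMatrix:
    vals = np.vstack([smooth_profile(row, padlen) for row in m.data.to_numpy(dtype=float)]) \
        if len(m.data) else m.data.to_numpy(dtype=float)
    df = pd.DataFrame(vals, index=m.data.index, columns=m.fractions) if len(m.data) else m.data
    return ElutionMatrix(df, dataset=m.dataset, condition=m.condition,
                         replicate=m.replicate, level=m.level)


def collapse_to_protein(
    peptide_matrix: ElutionMatrix, peptide_to_protein: Mapping[str, str]
) -> ElutionMatrix:
    """Collapse peptides to protein level by summing the top-3 peptides.

    Peptides are ranked by their total intensity summed over all fractions;
    per protein and fraction the intensities of the top three peptides are
    summed (all peptides when a protein has three or fewer).  Rank order is
    deterministic: ties broken by peptide id.
    """
    df = peptide_matrix.data
    proteins = pd.Series(
        [peptide_to_protein.get(p, "") for p in df.index], index=df.index, name="protein"
    )
    keep = proteins != ""
    df = df[keep]
    proteins = proteins[keep]
    totals = df.sum(axis=1)
    order = pd.DataFrame({"protein": proteins, "total": totals, "pep": df.index})
    order = order.sort_values(["protein", "total", "pep"], ascending=[True, False, True])
    top = order.groupby("protein").head(3)["pep"]
    collapsed = df.loc[top].groupby(proteins.loc[top]).sum()
    collapsed.index = collapsed.index.astype(str)
    collapsed.index.name = None
    return ElutionMatrix(
        collapsed.sort_index(),
        dataset=peptide_matrix.dataset,
        condition=peptide_matrix.condition,
        replicate=peptide_matrix.replicate,
        level="protein",
    )


def minmax_normalize(vector: np.ndarray) -> np.ndarray:
    """Scale a profile to [0, 1] by its maximum (all-zero stays all-zero)."""
    x = np.asarray(vector, dtype=float)
    mx = x.max() if x.size else 0.0
    return x / mx if mx > 0 else np.zeros_like(x)


def phospho_enrichment_efficiency(records: pd.DataFrame) -> pd.Series:
    """Per-mix phosphopeptide enrichment efficiency.

    Unique phosphorylated stripped sequences over unique stripped sequences
    identified in the mix — alternative site placements of one sequence count
    once.  Mixes with zero identifications are reported as NaN.
    """
    df = records.copy()
    df["stripped"] = df["modified_seq"].map(stripped_sequence)
    def eff(grp: pd.DataFrame) -> float:
        total = grp["stripped"].nunique()
        if total == 0:
            return float("nan")
        return grp.loc[grp["is_phospho"], "stripped"].nunique() / total
    return df.groupby("mix", sort=True).apply(eff, include_groups=False)
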