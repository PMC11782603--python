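"""Read/write the package's tabular artifacts.

Everything is TSV with a header row.  Elution matrices are wide: an
``entity_id`` column followed by one column per fraction named ``F<index>``.
A configurable column dictionary maps vendor report headers onto the
canonical quant-table schema so reports from different search engines are
ingestible without code changes.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model import (
    QUANT_COLUMNS,
    DesignEntry,
    ElutionMatrix,
    ExperimentDesign,
    FormatError,
    ReferenceError_,
    ValidationError,
)

log = logging.getLogger("secmx")

__all__ = [
    "read_quant_report",
    "write_quant_report",
    "read_design",
    "write_design",
    "read_matrix",
    "write_matrix",
    "read_calibration_standard",
    "write_calibration_standard",
    "read_monomer_masses",
    "write_monomer_masses",
    "read_config",
    "write_config",
]

_BOOL_COLS = ("is_phospho", "is_decoy", "is_proteotypic")
_FLOAT_COLS = ("reporter_intensity", "ms1_intensity")

#: Default vendor-header -> canonical-field dictionary (identity mapping).
DEFAULT_COLUMN_DICT: dict[str, str] = {c: c for c in QUANT_COLUMNS}


def _as_bool(s: pd.Series) -> pd.Series:
    if s.dtype == bool:
        return s
    return s.astype(str).str.strip().str.lower().isin(("true", "1", "t", "yes"))


def read_quant_report(
    path: str | Path,
    design: ExperimentDesign,
    column_dict: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a peptide-level quantification report into the canonical schema.

    ``column_dict`` maps source header -> canonical field name.  Condition,
    replicate and fraction are resolved through the design; a channel absent
    from the design is an error.  Missing reporter intensities are kept as
    NaN so raw completeness can be logged before the zero-fill step of
    preprocessing.
    """
    column_dict = dict(column_dict or DEFAULT_COLUMN_DICT)
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [src for src, dst in column_dict.items() if src not in raw.columns]
    if missing:
        raise FormatError(f"quant report missing mandatory column(s): {', '.join(missing)}")
    df = raw[list(column_dict)].rename(columns=column_dict)
    for c in _BOOL_COLS:
        df[c] = _as_bool(df[c])
    for c in _FLOAT_COLS:
        df[c] = pd.to_numeric(df[c].replace("", np.nan), errors="raise")
    if (df["reporter_intensity"].dropna() < 0).any():
        raise ValidationError("negative reporter intensities in quant report")

    # Resolve (mix, channel) through the design.
    key = pd.MultiIndex.from_frame(df[["mix", "channel"]])
    design_idx = design.frame.set_index(["mix", "channel"])
    unknown = key.difference(design_idx.index)
    if len(unknown):
        names = sorted({f"{m}/{c}" for m, c in unknown})
        raise ReferenceError_(f"channel(s) not in design: {', '.join(names[:10])}")
    resolved = design_idx.loc[key].reset_index(drop=True)
    df = pd.concat([df.reset_index(drop=True), resolved], axis=1)
    log.info("read_quant_report: %d rows from %s", len(df), path)
    return df


def write_quant_report(df: pd.DataFrame, path: str | Path) -> None:
    df[QUANT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> ExperimentDesign:
    """Read an experiment-design table (mix, channel, condition, replicate, fraction)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["mix", "channel", "condition", "replicate", "fraction"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(f"design missing column(s): {', '.join(missing)}")
    entries = [
        DesignEntry(r.mix, r.channel, r.condition, r.replicate, int(r.fraction))
        for r in df.itertuples(index=False)
    ]
    return ExperimentDesign(entries)


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    design.frame.to_csv(path, sep="\t", index=False)


def write_matrix(m: ElutionMatrix, path: str | Path) -> None:
    """Serialize an elution matrix at full precision (round-trip exact).

    Entity ids containing tabs or newlines are rejected (they would corrupt
    the TSV layout).
    """
    bad = [e for e in m.data.index if "\t" in str(e) or "\n" in str(e)]
    if bad:
        raise ValidationError(f"entity id(s) contain tab/newline: {bad[:3]}")
    out = m.data.copy()
    out.columns = [f"F{c}" for c in out.columns]
    out.index.name = "entity_id"
    with open(path, "w") as fh:
        fh.write(f"# dataset={m.dataset}\tcondition={m.condition}"
                 f"\treplicate={m.replicate}\tlevel={m.level}\n")
        # default float formatting is the shortest round-trip repr: bit-exact
        out.to_csv(fh, sep="\t")


def read_matrix(path: str | Path) -> ElutionMatrix:
    meta = {"dataset": "global", "condition": "", "replicate": "", "level": "peptide"}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].strip().split("\t"):
                k, _, v = tok.partition("=")
                meta[k.strip()] = v
        else:
            fh.seek(0)
        try:
            df = pd.read_csv(fh, sep="\t", index_col="entity_id",
                             float_precision="round_trip")
        except pd.errors.ParserError as err:
            raise FormatError(f"ragged or malformed matrix file {path}: {err}") from err
    if df.isna().to_numpy().any():
        raise FormatError(f"ragged rows (missing cells) in matrix file {path}")
    df.columns = [int(str(c).lstrip("F")) for c in df.columns]
    df.index = df.index.astype(str)
    df.index.name = None
    return ElutionMatrix(df, **meta)


def read_calibration_standard(path: str | Path) -> list[tuple[int, float]]:
    df = pd.read_csv(path, sep="\t")
    if not {"fraction", "mw_da"} <= set(df.columns):
        raise FormatError("calibration standard needs columns: fraction, mw_da")
    return [(int(f), float(w)) for f, w in zip(df["fraction"], df["mw_da"])]


def write_calibration_standard(points: list[tuple[int, float]], path: str | Path) -> None:
    pd.DataFrame(points, columns=["fraction", "mw_da"]).to_csv(path, sep="\t", index=False)


def read_monomer_masses(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if not {"entity_id", "mw_da"} <= set(df.columns):
        raise FormatError("monomer mass table needs columns: entity_id, mw_da")
    masses = dict(zip(df["entity_id"].astype(str), df["mw_da"].astype(float)))
    if any(w <= 0 for w in masses.values()):
        raise ValidationError("monomer masses must be positive")
    return masses


def write_monomer_masses(masses: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(sorted(masses.items()), columns=["entity_id", "mw_da"]).to_csv(
        path, sep="\t", index=False
    )


def read_config(path: str | Path) -> dict[str, str]:
    """Read a flat ``key = value`` run-configuration file ('#' comments allowed)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"config line without '=': {line!r}")
        k, _, v = line.partition("=")
        out[k.strip()] = v.strip()
    return out


def write_config(cfg: Mapping[str, object], path: str | Path) -> None:
    Path(path).write_text("".join(f"{k} = {v}\n" for k, v in cfg.items()))
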