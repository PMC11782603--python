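"""Shared data model for SEC co-fractionation experiments.

The package analyses size-exclusion chromatography (SEC) co-fractionation
experiments quantified with isobaric (TMT) labels: native protein assemblies
are separated by hydrodynamic size into ~55 fractions, fractions are pooled
into TMT mixes, and each reporter channel maps back to one SEC fraction of
one condition/replicate.  The types here carry that bookkeeping:

* :class:`QuantRecord` / the quant-table schema — one reporter measurement.
* :class:`ExperimentDesign` — the (mix, channel) -> (condition, replicate,
  fraction) map, including the overlap structure between adjacent mixes.
* :class:`ElutionMatrix` — entity x fraction intensity matrix.
* :class:`Peak`, :class:`AlignmentPath`, :class:`AssemblyState` — peak-level
  objects produced by detection and cross-sample alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ReferenceError_",
    "ValidationError",
    "QuantRecord",
    "QUANT_COLUMNS",
    "DesignEntry",
    "ExperimentDesign",
    "ElutionMatrix",
    "Peak",
    "AlignmentPath",
    "AssemblyState",
    "PTMAnnotation",
]


class FormatError(ValueError):
    """A table does not match the expected layout (missing/ragged columns)."""


class ReferenceError_(KeyError):
    """A record refers to something absent from the experiment design."""


class ValidationError(ValueError):
    """An invariant of the data model is violated."""


# Canonical column schema for the quantification table.  Readers map vendor
# headers onto these names; everything downstream uses them.
QUANT_COLUMNS = [
    "protein_ids",        # ';'-joined accession list of the protein group
    "peptide_seq",        # stripped amino-acid sequence
    "modified_seq",       # sequence with modification annotations
    "is_phospho",         # bool
    "site_probs",         # 'S:12:0.98;T:15:0.40' style string, may be empty
    "is_decoy",           # bool
    "is_proteotypic",     # bool
    "mix",                # TMT mix label
    "channel",            # TMT channel label
    "reporter_intensity",  # float, >= 0 or NaN (missing)
    "ms1_intensity",      # float, >= 0; precursor intensity of the spectrum
]


@dataclass
class QuantRecord:
    """One reporter-channel measurement of one peptide spectrum.

    Mostly a documentation/validation vehicle: pipelines operate on the
    equivalent DataFrame rows (see :data:`QUANT_COLUMNS`).
    """

    protein_ids: list[str]
    peptide_seq: str
    modified_seq: str
    is_phospho: bool
    site_localizations: list[tuple[str, int, float]]
    is_decoy: bool
    is_proteotypic: bool
    mix_id: str
    channel_id: str
    reporter_intensity: float  # NaN when missing
    ms1_intensity: float
    condition: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        if not math.isnan(self.reporter_intensity) and self.reporter_intensity < 0:
            raise ValidationError("reporter_intensity must be >= 0 or missing")
        for _, _, p in self.site_localizations:
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"site localization probability {p} not in [0, 1]")

    def to_row(self) -> dict:
        return {
            "protein_ids": ";".join(self.protein_ids),
            "peptide_seq": self.peptide_seq,
            "modified_seq": self.modified_seq,
            "is_phospho": self.is_phospho,
            "site_probs": ";".join(f"{r}:{pos}:{p:g}" for r, pos, p in self.site_localizations),
            "is_decoy": self.is_decoy,
            "is_proteotypic": self.is_proteotypic,
            "mix": self.mix_id,
            "channel": self.channel_id,
            "reporter_intensity": self.reporter_intensity,
            "ms1_intensity": self.ms1_intensity,
        }


@dataclass(frozen=True)
class DesignEntry:
    mix: str
    channel: str
    condition: str
    replicate: str
    fraction: int


class ExperimentDesign:
    """TMT mixing scheme: bijection (mix, channel) -> (condition, replicate, fraction).

    Two schemes occur in practice:

    * ``full_overlap`` — every interior fraction is split and measured in two
      adjacent mixes, enabling overlap-based batch correction;
    * ``no_overlap`` — every fraction is measured in exactly one mix (a mix
      may pool fractions of both conditions).
    """

    def __init__(self, entries: Sequence[DesignEntry]):
        if not entries:
            raise ValidationError("design has no entries")
        self.entries = list(entries)
        self._by_key: dict[tuple[str, str], DesignEntry] = {}
        for e in self.entries:
            key = (e.mix, e.channel)
            if key in self._by_key:
                raise FormatError(f"channel {e.channel!r} listed twice in mix {e.mix!r}")
            self._by_key[key] = e
        # Uniqueness: within one mix, one (condition, replicate, fraction) slot.
        seen: set[tuple[str, str, str, int]] = set()
        for e in self.entries:
            slot = (e.mix, e.condition, e.replicate, e.fraction)
            if slot in seen:
                raise FormatError(
                    f"fraction {e.fraction} of {e.condition}/{e.replicate} "
                    f"mapped twice within mix {e.mix!r}"
                )
            seen.add(slot)
        self.frame = pd.DataFrame(
            [(e.mix, e.channel, e.condition, e.replicate, e.fraction) for e in self.entries],
            columns=["mix", "channel", "condition", "replicate", "fraction"],
        )
        self.overlap_map = self._derive_overlap_map()
        self.scheme = (
            "full_overlap"
            if any(len(v) > 0 for v in self.overlap_map.values())
            else "no_overlap"
        )

    # -- derived structure -------------------------------------------------

    def _derive_overlap_map(self) -> dict[tuple[str, str], set[int]]:
        """Overlap fractions of each adjacent mix pair, per (condition, replicate) chain.

        Mixes are chained within a (condition, replicate) group in order of
        their lowest fraction; adjacency is defined on that order.
        """
        overlap: dict[tuple[str, str], set[int]] = {}
        for (cond, rep), grp in self.frame.groupby(["condition", "replicate"], sort=True):
            mixes = self.mix_chain_for(cond, rep)
            fr_sets = {
                m: set(grp.loc[grp["mix"] == m, "fraction"]) for m in mixes
            }
            for a, b in zip(mixes, mixes[1:]):
                overlap[(a, b)] = fr_sets[a] & fr_sets[b]
        return overlap

    def mix_chain_for(self, condition: str, replicate: str) -> list[str]:
        """Mix labels covering one (condition, replicate), ordered by lowest fraction."""
        grp = self.frame[
            (self.frame["condition"] == condition) & (self.frame["replicate"] == replicate)
        ]
        order = grp.groupby("mix")["fraction"].min().sort_values()
        return list(order.index)

    def resolve(self, mix: str, channel: str) -> DesignEntry:
        try:
            return self._by_key[(mix, channel)]
        except KeyError:
            raise ReferenceError_(f"channel {channel!r} of mix {mix!r} not in design") from None

    @property
    def conditions(self) -> list[str]:
        return sorted(self.frame["condition"].unique())

    @property
    def condition_order(self) -> list[str]:
        """Conditions in order of first appearance (the first is the reference)."""
        seen: list[str] = []
        for c in self.frame["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    @property
    def replicates(self) -> list[str]:
        return sorted(self.frame["replicate"].unique())

    def __eq__(self, other) -> bool:
        return isinstance(other, ExperimentDesign) and set(self.entries) == set(other.entries)


@dataclass
class ElutionMatrix:
    """Entity x SEC-fraction intensity matrix for one sample.

    ``data`` is indexed by entity id with integer fraction columns (1-based,
    collection order).  After preprocessing there are no missing values —
    unobserved cells are zero.
    """

    data: pd.DataFrame
    dataset: str = "global"      # 'global' | 'phospho'
    condition: str = ""
    replicate: str = ""
    level: str = "peptide"       # 'peptide' | 'protein'

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.columns = [int(c) for c in self.data.columns]
        if (self.data.to_numpy(dtype=float) < 0).any():
            raise ValidationError("elution matrix contains negative intensities")

    @property
    def fractions(self) -> list[int]:
        return list(self.data.columns)

    @property
    def entities(self) -> list[str]:
        return list(self.data.index)

    def profile(self, entity_id: str) -> np.ndarray:
        return self.data.loc[entity_id].to_numpy(dtype=float)

    def equals(self, other: "ElutionMatrix") -> bool:
        return (
            self.dataset == other.dataset
            and self.condition == other.condition
            and self.replicate == other.replicate
            and self.level == other.level
            and self.data.equals(other.data)
        )


@dataclass(frozen=True)
class Peak:
    """One detected elution maximum; the apex fraction is the peak's identity."""

    entity_id: str
    dataset: str
    condition: str
    apex: int                 # fraction index (1-based)
    height: float             # smoothed intensity at apex
    prominence: float
    width: float              # fractions, at half prominence
    left: float = float("nan")
    right: float = float("nan")


@dataclass
class AlignmentPath:
    """One candidate cross-sample peak correspondence.

    ``elements`` has one entry per sample: an apex fraction or ``None`` for a
    missing (unmatched) sample.  The score is 1 / (variance + 1) where missing
    elements contribute ``threshold**2`` to the variance — a peak further than
    the threshold from the path mean costs more than declaring it unmatched.
    """

    elements: tuple[float | None, ...]
    threshold: float
    mean: float = field(init=False)
    variance: float = field(init=False)
    score: float = field(init=False)

    def __post_init__(self) -> None:
        present = [e for e in self.elements if e is not None]
        if not present:
            raise ValidationError("all-missing path is not a valid alignment")
        n = len(self.elements)
        self.m = len(present)
        self.mean = sum(present) / self.m
        ss = sum((e - self.mean) ** 2 for e in present)
        ss += (n - self.m) * self.threshold**2
        self.variance = ss / n
        self.score = 1.0 / (self.variance + 1.0)


@dataclass
class AssemblyState:
    """A selected alignment path of one entity: one putative molecular assembly.

    ``members`` maps sample id (condition label, for condition alignment) to
    the member :class:`Peak`.  ``consensus_apex`` is the mean of the member
    apexes.
    """

    entity_id: str
    state_id: str
    members: dict[str, Peak]
    consensus_apex: float
    score: float
    classification: str = "unclassified"   # 'monomeric' | 'complexed' | 'unclassified'
    presence: str = ""                      # 'mutual' | '<sample>-only'

    @property
    def conditions(self) -> list[str]:
        return sorted(self.members)


@dataclass
class PTMAnnotation:
    """A phosphopeptide elution peak mapped onto a global assembly state.

    The annotation adopts the global peak's apex; ``status`` is ``mapped``,
    ``unmatched`` (no global peak within the cutoff) or ``orphan`` (parent
    protein absent from the global peak set).
    """

    peptide_id: str
    protein_id: str
    condition: str
    phospho_apex: int
    status: str
    state_id: str | None = None
    global_apex: int | None = None
    distance: int | None = None
    phospho_height: float = float("nan")
    site_probs: str = ""


def stripped_sequence(modified_seq: str) -> str:
    """Strip modification annotations like ``PEPT[ph]IDE`` or ``PEPT(ph)IDE``."""
    out = []
    depth = 0
    for ch in modified_seq:
        if ch in "([{":
            depth += 1
        elif ch in ")]}":
            depth = max(0, depth - 1)
        elif depth == 0 and ch.isalpha():
            out.append(ch)
    return "".join(out)
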