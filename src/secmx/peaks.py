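"""Elution peak detection on smoothed, replicate-averaged profiles.

Each local maximum that clears three constraints becomes a candidate
assembly state:

* ``min_height`` — absolute intensity floor at the apex (default 1000);
* ``prominence_frac`` — prominence of at least this fraction of the
  profile's maximum (default 0.05), with the standard topographic
  prominence definition;
* ``min_distance`` — apexes at least this many fractions apart (default 3);
  of two closer maxima the higher survives.

Detection delegates to :func:`scipy.signal.find_peaks` /
:func:`scipy.signal.peak_widths`; widths are measured at half prominence.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks, peak_widths

from .model import Peak

log = logging.getLogger("secmx")

__all__ = ["PeakParams", "detect_peaks", "detect_peaks_matrix", "drop_empty", "peak_multiplicity"]


@dataclass(frozen=True)
class PeakParams:
    prominence_frac: float = 0.05
    min_distance: int = 3
    min_height: float = 1000.0


def detect_peaks(
    profile: np.ndarray,
    params: PeakParams = PeakParams(),
    fractions: Sequence[int] | None = None,
    entity_id: str = "",
    dataset: str = "global",
    condition: str = "",
) -> list[Peak]:
    """Detect peaks on one smoothed profile; apexes reported in fraction coordinates.

    ``fractions`` gives the fraction index of each sample (default 1..len).
    A flat or all-zero profile yields no peaks.
    """
    x = np.asarray(profile, dtype=float)
    if fractions is None:
        fractions = list(range(1, x.size + 1))
    mx = x.max() if x.size else 0.0
    if mx <= 0:
        return []
    idx, props = find_peaks(
        x,
        height=params.min_height,
        distance=params.min_distance,
        prominence=mx * params.prominence_frac,
    )
    if idx.size == 0:
        return []
    widths, _, lips, rips = peak_widths(x, idx, rel_height=0.5)
    out = []
    offset = fractions[0]
    for i, p in enumerate(idx):
        out.append(
            Peak(
                entity_id=entity_id,
                dataset=dataset,
                condition=condition,
                apex=int(fractions[p]),
                height=float(x[p]),
                prominence=float(props["prominences"][i]),
                width=float(widths[i]),
                left=float(lips[i] + offset),
                right=float(rips[i] + offset),
            )
        )
    return out


def detect_peaks_matrix(
    matrix, params: PeakParams = PeakParams()
) -> dict[str, list[Peak]]:
    """Detect peaks for every row of a (smoothed) :class:`ElutionMatrix`.

    Returns entity_id -> ordered peak list; peakless entities are dropped
    (see :func:`drop_empty`) by the caller if desired — here they are kept
    so drop counts can be reported.
    """
    fr = matrix.fractions
    out: dict[str, list[Peak]] = {}
    vals = matrix.data.to_numpy(dtype=float)
    for entity, row in zip(matrix.data.index, vals):
        out[str(entity)] = detect_peaks(
            row, params, fractions=fr, entity_id=str(entity),
            dataset=matrix.dataset, condition=matrix.condition,
        )
    return out


def drop_empty(peaksets: Mapping[str, list[Peak]]) -> dict[str, list[Peak]]:
    """Remove entities in which no peak could be modeled (noise-only profiles)."""
    out = {e: ps for e, ps in peaksets.items() if ps}
    dropped = len(peaksets) - len(out)
    if dropped:
        log.info("drop_empty: removed %d peakless entities of %d", dropped, len(peaksets))
    return out


def peak_multiplicity(peaksets: Mapping[str, list[Peak]]) -> tuple[float, dict[int, int]]:
    """Mean peaks per entity and the integer histogram of peak counts."""
    counts = [len(ps) for ps in peaksets.values() if ps]
    if not counts:
        raise ValueError("peak_multiplicity of an empty peak set")
    hist = dict(sorted(Counter(counts).items()))
    return float(np.mean(counts)), hist
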