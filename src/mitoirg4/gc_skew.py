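"""Windowed and cumulative GC-skew profiles.

Skew per window is (G - C) / (G + C) on the forward strand (sign convention
documented here because tools differ); the cumulative curve is the running
sum of window skews. Extrema of the cumulative curve are the classical
candidates for replication origin and terminus, though in rearranged
genomes the signal is often inconclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome_io import GenomeRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SkewProfile:
    window: int
    step: int
    starts: np.ndarray  # window start positions, bp
    skew: np.ndarray  # per-window (G - C) / (G + C)
    cumulative: np.ndarray

    def __len__(self) -> int:
        return self.skew.size

    def midpoints(self) -> np.ndarray:
        return self.starts + self.window // 2


def gc_skew_profile(genome: GenomeRecord, window: int = 1000, step: int | None = None) -> SkewProfile:
    """Per-window and cumulative GC skew; windows are non-overlapping by
    default (step = window). Windows with no G or C get skew 0 (warned)."""
    if step is None:
        step = window
    L = genome.length
    if window > L:
        raise ValueError(f"window ({window}) exceeds genome length ({L})")
    arr = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    is_g = (arr == ord("G")).astype(np.int64)
    is_c = (arr == ord("C")).astype(np.int64)
    cg = np.concatenate(([0], np.cumsum(is_g)))
    cc = np.concatenate(([0], np.cumsum(is_c)))
    starts = np.arange(0, L - window + 1, step)
    g = cg[starts + window] - cg[starts]
    c = cc[starts + window] - cc[starts]
    tot = g + c
    if np.any(tot == 0):
        log.warning("%d window(s) contain no G or C; skew set to 0", int((tot == 0).sum()))
    skew = np.where(tot > 0, (g - c) / np.maximum(tot, 1), 0.0)
    return SkewProfile(window=window, step=step, starts=starts, skew=skew,
                       cumulative=np.cumsum(skew))


def extrema(profile: SkewProfile) -> dict:
    """Window indices and bp midpoints of the global min/max of the
    cumulative curve (first occurrence on ties)."""
    if len(profile) == 0:
        raise ValueError("empty profile")
    imax = int(np.argmax(profile.cumulative))
    imin = int(np.argmin(profile.cumulative))
    mids = profile.midpoints()
    return {
        "max_index": imax, "max_bp": int(mids[imax]),
        "min_index": imin, "min_bp": int(mids[imin]),
    }
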