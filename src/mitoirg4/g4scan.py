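"""G-quadruplex motif prediction by a run-based sliding-window score.

Per-base scoring: a G in a run of k consecutive G's scores +min(k, 4); a C
in a run of k C's scores -min(k, 4); A, T and N score 0. A window of width
``w`` is a hit when the absolute mean per-base score reaches the threshold
``s``; overlapping or adjacent same-sign hit windows are merged into maximal
regions. Positive region scores flag G-rich tracts on the given strand,
negative scores C-rich tracts (G4 potential on the complement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import GenomeRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanParams:
    """Window size, score threshold and overlap-elimination settings.

    ``s=1.7`` is the strict setting, ``s=1.2`` the relaxed one; both use
    ``w=25``. ``circular`` lets the scan wrap ``w-1`` bases past the origin
    of a circular genome (off by default: deposited records are scanned as
    linearized).
    """

    w: int = 25
    s: float = 1.7
    circular: bool = False
    max_overlap_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.w < 2:
            raise ValueError("window size w must be >= 2")
        if self.s <= 0:
            raise ValueError("threshold s must be > 0")
        if not 0 <= self.max_overlap_frac <= 1:
            raise ValueError("max_overlap_frac must be in [0, 1]")


STRICT = ScanParams(w=25, s=1.7)
RELAXED = ScanParams(w=25, s=1.2)


@dataclass(frozen=True)
class G4Motif:
    """A merged region of threshold-passing windows.

    ``score`` is the signed mean of the region's peak window; ``end`` may
    exceed the genome length for regions wrapping a circular origin.
    """

    start: int
    end: int
    score: float

    @property
    def peak_abs(self) -> float:
        return abs(self.score)

    @property
    def strand(self) -> str:
        return "+" if self.score >= 0 else "-"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def base_scores(sequence: str) -> np.ndarray:
    """Per-base run scores: +min(k,4) for G-runs, -min(k,4) for C-runs."""
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8)
    n = arr.size
    scores = np.zeros(n, dtype=np.int8)
    if n == 0:
        return scores
    for base, sign in ((ord("G"), 1), (ord("C"), -1)):
        mask = arr == base
        if not mask.any():
            continue
        # run-length encode the mask
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
        starts, ends = edges[::2], edges[1::2]
        for s, e in zip(starts, ends):
            scores[s:e] = sign * min(e - s, 4)
    return scores


def window_means(sequence: str, w: int, *, circular: bool = False) -> np.ndarray:
    """Mean per-base score of every window of width ``w`` (step 1).

    Linear scans yield ``L - w + 1`` values; circular scans yield ``L``
    values, the last ``w - 1`` windows wrapping past the origin (run scoring
    honours runs crossing the origin).
    """
    L = len(sequence)
    if circular:
        # score in triplicated context so origin-crossing runs are exact
        sc = base_scores(sequence * 3).astype(np.float64)
        csum = np.concatenate(([0.0], np.cumsum(sc)))
        starts = np.arange(L) + L
        return (csum[starts + w] - csum[starts]) / w
    sc = base_scores(sequence).astype(np.float64)
    csum = np.concatenate(([0.0], np.cumsum(sc)))
    starts = np.arange(L - w + 1)
    return (csum[starts + w] - csum[starts]) / w


def detect_motifs(genome: GenomeRecord, params: ScanParams = STRICT) -> list[G4Motif]:
    """Scan a genome and return merged, sign-homogeneous motif regions.

    A region's score is the signed mean of its highest-|mean| window (first
    such window on ties); a sign change terminates a region. Regions are
    returned sorted by start. Run :func:`deduplicate` afterwards to apply
    the overlap-elimination rule.
    """
    L = genome.length
    if L < params.w:
        log.warning("genome %s shorter than window (%d < %d): no scan", genome.id, L, params.w)
        return []
    wrap = params.circular and genome.circular
    means = window_means(genome.sequence, params.w, circular=wrap)
    hits = np.flatnonzero(np.abs(means) >= params.s)
    if hits.size == 0:
        return []
    motifs: list[G4Motif] = []
    cur_start = int(hits[0])
    cur_end = cur_start + params.w
    cur_sign = 1 if means[hits[0]] >= 0 else -1
    cur_peak = means[hits[0]]
    for h in hits[1:]:
        h = int(h)
        sign = 1 if means[h] >= 0 else -1
        if h <= cur_end and sign == cur_sign:
            cur_end = h + params.w
            if abs(means[h]) > abs(cur_peak):
                cur_peak = means[h]
        else:
            motifs.append(G4Motif(cur_start, cur_end, float(cur_peak)))
            cur_start, cur_end, cur_sign, cur_peak = h, h + params.w, sign, means[h]
    motifs.append(G4Motif(cur_start, cur_end, float(cur_peak)))
    if wrap and len(motifs) > 1:
        first, last = motifs[0], motifs[-1]
        # a region wrapping past the origin meets one starting at 0
        if last.end > L and first.start <= last.end - L and (
            (first.score >= 0) == (last.score >= 0)
        ):
            peak = first.score if abs(first.score) > abs(last.score) else last.score
            motifs = [G4Motif(last.start, max(last.end, first.end + L), float(peak))] + motifs[1:-1]
    return sorted(motifs, key=lambda m: m.start)


def deduplicate(motifs: Sequence[G4Motif], max_overlap_frac: float = 0.5) -> list[G4Motif]:
    """Eliminate motifs overlapping an already-retained one by more than
    ``max_overlap_frac`` of their own length.

    Greedy pass in priority order (descending |score|, ties by smaller
    start); the strict inequality means an exactly-half overlap is kept.
    """
    order = sorted(motifs, key=lambda m: (-abs(m.score), m.start))
    retained: list[G4Motif] = []
    for m in order:
        own = m.length
        keep = True
        for r in retained:
            ov = max(0, min(m.end, r.end) - max(m.start, r.start))
            if ov > max_overlap_frac * own:
                keep = False
                break
        if keep:
            retained.append(m)
    return sorted(retained, key=lambda m: m.start)


def scan(genome: GenomeRecord, params: ScanParams = STRICT) -> list[G4Motif]:
    """Detect, then apply the overlap-elimination rule."""
    return deduplicate(detect_motifs(genome, params), params.max_overlap_frac)


def density(motifs: Sequence, region_length_bp: float) -> float:
    """Motifs per kilobase."""
    if region_length_bp <= 0:
        raise ValueError("region length must be positive")
    return len(motifs) * 1000.0 / region_length_bp
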