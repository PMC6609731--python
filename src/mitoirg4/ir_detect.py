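"""Large inverted-repeat (IR) detection and IR/SC genome partition.

Two detectors are provided: a sequence-based seed-and-extend search of a
finished genome against its own reverse complement, and a read-depth
detector that finds the two-fold coverage plateau a collapsed IR leaves in
an assembly. The partition step labels the four regions (two IR arms, two
single-copy regions) and reports border-flanking genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import median_filter

from .genome_io import Feature, FeatureSet, GenomeRecord, canonical_gene_name
from .intervals import Interval, circular_gap, contains, linear_pieces

log = logging.getLogger(__name__)

_COMP_B = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class IRAnnotation:
    """Coordinates of the two IR arms and the derived single-copy regions.

    Intervals use wrap notation: start in ``[0, L)``, end may exceed ``L``
    for intervals spanning a circular origin. ``arm2`` is the reverse
    complement of ``arm1`` up to ``identity``. ``sc1`` is the single-copy
    region containing cox1 when annotation allows, otherwise the longer one.
    """

    arm1: Interval
    arm2: Interval
    sc1: Interval
    sc2: Interval
    identity: float
    genome_length: int

    @property
    def arm_length(self) -> int:
        return self.arm1[1] - self.arm1[0]

    def regions(self) -> dict[str, Interval]:
        return {"IR_copy1": self.arm1, "IR_copy2": self.arm2, "SC1": self.sc1, "SC2": self.sc2}

    def region_pieces(self, name: str) -> list[Interval]:
        return linear_pieces(self.regions()[name], self.genome_length)

    def tiles_genome(self) -> bool:
        total = sum(e - s for s, e in self.regions().values())
        return total == self.genome_length


def _match(a: str, b: str) -> bool:
    return a == _COMP_B[b] and a != "N"


def _extend(seq: str, d: int, lo: int, hi: int, min_identity: float,
            max_streak: int, lo_limit: int, hi_limit: int) -> tuple[int, int, int]:
    """Extend an all-match core [lo, hi) outward along anti-diagonal ``d``.

    Position q pairs with d - q. Mismatches are absorbed while the running
    identity stays >= min_identity and no mismatch streak exceeds
    ``max_streak``; trailing mismatches are trimmed. Returns (lo, hi,
    n_mismatch) for the extended arm1 interval.
    """
    mism = sum(0 if _match(seq[q], seq[d - q]) else 1 for q in range(lo, hi))
    # rightward
    q, streak, pend = hi, 0, 0
    best_hi, best_mism = hi, mism
    while q < hi_limit:
        p = d - q
        if p < 0 or p >= len(seq) or p <= q:  # stop at palindrome centre
            break
        if _match(seq[q], seq[p]):
            streak = 0
            length = q + 1 - lo
            if (mism + pend) / length <= 1 - min_identity:
                mism += pend
                pend = 0
                best_hi, best_mism = q + 1, mism
            else:
                break
        else:
            pend += 1
            streak += 1
            if streak > max_streak:
                break
        q += 1
    hi, mism = best_hi, best_mism
    # leftward
    q, streak, pend = lo - 1, 0, 0
    best_lo, best_mism = lo, mism
    while q >= lo_limit:
        p = d - q
        if p >= len(seq) or p <= q:
            break
        if _match(seq[q], seq[p]):
            streak = 0
            length = hi - q
            if (mism + pend) / length <= 1 - min_identity:
                mism += pend
                pend = 0
                best_lo, best_mism = q, mism
            else:
                break
        else:
            pend += 1
            streak += 1
            if streak > max_streak:
                break
        q -= 1
    return best_lo, hi, best_mism


def find_inverted_repeat(
    genome: GenomeRecord,
    min_arm: int = 1000,
    min_identity: float = 0.99,
    *,
    k: int = 21,
    max_mismatch_streak: int = 10,
    features: Optional[FeatureSet] = None,
) -> Optional[IRAnnotation]:
    """Find the highest-scoring pair of inverted-repeat arms, or None.

    Exact k-mer seeds between the sequence and its reverse complement are
    grouped by anti-diagonal and extended ungapped, allowing mismatches
    while the running identity stays above ``min_identity``. Circular
    genomes are searched over all rotations by doubling the sequence.
    Candidates are ranked by arm length, then identity, then start.
    """
    L = genome.length
    if L < 2 * min_arm:
        return None
    seq = genome.sequence + genome.sequence if genome.circular else genome.sequence
    n = len(seq)
    # index k-mers of the reverse complement; a hit at (i, j) pairs
    # seq[i:i+k] with revcomp(seq[p:p+k]) at p = n - j - k, i.e. every base
    # q in [i, i+k) pairs with d - q where d = i + p + k - 1.
    rc = seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
    index: dict[str, list[int]] = {}
    for j in range(n - k + 1):
        index.setdefault(rc[j : j + k], []).append(j)
    diags: dict[int, list[int]] = {}
    for i in range(n - k + 1):
        for j in index.get(seq[i : i + k], ()):
            p = n - j - k
            if p <= i:  # count each pair once, arm1 left of arm2
                continue
            diags.setdefault(i + p + k - 1, []).append(i)

    candidates: list[tuple[int, float, int, Interval, Interval]] = []
    seen: set[tuple[int, int]] = set()
    for d, starts in diags.items():
        starts.sort()
        # cluster seeds separated by > 2k on the same anti-diagonal
        clusters: list[list[int]] = [[starts[0]]]
        for s in starts[1:]:
            if s - clusters[-1][-1] > 2 * k:
                clusters.append([s])
            else:
                clusters[-1].append(s)
        for cl in clusters:
            lo, hi = cl[0], min(cl[-1] + k, (d + 1) // 2)
            if hi <= lo:
                continue
            lo, hi, _ = _extend(
                seq, d, lo, hi, min_identity, max_mismatch_streak,
                max(0, d - n + 1), (d + 1) // 2,
            )
            mism = sum(0 if _match(seq[q], seq[d - q]) else 1 for q in range(lo, hi))
            arm_len = hi - lo
            if arm_len < min_arm:
                continue
            ident = 1 - mism / arm_len
            if ident < min_identity:
                continue
            a1 = (lo, hi)
            a2 = (d - hi + 1, d - lo + 1)
            if a2[0] < a1[1]:  # arms overlap: degenerate palindrome
                continue
            if genome.circular:
                # normalise to arm1 start in [0, L); skip doubled duplicates
                if a1[0] >= L:
                    continue
                if a2[1] - a1[0] > L:  # pair does not fit on the circle once
                    continue
                key = (a1[0] % L, a2[0] % L)
            else:
                key = (a1[0], a2[0])
            if key in seen:
                continue
            seen.add(key)
            candidates.append((arm_len, ident, a1[0], a1, a2))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
    arm_len, ident, _, a1, a2 = candidates[0]
    if 2 * arm_len >= L:
        raise ValueError(
            "inverted repeat covers the entire genome (perfect palindrome); "
            "single-copy regions would be empty"
        )
    return _annotate(a1, a2, ident, L, features)


def _annotate(
    a1: Interval, a2: Interval, ident: float, L: int, features: Optional[FeatureSet]
) -> IRAnnotation:
    arm_len = a1[1] - a1[0]
    a1 = (a1[0] % L, a1[0] % L + arm_len)
    a2 = (a2[0] % L, a2[0] % L + arm_len)
    if a2[0] < a1[0]:
        a1, a2 = a2, a1
    sc_a = circular_gap(a1[1], a2[0], L)
    sc_b = circular_gap(a2[1], a1[0], L)
    sc1, sc2 = _name_scs(sc_a, sc_b, L, features)
    return IRAnnotation(arm1=a1, arm2=a2, sc1=sc1, sc2=sc2, identity=ident, genome_length=L)


def _name_scs(
    sc_a: Interval, sc_b: Interval, L: int, features: Optional[FeatureSet]
) -> tuple[Interval, Interval]:
    """SC1 = the single-copy region containing cox1; else the longer one."""
    if features is not None:
        for f in features:
            if f.kind in ("gene", "exon") and canonical_gene_name(f.gene or f.name) == "cox1":
                mid = (f.start + f.end) // 2
                if contains(sc_a, mid, L):
                    return sc_a, sc_b
                if contains(sc_b, mid, L):
                    return sc_b, sc_a
        log.info("cox1 not found in any single-copy region; falling back to length rule")
    else:
        log.info("no annotation supplied; SC1 = longer single-copy region")
    len_a, len_b = sc_a[1] - sc_a[0], sc_b[1] - sc_b[0]
    return (sc_a, sc_b) if len_a >= len_b else (sc_b, sc_a)


def detect_duplication_from_depth(
    depth: np.ndarray,
    fold_min: float = 1.75,
    fold_max: float = 2.5,
    min_len: int = 2000,
    *,
    smooth_window: int = 201,
) -> list[Interval]:
    """Intervals where smoothed, median-normalised depth sits near 2x.

    Emulates the assembly-time signal: a collapsed IR shows a two-fold
    coverage increase over the single-copy baseline.
    """
    depth = np.asarray(depth, dtype=float)
    if depth.size == 0 or not np.any(depth > 0):
        raise ValueError("depth track is empty or all zero")
    baseline = np.median(depth)
    if baseline <= 0:
        raise ValueError("median depth is zero; baseline not estimable")
    smoothed = median_filter(depth / baseline, size=smooth_window, mode="nearest")
    inside = (smoothed >= fold_min) & (smoothed <= fold_max)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], inside.view(np.int8), [0]))))
    out = []
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s >= min_len:
            out.append((int(s), int(e)))
    return out


@dataclass(frozen=True)
class BorderReport:
    """Flanking genes at one IR/SC border."""

    border: str  # e.g. "IR1-SC1"
    position: int
    upstream_gene: Optional[str]
    downstream_gene: Optional[str]


def partition(
    genome: GenomeRecord,
    ir: IRAnnotation,
    features: Optional[FeatureSet] = None,
) -> dict:
    """Label the four regions and, given annotation, report border genes and
    genes partially overlapping an IR arm."""
    regions = ir.regions()
    out: dict = {"regions": regions, "borders": [], "partially_overlapping": []}
    if features is None:
        return out
    L = ir.genome_length
    genes = [f for f in features if f.kind == "gene"]
    borders = {
        "SC-before-IR1/IR1": ir.arm1[0] % L,
        "IR1/SC-after-IR1": ir.arm1[1] % L,
        "SC-before-IR2/IR2": ir.arm2[0] % L,
        "IR2/SC-after-IR2": ir.arm2[1] % L,
    }
    for name, pos in borders.items():
        up = _nearest_gene(genes, pos, L, side="up")
        down = _nearest_gene(genes, pos, L, side="down")
        out["borders"].append(BorderReport(name, pos, up, down))
    for arm in (ir.arm1, ir.arm2):
        for g in genes:
            inside = contains(arm, g.start, L) or contains(arm, g.end - 1, L)
            fully = contains(arm, g.start, L) and contains(arm, g.end - 1, L)
            if inside and not fully:
                out["partially_overlapping"].append(g.name)
    return out


def _nearest_gene(genes: Sequence[Feature], pos: int, L: int, side: str) -> Optional[str]:
    best, best_d = None, None
    for g in genes:
        ref = g.end - 1 if side == "up" else g.start
        d = (pos - ref) % L if side == "up" else (ref - pos) % L
        if best_d is None or d < best_d:
            best, best_d = g.name, d
    return best
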