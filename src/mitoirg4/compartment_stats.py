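"""Exon/intron/intergenic partition, enrichment tests and IR-vs-SC densities.

The "exon" compartment is the union of conserved-gene exons plus the full
rRNA subunit spans; "intron" the introns of those genes not covered by an
exon; "intergenic" everything else. Motifs are assigned to the compartment
of their midpoint base. Observed counts are compared with expectations
proportional to compartment length using a chi-square goodness-of-fit test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .genome_io import FeatureSet, GenomeRecord, conserved_exon_set
from .intervals import Interval, linear_pieces, merge
from .ir_detect import IRAnnotation

log = logging.getLogger(__name__)

COMPARTMENTS = ("exon", "intron", "intergenic")
_CODE = {name: i for i, name in enumerate(COMPARTMENTS)}


@dataclass
class CompartmentPartition:
    """Disjoint exon/intron/intergenic intervals tiling the genome."""

    genome_length: int
    labels: np.ndarray  # int8 per-base compartment code
    intervals: dict[str, list[Interval]] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        counts = np.bincount(self.labels, minlength=3)
        return {name: int(counts[_CODE[name]]) for name in COMPARTMENTS}

    def compartment_of(self, pos: int) -> str:
        return COMPARTMENTS[self.labels[pos % self.genome_length]]

    def assert_tiles(self) -> None:
        assert sum(self.lengths.values()) == self.genome_length


@dataclass(frozen=True)
class EnrichmentResult:
    observed: dict[str, int]
    expected: dict[str, float]
    chi2: float
    df: int
    p: float
    small_expected: bool  # any retained expected count < 5


def partition_compartments(
    genome: GenomeRecord,
    features: FeatureSet,
    *,
    include_nad4L: bool = True,
    aliases: Optional[dict] = None,
) -> CompartmentPartition:
    """Partition the genome by base priority exon > intron > intergenic."""
    from .genome_io import CONSERVED_GENES, canonical_gene_name

    conserved = conserved_exon_set(features, include_nad4L=include_nad4L, aliases=aliases)
    exonic = merge(f.interval for f in conserved)
    wanted = CONSERVED_GENES if include_nad4L else CONSERVED_GENES - {"nad4L"}
    intronic = merge(
        f.interval
        for f in features
        if f.kind == "intron" and canonical_gene_name(f.gene or f.name, aliases) in wanted
    )
    labels = np.full(genome.length, _CODE["intergenic"], dtype=np.int8)
    for s, e in intronic:
        labels[s:e] = _CODE["intron"]
    for s, e in exonic:
        labels[s:e] = _CODE["exon"]
    part = CompartmentPartition(genome_length=genome.length, labels=labels)
    part.intervals = {
        name: _runs(labels, _CODE[name]) for name in COMPARTMENTS
    }
    part.assert_tiles()
    return part


def _runs(labels: np.ndarray, code: int) -> list[Interval]:
    mask = (labels == code).view(np.int8)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask, [0]))))
    return [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]


def assign_motifs(motifs: Sequence, partition: CompartmentPartition) -> dict[str, int]:
    """Observed motif counts per compartment, by midpoint base."""
    counts = {name: 0 for name in COMPARTMENTS}
    for m in motifs:
        counts[partition.compartment_of(m.midpoint)] += 1
    return counts


def expected_counts(total_motifs: int, partition: CompartmentPartition) -> dict[str, float]:
    """Counts expected under an unbiased (length-proportional) distribution."""
    if total_motifs < 0:
        raise ValueError("total_motifs must be >= 0")
    L = partition.genome_length
    return {name: total_motifs * ln / L for name, ln in partition.lengths.items()}


def chisq_enrichment(observed: dict[str, int], expected: dict[str, float]) -> EnrichmentResult:
    """Chi-square goodness of fit of observed vs expected compartment counts.

    Compartments with expected == 0 and observed == 0 are dropped;
    expected == 0 with observed > 0 is an error. df = retained - 1.
    """
    keys = [k for k in observed if not (expected.get(k, 0) == 0 and observed[k] == 0)]
    if not keys:
        raise ValueError("nothing to test: all compartments empty")
    for k in keys:
        if expected.get(k, 0) == 0 and observed[k] > 0:
            raise ValueError(f"compartment {k!r}: observed > 0 with expected == 0")
    obs = np.array([observed[k] for k in keys], dtype=float)
    exp = np.array([expected[k] for k in keys], dtype=float)
    if abs(obs.sum() - exp.sum()) > 1e-9 * max(1.0, obs.sum()):
        raise ValueError("observed and expected totals differ")
    if len(keys) == 1:
        return EnrichmentResult(dict(observed), dict(expected), 0.0, 0, 1.0, bool(exp[0] < 5))
    chi2, p = stats.chisquare(obs, exp)
    small = bool((exp < 5).any())
    if small:
        warnings.warn("expected count < 5 in at least one compartment; chi-square "
                      "approximation is weak in this regime", stacklevel=2)
    return EnrichmentResult(
        observed=dict(observed), expected=dict(expected),
        chi2=float(chi2), df=len(keys) - 1, p=float(p), small_expected=small,
    )


def enrichment_test(
    genome: GenomeRecord, features: FeatureSet, motifs: Sequence, **kw
) -> EnrichmentResult:
    """Full observed-vs-expected compartment enrichment test."""
    part = partition_compartments(genome, features, **kw)
    obs = assign_motifs(motifs, part)
    exp = expected_counts(sum(obs.values()), part)
    return chisq_enrichment(obs, exp)


def _exonic_bases_in(pieces: list[Interval], labels: np.ndarray) -> int:
    return int(sum((labels[s:e] == _CODE["exon"]).sum() for s, e in pieces))


def exon_fraction(partition: CompartmentPartition, ir: IRAnnotation) -> dict[str, float]:
    """Percent of IR (one arm) and SC (SC1+SC2) bases that are exonic."""
    L = ir.genome_length
    arm_pieces = linear_pieces(ir.arm1, L)
    sc_pieces = linear_pieces(ir.sc1, L) + linear_pieces(ir.sc2, L)
    arm_len = sum(e - s for s, e in arm_pieces)
    sc_len = sum(e - s for s, e in sc_pieces)
    return {
        "IR": 100.0 * _exonic_bases_in(arm_pieces, partition.labels) / arm_len,
        "SC": 100.0 * _exonic_bases_in(sc_pieces, partition.labels) / sc_len if sc_len else 0.0,
    }


def ir_sc_density(motifs: Sequence, ir: IRAnnotation, *, ir_copies: int = 1) -> dict[str, float]:
    """G4 motif density (per kb) inside the IR versus the single-copy regions.

    By default only motifs whose midpoint falls in arm 1 are counted against
    one arm's length, so the homogenised duplicate copies are not counted
    twice; ``ir_copies=2`` counts both arms over both lengths (a pure scale
    convention — the IR/SC comparison is unchanged).
    """
    if ir_copies not in (1, 2):
        raise ValueError("ir_copies must be 1 or 2")
    L = ir.genome_length
    arms = [ir.arm1] if ir_copies == 1 else [ir.arm1, ir.arm2]
    sc_regions = [ir.sc1, ir.sc2]
    n_ir = sum(1 for m in motifs if any(_in_region(m.midpoint, r, L) for r in arms))
    n_sc = sum(1 for m in motifs if any(_in_region(m.midpoint, r, L) for r in sc_regions))
    ir_len = sum(r[1] - r[0] for r in arms)
    sc_len = sum(r[1] - r[0] for r in sc_regions)
    return {
        "density_IR": 1000.0 * n_ir / ir_len if ir_len else 0.0,
        "density_SC": 1000.0 * n_sc / sc_len if sc_len else 0.0,
    }


def _in_region(pos: int, region: Interval, L: int) -> bool:
    from .intervals import contains

    return contains(region, pos % L, L)
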