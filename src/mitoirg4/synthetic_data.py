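"""Synthetic circular mitochondrial genomes with full ground truth.

The generator emulates the statistical structure the analysis assumes:
a circular genome of 40-250 kb, a planted two-arm inverted repeat (IR)
occupying up to roughly half the genome, conserved genes with exons and
introns plus the two rRNA subunits, G-rich/C-rich motifs planted at
controlled per-region or per-compartment densities, Poisson depth tracks
with a two-fold plateau over a collapsed IR, and paired species traits
evolving on a tree under Brownian motion.

Background sequence is i.i.d. at the requested GC content with G/C runs
capped at two bases, so background windows cannot reach the strict G4
threshold and planted motif counts are exact. Twelve-base mismatch "walls"
flank each IR arm so the planted arm ends are the unique maximal extension
endpoints. One integer seed drives a whole batch through NumPy's
SeedSequence spawning.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import dendropy
import numpy as np

from .g4scan import STRICT, window_means
from .genome_io import Feature, FeatureSet, GenomeRecord, revcomp
from .intervals import Interval, complement, merge
from .ir_detect import IRAnnotation
from .phylo_stats import PhyloTree, from_dendropy, phylo_vcv

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GeneSpec:
    """One planted gene: exon/intron layout and target region."""

    name: str
    n_exons: int = 1
    exon_len: int = 800
    intron_len: int = 0
    region: str = "SC1"  # SC1 | SC2 | IR
    kind: str = "CDS"  # CDS | rRNA

    @property
    def span(self) -> int:
        return self.n_exons * self.exon_len + (self.n_exons - 1) * self.intron_len


def default_genes() -> tuple[GeneSpec, ...]:
    """A conserved-core layout echoing the organisation of fungal mtDNA with
    a large IR: rRNA subunits and several genes inside the repeat, cox1 in
    the long single-copy region, cox3/rps3 in the other."""
    return (
        GeneSpec("cox1", 3, 500, 700, "SC1"),
        GeneSpec("nad1", 1, 900, 0, "SC1"),
        GeneSpec("nad5", 1, 1900, 0, "SC1"),
        GeneSpec("nad4L", 1, 270, 0, "SC1"),
        GeneSpec("rnl", 2, 1600, 500, "IR", kind="rRNA"),
        GeneSpec("rns", 1, 1500, 0, "IR", kind="rRNA"),
        GeneSpec("cox2", 1, 750, 0, "IR"),
        GeneSpec("nad2", 1, 1700, 0, "IR"),
        GeneSpec("nad3", 1, 400, 0, "IR"),
        GeneSpec("nad4", 1, 1450, 0, "IR"),
        GeneSpec("atp6", 1, 780, 0, "IR"),
        GeneSpec("cox3", 1, 810, 0, "SC2"),
        GeneSpec("rps3", 1, 1100, 0, "SC2"),
        GeneSpec("cob", 2, 600, 500, "SC2"),
        GeneSpec("nad6", 1, 650, 0, "SC2"),
        GeneSpec("atp8", 1, 160, 0, "SC2"),
        GeneSpec("atp9", 1, 225, 0, "SC2"),
    )


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic genome. Defaults emulate a mid-sized
    IR-bearing mitochondrial genome (150 kb, 35 kb arms, GC 0.35) with
    G4 motif densities higher inside the IR than outside (1.0 vs 0.4 per
    kb), the regime the real genomes show."""

    genome_length: int = 150_000
    gc_content: float = 0.35
    ir_arm_length: int = 35_000
    ir_mismatch_rate: float = 0.0
    genes: tuple[GeneSpec, ...] = field(default_factory=default_genes)
    g4_rate_per_kb_region: Optional[dict] = None  # {"IR": .., "SC": ..}
    g4_rate_per_kb_compartment: Optional[dict] = None  # {"exon": .., ...}
    motif_template: str = "GGGT" * 7
    depth_mean: float = 100.0
    boundary_gene: bool = False  # plant a gene straddling the arm1 start
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g4_rate_per_kb_region is None and self.g4_rate_per_kb_compartment is None:
            self.g4_rate_per_kb_region = {"IR": 1.0, "SC": 0.4}
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if self.ir_arm_length and 2 * self.ir_arm_length >= self.genome_length:
            raise ValueError("IR arms cannot cover the whole genome")
        # planted template must clear the strict threshold
        probe = "A" * 25 + self.motif_template + "A" * 25
        if float(np.abs(window_means(probe, STRICT.w)).max()) < STRICT.s:
            raise ValueError("motif_template does not reach the strict G4 threshold")


@dataclass(frozen=True)
class PlantedMotif:
    start: int
    end: int
    sign: int  # +1 G-rich on forward strand, -1 C-rich
    region: str  # IR1 | IR2 | SC1 | SC2 | SC
    compartment: str  # exon | intron | intergenic


@dataclass
class GenomeTruth:
    ir: Optional[IRAnnotation]
    motifs: list[PlantedMotif]
    spec: SyntheticSpec


_WALL = 12  # forced-mismatch bases flanking each IR arm


def _background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(_BASES, size=length, p=probs)
    # cap G/C runs at 2 so background windows stay far below threshold
    at = np.frombuffer(b"AT", dtype=np.uint8)
    while True:
        gc_mask = (arr == ord("G")) | (arr == ord("C"))
        tri = gc_mask[2:] & (arr[2:] == arr[1:-1]) & (arr[1:-1] == arr[:-2])
        pos = np.flatnonzero(tri) + 2
        if pos.size == 0:
            return arr
        arr[pos] = rng.choice(at, size=pos.size)


def _place_genes(
    genes: Sequence[GeneSpec], usable: Interval, rng: np.random.Generator
) -> list[Feature]:
    """Place genes sequentially in a region with random intergenic gaps."""
    total = sum(g.span for g in genes)
    free = (usable[1] - usable[0]) - total
    if free < 0:
        raise ValueError(
            f"genes need {total} bp but region offers {usable[1] - usable[0]} bp"
        )
    gaps = rng.multinomial(free, np.full(len(genes) + 1, 1 / (len(genes) + 1)))
    feats: list[Feature] = []
    pos = usable[0]
    for g, gap in zip(genes, gaps):
        pos += int(gap)
        feats.extend(_gene_features(g, pos, "+" if rng.random() < 0.5 else "-"))
        pos += g.span
    return feats


def _gene_features(g: GeneSpec, start: int, strand: str) -> list[Feature]:
    feats = [Feature("gene", g.name, start, start + g.span, strand, gene=g.name)]
    if g.kind == "rRNA":
        feats.append(Feature("rRNA", g.name, start, start + g.span, strand, gene=g.name))
        return feats
    pos = start
    for i in range(g.n_exons):
        feats.append(Feature("exon", f"{g.name}.e{i + 1}", pos, pos + g.exon_len, strand, gene=g.name))
        pos += g.exon_len
        if i < g.n_exons - 1:
            feats.append(
                Feature("intron", f"{g.name}.i{i + 1}", pos, pos + g.intron_len, strand, gene=g.name)
            )
            pos += g.intron_len
    return feats


def _mirror_interval(iv: Interval, arm1: Interval, arm2: Interval) -> Interval:
    """Map an interval inside arm 1 to its inverted copy inside arm 2."""
    return (arm2[0] + (arm1[1] - iv[1]), arm2[0] + (arm1[1] - iv[0]))


def _mirror_feature(f: Feature, arm1: Interval, arm2: Interval) -> Feature:
    s, e = _mirror_interval((f.start, f.end), arm1, arm2)
    return replace(f, start=s, end=e, strand="-" if f.strand == "+" else "+")


def _sample_positions(
    free: list[Interval], n: int, motif_len: int, gap: int, rng: np.random.Generator
) -> list[int]:
    """Draw n non-overlapping motif start positions from free intervals."""
    slots = [(s, e) for s, e in free if e - s >= motif_len + gap]
    out: list[int] = []
    for _ in range(n):
        if not slots:
            raise ValueError("not enough free space to plant requested motifs")
        lens = np.array([e - s - motif_len for s, e in slots], dtype=float)
        i = int(rng.choice(len(slots), p=lens / lens.sum()))
        s, e = slots[i]
        pos = int(rng.integers(s, e - motif_len + 1))
        out.append(pos)
        # split the slot, keeping a guard gap around the planted motif
        left, right = (s, pos - gap), (pos + motif_len + gap, e)
        slots.pop(i)
        for piece in (left, right):
            if piece[1] - piece[0] >= motif_len + gap:
                slots.append(piece)
    return sorted(out)


def generate_genome(
    spec: SyntheticSpec, seed: Optional[int] = None
) -> tuple[GenomeRecord, FeatureSet, GenomeTruth]:
    """Generate one genome; deterministic given (spec, seed).

    Returns the record, its annotation (both IR copies of planted genes
    annotated), and ground truth (IR coordinates, planted motif list).
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    L, A = spec.genome_length, spec.ir_arm_length
    arr = _background(rng, L, spec.gc_content)

    margin, gap = 300, 50
    if A > 0:
        rest = L - 2 * A
        s1 = int(round(rest * 0.6))
        s2 = rest - s1
        arm1, arm2 = (s1, s1 + A), (s1 + A + s2, L)
        sc1, sc2 = (0, s1), (s1 + A, s1 + A + s2)
        region_spans = {"SC1": sc1, "SC2": sc2, "IR": arm1}
    else:
        arm1 = arm2 = None
        region_spans = {"SC": (0, L), "SC1": (0, L), "SC2": (0, L), "IR": None}

    # genes
    feats: list[Feature] = []
    for region in ("SC1", "SC2", "IR"):
        glist = [g for g in spec.genes if (g.region if A > 0 else "SC1") == region]
        if not glist:
            continue
        span = region_spans[region]
        if span is None:
            raise ValueError(f"genes assigned to IR but ir_arm_length == 0")
        usable = (span[0] + margin, span[1] - margin)
        feats.extend(_place_genes(glist, usable, rng))
    if spec.boundary_gene:
        if A == 0:
            raise ValueError("boundary_gene requires an IR")
        s = arm1[0] - 400
        feats.append(Feature("gene", "nad4", s, s + 1000, "+", gene="nad4"))
        feats.append(Feature("exon", "nad4.e1", s, s + 1000, "+", gene="nad4"))

    # motifs
    template = np.frombuffer(spec.motif_template.encode(), dtype=np.uint8)
    m = template.size
    gene_blocks = merge(
        [(max(0, f.start - gap), min(L, f.end + gap)) for f in feats if f.kind == "gene"]
    )
    motifs: list[PlantedMotif] = []

    def free_in(span: Interval, blocked: list[Interval]) -> list[Interval]:
        edge = 60
        inner = (span[0] + edge, span[1] - edge)
        pieces = []
        for s, e in complement(blocked, L):
            s2_, e2_ = max(s, inner[0]), min(e, inner[1])
            if e2_ > s2_:
                pieces.append((s2_, e2_))
        return pieces

    def plant(span: Interval, n: int, region_name: str, compartment: str,
              blocked: list[Interval]) -> None:
        if n <= 0:
            return
        positions = _sample_positions(free_in(span, blocked), n, m, gap, rng)
        for pos in positions:
            arr[pos : pos + m] = template
            motifs.append(PlantedMotif(pos, pos + m, +1, region_name, compartment))

    if spec.g4_rate_per_kb_region is not None:
        rates = spec.g4_rate_per_kb_region
        if A > 0:
            n_ir = int(round(rates.get("IR", 0) * A / 1000))
            plant(arm1, n_ir, "IR1", "intergenic", gene_blocks)
            sc_len = (sc1[1] - sc1[0]) + (sc2[1] - sc2[0])
            n_sc = int(round(rates.get("SC", 0) * sc_len / 1000))
            n_sc1 = int(round(n_sc * (sc1[1] - sc1[0]) / sc_len)) if sc_len else 0
            plant(sc1, n_sc1, "SC1", "intergenic", gene_blocks)
            plant(sc2, n_sc - n_sc1, "SC2", "intergenic", gene_blocks)
        else:
            n_sc = int(round(rates.get("SC", 0) * L / 1000))
            plant((0, L), n_sc, "SC", "intergenic", gene_blocks)
    if spec.g4_rate_per_kb_compartment is not None:
        comp_intervals = {
            "exon": merge(f.interval for f in feats if f.kind in ("exon", "rRNA")),
            "intron": merge(f.interval for f in feats if f.kind == "intron"),
        }
        comp_intervals["intergenic"] = complement(
            comp_intervals["exon"] + comp_intervals["intron"], L
        )
        placed = [(mo.start - gap, mo.end + gap) for mo in motifs]
        if A > 0:
            # arm 2 is rewritten as revcomp(arm 1) below; compartment-rate
            # planting stays in single-copy DNA so the truth list is exact
            placed = placed + [arm1, arm2]
        for comp, rate in spec.g4_rate_per_kb_compartment.items():
            total = sum(e - s for s, e in comp_intervals[comp])
            n = int(round(rate * total / 1000))
            if n <= 0:
                continue
            blocked = placed if comp != "intergenic" else merge(gene_blocks + placed)
            # plant inside the compartment's own intervals
            free = []
            for s, e in comp_intervals[comp]:
                for fs, fe in complement(blocked, L):
                    a, b = max(s, fs), min(e, fe)
                    if b - a >= m + 2 * gap:
                        free.append((a + gap, b - gap))
            positions = _sample_positions(free, n, m, gap, rng)
            for pos in positions:
                arr[pos : pos + m] = template
                motifs.append(PlantedMotif(pos, pos + m, +1, "SC", comp))
                placed.append((pos - gap, pos + m + gap))

    truth_ir = None
    if A > 0:
        # build arm 2 as the (possibly mismatched) reverse complement of arm 1
        arm_seq = arr[arm1[0] : arm1[1]].tobytes().decode()
        arm2_seq = np.frombuffer(revcomp(arm_seq).encode(), dtype=np.uint8).copy()
        n_mis = 0
        if spec.ir_mismatch_rate > 0:
            protected = np.zeros(A, dtype=bool)
            for mo in [mo for mo in motifs if mo.region == "IR1"]:
                ms, me = _mirror_interval((mo.start, mo.end), arm1, arm2)
                protected[ms - arm2[0] : me - arm2[0]] = True
            candidates = np.flatnonzero(~protected)
            want = int(round(spec.ir_mismatch_rate * A))
            chosen = rng.choice(candidates, size=min(want, candidates.size), replace=False)
            for c in chosen:
                others = _BASES[_BASES != arm2_seq[c]]
                arm2_seq[c] = rng.choice(others)
            n_mis = chosen.size
        arr[arm2[0] : arm2[1]] = arm2_seq
        # mirror planted arm-1 motifs and gene annotation into arm 2
        for mo in [mo for mo in motifs if mo.region == "IR1"]:
            ms, me = _mirror_interval((mo.start, mo.end), arm1, arm2)
            motifs.append(PlantedMotif(ms, me, -mo.sign, "IR2", mo.compartment))
        for f in [f for f in feats if arm1[0] <= f.start and f.end <= arm1[1]]:
            feats.append(_mirror_feature(f, arm1, arm2))
        _plant_walls(arr, arm1, arm2, L, rng)
        ident = 1 - n_mis / A
        truth_ir = IRAnnotation(
            arm1=arm1, arm2=arm2, sc1=sc1, sc2=sc2, identity=ident, genome_length=L
        )

    genome = GenomeRecord(id=f"synthetic_{seed}", sequence=arr.tobytes().decode(), circular=True)
    featset = FeatureSet(genome_id=genome.id, features=sorted(feats, key=lambda f: f.start))
    motifs.sort(key=lambda mo: mo.start)
    return genome, featset, GenomeTruth(ir=truth_ir, motifs=motifs, spec=spec)


def _plant_walls(
    arr: np.ndarray, arm1: Interval, arm2: Interval, L: int, rng: np.random.Generator
) -> None:
    """Force mismatches flanking both arms so extension stops at the planted
    ends. Base q pairs with s1 + L - 1 - q (mod L) on the IR anti-diagonal;
    walls use A/T to avoid creating G/C runs."""
    comp = {ord("A"): ord("T"), ord("C"): ord("G"), ord("G"): ord("C"), ord("T"): ord("A")}
    pairs = []
    for j in range(_WALL):
        pairs.append(((arm1[0] - 1 - j) % L, (arm2[1] + j) % L))  # outward left of arm1
        pairs.append(((arm1[1] + j) % L, (arm2[0] - 1 - j) % L))  # outward right of arm1
    for q, p in pairs:
        partner = arr[p]
        forbidden = comp[int(partner)]
        choice = [b for b in (ord("A"), ord("T")) if b != forbidden]
        arr[q] = choice[0] if len(choice) == 1 else int(rng.choice(choice))


def generate_depth(
    genome_length: int,
    ir: Optional[IRAnnotation],
    depth_mean: float,
    seed: int,
    *,
    collapsed: bool = True,
) -> tuple[np.ndarray, Optional[Interval]]:
    """Poisson depth track emulating a collapsed-IR assembly.

    With an IR and ``collapsed=True`` the track covers the genome minus the
    second arm (its coordinates are absent from the collapsed assembly) and
    shows Poisson(2 * depth_mean) over arm 1. Returns the track and the
    arm-1 interval in track coordinates (None without an IR).
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if ir is None:
        return rng.poisson(depth_mean, size=genome_length).astype(float), None
    if collapsed:
        keep = genome_length - ir.arm_length  # arm 2 dropped
        track = rng.poisson(depth_mean, size=keep).astype(float)
        a1 = ir.arm1 if ir.arm1[1] <= ir.arm2[0] else ir.arm2
        track[a1[0] : a1[1]] = rng.poisson(2 * depth_mean, size=a1[1] - a1[0])
        return track, a1
    track = rng.poisson(depth_mean, size=genome_length).astype(float)
    return track, ir.arm1


def yule_tree(n_tips: int, seed: int, *, birth_rate: float = 1.0) -> PhyloTree:
    """A random pure-birth tree with ``n_tips`` extant tips (labels t1..tn)."""
    from dendropy.simulate import treesim

    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_tips)])
    pyrng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_tips,
        taxon_namespace=taxa, rng=pyrng,
    )
    # the simulation stops exactly at the n-th speciation, leaving a
    # zero-length terminal pair (singular covariance); complete the final
    # waiting interval so all terminal branches are strictly positive
    extra = pyrng.expovariate(n_tips * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    return from_dendropy(tree)


def simulate_paired_traits(
    tree: PhyloTree,
    mu: float,
    sigma: float,
    lam: float,
    seed: int,
    *,
    sigma_base: float = 1.0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Paired species traits: y is Brownian on the tree, x = y + d with
    d ~ MVN(mu * 1, sigma^2 * V(lambda))."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = tree.n_tips
    V1 = tree.vcv + 1e-12 * np.eye(n)
    y = np.linalg.cholesky(sigma_base**2 * V1) @ rng.standard_normal(n)
    Vl = phylo_vcv(tree, lam) + 1e-12 * np.eye(n)
    d = mu + np.linalg.cholesky(sigma**2 * Vl) @ rng.standard_normal(n)
    x = y + d
    labels = tree.tip_labels
    return dict(zip(labels, x)), dict(zip(labels, y))
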