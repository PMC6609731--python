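"""Genome and annotation ingest, the shared data model, and flat-file output.

Coordinates are 0-based half-open everywhere inside the package; conversion
from the 1-based inclusive GFF3/GenBank convention happens only here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

from .intervals import Interval, merge

log = logging.getLogger(__name__)

_VALID = set("ACGTN")
_COMP = str.maketrans("ACGTN", "TGCAN")

#: Conserved protein-coding genes whose exons define the "exon" compartment.
#: nad4L is included by default (present in the conserved core of fungal
#: mtDNA) but can be toggled off.
CONSERVED_GENES = frozenset(
    {
        "cox1", "cox2", "cox3",
        "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
        "atp6", "atp8", "atp9",
        "cob", "rps3",
    }
)

#: rRNA subunits whose full spans count as exonic DNA (large, functional
#: transcripts).
RRNA_GENES = frozenset({"rns", "rnl"})

#: Alias table: normalized (lowercase, alphanumeric-only) name -> canonical.
DEFAULT_ALIASES = {
    "cytb": "cob", "cytochromeb": "cob", "cob": "cob", "cytochromeoxidase1": "cox1",
    "co1": "cox1", "coi": "cox1", "coxi": "cox1",
    "co2": "cox2", "coii": "cox2", "coxii": "cox2",
    "co3": "cox3", "coiii": "cox3", "coxiii": "cox3",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4L", "nad4l": "nad4L", "nd5": "nad5", "nd6": "nad6",
    "atpase6": "atp6", "atpase8": "atp8", "atpase9": "atp9",
    "rrnl": "rnl", "lsu": "rnl", "23srrna": "rnl", "rrn23": "rnl", "rrn26": "rnl",
    "largesubunitribosomalrna": "rnl",
    "rrns": "rns", "ssu": "rns", "16srrna": "rns", "rrn16": "rns", "rrn18": "rns",
    "smallsubunitribosomalrna": "rns",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """A named nucleotide sequence with circular/linear topology."""

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(f"genome {self.id!r}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gc_content(self) -> float:
        s = self.sequence
        acgt = sum(s.count(b) for b in "ACGT")
        return (s.count("G") + s.count("C")) / acgt if acgt else 0.0


@dataclass(frozen=True)
class Feature:
    """A typed, stranded interval; exon/intron features carry their gene."""

    kind: str  # gene | exon | intron | rRNA | other
    name: str
    start: int
    end: int
    strand: str = "+"
    gene: Optional[str] = None
    group: Optional[str] = None  # shared id for wrap-split halves

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"feature {self.name!r}: bad interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name!r}: bad strand {self.strand!r}")

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)


@dataclass
class FeatureSet:
    genome_id: str
    features: list[Feature] = field(default_factory=list)

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def of_kind(self, *kinds: str) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]

    def validate_against(self, genome: GenomeRecord) -> None:
        for f in self.features:
            if f.end > genome.length:
                raise ValueError(
                    f"feature {f.name!r} [{f.start},{f.end}) exceeds genome length {genome.length}"
                )


def normalize_sequence(raw: str, *, id: str = "?") -> str:
    """Uppercase and map non-ACGTN ambiguity codes to N (with a warning)."""
    seq = raw.upper()
    extra = set(seq) - _VALID
    if extra:
        log.warning("genome %s: mapping ambiguity codes %s to N", id, sorted(extra))
        seq = seq.translate(str.maketrans({c: "N" for c in extra}))
    return seq


def read_genome(path: str | Path, format: str = "fasta", *, circular: Optional[bool] = None) -> GenomeRecord:
    """Read exactly one record from a FASTA or GenBank flat file.

    GenBank topology ("circular" in the LOCUS line) is honored; FASTA
    defaults to linear unless ``circular`` is passed.
    """
    fmt = format.lower()
    if fmt not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format {format!r}")
    records = list(SeqIO.parse(str(path), fmt))
    if len(records) == 0:
        raise ValueError(f"{path}: no records found")
    if len(records) > 1:
        raise ValueError(f"{path}: expected exactly one record, found {len(records)}")
    rec = records[0]
    if circular is None:
        if fmt == "genbank":
            circular = rec.annotations.get("topology", "linear") == "circular"
        else:
            circular = False
    seq = normalize_sequence(str(rec.seq), id=rec.id)
    return GenomeRecord(id=rec.id, sequence=seq, circular=bool(circular))


def _segments_to_features(
    name: str, segments: list[Interval], strand: str, gene: Optional[str]
) -> list[Feature]:
    """One exon per segment plus one intron per inter-segment gap."""
    segments = sorted(segments)
    out: list[Feature] = []
    for i, (s, e) in enumerate(segments):
        out.append(Feature("exon", f"{name}.e{i + 1}", s, e, strand, gene=gene))
    for i in range(len(segments) - 1):
        gap = (segments[i][1], segments[i + 1][0])
        if gap[1] > gap[0]:
            out.append(Feature("intron", f"{name}.i{i + 1}", gap[0], gap[1], strand, gene=gene))
    return out


def _split_wrapping(kind, name, start, end, strand, gene, length) -> list[Feature]:
    """Split a feature extending past the genome end into two grouped halves."""
    if end <= length:
        return [Feature(kind, name, start, end, strand, gene=gene)]
    gid = f"{name}.wrap"
    return [
        Feature(kind, name, start, length, strand, gene=gene, group=gid),
        Feature(kind, name, 0, end - length, strand, gene=gene, group=gid),
    ]


def read_features(
    path: str | Path,
    format: str = "gff3",
    *,
    genome: Optional[GenomeRecord] = None,
) -> FeatureSet:
    """Read GFF3 or GenBank features into a FeatureSet (0-based half-open).

    A GenBank CDS with a multi-segment (join) location yields one exon per
    segment and one intron per gap. Features extending past the genome end
    are split in two when the genome is circular, rejected otherwise.
    """
    fmt = format.lower()
    if fmt == "gff3":
        return _read_gff3(path, genome=genome)
    if fmt == "genbank":
        return _read_genbank_features(path, genome=genome)
    raise ValueError(f"unsupported annotation format {format!r}")


_GFF_KINDS = {"gene": "gene", "exon": "exon", "intron": "intron", "rRNA": "rRNA"}


def _read_gff3(path: str | Path, genome: Optional[GenomeRecord]) -> FeatureSet:
    import gffutils

    feats: list[Feature] = []
    genome_id = genome.id if genome else ""
    length = genome.length if genome else None
    circular = genome.circular if genome else False
    path = str(path)
    try:
        iterator = list(gffutils.DataIterator(path))
    except Exception:  # empty file: gffutils chokes on no-directive empties
        iterator = []
    for rec in iterator:
        kind = _GFF_KINDS.get(rec.featuretype, "other")
        name = (
            rec.attributes.get("Name", [None])[0]
            or rec.attributes.get("ID", [None])[0]
            or rec.featuretype
        )
        gene = rec.attributes.get("gene", [None])[0] or rec.attributes.get("Parent", [None])[0]
        if not genome_id:
            genome_id = rec.seqid
        start, end = rec.start - 1, rec.end  # 1-based inclusive -> half-open
        strand = rec.strand if rec.strand in "+-" else "+"
        if length is not None and end > length:
            if not circular:
                raise ValueError(f"feature {name!r} exceeds linear genome length {length}")
            feats.extend(_split_wrapping(kind, name, start, end, strand, gene, length))
        else:
            feats.append(Feature(kind, name, start, end, strand, gene=gene))
    return FeatureSet(genome_id=genome_id, features=feats)


def _read_genbank_features(path: str | Path, genome: Optional[GenomeRecord]) -> FeatureSet:
    recs = list(SeqIO.parse(str(path), "genbank"))
    if len(recs) != 1:
        raise ValueError(f"{path}: expected exactly one GenBank record, found {len(recs)}")
    rec = recs[0]
    length = len(rec.seq)
    circular = rec.annotations.get("topology", "linear") == "circular"
    if genome is not None:
        length, circular = genome.length, genome.circular
    feats: list[Feature] = []
    for ft in rec.features:
        if ft.type in ("source",):
            continue
        strand = "-" if (ft.location.strand or 1) < 0 else "+"
        name = (
            ft.qualifiers.get("gene", [None])[0]
            or ft.qualifiers.get("product", [None])[0]
            or ft.qualifiers.get("locus_tag", [ft.type])[0]
        )
        parts = sorted((int(p.start), int(p.end)) for p in ft.location.parts)
        if ft.type == "CDS" and len(parts) > 1:
            feats.extend(_segments_to_features(name, parts, strand, gene=name))
        elif ft.type in ("CDS", "exon"):
            for s, e in parts:
                feats.extend(_split_wrapping("exon", name, s, e, strand, name, length)
                             if e > length and circular
                             else [Feature("exon", name, s, e, strand, gene=name)])
        elif ft.type == "rRNA":
            s, e = parts[0][0], parts[-1][1]
            feats.append(Feature("rRNA", name, s, e, strand, gene=name))
        elif ft.type == "gene":
            s, e = parts[0][0], parts[-1][1]
            feats.append(Feature("gene", name, s, e, strand, gene=name))
        elif ft.type == "intron":
            for s, e in parts:
                feats.append(Feature("intron", name, s, e, strand, gene=name))
        else:
            s, e = parts[0][0], parts[-1][1]
            feats.append(Feature("other", name, s, e, strand, gene=name))
    return FeatureSet(genome_id=rec.id, features=feats)


def canonical_gene_name(name: Optional[str], aliases: Optional[dict] = None) -> Optional[str]:
    """Map a gene name to its canonical form via the (extensible) alias table."""
    if name is None:
        return None
    norm = "".join(ch for ch in name.lower() if ch.isalnum())
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update({
            "".join(ch for ch in k.lower() if ch.isalnum()): v for k, v in aliases.items()
        })
    if norm in table:
        return table[norm]
    for canon in CONSERVED_GENES | RRNA_GENES:
        if norm == canon.lower():
            return canon
    return None


def conserved_exon_set(
    features: FeatureSet,
    *,
    include_nad4L: bool = True,
    aliases: Optional[dict] = None,
) -> FeatureSet:
    """Exons of the conserved protein-coding genes plus full rns/rnl spans.

    Conserved set: cox1-3, nad1-6 (optionally nad4L), atp6/8/9, cob, rps3;
    the two rRNA subunits count with their full spans.
    """
    wanted = set(CONSERVED_GENES)
    if not include_nad4L:
        wanted.discard("nad4L")
    out: list[Feature] = []
    for f in features:
        canon = canonical_gene_name(f.gene or f.name, aliases)
        if canon is None:
            continue
        if f.kind == "exon" and canon in wanted:
            out.append(f)
        elif canon in RRNA_GENES and f.kind in ("rRNA", "gene", "exon"):
            out.append(f)
    return FeatureSet(genome_id=features.genome_id, features=out)


def conserved_completeness(
    features: FeatureSet, *, include_nad4L: bool = True, aliases: Optional[dict] = None
) -> dict[str, bool]:
    """Which members of the conserved gene set were found in the annotation."""
    wanted = sorted((CONSERVED_GENES if include_nad4L else CONSERVED_GENES - {"nad4L"}) | RRNA_GENES)
    present = {
        canonical_gene_name(f.gene or f.name, aliases) for f in features
    }
    return {g: g in present for g in wanted}


def write_gff3(features: FeatureSet, path: str | Path, *, source: str = "mitoirg4") -> None:
    """Emit a fixed-dialect GFF3 (1-based inclusive, Name/gene attributes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"Name={f.name}"
            if f.gene:
                attrs += f";gene={f.gene}"
            if f.group:
                attrs += f";group={f.group}"
            fh.write(
                "\t".join(
                    [
                        features.genome_id or "genome",
                        source,
                        f.kind if f.kind != "other" else "region",
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def write_bed(
    intervals: Sequence,
    path: str | Path,
    *,
    chrom: str = "genome",
    name_prefix: str = "G4",
    track_name: str = "mitoirg4",
) -> None:
    """Write scored intervals as BED6 plus a full-precision sidecar TSV.

    Each element needs ``start``, ``end``, ``score`` (signed) attributes or is
    a ``(start, end, score)`` tuple. The BED score column is the score scaled
    by 1000 and truncated to an integer; the sidecar ``<path>.tsv`` keeps full
    precision.
    """
    rows = []
    for i, iv in enumerate(intervals, start=1):
        if hasattr(iv, "start"):
            s, e, sc = iv.start, iv.end, iv.score
        else:
            s, e, sc = iv
        strand = "+" if sc >= 0 else "-"
        rows.append((s, e, f"{name_prefix}_{i}", int(sc * 1000), strand, sc))
    with open(path, "w") as fh:
        fh.write(f'track name="{track_name}"\n')
        for s, e, nm, isc, strand, _ in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{nm}\t{isc}\t{strand}\n")
    with open(f"{path}.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tname\tscore\tlength\tstrand\n")
        for s, e, nm, _, strand, sc in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{nm}\t{sc:.6g}\t{e - s}\t{strand}\n")


def union_exonic_intervals(exons: Iterable[Feature]) -> list[Interval]:
    """Merged genomic intervals covered by a collection of exon features."""
    return merge(f.interval for f in exons)
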