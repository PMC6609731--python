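"""Generate the synthetic species cohort and summarise what was planted.

Writes results/cohort_genomes.tsv (one row per species: genome size, GC,
IR arm length, planted motif counts per region) and drops the FASTA/GFF3
flat files under scratch/cohort/ for anyone who wants to poke at them with
other tools.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _cohort import RESULTS, cohort

from mitoirg4.genome_io import write_gff3

SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "cohort"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
    rows = []
    for label, genome, feats, truth in cohort():
        n_ir = sum(m.region in ("IR1", "IR2") for m in truth.motifs)
        n_sc = len(truth.motifs) - n_ir
        rows.append(
            (label, genome.length, round(100 * genome.gc_content(), 1),
             truth.ir.arm_length, n_ir, n_sc)
        )
        with open(SCRATCH / f"{label}.fasta", "w") as fh:
            fh.write(f">{label}\n")
            for i in range(0, genome.length, 70):
                fh.write(genome.sequence[i : i + 70] + "\n")
        write_gff3(feats, SCRATCH / f"{label}.gff3")
    out = RESULTS / "cohort_genomes.tsv"
    with open(out, "w") as fh:
        fh.write("species\tgenome_bp\tgc_pct\tir_arm_bp\tplanted_motifs_ir\tplanted_motifs_sc\n")
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
    print(f"wrote {out} ({len(rows)} species); flat files under {SCRATCH}")
    sizes = [r[1] for r in rows]
    print(f"genome sizes {min(sizes):,}-{max(sizes):,} bp; "
          f"IR arms {min(r[3] for r in rows):,}-{max(r[3] for r in rows):,} bp")


if __name__ == "__main__":
    main()
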