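"""Shared synthetic cohort for the numbered analysis scripts.

Nine IR-bearing "species" (100-200 kb genomes, 20-50 kb arms, G4 motifs
planted at 1.0/kb inside the IR vs 0.4/kb outside) plus a pure-birth tree
relating them. Everything is regenerated deterministically from one master
seed, so each script can be run independently.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from mitoirg4.synthetic_data import SyntheticSpec, generate_genome, yule_tree

MASTER_SEED = 20240901
RESULTS = Path(__file__).resolve().parent.parent / "results"


def cohort():
    """Yield (label, genome, features, truth) for the nine species."""
    rng = np.random.default_rng(np.random.SeedSequence(MASTER_SEED))
    out = []
    for i in range(9):
        L = int(rng.integers(100_000, 200_001))
        arm = int(rng.integers(20_000, min(50_000, (L - 10_000) // 2) + 1))
        spec = SyntheticSpec(
            genome_length=L,
            ir_arm_length=arm,
            g4_rate_per_kb_region={"IR": 1.0, "SC": 0.4},
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append((f"sp{i + 1}", *generate_genome(spec)))
    return out


def cohort_tree():
    return yule_tree(9, seed=MASTER_SEED)


def relabel_tree_tips(tree):
    """Map the generic tip labels t1..t9 onto the species labels sp1..sp9."""
    return {f"t{i}": f"sp{i}" for i in range(1, 10)}
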