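"""Run-based G4 scoring, window merging, dedup rule and densities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoirg4.genome_io import GenomeRecord, revcomp
from mitoirg4.g4scan import (
    G4Motif,
    STRICT,
    ScanParams,
    base_scores,
    deduplicate,
    density,
    detect_motifs,
)

SEQS = st.text(alphabet="ACGTN", min_size=1, max_size=300)


def brute_force_regions(seq: str, w: int, s: float) -> list[tuple[int, int, float]]:
    """Independent oracle: per-base scores via explicit run walking, every
    window enumerated, naive merge of adjacent same-sign hits."""
    scores = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = j - i
        val = 0
        if seq[i] == "G":
            val = min(run, 4)
        elif seq[i] == "C":
            val = -min(run, 4)
        scores.extend([val] * run)
        i = j
    hits = []
    for start in range(n - w + 1):
        m = sum(scores[start : start + w]) / w
        if abs(m) >= s:
            hits.append((start, m))
    regions = []
    for start, m in hits:
        sign = m >= 0
        if regions and start <= regions[-1][1] and sign == (regions[-1][2] >= 0):
            prev = regions[-1]
            peak = m if abs(m) > abs(prev[2]) else prev[2]
            regions[-1] = (prev[0], start + w, peak)
        else:
            regions.append((start, start + w, m))
    return regions


class TestBaseScores:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AATT", [0, 0, 0, 0]),
            ("GGGT", [3, 3, 3, 0]),
            ("CCCCC", [-4, -4, -4, -4, -4]),  # run of 5 capped at 4
            ("GCGC", [1, -1, 1, -1]),
            ("GGNNGG", [2, 2, 0, 0, 2, 2]),  # N breaks runs, scores 0
        ],
    )
    def test_scoring_table(self, seq, expected):
        assert base_scores(seq).tolist() == expected

    @given(SEQS)
    @settings(max_examples=60, deadline=None)
    def test_strand_antisymmetry(self, seq):
        fwd = base_scores(seq)
        rev = base_scores(revcomp(seq))
        assert np.array_equal(rev, -fwd[::-1])


class TestDetectMotifs:
    def test_all_a_genome_no_hits(self):
        assert detect_motifs(GenomeRecord("g", "A" * 25)) == []

    def test_known_region_score(self):
        # (GGGT)x6 + G: six 3-runs plus one lone G -> mean (6*9 + 1)/25 = 2.2
        g = GenomeRecord("g", "GGGTGGGTGGGTGGGTGGGTGGGTG")
        motifs = detect_motifs(g, STRICT)
        assert len(motifs) == 1
        assert motifs[0].score == pytest.approx(2.2)

    def test_all_c_genome(self):
        motifs = detect_motifs(GenomeRecord("g", "C" * 25), STRICT)
        assert len(motifs) == 1 and motifs[0].score == pytest.approx(-4.0)

    def test_short_genome_warns_empty(self):
        assert detect_motifs(GenomeRecord("g", "G" * 10), STRICT) == []

    def test_sign_change_terminates_region(self):
        seq = "G" * 30 + "C" * 30
        motifs = detect_motifs(GenomeRecord("g", seq), STRICT)
        signs = sorted(m.score > 0 for m in motifs)
        assert len(motifs) == 2 and signs == [False, True]

    def test_monotone_in_threshold(self, standard_synthetic):
        genome, _, _ = standard_synthetic
        strict = detect_motifs(genome, STRICT)
        relaxed = detect_motifs(genome, ScanParams(s=1.2))
        # every strict region lies inside some relaxed region
        for m in strict:
            assert any(r.start <= m.start and m.end <= r.end for r in relaxed)
        assert len(relaxed) >= len(strict)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_revcomp_mirror_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 500, p=[0.3, 0.2, 0.3, 0.2]))
        fwd = detect_motifs(GenomeRecord("f", seq), ScanParams(s=1.2))
        rev = detect_motifs(GenomeRecord("r", revcomp(seq)), ScanParams(s=1.2))
        n = len(seq)
        mirrored = sorted((n - m.end, n - m.start, -m.score) for m in rev)
        assert mirrored == sorted((m.start, m.end, m.score) for m in fwd)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(1000 + seed)
        seq = "".join(rng.choice(list("ACGT"), 2000, p=[0.25, 0.3, 0.3, 0.15]))
        got = detect_motifs(GenomeRecord("g", seq), ScanParams(w=25, s=1.2))
        exp = brute_force_regions(seq, 25, 1.2)
        assert [(m.start, m.end) for m in got] == [(s, e) for s, e, _ in exp]
        for m, (_, _, peak) in zip(got, exp):
            assert m.score == pytest.approx(peak)

    def test_circular_wrap_merges_origin(self):
        seq = "G" * 8 + "A" * 200 + "G" * 8
        lin = detect_motifs(GenomeRecord("g", seq, circular=True), STRICT)
        wrapped = detect_motifs(
            GenomeRecord("g", seq, circular=True), ScanParams(s=1.7, circular=True)
        )
        assert lin == []  # an 8-base run alone cannot fill a 25-nt window
        # across the origin the two runs fuse into one 16-G tract
        assert len(wrapped) == 1 and wrapped[0].end > len(seq)


class TestDeduplicate:
    def test_majority_overlap_eliminated(self):
        m = [G4Motif(0, 100, 2.0), G4Motif(40, 140, 2.0)]
        kept = deduplicate(m, 0.5)
        assert kept == [G4Motif(0, 100, 2.0)]  # 60% overlap > 50%

    def test_exactly_half_overlap_retained(self):
        m = [G4Motif(0, 100, 2.0), G4Motif(50, 150, 2.0)]
        assert len(deduplicate(m, 0.5)) == 2  # rule is strictly >

    def test_empty(self):
        assert deduplicate([], 0.5) == []

    def test_stronger_motif_wins(self):
        m = [G4Motif(0, 100, 1.8), G4Motif(10, 110, 3.5)]
        kept = deduplicate(m, 0.5)
        assert kept == [G4Motif(10, 110, 3.5)]

    @given(st.lists(
        st.tuples(st.integers(0, 500), st.integers(5, 80), st.floats(1.2, 4.0)),
        max_size=20,
    ))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, raw):
        motifs = [G4Motif(s, s + ln, sc) for s, ln, sc in raw]
        once = deduplicate(motifs, 0.5)
        assert deduplicate(once, 0.5) == once


class TestDensity:
    @pytest.mark.parametrize("n,length,expected", [(0, 10000, 0.0), (5, 10000, 0.5)])
    def test_arithmetic(self, n, length, expected):
        assert density([None] * n, length) == pytest.approx(expected)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            density([], 0)
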