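import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from consreg.io_formats import MotifModel
from consreg.patterns import ConservedPattern
from consreg.tfbs import (
    pwm_to_logodds,
    reverse_complement,
    scan_all,
    scan_pattern,
    window_score,
)

from .conftest import naive_pwm_hits


def sharp_motif(consensus, sharpness=1.0, motif_id="M1", family="Fam", tfs=("TF1",)):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    off = (1.0 - sharpness) / 3.0
    mat = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus):
        mat[i, idx[b]] = sharpness
    return MotifModel(motif_id, list(tfs), family, mat)


class TestLogOdds:
    def test_uniform_motif_scores_zero(self):
        m = MotifModel("U", ["T"], "F", np.full((10, 4), 0.25))
        lom = pwm_to_logodds(m, pseudocount=0.01)
        np.testing.assert_allclose(lom.scores, 0.0, atol=1e-12)
        lom2 = pwm_to_logodds(m, pseudocount=0.5)
        np.testing.assert_allclose(lom2.scores, 0.0, atol=1e-12)

    def test_certain_base_score_closed_form(self):
        m = sharp_motif("A" * 10)
        lom = pwm_to_logodds(m, pseudocount=0.01)
        expected = math.log2(1.0025 / (1.01 * 0.25))  # ~1.98949 bits
        assert lom.scores[0, 0] == pytest.approx(expected, abs=1e-6)
        assert lom.max_score == pytest.approx(10 * expected, abs=1e-6)

    def test_scores_monotone_in_probability(self):
        ps = np.linspace(0.05, 0.95, 10)
        scores = []
        for p in ps:
            rest = (1 - p) / 3
            m = MotifModel("M", ["T"], "F", np.array([[p, rest, rest, rest]]))
            scores.append(pwm_to_logodds(m).scores[0, 0])
        assert all(a < b for a, b in zip(scores, scores[1:]))

    def test_nonpositive_pseudocount_rejected(self):
        m = sharp_motif("ACGTACGTAC")
        with pytest.raises(ValueError):
            pwm_to_logodds(m, pseudocount=0.0)


class TestScanPattern:
    def test_motif_narrower_than_min_width_never_matches(self):
        m = sharp_motif("ACGTACGT")  # width 8 < 10
        lom = pwm_to_logodds(m)
        assert scan_pattern("ACGTACGT" * 5, lom, threshold=-100.0) == []

    def test_consensus_scores_above_default_threshold(self):
        m = sharp_motif("ACGTTGCAGT")
        lom = pwm_to_logodds(m)
        hits = scan_pattern("ACGTTGCAGT", lom, strands="+")
        assert len(hits) == 1
        assert hits[0].score == pytest.approx(10 * math.log2(1.0025 / (1.01 * 0.25)), abs=1e-6)
        assert hits[0].score >= 10.0

    def test_reverse_strand_hit_reported_in_forward_coordinates(self):
        consensus = "ACGTTGCAGTCC"
        m = sharp_motif(consensus)
        lom = pwm_to_logodds(m)
        seq = "TTTT" + reverse_complement(consensus) + "TTTT"
        hits = scan_pattern(seq, lom, strands="both")
        assert [(h.offset, h.strand) for h in hits] == [(4, "-")]
        assert reverse_complement(seq[4 : 4 + len(consensus)]) == consensus

    def test_hit_score_recomputable_from_subsequence(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 80))
        m = sharp_motif("ACGTACGTACGT", sharpness=0.6)
        lom = pwm_to_logodds(m)
        for h in scan_pattern(seq, lom, threshold=-5):
            if h.strand == "+":
                assert window_score(seq, lom, h.offset) == pytest.approx(h.score, abs=1e-9)
            else:
                sub = reverse_complement(seq[h.offset : h.offset + lom.width])
                assert window_score(sub, lom, 0) == pytest.approx(h.score, abs=1e-9)

    def test_short_sequence_gives_empty_list(self):
        lom = pwm_to_logodds(sharp_motif("ACGTACGTAC"))
        assert scan_pattern("ACG", lom) == []

    def test_windows_with_n_never_match(self):
        lom = pwm_to_logodds(sharp_motif("ACGTACGTAC"))
        assert scan_pattern("ACGTNCGTAC", lom, threshold=-100) == []

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 100_000))
    def test_matches_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 120))
        seq = "".join(rng.choice(list("ACGT"), n))
        w = int(rng.integers(10, 16))
        mat = rng.dirichlet(np.full(4, 0.5), size=w)
        m = MotifModel("M", ["T"], "F", mat)
        threshold = float(rng.uniform(-5, 12))
        lom = pwm_to_logodds(m)
        got = [(h.offset, h.strand, h.score) for h in scan_pattern(seq, lom, threshold=threshold)]
        want = naive_pwm_hits(seq, mat.tolist(), threshold, 10)
        assert [(o, s) for o, s, _ in sorted(got)] == [(o, s) for o, s, _ in want]
        for (_, _, a), (_, _, b) in zip(sorted(got), want):
            assert a == pytest.approx(b, abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 100_000))
    def test_threshold_and_strand_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 60))
        lom = pwm_to_logodds(sharp_motif("ACGTACGTACGT", sharpness=0.7))
        lo = {(h.offset, h.strand) for h in scan_pattern(seq, lom, threshold=2.0)}
        hi = {(h.offset, h.strand) for h in scan_pattern(seq, lom, threshold=6.0)}
        assert hi <= lo
        fwd = {(h.offset, h.strand) for h in scan_pattern(seq, lom, threshold=2.0, strands="+")}
        assert fwd <= lo


class TestScanAll:
    def test_empty_library_empty_hits(self):
        p = ConservedPattern("G", "intron", 1, 0, 20, "ACGT" * 5)
        assert scan_all([p], []) == []

    def test_planted_instance_found_with_deterministic_order(self, sim_bundle):
        motifs = {m.motif_id: m for m in sim_bundle["motifs"]}
        truth = sim_bundle["truth"]
        planted = truth[truth.element.str.startswith("motif:")]
        sets_by_region = {(s.gene_id, s.ordinal): s for s in sim_bundle["sets"]}
        for row in planted.itertuples():
            motif_id = row.element.split(":", 1)[1]
            region = sets_by_region[(row.gene, row.ordinal)]
            block_seq = next(iter(region.sequences.values()))[row.offset : row.offset + row.length]
            p = ConservedPattern(row.gene, "intron", row.ordinal, row.offset,
                                 row.offset + row.length, block_seq)
            hits = scan_all([p], [motifs[motif_id]])
            covered = [h for h in hits if h.offset <= row.element_offset - row.offset < h.offset + motifs[motif_id].width]
            assert covered, f"planted {motif_id} not found in {p.pattern_id}"
            again = scan_all([p], [motifs[motif_id]])
            assert [(h.offset, h.strand, h.score) for h in hits] == [
                (h.offset, h.strand, h.score) for h in again
            ]
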