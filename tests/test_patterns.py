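import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from consreg.consensus import build_pssm, dumb_consensus
from consreg.io_formats import MsaBlock
from consreg.patterns import (
    conserved_mask,
    extract_conserved_patterns,
    extract_nonconserved_controls,
    group_by_ordinal,
    normalize_counts,
    ConservedPattern,
)

from .conftest import FIXTURE_SEED, naive_conserved_runs, random_alignment


def msa_of(*rows, **kw):
    return MsaBlock({f"sp{i}": r for i, r in enumerate(rows)}, **kw)


class TestExtractConserved:
    def test_fully_conserved_region_is_one_pattern(self):
        msa = msa_of(*(["ACGTACGTACGTACGTACGT"] * 5))
        pats = extract_conserved_patterns(build_pssm(msa), msa)
        assert len(pats) == 1
        p = pats[0]
        assert (p.aln_start, p.aln_end) == (0, 20)
        assert p.sequence == "ACGTACGTACGTACGTACGT"
        assert all(v == 0 for v in p.per_species_coords.values())

    def test_single_mismatch_splits_below_min_len(self):
        base = "ACGTACGTACGTACGTACGT"
        other = base[:10] + ("C" if base[10] != "C" else "G") + base[11:]
        msa = msa_of(*([base] * 4 + [other]))
        assert extract_conserved_patterns(build_pssm(msa), msa) == []

    def test_pattern_sequence_matches_every_species(self, sim_bundle):
        for oset in sim_bundle["sets"][:10]:
            msa = MsaBlock.from_ortholog_set(oset)
            for p in extract_conserved_patterns(build_pssm(msa), msa):
                for sp, start in p.per_species_coords.items():
                    ungapped = msa.degap(sp)
                    assert ungapped[start : start + len(p)] == p.sequence

    def test_recovers_planted_blocks(self, sim_bundle):
        pats = []
        for oset in sim_bundle["sets"]:
            msa = MsaBlock.from_ortholog_set(oset)
            pats.extend(extract_conserved_patterns(build_pssm(msa), msa))
        truth = sim_bundle["truth"]
        assert len(pats) == len(truth)
        by_region = {(p.gene_id, p.ordinal): p for p in pats}
        for row in truth.itertuples():
            p = by_region[(row.gene, row.ordinal)]
            # the recovered run contains the planted block; it may extend only
            # by flanking columns that happen to be conserved by chance
            assert p.aln_start <= row.offset and p.aln_end >= row.offset + row.length

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 100_000), st.integers(5, 25))
    def test_matches_bruteforce_scan(self, seed, min_len):
        rng = np.random.default_rng(seed)
        msa = random_alignment(
            rng, n_rows=int(rng.integers(2, 6)), length=int(rng.integers(30, 300)),
            gap_prob=0.05, n_prob=0.02, conserved_bias=0.7,
        )
        pats = extract_conserved_patterns(build_pssm(msa), msa, min_len=min_len)
        assert [(p.aln_start, p.aln_end) for p in pats] == naive_conserved_runs(msa, min_len)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 100_000))
    def test_min_len_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        msa = random_alignment(rng, n_rows=3, length=200, conserved_bias=0.8)
        pssm = build_pssm(msa)
        short = {(p.aln_start, p.aln_end) for p in extract_conserved_patterns(pssm, msa, min_len=10)}
        long = {(p.aln_start, p.aln_end) for p in extract_conserved_patterns(pssm, msa, min_len=20)}
        assert long <= short

    def test_final_patterns_do_not_depend_on_profile_threshold(self):
        # the profile stage and the 100%-conservation stage are distinct:
        # extraction reads the PSSM, so the profile threshold cannot change it
        rng = np.random.default_rng(5)
        msa = random_alignment(rng, n_rows=5, length=300, conserved_bias=0.85)
        pssm = build_pssm(msa)
        for thr in (0.5, 0.7, 0.9):
            profile = dumb_consensus(pssm, threshold=thr)
            assert len(profile) == msa.length
        ref = extract_conserved_patterns(pssm, msa)
        again = extract_conserved_patterns(build_pssm(msa), msa)
        assert [(p.aln_start, p.aln_end) for p in ref] == [(p.aln_start, p.aln_end) for p in again]


class TestControls:
    def test_fully_conserved_alignment_yields_none(self, caplog):
        msa = msa_of(*(["ACGT" * 10] * 5))
        pssm = build_pssm(msa)
        with caplog.at_level(logging.WARNING):
            out = extract_nonconserved_controls(pssm, msa, n=3, seed=1)
        assert out == [] and "non-conserved runs" in caplog.text

    def test_deterministic_under_seed(self, sim_bundle):
        oset = sim_bundle["sets"][0]
        msa = MsaBlock.from_ortholog_set(oset)
        pssm = build_pssm(msa)
        a = extract_nonconserved_controls(pssm, msa, n=5, seed=99)
        b = extract_nonconserved_controls(pssm, msa, n=5, seed=99)
        assert [(c.aln_start, c.aln_end, c.sequence) for c in a] == [
            (c.aln_start, c.aln_end, c.sequence) for c in b
        ]
        c = extract_nonconserved_controls(pssm, msa, n=5, seed=100)
        assert [(x.aln_start, x.aln_end) for x in a] != [(x.aln_start, x.aln_end) for x in c]

    def test_windows_are_nonconserved_and_disjoint_from_patterns(self, sim_bundle):
        for oset in sim_bundle["sets"][:15]:
            msa = MsaBlock.from_ortholog_set(oset)
            pssm = build_pssm(msa)
            mask = conserved_mask(pssm)
            pats = extract_conserved_patterns(pssm, msa)
            ctrls = extract_nonconserved_controls(pssm, msa, n=4, seed=FIXTURE_SEED)
            for c in ctrls:
                assert len(c) >= 15
                assert not mask[c.aln_start : c.aln_end].any()
                for p in pats:
                    assert c.aln_end <= p.aln_start or c.aln_start >= p.aln_end

    def test_control_sequence_is_columnwise_majority(self):
        rows = ["AAAAAAAAAAAAAAAAAAAA",
                "AAAAAAAAAAAAAAAAAAAC",
                "CCCCCCCCCCCCCCCCCCCC"]
        msa = msa_of(*rows)
        pssm = build_pssm(msa)
        ctrls = extract_nonconserved_controls(pssm, msa, n=1, min_len=15, seed=0)
        assert len(ctrls) == 1
        assert set(ctrls[0].sequence) == {"A"}  # A is the 2-of-3 majority everywhere

    def test_requests_capped_at_available_runs(self, caplog):
        rows = ["A" * 40, "A" * 39 + "C", "A" * 40]
        msa = msa_of(*rows)  # a single non-conserved column: no run >= 15
        with caplog.at_level(logging.WARNING):
            out = extract_nonconserved_controls(build_pssm(msa), msa, n=2, seed=0)
        assert out == []


class TestGroupingAndNormalization:
    def test_group_by_ordinal_partitions(self):
        mk = lambda o: ConservedPattern("G", "intron", o, 0, 20, "A" * 20)
        groups = group_by_ordinal([mk(1), mk(1), mk(3)])
        assert {k: len(v) for k, v in groups.items()} == {1: 2, 3: 1}
        assert group_by_ordinal([]) == {}

    def test_normalization_arithmetic(self):
        df = normalize_counts({1: 10}, {1: 5}, {1: 2000})
        row = df.iloc[0]
        assert row["per_gene"] == pytest.approx(2.0)
        assert row["per_kb"] == pytest.approx(5.0)

    def test_missing_denominator_omits_ordinal(self, caplog):
        with caplog.at_level(logging.WARNING):
            df = normalize_counts({1: 10, 2: 4}, {1: 5}, {1: 1000, 2: 500})
        assert df["ordinal"].tolist() == [1]
        assert "omitted" in caplog.text
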