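"""SP-G grouping and the unanimity / duplex consensus rules."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_pair, oracle_duplex
from duplexmut import (
    build_duplex_consensus,
    build_strand_consensus,
    consensus_pipeline,
    group_same_position,
    make_reference,
    simulate_family_set,
)
from duplexmut.consensus import (
    AlignedReadPair,
    SamePositionGroup,
    read_duplex_tsv,
    write_duplex_tsv,
)
from scipy import stats


class TestGrouping:
    def test_exact_key_partition(self):
        pairs = [
            make_pair(f"a{i}", "ACGT" * 10, start=100) for i in range(3)
        ] + [make_pair(f"b{i}", "ACGT" * 10 + "A", start=100) for i in range(2)]
        groups = group_same_position(pairs)
        assert sorted(len(g) for g in groups) == [2, 3]
        for g in groups:
            assert all(p.key == g.key for p in g.members)

    def test_singleton(self):
        groups = group_same_position([make_pair("x", "ACGTA")])
        assert len(groups) == 1 and len(groups[0]) == 1

    def test_partition_matches_sort_and_scan_oracle(self):
        rng = np.random.default_rng(5)
        pairs = []
        for i in range(10_000):
            start = int(rng.integers(0, 50))
            length = int(rng.integers(4, 8))
            seq = "".join(rng.choice(list("ACGT"), size=length))
            pairs.append(make_pair(f"p{i}", seq, start=start))
        groups = group_same_position(pairs)
        assert sum(len(g) for g in groups) == 10_000
        # brute-force oracle: sort by key and scan for runs
        keyed = sorted((p.key, p.pair_id) for p in pairs)
        oracle_sizes: dict = {}
        for key, _ in keyed:
            oracle_sizes[key] = oracle_sizes.get(key, 0) + 1
        assert {g.key: len(g) for g in groups} == oracle_sizes

    def test_invalid_pair_rejected(self):
        with pytest.raises(ValueError):
            AlignedReadPair("bad", "c1", 10, 10, True, ())


class TestStrandConsensus:
    def test_unanimous_pairs_reproduce_sequence(self):
        pairs = [make_pair(f"p{i}", "ACGTACGT") for i in range(2)]
        cons = build_strand_consensus(pairs)
        assert cons.bases.tobytes() == b"ACGTACGT"
        assert (cons.depth == 2).all()

    def test_single_disagreement_masks_position(self):
        pairs = [make_pair("p0", "ACGTACGT"), make_pair("p1", "ACGAACGT")]
        cons = build_strand_consensus(pairs)
        assert cons.bases.tobytes() == b"ACGNACGT"

    def test_mate_conflict_always_masks(self):
        # overlapping mates disagreeing at the split position
        p = make_pair("p0", "ACGTACGT", split=3)
        p.mates[1][1][0] = ord("C")  # corrupt the second mate's first base
        p._obs = None
        cons = build_strand_consensus([p, make_pair("p1", "ACGTACGT")])
        assert chr(cons.bases[3]) == "N"

    def test_uncovered_positions_are_n_not_votes(self):
        # one pair covers only the first half; unanimity is judged among
        # covering reads, so the second half keeps the lone observation
        short = AlignedReadPair(
            "s", "sim1", 0, 8, True, ((0, np.frombuffer(b"ACGT", np.uint8).copy()),)
        )
        full = make_pair("f", "ACGTACGT")
        cons = build_strand_consensus([short, full])
        assert cons.bases.tobytes() == b"ACGTACGT"
        assert list(cons.depth) == [2, 2, 2, 2, 1, 1, 1, 1]

    def test_mixed_orientation_rejected(self):
        with pytest.raises(ValueError):
            build_strand_consensus(
                [make_pair("a", "ACGT"), make_pair("b", "ACGT", r1_forward=False)]
            )
        with pytest.raises(ValueError):
            build_strand_consensus([])

    def test_majority_rule_breaks_ties_to_n(self):
        pairs = [
            make_pair("a", "AAAA"),
            make_pair("b", "AAAT"),
            make_pair("c", "AAAT"),
        ]
        cons = build_strand_consensus(pairs, rule="majority")
        assert cons.bases.tobytes() == b"AAAT"
        tie = build_strand_consensus(pairs[:2], rule="majority")
        assert tie.bases.tobytes() == b"AAAN"

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_random_subgroups_match_bruteforce_oracle(self, data):
        rng_seqs = data.draw(
            st.lists(
                st.text(alphabet="ACGTN", min_size=6, max_size=6),
                min_size=1,
                max_size=5,
            )
        )
        rule = data.draw(st.sampled_from(["unanimity", "majority"]))
        pairs = [make_pair(f"p{i}", s) for i, s in enumerate(rng_seqs)]
        cons = build_strand_consensus(pairs, rule=rule)
        from conftest import oracle_strand_base

        expected = "".join(
            oracle_strand_base(pairs, pos, rule) for pos in range(6)
        )
        assert cons.bases.tobytes().decode() == expected


class TestDuplexConsensus:
    def test_single_orientation_yields_none(self):
        group = SamePositionGroup(
            ("sim1", 0, 8), [make_pair(f"p{i}", "ACGTACGT") for i in range(3)]
        )
        assert build_duplex_consensus(group) is None

    def test_error_free_strands_reproduce_fragment(self):
        members = [
            make_pair("f", "ACGTACGT"),
            make_pair("r", "ACGTACGT", r1_forward=False),
        ]
        d = build_duplex_consensus(SamePositionGroup(("sim1", 0, 8), members))
        assert d is not None and d.sequence == "ACGTACGT"
        assert (d.n_plus, d.n_minus) == (1, 1)

    def test_lone_read_error_is_masked_by_other_strand(self):
        # plus strand consensus carries the error (only read), minus strand
        # is correct: the duplex must be N there — the error-suppression rule
        members = [
            make_pair("f", "ACGAACGT"),  # error at position 3 (T->A)
            make_pair("r", "ACGTACGT", r1_forward=False),
        ]
        d = build_duplex_consensus(SamePositionGroup(("sim1", 0, 8), members))
        assert d.sequence == "ACGNACGT"

    def test_min_pairs_per_strand_threshold(self):
        members = [
            make_pair("f1", "ACGT"),
            make_pair("f2", "ACGT"),
            make_pair("r1", "ACGT", r1_forward=False),
        ]
        group = SamePositionGroup(("sim1", 0, 4), members)
        assert build_duplex_consensus(group, min_pairs_per_strand=1) is not None
        assert build_duplex_consensus(group, min_pairs_per_strand=2) is None

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.data())
    def test_unanimous_observation_is_never_contradicted(self, data):
        """If every read on both strands shows base b at p, the duplex is b."""
        n_plus = data.draw(st.integers(1, 3))
        n_minus = data.draw(st.integers(1, 3))
        seq = data.draw(st.text(alphabet="ACGT", min_size=5, max_size=5))
        members = [make_pair(f"f{i}", seq) for i in range(n_plus)] + [
            make_pair(f"r{i}", seq, r1_forward=False) for i in range(n_minus)
        ]
        d = build_duplex_consensus(SamePositionGroup(("sim1", 0, 5), members))
        assert d.sequence == seq


@pytest.fixture(scope="module")
def ref():
    return make_reference(500_000, 0.42, seed=7)


class TestPipeline:
    def test_all_both_strand_families_become_dsdcs(self, ref):
        rs = simulate_family_set(
            ref, 300, both_strand_prob=1.0, fragment_length=(350, 40), seed=3
        )
        duplexes, summary = consensus_pipeline(rs.pairs)
        # distinct fragment coordinates may rarely collide and merge
        assert summary.n_duplex == summary.n_groups
        assert 298 <= summary.n_duplex <= 300

    def test_dsdcs_count_matches_binomial_oracle(self, ref):
        rs = simulate_family_set(
            ref,
            10_000,
            both_strand_prob=0.5,
            fragment_length=(350, 40),
            seed=43,
        )
        _, summary = consensus_pipeline(rs.pairs)
        lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.5)
        assert lo <= summary.n_duplex <= hi
        assert summary.n_duplex <= summary.n_groups <= summary.input_pairs

    def test_empty_sam_is_clean(self, tmp_path):
        path = tmp_path / "empty.sam"
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "sim1", "LN": 1000}]}
        with pysam.AlignmentFile(path, "w", header=header):
            pass
        duplexes, summary = consensus_pipeline(path)
        assert duplexes == []
        assert summary.n_groups == 0 and summary.n_duplex == 0

    def test_secondary_and_unmapped_records_are_skipped(self, tmp_path):
        path = tmp_path / "dirty.sam"
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "sim1", "LN": 1000}]}
        with pysam.AlignmentFile(path, "w", header=header) as fh:
            a = pysam.AlignedSegment()
            a.query_name = "lonely"
            a.query_sequence = "ACGT"
            a.reference_id = 0
            a.reference_start = 10
            a.cigartuples = [(0, 4)]
            a.is_paired = True
            a.is_read1 = True
            fh.write(a)
            b = pysam.AlignedSegment()
            b.query_name = "ghost"
            b.query_sequence = "ACGT"
            b.is_unmapped = True
            fh.write(b)
        _, summary = consensus_pipeline(path)
        assert summary.skipped_unmapped == 1
        assert summary.skipped_unpaired == 1
        assert summary.input_pairs == 0

    def test_duplex_tsv_round_trip(self, ref, tmp_path):
        rs = simulate_family_set(ref, 50, both_strand_prob=1.0, seed=47)
        duplexes, _ = consensus_pipeline(rs.pairs)
        path = tmp_path / "dsdcs.tsv"
        write_duplex_tsv(duplexes, path, comment="test")
        back = read_duplex_tsv(path)
        assert [(d.key, d.sequence, d.n_plus, d.n_minus) for d in back] == [
            (d.key, d.sequence, d.n_plus, d.n_minus) for d in duplexes
        ]


class TestOracleEquivalence:
    def test_random_small_groups_match_bruteforce(self):
        """Vectorised consensus equals the per-position brute force on random
        SP-Gs of <= 5 pairs over short fragments with injected errors."""
        rng = np.random.default_rng(101)
        for case in range(200):
            length = int(rng.integers(4, 21))
            frag = "".join(rng.choice(list("ACGT"), size=length))
            members = []
            n_plus = int(rng.integers(0, 4))
            n_minus = int(rng.integers(0, 4))
            for i in range(n_plus + n_minus):
                seq = list(frag)
                for _ in range(int(rng.integers(0, 3))):
                    j = int(rng.integers(0, length))
                    seq[j] = str(rng.choice(list("ACGTN")))
                split = (
                    int(rng.integers(1, length - 1)) if length > 2 and rng.random() < 0.5 else None
                )
                members.append(
                    make_pair(f"m{i}", "".join(seq), r1_forward=i < n_plus, split=split)
                )
            if not members:
                continue
            group = SamePositionGroup(("sim1", 0, length), members)
            expected = oracle_duplex(members, 0, length)
            got = build_duplex_consensus(group)
            if expected is None:
                assert got is None
            else:
                assert got is not None and got.sequence == expected
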