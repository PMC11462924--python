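"""96-channel classification, spectra, cosine similarity, decomposition."""

import itertools

import numpy as np
import pytest
from scipy import stats

from conftest import grid_search_weights
from duplexmut import (
    build_spectrum96,
    call_mutations,
    classify_trinucleotide,
    consensus_pipeline,
    cosine_similarity,
    decompose_spectrum,
    make_reference,
    simulate_family_set,
)
from duplexmut.calling import MutationCall
from duplexmut.reference import ReferenceGenome
from duplexmut.simulate import MutationModel
from duplexmut.spectra import SignatureMatrix, Spectrum96
from duplexmut.substitutions import (
    CHANNELS,
    TRINUC32,
    channel_index,
    class_of,
)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def call_at(ref, contig, pos, alt):
    r = chr(ref.array(contig)[pos])
    return MutationCall(contig, pos, r, alt, class_of(r, alt), 1, 1)


class TestChannelClassification:
    def test_pyrimidine_centred_direct(self):
        ref = ReferenceGenome({"c1": "ACA" + "T" * 100})
        idx = classify_trinucleotide(ref, call_at(ref, "c1", 1, "T"))
        assert CHANNELS[idx] == "A[C>T]A"

    def test_purine_centre_is_reverse_complemented(self):
        # TGT with G->A folds to ACA with C>T on the opposite strand
        ref = ReferenceGenome({"c1": "TGT" + "A" * 100})
        idx = classify_trinucleotide(ref, call_at(ref, "c1", 1, "A"))
        assert CHANNELS[idx] == "A[C>T]A"

    def test_all_192_combinations_fold_onto_96_channels_twice(self):
        """Exhaustive oracle: every (trinucleotide, alt) maps to a channel,
        and reverse-complement partners share it, covering each channel
        exactly twice."""
        hits = {label: 0 for label in CHANNELS}
        for l, c, r in itertools.product("ACGT", repeat=3):
            for a in "ACGT":
                if a == c:
                    continue
                label = CHANNELS[channel_index(l, c, a, r)]
                hits[label] += 1
                # independent fold: the reverse-complemented observation
                partner = CHANNELS[
                    channel_index(COMP[r], COMP[c], COMP[a], COMP[l])
                ]
                assert partner == label
        assert set(hits.values()) == {2}

    def test_strand_fold_symmetry_of_spectra(self):
        """Relabelling every call as its reverse complement leaves the
        spectrum unchanged."""
        fwd = ReferenceGenome({"c1": "AACGTACGTTGCA" + "A" * 90})
        for pos in range(1, 12):
            c = chr(fwd.array("c1")[pos])
            for a in "ACGT":
                if a == c:
                    continue
                direct = classify_trinucleotide(
                    fwd, call_at(fwd, "c1", pos, a)
                )
                l = chr(fwd.array("c1")[pos - 1])
                r = chr(fwd.array("c1")[pos + 1])
                relabelled = channel_index(COMP[r], COMP[c], COMP[a], COMP[l])
                assert relabelled == direct

    def test_flank_off_contig_raises(self):
        ref = ReferenceGenome({"c1": "ACGT"})
        with pytest.raises(ValueError):
            classify_trinucleotide(ref, call_at(ref, "c1", 0, "G"))
        with pytest.raises(ValueError):
            classify_trinucleotide(ref, call_at(ref, "c1", 3, "G"))


class TestBuildSpectrum:
    def test_empty_and_single_call(self):
        ref = ReferenceGenome({"c1": "ACA" + "T" * 100})
        denoms = np.ones(32, dtype=np.int64)
        empty = build_spectrum96([], ref, denoms)
        assert empty.total == 0 and (empty.counts == 0).all()
        one = build_spectrum96([call_at(ref, "c1", 1, "T")], ref, denoms)
        assert one.total == 1
        assert one.counts[CHANNELS.index("A[C>T]A")] == 1

    def test_edge_calls_excluded_with_count(self, caplog):
        ref = ReferenceGenome({"c1": "CCGT" + "A" * 100})
        calls = [call_at(ref, "c1", 0, "A"), call_at(ref, "c1", 2, "T")]
        spec = build_spectrum96(calls, ref, np.ones(32, dtype=np.int64))
        assert spec.total == 1  # position 0 has no 5' flank

    def test_context_weighted_simulation_matches_expected_distribution(self):
        """Channel counts of planted, context-weighted G:C>T:A mutations
        match the (composition x weight) expectation (chi-square GOF)."""
        ref = make_reference(400_000, 0.42, seed=7)
        w = np.asarray(
            [8, 4, 2, 1, 1, 1, 1, 1, 4, 2, 1, 1, 2, 1, 1, 1], dtype=float
        )
        w /= w.sum()
        model = MutationModel(
            {"G:C>T:A": 1.2e-3}, context_weights={"G:C>T:A": w}
        )
        rs = simulate_family_set(
            ref,
            7_000,
            fragment_length=(300, 0),
            reads_per_strand=("fixed", 1),
            both_strand_prob=1.0,
            model=model,
            seed=71,
        )
        # ~1e3 expected: 7000 families x 300 bp x 42% GC x 1.2e-3
        assert len(rs.truth) > 800
        observed = np.zeros(16)
        for rec in rs.truth:
            idx = classify_trinucleotide(
                ref, MutationCall(rec.contig, rec.pos0, rec.ref, rec.alt,
                                  rec.cls, 1, 1)
            )
            assert CHANNELS[idx].startswith(("A[C>A]", "C[C>A]", "G[C>A]", "T[C>A]"))
            observed[idx % 16] += 1
        # expectation: genome trinucleotide composition times channel weight
        carr = ref.array("sim1")
        comp = np.zeros(32)
        from duplexmut._bases import BASE_INDEX
        from duplexmut.substitutions import TRINUC_FOLD

        codes = (
            BASE_INDEX[carr[:-2]].astype(int) * 16
            + BASE_INDEX[carr[1:-1]].astype(int) * 4
            + BASE_INDEX[carr[2:]]
        )
        comp = np.bincount(TRINUC_FOLD[codes], minlength=32)
        c_contexts = comp[:16]  # C-centred trinucleotide counts
        expected = c_contexts * w
        expected = expected / expected.sum() * observed.sum()
        _, p = stats.chisquare(observed, expected)
        assert p > 0.01


class TestCosine:
    def test_identity_scale_and_orthogonality(self):
        x = np.zeros(96)
        x[:10] = np.arange(1, 11)
        assert cosine_similarity(x, x) == pytest.approx(1.0)
        assert cosine_similarity(x, 3 * x) == pytest.approx(1.0)
        y = np.zeros(96)
        y[20:30] = 1.0
        assert cosine_similarity(x, y) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            cosine_similarity(x, np.zeros(96))

    def test_replicate_simulations_agree(self):
        """Two replicates of one mutation model give highly similar spectra
        (counts), mirroring cross-platform reproducibility."""
        ref = make_reference(400_000, 0.42, seed=7)
        model = MutationModel({"G:C>T:A": 1.0e-3, "G:C>A:T": 4e-4, "A:T>G:C": 3e-4})
        specs = []
        for seed in (73, 79):
            rs = simulate_family_set(
                ref,
                3_000,
                fragment_length=(300, 0),
                reads_per_strand=("fixed", 1),
                both_strand_prob=1.0,
                model=model,
                seed=seed,
            )
            duplexes, _ = consensus_pipeline(rs.pairs)
            calls, denoms = call_mutations(duplexes, ref)
            assert len(calls) >= 500
            specs.append(build_spectrum96(calls, ref, denoms))
        assert cosine_similarity(specs[0], specs[1], on="counts") > 0.9


class TestSignatureMatrix:
    def test_fixture_loads_and_validates(self, signatures):
        assert signatures.k == 5
        assert set(signatures.names) >= {"SYN_A", "SYN_B", "SYN_C"}
        assert np.allclose(signatures.matrix.sum(axis=0), 1.0, atol=1e-6)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            SignatureMatrix(["a"], np.ones((96, 1)))  # column sums to 96
        m = np.full((96, 1), 1 / 96)
        m[0, 0] = -m[0, 0]
        with pytest.raises(ValueError):
            SignatureMatrix(["a"], m)
        with pytest.raises(ValueError):
            SignatureMatrix(["a", "b"], np.full((96, 1), 1 / 96))


class TestDecomposition:
    def test_exact_member_recovered(self, signatures):
        res = decompose_spectrum(signatures.column("SYN_B"), signatures)
        assert res.weight("SYN_B") == pytest.approx(1.0, abs=1e-6)
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-6)
        assert res.cosine == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_two_signature_mixture(self, signatures):
        mix = 0.7 * signatures.column("SYN_A") + 0.3 * signatures.column("SYN_B")
        res = decompose_spectrum(mix, signatures)
        assert res.weight("SYN_A") == pytest.approx(0.7, abs=0.02)
        assert res.weight("SYN_B") == pytest.approx(0.3, abs=0.02)
        others = [n for n in signatures.names if n not in ("SYN_A", "SYN_B")]
        assert all(res.weight(n) == 0.0 for n in others)

    def test_noisy_mixture_matches_grid_search_oracle(self, signatures):
        """Multinomial noise at n=500: greedy NNLS recovers the mixture
        within ±0.1 and is at least as good as a 0.01-resolution exhaustive
        grid search over the K=3 weight simplex."""
        rng = np.random.default_rng(83)
        sub = signatures.subset(["SYN_A", "SYN_B", "SYN_C"])
        truth = np.array([0.7, 0.3, 0.0])
        probs = sub.matrix @ truth
        counts = rng.multinomial(500, probs)
        res = decompose_spectrum(counts, sub, weight_cutoff=0.06)
        assert np.abs(res.weights - truth).max() < 0.1
        target = counts / counts.sum()
        grid_w, grid_sse = grid_search_weights(target, sub.matrix, step=0.01)
        # allow the grid's own resolution on top of its optimum
        assert res.rss <= grid_sse + 1e-6
        assert np.abs(res.weights - grid_w).max() <= 0.02

    def test_residual_never_increases_and_beats_single_signatures(self, signatures):
        rng = np.random.default_rng(89)
        mix = (
            0.5 * signatures.column("SYN_A")
            + 0.3 * signatures.column("DEAM_LIKE")
            + 0.2 * signatures.column("SYN_C")
        )
        counts = rng.multinomial(2_000, mix)
        res = decompose_spectrum(counts, signatures)
        target = counts / counts.sum()
        best_single = max(
            cosine_similarity(target, signatures.matrix[:, j])
            for j in range(signatures.k)
        )
        assert res.cosine >= best_single - 1e-9
        # residual of each prefix of the inclusion order is non-increasing
        from duplexmut.spectra import _nnls_fit

        prev = float(target @ target)
        for i in range(1, len(res.inclusion_order) + 1):
            sel = [signatures.names.index(n) for n in res.inclusion_order[:i]]
            _, rss = _nnls_fit(target, signatures, sel)
            assert rss <= prev + 1e-12
            prev = rss

    def test_degenerate_inputs(self, signatures):
        with pytest.raises(ValueError):
            decompose_spectrum(np.zeros(96), signatures)
        with pytest.raises(ValueError):
            decompose_spectrum(
                np.ones(96), SignatureMatrix([], np.zeros((96, 0)))
            )

    def test_weight_cutoff_zeroes_trace_contributions(self, signatures):
        mix = 0.97 * signatures.column("SYN_A") + 0.03 * signatures.column("SYN_B")
        res = decompose_spectrum(mix, signatures, weight_cutoff=0.06)
        assert res.weight("SYN_B") == 0.0
        assert res.weight("SYN_A") > 0.9


class TestSpectrumIO:
    def test_tsv_round_trip(self, tmp_path):
        counts = np.zeros(96, dtype=np.int64)
        counts[[3, 40, 90]] = (5, 2, 7)
        denoms = np.full(96, 1000, dtype=np.int64)
        spec = Spectrum96(counts, denoms, name="t")
        path = tmp_path / "spec.tsv"
        spec.to_tsv(path, comment="unit test")
        back = Spectrum96.from_tsv(path)
        assert (back.counts == spec.counts).all()
        assert (back.denominators == spec.denominators).all()

    def test_trinucleotide_labels_align_with_channels(self):
        # the denominator bin of channel "A[C>T]G" is trinucleotide ACG
        from duplexmut.substitutions import CHANNEL_TRINUC

        idx = CHANNELS.index("A[C>T]G")
        assert TRINUC32[CHANNEL_TRINUC[idx]] == "ACG"
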