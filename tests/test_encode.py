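"""Descriptor encoders: worked values, brute-force oracles, invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from a2isite import EncoderSpec, RnaSequence, encode_all, species_feature_preset
from a2isite.encode import (
    encode_asdc,
    encode_binary,
    encode_cksnap,
    encode_dbe,
    encode_dpcp,
    encode_dpcp2,
    encode_enac,
    encode_kmer,
    encode_ncp,
    encode_ps2,
    encode_psednc,
)
from a2isite.properties import DINUCLEOTIDES, load_default_table
from a2isite.seqio import build_dataset
from conftest import random_sequence

rna = st.text(alphabet="ACGU", min_size=5, max_size=20).map(
    lambda s: RnaSequence("h", s)
)

DI = list(DINUCLEOTIDES)


# --- independent brute-force oracles -------------------------------------

def brute_kmer(res, k):
    words = ["".join(p) for p in itertools.product("ACGU", repeat=k)]
    counts = {w: 0 for w in words}
    for i in range(len(res) - k + 1):
        counts[res[i : i + k]] += 1
    return np.array([counts[w] for w in words], dtype=float)


def brute_pairs(res, gap):
    counts = {d: 0 for d in DI}
    for i in range(len(res)):
        j = i + gap + 1
        if j < len(res):
            counts[res[i] + res[j]] += 1
    return np.array([counts[d] for d in DI], dtype=float)


class TestKmer:
    def test_homopolymer(self):
        fv = encode_kmer(RnaSequence("x", "AAAA"), k=2)
        assert fv.values[0] == 1.0 and fv.values[1:].sum() == 0

    def test_uniform_composition(self):
        fv = encode_kmer(RnaSequence("x", "ACGU"), k=1)
        assert np.allclose(fv.values, 0.25)

    def test_matches_brute_force_3mers_on_51nt(self, rng):
        seq = random_sequence(rng, 51)
        fv = encode_kmer(seq, k=3, mode="windows")
        assert np.array_equal(fv.values, brute_kmer(seq.residues, 3) / 49)

    def test_length_mode_divides_by_L(self):
        fv = encode_kmer(RnaSequence("x", "AAAA"), k=2, mode="length")
        assert fv.values[0] == pytest.approx(3 / 4)

    def test_k_larger_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            encode_kmer(RnaSequence("x", "ACG"), k=4)


class TestCksnap:
    def test_dimension_48_for_gap2(self, rng):
        fv = encode_cksnap(random_sequence(rng, 51), gap_max=2)
        assert len(fv.values) == 48

    def test_manual_count_acgu_gap0(self):
        fv = encode_cksnap(RnaSequence("x", "ACGU"), gap_max=2)
        block0 = dict(zip(DI, fv.values[:16]))
        assert block0["AC"] == block0["CG"] == block0["GU"] == pytest.approx(1 / 3)
        assert sum(block0.values()) == pytest.approx(1.0)

    def test_homopolymer_aa_in_every_block(self):
        fv = encode_cksnap(RnaSequence("x", "AAAAAA"), gap_max=2)
        for g in range(3):
            block = fv.values[16 * g : 16 * (g + 1)]
            assert block[0] == 1.0 and block[1:].sum() == 0

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            encode_cksnap(RnaSequence("x", "ACG"), gap_max=2)


class TestAsdc:
    def test_enumerated_pairs_aacc(self):
        fv = encode_asdc(RnaSequence("x", "AACC"))
        vals = dict(zip([n.split("_")[1] for n in fv.names], fv.values))
        assert vals["AA"] == pytest.approx(1 / 6)
        assert vals["AC"] == pytest.approx(4 / 6)
        assert vals["CC"] == pytest.approx(1 / 6)

    def test_single_pair(self):
        fv = encode_asdc(RnaSequence("x", "AU"))
        assert dict(zip(fv.names, fv.values))["ASDC_AU"] == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(rna)
    def test_sums_to_one(self, seq):
        assert encode_asdc(seq).values.sum() == pytest.approx(1.0, abs=1e-9)


class TestEnac:
    def test_dimension_200_for_window2_51nt(self, rng):
        assert len(encode_enac(random_sequence(rng, 51), window=2).values) == 200

    def test_window_counts_aacg(self):
        fv = encode_enac(RnaSequence("x", "AACG"), window=2)
        expected = [1, 0, 0, 0, 0.5, 0.5, 0, 0, 0, 0.5, 0.5, 0]
        assert np.allclose(fv.values, expected)

    def test_homopolymer(self):
        fv = encode_enac(RnaSequence("x", "AAAA"), window=2)
        assert np.allclose(fv.values.reshape(-1, 4), [[1, 0, 0, 0]] * 3)

    def test_window_too_large_rejected(self):
        with pytest.raises(ValueError):
            encode_enac(RnaSequence("x", "ACG"), window=4)


def test_composition_encoders_match_brute_force_enumeration(rng):
    """Kmer/CKSNAP/ASDC/ENAC equal independent sliding-window/pair tallies."""
    for _ in range(100):
        L = int(rng.integers(6, 21))
        seq = random_sequence(rng, L)
        res = seq.residues
        for k in (1, 2, 3):
            assert np.array_equal(
                encode_kmer(seq, k=k).values, brute_kmer(res, k) / (L - k + 1)
            )
        got = encode_cksnap(seq, gap_max=2).values
        want = np.concatenate([brute_pairs(res, g) / (L - g - 1) for g in range(3)])
        assert np.array_equal(got, want)
        all_gaps = sum(brute_pairs(res, g) for g in range(L - 1))
        assert np.allclose(
            encode_asdc(seq).values, all_gaps / all_gaps.sum(), atol=1e-12
        )
        enac = encode_enac(seq, window=3).values.reshape(-1, 4)
        for p in range(L - 2):
            frame = res[p : p + 3]
            assert np.allclose(enac[p], [frame.count(b) / 3 for b in "ACGU"])


class TestNcp:
    def test_coordinate_table(self):
        fv = encode_ncp(RnaSequence("x", "ACGU"))
        assert fv.values.tolist() == [1, 1, 1, 0, 1, 0, 1, 0, 0, 0, 0, 1]

    def test_dimension_3L(self, rng):
        assert len(encode_ncp(random_sequence(rng, 51)).values) == 153

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(rna)
    def test_every_triple_is_a_valid_coordinate(self, seq):
        triples = encode_ncp(seq).values.reshape(-1, 3)
        valid = {(1, 1, 1), (0, 1, 0), (1, 0, 0), (0, 0, 1)}
        assert {tuple(int(v) for v in t) for t in triples} <= valid


class TestDpcp:
    def test_dimension_96(self, rng):
        assert len(encode_dpcp(random_sequence(rng, 51)).values) == 96

    def test_homopolymer_only_aa_components(self):
        table = load_default_table()
        fv = encode_dpcp(RnaSequence("x", "AAAA"))
        vals = dict(zip(fv.names, fv.values))
        for prop in table.properties:
            assert vals[f"DPCP_AA_{prop.capitalize()}"] == pytest.approx(
                table.lookup("AA", prop)
            )
        others = [v for n, v in vals.items() if not n.startswith("DPCP_AA")]
        assert all(v == 0 for v in others)

    def test_absent_dinucleotide_exactly_zero(self):
        fv = encode_dpcp(RnaSequence("x", "ACAC"))
        vals = dict(zip(fv.names, fv.values))
        assert all(v == 0 for n, v in vals.items() if n.startswith("DPCP_GG"))

    def test_missing_property_column_rejected(self):
        table = load_default_table()
        partial = table.subset(("rise", "roll"))
        with pytest.raises(KeyError):
            encode_dpcp(RnaSequence("x", "ACGU"), table=partial)


class TestDpcp2:
    def test_dimension_4_by_L_minus_1(self, rng):
        assert len(encode_dpcp2(random_sequence(rng, 41)).values) == 160

    def test_homopolymer_constant_per_property(self):
        table = load_default_table()
        fv = encode_dpcp2(RnaSequence("x", "AAAA"))
        arr = fv.values.reshape(4, -1)
        for row, prop in zip(arr, ("rise", "roll", "shift", "slide")):
            assert np.allclose(row, table.lookup("AA", prop))

    def test_shared_prefix_agrees_positionally(self):
        a = encode_dpcp2(RnaSequence("a", "ACGUA"))
        b = encode_dpcp2(RnaSequence("b", "ACGUC"))
        # pair positions 1..3 are identical; only position 4 may differ
        va, vb = a.values.reshape(4, -1), b.values.reshape(4, -1)
        assert np.array_equal(va[:, :3], vb[:, :3])

    def test_names_carry_property_and_position(self):
        fv = encode_dpcp2(RnaSequence("x", "ACG"))
        assert "DPCP2_Roll_pos2" in fv.names


class TestPsednc:
    def test_dimension_and_sum(self, rng):
        fv = encode_psednc(random_sequence(rng, 51), lam=2, w=0.1)
        assert len(fv.values) == 18
        assert fv.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_homopolymer_thetas_vanish(self):
        fv = encode_psednc(RnaSequence("x", "AAAAA"), lam=2, w=0.5)
        assert fv.values[0] == pytest.approx(1.0)
        assert np.allclose(fv.values[16:], 0.0)

    def test_w_zero_reduces_to_dinucleotide_frequencies(self, rng):
        seq = random_sequence(rng, 31)
        fv = encode_psednc(seq, lam=3, w=0.0)
        freqs = brute_pairs(seq.residues, 0) / (len(seq) - 1)
        assert np.allclose(fv.values[:16], freqs, atol=1e-12)
        assert np.allclose(fv.values[16:], 0.0)

    def test_lambda_too_large_rejected(self):
        with pytest.raises(ValueError):
            encode_psednc(RnaSequence("x", "ACGU"), lam=3)

    def test_weight_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            encode_psednc(RnaSequence("x", "ACGUACGU"), lam=2, w=1.5)


class TestResidueEncodings:
    def test_binary_identity_pattern(self):
        fv = encode_binary(RnaSequence("x", "ACGU"))
        assert np.array_equal(fv.values.reshape(4, 4), np.eye(4))

    def test_binary_dimension_164_for_41nt(self, rng):
        assert len(encode_binary(random_sequence(rng, 41)).values) == 164

    @pytest.mark.parametrize(
        "pair,bits",
        [("AA", [0, 0, 0, 0]), ("AU", [0, 0, 0, 1]), ("AC", [0, 0, 1, 0]),
         ("GG", [1, 1, 1, 1])],
    )
    def test_dbe_printed_examples(self, pair, bits):
        assert encode_dbe(RnaSequence("x", pair)).values.tolist() == bits

    def test_ps2_aa_bit_string(self):
        v = encode_ps2(RnaSequence("x", "AA")).values
        assert v[0] == 1 and v[1:].sum() == 0

    def test_ps2_aac_bit_string(self):
        v = encode_ps2(RnaSequence("x", "AAC")).values
        expect = np.zeros(32)
        expect[0] = 1   # AA in block 1
        expect[17] = 1  # AC in block 2
        assert np.array_equal(v, expect)

    def test_ps2_dimension_800_for_51nt(self, rng):
        assert len(encode_ps2(random_sequence(rng, 51)).values) == 800

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(rna)
    def test_binary_blocks_one_hot(self, seq):
        blocks = encode_binary(seq).values.reshape(-1, 4)
        assert np.all(blocks.sum(axis=1) == 1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(rna)
    def test_ps2_blocks_one_hot(self, seq):
        blocks = encode_ps2(seq).values.reshape(-1, 16)
        assert np.all(blocks.sum(axis=1) == 1)


@pytest.mark.parametrize("L", [9, 41, 51])
def test_dimensional_contract_all_encoders(rng, L):
    seq = random_sequence(rng, L)
    specs = [
        EncoderSpec("Kmer", {"k": 2}),
        EncoderSpec("CKSNAP", {"gap_max": 2}),
        EncoderSpec("ASDC"),
        EncoderSpec("ENAC", {"window": 2}),
        EncoderSpec("NCP"),
        EncoderSpec("DPCP"),
        EncoderSpec("DPCP2"),
        EncoderSpec("PseDNC", {"lambda": 2, "w": 0.1}),
        EncoderSpec("Binary"),
        EncoderSpec("DBE"),
        EncoderSpec("PS2"),
    ]
    for spec in specs:
        fv = spec.encode(seq)
        assert len(fv.values) == spec.dimension(L), spec.name
        assert len(fv.names) == len(fv.values)


def test_permutation_sensitivity(rng):
    """Positional encoders separate permuted sequences; 1-mer cannot."""
    a = RnaSequence("a", "AACGUCGUA")
    b = RnaSequence("b", "AAUGCUGCA")  # same composition, different order
    assert sorted(a.residues) == sorted(b.residues)
    for fn in (encode_binary, encode_dbe, encode_ps2, encode_ncp,
               encode_dpcp2, lambda s: encode_enac(s, window=2)):
        assert not np.array_equal(fn(a).values, fn(b).values)
    assert np.array_equal(
        encode_kmer(a, k=1).values, encode_kmer(b, k=1).values
    )


class TestEncodeAll:
    def _dataset(self, rng, L=41, n=4):
        pos = [random_sequence(rng, L) for _ in range(n // 2)]
        neg = [random_sequence(rng, L) for _ in range(n - n // 2)]
        for i, s in enumerate(pos + neg):
            object.__setattr__(s, "id", f"s{i}")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return build_dataset(pos, neg)

    def test_block_concatenation_dimensions(self, rng):
        ds = self._dataset(rng, L=41)
        fm = encode_all(ds, [EncoderSpec("Binary"), EncoderSpec("DBE")])
        assert fm.X.shape == (4, 164 + 160)
        assert fm.columns[0].startswith("Binary") and fm.columns[-1].startswith("DBE")

    def test_empty_spec_list_rejected(self, rng):
        with pytest.raises(ValueError):
            encode_all(self._dataset(rng), [])

    def test_deterministic(self, rng):
        ds = self._dataset(rng)
        specs = species_feature_preset("Mm")
        a = encode_all(ds, specs)
        b = encode_all(ds, specs)
        assert a.data.equals(b.data)

    def test_matrix_round_trip(self, rng, tmp_path):
        ds = self._dataset(rng)
        fm = encode_all(ds, [EncoderSpec("NCP")])
        fm.write(tmp_path / "m.tsv")
        from a2isite import FeatureMatrix

        back = FeatureMatrix.read(tmp_path / "m.tsv")
        assert np.allclose(back.X, fm.X)
        assert back.columns == fm.columns
        assert back.specs == fm.specs


class TestSpeciesPresets:
    def test_dm_preset(self):
        names = [s.name for s in species_feature_preset("Dm")]
        assert names == ["CKSNAP", "Kmer", "ASDC", "PseDNC", "DPCP"]

    def test_mm_preset_includes_dpcp2(self):
        names = [s.name for s in species_feature_preset("Mm")]
        assert len(names) == 5 and "DPCP2" in names

    def test_hs_preset(self):
        names = [s.name for s in species_feature_preset("Hs")]
        assert names == ["NCP", "Binary", "DBE", "PS2"]

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            species_feature_preset("other")
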