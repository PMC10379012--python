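from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from promgraph.encoders import (AlphabetError, BPBEncoder, LocalEncoder,
                                encode_bpb, encode_eiip, encode_local,
                                encode_ncp, encode_ncp_nd, encode_nd, fit_bpb,
                                local_feature_names)
from promgraph.io import SequenceRecord

dna = st.text(alphabet="ACGT", min_size=1, max_size=500)


def nd_oracle(sequence: str) -> list[Fraction]:
    """Brute-force prefix counting in exact rational arithmetic."""
    out = []
    for i, base in enumerate(sequence, start=1):
        out.append(Fraction(sequence[:i].count(base), i))
    return out


class TestNCP:
    @pytest.mark.parametrize(
        "base,expected",
        [("A", (1, 1, 1)), ("C", (0, 0, 1)), ("G", (1, 0, 0)), ("T", (0, 1, 0))],
    )
    def test_truth_table(self, base, expected):
        assert encode_ncp(base) == expected

    def test_rejects_other_characters(self):
        with pytest.raises(AlphabetError):
            encode_ncp("N")


class TestND:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAA", [1, 1, 1, 1]),
            ("ACGT", [1, 0.5, 1 / 3, 0.25]),
            ("AACA", [1, 1, 1 / 3, 0.75]),
        ],
    )
    def test_examples(self, seq, expected):
        np.testing.assert_allclose(encode_nd(seq), expected, atol=1e-12)

    @settings(max_examples=200, deadline=None)
    @given(dna)
    def test_matches_rational_oracle(self, seq):
        expected = [float(f) for f in nd_oracle(seq)]
        np.testing.assert_allclose(encode_nd(seq), expected, atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            encode_nd("")


class TestEIIP:
    def test_table(self):
        np.testing.assert_array_equal(
            encode_eiip("TAGC"), [0.1335, 0.1260, 0.0806, 0.1340]
        )

    def test_positional_substitution(self):
        np.testing.assert_array_equal(encode_eiip("AA"), [0.1260, 0.1260])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            encode_eiip("")


def make_records(pos, neg):
    recs = [SequenceRecord(f"p{i}", s, 1) for i, s in enumerate(pos)]
    recs += [SequenceRecord(f"n{i}", s, 0) for i, s in enumerate(neg)]
    return recs


class TestBPB:
    def test_degenerate_columns(self):
        model = fit_bpb(make_records(["AA", "AA"], ["CC", "CC"]), 2, pseudocount=0)
        assert model.positive_profile[0, 0] == 1.0   # p+(1, A)
        assert model.negative_profile[0, 1] == 1.0   # p-(1, C)
        assert model.positive_profile[0, 1] == 0.0
        np.testing.assert_array_equal(encode_bpb("AA", model), [1, 1, 0, 0])

    def test_column_counting(self):
        model = fit_bpb(make_records(["AC", "GC"], ["TT", "TT"]), 2, pseudocount=0)
        assert model.positive_profile[0, 0] == 0.5
        assert model.positive_profile[0, 2] == 0.5
        assert model.positive_profile[1, 1] == 1.0

    def test_laplace_smoothing(self):
        model = fit_bpb(make_records(["A"], ["C"]), 1, pseudocount=1)
        assert model.positive_profile[0, 0] == pytest.approx(2 / 5)
        assert model.positive_profile[0, 1] == pytest.approx(1 / 5)

    def test_rows_normalised_random_corpora(self, rng):
        for _ in range(20):
            n_pos, n_neg, L = rng.integers(2, 8), rng.integers(2, 8), rng.integers(1, 15)
            pos = ["".join("ACGT"[j] for j in rng.integers(0, 4, L)) for _ in range(n_pos)]
            neg = ["".join("ACGT"[j] for j in rng.integers(0, 4, L)) for _ in range(n_neg)]
            pc = float(rng.choice([0.0, 1.0]))
            model = fit_bpb(make_records(pos, neg), int(L), pc)
            np.testing.assert_allclose(model.positive_profile.sum(axis=1), 1, atol=1e-12)
            np.testing.assert_allclose(model.negative_profile.sum(axis=1), 1, atol=1e-12)
            # frequency agreement against direct counting
            for i in range(int(L)):
                for bi, b in enumerate("ACGT"):
                    count = sum(s[i] == b for s in pos)
                    expected = (count + pc) / (len(pos) + 4 * pc)
                    assert model.positive_profile[i, bi] == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_bpb(make_records(["AA"], []), 2)

    def test_length_mismatch(self):
        model = fit_bpb(make_records(["AA"], ["CC"]), 2)
        with pytest.raises(ValueError):
            encode_bpb("AAA", model)

    def test_json_roundtrip(self, tmp_path):
        from promgraph.encoders import BPBModel

        model = fit_bpb(make_records(["AC", "GT"], ["CC", "GG"]), 2, 0.5)
        model.to_json(tmp_path / "bpb.json")
        back = BPBModel.from_json(tmp_path / "bpb.json")
        np.testing.assert_array_equal(back.positive_profile, model.positive_profile)
        assert back.pseudocount == 0.5


class TestEncodeLocal:
    def test_eiip_only(self):
        vec = encode_local("TA", parts=("EIIP",))
        np.testing.assert_array_equal(vec, [0.1335, 0.1260])
        assert local_feature_names(2, ("EIIP",)) == ["EIIP_0", "EIIP_1"]

    def test_single_base_ncp_nd(self):
        np.testing.assert_array_equal(encode_local("A", parts=("NCP_ND",)), [1, 1, 1, 1])

    @pytest.mark.parametrize(
        "parts", [("NCP_ND",), ("EIIP",), ("BPB",), ("NCP_ND", "EIIP"),
                  ("NCP_ND", "BPB"), ("EIIP", "BPB"), ("NCP_ND", "EIIP", "BPB")]
    )
    def test_width_arithmetic(self, parts, rng):
        L = 30
        seqs = ["".join("ACGT"[j] for j in rng.integers(0, 4, L)) for _ in range(6)]
        model = fit_bpb(make_records(seqs[:3], seqs[3:]), L)
        vec = encode_local(seqs[0], model, parts)
        width = 4 * L * ("NCP_ND" in parts) + L * ("EIIP" in parts) + 2 * L * ("BPB" in parts)
        assert vec.shape == (width,)
        assert len(local_feature_names(L, parts)) == width

    def test_full_width_300bp(self, rng):
        seqs = ["".join("ACGT"[j] for j in rng.integers(0, 4, 300)) for _ in range(4)]
        model = fit_bpb(make_records(seqs[:2], seqs[2:]), 300)
        assert encode_local(seqs[0], model).shape == (2100,)

    def test_empty_parts_rejected(self):
        with pytest.raises(ValueError):
            encode_local("ACGT", parts=())

    def test_positional_locality(self):
        """Swapping two equal-prefix-density positions permutes only their blocks."""
        a, b = "ACGTAC", "ACGTCA"   # positions 4 and 5 swapped
        ncp_a = encode_ncp_nd(a).reshape(-1, 4)
        ncp_b = encode_ncp_nd(b).reshape(-1, 4)
        np.testing.assert_array_equal(ncp_a[:4], ncp_b[:4])
        eiip_a, eiip_b = encode_eiip(a), encode_eiip(b)
        np.testing.assert_array_equal(eiip_a[:4], eiip_b[:4])
        np.testing.assert_array_equal(eiip_a[[4, 5]], eiip_b[[5, 4]])


class TestSklearnFacade:
    def test_local_encoder_matrix(self, rng):
        seqs = ["".join("ACGT"[j] for j in rng.integers(0, 4, 10)) for _ in range(8)]
        y = [1, 1, 1, 1, 0, 0, 0, 0]
        enc = LocalEncoder().fit(seqs, y)
        X = enc.transform(seqs)
        assert X.shape == (8, 70)
        assert list(enc.get_feature_names_out()) == enc.feature_names_

    def test_bpb_encoder_requires_labels(self, rng):
        seqs = ["ACGT", "TTTT"]
        with pytest.raises(ValueError):
            LocalEncoder(parts=("BPB",)).fit(seqs, None)

    def test_get_params_roundtrip(self):
        enc = LocalEncoder(parts=("EIIP",), pseudocount=2.0)
        params = enc.get_params()
        assert params["pseudocount"] == 2.0
        enc2 = LocalEncoder(**params)
        assert enc2.parts == ("EIIP",)

    def test_bpb_encoder_transform(self):
        enc = BPBEncoder(pseudocount=0).fit(["AA", "CC"], [1, 0])
        np.testing.assert_array_equal(enc.transform(["AA"]), [[1, 1, 0, 0]])
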