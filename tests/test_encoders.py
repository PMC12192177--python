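"""Encoder correctness against hand-computed values and brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxipept import (
    FeatureSetSpec,
    PeptideRecord,
    encode_aaindex,
    encode_asdc,
    encode_blosum62,
    encode_ctd,
    encode_fusion,
    enumerate_feature_sets,
)
from oxipept.sequence_io import AMINO_ACIDS

peptides = st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=30)


def brute_force_asdc(seq: str) -> np.ndarray:
    """Independent oracle: enumerate every index pair i < j explicitly."""
    counts = {}
    for i, j in itertools.combinations(range(len(seq)), 2):
        counts[(seq[i], seq[j])] = counts.get((seq[i], seq[j]), 0) + 1
    total = len(seq) * (len(seq) - 1) / 2
    vec = np.zeros(400)
    for (a, b), c in counts.items():
        vec[AMINO_ACIDS.index(a) * 20 + AMINO_ACIDS.index(b)] = c / total
    return vec


class TestAsdc:
    def test_single_pair(self):
        blk = encode_asdc(PeptideRecord("p", "AC"))
        expected = np.zeros(400)
        expected[AMINO_ACIDS.index("A") * 20 + AMINO_ACIDS.index("C")] = 1.0
        np.testing.assert_array_equal(blk.values, expected)

    def test_aca_three_pairs(self):
        blk = encode_asdc(PeptideRecord("p", "ACA"))
        get = lambda a, b: blk.values[AMINO_ACIDS.index(a) * 20 + AMINO_ACIDS.index(b)]
        assert get("A", "C") == pytest.approx(1 / 3)
        assert get("A", "A") == pytest.approx(1 / 3)
        assert get("C", "A") == pytest.approx(1 / 3)
        assert blk.values.sum() == pytest.approx(1.0)

    def test_matches_brute_force_exhaustively(self):
        """Exact agreement for every peptide of length 2-5 over {A, C, D}."""
        for L in range(2, 6):
            for combo in itertools.product("ACD", repeat=L):
                seq = "".join(combo)
                got = encode_asdc(PeptideRecord("p", seq)).values
                np.testing.assert_array_equal(got, brute_force_asdc(seq))

    @settings(max_examples=60, derandomize=True)
    @given(peptides)
    def test_probability_distribution(self, seq):
        v = encode_asdc(PeptideRecord("p", seq)).values
        assert v.sum() == pytest.approx(1.0)
        assert (v >= 0).all()


class TestAaindex:
    def test_homopolymer_equals_property_column(self, bundle):
        blk = encode_aaindex(PeptideRecord("p", "AAAA"), bundle.aaindex)
        np.testing.assert_array_equal(blk.values, bundle.aaindex.values[:, 0])

    def test_pair_is_elementwise_mean(self, bundle):
        blk = encode_aaindex(PeptideRecord("p", "AC"), bundle.aaindex)
        expected = (bundle.aaindex.values[:, 0] + bundle.aaindex.values[:, 1]) / 2
        np.testing.assert_allclose(blk.values, expected)

    def test_dimension(self, bundle, peptide):
        assert encode_aaindex(peptide, bundle.aaindex).dim == 566

    def test_composition_invariant_under_repetition(self, bundle):
        a = encode_aaindex(PeptideRecord("p", "ACWY"), bundle.aaindex)
        b = encode_aaindex(PeptideRecord("q", "AACCWWYY"), bundle.aaindex)
        np.testing.assert_allclose(a.values, b.values)


class TestCtd:
    def test_homopolymer(self, bundle):
        blk = encode_ctd(PeptideRecord("p", "AAAA"), bundle.ctd_groups)
        for pi, prop in enumerate(bundle.ctd_groups.properties):
            g = bundle.ctd_groups.group_of(prop, "A")
            comp = blk.values[pi * 21: pi * 21 + 3]
            expected = np.zeros(3)
            expected[g - 1] = 1.0
            np.testing.assert_array_equal(comp, expected)
            # no transitions in a single-group sequence
            np.testing.assert_array_equal(blk.values[pi * 21 + 3: pi * 21 + 6], 0)

    def test_alternating_sequence_transitions(self, bundle):
        # A and R fall in different groups for the charge property
        blk = encode_ctd(PeptideRecord("p", "ARARAR"), bundle.ctd_groups)
        pi = bundle.ctd_groups.properties.index("charge")
        ga = bundle.ctd_groups.group_of("charge", "A")  # 2
        gr = bundle.ctd_groups.group_of("charge", "R")  # 1
        pair = tuple(sorted((ga, gr)))
        offsets = {(1, 2): 3, (1, 3): 4, (2, 3): 5}
        trans = blk.values[pi * 21 + 3: pi * 21 + 6]
        assert trans[offsets[pair] - 3] == pytest.approx(5 / 5)
        assert trans.sum() == pytest.approx(1.0)

    def test_absent_group_yields_zeros(self, bundle):
        # "KR" has no charge-group-3 (D/E) residues
        blk = encode_ctd(PeptideRecord("p", "KR"), bundle.ctd_groups)
        pi = bundle.ctd_groups.properties.index("charge")
        base = pi * 21
        assert blk.values[base + 2] == 0  # C group3
        np.testing.assert_array_equal(blk.values[base + 6 + 10: base + 6 + 15], 0)

    def test_distribution_milestones_hand_computed(self, bundle):
        # charge of "KDKDK": K group1 at positions 1,3,5; D group3 at 2,4 (L=5)
        blk = encode_ctd(PeptideRecord("p", "KDKDK"), bundle.ctd_groups)
        pi = bundle.ctd_groups.properties.index("charge")
        d1 = blk.values[pi * 21 + 6: pi * 21 + 11]
        # group1 occurrences [1,3,5]: first=1, 25%->1st, 50%->2nd, 75%->3rd, last=5
        np.testing.assert_allclose(d1, [1 / 5, 1 / 5, 3 / 5, 5 / 5, 5 / 5])
        d3 = blk.values[pi * 21 + 16: pi * 21 + 21]
        # group3 occurrences [2,4]
        np.testing.assert_allclose(d3, [2 / 5, 2 / 5, 2 / 5, 4 / 5, 4 / 5])

    def test_ratio_variant(self, bundle):
        blk = encode_ctd(PeptideRecord("p", "KDKDK"), bundle.ctd_groups,
                         d_variant="ratio")
        pi = bundle.ctd_groups.properties.index("charge")
        d1 = blk.values[pi * 21 + 6: pi * 21 + 11]
        # fraction of group-1 residues within the first 0/25/50/75/100% positions
        np.testing.assert_allclose(d1, [0, 1 / 3, 1 / 3, 2 / 3, 1.0])

    @settings(max_examples=40, derandomize=True)
    @given(peptides)
    def test_composition_sums_to_one_transitions_bounded(self, bundle, seq):
        blk = encode_ctd(PeptideRecord("p", seq), bundle.ctd_groups)
        for pi in range(13):
            comp = blk.values[pi * 21: pi * 21 + 3]
            assert comp.sum() == pytest.approx(1.0)
            assert blk.values[pi * 21 + 3: pi * 21 + 6].sum() <= 1.0 + 1e-12

    def test_dimension(self, bundle, peptide):
        assert encode_ctd(peptide, bundle.ctd_groups).dim == 273


class TestBlosum62:
    def test_homopolymer_is_matrix_row(self, bundle):
        blk = encode_blosum62(PeptideRecord("p", "AAAA"), bundle.blosum62)
        np.testing.assert_array_equal(blk.values[:21], bundle.blosum62.row("A"))
        np.testing.assert_array_equal(blk.values[21:], 0)

    def test_frequency_weighting(self, bundle):
        blk = encode_blosum62(PeptideRecord("p", "AC"), bundle.blosum62)
        np.testing.assert_allclose(blk.values[:21], 0.5 * bundle.blosum62.row("A"))
        ci = AMINO_ACIDS.index("C")
        np.testing.assert_allclose(
            blk.values[ci * 21: (ci + 1) * 21], 0.5 * bundle.blosum62.row("C")
        )
        mask = np.ones(420, dtype=bool)
        mask[:21] = False
        mask[ci * 21: (ci + 1) * 21] = False
        np.testing.assert_array_equal(blk.values[mask], 0)

    def test_dimension(self, bundle, peptide):
        assert encode_blosum62(peptide, bundle.blosum62).dim == 420

    def test_composition_invariant_under_repetition(self, bundle):
        a = encode_blosum62(PeptideRecord("p", "ACWY"), bundle.blosum62)
        b = encode_blosum62(PeptideRecord("q", "AACCWWYY"), bundle.blosum62)
        np.testing.assert_allclose(a.values, b.values)


class TestFusion:
    def test_ctd_blosum_dim(self, bundle, peptide):
        blk = encode_fusion(peptide, FeatureSetSpec.of("ctd", "blosum62"), bundle)
        assert blk.dim == 273 + 420 == 693

    def test_singleton_equals_single_encoder(self, bundle, peptide):
        fused = encode_fusion(peptide, FeatureSetSpec.of("asdc"), bundle)
        np.testing.assert_array_equal(fused.values, encode_asdc(peptide).values)

    def test_full_fusion_dim(self, bundle, peptide):
        spec = FeatureSetSpec.of("aaindex", "asdc", "blosum62", "ctd")
        assert encode_fusion(peptide, spec, bundle).dim == 1659

    def test_canonical_order_regardless_of_user_order(self, bundle, peptide):
        a = encode_fusion(peptide, FeatureSetSpec.of("ctd", "blosum62"), bundle)
        b = encode_fusion(peptide, FeatureSetSpec.of("blosum62", "ctd"), bundle)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.labels == b.labels

    def test_labels_prefixed_and_aligned(self, bundle, peptide):
        blk = encode_fusion(peptide, FeatureSetSpec.of("ctd", "blosum62"), bundle)
        assert blk.labels[0].startswith("blosum62.")
        assert blk.labels[-1].startswith("ctd.")
        assert len(blk.labels) == blk.dim

    def test_determinism(self, bundle, peptide):
        spec = FeatureSetSpec.of("aaindex", "ctd")
        a = encode_fusion(peptide, spec, bundle)
        b = encode_fusion(peptide, spec, bundle)
        np.testing.assert_array_equal(a.values, b.values)


class TestEnumerateFeatureSets:
    def test_four_encoders_give_fifteen_specs(self):
        specs = enumerate_feature_sets()
        assert len(specs) == 15
        assert sum(1 for s in specs if len(s.members) >= 2) == 11
        assert [len(s.members) for s in specs[:4]] == [1, 1, 1, 1]

    def test_three_encoders_give_seven(self):
        assert len(enumerate_feature_sets(["aaindex", "asdc", "ctd"])) == 7

    def test_single_encoder(self):
        assert len(enumerate_feature_sets(["ctd"])) == 1

    def test_empty_base_rejected(self):
        with pytest.raises(ValueError):
            enumerate_feature_sets([])

    def test_unknown_encoder_rejected(self):
        with pytest.raises(ValueError, match="valid names"):
            FeatureSetSpec.of("ctd", "onehot")
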