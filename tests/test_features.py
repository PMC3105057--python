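import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afpid.features import (
    AttributeMatch,
    DegenerateInputError,
    SchemeSpec,
    UnknownAttributeError,
    attribute_names,
    build_scheme_matrix,
    compute_features,
    default_scheme_set,
    gapped_dipeptide_composition,
    iter_matches,
    match_attribute_positions,
    npeptide_composition,
    partitioned_composition,
    segment_bounds,
    window_composition,
)
from afpid.seqio import CANONICAL_RESIDUES, ProteinRecord
from helpers import bf_counts

seq_strategy = st.text(alphabet=CANONICAL_RESIDUES, min_size=1, max_size=30)

scheme_strategy = st.one_of(
    st.builds(
        SchemeSpec,
        kind=st.just("npeptide"),
        alphabet=st.sampled_from("AHSE"),
        n=st.integers(1, 3),
    ),
    st.builds(
        SchemeSpec,
        kind=st.just("partitioned"),
        alphabet=st.sampled_from("AH"),
        n=st.integers(1, 2),
        k=st.integers(1, 4),
    ),
    st.builds(SchemeSpec, kind=st.just("gapped_dipeptide"), g=st.integers(0, 4)),
    st.builds(SchemeSpec, kind=st.just("window"), l=st.sampled_from([3, 5, 7])),
)


class TestNPeptide:
    def test_aaag_monomers(self):
        fv = npeptide_composition("AAAG", 1)
        assert fv.values["A"] == pytest.approx(0.75)
        assert fv.values["G"] == pytest.approx(0.25)
        assert sum(v for a, v in fv.values.items() if a not in "AG") == 0

    def test_ntalt_dipeptides(self):
        fv = npeptide_composition("NTALT", 2)
        nonzero = {a: v for a, v in fv.values.items() if v}
        assert nonzero == {
            "NT": pytest.approx(0.25),
            "TA": pytest.approx(0.25),
            "AL": pytest.approx(0.25),
            "LT": pytest.approx(0.25),
        }

    @given(seq=seq_strategy)
    @settings(max_examples=30, deadline=None)
    def test_monomer_normalization(self, seq):
        fv = npeptide_composition(seq, 1)
        assert sum(fv.values.values()) == pytest.approx(1.0, abs=1e-12)

    def test_too_short_errors(self):
        with pytest.raises(DegenerateInputError):
            npeptide_composition("AC", 3)


class TestPartitioned:
    def test_hand_split(self):
        fv = partitioned_composition("AAAAGG", k=2, n=1)
        assert fv.values["s1|A"] == pytest.approx(1.0)  # "AAA"
        assert fv.values["s2|A"] == pytest.approx(1 / 3)  # "AGG"
        assert fv.values["s2|G"] == pytest.approx(2 / 3)

    def test_k1_reduces_to_npeptide(self):
        plain = npeptide_composition("NTALT", 2)
        part = partitioned_composition("NTALT", k=1, n=2)
        for attr, v in plain.values.items():
            assert part.values[f"s1|{attr}"] == pytest.approx(v)

    @given(seq=st.text(alphabet=CANONICAL_RESIDUES, min_size=6, max_size=30), k=st.integers(1, 3))
    @settings(max_examples=30, deadline=None)
    def test_each_segment_sums_to_one(self, seq, k):
        fv = partitioned_composition(seq, k=k, n=1)
        for seg in range(1, k + 1):
            total = sum(v for a, v in fv.values.items() if a.startswith(f"s{seg}|"))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_total_sums_to_k(self):
        fv = partitioned_composition("NTALTNTALT", k=3, n=1)
        assert sum(fv.values.values()) == pytest.approx(3.0, abs=1e-12)

    def test_remainder_to_leading_segments(self):
        assert segment_bounds(7, 3) == [(0, 3), (3, 5), (5, 7)]

    def test_too_short_errors(self):
        with pytest.raises(DegenerateInputError):
            partitioned_composition("ACD", k=2, n=2)


class TestGappedDipeptide:
    def test_ntalt_g0_lt(self):
        fv = gapped_dipeptide_composition("NTALT", 0)
        assert fv.values["LT"] == pytest.approx(0.25)

    def test_ntalt_g2_txxt(self):
        fv = gapped_dipeptide_composition("NTALT", 2)
        assert fv.values["TxxT"] == pytest.approx(0.5)

    @given(seq=st.text(alphabet=CANONICAL_RESIDUES, min_size=2, max_size=30))
    @settings(max_examples=30, deadline=None)
    def test_g0_equals_dipeptide_composition(self, seq):
        gapped = gapped_dipeptide_composition(seq, 0)
        plain = npeptide_composition(seq, 2)
        for attr, v in plain.values.items():
            assert gapped.values[attr] == pytest.approx(v)

    def test_too_short_errors(self):
        with pytest.raises(DegenerateInputError):
            gapped_dipeptide_composition("ACD", 2)


class TestWindow:
    def test_aaa_l3(self):
        fv = window_composition("AAA", 3)
        assert fv.values["A|A"] == pytest.approx(1.0)
        assert sum(fv.values.values()) == pytest.approx(1.0)

    def test_absent_center_all_zero(self):
        fv = window_composition("ACDE", 5)
        assert all(v == 0 for a, v in fv.values.items() if a.startswith("K|"))

    @given(seq=st.text(alphabet=CANONICAL_RESIDUES, min_size=2, max_size=30), l=st.sampled_from([3, 7]))
    @settings(max_examples=30, deadline=None)
    def test_per_center_normalization(self, seq, l):
        fv = window_composition(seq, l)
        for c in set(seq):
            total = sum(v for a, v in fv.values.items() if a.startswith(f"{c}|"))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            SchemeSpec("window", l=4)


class TestCountOracle:
    @given(seq=seq_strategy, scheme=scheme_strategy)
    @settings(max_examples=80, deadline=None)
    def test_counts_match_brute_force(self, registry, seq, scheme):
        if len(seq) < scheme.min_length():
            with pytest.raises(DegenerateInputError):
                compute_features(seq, scheme, registry)
            return
        ab = registry[scheme.alphabet]
        expected = bf_counts(ab.encode(seq), scheme, ab.symbols)
        observed = {}
        for m in iter_matches(seq, scheme, registry):
            observed[m.attribute] = observed.get(m.attribute, 0) + 1
        assert observed == expected

    @given(seq=seq_strategy, scheme=scheme_strategy)
    @settings(max_examples=40, deadline=None)
    def test_matches_reproduce_values(self, registry, seq, scheme):
        """|occurrences| / denominator reproduces every nonzero value."""
        if len(seq) < scheme.min_length():
            return
        fv = compute_features(seq, scheme, registry)
        ab = registry[scheme.alphabet]
        enc = ab.encode(seq)
        L = len(enc)

        def denominator(attr: str) -> float:
            if scheme.kind == "npeptide":
                return L - scheme.n + 1
            if scheme.kind == "partitioned":
                seg = int(attr.split("|")[0][1:])
                lo, hi = segment_bounds(L, scheme.k)[seg - 1]
                return hi - lo - scheme.n + 1
            if scheme.kind == "gapped_dipeptide":
                return L - scheme.g - 1
            center = attr.split("|")[0]
            h = (scheme.l - 1) // 2
            return sum(
                min(L, i + h + 1) - max(0, i - h) - 1
                for i, c in enumerate(enc)
                if c == center
            )

        for attr, v in fv.values.items():
            if v:
                n_occ = len(match_attribute_positions(seq, scheme, attr, registry))
                assert v == pytest.approx(n_occ / denominator(attr))


class TestMatchPositions:
    def test_ntalt_d0_lt(self):
        ms = match_attribute_positions("NTALT", SchemeSpec("gapped_dipeptide", g=0), "LT")
        assert ms == [AttributeMatch("LT", (3, 4))]

    def test_ntalt_g2_anchors_only(self):
        ms = match_attribute_positions("NTALT", SchemeSpec("gapped_dipeptide", g=2), "TxxT")
        assert ms == [AttributeMatch("TxxT", (1, 4))]

    def test_overlapping_npeptide_occurrences(self):
        ms = match_attribute_positions("AAAA", SchemeSpec("npeptide", n=2), "AA")
        assert [m.positions for m in ms] == [(0, 1), (1, 2), (2, 3)]

    def test_partitioned_offsets_into_segment(self):
        ms = match_attribute_positions(
            "AAAAGG", SchemeSpec("partitioned", k=2), "s2|G"
        )
        assert [m.positions for m in ms] == [(4,), (5,)]

    def test_unknown_attribute(self):
        with pytest.raises(UnknownAttributeError):
            match_attribute_positions("NTALT", SchemeSpec("npeptide", n=1), "ZZ")

    @given(seq=st.text(alphabet="ATL", min_size=4, max_size=20), prefix_len=st.integers(1, 5))
    @settings(max_examples=30, deadline=None)
    def test_shift_consistency(self, seq, prefix_len):
        """A prefix of an absent symbol shifts gapped anchors by its length."""
        scheme = SchemeSpec("gapped_dipeptide", g=1)
        base = [
            m.positions
            for m in iter_matches(seq, scheme)
            if "W" not in m.attribute
        ]
        shifted = [
            m.positions
            for m in iter_matches("W" * prefix_len + seq, scheme)
            if "W" not in m.attribute
        ]
        assert shifted == [tuple(p + prefix_len for p in ps) for ps in base]


class TestDefaultSchemeSet:
    def test_thirteen_schemes(self):
        names = [s.name for s in default_scheme_set()]
        assert names == [
            "C", "X5", "X6", "X7", "D0", "D1", "D3", "D6",
            "H3X5", "P3X5", "S2X5", "W7", "W11",
        ]

    @pytest.mark.parametrize(
        "name,count",
        [
            ("C", 20), ("X5", 100), ("X6", 120), ("X7", 140),
            ("D0", 400), ("D1", 400), ("D3", 400), ("D6", 400),
            ("H3X5", 135), ("P3X5", 135), ("S2X5", 245),
            ("W7", 400), ("W11", 400),
        ],
    )
    def test_attribute_counts(self, registry, name, count):
        scheme = {s.name: s for s in default_scheme_set()}[name]
        assert len(attribute_names(scheme, registry)) == count


class TestBuildSchemeMatrix:
    def test_identical_rows(self, registry):
        recs = [
            ProteinRecord(id="a", sequence="NTALT"),
            ProteinRecord(id="b", sequence="NTALT"),
        ]
        sm = build_scheme_matrix(recs, SchemeSpec("npeptide", n=2), registry)
        assert np.array_equal(sm.matrix[0], sm.matrix[1])

    def test_all_zero_column_retained(self, registry):
        recs = [ProteinRecord(id="a", sequence="AAAA")]
        sm = build_scheme_matrix(recs, SchemeSpec("npeptide", n=1), registry)
        assert sm.matrix.shape == (1, 20)
        assert sm.matrix[0, sm.attribute_order.index("W")] == 0.0

    def test_short_records_flagged_not_zero_filled(self, registry):
        recs = [
            ProteinRecord(id="long", sequence="NTALTNTALT"),
            ProteinRecord(id="short", sequence="ACD"),
        ]
        with pytest.warns(UserWarning, match="short"):
            sm = build_scheme_matrix(recs, SchemeSpec("gapped_dipeptide", g=6), registry)
        assert sm.record_ids == ["long"]
        assert sm.skipped_ids == ["short"]
        assert sm.matrix.shape[0] == 1

    def test_row_and_column_order_deterministic(self, registry, small_benchmark):
        recs = small_benchmark.dataset.records[:10]
        a = build_scheme_matrix(recs, SchemeSpec("gapped_dipeptide", g=0), registry)
        b = build_scheme_matrix(recs, SchemeSpec("gapped_dipeptide", g=0), registry)
        assert a.record_ids == b.record_ids == [r.id for r in recs]
        assert a.attribute_order == b.attribute_order
        assert np.array_equal(a.matrix, b.matrix)
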