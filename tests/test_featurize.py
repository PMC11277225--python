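"""Fingerprints, Tanimoto, Shannon entropy, the two-stage filter, and the
physicochemical profile."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from reprotox import (BitFingerprint, EntropyFilter, MoleculeRecord,
                      ZeroFractionFilter, compute_descriptors, entropy_filter,
                      maccs_fingerprint, morgan_fingerprint, property_profile,
                      shannon_entropy, tanimoto, zero_fraction_filter)


def _fp(on_bits, nbits=16):
    bits = np.zeros(nbits, dtype=np.uint8)
    bits[list(on_bits)] = 1
    return BitFingerprint(bits=bits, scheme="morgan", nbits=nbits, radius=2)


class TestFingerprints:
    def test_deterministic_and_smiles_invariant(self):
        a = morgan_fingerprint(MoleculeRecord("a", "CCO", 1))
        b = morgan_fingerprint(MoleculeRecord("b", "OCC", 0))
        assert np.array_equal(a.bits, b.bits)
        assert a.nbits == 2048 and a.radius == 2

    def test_methane_has_a_single_environment(self):
        # one heavy atom: a radius-0 environment only
        assert morgan_fingerprint(MoleculeRecord("m", "C", 1)).popcount() == 1

    def test_maccs_has_166_keyed_bits(self):
        fp = maccs_fingerprint(MoleculeRecord("p", "c1ccccc1O", 1))
        assert fp.nbits == 166 and fp.scheme == "maccs"
        assert 0 < fp.popcount() <= 166


class TestTanimoto:
    def test_hand_computed_overlap(self):
        # bits {1,2,3} vs {2,3,4}: intersection 2, union 4
        assert tanimoto(_fp({1, 2, 3}), _fp({2, 3, 4})) == 0.5

    def test_identical_and_disjoint(self):
        assert tanimoto(_fp({1, 5}), _fp({1, 5})) == 1.0
        assert tanimoto(_fp({1}), _fp({2})) == 0.0

    def test_all_zero_convention(self):
        assert tanimoto(_fp(set()), _fp(set())) == 1.0

    def test_mismatched_length_raises(self):
        with pytest.raises(ValueError):
            tanimoto(_fp({1}, nbits=16), _fp({1}, nbits=32))

    @given(st.sets(st.integers(0, 15)), st.sets(st.integers(0, 15)))
    @settings(derandomize=True, max_examples=80)
    def test_symmetry_and_bounds(self, a_bits, b_bits):
        a, b = _fp(a_bits), _fp(b_bits)
        s = tanimoto(a, b)
        assert 0.0 <= s <= 1.0
        assert s == tanimoto(b, a)
        assert tanimoto(a, a) == 1.0


class TestShannonEntropy:
    def test_constant_column_is_zero_bits(self):
        assert shannon_entropy([3.3] * 12) == 0.0

    def test_uniform_occupation_is_log2_bins(self):
        assert shannon_entropy(np.arange(10) + 0.5, bins=10) == \
            pytest.approx(np.log2(10), abs=1e-12)

    def test_hand_histogram_example(self):
        # [0,0,0,0,1,1,2,3] over 4 bins: p = (4,2,1,1)/8 -> 1.75 bits
        assert shannon_entropy([0, 0, 0, 0, 1, 1, 2, 3], bins=4) == \
            pytest.approx(1.75, abs=1e-12)

    def test_matches_numpy_histogram_oracle_on_random_columns(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 17))
            col = rng.normal(size=n) * rng.uniform(0.1, 50)
            counts, _ = np.histogram(col, bins=10)
            p = counts[counts > 0] / n
            expected = float(-(p * np.log2(p)).sum())
            assert shannon_entropy(col, bins=10) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0.1, 100), st.floats(-50, 50))
    @settings(derandomize=True, max_examples=50)
    def test_affine_invariance(self, scale, shift):
        # interior values kept off bin edges so rescaling cannot flip a bin
        col = np.array([0.0, 0.13, 0.27, 0.52, 0.55, 0.61, 0.77, 0.94, 1.0])
        assert shannon_entropy(col * scale + shift) == \
            pytest.approx(shannon_entropy(col), abs=1e-9)

    def test_entropy_bounds(self, rng):
        for _ in range(20):
            col = rng.uniform(size=30)
            h = shannon_entropy(col, bins=8)
            assert 0.0 <= h <= np.log2(8) + 1e-12


def _table(columns: dict) -> pd.DataFrame:
    return pd.DataFrame(columns)


class TestFilters:
    def test_zero_fraction_boundary_is_strict(self):
        t = _table({
            "nine_of_ten": [0.0] * 9 + [1.0],    # exactly 0.9 -> kept
            "all_zero": [0.0] * 10,              # 1.0 -> dropped
            "dense": list(range(1, 11)),         # kept
        })
        out, report = zero_fraction_filter(t, threshold=0.9)
        assert list(out.columns) == ["nine_of_ten", "dense"]
        assert report.dropped_zero == ["all_zero"]

    def test_entropy_filter_drops_constant_and_keeps_rich(self):
        rich = np.arange(10) + 0.5           # log2(10) ~ 3.32 bits
        t = _table({"const": [5.0] * 10, "rich": rich})
        out, report = entropy_filter(t, threshold=2.5, bins=10)
        assert list(out.columns) == ["rich"]
        assert report.dropped_entropy == ["const"]

    def test_threshold_boundary_value_is_kept(self):
        # strictly-below rule: a column at exactly the threshold survives
        col = np.arange(10) + 0.5
        h = shannon_entropy(col, bins=10)
        t = _table({"at_threshold": col})
        out, _ = entropy_filter(t, threshold=h, bins=10)
        assert list(out.columns) == ["at_threshold"]

    def test_two_stage_report_partitions_columns(self):
        t = _table({
            "sparse": [0.0] * 19 + [1.0],
            "const": [2.0] * 20,
            "rich": np.linspace(0, 10, 20),
        })
        stage1, rep1 = zero_fraction_filter(t)
        stage2, rep2 = entropy_filter(stage1, prior=rep1)
        rep2.validate(t.columns)
        assert set(rep2.dropped_zero) == {"sparse"}
        assert set(rep2.dropped_entropy) == {"const"}
        assert set(rep2.kept) == {"rich"}

    def test_filter_idempotence(self):
        t = _table({
            "sparse": [0.0] * 19 + [1.0],
            "rich": np.linspace(0, 10, 20),
        })
        once, _ = zero_fraction_filter(t)
        twice, _ = zero_fraction_filter(once)
        pd.testing.assert_frame_equal(once, twice)
        e_once, _ = entropy_filter(once)
        e_twice, _ = entropy_filter(e_once)
        pd.testing.assert_frame_equal(e_once, e_twice)

    def test_sklearn_transformer_api(self):
        t = _table({"a": [0.0] * 10, "b": np.arange(10.0)})
        f = ZeroFractionFilter().fit(t)
        assert f.get_params() == {"threshold": 0.9}
        assert list(f.transform(t).columns) == ["b"]
        e = EntropyFilter(threshold=1.0, bins=5).fit(t[["b"]])
        assert e.entropies_["b"] > 1.0


class TestDescriptorsAndProfile:
    def test_descriptor_table_shape_and_determinism(self, toy_records):
        t = compute_descriptors(toy_records[:4])
        assert t.shape[0] == 4 and t.shape[1] > 150
        assert not t.isna().any().any()
        t2 = compute_descriptors(toy_records[:4])
        pd.testing.assert_frame_equal(t, t2)

    def test_identical_molecules_identical_rows(self):
        recs = [MoleculeRecord("a", "CCO", 1), MoleculeRecord("b", "CCO", 0)]
        t = compute_descriptors(recs)
        assert np.array_equal(t.iloc[0].to_numpy(), t.iloc[1].to_numpy())

    def test_benzene_ring_descriptors(self):
        t = compute_descriptors([MoleculeRecord("b", "c1ccccc1", 0)])
        assert t["RingCount"].iloc[0] == 1

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            compute_descriptors([])

    def test_phenol_profile(self):
        p = property_profile(MoleculeRecord("p", "Oc1ccccc1", 1))
        assert (p.nHD, p.nHA, p.nRing, p.MaxRing) == (1, 1, 1, 6)
        assert p.fChar == 1.0

    def test_methane_profile(self):
        p = property_profile(MoleculeRecord("m", "C", 0))
        assert p.TPSA == 0.0
        assert p.nRing == 0 and p.MaxRing == 0

    def test_counts_non_negative_and_ring_invariant(self, toy_records):
        for rec in toy_records[:10]:
            p = property_profile(rec)
            assert min(p.nHD, p.nHA, p.nRot, p.nRing, p.nHet, p.nRig) >= 0
            assert p.TPSA >= 0
            if p.nRing > 0:
                assert p.MaxRing >= 3
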