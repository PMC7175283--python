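"""Segment scheme, f/s/l encoding, prevalence profiles, sensitive filter."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flexsig.features import (FEATURE_NAMES, N_FEATURES, SEGMENT_NAMES,
                              FeatureMatrix, PrevalenceProfile, SegmentScheme,
                              SegmentStateVector, classify_segment_state,
                              encode_feature_vector, load_segment_schemes,
                              prevalence_profile, select_sensitive_features,
                              split_helix)
from flexsig.rigidity import AnalysisConfig
from flexsig.synthetic import FeatureGenSpec, make_feature_dataset


def test_segment_scheme_has_29_segments_87_features():
    assert len(SEGMENT_NAMES) == 29
    assert len(FEATURE_NAMES) == 87
    assert "H2.2s" in FEATURE_NAMES and "ECL1l" in FEATURE_NAMES


@pytest.mark.parametrize("n,expected", [
    (30, (10, 10, 10)),
    (31, (11, 10, 10)),
    (32, (11, 11, 10)),
])
def test_split_helix_remainder_rule(n, expected):
    parts = split_helix(1, n)
    sizes = tuple(b - a + 1 for a, b in parts)
    assert sizes == expected
    # contiguous and in N->C order
    assert parts[0][0] == 1 and parts[-1][1] == n
    assert parts[0][1] + 1 == parts[1][0] and parts[1][1] + 1 == parts[2][0]


def test_split_helix_too_short():
    with pytest.raises(ValueError):
        split_helix(1, 2)


_HELICES = {
    "H1": (30, 60), "H2": (67, 96), "H3": (103, 136), "H4": (147, 171),
    "H5": (197, 229), "H6": (267, 298), "H7": (305, 328), "H8": (330, 341),
}


def test_scheme_from_helix_ranges_is_complete_and_disjoint():
    scheme = SegmentScheme.from_helix_ranges(_HELICES)
    assert set(scheme.ranges) == set(SEGMENT_NAMES)
    spans = sorted(scheme.ranges.values())
    assert all(e1 < s2 for (_, e1), (s2, _) in zip(spans, spans[1:]))
    # loops fill the gaps between helices
    assert scheme.ranges["ICL1"] == (61, 66)
    assert scheme.ranges["ECL1"] == (97, 102)


def test_scheme_toml_roundtrip(tmp_path):
    text = "[demo]\n" + "\n".join(
        f'{name} = "{a}-{b}"' for name, (a, b) in _HELICES.items())
    p = tmp_path / "segs.toml"
    p.write_text(text)
    schemes = load_segment_schemes(p)
    assert schemes["demo"].ranges == SegmentScheme.from_helix_ranges(_HELICES).ranges


class TestClassifySegmentState:
    scheme = SegmentScheme.from_helix_ranges(_HELICES)

    def test_unanimous_largest(self):
        labels = {r: "largest" for r in self.scheme.residues_of("H1.1")}
        assert classify_segment_state(labels, self.scheme, "H1.1") == "l"

    def test_plurality_flexible(self):
        rs = list(self.scheme.residues_of("ICL1"))  # 6 residues
        labels = {r: "flexible" for r in rs[:4]}
        labels.update({r: "largest" for r in rs[4:]})
        assert classify_segment_state(labels, self.scheme, "ICL1") == "f"

    def test_tie_breaks_l_over_s_over_f(self):
        rs = list(self.scheme.residues_of("ICL1"))[:5]
        labels = dict(zip(rs, ["largest", "largest", "separate", "separate",
                               "flexible"]))
        assert classify_segment_state(labels, self.scheme, "ICL1") == "l"

    def test_missing_residues_excluded_from_vote(self):
        rs = list(self.scheme.residues_of("ICL1"))
        labels = {rs[0]: "separate"}  # the rest unresolved
        assert classify_segment_state(labels, self.scheme, "ICL1") == "s"

    def test_fully_missing_segment_defaults_flexible(self):
        with pytest.warns(UserWarning):
            assert classify_segment_state({}, self.scheme, "ECL2") == "f"

    def test_permutation_invariant(self):
        rs = list(self.scheme.residues_of("H3.2"))
        lab = (["flexible", "separate", "largest"] * len(rs))[:len(rs)]
        rng = np.random.default_rng(4)
        a = classify_segment_state(dict(zip(rs, lab)), self.scheme, "H3.2")
        b = classify_segment_state(dict(zip(rs, rng.permutation(lab))),
                                   self.scheme, "H3.2")
        assert a == b


def _vector(**states):
    full = {seg: "l" for seg in SEGMENT_NAMES}
    full.update(states)
    return SegmentStateVector(structure_id="x", states=full, activity=0)


class TestEncoding:
    def _bits(self, row, names):
        pos = {n: i for i, n in enumerate(FEATURE_NAMES)}
        return tuple(int(row[pos[n]]) for n in names)

    def test_worked_inactive_pattern(self):
        """H5.1 in the largest rigid region, H2.2 not separately rigid,
        H3.1 not flexible encodes (1, 0, 0) on (H5.1l, H2.2s, H3.1f)."""
        row = encode_feature_vector(_vector())
        assert self._bits(row, ("H5.1l", "H2.2s", "H3.1f")) == (1, 0, 0)

    def test_worked_active_pattern(self):
        row = encode_feature_vector(_vector(**{"H3.1": "f"}))
        assert self._bits(row, ("H5.1l", "H2.2s", "H3.1f")) == (1, 0, 1)

    def test_row_sum_is_29(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            states = {seg: rng.choice(["f", "s", "l"])
                      for seg in SEGMENT_NAMES}
            row = encode_feature_vector(
                SegmentStateVector("x", states, activity=1))
            assert row.sum() == 29


class TestPrevalence:
    def _matrix(self, col_active, col_inactive, feature="ECL1l"):
        n_a, n_i = len(col_active), len(col_inactive)
        data = np.zeros((n_a + n_i, N_FEATURES), dtype=np.int8)
        fidx = FEATURE_NAMES.index(feature)
        data[:n_i, fidx] = col_inactive
        data[n_i:, fidx] = col_active
        # keep one-hot-ish rows irrelevant here; labels are what matters
        labels = np.array([0] * n_i + [1] * n_a, dtype=np.int8)
        ids = [f"s{i}" for i in range(n_a + n_i)]
        return FeatureMatrix(ids, data, labels)

    def test_frequencies_and_difference(self):
        m = self._matrix([1] * 6 + [0] * 3, [1] * 3 + [0] * 15)
        p = prevalence_profile(m)
        row = p.table.loc["ECL1l"]
        assert row.freq_active == pytest.approx(6 / 9)
        assert row.freq_inactive == pytest.approx(3 / 18)
        assert row.abs_difference == pytest.approx(0.5)

    def test_absent_feature_zero_difference(self):
        m = self._matrix([0] * 9, [0] * 18)
        assert prevalence_profile(m).table.loc["ECL1l"].abs_difference == 0

    def test_single_class_rejected(self):
        m = self._matrix([1] * 9, [0] * 18)
        m.labels[:] = 1
        with pytest.raises(ValueError):
            prevalence_profile(m)

    def test_per_segment_frequencies_sum_to_one(self):
        m = make_feature_dataset(FeatureGenSpec(seed=3))
        p = prevalence_profile(m)
        for seg in SEGMENT_NAMES:
            for col in ("freq_active", "freq_inactive"):
                total = sum(p.table.loc[f"{seg}{st}", col]
                            for st in ("f", "s", "l"))
                assert total == pytest.approx(1.0)


class TestSensitiveFeatures:
    def _profile(self, diffs):
        import pandas as pd
        table = pd.DataFrame(
            {"freq_active": 0.0, "freq_inactive": 0.0,
             "abs_difference": [diffs.get(f, 0.0) for f in FEATURE_NAMES]},
            index=list(FEATURE_NAMES))
        return PrevalenceProfile(table=table)

    def test_one_feature_per_segment(self):
        p = self._profile({"H2.1f": 0.30, "H2.1l": 0.40})
        assert select_sensitive_features(p) == ["H2.1l"]

    def test_threshold_is_inclusive_at_quarter(self):
        p = self._profile({"H2.1f": 0.24, "H3.1f": 0.25})
        assert select_sensitive_features(p) == ["H3.1f"]

    def test_ordered_by_descending_difference(self):
        p = self._profile({"H2.1s": 0.5, "ECL1l": 0.3, "H3.1f": 0.4})
        assert select_sensitive_features(p) == ["H2.1s", "H3.1f", "ECL1l"]

    def test_planted_feature_recovered(self):
        spec = FeatureGenSpec(n_active=300, n_inactive=600,
                              planted=(("H2.2s", 0.6, 0.0),), seed=1)
        m = make_feature_dataset(spec)
        sens = select_sensitive_features(prevalence_profile(m))
        assert sens[0] == "H2.2s"

    def test_stable_under_row_shuffling(self):
        m = make_feature_dataset(FeatureGenSpec(seed=8))
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.n)
        shuffled = FeatureMatrix([m.structure_ids[i] for i in perm],
                                 m.data[perm], m.labels[perm])
        assert (select_sensitive_features(prevalence_profile(m))
                == select_sensitive_features(prevalence_profile(shuffled)))


def test_feature_matrix_csv_roundtrip(tmp_path, planted_matrix):
    p = tmp_path / "features.csv"
    planted_matrix.to_csv(p)
    back = FeatureMatrix.from_csv(p)
    assert back.structure_ids == planted_matrix.structure_ids
    np.testing.assert_array_equal(back.data, planted_matrix.data)
    np.testing.assert_array_equal(back.labels, planted_matrix.labels)
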