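"""The 29-segment receptor scheme and its 87-bit flexibility encoding.

Class A G protein-coupled receptors are partitioned into 29 segments: each
of the seven transmembrane helices contributes three thirds (numbered from
the N-terminus), the short intracellular helix 8 contributes two halves,
and the six connecting loops (ICL1-3, ECL1-3) contribute one segment each.
Every segment is assigned one flexibility state per structure — flexible
(f), separately rigid (s), or part of the largest rigid region (l) — giving
a one-hot encoding over 29 x 3 = 87 binary features named like ``H2.2s`` or
``ECL1l``.
"""

from __future__ import annotations

import logging
import math
import tomllib
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .rigidity import LABEL_FLEXIBLE, LABEL_LARGEST, LABEL_SEPARATE, AnalysisConfig

logger = logging.getLogger(__name__)

#: Segment order along the sequence: helix thirds N->C, loops in between.
SEGMENT_NAMES: tuple[str, ...] = (
    "H1.1", "H1.2", "H1.3", "ICL1",
    "H2.1", "H2.2", "H2.3", "ECL1",
    "H3.1", "H3.2", "H3.3", "ICL2",
    "H4.1", "H4.2", "H4.3", "ECL2",
    "H5.1", "H5.2", "H5.3", "ICL3",
    "H6.1", "H6.2", "H6.3", "ECL3",
    "H7.1", "H7.2", "H7.3",
    "H8.1", "H8.2",
)

STATES: tuple[str, ...] = ("f", "s", "l")

#: The 87 feature names, segment-major then state.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{seg}{st}" for seg in SEGMENT_NAMES for st in STATES
)

N_SEGMENTS = len(SEGMENT_NAMES)
N_FEATURES = len(FEATURE_NAMES)

_STATE_OF_LABEL = {LABEL_FLEXIBLE: "f", LABEL_SEPARATE: "s", LABEL_LARGEST: "l"}


def split_helix(start: int, end: int) -> list[tuple[int, int]]:
    """Split an inclusive residue range into three contiguous thirds.

    Thirds are emitted in N->C residue order with sizes ``ceil(n/3)``,
    ``n - n1 - n3`` and ``floor(n/3)``.
    """
    n = end - start + 1
    if n < 3:
        raise ValueError(f"helix range {start}-{end} too short to split in three")
    n1 = math.ceil(n / 3)
    n3 = n // 3
    n2 = n - n1 - n3
    b1 = start + n1 - 1
    b2 = b1 + n2
    return [(start, b1), (b1 + 1, b2), (b2 + 1, end)]


def split_h8(start: int, end: int) -> list[tuple[int, int]]:
    """Split helix 8 into two halves (first half gets the extra residue)."""
    n = end - start + 1
    if n < 2:
        raise ValueError(f"helix 8 range {start}-{end} too short to split in two")
    n1 = math.ceil(n / 2)
    return [(start, start + n1 - 1), (start + n1, end)]


@dataclass
class SegmentScheme:
    """Residue ranges (author numbering, inclusive) for the 29 segments of
    one structure."""

    ranges: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        missing = set(SEGMENT_NAMES) - set(self.ranges)
        extra = set(self.ranges) - set(SEGMENT_NAMES)
        if missing or extra:
            raise ValueError(f"segment scheme mismatch; missing={sorted(missing)},"
                             f" unexpected={sorted(extra)}")
        spans = sorted(self.ranges.values())
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping segment ranges {s1}-{e1} and {s2}-{e2}")

    @classmethod
    def from_helix_ranges(cls, helices: Mapping[str, tuple[int, int]],
                          loops: Mapping[str, tuple[int, int]] | None = None,
                          ) -> "SegmentScheme":
        """Derive the 29 segments from whole-helix ranges H1..H8.

        Loop ranges may be given explicitly; otherwise each loop takes the
        residues strictly between its flanking helices.
        """
        loops = dict(loops or {})
        ranges: dict[str, tuple[int, int]] = {}
        for h in range(1, 8):
            name = f"H{h}"
            if name not in helices:
                raise ValueError(f"missing helix range {name}")
            for i, rng in enumerate(split_helix(*helices[name]), start=1):
                ranges[f"{name}.{i}"] = rng
        if "H8" not in helices:
            raise ValueError("missing helix range H8")
        for i, rng in enumerate(split_h8(*helices["H8"]), start=1):
            ranges[f"H8.{i}"] = rng
        loop_between = {
            "ICL1": ("H1", "H2"), "ECL1": ("H2", "H3"), "ICL2": ("H3", "H4"),
            "ECL2": ("H4", "H5"), "ICL3": ("H5", "H6"), "ECL3": ("H6", "H7"),
        }
        for loop, (ha, hb) in loop_between.items():
            if loop in loops:
                ranges[loop] = tuple(loops[loop])
            else:
                ranges[loop] = (helices[ha][1] + 1, helices[hb][0] - 1)
        return cls(ranges=ranges)

    def residues_of(self, name: str) -> range:
        start, end = self.ranges[name]
        return range(start, end + 1)


def load_segment_schemes(path: str | Path) -> dict[str, SegmentScheme]:
    """Read per-structure segment definitions from a TOML file.

    Each ``[<structure id>]`` table maps helix names (``H1`` ... ``H8``) and
    optionally loop names to ``"start-end"`` strings or two-element arrays;
    helices are split into thirds (halves for H8) automatically.  Explicit
    per-segment tables (``H2.2 = "70-75"``) are also accepted.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    def parse_range(value) -> tuple[int, int]:
        if isinstance(value, str):
            a, b = value.replace(" ", "").split("-")
            return int(a), int(b)
        a, b = value
        return int(a), int(b)

    out: dict[str, SegmentScheme] = {}
    for sid, table in raw.items():
        entries = {k: parse_range(v) for k, v in table.items()}
        if set(entries) >= set(SEGMENT_NAMES):
            out[sid] = SegmentScheme(ranges={k: entries[k] for k in SEGMENT_NAMES})
        else:
            helices = {k: v for k, v in entries.items()
                       if k.startswith("H") and "." not in k}
            loops = {k: v for k, v in entries.items() if k.startswith(("ICL", "ECL"))}
            out[sid] = SegmentScheme.from_helix_ranges(helices, loops)
    return out


@dataclass
class SegmentStateVector:
    """One structure's per-segment f/s/l states and its activity label."""

    structure_id: str
    states: dict[str, str]
    activity: int  # 0 inactive, 1 active

    def __post_init__(self) -> None:
        if set(self.states) != set(SEGMENT_NAMES):
            raise ValueError("state vector must cover all 29 segments exactly")
        bad = {v for v in self.states.values()} - set(STATES)
        if bad:
            raise ValueError(f"invalid states {bad}")
        if self.activity not in (0, 1):
            raise ValueError("activity must be 0 or 1")


def classify_segment_state(residue_labels: Mapping[int, str],
                           scheme: SegmentScheme, segment: str) -> str:
    """Plurality f/s/l vote over the residues of one segment.

    ``residue_labels`` maps author residue numbers to rigidity labels;
    residues without labels (missing coordinates) are excluded from the
    vote.  Ties are broken in the order l > s > f; a fully missing segment
    defaults to flexible, the high-mobility interpretation.
    """
    votes = {"f": 0, "s": 0, "l": 0}
    n_seen = 0
    for resnum in scheme.residues_of(segment):
        label = residue_labels.get(resnum)
        if label is None:
            continue
        votes[_STATE_OF_LABEL[label]] += 1
        n_seen += 1
    if n_seen == 0:
        warnings.warn(f"segment {segment}: no resolved residues; defaulting to"
                      " flexible", stacklevel=2)
        return "f"
    return max(("l", "s", "f"), key=lambda st: votes[st])


def segment_states(residue_labels: Mapping[int, str], scheme: SegmentScheme,
                   structure_id: str, activity: int) -> SegmentStateVector:
    states = {seg: classify_segment_state(residue_labels, scheme, seg)
              for seg in SEGMENT_NAMES}
    return SegmentStateVector(structure_id=structure_id, states=states,
                              activity=activity)


def encode_feature_vector(v: SegmentStateVector) -> np.ndarray:
    """One-hot 87-bit row; exactly 29 bits set."""
    row = np.zeros(N_FEATURES, dtype=np.int8)
    for i, seg in enumerate(SEGMENT_NAMES):
        state = v.states.get(seg)
        if state is None:
            raise ValueError(f"missing state for segment {seg}")
        row[i * 3 + STATES.index(state)] = 1
    return row


@dataclass
class FeatureMatrix:
    """Binary structure-by-feature matrix with activity labels."""

    structure_ids: list[str]
    data: np.ndarray          # (n, 87) int8
    labels: np.ndarray        # (n,) int8; 1 = active
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.data.shape != (len(self.structure_ids), len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")

    @property
    def n(self) -> int:
        return len(self.structure_ids)

    def column(self, feature: str) -> np.ndarray:
        return self.data[:, self.feature_names.index(feature)]

    def columns(self, features: Sequence[str]) -> np.ndarray:
        idx = [self.feature_names.index(f) for f in features]
        return self.data[:, idx]

    @classmethod
    def from_state_vectors(cls, vectors: Sequence[SegmentStateVector]
                           ) -> "FeatureMatrix":
        data = np.vstack([encode_feature_vector(v) for v in vectors])
        return cls(structure_ids=[v.structure_id for v in vectors],
                   data=data,
                   labels=np.array([v.activity for v in vectors], dtype=np.int8))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=list(self.feature_names),
                          index=self.structure_ids)
        df["activity"] = self.labels
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="structure")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="structure")
        if "activity" not in df.columns:
            raise ValueError("feature CSV must contain an 'activity' column")
        labels = df.pop("activity").to_numpy()
        return cls(structure_ids=[str(i) for i in df.index],
                   data=df.to_numpy(),
                   labels=labels,
                   feature_names=tuple(df.columns))


@dataclass
class PrevalenceProfile:
    """Class-conditional feature frequencies and their absolute difference."""

    table: pd.DataFrame  # index: feature names; columns freq_active, freq_inactive, abs_difference


def prevalence_profile(m: FeatureMatrix) -> PrevalenceProfile:
    """Frequency of each feature in active versus inactive structures."""
    active = m.labels == 1
    if active.all() or not active.any():
        raise ValueError("both classes must be present")
    freq_a = m.data[active].mean(axis=0)
    freq_i = m.data[~active].mean(axis=0)
    table = pd.DataFrame({
        "freq_active": freq_a,
        "freq_inactive": freq_i,
        "abs_difference": np.abs(freq_a - freq_i),
    }, index=list(m.feature_names))
    return PrevalenceProfile(table=table)


def select_sensitive_features(p: PrevalenceProfile,
                              config: AnalysisConfig | None = None) -> list[str]:
    """Features whose class prevalence differs by at least the configured
    threshold, keeping at most one (the largest-difference) feature per
    segment; ordered by descending difference then name."""
    config = config or AnalysisConfig()
    best: dict[str, tuple[float, str]] = {}
    for feat, diff in p.table["abs_difference"].items():
        seg = feat[:-1]
        if diff < config.delta_prevalence:
            continue
        # larger difference wins; ties to the lexicographically earlier name
        if seg not in best or (diff, _neg_name(feat)) > (best[seg][0],
                                                         _neg_name(best[seg][1])):
            best[seg] = (diff, feat)
    chosen = sorted(best.values(), key=lambda t: (-t[0], t[1]))
    return [feat for _, feat in chosen]


def _neg_name(name: str):
    # sortable helper so that among equal differences the earlier name wins
    return tuple(-ord(c) for c in name)
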