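"""Per-position features for the error classifier.

Each called base gets a 13-attribute vector: five attributes of the position
itself (1-based position in the read, Phred score, homopolymer code,
carry-forward sensitivity, flow signal intensity) and eight derived from the
two neighbouring bases (their Phred scores, homopolymer codes and flow
intensities, plus — in each direction — the highest flow signal between the
two calling flows that did not result in a base call).

Homopolymer codes: 'N' for an isolated base, 'A' for the first and 'Z' for
the last base of a run, and 'B', 'C', ... for second, third, ... interior
positions. With runs capped at 8 by basic trimming the full alphabet is
{N, A, B, C, D, E, F, G, Z}.

Missing neighbours at read ends take fixed sentinels (Phred -1, code 'N',
intensity 0.0, max-uncalled 0.0) so the schema stays rectangular.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from pyrodenoise.flowgram_io import FlowRead

HOMOPOLYMER_CODES = ("N", "A", "B", "C", "D", "E", "F", "G", "Z")
MAX_RUN = 8

#: the 13 attributes, in the fixed schema order used by the classifier
FEATURE_COLUMNS = (
    "position",
    "phred",
    "homopolymer_code",
    "carry_forward_sensitive",
    "flow_intensity",
    "prev_phred",
    "next_phred",
    "prev_homopolymer_code",
    "next_homopolymer_code",
    "prev_flow_intensity",
    "next_flow_intensity",
    "prev_max_uncalled",
    "next_max_uncalled",
)

_CATEGORICAL = ("homopolymer_code", "prev_homopolymer_code", "next_homopolymer_code")


@dataclass
class PositionFeatures:
    """The 13-attribute vector for one called base (5 self + 8 neighbour)."""

    position: int
    phred: int
    homopolymer_code: str
    carry_forward_sensitive: bool
    flow_intensity: float
    prev_phred: int
    next_phred: int
    prev_homopolymer_code: str
    next_homopolymer_code: str
    prev_flow_intensity: float
    next_flow_intensity: float
    prev_max_uncalled: float
    next_max_uncalled: float


assert tuple(f.name for f in fields(PositionFeatures)) == FEATURE_COLUMNS
assert len(FEATURE_COLUMNS) == 13


def annotate_homopolymers(bases: str) -> str:
    """Length-preserving homopolymer position codes for a base string."""
    out = []
    i = 0
    n = len(bases)
    while i < n:
        j = i
        while j < n and bases[j] == bases[i]:
            j += 1
        run = j - i
        if run > MAX_RUN:
            raise ValueError(
                f"homopolymer run of {run} exceeds {MAX_RUN}; apply basic trimming first"
            )
        if run == 1:
            out.append("N")
        else:
            out.append("A")
            for k in range(run - 2):
                out.append(chr(ord("B") + k))
            out.append("Z")
        i = j
    return "".join(out)


def max_uncalled_between(read: FlowRead, base_i: int, base_j: int) -> float:
    """Highest flow value strictly between two adjacent bases' calling flows.

    0.0 when the calling flows are identical or adjacent. Base indices are
    1-based and must be adjacent in the read.
    """
    if abs(base_i - base_j) != 1:
        raise ValueError("base indices must be adjacent")
    n = len(read.bases)
    if not (1 <= base_i <= n and 1 <= base_j <= n):
        raise ValueError(f"base index out of range 1..{n}")
    fi = read.flow_index_per_base[base_i - 1]
    fj = read.flow_index_per_base[base_j - 1]
    lo, hi = min(fi, fj), max(fi, fj)
    if hi - lo <= 1:
        return 0.0
    return max(read.flow_values[lo : hi - 1])


def carry_forward_sensitive(read: FlowRead, position: int) -> bool:
    """True iff an uncalled flow of this base's nucleotide sits just upstream.

    Checks the flows strictly between this base's calling flow and the
    previous base's calling flow (the read start for the first base): a
    same-nucleotide flow there means the nucleotide was flowed but uncalled
    immediately upstream — the carry-forward signature.
    """
    n = len(read.bases)
    if not 1 <= position <= n:
        raise ValueError(f"position out of range 1..{n}")
    f = read.flow_index_per_base[position - 1]
    lower = read.flow_index_per_base[position - 2] if position >= 2 else 0
    base = read.bases[position - 1]
    for g in range(lower + 1, f):
        if read.flow_chars[g - 1] == base:
            return True
    return False


def extract_features(read: FlowRead) -> list[PositionFeatures]:
    """Compute the 13-attribute vector for every called base of one read."""
    if "N" in read.bases:
        raise ValueError(f"{read.read_id}: contains ambiguous bases; apply basic_trim first")
    n = len(read.bases)
    codes = annotate_homopolymers(read.bases)
    intensities = [read.flow_values[f - 1] for f in read.flow_index_per_base]
    uncalled = [max_uncalled_between(read, k, k + 1) for k in range(1, n)]
    out: list[PositionFeatures] = []
    for k in range(1, n + 1):
        i = k - 1
        out.append(
            PositionFeatures(
                position=k,
                phred=read.quals[i],
                homopolymer_code=codes[i],
                carry_forward_sensitive=carry_forward_sensitive(read, k),
                flow_intensity=intensities[i],
                prev_phred=read.quals[i - 1] if k > 1 else -1,
                next_phred=read.quals[i + 1] if k < n else -1,
                prev_homopolymer_code=codes[i - 1] if k > 1 else "N",
                next_homopolymer_code=codes[i + 1] if k < n else "N",
                prev_flow_intensity=intensities[i - 1] if k > 1 else 0.0,
                next_flow_intensity=intensities[i + 1] if k < n else 0.0,
                prev_max_uncalled=uncalled[i - 1] if k > 1 else 0.0,
                next_max_uncalled=uncalled[i] if k < n else 0.0,
            )
        )
    return out


def features_frame(reads: list[FlowRead]) -> pd.DataFrame:
    """Feature table for many reads: read_id, position, then the 13 attributes."""
    rows = []
    for read in reads:
        codes = annotate_homopolymers(read.bases) if "N" not in read.bases else None
        if codes is None:
            raise ValueError(f"{read.read_id}: contains ambiguous bases; apply basic_trim first")
        for pf in extract_features(read):
            rows.append((read.read_id, *(getattr(pf, c) for c in FEATURE_COLUMNS)))
    return pd.DataFrame(rows, columns=("read_id", *FEATURE_COLUMNS))


def encode_matrix(frame: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix: one-hot homopolymer codes, booleans as {0,1}.

    Column layout is fixed regardless of which codes appear in the data, so
    models trained on one table apply to any other.
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    for feat in FEATURE_COLUMNS:
        if feat in _CATEGORICAL:
            values = frame[feat].to_numpy()
            for code in HOMOPOLYMER_CODES:
                cols.append((values == code).astype(np.float64))
                names.append(f"{feat}={code}")
        else:
            cols.append(frame[feat].to_numpy(dtype=np.float64))
            names.append(feat)
    return np.column_stack(cols), names
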