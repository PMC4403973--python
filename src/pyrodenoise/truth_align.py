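"""Reference-based ground-truth error labeling.

Each read is matched to its best reference by a k-mer prescreen followed by a
deterministic glocal affine-gap alignment (the read aligned end-to-end, the
reference locally: reference overhangs are free). Scoring: match +1,
mismatch -1, gap open -2, gap extend -1. Indel gaps inside homopolymers are
canonicalized to the 3' end of the run before labeling, so score-equivalent
gap placements yield identical labels, and adjacent opposite indels are
reported as substitutions (as an optimal aligner would).

Label classes: clean, insertion, deletion, substitution. A deletion is
anchored to the called base immediately 3' of the missing reference base.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import Align

from pyrodenoise import _alncols
from pyrodenoise.features import FEATURE_COLUMNS, features_frame
from pyrodenoise.flowgram_io import FlowRead, SeqEntry

LABELS = ("clean", "insertion", "deletion", "substitution")

KMER = 8
TOP_CANDIDATES = 5


@dataclass
class LabeledInstance:
    """A feature vector with its ground-truth class."""

    read_id: str
    position: int
    features: object
    label: str


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = 1
    aligner.mismatch_score = -1
    # Biopython's open_gap_score covers the first gapped position, so a gap of
    # length L costs open + (L-1)*extend; open=-3/extend=-1 realises the
    # "open -2, extend -1 per position" scheme.
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    # read = query, global; reference = target, local (free end gaps on the
    # query row correspond to unaligned reference overhangs)
    try:
        aligner.end_deletion_score = 0
    except AttributeError:  # older Biopython spelling
        aligner.query_end_gap_score = 0
    return aligner


_ALIGNER = _make_aligner()


def _kmers(seq: str, k: int = KMER) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _alignment_columns(ref_seq: str, read_seq: str) -> tuple[float, list[_alncols.Column]]:
    aln = _ALIGNER.align(ref_seq, read_seq)[0]
    ref_row = str(aln[0])
    read_row = str(aln[1])
    cols = list(zip(read_row, ref_row))
    return float(aln.score), _alncols.trim_terminal_read_gaps(cols)


def assign_reference(
    read_bases: str,
    references: list[SeqEntry],
    k: int = KMER,
    top: int = TOP_CANDIDATES,
) -> tuple[str | None, list[_alncols.Column] | None]:
    """Best reference for a read, with the alignment column list.

    Candidates are shortlisted by shared k-mer count, aligned glocally, and
    ranked by score; ties break by fewest indel columns, then lexicographic
    reference id. Returns ``(None, None)`` when the read shares no k-mer with
    any reference ("unmatched").
    """
    if not references:
        raise ValueError("need at least one reference")
    read_kmers = _kmers(read_bases, k)
    counts = [(len(read_kmers & _kmers(r.seq, k)), r.id) for r in references]
    by_id = {r.id: r for r in references}
    counts.sort(key=lambda t: (-t[0], t[1]))
    if counts[0][0] == 0:
        return None, None
    shortlist = [rid for c, rid in counts[:top] if c > 0]
    best: tuple[float, int, str] | None = None
    best_cols: list[_alncols.Column] | None = None
    for rid in shortlist:
        score, cols = _alignment_columns(by_id[rid].seq, read_bases)
        n_indels = sum(1 for r, q in cols if r == _alncols.GAP or q == _alncols.GAP)
        key = (-score, n_indels, rid)
        if best is None or key < best:
            best = key
            best_cols = cols
    assert best is not None
    return best[2], best_cols


def label_errors(cols: list[_alncols.Column]) -> list[str]:
    """Per-position labels (index 0 = read position 1) from alignment columns."""
    cols = _alncols.trim_terminal_read_gaps(_alncols.canonicalize(cols))
    read_len = sum(1 for r, _ in cols if r != _alncols.GAP)
    labels = ["clean"] * read_len
    for pos, kind in _alncols.events_from_columns(cols):
        labels[pos - 1] = kind
    return labels


def label_reads(
    reads: list[FlowRead],
    references: list[SeqEntry],
) -> tuple[pd.DataFrame, int]:
    """Feature table with a ground-truth label column.

    Returns (instances, n_unmatched): one row per called base of every read
    that found a reference (read_id, position, 13 features, label); reads
    sharing no k-mer with any reference are excluded and counted.
    """
    matched: list[FlowRead] = []
    label_map: dict[str, list[str]] = {}
    ref_map: dict[str, str] = {}
    unmatched = 0
    for read in reads:
        rid, cols = assign_reference(read.bases, references)
        if rid is None:
            unmatched += 1
            continue
        matched.append(read)
        label_map[read.read_id] = label_errors(cols)
        ref_map[read.read_id] = rid
    if not matched:
        return (
            pd.DataFrame(columns=("read_id", *FEATURE_COLUMNS, "label", "reference_id")),
            unmatched,
        )
    frame = features_frame(matched)
    frame["label"] = [
        label_map[rid][pos - 1]
        for rid, pos in zip(frame["read_id"], frame["position"])
    ]
    frame["reference_id"] = frame["read_id"].map(ref_map)
    return frame, unmatched
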