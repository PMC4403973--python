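"""Mock-community evaluation: chimera detection, error rates, error profiles.

A read is called chimeric when some two-parent reference chimera (a prefix of
one reference followed by a suffix of another, split at any column) is at
least ``margin`` (default 3) mismatches more similar to the read than the
best single reference is. The search over all ordered reference pairs and
breakpoints is done with per-reference prefix mismatch arrays in
O(refs * columns) per read.

The global error rate is the number of erroneous nucleotides over the total
number of nucleotides across non-chimeric reads, abundance-weighted; per-read
error counts reuse the canonicalized reference-based labeling so one
definition of "error" holds across the codebase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pyrodenoise.denoise import GAP_BYTES, align_to_template
from pyrodenoise.flowgram_io import SeqEntry
from pyrodenoise.truth_align import assign_reference, label_errors


@dataclass
class ErrorReport:
    """Per-read and aggregate error statistics for a read set."""

    per_read: pd.DataFrame  # read_id, best_reference, n_sub, n_ins, n_del, n_bases, abundance, is_chimera
    error_rate: float
    chimera_pct: float
    events: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return int(self.per_read["abundance"].sum())


def _row_arrays(rows: list[tuple[str, str]]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(chars uint8 with gaps normalised, gap mask, terminal mask) per row."""
    mat = np.vstack([np.frombuffer(s.encode(), dtype=np.uint8) for _, s in rows]).copy()
    gap = (mat == GAP_BYTES[0]) | (mat == GAP_BYTES[1])
    mat[gap] = GAP_BYTES[0]
    term = np.ones_like(gap)
    for i in range(len(rows)):
        nz = np.flatnonzero(~gap[i])
        if nz.size:
            term[i, nz[0] : nz[-1] + 1] = False
    return mat, gap, term


def detect_chimeras(
    read_rows: list[tuple[str, str]],
    ref_rows: list[tuple[str, str]],
    margin: int = 3,
) -> pd.DataFrame:
    """Flag reads better explained by a two-parent reference chimera.

    Reads and references must share one alignment coordinate space. Columns
    in a read's terminal-gap region are ignored; internal gap-vs-base columns
    count as mismatches; both-gap columns never do. Returns a table with
    read_id, best_single, best_chimera, is_chimera.
    """
    if len(ref_rows) < 2:
        warnings.warn("fewer than 2 references: chimera detection disabled")
        return pd.DataFrame(
            {
                "read_id": [rid for rid, _ in read_rows],
                "best_single": 0,
                "best_chimera": 0,
                "is_chimera": False,
            }
        )
    widths = {len(s) for _, s in read_rows} | {len(s) for _, s in ref_rows}
    if len(widths) != 1:
        raise ValueError("reads and references are not in a common alignment space")

    rmat, rgap, _ = _row_arrays(ref_rows)
    out = []
    for rid, row in read_rows:
        arr = np.frombuffer(row.encode(), dtype=np.uint8).copy()
        gap = (arr == GAP_BYTES[0]) | (arr == GAP_BYTES[1])
        arr[gap] = GAP_BYTES[0]
        nz = np.flatnonzero(~gap)
        valid = np.zeros(arr.size, dtype=bool)
        if nz.size:
            valid[nz[0] : nz[-1] + 1] = True
        both_gap = gap & rgap
        mism = (rmat != arr) & valid & ~both_gap  # refs x columns
        prefix = np.concatenate(
            [np.zeros((mism.shape[0], 1), dtype=np.int64), np.cumsum(mism, axis=1)], axis=1
        )
        totals = prefix[:, -1]
        best_single = int(totals.min())
        min_prefix = prefix.min(axis=0)
        min_suffix = (totals[:, None] - prefix).min(axis=0)
        best_chimera = int((min_prefix + min_suffix).min())
        out.append((rid, best_single, best_chimera, best_single - best_chimera >= margin))
    return pd.DataFrame(out, columns=("read_id", "best_single", "best_chimera", "is_chimera"))


def compute_error_report(
    reads: list[SeqEntry],
    references: list[SeqEntry],
    margin: int = 3,
) -> ErrorReport:
    """Chimera-filtered, abundance-weighted error report against references.

    ``references`` must be mutually aligned (equal lengths; an ungapped
    equal-length set qualifies); they double as the template alignment used to
    bring the reads into a common coordinate space for chimera scoring.
    """
    widths = {len(r.seq) for r in references}
    if len(widths) != 1:
        raise ValueError("references must be mutually aligned (equal lengths)")
    aligned = align_to_template(reads, references)
    chim = detect_chimeras(aligned.reads, aligned.template_rows, margin=margin)
    chim_ids = set(chim.loc[chim["is_chimera"], "read_id"])

    by_id = {e.id: e for e in reads}
    degapped_refs = [SeqEntry(r.id, r.seq.replace("-", "").replace(".", "")) for r in references]
    rows = []
    events: dict[str, list[tuple[int, str]]] = {}
    total_errors = 0
    total_bases = 0
    chim_abund = 0
    total_abund = 0
    for rid, _row in aligned.reads:
        entry = by_id[rid]
        total_abund += entry.abundance
        if rid in chim_ids:
            chim_abund += entry.abundance
            rows.append((rid, None, 0, 0, 0, len(entry.seq), entry.abundance, True))
            continue
        ref_id, cols = assign_reference(entry.seq, degapped_refs)
        labels = label_errors(cols)
        ev = [(i + 1, lab) for i, lab in enumerate(labels) if lab != "clean"]
        events[rid] = ev
        n_sub = sum(1 for _, l in ev if l == "substitution")
        n_ins = sum(1 for _, l in ev if l == "insertion")
        n_del = sum(1 for _, l in ev if l == "deletion")
        rows.append((rid, ref_id, n_sub, n_ins, n_del, len(entry.seq), entry.abundance, False))
        total_errors += (n_sub + n_ins + n_del) * entry.abundance
        total_bases += len(entry.seq) * entry.abundance
    for rid in aligned.unaligned_ids:
        total_abund += by_id[rid].abundance

    if total_bases == 0:
        raise ValueError("no non-chimeric reads to evaluate")
    per_read = pd.DataFrame(
        rows,
        columns=(
            "read_id",
            "best_reference",
            "n_sub",
            "n_ins",
            "n_del",
            "n_bases",
            "abundance",
            "is_chimera",
        ),
    )
    return ErrorReport(
        per_read=per_read,
        error_rate=total_errors / total_bases,
        chimera_pct=100.0 * chim_abund / max(total_abund, 1),
        events=events,
    )


def positional_profile(report: ErrorReport) -> pd.DataFrame:
    """Per-position error rates: events of each type / reads covering the position."""
    if len(report.per_read) == 0:
        raise ValueError("empty error report")
    nonchim = report.per_read[~report.per_read["is_chimera"]]
    max_len = int(nonchim["n_bases"].max())
    coverage = np.zeros(max_len, dtype=np.int64)
    for n, a in zip(nonchim["n_bases"], nonchim["abundance"]):
        coverage[: int(n)] += int(a)
    counts = {kind: np.zeros(max_len, dtype=np.int64) for kind in ("insertion", "deletion", "substitution")}
    abund = dict(zip(nonchim["read_id"], nonchim["abundance"]))
    for rid, evs in report.events.items():
        a = int(abund.get(rid, 0))
        for pos, kind in evs:
            counts[kind][pos - 1] += a
    with np.errstate(divide="ignore", invalid="ignore"):
        ins = np.where(coverage > 0, counts["insertion"] / coverage, 0.0)
        dele = np.where(coverage > 0, counts["deletion"] / coverage, 0.0)
        sub = np.where(coverage > 0, counts["substitution"] / coverage, 0.0)
    return pd.DataFrame(
        {
            "position": np.arange(1, max_len + 1),
            "ins_rate": ins,
            "del_rate": dele,
            "sub_rate": sub,
            "total_rate": ins + dele + sub,
            "coverage": coverage,
        }
    )
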