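"""Alignment-column utilities.

An alignment between a read and a reference is held as a list of columns
``(read_char, ref_char)`` where ``'-'`` marks a gap. Two normalisations make
per-position error labels well defined and comparable across code paths:

* **3' gap canonicalisation** — indel gaps are pushed as far as possible
  toward the 3' end (right) when the surrounding letters permit, so the many
  score-equivalent gap placements inside a homopolymer collapse to one.
* **Indel merging** — an insertion column immediately adjacent to a deletion
  column is what an optimal affine aligner would report as a single mismatch
  column; adjacent opposite-gap pairs are therefore merged into substitution
  columns (or into a match when the two letters happen to be equal).

Per-position events use 1-based read coordinates. A deletion is anchored to
the called base immediately 3' of the missing reference base(s); a deleted
run of several bases yields a single deletion event at that anchor. When one
position carries several event types the label precedence is
substitution > insertion > deletion.
"""

from __future__ import annotations

GAP = "-"

Column = tuple[str, str]

LABEL_PRECEDENCE = {"substitution": 0, "insertion": 1, "deletion": 2}


def shift_gaps_3prime(cols: list[Column]) -> list[Column]:
    """Push gap columns rightward wherever letters commute.

    An insertion column ``(x, -)`` may swap with a following column whose read
    char is also ``x`` (and which is not itself a ref gap); symmetrically for
    deletion columns on the reference row. Repeated passes until fixpoint.
    """
    cols = list(cols)
    changed = True
    while changed:
        changed = False
        for i in range(len(cols) - 1):
            r1, q1 = cols[i]
            r2, q2 = cols[i + 1]
            if q1 == GAP and r1 != GAP and q2 != GAP and r2 == r1:
                cols[i], cols[i + 1] = (r2, q2), (r1, q1)
                changed = True
            elif r1 == GAP and q1 != GAP and r2 != GAP and q2 == q1:
                cols[i], cols[i + 1] = (r2, q2), (r1, q1)
                changed = True
    return cols


# alignment scoring used across the package: match +1, mismatch -1, a gap run
# of length L costs -(2 + L) (open -2, extend -1 per gapped position)
def _score(cols: list[Column]) -> int:
    s = 0
    in_read_gap = in_ref_gap = False
    for r, q in cols:
        if r == GAP:
            s -= 1 if in_read_gap else 3
            in_read_gap, in_ref_gap = True, False
        elif q == GAP:
            s -= 1 if in_ref_gap else 3
            in_ref_gap, in_read_gap = True, False
        else:
            s += 1 if r == q else -1
            in_read_gap = in_ref_gap = False
    return s


def _gap_run(cols: list[Column], i: int) -> tuple[str, int]:
    """('ins'|'del'|'', run length) for the gap run starting at i."""
    r, q = cols[i]
    kind = "ins" if q == GAP else "del" if r == GAP else ""
    if not kind:
        return "", 0
    n = 0
    while i + n < len(cols):
        rr, qq = cols[i + n]
        if (kind == "ins" and qq == GAP and rr != GAP) or (
            kind == "del" and rr == GAP and qq != GAP
        ):
            n += 1
        else:
            break
    return kind, n


def rewrite_split_indels(cols: list[Column], max_bridge: int = 6) -> list[Column]:
    """Re-render opposite indel runs split by a short bridge as substitutions.

    An insertion run and a deletion run separated by up to ``max_bridge``
    aligned (both-character) columns describe the same sequences as a run of
    substitution columns; an optimal affine aligner reports whichever scores
    better. The window is rewritten gap-free (surplus letters re-gapped at its
    3' end) whenever that rendering scores at least as well, so both the
    flow-space truth bookkeeping and aligner output converge to one form.
    """
    cols = list(cols)
    i = 0
    while i < len(cols):
        kind1, g1 = _gap_run(cols, i)
        if not kind1:
            i += 1
            continue
        j = i + g1
        k = 0
        while j + k < len(cols) and cols[j + k][0] != GAP and cols[j + k][1] != GAP and k <= max_bridge:
            k += 1
        end = j + k
        kind2, g2 = _gap_run(cols, end) if end < len(cols) else ("", 0)
        if k <= max_bridge and kind2 and kind2 != kind1:
            window = cols[i : end + g2]
            reads = [r for r, _ in window if r != GAP]
            refs = [q for _, q in window if q != GAP]
            m = min(len(reads), len(refs))
            new = [(reads[t], refs[t]) for t in range(m)]
            new += [(r, GAP) for r in reads[m:]]
            new += [(GAP, q) for q in refs[m:]]
            if _score(new) >= _score(window):
                cols[i : end + g2] = new
                continue  # rescan from i: the rewrite may expose new patterns
        i = j  # skip past this gap run
    return cols


def canonicalize(cols: list[Column]) -> list[Column]:
    """3'-shift gaps and re-render split indel pairs, to fixpoint."""
    for _ in range(100):
        cols = shift_gaps_3prime(cols)
        new = rewrite_split_indels(cols)
        if new == cols:
            return cols
        cols = new
    return cols


def events_from_columns(cols: list[Column]) -> list[tuple[int, str]]:
    """Per-position error events from canonicalized columns.

    Returns sorted ``(read_position, type)`` pairs, at most one event per
    position (precedence substitution > insertion > deletion). Terminal
    reference overhangs (read-gap columns at either end) are not deletions
    and must be trimmed by the caller beforehand.
    """
    events: dict[int, str] = {}

    def put(pos: int, label: str) -> None:
        old = events.get(pos)
        if old is None or LABEL_PRECEDENCE[label] < LABEL_PRECEDENCE[old]:
            events[pos] = label

    read_pos = 0
    pending_deletion = False
    read_len = sum(1 for r, _ in cols if r != GAP)
    for r, q in cols:
        if r != GAP:
            read_pos += 1
            if pending_deletion:
                put(read_pos, "deletion")
                pending_deletion = False
        if r != GAP and q != GAP:
            if r != q:
                put(read_pos, "substitution")
        elif r != GAP and q == GAP:
            put(read_pos, "insertion")
        elif r == GAP and q != GAP:
            pending_deletion = True
    if pending_deletion and read_len > 0:
        put(read_len, "deletion")
    return sorted(events.items())


def trim_terminal_read_gaps(cols: list[Column]) -> list[Column]:
    """Drop leading/trailing columns where the read row is a gap."""
    start = 0
    end = len(cols)
    while start < end and cols[start][0] == GAP:
        start += 1
    while end > start and cols[end - 1][0] == GAP:
        end -= 1
    return cols[start:end]
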