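"""Independent brute-force reference implementations used only by tests.

These are deliberately naive (double loops, exhaustive search) and share no
code with the package's optimized implementations.
"""

from __future__ import annotations

import math


def naive_precluster(reads, diff_pct=0.02):
    """All-pairs reference preclustering over MaskedAlignedRead-like objects.

    Same ordering rules as the package: abundance desc, unaligned length desc,
    id asc; merge into the first seed within floor(diff_pct * read length)
    differences; a column is skipped when masked in either read, when inside
    either read's terminal gap region, or when both have gaps; gap-vs-base
    counts as a difference.
    Returns (seed_map, [(seed_id, seq, abundance)]).
    """
    order = sorted(
        reads, key=lambda r: (-r.abundance, -len(r.original_unaligned), r.read_id)
    )
    seeds = []  # (read, abundance)
    seed_map = {}

    def terminal(s):
        n = len(s)
        first = next((i for i, c in enumerate(s) if c not in "-."), n)
        last = next((i for i in range(n - 1, -1, -1) if s[i] not in "-."), -1)
        return first, last

    for read in order:
        budget = math.floor(diff_pct * len(read.original_unaligned))
        f1, l1 = terminal(read.aligned)
        placed = False
        for entry in seeds:
            seed = entry[0]
            f2, l2 = terminal(seed.aligned)
            diffs = 0
            for c in range(len(read.aligned)):
                if c < f1 or c > l1 or c < f2 or c > l2:
                    continue  # terminal gap region of either read
                if (c + 1) in read.mask_columns or (c + 1) in seed.mask_columns:
                    continue
                a = read.aligned[c]
                b = seed.aligned[c]
                a = "-" if a in "-." else a
                b = "-" if b in "-." else b
                if a == "-" and b == "-":
                    continue
                if a != b:
                    diffs += 1
            if diffs <= budget:
                entry[1] += read.abundance
                seed_map[read.read_id] = seed.read_id
                placed = True
                break
        if not placed:
            seeds.append([read, read.abundance])
            seed_map[read.read_id] = read.read_id
    return seed_map, [(s.read_id, s.original_unaligned, a) for s, a in seeds]


def naive_chimera_scores(read_row: str, ref_rows: list[tuple[str, str]]):
    """Exhaustive two-parent chimera search over all pairs and breakpoints.

    Returns (best_single, best_chimera) mismatch counts with the same column
    semantics as the package: read terminal gaps ignored, both-gap columns
    never mismatch, internal gap-vs-base does.
    """
    n = len(read_row)
    first = next((i for i, c in enumerate(read_row) if c not in "-."), n)
    last = next((i for i in range(n - 1, -1, -1) if read_row[i] not in "-."), -1)

    def mismatch_vector(ref_row):
        v = []
        for c in range(n):
            if c < first or c > last:
                v.append(0)
                continue
            a = read_row[c]
            b = ref_row[c]
            a = "-" if a in "-." else a
            b = "-" if b in "-." else b
            v.append(0 if (a == b or (a == "-" and b == "-")) else 1)
        return v

    vecs = {rid: mismatch_vector(row) for rid, row in ref_rows}
    totals = {rid: sum(v) for rid, v in vecs.items()}
    best_single = min(totals.values())
    best_chimera = best_single
    ids = list(vecs)
    for p in ids:
        for q in ids:
            left = 0
            vp, vq = vecs[p], vecs[q]
            tq = totals[q]
            right = tq
            for b in range(n + 1):
                score = left + right
                if score < best_chimera:
                    best_chimera = score
                if b < n:
                    left += vp[b]
                    right -= vq[b]
    return best_single, best_chimera
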