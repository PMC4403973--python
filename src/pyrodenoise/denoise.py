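"""The correction stage: masked, abundance-sorted single-linkage preclustering.

Reads are projected into the fixed column space of a template alignment
(NAST style: each read is pairwise-aligned to its best template record and
its bases are placed in that record's columns; read insertions relative to
the template are squeezed into existing template gap columns when possible,
and otherwise a minimal set of '.'-padded extra columns is opened once for
the whole read set). Leading/trailing unoccupied columns are '.'-filled,
internal gaps are '-'.

Preclustering processes reads from most to least abundant. A read merges into
the first already-fixed seed from which it differs at no more than
``floor(diff_pct * read length)`` columns, where columns masked in either
read are skipped, terminal-gap columns are skipped, gap-vs-base counts as a
difference, and both-gap columns are ignored. Merging adds the read's
abundance to the seed. After clustering, reads that never merged are restored
byte-identically to their pre-masking originals — masking influences only the
difference counting, never the emitted sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pyrodenoise.flowgram_io import SeqEntry
from pyrodenoise.truth_align import _alignment_columns, _kmers

GAP_BYTES = (ord("-"), ord("."))


@dataclass
class MaskedAlignedRead:
    """An alignment-space read with abundance and classifier mask columns."""

    read_id: str
    aligned: str
    abundance: int
    mask_columns: set[int] = field(default_factory=set)
    original_unaligned: str = ""

    def __post_init__(self) -> None:
        if self.abundance < 1:
            raise ValueError(f"{self.read_id}: abundance must be >= 1")
        if not self.original_unaligned:
            self.original_unaligned = degap(self.aligned)


def degap(aligned: str) -> str:
    return aligned.replace("-", "").replace(".", "")


@dataclass
class AlignedSet:
    """Template-space read set: rows, per-read position->column maps, template rows."""

    reads: list[tuple[str, str]]  # (read_id, aligned row)
    maps: list[dict[int, int]]  # 1-based read position -> 1-based column
    template_rows: list[tuple[str, str]]  # template records in the same (augmented) space
    n_padding_columns: int
    unaligned_ids: list[str]
    width: int


def _template_colmap(aligned: str) -> list[int]:
    """1-based column of each template base (index 0 = base 1)."""
    return [i + 1 for i, ch in enumerate(aligned) if ch not in "-."]


def align_to_template(
    reads: list[SeqEntry],
    template_alignment: list[SeqEntry],
    k: int = 8,
    top: int = 5,
) -> AlignedSet:
    """Project reads into a template alignment's column space (NAST style)."""
    widths = {len(t.seq) for t in template_alignment}
    if len(widths) != 1:
        raise ValueError("template alignment columns are not of uniform length")
    width = widths.pop()
    degapped = [SeqEntry(t.id, degap(t.seq)) for t in template_alignment]
    colmaps = {t.id: _template_colmap(t.seq) for t in template_alignment}
    by_id = {t.id: t for t in degapped}

    # pass 1: align each read to its best template record, note the template
    # column of every matched base, and the insertion demands per inter-base
    # slot (keyed by the anchor column — the template base column to the left;
    # 0 for insertions before the first template base).
    placements: list[tuple[str, dict[int, str], list[tuple[int, list[str], int]]] | None] = []
    unaligned: list[str] = []
    extra_by_anchor: dict[int, int] = {}
    for read in reads:
        read_kmers = _kmers(read.seq, k)
        counts = sorted(
            ((len(read_kmers & _kmers(t.seq, k)), t.id) for t in degapped),
            key=lambda t: (-t[0], t[1]),
        )
        if counts[0][0] == 0:
            unaligned.append(read.id)
            placements.append(None)
            continue
        best = None
        best_tid = None
        for cnt, tid in counts[:top]:
            if cnt == 0:
                break
            score, cols = _alignment_columns(by_id[tid].seq, read.seq)
            n_indels = sum(1 for r, q in cols if "-" in (r, q))
            key = (-score, n_indels, tid)
            if best is None or key < best:
                best, best_tid = key, tid
        colmap = colmaps[best_tid]
        _, full_cols = _alignment_columns_full(by_id[best_tid].seq, read.seq)
        tpos = 0
        base_col: dict[int, str] = {}
        slot_chars: dict[int, list[str]] = {}
        for r, q in full_cols:
            if q != "-" and r != "-":
                tpos += 1
                base_col[colmap[tpos - 1]] = r
            elif q != "-":
                tpos += 1
            else:  # insertion relative to the template
                slot_chars.setdefault(tpos, []).append(r)
        inserts: list[tuple[int, list[str], int]] = []
        for slot, chars in sorted(slot_chars.items()):
            left = colmap[slot - 1] if slot >= 1 else 0
            right = colmap[slot] if slot < len(colmap) else width + 1
            cap = right - left - 1
            inserts.append((left, chars, cap))
            overflow = len(chars) - cap
            if overflow > 0:
                extra_by_anchor[left] = max(extra_by_anchor.get(left, 0), overflow)
        placements.append((read.id, base_col, inserts))

    anchors = sorted(extra_by_anchor)
    new_width = width + sum(extra_by_anchor.values())
    # new position of old column c
    shift = np.zeros(width + 2, dtype=int)
    for a in anchors:
        shift[a + 1 :] += extra_by_anchor[a]
    old_to_new = [c + int(shift[c]) for c in range(width + 1)]  # index by old col
    # extra region after old column a occupies new cols old_to_new[a]+1 .. +n

    out_reads: list[tuple[str, str]] = []
    maps: list[dict[int, int]] = []
    for read, placement in zip(reads, placements):
        if placement is None:
            continue
        rid, base_col, inserts = placement
        row = ["."] * new_width
        posmap: dict[int, int] = {}
        filled: list[tuple[int, str]] = []  # (new column, char) for every read base
        for old_c, ch in base_col.items():
            filled.append((old_to_new[old_c], ch))
        for anchor_col, chars, _cap in inserts:
            # slot region in new coords starts right after the anchor column
            # (extra columns first, then the template's own gap columns);
            # len(chars) <= extras + cap by construction, so left-packing fits
            left_new = old_to_new[anchor_col] if anchor_col >= 1 else 0
            for offset, ch in enumerate(chars):
                filled.append((left_new + 1 + offset, ch))
        filled.sort()
        read_pos = 0
        for col, ch in filled:
            read_pos += 1
            row[col - 1] = ch
            posmap[read_pos] = col
        first = filled[0][0]
        last = filled[-1][0]
        for c in range(first, last + 1):
            if row[c - 1] == ".":
                row[c - 1] = "-"
        out_reads.append((rid, "".join(row)))
        maps.append(posmap)

    template_rows = []
    for t in template_alignment:
        row = ["."] * new_width
        for old_c in range(1, width + 1):
            ch = t.seq[old_c - 1]
            if ch not in "-.":
                row[old_to_new[old_c] - 1] = ch
        template_rows.append((t.id, "".join(row)))

    return AlignedSet(
        reads=out_reads,
        maps=maps,
        template_rows=template_rows,
        n_padding_columns=new_width - width,
        unaligned_ids=unaligned,
        width=new_width,
    )


def _alignment_columns_full(ref_seq: str, read_seq: str):
    """Glocal alignment columns including terminal reference overhangs."""
    from pyrodenoise.truth_align import _ALIGNER

    aln = _ALIGNER.align(ref_seq, read_seq)[0]
    cols = list(zip(str(aln[1]), str(aln[0])))
    return float(aln.score), cols


@dataclass
class ClusterResult:
    """Outcome of one preclustering pass."""

    seed_map: dict[str, str]  # read_id -> seed read_id (seeds map to themselves)
    corrected: list[tuple[str, str, int]]  # (seed id, unaligned sequence, abundance)
    merge_log: list[dict]


def precluster_masked(
    reads: list[MaskedAlignedRead],
    diff_pct: float = 0.02,
) -> ClusterResult:
    """Abundance-sorted single-linkage preclustering that skips masked columns.

    Reads are processed most- to least-abundant (ties: longer unaligned
    sequence first, then lexicographic id). Each read merges into the first
    fixed seed within ``floor(diff_pct * len(read))`` counted differences;
    otherwise it becomes a seed itself. Total abundance is conserved.
    """
    if not reads:
        return ClusterResult({}, [], [])
    widths = {len(r.aligned) for r in reads}
    if len(widths) != 1:
        raise ValueError(f"aligned reads have unequal lengths: {sorted(widths)}")
    width = widths.pop()

    order = sorted(
        range(len(reads)),
        key=lambda i: (-reads[i].abundance, -len(reads[i].original_unaligned), reads[i].read_id),
    )

    seq_rows: list[np.ndarray] = []
    mask_rows: list[np.ndarray] = []
    term_rows: list[np.ndarray] = []
    seeds: list[int] = []  # indices into `reads`
    seed_abundance: list[int] = []
    seed_map: dict[str, str] = {}
    merge_log: list[dict] = []

    for idx in order:
        read = reads[idx]
        arr = np.frombuffer(read.aligned.encode(), dtype=np.uint8).copy()
        gap = (arr == GAP_BYTES[0]) | (arr == GAP_BYTES[1])
        arr[gap] = GAP_BYTES[0]  # normalise gap characters
        nongap = np.flatnonzero(~gap)
        term = np.ones(width, dtype=bool)
        if nongap.size:
            term[nongap[0] : nongap[-1] + 1] = False
        mask = np.zeros(width, dtype=bool)
        for c in read.mask_columns:
            mask[c - 1] = True

        budget = int(np.floor(diff_pct * len(read.original_unaligned)))
        merged = False
        if seeds:
            S = np.vstack(seq_rows)
            differ = S != arr
            both_gap = (S == GAP_BYTES[0]) & (arr == GAP_BYTES[0])
            terminal = np.vstack(term_rows) | term
            masked = np.vstack(mask_rows) | mask
            countable = differ & ~both_gap & ~terminal
            diffs = (countable & ~masked).sum(axis=1)
            ok = np.flatnonzero(diffs <= budget)
            if ok.size:
                s = int(ok[0])
                seed = reads[seeds[s]]
                seed_abundance[s] += read.abundance
                seed_map[read.read_id] = seed.read_id
                merge_log.append(
                    {
                        "read_id": read.read_id,
                        "seed_id": seed.read_id,
                        "diffs_counted": int(diffs[s]),
                        "diffs_skipped_masked": int((countable & masked)[s].sum()),
                        "abundance": read.abundance,
                    }
                )
                merged = True
        if not merged:
            seeds.append(idx)
            seed_abundance.append(read.abundance)
            seed_map[read.read_id] = read.read_id
            seq_rows.append(arr)
            mask_rows.append(mask)
            term_rows.append(term)

    corrected = [
        (reads[i].read_id, reads[i].original_unaligned, seed_abundance[s])
        for s, i in enumerate(seeds)
    ]
    total_in = sum(r.abundance for r in reads)
    total_out = sum(a for _, _, a in corrected)
    assert total_in == total_out, "abundance not conserved"
    return ClusterResult(seed_map, corrected, merge_log)


def restore_masks(
    result: ClusterResult,
    originals: dict[str, str],
) -> list[SeqEntry]:
    """Emit the corrected read set, restoring unmerged reads byte-identically.

    Reads merged into a seed are represented by the seed's sequence (their
    abundance was added to it); seeds — including reads whose masked positions
    never led to a merge — are emitted exactly as their pre-masking originals.
    """
    out: list[SeqEntry] = []
    for seed_id, _seq, abundance in result.corrected:
        if seed_id not in originals:
            raise ValueError(f"missing original sequence for unmerged read {seed_id}")
        out.append(SeqEntry(seed_id, originals[seed_id], None, abundance))
    return out


def dereplicate(
    reads: list[tuple[str, str]],
    masks: dict[str, set[int]] | None = None,
) -> tuple[list[SeqEntry], dict[str, set[int]], dict[str, str]]:
    """Collapse identical sequences, summing abundance and unioning masks.

    Returns (unique entries, mask per representative id, read->representative
    map). The representative is the lexicographically smallest member id.
    """
    groups: dict[str, list[str]] = {}
    for rid, seq in reads:
        groups.setdefault(seq, []).append(rid)
    entries: list[SeqEntry] = []
    rep_masks: dict[str, set[int]] = {}
    member_map: dict[str, str] = {}
    for seq, ids in groups.items():
        rep = min(ids)
        entries.append(SeqEntry(rep, seq, None, len(ids)))
        union: set[int] = set()
        for rid in ids:
            member_map[rid] = rep
            if masks:
                union |= masks.get(rid, set())
        rep_masks[rep] = union
    entries.sort(key=lambda e: e.id)
    return entries, rep_masks, member_map


def denoise_reads(
    reads: list[tuple[str, str]],
    masks: dict[str, set[int]],
    template_alignment: list[SeqEntry],
    diff_pct: float = 0.02,
) -> tuple[list[SeqEntry], ClusterResult]:
    """Full correction stage for (read_id, sequence) pairs with masks.

    Dereplicates, projects into template space, transfers masks to columns,
    preclusters with mask-aware distances, and restores unmerged originals.
    Returns the corrected entries (abundance-annotated) and the cluster log.
    """
    uniques, rep_masks, _ = dereplicate(reads, masks)
    aligned = align_to_template(uniques, template_alignment)
    abundance = {e.id: e.abundance for e in uniques}
    mar = []
    for (rid, row), posmap in zip(aligned.reads, aligned.maps):
        cols = {posmap[p] for p in rep_masks.get(rid, set()) if p in posmap}
        mar.append(
            MaskedAlignedRead(
                read_id=rid,
                aligned=row,
                abundance=abundance[rid],
                mask_columns=cols,
            )
        )
    result = precluster_masked(mar, diff_pct=diff_pct)
    originals = {e.id: e.seq for e in uniques}
    return restore_masks(result, originals), result
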