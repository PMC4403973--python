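"""Template projection, masked preclustering and restoration."""

import numpy as np
import pytest

from pyrodenoise.denoise import (
    MaskedAlignedRead,
    align_to_template,
    degap,
    dereplicate,
    precluster_masked,
    restore_masks,
)
from pyrodenoise.flowgram_io import SeqEntry
from tests.oracles import naive_precluster


def mar(read_id, aligned, abundance=1, masks=(), original=None):
    return MaskedAlignedRead(
        read_id=read_id,
        aligned=aligned,
        abundance=abundance,
        mask_columns=set(masks),
        original_unaligned=original or degap(aligned),
    )


# ---------------------------------------------------------------- projection
def test_read_identical_to_template_projects_onto_it(references):
    refs, _ = references
    reads = [SeqEntry("q1", refs[2].seq)]
    out = align_to_template(reads, refs)
    assert out.reads[0][1] == refs[2].seq
    assert out.maps[0] == {p: p for p in range(1, len(refs[2].seq) + 1)}
    assert out.n_padding_columns == 0


def test_degap_invariant_for_noisy_reads(references, sim_batch):
    refs, _ = references
    reads, _ = sim_batch
    entries = [SeqEntry(r.read_id, r.bases) for r in reads[:60]]
    out = align_to_template(entries, refs)
    by_id = {e.id: e.seq for e in entries}
    assert len(out.reads) == 60
    for rid, row in out.reads:
        assert degap(row) == by_id[rid]


def test_insertions_open_padding_columns():
    template = [SeqEntry("t", "ACGTACGTACGTACGTACGT")]
    reads = [SeqEntry("q", "ACGTACGTAAACGTACGTACGT")]  # AA inserted mid-read
    out = align_to_template(reads, template)
    assert out.n_padding_columns == 2
    assert degap(out.reads[0][1]) == reads[0].seq
    # the template row is re-emitted in the augmented space
    assert degap(out.template_rows[0][1]) == template[0].seq
    assert len(out.template_rows[0][1]) == out.width


def test_alignment_space_distance_tracks_pairwise(references, sim_batch):
    """Column-space mismatch counts track direct pairwise alignment distances.

    Score-equivalent gap placements in homopolymers make the two measures
    differ by the odd unit, and projection through an ungapped template adds
    up to a few units between reads of different references; the contract is
    agreement within +-1 for same-source pairs and +-3 everywhere.
    """
    from pyrodenoise.truth_align import _alignment_columns

    refs, _ = references
    reads, truths = sim_batch
    src = {t.read_id: t.reference_id for t in truths}
    entries = [SeqEntry(r.read_id, r.bases) for r in reads[:40]]
    out = align_to_template(entries, refs)
    rows = dict(out.reads)
    ids = list(rows)
    rng = np.random.default_rng(0)
    n_same = 0
    for _ in range(150):
        a, b = rng.choice(len(ids), size=2, replace=False)
        ra, rb = rows[ids[a]], rows[ids[b]]
        # column-space distance (internal columns, both-gap skipped)
        d_cols = 0
        first = max(min(i for i, c in enumerate(r) if c not in "-.") for r in (ra, rb))
        last = min(max(i for i, c in enumerate(r) if c not in "-.") for r in (ra, rb))
        for i in range(first, last + 1):
            x = "-" if ra[i] in "-." else ra[i]
            y = "-" if rb[i] in "-." else rb[i]
            if x != y and not (x == "-" and y == "-"):
                d_cols += 1
        # direct pairwise alignment distance
        _, cols = _alignment_columns(degap(ra), degap(rb))
        d_direct = sum(1 for r, q in cols if r != q)
        delta = abs(d_cols - d_direct)
        assert delta <= 3
        if src[ids[a]] == src[ids[b]]:
            n_same += 1
            assert delta <= 1
    assert n_same >= 20


# ------------------------------------------------------------- preclustering
WIDTH = 100


def _pad(seq, start=0):
    return "." * start + seq + "." * (WIDTH - start - len(seq))


def test_identical_reads_merge_and_conserve_abundance():
    a = mar("a", _pad("ACGT" * 20), abundance=10)
    b = mar("b", _pad("ACGT" * 20), abundance=1)
    result = precluster_masked([a, b])
    assert result.seed_map == {"a": "a", "b": "a"}
    assert result.corrected == [("a", "ACGT" * 20, 11)]


def test_masked_column_not_counted_and_budget_semantics():
    seed_seq = "ACGT" * 25  # length 100
    variant = "A" + "A" + seed_seq[2:]  # differs at column 2 (C->A)
    s = mar("s", _pad(seed_seq), abundance=50)
    # masked difference: merged with 0 counted diffs
    v1 = mar("v1", _pad(variant), abundance=1, masks=[2])
    r = precluster_masked([s, v1])
    assert r.seed_map["v1"] == "s"
    assert r.merge_log[0]["diffs_counted"] == 0
    assert r.merge_log[0]["diffs_skipped_masked"] == 1
    # unmasked single difference: still within floor(0.02*100)=2
    v2 = mar("v2", _pad(variant), abundance=1)
    r = precluster_masked([s, v2])
    assert r.seed_map["v2"] == "s"
    assert r.merge_log[0]["diffs_counted"] == 1
    # three unmasked differences: budget exceeded, becomes its own seed
    variant3 = "AAA" + "A" + seed_seq[4:]
    v3 = mar("v3", _pad(variant3), abundance=1)
    r = precluster_masked([s, v3])
    assert r.seed_map["v3"] == "v3"
    assert len(r.corrected) == 2


def test_terminal_gaps_skipped_but_internal_gap_counts():
    s = mar("s", _pad("ACGTACGTACGT"), abundance=9)
    # truncated read: the missing tail is terminal-gap region, not a difference
    t = mar("t", _pad("ACGTACGT"), abundance=1)
    r = precluster_masked([s, t])
    assert r.seed_map["t"] == "s"
    assert r.merge_log[0]["diffs_counted"] == 0
    # internal gap vs base is a difference
    u = mar("u", _pad("ACGT-CGTACGT"), abundance=1, original="ACGTCGTACGT")
    r = precluster_masked([s, u], diff_pct=0.2)  # budget floor(0.2*11) = 2
    assert r.merge_log[0]["diffs_counted"] == 1


def test_unequal_aligned_lengths_rejected():
    with pytest.raises(ValueError, match="unequal"):
        precluster_masked([mar("a", "ACGT"), mar("b", "ACGTA")])


def test_precluster_matches_naive_oracle_randomized(rng):
    """Optimized implementation is identical to the brute-force reference on
    randomized instances with random masks and abundances."""
    for trial in range(40):
        n_reads = int(rng.integers(2, 40))
        width = int(rng.integers(20, 120))
        base = rng.choice(list("ACGT"), size=width)
        reads = []
        for i in range(n_reads):
            seq = base.copy()
            n_mut = int(rng.integers(0, max(2, width // 10)))
            for _ in range(n_mut):
                seq[rng.integers(width)] = "ACGT"[rng.integers(4)]
            start = int(rng.integers(0, 5))
            end = int(rng.integers(0, 5))
            row = list("." * start) + list(seq[start : width - end]) + list("." * end)
            # sprinkle internal gaps
            for _ in range(int(rng.integers(0, 3))):
                c = int(rng.integers(start + 1, width - end - 1))
                row[c] = "-"
            aligned = "".join(row)
            masks = set(int(c) + 1 for c in rng.integers(0, width, size=rng.integers(0, 6)))
            reads.append(
                mar(f"r{i:03d}", aligned, abundance=int(rng.integers(1, 30)), masks=masks)
            )
        ours = precluster_masked(reads)
        oracle_map, oracle_seeds = naive_precluster(reads)
        assert ours.seed_map == oracle_map
        assert ours.corrected == oracle_seeds
        assert sum(a for _, _, a in ours.corrected) == sum(r.abundance for r in reads)


def test_restore_unmerged_reads_byte_identical():
    s = mar("s", _pad("ACGT" * 25), abundance=5)
    lone = mar("x", _pad("TTTT" * 25), abundance=1, masks=[3, 7, 11, 13, 17])
    r = precluster_masked([s, lone])
    assert r.seed_map["x"] == "x"
    originals = {"s": "ACGT" * 25, "x": "TTTT" * 25}
    out = restore_masks(r, originals)
    by_id = {e.id: e for e in out}
    assert by_id["x"].seq == "TTTT" * 25  # exact original despite 5 masked positions
    assert by_id["s"].abundance == 5


def test_restore_missing_original_rejected():
    s = mar("s", _pad("ACGT" * 25))
    r = precluster_masked([s])
    with pytest.raises(ValueError, match="missing original"):
        restore_masks(r, {})


def test_empty_masks_equal_plain_preclustering(rng):
    # regression property: with no masks the algorithm IS plain preclustering
    reads = []
    base = rng.choice(list("ACGT"), size=80)
    for i in range(25):
        seq = base.copy()
        for _ in range(int(rng.integers(0, 4))):
            seq[rng.integers(80)] = "ACGT"[rng.integers(4)]
        reads.append(mar(f"r{i}", "".join(seq), abundance=int(rng.integers(1, 20))))
    masked = [
        mar(r.read_id, r.aligned, r.abundance, masks=set()) for r in reads
    ]
    r1 = precluster_masked(reads)
    r2 = precluster_masked(masked)
    assert r1.seed_map == r2.seed_map
    assert r1.corrected == r2.corrected


def test_dereplicate_unions_masks_and_counts():
    reads = [("b", "ACGT"), ("a", "ACGT"), ("c", "TTTT")]
    masks = {"a": {1}, "b": {2}, "c": set()}
    uniques, rep_masks, member_map = dereplicate(reads, masks)
    assert [(e.id, e.seq, e.abundance) for e in uniques] == [("a", "ACGT", 2), ("c", "TTTT", 1)]
    assert rep_masks["a"] == {1, 2}
    assert member_map == {"a": "a", "b": "a", "c": "c"}
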