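"""Chimera detection, error-rate reporting and positional profiles."""

import numpy as np
import pytest

from pyrodenoise.assess import compute_error_report, detect_chimeras, positional_profile
from pyrodenoise.flowgram_io import SeqEntry
from pyrodenoise.sim454 import make_chimeras
from tests.oracles import naive_chimera_scores


def test_read_identical_to_reference_not_chimeric(references):
    refs, _ = references
    rows = [(r.id, r.seq) for r in refs]
    out = detect_chimeras([("q", refs[0].seq)], rows)
    row = out.iloc[0]
    assert row["best_single"] == 0 and not row["is_chimera"]


def test_constructed_chimera_detected(references):
    refs, _ = references
    chims, meta = make_chimeras(refs, 10, seed=3)
    rows = [(r.id, r.seq) for r in refs]
    out = detect_chimeras([(c.id, c.seq) for c in chims], rows)
    # parents at 10% divergence: most chimeras beat the margin comfortably
    assert out["is_chimera"].mean() >= 0.8
    assert (out["best_chimera"] == 0).all()


def test_margin_is_strict_at_three():
    # parents differing at exactly 4 columns, split 2+2 around the breakpoint:
    # best_single = 2, best_chimera = 0, improvement 2 < 3 -> not chimeric
    a = "AAAAAAAAAAAAAAAAAAAA"
    b = "AACAACAAAAAAACAAACAA"  # diffs at cols 3, 6, 14, 18
    read = b[:10] + a[10:]  # chimera of b then a
    out = detect_chimeras([("q", read)], [("a", a), ("b", b)])
    row = out.iloc[0]
    assert row["best_single"] == 2 and row["best_chimera"] == 0
    assert not row["is_chimera"]
    # 6 differences split 3+3: improvement 3 >= 3 -> chimeric
    b6 = "AACAACAAACAAACAAACAA"  # diffs at 3, 6, 10, 14, 18 -> 5... use margin calc below
    b6 = "ACCAACAAACAAACAAACAA"  # diffs at 2, 3, 6, 10, 14, 18
    read6 = b6[:8] + a[8:]
    out = detect_chimeras([("q", read6)], [("a", a), ("b", b6)])
    row = out.iloc[0]
    assert row["best_single"] == 3 and row["best_chimera"] == 0
    assert row["is_chimera"]


def test_fewer_than_two_references_disables_detection(references):
    refs, _ = references
    with pytest.warns(UserWarning, match="fewer than 2"):
        out = detect_chimeras([("q", refs[0].seq)], [(refs[0].id, refs[0].seq)])
    assert not out["is_chimera"].any()


def test_chimera_scores_match_bruteforce_randomized(rng):
    """Prefix-array chimera scoring equals the exhaustive breakpoint search."""
    for trial in range(25):
        n_refs = int(rng.integers(2, 8))
        width = int(rng.integers(30, 120))
        base = rng.choice(list("ACGT"), size=width)
        ref_rows = []
        for i in range(n_refs):
            seq = base.copy()
            for _ in range(int(rng.integers(1, width // 4))):
                seq[rng.integers(width)] = "ACGT"[rng.integers(4)]
            ref_rows.append((f"ref{i}", "".join(seq)))
        # reads: mutated single refs and spliced pairs, with terminal gaps
        read_rows = []
        for j in range(6):
            ia, ib = rng.integers(n_refs), rng.integers(n_refs)
            bp = int(rng.integers(5, width - 5))
            seq = list(ref_rows[ia][1][:bp] + ref_rows[ib][1][bp:])
            for _ in range(int(rng.integers(0, 4))):
                seq[rng.integers(width)] = "ACGT"[rng.integers(4)]
            start = int(rng.integers(0, 6))
            end = int(rng.integers(0, 6))
            row = "." * start + "".join(seq[start : width - end]) + "." * end
            read_rows.append((f"q{j}", row))
        out = detect_chimeras(read_rows, ref_rows)
        for _, r in out.iterrows():
            bs, bc = naive_chimera_scores(dict(read_rows)[r["read_id"]], ref_rows)
            assert r["best_single"] == bs
            assert r["best_chimera"] == bc


def test_error_report_zero_for_perfect_reads(references):
    refs, _ = references
    reads = [SeqEntry(f"q{i}", r.seq) for i, r in enumerate(refs[:4])]
    report = compute_error_report(reads, refs)
    assert report.error_rate == 0.0
    assert report.chimera_pct == 0.0


def test_error_rate_arithmetic():
    refs = [SeqEntry("ref1", "ACGT" * 25)]
    clean = SeqEntry("c", refs[0].seq)
    mutated = "ACGT" * 12 + "AAGT" + "ACGT" * 12  # one substitution, 100 nt
    one_sub = SeqEntry("m", mutated)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # single reference: chimera check off
        report = compute_error_report([clean, one_sub], refs)
    assert report.error_rate == pytest.approx(1 / 200)


def test_error_rate_abundance_weighting_equals_duplication():
    import warnings

    refs = [SeqEntry("ref1", "ACGTACGTAT" * 10), SeqEntry("ref2", "TTGACCGTAT" * 10)]
    mutated = "ACGTACGTAT" * 5 + "ACGAACGTAT" + "ACGTACGTAT" * 4
    weighted = [SeqEntry("c", refs[0].seq, None, 3), SeqEntry("m", mutated, None, 2)]
    expanded = [
        SeqEntry("c1", refs[0].seq),
        SeqEntry("c2", refs[0].seq),
        SeqEntry("c3", refs[0].seq),
        SeqEntry("m1", mutated),
        SeqEntry("m2", mutated),
    ]
    r1 = compute_error_report(weighted, refs)
    r2 = compute_error_report(expanded, refs)
    assert r1.error_rate == pytest.approx(r2.error_rate)


def test_chimeric_reads_excluded_from_error_rate(references):
    refs, _ = references
    chims, _ = make_chimeras(refs, 3, seed=1)
    reads = [SeqEntry(f"q{i}", r.seq) for i, r in enumerate(refs[:3])] + chims
    report = compute_error_report(reads, refs)
    assert report.chimera_pct > 0
    flagged = report.per_read[report.per_read["is_chimera"]]
    # only constructed chimeras may be flagged (one with a near-terminal
    # breakpoint can legitimately stay under the 3-mismatch margin)
    assert set(flagged["read_id"]) <= {c.id for c in chims}
    assert len(flagged) >= 2
    # the aggregate rate is computed over non-chimeric reads only
    nonchim = report.per_read[~report.per_read["is_chimera"]]
    expected = float(
        ((nonchim["n_sub"] + nonchim["n_ins"] + nonchim["n_del"]) * nonchim["abundance"]).sum()
        / (nonchim["n_bases"] * nonchim["abundance"]).sum()
    )
    assert report.error_rate == pytest.approx(expected)


def test_positional_profile_conservation(references, sim_batch):
    refs, _ = references
    reads, _ = sim_batch
    entries = [SeqEntry(r.read_id, r.bases) for r in reads[:80]]
    report = compute_error_report(entries, refs)
    prof = positional_profile(report)
    total_from_profile = float((prof["total_rate"] * prof["coverage"]).sum())
    nonchim = report.per_read[~report.per_read["is_chimera"]]
    total_from_reads = int(
        ((nonchim["n_sub"] + nonchim["n_ins"] + nonchim["n_del"]) * nonchim["abundance"]).sum()
    )
    assert total_from_profile == pytest.approx(total_from_reads)


def test_positional_profile_zero_on_clean_input(references):
    refs, _ = references
    reads = [SeqEntry("q", refs[0].seq)]
    report = compute_error_report(reads, refs)
    prof = positional_profile(report)
    assert (prof["total_rate"] == 0).all()
    assert (prof["coverage"] == 1).all()
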