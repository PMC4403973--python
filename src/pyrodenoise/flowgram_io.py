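"""Flowgram-aware sequence I/O.

The central container is :class:`FlowRead`, a lossless model of one 454 read:
the flowgram (one signal per nucleotide flow, in flow units where 1.0 is one
incorporated base), the per-base index into the flowgram, the called bases,
Phred scores, and the two clip-point pairs. SFF files store flow signals as
integer hundredths; the conversion happens only at the file boundary, so all
in-memory values are in flow units.

Coordinates are 1-based inclusive throughout (the SFF clip-point convention).

SFF parsing/serialisation is delegated to Biopython's ``Bio.SeqIO.SffIO``;
FASTA / QUAL / FASTQ / aligned FASTA go through ``Bio.SeqIO``. Abundances use
the ``id;size=N`` header dialect (default 1 when absent).
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.SffIO import SffWriter

from pyrodenoise.errors import FormatError

SFF_MAGIC = b".sff"
SFF_VERSION = b"\x00\x00\x00\x01"

_SIZE_RE = re.compile(r"^(?P<id>.+?);size=(?P<size>\d+);?$")


@dataclass
class FlowRead:
    """One 454 read with its full flowgram context.

    ``flow_values`` are reals in flow units; ``flow_index_per_base`` holds the
    1-based flow that called each base; ``clip_qual``/``clip_adapter`` are
    1-based inclusive coordinate pairs ((0, 0) = no clip recorded).
    """

    read_id: str
    flow_chars: str
    flow_values: list[float]
    flow_index_per_base: list[int]
    bases: str
    quals: list[int]
    clip_qual: tuple[int, int] = (0, 0)
    clip_adapter: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if not (len(self.bases) == len(self.quals) == len(self.flow_index_per_base)):
            raise ValueError(
                f"{self.read_id}: bases/quals/flow_index lengths differ "
                f"({len(self.bases)}/{len(self.quals)}/{len(self.flow_index_per_base)})"
            )
        if len(self.flow_chars) != len(self.flow_values):
            raise ValueError(f"{self.read_id}: flow_chars and flow_values lengths differ")
        prev = 1
        for base, idx in zip(self.bases, self.flow_index_per_base):
            if idx < prev or idx > len(self.flow_values):
                raise ValueError(f"{self.read_id}: flow index {idx} out of order or range")
            if base != "N" and self.flow_chars[idx - 1] != base:
                raise ValueError(
                    f"{self.read_id}: base {base} called from a {self.flow_chars[idx - 1]} flow"
                )
            prev = idx

    def __len__(self) -> int:
        return len(self.bases)

    def truncate(self, n_bases: int) -> "FlowRead":
        """Return a copy keeping only the first ``n_bases`` called bases."""
        return replace(
            self,
            bases=self.bases[:n_bases],
            quals=self.quals[:n_bases],
            flow_index_per_base=self.flow_index_per_base[:n_bases],
            clip_qual=(min(self.clip_qual[0], n_bases), min(self.clip_qual[1], n_bases)),
            clip_adapter=(
                min(self.clip_adapter[0], n_bases),
                min(self.clip_adapter[1], n_bases),
            ),
        )


@dataclass
class SeqEntry:
    """A plain sequence record with optional quality and abundance annotation."""

    id: str
    seq: str
    quals: list[int] | None = None
    abundance: int = 1

    def header(self) -> str:
        return f"{self.id};size={self.abundance}" if self.abundance != 1 else self.id


def _check_sff_header(path: str | Path) -> None:
    with open(path, "rb") as fh:
        head = fh.read(8)
    if len(head) < 8 or head[:4] != SFF_MAGIC:
        raise FormatError(f"{path}: bad SFF magic number at offset 0 (expected {SFF_MAGIC!r})")
    if head[4:8] != SFF_VERSION:
        raise FormatError(f"{path}: unsupported SFF version at offset 4")


def read_sff(path: str | Path) -> list[FlowRead]:
    """Read an SFF file into FlowReads (flow values rescaled to flow units)."""
    _check_sff_header(path)
    reads: list[FlowRead] = []
    try:
        for ordinal, rec in enumerate(SeqIO.parse(str(path), "sff"), start=1):
            ann = rec.annotations
            deltas = list(ann["flow_index"])
            absolute: list[int] = []
            pos = 0
            for d in deltas:
                pos += d
                absolute.append(pos)
            reads.append(
                FlowRead(
                    read_id=rec.id,
                    flow_chars=str(ann["flow_chars"]),
                    flow_values=[v / 100.0 for v in ann["flow_values"]],
                    flow_index_per_base=absolute,
                    bases=str(rec.seq).upper(),
                    quals=list(rec.letter_annotations["phred_quality"]),
                    clip_qual=(int(ann["clip_qual_left"]), int(ann["clip_qual_right"])),
                    clip_adapter=(
                        int(ann["clip_adapter_left"]),
                        int(ann["clip_adapter_right"]),
                    ),
                )
            )
    except ValueError as exc:
        raise FormatError(
            f"{path}: truncated or malformed SFF at record {len(reads) + 1}: {exc}"
        ) from exc
    return reads


def _write_empty_sff(path: str | Path, flow_chars: str, key_sequence: str) -> None:
    # Common header only, number_of_reads = 0. Header length padded to 8 bytes.
    base = 31 + len(flow_chars) + len(key_sequence)
    header_length = (base + 7) // 8 * 8
    with open(path, "wb") as fh:
        fh.write(SFF_MAGIC)
        fh.write(SFF_VERSION)
        fh.write(struct.pack(">QLL", 0, 0, 0))  # index offset/length, number_of_reads
        fh.write(struct.pack(">HHHB", header_length, len(key_sequence), len(flow_chars), 1))
        fh.write(flow_chars.encode())
        fh.write(key_sequence.encode())
        fh.write(b"\x00" * (header_length - base))


def write_sff(
    reads: Sequence[FlowRead],
    path: str | Path,
    *,
    flow_chars: str | None = None,
    key_sequence: str = "TCAG",
) -> None:
    """Write FlowReads to a spec-conformant big-endian SFF file.

    Flow units are rescaled to stored hundredths and clamped to uint16.
    All reads must share one flow order. ``flow_chars`` is only needed for an
    empty read list (the common header still records a flow order).
    """
    if not reads:
        _write_empty_sff(path, flow_chars or "TACG" * 100, key_sequence)
        return
    orders = {r.flow_chars for r in reads}
    if len(orders) > 1:
        raise ValueError(f"heterogeneous flow orders in one SFF file: {sorted(orders)}")
    records = []
    for r in reads:
        deltas: list[int] = []
        prev = 0
        for idx in r.flow_index_per_base:
            d = idx - prev
            if d > 255:
                raise ValueError(
                    f"{r.read_id}: flow index step {d} exceeds the SFF uint8 delta limit"
                )
            deltas.append(d)
            prev = idx
        rec = SeqRecord(Seq(r.bases), id=r.read_id, name=r.read_id, description="")
        rec.annotations["flow_key"] = key_sequence
        rec.annotations["flow_chars"] = r.flow_chars
        rec.annotations["flow_values"] = [
            min(65535, max(0, round(v * 100.0))) for v in r.flow_values
        ]
        rec.annotations["flow_index"] = deltas
        rec.annotations["clip_qual_left"] = r.clip_qual[0]
        rec.annotations["clip_qual_right"] = r.clip_qual[1]
        rec.annotations["clip_adapter_left"] = r.clip_adapter[0]
        rec.annotations["clip_adapter_right"] = r.clip_adapter[1]
        rec.annotations["molecule_type"] = "DNA"
        rec.letter_annotations["phred_quality"] = list(r.quals)
        records.append(rec)
    with open(path, "wb") as fh:
        SffWriter(fh).write_file(records)


def parse_abundance(header: str) -> tuple[str, int]:
    """Split an ``id;size=N`` header into (id, N); plain ids get abundance 1."""
    m = _SIZE_RE.match(header)
    if m:
        return m.group("id"), int(m.group("size"))
    return header, 1


def read_sequences(
    path: str | Path,
    format: str,
    qual_path: str | Path | None = None,
) -> list[SeqEntry]:
    """Read sequence records; ``format`` in {fasta, fasta+qual, fastq, aligned-fasta}."""
    entries: list[SeqEntry] = []
    if format == "fasta" or format == "aligned-fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            rid, size = parse_abundance(rec.description.split()[0] if rec.description else rec.id)
            entries.append(SeqEntry(rid, str(rec.seq), None, size))
        if format == "aligned-fasta":
            lengths = {len(e.seq) for e in entries}
            if len(lengths) > 1:
                raise FormatError(f"{path}: aligned-fasta records of unequal length {sorted(lengths)}")
    elif format == "fastq":
        for rec in SeqIO.parse(str(path), "fastq"):
            rid, size = parse_abundance(rec.id)
            entries.append(
                SeqEntry(rid, str(rec.seq), list(rec.letter_annotations["phred_quality"]), size)
            )
    elif format == "fasta+qual":
        if qual_path is None:
            qual_path = str(path) + ".qual" if not str(path).endswith(".fasta") else str(path)[:-6] + ".qual"
        seqs = list(SeqIO.parse(str(path), "fasta"))
        quals = list(SeqIO.parse(str(qual_path), "qual"))
        if len(seqs) != len(quals):
            raise FormatError(f"{path}: FASTA and QUAL record counts differ")
        for s, q in zip(seqs, quals):
            if s.id != q.id:
                raise FormatError(f"{path}: FASTA/QUAL id mismatch ({s.id} vs {q.id})")
            qv = list(q.letter_annotations["phred_quality"])
            if len(qv) != len(s.seq):
                raise FormatError(f"{path}: quality/sequence length mismatch for {s.id}")
            rid, size = parse_abundance(s.id)
            entries.append(SeqEntry(rid, str(s.seq), qv, size))
    else:
        raise ValueError(f"unknown sequence format: {format}")
    return entries


def write_sequences(
    entries: Iterable[SeqEntry],
    path: str | Path,
    format: str,
    qual_path: str | Path | None = None,
) -> None:
    """Write sequence records in the given format (see :func:`read_sequences`)."""
    entries = list(entries)
    if format in ("fasta", "aligned-fasta"):
        if format == "aligned-fasta":
            lengths = {len(e.seq) for e in entries}
            if len(lengths) > 1:
                raise FormatError("aligned-fasta records of unequal length")
        with open(path, "w") as fh:
            for e in entries:
                fh.write(f">{e.header()}\n{e.seq}\n")
    elif format == "fastq":
        with open(path, "w") as fh:
            for e in entries:
                if e.quals is None:
                    raise ValueError(f"{e.id}: fastq output requires quality scores")
                q = "".join(chr(min(40, max(0, v)) + 33) for v in e.quals)
                fh.write(f"@{e.header()}\n{e.seq}\n+\n{q}\n")
    elif format == "fasta+qual":
        if qual_path is None:
            qual_path = str(path) + ".qual"
        with open(path, "w") as fh, open(qual_path, "w") as qh:
            for e in entries:
                if e.quals is None:
                    raise ValueError(f"{e.id}: fasta+qual output requires quality scores")
                fh.write(f">{e.header()}\n{e.seq}\n")
                qh.write(f">{e.header()}\n{' '.join(str(v) for v in e.quals)}\n")
    else:
        raise ValueError(f"unknown sequence format: {format}")
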