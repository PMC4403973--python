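"""Flowgram read simulator with exact ground-truth error annotations.

The generative model walks a reference sequence through the cyclic flow
order. The true incorporation count ``n`` at each flow is perturbed by:

* **Gaussian intensity noise** — sd grows linearly with homopolymer length
  (``sd(n) = sd0 + slope * n``) and inflates multiplicatively along the read
  (``decay(f) = 1 + positional_decay * f``), reproducing the two dominant 454
  failure modes: homopolymer length miscalls and quality decline toward the
  read end.
* **CAFIE leakage** — carry-forward moves a random fraction of a flow's
  signal into the most recent preceding flow of the same nucleotide;
  incomplete extension leaves a residual for the next same-nucleotide flow.
  Both produce the insertion/substitution artifacts seen near homopolymers.

The called homopolymer length is ``round(signal)`` clamped at zero. Phred
scores come from a crude but monotone model in the two drivers the classifier
uses: distance of the signal from its rounded value, and flow position.

Ground truth is bookkept flow by flow during generation (never recovered by
re-alignment), which makes the simulator an oracle that is independent of the
alignment-based labeling code it is used to validate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from pyrodenoise import _alncols
from pyrodenoise.flowgram_io import FlowRead, SeqEntry

BASES = "ACGT"


@dataclass
class SimParams:
    """Error-model parameters for the flowgram simulator.

    All probabilities are per flow; ``sd0``/``sd_slope`` define the signal
    standard deviation ``sd(n) = sd0 + sd_slope * n`` for a true homopolymer
    of length ``n``; ``positional_decay`` multiplies the sd by
    ``1 + positional_decay * flow``; leak fractions for CAFIE events are drawn
    uniformly from ``[leak_low, leak_high]``.
    """

    flow_order: str = "TACG"
    n_flows: int = 800
    sd0: float = 0.04
    sd_slope: float = 0.04
    carry_forward_rate: float = 0.003
    incomplete_extension_rate: float = 0.003
    positional_decay: float = 0.0015
    leak_low: float = 0.15
    leak_high: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("carry_forward_rate", "incomplete_extension_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_flows < 1:
            raise ValueError("n_flows must be >= 1")
        if self.intensity_sd(0) < 0 or self.intensity_sd(1) <= 0:
            raise ValueError("intensity sd must be positive")

    def intensity_sd(self, n: int) -> float:
        return self.sd0 + self.sd_slope * n

    def decay(self, flow: int) -> float:
        return 1.0 + self.positional_decay * flow

    def phred(self, signal: float, flow: int) -> int:
        # crude but monotone in the two drivers the classifier uses: distance
        # of the signal from its rounded value, and position along the read.
        # Coefficients put typical clean bases in the low-to-mid 30s with the
        # read tail drifting below Q30, as on real plates.
        dev = abs(signal - round(signal))
        return int(min(40, max(2, round(40.0 - 50.0 * dev - 0.005 * flow))))


@dataclass
class SimTruth:
    """Ground-truth error events for one simulated read.

    ``events`` holds sorted (1-based read position, type) pairs with type in
    {insertion, deletion, substitution}; a deletion is anchored to the called
    base immediately 3' of the missing reference base(s). ``truncated`` marks
    reads whose reference was not fully covered by ``n_flows``.
    """

    read_id: str
    reference_id: str
    events: list[tuple[int, str]] = field(default_factory=list)
    truncated: bool = False


def generate_references(
    n_species: int,
    length: int,
    divergence: float,
    seed: int,
) -> tuple[list[SeqEntry], np.ndarray]:
    """Random reference set: one ancestor mutated into diverged species.

    Mutations are substitutions only, so the returned references are mutually
    aligned as-is (equal length, no gaps) and double as a template alignment.
    Abundance weights are log-uniform over [0.5%, 50%] before normalisation,
    emulating an uneven mock community. Deterministic under ``seed``.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if length < 50:
        raise ValueError("length must be >= 50")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_species)))
    for _attempt in range(100):
        ancestor = rng.choice(list(BASES), size=length)
        refs: list[str] = []
        for _ in range(n_species):
            seq = ancestor.copy()
            mutate = rng.random(length) < divergence / 2.0
            for i in np.flatnonzero(mutate):
                choices = [b for b in BASES if b != seq[i]]
                seq[i] = choices[rng.integers(3)]
            refs.append("".join(seq))
        if len(set(refs)) == n_species:
            raw = np.exp(rng.uniform(math.log(0.005), math.log(0.5), size=n_species))
            weights = raw / raw.sum()
            entries = [SeqEntry(f"ref{i + 1:0{width}d}", s) for i, s in enumerate(refs)]
            return entries, weights
        warnings.warn(
            f"reference collision at divergence {divergence}; regenerating "
            f"(attempt {_attempt + 1})"
        )
    raise ValueError(
        "could not generate distinct references after 100 attempts; increase divergence"
    )


def _true_flow_counts(reference: str, flow_chars: str) -> tuple[list[int], int]:
    """Walk the reference through the flow order: per-flow incorporation counts."""
    counts = []
    pos = 0
    n = len(reference)
    for ch in flow_chars:
        run = 0
        while pos + run < n and reference[pos + run] == ch:
            run += 1
        counts.append(run)
        pos += run
    return counts, pos


def _simulate_one(
    reference: str,
    flow_chars: str,
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[list[float], list[int], list[int], int]:
    """One flowgram: (signals, called counts, true counts, ref bases consumed)."""
    true_counts, consumed = _true_flow_counts(reference, flow_chars)
    mean = np.asarray(true_counts, dtype=np.float64)

    for f in range(params.n_flows):
        if true_counts[f] == 0:
            continue
        if rng.random() < params.carry_forward_rate:
            ch = flow_chars[f]
            g = next((h for h in range(f - 1, -1, -1) if flow_chars[h] == ch), None)
            if g is not None:
                a = rng.uniform(params.leak_low, params.leak_high)
                mean[g] += a
                mean[f] -= a
        if rng.random() < params.incomplete_extension_rate:
            ch = flow_chars[f]
            g = next((h for h in range(f + 1, params.n_flows) if flow_chars[h] == ch), None)
            if g is not None:
                a = rng.uniform(params.leak_low, params.leak_high)
                mean[g] += a
                mean[f] -= a

    sds = np.array(
        [params.intensity_sd(true_counts[f]) * params.decay(f + 1) for f in range(params.n_flows)]
    )
    signals = np.maximum(0.0, mean + rng.normal(0.0, 1.0, params.n_flows) * sds)
    called = np.maximum(0, np.floor(signals + 0.5).astype(int))
    return list(signals), list(called), true_counts, consumed


def _truth_events(
    flow_chars: str,
    true_counts: list[int],
    called: list[int],
) -> list[tuple[int, str]]:
    """Flow-space alignment columns -> canonicalized per-position events."""
    cols: list[_alncols.Column] = []
    for f, ch in enumerate(flow_chars):
        n, c = true_counts[f], called[f]
        m = min(n, c)
        cols.extend([(ch, ch)] * m)
        if c > n:
            cols.extend([(ch, _alncols.GAP)] * (c - n))
        elif n > c:
            cols.extend([(_alncols.GAP, ch)] * (n - c))
    cols = _alncols.trim_terminal_read_gaps(_alncols.canonicalize(cols))
    return _alncols.events_from_columns(cols)


def simulate_reads(
    references: list[SeqEntry],
    weights,
    n_reads: int,
    params: SimParams,
) -> tuple[list[FlowRead], list[SimTruth]]:
    """Simulate flowgram reads from weighted references, with ground truth."""
    weights = np.asarray(weights, dtype=np.float64)
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("weights must sum to 1")
    rng = np.random.default_rng(params.seed)
    flow_chars = (params.flow_order * math.ceil(params.n_flows / len(params.flow_order)))[
        : params.n_flows
    ]
    reads: list[FlowRead] = []
    truths: list[SimTruth] = []
    for i in range(n_reads):
        ref = references[int(rng.choice(len(references), p=weights))]
        signals, called, true_counts, consumed = _simulate_one(ref.seq, flow_chars, params, rng)
        bases = []
        flow_index = []
        quals = []
        for f in range(params.n_flows):
            if called[f] == 0:
                continue
            q = params.phred(signals[f], f + 1)
            for _ in range(called[f]):
                bases.append(flow_chars[f])
                flow_index.append(f + 1)
                quals.append(q)
        read_id = f"sim{i:05d}"
        events = _truth_events(flow_chars, true_counts, called)
        read = FlowRead(
            read_id=read_id,
            flow_chars=flow_chars,
            flow_values=signals,
            flow_index_per_base=flow_index,
            bases="".join(bases),
            quals=quals,
            clip_qual=(1, len(bases)),
            clip_adapter=(0, 0),
        )
        reads.append(read)
        truths.append(
            SimTruth(
                read_id=read_id,
                reference_id=ref.id,
                events=events,
                truncated=consumed < len(ref.seq),
            )
        )
    return reads, truths


@dataclass
class ChimeraRecord:
    id: str
    parent_a: str
    parent_b: str
    breakpoint: int


def make_chimeras(
    references: list[SeqEntry],
    n: int,
    seed: int,
) -> tuple[list[SeqEntry], list[ChimeraRecord]]:
    """Two-parent chimeras: prefix of A up to a breakpoint + suffix of B.

    Breakpoints are drawn uniformly from [10, L-10] so neither parent
    contributes a trivially short fragment.
    """
    if len(references) < 2:
        raise ValueError("need at least 2 references to form chimeras")
    rng = np.random.default_rng(seed)
    out: list[SeqEntry] = []
    meta: list[ChimeraRecord] = []
    for i in range(n):
        ia, ib = rng.choice(len(references), size=2, replace=False)
        a, b = references[int(ia)], references[int(ib)]
        lo, hi = 10, min(len(a.seq), len(b.seq)) - 10
        bp = int(rng.integers(lo, hi + 1))
        cid = f"chimera{i:04d}"
        out.append(SeqEntry(cid, a.seq[:bp] + b.seq[bp:]))
        meta.append(ChimeraRecord(cid, a.id, b.id, bp))
    return out, meta
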