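# Methods

## The problem

454 pyrosequencing infers homopolymer lengths from analog flow signals: at
each nucleotide flow the light intensity is proportional to the number of
incorporated bases, and the called run length is the rounded signal. This
makes run-length miscalls (insertions and deletions at homopolymers) the
platform's dominant error mode, with two systematic aggravators: signal
noise grows with homopolymer length and with position along the read, and
incomplete washing leaks signal between same-nucleotide flows (carry-forward
and incomplete extension, "CAFIE"), producing spurious calls near
homopolymers. In 16S rRNA amplicon surveys these errors inflate the number
of operational taxonomic units and distort diversity estimates, so error
correction precedes clustering.

## The two-stage correction

**Stage 1 — flag suspect positions.** Every called base gets 13 attributes
from the flowgram: position in the read, Phred score, homopolymer code
(N for isolated bases; A/B/.../Z marking first/interior/last positions of a
run), carry-forward sensitivity (was this nucleotide flowed but uncalled
immediately upstream?), and the flow signal intensity — plus, for each of
the two neighbouring bases, their Phred, homopolymer code and intensity, and
the strongest *uncalled* flow signal between the two calling flows. A
support-vector machine with the Pearson VII universal kernel

    K(x, y) = 1 / [1 + (2 sqrt(2^(1/w) - 1) ||x - y|| / s)^2]^w

classifies each position as clean, insertion, deletion or substitution
(one-vs-one pairwise voting, trained by sequential minimal optimization;
defaults w = s = C = 1, the conventional defaults of the toolkit family this
kernel comes from). Any non-clean call marks the position.

Training data come from reads whose source sequences are known: each read is
matched to its best reference (8-mer count prescreen, then glocal affine
alignment — read global, reference local; match +1, mismatch −1, gap open
−2, extend −1), indel gaps are canonicalized to the 3' end of homopolymer
runs, and each position is labeled clean/insertion/deletion/substitution
(a deletion is anchored to the called base immediately 3' of the missing
reference base; at one position the precedence is substitution > insertion >
deletion). The labeled table is dereplicated on exact feature-vector
equality, split 1:9 (training:held-out) stratified by class, and the
training subset is balanced to 132 instances per error type plus 700 clean
instances — errors are otherwise outnumbered ~100:1 and the classifier would
collapse to the majority class. When a class has fewer instances than its
target, all targets scale down proportionally. Features are min–max
normalized to [0,1] with statistics frozen from the training subset;
homopolymer codes are one-hot encoded (9 indicators per code field).
Evaluation collapses the four classes to error/clean: sensitivity =
TP/(TP+FN), specificity = TN/(TN+FP) over held-out positions.

**Stage 2 — masked preclustering.** Reads are dereplicated (identical
sequences pooled; their masks are unioned) and projected into the column
space of a template alignment, NAST style: each read is pairwise-aligned to
its best template record and its bases inherit that record's columns; read
insertions relative to the template are squeezed into existing template gap
columns, and only when no capacity exists is a minimal set of '.'-padded
columns opened once for the whole read set. Reads are then processed from
most to least abundant (ties: longer read, then lexicographic id); each read
merges into the first already-fixed seed from which it differs at no more
than floor(0.02 × read length) columns, where

* a column masked in *either* read is skipped (the masking is what lets an
  error-containing read reach its error-free seed),
* terminal-gap columns are skipped, gap-vs-base counts as a difference,
  both-gap columns are ignored,

and merging adds the read's abundance to the seed. Reads that never merge
are emitted byte-identical to their pre-masking originals — masking affects
only the difference counting, never the output sequence. Seeds keep their
called sequence even when they accrete members. Total abundance is conserved
exactly.

## Evaluation machinery

Error rates against a mock community are computed after reference-based
chimera filtering: a read is chimeric when some two-parent reference chimera
(prefix of one reference + suffix of another, any breakpoint column) is at
least 3 mismatches closer to it than the best single reference. The search
is exact but linear-time per read via per-reference prefix-mismatch arrays.
The global error rate is erroneous nucleotides over total nucleotides across
non-chimeric reads, abundance-weighted, with per-read counts reusing the
same canonicalized labeling as training — one definition of "error"
throughout. A positional profile (events of each type at position p over
reads covering p) reproduces the characteristic rise of the error rate
toward the read end.

## The simulator

The generator emulates a 454 run on a known community so the whole pipeline
is testable without external data. References descend from one random
ancestor by substitutions only (so the reference set is mutually aligned
as-is and doubles as the template alignment); abundance weights are
log-uniform on [0.5%, 50%], the uneven-mock design. Each read walks its
reference through the cyclic flow order (default TACG); the true
incorporation count n at each flow is perturbed by

* Gaussian intensity noise, sd(n) = sd0 + slope·n (defaults 0.04 + 0.04 n),
  inflated by 1 + 0.0015·flow along the read;
* carry-forward: with probability 0.003 per active flow, a fraction
  U(0.15, 0.6) of the flow's signal moves into the most recent preceding
  same-nucleotide flow;
* incomplete extension: with the same probability, a residual moves to the
  next same-nucleotide flow.

The called run length is round(signal) clamped at zero; Phred scores follow
Q = clamp(round(40 − 50·|signal − round(signal)| − 0.005·flow), 2, 40),
crude but monotone in the two drivers the classifier uses, putting typical
clean bases in the low-to-mid 30s with tails drifting below Q30 so strict
trimming truncates tails rather than rejecting whole reads. These defaults
yield a per-base error rate around half a percent dominated by homopolymer
indels with substitutions rarest — the error magnitude and type ordering of
basically-trimmed real 454 mock data.

Ground truth is bookkept flow by flow during generation, never recovered by
re-alignment, so the simulator is an oracle independent of the
alignment-based labeler. The flow-space alignment implied by (true counts,
called counts) is canonicalized exactly as aligner output is: gaps shift 3',
and an insertion/deletion pair separated by a short bridge is re-rendered as
a substitution run whenever that scores at least as well under the alignment
scoring (an optimal affine aligner reports a 3-mismatch run, score −3, over
two single-base gaps, score −6). With this shared canonical form the test
suite asserts that the two labeling routes agree on at least 95% of events;
residual disagreement sits at homopolymer boundaries where several
renderings tie.

## What the simulator does not model

PCR-cycle chimera kinetics (chimeras for testing are constructed directly as
two-parent splices), plate-position effects, per-nucleotide transition-rate
asymmetries, and polymerase point errors as a separate channel. Passing
tests therefore demonstrate the machinery is correct under the stated error
model, not that real-plate sensitivities will match; on real data the
classifier would be retrained on a mock run from the same platform.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere (the SFF clip-point
  convention); flow values live in flow units in memory and convert to
  stored hundredths only at the file boundary.
* Strict trimming: window 100, step 1, cut before the first failing window
  (the semantics of the mothur-style sliding-window trimmer), minimum
  length re-applied after trimming.
* Missing-neighbour sentinels at read ends: Phred −1, code 'N',
  intensity 0.0, max-uncalled 0.0 — keeps the feature schema rectangular.
* Merge budget: floor(0.02 × unaligned length of the less abundant read);
  floor is conservative (never merges above 2%).
* All ordering rules (candidate references, preclustering, class voting)
  have total deterministic tie-breaks, so identical inputs give identical
  outputs; every random operation takes an explicit seed.
* The bundled study (selftest, examples, acceptance script) uses 10
  references of length 350 at 10% divergence and 2,000 simulated reads —
  read length chosen as a desk-scale stand-in for the ~480–510 nt reads of
  real runs.
* Models serialize to versioned JSON (kernel parameters, normalization
  statistics, support vectors, dual coefficients, intercepts); prediction
  runs from the serialized document alone, so a saved model is
  self-contained and exactly reproducible.

## Known limitations

Distances measured in the projected template space can differ from direct
pairwise alignment distances by a few units between reads of different
references (insertion squeezing picks one of several score-equivalent
renderings); this is inherent to fixed-template projection and matches the
behaviour of filtered-alignment distances in standard 16S pipelines. The
classifier's sensitivity is bounded by physics: interior positions of a
shifted CAFIE substitution run are locally indistinguishable from clean
calls, and only their run edges carry flowgram evidence. Chimera scoring
considers two-parent chimeras only.
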