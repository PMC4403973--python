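"""Trim reads and extract the 13 per-position classifier attributes.

Basic trimming removes ambiguous, short (<200 nt) and long-homopolymer (>8)
reads; strict trimming additionally truncates reads where a 100-nt window's
mean Phred drops below 30. Each surviving base then gets a 13-attribute
vector combining its own flowgram context with that of its two neighbours.
"""

from pyrodenoise import SimParams, generate_references, simulate_reads, features_frame
from pyrodenoise.preprocess import basic_trim, strict_trim_batch

refs, weights = generate_references(10, 350, 0.10, seed=42)
reads, _ = simulate_reads(refs, weights, 300, SimParams(n_flows=900, seed=7))

kept, report = basic_trim(reads)
print("basic trimming:", report.as_dict())

strict, sreport = strict_trim_batch(kept)
print("strict trimming:", sreport.as_dict())

frame = features_frame(kept[:20])
print(f"feature table: {len(frame)} positions x {len(frame.columns) - 1} attributes")
print(frame.head(8).to_string(index=False))
# homopolymer_code marks where a base sits inside a run (N = isolated,
# A/B/.../Z = first/interior/last); *_max_uncalled is the strongest flow
# signal between neighbouring calls that produced no base - the carry-forward
# fingerprint the classifier keys on.
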