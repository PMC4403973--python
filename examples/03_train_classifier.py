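"""Train the PUK-kernel SVM that flags error-prone read positions.

Reads are labeled against their source references (k-mer prescreen, glocal
affine alignment, 3'-canonicalized indels), the labeled table is dereplicated
and split 1:9 stratified, the training subset is balanced (132 per error type
+ 700 clean at full scale), and a one-vs-one SVM with the Pearson VII
universal kernel is fit by SMO.
"""

import warnings

from pyrodenoise import (
    SimParams,
    generate_references,
    simulate_reads,
    label_reads,
    prepare_training_sets,
    train,
    evaluate,
)
from pyrodenoise.preprocess import basic_trim

refs, weights = generate_references(10, 350, 0.10, seed=42)
reads, _ = simulate_reads(refs, weights, 800, SimParams(n_flows=900, seed=7))
kept, _ = basic_trim(reads)

instances, unmatched = label_reads(kept, refs)
print(f"{len(instances)} labeled positions ({unmatched} unmatched reads)")
print("label counts:", instances["label"].value_counts().to_dict())

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # balance targets scale down at this size
    sets = prepare_training_sets(instances, seed=11)
print("training subset:", sets.subset_a["label"].value_counts().to_dict())
print(f"native clean:error ratio {sets.native_clean_to_error:.0f}:1")

model = train(sets, omega=1.0, sigma=1.0, C=1.0)
sensitivity, specificity, confusion = evaluate(model, sets.subset_b)
print(f"held-out sensitivity {sensitivity:.3f}, specificity {specificity:.3f}")
print(confusion)
# sensitivity = detected fraction of truly erroneous positions; specificity =
# correctly passed fraction of clean positions (binary collapse over the four
# classes). The model serializes to a self-contained JSON document.
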