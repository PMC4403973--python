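import warnings

import numpy as np
import pytest

from pyrodenoise.flowgram_io import FlowRead
from pyrodenoise.sim454 import SimParams, generate_references, simulate_reads


@pytest.fixture(scope="session")
def references():
    refs, weights = generate_references(10, 350, 0.10, seed=42)
    return refs, weights


@pytest.fixture(scope="session")
def sim_batch(references):
    """200 reads at the default error model."""
    refs, weights = references
    params = SimParams(n_flows=900, seed=7)
    reads, truths = simulate_reads(refs, weights, 200, params)
    return reads, truths


@pytest.fixture(scope="session")
def scenario():
    """The bundled end-to-end study (expensive; shared across tests)."""
    from pyrodenoise.pipeline import default_scenario

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return default_scenario(seed=7)


def make_flowread(bases: str, flow_order: str = "TACG", read_id: str = "r1",
                  quals=None, signals=None) -> FlowRead:
    """Construct a consistent FlowRead whose flowgram calls exactly `bases`."""
    flow_values = []
    flow_chars = []
    flow_index = []
    pos = 0
    flow = 0
    n = len(bases)
    while pos < n:
        ch = flow_order[flow % len(flow_order)]
        flow_chars.append(ch)
        if bases[pos] == "N":
            # ambiguous call: attribute it to the current flow with a
            # sub-threshold signal (an N never matches a flow character)
            flow_values.append(0.45)
            flow_index.append(flow + 1)
            pos += 1
            flow += 1
            continue
        run = 0
        while pos + run < n and bases[pos + run] == ch:
            run += 1
        flow_values.append(float(run))
        if run:
            for _ in range(run):
                flow_index.append(flow + 1)
            pos += run
        flow += 1
    if signals is not None:
        assert len(signals) == len(flow_values)
        flow_values = list(signals)
    q = list(quals) if quals is not None else [35] * n
    return FlowRead(
        read_id=read_id,
        flow_chars="".join(flow_chars),
        flow_values=flow_values,
        flow_index_per_base=flow_index,
        bases=bases,
        quals=q,
        clip_qual=(1, n),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
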