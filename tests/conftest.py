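import numpy as np
import pytest

from retrozyme.annotate import annotate_genome
from retrozyme.descriptor import HHRDescriptor
from retrozyme.evaluate import evaluate
from retrozyme.scan import scan_sequence
from retrozyme.simulate import SyntheticSpec, build_genome


@pytest.fixture(scope="session")
def desc() -> HHRDescriptor:
    return HHRDescriptor()


@pytest.fixture(scope="session")
def benchmark():
    """The default synthetic benchmark (5 Mb, 20 full + 5 solo +
    2 multimer + 10 decoys, fixed seed), run once through the whole
    pipeline."""
    spec = SyntheticSpec()
    records, truths = build_genome(spec)
    hits = scan_sequence(records)
    elements = annotate_genome(records, hits)
    metrics = evaluate(elements, truths)
    return {"spec": spec, "records": records, "truths": truths,
            "hits": hits, "elements": elements, "metrics": metrics}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
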