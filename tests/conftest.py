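import logging

import numpy as np
import pytest

from crzpulse.detect import ThresholdSpec
from crzpulse.synthetic import SynthCalciumSpec, SynthCrzSpec, SynthPixelSpec, gen_calcium, gen_crz_train

# Model internals log a warning when import probabilities clamp at 1; the
# suite exercises large bursts deliberately, so keep the log quiet.
logging.getLogger("crzpulse.tdm").setLevel(logging.ERROR)


@pytest.fixture
def thresholds():
    return ThresholdSpec()


@pytest.fixture
def coupled_cells():
    """Ten cells with calcium bursts and burst-coupled Crz1 pulse trains."""
    cells = []
    for i in range(10):
        ca_spec = SynthCalciumSpec(duration_sec=3600.0, seed=100 + i)
        ca, bursts = gen_calcium(ca_spec)
        crz_spec = SynthCrzSpec(seed=200 + i)
        crz, pulses = gen_crz_train(bursts, crz_spec, ca_spec.duration_sec, cell_id=f"c{i}")
        ca = type(ca)(f"c{i}", "calcium", ca.times, ca.values)
        cells.append({"ca": ca, "crz": crz, "bursts": bursts, "pulses": pulses})
    return cells
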