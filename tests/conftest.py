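import pytest

from negevkit import synthetic_data as syn
from negevkit.qpcr_quant import CalibrationCurve


@pytest.fixture(scope="session")
def default_genome():
    """One default-layout synthetic genome shared across tests."""
    return syn.generate_genome(syn.GenomeSpec(), seed=11)


@pytest.fixture(scope="session")
def calibration():
    """The simulation calibration line: slope -3.32, intercept 37."""
    return CalibrationCurve(
        slope=-3.32,
        intercept=37.0,
        r2=1.0,
        efficiency=10 ** (1 / 3.32) - 1,
        range_log10=(0.0, 8.0),
    )
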