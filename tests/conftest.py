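import numpy as np
import pytest

from flowmet import (
    KineticParams,
    PhantomSpec,
    default_scan_schedule,
    simulate_dynamic_series,
)
from flowmet.perfusion import extract_aif, segment_voi

#: treatment-group baseline kinetics used as a canonical recovery target
BASELINE_KIN = KineticParams(bf=36.16, bv=25.36, ps=9.47)


@pytest.fixture(scope="session")
def schedule():
    return default_scan_schedule()


@pytest.fixture(scope="session")
def baseline_phantom():
    """Noiseless uniform-kinetics phantom at the treatment baseline."""
    series, tumor, aorta, _ = simulate_dynamic_series(
        PhantomSpec(kinetics=BASELINE_KIN)
    )
    return series, tumor, aorta


@pytest.fixture(scope="session")
def baseline_analysis(baseline_phantom):
    """Refined VOI and extracted AIF for the baseline phantom."""
    series, tumor, aorta = baseline_phantom
    refined = segment_voi(series.baseline_volume(3), tumor)
    aif = extract_aif(series, aorta)
    return series, refined, aif
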