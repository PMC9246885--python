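import numpy as np
import pytest

from rnarray.design import DesignTable, TemplateSpec, make_control, make_template
from rnarray.imagecode import CHANNELS, CHANNEL_TEMPLATES, CalibrationCurve, select_levels
from rnarray.seqcore import DEFAULT_PRIMER

#: Shared 3' block of every transcribable probe: primer complement + dT5.
SHARED_3P_BLOCK = "TTCGCCGTGTCCCTATTTTT"

GREEN = CHANNEL_TEMPLATES["green"]
RED = CHANNEL_TEMPLATES["red"]
BLUE = CHANNEL_TEMPLATES["blue"]


@pytest.fixture(scope="session")
def primer():
    return DEFAULT_PRIMER


@pytest.fixture
def green_template():
    return make_template(GREEN, 5, probe_id="green")


@pytest.fixture(scope="session")
def saturating_level_maps():
    """Default level maps from a saturating length-response calibration."""
    maps = {}
    for ch in CHANNELS:
        full = len(CHANNEL_TEMPLATES[ch])
        curve = CalibrationCurve(ch, {L: L / (8.0 + L) for L in range(1, full + 1)})
        maps[ch] = select_levels(curve, 8)
    return maps


@pytest.fixture
def paired_design():
    """Four template/control pairs plus a dark background probe, 62 reps."""
    variables = [GREEN, RED, BLUE, "GATTACACTGATCGATCCGA"]
    templates = [make_template(v, 5, probe_id=f"t{i}") for i, v in enumerate(variables)]
    controls = [make_control(v, 5, probe_id=f"c{i}") for i, v in enumerate(variables)]
    dark = TemplateSpec(
        probe_id="bgdark", variable="TG" * 10, linker_len=5, role="control", response_len=0
    )
    return DesignTable(templates + controls + [dark], replicate_count=62)


@pytest.fixture
def pairing():
    return {f"t{i}": f"c{i}" for i in range(4)}
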