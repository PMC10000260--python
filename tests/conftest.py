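import numpy as np
import pytest

from pnquant.detect import PNDetection, area_to_microns


def make_detection(
    embryo_id="E1",
    frame_index=0,
    time_h=10.0,
    center=(0.0, 0.0),
    area_px=1000.0,
    scale=0.3275,
    sex="unassigned",
):
    return PNDetection(
        embryo_id=embryo_id,
        frame_index=frame_index,
        time_h=time_h,
        center_px=center,
        area_px=area_px,
        area_um2=area_to_microns(area_px, scale),
        sex=sex,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
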