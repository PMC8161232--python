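import pytest

from vocamood.segmentation import SegmentationParams
from vocamood.synthetic import simulate_audio_fixture


@pytest.fixture
def two_burst_recording():
    """1 s tone, 0.8 s silence, 1 s tone at amplitude 0.5 (RMS ~0.354)."""
    return simulate_audio_fixture([
        ("tone", 1.0, 0.5, 440.0),
        ("silence", 0.8),
        ("tone", 1.0, 0.5, 440.0),
    ])


@pytest.fixture
def default_params():
    return SegmentationParams(volume_threshold=0.1)
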