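import numpy as np
import pytest

from gestseg.annotation import AnnotationEvent, AnnotationTrack, GestureClass


@pytest.fixture
def simple_track():
    """One BND video with three abutting/overlapping-free events."""
    return AnnotationTrack(
        video_id="v1", duration_s=12.0, procedure="BND",
        surgeon_id="E01", experience="experienced",
        events=[
            AnnotationEvent(GestureClass.G1, 0.0, 5.0),
            AnnotationEvent(GestureClass.G2, 5.0, 8.0),
            AnnotationEvent(GestureClass.G1, 8.0, 12.0),
        ])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
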