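import numpy as np
import pytest

from swimclass.trajectory import ArenaGeometry, ClassLabel, TrackSegment


@pytest.fixture
def arena():
    return ArenaGeometry(center=(120.0, 120.0), radius=100.0)


@pytest.fixture
def make_segment(arena):
    """Build a TrackSegment from raw coordinates (fps inferred from length)."""

    def _make(coords, window_seconds=None, fps=25.0, label=None, arena_=None,
              fish_id="f0", start_time=0.0, segment_id=0):
        coords = np.asarray(coords, dtype=float)
        if window_seconds is None:
            window_seconds = len(coords) / fps
        return TrackSegment(
            fish_id=fish_id,
            label=label or ClassLabel.control(),
            start_time=start_time,
            coords=coords,
            window_seconds=window_seconds,
            fps=fps,
            arena=arena_ or arena,
            segment_id=segment_id,
        )

    return _make


@pytest.fixture
def blob_images():
    """Tiny synthetic two-class image set: bright patch top-left vs bottom-right.

    Much faster than rendering real tracks; used for classifier mechanics
    tests where the image content does not need to be a swim path.
    """

    def _make(n_per_class=30, size=32, seed=0, n_classes=2):
        rng = np.random.default_rng(seed)
        images, labels = [], []
        for k in range(n_classes):
            for _ in range(n_per_class):
                img = rng.integers(0, 40, size=(size, size, 3), dtype=np.uint8)
                r0 = (k * size // n_classes)
                img[r0:r0 + size // n_classes, r0:r0 + size // n_classes] = 220
                images.append(img)
                labels.append(
                    ClassLabel.drug("ethanol", 0.5 * k) if k else ClassLabel.control())
        return np.stack(images), np.array(labels, dtype=object)

    return _make
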