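import numpy as np
import pytest
from PIL import Image

from woundmm.bodymap import BodyMapRegistry
from woundmm.pipeline import DatasetManifest, WoundClass, WoundRecord


@pytest.fixture
def tiny_registry() -> BodyMapRegistry:
    return BodyMapRegistry(
        {code: (f"Location {code}", "fixture") for code in (100, 152, 200, 210, 305, 310)},
        version="tiny-6",
    )


def make_image(path, size=(12, 10), color=(120, 80, 60)):
    Image.new("RGB", size, color).save(path)


@pytest.fixture
def small_manifest(tmp_path, tiny_registry) -> DatasetManifest:
    """Manifest of 24 original ROIs (4 classes x 6) with real image files."""
    (tmp_path / "images").mkdir()
    rng = np.random.default_rng(0)
    records = []
    classes = [WoundClass.D, WoundClass.P, WoundClass.BG, WoundClass.N]
    codes = tiny_registry.codes
    idx = 0
    for cls in classes:
        for _ in range(6):
            rel = f"images/roi_{idx:03d}.png"
            make_image(tmp_path / rel, color=tuple(int(v) for v in rng.integers(0, 255, 3)))
            loc = -1 if cls == WoundClass.BG else int(codes[rng.integers(len(codes))])
            records.append(
                WoundRecord(index=idx, source_index=idx, image_path=rel,
                            wound_class=cls, location=loc)
            )
            idx += 1
    return DatasetManifest("small", records, tiny_registry.version, root=tmp_path)
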