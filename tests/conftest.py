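import numpy as np
import pandas as pd
import pytest

from rgcount import CountTable, DetectorConfig, MosaicImage, SyntheticSpec, generate_segment


@pytest.fixture(scope="session")
def clean_spec():
    """Uniform, well-separated cells on a quiet background: the detector
    should recover the planted count exactly."""
    return SyntheticSpec(
        density=1500.0,
        cell_radius_cv=0.0,
        overlap_pair_fraction=0.0,
        noise_sd=3.0,  # 2% of the 150-unit contrast
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_scene(clean_spec):
    return generate_segment(clean_spec)


@pytest.fixture(scope="session")
def mild_scene():
    """Default mild-realism scene (size scatter, pairs, 5% noise)."""
    spec = SyntheticSpec(density=3600.0, seed=7)
    return spec, *generate_segment(spec)


@pytest.fixture
def count_frame():
    rows = []
    for q in (1, 2, 3, 4):
        for ecc, c in (("central", 49), ("middle", 36), ("peripheral", 25)):
            rows.append(
                {
                    "animal_id": "m1",
                    "eye": "left",
                    "group": "EAE",
                    "timepoint": 42,
                    "quadrant": q,
                    "eccentricity": ecc,
                    "count": c,
                    "density": c / 0.1225,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def count_table(count_frame):
    return CountTable(count_frame)


@pytest.fixture
def flat_image():
    return MosaicImage(np.full((200, 200), 10.0), pixel_size=1.0)
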