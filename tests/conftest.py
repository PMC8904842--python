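import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def nuclei_phantom():
    """Fiber-free stained-section phantom isolating the counting protocol."""
    from vasomech import synthetic as syn

    ph = syn.HistologyPhantom(
        n_nuclei=50, elastin_fraction=0.0, collagen_fraction=0.0, seed=2
    )
    image, truth = syn.gen_histology_image(ph)
    return ph, image, truth


@pytest.fixture(scope="session")
def nuclei_analysis(nuclei_phantom):
    """Shared run of the blur/threshold/watershed protocol on the phantom."""
    from vasomech import histology as h

    _, image, truth = nuclei_phantom
    gray, mask = h.preprocess(image)
    labels = h.segment_nuclei(gray, mask, image.pixel_size)
    stats = h.nuclei_stats(labels, image.pixel_size, truth.roi_area_um2)
    return labels, stats


@pytest.fixture(scope="session")
def fiber_phantom():
    """Phantom with painted elastin (25%) and collagen (15%) fractions."""
    from vasomech import synthetic as syn

    ph = syn.HistologyPhantom(seed=5)
    image, truth = syn.gen_histology_image(ph)
    return ph, image, truth


@pytest.fixture(scope="session")
def vessel_phantom():
    """Large-vessel phantom with realistic aortic dimensions for morphometry."""
    from vasomech import synthetic as syn

    ph = syn.HistologyPhantom(
        inner_diameter=1600.0,
        outer_diameter=2100.0,
        media_outer_diameter=1842.8,
        pixel_size=2.0,
        n_nuclei=0,
        elastin_fraction=0.0,
        collagen_fraction=0.0,
        seed=11,
    )
    image, truth = syn.gen_histology_image(ph)
    return ph, image, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
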