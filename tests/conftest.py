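import numpy as np
import pytest

from neuroscreen.core import FieldImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_image(channels: dict, pixel_size_um: float = 0.65) -> FieldImage:
    """Build a FieldImage from a {name: 2-D array} dict."""
    names = list(channels)
    pixels = np.stack([np.asarray(channels[n], dtype=float) for n in names])
    return FieldImage(pixels, {n: i for i, n in enumerate(names)}, pixel_size_um)


@pytest.fixture
def tiny_nuclei_config():
    """Minimal field-simulation config for segmentation tests."""
    return {
        "image_sim": {
            "field_shape": [256, 256],
            "pixel_size_um": 0.65,
            "background": 100,
            "noise_sd": 8,
            "illumination_gradient": 0.1,
            "nuclei": {
                "per_field": 30,
                "radius_px": [7, 10],
                "intensity_mean": 600,
                "intensity_sd": 60,
                "dead_fraction": 0.1,
                "dead_size_mult": 0.65,
                "dead_intensity_mult": 2.2,
                "debris_fraction": 0.1,
                "debris_radius_px": [2, 4],
                "debris_intensity_mult": 0.6,
            },
        },
        "conditions": {
            "test": {"ki67_fraction": 0.3, "hucd_fraction": 0.5, "marker_snr": 40},
            "no_ki67": {"ki67_fraction": 0.0, "hucd_fraction": 0.5, "marker_snr": 40},
        },
    }


@pytest.fixture
def tiny_synapse_config():
    """Minimal neurite/puncta simulation config."""
    return {
        "image_sim": {
            "field_shape": [256, 256],
            "pixel_size_um": 0.108,
            "background": 100,
            "noise_sd": 8,
            "illumination_gradient": 0.0,
            "neurites": {"n_trees": 4, "segment_mean_um": 8, "levels": 2,
                         "sigma_px": 1.5, "amplitude": 1200},
            "puncta": {"sigma_px": 1.8, "amplitude": 500, "amplitude_sd": 60},
        },
        "conditions": {
            "paired_only": {"synapses_per_100um": 4.0, "extra_synapsin_per_100um": 0.0,
                            "extra_shank3_per_100um": 0.0, "off_skeleton_per_field": 0.0},
            "mixed": {"synapses_per_100um": 3.0, "extra_synapsin_per_100um": 1.5,
                      "extra_shank3_per_100um": 1.0, "off_skeleton_per_field": 6.0},
        },
    }


@pytest.fixture
def tiny_mea_config():
    return {
        "mea_sim": {"n_electrodes": 8, "duration_s": 120.0, "jitter_ms": 2.0},
        "conditions": {
            "poisson5": {"rate_hz": 5.0, "rho": 0.0},
            "silent": {"rate_hz": 0.0, "rho": 0.0},
            "corr": {"rate_hz": 5.0, "rho": 0.6},
            "burst": {"burst": {"tonic_rate_hz": 1.0, "burst_rate_hz": 0.3,
                                "intra_rate_hz": 80.0, "length_s": 0.25}, "rho": 0.0},
        },
    }
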