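import numpy as np
import pytest

from blastopol import SimulationConfig
from blastopol.io import ImageStack
from blastopol.synthetic import render_embryo_movie


@pytest.fixture(scope="session")
def noise_free_movie():
    """One rendered noise-free embryo movie with ground truth."""
    cfg = SimulationConfig(noise_sd=0.0, seed=11)
    return cfg, render_embryo_movie(cfg, np.random.default_rng(11))


@pytest.fixture(scope="session")
def noise_free_stack(noise_free_movie):
    cfg, movie = noise_free_movie
    return ImageStack(
        data=movie.data,
        labels=movie.labels,
        nuclei=movie.nuclei,
        pixel_size_um=movie.pixel_size_um,
        z_step_um=movie.z_step_um,
        frame_interval_min=movie.frame_interval_min,
    )


def two_discs(radius: float, distance: float, size: int | None = None):
    """Two equal discs partitioned by nearest center (shared chord interface)."""
    size = size or int(2 * radius + distance) + 12
    yy, xx = np.mgrid[0:size, 0:size]
    cy = size / 2.0
    x1, x2 = size / 2.0 - distance / 2.0, size / 2.0 + distance / 2.0
    d1 = np.hypot(yy - cy, xx - x1)
    d2 = np.hypot(yy - cy, xx - x2)
    return (d1 <= radius) & (d1 <= d2), (d2 <= radius) & (d2 < d1)
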