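"""Shared fixtures: the expensive full-scale reconstructions are computed
once per session and reused across unit and acceptance tests."""

import numpy as np
import pytest

import gridrec as gr


def reconstruct(sino, **kwargs):
    cfg = gr.ReconConfig(**kwargs)
    fn = gr.reconstruct_fbp if cfg.method == "fbp" else gr.reconstruct_gridrec
    return fn(sino, cfg)


@pytest.fixture(scope="session")
def sl_spec():
    return gr.shepp_logan_spec("standard")


@pytest.fixture(scope="session")
def mod_spec():
    return gr.shepp_logan_spec("modified")


@pytest.fixture(scope="session")
def sl_truth_512(sl_spec):
    return gr.rasterize(sl_spec, 512)


@pytest.fixture(scope="session")
def sl_sino_512(sl_spec):
    return gr.project_ellipses(sl_spec, 1501, 512)


@pytest.fixture(scope="session")
def mod_truth_512(mod_spec):
    return gr.rasterize(mod_spec, 512)


@pytest.fixture(scope="session")
def mod_sino_512(mod_spec):
    return gr.project_ellipses(mod_spec, 1501, 512)


@pytest.fixture(scope="session")
def bg_mask_512(sl_spec):
    return gr.background_mask(sl_spec, 512, margin=0.05)


@pytest.fixture(scope="session")
def points_512():
    return gr.make_point_pattern(512, 9)


@pytest.fixture(scope="session")
def points_sino_512(points_512):
    return gr.project_ellipses(points_512, 1501, 512)


@pytest.fixture(scope="session")
def small_sino():
    """A small asymmetric two-ellipse phantom sinogram (32 bins)."""
    spec = gr.PhantomSpec(
        ellipses=(
            gr.Ellipse(0.1, -0.05, 0.5, 0.35, 20.0, 1.0),
            gr.Ellipse(-0.2, 0.2, 0.15, 0.15, 0.0, 0.5),
        ),
        variant="standard",
    )
    return gr.project_ellipses(spec, 60, 32)


@pytest.fixture(scope="session")
def disc_spec():
    return gr.PhantomSpec(
        ellipses=(gr.Ellipse(0.0, 0.0, 0.5, 0.5, 0.0, 1.0),), variant="standard"
    )


@pytest.fixture(scope="session")
def disc_sino_128(disc_spec):
    return gr.project_ellipses(disc_spec, 300, 128)


def radial_coords(size):
    xs = (2.0 * np.arange(size) + 1.0) / size - 1.0
    x, y = np.meshgrid(xs, xs[::-1])
    return x, y, np.hypot(x, y)
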