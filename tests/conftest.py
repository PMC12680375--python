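"""Shared fixtures: small synthetic tissues reused across test modules."""

import numpy as np
import pytest

from pcpquant import geometry as geo
from pcpquant import synthetic as syn


@pytest.fixture(scope="session")
def hex_tissue():
    """Default jittered hexagonal tissue (210 cells, seed 1)."""
    return syn.generate_tissue(syn.TissueSpec(seed=1))


@pytest.fixture(scope="session")
def hex_graph(hex_tissue):
    graph = geo.parse_tissue(hex_tissue.labels)
    graph.fit_all_geometry()
    return graph


@pytest.fixture(scope="session")
def interior_cells(hex_tissue):
    """Cells not clipped by the image border."""
    t = hex_tissue.cells
    return set(t.loc[~t["on_border"], "cell"])


@pytest.fixture(scope="session")
def uniform_render(hex_tissue):
    """Uniform polarity field at 25 deg, A/B = 1, noiseless."""
    fld = syn.PolarityField(psi0_deg=25.0, amplitude=100.0, baseline=100.0)
    return syn.render_channels(hex_tissue, fld, seed=2)


def disc_coords(radius, centre=(60, 60), shape=(121, 121)):
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                         indexing="ij")
    mask = (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius ** 2
    return np.column_stack(np.nonzero(mask))


def ring_coords(radius, centre=(60.0, 60.0), n=720):
    """Pixelised ring sampled at n equally spaced angles (math convention)."""
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    rows = centre[0] - radius * np.sin(th)
    cols = centre[1] + radius * np.cos(th)
    return np.column_stack([rows, cols]), th
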