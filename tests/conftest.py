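"""Shared fixtures: tiny hand-built mosaics and generated retinas."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from retmosaic import (
    OmmatidiumRecord,
    RetinalMosaicMap,
    SyntheticRetinaParams,
    generate_hex_retina,
)
from retmosaic.mosaic_model import hex_to_pixels

PITCH = 40.0


def build_map(cells, equator=None, midline=None, canvas=(1400.0, 1400.0), **meta):
    """Build a map from (col, row, type) triples; pixels from the hex layout."""
    recs = []
    for i, (col, row, typ) in enumerate(cells):
        x, y = hex_to_pixels(np.array([col]), np.array([row]), PITCH, origin=(100.0, 100.0))
        recs.append(
            OmmatidiumRecord(id=i, col=col, row=row, x=float(x[0]), y=float(y[0]), type=typ)
        )
    rows = [r for _, r, _ in cells]
    if equator is None:
        equator = (min(rows) + max(rows)) / 2.0
        if equator == int(equator):
            equator += 0.5
    if midline is None:
        cols = [c for c, _, _ in cells]
        midline = int(round((min(cols) + max(cols)) / 2))
    return RetinalMosaicMap(
        ommatidia=recs,
        equator_boundary=equator,
        midline_col=midline,
        canvas=canvas,
        metadata=meta,
    )


#: centre + 6-ring of a hex rosette around (1, 1) in odd-r offset coords
ROSETTE_CELLS = [(1, 1), (2, 1), (0, 1), (1, 2), (2, 2), (1, 0), (2, 0)]


@pytest.fixture
def rosette_map():
    """7-hex rosette, all yellow: centre has all six neighbours present."""
    return build_map([(c, r, "Y") for c, r in ROSETTE_CELLS])


@pytest.fixture
def small_retina():
    """A mid-sized exchangeable synthetic retina (no patch, no gradient)."""
    return generate_hex_retina(
        SyntheticRetinaParams(n_target=300, p0=0.35, dra_count=20, seed=11)
    )


@pytest.fixture
def plain_retina():
    """An 800-ommatidium exchangeable retina with no unknowns."""
    return generate_hex_retina(
        SyntheticRetinaParams(n_target=800, p0=0.35, unknown_rate=0.0, seed=5)
    )
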