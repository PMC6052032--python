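import numpy as np
import pytest

import florisight as fl


@pytest.fixture(scope="session")
def grid():
    return 400.0 + np.arange(301.0)


@pytest.fixture(scope="session")
def phenotypes():
    return fl.default_phenotypes()


@pytest.fixture(scope="session")
def by_name(phenotypes):
    return {p.name: p for p in phenotypes}


def make_spectrum(grid, values, **meta):
    base = {
        "species": "sp",
        "item_kind": "flower",
        "part_label": "part",
        "surface": "n/a",
        "replicate_id": "r1",
    }
    base.update(meta)
    return fl.Spectrum(grid, np.asarray(values, float), base)


@pytest.fixture(scope="session")
def smooth_spectrum(grid):
    """A fixed, smooth, strictly positive reflectance curve."""
    vals = 0.2 + 0.15 * np.sin(grid / 40.0) ** 2 + 0.1 * np.exp(
        -(((grid - 620.0) / 60.0) ** 2)
    )
    return make_spectrum(grid, vals)


@pytest.fixture(scope="session")
def leafy_background(grid):
    from florisight.synthgen import DEFAULT_LEAF, leaf_curve

    return make_spectrum(
        grid, leaf_curve(grid, DEFAULT_LEAF), item_kind="leaf", part_label="leaf"
    )


@pytest.fixture(scope="session")
def red_edge_flower(grid):
    from florisight.synthgen import DEFAULT_FLOWER_CLASSES, flower_curve

    vals = flower_curve(grid, "red_edge", DEFAULT_FLOWER_CLASSES["red_edge"], None)
    return make_spectrum(grid, vals)
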