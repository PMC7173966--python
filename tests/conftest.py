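import numpy as np
import pytest

from gyrify.cellquant import classify_table
from gyrify.synthetic import (
    SyntheticConfig,
    generate_cell_table,
    generate_contour_pair,
    generate_zone_bands,
)


def circle(radius=4000.0, n=256, center=(0.0, 0.0)):
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
    )


@pytest.fixture(scope="session")
def folded_pair():
    """Three-sulcus EP / three-sulcus nonEP pair with ground truth."""
    return generate_contour_pair(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def dense_cells():
    """Cell table with >2000 cells per progenitor class, with classes assigned."""
    cfg = SyntheticConfig(
        seed=7,
        subtype_densities={
            "OSVZ": {"HOPX_pos_oRG": 800.0, "HOPX_neg_oRG": 800.0, "IP": 800.0}
        },
        gyral_enrichment=1.0,
    )
    pair = generate_contour_pair(cfg)
    zones = generate_zone_bands(cfg, pair.ep)
    cells = generate_cell_table(cfg, zones, pair.truth_ep)
    return cells.assign(cell_class=classify_table(cells))
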