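import numpy as np
import pytest

from marksel.panel import GenotypePanel, MarkerMap


def make_panel(dosages, maternal_id="MOTHER", individual_ids=None, marker_ids=None):
    """Panel from a (n_individuals x n_markers) array-like; None means missing."""
    arr = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in dosages]
    )
    n, m = arr.shape
    return GenotypePanel(
        individual_ids=individual_ids or [f"I{i}" for i in range(n)],
        marker_ids=marker_ids or [f"M{k}" for k in range(m)],
        dosages=arr,
        maternal_id=maternal_id,
    )


def make_map(entries, lengths):
    """MarkerMap from {marker: (chrom, pos)} and {chrom: length}."""
    return MarkerMap(
        chromosome={mk: c for mk, (c, _) in entries.items()},
        position={mk: p for mk, (_, p) in entries.items()},
        chromosome_length=dict(lengths),
    )


@pytest.fixture
def toy_panel():
    """Four candidate fathers at six markers, fully typed."""
    return make_panel(
        [
            [0, 2, 1, 0, 1, 2],
            [2, 0, 1, 1, 0, 2],
            [1, 1, 0, 2, 2, 0],
            [0, 2, 2, 1, 1, 1],
        ]
    )
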