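"""Shared helpers for building tiny binary range maps and grid-wide BAHs."""
import numpy as np
import pandas as pd

import enmrisk as e
from enmrisk.occurrences import OccurrenceSet


def binary_pair(cur_bool, fut_bool):
    cur_bool = np.asarray(cur_bool, bool)
    grid = e.GridSpec(*cur_bool.shape, 0.1, 0, 0)
    mask = np.ones(cur_bool.shape, bool)
    cur = e.BinaryRangeMap(grid, cur_bool, mask, 0.5)
    fut = e.BinaryRangeMap(grid, np.asarray(fut_bool, bool), mask, 0.5,
                           "SSP5-8.5", "2061-2080")
    return grid, cur, fut


def random_range_pair(seed, shape=(12, 12), p=0.4):
    rng = np.random.default_rng(seed)
    cur_b = rng.uniform(size=shape) < p
    fut_b = rng.uniform(size=shape) < p
    if not cur_b.any():
        cur_b[0, 0] = True
    return binary_pair(cur_b, fut_b)


def whole_grid_bah(grid):
    """A buffered BAH polygon guaranteed to cover every grid cell."""
    corners = [(grid.origin_lon, grid.origin_lat),
               (grid.origin_lon, grid.origin_lat + grid.n_rows * grid.cell_size),
               (grid.origin_lon + grid.n_cols * grid.cell_size, grid.origin_lat),
               (grid.origin_lon + grid.n_cols * grid.cell_size,
                grid.origin_lat + grid.n_rows * grid.cell_size)]
    occ = OccurrenceSet("bah", "herb", pd.DataFrame(
        {"decimalLongitude": [c[0] for c in corners],
         "decimalLatitude": [c[1] for c in corners]}))
    return e.build_bah(occ, buffer_km=100)
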