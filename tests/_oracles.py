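"""Independent brute-force oracles shared by the unit and acceptance tests."""

import numpy as np

from aprmap.geo import transform_points


def modal_oracle(values, factor, nodata):
    """Per-block histogram mode with smallest-code tie-break."""
    nrows, ncols = values.shape
    out = np.full(
        (-(-nrows // factor), -(-ncols // factor)), nodata, dtype=values.dtype
    )
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            block = values[i * factor : (i + 1) * factor, j * factor : (j + 1) * factor]
            vals = block[block != nodata] if nodata is not None else block.ravel()
            if vals.size == 0:
                continue
            codes, counts = np.unique(vals, return_counts=True)
            out[i, j] = codes[np.argmax(counts)]  # unique() sorts -> smallest wins
    return out


def nearest_oracle(coarse, target):
    """Exhaustive nearest-centre search over all (fine, coarse) cell pairs."""
    tx, ty = target.cell_centers()
    cx, cy = transform_points(target.crs, coarse.crs, tx.ravel(), ty.ravel())
    gx, gy = coarse.cell_centers()
    gx, gy = gx.ravel(), gy.ravel()
    out = np.empty(cx.size)
    for i, (x, y) in enumerate(zip(cx, cy)):
        out[i] = coarse.values.ravel()[np.argmin((gx - x) ** 2 + (gy - y) ** 2)]
    return out.reshape(target.shape)
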