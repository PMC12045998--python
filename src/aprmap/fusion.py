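"""Crop-map fusion: land-cover corrections, modal upscaling, class aggregation.

The fine crop map is corrected pixel-wise against a co-registered land-cover
raster with three rules (rice retrieval, permanent-crop identification
inside the woodland/shrubland class, pasture identification inside
grasslands), then coarsened by assigning each output pixel the modal code of
its input block, and finally cross-walked to the eight mapped crop classes.

Source-code conventions follow the fine crop map's legend (211 common
wheat ... 510 pastures) with two transient codes for land-cover classes that
only exist before correction: 300 woodland-and-shrubland, 500 grasslands.
The land-cover raster uses its own level-3 codes (213 rice fields,
221 vineyards, 222 fruit trees and berries, 223 olive groves, 231 pastures).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .domain import (
    EXCLUDED,
    PCG_CODES,
    PCG_NODATA,
    CropClassMap,
    pcg_class_of_code,
)
from .raster import Raster

logger = logging.getLogger("aprmap.fusion")

__all__ = [
    "apply_corine_corrections",
    "modal_upscale",
    "aggregate_labels",
    "class_area_table",
    "EUCM_RICE",
    "EUCM_ORCHARDS",
    "EUCM_PASTURES",
    "EUCM_WOODLAND",
    "EUCM_GRASSLAND",
    "CORINE_RICE",
    "CORINE_VINEYARDS",
    "CORINE_FRUIT",
    "CORINE_OLIVE",
    "CORINE_PASTURES",
]

# fine crop-map codes
EUCM_RICE = 217
EUCM_ORCHARDS = 350
EUCM_PASTURES = 510
EUCM_WOODLAND = 300   # woodland and shrubland (including permanent crops)
EUCM_GRASSLAND = 500  # grasslands

# land-cover (level-3) codes used by the correction rules
CORINE_RICE = 213
CORINE_VINEYARDS = 221
CORINE_FRUIT = 222
CORINE_OLIVE = 223
CORINE_PASTURES = 231


def apply_corine_corrections(eucm: Raster, corine: Raster) -> Raster:
    """Correct the fine crop raster against the land-cover raster.

    Rules, applied in a single pass (no pixel can trigger two of them since
    the triggering source codes are distinct):

    1. land cover says rice -> crop map becomes rice;
    2. crop map woodland/shrubland + land cover vineyard/fruit/olive ->
       orchards and grapes;
    3. crop map grasslands + land cover pastures -> pastures.
    """
    if not eucm.is_coregistered_with(corine):
        raise ValueError("crop and land-cover rasters are not co-registered")
    v = eucm.values.copy()
    c = corine.values

    rule1 = c == CORINE_RICE
    rule2 = (eucm.values == EUCM_WOODLAND) & np.isin(
        c, (CORINE_VINEYARDS, CORINE_FRUIT, CORINE_OLIVE)
    )
    rule3 = (eucm.values == EUCM_GRASSLAND) & (c == CORINE_PASTURES)
    if eucm.nodata is not None:
        valid = eucm.values != eucm.nodata
        rule1 &= valid
        rule2 &= valid
        rule3 &= valid

    v[rule1] = EUCM_RICE
    v[rule2] = EUCM_ORCHARDS
    v[rule3] = EUCM_PASTURES
    logger.info(
        "land-cover corrections: rice=%d orchards=%d pastures=%d",
        int(rule1.sum()), int(rule2.sum()), int(rule3.sum()),
    )
    return eucm.with_values(v)


def modal_upscale(r: Raster, factor: int) -> Raster:
    """Coarsen a categorical raster by the per-block modal code.

    Nodata cells are excluded from the counts; an all-nodata block stays
    nodata. Ties break to the smallest code so the result is deterministic
    and independent of traversal order. Edge blocks that do not fill a full
    ``factor x factor`` window are aggregated from the pixels available.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("upscale factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return r.with_values(r.values.copy())

    nrows, ncols = r.shape
    out_r = -(-nrows // factor)
    out_c = -(-ncols // factor)

    nodata = r.nodata if r.nodata is not None else np.iinfo(np.int64).min
    padded = np.full((out_r * factor, out_c * factor), nodata, dtype=np.int64)
    padded[:nrows, :ncols] = r.values
    blocks = (
        padded.reshape(out_r, factor, out_c, factor)
        .transpose(0, 2, 1, 3)
        .reshape(out_r, out_c, factor * factor)
    )

    codes = np.unique(blocks)
    codes = codes[codes != nodata]
    if codes.size == 0:
        return r.with_values(
            np.full((out_r, out_c), nodata, dtype=r.values.dtype),
            transform=r.transform.scale(factor),
        )
    # histogram per block over the (sorted) observed codes; argmax of a
    # sorted-code axis breaks ties toward the smallest code
    counts = (blocks[..., None] == codes[None, None, None, :]).sum(axis=2)
    out = codes[np.argmax(counts, axis=-1)]
    out[counts.sum(axis=-1) == 0] = nodata
    return r.with_values(out.astype(r.values.dtype), transform=r.transform.scale(factor))


def aggregate_labels(r: Raster, m: CropClassMap) -> Raster:
    """Replace source codes with mapped crop-class codes; EXCLUDED -> nodata."""
    out = np.full(r.shape, PCG_NODATA, dtype=np.int32)
    for code in np.unique(r.values):
        if r.nodata is not None and code == r.nodata:
            continue
        target = m.target_class(int(code))
        if target == EXCLUDED:
            continue
        out[r.values == code] = PCG_CODES[target]
    return r.with_values(out, nodata=PCG_NODATA)


def class_area_table(r: Raster) -> pd.DataFrame:
    """Percent of valid surface area per mapped crop class.

    Expects an aggregated (class-coded) raster; percentages are over
    non-nodata pixels and sum to 100.
    """
    valid = r.mask()
    total = int(valid.sum())
    if total == 0:
        raise ValueError("raster has no valid pixels")
    codes, counts = np.unique(r.values[valid], return_counts=True)
    rows = [
        (pcg_class_of_code(int(code)), 100.0 * n / total)
        for code, n in zip(codes, counts)
    ]
    return pd.DataFrame(rows, columns=["crop_class", "percent_area"]).sort_values(
        "crop_class", ignore_index=True
    )
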