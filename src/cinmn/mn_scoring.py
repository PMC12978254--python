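"""In-situ cGAS+ micronucleus scoring from segmented-object tables.

Candidate foci detected in the cGAS channel are filtered on area (inclusive
0.25-7.5 um^2 window) and a per-tumor intensity threshold; surviving foci in
the tumor compartment are counted and normalized to the number of tumor-cell
detections, giving the cGAS+ MN score (MN per 100 tumor cells) used as the
in-situ readout of ongoing chromosomal instability.  Marker intensities are
normalized per cell by dividing by the inferred autofluorescence mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MnScore",
    "filter_mn_candidates",
    "compute_mn_score",
    "normalize_marker_intensities",
    "otsu_intensity_threshold",
]

AREA_MIN_UM2 = 0.25
AREA_MAX_UM2 = 7.5


@dataclass
class MnScore:
    """cGAS+ MN per 100 tumor cells for one tumor."""

    tumor_id: str
    n_mn: int
    n_tumor_cells: int
    score: float  # MN per 100 tumor cells; NaN when no tumor cells
    valid: bool = True


def filter_mn_candidates(
    foci: pd.DataFrame,
    area_min: float = AREA_MIN_UM2,
    area_max: float = AREA_MAX_UM2,
    intensity_threshold: float = 0.0,
) -> pd.DataFrame:
    """Filter candidate foci on area (inclusive bounds) and mean intensity.

    The intensity threshold is a per-tumor value chosen by the caller (see
    :func:`otsu_intensity_threshold` for a heuristic); records with negative
    area are rejected with a warning.
    """
    foci = foci.copy()
    bad = foci["area"] < 0
    if bad.any():
        warnings.warn(f"rejecting {int(bad.sum())} foci with negative area")
        foci = foci[~bad]
    keep = (
        (foci["area"] >= area_min)
        & (foci["area"] <= area_max)
        & (foci["intensity"] >= intensity_threshold)
    )
    return foci[keep]


def compute_mn_score(
    foci: pd.DataFrame, cells: pd.DataFrame, tumor_id: str = ""
) -> MnScore:
    """Score = 100 x (tumor-compartment foci) / (tumor cells).

    ``foci`` should already be filtered.  Artifact-class cells never enter
    the denominator; stromal foci never enter the numerator.
    """
    n_mn = int((foci["compartment"] == "tumor").sum()) if len(foci) else 0
    n_tumor = int((cells["compartment"] == "tumor").sum())
    if n_tumor == 0:
        warnings.warn(f"tumor {tumor_id!r}: no tumor cells, MN score undefined")
        return MnScore(tumor_id, n_mn, 0, float("nan"), valid=False)
    return MnScore(tumor_id, n_mn, n_tumor, 100.0 * n_mn / n_tumor)


def normalize_marker_intensities(
    cells: pd.DataFrame,
    markers: list[str] | None = None,
    af_col: str = "af",
):
    """Autofluorescence-normalize marker intensities.

    Per-cell value = mean marker intensity / mean autofluorescence; the
    per-compartment value is the mean of per-cell normalized values within
    each compartment class (artifact excluded).  Cells with autofluorescence
    <= 0 are excluded with a warning.

    Returns ``(per_cell, per_compartment)`` DataFrames.
    """
    if markers is None:
        markers = [
            c
            for c in cells.columns
            if c not in ("cell_id", "x", "y", "compartment", "cell_type", af_col)
            and np.issubdtype(cells[c].dtype, np.number)
        ]
    bad = cells[af_col] <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} cells with autofluorescence <= 0")
    ok = cells[~bad]
    per_cell = ok[["cell_id", "compartment"]].copy() if "cell_id" in ok else ok[["compartment"]].copy()
    for m in markers:
        per_cell[m] = ok[m] / ok[af_col]
    usable = per_cell[per_cell["compartment"] != "artifact"]
    per_compartment = usable.groupby("compartment")[markers].mean()
    return per_cell, per_compartment


def otsu_intensity_threshold(intensities: np.ndarray) -> float:
    """Heuristic per-tumor cGAS intensity threshold by Otsu's method.

    The original workflow tuned the threshold manually per tumor; this
    two-class variance split is offered as a reproducible stand-in and should
    be checked against the focus intensity histogram.
    """
    from skimage.filters import threshold_otsu

    intensities = np.asarray(intensities, float)
    if len(np.unique(intensities)) < 2:
        raise ValueError("need at least two distinct intensities for Otsu")
    return float(threshold_otsu(intensities))
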