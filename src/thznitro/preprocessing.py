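"""Savitzky-Golay smoothing of power spectra.

Each spectrum is smoothed by sliding an odd-width window along the
frequency axis, least-squares fitting a low-order polynomial inside the
window, and replacing the center value by the fitted value. At the grid
edges the boundary window's polynomial is evaluated at the edge
positions, so the output grid is identical to the input grid (scipy's
``mode="interp"``) and downstream interval arithmetic stays aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .io_formats import SpectraSet

__all__ = ["SmoothingParams", "sg_smooth"]


@dataclass(frozen=True)
class SmoothingParams:
    """Window width (odd, points) and polynomial order of the S-G filter.

    The 7-point window is the width used in the THz leaf workflow this
    package implements; the quadratic order is the conventional default.
    """

    window_points: int = 7
    poly_order: int = 2

    def __post_init__(self) -> None:
        if self.window_points < 3 or self.window_points % 2 == 0:
            raise ValueError("window_points must be an odd integer >= 3")
        if not 0 <= self.poly_order < self.window_points:
            raise ValueError("poly_order must satisfy 0 <= order < window_points")


def sg_smooth(data: SpectraSet, params: SmoothingParams | None = None) -> SpectraSet:
    """Return a new SpectraSet with every spectrum S-G filtered.

    Frequencies, nitrogen references, ids and labels are unchanged;
    output rows have the same length as the input rows.

    Raises
    ------
    ValueError
        If spectra are shorter than the filter window.
    """
    params = params or SmoothingParams()
    if data.n_frequencies < params.window_points:
        raise ValueError(
            f"spectrum length {data.n_frequencies} shorter than window "
            f"{params.window_points}"
        )
    smoothed = savgol_filter(
        data.power, params.window_points, params.poly_order, axis=1, mode="interp"
    )
    return replace(data, power=smoothed)
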