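"""Shape classification of PSI-velocity response curves.

Genome-wide polymerase-speed perturbations sort cassette exons into four
response classes: exon inclusion that rises or falls monotonically with
polymerase speed, and non-monotonic bell- or U-shaped responses where slow
and fast polymerase shift splicing in the same direction.  This module
assigns one of those classes (plus ``flat``) to a simulated profile.
"""

from __future__ import annotations

import numpy as np

__all__ = ["classify_profile", "SHAPE_CLASSES"]

SHAPE_CLASSES = ("increasing", "decreasing", "bell", "U", "flat")


def classify_profile(profile, tol: float = 0.02) -> str:
    """Classify a PSI-vpol profile by endpoints and interior extrema.

    An interior maximum exceeding both endpoints by more than ``tol`` PSI
    units gives ``bell``; an interior minimum below both endpoints by more
    than ``tol`` gives ``U``; otherwise the sign of the net end-to-end change
    (beyond ``tol``) gives ``increasing``/``decreasing``, and ``flat`` is the
    fallback.  ``tol`` defaults to 0.02 PSI units, below the resolution at
    which the response classes are distinguished experimentally.
    """
    vpol = np.asarray(profile.vpol, dtype=float)
    values = np.asarray(profile.psi, dtype=float)
    if vpol.size < 5:
        raise ValueError("need at least 5 grid points to classify a profile")
    if np.any(np.diff(vpol) <= 0):
        raise ValueError("vpol grid must be sorted strictly ascending")
    first, last = values[0], values[-1]
    interior = values[1:-1]
    i_max = float(interior.max())
    i_min = float(interior.min())
    if i_max > first + tol and i_max > last + tol:
        return "bell"
    if i_min < first - tol and i_min < last - tol:
        return "U"
    if last > first + tol:
        return "increasing"
    if last < first - tol:
        return "decreasing"
    return "flat"
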