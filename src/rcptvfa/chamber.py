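"""Chamber geometry shared by the pose synthesiser and the analysis stages.

Coordinates follow the image convention of the top-down camera: origin at
the top-left corner, x increasing rightward, y increasing downward, units
pixels.  The stimulus window on the touchscreen wall projects to a 1-D
segment in this view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BODYPARTS = ("head_top", "left_ear", "right_ear")
COORDS = ("x", "y", "likelihood")


class LayoutError(ValueError):
    """Chamber layout fields are inconsistent."""


def _is_simple_quadrilateral(corners: np.ndarray) -> bool:
    """True when the 4 corners, taken in order, form a non-self-intersecting loop."""

    def seg_intersect(p1, p2, p3, p4) -> bool:
        def cross(o, a, b):
            return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])
        d1, d2 = cross(p3, p4, p1), cross(p3, p4, p2)
        d3, d4 = cross(p1, p2, p3), cross(p1, p2, p4)
        return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))

    # Opposite (non-adjacent) edge pairs must not cross: (0-1, 2-3) and (1-2, 3-0)
    c = corners
    return not (seg_intersect(c[0], c[1], c[2], c[3])
                or seg_intersect(c[1], c[2], c[3], c[0]))


@dataclass(frozen=True)
class ChamberLayout:
    """Arena corners, stimulus segment, video resolution and frame rate.

    ``arena_corners`` are the four marked corners of the chamber floor in
    camera pixels (a trapezoid under perspective); ``stimulus_segment`` is
    the projection of the centre stimulus window's bottom/top border onto
    the top-down view.
    """

    arena_corners: tuple = (
        (140.0, 80.0), (580.0, 80.0), (620.0, 420.0), (100.0, 420.0))
    stimulus_segment: tuple = ((310.0, 80.0), (410.0, 80.0))
    resolution: tuple = (720, 480)
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        corners = np.asarray(self.arena_corners, float)
        if corners.shape != (4, 2) or not np.isfinite(corners).all():
            raise LayoutError("arena_corners must be four finite (x, y) points")
        if not _is_simple_quadrilateral(corners):
            raise LayoutError("arena corners must form a simple quadrilateral")
        seg = np.asarray(self.stimulus_segment, float)
        if seg.shape != (2, 2) or not np.isfinite(seg).all():
            raise LayoutError("stimulus_segment must be two finite (x, y) points")
        if np.allclose(seg[0], seg[1]):
            raise LayoutError("stimulus_segment endpoints must be distinct")
        if not (self.frame_rate > 0 and np.isfinite(self.frame_rate)):
            raise LayoutError(f"frame_rate must be positive, got {self.frame_rate!r}")

    @property
    def arena_centroid(self) -> np.ndarray:
        return np.asarray(self.arena_corners, float).mean(axis=0)

    @property
    def segment_midpoint(self) -> np.ndarray:
        return np.asarray(self.stimulus_segment, float).mean(axis=0)
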