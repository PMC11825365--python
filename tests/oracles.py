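"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the visual-field oracle
computes sector fractions by exact interval arithmetic on the segment
parameter (the implementation discretises the segment into sample points),
and the quantile oracle inverts the normal CDF by bisection (the
implementation uses scipy's ppf).
"""

from __future__ import annotations

import math

from scipy.stats import norm


def signed_angle_deg(gaze_deg: float, origin, point) -> float:
    """Angle from the gaze axis to origin->point, (-180, 180], left positive."""
    g = math.radians(gaze_deg)
    gx, gy = math.cos(g), math.sin(g)
    vx, vy = point[0] - origin[0], point[1] - origin[1]
    return math.degrees(math.atan2(gx * vy - gy * vx, gx * vx + gy * vy))


def exact_field_fractions(origin, bearing_deg, segment,
                          frontal=20.0, lateral=103.4) -> dict[str, float]:
    """Exact sector fractions of a segment by interval arithmetic.

    The signed bearing theta(s) to the segment point at parameter s changes
    sector only where |theta| crosses a sector bound or theta crosses 0
    (which splits left_all/right_all inside the frontal sector).  A crossing
    theta(s) = alpha means the point lies on the ray rotated alpha from the
    gaze axis, a linear condition in s with at most one admissible root.
    Roots partition [0, 1] into subintervals of constant sector, classified
    at their midpoints; fractions are summed parameter lengths.
    """
    ox, oy = float(origin[0]), float(origin[1])
    (ax, ay), (bx, by) = segment
    dx, dy = bx - ax, by - ay
    g = math.radians(bearing_deg)
    gx, gy = math.cos(g), math.sin(g)

    cuts = [0.0, 1.0]
    for alpha in (0.0, frontal, -frontal, lateral, -lateral):
        ca, sa = math.cos(math.radians(alpha)), math.sin(math.radians(alpha))
        rx, ry = gx * ca - gy * sa, gx * sa + gy * ca
        wx, wy = ax - ox, ay - oy
        c0 = rx * wy - ry * wx
        c1 = rx * dy - ry * dx
        if c1 == 0.0:
            continue
        s = -c0 / c1
        if 0.0 < s < 1.0:
            vx, vy = wx + s * dx, wy + s * dy
            if rx * vx + ry * vy > 0.0:
                cuts.append(s)
    cuts.sort()

    frac = dict(frontal=0.0, lateral_left=0.0, lateral_right=0.0, blind=0.0,
                left_all=0.0, right_all=0.0)
    for s0, s1 in zip(cuts[:-1], cuts[1:]):
        if s1 <= s0:
            continue
        m = 0.5 * (s0 + s1)
        theta = signed_angle_deg(bearing_deg, (ox, oy),
                                 (ax + m * dx, ay + m * dy))
        length = s1 - s0
        at = abs(theta)
        if at <= frontal:
            frac["frontal"] += length
            frac["left_all" if theta > 0 else "right_all"] += length
        elif at <= lateral:
            if theta > 0:
                frac["lateral_left"] += length
                frac["left_all"] += length
            else:
                frac["lateral_right"] += length
                frac["right_all"] += length
        else:
            frac["blind"] += length
    return frac


def normal_quantile_bisect(p: float, lo=-10.0, hi=10.0, tol=1e-12) -> float:
    """Standard normal quantile by bisection on the CDF."""
    assert 0.0 < p < 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if norm.cdf(mid) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
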