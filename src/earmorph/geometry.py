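"""Scalar morphological variables of the cochlea from 3D landmark curves.

The measured anatomy is an ordered polyline following the outer wall of
the cochlear spiral from the round window to the apex, plus a closed
outline around the oval window.  From these we compute:

CL   cochlea length (mm)        polyline arc length
CW   cochlea width (mm)         max pairwise extent of the basal turn,
                                projected onto the plane of coiling
NT   number of turns            total winding about the spiral axis,
                                quantised down to 0.1-turn sectors
OWA  oval window area (mm^2)    planar polygon area of the outline
ACS  average cross-section      mean of 5 tube areas at fifths of arc length
CSR  base/apex area ratio       area(1/5) / area(5/5)
CS   centroid size (mm)         sqrt of summed squared landmark distances
                                to the configuration centroid

All metrics are invariant under rigid motion; CL, CW and CS scale
linearly, OWA quadratically, NT and CSR not at all.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist


class GeometryError(ValueError):
    pass


@dataclass
class CochleaMetrics:
    CL: float
    CW: float
    NT: float
    OWA: float
    ACS: float
    CSR: float
    CS: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("CL", "CW", "NT", "OWA", "ACS", "CSR", "CS")}


# ------------------------------------------------------------- resampling


def resample_equidistant(points: np.ndarray, m: int) -> np.ndarray:
    """Resample a polyline to m points with equal consecutive chord lengths.

    Endpoints are pinned.  Points lie on the input polyline; positions are
    refined iteratively until chords agree to relative 1e-9 (uniform
    arc-length spacing alone leaves chords unequal across corners).
    """
    pts = np.asarray(points, dtype=float)
    if m < 2:
        raise GeometryError("m must be >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = float(seg.sum())
    if total == 0.0:
        raise GeometryError("degenerate zero-length curve")
    t = np.concatenate([[0.0], np.cumsum(seg)])

    def interp_at(s):
        return np.column_stack([np.interp(s, t, pts[:, k]) for k in range(3)])

    s = np.linspace(0.0, total, m)
    q = interp_at(s)
    for _ in range(100):
        chords = np.linalg.norm(np.diff(q, axis=0), axis=1)
        mean = chords.mean()
        if mean == 0.0:
            raise GeometryError("degenerate resampling (coincident points)")
        if np.max(np.abs(chords - mean)) <= 1e-9 * mean:
            break
        cum = np.concatenate([[0.0], np.cumsum(chords)])
        target = np.linspace(0.0, cum[-1], m)
        s = np.interp(target, cum, s)
        s[0], s[-1] = 0.0, total
        q = interp_at(s)
    return q


def build_configuration(
    raw_curve: np.ndarray,
    round_window_landmarks: np.ndarray,
    n_semilandmarks: int = 127,
) -> np.ndarray:
    """Assemble the 130-point configuration [LM1, LM2, 127 semilandmarks, apex].

    ``raw_curve`` runs from the second round-window landmark (LM2) to the
    apex inclusive; the semilandmarks are equidistant points strictly
    between LM2 and the apex.
    """
    raw = np.asarray(raw_curve, float)
    rw = np.asarray(round_window_landmarks, float)
    if rw.shape != (2, 3):
        raise GeometryError("round_window_landmarks must be (2, 3)")
    if not np.allclose(raw[0], rw[1]):
        raise GeometryError("raw curve must start at the second round-window landmark")
    if np.linalg.norm(raw[-1] - raw[0]) == 0.0:
        raise GeometryError("apex coincident with round-window landmark")
    dense = resample_equidistant(raw, n_semilandmarks + 2)
    return np.vstack([rw[0], dense[0], dense[1:-1], dense[-1]])


def mirror_configuration(config: np.ndarray) -> np.ndarray:
    """Negate the x axis (left-side specimens, applied before alignment)."""
    out = np.asarray(config, float).copy()
    out[:, 0] = -out[:, 0]
    return out


# ------------------------------------------------------------ arc metrics


def curve_length(curve: np.ndarray) -> float:
    """CL: sum of consecutive Euclidean distances (mm)."""
    pts = np.asarray(curve, float)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def centroid_size(config: np.ndarray) -> float:
    """CS = sqrt(sum_i ||p_i - centroid||^2)."""
    pts = np.asarray(config, float)
    d = pts - pts.mean(axis=0)
    return float(np.sqrt(np.sum(d * d)))


# --------------------------------------------------------- spiral winding


def _initial_axis(pts: np.ndarray) -> np.ndarray:
    seg = np.diff(pts, axis=0)
    cr = np.cross(seg[:-1], seg[1:])
    v = cr.sum(axis=0)
    nv = np.linalg.norm(v)
    if nv < 1e-12 * max(1.0, np.abs(pts).max()) ** 2:
        raise GeometryError("axis estimation degenerate (collinear points)")
    return v / nv


def _canonical_sign(axis: np.ndarray) -> np.ndarray:
    # fixed sign convention so winding sign is a property of the curve,
    # not of the estimator: largest-|component| entry made positive
    k = int(np.argmax(np.abs(axis)))
    return axis if axis[k] > 0 else -axis


def _project(pts: np.ndarray, axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e1 = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(axis, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    uv = pts @ np.column_stack([e1, e2])
    z = pts @ axis
    return uv, z


def _radial_winding(uv: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Cumulative signed winding of radius vectors about ``center``."""
    r = uv - center
    cross = r[:-1, 0] * r[1:, 1] - r[:-1, 1] * r[1:, 0]
    dot = np.sum(r[:-1] * r[1:], axis=1)
    steps = np.arctan2(cross, dot)
    return np.concatenate([[0.0], np.cumsum(steps)])


def estimate_spiral_axis(curve: np.ndarray, n_iter: int = 8) -> np.ndarray:
    """Spiral axis as the basal-turn plane normal after axial detrending.

    The naive least-squares plane through the first turn of a helix is
    tilted by the axial rise accumulated over that turn.  We therefore
    iterate: compute winding under the current axis, regress the axial
    coordinate on winding, subtract the fitted rise, refit the plane to the
    detrended points.  For a noiseless helix the detrended basal turn is
    exactly planar, so the iteration recovers the true axis to machine
    precision.
    """
    pts = np.asarray(curve, float)
    axis = _canonical_sign(_initial_axis(pts))
    for _ in range(n_iter):
        uv, z = _project(pts, axis)
        wind = _radial_winding(uv, uv.mean(axis=0))
        mask = np.abs(wind) <= 2.0 * np.pi
        if mask.sum() < 4:
            mask = np.ones(len(pts), bool)
        phi = wind[mask]
        zz = z[mask]
        A = np.column_stack([np.ones(phi.size), phi])
        coef, *_ = np.linalg.lstsq(A, zz, rcond=None)
        detr = pts[mask] - np.outer(phi * coef[1], axis)
        centered = detr - detr.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        new_axis = _canonical_sign(vt[2])
        if np.linalg.norm(new_axis - axis) < 1e-14:
            axis = new_axis
            break
        axis = new_axis
    return axis


def winding_angle(curve: np.ndarray) -> float:
    """Total signed winding (radians) of the curve about its spiral axis.

    Measured as the accumulated rotation of consecutive projected chord
    directions, plus half of the first and last rotation steps to account
    for the half-chords the discrete tangent misses at each end.  For a
    uniformly sampled logarithmic spiral this is exact.
    """
    pts = np.asarray(curve, float)
    axis = estimate_spiral_axis(pts)
    uv, _ = _project(pts, axis)
    d = np.diff(uv, axis=0)
    keep = np.linalg.norm(d, axis=1) > 0
    d = d[keep]
    if len(d) < 2:
        raise GeometryError("too few distinct points for winding")
    cross = d[:-1, 0] * d[1:, 1] - d[:-1, 1] * d[1:, 0]
    dot = np.sum(d[:-1] * d[1:], axis=1)
    steps = np.arctan2(cross, dot)
    return float(steps.sum() + 0.5 * (steps[0] + steps[-1]))


#: a sector boundary missed by less than this many turns still counts as
#: crossed -- guards the exact-multiple case against roundoff
NT_SNAP_TURNS = 1e-3


def number_of_turns(curve: np.ndarray, rounding: str = "floor") -> float:
    """NT: winding in 0.1-turn increments from the round-window inflection.

    ``rounding='floor'`` counts only fully crossed sectors (default);
    ``'nearest'`` rounds to the nearest 0.1.
    """
    turns = abs(winding_angle(curve)) / (2.0 * np.pi)
    if turns < 1.0:
        warnings.warn(f"curve winds only {turns:.2f} turns (< 1 full turn)")
    if rounding == "floor":
        nt = np.floor(10.0 * turns + 10.0 * NT_SNAP_TURNS) / 10.0
    elif rounding == "nearest":
        nt = np.round(10.0 * turns) / 10.0
    else:
        raise ValueError("rounding must be 'floor' or 'nearest'")
    return float(nt)


def first_turn_points(curve: np.ndarray) -> np.ndarray:
    """Points of the basal (first full) turn: winding <= 2*pi from start."""
    pts = np.asarray(curve, float)
    axis = estimate_spiral_axis(pts)
    uv, _ = _project(pts, axis)
    wind = _radial_winding(uv, uv.mean(axis=0))
    mask = np.abs(wind) <= 2.0 * np.pi + 1e-12
    return pts[mask]


def cochlea_width(curve: np.ndarray) -> float:
    """CW: max pairwise distance among basal-turn points projected onto the
    plane perpendicular to the spiral axis (mm)."""
    pts = np.asarray(curve, float)
    axis = estimate_spiral_axis(pts)
    ft = first_turn_points(pts)
    uv, _ = _project(ft, axis)
    if len(uv) < 2:
        raise GeometryError("too few basal-turn points for width")
    return float(pdist(uv).max())


# -------------------------------------------------------- areas and tubes


def cross_section_summary(areas: np.ndarray) -> tuple[float, float]:
    """(ACS, CSR) from tube areas at s = 1/5 .. 5/5 of arc length.

    ACS is the arithmetic mean of the five; CSR = area(1/5) / area(5/5).
    """
    a = np.asarray(areas, float)
    if a.shape != (5,):
        raise GeometryError("need exactly 5 cross-section areas (base to apex)")
    if np.any(a <= 0):
        raise GeometryError("cross-section areas must be positive")
    return float(a.mean()), float(a[0] / a[4])


def areas_at_fifths(config: np.ndarray, station_areas: np.ndarray) -> np.ndarray:
    """Pick the 5 stations nearest to 1/5..5/5 of configuration arc length."""
    pts = np.asarray(config, float)
    areas = np.asarray(station_areas, float)
    if len(areas) != len(pts):
        raise GeometryError("one area per configuration station required")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    frac = cum / cum[-1]
    idx = [int(np.argmin(np.abs(frac - k / 5.0))) for k in range(1, 6)]
    return areas[idx]


def _segments_intersect(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1, d2 = orient(p3, p4, p1), orient(p3, p4, p2)
    d3, d4 = orient(p1, p2, p3), orient(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def oval_window_area(outline: np.ndarray) -> float:
    """OWA: polygon area of the outline projected onto its best-fit plane.

    The loop is closed implicitly; orientation does not matter.  A
    self-intersecting projection triggers a warning and the absolute
    shoelace area is returned.
    """
    pts = np.asarray(outline, float)
    if len(pts) < 3:
        raise GeometryError("need >= 3 outline points")
    centered = pts - pts.mean(axis=0)
    _, sv, vt = np.linalg.svd(centered, full_matrices=False)
    if sv[1] < 1e-12 * max(sv[0], 1e-300):
        raise GeometryError("outline points are collinear")
    uv = centered @ vt[:2].T
    n = len(uv)
    closed = np.vstack([uv, uv[0]])
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through closure
            if _segments_intersect(closed[i], closed[i + 1], closed[j], closed[j + 1]):
                warnings.warn("self-intersecting oval-window outline; "
                              "absolute area returned")
                break
        else:
            continue
        break
    x, y = uv[:, 0], uv[:, 1]
    area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(abs(area))


def compute_metrics(
    config: np.ndarray,
    station_areas: np.ndarray,
    ow_outline: np.ndarray,
    nt_rounding: str = "floor",
    include_rw_segment: bool = True,
) -> CochleaMetrics:
    """All scalar metrics for one 130-point configuration.

    CL includes the LM1-LM2 round-window segment by default; NT and CW are
    measured on the curve from LM2 (the round-window inflection) to the
    apex.
    """
    config = np.asarray(config, float)
    curve = config[1:]  # LM2 .. apex
    cl = curve_length(config if include_rw_segment else curve)
    nt = number_of_turns(curve, rounding=nt_rounding)
    cw = cochlea_width(curve)
    acs, csr = cross_section_summary(areas_at_fifths(config, station_areas))
    owa = oval_window_area(ow_outline)
    cs = centroid_size(config)
    return CochleaMetrics(CL=cl, CW=cw, NT=nt, OWA=owa, ACS=acs, CSR=csr, CS=cs)
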