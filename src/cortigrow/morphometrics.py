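"""Morphometric readouts of simulated folding states.

Everything the simulator reports about a deformed configuration lives
here: folding evolution (outer perimeter ratio), sulcus/gyrus landmark
detection with depths and inter-sulcal distances, instability-point
detection on metric time series, normalized radial density profiles, and
OSVZ thickness maps beneath gyri vs. sulci. A fixture generator provides
analytic wavy and period-doubled boundaries plus synthetic density
states so every metric can be tested without running the solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .geometry import GeometryParams, Mesh, build_quarter_annulus, osvz_outer_radius

__all__ = [
    "SurfaceTrace",
    "MorphoTrace",
    "Landmark",
    "folding_evolution",
    "detect_sulci",
    "sulcus_depth",
    "detect_instability_points",
    "folding_kink_index",
    "intersulcal_distance",
    "radial_profile",
    "osvz_thickness_map",
    "generate_fixture_surface",
    "generate_fixture_state",
]


@dataclass
class SurfaceTrace:
    """Ordered polyline along the deformed outer boundary."""

    points: np.ndarray  # (m, 2), ordered along the boundary

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("trace points must be (m, 2)")
        if len(self.points) and np.any(
            np.all(np.diff(self.points, axis=0) == 0.0, axis=1)
        ):
            raise ValueError("trace contains duplicate consecutive points")

    @property
    def arc_length(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc_length[-1]) if len(self.points) > 1 else 0.0

    @property
    def radii(self) -> np.ndarray:
        return np.linalg.norm(self.points, axis=1)


@dataclass
class MorphoTrace:
    """Metric time series accumulated over a run."""

    times: list = field(default_factory=list)
    folding_evolution: list = field(default_factory=list)
    max_density: list = field(default_factory=list)
    max_stretch: list = field(default_factory=list)
    sulcus_depths: list = field(default_factory=list)   # list of arrays per step
    events: list = field(default_factory=list)

    def append(self, t, fe, cmax, s, depths):
        self.times.append(float(t))
        self.folding_evolution.append(float(fe))
        self.max_density.append(float(cmax))
        self.max_stretch.append(float(s))
        self.sulcus_depths.append(np.asarray(depths, dtype=float))


@dataclass(frozen=True)
class Landmark:
    index: int
    kind: str            # "sulcus" | "gyrus"
    arc_position: float
    radius: float
    boundary: bool = False


def trace_self_intersects(trace: SurfaceTrace) -> bool:
    """True when the boundary polyline intersects itself (sulcal walls in
    contact); the simulator stops on this condition since self-contact is
    not modeled."""
    p = trace.points
    m = len(p) - 1
    if m < 3:
        return False
    a = p[:-1]
    d = np.diff(p, axis=0)
    for i in range(m - 2):
        # vectorized segment-segment test of segment i vs j > i + 1
        j = np.arange(i + 2, m)
        r = d[i]
        s = d[j]
        qp = a[j] - a[i]
        denom = r[0] * s[:, 1] - r[1] * s[:, 0]
        tnum = qp[:, 0] * s[:, 1] - qp[:, 1] * s[:, 0]
        unum = qp[:, 0] * r[1] - qp[:, 1] * r[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = tnum / denom
            u = unum / denom
        hit = (np.abs(denom) > 1e-14) & (t > 0) & (t < 1) & (u > 0) & (u < 1)
        if np.any(hit):
            return True
    return False


def folding_evolution(trace: SurfaceTrace, initial_perimeter: float) -> float:
    """Ratio of the current outer perimeter to the initial perimeter."""
    if initial_perimeter <= 0:
        raise ValueError("initial_perimeter must be positive")
    if len(trace.points) < 2:
        raise ValueError("empty trace")
    return trace.length / initial_perimeter


def _smooth(x: np.ndarray, frac: float) -> np.ndarray:
    win = max(3, int(round(frac * len(x))))
    if win % 2 == 0:
        win += 1
    if win >= len(x):
        return x.copy()
    kernel = np.ones(win) / win
    pad = win // 2
    xp = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]])  # reflect
    return np.convolve(xp, kernel, mode="valid")


def detect_sulci(
    trace: SurfaceTrace,
    smooth_frac: float = 0.05,
    prominence: float | None = None,
    include_boundary: bool = False,
) -> list:
    """Sulcal minima and gyral maxima of the radial coordinate.

    The radius-vs-arc-length signal is smoothed with a moving average
    (window = ``smooth_frac`` of the trace) and extrema below the
    persistence threshold (default 0.5% of the mean radius) are
    discarded. Extrema at the symmetry edges are excluded unless
    ``include_boundary``.
    """
    rho = trace.radii
    if len(rho) < 5:
        return []
    rs = _smooth(rho, smooth_frac)
    if prominence is None:
        prominence = 0.005 * float(np.mean(rho))
    s = trace.arc_length
    out = []
    for sign, kind in ((-1.0, "sulcus"), (1.0, "gyrus")):
        idx, _ = find_peaks(sign * rs, prominence=prominence)
        for i in idx:
            out.append(Landmark(int(i), kind, float(s[i]), float(rho[i])))
    if include_boundary:
        # endpoints count as half-extrema when they dominate their neighbor
        for i in (0, len(rho) - 1):
            j = 1 if i == 0 else len(rho) - 2
            if rs[i] > rs[j] + prominence:
                out.append(Landmark(i, "gyrus", float(s[i]), float(rho[i]), True))
            elif rs[i] < rs[j] - prominence:
                out.append(Landmark(i, "sulcus", float(s[i]), float(rho[i]), True))
    out.sort(key=lambda L: L.index)
    return out


def sulcus_depth(trace: SurfaceTrace, landmark: Landmark, landmarks: list | None = None):
    """Depth of a sulcus against its flanking gyral crowns.

    depth = mean radius of the two nearest gyral maxima minus the sulcal
    radius. With only one flank (boundary sulcus) the single flank is
    used. Returns 0 for a smooth surface (no flanking gyri).
    """
    if landmark.kind != "sulcus":
        raise ValueError("landmark is not a sulcus")
    if landmarks is None:
        landmarks = detect_sulci(trace, include_boundary=True)
    gyri = [L for L in landmarks if L.kind == "gyrus"]
    left = [g for g in gyri if g.index < landmark.index]
    right = [g for g in gyri if g.index > landmark.index]
    flanks = []
    if left:
        flanks.append(left[-1].radius)
    if right:
        flanks.append(right[0].radius)
    if not flanks:
        return 0.0
    return float(np.mean(flanks) - landmark.radius)


def all_sulcus_depths(trace: SurfaceTrace, **kw) -> np.ndarray:
    """Depths of all interior sulci of a trace (helper for run metrics)."""
    lm = detect_sulci(trace, **kw)
    lm_all = detect_sulci(trace, include_boundary=True, **kw)
    return np.array(
        [sulcus_depth(trace, L, lm_all) for L in lm if L.kind == "sulcus"]
    )


def folding_kink_index(times, fe, smooth_frac: float = 0.05) -> int | None:
    """Index of the kink (max discrete curvature) of the folding-evolution
    series; None for a series too short to differentiate twice."""
    fe = np.asarray(fe, dtype=float)
    if len(fe) < 5:
        return None
    fs = _smooth(fe, smooth_frac)
    d2 = np.abs(np.diff(fs, 2))
    # the reflect padding of the smoother bends the series at its ends;
    # exclude one smoothing window on each side from the search
    win = max(3, int(round(smooth_frac * len(fe)))) | 1
    margin = min(win, (len(d2) - 1) // 2)
    core = d2[margin : len(d2) - margin] if margin > 0 else d2
    if len(core) == 0:
        return int(np.argmax(d2)) + 1
    return int(np.argmax(core)) + margin + 1


def detect_instability_points(
    morpho: MorphoTrace,
    depth_eps: float | None = None,
    cortical_thickness: float = 0.2,
    bifurcation_ratio: float = 1.5,
    persistence: int = 3,
):
    """Times of the primary (wrinkling) and secondary (period-doubling)
    instabilities from the metric series.

    Primary: first time the maximum sulcus depth exceeds ``depth_eps``
    (default 1% of the cortical thickness) while increasing. Secondary:
    first time the ratio of the deepest to the shallowest tracked sulcus
    exceeds ``bifurcation_ratio`` for ``persistence`` consecutive steps.
    Returns ``(t_primary, t_secondary)``; either may be None.
    """
    n = len(morpho.times)
    if n < 10:
        raise ValueError("series too short (need >= 10 steps)")
    if depth_eps is None:
        depth_eps = 0.01 * cortical_thickness
    dmax = np.array(
        [d.max() if len(d) else 0.0 for d in morpho.sulcus_depths]
    )
    t_primary = None
    for i in range(1, n):
        if dmax[i] > depth_eps and dmax[i] >= dmax[i - 1]:
            t_primary = morpho.times[i]
            break
    t_secondary = None
    streak = 0
    for i in range(n):
        d = morpho.sulcus_depths[i]
        d = d[d > depth_eps]
        if len(d) >= 2 and d.max() / max(d.min(), 1e-12) > bifurcation_ratio:
            streak += 1
            if streak >= persistence:
                t_secondary = morpho.times[i - persistence + 1]
                break
        else:
            streak = 0
    return t_primary, t_secondary


def intersulcal_distance(trace: SurfaceTrace, landmarks: list | None = None):
    """Euclidean chords between consecutive sulcal minima, mm.

    Returns an empty list when fewer than two sulci are present.
    """
    if landmarks is None:
        landmarks = detect_sulci(trace)
    sulci = [L for L in landmarks if L.kind == "sulcus"]
    if len(sulci) < 2:
        return []
    pts = trace.points[[L.index for L in sulci]]
    return list(np.linalg.norm(np.diff(pts, axis=0), axis=1))


def _structured_interp(mesh: Mesh, nodal: np.ndarray, r_s: np.ndarray, theta: float):
    """Bilinear interpolation of a nodal field at material (radius, angle)
    query points using the structured parameter grid of annulus meshes."""
    if mesh.radial_coords.size == 0:
        raise ValueError("mesh lacks structured parameter grid")
    rs, ts = mesh.radial_coords, mesh.theta_coords
    nt = len(ts)
    vals2d = np.asarray(nodal).reshape(len(rs), nt, -1)
    ir = np.clip(np.searchsorted(rs, r_s) - 1, 0, len(rs) - 2)
    it = int(np.clip(np.searchsorted(ts, theta) - 1, 0, nt - 2))
    wr = (r_s - rs[ir]) / (rs[ir + 1] - rs[ir])
    wt = (theta - ts[it]) / (ts[it + 1] - ts[it])
    v = (
        (1 - wr)[:, None] * ((1 - wt) * vals2d[ir, it] + wt * vals2d[ir, it + 1])
        + wr[:, None] * ((1 - wt) * vals2d[ir + 1, it] + wt * vals2d[ir + 1, it + 1])
    )
    return v.squeeze(-1) if v.shape[-1] == 1 else v


def radial_profile(state, theta: float, n_samples: int = 100, geom: GeometryParams | None = None):
    """Normalized density profile along the deformed image of a material ray.

    Samples the density at ``n_samples`` material radii from the
    ventricular to the outer surface along the reference ray at ``theta``;
    the abscissa is arc length along the deformed ray normalized to
    [0, 1], the ordinate is density normalized by its maximum among
    cortical samples (material radius > r_cp); falls back to the global
    max (with a warning flag) when the cortex is empty.
    """
    import warnings

    mesh = state.mesh
    geom = geom or state.geom
    r_s = np.linspace(mesh.radial_coords[0], mesh.radial_coords[-1], n_samples)
    xy = _structured_interp(mesh, mesh.nodes + state.u, r_s, theta)
    c = _structured_interp(mesh, state.c, r_s, theta)
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    xi = arc / arc[-1]
    cortical = c[r_s > geom.r_cp]
    cmax = cortical.max(initial=0.0)
    if cmax <= 0:
        warnings.warn("cortical density is zero; normalizing by global max")
        cmax = max(c.max(initial=0.0), 1e-300)
    return xi, c / cmax


def osvz_thickness_map(state, n_angles: int | None = None, geom: GeometryParams | None = None):
    """OSVZ thickness along deformed rays, with gyral/sulcal tags.

    For each sampled angle the material OSVZ band [r_isvz, r_osvz(t)] is
    mapped through the deformation and its Euclidean extent measured.
    Each angle is tagged gyral when the deformed outer-surface radius
    above it exceeds its smoothed (moving-average) trend.
    Returns ``(angles, thickness, is_gyrus)``.
    """
    mesh = state.mesh
    geom = geom or state.geom
    thetas = mesh.theta_coords if n_angles is None else np.linspace(
        mesh.theta_coords[0], mesh.theta_coords[-1], n_angles
    )
    ro = float(osvz_outer_radius(state.time, geom))
    xdef = mesh.nodes + state.u
    thick = np.empty(len(thetas))
    rho_out = np.empty(len(thetas))
    for i, th in enumerate(thetas):
        r_s = np.array([geom.r_isvz, ro, mesh.radial_coords[-1]])
        xy = _structured_interp(mesh, xdef, r_s, float(th))
        thick[i] = np.linalg.norm(xy[1] - xy[0])
        rho_out[i] = np.linalg.norm(xy[2])
    trend = _smooth(rho_out, 0.25)
    is_gyrus = rho_out >= trend
    return thetas, thick, is_gyrus


# ---------------------------------------------------------------------------
# analytic fixtures


def generate_fixture_surface(kind: str, params: dict | None = None, seed: int = 0) -> SurfaceTrace:
    """Analytic outer-boundary traces for metric tests.

    kinds:
      - ``circle``: rho = R on [0, pi/2]
      - ``wavy``: rho = R + amplitude sin(modes * theta)
      - ``period_doubled``: alternating deep/shallow troughs,
        rho = R - deep*(1-cos(m theta))/2 ... realized as
        R + a1 sin(m theta) - a2 cos(m/2 theta) style superposition with
        trough depths ``deep`` and ``shallow``.
    """
    p = dict(params or {})
    R = p.get("radius", 2.0)
    n = p.get("n_points", 400)
    theta = np.linspace(0.0, np.pi / 2.0, n)
    if kind == "circle":
        rho = np.full_like(theta, R)
    elif kind == "wavy":
        a = p.get("amplitude", 0.1)
        m = p.get("modes", 8)
        rho = R + a * np.sin(m * theta)
    elif kind == "period_doubled":
        deep = p.get("deep", 0.3)
        shallow = p.get("shallow", 0.1)
        m = p.get("modes", 8)
        # troughs of sin(m theta) alternate in depth via the half-frequency term
        base = 0.5 * (deep + shallow)
        mod = 0.5 * (deep - shallow)
        rho = R - (base + mod * np.cos(0.5 * m * theta)) * np.clip(
            -np.sin(m * theta), 0.0, 1.0
        )
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return SurfaceTrace(np.column_stack([rho * np.cos(theta), rho * np.sin(theta)]))


@dataclass
class FixtureState:
    """Minimal state object (mesh + fields) for metric tests; synthetic,
    not produced by the solver."""

    mesh: Mesh
    u: np.ndarray
    c: np.ndarray
    time: float
    geom: GeometryParams


def generate_fixture_state(
    kind: str = "zone_peaks",
    geom: GeometryParams = GeometryParams(),
    n_radial: int = 40,
    n_circ: int = 40,
    time: float = 30.0,
    params: dict | None = None,
    seed: int = 0,
) -> FixtureState:
    """Synthetic solver-free states with prescribed density/deformation.

    kinds:
      - ``uniform``: constant density, zero displacement.
      - ``zone_peaks``: Gaussian density bumps at given material radii.
      - ``radial_map``: density zero, radial deformation rho -> f(rho)
        given as piecewise-linear (params: "knots", "values"), optionally
        modulated by an angular bump (params: "bump_amp", "bump_mode").
    """
    p = dict(params or {})
    mesh = build_quarter_annulus(geom, n_radial, n_circ)
    ri = mesh.material_radius
    theta = np.arctan2(mesh.nodes[:, 1], mesh.nodes[:, 0])
    u = np.zeros_like(mesh.nodes)
    if kind == "uniform":
        c = np.full(mesh.n_nodes, p.get("value", 100.0))
    elif kind == "zone_peaks":
        centers = p.get("centers", [0.45, 1.0, 1.9])
        amps = p.get("amplitudes", [600.0, 400.0, 700.0])
        width = p.get("width", 0.05)
        c = np.zeros(mesh.n_nodes)
        for c0, a in zip(centers, amps):
            c += a * np.exp(-0.5 * ((ri - c0) / width) ** 2)
    elif kind == "radial_map":
        knots = np.asarray(p.get("knots", [geom.r, geom.R]))
        values = np.asarray(p.get("values", [geom.r, geom.R]))
        rho_new = np.interp(ri, knots, values)
        rho_new = rho_new * (
            1.0 + p.get("bump_amp", 0.0) * np.cos(p.get("bump_mode", 8) * theta)
            * np.clip((ri - geom.r_isvz) / (geom.R - geom.r_isvz), 0.0, 1.0)
        )
        xy = np.column_stack([rho_new * np.cos(theta), rho_new * np.sin(theta)])
        u = xy - mesh.nodes
        c = np.zeros(mesh.n_nodes)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return FixtureState(mesh, u, c, time, geom)
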