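"""Cremer-Pople puckering coordinates, conformer classification, and a
classical well-tempered metadynamics engine on analytic 2-D potentials.

For a six-membered ring ordered O5, C1, C2, C3, C4, C5 the Cremer-Pople
construction yields a total puckering amplitude Q (Å), a polar angle
θ ∈ [0°, 180°] and a phase φ ∈ [0°, 360°).  With this atom ordering the
north pole θ = 0 is the ⁴C₁ chair.  The 38 canonical IUPAC conformers
(2 chairs, 6 boats, 6 skew-boats, 12 half-chairs, 12 envelopes) are placed
on the (θ, φ) sphere by constructing each ideal out-of-plane displacement
pattern and running it through the same Cremer-Pople code, so the
classifier and any generated ligand share one convention by construction.

The metadynamics engine runs an overdamped Langevin walker on an analytic
2-D potential with history-dependent Gaussian bias whose height decays by
the well-tempered rule; the free energy is recovered from the bias as
F = −γ/(γ−1) · V_bias.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PuckerCoords",
    "MetadConfig",
    "FELGrid",
    "cremer_pople",
    "classify_conformer",
    "canonical_vertices",
    "run_wt_metadynamics",
    "fel_extrema",
]

RING_ORDER = ("O5", "C1", "C2", "C3", "C4", "C5")


@dataclass
class PuckerCoords:
    """Cremer-Pople coordinates: amplitude Q (Å), angles in degrees, and the
    Cartesian components qx = Q sinθ cosφ, qy = Q sinθ sinφ, qz = Q cosθ."""

    Q: float
    theta: float
    phi: float

    @property
    def qx(self) -> float:
        return self.Q * np.sin(np.deg2rad(self.theta)) * np.cos(np.deg2rad(self.phi))

    @property
    def qy(self) -> float:
        return self.Q * np.sin(np.deg2rad(self.theta)) * np.sin(np.deg2rad(self.phi))

    @property
    def qz(self) -> float:
        return self.Q * np.cos(np.deg2rad(self.theta))


def cremer_pople(ring: np.ndarray) -> PuckerCoords:
    """Cremer-Pople puckering coordinates of 6 ordered ring positions.

    Standard construction: centroid translation; mean plane from the two
    Fourier sums R' and R''; out-of-plane projections z_j; then
    q2 e^{iφ2} from the m = 2 Fourier component and q3 from the alternating
    sum.  Invariant under rigid motion of the ring.
    """
    ring = np.asarray(ring, dtype=float)
    if ring.shape != (6, 3):
        raise ValueError("cremer_pople expects exactly 6 ordered ring positions")
    r = ring - ring.mean(axis=0)
    j = np.arange(6)
    ang = 2.0 * np.pi * j / 6.0
    r1 = (r * np.sin(ang)[:, None]).sum(axis=0)
    r2 = (r * np.cos(ang)[:, None]).sum(axis=0)
    # normal oriented so that the north pole (theta = 0) is the 4C1 chair
    # for the O5,C1..C5 ordering used throughout this package
    n = np.cross(r2, r1)
    nn = np.linalg.norm(n)
    if nn == 0.0:
        # degenerate (collinear) ring; no defined plane
        raise ValueError("degenerate ring geometry: undefined mean plane")
    n /= nn
    z = r @ n
    q2c = np.sqrt(1.0 / 3.0) * (z * np.cos(2.0 * ang)).sum()
    q2s = -np.sqrt(1.0 / 3.0) * (z * np.sin(2.0 * ang)).sum()
    q3 = np.sqrt(1.0 / 6.0) * (z * (-1.0) ** j).sum()
    q2 = np.hypot(q2c, q2s)
    Q = np.hypot(q2, q3)
    theta = np.degrees(np.arctan2(q2, q3))
    phi = np.degrees(np.arctan2(q2s, q2c)) % 360.0
    return PuckerCoords(float(Q), float(theta), float(phi))


# ---------------------------------------------------------------------------
# canonical conformer table

def _pattern_positions(z_pattern: np.ndarray, amplitude: float = 0.35,
                       rho: float = 1.45) -> np.ndarray:
    """Ideal ring: regular hexagon of radius rho plus an out-of-plane pattern."""
    ang = 2.0 * np.pi * np.arange(6) / 6.0
    xy = np.stack([rho * np.cos(ang), rho * np.sin(ang)], axis=1)
    z = np.asarray(z_pattern, dtype=float)
    if np.any(z):
        z = z / np.linalg.norm(z) * amplitude * np.sqrt(6) / np.sqrt(6)
        z = z * (amplitude / np.abs(z).max())
    return np.column_stack([xy, z])


def _canonical_patterns() -> list[tuple[str, np.ndarray]]:
    """The 38 ideal out-of-plane patterns with their IUPAC labels.

    Atom j index: 0=O5, 1=C1, 2=C2, 3=C3, 4=C4, 5=C5; symbol "O" for O5.
    Superscripts (atoms above the plane) precede the letter, subscripts
    (below) follow, e.g. ``4C1``, ``1S3``, ``B3O``, ``3E``, ``E3``, ``3H4``.
    """
    sym = ["O", "1", "2", "3", "4", "5"]
    out: list[tuple[str, np.ndarray]] = []

    def zvec(**kw) -> np.ndarray:
        z = np.zeros(6)
        for k, v in kw.items():
            z[int(k[1])] = v
        return z

    # chairs: alternating pattern; O5,C2,C4 up -> 4C1; inverted -> 1C4
    alt = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
    out.append(("4C1", alt))
    out.append(("1C4", -alt))
    # boats: opposite pair (j, j+3) displaced to the same side
    for a, b in ((1, 4), (2, 5), (3, 0)):
        pair = "".join(sorted((sym[a], sym[b]), key=lambda s: (s == "O", s)))
        up = zvec(**{f"_{a}": 1.0, f"_{b}": 1.0})
        out.append((f"{pair}B", up))
        out.append((f"B{pair}", -up))
    # skew-boats: the six canonical twist forms
    for a, b in ((1, 3), (3, 1), (1, 5), (5, 1), (2, 0), (0, 2)):
        z = zvec(**{f"_{a}": 1.0, f"_{b}": -1.0})
        out.append((f"{sym[a]}S{sym[b]}", z))
    # envelopes: a single atom out of plane
    for a in range(6):
        z = zvec(**{f"_{a}": 1.0})
        out.append((f"{sym[a]}E", z))
        out.append((f"E{sym[a]}", -z))
    # half-chairs: adjacent pair on opposite sides
    for a in range(6):
        b = (a + 1) % 6
        z = zvec(**{f"_{a}": 1.0, f"_{b}": -1.0})
        out.append((f"{sym[a]}H{sym[b]}", z))
        out.append((f"{sym[b]}H{sym[a]}", -z))
    return out


_VERTEX_CACHE: list[tuple[str, float, float]] | None = None


def canonical_vertices() -> list[tuple[str, float, float]]:
    """(label, theta_deg, phi_deg) of the 38 canonical conformers."""
    global _VERTEX_CACHE
    if _VERTEX_CACHE is None:
        verts = []
        for label, z in _canonical_patterns():
            pc = cremer_pople(_pattern_positions(z))
            verts.append((label, pc.theta, pc.phi))
        _VERTEX_CACHE = verts
    return _VERTEX_CACHE


def classify_conformer(coords: PuckerCoords, planar_tol: float = 1e-6) -> str:
    """Nearest canonical conformer on the (θ, φ) sphere, or "planar".

    Distance is the great-circle angle; ties break by the fixed canonical
    ordering (chairs, boats, skew-boats, envelopes, half-chairs).
    """
    if coords.Q < planar_tol:
        return "planar"
    t1 = np.deg2rad(coords.theta)
    p1 = np.deg2rad(coords.phi)
    best_label, best_d = "", np.inf
    for label, t2d, p2d in canonical_vertices():
        t2 = np.deg2rad(t2d)
        p2 = np.deg2rad(p2d)
        cosd = np.cos(t1) * np.cos(t2) + np.sin(t1) * np.sin(t2) * np.cos(p1 - p2)
        d = np.arccos(np.clip(cosd, -1.0, 1.0))
        if d < best_d - 1e-12:
            best_d, best_label = d, label
    return best_label


# ---------------------------------------------------------------------------
# well-tempered metadynamics on analytic 2-D potentials

@dataclass
class MetadConfig:
    """Parameters of the well-tempered metadynamics run.

    Gaussian hills of initial height ``gauss_height`` (kcal/mol) and width
    ``gauss_width`` (CV units) are deposited every ``stride`` steps with the
    height decaying as exp(−V_bias / ((γ−1) kT)).
    """

    gauss_height: float = 1.0
    gauss_width: float = 0.1
    bias_factor: float = 10.0
    stride: int = 200
    kT: float = 0.596          # kcal/mol (300 K)
    n_steps: int = 800_000
    seed: int = 0
    x_range: tuple[float, float] = (-1.8, 1.8)
    y_range: tuple[float, float] = (-1.8, 1.8)
    n_grid: int = 101
    dt: float = 2e-3           # walker time step (CV units² per kT)
    start: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.bias_factor <= 1.0:
            raise ValueError("bias factor must exceed 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class FELGrid:
    """Gridded free-energy surface (kcal/mol), minimum shifted to zero."""

    x_axis: np.ndarray
    y_axis: np.ndarray
    values: np.ndarray          # shape (nx, ny)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("free-energy grid contains non-finite values")


def _bilinear(grid: np.ndarray, xa: np.ndarray, ya: np.ndarray,
              x: float, y: float) -> float:
    ix = np.clip(np.searchsorted(xa, x) - 1, 0, len(xa) - 2)
    iy = np.clip(np.searchsorted(ya, y) - 1, 0, len(ya) - 2)
    tx = (x - xa[ix]) / (xa[ix + 1] - xa[ix])
    ty = (y - ya[iy]) / (ya[iy + 1] - ya[iy])
    tx = min(max(tx, 0.0), 1.0)
    ty = min(max(ty, 0.0), 1.0)
    return float(
        grid[ix, iy] * (1 - tx) * (1 - ty) + grid[ix + 1, iy] * tx * (1 - ty)
        + grid[ix, iy + 1] * (1 - tx) * ty + grid[ix + 1, iy + 1] * tx * ty)


def run_wt_metadynamics(potential, config: MetadConfig) -> FELGrid:
    """Well-tempered metadynamics of an overdamped walker on ``potential``.

    ``potential(x, y)`` must be finite over the CV domain (it may accept
    arrays).  The bias and its gradient are accumulated analytically on the
    grid and interpolated at the walker; reflective boundaries confine the
    walker to the domain.  Returns the free-energy estimate
    F = −γ/(γ−1) · V_bias, min-shifted, with hills and a basin-ΔF
    convergence series in the metadata.
    """
    cfg = config
    xa = np.linspace(*cfg.x_range, cfg.n_grid)
    ya = np.linspace(*cfg.y_range, cfg.n_grid)
    XX, YY = np.meshgrid(xa, ya, indexing="ij")
    vgrid = np.asarray(potential(XX, YY), dtype=float)
    if not np.all(np.isfinite(vgrid)):
        raise ValueError("potential is non-finite on the CV grid")
    bias = np.zeros_like(vgrid)
    gamma, kT = cfg.bias_factor, cfg.kT
    rng = np.random.default_rng(cfg.seed)
    x, y = cfg.start if cfg.start is not None else (float(xa[cfg.n_grid // 4]), 0.0)
    # locate walker start at the potential minimum if no start given
    if cfg.start is None:
        i0, j0 = np.unravel_index(np.argmin(vgrid), vgrid.shape)
        x, y = float(xa[i0]), float(ya[j0])
    dt = cfg.dt
    sq = np.sqrt(2.0 * kT * dt)
    hills: list[tuple[int, float, float, float]] = []
    delta_f_series: list[tuple[int, float]] = []
    mid = cfg.n_grid // 2
    fel_accum = None
    n_accum = 0
    w2 = 2.0 * cfg.gauss_width ** 2
    # static potential gradient on the grid (central differences)
    vgx, vgy = np.gradient(vgrid, xa, ya)
    # bias and its gradient accumulated analytically on the grid
    bgx = np.zeros_like(bias)
    bgy = np.zeros_like(bias)
    dx_grid = xa[1] - xa[0]
    dy_grid = ya[1] - ya[0]
    inv_dx, inv_dy = 1.0 / dx_grid, 1.0 / dy_grid
    x0a, y0a = xa[0], ya[0]
    nx_g = cfg.n_grid
    noise = rng.standard_normal((cfg.n_steps, 2)) * sq

    def interp(grid, px, py):
        fx = (px - x0a) * inv_dx
        fy = (py - y0a) * inv_dy
        ix = min(max(int(fx), 0), nx_g - 2)
        iy = min(max(int(fy), 0), nx_g - 2)
        tx = min(max(fx - ix, 0.0), 1.0)
        ty = min(max(fy - iy, 0.0), 1.0)
        return (grid[ix, iy] * (1 - tx) * (1 - ty)
                + grid[ix + 1, iy] * tx * (1 - ty)
                + grid[ix, iy + 1] * (1 - tx) * ty
                + grid[ix + 1, iy + 1] * tx * ty)

    for step in range(cfg.n_steps):
        gx = interp(vgx, x, y) + interp(bgx, x, y)
        gy = interp(vgy, x, y) + interp(bgy, x, y)
        x = x - dt * gx + noise[step, 0]
        y = y - dt * gy + noise[step, 1]
        # reflective boundaries
        x = float(np.clip(2 * xa[0] - x if x < xa[0] else (2 * xa[-1] - x if x > xa[-1] else x), xa[0], xa[-1]))
        y = float(np.clip(2 * ya[0] - y if y < ya[0] else (2 * ya[-1] - y if y > ya[-1] else y), ya[0], ya[-1]))
        if (step + 1) % cfg.stride == 0:
            vb = interp(bias, x, y)
            height = cfg.gauss_height * np.exp(-vb / ((gamma - 1.0) * kT))
            gauss = height * np.exp(-((XX - x) ** 2 + (YY - y) ** 2) / w2)
            bias += gauss
            bgx += gauss * (-2.0 * (XX - x) / w2)
            bgy += gauss * (-2.0 * (YY - y) / w2)
            hills.append((step + 1, x, y, float(height)))
            fl = -gamma / (gamma - 1.0) * bias
            # basin free energies by Boltzmann integration over the two
            # half-planes (much smoother than tracking grid minima)
            f0 = fl.min()
            zl = np.exp(-(fl[:mid, :] - f0) / kT).sum()
            zr = np.exp(-(fl[mid:, :] - f0) / kT).sum()
            delta_f_series.append((step + 1, float(-kT * np.log(zr / zl))))
            n_dep_total = cfg.n_steps // cfg.stride
            if len(hills) > 0.8 * n_dep_total:
                fel_accum = fel_accum + fl if fel_accum is not None else fl.copy()
                n_accum += 1
    if n_accum:
        fel = fel_accum / n_accum
    else:
        fel = -gamma / (gamma - 1.0) * bias
    fel = fel - fel.min()
    series = np.array([d for _, d in delta_f_series]) if delta_f_series else np.zeros(0)
    tail = series[int(0.8 * len(series)):] if len(series) else series
    # drift = systematic trend across the tail (difference of half-means),
    # as opposed to the deposition-noise fluctuation range
    if len(tail) >= 4:
        half = len(tail) // 2
        drift = float(abs(tail[half:].mean() - tail[:half].mean()))
    else:
        drift = 0.0
    meta = {
        "config": cfg,
        "hills": hills,
        "delta_f_series": delta_f_series,
        "basin_delta_f": float(tail.mean()) if len(tail) else 0.0,
        "delta_f_drift": drift,
    }
    return FELGrid(xa, ya, fel, meta)


def hills_to_tsv(fel: FELGrid, path) -> None:
    """Write the deposited-hills log (step, x, y, height) as TSV."""
    with open(path, "w") as fh:
        fh.write("step\tx\ty\theight\n")
        for step, x, y, h in fel.metadata.get("hills", []):
            fh.write(f"{step}\t{x:.6f}\t{y:.6f}\t{h:.6f}\n")


def fel_extrema(fel: FELGrid, basin_a: tuple[float, float] | None = None,
                basin_b: tuple[float, float] | None = None,
                depth_threshold: float = np.inf):
    """Local minima of the grid and the minimax barrier between two basins.

    Minima are 4/8-neighbour grid-local minima with value below
    ``depth_threshold``.  The barrier between the minima nearest the two
    named basin points is the maximum energy along the path minimising that
    maximum (bottleneck Dijkstra on the 4-connected grid graph).
    Returns ``(minima, barrier)`` where minima is a list of
    (x, y, F) and barrier is None when no basins were named.
    """
    F = fel.values
    nx, ny = F.shape
    minima = []
    for i in range(nx):
        for j in range(ny):
            nb = F[max(i - 1, 0):i + 2, max(j - 1, 0):j + 2]
            if F[i, j] <= nb.min() and F[i, j] < depth_threshold:
                # strictly no lower neighbour
                if np.sum(nb == F[i, j]) == 1 or F[i, j] == nb.min():
                    minima.append((float(fel.x_axis[i]), float(fel.y_axis[j]),
                                   float(F[i, j])))
    # deduplicate plateau minima by removing near-duplicates
    if basin_a is None or basin_b is None:
        return minima, None

    def nearest_min(p):
        if not minima:
            raise ValueError("no basin minima found in the grid")
        d = [np.hypot(m[0] - p[0], m[1] - p[1]) for m in minima]
        return minima[int(np.argmin(d))]

    ma, mb = nearest_min(basin_a), nearest_min(basin_b)
    ia = (int(np.argmin(np.abs(fel.x_axis - ma[0]))),
          int(np.argmin(np.abs(fel.y_axis - ma[1]))))
    ib = (int(np.argmin(np.abs(fel.x_axis - mb[0]))),
          int(np.argmin(np.abs(fel.y_axis - mb[1]))))
    # bottleneck Dijkstra: minimise the maximum node energy along the path
    best = np.full(F.shape, np.inf)
    best[ia] = F[ia]
    pq = [(F[ia], ia)]
    while pq:
        cost, (i, j) = heapq.heappop(pq)
        if cost > best[i, j]:
            continue
        if (i, j) == ib:
            return minima, float(cost - F[ia[0], ia[1]])
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < nx and 0 <= nj < ny:
                c = max(cost, F[ni, nj])
                if c < best[ni, nj]:
                    best[ni, nj] = c
                    heapq.heappush(pq, (c, (ni, nj)))
    raise ValueError("basin not reachable on the grid")
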