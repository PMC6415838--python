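"""Synthetic 3D angiogram phantoms with exact ground truth.

The generator emulates the statistical structure of in-vivo multiphoton
angiograms: bright tubular vessels (labeled blood plasma) on a dark tissue
background, dark intraluminal streaks where unlabeled red blood cells
displace the dye, image contrast that decays with imaging depth, and
per-slice in-plane motion jitter from respiration/heartbeat.

Vessels are swept spheres along smooth random curves with bounded curvature
(a straight chord plus a windowed sinusoidal perpendicular perturbation), so
centerline paths, radii, lengths and end-to-end distances are known
analytically and every downstream stage can be validated without real data.

Intensity model: background 0.1, vessel lumen 0.9 on a 0-1 scale, matching
the post-normalization range the CNN consumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .core import (
    CenterlineGraph,
    GraphEdge,
    GraphNode,
    ImageStack,
    SliceDeformation,
    Spacing,
    VesselSegment,
)

BACKGROUND_INTENSITY = 0.1
VESSEL_INTENSITY = 0.9
SHADOW_INTENSITY = 0.3
_CURVE_STEP_UM = 0.3  # arc-length sampling step for rasterization


@dataclass
class PhantomSpec:
    """Study conditions for one synthetic angiogram.

    Parameters
    ----------
    volume_shape
        ``(z, y, x)`` voxel counts, each >= 16.
    voxel_size_um
        Voxel spacing in micrometres.
    n_vessels
        Number of non-touching tubes to generate.
    radius_range_um
        Uniform sampling range of per-vessel radii.
    tortuosity_amplitude_um
        Peak perpendicular deviation of the centerline from its chord; 0
        gives perfectly straight vessels.
    rbc_shadow_density
        Expected red-blood-cell shadows per 100 um of centerline.
    noise_sigma
        Additive Gaussian noise standard deviation (intensity units).
    snr_decay_length_um
        Depth at which foreground/background contrast halves; ``inf``
        disables depth decay.
    motion_max_shift_px
        Bound on per-slice in-plane displacement magnitude.
    seed
        Master RNG seed; the whole phantom is a pure function of the spec.
    """

    volume_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_um: Spacing = (1.0, 1.0, 1.0)
    n_vessels: int = 5
    radius_range_um: tuple[float, float] = (2.0, 5.0)
    tortuosity_amplitude_um: float = 3.0
    rbc_shadow_density: float = 2.0
    noise_sigma: float = 0.05
    snr_decay_length_um: float = 150.0
    motion_max_shift_px: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_range_um[0] <= 0:
            raise ValueError("minimum vessel radius must be positive")
        if self.n_vessels < 0 or self.rbc_shadow_density < 0 or self.motion_max_shift_px < 0:
            raise ValueError("counts and densities must be non-negative")
        if any(s < 16 for s in self.volume_shape):
            raise ValueError("volume_shape entries must all be >= 16")


@dataclass
class PhantomOutput:
    """A phantom plus its exact ground truth."""

    image: ImageStack
    truth_mask: np.ndarray  # uint8 {0,1}, same grid as image
    truth_centerlines: CenterlineGraph
    truth_segments: list[VesselSegment]
    meta: dict = field(default_factory=dict)

    def copy(self) -> "PhantomOutput":
        return PhantomOutput(
            image=self.image.copy(),
            truth_mask=self.truth_mask.copy(),
            truth_centerlines=self.truth_centerlines,
            truth_segments=list(self.truth_segments),
            meta=dict(self.meta),
        )


# ---------------------------------------------------------------------------
# curve construction


def _perpendicular_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(u, helper)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return v, w


def _sample_curve(a: np.ndarray, b: np.ndarray, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Dense (n, 3) polyline in um from ``a`` to ``b`` (z, y, x order)."""
    chord = b - a
    dist = float(np.linalg.norm(chord))
    n = max(2, int(np.ceil(dist / _CURVE_STEP_UM)) + 1)
    t = np.linspace(0.0, 1.0, n)
    pts = a[None, :] + t[:, None] * chord[None, :]
    if amplitude > 0:
        u = chord / dist
        v, w = _perpendicular_basis(u)
        freq = rng.uniform(1.0, 2.0)
        phase_v, phase_w = rng.uniform(0, 2 * np.pi, size=2)
        amp = amplitude * rng.uniform(0.6, 1.0)
        envelope = np.sin(np.pi * t)  # endpoints stay fixed
        pts = (
            pts
            + (amp * envelope * np.sin(2 * np.pi * freq * t + phase_v))[:, None] * v[None, :]
            + (amp * envelope * np.sin(2 * np.pi * freq * t + phase_w))[:, None] * w[None, :]
        )
    return pts


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# rasterization


def _stamp_tube(mask: np.ndarray, pts_um: np.ndarray, radius_um: float, spacing: Spacing) -> None:
    """Mark voxels whose centers lie within ``radius_um`` of the polyline."""
    sp = np.asarray(spacing)
    shape = np.asarray(mask.shape)
    lo = np.maximum(np.floor((pts_um.min(axis=0) - radius_um) / sp - 1), 0).astype(int)
    hi = np.minimum(np.ceil((pts_um.max(axis=0) + radius_um) / sp + 1), shape - 1).astype(int)
    grids = np.meshgrid(*[np.arange(l, h + 1) for l, h in zip(lo, hi)], indexing="ij")
    centers = np.stack([g.ravel() * s for g, s in zip(grids, sp)], axis=1)
    tree = cKDTree(pts_um)
    d, _ = tree.query(centers, k=1)
    inside = d <= radius_um
    idx = tuple(g.ravel()[inside] for g in grids)
    mask[idx] = 1


def _polyline_to_voxel_path(pts_um: np.ndarray, spacing: Spacing, shape) -> np.ndarray:
    vox = np.round(pts_um / np.asarray(spacing)).astype(np.int64)
    vox = np.clip(vox, 0, np.asarray(shape) - 1)
    keep = np.ones(len(vox), dtype=bool)
    keep[1:] = np.any(np.diff(vox, axis=0) != 0, axis=1)
    return vox[keep]


def generate_from_polylines(
    polylines_um: list[np.ndarray],
    radii_um: list[float],
    volume_shape: tuple[int, int, int],
    voxel_size_um: Spacing = (1.0, 1.0, 1.0),
) -> PhantomOutput:
    """Rasterize explicit centerline polylines (um coordinates) into a phantom.

    The workhorse behind :func:`generate_tube_network` and the canonical
    test fixtures (Y junction, loop, gapped tube).
    """
    mask = np.zeros(volume_shape, dtype=np.uint8)
    nodes: dict[int, GraphNode] = {}
    edges: list[GraphEdge] = []
    segments: list[VesselSegment] = []
    for i, (pts, r) in enumerate(zip(polylines_um, radii_um)):
        pts = np.asarray(pts, dtype=float).reshape(-1, 3)
        _stamp_tube(mask, pts, float(r), voxel_size_um)
        path = _polyline_to_voxel_path(pts, voxel_size_um, volume_shape)
        closed = np.array_equal(path[0], path[-1]) and len(path) > 1
        n0, n1 = 2 * i, 2 * i + 1
        nodes[n0] = GraphNode(id=n0, coordinate=tuple(path[0]), kind="loop" if closed else "endpoint")
        if closed:
            edges.append(GraphEdge(id=i, path=path, u=n0, v=n0))
        else:
            nodes[n1] = GraphNode(id=n1, coordinate=tuple(path[-1]), kind="endpoint")
            edges.append(GraphEdge(id=i, path=path, u=n0, v=n1))
        straight = _is_straight(pts)
        end_to_end = float(np.linalg.norm(pts[-1] - pts[0]))
        length = end_to_end if straight else _polyline_length(pts)
        tort = 1.0 if straight else (length / end_to_end if end_to_end > 0 else float("nan"))
        segments.append(
            VesselSegment(
                edge_id=i,
                path=path,
                length_um=length,
                diameter_um=2.0 * float(r),
                tortuosity=tort,
                endpoints=(tuple(path[0]), tuple(path[-1])),
            )
        )
    image = np.full(volume_shape, BACKGROUND_INTENSITY, dtype=np.float32)
    image[mask == 1] = VESSEL_INTENSITY
    graph = CenterlineGraph(nodes=nodes, edges=edges, voxel_size_um=voxel_size_um)
    return PhantomOutput(
        image=ImageStack(image, voxel_size_um),
        truth_mask=mask,
        truth_centerlines=graph,
        truth_segments=segments,
        meta={"curves_um": [np.asarray(p, dtype=float) for p in polylines_um],
              "radii_um": [float(r) for r in radii_um],
              "n_shadows": 0},
    )


def _is_straight(pts: np.ndarray, tol: float = 1e-9) -> bool:
    if len(pts) < 3:
        return True
    chord = pts[-1] - pts[0]
    d = np.linalg.norm(chord)
    if d == 0:
        return False
    rel = pts - pts[0]
    cross = np.cross(rel, chord / d)
    return bool(np.max(np.linalg.norm(cross, axis=1)) < tol)


# ---------------------------------------------------------------------------
# main generator


def generate_tube_network(spec: PhantomSpec) -> PhantomOutput:
    """Generate a clean (noise-free, motion-free) random tube network.

    Vessels are placed by rejection sampling so that no two tubes come
    within 1 um of touching; the analytic ground truth (centerline graph,
    per-vessel radius/length/tortuosity) therefore stays valid.
    """
    rng = np.random.default_rng([spec.seed, 1])
    sp = np.asarray(spec.voxel_size_um)
    extent = (np.asarray(spec.volume_shape) - 1) * sp
    r_min, r_max = spec.radius_range_um
    margin = r_min + 1.0
    if np.any(extent <= 2 * margin + 2.0):
        raise ValueError(
            f"volume extent {tuple(extent)} um too small to contain a tube of radius {r_min} um"
        )

    polylines: list[np.ndarray] = []
    radii: list[float] = []
    trees: list[cKDTree] = []
    attempts = 0
    while len(polylines) < spec.n_vessels:
        attempts += 1
        if attempts > 200 * max(1, spec.n_vessels):
            raise RuntimeError(
                f"could not place {spec.n_vessels} non-touching vessels in this volume"
            )
        r = float(rng.uniform(r_min, r_max))
        m = r + 1.0 + spec.tortuosity_amplitude_um
        lo = np.minimum(m, extent / 2 - 1)
        a = rng.uniform(lo, extent - lo)
        b = rng.uniform(lo, extent - lo)
        if np.linalg.norm(b - a) < 0.5 * extent.min():
            continue
        pts = _sample_curve(a, b, spec.tortuosity_amplitude_um, rng)
        ok = True
        for tree, r_old in zip(trees, radii):
            d = tree.query(pts, k=1)[0].min()
            # surfaces at least 2 um apart: rasterized tubes can touch
            # diagonally (sqrt(3) voxel) at smaller clearances
            if d <= r + r_old + 2.0:
                ok = False
                break
        if not ok:
            continue
        polylines.append(pts)
        radii.append(r)
        trees.append(cKDTree(pts))

    out = generate_from_polylines(polylines, radii, spec.volume_shape, spec.voxel_size_um)
    out.meta["spec"] = dataclasses.asdict(spec)
    return out


# ---------------------------------------------------------------------------
# degradation operators


def add_rbc_shadows(out: PhantomOutput, spec: PhantomSpec) -> PhantomOutput:
    """Place dark ellipsoidal voids (unlabeled red blood cells) inside lumina.

    Shadow centers are Poisson-sampled along the centerlines at
    ``spec.rbc_shadow_density`` per 100 um.  The truth mask is untouched:
    shadowed voxels are still lumen.
    """
    out = out.copy()
    rng = np.random.default_rng([spec.seed, 2])
    curves = out.meta["curves_um"]
    radii = out.meta["radii_um"]
    lengths = np.array([_polyline_length(np.asarray(c)) for c in curves])
    total = lengths.sum()
    if spec.rbc_shadow_density == 0 or total == 0:
        out.meta["n_shadows"] = 0
        return out
    n_shadows = int(rng.poisson(spec.rbc_shadow_density * total / 100.0))
    sp = np.asarray(out.image.voxel_size_um)
    img = out.image.data
    mask = out.truth_mask
    shape = np.asarray(mask.shape)
    probs = lengths / total
    for _ in range(n_shadows):
        ci = int(rng.choice(len(curves), p=probs))
        pts = np.asarray(curves[ci])
        j = int(rng.integers(1, len(pts) - 1)) if len(pts) > 2 else 0
        c = pts[j]
        tangent = pts[min(j + 1, len(pts) - 1)] - pts[max(j - 1, 0)]
        nrm = np.linalg.norm(tangent)
        tangent = tangent / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
        a_par = float(rng.uniform(2.0, 4.0))  # streak half-length, um
        b_perp = max(0.5, 0.75 * radii[ci])
        lo = np.maximum(np.floor((c - a_par) / sp).astype(int), 0)
        hi = np.minimum(np.ceil((c + a_par) / sp).astype(int), shape - 1)
        grids = np.meshgrid(*[np.arange(l, h + 1) for l, h in zip(lo, hi)], indexing="ij")
        centers = np.stack([g.ravel() * s for g, s in zip(grids, sp)], axis=1)
        rel = centers - c
        d_par = rel @ tangent
        d_perp_sq = np.maximum(np.einsum("ij,ij->i", rel, rel) - d_par**2, 0.0)
        inside = (d_par / a_par) ** 2 + d_perp_sq / b_perp**2 <= 1.0
        idx = tuple(g.ravel()[inside] for g in grids)
        lumen = mask[idx] == 1
        idx = tuple(i[lumen] for i in idx)
        img[idx] = np.minimum(img[idx], SHADOW_INTENSITY)
    out.meta["n_shadows"] = n_shadows
    return out


def add_noise_and_depth_decay(out: PhantomOutput, spec: PhantomSpec) -> PhantomOutput:
    """Depth-dependent contrast loss plus additive Gaussian noise.

    Foreground/background contrast is multiplied by ``0.5 ** (depth /
    snr_decay_length_um)`` so that it halves exactly at the stated decay
    length; noise is then added and intensities clipped to [0, 1].
    """
    if spec.noise_sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    out = out.copy()
    img = out.image.data
    dz = out.image.voxel_size_um[0]
    changed = False
    if np.isfinite(spec.snr_decay_length_um):
        depth = np.arange(img.shape[0]) * dz
        factor = (0.5 ** (depth / spec.snr_decay_length_um)).astype(img.dtype)
        img[...] = BACKGROUND_INTENSITY + (img - BACKGROUND_INTENSITY) * factor[:, None, None]
        changed = True
    if spec.noise_sigma > 0:
        rng = np.random.default_rng([spec.seed, 3])
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape).astype(img.dtype)
        changed = True
    if changed:
        np.clip(img, 0.0, 1.0, out=img)
    return out


def add_slice_motion(
    out: PhantomOutput, spec: PhantomSpec, shifts: np.ndarray | None = None
) -> PhantomOutput:
    """Warp each z-slice by a random in-plane translation (smooth in-plane).

    Each slice is acquired at a different time, so jitter is drawn
    independently per slice (Gaussian, rescaled so the largest magnitude
    equals ``motion_max_shift_px``); slice 0 stays fixed.  Pass ``shifts``
    (``(Z, 2)``, (dy, dx) pixels) to impose a known profile.  The applied
    displacement fields are stored in ``meta["motion"]`` so registration
    recovery is testable.
    """
    out = out.copy()
    img = out.image.data
    nz, ny, nx = img.shape
    if shifts is None:
        if spec.motion_max_shift_px == 0:
            shifts = np.zeros((nz, 2))
        else:
            rng = np.random.default_rng([spec.seed, 4])
            shifts = rng.standard_normal((nz, 2))
            shifts[0] = 0.0
            mag = np.linalg.norm(shifts, axis=1).max()
            if mag > 0:
                shifts *= spec.motion_max_shift_px / mag
    shifts = np.asarray(shifts, dtype=np.float64)
    fields = np.zeros((nz, 2, ny, nx), dtype=np.float32)
    fields[:, 0] = shifts[:, 0, None, None]
    fields[:, 1] = shifts[:, 1, None, None]
    yy, xx = np.meshgrid(np.arange(ny, dtype=np.float64), np.arange(nx, dtype=np.float64), indexing="ij")
    for z in range(nz):
        if shifts[z, 0] == 0 and shifts[z, 1] == 0:
            continue
        img[z] = map_coordinates(
            img[z], [yy + shifts[z, 0], xx + shifts[z, 1]], order=1, mode="nearest"
        )
    out.meta["motion"] = SliceDeformation(fields)
    out.meta["motion_shifts"] = shifts
    return out


# ---------------------------------------------------------------------------
# canonical fixture phantoms


def penetrating_vessel_phantom(
    shape=(32, 64, 64),
    n_vessels: int = 4,
    radius_range_um: tuple[float, float] = (2.0, 4.0),
    seed: int = 0,
) -> PhantomOutput:
    """Vessels diving through the stack roughly along z (depth).

    Mimics penetrating cortical vessels.  Because each vessel crosses every
    slice almost perpendicularly, consecutive slices are nearly identical,
    which makes this the fixture of choice for motion-correction recovery:
    adjacent-slice differences are dominated by the injected jitter rather
    than by anatomy.
    """
    rng = np.random.default_rng([seed, 5])
    nz, ny, nx = shape
    polylines = []
    radii = []
    attempts = 0
    while len(polylines) < n_vessels and attempts < 200:
        attempts += 1
        r = float(rng.uniform(*radius_range_um))
        m = r + 3.0
        y0, x0 = rng.uniform([m, m], [ny - 1 - m, nx - 1 - m])
        drift = rng.uniform(-6.0, 6.0, size=2)  # gentle lateral drift, um
        y1 = np.clip(y0 + drift[0], m, ny - 1 - m)
        x1 = np.clip(x0 + drift[1], m, nx - 1 - m)
        pts = np.linspace([0.0, y0, x0], [float(nz - 1), y1, x1], 4 * nz)
        ok = all(
            cKDTree(p).query(pts, k=1)[0].min() > r + rr + 2.0
            for p, rr in zip(polylines, radii)
        )
        if ok:
            polylines.append(pts)
            radii.append(r)
    return generate_from_polylines(polylines, radii, shape)


def straight_tube_phantom(
    shape=(32, 32, 96), radius_um: float = 3.0, voxel_size_um: Spacing = (1.0, 1.0, 1.0)
) -> PhantomOutput:
    """A single straight x-aligned tube through the volume center.

    The axis passes through integer voxel centers so the rasterized
    centerline lies exactly on it.
    """
    z0, y0 = float(shape[0] // 2), float(shape[1] // 2)
    sp = np.asarray(voxel_size_um)
    a = np.array([z0 * sp[0], y0 * sp[1], (radius_um + 2) * 1.0])
    b = np.array([z0 * sp[0], y0 * sp[1], ((shape[2] - 1) * sp[2]) - (radius_um + 2)])
    pts = np.linspace(a, b, int(np.ceil(np.linalg.norm(b - a) / _CURVE_STEP_UM)) + 1)
    return generate_from_polylines([pts], [radius_um], shape, voxel_size_um)


def y_junction_phantom(shape=(32, 64, 64), radius_um: float = 2.5) -> PhantomOutput:
    """Three straight branches meeting at one bifurcation."""
    z0 = float(shape[0] // 2)
    c = np.array([z0, shape[1] / 2.0, shape[2] / 2.0])
    tips = [
        np.array([z0, 6.0, shape[2] / 2.0]),
        np.array([z0, shape[1] - 7.0, 8.0]),
        np.array([z0, shape[1] - 7.0, shape[2] - 9.0]),
    ]
    lines = [np.linspace(t, c, 120) for t in tips]
    return generate_from_polylines(lines, [radius_um] * 3, shape)


def gapped_tube_phantom(shape=(32, 32, 96), radius_um: float = 3.0, gap_px: int = 2) -> PhantomOutput:
    """Two collinear tube fragments separated by a small gap (RBC-shadow
    artifact).  ``gap_px`` counts the background voxels between the two
    fragment surfaces; gaps up to twice the centerline-mask dilation radius
    can be healed by connectivity repair."""
    z0, y0 = float(shape[0] // 2), float(shape[1] // 2)
    mid = shape[2] / 2.0
    a1 = np.array([z0, y0, radius_um + 2])
    b1 = np.array([z0, y0, mid - gap_px / 2.0 - radius_um])
    a2 = np.array([z0, y0, mid + gap_px / 2.0 + radius_um])
    b2 = np.array([z0, y0, shape[2] - 1.0 - radius_um - 2])
    l1 = np.linspace(a1, b1, 200)
    l2 = np.linspace(a2, b2, 200)
    return generate_from_polylines([l1, l2], [radius_um] * 2, shape)


def loop_phantom(shape=(24, 64, 64), radius_um: float = 2.5, ring_radius_um: float = 20.0) -> PhantomOutput:
    """A solid ring (torus) in one z-plane."""
    z0 = float(shape[0] // 2)
    c = np.array([z0, float(shape[1] // 2), float(shape[2] // 2)])
    theta = np.linspace(0, 2 * np.pi, 400)
    pts = np.stack(
        [np.full_like(theta, c[0]), c[1] + ring_radius_um * np.cos(theta), c[2] + ring_radius_um * np.sin(theta)],
        axis=1,
    )
    return generate_from_polylines([pts], [radius_um], shape)
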