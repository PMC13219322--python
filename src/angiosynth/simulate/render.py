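"""Rendering of vessel trees into subtracted-angiography-like frame stacks.

Convention: vessels are dark structures on a light background (the clinical
subtracted-image display). An ``invert`` flag flips this. 3d mode projects
the unit-cube tree orthographically while rotating it about the vertical
axis, one angle per frame, spanning 0-180 degrees uniformly.
"""

from __future__ import annotations

import numpy as np
from scipy import interpolate as _interp
from scipy import ndimage as _ndi

from angiosynth.simulate.tree import VesselTree
from angiosynth.types import FrameSequence, GroundTruth

#: maximum darkness a fully opacified large vessel subtracts from the background
VESSEL_STRENGTH = 0.62
WIRE_STRENGTH = 0.55
MASK_THRESHOLD = 0.03


def project_point(p: np.ndarray, angle_deg: float, resolution: int) -> np.ndarray:
    """Orthographic projection of a unit-cube point at a C-arm angle.

    Rotation is about the vertical axis through the cube centre. Returns
    (row, col) in pixel coordinates.
    """
    p = np.asarray(p, dtype=np.float64)
    th = np.deg2rad(angle_deg)
    x = (p[..., 0] - 0.5) * np.cos(th) + (p[..., 2] - 0.5) * np.sin(th) + 0.5
    row = (1.0 - p[..., 1]) * (resolution - 1)
    col = x * (resolution - 1)
    return np.stack([row, col], axis=-1)


def _draw_capsule(canvas: np.ndarray, p0, p1, radius: float, amount: float) -> None:
    """Additively draw an anti-aliased thick line segment (in place)."""
    if amount <= 0:
        return
    h, w = canvas.shape
    r0, c0 = p0
    r1, c1 = p1
    margin = radius + 1.5
    rmin = max(int(np.floor(min(r0, r1) - margin)), 0)
    rmax = min(int(np.ceil(max(r0, r1) + margin)) + 1, h)
    cmin = max(int(np.floor(min(c0, c1) - margin)), 0)
    cmax = min(int(np.ceil(max(c0, c1) + margin)) + 1, w)
    if rmin >= rmax or cmin >= cmax:
        return
    rr, cc = np.meshgrid(
        np.arange(rmin, rmax, dtype=np.float64),
        np.arange(cmin, cmax, dtype=np.float64),
        indexing="ij",
    )
    dr, dc = r1 - r0, c1 - c0
    seg_len2 = dr * dr + dc * dc
    if seg_len2 < 1e-12:
        t = np.zeros_like(rr)
    else:
        t = np.clip(((rr - r0) * dr + (cc - c0) * dc) / seg_len2, 0.0, 1.0)
    dist = np.hypot(rr - (r0 + t * dr), cc - (c0 + t * dc))
    profile = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    canvas[rmin:rmax, cmin:cmax] += amount * profile


def _vessel_layer(
    tree: VesselTree,
    opacity_t: np.ndarray,
    angle_deg: float,
    resolution: int,
) -> np.ndarray:
    """Noise-free darkness layer contributed by the vessels at one frame."""
    layer = np.zeros((resolution, resolution))
    scale = resolution / tree.domain_px
    for i, seg in enumerate(tree.segments):
        op = float(opacity_t[i])
        if op <= 1e-4:
            continue
        p0 = project_point(seg.start, angle_deg, resolution)
        p1 = project_point(seg.end, angle_deg, resolution)
        # thicker vessels attenuate more
        depth = min(1.0, 0.55 + 0.15 * seg.radius)
        _draw_capsule(layer, p0, p1, seg.radius * scale, op * VESSEL_STRENGTH * depth)
    if tree.aneurysm is not None:
        centre, radius_px, host = tree.aneurysm
        op = float(opacity_t[host])
        if op > 1e-4:
            p = project_point(centre, angle_deg, resolution)
            _draw_capsule(layer, p, p, radius_px * scale, op * VESSEL_STRENGTH)
    return np.minimum(layer, 0.95)


def _make_wire_path(rng: np.random.Generator, resolution: int) -> np.ndarray:
    """Dense polyline (row, col) of a guidewire entering from the bottom edge."""
    n_ctrl = 5
    cols = np.empty(n_ctrl)
    rows = np.linspace(resolution - 1, resolution * 0.18, n_ctrl)
    cols[0] = resolution * rng.uniform(0.35, 0.65)
    for i in range(1, n_ctrl):
        cols[i] = np.clip(
            cols[i - 1] + resolution * rng.uniform(-0.14, 0.14),
            resolution * 0.12,
            resolution * 0.88,
        )
    u = np.linspace(0, 1, n_ctrl)
    spl_r = _interp.CubicSpline(u, rows)
    spl_c = _interp.CubicSpline(u, cols)
    uu = np.linspace(0, 1, 600)
    return np.stack([spl_r(uu), spl_c(uu)], axis=1)


def _wire_layer(path: np.ndarray, arc: np.ndarray, s_end: float, radius: float, shape):
    layer = np.zeros(shape)
    idx = int(np.searchsorted(arc, s_end))
    idx = max(2, min(idx, len(path) - 1))
    pts = path[:idx]
    step = max(1, len(pts) // 220)
    for k in range(0, len(pts) - 1, step):
        _draw_capsule(layer, pts[k], pts[min(k + step, len(pts) - 1)], radius, 1.0)
    tip = path[idx - 1]
    return np.minimum(layer, 1.0) * WIRE_STRENGTH, tip


def render_sequence(
    tree: VesselTree,
    opacity: np.ndarray,
    n_frames: int,
    mode: str = "2d",
    resolution: int = 128,
    guidewire: bool = False,
    seed: int = 0,
    noise_sigma: float = 0.008,
    invert: bool = False,
) -> tuple[FrameSequence, GroundTruth]:
    """Render a tree + bolus into a frame sequence with full ground truth.

    ``opacity`` is the (n_segments, n_frames) array from ``simulate_bolus``.
    In 3d mode the per-frame C-arm angle spans [0, 180] uniformly. TIC probe
    series are recorded noise-free; in 3d mode the probe follows the moving
    projection of its segment (the stored pixel is the frame-0 position).
    """
    if resolution < 32:
        raise ValueError("resolution must be >= 32")
    if opacity.shape != (tree.n_segments, n_frames):
        raise ValueError("opacity must have shape (n_segments, n_frames)")
    if mode not in ("2d", "3d"):
        raise ValueError("mode must be '2d' or '3d'")

    rng = np.random.default_rng(seed)
    if mode == "3d":
        angles = 180.0 * np.arange(n_frames) / (n_frames - 1)
    else:
        angles = np.zeros(n_frames)

    # static smooth background field
    coarse = rng.normal(0, 1, size=(6, 6))
    bg_field = _ndi.zoom(coarse, resolution / 6.0, order=3)[:resolution, :resolution]
    if bg_field.shape != (resolution, resolution):
        bg_field = np.pad(
            bg_field,
            ((0, resolution - bg_field.shape[0]), (0, resolution - bg_field.shape[1])),
            mode="edge",
        )
    background = 0.88 + 0.04 * bg_field / max(np.abs(bg_field).max(), 1e-9)

    wire_path = arc = None
    wire_radius = max(1.0, resolution / 128.0)
    if guidewire:
        wire_path = _make_wire_path(rng, resolution)
        steps = np.linalg.norm(np.diff(wire_path, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(steps)])

    probes = _pick_probe_segments(tree)
    probe_px = [
        np.round(project_point(0.5 * (tree.segments[i].start + tree.segments[i].end), angles[0], resolution)).astype(int)
        for i in probes
    ]
    probe_series = np.zeros((len(probes), n_frames))

    frames = np.empty((n_frames, resolution, resolution))
    masks = np.zeros((n_frames, resolution, resolution), dtype=bool)
    tips = np.zeros((n_frames, 2)) if guidewire else None

    for t in range(n_frames):
        vessels = _vessel_layer(tree, opacity[:, t], angles[t], resolution)
        masks[t] = vessels > MASK_THRESHOLD
        dark = vessels.copy()
        if guidewire:
            s_end = arc[-1] * (0.25 + 0.70 * t / max(n_frames - 1, 1))
            wl, tip = _wire_layer(wire_path, arc, s_end, wire_radius, vessels.shape)
            dark = np.maximum(dark, wl)
            tips[t] = np.clip(tip, 0, resolution - 1)
        for k, i in enumerate(probes):
            mid = 0.5 * (tree.segments[i].start + tree.segments[i].end)
            pr, pc = np.round(project_point(mid, angles[t], resolution)).astype(int)
            pr = int(np.clip(pr, 0, resolution - 1))
            pc = int(np.clip(pc, 0, resolution - 1))
            probe_series[k, t] = vessels[pr, pc]
        noise = rng.normal(0, noise_sigma, size=vessels.shape)
        img = np.clip(background - dark + noise, 0.02, 1.0)
        frames[t] = 1.0 - img if invert else img

    seq = FrameSequence(
        frames=frames,
        frame_times=np.arange(n_frames, dtype=np.float64),
        mode=mode,
        angles_deg=angles,
        pixel_spacing=0.3 * 128.0 / resolution,
    )
    gt = GroundTruth(
        vessel_mask=masks,
        tic_points=[((int(p[0]), int(p[1])), probe_series[k].copy()) for k, p in enumerate(probe_px)],
        tip_xy=tips,
    )
    gt.validate_against(seq)
    return seq, gt


def _pick_probe_segments(tree: VesselTree) -> list[int]:
    """Stenotic / proximal / distal probe segments (or root / mid / leaf)."""
    if tree.stenotic_idx >= 0:
        i = tree.stenotic_idx
        kids = tree.children_of(i)
        probes = [tree.segments[i].parent, i]
        if kids:
            probes.append(kids[0])
        return probes
    leaves = [i for i in range(tree.n_segments) if not tree.children_of(i)]
    mid = tree.n_segments // 2
    out = [0]
    if mid not in out:
        out.append(mid)
    if leaves and leaves[-1] not in out:
        out.append(leaves[-1])
    return out
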