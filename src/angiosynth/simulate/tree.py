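"""Procedural vascular trees with disease-like morphologies.

Trees are grown inside the unit cube so that rotational (3d) rendering can
project them orthographically at arbitrary C-arm angles. Radii taper from
parent to child by a Murray-law-like factor with jitter; bolus arrival times
accumulate along the path from the root.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MORPHOLOGY_CLASSES = ("normal", "aneurysm", "stenosis", "av_shunt", "collateral_net")

#: parent-to-child radius taper and its jitter half-width
TAPER = 0.79
TAPER_JITTER = 0.10

#: stenotic radius as a fraction of the smaller neighbouring radius
STENOSIS_FACTOR = 0.35


@dataclass
class Segment:
    """One straight vessel segment in unit-cube coordinates."""

    start: np.ndarray  # (3,) in [0, 1]^3
    end: np.ndarray  # (3,)
    radius: float  # rendered half-width in pixels (at the reference resolution)
    parent: int  # index into the segment list, -1 for the root

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))


@dataclass
class VesselTree:
    segments: list[Segment]
    arrival_time: np.ndarray  # per-segment bolus arrival, frame units
    morphology_class: str
    domain_px: int
    stenotic_idx: int = -1
    shunt_idx: int = -1
    aneurysm: tuple | None = None  # ((3,) centre, radius px, host segment index)
    collateral_indices: list[int] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def children_of(self, i: int) -> list[int]:
        return [j for j, s in enumerate(self.segments) if s.parent == i]

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        n = self.n_segments
        if self.morphology_class not in MORPHOLOGY_CLASSES:
            raise ValueError(f"morphology_class must be one of {MORPHOLOGY_CLASSES}")
        roots = [i for i, s in enumerate(self.segments) if s.parent == -1]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        for i, s in enumerate(self.segments):
            if s.radius <= 0:
                raise ValueError(f"segment {i} has non-positive radius")
            if s.parent >= 0:
                if not (0 <= s.parent < n) or s.parent == i:
                    raise ValueError(f"segment {i} has invalid parent {s.parent}")
                p = self.segments[s.parent]
                # a stenotic parent narrows locally; its child recovers calibre
                if s.parent != self.stenotic_idx and s.radius > p.radius + 1e-9:
                    raise ValueError(
                        f"segment {i} radius exceeds its parent's ({s.radius} > {p.radius})"
                    )
                if self.arrival_time[i] < self.arrival_time[s.parent] - 1e-9:
                    raise ValueError(f"arrival_time decreases from {s.parent} to {i}")
        # connectivity: walk up from every node
        for i in range(n):
            seen, j = set(), i
            while j != -1:
                if j in seen:
                    raise ValueError("parent cycle detected")
                seen.add(j)
                j = self.segments[j].parent


def _unit(v: np.ndarray) -> np.ndarray:
    return v / max(np.linalg.norm(v), 1e-12)


def generate_vessel_tree(
    seed: int,
    n_branches: int,
    morphology_class: str = "normal",
    domain_px: int = 128,
) -> VesselTree:
    """Grow a random branching vessel tree.

    Parameters
    ----------
    seed : int
        RNG seed; generation is fully deterministic for a fixed seed.
    n_branches : int
        Minimum number of segments in the grown tree (before morphology
        extras are attached).
    morphology_class : str
        One of ``normal``, ``aneurysm`` (one saccular bulge), ``stenosis``
        (one locally narrowed segment), ``av_shunt`` (one small-calibre
        direct connection between two distal branches), ``collateral_net``
        (a dense fine-radius subnetwork).
    domain_px : int
        Reference resolution; radii are expressed in pixels at this size.
    """
    if morphology_class not in MORPHOLOGY_CLASSES:
        raise ValueError(
            f"unknown morphology class {morphology_class!r}; "
            f"valid classes: {', '.join(MORPHOLOGY_CLASSES)}"
        )
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    if domain_px < 32:
        raise ValueError("domain_px must be >= 32")

    rng = np.random.default_rng(seed)
    root_r = domain_px * 0.022  # ~2.8 px at 128

    segments: list[Segment] = []
    arrivals: list[float] = []

    start = np.array([0.5 + 0.05 * rng.uniform(-1, 1), 0.06, 0.5])
    direction = _unit(np.array([rng.uniform(-0.15, 0.15), 1.0, rng.uniform(-0.15, 0.15)]))
    length = 0.22
    segments.append(Segment(start, start + direction * length, root_r, -1))
    arrivals.append(1.0)

    # frames of bolus travel per unit cube length
    slowness = 10.0

    tips = [0]
    while len(segments) < n_branches:
        ti = int(rng.integers(len(tips)))
        parent = tips.pop(ti)
        p = segments[parent]
        p_dir = _unit(p.end - p.start)
        n_children = 2 if rng.random() < 0.65 else 1
        for _ in range(n_children):
            # deflect the parent direction, keep a mild upward drift
            deflect = rng.normal(0, 0.45, size=3)
            deflect[1] = abs(deflect[1]) * 0.4
            d = _unit(p_dir + deflect)
            ln = max(p.length * rng.uniform(0.65, 0.9), 0.03)
            end = np.clip(p.end + d * ln, 0.04, 0.96)
            taper = TAPER * (1.0 + TAPER_JITTER * rng.uniform(-1, 1))
            r = max(p.radius * min(taper, 1.0), 0.35)
            r = min(r, p.radius)  # child never exceeds its parent
            segments.append(Segment(p.end.copy(), end, r, parent))
            arrivals.append(arrivals[parent] + p.length * slowness)
            tips.append(len(segments) - 1)

    tree = VesselTree(
        segments=segments,
        arrival_time=np.array(arrivals),
        morphology_class=morphology_class,
        domain_px=domain_px,
    )
    _apply_morphology(tree, rng, slowness)
    tree.validate()
    return tree


def _interior_chain_segment(tree: VesselTree, rng: np.random.Generator) -> int:
    """Pick a segment that has both a parent and at least one child."""
    candidates = [
        i
        for i, s in enumerate(tree.segments)
        if s.parent >= 0 and tree.children_of(i)
    ]
    if not candidates:  # fall back to the root's first child
        candidates = [i for i, s in enumerate(tree.segments) if s.parent == 0] or [0]
    return int(rng.choice(candidates))


def _apply_morphology(tree: VesselTree, rng: np.random.Generator, slowness: float) -> None:
    cls = tree.morphology_class
    if cls == "normal":
        return

    if cls == "stenosis":
        i = _interior_chain_segment(tree, rng)
        kids = tree.children_of(i)
        neighbour_r = [tree.segments[tree.segments[i].parent].radius]
        neighbour_r += [tree.segments[k].radius for k in kids]
        tree.segments[i].radius = STENOSIS_FACTOR * min(neighbour_r)
        tree.stenotic_idx = i
        return

    if cls == "aneurysm":
        i = _interior_chain_segment(tree, rng)
        s = tree.segments[i]
        mid = 0.5 * (s.start + s.end)
        offset = _unit(np.cross(s.end - s.start, np.array([0.0, 0.0, 1.0])))
        centre = np.clip(mid + offset * 0.015, 0.04, 0.96)
        tree.aneurysm = (centre, s.radius * 2.6, i)
        return

    if cls == "av_shunt":
        leaves = [i for i in range(tree.n_segments) if not tree.children_of(i)]
        if len(leaves) < 2:
            leaves = list(range(tree.n_segments))
        a = int(rng.choice(leaves))
        ends = np.array([tree.segments[j].end for j in leaves])
        dists = np.linalg.norm(ends - tree.segments[a].end, axis=1)
        b = leaves[int(np.argmax(dists))]
        sa, sb = tree.segments[a], tree.segments[b]
        r = max(0.3 * min(sa.radius, sb.radius), 0.3)
        tree.segments.append(Segment(sa.end.copy(), sb.end.copy(), r, a))
        new_len = tree.segments[-1].length
        tree.arrival_time = np.append(
            tree.arrival_time, tree.arrival_time[a] + new_len * slowness * 0.5
        )
        tree.shunt_idx = tree.n_segments - 1
        return

    if cls == "collateral_net":
        i = _interior_chain_segment(tree, rng)
        anchor = tree.segments[i]
        base = anchor.end
        n_fine = 12
        prev = i
        prev_pt = base
        for k in range(n_fine):
            if k > 0 and rng.random() < 0.4:
                prev = int(rng.choice(tree.collateral_indices))
                prev_pt = tree.segments[prev].end
            d = _unit(rng.normal(0, 1, size=3))
            end = np.clip(prev_pt + d * rng.uniform(0.02, 0.05), 0.04, 0.96)
            r = min(max(0.35, anchor.radius * 0.2), tree.segments[prev].radius)
            tree.segments.append(Segment(prev_pt.copy(), end, r, prev))
            tree.arrival_time = np.append(
                tree.arrival_time,
                tree.arrival_time[prev] + tree.segments[-1].length * slowness,
            )
            tree.collateral_indices.append(tree.n_segments - 1)
            prev = tree.n_segments - 1
            prev_pt = end
        return
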