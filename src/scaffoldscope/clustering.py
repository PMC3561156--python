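"""Maxmin clustering of scaffolds and frequency-weighted treemap layout.

Clustering operates on the *unique* scaffold set.  The number of centers is
``ceil(N / target_avg_size)`` (default target 50 scaffolds per cluster).
The first center is drawn uniformly under the seed; each further center is
the scaffold maximizing the minimum Tanimoto *distance* (1 - similarity) to
all centers chosen so far, ties broken by canonical-SMILES order.  Every
non-center joins its nearest center, ties toward the lower cluster number,
so a rerun with the same seed is bit-reproducible.

The treemap is a squarified-rectangle layout: one outer region per cluster
sized by its summed member frequency, tiled inside by one region per
scaffold sized by its own frequency.  Rectangles (not the circle packs some
tools draw) keep the area-vs-frequency invariant exact and testable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diversity import FrequencyTable
from .similarity import Fingerprint, circular_fingerprint, tanimoto

DEFAULT_TARGET_AVG_SIZE = 50


@dataclass
class ScaffoldAssignment:
    scaffold: str
    cluster_number: int      # 1-based
    is_center: bool
    cluster_size: int
    distance_to_closest: float  # 1 - Tanimoto to own cluster center


@dataclass
class ClusterModel:
    centers: list[str]
    assignments: dict[str, ScaffoldAssignment]
    seed: int

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def members(self, cluster_number: int) -> list[str]:
        return [s for s, a in self.assignments.items() if a.cluster_number == cluster_number]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "scaffold": a.scaffold,
                "cluster_number": a.cluster_number,
                "is_center": int(a.is_center),
                "cluster_size": a.cluster_size,
                "distance_to_closest": a.distance_to_closest,
            }
            for a in sorted(self.assignments.values(), key=lambda a: (a.cluster_number, a.scaffold))
        ]
        return pd.DataFrame(rows)


def cluster_scaffolds(scaffolds: Sequence[str], target_avg_size: int = DEFAULT_TARGET_AVG_SIZE,
                      seed: int = 0, diameter: int = 6) -> ClusterModel:
    """Maxmin-select centers and assign every scaffold to its nearest one."""
    if target_avg_size <= 0:
        raise ValueError("target_avg_size must be positive")
    scaffolds = list(scaffolds)
    n = len(scaffolds)
    if n == 0:
        raise ValueError("cannot cluster an empty scaffold set")
    if len(set(scaffolds)) != n:
        raise ValueError("scaffold set contains duplicates; deduplicate first")
    n_centers = math.ceil(n / target_avg_size)

    fps = [circular_fingerprint(s, diameter) for s in scaffolds]
    rng = np.random.default_rng(seed)
    first = int(rng.integers(n))
    center_idx = [first]
    # min distance of every scaffold to the chosen centers
    min_dist = np.array([1.0 - tanimoto(fp, fps[first]) for fp in fps])
    while len(center_idx) < n_centers:
        chosen = set(center_idx)
        best = None
        for i in range(n):
            if i in chosen:
                continue
            if best is None or min_dist[i] > min_dist[best] or (
                min_dist[i] == min_dist[best] and scaffolds[i] < scaffolds[best]
            ):
                best = i
        center_idx.append(best)
        for i in range(n):
            d = 1.0 - tanimoto(fps[i], fps[best])
            if d < min_dist[i]:
                min_dist[i] = d

    # nearest-center assignment, ties toward the lower cluster number
    cluster_of = np.empty(n, dtype=int)
    dist_own = np.empty(n)
    for i in range(n):
        best_c, best_d = 0, None
        for c, ci in enumerate(center_idx):
            d = 1.0 - tanimoto(fps[i], fps[ci])
            if best_d is None or d < best_d:
                best_c, best_d = c, d
        cluster_of[i] = best_c
        dist_own[i] = best_d
    for c, ci in enumerate(center_idx):
        cluster_of[ci] = c
        dist_own[ci] = 0.0

    sizes = np.bincount(cluster_of, minlength=n_centers)
    assignments = {
        scaffolds[i]: ScaffoldAssignment(
            scaffold=scaffolds[i],
            cluster_number=int(cluster_of[i]) + 1,
            is_center=(i in center_idx) and center_idx[cluster_of[i]] == i,
            cluster_size=int(sizes[cluster_of[i]]),
            distance_to_closest=float(dist_own[i]),
        )
        for i in range(n)
    }
    return ClusterModel(centers=[scaffolds[i] for i in center_idx], assignments=assignments, seed=seed)


# ---------------------------------------------------------------------------
# squarified treemap
# ---------------------------------------------------------------------------

@dataclass
class Region:
    scaffold: Optional[str]
    cluster_number: int
    x: float
    y: float
    w: float
    h: float
    frequency: int
    is_center: bool = False
    distance_to_closest: float = 0.0


@dataclass
class TreemapLayout:
    cluster_regions: list[Region]
    scaffold_regions: list[Region]
    width: float
    height: float

    def to_json(self) -> str:
        payload = [
            {
                "scaffold": r.scaffold,
                "cluster_number": r.cluster_number,
                "is_center": r.is_center,
                "distance_to_closest": r.distance_to_closest,
                "x": r.x, "y": r.y, "w": r.w, "h": r.h,
                "frequency": r.frequency,
            }
            for r in self.scaffold_regions
        ]
        return json.dumps({"width": self.width, "height": self.height,
                           "clusters": [
                               {"cluster_number": r.cluster_number, "x": r.x, "y": r.y,
                                "w": r.w, "h": r.h, "frequency": r.frequency}
                               for r in self.cluster_regions],
                           "scaffolds": payload}, indent=1)


def _squarify(sizes: Sequence[float], x: float, y: float, w: float, h: float) -> list[tuple[float, float, float, float]]:
    """Squarified treemap of ``sizes`` (descending, summing to w*h) in a rect."""
    sizes = list(sizes)
    rects: list[tuple[float, float, float, float]] = []

    def worst(row: list[float], side: float) -> float:
        s = sum(row)
        if s == 0 or side == 0:
            return float("inf")
        mx, mn = max(row), min(row)
        return max(side * side * mx / (s * s), s * s / (side * side * mn))

    def layout_row(row: list[float], x: float, y: float, w: float, h: float):
        s = sum(row)
        if w >= h:  # lay the row along the left edge
            rw = s / h if h > 0 else 0.0
            ry = y
            for sz in row:
                rh = sz / rw if rw > 0 else 0.0
                rects.append((x, ry, rw, rh))
                ry += rh
            return x + rw, y, w - rw, h
        rh = s / w if w > 0 else 0.0
        rx = x
        for sz in row:
            rw2 = sz / rh if rh > 0 else 0.0
            rects.append((rx, y, rw2, rh))
            rx += rw2
        return x, y + rh, w, h - rh

    row: list[float] = []
    i = 0
    while i < len(sizes):
        side = min(w, h)
        if not row or worst(row + [sizes[i]], side) <= worst(row, side):
            row.append(sizes[i])
            i += 1
        else:
            x, y, w, h = layout_row(row, x, y, w, h)
            row = []
    if row:
        x, y, w, h = layout_row(row, x, y, w, h)
    return rects


def layout_treemap(model: ClusterModel, frequencies: FrequencyTable,
                   width: float = 1000.0, height: float = 700.0) -> TreemapLayout:
    """Nested squarified layout: clusters sized by summed member frequency."""
    freq = frequencies.counts
    missing = [s for s in model.assignments if s not in freq]
    if missing:
        raise ValueError(f"{len(missing)} clustered scaffold(s) lack a frequency")
    total = sum(freq[s] for s in model.assignments)
    if total <= 0:
        raise ValueError("zero total frequency")

    cluster_freq: dict[int, int] = {}
    for s, a in model.assignments.items():
        cluster_freq[a.cluster_number] = cluster_freq.get(a.cluster_number, 0) + freq[s]
    # descending by frequency, ties by cluster number
    cluster_order = sorted(cluster_freq, key=lambda c: (-cluster_freq[c], c))
    scale = width * height / total
    outer_sizes = [cluster_freq[c] * scale for c in cluster_order]
    outer_rects = _squarify(outer_sizes, 0.0, 0.0, width, height)

    cluster_regions = []
    scaffold_regions = []
    for c, (x, y, w, h) in zip(cluster_order, outer_rects):
        cluster_regions.append(Region(None, c, x, y, w, h, cluster_freq[c]))
        members = sorted(
            (s for s, a in model.assignments.items() if a.cluster_number == c),
            key=lambda s: (-freq[s], s),
        )
        inner_scale = (w * h) / cluster_freq[c]
        inner = _squarify([freq[s] * inner_scale for s in members], x, y, w, h)
        for s, (ix, iy, iw, ih) in zip(members, inner):
            a = model.assignments[s]
            scaffold_regions.append(
                Region(s, c, ix, iy, iw, ih, freq[s], a.is_center, a.distance_to_closest)
            )
    return TreemapLayout(cluster_regions, scaffold_regions, width, height)


def treemap_svg(layout: TreemapLayout, out_path: str) -> None:
    """Render the layout as a standalone SVG, color encoding log-frequency."""
    max_f = max((r.frequency for r in layout.scaffold_regions), default=1)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{layout.width:.0f}" '
        f'height="{layout.height:.0f}" viewBox="0 0 {layout.width:.2f} {layout.height:.2f}">'
    ]
    for r in layout.scaffold_regions:
        t = math.log1p(r.frequency) / math.log1p(max_f)
        red = int(255 * t)
        blue = int(255 * (1 - t))
        parts.append(
            f'<rect x="{r.x:.2f}" y="{r.y:.2f}" width="{r.w:.2f}" height="{r.h:.2f}" '
            f'fill="rgb({red},80,{blue})" stroke="white" stroke-width="0.5">'
            f"<title>{r.scaffold} (n={r.frequency}, cluster {r.cluster_number})</title></rect>"
        )
    for r in layout.cluster_regions:
        parts.append(
            f'<rect x="{r.x:.2f}" y="{r.y:.2f}" width="{r.w:.2f}" height="{r.h:.2f}" '
            f'fill="none" stroke="gray" stroke-width="2"/>'
        )
    parts.append("</svg>")
    with open(out_path, "w") as fh:
        fh.write("\n".join(parts))


__all__ = [
    "ClusterModel",
    "Region",
    "ScaffoldAssignment",
    "TreemapLayout",
    "cluster_scaffolds",
    "layout_treemap",
    "treemap_svg",
    "DEFAULT_TARGET_AVG_SIZE",
]
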