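"""Segmentation and tracking by 4D connected-component labeling.

A binary (x, y, z, t) stack is partitioned into connected components under
a box neighborhood kernel (default [3,3,3,3]: all 80 offsets with per-axis
magnitude <= 1). One 4D component is one tracked cell: spatial overlap
between consecutive timepoints links detections through time without any
explicit matching step. Components that a low-signal interim timepoint has
split apart can be re-joined by a spatio-temporal merge window, small
components are removed, and per-timepoint cell fates (total / new / lost)
are derived from each component's first and last detection.

Timepoint convention: internal indices are 0-based; reported fate tables
use 1-based timepoints. A cell first detected at (1-based) timepoint t+1 is
counted as *new* at index t, and a cell last detected at t as *lost* at t,
matching the convention that a change is reported at the timepoint
preceding its observation.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# types


@dataclass
class ComponentGraph:
    """Labeled 4D voxel partition: 0 = background, 1..n = components."""

    labels: np.ndarray
    n_components: int
    kernel: tuple[int, int, int, int] = (3, 3, 3, 3)

    @property
    def shape(self):
        return self.labels.shape


@dataclass
class CellComponent:
    """One tracked cell: its voxels, presence span and centroids."""

    cell_id: int
    voxels_by_timepoint: dict  # t (0-based) -> (n, 3) array of (x, y, z)
    present_at: list  # sorted 0-based timepoints with >= 1 voxel
    size_total: int
    centroid_by_timepoint: dict  # t -> (x, y, z) in voxel units
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def first_t(self) -> int:
        return self.present_at[0]

    @property
    def last_t(self) -> int:
        return self.present_at[-1]

    def centroid_um(self, t: int) -> tuple[float, float, float]:
        c = self.centroid_by_timepoint[t]
        return tuple(ci * vi for ci, vi in zip(c, self.voxel_size))

    def depth_um(self) -> float:
        """Depth of the z-centroid at first detection (z index 0 = surface)."""
        return self.centroid_by_timepoint[self.first_t][2] * self.voxel_size[2]


@dataclass
class FateTable:
    """Per-timepoint totals and new/lost counts (arrays of length T)."""

    n_total: np.ndarray
    n_new: np.ndarray
    n_lost: np.ndarray

    @property
    def T(self) -> int:
        return len(self.n_total)

    def validate(self) -> None:
        for t in range(self.T - 1):
            if self.n_total[t + 1] != self.n_total[t] + self.n_new[t] - self.n_lost[t]:
                raise AssertionError(f"fate conservation violated at timepoint {t + 1}")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "timepoint": np.arange(1, self.T + 1),
                "n_total": self.n_total.astype(int),
                "n_new": self.n_new.astype(int),
                "n_lost": self.n_lost.astype(int),
            }
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FateTable)
            and np.array_equal(self.n_total, other.n_total)
            and np.array_equal(self.n_new, other.n_new)
            and np.array_equal(self.n_lost, other.n_lost)
        )


# ---------------------------------------------------------------------------
# labeling


def _validate_odd(extents, name):
    extents = tuple(int(e) for e in extents)
    if any(e < 1 or e % 2 == 0 for e in extents):
        raise ValueError(f"{name} extents must be odd and >= 1, got {extents}")
    return extents


def _relabel_scan_order(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Renumber labels 1..n by lexicographic order of their minimal (t,z,y,x) voxel."""
    flat = np.transpose(labels, (3, 2, 1, 0)).ravel()
    fg = flat[flat > 0]
    if fg.size == 0:
        return np.zeros_like(labels), 0
    uniq, first_idx = np.unique(fg, return_index=True)
    order = np.argsort(first_idx, kind="stable")
    mapping = np.zeros(int(uniq.max()) + 1, dtype=np.int32)
    mapping[uniq[order]] = np.arange(1, len(uniq) + 1, dtype=np.int32)
    return mapping[labels], len(uniq)


def _label_bfs(binary: np.ndarray, halfwidths) -> np.ndarray:
    """Flood-fill labeling for arbitrary odd box kernels (small volumes only)."""
    offsets = [
        (dx, dy, dz, dt)
        for dx in range(-halfwidths[0], halfwidths[0] + 1)
        for dy in range(-halfwidths[1], halfwidths[1] + 1)
        for dz in range(-halfwidths[2], halfwidths[2] + 1)
        for dt in range(-halfwidths[3], halfwidths[3] + 1)
        if (dx, dy, dz, dt) != (0, 0, 0, 0)
    ]
    labels = np.zeros(binary.shape, dtype=np.int32)
    fg = set(map(tuple, np.argwhere(binary)))
    current = 0
    for start in sorted(fg):
        if labels[start]:
            continue
        current += 1
        queue = deque([start])
        labels[start] = current
        while queue:
            v = queue.popleft()
            for off in offsets:
                w = tuple(a + b for a, b in zip(v, off))
                if w in fg and not labels[w]:
                    labels[w] = current
                    queue.append(w)
    return labels


def label_components_4d(binary: np.ndarray, kernel=(3, 3, 3, 3)) -> ComponentGraph:
    """Label 4D connected components under a box neighborhood kernel.

    Two foreground voxels are connected iff every coordinate offset between
    them has magnitude <= the kernel half-extent on that axis (and they are
    not the same voxel). Labels are contiguous positive integers ordered by
    each component's minimal (t, z, y, x) voxel.
    """
    binary = np.asarray(binary)
    if binary.ndim != 4:
        raise ValueError(f"expected 4D (x, y, z, t) input, got ndim={binary.ndim}")
    kernel = _validate_odd(kernel, "kernel")
    mask = binary > 0
    if kernel == (3, 3, 3, 3):
        labels, _ = ndimage.label(mask, structure=np.ones((3,) * 4, dtype=bool))
    else:
        halfwidths = tuple(k // 2 for k in kernel)
        labels = _label_bfs(mask, halfwidths)
    labels, n = _relabel_scan_order(labels)
    return ComponentGraph(labels=labels, n_components=n, kernel=kernel)


# ---------------------------------------------------------------------------
# split-merge


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # attach the larger root id under the smaller for determinism
            if ra < rb:
                self.parent[rb] = ra
            else:
                self.parent[ra] = rb


def merge_split_components(
    graph: ComponentGraph,
    merge_halfwidth: tuple[int, int, int] = (2, 2, 2),
    merge_gap: int = 1,
) -> ComponentGraph:
    """Re-join components split by low-signal interim timepoints.

    Two components merge when some voxel of one lies within the spatial
    window (per-axis half-widths ``merge_halfwidth``) of a voxel of the
    other at timepoints at most ``merge_gap + 1`` apart (a gap of
    ``merge_gap`` undetected frames is bridged). Merging is transitive;
    the result is independent of processing order. With all half-widths 0
    the graph is returned unchanged.
    """
    from scipy.spatial import cKDTree

    hw = tuple(int(h) for h in merge_halfwidth)
    if len(hw) != 3 or any(h < 0 for h in hw):
        raise ValueError(f"merge_halfwidth must be 3 nonnegative ints, got {hw}")
    if merge_gap < 0:
        raise ValueError("merge_gap must be >= 0")
    if graph.n_components == 0 or all(h == 0 for h in hw):
        return ComponentGraph(graph.labels.copy(), graph.n_components, graph.kernel)

    coords = np.argwhere(graph.labels > 0)  # (n, 4) rows (x, y, z, t)
    labs = graph.labels[tuple(coords.T)]
    # scale so the merge condition becomes an inf-norm ball of radius 1
    scale = np.array([h if h >= 1 else 0.5 for h in hw] + [merge_gap + 1], dtype=np.float64)
    scaled = coords / scale

    by_label = {lab: scaled[labs == lab] for lab in range(1, graph.n_components + 1)}
    boxes = {lab: (pts.min(axis=0), pts.max(axis=0)) for lab, pts in by_label.items()}

    uf = _UnionFind(graph.n_components + 1)
    labels_list = sorted(by_label)
    trees = {}
    for i, la in enumerate(labels_list):
        lo_a, hi_a = boxes[la]
        for lb in labels_list[i + 1 :]:
            lo_b, hi_b = boxes[lb]
            if np.any(lo_b > hi_a + 1.0) or np.any(lo_a > hi_b + 1.0):
                continue  # expanded bounding boxes disjoint
            if la not in trees:
                trees[la] = cKDTree(by_label[la])
            d, _ = trees[la].query(
                by_label[lb], k=1, p=np.inf, distance_upper_bound=1.0 + 1e-9
            )
            if np.any(np.isfinite(d)):
                uf.union(la, lb)

    root = np.zeros(graph.n_components + 1, dtype=np.int32)
    for lab in range(1, graph.n_components + 1):
        root[lab] = uf.find(lab)
    merged = root[graph.labels]
    merged, n = _relabel_scan_order(merged)
    return ComponentGraph(labels=merged, n_components=n, kernel=graph.kernel)


# ---------------------------------------------------------------------------
# size filter


def filter_small_components(graph: ComponentGraph, min_size: int = 30) -> ComponentGraph:
    """Remove components with fewer than ``min_size`` voxels (4D node count)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if graph.n_components == 0:
        return ComponentGraph(graph.labels.copy(), 0, graph.kernel)
    sizes = np.bincount(graph.labels.ravel(), minlength=graph.n_components + 1)
    keep = sizes >= min_size
    keep[0] = False
    mapping = np.where(keep, np.arange(len(sizes)), 0).astype(np.int32)
    labels = mapping[graph.labels]
    labels, n = _relabel_scan_order(labels)
    return ComponentGraph(labels=labels, n_components=n, kernel=graph.kernel)


# ---------------------------------------------------------------------------
# cells and fates


def extract_components(
    graph: ComponentGraph, voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> list[CellComponent]:
    """Materialize per-cell voxel sets, presence spans and centroids."""
    cells = []
    coords = np.argwhere(graph.labels > 0)
    labs = graph.labels[tuple(coords.T)]
    for cell_id in range(1, graph.n_components + 1):
        pts = coords[labs == cell_id]
        voxels = {}
        centroids = {}
        for t in np.unique(pts[:, 3]):
            p = pts[pts[:, 3] == t][:, :3]
            voxels[int(t)] = p
            centroids[int(t)] = tuple(p.mean(axis=0))
        present = sorted(voxels)
        cells.append(
            CellComponent(
                cell_id=cell_id,
                voxels_by_timepoint=voxels,
                present_at=present,
                size_total=int(len(pts)),
                centroid_by_timepoint=centroids,
                voxel_size=tuple(voxel_size),
            )
        )
    return cells


def fate_table_from_spans(firsts, lasts, T: int) -> FateTable:
    """Fate counts from (first, last) detection spans (0-based, inclusive).

    A cell counts toward ``n_total(t)`` for every ``first <= t <= last``
    (span-based presence: a gap-merged cell is considered tracked through
    its gap). ``n_new(t)`` counts cells with first detection at t+1 and
    ``n_lost(t)`` cells with last detection at t (t < T-1); both are 0 at
    the final timepoint. This makes the conservation identity
    ``n_total(t+1) = n_total(t) + n_new(t) - n_lost(t)`` an invariant.
    """
    firsts = np.asarray(list(firsts), dtype=int)
    lasts = np.asarray(list(lasts), dtype=int)
    n_total = np.zeros(T, dtype=int)
    n_new = np.zeros(T, dtype=int)
    n_lost = np.zeros(T, dtype=int)
    for f, l in zip(firsts, lasts):
        if not (0 <= f <= l <= T - 1):
            raise ValueError(f"invalid span [{f}, {l}] for T={T}")
        n_total[f : l + 1] += 1
        if f > 0:
            n_new[f - 1] += 1
        if l < T - 1:
            n_lost[l] += 1
    return FateTable(n_total=n_total, n_new=n_new, n_lost=n_lost)


def classify_fates(components: list[CellComponent], T: int) -> FateTable:
    """Per-timepoint totals and new/lost counts of the tracked cells."""
    ft = fate_table_from_spans(
        (c.first_t for c in components), (c.last_t for c in components), T
    )
    ft.validate()
    return ft


def stratify_by_depth(
    components: list[CellComponent],
    bin_edges_um,
    voxel_size: tuple[float, float, float],
    T: int,
) -> dict[str, FateTable]:
    """Per-depth-bin fate tables; depth = z-centroid (um) at first detection.

    ``bin_edges_um`` are ascending edges in micrometres; bins are half-open
    ``[e_i, e_{i+1})``. Cells at or beyond the last edge land in an
    ``overflow`` bin (with a warning); the per-bin tables sum to the
    unstratified table.
    """
    edges = np.asarray(list(bin_edges_um), dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges_um must be >= 2 strictly ascending values")
    names = [f"[{edges[i]:g},{edges[i + 1]:g})" for i in range(len(edges) - 1)]
    binned: dict[str, list] = {name: [] for name in names}
    overflow: list = []
    for c in components:
        depth = c.centroid_by_timepoint[c.first_t][2] * voxel_size[2]
        idx = int(np.searchsorted(edges, depth, side="right")) - 1
        if idx < 0:
            idx = 0  # shallower than the first edge: first bin
        if idx >= len(names):
            logger.warning("cell %d at depth %.1f um beyond last edge; overflow bin", c.cell_id, depth)
            overflow.append(c)
        else:
            binned[names[idx]].append(c)
    tables = {name: classify_fates(cells, T) for name, cells in binned.items()}
    if overflow:
        tables["overflow"] = classify_fates(overflow, T)
    return tables
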