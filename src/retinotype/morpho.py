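"""Dendritic-arbor morphometry on SWC trees and IPL lamination profiles.

Arbors are rooted trees of 3-D nodes with radii, as produced by manual
tracing.  Metrics mirror the standard whole-mount measurements: cumulative
dendritic length, branch structure (branch points, terminals, per-segment
lengths), en-face convex-hull area, and Sholl intersection counts.  Lamination
is summarized from linescans of reporter and reference (e.g. VAChT) intensity
across the inner plexiform layer, expressed as % IPL depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "Arbor",
    "BranchStats",
    "ShollProfile",
    "DepthProfile",
    "SwcError",
    "read_swc",
    "write_swc",
    "total_length",
    "branch_statistics",
    "arbor_area",
    "sholl",
    "ipl_depth_profile",
]


class SwcError(ValueError):
    """Malformed SWC file or arbor topology."""


@dataclass
class Arbor:
    """Rooted neuron morphology.

    ``xyz`` is (n, 3) in µm, ``radius`` (n,) in µm, ``parent`` (n,) holds the
    positional index of each node's parent with −1 for the single root, and
    ``ntype`` carries the SWC structure code (1 = soma, 3 = dendrite, ...).
    """

    xyz: np.ndarray
    radius: np.ndarray
    parent: np.ndarray
    ntype: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        n = len(self.xyz)
        self.radius = np.asarray(self.radius, dtype=float).ravel()
        self.parent = np.asarray(self.parent, dtype=int).ravel()
        if self.ntype is None:
            self.ntype = np.full(n, 3, dtype=int)
            self.ntype[self.parent == -1] = 1
        else:
            self.ntype = np.asarray(self.ntype, dtype=int).ravel()
        if not (len(self.radius) == len(self.parent) == len(self.ntype) == n):
            raise SwcError("node attribute arrays differ in length")
        self._validate()

    def _validate(self) -> None:
        n = len(self.xyz)
        if n == 0:
            raise SwcError("arbor has no nodes")
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise SwcError(f"arbor must have exactly one root, found {len(roots)}")
        if np.any((self.parent < -1) | (self.parent >= n)):
            raise SwcError("parent index out of range")
        # cycle check by walking each node to the root
        state = np.zeros(n, dtype=int)  # 0 unseen, 1 on current path, 2 done
        for start in range(n):
            path = []
            node = start
            while node != -1 and state[node] == 0:
                state[node] = 1
                path.append(node)
                node = self.parent[node]
            if node != -1 and state[node] == 1:
                raise SwcError(f"cycle detected through node index {node}")
            for p in path:
                state[p] = 2

    @property
    def n_nodes(self) -> int:
        return len(self.xyz)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(i)
        return kids

    def edge_lengths(self) -> np.ndarray:
        """Euclidean length of every parent→child edge (child-indexed; root entry 0)."""
        out = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        out[has_parent] = np.linalg.norm(
            self.xyz[has_parent] - self.xyz[self.parent[has_parent]], axis=1
        )
        return out

    def transformed(self, rotation: np.ndarray | None = None, offset=(0, 0, 0)) -> "Arbor":
        xyz = self.xyz @ (rotation.T if rotation is not None else np.eye(3)) + np.asarray(offset, float)
        return Arbor(xyz, self.radius.copy(), self.parent.copy(), self.ntype.copy())


@dataclass
class BranchStats:
    n_branch_points: int
    n_terminals: int
    segment_lengths: np.ndarray


@dataclass
class ShollProfile:
    radius_step: float
    radii: np.ndarray
    intersections: np.ndarray


@dataclass
class DepthProfile:
    """Normalized IPL linescan summary.

    ``depth_pct`` runs 0–100% from the inner nuclear layer border toward the
    ganglion-cell layer.  ``band_depths_pct`` are the two largest reference
    (VAChT) peaks — the S2/S4 cholinergic bands; ``reporter_peak_depths_pct``
    are the reporter channel's peak positions.
    """

    depth_pct: np.ndarray
    reporter: np.ndarray
    reference: np.ndarray
    band_depths_pct: tuple[float, float]
    reporter_peak_depths_pct: np.ndarray


# ---------------------------------------------------------------------- SWC IO

def read_swc(path: str | Path) -> Arbor:
    """Parse whitespace-delimited SWC (7 columns, '#' comments, root parent −1).

    Multi-sample somas (several type-1 nodes attached to the root) are
    collapsed to their centroid.  Cycles and multiple roots are rejected with
    the offending line number.
    """
    path = Path(path)
    ids: list[int] = []
    rows: list[tuple[int, float, float, float, float, int]] = []
    line_of: dict[int, int] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SwcError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        try:
            nid = int(parts[0])
            ntype = int(parts[1])
            x, y, z, r = (float(v) for v in parts[2:6])
            par = int(parts[6])
        except ValueError as exc:
            raise SwcError(f"{path}:{lineno}: {exc}") from None
        if nid in line_of:
            raise SwcError(f"{path}:{lineno}: duplicate node id {nid}")
        line_of[nid] = lineno
        ids.append(nid)
        rows.append((ntype, x, y, z, r, par))

    if not rows:
        raise SwcError(f"{path}: no nodes")
    index_of = {nid: i for i, nid in enumerate(ids)}
    n = len(rows)
    xyz = np.array([[r[1], r[2], r[3]] for r in rows])
    radius = np.array([r[4] for r in rows])
    ntype = np.array([r[0] for r in rows], dtype=int)
    parent = np.empty(n, dtype=int)
    for i, (nid, row) in enumerate(zip(ids, rows)):
        par = row[5]
        if par == -1:
            parent[i] = -1
        elif par in index_of:
            parent[i] = index_of[par]
        else:
            raise SwcError(f"{path}:{line_of[nid]}: node {nid} references missing parent {par}")

    try:
        arbor = Arbor(xyz, radius, parent, ntype)
    except SwcError as exc:
        # attach the file context; name an involved node where we can
        raise SwcError(f"{path}: {exc}") from None
    return _collapse_soma(arbor)


def _collapse_soma(arbor: Arbor) -> Arbor:
    root = arbor.root
    n = arbor.n_nodes
    is_soma = (arbor.ntype == 1) & (
        (arbor.parent == root) | (np.arange(n) == root)
    )
    if is_soma.sum() <= 1:
        return arbor
    centroid = arbor.xyz[is_soma].mean(axis=0)
    keep = ~is_soma
    keep[root] = True
    old_to_new = -np.ones(n, dtype=int)
    old_to_new[keep] = np.arange(int(keep.sum()))
    root_new = int(old_to_new[root])
    parent = np.array(
        [
            -1 if p == -1 else (int(old_to_new[p]) if keep[p] else root_new)
            for p in arbor.parent[keep]
        ],
        dtype=int,
    )
    xyz = arbor.xyz[keep].copy()
    xyz[root_new] = centroid
    return Arbor(xyz, arbor.radius[keep], parent, arbor.ntype[keep])


def write_swc(arbor: Arbor, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# index type x y z radius parent\n")
        for i in range(arbor.n_nodes):
            x, y, z = arbor.xyz[i]
            par = arbor.parent[i]
            fh.write(
                f"{i + 1} {arbor.ntype[i]} {x:.6f} {y:.6f} {z:.6f} "
                f"{arbor.radius[i]:.6f} {par + 1 if par >= 0 else -1}\n"
            )


# ------------------------------------------------------------------- metrics

def total_length(arbor: Arbor) -> float:
    """Cumulative dendritic length: Σ Euclidean parent→child edge lengths (µm)."""
    return float(arbor.edge_lengths().sum())


def branch_statistics(arbor: Arbor) -> BranchStats:
    """Branch points (≥ 2 children), terminals (0 children, excluding the root),
    and the lengths of maximal unbranched segments between them."""
    kids = arbor.children()
    n_children = np.array([len(k) for k in kids])
    root = arbor.root
    branch_points = np.flatnonzero(n_children >= 2)
    terminals = np.flatnonzero((n_children == 0) & (np.arange(arbor.n_nodes) != root))
    edge_len = arbor.edge_lengths()

    segment_lengths: list[float] = []
    # a segment starts at each child of the root or of a branch point and
    # runs until the next branch point or terminal
    starts = [c for bp in dict.fromkeys([root, *branch_points]) for c in kids[bp]]
    for start in starts:
        length = edge_len[start]
        node = start
        while len(kids[node]) == 1:
            node = kids[node][0]
            length += edge_len[node]
        segment_lengths.append(float(length))
    return BranchStats(
        int(branch_points.size), int(terminals.size), np.asarray(segment_lengths)
    )


def arbor_area(arbor: Arbor) -> float:
    """En-face arbor area: 2-D convex hull of the x-y node projection (µm²).

    Collinear/degenerate arbors return 0 with a warning rather than raising.
    """
    pts = arbor.xyz[:, :2]
    if len(np.unique(pts, axis=0)) < 3:
        warnings.warn("fewer than 3 distinct x-y positions: hull area is 0")
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        warnings.warn("degenerate (collinear) arbor projection: hull area is 0")
        return 0.0
    return float(hull.volume)  # in 2-D, ConvexHull.volume is the area


def sholl(
    arbor: Arbor, radius_step: float = 10.0, center: np.ndarray | None = None
) -> ShollProfile:
    """Count dendrite crossings of spheres of radius k·step around the soma.

    Each edge is split at its point of closest approach to the center so that
    distance varies monotonically on each piece; a piece crosses the sphere of
    radius r iff r lies strictly above its near end and at-or-below its far
    end, so an edge bending back through the same shell counts twice.
    Radii run from ``radius_step`` up to (but excluding) the maximal node
    distance.
    """
    if not radius_step > 0:
        raise ValueError("radius_step must be > 0")
    c = arbor.xyz[arbor.root] if center is None else np.asarray(center, dtype=float)
    dist = np.linalg.norm(arbor.xyz - c, axis=1)
    max_extent = float(dist.max())
    n_radii = int(np.ceil(max_extent / radius_step - 1e-9)) - 1
    n_radii = max(n_radii, 0)
    radii = radius_step * np.arange(1, n_radii + 1)
    if radii.size == 0:
        return ShollProfile(radius_step, radii, np.zeros(0, dtype=int))

    pieces: list[tuple[float, float]] = []  # (d_near, d_far) per monotone piece
    for child in range(arbor.n_nodes):
        par = arbor.parent[child]
        if par < 0:
            continue
        a = arbor.xyz[par] - c
        b = arbor.xyz[child] - c
        ab = b - a
        denom = float(ab @ ab)
        t_star = float(np.clip(-(a @ ab) / denom, 0.0, 1.0)) if denom > 0 else 0.0
        d_a, d_b = float(np.linalg.norm(a)), float(np.linalg.norm(b))
        if 0.0 < t_star < 1.0:
            d_m = float(np.linalg.norm(a + t_star * ab))
            pieces.append((min(d_a, d_m), max(d_a, d_m)))
            pieces.append((min(d_m, d_b), max(d_m, d_b)))
        else:
            pieces.append((min(d_a, d_b), max(d_a, d_b)))

    lo = np.array([p[0] for p in pieces])
    hi = np.array([p[1] for p in pieces])
    counts = np.array([int(np.sum((lo < r) & (r <= hi))) for r in radii])
    return ShollProfile(radius_step, radii, counts)


# -------------------------------------------------------------- IPL linescans

def ipl_depth_profile(
    reporter_linescan: np.ndarray, reference_linescan: np.ndarray
) -> DepthProfile:
    """Normalize IPL linescans and locate the reference (VAChT) bands.

    Both channels are divided by their maximum and mapped onto a 0–100% depth
    axis.  The two largest reference peaks are reported as the cholinergic
    band depths (sorted by depth); reporter peak depths allow placing a cell's
    stratum relative to those bands.
    """
    rep = np.asarray(reporter_linescan, dtype=float).ravel()
    ref = np.asarray(reference_linescan, dtype=float).ravel()
    if rep.size != ref.size:
        raise ValueError("reporter and reference linescans differ in length")
    if rep.size < 8:
        raise ValueError("linescans must contain at least 8 samples")
    if np.ptp(ref) == 0:
        raise ValueError("flat reference linescan: no bands detectable")
    depth = np.linspace(0.0, 100.0, rep.size)

    def norm(v: np.ndarray) -> np.ndarray:
        m = v.max()
        return v / m if m > 0 else v

    rep_n, ref_n = norm(rep), norm(ref)
    ref_peaks, props = find_peaks(ref_n, height=0.0)
    if ref_peaks.size < 2:
        raise ValueError("reference linescan must contain at least 2 local maxima")
    top2 = ref_peaks[np.argsort(props["peak_heights"])[-2:]]
    band_depths = tuple(sorted(float(depth[i]) for i in top2))
    rep_peaks, _ = find_peaks(rep_n, height=0.5)
    if rep_peaks.size == 0:
        rep_peaks = np.array([int(np.argmax(rep_n))])
    return DepthProfile(depth, rep_n, ref_n, band_depths, depth[rep_peaks])
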