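"""Periodic polygonal tilings of a flat torus.

The apical surface of the neuroepithelium is a cylinder; simulations use a
torus (periodic rectangle) to avoid boundary artefacts.  Cells are polygons
with straight edges; every interior vertex is trivalent, so on the torus
V - E + F = 0 forces 2E = 3V and a mean polygon side count of exactly six.

Conventions
-----------
* ``x`` is the dorsoventral (DV) coordinate, ``y`` the anterioposterior (AP)
  coordinate.  The box is half-open, ``[0, L_DV) x [0, L_AP)``.
* All geometry uses the minimum-image convention: a cell's vertex loop is
  unwrapped edge-by-edge relative to its first vertex before areas,
  perimeters or moments are computed, so cells straddling the periodic seam
  behave exactly like their translated copies.
* Cell loops are ordered counter-clockwise (positive shoelace area).

Topological operators
---------------------
``t1_transition``   edge swap: a short junction collapses and a new junction
                    of length ``l_new`` expands perpendicular to it.
``divide_cell``     splits a cell through the midpoints of a length-weighted
                    random edge and the opposite edge.
``remove_cell``     extrudes a two-sided cell, merging its two parallel
                    junctions into one.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import chain
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "TopologyParams",
    "Mesh",
    "IncidenceMap",
    "build_hexagonal_tissue",
    "cell_area",
    "cell_perimeter",
    "cell_centroid",
    "detect_short_edges",
    "t1_transition",
    "divide_cell",
    "remove_cell",
    "topology_audit",
    "MeshError",
]


class MeshError(ValueError):
    """Raised for invalid topological requests."""


@dataclass
class TopologyParams:
    """Parameters of the T1 edge-swap rule.

    Parameters
    ----------
    t1_threshold_fraction:
        An edge strictly shorter than this fraction of the tissue-mean edge
        length is eliminated (default 3%).
    l_new:
        Absolute length of the newly expanded perpendicular edge, or
        ``None`` (default) to scale it off the elimination length at the
        moment of the swap: ``l_new_factor * t1_threshold_fraction *
        mean_edge``.
    l_new_factor:
        Multiple of the elimination length used when ``l_new`` is None.
        Values above 1 keep the new edge strictly above threshold.
    """

    t1_threshold_fraction: float = 0.03
    l_new: float | None = None
    l_new_factor: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.t1_threshold_fraction < 1.0:
            raise ValueError("t1_threshold_fraction must lie in (0, 1)")
        if self.l_new is not None and not self.l_new > 0:
            raise ValueError("l_new must be positive")
        if not self.l_new_factor > 0:
            raise ValueError("l_new_factor must be positive")

    def new_edge_length(self, mean_edge: float) -> float:
        if self.l_new is not None:
            return self.l_new
        return self.l_new_factor * self.t1_threshold_fraction * mean_edge


class _Flat:
    """Flattened loop arrays shared by the vectorised geometry/force code.

    ``loop[k]`` is the vertex id occupying slot ``k``; slots of one cell are
    contiguous.  ``nxt``/``prv`` are slot indices of the neighbouring slots
    within the same cell, and ``starts`` the cell offsets (length n_cells+1).
    """

    __slots__ = ("loop", "cell_id", "nxt", "prv", "starts", "nsides")

    def __init__(self, cells: Sequence[Sequence[int]]):
        ns = np.fromiter((len(c) for c in cells), np.int64, count=len(cells))
        total = int(ns.sum())
        loop = np.fromiter(chain.from_iterable(cells), np.int64, count=total)
        starts = np.empty(len(cells) + 1, np.int64)
        starts[0] = 0
        np.cumsum(ns, out=starts[1:])
        idx = np.arange(total, dtype=np.int64)
        nxt = idx + 1
        prv = idx - 1
        ends = starts[1:] - 1
        nxt[ends] = starts[:-1]
        prv[starts[:-1]] = ends
        self.loop = loop
        self.cell_id = np.repeat(np.arange(len(cells), dtype=np.int64), ns)
        self.nxt = nxt
        self.prv = prv
        self.starts = starts
        self.nsides = ns


class Mesh:
    """Polygonal tiling of the periodic box ``[0, L_DV) x [0, L_AP)``.

    Attributes
    ----------
    vertices : (N_v, 2) float array of positions (x = DV, y = AP).
    cells : list of counter-clockwise vertex-index loops, one per cell.
    box : (2,) float array, current periodic box lengths (L_DV, L_AP).
    """

    def __init__(self, vertices, cells, box):
        self.vertices = np.array(vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array")
        self.cells = [list(map(int, c)) for c in cells]
        self.box = np.array(box, dtype=float)
        if self.box.shape != (2,) or not np.all(self.box > 0):
            raise ValueError("box must be two positive lengths")
        self._flat_cache: _Flat | None = None

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_edges(self) -> int:
        # each junction appears in exactly two cell loops
        return sum(len(c) for c in self.cells) // 2

    def invalidate(self) -> None:
        """Drop cached flat arrays after a topological change."""
        self._flat_cache = None

    def flat(self) -> _Flat:
        if self._flat_cache is None:
            self._flat_cache = _Flat(self.cells)
        return self._flat_cache

    def copy(self) -> "Mesh":
        return Mesh(self.vertices.copy(), [list(c) for c in self.cells], self.box.copy())

    # -- geometry ----------------------------------------------------------

    def minimum_image(self, d: np.ndarray) -> np.ndarray:
        """Wrap displacement(s) ``d`` into ``[-L/2, L/2)`` per axis."""
        return d - self.box * np.round(d / self.box)

    def wrap(self) -> None:
        """Fold all vertex positions back into the box."""
        np.mod(self.vertices, self.box, out=self.vertices)

    def unwrapped_loop(self, alpha: int) -> np.ndarray:
        """Vertex coordinates of cell ``alpha`` unwrapped by minimum image
        relative to its first vertex (anchor stays at its stored position)."""
        ids = self.cells[alpha]
        pos = self.vertices[ids]
        steps = self.minimum_image(np.diff(pos, axis=0, append=pos[:1]))
        out = np.empty_like(pos)
        out[0] = pos[0]
        out[1:] = pos[0] + np.cumsum(steps[:-1], axis=0)
        return out

    def edge_geometry(self):
        """Per-slot minimum-image edge vectors, lengths, unwrapped relative
        coordinates, signed areas and perimeters (vectorised over the tissue).
        """
        f = self.flat()
        p = self.vertices[f.loop]
        e = self.minimum_image(p[f.nxt] - p)
        lens = np.hypot(e[:, 0], e[:, 1])
        cs = np.cumsum(e, axis=0)
        u = np.empty_like(e)
        u[0] = 0.0
        u[1:] = cs[:-1]
        base = u[f.starts[:-1]]
        u -= np.repeat(base, f.nsides, axis=0)
        cross = u[:, 0] * e[:, 1] - u[:, 1] * e[:, 0]
        areas = 0.5 * np.add.reduceat(cross, f.starts[:-1])
        perims = np.add.reduceat(lens, f.starts[:-1])
        return e, lens, u, areas, perims

    def areas(self) -> np.ndarray:
        return self.edge_geometry()[3]

    def perimeters(self) -> np.ndarray:
        return self.edge_geometry()[4]

    def mean_edge_length(self) -> float:
        _, lens, _, _, _ = self.edge_geometry()
        # every junction appears twice in the slot arrays
        return float(lens.mean())

    def edges(self) -> Iterator[tuple[int, int]]:
        """Unique junctions as sorted vertex-id pairs."""
        f = self.flat()
        a, b = f.loop, f.loop[f.nxt]
        sel = a < b
        yield from zip(a[sel].tolist(), b[sel].tolist())

    def edge_lengths(self) -> dict[tuple[int, int], float]:
        f = self.flat()
        _, lens, _, _, _ = self.edge_geometry()
        a, b = f.loop, f.loop[f.nxt]
        sel = a < b
        return dict(zip(zip(a[sel].tolist(), b[sel].tolist()), lens[sel].tolist()))


# ---------------------------------------------------------------------------
# construction


def build_hexagonal_tissue(n_rows: int, n_cols: int, cell_area: float = 1.0) -> Mesh:
    """Defect-free hexagonal tiling of ``n_rows x n_cols`` cells on the torus.

    Cells are arranged in rows of width ``w = sqrt(3) s`` and height
    ``h = 1.5 s`` (``w * h = cell_area``), with each row offset horizontally
    by ``delta = w * ceil(n_rows/2) / n_rows``.  For even ``n_rows`` this is
    the regular honeycomb (``delta = w/2``); for odd ``n_rows`` the offset is
    slightly sheared so the pattern still closes periodically while every
    cell keeps exactly six sides.

    Raises
    ------
    MeshError
        If ``n_rows`` or ``n_cols`` is below 2 (the pattern cannot close
        periodically without degenerate self-adjacencies).
    """
    if n_rows < 2 or n_cols < 2:
        raise MeshError("need at least 2 rows and 2 columns for periodic closure")
    if cell_area <= 0:
        raise ValueError("cell_area must be positive")
    s = np.sqrt(cell_area / (1.5 * np.sqrt(3.0)))
    w = np.sqrt(3.0) * s
    h = 1.5 * s
    p = 0.25 * s  # vertical poke of the zig-zag vertices (regular for delta=w/2)
    k = (n_rows + 1) // 2
    delta = w * k / n_rows

    box = np.array([n_cols * w, n_rows * h])
    nv = 2 * n_rows * n_cols
    verts = np.empty((nv, 2))

    def uid(r: int, c: int) -> int:
        # index of the "up" vertex U(r, c); row wrap shifts the column by k
        m, rr = divmod(r, n_rows)
        return 2 * (rr * n_cols + (c + m * k) % n_cols)

    def did(r: int, c: int) -> int:
        m, rr = divmod(r, n_rows)
        return 2 * (rr * n_cols + (c + m * k) % n_cols) + 1

    for r in range(n_rows):
        for c in range(n_cols):
            x = (c + 1) * w + r * delta
            verts[uid(r, c)] = (x, (r + 1) * h - p)
            verts[did(r, c)] = (x, r * h + p)
    verts[:, 0] %= box[0]
    verts[:, 1] %= box[1]

    cells = []
    for r in range(n_rows):
        for c in range(n_cols):
            cells.append(
                [
                    did(r, c - 1),
                    uid(r - 1, c),
                    did(r, c),
                    uid(r, c),
                    did(r + 1, c - 1),
                    uid(r, c - 1),
                ]
            )
    return Mesh(verts, cells, box)


# ---------------------------------------------------------------------------
# single-cell geometry queries


def cell_area(mesh: Mesh, alpha: int) -> float:
    """Shoelace area of cell ``alpha`` on minimum-image unwrapped coordinates.

    Degenerate (self-intersecting or wrongly oriented) loops yield a
    non-positive shoelace value and raise :class:`MeshError`.
    """
    u = mesh.unwrapped_loop(alpha)
    x, y = u[:, 0], u[:, 1]
    a = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    if not a > 0:
        raise MeshError(f"cell {alpha} has non-positive signed area {a:g}")
    return a


def cell_perimeter(mesh: Mesh, alpha: int) -> float:
    """Sum of minimum-image edge lengths around the loop of cell ``alpha``."""
    ids = mesh.cells[alpha]
    pos = mesh.vertices[ids]
    steps = mesh.minimum_image(np.roll(pos, -1, axis=0) - pos)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def cell_centroid(mesh: Mesh, alpha: int) -> np.ndarray:
    """Vertex-mean centroid of the unwrapped loop, folded into the box."""
    u = mesh.unwrapped_loop(alpha)
    return np.mod(u.mean(axis=0), mesh.box)


# ---------------------------------------------------------------------------
# incidence map


class IncidenceMap:
    """Vertex -> incident cells lookup with cheap local updates.

    Built once per update cycle from the flat arrays (O(total slots) in
    numpy); topological operators patch it in place so several events can be
    applied within one cycle without a rebuild.  After operations that
    renumber vertices or cells (``remove_cell``) it must be rebuilt.
    """

    def __init__(self, mesh: Mesh):
        f = mesh.flat()
        order = np.argsort(f.loop, kind="stable")
        self._vs = f.loop[order]
        self._cs = f.cell_id[order]
        self._override: dict[int, list[int]] = {}

    def cells_of(self, v: int) -> list[int]:
        if v in self._override:
            return self._override[v]
        lo = int(np.searchsorted(self._vs, v, side="left"))
        hi = int(np.searchsorted(self._vs, v, side="right"))
        return self._cs[lo:hi].tolist()

    def set(self, v: int, cells: Sequence[int]) -> None:
        self._override[v] = list(cells)

    def replace(self, v: int, old: int, new: int) -> None:
        cs = self.cells_of(v)
        self._override[v] = [new if c == old else c for c in cs]


def _shared_cells(mesh: Mesh, inc: IncidenceMap, i: int, j: int) -> list[int]:
    """Cells whose loops contain the junction (i, j) as consecutive vertices."""
    out = []
    for c in inc.cells_of(i):
        loop = mesh.cells[c]
        n = len(loop)
        for p, v in enumerate(loop):
            if v == i and (loop[(p + 1) % n] == j or loop[(p - 1) % n] == j):
                out.append(c)
                break
    return out


# ---------------------------------------------------------------------------
# T1 transitions


def detect_short_edges(mesh: Mesh, params: TopologyParams) -> list[tuple[int, int]]:
    """Junctions strictly shorter than ``t1_threshold_fraction`` times the
    tissue-mean edge length, sorted by ascending length (ties by vertex ids).
    """
    f = mesh.flat()
    _, lens, _, _, _ = mesh.edge_geometry()
    a, b = f.loop, f.loop[f.nxt]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    cutoff = params.t1_threshold_fraction * float(lens.mean())
    short = lens < cutoff
    pairs = np.unique(np.stack([lo[short], hi[short]], axis=1), axis=0)
    if pairs.size == 0:
        return []
    # deterministic order: ascending length, ties by vertex ids
    key = {(int(p), int(q)): float(l) for p, q, l in zip(lo[short], hi[short], lens[short])}
    out = [tuple(p) for p in pairs.tolist()]
    out.sort(key=lambda e: (key[e], e))
    return out


def t1_transition(
    mesh: Mesh,
    junction: tuple[int, int],
    params: TopologyParams,
    inc: IncidenceMap | None = None,
    allow_collapse: bool = False,
):
    """Swap junction ``(i, j)``: collapse it to its midpoint and expand a new
    junction of length ``l_new`` perpendicular to it.

    The two cells sharing the old junction each lose one side; the two cells
    meeting it end-on each gain one.  ``(N_v, N_c, E)`` are conserved.

    Returns a dict with the old/new edge angles (radians, in ``[0, pi)``
    relative to the DV axis) and, when the swap makes one of the side cells
    two-sided, the outcome of the subsequent :func:`remove_cell` under key
    ``"removed"`` (requires ``allow_collapse=True``; otherwise such swaps
    raise).

    Raises
    ------
    MeshError
        If the junction does not exist, or the configuration is forbidden
        (a side cell with three sides while ``allow_collapse`` is false, or
        fewer than four distinct cells around the junction).
    """
    i, j = junction
    if inc is None:
        inc = IncidenceMap(mesh)
    ab = _shared_cells(mesh, inc, i, j)
    if len(ab) != 2:
        raise MeshError(f"junction {junction} not shared by exactly two cells")
    # orient: A traverses i -> j, B traverses j -> i
    a_cell = b_cell = None
    for c in ab:
        loop = mesh.cells[c]
        n = len(loop)
        p = loop.index(i)
        if loop[(p + 1) % n] == j:
            a_cell = c
        else:
            b_cell = c
    if a_cell is None or b_cell is None or a_cell == b_cell:
        raise MeshError(f"junction {junction} is degenerate")
    c_cell = next((c for c in inc.cells_of(i) if c not in (a_cell, b_cell)), None)
    d_cell = next((c for c in inc.cells_of(j) if c not in (a_cell, b_cell)), None)
    if c_cell is None or d_cell is None or c_cell == d_cell:
        raise MeshError(f"junction {junction} lacks four distinct cells")

    la, lb = mesh.cells[a_cell], mesh.cells[b_cell]
    if len(la) <= 3 or len(lb) <= 3:
        if not allow_collapse:
            raise MeshError(
                f"T1 on junction {junction} would reduce a 3-sided cell; deferred"
            )
        if len(la) <= 3 and len(lb) <= 3:
            raise MeshError("both side cells are triangles; swap deferred")
        # the resulting 2-gon is bounded by C and D; removing it strips two
        # sides from each, so they must end with >= 3 (i.e. >= 4 before the
        # swap adds them one)
        if len(mesh.cells[c_cell]) < 4 or len(mesh.cells[d_cell]) < 4:
            raise MeshError("extrusion would leave a neighbour with <3 sides; deferred")

    # geometry: collapse to midpoint, re-expand perpendicular
    ri = mesh.vertices[i].copy()
    rj = mesh.vertices[j].copy()
    d = mesh.minimum_image(rj - ri)
    old_len = float(np.hypot(*d))
    if old_len == 0.0:
        raise MeshError("zero-length junction")
    mid = ri + 0.5 * d
    uhat = d / old_len
    nhat = np.array([-uhat[1], uhat[0]])
    cen_a = cell_centroid(mesh, a_cell)
    side = np.sign(float(np.dot(nhat, mesh.minimum_image(cen_a - mid)))) or 1.0
    half = 0.5 * params.new_edge_length(mesh.mean_edge_length())

    def _signed_area(cell: int) -> float:
        pts = mesh.unwrapped_loop(cell)
        x, y = pts[:, 0], pts[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    # cells already degenerate before the swap are exempt from the
    # orientation check below (they are on their way out)
    was_positive = {c: _signed_area(c) > 0 for c in (a_cell, b_cell, c_cell, d_cell)}

    # topology: A keeps i, B keeps j, C and D gain the new junction
    pa = la.index(i)
    b_ix = la[(pa + 2) % len(la)]  # neighbour of j in A
    pb = lb.index(j)
    c_ix = lb[(pb + 2) % len(lb)]  # neighbour of i in B
    la.remove(j)
    lb.remove(i)
    lc = mesh.cells[c_cell]
    pc = lc.index(i)
    # C gains j on its c-side: ... c, j, i, ...
    if lc[(pc - 1) % len(lc)] == c_ix:
        lc.insert(pc, j)
    else:
        lc.insert(pc + 1, j)
    ld = mesh.cells[d_cell]
    pd = ld.index(j)
    # D gains i on its b-side: ... b, i, j, ...
    if ld[(pd - 1) % len(ld)] == b_ix:
        ld.insert(pd, i)
    else:
        ld.insert(pd + 1, i)
    mesh.invalidate()

    # place the new junction; try the centroid-preferred expansion sign
    # first, but accept only a placement that keeps the touched cells
    # positively oriented (crowded degenerate regions can fool the
    # centroid heuristic and invert a gaining cell)
    def _valid(sign: float) -> bool:
        mesh.vertices[i] = np.mod(mid + sign * half * nhat, mesh.box)
        mesh.vertices[j] = np.mod(mid - sign * half * nhat, mesh.box)
        for cell in (a_cell, b_cell, c_cell, d_cell):
            if len(mesh.cells[cell]) < 3:
                continue  # a 2-gon about to be extruded
            if was_positive[cell] and _signed_area(cell) <= 0:
                return False
        return True

    if not _valid(side) and not _valid(-side):
        # undo the loop surgery and defer the swap
        mesh.vertices[i] = ri
        mesh.vertices[j] = rj
        la.insert(la.index(i) + 1, j)
        lb.insert(lb.index(j) + 1, i)
        lc.remove(j)
        ld.remove(i)
        mesh.invalidate()
        raise MeshError(f"no valid expansion for junction {junction}; deferred")
    inc.set(i, [a_cell, c_cell, d_cell])
    inc.set(j, [b_cell, c_cell, d_cell])
    mesh.invalidate()

    info = {
        "old_angle": float(np.arctan2(uhat[1], uhat[0]) % np.pi),
        "new_angle": float(np.arctan2(nhat[1], nhat[0]) % np.pi),
        "cells": (a_cell, b_cell, c_cell, d_cell),
        "removed": None,
    }
    for c in (a_cell, b_cell):
        if len(mesh.cells[c]) == 2:
            info["removed"] = remove_cell(mesh, c)
            break
    return info


# ---------------------------------------------------------------------------
# division


def _opposite_edge_index(mesh: Mesh, loop_pts: np.ndarray, a: int) -> int:
    """Index of the edge opposite edge ``a`` in a loop of unwrapped points.

    Even side count 2k: the edge k positions around the loop.  Odd count:
    the nearer of the two candidates by Euclidean midpoint distance, ties
    broken by the lower edge index.
    """
    n = len(loop_pts)
    if n % 2 == 0:
        return (a + n // 2) % n
    mids = 0.5 * (loop_pts + np.roll(loop_pts, -1, axis=0))
    cand = sorted([(a + (n - 1) // 2) % n, (a + (n + 1) // 2) % n])
    d0 = np.linalg.norm(mids[cand[0]] - mids[a])
    d1 = np.linalg.norm(mids[cand[1]] - mids[a])
    return cand[0] if d0 <= d1 else cand[1]


def divide_cell(
    mesh: Mesh,
    alpha: int,
    rng: np.random.Generator,
    inc: IncidenceMap | None = None,
):
    """Split cell ``alpha`` through a new junction joining the midpoint of a
    length-weighted randomly chosen edge to the midpoint of the opposite edge.

    The first daughter reuses index ``alpha``; the second is appended at
    index ``mesh.n_cells`` (before the call).  Adds ``(2, 1, 3)`` to
    ``(N_v, N_c, E)``.

    Returns ``(alpha, beta, info)`` with ``info["angle"]`` the new-edge
    orientation in ``[0, pi)`` relative to the DV axis.
    """
    loop = mesh.cells[alpha]
    n = len(loop)
    if n < 4:
        raise MeshError(f"cell {alpha} has {n} sides; need >= 4 to divide")
    if inc is None:
        inc = IncidenceMap(mesh)

    pts = mesh.unwrapped_loop(alpha)
    edge_vec = np.roll(pts, -1, axis=0) - pts
    lens = np.hypot(edge_vec[:, 0], edge_vec[:, 1])
    a = int(rng.choice(n, p=lens / lens.sum()))
    b = _opposite_edge_index(mesh, pts, a)

    w1 = mesh.n_vertices
    w2 = w1 + 1
    m1 = np.mod(pts[a] + 0.5 * edge_vec[a], mesh.box)
    m2 = np.mod(pts[b] + 0.5 * edge_vec[b], mesh.box)
    mesh.vertices = np.vstack([mesh.vertices, m1[None], m2[None]])

    # insert the midpoints into the neighbours sharing the split edges
    for (e_ix, w) in ((a, w1), (b, w2)):
        u, v = loop[e_ix], loop[(e_ix + 1) % n]
        nb = next(
            c for c in _shared_cells(mesh, inc, u, v) if c != alpha
        )
        lnb = mesh.cells[nb]
        pv = lnb.index(v)
        # neighbour traverses v -> u; insert w between them
        if lnb[(pv + 1) % len(lnb)] == u:
            lnb.insert(pv + 1, w)
        else:
            lnb.insert(pv, w)
        inc.set(w, [alpha, nb])  # patched below with the daughter split

    # split the mother loop: d1 = w1, loop[a+1..b], w2 ; d2 = w2, loop[b+1..a], w1
    def seg(lo: int, hi: int) -> list[int]:
        out = []
        p = lo
        while True:
            out.append(loop[p])
            if p == hi:
                return out
            p = (p + 1) % n

    d1 = [w1] + seg((a + 1) % n, b) + [w2]
    d2 = [w2] + seg((b + 1) % n, a) + [w1]
    beta = mesh.n_cells
    mesh.cells[alpha] = d1
    mesh.cells.append(d2)
    for v in d2[1:-1]:
        inc.replace(v, alpha, beta)
    # the split-edge neighbours keep their ids; fix the new vertices' cells
    nb1 = [c for c in inc.cells_of(w1) if c != alpha]
    inc.set(w1, [alpha, beta] + nb1)
    nb2 = [c for c in inc.cells_of(w2) if c != alpha]
    inc.set(w2, [alpha, beta] + nb2)
    mesh.invalidate()

    dvec = mesh.minimum_image(m2 - m1)
    angle = float(np.arctan2(dvec[1], dvec[0]) % np.pi)
    return alpha, beta, {"angle": angle, "edge_pair": (a, b)}


# ---------------------------------------------------------------------------
# removal of two-sided cells


def remove_cell(mesh: Mesh, alpha: int):
    """Extrude a two-sided cell: its two parallel junctions merge into one,
    its two vertices disappear, and the neighbours are re-stitched.

    Subtracts ``(2, 1, 3)`` from ``(N_v, N_c, E)``.  Cell indices above
    ``alpha`` and vertex indices above the removed vertices shift down by
    one/two; callers keeping parallel per-cell state must re-index (the
    returned dict reports ``cell`` and ``vertices`` removed).

    Raises
    ------
    MeshError
        If the cell is not two-sided or a neighbour would be left with
        fewer than three sides.
    """
    loop = mesh.cells[alpha]
    if len(loop) != 2:
        raise MeshError(f"cell {alpha} has {len(loop)} sides; only 2-sided cells are removed")
    i, j = loop
    neighbours = [
        c for c, cl in enumerate(mesh.cells) if c != alpha and i in cl and j in cl
    ]
    if len(neighbours) != 2:
        raise MeshError("two-sided cell must have exactly two neighbours")
    for c in neighbours:
        if len(mesh.cells[c]) < 5:
            raise MeshError(
                "removing the two-sided cell would leave a neighbour with <3 sides"
            )
    for c in neighbours:
        mesh.cells[c] = [v for v in mesh.cells[c] if v not in (i, j)]

    mesh.cells.pop(alpha)
    keep = np.ones(mesh.n_vertices, dtype=bool)
    keep[[i, j]] = False
    remap = np.cumsum(keep) - 1
    mesh.vertices = mesh.vertices[keep]
    mesh.cells = [[int(remap[v]) for v in c] for c in mesh.cells]
    mesh.invalidate()
    return {"cell": alpha, "vertices": (i, j), "neighbours": neighbours}


# ---------------------------------------------------------------------------
# audit


def topology_audit(mesh: Mesh, tol: float = 1e-9) -> list[str]:
    """Verify all mesh invariants; return a list of violations (empty = pass).

    Checks: finite positions; positive box; trivalent vertices; every
    junction shared by exactly two cells; Euler characteristic zero
    (2E = 3V, mean side count 6); counter-clockwise loops with positive
    area; no cell with fewer than 3 sides; and the tiling property that cell
    areas sum to the box area within relative tolerance ``tol``.
    """
    issues: list[str] = []
    if not np.all(np.isfinite(mesh.vertices)):
        issues.append("non-finite vertex coordinates")
        return issues
    nv, nc, ne = mesh.n_vertices, mesh.n_cells, mesh.n_edges

    for c, loop in enumerate(mesh.cells):
        if len(loop) < 3:
            issues.append(f"cell {c} has {len(loop)} sides")
        if len(set(loop)) != len(loop):
            issues.append(f"cell {c} repeats a vertex")

    from collections import Counter

    edge_count: Counter = Counter()
    valence: Counter = Counter()
    for loop in mesh.cells:
        n = len(loop)
        for p in range(n):
            u, v = loop[p], loop[(p + 1) % n]
            edge_count[tuple(sorted((u, v)))] += 1
            valence[u] += 1
    bad_edges = [e for e, k in edge_count.items() if k != 2]
    if bad_edges:
        issues.append(f"{len(bad_edges)} junction(s) not shared by exactly two cells")
    bad_valence = [v for v, k in valence.items() if k != 3]
    if bad_valence:
        issues.append(f"{len(bad_valence)} vertex/vertices not trivalent")
    if nv - len(edge_count) + nc != 0:
        issues.append(f"Euler characteristic V-E+F = {nv - len(edge_count) + nc} != 0")
    if 2 * len(edge_count) != 3 * nv:
        issues.append("2E != 3V (mean side count not 6)")

    try:
        total = 0.0
        for c in range(nc):
            total += cell_area(mesh, c)
        box_area = float(mesh.box[0] * mesh.box[1])
        if abs(total - box_area) > tol * box_area:
            issues.append(
                f"cell areas sum to {total:.12g}, box area {box_area:.12g}"
            )
    except MeshError as err:
        issues.append(str(err))
    return issues
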