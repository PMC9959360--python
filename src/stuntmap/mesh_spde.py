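"""Triangulated mesh, SPDE/Matérn precision matrix, and projector matrix.

The latent spatial risk surface is a stationary isotropic Matérn Gaussian
field with smoothness nu = 1, represented as a Gaussian Markov random
field on a triangulation via the SPDE link: the field S(s) solving

    (kappa^2 - Delta)^(alpha/2) (tau S(s)) = W(s),      alpha = 2 in 2-D,

has Matérn covariance with range ~ sqrt(8 nu)/kappa and marginal variance
sigma^2 = 1 / (4 pi kappa^2 tau^2).  A linear finite-element basis on the
mesh turns the field into a Gaussian vector with the sparse precision

    Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^{-1} G),

where C is the (lumped, diagonal) mass matrix and G the stiffness matrix.
Observation and prediction locations are linked to mesh vertices through
the projector matrix A of barycentric interpolation weights.

Coordinates here are planar (lon/lat degrees treated as a plane); kappa is
per coordinate unit.  `matern_params_from` reports the derived range and
variance; converting degree ranges to km for display is done with
:func:`stuntmap.geoutils.degrees_to_km` at the domain's mean latitude.

The smoothness is fixed at nu = 1 (ALPHA = 2), the customary choice for
2-D prevalence mapping; it is a documented constant, not a parameter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import Delaunay, cKDTree
from scipy.special import kv

ALPHA = 2  # SPDE operator exponent; nu = ALPHA - d/2 = 1 in two dimensions
NU = 1.0


class MeshError(ValueError):
    """Raised when a usable triangulation cannot be built."""


@dataclass
class Mesh:
    """Linear finite-element mesh with assembled FEM matrices.

    vertices : (nv, 2) planar coordinates
    triangles : (nt, 3) vertex indices, positively oriented
    boundary : (nv,) bool, True for convex-hull vertices
    C : (nv,) diagonal of the lumped mass matrix (strictly positive)
    G : (nv, nv) sparse stiffness matrix (symmetric, zero row sums)
    """

    vertices: np.ndarray
    triangles: np.ndarray
    boundary: np.ndarray
    C: np.ndarray
    G: sp.csr_matrix
    _tri: Delaunay | None = field(default=None, repr=False, compare=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def locator(self) -> Delaunay:
        if self._tri is None:
            self._tri = Delaunay(self.vertices)
        return self._tri

    def interior_mask(self, margin: float = 0.0) -> np.ndarray:
        """Vertices at least `margin` (coordinate units) from the hull boundary."""
        if margin <= 0:
            return ~self.boundary
        hull_pts = self.vertices[self.boundary]
        d, _ = cKDTree(hull_pts).query(self.vertices)
        return d >= margin

    def to_json(self, path) -> None:
        obj = {
            "vertices": self.vertices.tolist(),
            "triangles": self.triangles.tolist(),
            "boundary": self.boundary.astype(int).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "Mesh":
        with open(path) as fh:
            obj = json.load(fh)
        verts = np.asarray(obj["vertices"], dtype=float)
        tris = np.asarray(obj["triangles"], dtype=int)
        C, G = assemble_fem(verts, tris)
        return cls(
            vertices=verts,
            triangles=tris,
            boundary=np.asarray(obj["boundary"], dtype=bool),
            C=C,
            G=G,
        )


@dataclass(frozen=True)
class SPDEParams:
    """Matérn/SPDE hyperparameters (nu fixed at 1).

    kappa : inverse range scale, per coordinate unit
    tau : precision scale of the SPDE white-noise forcing
    """

    kappa: float
    tau: float

    def __post_init__(self):
        if self.kappa <= 0 or self.tau <= 0:
            raise ValueError("kappa and tau must be positive")

    @property
    def range(self) -> float:
        return math.sqrt(8.0 * NU) / self.kappa

    @property
    def variance(self) -> float:
        return 1.0 / (4.0 * math.pi * self.kappa**2 * self.tau**2)

    @classmethod
    def from_range_variance(cls, spatial_range: float, variance: float) -> "SPDEParams":
        if spatial_range <= 0 or variance <= 0:
            raise ValueError("range and variance must be positive")
        kappa = math.sqrt(8.0 * NU) / spatial_range
        tau = 1.0 / (kappa * math.sqrt(4.0 * math.pi * variance))
        return cls(kappa=kappa, tau=tau)


def matern_params_from(kappa: float, tau: float) -> tuple[float, float]:
    """Derived (range, marginal variance) for nu = 1: range = sqrt(8)/kappa,
    sigma^2 = 1/(4 pi kappa^2 tau^2)."""
    p = SPDEParams(kappa=kappa, tau=tau)
    return p.range, p.variance


def matern_correlation(r, kappa: float):
    """Closed-form nu = 1 Matérn correlation (kappa r) K_1(kappa r)."""
    x = np.asarray(kappa * np.asarray(r, dtype=float))
    out = np.ones_like(x, dtype=float)
    pos = x > 0
    out[pos] = x[pos] * kv(1, x[pos])
    return out


def _thin_points(points: np.ndarray, cutoff: float) -> np.ndarray:
    """Greedy thinning: keep points in order, dropping any within `cutoff`
    of an already kept point."""
    if cutoff <= 0:
        return points
    kept: list[np.ndarray] = []
    tree: cKDTree | None = None
    pending: list[np.ndarray] = []
    # batched KD-tree rebuilds keep this O(n log n)-ish without cython
    for p in points:
        ok = True
        if tree is not None:
            if tree.query_ball_point(p, cutoff):
                ok = False
        if ok and pending:
            d = np.min(np.hypot(*(np.array(pending) - p).T))
            if d < cutoff:
                ok = False
        if ok:
            pending.append(p)
            if len(pending) >= 256:
                kept.extend(pending)
                tree = cKDTree(np.array(kept))
                pending = []
    kept.extend(pending)
    return np.array(kept)


def _fill_grid(bounds, spacing) -> np.ndarray:
    x0, y0, x1, y1 = bounds
    xs = np.arange(x0 + spacing / 2.0, x1, spacing)
    ys = np.arange(y0 + spacing / 2.0, y1, spacing)
    if len(xs) == 0 or len(ys) == 0:
        return np.empty((0, 2))
    xx, yy = np.meshgrid(xs, ys)
    return np.column_stack([xx.ravel(), yy.ravel()])


def build_mesh(
    points,
    max_edge: float,
    cutoff: float = 0.0,
    boundary_extension: float = 0.0,
    max_edge_extension: float | None = None,
) -> Mesh:
    """Build a Delaunay mesh over `points` plus quasi-regular fill vertices.

    Parameters
    ----------
    points : (n, 2) observation coordinates the mesh must cover
    max_edge : target edge length inside the data region; interior fill
        vertices are laid on a grid at this spacing
    cutoff : minimum distance between retained vertices; input points
        closer than this are merged (DHS clusters are dense in cities)
    boundary_extension : width of an outer coarse ring added beyond the
        data bounding box, mitigating the variance inflation the Neumann
        boundary condition induces at the mesh edge
    max_edge_extension : fill spacing in the extension ring
        (default 2 * max_edge)

    Raises
    ------
    MeshError : fewer than 3 distinct vertices, or all collinear.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise MeshError("points must be an (n, 2) array")
    if max_edge <= 0:
        raise MeshError("max_edge must be positive")

    retained = _thin_points(points, cutoff)
    x0, y0 = points.min(axis=0)
    x1, y1 = points.max(axis=0)

    cand = [retained]
    inner_fill = _fill_grid((x0, y0, x1, y1), max_edge)
    if len(inner_fill):
        cand.append(inner_fill)
    if boundary_extension > 0:
        ext_spacing = max_edge_extension if max_edge_extension is not None else 2.0 * max_edge
        ex0, ey0 = x0 - boundary_extension, y0 - boundary_extension
        ex1, ey1 = x1 + boundary_extension, y1 + boundary_extension
        # symmetric grid spanning the extended box edge-to-edge
        xs = np.linspace(ex0, ex1, max(2, int(math.ceil((ex1 - ex0) / ext_spacing)) + 1))
        ys = np.linspace(ey0, ey1, max(2, int(math.ceil((ey1 - ey0) / ext_spacing)) + 1))
        gx, gy = np.meshgrid(xs, ys)
        outer = np.column_stack([gx.ravel(), gy.ravel()])
        # keep only ring points outside the inner box
        ring = outer[
            (outer[:, 0] < x0) | (outer[:, 0] > x1) | (outer[:, 1] < y0) | (outer[:, 1] > y1)
        ]
        if len(ring):
            cand.append(ring)
    allpts = np.vstack(cand)
    # merge fill vertices into nearby data vertices; min separation keeps
    # triangle quality bounded
    min_sep = max(cutoff, 0.4 * max_edge) if len(allpts) > len(retained) else cutoff
    verts = _thin_points(allpts, min_sep) if min_sep > 0 else allpts
    if len(verts) < 3:
        raise MeshError(f"only {len(verts)} distinct vertices after thinning; need >= 3")

    try:
        tri = Delaunay(verts)
    except Exception as exc:  # qhull degenerate input
        raise MeshError(f"triangulation failed: {exc}") from exc
    if tri.simplices.size == 0:
        raise MeshError("all points are collinear")

    verts = tri.points
    simplices = _orient(verts, tri.simplices)
    C, G = assemble_fem(verts, simplices)
    boundary = np.zeros(len(verts), dtype=bool)
    boundary[np.unique(tri.convex_hull)] = True
    return Mesh(vertices=verts, triangles=simplices, boundary=boundary, C=C, G=G, _tri=tri)


def _orient(verts: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Flip triangles so all have positive signed area."""
    p = verts[simplices]
    area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    out = simplices.copy()
    flip = area2 < 0
    out[flip, 1], out[flip, 2] = simplices[flip, 2], simplices[flip, 1]
    return out


def assemble_fem(verts: np.ndarray, triangles: np.ndarray) -> tuple[np.ndarray, sp.csr_matrix]:
    """Assemble the lumped mass diagonal C and stiffness matrix G with
    linear (P1) elements.

    For a triangle with vertices p1, p2, p3 and area T, the local
    stiffness entries are grad(phi_i) . grad(phi_j) * T, and each vertex
    receives T/3 of lumped mass.
    """
    p = verts[triangles]  # (nt, 3, 2)
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    area = 0.5 * (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])
    if np.any(area <= 0):
        raise MeshError("degenerate (zero/negative area) triangle in mesh")

    # gradients of the three barycentric basis functions
    # phi_i has gradient rot90(opposite edge) / (2 area)
    grads = np.empty((len(triangles), 3, 2))
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        edge = p[:, k] - p[:, j]
        grads[:, i, 0] = -edge[:, 1]
        grads[:, i, 1] = edge[:, 0]
    grads /= (2.0 * area)[:, None, None]

    nv = len(verts)
    rows, cols, vals = [], [], []
    for i in range(3):
        for j in range(3):
            rows.append(triangles[:, i])
            cols.append(triangles[:, j])
            vals.append(np.einsum("td,td->t", grads[:, i], grads[:, j]) * area)
    G = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(nv, nv)
    )
    G.sum_duplicates()

    C = np.zeros(nv)
    for i in range(3):
        np.add.at(C, triangles[:, i], area / 3.0)
    return C, G


def spde_precision(mesh: Mesh, params: SPDEParams) -> sp.csc_matrix:
    """Sparse alpha=2 precision Q = tau^2 (k^4 C + 2 k^2 G + G C^-1 G)."""
    k2 = params.kappa**2
    C = sp.diags(mesh.C)
    Cinv = sp.diags(1.0 / mesh.C)
    G = mesh.G
    Q = params.tau**2 * (k2 * k2 * C + 2.0 * k2 * G + G @ Cinv @ G)
    Q = ((Q + Q.T) * 0.5).tocsc()  # symmetrize away roundoff
    return Q


def sample_field(Q: sp.spmatrix, rng: np.random.Generator, n_draws: int = 1) -> np.ndarray:
    """Draw zero-mean Gaussian vectors with precision Q.

    Small systems use a dense Cholesky factor; larger ones a banded
    Cholesky after reverse-Cuthill-McKee reordering (Q is a sparse GMRF
    precision, so its RCM bandwidth is small).  Raises with the
    smallest-eigenvalue diagnostic if Q is not numerically SPD.
    """
    n = Q.shape[0]
    if not sp.issparse(Q) or n <= 1500:
        Qd = Q.toarray() if sp.issparse(Q) else np.asarray(Q)
        try:
            L = np.linalg.cholesky(Qd)
        except np.linalg.LinAlgError as exc:
            w_min = float(np.linalg.eigvalsh(Qd)[0])
            raise np.linalg.LinAlgError(
                f"precision not positive definite (smallest eigenvalue {w_min:.3e})"
            ) from exc
        z = rng.standard_normal((n, n_draws))
        x = np.linalg.solve(L.T, z)
        return x[:, 0] if n_draws == 1 else x.T

    from scipy.linalg import cholesky_banded, solve_banded
    from scipy.sparse.csgraph import reverse_cuthill_mckee

    perm = reverse_cuthill_mckee(Q.tocsr(), symmetric_mode=True)
    Qp = Q.tocsr()[perm][:, perm].tocoo()
    bw = int(np.abs(Qp.row - Qp.col).max())
    ab = np.zeros((bw + 1, n))
    upper = Qp.col >= Qp.row
    ab[bw + Qp.row[upper] - Qp.col[upper], Qp.col[upper]] = Qp.data[upper]
    try:
        U = cholesky_banded(ab, lower=False)  # Q = U' U in band storage
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("precision not positive definite (banded factor failed)") from exc
    z = rng.standard_normal((n, n_draws))
    xp = solve_banded((0, bw), U, z)
    inv = np.empty(n, dtype=int)
    inv[perm] = np.arange(n)
    x = xp[inv]
    return x[:, 0] if n_draws == 1 else x.T


def projector(mesh: Mesh, locations) -> sp.csr_matrix:
    """Barycentric-weight projector matrix A (rows = locations, cols = vertices).

    Rows for locations outside the mesh hull are all zero; callers can
    detect them via ``A.sum(axis=1)``.
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    tri = mesh.locator()
    simplex = tri.find_simplex(locations)
    n = len(locations)
    rows, cols, vals = [], [], []
    inside = simplex >= 0
    if inside.any():
        idx = np.where(inside)[0]
        s = simplex[idx]
        X = tri.transform[s]
        bary2 = np.einsum("nij,nj->ni", X[:, :2], locations[idx] - X[:, 2])
        bary = np.column_stack([bary2, 1.0 - bary2.sum(axis=1)])
        bary = np.clip(bary, 0.0, 1.0)
        bary /= bary.sum(axis=1, keepdims=True)
        vtx = tri.simplices[s]
        for k in range(3):
            rows.append(idx)
            cols.append(vtx[:, k])
            vals.append(bary[:, k])
    if rows:
        A = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, mesh.n_vertices),
        )
    else:
        A = sp.csr_matrix((n, mesh.n_vertices))
    return A


def write_precision_mtx(Q: sp.spmatrix, path) -> None:
    from scipy.io import mmwrite

    mmwrite(str(path), sp.coo_matrix(Q))
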