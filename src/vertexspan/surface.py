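"""Spherical cortical surface meshes and the spin-rotation permutation machinery.

The analyses in this package run on spherical triangulated meshes that stand
in for registration spheres such as fsaverage / fsaverage4 (163,842 and 2,562
vertices per hemisphere).  Synthetic work uses icospheres: subdividing an
icosahedron ``s`` times yields ``10 * 4**s + 2`` vertices, so ``s = 4``
matches the per-hemisphere fsaverage4 resolution.

Three geometric primitives live here:

* iterative neighbor-averaging smoothing (the synthetic-mesh analogue of
  Gaussian surface smoothing specified in mm FWHM on real geometry),
* uniform random rotations of the sphere, and
* spin nulls: per-permutation vertex reassignment maps obtained by rotating
  one hemisphere, mirroring the rotation into the other, and replacing each
  vertex's value with that of the nearest rotated source vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.stats import special_ortho_group

__all__ = [
    "SurfaceMesh",
    "SpinNull",
    "make_icosphere",
    "mesh_adjacency",
    "smooth_on_mesh",
    "random_rotation",
    "build_spin_null",
    "fwhm_to_iterations",
]

#: Sagittal-plane mirror used to transfer a left-hemisphere rotation to the
#: right hemisphere (reflection of the x axis).
MIRROR = np.diag([-1.0, 1.0, 1.0])


@dataclass(frozen=True)
class SurfaceMesh:
    """A closed triangulated sphere for one hemisphere.

    Vertex coordinates are unit vectors (radius 1, dimensionless); ``faces``
    holds vertex-index triples.  The mesh must be a single connected
    2-manifold without boundary (Euler characteristic V - E + F = 2).
    """

    vertex_coords: np.ndarray  # (V, 3) float64, unit rows
    faces: np.ndarray  # (F, 3) int
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        coords = np.ascontiguousarray(self.vertex_coords, dtype=np.float64)
        faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        object.__setattr__(self, "vertex_coords", coords)
        object.__setattr__(self, "faces", faces)
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")
        norms = np.linalg.norm(coords, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("vertex coordinates must lie on the unit sphere (|x| = 1 within 1e-9)")
        if faces.min() < 0 or faces.max() >= len(coords):
            raise ValueError("face indices out of range")
        if len(np.unique(faces)) != len(coords):
            raise ValueError("every vertex must appear in at least one face")
        v = len(coords)
        e = len(_undirected_edges(faces))
        f = len(faces)
        if v - e + f != 2:
            raise ValueError(f"mesh is not a closed sphere: V-E+F = {v - e + f}, expected 2")

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_coords)

    def adjacency(self) -> sparse.csr_matrix:
        return mesh_adjacency(self)


def _undirected_edges(faces: np.ndarray) -> np.ndarray:
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        [-1, _ICO_T, 0], [1, _ICO_T, 0], [-1, -_ICO_T, 0], [1, -_ICO_T, 0],
        [0, -1, _ICO_T], [0, 1, _ICO_T], [0, -1, -_ICO_T], [0, 1, -_ICO_T],
        [_ICO_T, 0, -1], [_ICO_T, 0, 1], [-_ICO_T, 0, -1], [-_ICO_T, 0, 1],
    ],
    dtype=float,
)
_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


def make_icosphere(subdivisions: int, hemisphere: str = "left") -> SurfaceMesh:
    """Build an icosphere with ``10 * 4**subdivisions + 2`` vertices.

    Deterministic for a fixed subdivision level.  ``subdivisions`` must be in
    [0, 7]; level 7 already has 163,842 vertices (the fsaverage resolution)
    and higher levels are refused to guard memory.
    """
    if not isinstance(subdivisions, (int, np.integer)) or subdivisions < 0:
        raise ValueError(f"subdivisions must be a non-negative integer, got {subdivisions!r}")
    if subdivisions > 7:
        raise ValueError("subdivisions > 7 refused (guards memory)")
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    faces = _ICO_FACES
    for _ in range(subdivisions):
        verts, faces = _subdivide(verts, faces)
    return SurfaceMesh(verts, faces, hemisphere)


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One loop of edge-midpoint subdivision, midpoints projected to the sphere."""
    edges = _undirected_edges(faces)
    midpoint_index = {tuple(e): len(verts) + i for i, e in enumerate(edges)}
    mids = verts[edges[:, 0]] + verts[edges[:, 1]]
    mids /= np.linalg.norm(mids, axis=1, keepdims=True)
    new_verts = np.vstack([verts, mids])

    def mid(a: int, b: int) -> int:
        return midpoint_index[(a, b) if a < b else (b, a)]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
        new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
    return new_verts, np.asarray(new_faces, dtype=np.int64)


def mesh_adjacency(mesh: SurfaceMesh) -> sparse.csr_matrix:
    """Symmetric 0/1 vertex adjacency from the face list."""
    e = _undirected_edges(mesh.faces)
    n = mesh.n_vertices
    a = sparse.coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)
    )
    a = a + a.T
    return a.tocsr()


def smooth_on_mesh(
    mesh: SurfaceMesh,
    values: np.ndarray,
    iterations: int,
    self_weight: float = 0.5,
) -> np.ndarray:
    """Iterated neighbor averaging on the mesh.

    Each iteration replaces ``x`` with
    ``self_weight * x + (1 - self_weight) * (mean over mesh neighbors)``.
    Zero iterations is the identity; constant maps are fixed points; the
    operation is linear in ``values``.  Accepts a single map of length V or a
    (V, k) stack of maps.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if not 0.0 <= self_weight <= 1.0:
        raise ValueError("self_weight must be in [0, 1]")
    x = np.asarray(values, dtype=np.float64)
    if x.shape[0] != mesh.n_vertices:
        raise ValueError(
            f"values has {x.shape[0]} entries, mesh has {mesh.n_vertices} vertices"
        )
    if iterations == 0:
        return x.copy()
    adj = mesh_adjacency(mesh)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    inv_deg = 1.0 / deg
    out = x.copy()
    for _ in range(iterations):
        nb_mean = adj @ out
        if out.ndim == 1:
            nb_mean *= inv_deg
        else:
            nb_mean *= inv_deg[:, None]
        out = self_weight * out + (1.0 - self_weight) * nb_mean
    return out


def fwhm_to_iterations(fwhm_mm: float, mean_edge_mm: float, self_weight: float = 0.5) -> int:
    """Convert a Gaussian-kernel FWHM in mm to smoothing iterations.

    Real cortical smoothing is specified in mm FWHM (e.g. 15 mm); on an
    imported mesh with physical scale the equivalent number of
    neighbor-averaging iterations follows from the random-walk variance each
    iteration adds, ``(1 - self_weight) * edge**2`` per step:
    ``sigma**2 = fwhm**2 / (8 ln 2)`` and
    ``iterations = ceil(sigma**2 / ((1 - self_weight) * edge**2))``.
    """
    if fwhm_mm < 0 or mean_edge_mm <= 0:
        raise ValueError("fwhm must be >= 0 and mean edge length > 0")
    if fwhm_mm == 0:
        return 0
    sigma2 = fwhm_mm**2 / (8.0 * np.log(2.0))
    return int(np.ceil(sigma2 / ((1.0 - self_weight) * mean_edge_mm**2)))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """One rotation matrix drawn uniformly (Haar) from SO(3)."""
    return special_ortho_group.rvs(3, random_state=rng)


@dataclass(frozen=True)
class SpinNull:
    """A bank of spin permutations shared by all map comparisons of a run.

    ``left_maps[k, v]`` gives, for permutation ``k``, the source vertex whose
    value vertex ``v`` receives after the k-th random rotation; ``right_maps``
    is the same for the mirrored rotation on the right hemisphere.  The maps
    are functions, not necessarily bijections: nearest-neighbor reassignment
    may repeat a source index.
    """

    n_perm: int
    left_maps: np.ndarray  # (n_perm, V) int
    right_maps: np.ndarray  # (n_perm, V) int
    seed: int
    n_vertices: int = field(init=False)

    def __post_init__(self) -> None:
        if self.left_maps.shape != self.right_maps.shape:
            raise ValueError("left/right reassignment banks must have equal shape")
        if self.left_maps.shape[0] != self.n_perm:
            raise ValueError("reassignment bank row count must equal n_perm")
        object.__setattr__(self, "n_vertices", self.left_maps.shape[1])

    def apply(self, left_map: np.ndarray, right_map: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Spin a hemisphere pair of maps under every permutation.

        Returns arrays of shape (n_perm, V).
        """
        left_map = np.asarray(left_map)
        right_map = np.asarray(right_map)
        if left_map.shape[0] != self.n_vertices or right_map.shape[0] != self.n_vertices:
            raise ValueError("map length does not match the spin null's vertex count")
        return left_map[self.left_maps], right_map[self.right_maps]

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            n_perm=self.n_perm,
            left_maps=self.left_maps,
            right_maps=self.right_maps,
            seed=self.seed,
        )

    @classmethod
    def load(cls, path) -> "SpinNull":
        with np.load(path) as z:
            return cls(
                n_perm=int(z["n_perm"]),
                left_maps=z["left_maps"],
                right_maps=z["right_maps"],
                seed=int(z["seed"]),
            )


def _nearest_rotated_source(coords: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    """Exact nearest-neighbor reassignment: for every target vertex, the index
    of the rotated source vertex closest by great-circle distance.

    Ties (equidistant rotated vertices) resolve to the lowest source index
    because ``argmax`` returns the first maximizer.
    """
    rotated = coords @ rotation.T  # source coords after rotation
    # cosine similarity == monotone in great-circle distance on the unit sphere
    sim = coords @ rotated.T  # (targets, sources)
    return np.argmax(sim, axis=1)


def build_spin_null(
    mesh_left: SurfaceMesh,
    mesh_right: SurfaceMesh,
    n_perm: int,
    seed: int,
) -> SpinNull:
    """Generate ``n_perm`` spin permutations for a hemisphere pair.

    One uniform rotation R is drawn per permutation for the left hemisphere;
    the right hemisphere uses the sagittally mirrored rotation M R M with
    M = diag(-1, 1, 1).  Each permutation index maps deterministically to one
    rotation via a spawned seed sequence, so individual permutations can be
    regenerated independently.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if mesh_left.n_vertices != mesh_right.n_vertices:
        raise ValueError("hemisphere meshes must have identical vertex counts")
    children = np.random.SeedSequence(seed).spawn(n_perm)
    v = mesh_left.n_vertices
    left_maps = np.empty((n_perm, v), dtype=np.int64)
    right_maps = np.empty((n_perm, v), dtype=np.int64)
    for k, child in enumerate(children):
        rng = np.random.default_rng(child)
        rot = random_rotation(rng)
        left_maps[k] = _nearest_rotated_source(mesh_left.vertex_coords, rot)
        right_maps[k] = _nearest_rotated_source(
            mesh_right.vertex_coords, MIRROR @ rot @ MIRROR
        )
    return SpinNull(n_perm=n_perm, left_maps=left_maps, right_maps=right_maps, seed=seed)
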