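"""Cortical surface parcellation into ~1 cm^2 dipole patches.

A triangulated cortical surface is split into approximately equal-area
patches; each patch carries a centroid and an area-weighted average of its
vertex normals — the dipole orientation used for reciprocity targeting.
The parceling is iterative balanced region growing: k seeds from
farthest-point sampling over triangle centroids, greedy assignment of
triangles to the nearest seed, a Lloyd-style seed update, and one boundary
rebalancing pass, followed by a connectivity cleanup.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SurfaceMesh",
    "CorticalPatch",
    "Parcellation",
    "make_sphere_mesh",
    "make_wavy_sphere_mesh",
    "make_square_mesh",
    "parcellate_surface",
    "patch_normal",
    "nearest_patch",
]


@dataclass
class SurfaceMesh:
    """Triangle mesh with unit per-vertex outward normals (coordinates in mm)."""

    vertices: np.ndarray
    faces: np.ndarray
    vertex_normals: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.vertex_normals = np.asarray(self.vertex_normals, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.vertex_normals.shape != self.vertices.shape:
            raise ValueError("vertex normals must match vertices")
        norms = np.linalg.norm(self.vertex_normals, axis=1)
        bad = ~np.isclose(norms, 1.0, atol=1e-6)
        if bad.any():
            self.vertex_normals = self.vertex_normals / np.where(norms[:, None] > 0, norms[:, None], 1.0)

    @classmethod
    def from_trimesh(cls, tm) -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), np.asarray(tm.vertex_normals))

    @classmethod
    def load(cls, path: str | Path) -> "SurfaceMesh":
        """Read a PLY/STL/OBJ surface."""
        import trimesh

        tm = trimesh.load_mesh(str(path))
        return cls.from_trimesh(tm)

    def save(self, path: str | Path) -> None:
        import trimesh

        tm = trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)
        tm.export(str(path))

    def face_areas_mm2(self) -> np.ndarray:
        v = self.vertices
        a = v[self.faces[:, 1]] - v[self.faces[:, 0]]
        b = v[self.faces[:, 2]] - v[self.faces[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)

    def face_centroids_mm(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def total_area_cm2(self) -> float:
        return float(self.face_areas_mm2().sum()) / 100.0


@dataclass
class CorticalPatch:
    """~1 cm^2 surface parcel: member triangles, area, centroid, averaged normal."""

    id: int
    triangles: np.ndarray
    area_cm2: float
    centroid_mm: np.ndarray
    normal: np.ndarray
    degenerate_normal: bool = False


@dataclass
class Parcellation:
    """Disjoint patches covering every triangle of the mesh."""

    patches: list[CorticalPatch]
    target_area_cm2: float
    n_faces: int

    def centroids(self) -> np.ndarray:
        return np.array([p.centroid_mm for p in self.patches])

    def normals(self) -> np.ndarray:
        return np.array([p.normal for p in self.patches])

    def face_labels(self) -> np.ndarray:
        lab = -np.ones(self.n_faces, dtype=np.int64)
        for p in self.patches:
            lab[p.triangles] = p.id
        return lab

    def to_json(self, path: str | Path) -> None:
        data = {
            "target_area_cm2": self.target_area_cm2,
            "n_faces": self.n_faces,
            "patches": [
                {
                    "id": p.id,
                    "triangles": p.triangles.tolist(),
                    "area_cm2": p.area_cm2,
                    "centroid_mm": p.centroid_mm.tolist(),
                    "normal": p.normal.tolist(),
                }
                for p in self.patches
            ],
        }
        Path(path).write_text(json.dumps(data))

    @classmethod
    def from_json(cls, path: str | Path) -> "Parcellation":
        d = json.loads(Path(path).read_text())
        patches = [
            CorticalPatch(
                id=p["id"],
                triangles=np.asarray(p["triangles"], dtype=np.int64),
                area_cm2=p["area_cm2"],
                centroid_mm=np.asarray(p["centroid_mm"]),
                normal=np.asarray(p["normal"]),
            )
            for p in d["patches"]
        ]
        return cls(patches=patches, target_area_cm2=d["target_area_cm2"], n_faces=d["n_faces"])


# ---------------------------------------------------------------------------
# synthetic cortex fixtures


def make_sphere_mesh(radius_mm: float = 70.0, subdivisions: int = 3, center_mm=(0.0, 0.0, 0.0)) -> SurfaceMesh:
    """Icosphere cortex stand-in with exact outward normals."""
    import trimesh

    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius_mm)
    verts = np.asarray(tm.vertices)
    normals = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    return SurfaceMesh(verts + np.asarray(center_mm), np.asarray(tm.faces), normals)


def make_wavy_sphere_mesh(
    radius_mm: float = 70.0,
    amplitude_mm: float = 5.0,
    n_lobes: int = 6,
    subdivisions: int = 4,
    center_mm=(0.0, 0.0, 0.0),
) -> SurfaceMesh:
    """Sinusoidally perturbed sphere ("wavy gyri") to exercise opposing normals.

    Radius is modulated as ``r(u) = R + A sin(k x/R) sin(k y/R) sin(k z/R)``
    evaluated on unit directions, producing gyral/sulcal-like normal spread.
    """
    import trimesh

    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    u = np.asarray(tm.vertices)
    bump = np.sin(n_lobes * u[:, 0]) * np.sin(n_lobes * u[:, 1]) * np.sin(n_lobes * u[:, 2])
    verts = u * (radius_mm + amplitude_mm * bump)[:, None]
    out = trimesh.Trimesh(vertices=verts, faces=tm.faces, process=False)
    normals = np.asarray(out.vertex_normals)
    normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    return SurfaceMesh(verts + np.asarray(center_mm), np.asarray(out.faces), normals)


def make_square_mesh(side_mm: float = 20.0, n: int = 16) -> SurfaceMesh:
    """Flat square in the z=0 plane (normals +z); exact-tiling test surface."""
    xs = np.linspace(0.0, side_mm, n + 1)
    xv, yv = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xv.ravel(), yv.ravel(), np.zeros(xv.size)])
    faces = []
    for i in range(n):
        for j in range(n):
            v00 = i * (n + 1) + j
            v10 = (i + 1) * (n + 1) + j
            faces.append([v00, v10, v00 + 1])
            faces.append([v10, v10 + 1, v00 + 1])
    normals = np.tile([0.0, 0.0, 1.0], (verts.shape[0], 1))
    return SurfaceMesh(verts, np.asarray(faces), normals)


# ---------------------------------------------------------------------------
# parcellation


def _face_adjacency(faces: np.ndarray) -> list[list[int]]:
    edge_map: dict[tuple[int, int], list[int]] = {}
    for f, (a, b, c) in enumerate(faces):
        for e in ((a, b), (b, c), (c, a)):
            key = (min(e), max(e))
            edge_map.setdefault(key, []).append(f)
    adj: list[list[int]] = [[] for _ in range(len(faces))]
    for fs in edge_map.values():
        if len(fs) == 2:
            adj[fs[0]].append(fs[1])
            adj[fs[1]].append(fs[0])
    return adj


def _components(members: np.ndarray, adj: list[list[int]]) -> list[list[int]]:
    member_set = set(int(m) for m in members)
    seen: set[int] = set()
    comps = []
    for start in members:
        s = int(start)
        if s in seen:
            continue
        stack = [s]
        comp = []
        seen.add(s)
        while stack:
            f = stack.pop()
            comp.append(f)
            for g in adj[f]:
                if g in member_set and g not in seen:
                    seen.add(g)
                    stack.append(g)
        comps.append(comp)
    return comps


def patch_normal(mesh: SurfaceMesh, triangle_ids: np.ndarray, area_weighted: bool = True) -> tuple[np.ndarray, bool]:
    """Averaged outward orientation of a patch, renormalized to unit length.

    Vertex normals of the member triangles are averaged (area-weighted by
    default; plain mean with ``area_weighted=False``).  When opposing
    normals nearly cancel (mean norm < 1e-6) the patch is flagged
    degenerate and the largest member triangle's face normal is used.
    Returns ``(normal, degenerate_flag)``.
    """
    triangle_ids = np.asarray(triangle_ids, dtype=np.int64)
    if triangle_ids.size == 0:
        raise ValueError("patch has no triangles")
    areas = mesh.face_areas_mm2()[triangle_ids]
    vn = mesh.vertex_normals[mesh.faces[triangle_ids]]  # (m, 3 verts, 3)
    per_face = vn.mean(axis=1)
    if area_weighted:
        mean = (per_face * areas[:, None]).sum(axis=0) / max(areas.sum(), 1e-300)
    else:
        mean = per_face.mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-6:
        big = triangle_ids[int(np.argmax(areas))]
        a, b, c = mesh.vertices[mesh.faces[big]]
        n = np.cross(b - a, c - a)
        return n / np.linalg.norm(n), True
    return mean / norm, False


def _farthest_point_seeds(points: np.ndarray, k: int, weights: np.ndarray) -> np.ndarray:
    start = int(np.argmax(weights))  # largest triangle: deterministic
    seeds = [start]
    d = np.linalg.norm(points - points[start], axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d))
        seeds.append(nxt)
        d = np.minimum(d, np.linalg.norm(points - points[nxt], axis=1))
    return np.asarray(seeds)


def parcellate_surface(mesh: SurfaceMesh, target_area_cm2: float = 1.0) -> Parcellation:
    """Partition a surface into round(area/target) approximately equal patches.

    Degenerate (zero-area) triangles are removed from consideration with a
    warning reporting their count; every remaining triangle ends up in
    exactly one patch and patches are edge-connected.
    """
    if target_area_cm2 <= 0:
        raise ValueError("target area must be positive")
    areas = mesh.face_areas_mm2()
    degenerate = areas <= 0
    if degenerate.any():
        warnings.warn(f"removed {int(degenerate.sum())} degenerate zero-area triangles")
    live = np.flatnonzero(~degenerate)
    total_cm2 = areas[live].sum() / 100.0
    if total_cm2 < target_area_cm2:
        raise ValueError("mesh area is smaller than the target patch area")
    k = max(1, int(round(total_cm2 / target_area_cm2)))

    cents = mesh.face_centroids_mm()[live]
    w = areas[live]
    seeds = _farthest_point_seeds(cents, k, w)

    def assign(seed_pts: np.ndarray) -> np.ndarray:
        d2 = ((cents[:, None, :] - seed_pts[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)

    seed_pts = cents[seeds]
    lab = assign(seed_pts)
    for _ in range(2):  # Lloyd refinement: recentre seeds on their regions
        for j in range(k):
            m = lab == j
            if m.any():
                seed_pts[j] = (cents[m] * w[m, None]).sum(axis=0) / w[m].sum()
        lab = assign(seed_pts)

    # one rebalancing pass: move boundary faces from oversized to adjacent
    # undersized patches
    adj_live = _face_adjacency(mesh.faces[live])
    patch_area = np.bincount(lab, weights=w, minlength=k)
    target_mm2 = target_area_cm2 * 100.0
    order = np.argsort(-patch_area)
    for j in order:
        if patch_area[j] <= 1.5 * target_mm2:
            continue
        members = np.flatnonzero(lab == j)
        moved = True
        while patch_area[j] > 1.2 * target_mm2 and moved:
            moved = False
            for f in members:
                if lab[f] != j:
                    continue
                neigh = {lab[g] for g in adj_live[f] if lab[g] != j}
                under = [q for q in neigh if patch_area[q] < patch_area[j] - w[f]]
                if under:
                    q = min(under, key=lambda q: patch_area[q])
                    lab[f] = q
                    patch_area[j] -= w[f]
                    patch_area[q] += w[f]
                    moved = True
                    if patch_area[j] <= 1.2 * target_mm2:
                        break

    # connectivity cleanup: strand minor components onto their best neighbor
    for j in range(k):
        members = np.flatnonzero(lab == j)
        if members.size == 0:
            continue
        comps = _components(members, adj_live)
        if len(comps) <= 1:
            continue
        comps.sort(key=len, reverse=True)
        for comp in comps[1:]:
            votes: dict[int, int] = {}
            for f in comp:
                for g in adj_live[f]:
                    if lab[g] != j:
                        votes[lab[g]] = votes.get(lab[g], 0) + 1
            if votes:
                tgt = max(votes, key=lambda q: (votes[q], -q))
                for f in comp:
                    lab[f] = tgt

    patches = []
    pid = 0
    for j in range(k):
        members = live[np.flatnonzero(lab == j)]
        if members.size == 0:
            continue
        a_cm2 = float(areas[members].sum()) / 100.0
        cen = (mesh.face_centroids_mm()[members] * areas[members, None]).sum(axis=0) / areas[members].sum()
        nrm, degen = patch_normal(mesh, members)
        patches.append(
            CorticalPatch(
                id=pid,
                triangles=members,
                area_cm2=a_cm2,
                centroid_mm=cen,
                normal=nrm,
                degenerate_normal=degen,
            )
        )
        pid += 1
    return Parcellation(patches=patches, target_area_cm2=target_area_cm2, n_faces=mesh.faces.shape[0])


def nearest_patch(parcellation: Parcellation, point_mm: np.ndarray) -> int:
    """Patch id with the closest centroid; ties broken by lowest id."""
    if not parcellation.patches:
        raise ValueError("parcellation is empty")
    pts = parcellation.centroids()
    d = np.linalg.norm(pts - np.asarray(point_mm, dtype=float), axis=1)
    best = np.flatnonzero(np.isclose(d, d.min()))
    return int(min(parcellation.patches[i].id for i in best))
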