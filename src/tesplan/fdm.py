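"""Finite-difference forward solver and reciprocity lead fields.

The quasi-static current-flow equation ``div(sigma grad phi) = -s`` is
discretized on the voxel grid with a 7-point stencil.  The conductance of
each voxel face is the harmonic mean of the two adjacent voxel
conductivities times the spacing (SI), which makes faces adjacent to air
(sigma = 0) naturally insulating — a zero-flux Neumann boundary.  The
resulting operator is symmetric with zero row sums (discrete charge
conservation); the pure-Neumann singularity is removed by grounding one
reference node during the conjugate-gradient solve, after which potentials
are re-referenced to the average over conducting voxels.

Lead fields use the reciprocity construction: one forward solve per
electrode (unit current against a fixed reference electrode) yields, via
``entry(e, p) = grad(phi_e)(centroid_p) . n_p / I``, the scalp voltage that
a unit dipole at patch ``p`` oriented along its normal would produce at
electrode ``e``.  Columns are re-referenced to the average over electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from tesplan.phantom import ElectrodeSet, VoxelHeadModel

__all__ = [
    "FDMSystem",
    "InjectionPattern",
    "PotentialField",
    "LeadFieldMatrix",
    "CurrentDensityField",
    "assemble_fdm_system",
    "solve_injection",
    "solve_monopoles",
    "lead_field_from_reciprocity",
    "current_density",
]

_MM = 1e-3


@dataclass
class InjectionPattern:
    """Per-electrode injected currents in microamperes; must sum to zero."""

    currents_ua: np.ndarray

    def __post_init__(self) -> None:
        self.currents_ua = np.asarray(self.currents_ua, dtype=float)
        mx = np.max(np.abs(self.currents_ua)) if self.currents_ua.size else 0.0
        if mx > 0 and abs(self.currents_ua.sum()) > 1e-9 * mx:
            raise ValueError(
                f"injection currents must sum to zero (sum={self.currents_ua.sum():g} uA)"
            )


@dataclass
class PotentialField:
    """Scalar potential per voxel (V); NaN-free in conducting voxels."""

    values: np.ndarray
    reference: str = "average"
    spacing_mm: float = 1.0


@dataclass
class CurrentDensityField:
    """Vector current density per voxel (A/m^2), zero in air."""

    values: np.ndarray  # (nx, ny, nz, 3)
    spacing_mm: float = 1.0


@dataclass
class FDMSystem:
    """Assembled sparse system for one head model."""

    model: VoxelHeadModel
    laplacian: sp.csr_matrix  # symmetric, zero row sums, conducting voxels only
    index: np.ndarray  # voxel -> unknown index (-1 in air)
    voxels: np.ndarray  # unknown -> (i, j, k)

    @property
    def n_unknowns(self) -> int:
        return self.voxels.shape[0]

    def node_of_point(self, point_mm: np.ndarray, what: str = "point") -> int:
        """Unknown index of the conducting voxel nearest a point."""
        i, j, k = self.model.point_to_voxel(np.asarray(point_mm, dtype=float))
        node = int(self.index[i, j, k])
        if node >= 0:
            return node
        # nearest conducting voxel by Euclidean distance on voxel indices
        d2 = np.sum((self.voxels - np.array([i, j, k])) ** 2, axis=1)
        best = int(np.argmin(d2))
        if d2[best] > 3**2:
            raise ValueError(f"{what} at voxel {(i, j, k)} is far from any conducting voxel")
        return best


def assemble_fdm_system(model: VoxelHeadModel) -> FDMSystem:
    """Build the 7-point stencil operator with harmonic-mean face conductances.

    Raises if the model has no conducting voxel or the conducting region is
    disconnected (face connectivity), listing component sizes.
    """
    cond = model.conductivity
    mask = cond > 0
    if not mask.any():
        raise ValueError("model has no conducting voxel")
    labels, ncomp = ndi.label(mask, structure=ndi.generate_binary_structure(3, 1))
    if ncomp > 1:
        sizes = sorted((int(s) for s in np.bincount(labels.ravel())[1:]), reverse=True)
        raise ValueError(
            f"conducting region is disconnected: {ncomp} components with sizes {sizes}"
        )

    index = -np.ones(model.shape, dtype=np.int64)
    voxels = np.argwhere(mask)
    index[mask] = np.arange(voxels.shape[0])

    h = model.spacing_mm * _MM
    rows, cols, vals = [], [], []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(0, -1)
        sl_b[axis] = slice(1, None)
        ca = cond[tuple(sl_a)]
        cb = cond[tuple(sl_b)]
        both = (ca > 0) & (cb > 0)
        # face conductance (S): harmonic mean conductivity * spacing
        g = np.zeros_like(ca)
        g[both] = 2.0 * ca[both] * cb[both] / (ca[both] + cb[both]) * h
        ia = index[tuple(sl_a)][both]
        ib = index[tuple(sl_b)][both]
        gg = g[both]
        rows.extend([ia, ib])
        cols.extend([ib, ia])
        vals.extend([-gg, -gg])
        rows.extend([ia, ib])
        cols.extend([ia, ib])
        vals.extend([gg, gg])
    n = voxels.shape[0]
    L = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()
    return FDMSystem(model=model, laplacian=L, index=index, voxels=voxels)


def _grounded_solve(system: FDMSystem, b: np.ndarray, tol: float) -> np.ndarray:
    """Solve L x = b with node 0 grounded, return average-referenced x."""
    if abs(b.sum()) > 1e-9 * max(1.0, np.max(np.abs(b))):
        raise ValueError("source vector must sum to zero (pure Neumann problem)")
    L = system.laplacian
    n = system.n_unknowns
    keep = np.arange(1, n)
    Lr = L[keep][:, keep].tocsr()
    br = b[keep]
    diag = Lr.diagonal()
    M = spla.LinearOperator(Lr.shape, matvec=lambda v: v / diag)
    x0 = np.zeros(n - 1)
    xr, info = spla.cg(Lr, br, x0=x0, rtol=tol, atol=0.0, M=M, maxiter=200_000)
    if info != 0:
        raise RuntimeError(f"CG failed to converge (info={info})")
    x = np.zeros(n)
    x[keep] = xr
    return x - x.mean()


def solve_monopoles(
    system: FDMSystem,
    points_mm: np.ndarray,
    currents_a: np.ndarray,
    tol: float = 1e-8,
) -> PotentialField:
    """Forward solve for point current sources at arbitrary conducting locations.

    Currents in amperes, zero-sum.  Returns the potential (V) on the full
    grid, average-referenced over conducting voxels; air voxels are NaN.
    """
    b = np.zeros(system.n_unknowns)
    for p, I in zip(np.atleast_2d(points_mm), np.asarray(currents_a, dtype=float)):
        b[system.node_of_point(p, "source")] += I
    x = _grounded_solve(system, b, tol)
    vol = np.full(system.model.shape, np.nan)
    vol[tuple(system.voxels.T)] = x
    return PotentialField(values=vol, reference="average", spacing_mm=system.model.spacing_mm)


def solve_injection(
    system: FDMSystem,
    electrodes: ElectrodeSet,
    pattern: InjectionPattern,
    tol: float = 1e-8,
) -> PotentialField:
    """Forward solve for a zero-sum electrode injection pattern (uA)."""
    if len(pattern.currents_ua) != len(electrodes):
        raise ValueError("pattern length must match electrode count")
    if not np.any(pattern.currents_ua):
        vol = np.full(system.model.shape, np.nan)
        vol[tuple(system.voxels.T)] = 0.0
        return PotentialField(values=vol, reference="average", spacing_mm=system.model.spacing_mm)
    return solve_monopoles(
        system, electrodes.positions_mm, pattern.currents_ua * 1e-6, tol=tol
    )


def _gradient_at(system: FDMSystem, phi_flat: np.ndarray, voxel: tuple[int, int, int]) -> np.ndarray:
    """Central-difference gradient (V/m) of an unknown-vector potential at a voxel.

    Falls back to one-sided differences at air boundaries.
    """
    h = system.model.spacing_mm * _MM
    g = np.zeros(3)
    idx = system.index
    shape = system.model.shape
    for axis in range(3):
        lo = list(voxel)
        hi = list(voxel)
        lo[axis] -= 1
        hi[axis] += 1
        n_lo = idx[tuple(lo)] if lo[axis] >= 0 else -1
        n_hi = idx[tuple(hi)] if hi[axis] < shape[axis] else -1
        n_c = idx[voxel]
        if n_lo >= 0 and n_hi >= 0:
            g[axis] = (phi_flat[n_hi] - phi_flat[n_lo]) / (2 * h)
        elif n_hi >= 0:
            g[axis] = (phi_flat[n_hi] - phi_flat[n_c]) / h
        elif n_lo >= 0:
            g[axis] = (phi_flat[n_c] - phi_flat[n_lo]) / h
    return g


@dataclass
class LeadFieldMatrix:
    """Electrodes x patches map: volts at the electrode per unit dipole (A·m).

    Dipoles are oriented along each patch's averaged outward normal; rows
    are average-referenced over electrodes.
    """

    matrix: np.ndarray
    electrode_ids: list[str]
    patch_ids: list[int]
    reference: str = "average"

    def column(self, patch_id: int) -> np.ndarray:
        try:
            j = self.patch_ids.index(patch_id)
        except ValueError:
            raise KeyError(f"patch {patch_id} not in lead field") from None
        return self.matrix[:, j]

    def save_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("matrix", data=self.matrix)
            f.create_dataset("electrode_ids", data=np.array(self.electrode_ids, dtype="S"))
            f.create_dataset("patch_ids", data=np.asarray(self.patch_ids, dtype=np.int64))
            f.attrs["reference"] = self.reference

    @classmethod
    def load_hdf5(cls, path: str | Path) -> "LeadFieldMatrix":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                matrix=f["matrix"][()],
                electrode_ids=[s.decode() for s in f["electrode_ids"][()]],
                patch_ids=[int(i) for i in f["patch_ids"][()]],
                reference=str(f.attrs["reference"]),
            )


def lead_field_from_reciprocity(
    system: FDMSystem,
    electrodes: ElectrodeSet,
    parcellation,
    tol: float = 1e-8,
    reference_electrode: int = 0,
    return_solutions: bool = False,
):
    """Build the lead-field matrix from per-electrode reciprocal solves.

    For each electrode a unit current is injected against the fixed
    reference electrode; the entry for patch ``p`` is the directional
    derivative of that potential at the patch centroid along the patch
    normal.  Rows are then re-referenced to the electrode average, which
    also yields a valid row for the reference electrode itself.

    Patch centroids must map to conducting voxels (gray matter on the
    standard phantom); a centroid stranded in air raises an error naming
    the patch.

    With ``return_solutions=True`` the per-electrode unknown-vector
    potentials are returned as well (used for fast montage evaluation by
    superposition).
    """
    n_el = len(electrodes)
    if n_el < 2:
        raise ValueError("need at least 2 electrodes")
    patches = parcellation.patches
    centroids = np.array([p.centroid_mm for p in patches])
    normals = np.array([p.normal for p in patches])

    patch_voxels = []
    for p, c in zip(patches, centroids):
        i, j, k = system.model.point_to_voxel(c)
        if system.index[i, j, k] < 0:
            d2 = np.sum((system.voxels - np.array([i, j, k])) ** 2, axis=1)
            best = int(np.argmin(d2))
            if d2[best] > 3**2:
                raise ValueError(f"patch {p.id} centroid {c} lies in air, far from conducting tissue")
            i, j, k = (int(v) for v in system.voxels[best])
        patch_voxels.append((i, j, k))

    ref_node = system.node_of_point(electrodes.positions_mm[reference_electrode], "reference electrode")
    I_unit = 1.0  # ampere; entries are per unit current, so the value is immaterial

    M = np.zeros((n_el, len(patches)))
    solutions = np.zeros((n_el, system.n_unknowns))
    for e in range(n_el):
        if e == reference_electrode:
            continue
        node = system.node_of_point(electrodes.positions_mm[e], f"electrode {electrodes.ids[e]}")
        b = np.zeros(system.n_unknowns)
        b[node] += I_unit
        b[ref_node] -= I_unit
        x = _grounded_solve(system, b, tol)
        solutions[e] = x
        for j, vox in enumerate(patch_voxels):
            M[e, j] = _gradient_at(system, x, vox) @ normals[j] / I_unit
    M = M - M.mean(axis=0, keepdims=True)
    lfm = LeadFieldMatrix(
        matrix=M, electrode_ids=list(electrodes.ids), patch_ids=[p.id for p in patches]
    )
    if return_solutions:
        return lfm, solutions
    return lfm


def dipole_scalp_voltages(
    system: FDMSystem,
    electrodes: ElectrodeSet,
    position_mm: np.ndarray,
    normal: np.ndarray,
    moment_am: float = 1.0,
    tol: float = 1e-8,
) -> np.ndarray:
    """Average-referenced electrode voltages from a discrete dipole source.

    The dipole is represented as pairs of opposite monopoles one grid
    spacing apart along each axis component of ``normal`` (the adjoint of
    the central-difference stencil), with total moment ``moment_am`` (A·m).
    This is the direct-solve counterpart of a reciprocity lead-field entry:
    by symmetry of the discrete operator the two must agree to solver
    tolerance.
    """
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    v = system.model.point_to_voxel(np.asarray(position_mm, dtype=float))
    if system.index[v] < 0:
        raise ValueError(f"dipole position {position_mm} lies in air")
    h = system.model.spacing_mm * _MM
    b = np.zeros(system.n_unknowns)
    for axis in range(3):
        if normal[axis] == 0.0:
            continue
        hi = list(v)
        lo = list(v)
        hi[axis] += 1
        lo[axis] -= 1
        n_hi = system.index[tuple(hi)] if hi[axis] < system.model.shape[axis] else -1
        n_lo = system.index[tuple(lo)] if lo[axis] >= 0 else -1
        q = moment_am * normal[axis] / (2 * h)
        if n_hi >= 0 and n_lo >= 0:
            b[n_hi] += q
            b[n_lo] -= q
        elif n_hi >= 0:  # one-sided at boundaries, mirroring the gradient stencil
            b[n_hi] += 2 * q
            b[system.index[v]] -= 2 * q
        elif n_lo >= 0:
            b[system.index[v]] += 2 * q
            b[n_lo] -= 2 * q
        else:
            raise ValueError("dipole has no conducting neighbors along a needed axis")
    x = _grounded_solve(system, b, tol)
    volts = np.array(
        [x[system.node_of_point(p, f"electrode {eid}")] for eid, p in zip(electrodes.ids, electrodes.positions_mm)]
    )
    return volts - volts.mean()


def sample_surface_potential(
    system: FDMSystem,
    field: PotentialField,
    directions: np.ndarray,
    center_mm: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the potential at the outermost conducting voxel along each ray.

    Returns ``(positions_mm, values)`` where positions are the sampled voxel
    centers — the natural "scalp electrode" sampling that stays well defined
    at coarse spacings where thin shells are not contiguous.
    """
    model = system.model
    if center_mm is None:
        center_mm = getattr(model, "_center_mm", None)
    if center_mm is None:
        idx = np.argwhere(model.conducting_mask)
        center_mm = (idx.mean(axis=0) + 0.5) * model.spacing_mm
    center_mm = np.asarray(center_mm, dtype=float)
    h = model.spacing_mm
    r_max = float(np.max(np.array(model.shape)) * h)
    positions, values = [], []
    for d in np.atleast_2d(directions):
        d = np.asarray(d, dtype=float)
        d = d / np.linalg.norm(d)
        hit = None
        for r in np.arange(r_max, 0.0, -h / 4.0):
            i, j, k = np.floor((center_mm + r * d) / h).astype(int)
            if not (0 <= i < model.shape[0] and 0 <= j < model.shape[1] and 0 <= k < model.shape[2]):
                continue
            if system.index[i, j, k] >= 0:
                hit = (int(i), int(j), int(k))
                break
        if hit is None:
            raise ValueError(f"ray along {d} never crossed conducting tissue")
        positions.append((np.array(hit) + 0.5) * h)
        values.append(field.values[hit])
    return np.array(positions), np.array(values)


def current_density(model: VoxelHeadModel, potential: PotentialField) -> CurrentDensityField:
    """J = -sigma grad(phi) by central differences (A/m^2); zero in air.

    Differences straddling air use one-sided stencils so the field stays
    finite up to the boundary.
    """
    if potential.values.shape != model.shape:
        raise ValueError("potential shape does not match model")
    phi = potential.values
    h = model.spacing_mm * _MM
    cond = model.conductivity
    mask = cond > 0
    J = np.zeros(model.shape + (3,))
    phi0 = np.where(mask, phi, 0.0)
    for axis in range(3):
        fwd = np.zeros(model.shape)
        bwd = np.zeros(model.shape)
        ok_f = np.zeros(model.shape, dtype=bool)
        ok_b = np.zeros(model.shape, dtype=bool)
        sl_c = [slice(None)] * 3
        sl_f = [slice(None)] * 3
        sl_c[axis] = slice(0, -1)
        sl_f[axis] = slice(1, None)
        dif = phi0[tuple(sl_f)] - phi0[tuple(sl_c)]
        valid = mask[tuple(sl_f)] & mask[tuple(sl_c)]
        fwd[tuple(sl_c)] = np.where(valid, dif, 0.0)
        ok_f[tuple(sl_c)] = valid
        bwd[tuple(sl_f)] = np.where(valid, dif, 0.0)
        ok_b[tuple(sl_f)] = valid
        denom = (ok_f.astype(float) + ok_b.astype(float)) * h
        grad = np.zeros(model.shape)
        np.divide(fwd + bwd, denom, out=grad, where=denom > 0)
        J[..., axis] = -cond * grad
    J[~mask] = 0.0
    return CurrentDensityField(values=J, spacing_mm=model.spacing_mm)
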