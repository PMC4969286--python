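"""Synthetic volume-conductor head phantoms and geodesic electrode layouts.

The phantoms are voxelized concentric-shell models (scalp/skull/CSF/brain)
on a regular isotropic grid.  They stand in for MRI-derived individual head
models: every voxel carries one of seven tissue labels and the isotropic
conductivity assigned to that tissue.  Electrode layouts emulate a dense
geodesic sensor net: approximately evenly spaced points on the upper scalp
surface, produced by Fibonacci-spiral sampling of a spherical cap followed
by ray projection onto the voxelized scalp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TISSUES",
    "AIR",
    "ConductivityTable",
    "DEFAULT_CONDUCTIVITIES",
    "ShellSpec",
    "VoxelHeadModel",
    "ElectrodeSet",
    "build_shell_phantom",
    "assign_conductivities",
    "place_geodesic_electrodes",
]

#: Canonical tissue order; voxel labels are indices into this tuple.
TISSUES = ("air", "scalp", "skull", "csf", "gray_matter", "white_matter", "eyeball")
AIR = 0

_BRAIN_TISSUES = {"gray_matter", "white_matter"}


@dataclass(frozen=True)
class ConductivityTable:
    """Isotropic tissue conductivities in S/m.

    Must cover all seven tissue labels; air is exactly 0 and every value is
    non-negative.
    """

    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(TISSUES) - set(self.values)
        if missing:
            raise ValueError(f"conductivity table missing tissues: {sorted(missing)}")
        extra = set(self.values) - set(TISSUES)
        if extra:
            raise ValueError(f"unknown tissues in conductivity table: {sorted(extra)}")
        for name, sigma in self.values.items():
            if not np.isfinite(sigma) or sigma < 0:
                raise ValueError(f"conductivity of {name!r} must be finite and >= 0, got {sigma}")
        if self.values["air"] != 0.0:
            raise ValueError("air conductivity must be exactly 0")

    def __getitem__(self, tissue: str) -> float:
        try:
            return self.values[tissue]
        except KeyError:
            raise KeyError(f"tissue {tissue!r} not in conductivity table") from None

    def as_array(self) -> np.ndarray:
        """Conductivity per label code, aligned with :data:`TISSUES`."""
        return np.array([self.values[t] for t in TISSUES], dtype=float)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.values, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConductivityTable":
        return cls(json.loads(Path(path).read_text()))


#: Literature tissue conductivities (S/m) used throughout the package.
DEFAULT_CONDUCTIVITIES = ConductivityTable(
    {
        "eyeball": 1.5,
        "scalp": 0.44,
        "skull": 0.018,
        "csf": 1.79,
        "gray_matter": 0.25,
        "white_matter": 0.35,
        "air": 0.0,
    }
)


@dataclass(frozen=True)
class ShellSpec:
    """Concentric-shell geometry: outer radii (mm, strictly increasing) and tissues.

    ``shells[k]`` is ``(outer_radius_mm, tissue)``; region k occupies radii
    between the previous shell radius (0 for the innermost) and its own.
    The innermost tissue must be a brain tissue.
    """

    shells: tuple[tuple[float, str], ...]
    center_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not self.shells:
            raise ValueError("shell spec needs at least one shell")
        radii = [r for r, _ in self.shells]
        if any(r2 <= r1 for r1, r2 in zip(radii, radii[1:])):
            raise ValueError(f"shell radii must be strictly increasing, got {radii}")
        if radii[0] <= 0:
            raise ValueError("innermost radius must be positive")
        for _, tissue in self.shells:
            if tissue not in TISSUES:
                raise ValueError(f"unknown tissue {tissue!r}")

    @property
    def radii_mm(self) -> tuple[float, ...]:
        return tuple(r for r, _ in self.shells)

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(t for _, t in self.shells)

    @property
    def outer_radius_mm(self) -> float:
        return self.shells[-1][0]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"shells": [list(s) for s in self.shells], "center_mm": self.center_mm}, indent=2)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ShellSpec":
        d = json.loads(Path(path).read_text())
        center = tuple(d["center_mm"]) if d.get("center_mm") else None
        return cls(tuple((float(r), t) for r, t in d["shells"]), center)


#: Default 4-shell head: gray matter core, thin CSF, resistive skull, scalp.
#: Eyeball is omitted — a concentric phantom has no anatomical analog for it.
DEFAULT_4SHELL = ShellSpec(
    shells=((78.0, "gray_matter"), (80.0, "csf"), (85.0, "skull"), (92.0, "scalp"))
)


@dataclass
class VoxelHeadModel:
    """Labeled conductivity volume on a regular isotropic grid.

    ``labels`` holds tissue codes (indices into :data:`TISSUES`);
    ``conductivity`` is in S/m and always equals the label volume mapped
    through a :class:`ConductivityTable`.  Coordinates are millimeters in a
    right-handed grid-aligned frame with the origin at the volume corner:
    voxel ``(i,j,k)`` has its center at ``(i+0.5, j+0.5, k+0.5) * spacing``.
    """

    labels: np.ndarray
    spacing_mm: float
    conductivity: np.ndarray
    table: ConductivityTable = field(default_factory=lambda: DEFAULT_CONDUCTIVITIES)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D volume")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        if self.labels.min() < 0 or self.labels.max() >= len(TISSUES):
            raise ValueError("labels out of range of the seven tissues")
        if self.conductivity.shape != self.labels.shape:
            raise ValueError("conductivity volume must match label volume shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nx, ny, nz = self.shape
        h = self.spacing_mm
        return (
            (np.arange(nx) + 0.5) * h,
            (np.arange(ny) + 0.5) * h,
            (np.arange(nz) + 0.5) * h,
        )

    def tissue_mask(self, tissue: str) -> np.ndarray:
        return self.labels == TISSUES.index(tissue)

    @property
    def conducting_mask(self) -> np.ndarray:
        return self.conductivity > 0

    def point_to_voxel(self, point_mm: np.ndarray) -> tuple[int, int, int]:
        """Voxel index containing a point (clipped to the grid)."""
        idx = np.floor(np.asarray(point_mm, dtype=float) / self.spacing_mm).astype(int)
        idx = np.clip(idx, 0, np.array(self.shape) - 1)
        return tuple(int(i) for i in idx)


def build_shell_phantom(
    spec: ShellSpec = DEFAULT_4SHELL,
    spacing_mm: float = 2.0,
    table: ConductivityTable = DEFAULT_CONDUCTIVITIES,
    margin_voxels: int = 2,
) -> VoxelHeadModel:
    """Voxelize a concentric-shell spec into a labeled head model.

    Each voxel is labeled by the innermost shell whose outer radius contains
    the voxel center (a point-membership rule, no partial-volume weighting);
    voxels outside the outermost shell are air.  The grid is sized so an air
    layer of ``margin_voxels`` voxels surrounds the outermost shell.
    """
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    r_out = spec.outer_radius_mm
    half = int(np.ceil(r_out / spacing_mm)) + margin_voxels
    n = 2 * half  # grid centered on the shell center
    center = np.full(3, half * spacing_mm) if spec.center_mm is None else np.asarray(spec.center_mm)

    xs, ys, zs = ((np.arange(n) + 0.5) * spacing_mm for _ in range(3))
    dx = xs - center[0]
    dy = ys - center[1]
    dz = zs - center[2]
    r2 = dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2

    labels = np.zeros((n, n, n), dtype=np.int8)
    # Assign from outermost inwards so inner shells overwrite outer ones.
    for radius, tissue in reversed(spec.shells):
        labels[r2 <= radius**2] = TISSUES.index(tissue)

    model = VoxelHeadModel(labels=labels, spacing_mm=spacing_mm, conductivity=np.zeros_like(labels, dtype=float))
    model._center_mm = center  # geometric center; used by electrode placement
    return assign_conductivities(model, table)


def assign_conductivities(model: VoxelHeadModel, table: ConductivityTable) -> VoxelHeadModel:
    """Map the label volume through a conductivity table (in place, returned)."""
    present = np.unique(model.labels)
    for code in present:
        name = TISSUES[int(code)]
        if name not in table.values:
            raise KeyError(f"tissue {name!r} present in model but absent from table")
    model.conductivity = table.as_array()[model.labels]
    model.table = table
    return model


@dataclass
class ElectrodeSet:
    """Scalp electrodes: unique ids, positions (mm) on the scalp surface, contact areas (cm^2)."""

    ids: list[str]
    positions_mm: np.ndarray
    areas_cm2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions_mm = np.atleast_2d(np.asarray(self.positions_mm, dtype=float))
        if self.positions_mm.shape != (len(self.ids), 3):
            raise ValueError("positions must be (n_electrodes, 3)")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate electrode ids: {dupes}")
        if self.areas_cm2 is None:
            self.areas_cm2 = np.ones(len(self.ids))
        else:
            self.areas_cm2 = np.asarray(self.areas_cm2, dtype=float)
            if self.areas_cm2.shape != (len(self.ids),):
                raise ValueError("areas must have one entry per electrode")

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, electrode_id: str) -> int:
        try:
            return self.ids.index(electrode_id)
        except ValueError:
            raise KeyError(f"unknown electrode id {electrode_id!r}") from None

    def validate_on_scalp(self, model: VoxelHeadModel) -> None:
        """Check every position lies within one voxel of a scalp-labeled voxel."""
        scalp = model.tissue_mask("scalp")
        h = model.spacing_mm
        for eid, pos in zip(self.ids, self.positions_mm):
            i, j, k = model.point_to_voxel(pos)
            lo = np.maximum([i - 1, j - 1, k - 1], 0)
            hi = np.minimum([i + 2, j + 2, k + 2], model.shape)
            if not scalp[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].any():
                raise ValueError(f"electrode {eid!r} at {pos} (voxel {(i, j, k)}, h={h}) is not near scalp")


def _fibonacci_cap_directions(n: int, polar_cutoff_deg: float) -> np.ndarray:
    """n unit vectors approximately evenly spread over the polar cap theta <= cutoff."""
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n)
    cos_max = np.cos(np.deg2rad(polar_cutoff_deg))
    # Equal-area stratification of cos(theta) over [cos_max, 1].
    cos_t = 1.0 - (i + 0.5) / n * (1.0 - cos_max)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    phi = i * golden
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def place_geodesic_electrodes(
    model: VoxelHeadModel,
    n_electrodes: int,
    polar_cutoff_deg: float = 120.0,
    center_mm: np.ndarray | None = None,
) -> ElectrodeSet:
    """Place ~evenly spaced electrodes on the upper scalp surface.

    Directions are sampled on a spherical spiral over a polar cap (default
    120 degrees, mimicking a sensor-net coverage that spares the lower head),
    then each is projected inward from outside the head onto the outermost
    scalp voxel along that ray.  The +z axis is "up".

    Raises if fewer than ``n_electrodes`` distinct scalp positions can be
    resolved at the model's voxel resolution.
    """
    if n_electrodes < 2:
        raise ValueError("need at least 2 electrodes")
    scalp = model.tissue_mask("scalp")
    if not scalp.any():
        raise ValueError("model has no scalp voxels")
    if center_mm is None:
        center_mm = getattr(model, "_center_mm", None)
    if center_mm is None:
        idx = np.argwhere(model.conducting_mask)
        center_mm = (idx.mean(axis=0) + 0.5) * model.spacing_mm
    center_mm = np.asarray(center_mm, dtype=float)

    h = model.spacing_mm
    r_max = float(np.max(np.array(model.shape)) * h)
    dirs = _fibonacci_cap_directions(n_electrodes, polar_cutoff_deg)

    positions = []
    taken: set[tuple[int, int, int]] = set()
    for d in dirs:
        # march inward from outside the volume; first scalp voxel wins
        hit = None
        for r in np.arange(r_max, 0.0, -h / 4.0):
            p = center_mm + r * d
            i, j, k = np.floor(p / h).astype(int)
            if not (0 <= i < model.shape[0] and 0 <= j < model.shape[1] and 0 <= k < model.shape[2]):
                continue
            if scalp[i, j, k]:
                hit = (int(i), int(j), int(k))
                break
        if hit is None:
            raise ValueError(f"ray along {d} never crossed scalp; check phantom geometry")
        if hit in taken:
            raise ValueError(
                f"{n_electrodes} electrodes exceed the scalp surface resolution at {h} mm spacing"
            )
        taken.add(hit)
        positions.append((np.array(hit) + 0.5) * h)

    ids = [f"E{i + 1:03d}" for i in range(n_electrodes)]
    es = ElectrodeSet(ids=ids, positions_mm=np.array(positions))
    es.validate_on_scalp(model)
    return es
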