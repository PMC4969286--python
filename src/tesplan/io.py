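"""Standard-format readers and writers.

Coordinates are millimeters in a right-handed grid-aligned frame with the
origin at the volume corner; NIfTI affines encode the voxel spacing on the
diagonal so label and conductivity volumes round-trip through other tools.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from tesplan.phantom import ConductivityTable, DEFAULT_CONDUCTIVITIES, ElectrodeSet, VoxelHeadModel
from tesplan.targeting import Montage

__all__ = [
    "save_label_volume",
    "load_label_volume",
    "save_potential_nifti",
    "load_electrode_positions",
    "save_electrode_positions",
    "save_montage_json",
    "load_montage_json",
    "save_montage_csv",
]


def _affine(spacing_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = spacing_mm
    aff[:3, 3] = spacing_mm / 2.0  # voxel (0,0,0) center
    return aff


def save_label_volume(model: VoxelHeadModel, path: str | Path, what: str = "labels") -> None:
    """Write the label or conductivity volume as NIfTI."""
    import nibabel as nib

    if what == "labels":
        data = model.labels.astype(np.int16)
    elif what == "conductivity":
        data = model.conductivity.astype(np.float32)
    else:
        raise ValueError("what must be 'labels' or 'conductivity'")
    nib.save(nib.Nifti1Image(data, _affine(model.spacing_mm)), str(path))


def load_label_volume(
    path: str | Path, table: ConductivityTable = DEFAULT_CONDUCTIVITIES
) -> VoxelHeadModel:
    """Read a label NIfTI back into a head model (conductivities reassigned)."""
    import nibabel as nib

    from tesplan.phantom import assign_conductivities

    img = nib.load(str(path))
    spacing = float(img.affine[0, 0])
    labels = np.asarray(img.get_fdata(), dtype=np.int8)
    model = VoxelHeadModel(
        labels=labels, spacing_mm=spacing, conductivity=np.zeros(labels.shape)
    )
    return assign_conductivities(model, table)


def save_potential_nifti(values: np.ndarray, spacing_mm: float, path: str | Path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(values.astype(np.float32), _affine(spacing_mm)), str(path))


def load_electrode_positions(path: str | Path) -> ElectrodeSet:
    """Read electrodes from CSV (id,x,y,z[,area]) or .sfp-style whitespace text.

    The area column defaults to 1.0 cm^2 when absent.  Malformed rows and
    duplicate ids raise errors that name the offending line.
    """
    path = Path(path)
    ids: list[str] = []
    pos: list[list[float]] = []
    areas: list[float] = []
    text = path.read_text().strip().splitlines()
    is_csv = path.suffix.lower() == ".csv" or ("," in text[0] if text else False)
    start = 0
    if is_csv and text and text[0].lower().replace(" ", "").startswith("id,"):
        start = 1  # header
    for lineno, line in enumerate(text[start:], start=start + 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in (line.split(",") if is_csv else line.split())]
        if len(parts) not in (4, 5):
            raise ValueError(f"{path.name}:{lineno}: expected id,x,y,z[,area], got {line!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
            area = float(parts[4]) if len(parts) == 5 else 1.0
        except ValueError:
            raise ValueError(f"{path.name}:{lineno}: non-numeric coordinate in {line!r}") from None
        if parts[0] in ids:
            raise ValueError(f"{path.name}:{lineno}: duplicate electrode id {parts[0]!r}")
        ids.append(parts[0])
        pos.append(xyz)
        areas.append(area)
    if not ids:
        raise ValueError(f"{path.name}: no electrodes found")
    return ElectrodeSet(ids=ids, positions_mm=np.asarray(pos), areas_cm2=np.asarray(areas))


def save_electrode_positions(electrodes: ElectrodeSet, path: str | Path) -> None:
    """Write electrodes as CSV (``.csv``) or .sfp-style text (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        with path.open("w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["id", "x", "y", "z", "area"])
            for eid, p, a in zip(electrodes.ids, electrodes.positions_mm, electrodes.areas_cm2):
                w.writerow([eid, f"{p[0]:.6f}", f"{p[1]:.6f}", f"{p[2]:.6f}", f"{a:g}"])
    else:
        with path.open("w") as f:
            for eid, p, a in zip(electrodes.ids, electrodes.positions_mm, electrodes.areas_cm2):
                f.write(f"{eid}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}\t{a:g}\n")


def save_montage_json(montage: Montage, path: str | Path, meta: dict | None = None) -> None:
    data = {"currents_ua": montage.to_dict()}
    if meta:
        data["meta"] = meta
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))


def load_montage_json(path: str | Path) -> Montage:
    d = json.loads(Path(path).read_text())["currents_ua"]
    return Montage(electrode_ids=list(d.keys()), currents_ua=np.array(list(d.values())))


def save_montage_csv(montage: Montage, path: str | Path) -> None:
    with Path(path).open("w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["electrode", "current_ua"])
        for eid, c in zip(montage.electrode_ids, montage.currents_ua):
            w.writerow([eid, f"{c:.6f}"])
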