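"""Serialization: HDF5 containers, CSV tables, legacy-ASCII VTK fields.

Internally the AP axis is ``z``; serialized vector fields follow the
presentation convention in which the AP axis is relabelled to ``x`` (axes
cycled ``z -> x, x -> y, y -> z``), so downstream tools see anterior at low
x.  All containers embed the resolved configuration as JSON metadata.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .fields import CoarseGrid, MotorVelocityField
from .geometry import OocyteGeometry
from .nucleation import SeedingDensityParams, SeedSet
from .polymer import CytoskeletonRealization, PolymerParams

__all__ = [
    "save_realization",
    "load_realization",
    "save_field_h5",
    "load_field_h5",
    "write_vtk_structured",
    "ap_axis_to_x",
]


def ap_axis_to_x(vectors: np.ndarray) -> np.ndarray:
    """Cycle vector components so the internal z (AP) axis becomes x."""
    return vectors[..., [2, 0, 1]]


def _meta(**kwargs) -> str:
    return json.dumps(kwargs, sort_keys=True)


def save_realization(path, realization: CytoskeletonRealization) -> None:
    """Write a cytoskeleton realization to HDF5.

    Layout: ``/seeds/{cap,rho,phi,position,normal}``,
    ``/polymers/{offsets,orientations,midpoints,target_length,terminated_by}``,
    and a JSON ``meta`` attribute with geometry/seeding/polymer parameters
    and the RNG seed.
    """
    r = realization
    with h5py.File(path, "w") as f:
        f.attrs["meta"] = _meta(
            geometry=r.geometry.to_dict(),
            seeding=r.seeds.params.to_dict(),
            polymer=r.params.to_dict(),
            rng_seed=r.seed,
        )
        gs = f.create_group("seeds")
        gs.create_dataset("cap", data=r.seeds.cap)
        gs.create_dataset("rho", data=r.seeds.rho)
        gs.create_dataset("phi", data=r.seeds.phi)
        gs.create_dataset("position", data=r.seeds.position)
        gs.create_dataset("normal", data=r.seeds.normal)
        gp = f.create_group("polymers")
        gp.create_dataset("offsets", data=r.offsets)
        gp.create_dataset("orientations", data=r.orientations)
        gp.create_dataset("midpoints", data=r.midpoints)
        gp.create_dataset("target_length", data=r.target_length)
        gp.create_dataset("terminated_by", data=r.terminated_by)


def load_realization(path) -> CytoskeletonRealization:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        geom = OocyteGeometry(**meta["geometry"])
        seeds = SeedSet(
            geometry=geom,
            params=SeedingDensityParams(**meta["seeding"]),
            cap=f["seeds/cap"][:],
            rho=f["seeds/rho"][:],
            phi=f["seeds/phi"][:],
            position=f["seeds/position"][:],
            normal=f["seeds/normal"][:],
            seed=meta.get("rng_seed"),
        )
        return CytoskeletonRealization(
            geometry=geom,
            seeds=seeds,
            params=PolymerParams(**meta["polymer"]),
            offsets=f["polymers/offsets"][:],
            orientations=f["polymers/orientations"][:],
            midpoints=f["polymers/midpoints"][:],
            target_length=f["polymers/target_length"][:],
            terminated_by=f["polymers/terminated_by"][:],
            seed=meta.get("rng_seed"),
        )


def save_field_h5(path, grid: CoarseGrid, name: str, array: np.ndarray, **meta) -> None:
    """Write one gridded field (scalar or vector) with grid metadata."""
    with h5py.File(path, "w") as f:
        f.attrs["meta"] = _meta(
            geometry=grid.geometry.to_dict(), dG=grid.dG, **meta
        )
        f.create_dataset(name, data=array)


def load_field_h5(path, name: str):
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        geom = OocyteGeometry(**meta.pop("geometry"))
        grid = CoarseGrid(geom, dG=meta.pop("dG"))
        return grid, f[name][:], meta


def write_vtk_structured(
    path,
    grid: CoarseGrid,
    fields: dict[str, np.ndarray],
    relabel_ap_to_x: bool = True,
) -> None:
    """Write cell-centered fields as a legacy-ASCII VTK structured-points
    file (scalars and 3-vectors supported).

    With ``relabel_ap_to_x`` the data axes are transposed so the AP axis is
    the VTK x axis.
    """
    nx, ny, nz = grid.shape
    if relabel_ap_to_x:
        dims = (nz, nx, ny)
        origin = (grid.origin[2], grid.origin[0], grid.origin[1])
    else:
        dims = (nx, ny, nz)
        origin = grid.origin
    n_pts = dims[0] * dims[1] * dims[2]
    lines = [
        "# vtk DataFile Version 3.0",
        "oostream field export",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}",
        f"ORIGIN {origin[0] + grid.dG / 2} {origin[1] + grid.dG / 2} {origin[2] + grid.dG / 2}",
        f"SPACING {grid.dG} {grid.dG} {grid.dG}",
        f"POINT_DATA {n_pts}",
    ]
    for name, arr in fields.items():
        arr = np.asarray(arr)
        is_vec = arr.ndim == 4
        if relabel_ap_to_x:
            perm = (2, 0, 1, 3) if is_vec else (2, 0, 1)
            arr = np.transpose(arr, perm)
            if is_vec:
                arr = ap_axis_to_x(arr)
        # VTK point ordering: first grid axis fastest
        if is_vec:
            flat = np.transpose(arr, (2, 1, 0, 3)).reshape(-1, 3)
            lines.append(f"VECTORS {name} float")
            lines.extend(" ".join(f"{v:.6g}" for v in row) for row in flat)
        else:
            flat = np.transpose(arr, (2, 1, 0)).reshape(-1)
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.6g}" for v in flat)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
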