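"""Snapshot, checkpoint and time-series writers.

Snapshots go out as legacy ASCII VTK polydata (points + species + cell-id
scalars) or XYZ; checkpoints as HDF5; time series as CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .core import ParticleSystem

__all__ = ["write_vtk", "write_xyz", "save_checkpoint", "load_checkpoint",
           "write_csv"]

_SPECIES_LETTER = {0: "F", 1: "W", 2: "M", 3: "G", 4: "S"}


def write_vtk(ps: ParticleSystem, path) -> None:
    path = Path(path)
    n = ps.n
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nhemoflow snapshot\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {n} float\n")
        np.savetxt(fh, ps.pos, fmt="%.6g")
        fh.write(f"POINT_DATA {n}\n")
        fh.write("SCALARS species int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, ps.species, fmt="%d")
        fh.write("SCALARS cell_id int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, ps.cell_id, fmt="%d")
        fh.write("VECTORS velocity float\n")
        np.savetxt(fh, ps.vel, fmt="%.6g")


def write_xyz(ps: ParticleSystem, path, append: bool = False) -> None:
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{ps.n}\nhemoflow\n")
        for k in range(ps.n):
            s = _SPECIES_LETTER.get(int(ps.species[k]), "X")
            fh.write(f"{s} {ps.pos[k, 0]:.6g} {ps.pos[k, 1]:.6g} "
                     f"{ps.pos[k, 2]:.6g}\n")


def save_checkpoint(ps: ParticleSystem, path, step: int = 0) -> None:
    import h5py
    with h5py.File(path, "w") as fh:
        for name in ("pos", "vel", "species", "cell_id", "region"):
            fh.create_dataset(name, data=getattr(ps, name))
        if ps.box is not None:
            fh.attrs["box"] = ps.box
        fh.attrs["periodic"] = ps.periodic
        fh.attrs["step"] = step


def load_checkpoint(path) -> tuple[ParticleSystem, int]:
    import h5py
    with h5py.File(path, "r") as fh:
        ps = ParticleSystem(
            pos=fh["pos"][...], vel=fh["vel"][...], species=fh["species"][...],
            cell_id=fh["cell_id"][...], region=fh["region"][...],
            box=fh.attrs.get("box"), periodic=fh.attrs["periodic"])
        return ps, int(fh.attrs["step"])


def write_csv(rows, header, path) -> None:
    import pandas as pd
    pd.DataFrame(rows, columns=header).to_csv(path, index=False)
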