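"""File formats: OFF meshes + neighbor TSV, HDF5 result containers, TSV tables.

Layout of the HDF5 container:

    /mesh/coords, /mesh/faces
    /hierarchy
    /subjects/<id>/timeseries
    /truth/scale_<K>/V                  planted group loadings
    /atlas/scale_<K>/V                  fused consensus atlas
    /personalized/<id>/scale_<K>/V      subject loadings
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import SurfaceMesh

__all__ = [
    "write_mesh_off", "read_mesh_off", "write_neighbors_tsv",
    "save_array", "load_array", "list_keys",
    "write_table", "read_table",
]


def write_mesh_off(path: str | Path, mesh: SurfaceMesh) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {len(mesh.faces)} 0\n")
        for v in mesh.coords:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_mesh_off(path: str | Path) -> SurfaceMesh:
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "OFF":
            raise ValueError("not an OFF file")
        nv, nf, _ = (int(t) for t in fh.readline().split())
        coords = np.array([[float(t) for t in fh.readline().split()] for _ in range(nv)])
        faces = np.array([[int(t) for t in fh.readline().split()][1:] for _ in range(nf)],
                         dtype=np.intp)
    nb: list[set[int]] = [set() for _ in range(nv)]
    for a, b, c in faces:
        nb[a].update((b, c)); nb[b].update((a, c)); nb[c].update((a, b))
    neighbors = tuple(np.array(sorted(s), dtype=np.intp) for s in nb)
    mesh = SurfaceMesh(coords=coords, neighbors=neighbors, faces=faces)
    mesh.validate()
    return mesh


def write_neighbors_tsv(path: str | Path, mesh: SurfaceMesh) -> None:
    with open(path, "w") as fh:
        fh.write("vertex\tneighbors\n")
        for v, nb in enumerate(mesh.neighbors):
            fh.write(f"{v}\t{','.join(str(u) for u in nb)}\n")


def save_array(h5path: str | Path, key: str, arr: np.ndarray) -> None:
    with h5py.File(h5path, "a") as f:
        if key in f:
            del f[key]
        f.create_dataset(key, data=np.asarray(arr))


def load_array(h5path: str | Path, key: str) -> np.ndarray:
    with h5py.File(h5path, "r") as f:
        return f[key][()]


def list_keys(h5path: str | Path, prefix: str = "/") -> list[str]:
    out: list[str] = []
    with h5py.File(h5path, "r") as f:
        def visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                out.append("/" + name)
        f[prefix].visititems(lambda n, o: visit(f"{prefix.strip('/')}/{n}".strip("/"), o))
    return out


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"table {path} missing required columns: {missing}")
    return df
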