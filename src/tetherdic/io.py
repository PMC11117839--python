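"""File formats: PLY meshes, FEM CSV exports, match tables, images.

The FEM surface dialect is two plain CSV tables per state:
``nodes``: node_id,x,y,z (mm) and ``elements``: elem_id,n1,n2,n3
(0-based node ids). The same triangle connectivity must apply to the
reference and loaded node tables so that surface-area post-processing is
the identical operation used for DIC meshes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .surface import SurfaceMesh


def write_mesh_ply(mesh: SurfaceMesh, path: str | Path, ascii_ply: bool = True) -> None:
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path), encoding="ascii" if ascii_ply else "binary")


def read_mesh_ply(path: str | Path, state: str = "reference",
                  provenance: str = "synthetic") -> SurfaceMesh:
    import trimesh

    tm = trimesh.load(str(path), process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), state, provenance)


def write_fem_surface(mesh: SurfaceMesh, nodes_path: str | Path,
                      elements_path: str | Path | None = None) -> None:
    nodes = pd.DataFrame({"node_id": np.arange(len(mesh.vertices)),
                          "x": mesh.vertices[:, 0], "y": mesh.vertices[:, 1],
                          "z": mesh.vertices[:, 2]})
    nodes.to_csv(nodes_path, index=False)
    if elements_path is not None:
        elems = pd.DataFrame({"elem_id": np.arange(len(mesh.faces)),
                              "n1": mesh.faces[:, 0], "n2": mesh.faces[:, 1],
                              "n3": mesh.faces[:, 2]})
        elems.to_csv(elements_path, index=False)


def read_fem_surface(nodes_ref: str | Path, nodes_loaded: str | Path,
                     elements: str | Path) -> tuple[SurfaceMesh, SurfaceMesh]:
    """Load a FEM surface export as a reference/loaded mesh pair."""
    elems = pd.read_csv(elements).sort_values("elem_id")
    faces = elems[["n1", "n2", "n3"]].to_numpy(dtype=np.int64)
    meshes = []
    for path, state in ((nodes_ref, "reference"), (nodes_loaded, "loaded")):
        nd = pd.read_csv(path).sort_values("node_id")
        verts = nd[["x", "y", "z"]].to_numpy(dtype=float)
        meshes.append(SurfaceMesh(verts, faces, state, "fem"))
    return meshes[0], meshes[1]


def write_matches_csv(matches, path: str | Path) -> None:
    pd.DataFrame([{"ref_u": m.ref_center[0], "ref_v": m.ref_center[1],
                   "def_u": m.def_center[0], "def_v": m.def_center[1],
                   "score": m.score, "status": m.status,
                   "reason": m.reason or ""} for m in matches]
                 ).to_csv(path, index=False)


def read_matches_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_correspondences_csv(points3d: np.ndarray, points2d: np.ndarray,
                              camera_id: str, path: str | Path,
                              state: str = "calibration") -> None:
    pd.DataFrame({"x_mm": points3d[:, 0], "y_mm": points3d[:, 1],
                  "z_mm": points3d[:, 2], "u_px": points2d[:, 0],
                  "v_px": points2d[:, 1], "camera_id": camera_id,
                  "state": state}).to_csv(path, index=False)


def read_correspondences_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return (df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
            df[["u_px", "v_px"]].to_numpy(dtype=float))


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Save a float [0, 1] image as 16-bit TIFF or 8-bit PNG by extension."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.round(image * 65535).astype(np.uint16))
    else:
        from PIL import Image

        Image.fromarray(np.round(image * 255).astype(np.uint8)).save(path)


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
    return arr.astype(float) / (info.max if info else 1.0)


def write_tensile_csv(record, path: str | Path, sidecar: str | Path | None = None) -> None:
    n = len(record.force_n)
    t = np.arange(n) / record.sample_rate_hz
    pd.DataFrame({"time_s": t, "force_N": record.force_n,
                  "length_mm": record.length_mm}).to_csv(path, index=False)
    if sidecar is not None:
        import yaml

        with open(sidecar, "w") as fh:
            yaml.safe_dump({"width_mm": record.width_mm,
                            "thickness_mm": record.thickness_mm,
                            "gauge_length_0": record.gauge_length_0,
                            "region_label": record.region_label,
                            "preload_n": record.preload_n,
                            "sample_rate_hz": record.sample_rate_hz}, fh)


def read_tensile_csv(path: str | Path, sidecar: str | Path):
    import yaml

    from .tensile import TensileRecord

    df = pd.read_csv(path)
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    return TensileRecord(df["force_N"].to_numpy(), df["length_mm"].to_numpy(),
                         meta["width_mm"], meta["thickness_mm"],
                         meta["gauge_length_0"], meta.get("region_label", "posterior"),
                         meta.get("preload_n", 0.02), meta.get("sample_rate_hz", 5.0))
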