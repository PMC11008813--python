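"""File formats: FreeSurfer overlays/geometry and plain-text fallbacks.

Binary morphometry ("curv") overlays and triangle geometry files go through
nibabel's FreeSurfer readers/writers so real sphere geometry and real
per-vertex maps can enter the pipeline.  A plain-text tab-separated format
(one column per map, header row of map names) covers environments where
binary artifacts are unwanted; it round-trips through ``repr``-precision
floats rather than bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from nibabel.freesurfer import io as fsio

from .cohort import GroundTruth, VertexData
from .surface import SurfaceMesh

__all__ = [
    "read_overlay",
    "write_overlay",
    "read_geometry",
    "write_geometry",
    "read_text_maps",
    "write_text_maps",
    "write_cohort_table",
    "read_cohort_table",
    "save_ground_truth",
    "load_ground_truth",
]


def write_overlay(values: np.ndarray, path) -> None:
    """Write one per-vertex map as a FreeSurfer binary curv overlay."""
    values = np.asarray(values, dtype=np.float32)
    if values.ndim != 1:
        raise ValueError("an overlay holds exactly one per-vertex map")
    fsio.write_morph_data(str(path), values)


def read_overlay(path, n_vertices: int | None = None) -> np.ndarray:
    """Read a FreeSurfer binary curv overlay; optionally check vertex count.

    Only the new-format (float32) curv layout is accepted; the 3-byte magic
    0xFFFFFF is checked explicitly since arbitrary bytes can otherwise parse
    as the legacy int16 layout.
    """
    with open(path, "rb") as fh:
        magic = fh.read(3)
    if magic != b"\xff\xff\xff":
        raise ValueError(f"not a new-format curv overlay (bad magic bytes): {path}")
    try:
        values = np.asarray(fsio.read_morph_data(str(path)), dtype=np.float64)
    except Exception as exc:
        raise ValueError(f"not a readable curv overlay: {path}") from exc
    if n_vertices is not None and len(values) != n_vertices:
        raise ValueError(
            f"overlay has {len(values)} vertices, expected {n_vertices}"
        )
    return values


def write_geometry(mesh: SurfaceMesh, path) -> None:
    """Write mesh geometry as a FreeSurfer triangle surface file."""
    fsio.write_geometry(str(path), mesh.vertex_coords, mesh.faces)


def read_geometry(path, hemisphere: str = "left") -> SurfaceMesh:
    coords, faces = fsio.read_geometry(str(path))
    coords = np.asarray(coords, dtype=np.float64)
    norms = np.linalg.norm(coords, axis=1, keepdims=True)
    return SurfaceMesh(coords / norms, np.asarray(faces, dtype=np.int64), hemisphere)


def write_text_maps(maps: dict[str, np.ndarray], path) -> None:
    """Plain-text fallback: tab-separated, one column per map, header row."""
    pd.DataFrame(maps).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_text_maps(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return {c: df[c].to_numpy(dtype=np.float64) for c in df.columns}


def write_cohort_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort_table(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        dtype={"observation_id": str, "subject_id": str, "cohort": str, "site": str},
    )


def save_ground_truth(truth: GroundTruth, directory) -> None:
    """Ground truth as a compressed archive plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        directory / "truth_maps.npz",
        corrupted_rows=truth.corrupted_rows,
        **{f"map_{k}": v for k, v in truth.maps.items()},
        **{f"cap_{k}": v for k, v in truth.cap_masks.items()},
    )
    manifest = {
        "sigma_u": truth.sigma_u,
        "sigma_e": truth.sigma_e,
        "site_offsets": truth.site_offsets,
        "n_vertices": truth.n_vertices,
        "amplitudes": dict(truth.spec.amplitudes) if truth.spec else None,
    }
    (directory / "truth_manifest.json").write_text(json.dumps(manifest, indent=2))


def load_ground_truth(directory, mesh_left: SurfaceMesh, mesh_right: SurfaceMesh) -> GroundTruth:
    directory = Path(directory)
    manifest = json.loads((directory / "truth_manifest.json").read_text())
    with np.load(directory / "truth_maps.npz") as z:
        maps = {k[4:]: z[k] for k in z.files if k.startswith("map_")}
        caps = {k[4:]: z[k] for k in z.files if k.startswith("cap_")}
        corrupted = z["corrupted_rows"]
    return GroundTruth(
        maps=maps,
        site_offsets=manifest["site_offsets"],
        sigma_u=manifest["sigma_u"],
        sigma_e=manifest["sigma_e"],
        mesh_left=mesh_left,
        mesh_right=mesh_right,
        corrupted_rows=corrupted,
        cap_masks=caps,
    )
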