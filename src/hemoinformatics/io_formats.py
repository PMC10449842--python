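"""Mesh, image and feature-table I/O plus the core in-memory domain types.

Vector fields exported by CFD post-processing are exchanged as VTK-family
files: legacy ASCII ``.vtk``, XML unstructured grids ``.vtu`` (volume data)
and XML polydata ``.vtp`` (surface data).  Only ASCII-encoded data arrays
are supported; points and vectors are read back in file order, never
reordered.  Images travel as NRRD (default) or NIfTI-1 through SimpleITK,
with the mask written as a companion ``*_mask`` volume.  Feature tables are
plain CSV with ``case_id`` and ``label`` columns.

Coordinates are millimetres, velocity m/s, WSS Pa; units are recorded in
file metadata but never converted automatically.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

__all__ = [
    "UnstructuredVectorField",
    "FeatureTable",
    "FormatError",
    "read_field",
    "write_field",
    "write_image",
    "read_image",
    "read_feature_table",
    "write_feature_table",
]

_FLOAT_FMT = "%.17g"  # lossless text round-trip for float64


class FormatError(ValueError):
    """Raised when a file lacks the structure the pipeline needs."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class UnstructuredVectorField:
    """A 3-component field sampled on unstructured points (volume or surface).

    ``cells`` holds tetrahedra (volume meshes, shape (m, 4)) or triangles
    (surface meshes, shape (m, 3)); it may be None for pure point clouds.
    ``roi_mask`` marks points inside the aneurysm sac.
    """

    points: np.ndarray  # (n, 3) mm
    vectors: np.ndarray  # (n, 3) m/s or Pa
    field_kind: str  # "velocity" | "wss"
    cells: np.ndarray | None = None
    roi_mask: np.ndarray | None = None
    case_id: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if self.vectors.shape != self.points.shape:
            raise ValueError("vectors must align with points")
        if self.cells is not None:
            self.cells = np.asarray(self.cells, dtype=np.int64)
            if self.cells.size and self.cells.max() >= len(self.points):
                raise ValueError("cell indices out of range")
        if self.roi_mask is not None:
            self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
            if self.roi_mask.shape != (len(self.points),):
                raise ValueError("roi_mask must be per-point")
        if self.field_kind not in ("velocity", "wss"):
            raise ValueError("field_kind must be 'velocity' or 'wss'")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def roi_points(self) -> np.ndarray:
        if self.roi_mask is None:
            return self.points
        return self.points[self.roi_mask]


@dataclass
class FeatureTable:
    """Case-by-feature matrix with growth-status labels (fast | slow)."""

    case_ids: list[str]
    feature_names: list[str]
    matrix: np.ndarray  # (cases, features)
    labels: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if len(set(self.feature_names)) != len(self.feature_names):
            dupes = {n for n in self.feature_names if self.feature_names.count(n) > 1}
            raise ValueError(f"duplicate feature names: {sorted(dupes)}")
        if len(set(self.case_ids)) != len(self.case_ids):
            raise ValueError("duplicate case ids")
        if self.matrix.shape != (len(self.case_ids), len(self.feature_names)):
            raise ValueError("matrix shape mismatch")
        if len(self.labels) != len(self.case_ids) or any(
            lab not in ("fast", "slow") for lab in self.labels
        ):
            raise ValueError("labels must be 'fast'/'slow', one per case")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "case_id", self.case_ids)
        return df

    def subset(self, names: list[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(
            case_ids=list(self.case_ids),
            feature_names=list(names),
            matrix=self.matrix[:, idx],
            labels=list(self.labels),
        )

    def y(self, positive: str = "fast") -> np.ndarray:
        return np.array([1 if lab == positive else 0 for lab in self.labels])


# ---------------------------------------------------------------------------
# VTK-family readers/writers (ASCII only)
# ---------------------------------------------------------------------------


def _parse_ascii_floats(text: str) -> np.ndarray:
    return np.array(text.split(), dtype=float)


def _read_vtk_xml(path: Path) -> tuple[np.ndarray, np.ndarray | None, dict]:
    """Read points, cells and point-data arrays from a VTU/VTP file."""
    tree = ET.parse(path)
    root = tree.getroot()
    grid = root.find("UnstructuredGrid") or root.find("PolyData")
    if grid is None:
        raise FormatError(f"{path}: not a VTU/VTP file")
    piece = grid.find("Piece")
    pts_el = piece.find("Points/DataArray")
    if pts_el.get("format", "ascii") != "ascii":
        raise FormatError(f"{path}: only ascii-format DataArrays are supported")
    points = _parse_ascii_floats(pts_el.text).reshape(-1, 3)

    cells = None
    if grid.tag == "UnstructuredGrid":
        cells_el = piece.find("Cells")
        if cells_el is not None:
            conn = types_arr = offs = None
            for da in cells_el.findall("DataArray"):
                vals = np.array(da.text.split(), dtype=np.int64) if da.text and da.text.strip() else np.array([], dtype=np.int64)
                if da.get("Name") == "connectivity":
                    conn = vals
                elif da.get("Name") == "offsets":
                    offs = vals
                elif da.get("Name") == "types":
                    types_arr = vals
            if conn is not None and len(conn):
                size = offs[0] if offs is not None and len(offs) else 4
                cells = conn.reshape(-1, int(size))
    else:  # PolyData
        polys = piece.find("Polys")
        if polys is not None:
            conn = None
            for da in polys.findall("DataArray"):
                if da.get("Name") == "connectivity" and da.text and da.text.strip():
                    conn = np.array(da.text.split(), dtype=np.int64)
            if conn is not None and len(conn):
                cells = conn.reshape(-1, 3)

    point_data = {}
    pd_el = piece.find("PointData")
    if pd_el is not None:
        for da in pd_el.findall("DataArray"):
            name = da.get("Name", "")
            ncomp = int(da.get("NumberOfComponents", "1"))
            vals = _parse_ascii_floats(da.text)
            point_data[name] = vals.reshape(-1, ncomp) if ncomp > 1 else vals
    return points, cells, point_data


def _read_vtk_legacy(path: Path) -> tuple[np.ndarray, np.ndarray | None, dict]:
    """Minimal legacy-VTK ASCII reader (POINTS, CELLS/POLYGONS, POINT_DATA)."""
    lines = Path(path).read_text().splitlines()
    if len(lines) > 2 and lines[2].strip().upper() != "ASCII":
        raise FormatError(f"{path}: only ASCII legacy VTK is supported")
    toks: list[str] = []
    starts = {}
    for ln in lines[4:]:
        parts = ln.split()
        if parts and parts[0].replace("_", "").isalpha() and parts[0].isupper():
            starts[len(toks)] = parts
        toks.extend(parts)

    points = cells = None
    point_data: dict = {}
    i = 0
    n_points = 0
    in_point_data = False
    while i < len(toks):
        if i in starts:
            kw = starts[i]
            if kw[0] == "POINTS":
                n_points = int(kw[1])
                points = np.array(toks[i + 3 : i + 3 + 3 * n_points], dtype=float).reshape(-1, 3)
                i += 3 + 3 * n_points
                continue
            if kw[0] in ("CELLS", "POLYGONS"):
                n_cells, total = int(kw[1]), int(kw[2])
                raw = np.array(toks[i + 3 : i + 3 + total], dtype=np.int64)
                if n_cells:
                    size = int(raw[0])
                    cells = raw.reshape(n_cells, size + 1)[:, 1:]
                i += 3 + total
                continue
            if kw[0] == "POINT_DATA":
                in_point_data = True
                i += 2
                continue
            if in_point_data and kw[0] in ("VECTORS", "SCALARS"):
                name = kw[1]
                if kw[0] == "VECTORS":
                    vals = np.array(toks[i + 3 : i + 3 + 3 * n_points], dtype=float)
                    point_data[name] = vals.reshape(-1, 3)
                    i += 3 + 3 * n_points
                else:
                    # SCALARS name type [numComp] then LOOKUP_TABLE default
                    j = i + len(kw)
                    if toks[j] == "LOOKUP_TABLE":
                        j += 2
                    point_data[name] = np.array(toks[j : j + n_points], dtype=float)
                    i = j + n_points
                continue
        i += 1
    if points is None:
        raise FormatError(f"{path}: no POINTS section found")
    return points, cells, point_data


def read_field(path, kind: str, roi_spec=None, case_id: str | None = None) -> UnstructuredVectorField:
    """Read a velocity or WSS field from a VTK-family file.

    Parameters
    ----------
    path : str or Path
        ``.vtu`` / ``.vtp`` (XML, ascii) or ``.vtk`` (legacy ascii).
    kind : {"velocity", "wss"}
        Selects the vector array by name (falling back to the single
        3-component array present).
    roi_spec : str, tuple or None
        Name of a point-data array marking the sac (nonzero = inside), or an
        axis-aligned slab ``(axis_index, lo, hi)`` in mm with closed bounds.
    """
    path = Path(path)
    if path.suffix in (".vtu", ".vtp"):
        points, cells, point_data = _read_vtk_xml(path)
    elif path.suffix == ".vtk":
        points, cells, point_data = _read_vtk_legacy(path)
    else:
        raise FormatError(f"{path}: unsupported extension {path.suffix!r}")

    vec_arrays = {k: v for k, v in point_data.items() if v.ndim == 2 and v.shape[1] == 3}
    if kind in vec_arrays:
        vectors = vec_arrays[kind]
    elif len(vec_arrays) == 1:
        vectors = next(iter(vec_arrays.values()))
    else:
        raise FormatError(
            f"{path}: no 3-component array named {kind!r}; available arrays: "
            f"{sorted(point_data)}"
        )

    roi_mask = None
    if isinstance(roi_spec, str):
        if roi_spec not in point_data:
            raise FormatError(
                f"{path}: no ROI array {roi_spec!r}; available arrays: {sorted(point_data)}"
            )
        roi_mask = np.asarray(point_data[roi_spec]).ravel() > 0.5
    elif roi_spec is not None:
        ax, lo, hi = roi_spec
        coord = points[:, int(ax)]
        roi_mask = (coord >= lo) & (coord <= hi)
    elif "roi" in point_data:
        roi_mask = np.asarray(point_data["roi"]).ravel() > 0.5

    if roi_mask is not None and not roi_mask.any():
        raise FormatError(f"{path}: empty ROI")

    return UnstructuredVectorField(
        points=points,
        vectors=vectors,
        field_kind=kind,
        cells=cells,
        roi_mask=roi_mask,
        case_id=case_id if case_id is not None else path.stem,
    )


def _fmt_array(a: np.ndarray) -> str:
    return " ".join(_FLOAT_FMT % x for x in np.asarray(a, dtype=float).ravel())


def write_field(field: UnstructuredVectorField, path) -> Path:
    """Write a field as ascii VTU (volume/point-cloud) or VTP (surface).

    The extension decides the flavour; arrays are named by ``field_kind``
    and the ROI mask (if any) is stored as a point-data array ``roi``.
    """
    path = Path(path)
    n = field.n_points
    arrays = [
        f'<DataArray type="Float64" Name="{field.field_kind}" '
        f'NumberOfComponents="3" format="ascii">{_fmt_array(field.vectors)}</DataArray>'
    ]
    if field.roi_mask is not None:
        roi_txt = " ".join("1" if b else "0" for b in field.roi_mask)
        arrays.append(
            f'<DataArray type="Float64" Name="roi" format="ascii">{roi_txt}</DataArray>'
        )
    pts = (
        f'<Points><DataArray type="Float64" NumberOfComponents="3" '
        f'format="ascii">{_fmt_array(field.points)}</DataArray></Points>'
    )
    pdata = f"<PointData>{''.join(arrays)}</PointData>"

    if path.suffix == ".vtp":
        tris = field.cells if field.cells is not None else np.empty((0, 3), dtype=np.int64)
        conn = " ".join(str(i) for i in tris.ravel())
        offs = " ".join(str(3 * (i + 1)) for i in range(len(tris)))
        body = (
            f'<PolyData><Piece NumberOfPoints="{n}" NumberOfPolys="{len(tris)}">'
            f"{pts}{pdata}"
            f'<Polys><DataArray type="Int64" Name="connectivity" format="ascii">{conn}'
            f'</DataArray><DataArray type="Int64" Name="offsets" format="ascii">{offs}'
            f"</DataArray></Polys></Piece></PolyData>"
        )
        vtk_type = "PolyData"
    elif path.suffix == ".vtu":
        cells = field.cells if field.cells is not None else np.empty((0, 4), dtype=np.int64)
        size = cells.shape[1] if cells.size else 4
        ctype = 10 if size == 4 else 5  # VTK_TETRA / VTK_TRIANGLE
        conn = " ".join(str(i) for i in cells.ravel())
        offs = " ".join(str(size * (i + 1)) for i in range(len(cells)))
        typs = " ".join(str(ctype) for _ in range(len(cells)))
        body = (
            f'<UnstructuredGrid><Piece NumberOfPoints="{n}" NumberOfCells="{len(cells)}">'
            f"{pts}{pdata}"
            f'<Cells><DataArray type="Int64" Name="connectivity" format="ascii">{conn}'
            f'</DataArray><DataArray type="Int64" Name="offsets" format="ascii">{offs}'
            f'</DataArray><DataArray type="UInt8" Name="types" format="ascii">{typs}'
            f"</DataArray></Cells></Piece></UnstructuredGrid>"
        )
        vtk_type = "UnstructuredGrid"
    else:
        raise FormatError(f"{path}: unsupported extension {path.suffix!r} for writing")

    doc = (
        '<?xml version="1.0"?>\n'
        f'<VTKFile type="{vtk_type}" version="0.1" byte_order="LittleEndian">'
        f"{body}</VTKFile>\n"
    )
    path.write_text(doc)
    return path


# ---------------------------------------------------------------------------
# image I/O (NRRD default, NIfTI optional) via SimpleITK
# ---------------------------------------------------------------------------


def write_image(image, path) -> Path:
    """Write a VectorImage/ScalarImage as NRRD (default) or NIfTI.

    The boolean mask is written next to the image as ``<stem>_mask<ext>``.
    Requires uniform (but possibly anisotropic) spacing; SimpleITK stores
    geometry in the header so a round-trip restores array, spacing, origin.
    """
    path = Path(path)
    if path.suffix not in (".nrrd", ".nii", ".gz"):
        raise FormatError(f"{path}: write_image supports .nrrd and .nii")
    arr = np.asarray(image.array, dtype=float)
    spacing = np.atleast_1d(np.asarray(image.spacing, dtype=float))
    ndim = arr.ndim if arr.shape[-1] != 3 or arr.ndim == 2 else arr.ndim - 1
    if spacing.size == 1:
        spacing = np.repeat(spacing, ndim)
    if np.any(spacing <= 0):
        raise FormatError("spacing must be positive")

    is_vector = arr.ndim == ndim + 1
    itk = sitk.GetImageFromArray(np.ascontiguousarray(arr), isVector=is_vector)
    itk.SetSpacing(tuple(float(s) for s in spacing[::-1]))
    origin = np.atleast_1d(np.asarray(image.origin, dtype=float))
    itk.SetOrigin(tuple(float(o) for o in origin[::-1]))
    sitk.WriteImage(itk, str(path))

    mask = np.asarray(image.mask, dtype=np.uint8)
    itk_m = sitk.GetImageFromArray(mask)
    itk_m.SetSpacing(itk.GetSpacing())
    itk_m.SetOrigin(itk.GetOrigin())
    sitk.WriteImage(itk_m, str(path.with_name(path.stem + "_mask" + path.suffix)))
    return path


def read_image(path):
    """Read an image written by :func:`write_image` (with its mask)."""
    from .velocity_imaging import ScalarImage, VectorImage  # local: avoid cycle

    path = Path(path)
    itk = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(itk)
    spacing = np.array(itk.GetSpacing())[::-1]
    origin = np.array(itk.GetOrigin())[::-1]
    mask_path = path.with_name(path.stem + "_mask" + path.suffix)
    if mask_path.exists():
        mask = sitk.GetArrayFromImage(sitk.ReadImage(str(mask_path))).astype(bool)
    else:
        mask = np.ones(arr.shape[: len(spacing)], dtype=bool)
    if itk.GetNumberOfComponentsPerPixel() == 3:
        return VectorImage(array=arr, spacing=spacing, origin=origin, mask=mask)
    return ScalarImage(array=arr, spacing=spacing, origin=origin, mask=mask)


# ---------------------------------------------------------------------------
# feature tables (CSV)
# ---------------------------------------------------------------------------


def write_feature_table(table: FeatureTable, path) -> Path:
    path = Path(path)
    table.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, float_precision="round_trip")
    if "case_id" not in df.columns or "label" not in df.columns:
        raise FormatError(f"{path}: feature table needs 'case_id' and 'label' columns")
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise FormatError(f"{path}: duplicate case_id values: {dupes}")
    if df["label"].isna().any():
        missing = df.loc[df["label"].isna(), "case_id"].tolist()
        raise FormatError(f"{path}: missing labels for cases: {missing}")
    feats = [c for c in df.columns if c not in ("case_id", "label")]
    return FeatureTable(
        case_ids=df["case_id"].astype(str).tolist(),
        feature_names=feats,
        matrix=df[feats].to_numpy(dtype=float),
        labels=df["label"].astype(str).tolist(),
    )
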