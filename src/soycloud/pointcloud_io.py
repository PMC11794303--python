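"""Point-cloud container and file I/O.

The canonical in-memory form for every stage of the pipeline is
:class:`PointCloud`: an ``(N, 3)`` float64 coordinate array in meters with
optional per-point color, semantic class and plant-instance labels.

Three interoperable on-disk formats are supported:

``xyz``
    Whitespace-delimited text, columns ``x y z [r g b] [class] [instance]``,
    ``#`` comment lines skipped.  Column count disambiguates the optional
    blocks: 3 = coords, 4 = +class, 5 = +class+instance, 6 = +rgb,
    7 = +rgb+class, 8 = +rgb+class+instance.
``ply``
    Vertex-only PLY, ascii or binary_little_endian, with optional
    ``red/green/blue`` (uchar) and ``class``/``instance`` (int) properties.
``pcd``
    ASCII PCD with fields ``x y z [r g b] [class] [instance]``.

Class-label convention: 0 = ground/background, 1 = plant, -1 = sensor noise
(used by the synthetic generator).  Instance labels are -1 for unassigned
points and >= 0 for plant IDs.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["PointCloud", "read_cloud", "write_cloud", "ParseError"]


class ParseError(ValueError):
    """A point-cloud file is malformed; the message names the offending record."""


@dataclass
class PointCloud:
    """N points in meters with optional per-point attributes.

    Parameters
    ----------
    coords
        ``(N, 3)`` array of x, y, z in meters.  Must be finite.
    color
        Optional ``(N, 3)`` uint8 RGB in [0, 255].
    class_label
        Optional ``(N,)`` int semantic label (0 ground, 1 plant, -1 noise).
    instance_label
        Optional ``(N,)`` int plant ID; -1 means unassigned.
    """

    coords: np.ndarray
    color: np.ndarray | None = None
    class_label: np.ndarray | None = None
    instance_label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = len(self.coords)
        if self.color is not None:
            self.color = np.asarray(self.color, dtype=np.uint8).reshape(-1, 3)
            if len(self.color) != n:
                raise ValueError(f"color has {len(self.color)} rows, expected {n}")
        for name in ("class_label", "instance_label"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=np.int64).reshape(-1)
                if len(arr) != n:
                    raise ValueError(f"{name} has {len(arr)} entries, expected {n}")
                setattr(self, name, arr)
        if self.instance_label is not None and np.any(self.instance_label < -1):
            raise ValueError("instance labels must be -1 or non-negative")

    def __len__(self) -> int:
        return len(self.coords)

    def select(self, index: np.ndarray) -> "PointCloud":
        """Return a new cloud restricted to ``index`` (bool mask or int array),
        filtering all attribute arrays consistently."""
        return PointCloud(
            coords=self.coords[index],
            color=None if self.color is None else self.color[index],
            class_label=None if self.class_label is None else self.class_label[index],
            instance_label=(
                None if self.instance_label is None else self.instance_label[index]
            ),
        )

    def with_instances(self, labels: np.ndarray) -> "PointCloud":
        """Copy of this cloud with ``instance_label`` replaced."""
        return PointCloud(
            coords=self.coords.copy(),
            color=None if self.color is None else self.color.copy(),
            class_label=None if self.class_label is None else self.class_label.copy(),
            instance_label=np.asarray(labels, dtype=np.int64).copy(),
        )


# ---------------------------------------------------------------------------
# format detection

_FORMATS = ("ply", "pcd", "xyz")


def _infer_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in _FORMATS:
            raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    if suffix in ("txt", "asc", "pts"):
        return "xyz"
    raise ValueError(f"cannot infer format from extension of {path}")


def read_cloud(path: str | Path, format: str = "auto") -> PointCloud:
    """Read a point cloud from ``path`` in the named or inferred format."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "ply":
        return _read_ply(path)
    return _read_pcd(path)


def write_cloud(cloud: PointCloud, path: str | Path, format: str = "auto") -> None:
    """Write ``cloud`` to ``path``; labels and color round-trip losslessly."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        _write_xyz(cloud, path)
    elif fmt == "ply":
        _write_ply(cloud, path)
    else:
        _write_pcd(cloud, path)


# ---------------------------------------------------------------------------
# XYZ text

def _read_xyz(path: Path) -> PointCloud:
    coords, colors, classes, instances = [], [], [], []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if ncols is None:
                if len(parts) not in (3, 4, 5, 6, 7, 8):
                    raise ParseError(
                        f"{path}:{lineno}: expected 3-8 columns, got {len(parts)}"
                    )
                ncols = len(parts)
            elif len(parts) != ncols:
                raise ParseError(
                    f"{path}:{lineno}: inconsistent column count "
                    f"({len(parts)} vs {ncols})"
                )
            try:
                vals = [float(v) for v in parts]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            coords.append(vals[:3])
            rest = vals[3:]
            if ncols >= 6:
                colors.append(rest[:3])
                rest = rest[3:]
            if rest:
                classes.append(int(rest[0]))
            if len(rest) > 1:
                instances.append(int(rest[1]))
    return PointCloud(
        coords=np.array(coords, dtype=np.float64).reshape(-1, 3),
        color=np.array(colors, dtype=np.uint8) if colors else None,
        class_label=np.array(classes, dtype=np.int64) if classes else None,
        instance_label=np.array(instances, dtype=np.int64) if instances else None,
    )


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    cols: list[np.ndarray] = [cloud.coords]
    fmts = ["%.8f", "%.8f", "%.8f"]
    if cloud.color is not None:
        cols.append(cloud.color.astype(np.float64))
        fmts += ["%d", "%d", "%d"]
    has_cls = cloud.class_label is not None
    has_inst = cloud.instance_label is not None
    if has_cls or has_inst:
        cls = cloud.class_label if has_cls else np.zeros(len(cloud), dtype=np.int64)
        cols.append(cls[:, None].astype(np.float64))
        fmts.append("%d")
    if has_inst:
        cols.append(cloud.instance_label[:, None].astype(np.float64))
        fmts.append("%d")
    data = np.hstack(cols) if len(cloud) else np.empty((0, len(fmts)))
    np.savetxt(path, data, fmt=" ".join(fmts), comments="")


# ---------------------------------------------------------------------------
# PLY (vertex element only)

_PLY_TYPES = {
    "char": "b", "int8": "b", "uchar": "B", "uint8": "B",
    "short": "h", "int16": "h", "ushort": "H", "uint16": "H",
    "int": "i", "int32": "i", "uint": "I", "uint32": "I",
    "float": "f", "float32": "f", "double": "d", "float64": "d",
}


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ParseError(f"{path}: missing 'ply' magic")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            raw = fh.readline()
            if not raw:
                raise ParseError(f"{path}: header not terminated")
            line = raw.decode("ascii", "replace").strip()
            if line.startswith("comment"):
                continue
            if line.startswith("format"):
                fmt = line.split()[1]
                if fmt not in ("ascii", "binary_little_endian"):
                    raise ParseError(f"{path}: unsupported PLY format {fmt!r}")
            elif line.startswith("element"):
                _, name, count = line.split()
                in_vertex = name == "vertex"
                if in_vertex:
                    n_vertex = int(count)
            elif line.startswith("property") and in_vertex:
                parts = line.split()
                if parts[1] == "list":
                    raise ParseError(f"{path}: list properties unsupported on vertex")
                props.append((parts[2], parts[1]))
            elif line == "end_header":
                break
        if fmt is None or n_vertex is None:
            raise ParseError(f"{path}: incomplete PLY header")
        names = [p[0] for p in props]
        if fmt == "ascii":
            rows = []
            for i in range(n_vertex):
                line = fh.readline().decode("ascii", "replace").split()
                if len(line) != len(props):
                    raise ParseError(f"{path}: vertex {i}: bad field count")
                rows.append([float(v) for v in line])
            table = np.array(rows, dtype=np.float64).reshape(n_vertex, len(props))
        else:
            rec = struct.Struct("<" + "".join(_PLY_TYPES[t] for _, t in props))
            buf = fh.read(rec.size * n_vertex)
            if len(buf) != rec.size * n_vertex:
                raise ParseError(f"{path}: truncated binary vertex data")
            table = np.array(
                [rec.unpack_from(buf, i * rec.size) for i in range(n_vertex)],
                dtype=np.float64,
            ).reshape(n_vertex, len(props))
    def col(name: str) -> np.ndarray | None:
        return table[:, names.index(name)] if name in names else None

    for axis in ("x", "y", "z"):
        if axis not in names:
            raise ParseError(f"{path}: vertex element lacks property {axis!r}")
    coords = np.column_stack([col("x"), col("y"), col("z")])
    color = None
    if all(c in names for c in ("red", "green", "blue")):
        color = np.column_stack([col("red"), col("green"), col("blue")]).astype(np.uint8)
    cls = col("class")
    inst = col("instance")
    return PointCloud(
        coords=coords,
        color=color,
        class_label=None if cls is None else cls.astype(np.int64),
        instance_label=None if inst is None else inst.astype(np.int64),
    )


def _write_ply(cloud: PointCloud, path: Path, binary: bool = False) -> None:
    props: list[tuple[str, str, np.ndarray]] = [
        ("x", "double", cloud.coords[:, 0]),
        ("y", "double", cloud.coords[:, 1]),
        ("z", "double", cloud.coords[:, 2]),
    ]
    if cloud.color is not None:
        for i, name in enumerate(("red", "green", "blue")):
            props.append((name, "uchar", cloud.color[:, i]))
    if cloud.class_label is not None:
        props.append(("class", "int", cloud.class_label))
    if cloud.instance_label is not None:
        props.append(("instance", "int", cloud.instance_label))
    header = ["ply", f"format {'binary_little_endian' if binary else 'ascii'} 1.0",
              f"element vertex {len(cloud)}"]
    header += [f"property {t} {n}" for n, t, _ in props]
    header.append("end_header")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            rec = struct.Struct("<" + "".join(_PLY_TYPES[t] for _, t, _ in props))
            for i in range(len(cloud)):
                fh.write(rec.pack(*(arr[i] for _, _, arr in props)))
        else:
            for i in range(len(cloud)):
                fields = []
                for _, t, arr in props:
                    v = arr[i]
                    fields.append(f"{float(v):.10g}" if t == "double" else str(int(v)))
                fh.write((" ".join(fields) + "\n").encode("ascii"))


# ---------------------------------------------------------------------------
# PCD (ascii)

def _read_pcd(path: Path) -> PointCloud:
    fields: list[str] = []
    n_points = None
    data_mode = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key = line.split()[0].upper()
            if data_mode is None:
                if key == "FIELDS":
                    fields = line.split()[1:]
                elif key == "POINTS":
                    n_points = int(line.split()[1])
                elif key == "DATA":
                    mode = line.split()[1]
                    if mode != "ascii":
                        raise ParseError(f"{path}: only ascii PCD supported, got {mode}")
                    data_mode = mode
                continue
            parts = line.split()
            if len(parts) != len(fields):
                raise ParseError(
                    f"{path}: data row {len(rows)}: {len(parts)} values for "
                    f"{len(fields)} fields"
                )
            rows.append([float(v) for v in parts])
    if data_mode is None or not fields:
        raise ParseError(f"{path}: missing PCD header")
    if n_points is not None and len(rows) != n_points:
        raise ParseError(f"{path}: POINTS={n_points} but {len(rows)} rows")
    table = np.array(rows, dtype=np.float64).reshape(len(rows), len(fields))

    def col(name: str) -> np.ndarray | None:
        return table[:, fields.index(name)] if name in fields else None

    for axis in ("x", "y", "z"):
        if axis not in fields:
            raise ParseError(f"{path}: PCD lacks field {axis!r}")
    coords = np.column_stack([col("x"), col("y"), col("z")])
    color = None
    if all(c in fields for c in ("r", "g", "b")):
        color = np.column_stack([col("r"), col("g"), col("b")]).astype(np.uint8)
    cls = col("class")
    inst = col("instance")
    return PointCloud(
        coords=coords,
        color=color,
        class_label=None if cls is None else cls.astype(np.int64),
        instance_label=None if inst is None else inst.astype(np.int64),
    )


def _write_pcd(cloud: PointCloud, path: Path) -> None:
    fields = ["x", "y", "z"]
    types = ["F", "F", "F"]
    sizes = ["8", "8", "8"]
    cols: list[np.ndarray] = [cloud.coords[:, 0], cloud.coords[:, 1], cloud.coords[:, 2]]
    if cloud.color is not None:
        fields += ["r", "g", "b"]
        types += ["U", "U", "U"]
        sizes += ["1", "1", "1"]
        cols += [cloud.color[:, i] for i in range(3)]
    if cloud.class_label is not None:
        fields.append("class")
        types.append("I")
        sizes.append("4")
        cols.append(cloud.class_label)
    if cloud.instance_label is not None:
        fields.append("instance")
        types.append("I")
        sizes.append("4")
        cols.append(cloud.instance_label)
    n = len(cloud)
    header = "\n".join(
        [
            "# .PCD v0.7 - Point Cloud Data file format",
            "VERSION 0.7",
            "FIELDS " + " ".join(fields),
            "SIZE " + " ".join(sizes),
            "TYPE " + " ".join(types),
            "COUNT " + " ".join(["1"] * len(fields)),
            f"WIDTH {n}",
            "HEIGHT 1",
            "VIEWPOINT 0 0 0 1 0 0 0",
            f"POINTS {n}",
            "DATA ascii",
        ]
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for i in range(n):
            vals = []
            for t, arr in zip(types, cols):
                vals.append(f"{float(arr[i]):.10g}" if t == "F" else str(int(arr[i])))
            fh.write(" ".join(vals) + "\n")
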