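"""Point-cloud and region containers with LAS/PLY/CSV and GeoJSON I/O.

Coordinates live in a single local projected metric frame (ENU-like);
no CRS handling is performed — callers must pre-project.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, shape, mapping

from . import _las

__all__ = [
    "PointCloud",
    "RegionOfInterest",
    "read_point_cloud",
    "write_point_cloud",
    "read_regions",
    "write_regions",
    "region_mask",
    "clip_to_region",
]


@dataclass
class PointCloud:
    """Columnar x/y/z point cloud in meters.

    Optional per-point attributes (intensity, return number, ...) are
    carried opaquely in ``attributes`` and subset together with the
    coordinates.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    attributes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (self.x.shape == self.y.shape == self.z.shape) or self.x.ndim != 1:
            raise ValueError("x, y, z must be 1-D arrays of equal length")
        for arr in (self.x, self.y, self.z):
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError("coordinates must be finite")
        for key, val in self.attributes.items():
            val = np.asarray(val)
            if val.shape[0] != self.x.shape[0]:
                raise ValueError(f"attribute {key!r} length mismatch")
            self.attributes[key] = val

    @property
    def n(self) -> int:
        return self.x.size

    def __len__(self) -> int:
        return self.n

    def xyz(self) -> np.ndarray:
        """Return an (n, 3) coordinate array (copy)."""
        return np.column_stack([self.x, self.y, self.z])

    @classmethod
    def from_xyz(cls, xyz: np.ndarray, **attributes: np.ndarray) -> "PointCloud":
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        return cls(xyz[:, 0], xyz[:, 1], xyz[:, 2], dict(attributes))

    def take(self, index: np.ndarray) -> "PointCloud":
        """Subset by boolean mask or integer index, attributes included."""
        return PointCloud(
            self.x[index],
            self.y[index],
            self.z[index],
            {k: v[index] for k, v in self.attributes.items()},
        )

    @classmethod
    def concatenate(cls, clouds: Sequence["PointCloud"]) -> "PointCloud":
        if not clouds:
            return cls(np.empty(0), np.empty(0), np.empty(0))
        keys = set(clouds[0].attributes)
        for c in clouds[1:]:
            keys &= set(c.attributes)
        return cls(
            np.concatenate([c.x for c in clouds]),
            np.concatenate([c.y for c in clouds]),
            np.concatenate([c.z for c in clouds]),
            {k: np.concatenate([c.attributes[k] for c in clouds]) for k in keys},
        )


@dataclass
class RegionOfInterest:
    """One analysis unit: a plot or two-row block polygon plus identity.

    ``replicate`` follows the two-replicate field design and must be 1 or 2.
    """

    region_id: str
    polygon: Polygon
    genotype: str = ""
    replicate: int = 1
    plot: str = ""
    rows: tuple[int, ...] = ()
    date: str = ""
    das: int | None = None
    platform: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(self.polygon)
        if not self.polygon.is_valid or self.polygon.area <= 0:
            raise ValueError(
                f"region {self.region_id!r}: polygon must be simple with positive area"
            )
        if self.replicate not in (1, 2):
            raise ValueError(f"region {self.region_id!r}: replicate must be 1 or 2")
        self.rows = tuple(int(r) for r in self.rows)


def _read_csv(path: Path) -> PointCloud:
    text = path.read_text(encoding="utf-8").strip()
    if not text:
        return PointCloud(np.empty(0), np.empty(0), np.empty(0))
    lines = text.splitlines()
    start = 0
    header: list[str] = []
    first = [t.strip() for t in lines[0].split(",")]
    try:
        float(first[0])
    except ValueError:
        header = [t.lower() for t in first]
        start = 1
    if header and header[:3] != ["x", "y", "z"]:
        raise ValueError(f"{path}: CSV header must start with x,y,z (got {header[:3]})")
    rows = []
    for i, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        toks = line.split(",")
        try:
            rows.append([float(t) for t in toks])
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric value at line {i}") from exc
    if not rows:
        return PointCloud(np.empty(0), np.empty(0), np.empty(0))
    width = len(rows[0])
    if width < 3 or any(len(r) != width for r in rows):
        raise ValueError(f"{path}: ragged or <3-column CSV")
    arr = np.asarray(rows, dtype=float)
    attrs = {}
    names = header[3:] if header else [f"attr{j}" for j in range(width - 3)]
    for j, name in enumerate(names):
        attrs[name] = arr[:, 3 + j]
    return PointCloud(arr[:, 0], arr[:, 1], arr[:, 2], attrs)


def _write_csv(cloud: PointCloud, path: Path) -> None:
    names = list(cloud.attributes)
    header = ",".join(["x", "y", "z", *names])
    cols = [cloud.x, cloud.y, cloud.z] + [np.asarray(cloud.attributes[n], float) for n in names]
    body = np.column_stack(cols) if cloud.n else np.empty((0, 3 + len(names)))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, body, fmt="%.8g", delimiter=",")


_EMPTY_PLY = (
    "ply\nformat ascii 1.0\nelement vertex 0\n"
    "property float x\nproperty float y\nproperty float z\nend_header\n"
)


def _read_ply(path: Path) -> PointCloud:
    import trimesh

    if b"element vertex 0" in path.read_bytes()[:512]:
        return PointCloud(np.empty(0), np.empty(0), np.empty(0))
    loaded = trimesh.load(str(path), process=False)
    verts = np.asarray(loaded.vertices, dtype=float)
    return PointCloud.from_xyz(verts)


def _write_ply(cloud: PointCloud, path: Path) -> None:
    if cloud.n == 0:
        path.write_text(_EMPTY_PLY, encoding="utf-8")
        return
    import trimesh
    from trimesh.exchange.ply import export_ply

    path.write_bytes(export_ply(trimesh.points.PointCloud(cloud.xyz()), encoding="ascii"))


_FORMATS = ("las", "csv", "ply")


def _guess_format(path: Path, format: str | None) -> str:
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("xyz", "txt"):
        fmt = "csv"
    if fmt not in _FORMATS:
        raise ValueError(f"unknown point-cloud format {fmt!r}; expected one of {_FORMATS}")
    return fmt


def read_point_cloud(path: str | Path, format: str | None = None) -> PointCloud:
    """Read a point cloud from LAS, ASCII PLY, or ``x,y,z[,...]`` CSV.

    The format is taken from ``format`` if given, else from the file suffix.
    Point order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"point-cloud file not found: {path}")
    fmt = _guess_format(path, format)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "ply":
        return _read_ply(path)
    x, y, z = _las.read_las(path)
    return PointCloud(x, y, z)


def write_point_cloud(cloud: PointCloud, path: str | Path, format: str | None = None) -> None:
    """Write a point cloud; round-trips through :func:`read_point_cloud`.

    CSV is exact to 8 significant digits, PLY to float32, LAS to its
    scale quantum (1 mm by default).
    """
    path = Path(path)
    fmt = _guess_format(path, format)
    try:
        if fmt == "csv":
            _write_csv(cloud, path)
        elif fmt == "ply":
            _write_ply(cloud, path)
        else:
            _las.write_las(cloud.x, cloud.y, cloud.z, path)
    except OSError as exc:
        raise IOError(f"cannot write point cloud to {path}: {exc}") from exc


def region_mask(cloud: PointCloud, roi: RegionOfInterest) -> np.ndarray:
    """Boolean mask of points whose (x, y) lie inside or ON the polygon."""
    if roi.polygon.area <= 0:
        raise ValueError(f"region {roi.region_id!r}: degenerate polygon")
    mask = np.zeros(cloud.n, dtype=bool)
    if cloud.n == 0:
        return mask
    # bbox prefilter keeps the vectorized predicate cheap on large scenes
    minx, miny, maxx, maxy = roi.polygon.bounds
    box = (cloud.x >= minx) & (cloud.x <= maxx) & (cloud.y >= miny) & (cloud.y <= maxy)
    idx = np.flatnonzero(box)
    if idx.size == 0:
        return mask
    pts = shapely.points(cloud.x[idx], cloud.y[idx])
    mask[idx[shapely.covers(roi.polygon, pts)]] = True
    return mask


def clip_to_region(cloud: PointCloud, roi: RegionOfInterest) -> PointCloud:
    """Return the points whose (x, y) lie inside or ON the region polygon.

    Boundary points are included (inclusive test), which is deterministic
    and conservative for narrow row blocks. Idempotent.
    """
    return cloud.take(region_mask(cloud, roi))


def _roi_to_feature(roi: RegionOfInterest) -> dict:
    return {
        "type": "Feature",
        "geometry": mapping(roi.polygon),
        "properties": {
            "region_id": roi.region_id,
            "genotype": roi.genotype,
            "replicate": roi.replicate,
            "plot": roi.plot,
            "rows": list(roi.rows),
            "date": roi.date,
            "das": roi.das,
            "platform": roi.platform,
        },
    }


def write_regions(regions: Iterable[RegionOfInterest], path: str | Path) -> None:
    """Write regions as a GeoJSON FeatureCollection of polygons."""
    fc = {"type": "FeatureCollection", "features": [_roi_to_feature(r) for r in regions]}
    Path(path).write_text(json.dumps(fc, indent=1), encoding="utf-8")


def read_regions(path: str | Path) -> list[RegionOfInterest]:
    """Read a GeoJSON FeatureCollection written by :func:`write_regions`."""
    fc = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for feat in fc.get("features", []):
        props: Mapping = feat.get("properties") or {}
        out.append(
            RegionOfInterest(
                region_id=str(props.get("region_id", "")),
                polygon=shape(feat["geometry"]),
                genotype=str(props.get("genotype", "")),
                replicate=int(props.get("replicate", 1)),
                plot=str(props.get("plot", "")),
                rows=tuple(props.get("rows") or ()),
                date=str(props.get("date", "")),
                das=props.get("das"),
                platform=str(props.get("platform", "")),
            )
        )
    return out
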