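"""Readers and writers for common particle-list formats.

Supported dialects
------------------
``twist_csv``
    This package's native, convention-free interchange format: a CSV with
    header ``particle_id,tomo_id,x,y,z,r11..r33,score,object_id,class_label``
    where the rotation is stored as a row-major matrix (no Euler ambiguity).
``relion_star``
    Relion 3+ STAR particle tables: ``rlnCoordinateX/Y/Z`` voxel
    coordinates, ``rlnAngleRot/Tilt/Psi`` ZYZ intrinsic Euler angles and
    optional ``rlnOriginX/Y/ZAngst`` sub-voxel shifts (folded into the
    position when a pixel size is available).  The STOPGAP dialect is read
    through this path with an explicit format flag, never sniffed.
``motl_em`` / ``motl_csv``
    TOM/AV3 motive lists: a 20-row matrix (EM binary) or the equivalent
    named-column CSV.  Rows 8-10 hold positions, 11-13 shifts (folded in),
    17-19 the ZXZ Euler angles phi/psi/theta; row 4 is the particle number,
    row 5 the tomogram number, row 1 the score.  Row 6 carries the object
    affiliation on output (this package's documented choice).
``dynamo_tbl``
    Dynamo tables: column 1 tag, 4-6 shifts, 7-9 ZXZ Euler angles
    (tdrot, tilt, narot), 10 score, 20 tomogram, 21 object, 24-26 position.

Euler conventions are converted to the internal rotation-matrix convention
(the stored matrix maps the canonical frame onto the particle) at read
time; writers invert the conversion, and every reader/writer pair is
round-trip tested.  Angles on disk are degrees.
"""

from __future__ import annotations

import struct
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation as _R

from .particles import ParticleList, warn_dropped

__all__ = [
    "read_particle_list",
    "write_particle_list",
    "read_em",
    "write_em",
    "read_mask",
    "FORMATS",
]

FORMATS = ("twist_csv", "relion_star", "stopgap_star", "motl_em", "motl_csv", "dynamo_tbl")

_FLOAT_FMT = "%.6f"


# ---------------------------------------------------------------------------
# Euler conversions (internal convention: omega maps reference -> particle)

def _from_relion(rot: np.ndarray, tilt: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Relion stores the ZYZ intrinsic angles rotating the particle onto the
    reference; the internal matrix is the inverse of that rotation."""
    angles = np.column_stack([rot, tilt, psi])
    return _R.from_euler("ZYZ", angles, degrees=True).inv().as_matrix()


def _to_relion(rotations: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # gimbal-lock warnings; any branch is valid
        return _R.from_matrix(rotations).inv().as_euler("ZYZ", degrees=True)


def _from_motl(phi: np.ndarray, psi: np.ndarray, theta: np.ndarray) -> np.ndarray:
    angles = np.column_stack([phi, theta, psi])
    return _R.from_euler("ZXZ", angles, degrees=True).as_matrix()


def _to_motl(rotations: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        e = _R.from_matrix(rotations).as_euler("ZXZ", degrees=True)
    return e[:, 0], e[:, 2], e[:, 1]  # phi, psi, theta


def _from_dynamo(tdrot, tilt, narot) -> np.ndarray:
    angles = np.column_stack([tdrot, tilt, narot])
    return _R.from_euler("ZXZ", angles, degrees=True).as_matrix()


def _to_dynamo(rotations: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _R.from_matrix(rotations).as_euler("ZXZ", degrees=True)


# ---------------------------------------------------------------------------
# EM binary codec (TOM-era format: 512-byte header, little-endian float32)

def read_em(path) -> np.ndarray:
    """Read a TOM/AV3 EM volume as an array of shape (xdim, ydim, zdim)."""
    raw = Path(path).read_bytes()
    if len(raw) < 512:
        raise ValueError(f"{path}: truncated EM header")
    machine, _, _, dtype_code = raw[0], raw[1], raw[2], raw[3]
    dims = struct.unpack("<3i", raw[4:16])
    codes = {1: np.int8, 2: np.int16, 4: np.int32, 5: np.float32, 9: np.float64}
    if dtype_code not in codes:
        raise ValueError(f"{path}: unsupported EM data code {dtype_code}")
    count = dims[0] * dims[1] * dims[2]
    data = np.frombuffer(raw[512:], dtype=codes[dtype_code], count=count)
    return data.reshape(dims[::-1]).transpose(2, 1, 0).astype(float)


def write_em(path, volume: np.ndarray) -> None:
    volume = np.asarray(volume, dtype=np.float32)
    header = bytearray(512)
    header[0] = 6  # PC byte order
    header[3] = 5  # float32
    header[4:16] = struct.pack("<3i", *volume.shape)
    Path(path).write_bytes(bytes(header) + volume.transpose(2, 1, 0).tobytes())


def read_mask(path) -> tuple[np.ndarray, float | None]:
    """Read a binary 3D mask from an MRC/CCP4 map (via gemmi) or an EM file.

    Returns ``(array, voxel_size)``; the voxel size is in angstrom for MRC
    maps and ``None`` for EM files (the caller must supply it).
    """
    path = Path(path)
    if path.suffix.lower() == ".em":
        return read_em(path), None
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    m.setup(0.0)
    arr = np.array(m.grid, copy=True)
    voxel = float(m.grid.spacing[0]) if m.grid.spacing[0] > 0 else None
    return arr, voxel


# ---------------------------------------------------------------------------
# dialect readers

def _require(df: pd.DataFrame, cols: list[str], fmt: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{fmt}: missing mandatory columns {missing}")


def _read_twist_csv(path, unit, pixel_size) -> ParticleList:
    df = pd.read_csv(path)
    rot_cols = [f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]
    _require(df, ["particle_id", "tomo_id", "x", "y", "z", *rot_cols], "twist_csv")
    rotations = df[rot_cols].to_numpy(dtype=float).reshape(-1, 3, 3)
    return ParticleList.from_arrays(
        df[["x", "y", "z"]].to_numpy(dtype=float),
        rotations,
        particle_ids=df["particle_id"].to_numpy(dtype=int),
        tomo_ids=df["tomo_id"].to_numpy(dtype=int),
        object_ids=df["object_id"] if "object_id" in df else None,
        scores=df["score"] if "score" in df else None,
        class_labels=df["class_label"] if "class_label" in df else None,
        unit=unit,
        pixel_size=pixel_size,
        provenance={"format": "twist_csv", "path": str(path)},
    )


def _star_blocks(text: str) -> dict[str, pd.DataFrame]:
    """Minimal STAR parser: every ``data_`` block with a ``loop_`` becomes a
    DataFrame keyed by block name."""
    blocks: dict[str, pd.DataFrame] = {}
    lines = text.splitlines()
    i, n = 0, len(lines)
    while i < n:
        line = lines[i].strip()
        if line.startswith("data_"):
            name = line[5:]
            i += 1
            while i < n and lines[i].strip() != "loop_":
                if lines[i].strip().startswith("data_"):
                    break
                i += 1
            if i >= n or lines[i].strip() != "loop_":
                continue
            i += 1
            cols = []
            while i < n and lines[i].strip().startswith("_"):
                cols.append(lines[i].strip().split()[0].lstrip("_"))
                i += 1
            rows = []
            while i < n:
                s = lines[i].strip()
                if not s or s.startswith(("data_", "#")):
                    break
                rows.append(s.split())
                i += 1
            blocks[name] = pd.DataFrame(rows, columns=cols)
        else:
            i += 1
    return blocks


def _read_star(path, unit, pixel_size, fmt) -> ParticleList:
    blocks = _star_blocks(Path(path).read_text())
    table = None
    for df in blocks.values():
        if "rlnCoordinateX" in df.columns:
            table = df
            break
    if table is None:
        raise ValueError(f"{fmt}: no data block with rlnCoordinateX found in {path}")
    _require(
        table,
        ["rlnCoordinateX", "rlnCoordinateY", "rlnCoordinateZ",
         "rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi"],
        fmt,
    )
    pos = table[["rlnCoordinateX", "rlnCoordinateY", "rlnCoordinateZ"]].to_numpy(dtype=float)
    origin_cols = ["rlnOriginXAngst", "rlnOriginYAngst", "rlnOriginZAngst"]
    if all(c in table.columns for c in origin_cols):
        if not pixel_size:
            raise ValueError(f"{fmt}: rlnOriginXAngst present; pixel_size required to fold shifts in")
        pos = pos - table[origin_cols].to_numpy(dtype=float) / pixel_size
    rotations = _from_relion(
        table["rlnAngleRot"].to_numpy(dtype=float),
        table["rlnAngleTilt"].to_numpy(dtype=float),
        table["rlnAnglePsi"].to_numpy(dtype=float),
    )
    n = len(table)
    tomo = (
        table["rlnTomoName"].str.extract(r"(\d+)")[0].astype(int).to_numpy()
        if "rlnTomoName" in table.columns
        else np.zeros(n, dtype=int)
    )
    return ParticleList.from_arrays(
        pos,
        rotations,
        particle_ids=(
            table["rlnParticleID"].to_numpy(dtype=int)
            if "rlnParticleID" in table.columns
            else np.arange(n)
        ),
        tomo_ids=tomo,
        object_ids=(
            table["rlnObjectNumber"].astype(float).astype("Int64")
            if "rlnObjectNumber" in table.columns
            else None
        ),
        scores=(
            table["rlnAutopickFigureOfMerit"].to_numpy(dtype=float)
            if "rlnAutopickFigureOfMerit" in table.columns
            else None
        ),
        class_labels=table["rlnClassLabel"] if "rlnClassLabel" in table.columns else None,
        unit=unit,
        pixel_size=pixel_size,
        provenance={"format": fmt, "path": str(path)},
    )


_MOTL_COLUMNS = [
    "score", "geom1", "geom2", "subtomo_id", "tomo_id", "object_id",
    "subtomo_mean", "x", "y", "z", "shift_x", "shift_y", "shift_z",
    "geom3", "geom4", "geom5", "phi", "psi", "theta", "class",
]


def _motl_frame_to_list(df: pd.DataFrame, unit, pixel_size, fmt, path) -> ParticleList:
    pos = df[["x", "y", "z"]].to_numpy(dtype=float) + df[
        ["shift_x", "shift_y", "shift_z"]
    ].to_numpy(dtype=float)
    rotations = _from_motl(
        df["phi"].to_numpy(dtype=float),
        df["psi"].to_numpy(dtype=float),
        df["theta"].to_numpy(dtype=float),
    )
    obj = df["object_id"].to_numpy(dtype=float)
    return ParticleList.from_arrays(
        pos,
        rotations,
        particle_ids=df["subtomo_id"].to_numpy(dtype=int),
        tomo_ids=df["tomo_id"].to_numpy(dtype=int),
        object_ids=pd.array(np.where(obj == 0, np.nan, obj), dtype="float64").astype("Int64"),
        scores=df["score"].to_numpy(dtype=float),
        unit=unit,
        pixel_size=pixel_size,
        provenance={"format": fmt, "path": str(path)},
    )


def _read_motl_em(path, unit, pixel_size) -> ParticleList:
    mat = read_em(path)
    if mat.ndim == 3 and mat.shape[2] == 1:
        mat = mat[:, :, 0]
    if mat.shape[0] != 20:
        raise ValueError(f"motl_em: expected a 20-row motive list, got shape {mat.shape}")
    df = pd.DataFrame(mat.T, columns=_MOTL_COLUMNS)
    return _motl_frame_to_list(df, unit, pixel_size, "motl_em", path)


def _read_motl_csv(path, unit, pixel_size) -> ParticleList:
    df = pd.read_csv(path)
    _require(df, _MOTL_COLUMNS[:1] + ["subtomo_id", "tomo_id", "x", "y", "z", "phi", "psi", "theta"], "motl_csv")
    for c in _MOTL_COLUMNS:
        if c not in df.columns:
            df[c] = 0.0
    return _motl_frame_to_list(df, unit, pixel_size, "motl_csv", path)


def _read_dynamo(path, unit, pixel_size) -> ParticleList:
    df = pd.read_csv(path, sep=r"\s+", header=None)
    if df.shape[1] < 26:
        raise ValueError(f"dynamo_tbl: expected >=26 columns, got {df.shape[1]}")
    pos = df.iloc[:, 23:26].to_numpy(dtype=float) + df.iloc[:, 3:6].to_numpy(dtype=float)
    rotations = _from_dynamo(
        df.iloc[:, 6].to_numpy(dtype=float),
        df.iloc[:, 7].to_numpy(dtype=float),
        df.iloc[:, 8].to_numpy(dtype=float),
    )
    obj = df.iloc[:, 20].to_numpy(dtype=float)
    return ParticleList.from_arrays(
        pos,
        rotations,
        particle_ids=df.iloc[:, 0].to_numpy(dtype=int),
        tomo_ids=df.iloc[:, 19].to_numpy(dtype=int),
        object_ids=pd.array(np.where(obj == 0, np.nan, obj), dtype="float64").astype("Int64"),
        scores=df.iloc[:, 9].to_numpy(dtype=float),
        unit=unit,
        pixel_size=pixel_size,
        provenance={"format": "dynamo_tbl", "path": str(path)},
    )


def read_particle_list(
    path, format: str, unit: str = "nm", pixel_size: float | None = None
) -> ParticleList:
    """Read a particle list, converting orientations to the internal
    rotation-matrix convention.  Row order is preserved."""
    if format == "twist_csv":
        return _read_twist_csv(path, unit, pixel_size)
    if format in ("relion_star", "stopgap_star"):
        return _read_star(path, unit, pixel_size, format)
    if format == "motl_em":
        return _read_motl_em(path, unit, pixel_size)
    if format == "motl_csv":
        return _read_motl_csv(path, unit, pixel_size)
    if format == "dynamo_tbl":
        return _read_dynamo(path, unit, pixel_size)
    raise ValueError(f"unknown format {format!r}; choose from {FORMATS}")


# ---------------------------------------------------------------------------
# writers (deterministic field ordering, 6-decimal floats)

def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def _write_twist_csv(pl: ParticleList, path) -> None:
    rot_cols = [f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]
    df = pd.DataFrame(
        {
            "particle_id": pl.particle_ids,
            "tomo_id": pl.tomo_ids,
            "x": pl.positions[:, 0],
            "y": pl.positions[:, 1],
            "z": pl.positions[:, 2],
        }
    )
    flat = pl.rotations.reshape(-1, 9)
    for k, c in enumerate(rot_cols):
        df[c] = flat[:, k]
    df["score"] = pl.meta["score"].to_numpy(dtype=float)
    df["object_id"] = pl.meta["object_id"]
    df["class_label"] = pl.meta["class_label"]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _write_star(pl: ParticleList, path) -> None:
    euler = _to_relion(pl.rotations) if len(pl) else np.zeros((0, 3))
    cols = [
        ("rlnCoordinateX", [_fmt(v) for v in pl.positions[:, 0]]),
        ("rlnCoordinateY", [_fmt(v) for v in pl.positions[:, 1]]),
        ("rlnCoordinateZ", [_fmt(v) for v in pl.positions[:, 2]]),
        ("rlnAngleRot", [_fmt(v) for v in euler[:, 0]]),
        ("rlnAngleTilt", [_fmt(v) for v in euler[:, 1]]),
        ("rlnAnglePsi", [_fmt(v) for v in euler[:, 2]]),
        ("rlnTomoName", [f"tomo_{t}" for t in pl.tomo_ids]),
        ("rlnParticleID", [str(i) for i in pl.particle_ids]),
        ("rlnAutopickFigureOfMerit", [_fmt(0.0 if np.isnan(s) else s) for s in pl.meta["score"].to_numpy(dtype=float)]),
    ]
    if pl.meta["object_id"].notna().any():
        cols.append(
            ("rlnObjectNumber", ["-1" if pd.isna(o) else str(int(o)) for o in pl.meta["object_id"]])
        )
    if pl.meta["class_label"].notna().any():
        cols.append(
            ("rlnClassLabel", ["NA" if pd.isna(c) else str(c) for c in pl.meta["class_label"]])
        )
    lines = ["data_particles", "", "loop_"]
    lines += [f"_{name} #{k+1}" for k, (name, _) in enumerate(cols)]
    for row in zip(*(vals for _, vals in cols)) if len(pl) else []:
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def _motl_matrix(pl: ParticleList, fmt: str) -> np.ndarray:
    if pl.meta["class_label"].notna().any():
        warn_dropped("class_label", fmt)
    phi, psi, theta = _to_motl(pl.rotations) if len(pl) else (np.zeros(0),) * 3
    mat = np.zeros((20, len(pl)))
    mat[0] = np.nan_to_num(pl.meta["score"].to_numpy(dtype=float))
    mat[3] = pl.particle_ids
    mat[4] = pl.tomo_ids
    mat[5] = pl.meta["object_id"].fillna(0).to_numpy(dtype=float)
    mat[7:10] = pl.positions.T
    mat[16], mat[17], mat[18] = phi, psi, theta
    return np.round(mat, 6)


def _write_motl_em(pl: ParticleList, path) -> None:
    write_em(path, _motl_matrix(pl, "motl_em")[:, :, None])


def _write_motl_csv(pl: ParticleList, path) -> None:
    df = pd.DataFrame(_motl_matrix(pl, "motl_csv").T, columns=_MOTL_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _write_dynamo(pl: ParticleList, path) -> None:
    if pl.meta["class_label"].notna().any():
        warn_dropped("class_label", "dynamo_tbl")
    euler = _to_dynamo(pl.rotations) if len(pl) else np.zeros((0, 3))
    mat = np.zeros((len(pl), 26))
    mat[:, 0] = pl.particle_ids
    mat[:, 1] = 1.0
    mat[:, 6:9] = euler
    mat[:, 9] = np.nan_to_num(pl.meta["score"].to_numpy(dtype=float))
    mat[:, 19] = pl.tomo_ids
    mat[:, 20] = pl.meta["object_id"].fillna(0).to_numpy(dtype=float)
    mat[:, 23:26] = pl.positions
    lines = [" ".join(_fmt(v) for v in row) for row in mat]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_particle_list(pl: ParticleList, path, format: str) -> None:
    """Write ``pl`` in the chosen dialect.  Output is bit-stable for
    identical input; fields a format cannot hold are dropped with a
    warning, never silently."""
    writers = {
        "twist_csv": _write_twist_csv,
        "relion_star": _write_star,
        "stopgap_star": _write_star,
        "motl_em": _write_motl_em,
        "motl_csv": _write_motl_csv,
        "dynamo_tbl": _write_dynamo,
    }
    if format not in writers:
        raise ValueError(f"unknown format {format!r}; choose from {FORMATS}")
    writers[format](pl, path)
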