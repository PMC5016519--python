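"""Localization-table input/output and rectangular observation windows.

The universal currency of the pipeline is a flat table of single-molecule
localizations: one row per fitted emitter position, with x/y coordinates,
the acquisition frame the fit came from, and (optionally) the fitted
photon count.  Coordinates are stored in nanometres internally no matter
which dialect they were read from; densities elsewhere in the package are
per square micrometre.  Unit conversion happens here, at the I/O boundary,
and nowhere else.

Supported dialects
------------------
``generic_csv``
    Comma-separated with a header row ``x_nm,y_nm,frame,photons``
    (``photons`` optional).  This is also the only write dialect.

``rapidstorm_txt``
    Whitespace-separated values as exported by rapidSTORM, with an
    optional leading ``#`` comment header describing the columns in an
    XML-like syntax.  When the header is present, column roles and units
    are taken from it; when it is absent, columns are taken positionally
    as x, y, frame, intensity.  Coordinates are assumed to be nanometres
    unless the header declares micrometres (the exporting software does
    not always record the unit; nm is the documented convention here).

Rows whose coordinates are non-finite (fit failures in real exports) are
skipped with a logged count rather than aborting the read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LocalizationTable",
    "Region",
    "FormatError",
    "EmptyInputError",
    "read_localizations",
    "write_localizations",
    "crop_region",
    "DIALECTS",
]

DIALECTS = ("generic_csv", "rapidstorm_txt")

#: column order of the generic CSV dialect (photons optional)
GENERIC_CSV_COLUMNS = ("x_nm", "y_nm", "frame", "photons")

NM_PER_UM = 1000.0


class FormatError(ValueError):
    """A file does not conform to the declared dialect (e.g. missing column)."""


class EmptyInputError(ValueError):
    """A file contains no parseable content at all."""


@dataclass(frozen=True)
class Region:
    """Axis-aligned rectangular observation window, in nm.

    Membership is half-open, ``[min, max)`` on both axes, so a tiling of
    windows partitions the plane without double-counting points on
    shared edges.  ``area()`` is the symbol *A* of the Ripley estimator.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_min) and np.isfinite(self.x_max)
                and np.isfinite(self.y_min) and np.isfinite(self.y_max)):
            raise ValueError("region bounds must be finite")
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate region: [{self.x_min}, {self.x_max}) x "
                f"[{self.y_min}, {self.y_max})"
            )

    @classmethod
    def square(cls, side_nm: float, origin: tuple[float, float] = (0.0, 0.0)) -> "Region":
        x0, y0 = origin
        return cls(x0, x0 + side_nm, y0, y0 + side_nm)

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    def area(self) -> float:
        """Window area in nm^2."""
        return self.width * self.height

    def area_um2(self) -> float:
        """Window area in um^2."""
        return self.area() / NM_PER_UM**2

    def buffered(self, pad_nm: float) -> "Region":
        """Region grown (pad > 0) or shrunk (pad < 0) by ``pad_nm`` on every side."""
        return Region(self.x_min - pad_nm, self.x_max + pad_nm,
                      self.y_min - pad_nm, self.y_max + pad_nm)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean half-open membership mask for coordinate arrays."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x_min) & (x < self.x_max) & (y >= self.y_min) & (y < self.y_max)


class LocalizationTable:
    """A list of localizations: x, y (nm), frame, optional photons.

    Thin wrapper over a :class:`pandas.DataFrame` with validated columns.
    Row count ``n`` is the symbol *n* of the Ripley estimator.
    """

    REQUIRED = ("x", "y", "frame")

    def __init__(self, data: pd.DataFrame, validate: bool = True):
        if validate:
            missing = [c for c in self.REQUIRED if c not in data.columns]
            if missing:
                raise FormatError(f"missing required column(s): {', '.join(missing)}")
            data = data.reset_index(drop=True)
            x = data["x"].to_numpy(dtype=float)
            y = data["y"].to_numpy(dtype=float)
            if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
                raise ValueError("non-finite coordinates in table; filter them at read time")
            frame = np.asarray(data["frame"])
            if not np.issubdtype(frame.dtype, np.integer):
                fframe = np.asarray(frame, dtype=float)
                if not np.all(np.isfinite(fframe)) or not np.all(fframe == np.floor(fframe)):
                    raise ValueError("frame indices must be integral")
                frame = fframe.astype(np.int64)
            if frame.size and frame.min() < 0:
                raise ValueError("frame indices must be >= 0")
            cols = {"x": x, "y": y, "frame": frame.astype(np.int64)}
            if "photons" in data.columns:
                cols["photons"] = data["photons"].to_numpy(dtype=float)
            data = pd.DataFrame(cols)
        self.data = data

    @classmethod
    def from_arrays(cls, x, y, frame=0, photons=None) -> "LocalizationTable":
        x = np.asarray(x, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        frame = np.broadcast_to(np.asarray(frame), x.shape).astype(np.int64)
        cols = {"x": x, "y": y, "frame": frame}
        if photons is not None:
            cols["photons"] = np.asarray(photons, dtype=float).ravel()
        return cls(pd.DataFrame(cols))

    @classmethod
    def empty(cls, photons: bool = False) -> "LocalizationTable":
        cols = {"x": np.empty(0), "y": np.empty(0),
                "frame": np.empty(0, dtype=np.int64)}
        if photons:
            cols["photons"] = np.empty(0)
        return cls(pd.DataFrame(cols))

    # -- accessors ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.data)

    def __len__(self) -> int:
        return self.n

    @property
    def x(self) -> np.ndarray:
        return self.data["x"].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.data["y"].to_numpy()

    @property
    def frame(self) -> np.ndarray:
        return self.data["frame"].to_numpy()

    @property
    def has_photons(self) -> bool:
        return "photons" in self.data.columns

    @property
    def photons(self) -> Optional[np.ndarray]:
        return self.data["photons"].to_numpy() if self.has_photons else None

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array in nm."""
        return np.column_stack([self.x, self.y])

    def take(self, indices) -> "LocalizationTable":
        """Row subset by positional indices, order preserved as given."""
        return LocalizationTable(self.data.iloc[np.asarray(indices)].reset_index(drop=True),
                                 validate=False)

    def equals(self, other: "LocalizationTable") -> bool:
        return self.data.equals(other.data)

    def __repr__(self) -> str:
        cols = "+photons" if self.has_photons else ""
        return f"<LocalizationTable n={self.n} {cols}>"


# ---------------------------------------------------------------------------
# reading


def _coerce_float(values) -> np.ndarray:
    """String-to-float with NaN on failure, correctly rounded to the last ulp
    (pandas' to_numeric string path is not, which would break round trips)."""
    arr = np.empty(len(values), dtype=float)
    for i, s in enumerate(np.asarray(values, dtype=object)):
        try:
            arr[i] = float(s)
        except (TypeError, ValueError):
            arr[i] = np.nan
    return arr


def _finish_table(df: pd.DataFrame, source: str) -> LocalizationTable:
    """Coerce, drop invalid rows with a logged count, and wrap."""
    for c in ("x", "y", "frame", "photons"):
        if c in df.columns:
            df[c] = _coerce_float(df[c])
    ok = np.isfinite(df["x"].to_numpy(dtype=float)) & np.isfinite(df["y"].to_numpy(dtype=float))
    fr = df["frame"].to_numpy(dtype=float)
    ok &= np.isfinite(fr) & (fr == np.floor(fr)) & (fr >= 0)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("%s: skipped %d row(s) with non-finite or invalid values",
                       source, n_skipped)
    df = df.loc[ok].reset_index(drop=True)
    df["frame"] = df["frame"].astype(np.int64)
    return LocalizationTable(df)


def _read_generic_csv(path: Path) -> LocalizationTable:
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    required = {"x_nm": "x", "y_nm": "y", "frame": "frame"}
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    df = raw.rename(columns={**required, "photons": "photons"})
    keep = ["x", "y", "frame"] + (["photons"] if "photons" in df.columns else [])
    return _finish_table(df[keep].copy(), str(path))


# rapidSTORM header fields we understand; anything else is carried but ignored
_RS_ROLES = {
    "Position-0-0": "x",
    "Position-1-0": "y",
    "ImageNumber-0-0": "frame",
    "Amplitude-0-0": "photons",
}
_RS_UNIT_SCALE = {"nanometer": 1.0, "nanometre": 1.0,
                  "micrometer": NM_PER_UM, "micrometre": NM_PER_UM}


def _parse_rapidstorm_header(line: str) -> list[tuple[str, float]]:
    """Return per-column (role, unit-scale) from a rapidSTORM comment header."""
    fields = re.findall(r"<field\b([^>]*)/?>", line)
    columns: list[tuple[str, float]] = []
    for attrs in fields:
        ident = re.search(r'identifier="([^"]+)"', attrs)
        unit = re.search(r'unit="([^"]+)"', attrs)
        role = _RS_ROLES.get(ident.group(1), "_ignored") if ident else "_ignored"
        scale = 1.0
        if role in ("x", "y") and unit:
            scale = _RS_UNIT_SCALE.get(unit.group(1), 1.0)
        columns.append((role, scale))
    return columns


def _read_rapidstorm_txt(path: Path) -> LocalizationTable:
    with open(path, "r") as fh:
        first = fh.readline()
    if first == "":
        raise EmptyInputError(f"{path}: file is empty")
    header_cols = None
    if first.lstrip().startswith("#"):
        header_cols = _parse_rapidstorm_header(first)
    try:
        raw = pd.read_csv(path, sep=r"\s+", comment="#", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: no data rows") from None
    if header_cols:
        if len(header_cols) != raw.shape[1]:
            raise FormatError(
                f"{path}: header declares {len(header_cols)} columns, "
                f"data has {raw.shape[1]}")
        roles = [r for r, _ in header_cols]
        scales = dict(zip(roles, (s for _, s in header_cols)))
    else:
        # positional fallback: x, y, frame, intensity
        roles = ["x", "y", "frame", "photons"][: raw.shape[1]]
        roles += ["_ignored"] * (raw.shape[1] - len(roles))
        scales = {}
    for need in ("x", "y", "frame"):
        if need not in roles:
            raise FormatError(f"{path}: required column '{need}' not present")
    df = pd.DataFrame()
    for j, role in enumerate(roles):
        if role == "_ignored" or role in df.columns:
            continue
        df[role] = raw.iloc[:, j]
    table = _finish_table(df, str(path))
    for axis in ("x", "y"):
        s = scales.get(axis, 1.0)
        if s != 1.0:
            table.data[axis] = table.data[axis] * s
    return table


def read_localizations(path, dialect: str = "generic_csv") -> LocalizationTable:
    """Read a localization table, normalizing coordinates to nm.

    Parameters
    ----------
    path : path-like
        File to read.
    dialect : {"generic_csv", "rapidstorm_txt"}
        Input format.

    Raises
    ------
    FormatError
        A required column is absent.
    EmptyInputError
        The file holds no parseable content (a header-only CSV is a
        valid *empty table*, not an error).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "generic_csv":
        return _read_generic_csv(path)
    if dialect == "rapidstorm_txt":
        return _read_rapidstorm_txt(path)
    raise ValueError(f"unsupported dialect {dialect!r}; choose from {DIALECTS}")


def write_localizations(table: LocalizationTable, path, dialect: str = "generic_csv") -> None:
    """Write a table; ``read_localizations`` of the result reproduces it exactly.

    Floats are written with Python's shortest round-tripping repr, so the
    read-write cycle is an identity at full precision.
    """
    if dialect != "generic_csv":
        raise ValueError(f"write supports only 'generic_csv', got {dialect!r}")
    # written by hand with Python's shortest round-tripping float repr:
    # pandas' to_csv clips to 15 significant digits, breaking the identity
    columns = [("x_nm", table.x), ("y_nm", table.y), ("frame", table.frame)]
    if table.has_photons:
        columns.append(("photons", table.photons))
    with open(path, "w") as fh:
        fh.write(",".join(name for name, _ in columns) + "\n")
        for i in range(table.n):
            cells = [repr(float(arr[i])) if name != "frame" else str(int(arr[i]))
                     for name, arr in columns]
            fh.write(",".join(cells) + "\n")


def crop_region(table: LocalizationTable, region: Region) -> LocalizationTable:
    """Rows with x_min <= x < x_max and y_min <= y < y_max, order preserved.

    Half-open on the max edges so that tilings of windows never
    double-count a localization.  An empty result is allowed.
    """
    mask = region.contains(table.x, table.y)
    return LocalizationTable(table.data.loc[mask].reset_index(drop=True), validate=False)
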