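"""Reading and writing the plain-text formats used by every pipeline stage.

All coordinates and distances are nanometres once inside the package.  The
formats are deliberately simple delimited text:

* **Localisation tables** — CSV/TSV with a header.  Default column names are
  ``x[nm]``, ``y[nm]``, ``mark`` and ``roi``; a ``column_map`` adapts other
  conventions (e.g. ThunderSTORM-style headers), and ``unit_scale`` converts
  the stored unit into nm.  Extra columns (z, frame, photons...) are carried
  through untouched but unused.
* **Polyline ROIs** — CSV with columns ``roi``, ``x_nm``, ``y_nm``; rows of one
  ROI are consecutive and ordered along the line.
* **Intensity profiles** — CSV with columns ``roi``, ``position_nm``,
  ``channel_a``, ``channel_b`` sampled at a constant arc-length step.
* **Stage results** — a metadata header of ``# key: <json>`` lines followed by
  one CSV table; :func:`write_results` / :func:`read_results` round-trip all
  values to full double precision.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: canonical column names of an in-memory localisation table
LOC_COLUMNS = ("x", "y", "mark", "roi")

#: default on-disk header names, mapped onto the canonical ones
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "x": "x[nm]",
    "y": "y[nm]",
    "mark": "mark",
    "roi": "roi",
}


@dataclass
class LocalisationTable:
    """Point cloud of single-molecule localisations in nm.

    ``df`` holds one row per localisation with columns ``x``, ``y`` (float,
    nm), ``mark`` (non-empty class label) and ``roi`` (identifier; a single
    implicit ROI is stored as ``"roi_0"``).
    """

    df: pd.DataFrame
    units: str = "nm"

    def __post_init__(self) -> None:
        missing = [c for c in LOC_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"localisation table missing column(s) {missing}")
        if len(self.df):
            xy = self.df[["x", "y"]].to_numpy(dtype=float)
            if not np.all(np.isfinite(xy)):
                raise ValidationError("non-finite coordinates in localisation table")
            if (self.df["mark"].astype(str) == "").any():
                raise ValidationError("empty mark label in localisation table")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def marks(self) -> list[str]:
        """Distinct mark labels, in order of first appearance."""
        return list(dict.fromkeys(self.df["mark"]))

    @property
    def rois(self) -> list[str]:
        """Distinct ROI identifiers, in order of first appearance."""
        return list(dict.fromkeys(self.df["roi"]))

    def coords(self) -> np.ndarray:
        """(n, 2) float array of x/y positions in nm."""
        return self.df[["x", "y"]].to_numpy(dtype=float)

    def for_mark(self, mark: str) -> "LocalisationTable":
        return LocalisationTable(self.df[self.df["mark"] == mark].reset_index(drop=True))

    def for_roi(self, roi: str) -> "LocalisationTable":
        return LocalisationTable(self.df[self.df["roi"] == roi].reset_index(drop=True))

    @classmethod
    def from_arrays(
        cls,
        x: Sequence[float],
        y: Sequence[float],
        mark: Sequence[str] | str,
        roi: Sequence[str] | str = "roi_0",
    ) -> "LocalisationTable":
        x = np.asarray(x, dtype=float)
        n = len(x)
        if isinstance(mark, str):
            mark = [mark] * n
        if isinstance(roi, str):
            roi = [roi] * n
        return cls(pd.DataFrame({"x": x, "y": np.asarray(y, dtype=float), "mark": list(mark), "roi": list(roi)}))


@dataclass
class PolylineROI:
    """Ordered open polyline traced along a fibre, vertices in nm."""

    roi_id: str
    vertices: np.ndarray  # (m, 2)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError(f"ROI {self.roi_id!r}: vertices must be (m, 2)")
        if len(self.vertices) < 2:
            raise ValidationError(f"ROI {self.roi_id!r}: needs >= 2 vertices")
        seg = np.diff(self.vertices, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        if np.any(seglen == 0):
            raise ValidationError(f"ROI {self.roi_id!r}: consecutive identical vertices")
        self._seg_lengths = seglen

    @property
    def arc_length(self) -> float:
        """Total polyline length in nm."""
        return float(self._seg_lengths.sum())


@dataclass
class IntensityProfile:
    """Paired two-channel intensity series sampled along a fibre arc.

    ``channel_a`` is conventionally the pan-chromatin (total histone)
    channel, ``channel_b`` the histone-mark channel; ``step`` is the constant
    arc-length sampling interval in nm.
    """

    roi_id: str
    step: float
    channel_a: np.ndarray
    channel_b: np.ndarray

    def __post_init__(self) -> None:
        self.channel_a = np.asarray(self.channel_a, dtype=float)
        self.channel_b = np.asarray(self.channel_b, dtype=float)
        if self.step <= 0:
            raise ValidationError(f"profile {self.roi_id!r}: step must be > 0")
        if self.channel_a.shape != self.channel_b.shape or self.channel_a.ndim != 1:
            raise ValidationError(f"profile {self.roi_id!r}: channels must be equal-length 1-D")
        if self.n < 2:
            raise ValidationError(f"profile {self.roi_id!r}: needs >= 2 samples")
        if np.any(self.channel_a < 0) or np.any(self.channel_b < 0):
            raise ValidationError(f"profile {self.roi_id!r}: negative intensities")

    @property
    def n(self) -> int:
        return len(self.channel_a)

    @property
    def positions(self) -> np.ndarray:
        """Arc-length sample positions in nm, starting at 0."""
        return np.arange(self.n) * self.step


# ---------------------------------------------------------------------------
# localisation tables


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_localisations(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    unit_scale: float = 1.0,
) -> LocalisationTable:
    """Read a delimited localisation table into nm coordinates.

    Parameters
    ----------
    path:
        CSV or TSV file with a header row.
    column_map:
        Maps canonical names (``x``, ``y``, ``mark``, ``roi``) to the file's
        header names; unspecified entries fall back to the defaults.  ``mark``
        and ``roi`` columns are optional in the file (missing ``mark`` becomes
        ``"unlabelled"``, missing ``roi`` becomes ``"roi_0"``).
    unit_scale:
        Multiplier taking file coordinates into nm (e.g. 1000 for µm files).

    Rows with non-finite coordinates are dropped and counted in a log message.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    for canon in ("x", "y"):
        if cmap[canon] not in raw.columns:
            raise FormatError(f"{path}: missing required column {cmap[canon]!r} (for {canon!r})")
    df = pd.DataFrame(
        {
            "x": pd.to_numeric(raw[cmap["x"]], errors="coerce") * unit_scale,
            "y": pd.to_numeric(raw[cmap["y"]], errors="coerce") * unit_scale,
        }
    )
    df["mark"] = raw[cmap["mark"]].astype(str) if cmap["mark"] in raw.columns else "unlabelled"
    df["roi"] = raw[cmap["roi"]].astype(str) if cmap["roi"] in raw.columns else "roi_0"
    finite = np.isfinite(df["x"]) & np.isfinite(df["y"])
    n_rejected = int((~finite).sum())
    if n_rejected:
        logger.warning("%s: rejected %d row(s) with non-finite coordinates", path, n_rejected)
    df = df[finite].reset_index(drop=True)
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no parsable localisation rows")
    table = LocalisationTable(df)
    table.n_rejected = n_rejected  # type: ignore[attr-defined]
    return table


def write_localisations(table: LocalisationTable, path: str | Path) -> None:
    out = table.df.rename(columns={"x": "x[nm]", "y": "y[nm]"})
    out.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# polyline ROIs


def read_polyline_rois(path: str | Path) -> list[PolylineROI]:
    """Read ordered-vertex polyline ROIs from a ``roi,x_nm,y_nm`` CSV."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    for col in ("roi", "x_nm", "y_nm"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing ROI column {col!r}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no ROI vertices")
    rois = []
    for roi_id, grp in df.groupby("roi", sort=False):
        rois.append(PolylineROI(str(roi_id), grp[["x_nm", "y_nm"]].to_numpy(dtype=float)))
    return rois


def write_polyline_rois(rois: Sequence[PolylineROI], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"roi": r.roi_id, "x_nm": r.vertices[:, 0], "y_nm": r.vertices[:, 1]})
        for r in rois
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# intensity profiles


def read_profiles(path: str | Path) -> list[IntensityProfile]:
    """Read paired profiles from a ``roi,position_nm,channel_a,channel_b`` CSV."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    for col in ("roi", "position_nm", "channel_a", "channel_b"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing profile column {col!r}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no profile samples")
    profiles = []
    for roi_id, grp in df.groupby("roi", sort=False):
        pos = grp["position_nm"].to_numpy(dtype=float)
        steps = np.diff(pos)
        if len(steps) == 0:
            raise ValidationError(f"{path}: profile {roi_id!r} has a single sample")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
            raise ValidationError(f"{path}: profile {roi_id!r} not uniformly sampled")
        profiles.append(
            IntensityProfile(
                str(roi_id),
                float(steps[0]),
                grp["channel_a"].to_numpy(dtype=float),
                grp["channel_b"].to_numpy(dtype=float),
            )
        )
    return profiles


def write_profiles(profiles: Sequence[IntensityProfile], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "roi": p.roi_id,
                "position_nm": p.positions,
                "channel_a": p.channel_a,
                "channel_b": p.channel_b,
            }
        )
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# stage results

_RESULT_MAGIC = "# loopstate-result"


@dataclass
class ResultDocument:
    """Serialisable form of any stage output: scalar metadata plus one table."""

    kind: str
    meta: dict = field(default_factory=dict)
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def write_results(result, path: str | Path) -> None:
    """Persist a stage output (anything exposing ``to_document()``).

    The file is ``# key: <json>`` metadata lines followed by a CSV table;
    floats are written with 17 significant digits so a read-back compares
    equal to full double precision.
    """
    doc = result if isinstance(result, ResultDocument) else result.to_document()
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{_RESULT_MAGIC}\n")
        fh.write(f"# kind: {json.dumps(doc.kind)}\n")
        for key, value in doc.meta.items():
            if isinstance(value, float) and not math.isfinite(value):
                value = None
            fh.write(f"# {key}: {json.dumps(_plain(value))}\n")
        doc.table.to_csv(fh, index=False, float_format="%.17g")


def read_results(path: str | Path) -> ResultDocument:
    path = Path(path)
    meta: dict = {}
    header_lines = 0
    kind = ""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(_RESULT_MAGIC):
            raise FormatError(f"{path}: not a loopstate result file")
        header_lines += 1
        for line in fh:
            if not line.startswith("# "):
                break
            header_lines += 1
            key, _, payload = line[2:].partition(": ")
            value = json.loads(payload)
            if key == "kind":
                kind = value
            else:
                meta[key] = value
    try:
        table = pd.read_csv(path, skiprows=header_lines, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        table = pd.DataFrame()
    return ResultDocument(kind=kind, meta=meta, table=table)


def _plain(value):
    """Coerce numpy scalars/arrays into JSON-encodable python values."""
    if isinstance(value, np.generic):
        return value.item()
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (list, tuple)):
        return [_plain(v) for v in value]
    return value
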