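"""Labelled point patterns and particle-table / results I/O.

The canonical on-disk input is a plain CSV/TSV particle table with the header
``image_id,label,x,y`` (comment lines starting with ``#`` are ignored).  An
ImageJ-Results-style dialect — an extra unnamed leading index column and
capitalised ``X``/``Y`` — is auto-detected.  Coordinates are converted to
nanometres via an explicit scale factor; there is no silent default unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import FormatError, ResultsError
from .geometry import DistanceBand, StudyWindow

__all__ = [
    "ParticleRecord",
    "PointPattern",
    "read_particle_table",
    "write_particle_table",
    "write_results",
    "read_results",
]

PathLike = Union[str, Path, IO[str]]


@dataclass(frozen=True)
class ParticleRecord:
    """A single particle row: image, per-image index, label (A/B), position (nm)."""

    image_id: object
    particle_index: int
    label: str
    x: float
    y: float


@dataclass
class PointPattern:
    """One image's dual-labelled particle coordinates plus its study window.

    ``points_a`` and ``points_b`` are (n, 2) float arrays in nanometres; every
    point must lie inside ``window``.
    """

    image_id: object
    window: StudyWindow
    points_a: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    points_b: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        self.points_a = np.asarray(self.points_a, dtype=float).reshape(-1, 2)
        self.points_b = np.asarray(self.points_b, dtype=float).reshape(-1, 2)
        for name, pts in (("A", self.points_a), ("B", self.points_b)):
            inside = self.window.contains(pts)
            if pts.shape[0] and not inside.all():
                bad = pts[~inside][0]
                raise ValueError(
                    f"image {self.image_id!r}: label-{name} particle at "
                    f"({bad[0]}, {bad[1]}) lies outside the "
                    f"{self.window.width} x {self.window.height} window"
                )

    @property
    def n_a(self) -> int:
        return self.points_a.shape[0]

    @property
    def n_b(self) -> int:
        return self.points_b.shape[0]

    def swapped(self) -> "PointPattern":
        """The same pattern with the A/B roles exchanged."""
        return PointPattern(self.image_id, self.window, self.points_b, self.points_a)

    def scaled(self, factor: float) -> "PointPattern":
        """Pattern with coordinates and window multiplied by a common factor."""
        return PointPattern(
            self.image_id,
            StudyWindow(self.window.width * factor, self.window.height * factor),
            self.points_a * factor,
            self.points_b * factor,
        )


_REQUIRED = ("image_id", "label", "x", "y")


def _normalise_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Lower-case headers; drop an ImageJ-style unnamed leading index column."""
    df = df.rename(columns=lambda c: str(c).strip().lower())
    first = df.columns[0] if len(df.columns) else None
    if first is not None and (first == "" or first.startswith("unnamed")):
        df = df.drop(columns=[first])
    return df


def read_particle_table(
    source: PathLike,
    window: StudyWindow,
    scale: float = 1.0,
    label_a: str = "A",
    label_b: str = "B",
    windows: Mapping[object, StudyWindow] | None = None,
) -> list[PointPattern]:
    """Read a particle table into one :class:`PointPattern` per image.

    Parameters
    ----------
    source
        Path or text stream with columns ``image_id, label, x, y``.
    window
        Study window applied to every image (in nm, after scaling).
    scale
        Nanometres per coordinate unit (e.g. nm per pixel); must be positive.
    label_a, label_b
        Which table label maps to type A / type B.  Any other label is an
        error — silently dropping a category would bias the frequency stage.
    windows
        Optional per-image window overrides keyed by image_id.

    Patterns are returned sorted by image_id; rows within an image keep table
    order, which no downstream coefficient depends on.
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    # dtype=str defers all numeric parsing to float(), which is correctly
    # rounded; the sniffing engine's own inference can lose the last ulp
    df = pd.read_csv(source, sep=None, engine="python", comment="#",
                     skipinitialspace=True, dtype=str)
    df = _normalise_columns(df)
    for col in _REQUIRED:
        if col not in df.columns:
            raise FormatError(f"particle table is missing required column {col!r}")
    if df.empty:
        return []

    labels = set(df["label"].astype(str).str.strip().unique())
    unmapped = labels - {label_a, label_b}
    if unmapped:
        raise FormatError(
            f"unmapped particle labels {sorted(unmapped)}; expected only "
            f"{label_a!r} (type A) and {label_b!r} (type B)"
        )

    # astype(float) parses via correctly-rounded float(), so a written table
    # reads back bit-exactly (pd.to_numeric's fast path can be off by 1 ulp)
    df = df.assign(
        label=df["label"].astype(str).str.strip(),
        x=df["x"].astype(float) * scale,
        y=df["y"].astype(float) * scale,
    )

    patterns: list[PointPattern] = []
    for image_id in sorted(df["image_id"].unique(), key=str):
        win = windows.get(image_id, window) if windows else window
        sub = df[df["image_id"] == image_id]
        inside = (
            (sub["x"] >= 0) & (sub["x"] <= win.width)
            & (sub["y"] >= 0) & (sub["y"] <= win.height)
        )
        if not inside.all():
            rows = (sub.index[~inside] + 2).tolist()  # 1-based incl. header
            raise FormatError(
                f"image {image_id!r}: particle(s) outside the "
                f"{win.width} x {win.height} nm window at table line(s) {rows}"
            )
        pts_a = sub.loc[sub["label"] == label_a, ["x", "y"]].to_numpy(float)
        pts_b = sub.loc[sub["label"] == label_b, ["x", "y"]].to_numpy(float)
        patterns.append(PointPattern(image_id, win, pts_a, pts_b))
    return patterns


def write_particle_table(patterns: Iterable[PointPattern], sink: PathLike) -> None:
    """Write patterns back to the canonical CSV dialect (coordinates in nm)."""
    rows = []
    for pat in patterns:
        for label, pts in (("A", pat.points_a), ("B", pat.points_b)):
            for x, y in pts:
                rows.append((pat.image_id, label, repr(float(x)), repr(float(y))))
    df = pd.DataFrame(rows, columns=list(_REQUIRED))
    df.to_csv(sink, index=False)


# -- results serialisation ---------------------------------------------------

_PER_IMAGE_COLUMNS = [
    "image_id", "n_a", "n_b", "n_col_a", "n_col_b",
    "cc1_abs", "cc1_rel_a", "cc1_rel_b", "cc2_a", "cc2_b",
    "coloc_a", "noncoloc_a", "coloc_b", "noncoloc_b", "cc3_ba", "cc3_ab",
]


def write_results(results, sink: PathLike, format: str = "json") -> None:
    """Serialise a :class:`~emcoloc.coefficients.CoefficientSet`.

    JSON output is nested (parameters / per_image / aggregate /
    effective_counts); CSV is flat with one row per image plus an
    ``aggregate`` row.  Floats are written at full precision.
    """
    if results.k < 1 or results.per_image.empty:
        raise ResultsError("refusing to write results covering zero images")
    if format == "json":
        payload = results.to_dict()
        text = json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)
        if hasattr(sink, "write"):
            sink.write(text + "\n")
        else:
            Path(sink).write_text(text + "\n")
    elif format == "csv":
        per_image = results.per_image.reindex(columns=_PER_IMAGE_COLUMNS)
        agg = {c: results.aggregate.get(c) for c in _PER_IMAGE_COLUMNS}
        agg["image_id"] = "aggregate"
        agg["n_a"] = results.per_image["n_a"].sum()
        agg["n_b"] = results.per_image["n_b"].sum()
        agg["n_col_a"] = results.per_image["n_col_a"].sum()
        agg["n_col_b"] = results.per_image["n_col_b"].sum()
        table = pd.concat([per_image, pd.DataFrame([agg])], ignore_index=True)
        table.to_csv(sink, index=False)
    else:
        raise ValueError(f"unknown results format {format!r}")


def read_results(source: PathLike, format: str = "json"):
    """Read results back: a dict for JSON, a DataFrame for CSV."""
    if format == "json":
        if hasattr(source, "read"):
            return json.load(source)
        return json.loads(Path(source).read_text())
    if format == "csv":
        return pd.read_csv(source)
    raise ValueError(f"unknown results format {format!r}")
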