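"""Core containers for serum SERS spectra and the segment partition.

A spectrum lives on a shared wavenumber grid (cm^-1).  For band selection the
grid is tiled into contiguous fixed-length *segments*; a candidate feature
subset ("chromosome") is a small set of segment identifiers which expands to
the union of their spectral variables.

Spectra circulate as wide CSV: one row per spectrum, columns
``sample_id,label,<wavenumber_1>,...,<wavenumber_N>``.  Derived results are
written as JSON with a schema-version field (see :func:`write_json`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SCHEMA_VERSION = "1"

LABEL_NORMAL = "normal"
LABEL_CANCER = "cancer"
#: "cancer" is the positive class everywhere (sensitivity = cancer recall).
VALID_LABELS = (LABEL_NORMAL, LABEL_CANCER)

DEFAULT_LO = 400.0
DEFAULT_HI = 1800.0
DEFAULT_N_POINTS = 1270
DEFAULT_SEG_LEN = 5


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly increasing wavenumber axis in cm^-1.

    Even spacing is not assumed; all downstream quadrature uses the stored
    values.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("grid needs at least two wavenumbers")
        if not np.all(np.diff(v) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        object.__setattr__(self, "values", v)

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    @property
    def lo(self) -> float:
        return float(self.values[0])

    @property
    def hi(self) -> float:
        return float(self.values[-1])

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the grid point closest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.values - wavenumber)))

    @classmethod
    def default(
        cls,
        lo: float = DEFAULT_LO,
        hi: float = DEFAULT_HI,
        n_points: int = DEFAULT_N_POINTS,
    ) -> "WavenumberGrid":
        return cls(np.linspace(lo, hi, n_points))


@dataclass
class Spectrum:
    """One spectrum: intensities (arbitrary units) on a grid, optional label."""

    grid: WavenumberGrid
    intensities: np.ndarray
    label: str | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        if y.shape != (self.grid.n_points,):
            raise ValueError(
                f"intensities length {y.size} != grid length {self.grid.n_points}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError(f"non-finite intensity in spectrum {self.sample_id!r}")
        if self.label is not None and self.label not in VALID_LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected {VALID_LABELS}")
        self.intensities = y


@dataclass
class SpectraSet:
    """A batch of spectra sharing one grid, with per-row labels and ids."""

    grid: WavenumberGrid
    matrix: np.ndarray
    labels: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        labels = np.asarray(self.labels, dtype=object)
        ids = np.asarray(self.ids, dtype=object)
        if m.ndim != 2 or m.shape[1] != self.grid.n_points:
            raise ValueError(
                f"matrix shape {m.shape} incompatible with grid of "
                f"{self.grid.n_points} points"
            )
        if labels.shape != (m.shape[0],) or ids.shape != (m.shape[0],):
            raise ValueError("labels/ids must have one entry per spectrum row")
        bad = [str(l) for l in labels if l not in VALID_LABELS]
        if bad:
            raise ValueError(f"unknown labels {sorted(set(bad))}; expected {VALID_LABELS}")
        if not np.all(np.isfinite(m)):
            rows = np.where(~np.isfinite(m).all(axis=1))[0]
            raise ValueError(f"non-finite intensities in rows {rows.tolist()}")
        self.matrix = m
        self.labels = labels
        self.ids = ids

    @property
    def n_spectra(self) -> int:
        return int(self.matrix.shape[0])

    def spectrum(self, row: int) -> Spectrum:
        return Spectrum(
            grid=self.grid,
            intensities=self.matrix[row].copy(),
            label=str(self.labels[row]),
            sample_id=str(self.ids[row]),
        )

    def class_matrix(self, label: str) -> np.ndarray:
        return self.matrix[self.labels == label]

    def require_two_classes(self) -> None:
        present = set(map(str, self.labels))
        if present != set(VALID_LABELS):
            raise ValueError(
                f"analysis requires both classes {VALID_LABELS}; found {sorted(present)}"
            )


@dataclass(frozen=True)
class SegmentIndex:
    """Exact tiling of the variable axis into contiguous equal segments.

    Segment ``k`` covers variable indices ``[k*seg_len, (k+1)*seg_len)``
    (0-based, half-open).  Reported wavenumber intervals are closed, using
    the first/last grid value of the segment.
    """

    n_points: int
    seg_len: int

    def __post_init__(self) -> None:
        if self.n_points <= 0 or self.seg_len <= 0:
            raise ValueError("n_points and seg_len must be positive")
        if self.n_points % self.seg_len != 0:
            raise ValueError(
                f"{self.n_points} not divisible by {self.seg_len}: "
                "segments must tile the variable axis exactly"
            )

    @property
    def n_segments(self) -> int:
        return self.n_points // self.seg_len

    def variables(self, segment: int) -> np.ndarray:
        """Variable indices covered by one segment."""
        self._check(segment)
        start = segment * self.seg_len
        return np.arange(start, start + self.seg_len)

    def segment_of(self, variable: int) -> int:
        if not 0 <= variable < self.n_points:
            raise ValueError(f"variable index {variable} out of range [0, {self.n_points})")
        return variable // self.seg_len

    def interval(self, segment: int, grid: WavenumberGrid) -> tuple[float, float]:
        """Closed wavenumber interval [first, last] of a segment."""
        if grid.n_points != self.n_points:
            raise ValueError("grid length does not match segment index")
        var = self.variables(segment)
        return float(grid.values[var[0]]), float(grid.values[var[-1]])

    def _check(self, segment: int) -> None:
        if not 0 <= segment < self.n_segments:
            raise ValueError(
                f"segment id {segment} out of range [0, {self.n_segments})"
            )


def build_segment_index(n_points: int, seg_len: int = DEFAULT_SEG_LEN) -> SegmentIndex:
    """Partition ``n_points`` spectral variables into ``seg_len``-wide segments."""
    return SegmentIndex(n_points=n_points, seg_len=seg_len)


def expand_chromosome(chrom: Sequence[int], idx: SegmentIndex) -> np.ndarray:
    """Union of variable indices covered by a chromosome's segments (sorted)."""
    segs = list(chrom)
    if len(set(segs)) != len(segs):
        raise ValueError(f"chromosome has duplicate segment ids: {segs}")
    parts = [idx.variables(int(s)) for s in segs]
    return np.sort(np.concatenate(parts)) if parts else np.array([], dtype=int)


@dataclass
class BandAnnotation:
    """Tentative biochemical annotation of a wavenumber band."""

    lo: float
    hi: float
    assignment: str
    direction: str  # "+" more intense in cancer, "-" more intense in normal
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("band interval reversed")
        if self.direction not in ("+", "-"):
            raise ValueError("direction must be '+' or '-'")


# ---------------------------------------------------------------------------
# Wide-CSV spectra I/O
# ---------------------------------------------------------------------------

_ID_COL = "sample_id"
_LABEL_COL = "label"


def write_spectra(sset: SpectraSet, path: str | Path) -> None:
    """Write a SpectraSet as wide CSV (full float precision, round-trippable)."""
    cols = {
        _ID_COL: [str(i) for i in sset.ids],
        _LABEL_COL: [str(l) for l in sset.labels],
    }
    df = pd.DataFrame(cols)
    body = pd.DataFrame(sset.matrix, columns=[repr(float(w)) for w in sset.grid.values])
    # %.17g round-trips IEEE doubles exactly
    pd.concat([df, body], axis=1).to_csv(path, index=False, float_format="%.17g")


def read_spectra(path: str | Path) -> SpectraSet:
    """Read a wide-CSV spectra file into a SpectraSet.

    Header row holds wavenumbers; ``sample_id`` and ``label`` columns are
    required.  Ragged rows, non-numeric intensities and unknown labels raise
    with row/column context.
    """
    try:
        df = pd.read_csv(path, dtype={_ID_COL: str, _LABEL_COL: str},
                         float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValueError(f"malformed spectra file {path}: {exc}") from exc
    for col in (_ID_COL, _LABEL_COL):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    wn_cols = [c for c in df.columns if c not in (_ID_COL, _LABEL_COL)]
    if not wn_cols:
        raise ValueError(f"{path}: no intensity columns")
    try:
        grid = WavenumberGrid(np.array([float(c) for c in wn_cols]))
    except ValueError as exc:
        raise ValueError(f"{path}: bad wavenumber header: {exc}") from exc
    body = df[wn_cols]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric intensity at row {r} column {wn_cols[c]!r}"
        )
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values (ragged row?)")
    return SpectraSet(
        grid=grid,
        matrix=numeric.to_numpy(dtype=float),
        labels=df[_LABEL_COL].to_numpy(dtype=object),
        ids=df[_ID_COL].to_numpy(dtype=object),
    )


def write_json(obj: dict, path: str | Path) -> None:
    """Write a result document as JSON, stamping the schema version."""
    doc = {"schema_version": SCHEMA_VERSION, **obj}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
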