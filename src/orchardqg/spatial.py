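"""Spatial diagnostics and residual correlation structures.

Covers three things used by the genetic-testing model:

* global spatial autocorrelation of a phenotype (Moran's I with a normal
  approximation and an optional permutation test),
* rasterization of irregularly spaced trees onto an ``nrows x ncols`` grid
  (one tree per cell, deterministic collision handling), and
* the candidate residual correlation structures: exponential, Gaussian,
  spherical, linear, rational(-quadratic), AR1 and the separable AR1xAR1
  (Kronecker) form on a grid.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import norm

__all__ = [
    "TreeRecord",
    "GridAssignment",
    "SpatialStructure",
    "MoranResult",
    "DISTANCE_KINDS",
    "AR1_KINDS",
    "morans_i",
    "rasterize",
    "correlation",
    "build_correlation_matrix",
    "read_tree_records",
    "write_tree_records",
]

DISTANCE_KINDS = ("exponential", "gaussian", "spherical", "linear", "rational")
AR1_KINDS = ("ar1", "ar1xar1")


@dataclass
class TreeRecord:
    """One measured tree: planar coordinates (m) and phenotype."""

    id: str
    x: float
    y: float
    dbh: float
    height: float | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"tree {self.id!r}: non-finite coordinates")
        if not (math.isfinite(self.dbh) and self.dbh > 0):
            raise ValueError(f"tree {self.id!r}: dbh must be finite and > 0")


@dataclass
class GridAssignment:
    """Injective mapping of tree ids to (row, col) cells, 0-based row-major."""

    nrows: int
    ncols: int
    cells: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple[int, int]] = set()
        for tid, (r, c) in self.cells.items():
            if not (0 <= r < self.nrows and 0 <= c < self.ncols):
                raise ValueError(f"tree {tid!r}: cell ({r}, {c}) outside grid")
            if (r, c) in seen:
                raise ValueError(f"cell ({r}, {c}) assigned to more than one tree")
            seen.add((r, c))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "row", "col"])
            for tid, (r, c) in self.cells.items():
                w.writerow([tid, r, c])

    @classmethod
    def from_csv(cls, path, nrows: int, ncols: int) -> "GridAssignment":
        cells = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                cells[row["id"]] = (int(row["row"]), int(row["col"]))
        return cls(nrows, ncols, cells)


@dataclass(frozen=True)
class SpatialStructure:
    """A named residual correlation family with its parameter(s).

    Distance-based kinds take a range ``r > 0``; ``ar1`` takes a single
    ``rho``; ``ar1xar1`` takes ``(rho_row, rho_col)``, all in (-1, 1).
    """

    kind: str
    r: float | None = None
    rho: float | None = None
    rho_row: float | None = None
    rho_col: float | None = None

    def __post_init__(self) -> None:
        if self.kind in DISTANCE_KINDS:
            if self.r is None or not self.r > 0:
                raise ValueError(f"{self.kind} structure needs range r > 0")
        elif self.kind == "ar1":
            if self.rho is None or not -1 < self.rho < 1:
                raise ValueError("ar1 structure needs rho in (-1, 1)")
        elif self.kind == "ar1xar1":
            for name, val in (("rho_row", self.rho_row), ("rho_col", self.rho_col)):
                if val is None or not -1 < val < 1:
                    raise ValueError(f"ar1xar1 structure needs {name} in (-1, 1)")
        else:
            raise ValueError(f"unknown structure kind {self.kind!r}")

    @property
    def n_params(self) -> int:
        return 2 if self.kind == "ar1xar1" else 1


def correlation(structure: SpatialStructure, separation) -> float:
    """Correlation at the given separation.

    ``separation`` is a Euclidean distance d >= 0 for distance-based kinds,
    an integer lag for ``ar1``, and an ``(delta_row, delta_col)`` pair of
    integer lags for ``ar1xar1``.
    """
    kind = structure.kind
    if kind == "ar1":
        return float(structure.rho ** abs(int(separation)))
    if kind == "ar1xar1":
        dr, dc = separation
        return float(structure.rho_row ** abs(int(dr)) * structure.rho_col ** abs(int(dc)))
    d = float(separation)
    if d < 0:
        raise ValueError("negative distance")
    u = d / structure.r
    if kind == "exponential":
        return math.exp(-u)
    if kind == "gaussian":
        return math.exp(-(u**2))
    if kind == "spherical":
        return 1.0 - 1.5 * u + 0.5 * u**3 if u < 1 else 0.0
    if kind == "linear":
        return 1.0 - u if u < 1 else 0.0
    if kind == "rational":
        return 1.0 - u**2 / (1.0 + u**2)
    raise ValueError(f"unknown structure kind {kind!r}")


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------


@dataclass
class MoranResult:
    I: float
    expected_I: float
    variance_I: float
    z: float
    p_value: float
    weight_scheme: str
    p_permutation: float | None = None


def _weight_matrix(coords: np.ndarray, scheme: str, knn_k: int) -> np.ndarray:
    n = coords.shape[0]
    d = cdist(coords, coords)
    if scheme == "inverse_distance":
        off = d[~np.eye(n, dtype=bool)]
        if np.any(off == 0):
            raise ValueError(
                "coincident points have zero distance; jitter coordinates before "
                "using inverse_distance weights"
            )
        with np.errstate(divide="ignore"):
            w = 1.0 / d
        np.fill_diagonal(w, 0.0)
    elif scheme == "knn":
        w = np.zeros((n, n))
        order = np.argsort(d, axis=1, kind="stable")
        for i in range(n):
            neighbours = [j for j in order[i] if j != i][:knn_k]
            w[i, neighbours] = 1.0
    elif scheme == "rook":
        # unit-pitch grid convention: neighbours at Euclidean distance exactly 1
        w = (np.abs(d - 1.0) < 1e-9).astype(float)
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    rs = w.sum(axis=1, keepdims=True)
    if np.any(rs == 0):
        raise ValueError("some observations have no neighbours under this scheme")
    return w / rs


def morans_i(
    values: Sequence[float],
    coords,
    weight_scheme: str = "inverse_distance",
    *,
    knn_k: int = 8,
    n_perm: int = 0,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I with row-standardized weights.

    The analytic p-value uses the normal approximation under the
    randomization assumption; pass ``n_perm > 0`` for an additional
    two-sided permutation p-value. Both p-values are two-sided.
    """
    x = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("Moran's I needs n >= 4")
    if np.allclose(x, x[0]):
        raise ValueError("values are constant; Moran's I undefined (zero variance)")
    w = _weight_matrix(coords, weight_scheme, knn_k)
    z = x - x.mean()
    s0 = w.sum()
    denom = float(z @ z)

    def stat(zv: np.ndarray) -> float:
        return float(n / s0 * (zv @ w @ zv) / (zv @ zv))

    i_obs = stat(z)
    e_i = -1.0 / (n - 1)
    s1 = 0.5 * np.sum((w + w.T) ** 2)
    s2 = np.sum((w.sum(axis=1) + w.sum(axis=0)) ** 2)
    b2 = n * np.sum(z**4) / denom**2
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    var_i = num / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
    zscore = (i_obs - e_i) / math.sqrt(var_i)
    p = 2 * norm.sf(abs(zscore))
    p_perm = None
    if n_perm:
        rng = np.random.default_rng(seed)
        extreme = 0
        for _ in range(n_perm):
            zp = rng.permutation(z)
            if abs(stat(zp) - e_i) >= abs(i_obs - e_i) - 1e-15:
                extreme += 1
        p_perm = (extreme + 1) / (n_perm + 1)
    return MoranResult(
        I=i_obs,
        expected_I=e_i,
        variance_I=float(var_i),
        z=float(zscore),
        p_value=float(p),
        weight_scheme=weight_scheme,
        p_permutation=p_perm,
    )


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def rasterize(records: Iterable[TreeRecord], nrows: int, ncols: int) -> GridAssignment:
    """Map irregular coordinates onto an ``nrows x ncols`` grid, one tree
    per cell.

    The coordinate bounding box is mapped affinely onto the grid and
    positions truncated to integer cells (row 0 at the minimum y). When a
    cell is already taken, the later tree in id order is moved to the
    nearest free cell by Chebyshev distance, scanning offsets in a fixed
    row-major order, which makes the assignment deterministic.
    """
    recs = sorted(records, key=lambda t: t.id)
    n = len(recs)
    if n == 0:
        raise ValueError("no records to rasterize")
    if n > nrows * ncols:
        raise ValueError(f"{n} trees do not fit in a {nrows}x{ncols} grid")
    xs = np.array([t.x for t in recs])
    ys = np.array([t.y for t in recs])
    xspan = xs.max() - xs.min()
    yspan = ys.max() - ys.min()
    if n > 1 and (xspan == 0 or yspan == 0) and n > max(nrows, ncols):
        raise ValueError("degenerate bounding box")
    cols = np.zeros(n, dtype=int)
    rows = np.zeros(n, dtype=int)
    if xspan > 0:
        cols = np.minimum((ncols * (xs - xs.min()) / xspan).astype(int), ncols - 1)
    if yspan > 0:
        rows = np.minimum((nrows * (ys - ys.min()) / yspan).astype(int), nrows - 1)
    taken: set[tuple[int, int]] = set()
    cells: dict[str, tuple[int, int]] = {}
    for i, rec in enumerate(recs):
        cell = (int(rows[i]), int(cols[i]))
        if cell in taken:
            cell = _nearest_free(cell, taken, nrows, ncols)
        taken.add(cell)
        cells[rec.id] = cell
    return GridAssignment(nrows=nrows, ncols=ncols, cells=cells)


def _nearest_free(
    cell: tuple[int, int], taken: set[tuple[int, int]], nrows: int, ncols: int
) -> tuple[int, int]:
    r0, c0 = cell
    for radius in range(1, max(nrows, ncols)):
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                if max(abs(dr), abs(dc)) != radius:
                    continue
                cand = (r0 + dr, c0 + dc)
                if 0 <= cand[0] < nrows and 0 <= cand[1] < ncols and cand not in taken:
                    return cand
    raise ValueError("no free cell found (grid full)")


# ---------------------------------------------------------------------------
# Correlation matrices
# ---------------------------------------------------------------------------


def build_correlation_matrix(
    structure: SpatialStructure,
    grid_or_coords,
    observed_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Correlation matrix over observed trees under ``structure``.

    For ``ar1xar1``/``ar1`` pass a :class:`GridAssignment`; the entries are
    the observed-cell submatrix of the full Kronecker product
    ``AR1(rho_row) (x) AR1(rho_col)`` without ever materializing the full
    grid matrix. ``ar1`` orders cells row-major and uses the 1-D lag along
    that scan (an explicit convention; the family is one-dimensional).
    Distance-based kinds take ``{id: (x, y)}`` coordinates.
    """
    if structure.kind in AR1_KINDS:
        if not isinstance(grid_or_coords, GridAssignment):
            raise TypeError(f"{structure.kind} needs a GridAssignment")
        grid = grid_or_coords
        ids = list(observed_ids) if observed_ids is not None else sorted(grid.cells)
        missing = [i for i in ids if i not in grid.cells]
        if missing:
            raise ValueError(f"ids missing from grid assignment: {missing[:5]}")
        rows = np.array([grid.cells[i][0] for i in ids])
        cols = np.array([grid.cells[i][1] for i in ids])
        if structure.kind == "ar1xar1":
            dr = np.abs(rows[:, None] - rows[None, :])
            dc = np.abs(cols[:, None] - cols[None, :])
            return structure.rho_row**dr * structure.rho_col**dc
        idx = rows * grid.ncols + cols
        lag = np.abs(idx[:, None] - idx[None, :])
        return structure.rho ** lag.astype(float)
    coords_map = grid_or_coords
    ids = list(observed_ids) if observed_ids is not None else list(coords_map)
    pts = np.array([coords_map[i] for i in ids], dtype=float)
    d = cdist(pts, pts)
    corr = np.vectorize(lambda dd: correlation(structure, dd))(d)
    np.fill_diagonal(corr, 1.0)
    return corr


# ---------------------------------------------------------------------------
# Phenotype/coordinate CSV I/O (id,x,y,dbh,height,group)
# ---------------------------------------------------------------------------


def read_tree_records(path) -> list[TreeRecord]:
    records = []
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    for row in csv.DictReader(lines):
        height = row.get("height", "")
        records.append(
            TreeRecord(
                id=row["id"],
                x=float(row["x"]),
                y=float(row["y"]),
                dbh=float(row["dbh"]),
                height=float(height) if height not in ("", None, "NA") else None,
                group=row.get("group") or None,
            )
        )
    return records


def write_tree_records(records: Iterable[TreeRecord], path, header_comment: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh)
        w.writerow(["id", "x", "y", "dbh", "height", "group"])
        for t in records:
            w.writerow(
                [
                    t.id,
                    repr(t.x),
                    repr(t.y),
                    repr(t.dbh),
                    "" if t.height is None else repr(t.height),
                    t.group or "",
                ]
            )
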