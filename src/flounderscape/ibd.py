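"""Individual-level isolation by distance.

Genetic distance between individuals is Rousset's a-hat, built from
probabilities of gene identity in state: with Q_w the probability that
the two gene copies within an individual are identical and Q_r the
probability that one gene from each of two individuals are identical,

    a_hat = (Q_w - Q_r) / (1 - Q_w).

Geographic distance is either the law-of-cosines great-circle distance
or a least-cost path across a passability raster (e.g. the continental
shelf shallower than the 200 m isobath).  The association between the
two matrices is assessed with a Mantel permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import (EmptyResultError, InvalidParameterError,
                     UndefinedDistanceError)
from .genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Default Earth radius in kilometres (WGS84 equatorial).
EARTH_RADIUS_KM = 6378.137

#: Default origin from which distance along the coast is measured.
DEFAULT_COAST_ORIGIN = (28.3849, -80.5463)


@dataclass
class DistanceMatrix:
    """Square symmetric matrix of pairwise distances with entity ids."""

    values: np.ndarray
    ids: list[str]
    units: str = "km"

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or len(self.ids) != n:
            raise InvalidParameterError("distance matrix must be square with "
                                        "matching ids")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise InvalidParameterError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]


# ---------------------------------------------------------------------------
# genetic distance

def rousset_distance(matrix: GenotypeMatrix,
                     q_within: str = "global") -> DistanceMatrix:
    """Pairwise Rousset's a-hat between individuals.

    Q_r for a pair is the mean over pairwise-complete loci of the
    probability that one gene drawn from each individual is identical
    in state (with within-individual allele frequencies 0, 1/2 or 1).
    Q_w is by default the global mean within-individual homozygosity
    over all individuals and called genotypes (``q_within="global"``);
    ``q_within="pair"`` instead averages the two members' homozygosities
    over the loci complete for the pair.
    """
    if matrix.n_individuals < 2:
        raise InvalidParameterError("need >= 2 individuals")
    if q_within not in ("global", "pair"):
        raise InvalidParameterError("q_within must be 'global' or 'pair'")
    d = matrix.dosages.astype(float)
    valid = matrix.dosages != MISSING
    f = np.where(valid, d / 2.0, 0.0)          # within-individual alt freq
    a, b = f, np.where(valid, 1.0 - f, 0.0)
    w = valid.astype(float)
    counts = w @ w.T
    if (counts == 0).any():
        logger.warning("some pairs share no called loci; their distance "
                       "is NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        q_r = (a @ a.T + b @ b.T) / counts
    hom = np.where(valid, (d == 0) | (d == 2), 0.0)
    if q_within == "global":
        q_w = hom.sum() / valid.sum()
        if q_w >= 1.0:
            raise UndefinedDistanceError(
                "all individuals are homozygous at all called loci; "
                "a-hat is undefined (Q_w = 1)")
        ahat = (q_w - q_r) / (1.0 - q_w)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            hom_rate = (hom @ w.T + w @ hom.T) / (2.0 * counts)
        if np.nanmax(hom_rate) >= 1.0 and np.isclose(np.nanmin(1 - hom_rate), 0):
            raise UndefinedDistanceError("some pairs are fully homozygous; "
                                         "pairwise Q_w = 1")
        ahat = (hom_rate - q_r) / (1.0 - hom_rate)
    np.fill_diagonal(ahat, 0.0)
    ids = list(matrix.samples["id"].astype(str))
    return DistanceMatrix(ahat, ids, units="dimensionless")


# ---------------------------------------------------------------------------
# geographic distance

def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float,
                    radius_km: float = EARTH_RADIUS_KM) -> float:
    """Law-of-cosines great-circle distance in kilometres."""
    if lat1 == lat2 and lon1 == lon2:
        return 0.0
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(np.asarray(lon2) - np.asarray(lon1))
    arg = np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl)
    return float(radius_km * np.arccos(np.clip(arg, -1.0, 1.0)))


def coast_distance_along(lats, lons,
                         origin: tuple[float, float] = DEFAULT_COAST_ORIGIN,
                         radius_km: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Great-circle distance of each point from the coastal origin."""
    lats = np.atleast_1d(np.asarray(lats, float))
    lons = np.atleast_1d(np.asarray(lons, float))
    return np.array([great_circle_km(origin[0], origin[1], la, lo, radius_km)
                     for la, lo in zip(lats, lons)])


def great_circle_matrix(lats, lons, ids=None) -> DistanceMatrix:
    """All-pairs law-of-cosines distances."""
    lats = np.asarray(lats, float)
    lons = np.asarray(lons, float)
    n = len(lats)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = great_circle_km(lats[i], lons[i],
                                                    lats[j], lons[j])
    if ids is None:
        ids = [str(i) for i in range(n)]
    return DistanceMatrix(out, list(ids))


@dataclass
class CoastRaster:
    """Lat/lon-registered grid with a passability mask.

    ``lats``/``lons`` are strictly monotone cell-centre coordinates;
    ``passable`` marks cells a path may cross (e.g. shelf cells with
    seafloor depth at most 200 m).
    """

    lats: np.ndarray
    lons: np.ndarray
    passable: np.ndarray

    def __post_init__(self):
        self.lats = np.asarray(self.lats, float)
        self.lons = np.asarray(self.lons, float)
        self.passable = np.asarray(self.passable, bool)
        if self.passable.shape != (len(self.lats), len(self.lons)):
            raise InvalidParameterError("mask shape must be (n_lats, n_lons)")
        for v in (self.lats, self.lons):
            dv = np.diff(v)
            if not (np.all(dv > 0) or np.all(dv < 0)):
                raise InvalidParameterError("registration must be strictly "
                                            "monotone")
        if not self.passable.any():
            raise InvalidParameterError("raster has no passable cells")

    @classmethod
    def from_ascii(cls, path: str, passable_range=(-200.0, 0.0)
                   ) -> "CoastRaster":
        """Read an ESRI ASCII grid of elevations (sea floor negative).

        Cells with values inside ``passable_range`` (inclusive) are
        passable; NODATA cells are not.
        """
        header = {}
        with open(path) as fh:
            lines = fh.readlines()
        i = 0
        while i < len(lines) and lines[i].split()[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"):
            key, val = lines[i].split()[:2]
            header[key.lower()] = float(val)
            i += 1
        ncols = int(header["ncols"])
        nrows = int(header["nrows"])
        cell = header["cellsize"]
        nodata = header.get("nodata_value", -9999.0)
        vals = np.loadtxt(lines[i:]).reshape(nrows, ncols)
        # ESRI grids store the northernmost row first
        lats = header["yllcorner"] + cell * (np.arange(nrows)[::-1] + 0.5)
        lons = header["xllcorner"] + cell * (np.arange(ncols) + 0.5)
        lo, hi = passable_range
        passable = (vals != nodata) & (vals >= lo) & (vals <= hi)
        return cls(lats=lats, lons=lons, passable=passable)

    def snap(self, lat: float, lon: float, max_radius_cells: float = 10.0
             ) -> tuple[int, int]:
        """Nearest passable cell (row, col) within a search radius."""
        ii, jj = np.nonzero(self.passable)
        d2 = (self.lats[ii] - lat) ** 2 + (self.lons[jj] - lon) ** 2
        best = int(np.argmin(d2))
        cell = max(abs(np.diff(self.lats).mean()),
                   abs(np.diff(self.lons).mean()))
        if np.sqrt(d2[best]) > max_radius_cells * cell:
            raise InvalidParameterError(
                f"point ({lat}, {lon}) is farther than {max_radius_cells} "
                "cells from any passable cell")
        return int(ii[best]), int(jj[best])


def _raster_graph(raster: CoastRaster) -> nx.Graph:
    g = getattr(raster, "_graph_cache", None)
    if g is not None:
        return g
    g = nx.Graph()
    nrows, ncols = raster.passable.shape
    for i in range(nrows):
        for j in range(ncols):
            if not raster.passable[i, j]:
                continue
            for di, dj in ((0, 1), (1, 0), (1, 1), (1, -1)):
                a, b = i + di, j + dj
                if 0 <= a < nrows and 0 <= b < ncols and raster.passable[a, b]:
                    w = great_circle_km(raster.lats[i], raster.lons[j],
                                        raster.lats[a], raster.lons[b])
                    g.add_edge((i, j), (a, b), weight=w)
    raster._graph_cache = g
    return g


def least_cost_km(raster: CoastRaster, p1: tuple[float, float],
                  p2: tuple[float, float],
                  max_snap_radius_cells: float = 10.0) -> float:
    """Shortest-path distance between two points over the passable grid.

    8-connected moves, edge weights equal to the great-circle length
    between cell centres.  Returns ``inf`` (with a warning) when no
    passable path exists.
    """
    a = raster.snap(*p1, max_snap_radius_cells)
    b = raster.snap(*p2, max_snap_radius_cells)
    if a == b:
        return 0.0
    g = _raster_graph(raster)
    try:
        return float(nx.shortest_path_length(g, a, b, weight="weight"))
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        logger.warning("no passable path between %s and %s", p1, p2)
        return float("inf")


def least_cost_matrix(raster: CoastRaster, lats, lons, ids=None
                      ) -> DistanceMatrix:
    """All-pairs least-cost distances (single multi-source Dijkstra per
    distinct snapped cell)."""
    cells = [raster.snap(la, lo) for la, lo in zip(lats, lons)]
    g = _raster_graph(raster)
    n = len(cells)
    out = np.zeros((n, n))
    lengths = {}
    for c in set(cells):
        lengths[c] = nx.single_source_dijkstra_path_length(g, c,
                                                           weight="weight")
    for i in range(n):
        for j in range(i + 1, n):
            d = lengths[cells[i]].get(cells[j], float("inf"))
            out[i, j] = out[j, i] = d
    if ids is None:
        ids = [str(i) for i in range(n)]
    return DistanceMatrix(out, list(ids))


# ---------------------------------------------------------------------------
# Mantel test

def mantel_test(d_gen: DistanceMatrix, d_geo: DistanceMatrix,
                n_perm: int = 10_000,
                rng: np.random.Generator | None = None,
                alternative: str = "greater") -> tuple[float, float]:
    """Mantel permutation test of matrix correlation.

    The statistic is the Pearson correlation over lower-triangle
    entries; the null distribution permutes one matrix's row/column
    order.  ``alternative="greater"`` (the isolation-by-distance
    direction) counts permutations with r at least the observed;
    ``"two-sided"`` compares absolute values.  The p-value is
    ``(1 + exceedances) / (n_perm + 1)``.
    """
    if d_gen.ids != d_geo.ids:
        raise InvalidParameterError("matrices must index the same entities "
                                    "in the same order")
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be >= 1")
    if alternative not in ("greater", "two-sided"):
        raise InvalidParameterError("alternative must be 'greater' or "
                                    "'two-sided'")
    if rng is None:
        rng = np.random.default_rng()
    x = d_gen.lower_triangle()
    y = d_geo.lower_triangle()
    ok = np.isfinite(x) & np.isfinite(y)
    if not ok.all():
        logger.warning("dropping %d non-finite pairs from the Mantel test",
                       int((~ok).sum()))
    if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        raise EmptyResultError("a distance matrix is constant; correlation "
                               "undefined")

    ti, tj = np.tril_indices(d_gen.n, k=-1)

    def corr(mat_y):
        yy = mat_y[ti, tj]
        sel = np.isfinite(x) & np.isfinite(yy)
        return np.corrcoef(x[sel], yy[sel])[0, 1]

    r_obs = corr(d_geo.values)
    n = d_gen.n
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(d_geo.values[np.ix_(perm, perm)])
        if alternative == "greater":
            count += r_p >= r_obs
        else:
            count += abs(r_p) >= abs(r_obs)
    p = (1.0 + count) / (n_perm + 1.0)
    return float(r_obs), float(p)
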