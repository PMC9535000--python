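"""Shannon alpha diversity, quartile-based sector definitions, and TIN
interpolation of diversity over the sampling area.

The sectorization follows the study design: within each realm, samples
are ranked by Shannon H (natural log), split into four near-equal
quartile groups, and named geographic sectors are validated against
rules of the form "at least 70% of the sector's samples fall in the
3rd/4th quartiles".  The spatial surface is a piecewise-linear
(barycentric) interpolation over the Delaunay triangulation of the
sampling points — the Triangulated Irregular Network used by GIS tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import Delaunay, QhullError

from .errors import ValidationError
from .io_formats import AbundanceTable, to_relative

log = logging.getLogger(__name__)


def shannon(p: Sequence[float]) -> float:
    """Shannon entropy H = -sum p_i ln p_i (nats) of one relative-abundance
    profile; the profile must sum to 1 within 1e-9."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValidationError("negative relative abundance")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"profile sums to {p.sum()}, not 1")
    pz = p[p > 0]
    return float(-(pz * np.log(pz)).sum())


def alpha_diversity(t: AbundanceTable) -> pd.Series:
    """Per-sample Shannon H; counts are converted to proportions first."""
    rel = t if t.is_relative else to_relative(t)
    return pd.Series([shannon(rel.values[:, j]) for j in range(len(rel.sample_ids))],
                     index=rel.sample_ids, name="shannon")


def rarefy(t: AbundanceTable, depth: int, seed: int) -> AbundanceTable:
    """Subsample each sample's counts to ``depth`` reads without
    replacement (seeded); samples shallower than ``depth`` are an error."""
    if t.is_relative:
        raise ValidationError("rarefaction requires counts, not proportions")
    counts = np.round(t.values).astype(np.int64)
    if np.any(counts.sum(axis=0) < depth):
        bad = t.sample_ids[int(np.argmin(counts.sum(axis=0)))]
        raise ValidationError(f"sample {bad!r} has fewer than {depth} reads")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], depth)
    return AbundanceTable(t.taxon_ids, t.sample_ids, out.astype(float),
                          is_relative=False, realm=t.realm)


def assign_quartiles(h: pd.Series) -> pd.Series:
    """Rank-based quartiles (1 = lowest H) with near-equal group sizes.

    Ties in H are broken by sample-id lexicographic order, so the
    assignment is deterministic; for n = 19 the group sizes are
    (5, 5, 5, 4).
    """
    if len(h) < 4:
        raise ValidationError("need at least 4 samples to form quartiles")
    order = sorted(h.index, key=lambda s: (h[s], str(s)))
    n = len(order)
    q = {s: (r * 4) // n + 1 for r, s in enumerate(order)}
    return pd.Series([q[s] for s in h.index], index=h.index, name="quartile",
                     dtype=int)


@dataclass
class SectorRule:
    """"At least ``min_fraction`` of sector ``name``'s samples lie in
    ``quartiles``" — the validation rule the sectors were drawn to meet."""

    name: str
    quartiles: frozenset
    min_fraction: float

    def __post_init__(self):
        self.quartiles = frozenset(int(q) for q in self.quartiles)
        if not self.quartiles or not self.quartiles <= {1, 2, 3, 4}:
            raise ValidationError("quartile set must be a non-empty subset of 1..4")
        if not (0.0 < self.min_fraction <= 1.0):
            raise ValidationError("min_fraction must lie in (0, 1]")


#: sector rules stated for the study area: water South/Central/North and
#: sediment South/North-East/North-West.  The North-West sediment rule is
#: ambiguous in its source ("between the 2nd and 4th quartiles"); the
#: inclusive reading {2, 3, 4} is the default.
WATER_SECTOR_RULES = [
    SectorRule("South", frozenset({3, 4}), 0.70),
    SectorRule("Central", frozenset({1, 2}), 1.00),
    SectorRule("North", frozenset({3, 4}), 0.65),
]
SEDIMENT_SECTOR_RULES = [
    SectorRule("South", frozenset({1, 2}), 0.80),
    SectorRule("North-East", frozenset({3, 4}), 0.90),
    SectorRule("North-West", frozenset({2, 3, 4}), 0.80),
]


def validate_sectors(quartiles: pd.Series, sectors: pd.Series,
                     rules: Sequence[SectorRule]) -> pd.DataFrame:
    """Fraction of each sector's samples inside the rule's quartile set,
    and pass/fail against the rule threshold."""
    sectors = sectors.loc[quartiles.index]
    rows = []
    for rule in rules:
        members = quartiles[sectors == rule.name]
        if len(members) == 0:
            raise ValidationError(f"sector {rule.name!r} has no samples")
        frac = float(members.isin(rule.quartiles).mean())
        rows.append((rule.name, len(members),
                     "".join(sorted(str(q) for q in rule.quartiles)),
                     rule.min_fraction, frac, frac >= rule.min_fraction))
    return pd.DataFrame(rows, columns=["sector", "n", "quartiles",
                                       "threshold", "fraction", "passed"])


@dataclass
class TINSurface:
    """Piecewise-linear surface over the Delaunay triangulation of the
    sampling points, evaluated on a regular lon/lat grid (NaN outside
    the convex hull)."""

    points: np.ndarray          # (n, 2) lon, lat
    values: np.ndarray          # (n,)
    triangulation: Delaunay
    grid_lon: np.ndarray
    grid_lat: np.ndarray
    grid_values: np.ndarray     # (n_lat, n_lon), NaN = no data
    _interp: LinearNDInterpolator = field(repr=False, default=None)

    def at(self, lon, lat) -> np.ndarray:
        """Interpolated value(s) at arbitrary points (NaN outside hull)."""
        return self._interp(np.column_stack([np.atleast_1d(lon),
                                             np.atleast_1d(lat)]))

    def to_frame(self) -> pd.DataFrame:
        lon, lat = np.meshgrid(self.grid_lon, self.grid_lat)
        vals = self.grid_values.ravel()
        return pd.DataFrame({"longitude": lon.ravel(), "latitude": lat.ravel(),
                             "value": vals, "nodata": ~np.isfinite(vals)})


def tin_interpolate(lon, lat, values, grid_res: int = 100) -> TINSurface:
    """Triangulated-irregular-network interpolation of point values.

    Builds the Delaunay triangulation of the (lon, lat) points and
    interpolates linearly (barycentric weights) within each triangle;
    exact at the sample points and bounded by the data range.
    """
    pts = np.column_stack([np.asarray(lon, float), np.asarray(lat, float)])
    vals = np.asarray(values, dtype=float)
    if len(pts) < 3:
        raise ValidationError("need at least 3 points")
    try:
        tri = Delaunay(pts)
    except QhullError as e:
        raise ValidationError(f"degenerate point configuration "
                              f"(collinear?): {e}") from e
    interp = LinearNDInterpolator(tri, vals)
    glon = np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid_res)
    glat = np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid_res)
    mlon, mlat = np.meshgrid(glon, glat)
    grid = interp(np.column_stack([mlon.ravel(), mlat.ravel()]))
    return TINSurface(pts, vals, tri, glon, glat,
                      grid.reshape(grid_res, grid_res), interp)
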