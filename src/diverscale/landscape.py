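"""Synthetic time-varying seascapes and cost-distance matrices.

A :class:`Landscape` holds everything the eco-evolutionary engine needs to
know about the physical world: gridded sea-surface temperature and depth
through time, a habitability mask (warm, shallow, marine cells), pairwise
least-cost distances between habitable cells, and a time-invariant partition
of the grid into named bioregions.

Synthetic worlds are built from a smooth random elevation field plus a
latitudinal temperature gradient.  Sea-level cycles and temperature drift
move the habitable mask over time so that populations can become isolated
and reconnected — the landscape dynamics that drive allopatric divergence.
Geometry is planar (cell sizes in km); a user-supplied distance function can
be plugged in for spherical or custom metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "WorldSpec",
    "Landscape",
    "UnseedableWorldError",
    "generate_world",
    "preprocess_climate",
    "cost_distance",
    "save_landscape",
    "load_landscape",
]

#: habitability cut-offs: warm-water reef habitat
DEFAULT_T_MIN = 17.0  # degC, minimum mean temperature
DEFAULT_D_MAX = 2000.0  # m, maximum depth


class UnseedableWorldError(ValueError):
    """Raised when a world has no habitable cell at the first timestep."""


@dataclass(frozen=True)
class WorldSpec:
    """Description of a synthetic world.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions (latitude x longitude).
    n_timesteps
        Number of timesteps to generate.
    cell_size_km
        Edge length of a grid cell in km (orthogonal step cost).
    timestep_ka
        Duration of one timestep in thousands of years.  Metadata only:
        all engine thresholds are expressed in timesteps, never converted
        to absolute time.
    lat_extent
        Half-width of the latitudinal band in degrees; rows span
        ``[+lat_extent, -lat_extent]``.
    equator_temp
        Sea-surface temperature at the equator (degC).
    lat_gradient
        Temperature decrease per degree of latitude (degC/deg).
    temp_anomaly_sd, temp_smooth_sigma
        Standard deviation and spatial smoothing length (cells) of the
        static spatial temperature anomaly field.
    temp_drift_amplitude, temp_drift_period
        Amplitude (degC) and period (timesteps) of a sinusoidal global
        temperature drift.
    land_fraction
        Fraction of cells above sea level at mean sea level.
    relief_m
        Vertical scale of the elevation field (m).
    elev_smooth_sigma
        Spatial smoothing length (cells) of the elevation field.
    sea_level_amplitude_m, sea_level_period
        Amplitude (m) and period (timesteps) of sinusoidal sea-level
        cycles; these move the coastline and reconnect/isolate habitat.
    n_bioregions
        Number of contiguous longitudinal bioregion blocks.
    t_min, d_max
        Habitability cut-offs (minimum temperature, maximum depth).
    seed
        Seed for the world's random fields.
    """

    n_rows: int = 20
    n_cols: int = 20
    n_timesteps: int = 100
    cell_size_km: float = 100.0
    timestep_ka: float = 166.7
    lat_extent: float = 35.0
    equator_temp: float = 28.0
    lat_gradient: float = 0.25
    temp_anomaly_sd: float = 1.5
    temp_smooth_sigma: float = 2.0
    temp_drift_amplitude: float = 2.0
    temp_drift_period: float = 80.0
    land_fraction: float = 0.25
    relief_m: float = 3000.0
    elev_smooth_sigma: float = 1.5
    sea_level_amplitude_m: float = 120.0
    sea_level_period: float = 40.0
    n_bioregions: int = 5
    t_min: float = DEFAULT_T_MIN
    d_max: float = DEFAULT_D_MAX
    seed: int = 0

    def validate(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.n_timesteps < 1:
            raise ValueError("n_timesteps must be >= 1")
        if not (0.0 <= self.land_fraction < 1.0):
            raise ValueError("land_fraction must be in [0, 1)")


@dataclass
class Landscape:
    """A gridded, time-indexed seascape.

    ``temperature`` and ``depth`` have shape ``(n_timesteps, n_rows,
    n_cols)``; depth is positive downward, so cells with ``depth <= 0``
    are land.  ``habitable`` is the conjunction of marine, warm
    (``temperature >= t_min``) and shallow (``depth <= d_max``).
    ``bioregion`` maps every cell to a region index into
    ``region_names``.  Cost-distance matrices between habitable cells are
    computed lazily per timestep and cached per unique marine mask.
    """

    temperature: np.ndarray
    depth: np.ndarray
    habitable: np.ndarray
    bioregion: np.ndarray
    region_names: list[str]
    cell_size_km: float = 100.0
    timestep_ka: float = 166.7
    lats: np.ndarray | None = None
    lons: np.ndarray | None = None
    t_min: float = DEFAULT_T_MIN
    d_max: float = DEFAULT_D_MAX
    distance_fn: Callable[[np.ndarray, np.ndarray, float], np.ndarray] | None = None
    _dist_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.habitable = np.asarray(self.habitable, dtype=bool)
        self.bioregion = np.asarray(self.bioregion, dtype=int)
        if self.temperature.shape != self.depth.shape:
            raise ValueError("temperature and depth shapes differ")
        if self.habitable.shape != self.temperature.shape:
            raise ValueError("habitable mask shape mismatch")
        if self.lats is None:
            self.lats = np.arange(self.n_rows, dtype=float)
        if self.lons is None:
            self.lons = np.arange(self.n_cols, dtype=float)

    # -- geometry ---------------------------------------------------------
    @property
    def n_timesteps(self) -> int:
        return self.temperature.shape[0]

    @property
    def n_rows(self) -> int:
        return self.temperature.shape[1]

    @property
    def n_cols(self) -> int:
        return self.temperature.shape[2]

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def marine(self, t: int) -> np.ndarray:
        """Boolean (rows, cols) mask of marine (submerged) cells at step t."""
        return self.depth[t] > 0.0

    def habitable_cells(self, t: int) -> np.ndarray:
        """Flat indices of habitable cells at timestep ``t``."""
        return np.flatnonzero(self.habitable[t].ravel())

    def recompute_habitable(self, t: int) -> np.ndarray:
        """Habitability recomputed from first principles (for validation)."""
        return (
            self.marine(t)
            & (self.temperature[t] >= self.t_min)
            & (self.depth[t] <= self.d_max)
        )

    def distances(self, t: int) -> tuple[np.ndarray, np.ndarray]:
        """Habitable cell ids and their pairwise cost-distance matrix at t.

        Returns ``(cells, D)`` where ``cells`` are flat indices and
        ``D[i, j]`` is the least-cost path length in km between
        ``cells[i]`` and ``cells[j]`` through marine cells;
        ``np.inf`` marks pairs separated by impassable land.
        """
        marine = self.marine(t)
        cells = self.habitable_cells(t)
        key = (marine.tobytes(), cells.tobytes())
        if key not in self._dist_cache:
            if self.distance_fn is not None:
                d = self.distance_fn(marine, cells, self.cell_size_km)
            else:
                d = cost_distance(marine, cells, self.cell_size_km)
            self._dist_cache[key] = d
        return cells, self._dist_cache[key]

    def region_of_cells(self, cells: np.ndarray) -> np.ndarray:
        return self.bioregion.ravel()[cells]


# ---------------------------------------------------------------------------
# world generation
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Standardised smooth Gaussian random field (wraps in longitude)."""
    z = rng.normal(size=shape)
    z = ndimage.gaussian_filter(z, sigma=sigma, mode="wrap")
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    return z


def generate_world(spec: WorldSpec) -> Landscape:
    """Generate a synthetic time-varying seascape.

    The world is bit-identical for identical ``spec`` (including seed).
    Raises :class:`UnseedableWorldError` if no cell is habitable at the
    first timestep.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    R, C, T = spec.n_rows, spec.n_cols, spec.n_timesteps

    # static elevation (m, positive up); threshold sets the land fraction
    z = _smooth_field(rng, (R, C), spec.elev_smooth_sigma)
    thresh = np.quantile(z, 1.0 - spec.land_fraction) if spec.land_fraction > 0 else z.max() + 10.0
    elev = (z - thresh) * spec.relief_m / 2.0

    lats = np.linspace(spec.lat_extent, -spec.lat_extent, R)
    lons = np.linspace(0.0, 360.0 * C / max(C, 1), C, endpoint=False)

    anomaly = _smooth_field(rng, (R, C), spec.temp_smooth_sigma) * spec.temp_anomaly_sd
    steps = np.arange(T)
    drift = spec.temp_drift_amplitude * np.sin(2.0 * np.pi * steps / spec.temp_drift_period)
    sea_level = spec.sea_level_amplitude_m * np.sin(2.0 * np.pi * steps / spec.sea_level_period)

    base_temp = spec.equator_temp - spec.lat_gradient * np.abs(lats)[:, None] + anomaly
    temperature = base_temp[None, :, :] + drift[:, None, None]
    depth = sea_level[:, None, None] - elev[None, :, :]

    habitable = (depth > 0.0) & (temperature >= spec.t_min) & (depth <= spec.d_max)

    bioregion = make_longitudinal_bioregions(R, C, spec.n_bioregions)

    world = Landscape(
        temperature=temperature,
        depth=depth,
        habitable=habitable,
        bioregion=bioregion,
        region_names=[f"realm_{i + 1}" for i in range(spec.n_bioregions)],
        cell_size_km=spec.cell_size_km,
        timestep_ka=spec.timestep_ka,
        lats=lats,
        lons=lons,
        t_min=spec.t_min,
        d_max=spec.d_max,
    )
    if world.habitable_cells(0).size == 0:
        raise UnseedableWorldError("no habitable cell at the first timestep")
    return world


def make_longitudinal_bioregions(n_rows: int, n_cols: int, n_regions: int) -> np.ndarray:
    """Partition the grid into contiguous longitudinal blocks."""
    if n_regions < 1:
        raise ValueError("need at least one bioregion")
    cols = np.arange(n_cols)
    labels = np.minimum((cols * n_regions) // n_cols, n_regions - 1)
    return np.broadcast_to(labels, (n_rows, n_cols)).copy()


# ---------------------------------------------------------------------------
# climate keyframe preprocessing
# ---------------------------------------------------------------------------

def preprocess_climate(
    keyframes: Sequence[np.ndarray],
    keyframe_times: Sequence[float],
    target_times: Sequence[float],
    focal_window: int = 81,
    pole_value: float = -20.0,
) -> np.ndarray:
    """Densify sparse temperature keyframes by smoothing + linear interpolation.

    Each keyframe is smoothed with a square moving-average focal window
    (side ``sqrt(focal_window)``); rows beyond the polar edges of the grid
    are treated as ``pole_value`` during smoothing and columns wrap in
    longitude.  Target fields are then linear interpolations in time of
    the bracketing smoothed keyframes.  No extrapolation: target times
    outside the keyframe range raise ``ValueError``.
    """
    frames = [np.asarray(f, dtype=float) for f in keyframes]
    times = np.asarray(keyframe_times, dtype=float)
    if len(frames) < 2:
        raise ValueError("need at least two keyframes")
    if len(frames) != times.size:
        raise ValueError("keyframes and keyframe_times length mismatch")
    if np.any(np.diff(times) <= 0):
        raise ValueError("keyframe_times must be strictly increasing")
    side = int(round(np.sqrt(focal_window)))
    if side * side != focal_window or side % 2 == 0:
        raise ValueError("focal_window must be a perfect square with odd side")

    smoothed = np.stack([_focal_smooth(f, side, pole_value) for f in frames])

    targets = np.asarray(target_times, dtype=float)
    if np.any(targets < times[0]) or np.any(targets > times[-1]):
        raise ValueError("target time outside keyframe range (no extrapolation)")

    out = np.empty((targets.size,) + frames[0].shape)
    idx = np.searchsorted(times, targets, side="right") - 1
    idx = np.clip(idx, 0, times.size - 2)
    for k, (i, tt) in enumerate(zip(idx, targets)):
        t0, t1 = times[i], times[i + 1]
        w = (tt - t0) / (t1 - t0)
        out[k] = (1.0 - w) * smoothed[i] + w * smoothed[i + 1]
    return out


def _focal_smooth(field2d: np.ndarray, side: int, pole_value: float) -> np.ndarray:
    """Moving-average smoothing: polar rows padded with a constant, lon wraps."""
    half = side // 2
    padded = np.pad(field2d, ((half, half), (0, 0)), mode="constant", constant_values=pole_value)
    padded = np.pad(padded, ((0, 0), (half, half)), mode="wrap")
    sm = ndimage.uniform_filter(padded, size=side, mode="nearest")
    return sm[half:-half, half:-half]


# ---------------------------------------------------------------------------
# cost distance
# ---------------------------------------------------------------------------

_SQRT2 = np.sqrt(2.0)


def cost_distance(
    marine_mask: np.ndarray,
    habitable_cells: np.ndarray,
    cell_size_km: float,
) -> np.ndarray:
    """Least-cost distances between habitable cells through marine cells.

    Movement follows an 8-direction adjacency scheme: marine cells are
    passable (conductance 1), land cells impassable (conductance 0).
    Orthogonal steps cost ``cell_size_km``, diagonal steps
    ``sqrt(2) * cell_size_km``.  Pairs with no marine path get ``np.inf``.

    Parameters
    ----------
    marine_mask
        Boolean (rows, cols); True where the cell is marine.
    habitable_cells
        Flat indices of the cells between which distances are wanted;
        must all be marine.
    cell_size_km
        Orthogonal step length in km.
    """
    marine_mask = np.asarray(marine_mask, dtype=bool)
    habitable_cells = np.asarray(habitable_cells, dtype=int)
    R, C = marine_mask.shape
    flat = marine_mask.ravel()
    if habitable_cells.size and not flat[habitable_cells].all():
        bad = habitable_cells[~flat[habitable_cells]]
        raise ValueError(f"habitable cells on land: {bad.tolist()}")

    marine_idx = np.flatnonzero(flat)
    n = marine_idx.size
    pos = -np.ones(R * C, dtype=int)
    pos[marine_idx] = np.arange(n)

    rows_i: list[np.ndarray] = []
    cols_j: list[np.ndarray] = []
    wts: list[np.ndarray] = []
    rr, cc = np.divmod(marine_idx, C)
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        nr, nc = rr + dr, cc + dc
        ok = (nr >= 0) & (nr < R) & (nc >= 0) & (nc < C)
        src = marine_idx[ok]
        dst = nr[ok] * C + nc[ok]
        sea = flat[dst]
        src, dst = src[sea], dst[sea]
        w = cell_size_km * (_SQRT2 if dr and dc else 1.0)
        rows_i.append(pos[src])
        cols_j.append(pos[dst])
        wts.append(np.full(src.size, w))
    if rows_i:
        i = np.concatenate(rows_i)
        j = np.concatenate(cols_j)
        w = np.concatenate(wts)
    else:  # pragma: no cover - degenerate single-cell sea
        i = j = np.empty(0, dtype=int)
        w = np.empty(0)
    graph = sparse.coo_matrix((w, (i, j)), shape=(n, n)).tocsr()

    hab_pos = pos[habitable_cells]
    if hab_pos.size == 0:
        return np.zeros((0, 0))
    d = dijkstra(graph, directed=False, indices=hab_pos)
    return d[:, hab_pos]


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def to_dataset(world: Landscape) -> xr.Dataset:
    """Pack the landscape's gridded arrays into an :class:`xarray.Dataset`."""
    coords = {
        "time": np.arange(world.n_timesteps),
        "lat": world.lats,
        "lon": world.lons,
    }
    ds = xr.Dataset(
        {
            "temperature": (("time", "lat", "lon"), world.temperature),
            "depth": (("time", "lat", "lon"), world.depth),
            "habitable": (("time", "lat", "lon"), world.habitable.astype(np.int8)),
            "bioregion": (("lat", "lon"), world.bioregion),
        },
        coords=coords,
        attrs={
            "cell_size_km": world.cell_size_km,
            "timestep_ka": world.timestep_ka,
            "t_min": world.t_min,
            "d_max": world.d_max,
            "region_names": ",".join(world.region_names),
        },
    )
    return ds


def save_landscape(world: Landscape, outdir) -> None:
    """Serialise a landscape to a directory (NetCDF grids + bioregion CSV)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    to_dataset(world).to_netcdf(out / "world.nc", engine="scipy")
    cells = np.arange(world.n_cells)
    pd.DataFrame(
        {
            "cell_id": cells,
            "region_name": [world.region_names[r] for r in world.bioregion.ravel()],
        }
    ).to_csv(out / "bioregions.csv", index=False)


def load_landscape(indir) -> Landscape:
    from pathlib import Path

    ds = xr.load_dataset(Path(indir) / "world.nc", engine="scipy")
    return Landscape(
        temperature=ds["temperature"].values,
        depth=ds["depth"].values,
        habitable=ds["habitable"].values.astype(bool),
        bioregion=ds["bioregion"].values,
        region_names=ds.attrs["region_names"].split(","),
        cell_size_km=float(ds.attrs["cell_size_km"]),
        timestep_ka=float(ds.attrs["timestep_ka"]),
        lats=ds["lat"].values,
        lons=ds["lon"].values,
        t_min=float(ds.attrs["t_min"]),
        d_max=float(ds.attrs["d_max"]),
    )
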