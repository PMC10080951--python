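"""Hexagonal detector mosaics for the retinal front end.

Cone photoreceptors and parasol-OFF retinal ganglion cell receptive
fields (P-OFF-RGC-RFs) are modelled as points of a regular hexagonal
lattice, the densest packing for circularly symmetric detectors.  For
efficient pooling the lattice is also indexed on an anisotropic
rectangular grid (row pitch ``spacing * sqrt(3)/2``, column pitch
``spacing``, alternate rows offset by half a column), which turns the
difference-of-Gaussians pooling step into a plain 2-D convolution.

Densities are in cells/deg^2, positions in visual degrees with the
origin at the stimulus centre.  The hexagonal packing identity links
density and centre-to-centre spacing::

    density = 2 / (sqrt(3) * spacing**2)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HexMosaic",
    "ConvergenceProfile",
    "hex_spacing",
    "hex_density",
    "build_hex_mosaic",
    "regularize_lattice",
    "convergence_ratio",
    "degrade_mosaic",
    "read_density_table",
]

_SQRT3 = np.sqrt(3.0)


def hex_spacing(density: float) -> float:
    """Centre-to-centre spacing (deg) of a hexagonal lattice of given density."""
    if density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    return float(np.sqrt(2.0 / (_SQRT3 * density)))


def hex_density(spacing: float) -> float:
    """Density (cells/deg^2) of a hexagonal lattice of given spacing."""
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    return float(2.0 / (_SQRT3 * spacing**2))


@dataclass(frozen=True)
class HexMosaic:
    """A hexagonal point lattice of retinal detectors.

    Attributes
    ----------
    positions : (N, 2) array of (x, y) in visual degrees.
    spacing : centre-to-centre distance, deg.
    density : cells/deg^2 (hex identity of ``spacing``).
    extent : (width, height) of the generated window, deg, centred on 0.
    phase_seed : seed used to jitter the global lattice phase, or None.
    rows, cols : integer regular-lattice index of each cell (anisotropic
        rectangular grid; row pitch spacing*sqrt(3)/2, column pitch
        spacing, odd rows offset half a column).
    alive : boolean mask of surviving cells (False after degradation).
    """

    positions: np.ndarray
    spacing: float
    extent: tuple[float, float]
    phase_seed: int | None
    rows: np.ndarray
    cols: np.ndarray
    alive: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.alive is None:
            object.__setattr__(self, "alive", np.ones(len(self.positions), bool))

    @property
    def density(self) -> float:
        return hex_density(self.spacing)

    @property
    def n_cells(self) -> int:
        return int(self.alive.sum())

    @property
    def row_pitch(self) -> float:
        return self.spacing * _SQRT3 / 2.0

    @property
    def col_pitch(self) -> float:
        return self.spacing

    def regular_index(self) -> dict[int, tuple[int, int]]:
        """Mapping cell index -> (row, col) on the rectangular grid."""
        return {i: (int(r), int(c)) for i, (r, c) in enumerate(zip(self.rows, self.cols))}


def build_hex_mosaic(
    density: float,
    extent: tuple[float, float],
    phase_seed: int | None = None,
) -> HexMosaic:
    """Generate a hexagonal mosaic of the given density over a centred window.

    The default phase places one lattice point at the origin; an integer
    ``phase_seed`` jitters the global lattice offset reproducibly within
    one unit cell (edge effects only, the lattice itself is unchanged).
    """
    width, height = float(extent[0]), float(extent[1])
    if density <= 0:
        raise ValueError(f"density must be positive, got {density}")
    if width <= 0 or height <= 0:
        raise ValueError(f"extent must be positive, got {extent}")
    s = hex_spacing(density)
    if width < 7 * s or height < 7 * s:
        raise ValueError(
            f"extent {extent} too small: need >= 7 cells per side at spacing {s:.4g}"
        )
    dy = s * _SQRT3 / 2.0
    phase = np.zeros(2)
    if phase_seed is not None:
        rng = np.random.default_rng(phase_seed)
        phase = rng.uniform(0.0, 1.0, 2) * np.array([s, dy])

    half_w, half_h = width / 2.0, height / 2.0
    rmax = int(np.ceil((half_h + dy) / dy))
    cmax = int(np.ceil((half_w + s) / s)) + 1
    rr, cc = np.meshgrid(np.arange(-rmax, rmax + 1), np.arange(-cmax, cmax + 1), indexing="ij")
    x = cc * s + (rr % 2) * (s / 2.0) + phase[0]
    y = rr * dy + phase[1]
    keep = (np.abs(x) <= half_w) & (np.abs(y) <= half_h)
    pos = np.column_stack([x[keep], y[keep]])
    return HexMosaic(
        positions=pos,
        spacing=s,
        extent=(width, height),
        phase_seed=phase_seed,
        rows=rr[keep].astype(int),
        cols=cc[keep].astype(int),
    )


def regularize_lattice(mosaic: HexMosaic) -> tuple[np.ndarray, dict]:
    """Rectangular grid view of the mosaic for convolution pooling.

    Returns ``(grid, meta)`` where ``grid`` is a 2-D int array holding the
    cell index at each occupied site and -1 elsewhere.  To keep true
    hexagonal distances on a *rectangular* grid the columns are laid out
    at half the lattice spacing: cell (row r, col c) sits at fine column
    ``2*c + (r % 2)``, so the grid pitches are (spacing*sqrt(3)/2,
    spacing/2) and occupied sites form a checkerboard.  ``meta`` carries
    the pitches and index offsets needed to embed per-cell values
    (:func:`mosaic_values_to_grid`) and to build a matching kernel.

    The view is lossless: every cell appears at exactly one grid site.
    """
    r0, c0 = mosaic.rows.min(), mosaic.cols.min()
    # fine-column parity follows the absolute row parity so the half-column
    # offset of odd rows survives the index shift
    fine_cols = 2 * (mosaic.cols - c0) + (mosaic.rows % 2)
    fine_cols -= fine_cols.min()
    rows = mosaic.rows - r0
    grid = np.full((rows.max() + 1, fine_cols.max() + 1), -1, dtype=int)
    grid[rows, fine_cols] = np.arange(len(rows))
    meta = {
        "row_pitch": mosaic.row_pitch,
        "col_pitch": mosaic.spacing / 2.0,
        "rows": rows,
        "fine_cols": fine_cols,
    }
    return grid, meta


def mosaic_values_to_grid(mosaic: HexMosaic, values: np.ndarray) -> tuple[np.ndarray, dict]:
    """Embed per-cell values on the rectangular grid view (zeros off-lattice)."""
    grid, meta = regularize_lattice(mosaic)
    arr = np.zeros(grid.shape, dtype=float)
    arr[meta["rows"], meta["fine_cols"]] = values
    return arr, meta


@dataclass(frozen=True)
class ConvergenceProfile:
    """Cone and RGC-RF density as functions of eccentricity.

    Densities may be constants or tabulated against eccentricity
    (interpolated linearly in log10-density, the conventional scale for
    retinal density gradients).  The convergence ratio
    ``c = cone_density / rgc_density`` weights each RGC's contribution to
    the total retinal input; it is applied multiplicatively, never by
    re-meshing the lattice.
    """

    eccentricity: np.ndarray | None = None
    cone_density: np.ndarray | float = 1.0
    rgc_density: np.ndarray | float = 1.0

    def _interp(self, dens, ecc: float) -> float:
        if np.isscalar(dens):
            return float(dens)
        e = np.asarray(self.eccentricity, float)
        d = np.asarray(dens, float)
        if ecc < e.min() - 1e-9 or ecc > e.max() + 1e-9:
            raise ValueError(f"eccentricity {ecc} outside tabulated range [{e.min()}, {e.max()}]")
        return float(10 ** np.interp(ecc, e, np.log10(d)))

    def cone_density_at(self, ecc: float) -> float:
        return self._interp(self.cone_density, ecc)

    def rgc_density_at(self, ecc: float) -> float:
        return self._interp(self.rgc_density, ecc)


def convergence_ratio(profile: ConvergenceProfile, eccentricity: float) -> float:
    """Cone/RGC convergence ratio c at an eccentricity (dimensionless, >= 1)."""
    cone = profile.cone_density_at(eccentricity)
    rgc = profile.rgc_density_at(eccentricity)
    if cone <= 0 or rgc <= 0:
        raise ValueError("densities must be positive")
    return cone / rgc


def degrade_mosaic(mosaic: HexMosaic, loss_fraction: float, seed: int) -> HexMosaic:
    """Delete each cell independently with probability ``loss_fraction``.

    Simulates diffuse ganglion-cell loss (e.g. glaucomatous): survivors
    keep their lattice positions, so the geometry of the remaining mosaic
    is an i.i.d. thinning of the original.
    """
    if not 0 <= loss_fraction < 1:
        raise ValueError(f"loss_fraction must be in [0, 1), got {loss_fraction}")
    if loss_fraction == 0:
        return mosaic
    rng = np.random.default_rng(seed)
    survive = rng.random(len(mosaic.positions)) >= loss_fraction
    alive = mosaic.alive & survive
    return HexMosaic(
        positions=mosaic.positions,
        spacing=mosaic.spacing,
        extent=mosaic.extent,
        phase_seed=mosaic.phase_seed,
        rows=mosaic.rows,
        cols=mosaic.cols,
        alive=alive,
    )


def read_density_table(path) -> ConvergenceProfile:
    """Read a delimited density table.

    Expected columns: ``eccentricity_deg``, ``rgc_rf_density_per_deg2``,
    ``cone_density_per_deg2``.  Interpolation between rows is linear in
    log10-density versus eccentricity.
    """
    df = pd.read_csv(path)
    required = {"eccentricity_deg", "rgc_rf_density_per_deg2", "cone_density_per_deg2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"density table missing columns: {sorted(missing)}")
    df = df.sort_values("eccentricity_deg")
    return ConvergenceProfile(
        eccentricity=df["eccentricity_deg"].to_numpy(float),
        cone_density=df["cone_density_per_deg2"].to_numpy(float),
        rgc_density=df["rgc_rf_density_per_deg2"].to_numpy(float),
    )
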