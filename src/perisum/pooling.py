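"""Retinal pooling: cone sampling, DoG receptive fields, total input S.

The (optionally blurred) stimulus is sampled by the cone mosaic; each
P-OFF-RGC pools cone values through a difference-of-Gaussians (DoG)
receptive field; the per-cell responses, weighted by the cone/RGC
convergence ratio c, are summed into the total spatial input

    S = sum_i R_i            (signed mode, default)
    S = sum_i |R_i|          (absolute mode)

Negative R_i arise from the inhibitory surround and are read as
suppression of background activity of the OFF mosaic.  The DoG follows
the Croner & Kaplan median macaque parameters: surround peak 1% of the
centre peak, surround SD 6.7x the centre SD, and the centre *radius*
(where the centre Gaussian falls to Kc/e) equal to the intercell
spacing, i.e. centre SD = spacing / 1.414.

Cones and RGC-RFs share one lattice here (1:1); convergence enters as a
multiplicative weight, which is equivalent to physically stacking a
denser cone mosaic (see tests for the discrete cross-check).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import fftconvolve

from .mosaic import HexMosaic, build_hex_mosaic, mosaic_values_to_grid
from .optics import OpticsParams, StimulusImage, blur_stimulus, make_disc_image

__all__ = [
    "DoGParams",
    "RGCResponseField",
    "RetinalContext",
    "dog_params_for_spacing",
    "dog_weight",
    "cone_response",
    "rgc_responses",
    "rgc_responses_bruteforce",
    "spatial_input",
]

#: centre radius (Kc/e point) equals the lattice spacing => SD = spacing/1.414
CENTER_RADIUS_TO_SD = 1.414
SURROUND_CENTER_SD_RATIO = 6.7
SURROUND_CENTER_PEAK_RATIO = 0.01
#: kernel truncation radius in surround SDs (tail mass < 1e-3 of surround)
KERNEL_TRUNCATION_SDS = 4.0


@dataclass(frozen=True)
class DoGParams:
    """Difference-of-Gaussians receptive-field profile.

    ``weight(r) = K_c exp(-r^2/(2 sigma_c^2)) - K_s exp(-r^2/(2 sigma_s^2))``
    """

    K_c: float = 1.0
    sigma_c: float = 1.0 / CENTER_RADIUS_TO_SD
    K_s: float = SURROUND_CENTER_PEAK_RATIO
    sigma_s: float = 6.7 / CENTER_RADIUS_TO_SD
    truncation_sds: float = KERNEL_TRUNCATION_SDS

    @property
    def center_radius(self) -> float:
        """Distance where the centre Gaussian equals K_c / e."""
        return self.sigma_c * np.sqrt(2.0)

    @property
    def truncation_radius(self) -> float:
        return self.truncation_sds * self.sigma_s


def _unit_lattice_gain() -> float:
    """Sum of the (K_c = 1) DoG over a unit-spacing hexagonal lattice.

    Scale-invariant: all DoG length scales are proportional to the
    spacing, so this constant (~2.0) holds for every mosaic density.
    Dividing the kernel by it gives each fully stimulated RGC a response
    of exactly 1, which calibrates the total input S in units of
    stimulated RGC counts.
    """
    global _UNIT_LATTICE_GAIN
    if _UNIT_LATTICE_GAIN is None:
        dog = DoGParams()  # unit spacing proportions, K_c = 1
        reach = dog.truncation_radius
        dy = _SQRT3_HALF
        rmax = int(np.ceil(reach / dy)) + 1
        cmax = int(np.ceil(reach)) + 1
        rr, cc = np.meshgrid(np.arange(-rmax, rmax + 1), np.arange(-cmax, cmax + 1), indexing="ij")
        x = cc + (rr % 2) * 0.5
        y = rr * dy
        _UNIT_LATTICE_GAIN = float(dog_weight(np.hypot(x, y), dog).sum())
    return _UNIT_LATTICE_GAIN


_UNIT_LATTICE_GAIN: float | None = None
_SQRT3_HALF = np.sqrt(3.0) / 2.0


def dog_params_for_spacing(spacing: float, K_c: float | None = None) -> DoGParams:
    """DoG whose centre radius equals the mosaic intercell spacing.

    By default the kernel is normalised to unit gain on its own lattice
    (a fully stimulated cell responds 1), so the total input S counts
    stimulated RGCs; pass an explicit ``K_c`` to override.
    """
    if K_c is None:
        K_c = 1.0 / _unit_lattice_gain()
    sigma_c = spacing / CENTER_RADIUS_TO_SD
    return DoGParams(
        K_c=K_c,
        sigma_c=sigma_c,
        K_s=SURROUND_CENTER_PEAK_RATIO * K_c,
        sigma_s=SURROUND_CENTER_SD_RATIO * sigma_c,
    )


def dog_weight(r, dog: DoGParams, truncate: bool = True):
    """DoG weight at distance r (deg), zero beyond the truncation radius."""
    r = np.asarray(r, float)
    w = dog.K_c * np.exp(-r**2 / (2 * dog.sigma_c**2)) - dog.K_s * np.exp(
        -r**2 / (2 * dog.sigma_s**2)
    )
    if truncate:
        w = np.where(r <= dog.truncation_radius, w, 0.0)
    return w if w.ndim else float(w)


@dataclass(frozen=True)
class RGCResponseField:
    """Per-RGC unit-contrast responses with their provenance."""

    values: np.ndarray
    mosaic: HexMosaic
    convergence: float = 1.0
    mode: str = "signed"


def cone_response(image: StimulusImage, cones: HexMosaic) -> np.ndarray:
    """Sample the stimulus image at cone positions (bilinear interpolation)."""
    n = image.pixels.shape[0]
    half = (n - 1) / 2.0
    pos = cones.positions
    ix = pos[:, 0] / image.pitch + half
    iy = pos[:, 1] / image.pitch + half
    if ix.min() < -0.5 or iy.min() < -0.5 or ix.max() > n - 0.5 or iy.max() > n - 0.5:
        raise ValueError("cone mosaic extends outside the stimulus image")
    # rows index y, columns index x
    return map_coordinates(image.pixels, np.vstack([iy, ix]), order=1, mode="nearest")


def _dog_kernel_on_grid(dog: DoGParams, row_pitch: float, col_pitch: float) -> np.ndarray:
    rmax = int(np.ceil(dog.truncation_radius / row_pitch))
    cmax = int(np.ceil(dog.truncation_radius / col_pitch))
    dr, dc = np.meshgrid(np.arange(-rmax, rmax + 1), np.arange(-cmax, cmax + 1), indexing="ij")
    return dog_weight(np.hypot(dr * row_pitch, dc * col_pitch), dog)


def rgc_responses(
    cone_values: np.ndarray,
    cones: HexMosaic,
    rgcs: HexMosaic | None = None,
    dog: DoGParams | None = None,
    convergence: float = 1.0,
    mode: str = "signed",
) -> RGCResponseField:
    """Pool cone values into per-RGC responses.

    With cones and RGCs on the same lattice (``rgcs is None`` or the same
    mosaic) the pooling is a 2-D convolution on the regularised grid
    view, which equals the brute-force per-cell sum to machine precision.
    Distinct mosaics fall back to the direct sum.
    """
    if dog is None:
        dog = dog_params_for_spacing((rgcs or cones).spacing)
    if dog.truncation_radius < 3.0 * dog.sigma_s:
        raise ValueError("DoG kernel truncated before 3 sigma_s")
    if rgcs is None or rgcs is cones:
        grid, meta = mosaic_values_to_grid(cones, cone_values)
        kernel = _dog_kernel_on_grid(dog, meta["row_pitch"], meta["col_pitch"])
        conv = fftconvolve(grid, kernel, mode="same")
        values = conv[meta["rows"], meta["fine_cols"]]
        out_mosaic = cones
    else:
        values = rgc_responses_bruteforce(cone_values, cones, rgcs, dog)
        out_mosaic = rgcs
    return RGCResponseField(
        values=convergence * values, mosaic=out_mosaic, convergence=convergence, mode=mode
    )


def rgc_responses_bruteforce(
    cone_values: np.ndarray,
    cones: HexMosaic,
    rgcs: HexMosaic,
    dog: DoGParams,
    chunk: int = 256,
) -> np.ndarray:
    """Direct per-cell weighted sum over all cones (oracle-grade, O(N*M))."""
    out = np.empty(len(rgcs.positions))
    cp = cones.positions
    for start in range(0, len(out), chunk):
        block = rgcs.positions[start:start + chunk]
        d = np.hypot(
            block[:, None, 0] - cp[None, :, 0], block[:, None, 1] - cp[None, :, 1]
        )
        out[start:start + chunk] = dog_weight(d, dog) @ cone_values
    return out


def spatial_input(fld: RGCResponseField) -> float:
    """Total spatial input S; dead (degraded) cells contribute nothing."""
    vals = fld.values[fld.mosaic.alive]
    if fld.mode == "absolute":
        return float(np.abs(vals).sum())
    if fld.mode != "signed":
        raise ValueError(f"unknown summation mode {fld.mode!r}")
    return float(vals.sum())


class ExtrapolationError(ValueError):
    """Area<->input query too far outside the tabulated range."""


@dataclass
class RetinalContext:
    """One visual-field location's retinal front end.

    Bundles RGC-RF density, cone/RGC convergence, the DoG profile implied
    by the lattice spacing, optics, and the summation mode; builds and
    caches the numeric mapping between stimulus area and total input S
    used for fitting and for Ricco-area readout.
    """

    rgc_density: float
    convergence: float = 1.0
    optics: OpticsParams = field(default_factory=lambda: OpticsParams(enabled=False))
    mode: str = "signed"
    eccentricity: float | None = None
    phase_seed: int | None = None
    max_diameter: float = 2.2  # deg; covers Goldmann V with margin
    table_points: int = 25

    def __post_init__(self):
        if self.rgc_density <= 0:
            raise ValueError("rgc_density must be positive")
        if self.convergence < 1.0 - 1e-9:
            raise ValueError("convergence ratio must be >= 1")
        self._mosaic: HexMosaic | None = None
        self._tables: dict[bool, np.ndarray] = {}

    # -- geometry ---------------------------------------------------------
    @property
    def spacing(self) -> float:
        from .mosaic import hex_spacing

        return hex_spacing(self.rgc_density)

    @property
    def dog(self) -> DoGParams:
        return dog_params_for_spacing(self.spacing)

    def mosaic(self) -> HexMosaic:
        if self._mosaic is None:
            half = self.max_diameter / 2.0 + 3.0 * self.dog.sigma_s + 0.5
            self._mosaic = build_hex_mosaic(
                self.rgc_density, (2 * half, 2 * half), phase_seed=self.phase_seed
            )
        return self._mosaic

    # -- forward pipeline -------------------------------------------------
    def _image_for(self, diameter: float, blur: bool) -> StimulusImage:
        extent = self.mosaic().extent[0] + 2 * self.spacing
        if blur:
            # fine enough that the MTF at Nyquist is negligible for any
            # admissible pupil diameter
            pitch = min(self.spacing / 2.0, diameter / 16.0, 0.004)
        else:
            pitch = min(self.spacing / 2.0, diameter / 16.0)
        img = make_disc_image(diameter, pitch, extent=extent)
        if blur:
            img = blur_stimulus(img, self.optics)
        return img

    def per_cell_inputs(self, diameter: float, blur: bool | None = None) -> np.ndarray:
        """Convergence-weighted unit-contrast response of every RGC."""
        if diameter <= 0:
            raise ValueError("diameter must be positive")
        if blur is None:
            blur = self.optics.enabled
        img = self._image_for(diameter, blur)
        cones = self.mosaic()
        vals = cone_response(img, cones)
        fld = rgc_responses(
            vals, cones, dog=self.dog, convergence=self.convergence, mode=self.mode
        )
        return fld.values

    def spatial_input_for_disc(self, diameter: float, blur: bool | None = None) -> float:
        """Total input S for a centred disc of the given diameter."""
        values = self.per_cell_inputs(diameter, blur=blur)
        fld = RGCResponseField(values, self.mosaic(), self.convergence, self.mode)
        return spatial_input(fld)

    # -- area <-> input mapping ------------------------------------------
    def _table(self, blur: bool) -> np.ndarray:
        if blur not in self._tables:
            d_max = self.max_diameter
            d_min = max(0.03, self.spacing / 3.0)
            diam = np.geomspace(d_min, d_max, self.table_points)
            areas = np.pi * (diam / 2.0) ** 2
            s = np.array([self.spatial_input_for_disc(d, blur=blur) for d in diam])
            if np.any(s <= 0):
                raise RuntimeError("non-positive spatial input in area ladder")
            self._tables[blur] = np.column_stack([np.log10(areas), np.log10(s)])
        return self._tables[blur]

    def _loglog_interp(self, xq: float, xs: np.ndarray, ys: np.ndarray) -> float:
        span = 0.0
        if xq < xs[0]:
            span = xs[0] - xq
        elif xq > xs[-1]:
            span = xq - xs[-1]
        if span > 1.0:
            raise ExtrapolationError(f"query {xq:.3f} is {span:.2f} log10 units outside the table")
        if span > 0.3:
            warnings.warn(
                f"extrapolating area<->input mapping by {span:.2f} log10 units",
                stacklevel=3,
            )
        # local linear in log-log, with linear extension at the ends
        return float(np.interp(xq, xs, ys)) if span == 0.0 else _lin_extend(xq, xs, ys)

    def area_to_input(self, area: float, blur: bool | None = None) -> float:
        """S for a disc of the given area (deg^2), log-log interpolated."""
        if blur is None:
            blur = self.optics.enabled
        t = self._table(blur)
        return 10 ** self._loglog_interp(np.log10(area), t[:, 0], t[:, 1])

    def input_to_area(self, s: float, blur: bool | None = None) -> float:
        """Inverse mapping: stimulus area (deg^2) yielding total input S.

        Below the cell spacing the forward map plateaus (only the centre
        cone is stimulated), so the inverse is taken on the strictly
        increasing branch of the table.
        """
        if blur is None:
            blur = self.optics.enabled
        t = self._table(blur)
        keep = np.concatenate([[True], np.diff(t[:, 1]) > 1e-9])
        # drop the sub-spacing plateau: keep the monotone tail only
        start = np.max(np.nonzero(~keep)[0]) + 1 if np.any(~keep) else 0
        tt = t[max(start - 1, 0):]
        return 10 ** self._loglog_interp(np.log10(s), tt[:, 1], tt[:, 0])

    def with_optics(self, enabled: bool) -> "RetinalContext":
        """Copy of this context with the optical stage toggled."""
        return RetinalContext(
            rgc_density=self.rgc_density,
            convergence=self.convergence,
            optics=replace(self.optics, enabled=enabled),
            mode=self.mode,
            eccentricity=self.eccentricity,
            phase_seed=self.phase_seed,
            max_diameter=self.max_diameter,
            table_points=self.table_points,
        )


@dataclass(frozen=True)
class UniformContext:
    """Idealised uniform retina with an exactly linear area->input map.

    ``S = convergence * rgc_density * area``: the infinite-mosaic,
    signed-summation limit where each RGC contributes its DoG volume and
    edge effects vanish.  Useful for fast fitting and for properties that
    hold exactly only under perfect linearity (e.g. the duration-shift
    invariance of the spatial summation curve).
    """

    rgc_density: float
    convergence: float = 1.0

    def area_to_input(self, area: float, blur: bool | None = None) -> float:
        if area <= 0:
            raise ValueError("area must be positive")
        return self.convergence * self.rgc_density * float(area)

    def input_to_area(self, s: float, blur: bool | None = None) -> float:
        if s <= 0:
            raise ValueError("input must be positive")
        return float(s) / (self.convergence * self.rgc_density)


def _lin_extend(xq: float, xs: np.ndarray, ys: np.ndarray) -> float:
    if xq < xs[0]:
        slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
        return float(ys[0] + slope * (xq - xs[0]))
    slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
    return float(ys[-1] + slope * (xq - xs[-1]))
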