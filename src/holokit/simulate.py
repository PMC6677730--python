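"""Synthetic hologram generator for lens-less in-line holography.

Builds complex transmission maps for micro-objects (opaque disks standing in
for polystyrene microspheres, projected-thickness phase spheres standing in
for red blood cells, USAF-1951 style bar targets), illuminates them with a
paraxial point source or a plane wave, and forms detector-plane intensity
holograms by angular-spectrum propagation.  A brute-force Fresnel-Kirchhoff
double-sum oracle with exact (non-paraxial) distances is provided for small
grids as the independent reference the FFT path is tested against.

Partial coherence is modelled by incoherent averaging of intensity holograms
over (a) Gauss-Hermite samples of a Gaussian spectral line of given FWHM and
(b) uniformly distributed points on the source aperture disk, each shifting
(point source) or tilting (plane wave) the illumination.  Shot noise and
quantization are applied last, seeded and reproducible.

The thin-sample cascade (multiply by each plane's transmission, propagate to
the next) assumes weakly scattering, effectively two-dimensional objects —
the regime these instruments are designed for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .optics_design import OpticalSetup, USAFElement, usaf_line_width, usaf_spatial_frequency
from .propagation import Hologram, WaveField, propagate

__all__ = [
    "SceneObject",
    "Scene",
    "NoiseModel",
    "transmission_map",
    "spherical_illumination",
    "simulate_hologram",
    "hologram_from_maps",
    "direct_integral_oracle",
    "apply_partial_coherence",
    "synth_usaf_target",
    "add_noise",
    "canonical_fixtures",
]

_ORACLE_MAX_SIDE = 64

#: Synthetic default refractive-index contrasts for phase objects.  These are
#: fixture conventions chosen to produce realistic fringe systems, not
#: measured material constants.
RBC_LIKE_DN = 0.06
CELL_WALL_LIKE_DN = 0.05


@dataclass(frozen=True)
class SceneObject:
    """One micro-object in a scene.

    kind
        ``opaque_disk`` — amplitude disk of radius ``radius`` with uniform
        transmittance inside;
        ``phase_sphere`` — sphere of radius ``radius`` and uniform index
        contrast ``delta_n``; its transmission is
        exp(i k delta_n * 2 sqrt(r^2 - rho^2)) (projected thickness);
        ``bar_target`` — one five-bar resolution element of line width
        ``line_width`` (bar length 5x width, gaps one width), oriented by
        ``orientation``.
    center
        (x, y) position in the object plane [m], origin on the optical axis.
    depth
        Distance z from the detector [m]; must lie in (0, f).
    """

    kind: str
    center: tuple[float, float]
    depth: float
    radius: float = 0.0
    line_width: float = 0.0
    amplitude_transmittance: float | None = None
    delta_n: float = 0.0
    orientation: str = "vertical"

    def __post_init__(self) -> None:
        if self.kind not in ("opaque_disk", "phase_sphere", "bar_target"):
            raise ValueError(f"unknown object kind {self.kind!r}")
        size = self.line_width if self.kind == "bar_target" else self.radius
        if size <= 0:
            raise ValueError("object size must be positive")
        if self.amplitude_transmittance is None:
            # opaque disks and bars absorb fully; phase spheres are transparent
            default = 1.0 if self.kind == "phase_sphere" else 0.0
            object.__setattr__(self, "amplitude_transmittance", default)
        if not 0.0 <= self.amplitude_transmittance <= 1.0:
            raise ValueError("amplitude_transmittance must be in [0, 1]")
        if self.orientation not in ("vertical", "horizontal"):
            raise ValueError("orientation must be 'vertical' or 'horizontal'")

    @property
    def extent_radius(self) -> float:
        """Circumscribing radius used for the overlap warning."""
        if self.kind == "bar_target":
            return 4.5 * self.line_width * np.sqrt(2.0)
        return self.radius


@dataclass
class Scene:
    """A set of micro-objects plus the instrument imaging them."""

    objects: list
    setup: OpticalSetup

    def __post_init__(self) -> None:
        f = self.setup.source_detector_distance
        for obj in self.objects:
            if not 0.0 < obj.depth < f:
                raise ValueError(
                    f"object depth {obj.depth} outside the source-detector gap (0, {f})"
                )
        self._warn_overlaps()

    def _warn_overlaps(self) -> None:
        by_depth: dict[float, list[SceneObject]] = {}
        for obj in self.objects:
            by_depth.setdefault(obj.depth, []).append(obj)
        for depth, group in by_depth.items():
            for i, a in enumerate(group):
                for b in group[i + 1 :]:
                    d = np.hypot(
                        a.center[0] - b.center[0], a.center[1] - b.center[1]
                    )
                    if d < a.extent_radius + b.extent_radius:
                        warnings.warn(
                            f"objects overlap within plane z={depth:g} m",
                            stacklevel=3,
                        )

    @property
    def depths(self) -> list[float]:
        """Distinct object depths, sorted source-side first (decreasing z)."""
        return sorted({o.depth for o in self.objects}, reverse=True)


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise description: shot noise level and quantization.

    photons_per_pixel
        Expected photon count for a pixel at the background intensity
        level; ``None`` disables shot noise.
    bit_depth
        Output quantization (8, 10 or 16); ``None`` disables quantization.
    seed
        Mandatory whenever shot noise is enabled.
    """

    photons_per_pixel: float | None = None
    bit_depth: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.photons_per_pixel is not None and self.photons_per_pixel <= 0:
            raise ValueError("photons_per_pixel must be positive")
        if self.bit_depth is not None and self.bit_depth not in (8, 10, 16):
            raise ValueError("bit_depth must be 8, 10 or 16")
        if self.photons_per_pixel is not None and self.seed is None:
            raise ValueError("a seed is mandatory for stochastic noise models")


def _grid_coords(rows: int, cols: int, pitch: float):
    """Centered physical coordinates of pixel centers; origin at (rows//2, cols//2)."""
    y = (np.arange(rows) - rows // 2) * pitch
    x = (np.arange(cols) - cols // 2) * pitch
    return y[:, None], x[None, :]


def _disk_coverage(rho: np.ndarray, radius: float, pitch: float) -> np.ndarray:
    # Fractional pixel coverage of a disk edge, linearised over one pitch.
    return np.clip((radius - rho) / pitch + 0.5, 0.0, 1.0)


def _interval_coverage(u: np.ndarray, edges, pitch: float) -> np.ndarray:
    """Fraction of each pixel (centre u, width pitch) covered by disjoint intervals."""
    cov = np.zeros_like(u)
    h = pitch / 2.0
    for a, b in edges:
        cov += np.clip(np.minimum(b, u + h) - np.maximum(a, u - h), 0.0, pitch)
    return cov / pitch


def _bar_element_map(
    obj: SceneObject, y: np.ndarray, x: np.ndarray, pitch: float, n_bars: int = 5
) -> np.ndarray:
    """Amplitude map (1 outside, transmittance inside bars) of one bar element."""
    w = obj.line_width
    cx, cy = obj.center
    if obj.orientation == "vertical":
        mod, par = x - cx, y - cy
    else:
        mod, par = y - cy, x - cx
    span = (2 * n_bars - 1) * w
    first = -span / 2.0
    edges = [(first + 2 * i * w, first + (2 * i + 1) * w) for i in range(n_bars)]
    cov_mod = _interval_coverage(mod + 0 * par, edges, pitch)
    length = 5.0 * w
    cov_par = _interval_coverage(
        par + 0 * mod, [(-length / 2.0, length / 2.0)], pitch
    )
    coverage = cov_mod * cov_par
    return 1.0 - coverage * (1.0 - obj.amplitude_transmittance)


def transmission_map(
    scene: Scene, z_plane: float, rows: int, cols: int, pitch: float
) -> np.ndarray:
    """Complex transmission t(x, y) of all scene objects lying at depth ``z_plane``.

    Objects multiply; a plane with no objects is all ones.  Disk and bar
    edges are rendered with fractional pixel coverage so sub-pixel size
    differences survive discretisation.
    """
    y, x = _grid_coords(rows, cols, pitch)
    t = np.ones((rows, cols), dtype=np.complex128)
    k = 2.0 * np.pi / scene.setup.wavelength
    for obj in scene.objects:
        if obj.depth != z_plane:
            continue
        if obj.kind == "opaque_disk":
            rho = np.hypot(x - obj.center[0], y - obj.center[1])
            cov = _disk_coverage(rho, obj.radius, pitch)
            t = t * (1.0 - cov * (1.0 - obj.amplitude_transmittance))
        elif obj.kind == "phase_sphere":
            rho = np.hypot(x - obj.center[0], y - obj.center[1])
            inside = rho < obj.radius
            thickness = np.where(
                inside,
                2.0 * np.sqrt(np.maximum(obj.radius**2 - rho**2, 0.0)),
                0.0,
            )
            phase = np.exp(1j * k * obj.delta_n * thickness)
            # transmittance below 1 adds uniform absorption over the disk
            cov = _disk_coverage(rho, obj.radius, pitch)
            amp = 1.0 - cov * (1.0 - obj.amplitude_transmittance)
            t = t * np.where(inside, phase, 1.0) * amp
        else:  # bar_target
            t = t * _bar_element_map(obj, y, x, pitch)
    return t


def _paraxial_point_source(
    rows: int,
    cols: int,
    pitch: float,
    wavelength: float,
    distance: float,
    offset: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    y, x = _grid_coords(rows, cols, pitch)
    k = 2.0 * np.pi / wavelength
    rho2 = (x - offset[0]) ** 2 + (y - offset[1]) ** 2
    return (1.0 / distance) * np.exp(1j * k * (distance + rho2 / (2.0 * distance)))


def _tilted_plane_wave(
    rows: int,
    cols: int,
    pitch: float,
    wavelength: float,
    travelled: float,
    tilt: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    y, x = _grid_coords(rows, cols, pitch)
    k = 2.0 * np.pi / wavelength
    ax, ay = tilt
    kx, ky = -k * ax, -k * ay
    kz = np.sqrt(max(k**2 - kx**2 - ky**2, 0.0))
    return np.exp(1j * (kx * x + ky * y + kz * travelled))


def spherical_illumination(
    setup: OpticalSetup,
    rows: int,
    cols: int,
    pitch: float,
    z_plane: float,
    kind: str = "spherical",
    source_offset: tuple[float, float] = (0.0, 0.0),
    wavelength: float | None = None,
) -> WaveField:
    """Incident wave at an object plane a distance ``z_plane`` before the detector.

    ``kind='spherical'`` gives the paraxial diverging wave of a point source
    at the setup's source-detector distance f (amplitude 1/d, phase
    k (d + rho^2 / 2d) with d = f - z_plane); ``kind='plane'`` gives a unit
    plane wave.  ``source_offset`` displaces the source point laterally
    (spherical) or tilts the plane wave by offset/f — the two descriptions
    blur an extended source identically at the object plane.
    """
    wl = setup.wavelength if wavelength is None else wavelength
    f = setup.source_detector_distance
    if not 0.0 < z_plane < f:
        raise ValueError("z_plane must lie strictly between detector and source")
    if kind == "plane":
        tilt = (source_offset[0] / f, source_offset[1] / f)
        amp = _tilted_plane_wave(rows, cols, pitch, wl, f - z_plane, tilt)
    elif kind == "spherical":
        amp = _paraxial_point_source(
            rows, cols, pitch, wl, f - z_plane, source_offset
        )
    else:
        raise ValueError("kind must be 'spherical' or 'plane'")
    return WaveField(amp, pitch, wl)


def _reference_at(
    setup: OpticalSetup,
    rows: int,
    cols: int,
    pitch: float,
    z_plane: float,
    illumination: str,
    source_offset: tuple[float, float],
    wavelength: float,
) -> np.ndarray:
    """Analytic unscattered reference wave at distance z_plane before the detector."""
    f = setup.source_detector_distance
    if illumination == "plane":
        tilt = (source_offset[0] / f, source_offset[1] / f)
        return _tilted_plane_wave(rows, cols, pitch, wavelength, f - z_plane, tilt)
    return _paraxial_point_source(
        rows, cols, pitch, wavelength, f - z_plane, source_offset
    )


def hologram_from_maps(
    maps: list[tuple[float, np.ndarray]],
    setup: OpticalSetup,
    illumination: str = "spherical",
    source_offset: tuple[float, float] = (0.0, 0.0),
    wavelength: float | None = None,
    aperture: str = "infinite",
    pad_to: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Detector intensity and background for explicit (depth, transmission) planes.

    Planes are traversed source-side first; at each one the field is
    multiplied by the plane's transmission and angular-spectrum propagated
    (zero-padded, i.e. aperiodic) to the next.  With the default
    ``aperture='infinite'`` the unscattered reference wave is carried
    analytically and only the compact scattered field is propagated
    numerically, so the illumination effectively extends beyond the grid.
    ``aperture='finite'`` instead propagates the full field truncated to the
    grid — the exact situation the brute-force integral oracle computes.

    Returns ``(intensity, background)`` as float arrays.
    """
    if not maps:
        raise ValueError("need at least one (depth, transmission) plane")
    wl = setup.wavelength if wavelength is None else wavelength
    pitch = setup.pixel_pitch
    maps = sorted(maps, key=lambda zt: -zt[0])
    rows, cols = maps[0][1].shape
    f = setup.source_detector_distance
    for z, _ in maps:
        if not 0.0 < z < f:
            raise ValueError("plane depth outside (0, f)")

    def ref(z):
        return _reference_at(
            setup, rows, cols, pitch, z, illumination, source_offset, wl
        )

    if aperture == "finite":
        field = WaveField(ref(maps[0][0]) * maps[0][1], pitch, wl)
        bg = WaveField(ref(maps[0][0]), pitch, wl)
        prev_z = maps[0][0]
        for z, t in maps[1:]:
            field = propagate(field, prev_z - z, pad=True, pad_to=pad_to)
            bg = propagate(bg, prev_z - z, pad=True, pad_to=pad_to)
            field = WaveField(field.amplitude * t, pitch, wl)
            prev_z = z
        u_det = propagate(field, prev_z, pad=True, pad_to=pad_to).amplitude
        b_det = propagate(bg, prev_z, pad=True, pad_to=pad_to).amplitude
        return np.abs(u_det) ** 2, np.abs(b_det) ** 2

    if aperture != "infinite":
        raise ValueError("aperture must be 'infinite' or 'finite'")

    scattered = np.zeros((rows, cols), dtype=np.complex128)
    prev_z = maps[0][0]
    for i, (z, t) in enumerate(maps):
        if i > 0:
            scattered = propagate(
                WaveField(scattered, pitch, wl), prev_z - z, pad=True, pad_to=pad_to
            ).amplitude
            scattered = scattered * t
        scattered = scattered + ref(z) * (t - 1.0)
        prev_z = z
    u_scat = propagate(
        WaveField(scattered, pitch, wl), prev_z, pad=True, pad_to=pad_to
    ).amplitude
    # reference at the detector plane itself (z = 0, source distance f)
    if illumination == "plane":
        tilt = (source_offset[0] / f, source_offset[1] / f)
        ref_det = _tilted_plane_wave(rows, cols, pitch, wl, f, tilt)
    else:
        ref_det = _paraxial_point_source(rows, cols, pitch, wl, f, source_offset)
    u_det = ref_det + u_scat
    return np.abs(u_det) ** 2, np.abs(ref_det) ** 2


def simulate_hologram(
    scene: Scene,
    rows: int,
    cols: int,
    illumination: str = "spherical",
    noise: NoiseModel | None = None,
    source_offset: tuple[float, float] = (0.0, 0.0),
    wavelength: float | None = None,
    aperture: str = "infinite",
    pad_to: int | None = None,
) -> Hologram:
    """Coherent hologram of a scene on a ``rows x cols`` detector grid.

    Builds the transmission map of every occupied depth plane, cascades
    multiply-and-propagate from the source side to the detector and records
    the intensity, together with the matching object-free background frame.
    Deterministic; shot noise/quantization are applied only when ``noise``
    is given (seeded).
    """
    pitch = scene.setup.pixel_pitch
    depths = scene.depths
    if depths:
        maps = [
            (z, transmission_map(scene, z, rows, cols, pitch)) for z in depths
        ]
    else:
        # empty scene: single pass-through plane mid-gap
        maps = [
            (
                scene.setup.object_detector_distance,
                np.ones((rows, cols), dtype=np.complex128),
            )
        ]
    intensity, background = hologram_from_maps(
        maps,
        scene.setup,
        illumination=illumination,
        source_offset=source_offset,
        wavelength=wavelength,
        aperture=aperture,
        pad_to=pad_to,
    )
    holo = Hologram(intensity, scene.setup, background)
    if noise is not None:
        holo = add_noise(holo, noise)
    return holo


def direct_integral_oracle(
    scene: Scene,
    rows: int,
    cols: int,
    pitch: float | None = None,
    illumination: str = "spherical",
    transmission: np.ndarray | None = None,
) -> Hologram:
    """Brute-force Fresnel-Kirchhoff double-sum hologram (reference implementation).

    Evaluates U_det(X, Y) = -(i/lambda) sum_xy U_in t exp(i k |r - R|)/|r - R|
    * pitch^2 with exact, non-paraxial distances, over the finite object
    grid.  Quadratic cost: grids above 64 per side are refused.  Only
    single-depth scenes are supported.  The background frame is the same
    sum with unit transmission (the finite illuminated aperture alone).
    ``transmission`` overrides the scene's rendered map (e.g. a pinhole
    screen, which scene objects cannot express); the scene then only
    provides the geometry and object depth.
    """
    if rows > _ORACLE_MAX_SIDE or cols > _ORACLE_MAX_SIDE:
        raise ValueError(
            f"oracle restricted to grids <= {_ORACLE_MAX_SIDE} per side"
        )
    pitch = scene.setup.pixel_pitch if pitch is None else pitch
    depths = scene.depths
    if len(depths) != 1:
        raise ValueError("oracle supports exactly one object plane")
    z = depths[0]
    wl = scene.setup.wavelength
    k = 2.0 * np.pi / wl
    f = scene.setup.source_detector_distance
    if transmission is not None:
        t = np.asarray(transmission, dtype=np.complex128)
        if t.shape != (rows, cols):
            raise ValueError("transmission override must match the grid shape")
    else:
        t = transmission_map(scene, z, rows, cols, pitch)
    y, x = _grid_coords(rows, cols, pitch)
    if illumination == "plane":
        u_in = np.exp(1j * k * (f - z)) * np.ones((rows, cols))
    elif illumination == "spherical":
        d = f - z
        r_src = np.sqrt(d**2 + x**2 + y**2)
        u_in = np.exp(1j * k * r_src) / r_src
    else:
        raise ValueError("illumination must be 'spherical' or 'plane'")

    def _sum(src: np.ndarray) -> np.ndarray:
        out = np.empty((rows, cols), dtype=np.complex128)
        yg = y + 0.0 * x  # broadcast object-plane coordinate grids
        xg = x + 0.0 * y
        for i in range(rows):
            dy2 = (yg - y[i, 0]) ** 2
            for j in range(cols):
                r = np.sqrt((xg - xg[0, j]) ** 2 + dy2 + z * z)
                out[i, j] = np.sum(src * np.exp(1j * k * r) / r)
        return (-1j / wl) * out * pitch**2

    u_det = _sum(u_in * t)
    b_det = _sum(u_in)
    return Hologram(np.abs(u_det) ** 2, scene.setup, np.abs(b_det) ** 2)


def _gauss_hermite_wavelengths(
    wavelength: float, fwhm: float, n: int
) -> list[tuple[float, float]]:
    """(wavelength, weight) samples of a Gaussian line; weights sum to 1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1 or fwhm == 0.0:
        return [(wavelength, 1.0)]
    nodes, weights = np.polynomial.hermite.hermgauss(n)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    weights = weights / weights.sum()
    return [
        (wavelength + np.sqrt(2.0) * sigma * t, float(w))
        for t, w in zip(nodes, weights)
    ]


def _source_disk_points(diameter: float, n: int) -> list[tuple[float, float]]:
    """Uniform-disk sample points (Vogel spiral); n=1 or zero diameter -> centre."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1 or diameter == 0.0:
        return [(0.0, 0.0)]
    radius = diameter / 2.0
    golden = np.pi * (3.0 - np.sqrt(5.0))
    pts = []
    for j in range(n):
        r = radius * np.sqrt((j + 0.5) / n)
        th = j * golden
        pts.append((r * np.cos(th), r * np.sin(th)))
    return pts


def apply_partial_coherence(
    scene: Scene,
    rows: int,
    cols: int,
    bandwidth: float | None = None,
    source_diameter: float | None = None,
    n_wavelengths: int = 7,
    n_source_points: int = 13,
    seed: int | None = None,
    illumination: str = "spherical",
    noise: NoiseModel | None = None,
    pad_to: int | None = None,
) -> Hologram:
    """Partially coherent hologram: incoherent average over source samples.

    The spectral line (FWHM ``bandwidth``, default the setup's) is sampled
    at Gauss-Hermite nodes; the source aperture (default the setup's
    diameter) at ``n_source_points`` uniform disk points, each displacing
    the point source or tilting the plane wave.  Intensities are averaged
    with the product weights.  With one wavelength, one source point and
    zero bandwidth/diameter the result is bit-identical to
    :func:`simulate_hologram`.  ``seed`` only feeds the optional noise
    model; the sampling itself is deterministic.
    """
    bw = scene.setup.bandwidth if bandwidth is None else bandwidth
    dia = (
        scene.setup.source_aperture_diameter
        if source_diameter is None
        else source_diameter
    )
    wavelengths = _gauss_hermite_wavelengths(scene.setup.wavelength, bw, n_wavelengths)
    points = _source_disk_points(dia, n_source_points)
    intensity = None
    background = None
    for wl, w_wl in wavelengths:
        for pt in points:
            h = simulate_hologram(
                scene,
                rows,
                cols,
                illumination=illumination,
                source_offset=pt,
                wavelength=wl,
                pad_to=pad_to,
            )
            w = w_wl / len(points)
            if len(wavelengths) == 1 and len(points) == 1:
                w = 1.0
            if intensity is None:
                intensity = w * h.intensity
                background = w * h.background
            else:
                intensity = intensity + w * h.intensity
                background = background + w * h.background
    holo = Hologram(intensity, scene.setup, background)
    if noise is not None:
        holo = add_noise(holo, noise)
    return holo


def synth_usaf_target(
    groups,
    rows: int,
    cols: int,
    pitch: float,
    n_bars: int = 5,
    margin_bars: float = 1.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a USAF-1951 style panel and its per-element ROI table.

    ``groups`` is a list of whole groups (ints: all six elements) and/or
    explicit ``(group, element)`` pairs / :class:`USAFElement` instances.
    Each element is drawn in both orientations side by side: ``n_bars``
    dark bars of one line width, separated by one width, bar length five
    widths.  Elements whose line width falls below 2x the pixel pitch are
    skipped with a warning and flagged unprintable in the table.

    Returns the complex amplitude map (1 background, 0 bars, anti-aliased
    edges) and a DataFrame with columns group, element, orientation,
    line_width, lp_per_mm, row0, col0, row1, col1, printable — boxes are
    half-open pixel bounds enclosing the bars plus ``margin_bars`` line
    widths of clear margin along the modulation axis.
    """
    elements: list[USAFElement] = []
    for g in groups:
        if isinstance(g, USAFElement):
            elements.append(g)
        elif isinstance(g, tuple):
            elements.append(USAFElement(*g))
        else:
            elements.extend(USAFElement(int(g), e) for e in range(1, 7))

    y, x = _grid_coords(rows, cols, pitch)
    panel = np.ones((rows, cols), dtype=np.complex128)
    records = []

    # column layout: vertical-bar patches left of centre, horizontal right
    span = lambda w: (2 * n_bars - 1) * w  # modulation extent of the bars
    gap = lambda w: 3.0 * w  # vertical spacing between element rows
    heights = [max(span(e_w), 5.0 * e_w) for e_w in map(usaf_line_width, elements)]
    widths_m = [usaf_line_width(e) for e in elements]
    total_h = sum(
        max(span(w), 5.0 * w) + gap(w) for w in widths_m
    ) - gap(widths_m[-1]) if elements else 0.0
    y_cursor = -total_h / 2.0
    col_offset = max(span(w) for w in widths_m) / 2.0 + 4.0 * max(widths_m) if elements else 0.0

    def _to_px(value: float, axis_len: int) -> int:
        return int(round(value / pitch)) + axis_len // 2

    for e, w in zip(elements, widths_m):
        printable = w >= 2.0 * pitch
        cell_h = max(span(w), 5.0 * w)
        cy = y_cursor + cell_h / 2.0
        for orientation, cx in (("vertical", -col_offset), ("horizontal", col_offset)):
            if printable:
                obj = SceneObject(
                    kind="bar_target",
                    center=(cx, cy),
                    depth=1.0,  # placeholder depth; map is depth-agnostic
                    line_width=w,
                    amplitude_transmittance=0.0,
                    orientation=orientation,
                )
                panel *= _bar_element_map(obj, y, x, pitch, n_bars=n_bars)
            if orientation == "vertical":
                half_mod = span(w) / 2.0 + margin_bars * w
                half_par = 5.0 * w / 2.0
                row0 = _to_px(cy - half_par, rows)
                row1 = _to_px(cy + half_par, rows)
                c0 = _to_px(cx - half_mod, cols)
                c1 = _to_px(cx + half_mod, cols)
            else:
                half_mod = span(w) / 2.0 + margin_bars * w
                half_par = 5.0 * w / 2.0
                row0 = _to_px(cy - half_mod, rows)
                row1 = _to_px(cy + half_mod, rows)
                c0 = _to_px(cx - half_par, cols)
                c1 = _to_px(cx + half_par, cols)
            records.append(
                {
                    "group": e.group,
                    "element": e.element,
                    "orientation": orientation,
                    "line_width": w,
                    "lp_per_mm": usaf_spatial_frequency(e),
                    "row0": row0,
                    "col0": c0,
                    "row1": row1,
                    "col1": c1,
                    "printable": printable,
                }
            )
        if not printable:
            warnings.warn(
                f"USAF group {e.group} element {e.element} line width "
                f"{w:.3e} m below 2x pitch; skipped",
                stacklevel=2,
            )
        y_cursor += cell_h + gap(w)

    table = pd.DataFrame.from_records(records)
    return panel, table


def add_noise(holo: Hologram, noise: NoiseModel | None) -> Hologram:
    """Apply seeded shot noise and/or quantization to a hologram.

    Shot noise: intensities are scaled so the background mean corresponds
    to ``photons_per_pixel`` expected photons, Poisson-sampled and scaled
    back (background gets an independent substream).  Quantization rounds
    to 2**bit_depth levels over the frame maximum.  ``None`` or an empty
    model returns the hologram unchanged.
    """
    if noise is None or (
        noise.photons_per_pixel is None and noise.bit_depth is None
    ):
        return holo
    intensity = holo.intensity.copy()
    background = None if holo.background is None else holo.background.copy()
    if noise.photons_per_pixel is not None:
        if noise.seed is None:
            raise ValueError("a seed is mandatory for stochastic noise models")
        ref = (
            background.mean() if background is not None else intensity.mean()
        )
        scale = noise.photons_per_pixel / ref
        rng = np.random.default_rng(noise.seed)
        intensity = rng.poisson(intensity * scale).astype(np.float64) / scale
        if background is not None:
            rng_b = np.random.default_rng(noise.seed + 1)
            background = (
                rng_b.poisson(background * scale).astype(np.float64) / scale
            )
    if noise.bit_depth is not None:
        levels = 2**noise.bit_depth - 1

        def _quantize(img: np.ndarray) -> np.ndarray:
            peak = img.max()
            if peak == 0:
                return img
            return np.round(img / peak * levels) / levels * peak

        intensity = _quantize(intensity)
        if background is not None:
            background = _quantize(background)
    return Hologram(intensity, holo.setup, background)


def canonical_fixtures(setup_ld: OpticalSetup, setup_led: OpticalSetup) -> dict:
    """Canonical synthetic scenes: microsphere-like disks, cell-like phase
    spheres, a two-depth scene and a USAF panel, for the laser and LED arms.

    Returns a dict name -> Scene (the USAF panel is generated separately by
    :func:`synth_usaf_target` since it is a full-plane map).
    """
    s = setup_ld.object_detector_distance
    pms = [
        SceneObject("opaque_disk", (0.0, 0.0), s, radius=3.25e-6,
                    amplitude_transmittance=0.0),
        SceneObject("opaque_disk", (35e-6, -20e-6), s, radius=3.25e-6,
                    amplitude_transmittance=0.0),
    ]
    rbc = [
        SceneObject("phase_sphere", (0.0, 0.0), s, radius=4.0e-6,
                    amplitude_transmittance=1.0, delta_n=RBC_LIKE_DN),
        SceneObject("phase_sphere", (-30e-6, 25e-6), s, radius=4.0e-6,
                    amplitude_transmittance=1.0, delta_n=RBC_LIKE_DN),
    ]
    two_depth = [
        SceneObject("opaque_disk", (-25e-6, 0.0), s, radius=3.25e-6,
                    amplitude_transmittance=0.0),
        SceneObject("opaque_disk", (25e-6, 0.0), s + 1.5e-3, radius=4.0e-6,
                    amplitude_transmittance=0.0),
    ]
    return {
        "pms_ld": Scene(pms, setup_ld),
        "pms_led": Scene(pms, setup_led),
        "rbc_ld": Scene(rbc, setup_ld),
        "rbc_led": Scene(rbc, setup_led),
        "two_depth_ld": Scene(two_depth, setup_ld),
    }
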