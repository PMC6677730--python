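"""Scalar-diffraction engine: angular-spectrum propagation and hologram reconstruction.

Free-space propagation of a sampled complex field is done with the angular
spectrum method: Fourier transform the field, multiply by the transfer
function

    H(f_x, f_y) = exp(i z sqrt(k^2 - 4 pi^2 (f_x^2 + f_y^2))),   k = 2 pi / lambda,

and transform back.  Spatial frequencies beyond 1/lambda (evanescent waves)
are set to zero: at the millimetre propagation distances of lens-less
holography they decay within nanometres and carry no usable signal.

Reconstruction works on the background-subtracted hologram contrast
I - B (linear in-line approximation): back-propagating the real contrast
image by the recording distance refocuses the object; the conjugate (twin)
image remains as a defocused background, which these instruments accept.

Sign convention: the optical axis points from the source (large z) through
the object to the detector (z = 0).  ``propagate(field, d)`` with d > 0
moves the field a distance d downstream (towards and past the detector);
reconstruction therefore propagates by -z.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import scipy.fft as sfft

from .optics_design import OpticalSetup

__all__ = [
    "WaveField",
    "Hologram",
    "ReconPlane",
    "ReconStack",
    "angular_spectrum_kernel",
    "propagate",
    "preprocess",
    "effective_geometry",
    "reconstruct",
    "reconstruct_stack",
    "focus_metric",
    "autofocus",
]


@dataclass
class WaveField:
    """Complex scalar field sampled on a uniform grid.

    Attributes
    ----------
    amplitude : ndarray, complex, shape (rows, cols)
    pixel_pitch : float
        Sample spacing [m], identical in both directions.
    wavelength : float
        Vacuum wavelength [m].
    """

    amplitude: np.ndarray
    pixel_pitch: float
    wavelength: float

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=np.complex128)
        if self.amplitude.ndim != 2 or min(self.amplitude.shape) < 2:
            raise ValueError("amplitude must be a 2-D grid with sides >= 2")
        if self.pixel_pitch <= 0 or self.wavelength <= 0:
            raise ValueError("pixel_pitch and wavelength must be positive")

    @property
    def wavenumber(self) -> float:
        return 2.0 * np.pi / self.wavelength

    @property
    def energy(self) -> float:
        """Total power proxy sum(|U|^2) (grid sum, not area-weighted)."""
        return float(np.sum(np.abs(self.amplitude) ** 2))


@dataclass
class Hologram:
    """Recorded intensity image plus the instrument that produced it.

    ``background`` is an optional object-free reference frame of the same
    shape (flat-field); reconstruction subtracts it when present.
    """

    intensity: np.ndarray
    setup: OpticalSetup
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2-D grid")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and nonnegative")
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=np.float64)
            if self.background.shape != self.intensity.shape:
                raise ValueError(
                    "background shape "
                    f"{self.background.shape} != intensity shape "
                    f"{self.intensity.shape}"
                )
            if not np.all(np.isfinite(self.background)) or np.any(
                self.background < 0
            ):
                raise ValueError("background must be finite and nonnegative")


@dataclass(frozen=True)
class ReconPlane:
    """One refocused plane: depth plus amplitude/phase/intensity images."""

    z: float
    amplitude: np.ndarray
    phase: np.ndarray
    intensity: np.ndarray


@dataclass
class ReconStack:
    """Reconstructions of one hologram at strictly increasing depths."""

    planes: list[ReconPlane] = dataclass_field(default_factory=list)

    def __post_init__(self) -> None:
        zs = [p.z for p in self.planes]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("plane depths must be strictly increasing")
        shapes = {p.amplitude.shape for p in self.planes}
        if len(shapes) > 1:
            raise ValueError("all planes must share one image shape")

    def __len__(self) -> int:
        return len(self.planes)

    def __iter__(self):
        return iter(self.planes)

    @property
    def zs(self) -> np.ndarray:
        return np.array([p.z for p in self.planes])


def angular_spectrum_kernel(
    rows: int, cols: int, pitch: float, wavelength: float, z: float
) -> np.ndarray:
    """Angular-spectrum transfer function on the discrete frequency grid.

    Frequencies are f = m / (n * pitch) (cycles per metre, FFT ordering).
    Evanescent components, where k^2 < 4 pi^2 (f_x^2 + f_y^2), are set to
    exactly 0; every propagating component has unit modulus.
    """
    if pitch <= 0 or wavelength <= 0:
        raise ValueError("pitch and wavelength must be positive")
    if rows < 2 or cols < 2:
        raise ValueError("grid must be at least 2x2")
    return _kernel_cached(rows, cols, pitch, wavelength, z, False).copy()


@functools.lru_cache(maxsize=8)
def _kernel_cached(
    rows: int, cols: int, pitch: float, wavelength: float, z: float, bandlimit: bool
) -> np.ndarray:
    # identical kernels recur heavily in z-sweeps and coherence averaging
    fy = sfft.fftfreq(rows, d=pitch)
    fx = sfft.fftfreq(cols, d=pitch)
    k = 2.0 * np.pi / wavelength
    arg = k**2 - 4.0 * np.pi**2 * (fy[:, None] ** 2 + fx[None, :] ** 2)
    propagating = arg >= 0.0
    kz = np.sqrt(np.where(propagating, arg, 0.0))
    kernel = np.where(propagating, np.exp(1j * z * kz), 0.0 + 0.0j)
    if bandlimit and z != 0.0:
        fmax_y = 1.0 / (
            wavelength * np.sqrt((2.0 * abs(z) / (rows * pitch)) ** 2 + 1.0)
        )
        fmax_x = 1.0 / (
            wavelength * np.sqrt((2.0 * abs(z) / (cols * pitch)) ** 2 + 1.0)
        )
        kernel = kernel * (
            (np.abs(fy[:, None]) <= fmax_y) & (np.abs(fx[None, :]) <= fmax_x)
        )
    kernel.setflags(write=False)
    return kernel


def propagate(
    field: WaveField, z: float, pad: bool = False, pad_to: int | None = None
) -> WaveField:
    """Propagate a field a signed distance ``z`` downstream.

    With ``pad=False`` (default) the convolution is circular on the given
    grid — exact for band-limited periodic fields and energy-conserving.
    With ``pad=True`` the grid is zero-padded (to at least twice its size,
    or to ``pad_to`` per side) before propagation and cropped back, which
    makes the result the *linear* diffraction of the finite-support input;
    use this when the field is an isolated aperture rather than a periodic
    sample.  On the padded grid the transfer function is additionally
    band-limited to the frequencies its discrete phase can represent
    without aliasing (|f| <= 1 / (lambda sqrt((2 df z)^2 + 1)) per axis),
    which suppresses the wraparound artifacts of long-distance kernels;
    enlarge ``pad_to`` until the retained band covers the content of
    interest.
    """
    a = field.amplitude
    rows, cols = a.shape
    if pad:
        prows = sfft.next_fast_len(max(2 * rows, pad_to or 0))
        pcols = sfft.next_fast_len(max(2 * cols, pad_to or 0))
        buf = np.zeros((prows, pcols), dtype=np.complex128)
        r0 = (prows - rows) // 2
        c0 = (pcols - cols) // 2
        buf[r0 : r0 + rows, c0 : c0 + cols] = a
        kern = _kernel_cached(
            prows, pcols, field.pixel_pitch, field.wavelength, z, True
        )
        out = sfft.ifft2(sfft.fft2(buf) * kern)
        out = out[r0 : r0 + rows, c0 : c0 + cols]
    else:
        kern = _kernel_cached(
            rows, cols, field.pixel_pitch, field.wavelength, z, False
        )
        out = sfft.ifft2(sfft.fft2(a) * kern)
    return WaveField(out, field.pixel_pitch, field.wavelength)


def preprocess(holo: Hologram) -> WaveField:
    """Turn a hologram into the real-valued contrast field used for reconstruction.

    With a background frame: (I - B), shifted to zero mean and scaled to
    unit maximum absolute value.  Without one the mean intensity stands in
    for the background: (I - mean(I)).  The result carries the setup's
    pixel pitch and wavelength.
    """
    if holo.background is not None:
        d = holo.intensity - holo.background
        d = d - d.mean()
        peak = np.max(np.abs(d))
        if peak > 0:
            d = d / peak
    else:
        d = holo.intensity - holo.intensity.mean()
    return WaveField(
        d.astype(np.complex128),
        holo.setup.pixel_pitch,
        holo.setup.wavelength,
    )


def effective_geometry(setup: OpticalSetup) -> tuple[float, float]:
    """Point-source/plane-wave equivalence for an object at the setup's s.

    A point source at distance f magnifies the hologram of an object at
    object-detector distance s by M = f/(f-s); the same hologram is produced
    by plane-wave illumination of the object at the effective distance
    z_eff = s (f - s) / f with the detector pitch divided by M.

    Returns
    -------
    (z_eff, magnification)
    """
    f = setup.source_detector_distance
    s = setup.object_detector_distance
    if not 0 < s < f:
        raise ValueError("requires 0 < s < f")
    m = f / (f - s)
    z_eff = s * (f - s) / f
    return z_eff, m


def _point_source_mapping(setup: OpticalSetup, z: float) -> tuple[float, float]:
    # Effective distance / magnification for an object at depth z (not
    # necessarily the setup's nominal s).
    f = setup.source_detector_distance
    if not 0 < z < f:
        raise ValueError("object depth must satisfy 0 < z < f")
    m = f / (f - z)
    return z * (f - z) / f, m


def reconstruct(
    holo: Hologram,
    z: float,
    use_effective_geometry: bool = False,
    mode: str = "contrast",
) -> ReconPlane:
    """Refocus a hologram at object-detector distance ``z`` (> 0).

    ``mode='contrast'`` (default) back-propagates the background-subtracted
    contrast image: objects appear bright on a dark background.
    ``mode='brightfield'`` back-propagates the reference-normalised
    hologram I/B (or I/mean(I) without a background frame) as a whole, so
    the unscattered wave travels with the scattered field and keeps its
    relative phase; absorbing objects appear dark on a bright unit
    background, as in conventional transmission microscopy, and the
    defocused twin image perturbs that bright baseline additively instead
    of multiplying the object contrast.

    With ``use_effective_geometry=True`` the point-source fringe
    magnification M = f/(f-z) is taken into account: back-propagation runs
    over z_eff = z (f-z)/f with the pixel pitch divided by M, so the
    returned images are sampled at p/M in true object-plane coordinates.

    Returns a :class:`ReconPlane` with |U|, arg(U) and |U|^2.
    """
    if z <= 0:
        raise ValueError("reconstruction distance z must be positive")
    if mode == "contrast":
        field = preprocess(holo)
    elif mode == "brightfield":
        ref = (
            holo.background
            if holo.background is not None
            else holo.intensity.mean()
        )
        d = holo.intensity / np.maximum(ref, np.finfo(float).tiny)
        field = WaveField(
            d.astype(np.complex128),
            holo.setup.pixel_pitch,
            holo.setup.wavelength,
        )
    else:
        raise ValueError("mode must be 'contrast' or 'brightfield'")
    if use_effective_geometry:
        z_eff, m = _point_source_mapping(holo.setup, z)
        field = WaveField(
            field.amplitude,
            field.pixel_pitch / m,
            field.wavelength,
        )
        u = propagate(field, -z_eff)
    else:
        u = propagate(field, -z)
    amplitude = np.abs(u.amplitude)
    return ReconPlane(
        z=z,
        amplitude=amplitude,
        phase=np.angle(u.amplitude),
        intensity=amplitude**2,
    )


def reconstruct_stack(
    holo: Hologram,
    z_values,
    use_effective_geometry: bool = False,
    mode: str = "contrast",
) -> ReconStack:
    """Reconstruct one hologram at each depth of a strictly increasing list."""
    z_values = list(z_values)
    if not z_values:
        raise ValueError("z_values must be non-empty")
    if any(b <= a for a, b in zip(z_values, z_values[1:])):
        raise ValueError("z_values must be strictly increasing")
    if z_values[0] <= 0:
        raise ValueError("all z values must be positive")
    planes = [
        reconstruct(holo, z, use_effective_geometry, mode) for z in z_values
    ]
    return ReconStack(planes)


def focus_metric(image: np.ndarray) -> float:
    """Normalized variance sharpness score: var(I) / mean(I)^2.

    Higher means sharper.  Scale-invariant under multiplication by a
    positive constant; zero for a constant image.  A simple, robust
    autofocus criterion for amplitude images; alternatives (Tamura
    coefficient, gradient energy) can be swapped in behind the same
    contract.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("image must be non-empty")
    mean = image.mean()
    if mean == 0:
        raise ValueError("focus metric undefined for zero-mean (all-zero) image")
    return float(image.var() / mean**2)


def autofocus(
    holo: Hologram,
    z_min: float,
    z_max: float,
    steps: int = 25,
    use_effective_geometry: bool = False,
    refine_tol: float = 1e-7,
) -> float:
    """Find the sharpest reconstruction depth in [z_min, z_max].

    Coarse grid search of :func:`focus_metric` over ``steps`` depths,
    followed by golden-section refinement inside the best bracket.  The
    coarse pass scores the reconstructed *intensity*, whose fourth-moment
    weighting keeps the focused spot ahead of the residual fringe field at
    strong defocus; the refinement scores the *amplitude*, whose variance
    peaks at the geometric plane without the intensity metric's
    axial-resolution-scale side peaks.  If the coarse optimum lies on the
    window boundary, a warning is issued and the boundary value returned —
    the true focus is probably outside the window.  Deterministic:
    identical inputs give identical output.
    """
    if not 0 < z_min < z_max:
        raise ValueError("need 0 < z_min < z_max")
    if steps < 3:
        raise ValueError("steps must be >= 3")

    def score_coarse(z: float) -> float:
        return focus_metric(reconstruct(holo, z, use_effective_geometry).intensity)

    def score(z: float) -> float:
        return focus_metric(reconstruct(holo, z, use_effective_geometry).amplitude)

    zs = np.linspace(z_min, z_max, steps)
    scores = [score_coarse(z) for z in zs]
    best = int(np.argmax(scores))
    if best in (0, steps - 1):
        warnings.warn(
            "autofocus optimum at search-window boundary; "
            "true focus may lie outside [z_min, z_max]",
            stacklevel=2,
        )
        return float(zs[best])

    # Golden-section maximisation inside the bracketing neighbours.
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = float(zs[best - 1]), float(zs[best + 1])
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = score(c), score(d)
    while b - a > refine_tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = score(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = score(d)
    return float((a + b) / 2.0)
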