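"""Closed-form optical design calculators for lens-less in-line holography.

A digital inline holographic microscope (DIHM) has no imaging lens: a point-like
source (laser-coupled fibre facet or an LED behind a pinhole) illuminates the
sample and a bare CMOS detector records the interference between scattered and
unscattered light.  Its achievable resolution is therefore fixed entirely by the
geometry (source-detector distance ``f``, object-detector distance ``s``),
the detector (``N`` pixels of pitch ``p``) and the illumination (wavelength
``lambda``, bandwidth ``delta_lambda``).  This module collects the standard
closed forms that connect those numbers:

* lateral resolution, as a numerical-aperture bound ``lambda / (2 NA)`` and in
  its pixel-grid form ``s * lambda / (N p)``,
* the object distance that maximises lateral resolution,
* axial resolution ``2 s^2 lambda / (N p)^2``,
* temporal coherence length of a Gaussian spectral line,
* Gaussian (TEM00) beam geometry: Rayleigh length and 1/e^2 diameter,
* USAF-1951 three-bar target arithmetic (spatial frequency and line width).

All lengths are SI metres unless a function name says otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "OpticalSetup",
    "GaussianBeam",
    "USAFElement",
    "lateral_resolution_from_na",
    "lateral_resolution",
    "numerical_aperture",
    "optimal_object_distance",
    "axial_resolution",
    "coherence_length",
    "rayleigh_length",
    "beam_diameter",
    "usaf_spatial_frequency",
    "usaf_line_width",
    "field_of_view",
    "design_report",
    "LASER_SETUP",
    "LED_SETUP",
]


@dataclass(frozen=True)
class OpticalSetup:
    """Geometry and illumination of one lens-less in-line holographic instrument.

    Parameters
    ----------
    wavelength : float
        Centre emission wavelength lambda [m].
    source_detector_distance : float
        Distance f between source (fibre facet / pinhole) and detector [m].
    object_detector_distance : float
        Distance s between the sample plane and the detector [m]; 0 < s < f.
    pixel_count : int
        Number of detector pixels N along the side used for reconstruction.
    pixel_pitch : float
        Detector pixel pitch p [m].
    bandwidth : float, optional
        FWHM spectral width delta-lambda [m]; 0 for a laser-like line.
    source_aperture_diameter : float, optional
        Pinhole diameter or fibre mode-field diameter [m]; 0 for an ideal point.
    """

    wavelength: float
    source_detector_distance: float
    object_detector_distance: float
    pixel_count: int
    pixel_pitch: float
    bandwidth: float = 0.0
    source_aperture_diameter: float = 0.0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.bandwidth < 0:
            raise ValueError("bandwidth must be >= 0")
        if not 0 < self.object_detector_distance < self.source_detector_distance:
            raise ValueError(
                "object_detector_distance must satisfy 0 < s < f "
                f"(got s={self.object_detector_distance}, "
                f"f={self.source_detector_distance})"
            )
        if int(self.pixel_count) != self.pixel_count or self.pixel_count < 2:
            raise ValueError("pixel_count must be an integer >= 2")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.source_aperture_diameter < 0:
            raise ValueError("source_aperture_diameter must be >= 0")

    @property
    def detector_side(self) -> float:
        """Detector side length N*p [m]."""
        return self.pixel_count * self.pixel_pitch


@dataclass(frozen=True)
class GaussianBeam:
    """Fundamental TEM00 Gaussian beam described by waist radius and wavelength.

    ``waist_radius`` is w0, the 1/e^2 intensity *radius* at the waist; a fibre
    data sheet usually quotes the mode-field *diameter* 2*w0.
    """

    waist_radius: float
    wavelength: float

    def __post_init__(self) -> None:
        if self.waist_radius <= 0:
            raise ValueError("waist_radius must be positive")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")


@dataclass(frozen=True)
class USAFElement:
    """One element of a USAF-1951 three-bar resolution target."""

    group: int
    element: int

    def __post_init__(self) -> None:
        if int(self.group) != self.group:
            raise ValueError("group must be an integer")
        if self.element not in (1, 2, 3, 4, 5, 6):
            raise ValueError("element must be in 1..6")


def lateral_resolution_from_na(wavelength: float, na: float) -> float:
    """Diffraction-limited lateral resolution lambda / (2 NA).

    ``na`` is the numerical aperture of the recording geometry (for a
    lens-less instrument: half detector width over object distance).
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if not 0 < na <= 1:
        raise ValueError("numerical aperture must be in (0, 1]")
    return wavelength / (2.0 * na)


def numerical_aperture(setup: OpticalSetup) -> float:
    """Recording NA of a lens-less setup: (N*p/2) / s (small-angle form)."""
    return setup.detector_side / 2.0 / setup.object_detector_distance


def lateral_resolution(setup: OpticalSetup) -> float:
    """Pixel-grid lateral resolution s * lambda / (N p).

    Equivalent to ``lateral_resolution_from_na`` with NA = (N p / 2) / s: the
    detector edge bounds the highest fringe angle the hologram can record.
    """
    return (
        setup.object_detector_distance
        * setup.wavelength
        / setup.detector_side
    )


def optimal_object_distance(
    f: float, wavelength: float, pixel_count: int, pixel_pitch: float
) -> float:
    """Object-detector distance maximising lateral resolution.

    s_opt = f / (1 + f*lambda / (N p^2)).  Closer objects give a larger
    recording NA, but their fringes eventually become finer than the pixel
    grid can sample; s_opt balances the two.  The result is strictly
    between 0 and f.
    """
    if f <= 0 or wavelength <= 0 or pixel_pitch <= 0:
        raise ValueError("f, wavelength and pixel_pitch must be positive")
    if int(pixel_count) != pixel_count or pixel_count < 1:
        raise ValueError("pixel_count must be a positive integer")
    return f / (1.0 + f * wavelength / (pixel_count * pixel_pitch**2))


def axial_resolution(setup: OpticalSetup) -> float:
    """Axial (depth) resolution 2 s^2 lambda / (N p)^2 = lambda / (2 NA^2)."""
    s = setup.object_detector_distance
    return 2.0 * s * s * setup.wavelength / setup.detector_side**2


def coherence_length(wavelength: float, bandwidth: float) -> float:
    """Temporal coherence length lambda^2 / (pi * delta_lambda).

    ``bandwidth`` is the FWHM of a Gaussian spectral line.  A zero bandwidth
    (ideal monochromatic source) returns ``math.inf`` rather than raising:
    laser-like configurations are legitimate inputs.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if bandwidth < 0:
        raise ValueError("bandwidth must be >= 0")
    if bandwidth == 0:
        return math.inf
    return wavelength**2 / (math.pi * bandwidth)


def rayleigh_length(beam: GaussianBeam) -> float:
    """Rayleigh length z_r = pi * w0^2 / lambda."""
    return math.pi * beam.waist_radius**2 / beam.wavelength


def beam_diameter(beam: GaussianBeam, z: float) -> float:
    """1/e^2 intensity beam diameter 2 w0 sqrt(1 + (z/z_r)^2) at distance z from the waist."""
    if z < 0:
        raise ValueError("z must be >= 0")
    zr = rayleigh_length(beam)
    return 2.0 * beam.waist_radius * math.sqrt(1.0 + (z / zr) ** 2)


def usaf_spatial_frequency(e: USAFElement) -> float:
    """Spatial frequency of a USAF-1951 element in line pairs per mm.

    The chart follows the standard progression 2**(group + (element-1)/6);
    each element step is a sixth of an octave.
    """
    return 2.0 ** (e.group + (e.element - 1) / 6.0)


def usaf_line_width(e: USAFElement) -> float:
    """Width of a single bar of a USAF-1951 element, in metres.

    One line pair = one dark + one bright bar, so the line width is half the
    line-pair period: 1 / (2 * frequency), with frequency in lp/mm.
    """
    return 1e-3 / (2.0 * usaf_spatial_frequency(e))


def field_of_view(setup: OpticalSetup) -> float:
    """Side length of the object-plane field of view, N*p*(f-s)/f [m].

    Under point-source illumination the hologram is magnified by
    M = f/(f-s) about the source axis, so the detector of side N*p sees
    an object-plane window of side N*p/M = N*p*(f-s)/f.
    """
    return (
        setup.detector_side
        * (setup.source_detector_distance - setup.object_detector_distance)
        / setup.source_detector_distance
    )


#: Reference Blu-ray laser-diode arm: 405 nm fibre-coupled source
#: (3.3 um mode-field diameter), f = 30 mm, object at s = 5.91 mm,
#: Raspberry Pi camera sensor side of 2464 pixels at 1.12 um pitch.
LASER_SETUP = OpticalSetup(
    wavelength=405e-9,
    source_detector_distance=30e-3,
    object_detector_distance=5.91e-3,
    pixel_count=2464,
    pixel_pitch=1.12e-6,
    bandwidth=0.0,
    source_aperture_diameter=3.3e-6,
)

#: Reference LED arm: 430 nm high-power LED (15 nm FWHM) behind a 15 um
#: pinhole, same geometry and detector as the laser arm.
LED_SETUP = OpticalSetup(
    wavelength=430e-9,
    source_detector_distance=30e-3,
    object_detector_distance=5.91e-3,
    pixel_count=2464,
    pixel_pitch=1.12e-6,
    bandwidth=15e-9,
    source_aperture_diameter=15e-6,
)


def design_report(setup: OpticalSetup, beam: GaussianBeam | None = None) -> dict:
    """Summarise the resolution theory of one instrument as a flat dict (SI units).

    Includes lateral and axial resolution, the optimal object distance,
    coherence length, recording NA and field of view; if ``beam`` is given,
    also the Rayleigh length and 1/e^2 beam diameters at the object and
    detector planes.
    """
    rep = {
        "wavelength": setup.wavelength,
        "bandwidth": setup.bandwidth,
        "source_detector_distance": setup.source_detector_distance,
        "object_detector_distance": setup.object_detector_distance,
        "pixel_count": setup.pixel_count,
        "pixel_pitch": setup.pixel_pitch,
        "numerical_aperture": numerical_aperture(setup),
        "lateral_resolution": lateral_resolution(setup),
        "axial_resolution": axial_resolution(setup),
        "optimal_object_distance": optimal_object_distance(
            setup.source_detector_distance,
            setup.wavelength,
            setup.pixel_count,
            setup.pixel_pitch,
        ),
        "coherence_length": coherence_length(setup.wavelength, setup.bandwidth),
        "field_of_view": field_of_view(setup),
    }
    if beam is not None:
        rep["rayleigh_length"] = rayleigh_length(beam)
        rep["beam_diameter_at_object"] = beam_diameter(
            beam,
            setup.source_detector_distance - setup.object_detector_distance,
        )
        rep["beam_diameter_at_detector"] = beam_diameter(
            beam, setup.source_detector_distance
        )
    return rep
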