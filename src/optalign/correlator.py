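"""Simulated Vander-Lugt optical correlation with a phase-only filter.

The correlator computes ``c = IFFT2(FFT2(scene) * H)`` where ``H`` is a
filter built from the object image: the classical matched filter (CMF)
``H = conj(G)`` or the phase-only filter (POF) ``H = conj(G) / |G|``, ``G``
being the object's 2-D Fourier transform.  The decision variable is the
magnitude of the correlation plane; its global maximum ("peak") encodes
match strength, and the peak coordinate encodes the object's position in
the scene.

Conventions (fixed, and load-bearing for any absolute threshold):

* forward FFT unnormalized, inverse divided by W*H (numpy default);
* circular (wraparound) correlation -- no linear-correlation zero padding;
  boundary spanning is handled by scene overlap instead;
* no fftshift: peak (0, 0) means zero displacement;
* peak ties break to the smallest row, then smallest column.

Because the raster is row-major, a match whose start column falls in the
second half of a row splits its correlation energy between rows ``r`` and
``r + 1``; when the majority of the object's bases wrap past the row end,
the dominant peak lands one row low and the estimated start is exactly
``width`` bases beyond the true one.  ``Detection.shift_flag`` marks that
condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .codec import ObjectImage, SceneImage

__all__ = [
    "CorrelationPlane",
    "Peak",
    "Detection",
    "pof",
    "matched_filter",
    "correlate",
    "find_peak",
    "detect",
    "search",
    "scene_spectra",
    "batch_peaks",
]

_EPS = 1e-12


@dataclass
class CorrelationPlane:
    """Magnitude of the inverse-transformed scene x filter product."""

    values: np.ndarray
    scene_index: int = 0


@dataclass
class Peak:
    intensity: float
    row: int
    col: int


@dataclass
class Detection:
    """Presence decision for one object-scene correlation.

    ``est_start_base`` is the database coordinate implied by the peak,
    ``db_offset + row * width + col`` (minus ``width`` when
    ``shift_correct`` was requested and the shift condition fired).
    """

    present: bool
    peak: Peak
    est_start_base: int
    shift_flag: bool
    scene_index: int = 0


def _object_frame(obj: ObjectImage, frame_width: int, frame_height: int) -> np.ndarray:
    if obj.width > frame_width or obj.height > frame_height:
        raise ValueError(
            f"object ({obj.height}x{obj.width}) does not fit the "
            f"{frame_height}x{frame_width} frame"
        )
    canvas = np.zeros((frame_height, frame_width), dtype=float)
    canvas[: obj.height, : obj.width] = obj.pixels
    return canvas


def pof(obj: ObjectImage, frame_width: int, frame_height: int) -> np.ndarray:
    """Phase-only filter of an object zero-padded into a frame.

    Returns ``conj(G) / |G|`` elementwise, with entries where ``|G| = 0``
    set to 0; ``|POF|`` is therefore 1 on the support of ``G`` and 0 off it.
    An all-zero object yields an all-zero filter (with a warning), never NaN.
    """
    G = np.fft.fft2(_object_frame(obj, frame_width, frame_height))
    mag = np.abs(G)
    out = np.zeros_like(G)
    nz = mag > _EPS
    if not nz.any():
        warnings.warn("all-zero object image: phase-only filter is identically zero")
        return out
    out[nz] = np.conj(G[nz]) / mag[nz]
    return out


def matched_filter(obj: ObjectImage, frame_width: int, frame_height: int) -> np.ndarray:
    """Classical matched filter ``conj(G)`` of the zero-padded object."""
    return np.conj(np.fft.fft2(_object_frame(obj, frame_width, frame_height)))


def correlate(scene: SceneImage, filt: np.ndarray) -> CorrelationPlane:
    """Circular frequency-domain correlation of a scene against a filter.

    ``plane = |IFFT2(FFT2(scene) * filt)|``; same dimensions as the scene.
    """
    if filt.shape != scene.pixels.shape:
        raise ValueError(
            f"filter shape {filt.shape} does not match scene shape {scene.pixels.shape}"
        )
    spectrum = np.fft.fft2(scene.pixels.astype(float))
    plane = np.abs(np.fft.ifft2(spectrum * filt))
    return CorrelationPlane(plane, scene_index=scene.scene_index)


def find_peak(plane: CorrelationPlane | np.ndarray) -> Peak:
    """Global maximum of the correlation plane.

    Ties break to the smallest row, then the smallest column (the first
    maximum in row-major order).
    """
    values = plane.values if isinstance(plane, CorrelationPlane) else plane
    if values.size == 0:
        raise ValueError("empty correlation plane")
    flat = int(np.argmax(values))
    row, col = divmod(flat, values.shape[1])
    return Peak(intensity=float(values[row, col]), row=row, col=col)


def _make_detection(
    peak: Peak,
    scene: SceneImage,
    threshold: float,
    shift_correct: bool,
) -> Detection:
    shift_flag = peak.col >= scene.width / 2
    est = scene.db_offset + peak.row * scene.width + peak.col
    if shift_correct and shift_flag:
        est -= scene.width
    return Detection(
        present=peak.intensity > threshold,
        peak=peak,
        est_start_base=est,
        shift_flag=bool(shift_flag),
        scene_index=scene.scene_index,
    )


def detect(
    scene: SceneImage,
    obj: ObjectImage,
    threshold: float,
    shift_correct: bool = False,
) -> Detection:
    """Full object-in-scene decision: POF -> correlate -> peak -> threshold.

    The object is present iff the peak intensity exceeds ``threshold``.
    ``shift_flag`` marks a start column in the second half of a row (the
    regime where the peak may land one row low, i.e. ``width`` bases past
    the true start); with ``shift_correct=True`` one row is subtracted from
    the estimate when flagged.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    filt = pof(obj, scene.width, scene.height)
    peak = find_peak(correlate(scene, filt))
    return _make_detection(peak, scene, threshold, shift_correct)


def search(
    scenes: list[SceneImage],
    obj: ObjectImage,
    threshold: float,
    shift_correct: bool = False,
) -> list[Detection]:
    """Correlate one object against every scene of a tiled database.

    The scenes must have been tiled with ``overlap >= object length`` so no
    occurrence can span a scene boundary uncovered.  Returns one Detection
    per scene, in scene order.  In overlap regions the same database start
    can be hit from two scenes; such duplicates are resolved by
    ``est_start_base``, keeping the higher-intensity hit present and
    demoting the other.
    """
    if not scenes:
        return []
    first = scenes[0]
    if len(scenes) > 1:
        stride = scenes[1].db_offset - scenes[0].db_offset
        overlap = first.capacity - stride
        if overlap < obj.length:
            raise ValueError(
                f"scene overlap ({overlap}) is smaller than the object length "
                f"({obj.length}); occurrences could span a scene boundary"
            )
    filt = pof(obj, first.width, first.height)
    detections = [
        _make_detection(find_peak(correlate(s, filt)), s, threshold, shift_correct)
        for s in scenes
    ]
    best: dict[int, Detection] = {}
    for d in detections:
        if not d.present:
            continue
        kept = best.get(d.est_start_base)
        if kept is None or d.peak.intensity > kept.peak.intensity:
            if kept is not None:
                kept.present = False
            best[d.est_start_base] = d
        else:
            d.present = False
    return detections


def scene_spectra(scenes: list[SceneImage]) -> np.ndarray:
    """Stacked 2-D FFTs of the scenes, shape ``(n_scenes, H, W)``.

    Precomputing the scene spectra once lets a benchmark correlate many
    objects against the whole tiling with one filter FFT plus one batched
    inverse FFT per object.
    """
    stack = np.stack([s.pixels.astype(float) for s in scenes])
    return np.fft.fft2(stack, axes=(-2, -1))


def batch_peaks(spectra: np.ndarray, filt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Peak intensity and coordinates of one filter against stacked spectra.

    Returns ``(intensities, rows, cols)``, each of length ``n_scenes``,
    with the same tie-break as :func:`find_peak`.
    """
    planes = np.abs(np.fft.ifft2(spectra * filt, axes=(-2, -1)))
    n, h, w = planes.shape
    flat = planes.reshape(n, h * w)
    idx = np.argmax(flat, axis=1)
    return flat[np.arange(n), idx], idx // w, idx % w
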