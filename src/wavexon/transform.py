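"""Signal transforms: period-3 band-pass, multilevel DWT, energy profile,
adaptive denoising, normalization.

Coding DNA carries excess spectral power at angular frequency 2*pi/3 (one
cycle per codon). The pipeline first sharpens that component with a narrow
zero-phase band-pass, then takes a Coiflet-5 level-2 discrete wavelet
transform; the 2*pi/3 band falls inside the level-1 detail sub-band at unit
sampling rate, so squared detail coefficients, mapped back to sequence
positions, form a per-base "coding energy" profile. Peaks of the smoothed,
normalized profile mark candidate exons.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .errors import DegenerateInputError, ValidationError
from .types import NumericSignal, WaveletDecomposition

PERIOD3_OMEGA = 2.0 * math.pi / 3.0


# ---------------------------------------------------------------------------
# band-pass


@dataclass(frozen=True)
class BandpassSpec:
    """Zero-phase band-pass around the codon frequency.

    center_frequency and bandwidth are in radians/sample; the pass-band
    edges sit at center_frequency +- bandwidth. ``order`` is the overall
    filter order (an order-4 IIR band-pass = two biquad sections).
    """

    center_frequency: float = PERIOD3_OMEGA
    bandwidth: float = 0.04 * math.pi
    order: int = 4
    design: str = "resonator_iir"

    def __post_init__(self) -> None:
        if not (0.0 < self.center_frequency < math.pi):
            raise ValidationError("center_frequency must lie in (0, pi)")
        if self.bandwidth <= 0.0:
            raise ValidationError("bandwidth must be positive")
        if self.order < 2 or self.order % 2:
            raise ValidationError("order must be a positive even integer")
        if self.design not in ("resonator_iir", "fir_window"):
            raise ValidationError(f"unknown band-pass design {self.design!r}")

    @property
    def band(self) -> tuple[float, float]:
        """Pass-band edges as fractions of the Nyquist frequency."""
        lo = (self.center_frequency - self.bandwidth) / math.pi
        hi = (self.center_frequency + self.bandwidth) / math.pi
        if not (0.0 < lo < hi < 1.0):
            raise ValidationError("pass band falls outside (0, Nyquist)")
        return lo, hi


def bandpass_period3(sig: NumericSignal, spec: BandpassSpec | None = None) -> NumericSignal:
    """Enhance the period-3 component with a zero-phase band-pass.

    Filtering is applied forward and backward (filtfilt), so the output has
    the same length as the input and spectral peaks are not shifted in
    position; the effective magnitude response is the square of the design's.
    """
    if spec is None:
        spec = BandpassSpec()
    if sig.stage != "eiip":
        raise ValidationError(f"bandpass_period3 expects stage 'eiip', got {sig.stage!r}")
    x = sig.values - np.mean(sig.values) if len(sig) else sig.values
    lo, hi = spec.band
    if spec.design == "resonator_iir":
        sos = sps.butter(spec.order // 2, [lo, hi], btype="bandpass", output="sos")
        padlen = 3 * (2 * sos.shape[0] + 1)
        if len(sig) <= padlen:
            raise ValidationError(
                f"signal of length {len(sig)} too short for zero-phase filtering "
                f"(needs > {padlen} samples)"
            )
        y = sps.sosfiltfilt(sos, x)
    else:
        ntaps = spec.order + 1 if spec.order % 2 == 0 else spec.order
        b = sps.firwin(ntaps, [lo, hi], pass_zero=False)
        padlen = 3 * ntaps
        if len(sig) <= padlen:
            raise ValidationError(
                f"signal of length {len(sig)} too short for zero-phase filtering "
                f"(needs > {padlen} samples)"
            )
        y = sps.filtfilt(b, [1.0], x)
    return NumericSignal(sig.sequence_id, y, stage="bandpassed")


# ---------------------------------------------------------------------------
# DWT


def dwt_decompose(
    sig: NumericSignal,
    wavelet_name: str = "coif5",
    levels: int = 2,
    boundary_mode: str = "symmetric",
) -> WaveletDecomposition:
    """Multilevel discrete wavelet transform (Mallat cascade).

    Stores everything needed for perfect reconstruction. ``levels`` deeper
    than the signal supports raises :class:`ValidationError`.
    """
    try:
        wavelet = pywt.Wavelet(wavelet_name)
    except ValueError as exc:
        raise ValidationError(f"unknown wavelet {wavelet_name!r}") from exc
    if levels < 1:
        raise ValidationError("levels must be >= 1")
    max_level = pywt.dwt_max_level(len(sig), wavelet.dec_len)
    if levels > max_level:
        raise ValidationError(
            f"signal of length {len(sig)} supports at most {max_level} "
            f"level(s) of {wavelet_name} (support {wavelet.dec_len}); got {levels}"
        )
    coeffs = pywt.wavedec(sig.values, wavelet, mode=boundary_mode, level=levels)
    approx, detail_coarse_to_fine = coeffs[0], coeffs[1:]
    return WaveletDecomposition(
        sequence_id=sig.sequence_id,
        wavelet_name=wavelet_name,
        levels=levels,
        approx=np.asarray(approx, dtype=float),
        details=[np.asarray(d, dtype=float) for d in reversed(detail_coarse_to_fine)],
        boundary_mode=boundary_mode,
        original_length=len(sig),
    )


def dwt_reconstruct(decomp: WaveletDecomposition) -> np.ndarray:
    """Invert :func:`dwt_decompose` exactly (up to float round-off)."""
    coeffs = [decomp.approx] + list(reversed(decomp.details))
    x = pywt.waverec(coeffs, decomp.wavelet_name, mode=decomp.boundary_mode)
    return x[: decomp.original_length]


# ---------------------------------------------------------------------------
# energy profile


@functools.lru_cache(maxsize=32)
def _band_shifts(wavelet_name: str, boundary_mode: str, levels: int) -> dict[str, int]:
    """Per-band coefficient->position shifts, calibrated by an impulse probe.

    For a unit impulse at position p, the energy of band-j coefficients
    centres on index c with 2**j * c - p constant across p; that constant is
    the shift to subtract when spreading coefficient energy back onto
    sequence coordinates. It differs between detail (wavelet) and
    approximation (scaling) bands, so it is measured, not derived.
    """
    wavelet = pywt.Wavelet(wavelet_name)
    n = max(512, wavelet.dec_len * 2 ** (levels + 2))
    p = n // 2
    x = np.zeros(n)
    x[p] = 1.0
    coeffs = pywt.wavedec(x, wavelet, mode=boundary_mode, level=levels)
    shifts: dict[str, int] = {}
    bands = [("approx", coeffs[0], levels)] + [
        (f"d{levels - i}", coeffs[1 + i], levels - i) for i in range(levels)
    ]
    for name, c, j in bands:
        e = c**2
        centroid = float(np.sum(e * np.arange(len(c))) / np.sum(e))
        shifts[name] = int(round(2**j * centroid - p))
    return shifts


def _spread_band(c: np.ndarray, level: int, shift: int, n: int) -> np.ndarray:
    """Spread per-coefficient energy uniformly over its 2**level support."""
    stride = 2**level
    up = np.repeat(c**2 / stride, stride)
    out = np.zeros(n)
    start = -shift  # position of coefficient 0
    src_lo = max(0, -start)
    dst_lo = max(0, start)
    span = min(len(up) - src_lo, n - dst_lo)
    if span > 0:
        out[dst_lo : dst_lo + span] = up[src_lo : src_lo + span]
    return out


def energy_profile(
    decomp: WaveletDecomposition,
    source: str = "detail_levels",
    smooth_window: int = 9,
) -> NumericSignal:
    """Per-position energy from selected sub-bands of a decomposition.

    Each coefficient's squared magnitude is spread uniformly over the 2**j
    input positions it summarises (after alignment calibration, see
    :func:`_band_shifts`), the selected sub-bands are summed, and the result
    is smoothed with a centred moving-average window. Output length equals
    the original sequence length; all values are >= 0.

    source: ``detail_levels`` (all detail bands — the default, since the
    band-passed 2*pi/3 component lives there), ``approx``, or ``all``.
    """
    if source not in ("detail_levels", "approx", "all"):
        raise ValidationError(f"unknown energy source {source!r}")
    if smooth_window < 1:
        raise ValidationError("smooth_window must be a positive integer")
    n = decomp.original_length
    shifts = _band_shifts(decomp.wavelet_name, decomp.boundary_mode, decomp.levels)
    profile = np.zeros(n)
    if source in ("detail_levels", "all"):
        for j, d in enumerate(decomp.details, start=1):
            profile += _spread_band(d, j, shifts[f"d{j}"], n)
    if source in ("approx", "all"):
        profile += _spread_band(decomp.approx, decomp.levels, shifts["approx"], n)
    if smooth_window > 1 and n:
        profile = uniform_filter1d(profile, size=smooth_window, mode="nearest")
    return NumericSignal(decomp.sequence_id, np.maximum(profile, 0.0), stage="energy")


# ---------------------------------------------------------------------------
# adaptive denoising


@dataclass(frozen=True)
class DenoiseSpec:
    """Pluggable noise-reduction step applied to the energy profile.

    moving_average: centred window of ``window`` positions (odd).
    lms_canceller:  normalised-LMS adaptive line enhancer; the reference is
                    the profile delayed by ``delay`` samples, so the filter
                    output keeps the predictable (slowly varying / periodic)
                    component and drops broadband noise. 0 < mu < 1.
    wavelet_shrink: soft universal-threshold shrinkage of detail
                    coefficients (VisuShrink, MAD noise estimate).
    """

    method: str = "moving_average"
    window: int = 51
    mu: float = 0.05
    filter_order: int = 16
    delay: int = 1
    threshold_rule: str = "universal"
    shrink_wavelet: str = "sym8"

    def __post_init__(self) -> None:
        if self.method not in ("moving_average", "lms_canceller", "wavelet_shrink"):
            raise ValidationError(f"unknown denoise method {self.method!r}")
        if self.window < 1 or self.window % 2 == 0:
            raise ValidationError("window must be a positive odd integer")
        if not (0.0 < self.mu < 1.0):
            raise ValidationError("mu must lie in (0, 1)")
        if self.filter_order < 1 or self.delay < 1:
            raise ValidationError("filter_order and delay must be positive")
        if self.threshold_rule != "universal":
            raise ValidationError(f"unknown threshold_rule {self.threshold_rule!r}")


def _nlms_line_enhance(x: np.ndarray, mu: float, order: int, delay: int) -> np.ndarray:
    scale = float(np.max(np.abs(x))) or 1.0
    xs = x / scale
    n = len(xs)
    w = np.zeros(order)
    y = np.zeros(n)
    eps = 1e-8
    for i in range(n):
        lo = i - delay - order + 1
        ref = xs[max(lo, 0) : i - delay + 1][::-1] if i - delay >= 0 else np.empty(0)
        if len(ref) < order:
            ref = np.concatenate([ref, np.zeros(order - len(ref))])
        y[i] = float(w @ ref)
        err = xs[i] - y[i]
        w += (mu / (eps + float(ref @ ref))) * err * ref
    return y * scale


def adaptive_denoise(profile: NumericSignal, spec: DenoiseSpec | None = None) -> NumericSignal:
    """Reduce noise in an energy profile; output is non-negative, same length."""
    if spec is None:
        spec = DenoiseSpec()
    if profile.stage != "energy":
        raise ValidationError(
            f"adaptive_denoise expects stage 'energy', got {profile.stage!r}"
        )
    x = profile.values
    if spec.method == "moving_average":
        y = uniform_filter1d(x, size=spec.window, mode="nearest") if len(x) else x
    elif spec.method == "lms_canceller":
        y = _nlms_line_enhance(x, spec.mu, spec.filter_order, spec.delay)
    else:  # wavelet_shrink
        level = min(4, pywt.dwt_max_level(len(x), pywt.Wavelet(spec.shrink_wavelet).dec_len))
        if level < 1:
            y = x.copy()
        else:
            coeffs = pywt.wavedec(x, spec.shrink_wavelet, mode="symmetric", level=level)
            sigma = float(np.median(np.abs(coeffs[-1]))) / 0.6745
            thr = sigma * math.sqrt(2.0 * math.log(max(len(x), 2)))
            coeffs = [coeffs[0]] + [pywt.threshold(d, thr, "soft") for d in coeffs[1:]]
            y = pywt.waverec(coeffs, spec.shrink_wavelet, mode="symmetric")[: len(x)]
    return NumericSignal(profile.sequence_id, np.maximum(y, 0.0), stage="denoised")


def normalize_profile(profile: NumericSignal) -> NumericSignal:
    """Scale a profile by its maximum so thresholds live on a [0, 1] scale."""
    if profile.stage not in ("energy", "denoised"):
        raise ValidationError(
            f"normalize_profile expects an energy/denoised profile, got {profile.stage!r}"
        )
    peak = float(np.max(profile.values)) if len(profile) else 0.0
    if peak <= 0.0:
        raise DegenerateInputError(
            f"sequence {profile.sequence_id!r}: all-zero energy profile cannot be normalized"
        )
    return NumericSignal(profile.sequence_id, profile.values / peak, stage="normalized")
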