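"""Spectral characterisation of simulated fields.

Spatial periodograms (radially averaged on the torus), angular fold-symmetry
scores (stripes vs hexagons), temporal periodograms with peak picking, and
beat-frequency extraction (carrier-difference and analytic-envelope
estimators).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, hilbert, periodogram

from .grid import GridSpec

#: peaks must rise above this fraction of the maximum power
PEAK_PROMINENCE_FRACTION = 0.05
#: fraction of a simulated record discarded as transient before analysis
TRANSIENT_FRACTION = 0.20


@dataclass
class SpectrumResult:
    """One-sided power spectrum with ranked peaks.

    ``abscissa`` is in rad/cm for spatial spectra and Hz for temporal ones;
    ``resolution`` is the bin width (one over the record length).  Peaks are
    sorted by descending power.
    """

    abscissa: np.ndarray
    power: np.ndarray
    peaks: list = field(default_factory=list)   # [(location, power), ...]
    resolution: float = 0.0

    @property
    def dominant(self) -> float:
        if self.peaks:
            return self.peaks[0][0]
        return float(self.abscissa[np.argmax(self.power)])


def _rank_peaks(x: np.ndarray, p: np.ndarray) -> list:
    if p.size < 3 or np.max(p) <= 0:
        return []
    idx, _ = find_peaks(p, prominence=PEAK_PROMINENCE_FRACTION * np.max(p))
    order = idx[np.argsort(p[idx])[::-1]]
    return [(float(x[i]), float(p[i])) for i in order]


def spatial_spectrum(values: np.ndarray, grid: GridSpec) -> SpectrumResult:
    """Radially averaged spatial periodogram over torus wavenumbers.

    The field mean is removed first.  Power is binned onto the radial
    wavenumber axis with bin width 2*pi/(N h) (the fundamental of the
    longest axis); the total binned power equals the spatial variance.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("field does not match grid")
    centred = values - values.mean()
    F = np.fft.fftn(centred)
    P = (np.abs(F) ** 2) / centred.size**2
    axes_q = [grid.wavenumbers(a) for a in range(grid.ndim)]
    if grid.ndim == 1:
        qmag = np.abs(axes_q[0])
    else:
        qmag = np.sqrt(axes_q[0][:, None] ** 2 + axes_q[1][None, :] ** 2)
    dq = 2.0 * np.pi / max(grid.side_lengths)
    nbins = int(np.ceil(qmag.max() / dq)) + 1
    which = np.rint(qmag / dq).astype(int).ravel()
    power = np.bincount(which, weights=P.ravel(), minlength=nbins)
    q_axis = dq * np.arange(nbins)
    peaks = _rank_peaks(q_axis, power)
    if not peaks and power.size:                      # monotone spectra
        k = int(np.argmax(power))
        peaks = [(float(q_axis[k]), float(power[k]))]
    return SpectrumResult(q_axis, power, peaks, resolution=dq)


def angular_modes(values: np.ndarray, grid: GridSpec,
                  q_band: tuple[float, float],
                  half_width_deg: float = 20.0) -> dict:
    """Fold-symmetry scores of the annulus power in an orientation window.

    The 2-D spectrum restricted to ``q_band`` (rad/cm) is resolved in
    orientation theta in [0, pi) (a real field has point-symmetric spectra,
    so opposite wavevectors are folded together).  Both scores are
    baseline-corrected: the fraction of annulus power a window would catch
    from an isotropic field is subtracted and the remainder rescaled, so an
    isotropic texture scores near 0.  Scores in [0, 1]:

    * ``two_fold``: excess concentration in a single orientation window --
      near 1 for a single plane wave, near 0 for hexagons and noise.
    * ``six_fold``: balanced occupation of three windows 60 degrees apart
      (three times the smallest window fraction, baseline-corrected) --
      near 1 for three equal waves at 120 degrees, near 0 for a single
      wave.
    """
    values = np.asarray(values, dtype=float)
    if grid.ndim != 2:
        raise ValueError("angular mode analysis requires a 2-D field")
    if values.shape != grid.shape:
        raise ValueError("field does not match grid")
    centred = values - values.mean()
    F = np.fft.fftn(centred)
    P = (np.abs(F) ** 2) / centred.size**2
    qx = grid.wavenumbers(0)[:, None]
    qy = grid.wavenumbers(1)[None, :]
    qmag = np.sqrt(qx**2 + qy**2)
    theta = np.mod(np.arctan2(qy, qx), np.pi)
    sel = (qmag >= q_band[0]) & (qmag <= q_band[1])
    total = float(P[sel].sum())
    if total <= 0:
        return {"two_fold": 0.0, "six_fold": 0.0, "annulus_power": 0.0}
    th = theta[sel]
    pw = P[sel]
    half = np.deg2rad(half_width_deg)

    def window_frac(centre: float) -> float:
        d = np.abs(np.mod(th - centre + np.pi / 2, np.pi) - np.pi / 2)
        return float(pw[d <= half].sum()) / total

    cover = 2.0 * half_width_deg / 180.0  # isotropic single-window fraction
    centres = np.deg2rad(np.arange(0.0, 180.0, 2.0))
    raw_two = max(window_frac(c) for c in centres)
    two = max(0.0, (raw_two - cover) / (1.0 - cover))
    raw_six = 0.0
    for c in np.deg2rad(np.arange(0.0, 60.0, 2.0)):
        fr = [window_frac(c + k * np.pi / 3.0) for k in range(3)]
        raw_six = max(raw_six, 3.0 * min(fr))
    six = max(0.0, (raw_six - 3.0 * cover) / (1.0 - 3.0 * cover))
    return {"two_fold": min(two, 1.0), "six_fold": min(six, 1.0),
            "annulus_power": total}


def temporal_spectrum(series: np.ndarray, dt: float, window: str = "hann",
                      target_frequency: float | None = None) -> SpectrumResult:
    """Windowed one-sided periodogram of a uniformly sampled series.

    Peaks are local maxima with prominence above 5% of the maximum power.
    With ``target_frequency`` given, the record must be at least 10 periods
    long; otherwise an error reports the achievable resolution.
    """
    series = np.asarray(series, dtype=float)
    n = series.size
    if n < 4:
        raise ValueError("series too short for spectral analysis")
    record = n * dt
    if target_frequency is not None and record < 10.0 / target_frequency:
        raise ValueError(
            f"record of {record:.3g} s resolves only down to "
            f"{10.0 / record:.3g} Hz at 10 periods; "
            f"requested {target_frequency:.3g} Hz"
        )
    freqs, power = periodogram(series, fs=1.0 / dt, window=window,
                               detrend="constant")
    return SpectrumResult(freqs, power, _rank_peaks(freqs, power),
                          resolution=1.0 / record)


@dataclass
class BeatEstimate:
    """Beat frequency by two estimators (they should agree within a bin)."""

    carrier_difference_hz: float   # spacing of the two strongest peaks
    envelope_peak_hz: float        # dominant peak of the amplitude envelope
    resolution_hz: float
    carriers_hz: tuple[float, float] = (0.0, 0.0)


def beat_frequency(series: np.ndarray, dt: float) -> BeatEstimate:
    """Beat (envelope) frequency of an oscillatory record.

    Estimator (i): difference of the two strongest periodogram peaks.
    Estimator (ii): dominant spectral peak of the analytic-signal amplitude
    envelope.  Raises when fewer than two carrier peaks stand above the
    noise floor.
    """
    series = np.asarray(series, dtype=float)
    spec = temporal_spectrum(series, dt)
    if len(spec.peaks) < 2:
        raise ValueError("no beat: fewer than two spectral peaks found")
    (f1, _), (f2, _) = spec.peaks[:2]
    centred = series - series.mean()
    env = np.abs(hilbert(centred))
    env_spec = temporal_spectrum(env - env.mean(), dt)
    # the beat envelope is by construction slower than the carriers, so the
    # search is restricted below half the lower carrier (an anharmonic
    # carrier leaks its own frequency into the Hilbert envelope otherwise)
    f_cut = 0.5 * min(f1, f2)
    slow = [(f, p) for f, p in env_spec.peaks if 0.0 < f < f_cut]
    if slow:
        f_env = max(slow, key=lambda fp: fp[1])[0]
    elif env_spec.peaks:
        f_env = env_spec.peaks[0][0]
    else:
        nz = env_spec.abscissa > 0
        f_env = float(env_spec.abscissa[nz][np.argmax(env_spec.power[nz])])
    return BeatEstimate(
        carrier_difference_hz=abs(f1 - f2),
        envelope_peak_hz=f_env,
        resolution_hz=spec.resolution,
        carriers_hz=(min(f1, f2), max(f1, f2)),
    )


def settled(series_or_states: np.ndarray,
            fraction: float = TRANSIENT_FRACTION) -> np.ndarray:
    """Drop the leading transient fraction of a simulated record."""
    n = np.asarray(series_or_states).shape[0]
    return np.asarray(series_or_states)[int(np.floor(fraction * n)):]
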