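"""Spectral estimation: Welch power spectra, segment-wise phase coherence,
time-shift conversion, significance thresholding and peak tracking.

Phase coherence between two signals is the resultant length of unit-
normalized per-segment cross-spectrum phasors,

    C(f) = | (1/K) sum_k S_xy,k(f) / |S_xy,k(f)| |,

with segments pooled across trials.  The resultant angle is the mean phase
lag Delta-phi(f), converted to a time shift Delta-tau = Delta-phi / (2 pi f).
Sign convention: positive time shift means the *first* signal leads.  For K
independent segments of unrelated signals the expected chance level is
sqrt(pi) / (2 sqrt(K)); significance is defined as exceeding four times the
band-averaged coherence of an uncoupled baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

__all__ = [
    "PSDResult",
    "CoherenceResult",
    "PeakSummary",
    "welch_psd",
    "phase_coherence",
    "time_shift",
    "chance_level",
    "coherence_threshold",
    "track_peaks",
]


@dataclass
class PSDResult:
    freqs: np.ndarray
    power: np.ndarray
    n_segments: int
    window: str

    def peak_frequency(self, band: tuple[float, float] | None = None) -> float:
        """Frequency of maximum power, optionally restricted to a band."""
        sel = np.ones(len(self.freqs), bool)
        if band is not None:
            sel = (self.freqs >= band[0]) & (self.freqs <= band[1])
        idx = np.flatnonzero(sel)
        return float(self.freqs[idx[np.argmax(self.power[idx])]])


@dataclass
class CoherenceResult:
    freqs: np.ndarray
    coherence: np.ndarray
    phase: np.ndarray  # mean phase lag in (-pi, pi]
    time_shift_ms: np.ndarray
    n_segments: int
    excluded: int = 0
    threshold: float | None = None

    @property
    def significant(self) -> np.ndarray:
        if self.threshold is None:
            raise ValueError("no significance threshold attached")
        return self.coherence > self.threshold

    def at(self, f: float) -> tuple[float, float, float]:
        """(coherence, phase, time shift) at the bin nearest ``f``."""
        i = int(np.argmin(np.abs(self.freqs - f)))
        return float(self.coherence[i]), float(self.phase[i]), float(self.time_shift_ms[i])


@dataclass
class PeakSummary:
    """Power-spectrum gamma peak and significant coherence maxima."""

    f_lfp: float
    gamma_extent: tuple[float, float]
    f_coherence: list[float] = field(default_factory=list)

    @property
    def gamma_period_ms(self) -> float:
        return 1000.0 / self.f_lfp


def _as_trials(x) -> list[np.ndarray]:
    from .observables import SignalTrace

    if isinstance(x, SignalTrace):
        return [np.asarray(x.values, float)]
    x0 = x[0] if len(x) else None
    if isinstance(x0, SignalTrace):
        return [np.asarray(t.values, float) for t in x]
    arr = np.asarray(x, float)
    if arr.ndim == 1:
        return [arr]
    return [row for row in arr]


def _infer_fs(x, fs):
    from .observables import SignalTrace

    if fs is not None:
        return float(fs)
    if isinstance(x, SignalTrace):
        return x.fs
    if len(x) and isinstance(x[0], SignalTrace):
        return x[0].fs
    raise ValueError("fs must be given for plain arrays")


def welch_psd(
    x, fs: float | None = None, nperseg: int = 1000, overlap: float = 0.5,
    window: str = "hamming",
) -> PSDResult:
    """Welch power spectral density with Hamming-windowed, 50%-overlapping
    segments, averaged over segments of all supplied trials."""
    trials = _as_trials(x)
    fs = _infer_fs(x, fs)
    if min(len(t) for t in trials) < nperseg:
        raise ValueError(f"signal shorter than nperseg={nperseg}")
    noverlap = int(round(nperseg * overlap))
    powers = []
    n_seg = 0
    for t in trials:
        f, p = scipy.signal.welch(
            t, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap,
            detrend="constant",
        )
        powers.append(p)
        n_seg += 1 + (len(t) - nperseg) // (nperseg - noverlap)
    return PSDResult(freqs=f, power=np.mean(powers, axis=0), n_segments=n_seg, window=window)


def _segment_ffts(x: np.ndarray, nperseg: int, noverlap: int) -> np.ndarray:
    """Hamming-windowed, demeaned rFFTs of overlapping segments (rows)."""
    step = nperseg - noverlap
    n_seg = 1 + (len(x) - nperseg) // step
    win = np.hamming(nperseg)
    segs = np.empty((n_seg, nperseg))
    for k in range(n_seg):
        s = x[k * step : k * step + nperseg]
        segs[k] = (s - s.mean()) * win
    return np.fft.rfft(segs, axis=1)


def phase_coherence(
    x, y, fs: float | None = None, nperseg: int = 1000, overlap: float = 0.5,
) -> CoherenceResult:
    """Resultant length and mean angle of per-segment cross-spectrum phasors.

    ``x`` and ``y`` may be single signals or matched collections of trials;
    segments are pooled across trials before averaging.  Segment-frequency
    bins with an exactly zero cross-spectrum are excluded from the average
    (their count is reported in ``excluded``).
    """
    xt, yt = _as_trials(x), _as_trials(y)
    fs = _infer_fs(x, fs)
    if len(xt) != len(yt):
        raise ValueError("x and y must have the same number of trials")
    noverlap = int(round(nperseg * overlap))
    phasor_sum = None
    counts = None
    n_seg = 0
    for tx, ty in zip(xt, yt):
        if len(tx) != len(ty):
            raise ValueError("paired trials must have equal length")
        X = _segment_ffts(tx, nperseg, noverlap)
        Y = _segment_ffts(ty, nperseg, noverlap)
        sxy = X * np.conj(Y)
        mag = np.abs(sxy)
        ok = mag > 0
        unit = np.where(ok, sxy / np.where(ok, mag, 1.0), 0.0)
        if phasor_sum is None:
            phasor_sum = unit.sum(axis=0)
            counts = ok.sum(axis=0)
        else:
            phasor_sum += unit.sum(axis=0)
            counts += ok.sum(axis=0)
        n_seg += X.shape[0]
    if n_seg < 2:
        raise ValueError("phase coherence needs at least two segments")
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    counts = np.maximum(counts, 1)
    mean_phasor = phasor_sum / counts
    coh = np.abs(mean_phasor)
    phase = np.angle(mean_phasor)
    excluded = int(n_seg * len(freqs) - counts.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = time_shift(phase, freqs)
    return CoherenceResult(
        freqs=freqs, coherence=coh, phase=phase, time_shift_ms=shift,
        n_segments=n_seg, excluded=excluded,
    )


def time_shift(dphi, f):
    """Convert a phase lag to a time shift in ms: ``dphi / (2 pi f) * 1000``.

    ``dphi`` is wrapped to (-pi, pi] first; positive shift = first signal
    leads.  At f = 0 the shift is undefined and returned as 0.
    """
    dphi = np.asarray(dphi, float)
    f = np.asarray(f, float)
    wrapped = np.angle(np.exp(1j * dphi))
    # np.angle maps pi to pi but -pi to -pi; fold -pi onto +pi
    wrapped = np.where(np.isclose(wrapped, -np.pi), np.pi, wrapped)
    out = np.where(f > 0, wrapped / (2.0 * np.pi * np.where(f > 0, f, 1.0)) * 1000.0, 0.0)
    return out if out.ndim else float(out)


def chance_level(K: int) -> float:
    """Expected resultant length of K uniformly random unit phasors."""
    return float(np.sqrt(np.pi) / (2.0 * np.sqrt(K)))


def coherence_threshold(
    baseline: CoherenceResult, band: tuple[float, float] = (30.0, 80.0), factor: float = 4.0
) -> float:
    """Significance threshold: ``factor`` times the band-averaged coherence of
    an uncoupled (coupling-off) baseline."""
    sel = (baseline.freqs >= band[0]) & (baseline.freqs <= band[1])
    if not np.any(sel):
        raise ValueError("baseline does not cover the requested band")
    return float(factor * baseline.coherence[sel].mean())


def track_peaks(
    psd: PSDResult,
    coh: CoherenceResult | None,
    band: tuple[float, float] = (30.0, 80.0),
    threshold: float | None = None,
) -> PeakSummary:
    """Locate the power-spectrum gamma peak and significant coherence maxima.

    ``f_lfp`` is the in-band argmax of power; the peak extent is the
    contiguous region around it above half of the peak's prominence over the
    band edges.  ``f_coherence`` lists all in-band local maxima of coherence
    exceeding the threshold (several may coexist), in increasing frequency
    order; it is empty when nothing is significant.
    """
    sel = np.flatnonzero((psd.freqs >= band[0]) & (psd.freqs <= band[1]))
    if len(sel) < 3:
        raise ValueError("band too narrow for the frequency resolution")
    p = psd.power[sel]
    # the gamma peak rides on a 1/f background: prefer the most prominent
    # in-band local maximum over the raw argmax (which can sit on the band edge)
    pk_idx, props = scipy.signal.find_peaks(p, prominence=0)
    if len(pk_idx):
        i_pk = int(pk_idx[np.argmax(props["prominences"])])
    else:
        i_pk = int(np.argmax(p))
    f_lfp = float(psd.freqs[sel[i_pk]])
    edge = min(p[0], p[-1])
    half = edge + 0.5 * (p[i_pk] - edge)
    lo = i_pk
    while lo > 0 and p[lo - 1] >= half:
        lo -= 1
    hi = i_pk
    while hi < len(p) - 1 and p[hi + 1] >= half:
        hi += 1
    extent = (float(psd.freqs[sel[lo]]), float(psd.freqs[sel[hi]]))

    f_c: list[float] = []
    if coh is not None:
        thr = threshold if threshold is not None else coh.threshold
        c = coh.coherence
        csel = np.flatnonzero((coh.freqs >= band[0]) & (coh.freqs <= band[1]))
        peaks, _ = scipy.signal.find_peaks(c[csel])
        for pk in peaks:
            if thr is None or c[csel[pk]] > thr:
                f_c.append(float(coh.freqs[csel[pk]]))
        # an in-band maximum at the band edge of the searched slice is still
        # a local maximum of the full spectrum; find_peaks on the slice
        # misses it, so check edges against their outer neighbours
        for e, nb in ((csel[0], csel[0] - 1), (csel[-1], min(csel[-1] + 1, len(c) - 1))):
            if 0 <= nb < len(c) and c[e] > c[nb] and (thr is None or c[e] > thr):
                inner = c[e + 1] if e == csel[0] else c[e - 1]
                if c[e] > inner and float(coh.freqs[e]) not in f_c:
                    f_c.append(float(coh.freqs[e]))
    return PeakSummary(f_lfp=f_lfp, gamma_extent=extent, f_coherence=sorted(f_c))
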