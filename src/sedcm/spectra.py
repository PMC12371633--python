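"""Spectral containers, Welch estimation, medication epochs and band powers.

Frequency-domain conventions used throughout the package: spectra are
one-sided power spectral densities in uV^2/Hz on a strictly increasing grid,
by default 1-45 Hz in 0.5-Hz steps (the broadband range the model is fitted
to).  Signal variance equals the integral of the density over frequency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps


def default_grid(lo: float = 1.0, hi: float = 45.0, step: float = 0.5) -> np.ndarray:
    return np.arange(lo, hi + step / 2, step)


@dataclass(frozen=True)
class SpectralData:
    """One-sided power spectral density on a frequency grid, with metadata."""

    freqs: np.ndarray
    values: np.ndarray
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        values = np.asarray(self.values)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "values", values)
        if freqs.ndim != 1 or values.shape != freqs.shape:
            raise ValueError("freqs and values must be 1-D arrays of equal length")
        if not np.all(np.diff(freqs) > 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.isrealobj(values) and np.any(values < 0):
            raise ValueError("power densities must be nonnegative")

    def with_meta(self, **meta) -> "SpectralData":
        return replace(self, meta={**self.meta, **meta})

    def to_csv(self, path: str | Path) -> None:
        """Write (freq_hz, power) CSV plus a JSON metadata sidecar."""
        path = Path(path)
        pd.DataFrame({"freq_hz": self.freqs, "power": np.real(self.values)}).to_csv(
            path, index=False
        )
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(dict(self.meta), indent=2, sort_keys=True, default=str))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralData":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(df["freq_hz"].to_numpy(), df["power"].to_numpy(), meta)


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not (0 < self.lo < self.hi):
            raise ValueError(f"band requires 0 < lo < hi, got ({self.lo}, {self.hi})")


#: clinical EEG bands; the gamma upper edge is capped at the 45-Hz fit limit
BANDS = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 14.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 45.0),
}

EVENT_LABELS = ("bzp_admin", "other_asm_admin", "se_termination", "seizure_offset")


@dataclass(frozen=True)
class Recording:
    """A sampled single-channel signal (uV) with medication/seizure events."""

    signal: np.ndarray
    fs: float
    events: tuple = ()
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "events", tuple((float(t), str(lbl)) for t, lbl in self.events))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        dur = sig.size / self.fs
        times = [t for t, _ in self.events]
        if any(t < 0 or t > dur for t in times):
            raise ValueError("event timestamps must lie within the signal duration")
        if times != sorted(times):
            raise ValueError("events must be time-ordered")

    @property
    def duration(self) -> float:
        return self.signal.size / self.fs

    def event_times(self, label: str) -> list[float]:
        return [t for t, lbl in self.events if lbl == label]

    def crop(self, t0: float, t1: float) -> "Recording":
        i0, i1 = int(round(t0 * self.fs)), int(round(t1 * self.fs))
        if i0 < 0 or i1 > self.signal.size:
            raise EpochUnavailableError(
                f"requested window [{t0:g}, {t1:g}] s exceeds recording of {self.duration:g} s"
            )
        return Recording(self.signal[i0:i1], self.fs, (), dict(self.meta))

    def to_csv(self, path: str | Path) -> None:
        t = np.arange(self.signal.size) / self.fs
        pd.DataFrame({"time_s": t, "amplitude_uV": self.signal}).to_csv(path, index=False)
        sidecar = Path(path).with_suffix(Path(path).suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "fs": self.fs,
                    "events": [{"label": lbl, "time_s": t} for t, lbl in self.events],
                    "meta": dict(self.meta),
                },
                indent=2,
                sort_keys=True,
                default=str,
            )
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Recording":
        path = Path(path)
        df = pd.read_csv(path)
        fs = 1.0 / np.median(np.diff(df["time_s"].to_numpy()))
        sidecar = path.with_suffix(path.suffix + ".json")
        events, meta = (), {}
        if sidecar.exists():
            d = json.loads(sidecar.read_text())
            fs = d.get("fs", fs)
            events = tuple((e["time_s"], e["label"]) for e in d.get("events", ()))
            meta = d.get("meta", {})
        return cls(df["amplitude_uV"].to_numpy(), fs, events, meta)


def read_edf(path: str | Path, channel: str) -> Recording:
    """Read one channel of an EDF file (requires :mod:`mne`); amplitudes in uV.

    Events are loaded from a JSON sidecar ``<path>.events.json`` holding a
    list of ``{"label": ..., "time_s": ...}`` records, if present.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), include=[channel], preload=True, verbose="error")
    sig = raw.get_data(picks=[channel])[0] * 1e6  # mne returns volts
    events = ()
    sidecar = Path(str(path) + ".events.json")
    if sidecar.exists():
        d = json.loads(sidecar.read_text())
        events = tuple(sorted((e["time_s"], e["label"]) for e in d))
    return Recording(sig, float(raw.info["sfreq"]), events, {"source": str(path), "channel": channel})


class EpochUnavailableError(RuntimeError):
    """A medication epoch cannot be extracted under the windowing rules."""


class SignalTooShortError(ValueError):
    pass


def welch_psd(
    rec: Recording,
    window_s: float = 4.0,
    overlap_frac: float = 0.5,
    freqs: np.ndarray | None = None,
    return_se: bool = False,
):
    """Averaged-periodogram (Welch) PSD in uV^2/Hz, interpolated onto ``freqs``.

    Defaults: 4-s Hann windows at 50% overlap (0.25-Hz native resolution).
    With ``return_se=True`` also returns a conservative standard error of the
    Welch mean at each grid frequency, computed from the spread of the
    per-segment periodograms with the effective number of independent
    segments taken as half the segment count (50% overlap).
    """
    if freqs is None:
        freqs = default_grid()
    nperseg = int(round(window_s * rec.fs))
    noverlap = int(round(nperseg * overlap_frac))
    if rec.signal.size < 2 * nperseg - noverlap:
        raise SignalTooShortError(
            f"signal of {rec.signal.size} samples supports fewer than 2 windows of {nperseg}"
        )
    f, _, spectro = sps.spectrogram(
        rec.signal,
        fs=rec.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        mode="psd",
    )
    segs = spectro  # (freq, segment) periodograms
    psd = segs.mean(axis=1)
    out = np.interp(freqs, f, psd)
    spec = SpectralData(freqs, out, {"window_s": window_s, "overlap_frac": overlap_frac, **rec.meta})
    if not return_se:
        return spec
    n_seg = segs.shape[1]
    n_eff = max(n_seg / 2.0, 1.0)
    se = segs.std(axis=1, ddof=1) / np.sqrt(n_eff) if n_seg > 1 else np.full_like(psd, np.inf)
    return spec, np.interp(freqs, f, se)


def extract_medication_epochs(rec: Recording, group: str) -> tuple[Recording, Recording]:
    """Extract the 300-s pre- and post-medication epochs.

    The pre epoch ends 1 min before drug administration.  The post epoch
    starts 6 min after administration in nonresponders, and 1 min after
    electrographic termination (the ``se_termination`` event, or the last
    ``seizure_offset`` for intermittent seizures) in responders.
    """
    if group not in ("responder", "nonresponder"):
        raise ValueError(f"group must be responder|nonresponder, got {group!r}")
    admins = rec.event_times("bzp_admin")
    if not admins:
        raise EpochUnavailableError("no bzp_admin event: cannot anchor medication epochs")
    admin = admins[0]
    pre = rec.crop(admin - 360.0, admin - 60.0)
    if group == "nonresponder":
        post = rec.crop(admin + 360.0, admin + 660.0)
    else:
        terms = rec.event_times("se_termination") or rec.event_times("seizure_offset")
        if not terms:
            raise EpochUnavailableError(
                "responder requires an se_termination (or last seizure_offset) event"
            )
        term = max(terms)
        post = rec.crop(term + 60.0, term + 360.0)
    meta = dict(rec.meta)
    return (
        replace(pre, meta={**meta, "condition": "pre"}),
        replace(post, meta={**meta, "condition": "post"}),
    )


def band_power(spec: SpectralData, band: BandDefinition) -> float:
    """Trapezoidal integral of the density over [lo, hi], in uV^2."""
    if band.lo < spec.freqs[0] or band.hi > spec.freqs[-1]:
        raise ValueError(
            f"band [{band.lo}, {band.hi}] Hz outside grid "
            f"[{spec.freqs[0]}, {spec.freqs[-1]}] Hz"
        )
    grid = np.unique(np.concatenate([[band.lo, band.hi], spec.freqs]))
    grid = grid[(grid >= band.lo) & (grid <= band.hi)]
    vals = np.interp(grid, spec.freqs, np.real(spec.values))
    return float(np.trapezoid(vals, grid))


def _randomized_spectrum_signal(
    psd_fn, n: int, fs: float, rng: np.random.Generator, rayleigh: bool = True
) -> np.ndarray:
    """Real signal of length n whose expected one-sided PSD is psd_fn(f).

    Fourier coefficients get uniform random phases; with ``rayleigh=True``
    amplitudes are chi-distributed as for a Gaussian process (a proper
    stochastic realization), otherwise amplitudes are deterministic
    (phase-randomized surrogate).
    """
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    S = np.zeros_like(f)
    pos = f > 0
    S[pos] = psd_fn(f[pos])
    amp = np.sqrt(S * n * fs / 2.0)  # |X_k| such that 2|X|^2/(N fs) = S
    phases = rng.uniform(0, 2 * np.pi, size=f.size)
    if rayleigh:
        scale = np.sqrt(rng.chisquare(2, size=f.size) / 2.0)
    else:
        scale = np.ones(f.size)
    X = amp * scale * np.exp(1j * phases)
    X[0] = 0.0
    if n % 2 == 0:
        X[-1] = np.real(X[-1]) * np.sqrt(2.0)
    return np.fft.irfft(X, n=n)


def spectrum_to_timeseries(
    spec: SpectralData, duration_s: float, fs: float, seed: int | np.random.Generator = 0
) -> Recording:
    """Random-phase inverse-Fourier surrogate with expected PSD ``spec``.

    Outside the grid the density is extended with its edge values (below the
    grid, and for half a typical window bandwidth above it, so the windowed
    estimate of the edge bin is unbiased) and zero beyond.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    vals = np.real(spec.values)
    guard = 0.5  # Hz beyond the upper grid edge

    def psd_fn(f):
        out = np.interp(f, spec.freqs, vals, left=vals[0], right=0.0)
        out[(f > spec.freqs[-1]) & (f <= spec.freqs[-1] + guard)] = vals[-1]
        out[f > spec.freqs[-1] + guard] = 0.0
        return out

    sig = _randomized_spectrum_signal(psd_fn, n, fs, rng, rayleigh=False)
    return Recording(sig, fs, (), dict(spec.meta))
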