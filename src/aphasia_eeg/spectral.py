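"""Per-window spectral decomposition and normalized band powers.

Each 5-s window is Fourier-transformed (raw periodogram, no taper by
default) into a one-sided power spectrum scaled so that the sum of the
bins equals the window's mean-square value — i.e. Parseval's identity
holds bin-for-bin against the time-domain RMS.  Band powers are sums of
bins over half-open frequency ranges; the five analyzed bands
(Theta 4–8, Alpha 8–12, BetaL 12–16, BetaH 16–25, Gamma 25–45 Hz) tile
[4, 45) Hz exactly.  Delta (1–4 Hz) is computed but excluded from the
normalized display, which divides each electrode's mean band powers by
their analyzed-band sum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import WindowSet

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "ANALYZED_BAND_NAMES",
    "analyzed_bands",
    "validate_bands",
    "power_spectrum",
    "band_power",
    "BandPowerTable",
    "aggregate",
    "DEFAULT_INCLUDE_LABELS",
]


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency band ``[low_hz, high_hz)``."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self):
        if not 0 <= self.low_hz < self.high_hz:
            raise ValueError(f"invalid band edges for {self.name}: "
                             f"[{self.low_hz}, {self.high_hz})")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("Delta", 1.0, 4.0),
    BandDefinition("Theta", 4.0, 8.0),
    BandDefinition("Alpha", 8.0, 12.0),
    BandDefinition("BetaL", 12.0, 16.0),
    BandDefinition("BetaH", 16.0, 25.0),
    BandDefinition("Gamma", 25.0, 45.0),
)

#: Bands entering the normalization; Delta is computed but hidden.
ANALYZED_BAND_NAMES = ("Theta", "Alpha", "BetaL", "BetaH", "Gamma")


def analyzed_bands(bands=DEFAULT_BANDS) -> tuple[BandDefinition, ...]:
    return tuple(b for b in bands if b.name != "Delta")


def validate_bands(bands):
    """Check that the analyzed (non-Delta) bands tile a contiguous range."""
    ana = sorted(analyzed_bands(bands), key=lambda b: b.low_hz)
    if not ana:
        raise ValueError("need at least one analyzed band")
    for a, b in zip(ana, ana[1:]):
        if a.high_hz != b.low_hz:
            raise ValueError(
                f"analyzed bands must tile without gaps or overlaps: "
                f"{a.name} ends at {a.high_hz}, {b.name} starts at {b.low_hz}"
            )
    names = [b.name for b in bands]
    if len(set(names)) != len(names):
        raise ValueError("band names must be unique")
    return tuple(bands)


def power_spectrum(window_samples: np.ndarray, fs: float,
                   taper: str | None = None):
    """One-sided power spectrum of a window, in µV² per bin.

    Scaling satisfies Parseval: ``spectrum.sum() == mean(x**2)`` (to float
    precision).  Bin spacing is ``fs / n``.  ``taper="hann"`` applies a
    Hann window with power-preserving normalization (a robustness option;
    the default analysis uses the raw periodogram).

    Returns ``(freqs_hz, power)`` arrays of length ``n // 2 + 1``.
    """
    x = np.asarray(window_samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("power_spectrum expects a single-channel window")
    n = x.size
    if n < 2:
        raise ValueError("window must hold at least 2 samples")
    if taper == "hann":
        w = np.hanning(n)
        x = x * w / np.sqrt(np.mean(w ** 2))
    elif taper is not None:
        raise ValueError(f"unknown taper {taper!r}")
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2 / n ** 2
    # one-sided: interior bins carry the conjugate half's power too
    if n % 2 == 0:
        power[1:-1] *= 2.0
    else:
        power[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, power


def band_power(freqs: np.ndarray, power: np.ndarray,
               band: BandDefinition) -> float:
    """Sum of spectrum bins with ``low_hz <= f < high_hz`` (half-open)."""
    nyquist = freqs[-1]
    if band.low_hz > nyquist:
        raise ValueError(
            f"band {band.name} [{band.low_hz}, {band.high_hz}) lies above "
            f"the Nyquist frequency {nyquist} Hz"
        )
    mask = (freqs >= band.low_hz) & (freqs < band.high_hz)
    return float(power[mask].sum())


DEFAULT_INCLUDE_LABELS = frozenset({"stimulus_sentence", "control_sentence"})


@dataclass(frozen=True)
class BandPowerTable:
    """Electrode × band table of mean raw and normalized band powers.

    ``raw_power_uv2`` holds every band including Delta; ``normalized``
    holds the analyzed bands only, each row summing to 1.
    """

    raw_power_uv2: pd.DataFrame
    normalized: pd.DataFrame
    n_windows_used: pd.Series

    @property
    def electrodes(self) -> tuple[str, ...]:
        return tuple(self.raw_power_uv2.index)

    def to_tsv(self, path):
        long = (
            self.raw_power_uv2.stack().rename("raw_power_uv2").reset_index()
        )
        long.columns = ["electrode", "band", "raw_power_uv2"]
        norm = self.normalized.stack().rename("normalized").reset_index()
        norm.columns = ["electrode", "band", "normalized"]
        long = long.merge(norm, on=["electrode", "band"], how="left")
        long["n_windows_used"] = long["electrode"].map(self.n_windows_used)
        long.to_csv(path, sep="\t", index=False, float_format="%.8g")
        return path

    def to_json_dict(self) -> dict:
        return {
            "raw_power_uv2": {e: self.raw_power_uv2.loc[e].to_dict()
                              for e in self.electrodes},
            "normalized": {e: self.normalized.loc[e].to_dict()
                           for e in self.electrodes},
            "n_windows_used": self.n_windows_used.to_dict(),
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)
        return path


def aggregate(ws: WindowSet, bands=DEFAULT_BANDS,
              include_labels=DEFAULT_INCLUDE_LABELS,
              taper: str | None = None) -> BandPowerTable:
    """Average per-window band powers over accepted windows, per electrode.

    Accepted means artifact-free with a paradigm label in
    ``include_labels`` (stimulus + control sentences by default).  Raw
    power is the arithmetic mean of per-window band powers (µV²);
    normalized power divides by the electrode's analyzed-band sum.
    """
    bands = validate_bands(bands)
    band_names = [b.name for b in bands]
    ana_names = [b.name for b in analyzed_bands(bands)]
    raw = {}
    n_used = {}
    for lab in ws.channel_labels:
        acc = [w for w in ws.for_channel(lab)
               if not w.artifact and w.label in include_labels]
        if not acc:
            raise ValueError(
                f"electrode {lab} has no accepted windows "
                "(all artifact-flagged or excluded by label)"
            )
        powers = np.zeros((len(acc), len(bands)))
        for i, w in enumerate(acc):
            freqs, spec = power_spectrum(ws.window_samples(w), ws.fs, taper=taper)
            for j, b in enumerate(bands):
                powers[i, j] = band_power(freqs, spec, b)
        raw[lab] = powers.mean(axis=0)
        n_used[lab] = len(acc)
    raw_df = pd.DataFrame.from_dict(raw, orient="index", columns=band_names)
    raw_df = raw_df.loc[list(ws.channel_labels)]
    denom = raw_df[ana_names].sum(axis=1)
    if (denom <= 0).any():
        zero = denom.index[denom <= 0][0]
        raise ValueError(f"electrode {zero} has zero analyzed-band power")
    normalized = raw_df[ana_names].div(denom, axis=0)
    return BandPowerTable(
        raw_power_uv2=raw_df,
        normalized=normalized,
        n_windows_used=pd.Series(n_used).loc[list(ws.channel_labels)],
    )
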