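"""Seed-reproducible synthetic recordings with known band structure.

Each channel is a sum of one representative sinusoid per frequency band
(Delta 2, Theta 6, Alpha 10, BetaL 14, BetaH 20, Gamma 35 Hz — strictly
interior to the half-open bands) with per-hemisphere amplitudes, plus a
DC offset, Gaussian broadband noise, optional high-amplitude artifact
bursts, and a marker "1" at the baseline/task boundary.  Because each
band holds a single tone the normalized band profile is closed-form:
the power of a tone of amplitude A is A²/2, so the analytic profile is
the amplitude-squared ratio over the analyzed bands.  That ground truth
is what every recovery test checks the pipeline against.

The generator emulates the published study conditions by default:
128 Hz sampling, the full 14-channel headset montage, a 40-s baseline
followed by a 240-s task (48 five-second windows), a mid-rail DC offset,
and 5 µV broadband noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np

from .ingest import (
    CsvDialect,
    DEFAULT_DIALECT,
    Recording,
    hemisphere_of,
    read_recording,
    write_recording,
)
from .paradigm import ParadigmSchedule, default_schedule
from .spectral import ANALYZED_BAND_NAMES

__all__ = [
    "REPRESENTATIVE_HZ",
    "FULL_MONTAGE_14",
    "SyntheticSpec",
    "GroundTruth",
    "default_band_amplitudes",
    "amplitudes_for_profiles",
    "generate",
    "write_fixture",
    "make_cohort",
]

#: One representative tone per band, strictly inside each half-open range.
REPRESENTATIVE_HZ = {
    "Delta": 2.0, "Theta": 6.0, "Alpha": 10.0,
    "BetaL": 14.0, "BetaH": 20.0, "Gamma": 35.0,
}

#: The 14 scalp channels of the consumer headset, 10-20 labels.
FULL_MONTAGE_14 = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Total oscillatory power over the analyzed bands per hemisphere, µV².
#: 400 µV² gives ~12.6 µV per-band amplitudes on a flat profile — large
#: against the 5 µV default noise so planted asymmetries survive the
#: broadband-noise dilution of the normalization.
DEFAULT_SIDE_POWER_UV2 = 400.0


def default_band_amplitudes(side_power_uv2: float = DEFAULT_SIDE_POWER_UV2,
                            delta_amplitude_uv: float | None = None):
    """Flat analyzed-band profile, identical on both sides."""
    flat = {b: 1.0 / len(ANALYZED_BAND_NAMES) for b in ANALYZED_BAND_NAMES}
    return amplitudes_for_profiles({"left": flat, "right": flat},
                                   side_power_uv2, delta_amplitude_uv)


def amplitudes_for_profiles(profiles: dict[str, dict[str, float]],
                            side_power_uv2: float = DEFAULT_SIDE_POWER_UV2,
                            delta_amplitude_uv: float | None = None):
    """Band amplitudes realizing given per-side normalized profiles.

    ``profiles[side][band]`` are analyzed-band simplex weights; the tone
    amplitude follows from power = A²/2, so A = sqrt(2 · weight · total).
    Delta carries the same amplitude on both sides (it never enters the
    normalization) — by default the amplitude of a flat analyzed band.
    """
    if delta_amplitude_uv is None:
        delta_amplitude_uv = float(np.sqrt(
            2.0 * side_power_uv2 / len(ANALYZED_BAND_NAMES)))
    amplitudes = {}
    for side in ("left", "right"):
        prof = profiles[side]
        total = sum(prof.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{side} profile must sum to 1 (got {total})")
        for band, w in prof.items():
            if w < 0:
                raise ValueError(f"negative profile weight for {side}/{band}")
            amplitudes[(side, band)] = float(np.sqrt(2.0 * w * side_power_uv2))
        amplitudes[(side, "Delta")] = delta_amplitude_uv
    return amplitudes


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic recording."""

    fs: int = 128
    montage: tuple[str, ...] = FULL_MONTAGE_14
    band_amplitudes: dict[tuple[str, str], float] = field(
        default_factory=default_band_amplitudes)
    stimulus_gain: float = 1.0
    noise_sd_uv: float = 5.0
    artifact_plan: tuple[tuple[str, int, float], ...] = ()
    dc_offset_uv: float = 4200.0
    seed: int = 0
    schedule: ParadigmSchedule = field(default_factory=default_schedule)

    def __post_init__(self):
        if any(a < 0 for a in self.band_amplitudes.values()):
            raise ValueError("band amplitudes must be non-negative")
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be non-negative")
        n_task_windows = int(self.schedule.task_duration / 5)
        for ch, w, amp in self.artifact_plan:
            if ch not in self.montage:
                raise ValueError(f"artifact channel {ch} not in montage")
            if not 0 <= w < n_task_windows:
                raise ValueError(f"artifact window {w} outside the task")
        for band, f in REPRESENTATIVE_HZ.items():
            if f >= self.fs / 2:
                raise ValueError(
                    f"{band} representative tone {f} Hz at or above Nyquist")

    def to_json_dict(self) -> dict:
        return {
            "fs": self.fs,
            "montage": list(self.montage),
            "band_amplitudes": {f"{s}/{b}": a for (s, b), a
                                in self.band_amplitudes.items()},
            "stimulus_gain": self.stimulus_gain,
            "noise_sd_uv": self.noise_sd_uv,
            "artifact_plan": [list(p) for p in self.artifact_plan],
            "dc_offset_uv": self.dc_offset_uv,
            "seed": self.seed,
            "schedule": [ev.to_dict() for ev in self.schedule.events],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SyntheticSpec":
        amps = {}
        for key, a in d["band_amplitudes"].items():
            side, band = key.split("/")
            amps[(side, band)] = a
        return cls(
            fs=int(d["fs"]),
            montage=tuple(d["montage"]),
            band_amplitudes=amps,
            stimulus_gain=float(d["stimulus_gain"]),
            noise_sd_uv=float(d["noise_sd_uv"]),
            artifact_plan=tuple(tuple(p) for p in d["artifact_plan"]),
            dc_offset_uv=float(d["dc_offset_uv"]),
            seed=int(d["seed"]),
            schedule=ParadigmSchedule.from_json(json.dumps(d["schedule"])),
        )


@dataclass(frozen=True)
class GroundTruth:
    """What the pipeline should recover from a synthetic recording."""

    normalized_profile: dict[str, dict[str, float]]  # side -> band -> weight
    raw_band_power_uv2: dict[str, dict[str, float]]  # side -> band -> µV²
    artifact_plan: tuple[tuple[str, int, float], ...]
    task_onset_sample: int

    @property
    def analytic_diff_pp(self) -> dict[str, float]:
        """Planted right-minus-left normalized difference, percentage points."""
        return {
            b: 100.0 * (self.normalized_profile["right"][b]
                        - self.normalized_profile["left"][b])
            for b in ANALYZED_BAND_NAMES
        }


def _analytic_truth(spec: SyntheticSpec) -> GroundTruth:
    raw = {}
    norm = {}
    for side in ("left", "right"):
        powers = {
            b: spec.band_amplitudes.get((side, b), 0.0) ** 2 / 2.0
            for b in REPRESENTATIVE_HZ
        }
        total = sum(powers[b] for b in ANALYZED_BAND_NAMES)
        if total <= 0:
            raise ValueError(f"{side} hemisphere has zero analyzed-band power")
        raw[side] = powers
        norm[side] = {b: powers[b] / total for b in ANALYZED_BAND_NAMES}
    onset = spec.schedule.baseline_duration * spec.fs
    return GroundTruth(
        normalized_profile=norm,
        raw_band_power_uv2=raw,
        artifact_plan=spec.artifact_plan,
        task_onset_sample=int(onset),
    )


def generate(spec: SyntheticSpec) -> tuple[Recording, GroundTruth]:
    """Synthesize a full-session recording (baseline + task) from a spec.

    Phases are randomized per channel and band; the noise stream and
    phases are the only stochastic elements, so two specs differing only
    in seed share the same GroundTruth.
    """
    truth = _analytic_truth(spec)
    rng = np.random.default_rng(spec.seed)
    n_total = int(spec.schedule.end * spec.fs)
    t = np.arange(n_total) / spec.fs

    # stimulus-gain envelope over the oscillatory components
    gain = np.ones(n_total)
    if spec.stimulus_gain != 1.0:
        for ev in spec.schedule.events:
            if ev.kind == "stimulus_sentence":
                i0 = int(ev.onset * spec.fs)
                i1 = int(ev.end * spec.fs)
                gain[i0:i1] = spec.stimulus_gain

    samples = np.empty((len(spec.montage), n_total))
    for ci, label in enumerate(spec.montage):
        side = hemisphere_of(label)
        osc = np.zeros(n_total)
        for band, f in REPRESENTATIVE_HZ.items():
            amp = spec.band_amplitudes.get((side, band), 0.0)
            if amp > 0:
                phase = rng.uniform(0, 2 * np.pi)
                osc += amp * np.sin(2 * np.pi * f * t + phase)
        chan = spec.dc_offset_uv + gain * osc
        if spec.noise_sd_uv > 0:
            chan = chan + rng.normal(0.0, spec.noise_sd_uv, n_total)
        samples[ci] = chan

    # artifact bursts: 1-s Hann-enveloped 25 Hz transients centred in the
    # requested task window
    onset_sample = truth.task_onset_sample
    win_len = 5 * spec.fs
    for ch, w, amp in spec.artifact_plan:
        ci = spec.montage.index(ch)
        start = onset_sample + w * win_len + win_len // 2 - spec.fs // 2
        dur = spec.fs  # 1 s
        tt = np.arange(dur) / spec.fs
        burst = amp * np.hanning(dur) * np.sin(2 * np.pi * 25.0 * tt)
        samples[ci, start:start + dur] += burst

    rec = Recording(
        samples=samples,
        fs=spec.fs,
        channel_labels=tuple(spec.montage),
        markers=[(onset_sample, "1")],
    )
    return rec, truth


def write_fixture(rec: Recording, spec: SyntheticSpec, out_dir,
                  stem: str = "synthetic",
                  dialect: CsvDialect = DEFAULT_DIALECT):
    """Write a recording as a CSV fixture plus a ground-truth JSON.

    The CSV uses the default ingest dialect so that
    ``read_recording(csv_path)`` round-trips the recording; the JSON holds
    the full spec and the analytic profiles.  Output is byte-identical for
    identical spec + seed.
    """
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise FileNotFoundError(f"{out_dir} is not a writable directory")
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}.truth.json"
    write_recording(rec, csv_path, dialect)
    truth = _analytic_truth(spec)
    payload = {
        "spec": spec.to_json_dict(),
        "ground_truth": {
            "normalized_profile": truth.normalized_profile,
            "raw_band_power_uv2": truth.raw_band_power_uv2,
            "artifact_plan": [list(p) for p in truth.artifact_plan],
            "task_onset_sample": truth.task_onset_sample,
        },
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return csv_path, json_path


def _balanced_profiles(plan_pp: dict[str, float]) -> dict[str, dict[str, float]]:
    """Left/right simplex profiles whose normalized difference equals the plan.

    The planted differences must cancel across the five analyzed bands for
    both profiles to stay on the simplex; bands absent from the plan share
    the balancing remainder equally.
    """
    unknown = set(plan_pp) - set(ANALYZED_BAND_NAMES)
    if unknown:
        raise ValueError(f"unknown band(s) in asymmetry plan: {sorted(unknown)}")
    x = {b: plan_pp.get(b, None) for b in ANALYZED_BAND_NAMES}
    free = [b for b in ANALYZED_BAND_NAMES if x[b] is None]
    planted_sum = sum(v for v in x.values() if v is not None)
    if free:
        for b in free:
            x[b] = -planted_sum / len(free)
    elif abs(planted_sum) > 1e-9:
        raise ValueError(
            "planted diffs over all five bands must sum to 0 "
            f"(got {planted_sum} pp)"
        )
    base = 100.0 / len(ANALYZED_BAND_NAMES)
    left, right = {}, {}
    for b in ANALYZED_BAND_NAMES:
        l = (base - x[b] / 2.0) / 100.0
        r = (base + x[b] / 2.0) / 100.0
        if l < 0 or r < 0:
            raise ValueError(
                f"planted diff for {b} ({x[b]} pp) pushes a hemisphere "
                "profile off the simplex"
            )
        left[b], right[b] = l, r
    return {"left": left, "right": right}


def make_cohort(n: int, asymmetry_plan, seed: int,
                **spec_overrides) -> list[SyntheticSpec]:
    """Specs for a cohort of ``n`` participants with planted asymmetries.

    ``asymmetry_plan`` is either one ``{band: diff_pp}`` mapping applied to
    every participant or a length-``n`` sequence of such mappings.  Band
    amplitudes are solved so each participant's analytic normalized
    profile difference equals the plan; per-participant seeds derive
    deterministically from ``seed``.
    """
    if n < 1:
        raise ValueError("cohort needs at least one participant")
    if isinstance(asymmetry_plan, dict):
        plans = [asymmetry_plan] * n
    else:
        plans = list(asymmetry_plan)
        if len(plans) != n:
            raise ValueError(f"plan length {len(plans)} != n={n}")
    child_seeds = [
        int(s) & 0x7FFFFFFF
        for s in np.random.SeedSequence(seed).generate_state(n)
    ]
    specs = []
    for plan, child in zip(plans, child_seeds):
        profiles = _balanced_profiles(plan)
        amps = amplitudes_for_profiles(profiles)
        specs.append(SyntheticSpec(
            band_amplitudes=amps, seed=child, **spec_overrides))
    return specs
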