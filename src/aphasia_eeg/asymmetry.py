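"""Hemispheric activation asymmetry.

For each frequency band the statistic is the signed difference, in
percentage points, between the mean normalized band power of the
right-hemisphere electrodes and that of the left-hemisphere electrodes:

    diff_pp(band) = 100 × (right_mean(band) − left_mean(band))

Positive values mean greater right-hemisphere activation (bars up in the
conventional plot), negative values greater left-hemisphere activation
(bars down).  Because normalized powers live on a simplex the difference
is bounded by ±100.  A ratio-based alternative — the classical laterality
index 100 × (R − L)/(R + L) — is available for sensitivity analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .ingest import DEFAULT_MONTAGE, MontageSelection
from .spectral import BandPowerTable

__all__ = [
    "AsymmetryResult",
    "GroupSummary",
    "hemispheric_diff",
    "classify_dominance",
    "group_average",
]


@dataclass(frozen=True)
class AsymmetryResult:
    """Per-band signed right-minus-left difference for one participant."""

    per_band_diff_pp: dict[str, float]
    left_mean: dict[str, float]
    right_mean: dict[str, float]
    montage: MontageSelection
    formula: str = "pp"

    def to_tsv(self, path, tie_eps_pp: float = 0.5):
        dom = classify_dominance(self, tie_eps_pp)
        with open(path, "w") as fh:
            fh.write("band\tleft_mean\tright_mean\tdiff_pp\tdominance\n")
            for band, diff in self.per_band_diff_pp.items():
                fh.write(
                    f"{band}\t{self.left_mean[band]:.8g}\t"
                    f"{self.right_mean[band]:.8g}\t{diff:.8g}\t{dom[band]}\n"
                )
        return path


def hemispheric_diff(table: BandPowerTable,
                     montage: MontageSelection = DEFAULT_MONTAGE,
                     formula: str = "pp") -> AsymmetryResult:
    """Signed right-minus-left difference of normalized band power.

    Each side's value is the unweighted mean over its electrodes (F7, F3
    left and F4, F8 right by default).  ``formula="pp"`` gives percentage
    points of normalized power; ``formula="ratio"`` the classical
    laterality index 100 × (R − L)/(R + L).
    """
    if formula not in ("pp", "ratio"):
        raise ValueError(f"unknown asymmetry formula {formula!r}")
    missing = [e for e in montage.electrodes if e not in table.electrodes]
    if missing:
        raise ValueError(f"montage electrode(s) missing from table: {missing}")
    for e in montage.electrodes:
        if table.n_windows_used[e] <= 0:
            raise ValueError(f"electrode {e} contributed no windows")

    norm = table.normalized
    left = norm.loc[list(montage.left_electrodes)].mean(axis=0)
    right = norm.loc[list(montage.right_electrodes)].mean(axis=0)
    if formula == "pp":
        diff = 100.0 * (right - left)
    else:
        diff = 100.0 * (right - left) / (right + left)
    return AsymmetryResult(
        per_band_diff_pp={b: float(diff[b]) for b in norm.columns},
        left_mean={b: float(left[b]) for b in norm.columns},
        right_mean={b: float(right[b]) for b in norm.columns},
        montage=montage,
        formula=formula,
    )


def classify_dominance(res: AsymmetryResult,
                       tie_eps_pp: float = 0.5) -> dict[str, str]:
    """Per-band dominance: right if diff > eps, left if diff < −eps, else tied."""
    out = {}
    for band, diff in res.per_band_diff_pp.items():
        if diff > tie_eps_pp:
            out[band] = "right"
        elif diff < -tie_eps_pp:
            out[band] = "left"
        else:
            out[band] = "tied"
    return out


@dataclass(frozen=True)
class GroupSummary:
    """Cohort aggregate: mean diffs and per-band dominance counts."""

    mean_diff_pp: dict[str, float]
    dominance_counts: dict[str, tuple[int, int, int]]
    n_participants: int
    #: participants right-dominant in at least ``dominance_min_bands`` bands
    n_right_dominant_any: int = 0
    dominance_min_bands: int = 1
    participant_ids: tuple[str, ...] = field(default=())

    def to_json_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "mean_diff_pp": self.mean_diff_pp,
            "dominance_counts": {
                b: {"right": c[0], "left": c[1], "tied": c[2]}
                for b, c in self.dominance_counts.items()
            },
            "n_right_dominant_any": self.n_right_dominant_any,
            "dominance_min_bands": self.dominance_min_bands,
            "participant_ids": list(self.participant_ids),
        }

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)
        return path


def group_average(results, tie_eps_pp: float = 0.5,
                  dominance_min_bands: int = 1,
                  participant_ids=None) -> GroupSummary:
    """Unweighted cohort mean of per-participant diffs, plus dominance counts.

    ``n_right_dominant_any`` counts participants whose dominance is
    "right" in at least ``dominance_min_bands`` bands (with the default 1,
    any right-greater band qualifies).
    """
    results = list(results)
    if not results:
        raise ValueError("group_average needs at least one participant")
    bands = list(results[0].per_band_diff_pp)
    for r in results[1:]:
        if list(r.per_band_diff_pp) != bands:
            raise ValueError("participants have inconsistent band sets")

    mean_diff = {
        b: sum(r.per_band_diff_pp[b] for r in results) / len(results)
        for b in bands
    }
    counts = {}
    n_right_any = 0
    for r in results:
        dom = classify_dominance(r, tie_eps_pp)
        if sum(1 for b in bands if dom[b] == "right") >= dominance_min_bands:
            n_right_any += 1
        for b in bands:
            c = counts.setdefault(b, [0, 0, 0])
            c[{"right": 0, "left": 1, "tied": 2}[dom[b]]] += 1
    return GroupSummary(
        mean_diff_pp=mean_diff,
        dominance_counts={b: tuple(c) for b, c in counts.items()},
        n_participants=len(results),
        n_right_dominant_any=n_right_any,
        dominance_min_bands=dominance_min_bands,
        participant_ids=tuple(participant_ids or ()),
    )
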