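"""End-to-end orchestration: cohort roster, per-participant runs, reports.

A run takes a raw CSV through ingest → DC removal → band-pass filter →
5-s windowing → artifact flagging → per-window FFT band powers →
per-electrode normalization → hemispheric asymmetry, and a cohort run
aggregates participants into a group summary after applying the
inclusion rule (only aphasic participants with preserved comprehension —
global aphasia, which impairs comprehension, is excluded).
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .asymmetry import (
    AsymmetryResult,
    GroupSummary,
    classify_dominance,
    group_average,
    hemispheric_diff,
)
from .ingest import (
    CsvDialect,
    DEFAULT_DIALECT,
    DEFAULT_MONTAGE,
    MontageSelection,
    Recording,
    locate_task_onset,
    read_recording,
    trim_to_task,
)
from .paradigm import ParadigmSchedule, default_schedule
from .preprocess import (
    DEFAULT_FILTER,
    FilterSpec,
    WindowSet,
    apply_filter,
    flag_artifacts,
    make_windows,
    remove_dc,
)
from .spectral import (
    BandPowerTable,
    DEFAULT_BANDS,
    DEFAULT_INCLUDE_LABELS,
    aggregate,
    validate_bands,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "DataError",
    "ProcessingError",
    "ParticipantRecord",
    "DEFAULT_ROSTER_TSV",
    "load_roster",
    "filter_cohort",
    "RunConfig",
    "ParticipantResult",
    "analyze_recording",
    "run_participant",
    "run_cohort",
    "plot_asymmetry",
]


class ConfigError(ValueError):
    """Invalid configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Unreadable or inconsistent input data (CLI exit code 3)."""


class ProcessingError(RuntimeError):
    """A pipeline stage failed on otherwise-valid data (CLI exit code 4)."""


# ---------------------------------------------------------------------------
# Cohort roster

@dataclass(frozen=True)
class ParticipantRecord:
    """One row of the study roster."""

    id: str
    gender: str
    age: int
    hemiparesis: str
    hemisphere_affected: str
    aphasia_type: str
    comprehension_preserved: bool | None = None

    def __post_init__(self):
        if self.comprehension_preserved is None:
            # global aphasia impairs comprehension; all other typologies
            # in scope preserve it
            preserved = not self.aphasia_type.strip().lower().startswith("global")
            object.__setattr__(self, "comprehension_preserved", preserved)


#: The study roster: eleven post-stroke aphasic participants.
DEFAULT_ROSTER_TSV = """\
id\tgender\tage\themiparesis\themisphere_affected\taphasia_type
Ap01\tF\t53\tright\tleft\tBroca
Ap02\tF\t51\tright\tleft\tBroca
Ap03\tF\t53\tright\tleft\tAnomic
Ap04\tF\t45\tright\tleft\tTranscortical motor
Ap05\tF\t63\tright\tleft\tBroca
Ap06\tF\t45\tright\tleft\tTranscortical motor
Ap07\tM\t58\tright\tleft\tBroca
Ap08\tM\t63\tright\tleft\tBroca
Ap09\tF\t59\tright\tleft\tBroca
Ap10\tF\t45\tleft\tright\tGlobal
Ap11\tM\t60\tright\tleft\tGlobal
"""


def load_roster(path=None) -> list[ParticipantRecord]:
    """Parse a roster TSV (id, gender, age, hemiparesis, hemisphere_affected,
    aphasia_type); defaults to the study roster shipped with the package."""
    if path is None:
        fh = io.StringIO(DEFAULT_ROSTER_TSV)
    else:
        fh = open(path)
    with fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"id", "gender", "age", "hemiparesis",
                    "hemisphere_affected", "aphasia_type"}
        missing = required - set(header)
        if missing:
            raise DataError(f"roster missing column(s): {sorted(missing)}")
        rows = []
        for line in fh:
            if not line.strip():
                continue
            cells = dict(zip(header, line.rstrip("\n").split("\t")))
            rows.append(ParticipantRecord(
                id=cells["id"],
                gender=cells["gender"],
                age=int(cells["age"]),
                hemiparesis=cells["hemiparesis"],
                hemisphere_affected=cells["hemisphere_affected"],
                aphasia_type=cells["aphasia_type"],
            ))
    return rows


def filter_cohort(roster) -> tuple[list[ParticipantRecord],
                                   list[tuple[str, str]]]:
    """Apply the inclusion rule: keep participants with preserved
    comprehension; return (included, [(id, reason), ...])."""
    roster = list(roster)
    if not roster:
        raise DataError("empty roster")
    included, excluded = [], []
    for p in roster:
        if p.comprehension_preserved:
            included.append(p)
        else:
            reason = (f"comprehension not preserved "
                      f"(aphasia type: {p.aphasia_type})")
            excluded.append((p.id, reason))
            logger.info("excluding %s: %s", p.id, reason)
    return included, excluded


# ---------------------------------------------------------------------------
# Run configuration

@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs, validated up front and echoed into outputs."""

    fs: int = 128
    dialect: CsvDialect = DEFAULT_DIALECT
    filter_spec: FilterSpec = DEFAULT_FILTER
    window_length_s: float = 5.0
    artifact_k_mad: float = 5.0
    artifact_amp_abs_uv: float = 150.0
    bands: tuple = DEFAULT_BANDS
    montage: MontageSelection = DEFAULT_MONTAGE
    include_labels: frozenset = DEFAULT_INCLUDE_LABELS
    asymmetry_formula: str = "pp"
    tie_eps_pp: float = 0.5
    taper: str | None = None
    task_duration_s: float = 240.0
    schedule: ParadigmSchedule = field(default_factory=default_schedule)
    marker_value: str = "1"

    def __post_init__(self):
        try:
            self.filter_spec.validate_for(self.fs)
            validate_bands(self.bands)
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        if self.asymmetry_formula not in ("pp", "ratio"):
            raise ConfigError(
                f"unknown asymmetry formula {self.asymmetry_formula!r}")
        if self.window_length_s <= 0:
            raise ConfigError("window_length_s must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a mapping")
        kwargs = {}
        try:
            if "fs" in raw:
                kwargs["fs"] = int(raw["fs"])
            if "dialect" in raw:
                kwargs["dialect"] = CsvDialect(**raw["dialect"])
            if "filter" in raw:
                f = dict(raw["filter"])
                if "cutoffs_hz" in f:
                    f["cutoffs_hz"] = tuple(f["cutoffs_hz"])
                kwargs["filter_spec"] = FilterSpec(**f)
            if "window_length_s" in raw:
                kwargs["window_length_s"] = float(raw["window_length_s"])
            if "artifact" in raw:
                a = raw["artifact"]
                if "k_mad" in a:
                    kwargs["artifact_k_mad"] = float(a["k_mad"])
                if "amp_abs_uv" in a:
                    kwargs["artifact_amp_abs_uv"] = float(a["amp_abs_uv"])
            if "bands" in raw:
                from .spectral import BandDefinition
                kwargs["bands"] = tuple(
                    BandDefinition(b["name"], float(b["low_hz"]),
                                   float(b["high_hz"]))
                    for b in raw["bands"]
                )
            if "montage" in raw:
                kwargs["montage"] = MontageSelection(
                    left_electrodes=tuple(raw["montage"]["left"]),
                    right_electrodes=tuple(raw["montage"]["right"]),
                )
            if "labels" in raw:
                if raw["labels"] == "stimulus_only":
                    kwargs["include_labels"] = frozenset({"stimulus_sentence"})
                elif raw["labels"] == "all_task":
                    kwargs["include_labels"] = frozenset(
                        {"stimulus_sentence", "control_sentence", "mixed"})
                else:
                    kwargs["include_labels"] = frozenset(raw["labels"])
            for key in ("asymmetry_formula", "tie_eps_pp", "taper",
                        "task_duration_s", "marker_value"):
                if key in raw:
                    kwargs[key] = raw[key]
        except (TypeError, KeyError, ValueError) as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                if isinstance(obj, ParadigmSchedule):
                    return json.loads(obj.to_json())
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (frozenset, set, tuple, list)):
                return sorted(map(enc, obj)) if isinstance(obj, (frozenset, set)) \
                    else [enc(v) for v in obj]
            return obj
        return {f.name: enc(getattr(self, f.name))
                for f in dataclasses.fields(self)}

    @property
    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Per-participant and cohort runs

@dataclass(frozen=True)
class ParticipantResult:
    """All products of one participant run."""

    band_table: BandPowerTable
    asymmetry: AsymmetryResult
    windows: WindowSet
    n_rejected_windows: int

    def window_report_tsv(self, path, fs: int):
        with open(path, "w") as fh:
            fh.write("channel\tindex\tstart_s\tlabel\trms_uv\tartifact\n")
            for w in self.windows.windows:
                fh.write(f"{w.channel}\t{w.index}\t{w.start_sample / fs:g}\t"
                         f"{w.label}\t{w.rms_uv:.6g}\t{int(w.artifact)}\n")
        return path


def analyze_recording(rec: Recording, config: RunConfig = RunConfig(),
                      trimmed: bool = False) -> ParticipantResult:
    """Run the analysis stages on an in-memory recording.

    ``trimmed=False`` locates the task-onset marker and cuts the recording
    to the task first; pass ``trimmed=True`` for a recording that already
    starts at task onset.
    """
    try:
        work = rec.select(config.montage.electrodes)
    except ValueError as exc:
        raise DataError(f"montage channel missing: {exc}") from exc
    if not trimmed:
        try:
            locate_task_onset(work, config.marker_value)
            work = trim_to_task(work, config.task_duration_s)
        except ValueError as exc:
            raise DataError(f"[ingest] {exc}") from exc
    try:
        conditioned = apply_filter(remove_dc(work.samples),
                                   config.filter_spec, config.fs)
        work = dataclasses.replace(work, samples=conditioned)
        ws = make_windows(work, config.schedule, config.window_length_s)
        ws = flag_artifacts(ws, config.artifact_k_mad,
                            config.artifact_amp_abs_uv)
    except ValueError as exc:
        raise ProcessingError(f"[preprocess] {exc}") from exc
    n_rejected = sum(1 for w in ws.windows if w.artifact)
    try:
        table = aggregate(ws, config.bands, config.include_labels,
                          taper=config.taper)
        asym = hemispheric_diff(table, config.montage,
                                config.asymmetry_formula)
    except ValueError as exc:
        raise ProcessingError(f"[spectral/asymmetry] {exc}") from exc
    logger.info("windows: %d per channel, %d rejected; diffs: %s",
                ws.n_windows, n_rejected,
                {b: round(d, 2) for b, d in asym.per_band_diff_pp.items()})
    return ParticipantResult(band_table=table, asymmetry=asym,
                             windows=ws, n_rejected_windows=n_rejected)


def run_participant(csv_path, config: RunConfig = RunConfig(),
                    out_dir=None, participant_id=None) -> ParticipantResult:
    """Full run on one raw CSV; optionally export all intermediates."""
    try:
        rec = read_recording(csv_path, config.dialect, config.fs,
                             require_channels=config.montage.electrodes)
    except (OSError, ValueError) as exc:
        raise DataError(f"[ingest] {csv_path}: {exc}") from exc
    result = analyze_recording(rec, config)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = participant_id or Path(csv_path).stem
        result.band_table.to_tsv(out_dir / f"{stem}.bandpower.tsv")
        result.asymmetry.to_tsv(out_dir / f"{stem}.asymmetry.tsv",
                                config.tie_eps_pp)
        result.window_report_tsv(out_dir / f"{stem}.windows.tsv", config.fs)
        _write_provenance(out_dir / f"{stem}.run.json", config, {
            "participant": stem,
            "n_windows": result.windows.n_windows,
            "n_rejected_windows": result.n_rejected_windows,
            "diff_pp": result.asymmetry.per_band_diff_pp,
        })
    return result


def run_cohort(manifest: dict, config: RunConfig = RunConfig(),
               out_dir=None) -> tuple[GroupSummary,
                                      dict[str, ParticipantResult]]:
    """Run every included participant of a cohort and aggregate.

    ``manifest`` maps participant id → ``{"path": csv, **roster fields}``.
    The inclusion rule runs first and every included participant's file
    must exist before any processing starts.
    """
    roster = []
    for pid, entry in manifest.items():
        roster.append(ParticipantRecord(
            id=pid,
            gender=entry.get("gender", "?"),
            age=int(entry.get("age", 0)),
            hemiparesis=entry.get("hemiparesis", "?"),
            hemisphere_affected=entry.get("hemisphere_affected", "?"),
            aphasia_type=entry.get("aphasia_type", "unknown"),
        ))
    included, excluded = filter_cohort(roster)
    missing = [p.id for p in included
               if not Path(manifest[p.id].get("path", "")).exists()]
    if missing:
        raise DataError(
            f"missing recording file(s) for included participant(s): {missing}")

    results: dict[str, ParticipantResult] = {}
    for p in included:
        results[p.id] = run_participant(
            manifest[p.id]["path"], config,
            out_dir=out_dir, participant_id=p.id)
    summary = group_average(
        [results[p.id].asymmetry for p in included],
        tie_eps_pp=config.tie_eps_pp,
        participant_ids=[p.id for p in included],
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary.to_json(out_dir / "cohort.summary.json")
        _write_provenance(out_dir / "cohort.run.json", config, {
            "included": [p.id for p in included],
            "excluded": [{"id": i, "reason": r} for i, r in excluded],
        })
    return summary, results


def _write_provenance(path, config: RunConfig, payload: dict):
    doc = {"package_version": __version__,
           "config_hash": config.config_hash,
           "config": config.to_dict()}
    doc.update(payload)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, default=str)
    return path


# ---------------------------------------------------------------------------
# Reporting

def plot_asymmetry(diff_pp: dict[str, float], path, title: str = ""):
    """Signed bar chart of per-band diffs: right-greater bars up (positive),
    left-greater bars down (negative)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bands = list(diff_pp)
    values = [diff_pp[b] for b in bands]
    fig, ax = plt.subplots(figsize=(6, 4))
    colors = ["tab:blue" if v >= 0 else "tab:red" for v in values]
    ax.bar(bands, values, color=colors)
    ax.axhline(0.0, color="k", linewidth=0.8)
    ax.set_ylabel("right − left activation difference (pp)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
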