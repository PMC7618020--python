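"""Tie the stages together: file formats, cohort trees, and the full run.

The interchange format is deliberately plain: per subject, a little-endian
float32 channel-major binary matrix (``meg.dat``) next to a JSON sidecar
(``meg.json``) carrying dimensions, sampling rate, channel metadata and a
payload hash; the cohort level is a BIDS-style tree with a
``participants.tsv``.  A FIF reader is available as an optional adapter
(requires mne) for real gradiometer recordings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .complexity import ComplexityConfig, MissingMarkerError, lzsum_subject
from .preprocess import PreprocessConfig, preprocess_recording
from .spectral import SpectralConfig, tar_subject
from .stats import AnalysisReport, run_battery
from .synthetic import CohortSpec, Recording, SubjectMeta, iter_cohort

logger = logging.getLogger("megmarkers.pipeline")

__all__ = [
    "RunConfig",
    "write_recording",
    "read_recording",
    "write_cohort",
    "read_cohort",
    "read_fif",
    "subject_markers",
    "simulate_marker_table",
    "run_all",
]

PARTICIPANT_COLUMNS = ["participant_id", "group", "age", "sex", "site", "mmse"]


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    complexity: ComplexityConfig = field(default_factory=ComplexityConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    output_dir: str = "megmarkers_out"
    master_seed: int = 0
    log_level: str = "INFO"

    def seeded(self) -> "RunConfig":
        """Derive module seeds from the master seed (counter-based split)."""
        def child(k: int) -> int:
            ss = np.random.SeedSequence(self.master_seed, spawn_key=(1000 + k,))
            return int(ss.generate_state(1)[0] % (2 ** 31))
        return dataclasses.replace(
            self,
            cohort=dataclasses.replace(self.cohort, seed=child(0)),
            complexity=dataclasses.replace(self.complexity, seed=child(1)),
        )


# ---------------------------------------------------------------------------
# recording container
# ---------------------------------------------------------------------------

def write_recording(directory: str | Path, recording: Recording) -> Path:
    """Write ``meg.dat`` (little-endian float32, channel-major) + sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = np.ascontiguousarray(recording.data, dtype="<f4").tobytes()
    (directory / "meg.dat").write_bytes(payload)
    sidecar = {
        "sfreq_hz": recording.sfreq_hz,
        "n_channels": recording.n_channels,
        "n_samples": recording.n_samples,
        "channel_names": list(recording.channel_names),
        "channel_types": list(recording.channel_types),
        "units": "a.u.",
        "dtype": "<f4",
        "order": "channel-major",
        "sha256": hashlib.sha256(payload).hexdigest(),
    }
    (directory / "meg.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
    return directory


def read_recording(directory: str | Path) -> Recording:
    directory = Path(directory)
    sidecar_path = directory / "meg.json"
    data_path = directory / "meg.dat"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    if not data_path.exists():
        raise FileNotFoundError(f"missing data file {data_path}")
    sidecar = json.loads(sidecar_path.read_text())
    n_ch, n_sp = sidecar["n_channels"], sidecar["n_samples"]
    payload = data_path.read_bytes()
    expected = n_ch * n_sp * 4
    if len(payload) != expected:
        raise ValueError(
            f"{data_path}: sidecar promises {expected} bytes "
            f"({n_ch} ch x {n_sp} samples x 4), file has {len(payload)}"
        )
    data = np.frombuffer(payload, dtype="<f4").reshape(n_ch, n_sp)
    return Recording(data=data.astype(np.float64),
                     sfreq_hz=float(sidecar["sfreq_hz"]),
                     channel_names=list(sidecar["channel_names"]),
                     channel_types=list(sidecar["channel_types"]))


# ---------------------------------------------------------------------------
# cohort tree
# ---------------------------------------------------------------------------

def write_cohort(directory: str | Path, cohort) -> Path:
    """Write a BIDS-style tree: participants.tsv + sub-*/meg/ containers.

    ``cohort`` is any iterable of (SubjectMeta, Recording); it is consumed
    one subject at a time, so generators stream without holding the whole
    cohort in memory.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for meta, rec in cohort:
        rows.append({c: getattr(meta, c) for c in PARTICIPANT_COLUMNS})
        write_recording(directory / meta.participant_id / "meg", rec)
    table = pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS)
    if table["participant_id"].duplicated().any():
        raise ValueError("duplicated participant_id in cohort")
    table.to_csv(directory / "participants.tsv", sep="\t", index=False)
    return directory


def read_participants(directory: str | Path) -> pd.DataFrame:
    path = Path(directory) / "participants.tsv"
    if not path.exists():
        raise FileNotFoundError(f"missing {path}")
    table = pd.read_csv(path, sep="\t")
    absent = [c for c in PARTICIPANT_COLUMNS if c not in table.columns]
    if absent:
        raise ValueError(f"{path}: missing columns {absent}")
    dupes = table.loc[table["participant_id"].duplicated(), "participant_id"]
    if len(dupes):
        raise ValueError(
            f"{path}: duplicated participant_id {sorted(set(dupes))}"
        )
    return table.sort_values("participant_id").reset_index(drop=True)


def read_cohort(directory: str | Path) -> list[tuple[SubjectMeta, Recording]]:
    """Read a cohort tree back; subjects sorted by participant_id."""
    directory = Path(directory)
    table = read_participants(directory)
    out = []
    for row in table.itertuples(index=False):
        meta = SubjectMeta(participant_id=row.participant_id, group=row.group,
                           age=int(row.age), sex=row.sex, site=row.site,
                           mmse=int(row.mmse))
        rec = read_recording(directory / row.participant_id / "meg")
        out.append((meta, rec))
    return out


def read_fif(path: str | Path) -> Recording:
    """Optional adapter: load gradiometer channels from a FIF file.

    Magnetometers (and any other channel types) are dropped with a log
    line.  Requires mne.
    """
    try:
        import mne
    except ImportError as exc:                      # pragma: no cover
        raise ImportError("read_fif requires the optional mne dependency") from exc
    path = Path(path)
    try:
        raw = mne.io.read_raw_fif(path, preload=True, verbose="ERROR")
    except Exception as exc:
        raise ValueError(f"{path} is not a readable FIF file: {exc}") from exc
    picks = mne.pick_types(raw.info, meg="grad")
    if len(picks) == 0:
        raise ValueError(f"{path} contains no gradiometer channels")
    dropped = len(raw.ch_names) - len(picks)
    if dropped:
        logger.info("dropping %d non-gradiometer channels from %s",
                    dropped, path.name)
    names = [raw.ch_names[i] for i in picks]
    return Recording(data=raw.get_data(picks=picks),
                     sfreq_hz=float(raw.info["sfreq"]),
                     channel_names=names,
                     channel_types=["grad"] * len(names))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _subject_seed(master_seed: int, participant_index: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(2000 + participant_index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def subject_markers(
    recording: Recording,
    pre_cfg: PreprocessConfig,
    cx_cfg: ComplexityConfig,
    sp_cfg: SpectralConfig,
    apply_filters: bool = True,
) -> dict:
    """Preprocess one recording and compute both markers.

    Returns a dict with subject-level ``lzsum`` and ``tar`` (NaN when no
    valid epoch survives), the per-epoch tables, and the rejection log.
    """
    epochs = preprocess_recording(recording, pre_cfg, apply_filters=apply_filters)
    out = {"n_epochs": epochs.n_epochs, "n_kept": epochs.n_kept,
           "rejection_log": epochs.rejection_log}
    try:
        out["lzsum"], out["lzsum_table"] = lzsum_subject(epochs, cx_cfg)
    except MissingMarkerError:
        logger.warning("subject has no kept epochs: LZsum missing")
        out["lzsum"], out["lzsum_table"] = float("nan"), pd.DataFrame()
    try:
        out["tar"], out["tar_table"] = tar_subject(epochs, sp_cfg)
    except MissingMarkerError:
        logger.warning("subject has no valid epochs: TAR missing")
        out["tar"], out["tar_table"] = float("nan"), pd.DataFrame()
    return out


def simulate_marker_table(config: RunConfig) -> pd.DataFrame:
    """Generate a cohort and compute the subject-level marker table.

    Streams subject by subject (no files written); the workhorse for
    simulation studies such as type-I-error or power estimation.
    """
    cfg = config.seeded()
    rows = []
    for i, (meta, rec) in enumerate(iter_cohort(cfg.cohort)):
        cx = dataclasses.replace(cfg.complexity,
                                 seed=_subject_seed(cfg.master_seed, i))
        res = subject_markers(rec, cfg.preprocess, cx, cfg.spectral)
        row = {c: getattr(meta, c) for c in PARTICIPANT_COLUMNS}
        row.update(lzsum=res["lzsum"], tar=res["tar"],
                   n_epochs=res["n_epochs"], n_kept=res["n_kept"])
        rows.append(row)
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> AnalysisReport:
    """simulate -> preprocess -> markers -> battery, writing the output tree.

    Writes the cohort tree, per-epoch and per-subject marker CSVs, per
    subject rejection reports, the analysis report JSON, and a run manifest
    with every tunable, so a rerun with the same config is byte-identical.
    """
    cfg = config.seeded()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort_dir = out_dir / "cohort"
    rej_dir = out_dir / "rejection_reports"
    rej_dir.mkdir(exist_ok=True)

    meta_rows, marker_rows, epoch_frames = [], [], []
    for i, (meta, rec) in enumerate(iter_cohort(cfg.cohort)):
        write_recording(cohort_dir / meta.participant_id / "meg", rec)
        meta_rows.append({c: getattr(meta, c) for c in PARTICIPANT_COLUMNS})
        cx = dataclasses.replace(cfg.complexity,
                                 seed=_subject_seed(cfg.master_seed, i))
        try:
            res = subject_markers(rec, cfg.preprocess, cx, cfg.spectral)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'markers' failed for subject {meta.participant_id}: {exc}"
            ) from exc
        (rej_dir / f"{meta.participant_id}.json").write_text(
            json.dumps(res["rejection_log"], indent=2, sort_keys=True) + "\n"
        )
        row = {c: getattr(meta, c) for c in PARTICIPANT_COLUMNS}
        row.update(lzsum=res["lzsum"], tar=res["tar"],
                   n_epochs=res["n_epochs"], n_kept=res["n_kept"])
        marker_rows.append(row)
        for key in ("lzsum_table", "tar_table"):
            tab = res[key].copy()
            if not tab.empty:
                tab.insert(0, "participant_id", meta.participant_id)
                epoch_frames.append(tab)

    pd.DataFrame(meta_rows, columns=PARTICIPANT_COLUMNS).to_csv(
        cohort_dir / "participants.tsv", sep="\t", index=False)
    markers = pd.DataFrame(marker_rows)
    markers.to_csv(out_dir / "markers_subject.csv", index=False)
    if epoch_frames:
        per_epoch = pd.concat(epoch_frames, ignore_index=True)
        per_epoch.to_csv(out_dir / "markers_epoch.csv", index=False)

    report = run_battery(markers)
    (out_dir / "analysis_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    manifest = {
        "software": {"name": "megmarkers", "version": __version__},
        "master_seed": cfg.master_seed,
        "config": {
            "cohort": dataclasses.asdict(cfg.cohort),
            "preprocess": dataclasses.asdict(cfg.preprocess),
            "complexity": dataclasses.asdict(cfg.complexity),
            "spectral": dataclasses.asdict(cfg.spectral),
        },
        "n_subjects": len(markers),
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return report
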