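"""Dataset container and format readers/writers.

A generated dataset lives under one directory:

    dataset/
      manifest.yaml                 # schema, config echo, per-run file index
      ratings.csv                   # subject, first_id, second_id, rating
      sub-01/run-01.edf             # continuous EEG, one EDF per run
      sub-01/run-01_events.tsv      # sample, stimulus_id, run, session, part, target_id
      ...

Continuous EEG is written as plain EDF (16-bit) by a small writer in this
module; reading goes through ``mne.io.read_raw_edf`` so the files stay
interoperable with standard EEG tooling.  Recordings are zero-padded to a
whole number of 1-second data records on write.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import ContinuousRecording, EventList, SimConfig

SCHEMA_VERSION = 1

EVENT_COLUMNS = ["sample", "stimulus_id", "run", "session", "part",
                 "target_id"]


class DatasetError(Exception):
    """Base class for dataset validation problems."""


class MissingFileError(DatasetError):
    pass


class ChannelMismatchError(DatasetError):
    pass


class SchemaError(DatasetError):
    pass


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field '{s}' longer than {width}")
    return s.ljust(width).encode("ascii")


def write_edf(path, recording: ContinuousRecording, *,
              patient_id: str = "X", recording_id: str = "affectp300") -> None:
    """Write a ContinuousRecording as a plain EDF file (16-bit, uV).

    Uses 1-second data records; the signal is zero-padded to a whole number
    of records.  The physical range is chosen symmetric around zero from the
    data so quantization error stays below ~0.01% of the peak.
    """
    data = np.asarray(recording.samples, dtype=float)
    n_ch, n_times = data.shape
    fs = recording.sample_rate
    spr = int(round(fs))  # samples per 1 s record
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    n_rec = int(np.ceil(n_times / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n_times] = data

    pmax = max(float(np.abs(padded).max()) * 1.05, 1.0)
    pmax = float(f"{pmax:.6g}")  # must round-trip through an 8-char field
    pmin = -pmax
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((padded - pmin) * scale + dmin).astype("<i2")

    header = b"".join([
        _edf_field("0", 8),
        _edf_field(patient_id, 80),
        _edf_field(recording_id, 80),
        _edf_field("01.01.01", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 + 256 * n_ch, 8),
        _edf_field("", 44),
        _edf_field(n_rec, 8),
        _edf_field(1, 8),
        _edf_field(n_ch, 4),
    ])
    sig = b"".join([
        b"".join(_edf_field(lbl, 16) for lbl in recording.channels),
        b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(n_ch)),
        b"".join(_edf_field("uV", 8) for _ in range(n_ch)),
        b"".join(_edf_field(f"{pmin:.6g}", 8) for _ in range(n_ch)),
        b"".join(_edf_field(f"{pmax:.6g}", 8) for _ in range(n_ch)),
        b"".join(_edf_field(dmin, 8) for _ in range(n_ch)),
        b"".join(_edf_field(dmax, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_field(spr, 8) for _ in range(n_ch)),
        b"".join(_edf_field("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for rec in range(n_rec):
            chunk = digital[:, rec * spr:(rec + 1) * spr]
            fh.write(chunk.tobytes())


def read_edf(path) -> ContinuousRecording:
    """Read an EDF file back into a ContinuousRecording (microvolts)."""
    import mne  # imported lazily; mne's import is slow

    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"EDF file not found: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # corrupt/truncated file
        raise DatasetError(f"cannot parse EDF file {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # mne returns volts
    return ContinuousRecording(samples=data, sample_rate=float(raw.info["sfreq"]),
                               channels=tuple(raw.ch_names))


def write_events(path, events: EventList) -> None:
    """Events as tab-separated text (one row per stimulus onset)."""
    frame = pd.DataFrame({
        "sample": events.onsets,
        "stimulus_id": events.stimulus_ids,
        "run": events.run_id,
        "session": events.session_id,
        "part": events.part_id,
        "target_id": events.target_id,
    })
    frame.to_csv(path, sep="\t", index=False)


def read_events(path) -> EventList:
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"events file not found: {path}")
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"events file {path} missing columns {missing}")
    return EventList(onsets=frame["sample"].to_numpy(dtype=int),
                     stimulus_ids=frame["stimulus_id"].to_numpy(dtype=int),
                     run_id=int(frame["run"].iloc[0]),
                     session_id=int(frame["session"].iloc[0]),
                     part_id=int(frame["part"].iloc[0]),
                     target_id=int(frame["target_id"].iloc[0]))


def write_ratings(path, ratings: pd.DataFrame) -> None:
    ratings.to_csv(path, index=False)


def read_ratings(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MissingFileError(f"ratings file not found: {path}")
    return pd.read_csv(path)


@dataclass
class Dataset:
    """Lazy handle on a written dataset; runs are loaded on demand."""

    root: Path
    manifest: dict

    @property
    def subjects(self) -> list[int]:
        return [s["id"] for s in self.manifest["subjects"]]

    @property
    def config(self) -> SimConfig:
        cfg = dict(self.manifest["config"])
        for key in ("channels", "true_valences", "subject_amp_range"):
            if key in cfg and isinstance(cfg[key], list):
                cfg[key] = tuple(cfg[key])
        return SimConfig(**cfg)

    def _subject_entry(self, subject: int) -> dict:
        for s in self.manifest["subjects"]:
            if s["id"] == subject:
                return s
        raise KeyError(f"subject {subject} not in dataset")

    def load_run(self, subject: int, run_index: int
                 ) -> tuple[ContinuousRecording, EventList]:
        entry = self._subject_entry(subject)["runs"][run_index]
        rec = read_edf(self.root / entry["edf"])
        expected = tuple(self.manifest["config"]["channels"])
        if rec.channels != expected:
            raise ChannelMismatchError(
                f"{entry['edf']}: channels {rec.channels} != montage "
                f"{expected}")
        return rec, read_events(self.root / entry["events"])

    def iter_runs(self, subject: int):
        n = len(self._subject_entry(subject)["runs"])
        for r in range(n):
            yield self.load_run(subject, r)

    def ratings(self) -> pd.DataFrame:
        return read_ratings(self.root / self.manifest["ratings"])


def write_dataset(config: SimConfig, outdir, subjects=None) -> Dataset:
    """Generate and write a full dataset directory for ``config``.

    ``subjects`` restricts generation to a subset of subject indices
    (0-based); defaults to all ``config.n_subjects``.
    """
    from .simulate import generate_run, simulate_ratings

    root = Path(outdir)
    root.mkdir(parents=True, exist_ok=True)
    subject_list = list(subjects) if subjects is not None \
        else list(range(config.n_subjects))
    manifest: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config": _config_dict(config),
        "ratings": "ratings.csv",
        "subjects": [],
    }
    for subject in subject_list:
        sub_id = subject + 1
        sub_dir = root / f"sub-{sub_id:02d}"
        sub_dir.mkdir(exist_ok=True)
        runs = []
        for r in range(config.runs_per_subject):
            rec, ev = generate_run(config, subject, r)
            edf_rel = f"sub-{sub_id:02d}/run-{r + 1:02d}.edf"
            ev_rel = f"sub-{sub_id:02d}/run-{r + 1:02d}_events.tsv"
            write_edf(root / edf_rel, rec)
            write_events(root / ev_rel, ev)
            runs.append({"edf": edf_rel, "events": ev_rel})
        manifest["subjects"].append({"id": sub_id, "runs": runs})
    ratings = simulate_ratings(config.true_valences, config.n_subjects,
                               config.rating_noise_sd,
                               config.rating_order_effect, config.seed)
    write_ratings(root / "ratings.csv", ratings)
    with open(root / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return Dataset(root=root, manifest=manifest)


def _config_dict(config: SimConfig) -> dict:
    from dataclasses import asdict

    d = asdict(config)
    for key, val in d.items():
        if isinstance(val, tuple):
            d[key] = list(val)
    return d


def read_dataset(path, validate: bool = True) -> Dataset:
    """Open a dataset directory, validating the manifest.

    Validation checks schema version, that every referenced file exists, and
    that each subject has the expected number of runs.
    """
    root = Path(path)
    manifest_path = root / "manifest.yaml"
    if not manifest_path.exists():
        raise MissingFileError(f"no manifest.yaml under {root}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if manifest.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported schema version {manifest.get('schema_version')}")
    ds = Dataset(root=root, manifest=manifest)
    if validate:
        cfg = ds.config
        for s in manifest["subjects"]:
            if len(s["runs"]) != cfg.runs_per_subject:
                raise SchemaError(
                    f"subject {s['id']} has {len(s['runs'])} runs; expected "
                    f"{cfg.runs_per_subject}")
            for entry in s["runs"]:
                for key in ("edf", "events"):
                    if not (root / entry[key]).exists():
                        raise MissingFileError(
                            f"missing file for subject {s['id']}: "
                            f"{entry[key]}")
        if not (root / manifest["ratings"]).exists():
            raise MissingFileError("missing ratings file")
    return ds
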