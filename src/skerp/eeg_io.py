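"""Read/write continuous EEG with event markers, and behavioral trial tables.

EEG travels as a BrainVision-style triplet: a text header (``.vhdr``), a text
marker file (``.vmrk``) and multiplexed IEEE float32 binary data in microvolts
(``.eeg``).  Stimulus markers follow amplifier conventions: ``S  1`` marks a
ball release, ``S  2`` the KR feedback moment.  Trial tables are TSV with a
fixed header and full-precision floats.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecording",
    "SCALP_CHANNELS",
    "EOG_CHANNELS",
    "MASTOID_CHANNEL",
    "DEFAULT_CHANNELS",
    "TRIAL_TABLE_COLUMNS",
    "TRIAL_LABELS",
    "write_brainvision",
    "read_brainvision",
    "write_trial_table",
    "read_trial_table",
]

SCALP_CHANNELS = ("F3", "Fz", "F4", "FCz", "C3", "Cz", "C4", "P3", "Pz", "P4")
MASTOID_CHANNEL = "M2"
EOG_CHANNELS = ("HEOGL", "HEOGR", "VEOGU", "VEOGD")
DEFAULT_CHANNELS = SCALP_CHANNELS + (MASTOID_CHANNEL,) + EOG_CHANNELS

TRIAL_TABLE_COLUMNS = ["participant", "trial", "theta", "theta_dot",
                       "min_distance", "label", "t_kr", "release_time"]
TRIAL_LABELS = frozenset({"hit", "error", "post_hit"})

_RELEASE_DESC = "S  1"
_FEEDBACK_DESC = "S  2"


@dataclass
class EEGRecording:
    """Continuous multichannel EEG (microvolts) with labelled event markers.

    ``events`` holds ``(label, trial_id, sample_index)`` tuples with label
    ``release`` or ``feedback``.  ``reference`` documents the montage:
    ``left_mastoid`` as recorded online, ``averaged_mastoids`` after offline
    re-referencing.
    """

    ch_names: list[str]
    sfreq: float
    data: np.ndarray  # (n_channels, n_samples), microvolts
    events: list[tuple[str, int, int]] = field(default_factory=list)
    reference: str = "left_mastoid"
    extra_markers: list[tuple[str, str, int]] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.ch_names):
            raise ValueError("data must be (n_channels, n_samples)")
        n = self.data.shape[1]
        for label, trial, sample in self.events:
            if not 0 <= sample < n:
                raise ValueError(f"event sample {sample} outside record")
        rel = [t for (lbl, t, _) in self.events if lbl == "release"]
        if any(b <= a for a, b in zip(rel, rel[1:])):
            raise ValueError("release events must be strictly increasing in trial id")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def ch_index(self, name: str) -> int:
        return self.ch_names.index(name)

    def get(self, name: str) -> np.ndarray:
        """View of one channel's samples."""
        return self.data[self.ch_index(name)]

    def events_of(self, label: str) -> list[tuple[int, int]]:
        """(trial_id, sample) pairs for one marker label, in file order."""
        return [(t, s) for (lbl, t, s) in self.events if lbl == label]

    def copy(self) -> "EEGRecording":
        return EEGRecording(list(self.ch_names), self.sfreq, self.data.copy(),
                            list(self.events), self.reference,
                            list(self.extra_markers))


def _paths(basepath) -> tuple[Path, Path, Path]:
    base = Path(basepath)
    if base.suffix in {".vhdr", ".vmrk", ".eeg"}:
        base = base.with_suffix("")
    return (base.with_suffix(".vhdr"), base.with_suffix(".vmrk"),
            base.with_suffix(".eeg"))


def write_brainvision(rec: EEGRecording, basepath) -> tuple[Path, Path, Path]:
    """Write header/marker/binary triplet; returns the three paths.

    Data are stored as multiplexed IEEE float32 in microvolts, so a
    round-trip is exact up to float32 quantization.  Marker positions are
    1-based sample indices per the file-format convention.
    """
    if not np.all(np.isfinite(rec.data)):
        raise ValueError("non-finite samples cannot be written")
    vhdr, vmrk, eeg = _paths(basepath)

    hdr = io.StringIO()
    hdr.write("Brain Vision Data Exchange Header File Version 1.0\n")
    hdr.write("; written by skerp\n\n")
    hdr.write("[Common Infos]\n")
    hdr.write("Codepage=UTF-8\n")
    hdr.write(f"DataFile={eeg.name}\n")
    hdr.write(f"MarkerFile={vmrk.name}\n")
    hdr.write("DataFormat=BINARY\n")
    hdr.write("DataOrientation=MULTIPLEXED\n")
    hdr.write(f"NumberOfChannels={len(rec.ch_names)}\n")
    hdr.write(f"SamplingInterval={1e6 / rec.sfreq:.10g}\n\n")
    hdr.write("[Binary Infos]\n")
    hdr.write("BinaryFormat=IEEE_FLOAT_32\n\n")
    hdr.write("[Channel Infos]\n")
    for i, name in enumerate(rec.ch_names, start=1):
        hdr.write(f"Ch{i}={name},,1,µV\n")
    hdr.write("\n[Comment]\n")
    hdr.write(f"Reference: {rec.reference}\n")
    vhdr.write_text(hdr.getvalue(), encoding="utf-8")

    mrk = io.StringIO()
    mrk.write("Brain Vision Data Exchange Marker File, Version 1.0\n\n")
    mrk.write("[Common Infos]\n")
    mrk.write("Codepage=UTF-8\n")
    mrk.write(f"DataFile={eeg.name}\n\n")
    mrk.write("[Marker Infos]\n")
    mrk.write("Mk1=New Segment,,1,1,0,00000000000000000000\n")
    k = 2
    for label, trial, sample in sorted(rec.events, key=lambda e: (e[2], e[0])):
        desc = _RELEASE_DESC if label == "release" else _FEEDBACK_DESC
        mrk.write(f"Mk{k}=Stimulus,{desc},{sample + 1},1,0\n")
        k += 1
    for mtype, desc, sample in rec.extra_markers:
        mrk.write(f"Mk{k}={mtype},{desc},{sample + 1},1,0\n")
        k += 1
    vmrk.write_text(mrk.getvalue(), encoding="utf-8")

    rec.data.T.astype("<f4").tofile(eeg)
    return vhdr, vmrk, eeg


def _parse_ini(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = {}
        elif "=" in line and current is not None:
            key, _, val = line.partition("=")
            sections[current][key.strip()] = val.strip()
    return sections


def read_brainvision(basepath) -> EEGRecording:
    """Read a header/marker/binary triplet written by :func:`write_brainvision`.

    Release/feedback stimulus markers are paired in file order: the k-th
    ``S  1`` marker is trial k's release and each ``S  2`` marker is assigned
    the trial id of the latest preceding release.  Unknown marker types are
    preserved in ``extra_markers`` and ignored downstream.
    """
    vhdr, vmrk, eeg = _paths(basepath)
    hdr = _parse_ini(vhdr.read_text(encoding="utf-8"))
    common = hdr.get("Common Infos", {})
    if common.get("DataFormat", "BINARY") != "BINARY":
        raise ValueError("only BINARY data format is supported")
    if common.get("DataOrientation", "MULTIPLEXED") != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED orientation is supported")
    binfmt = hdr.get("Binary Infos", {}).get("BinaryFormat", "IEEE_FLOAT_32")
    if binfmt != "IEEE_FLOAT_32":
        raise ValueError(f"unsupported binary format {binfmt!r}")
    n_ch = int(common["NumberOfChannels"])
    sfreq = 1e6 / float(common["SamplingInterval"])
    ch_names = []
    for i in range(1, n_ch + 1):
        entry = hdr["Channel Infos"][f"Ch{i}"]
        ch_names.append(entry.split(",")[0])

    raw = np.fromfile(eeg, dtype="<f4")
    if raw.size % n_ch:
        raise ValueError(
            f"format error: {raw.size * 4} data bytes not divisible by "
            f"{n_ch} channels * 4 bytes")
    data = raw.reshape(-1, n_ch).T.astype(float)

    reference = "left_mastoid"
    for line in vhdr.read_text(encoding="utf-8").splitlines():
        if line.startswith("Reference:"):
            reference = line.split(":", 1)[1].strip()

    events: list[tuple[str, int, int]] = []
    extra: list[tuple[str, str, int]] = []
    trial = 0
    mrk = vmrk.read_text(encoding="utf-8")
    for line in mrk.splitlines():
        line = line.strip()
        if not line.startswith("Mk") or "=" not in line:
            continue
        _, _, val = line.partition("=")
        parts = val.split(",")
        if len(parts) < 5:
            continue
        mtype, desc, pos = parts[0], parts[1], int(parts[2]) - 1
        if mtype == "Stimulus" and desc == _RELEASE_DESC:
            trial += 1
            events.append(("release", trial, pos))
        elif mtype == "Stimulus" and desc == _FEEDBACK_DESC:
            events.append(("feedback", max(trial, 1), pos))
        elif mtype != "New Segment":
            extra.append((mtype, desc, pos))
    return EEGRecording(ch_names, sfreq, data, events, reference, extra)


def write_trial_table(trials: pd.DataFrame, path) -> Path:
    """TSV trial table with fixed columns; floats at repr precision so the
    file round-trips bitwise."""
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    path = Path(path)
    trials[TRIAL_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_trial_table(path) -> pd.DataFrame:
    """Read a TSV trial table, enforcing columns and the label vocabulary."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    bad = ~df["label"].isin(TRIAL_LABELS)
    if bad.any():
        row = int(np.nonzero(bad.to_numpy())[0][0])
        raise ValueError(
            f"unknown label {df['label'].iloc[row]!r} in row {row + 2} of {path}")
    return df[TRIAL_TABLE_COLUMNS]
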