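"""In-memory signal model, scalp-montage metadata and file I/O.

The canonical container is :class:`Recording`: a channels-by-samples matrix of
scalp potentials in microvolts together with the sampling rate and ordered
10-20-system channel labels.  Channels are always rows and sample indices are
0-based; every stage of the pipeline relies on this single orientation.

Supported on-disk formats:

``delimited``
    Plain-text numeric matrix, comma or tab separated, one channel per row.
``npz``
    Self-describing binary array container (NumPy ``.npz``) holding the data
    matrix, sampling rate, labels and optional trial metadata.  Lossless.
``edf``
    European Data Format, read through :mod:`mne` (read-only).
``mat``
    MATLAB container.  Both the classic v5 layout (:mod:`scipy.io`) and the
    HDF5-based v7.3 layout (:mod:`h5py`) are read; v5 is written.  This is the
    layout in which 62-channel, 200 Hz emotion-trial corpora such as SEED are
    distributed (one 2-D array per trial).

Amplitudes are passed through unchanged; callers converting from volts or
millivolts apply ``scale`` at read time (thresholding downstream assumes
microvolts).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .errors import DataError, FormatError, MetadataError

__all__ = [
    "Recording",
    "LobeMap",
    "ESI62_LABELS",
    "LOBE_ORDER",
    "default_lobe_map",
    "read_recording",
    "write_recording",
]

#: Electrode order of the 62-channel ESI cap used by the SEED corpus
#: (channel 45 is P1, channel 56 is PO6, counting from 1).
ESI62_LABELS: tuple[str, ...] = (
    "FP1", "FPZ", "FP2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "CB1", "O1", "OZ", "O2", "CB2",
)

#: Fixed cascade order of the five analysis lobes.
LOBE_ORDER: tuple[str, ...] = (
    "prefrontal", "frontal", "central", "parietal", "occipital",
)


@dataclass
class Recording:
    """A multichannel scalp recording (channels x samples, microvolts)."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str | None = None
    trial_id: str | None = None
    state_label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError(
                f"expected a 2-D channels x samples matrix, got ndim={self.data.ndim}"
            )
        if self.fs <= 0:
            raise MetadataError(f"sampling rate must be positive, got {self.fs}")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.data.shape[0]:
            raise MetadataError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channel rows"
            )
        bad = ~np.isfinite(self.data).all(axis=1)
        if bad.any():
            names = [self.channel_labels[i] for i in np.flatnonzero(bad)]
            raise DataError(f"non-finite samples in channel(s): {', '.join(names)}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, channel_labels: list[str] | None = None) -> "Recording":
        """Copy of this recording with new samples (and optionally labels)."""
        return replace(
            self,
            data=data,
            channel_labels=list(channel_labels if channel_labels is not None else self.channel_labels),
        )

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class LobeMap:
    """Assignment of montage labels to the five analysis lobes.

    The mapping is configuration, not code: it can be edited, serialized to
    YAML and reloaded.  Lobes must be disjoint, and mapped plus excluded
    labels must together cover the montage they are applied to.
    """

    lobes: dict[str, list[str]]
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for lobe, labels in self.lobes.items():
            for lab in labels:
                if lab in seen:
                    raise MetadataError(f"label {lab!r} assigned to more than one lobe")
                seen.add(lab)
        overlap = seen.intersection(self.excluded)
        if overlap:
            raise MetadataError(f"labels both mapped and excluded: {sorted(overlap)}")

    def lobe_of(self, label: str) -> str | None:
        for lobe, labels in self.lobes.items():
            if label in labels:
                return lobe
        return None

    @property
    def mapped_labels(self) -> list[str]:
        return [lab for lobe in self.lobes.values() for lab in lobe]

    def validate_against(self, channel_labels: list[str]) -> None:
        """Check that the map exactly covers ``channel_labels``."""
        montage = set(channel_labels)
        for lab in self.mapped_labels:
            if lab not in montage:
                raise MetadataError(f"mapped label {lab!r} not present in montage")
        covered = set(self.mapped_labels) | set(self.excluded)
        missing = montage - covered
        if missing:
            raise MetadataError(f"labels neither mapped nor excluded: {sorted(missing)}")

    def to_yaml(self, path: str) -> str:
        with open(path, "w") as fh:
            yaml.safe_dump({"lobes": self.lobes, "excluded": self.excluded}, fh)
        return path

    @classmethod
    def from_yaml(cls, path: str) -> "LobeMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(lobes={k: list(v) for k, v in doc["lobes"].items()},
                   excluded=list(doc.get("excluded", [])))


def _classify_label(label: str) -> str | None:
    """Rule-based 10-20/10-10 label -> lobe assignment.

    Fronto-central, temporal, centro-parietal and cerebellar sites (FT*, FC*,
    T*, TP*, CP*, CB*) are deliberately unassigned: with the five-lobe scheme
    on a 62-channel cap this excludes exactly 22 channels.
    """
    lab = label.upper().rstrip("ZH")
    core = lab.rstrip("0123456789")
    if core in ("FP", "AF", "AFP"):
        return "prefrontal"
    if core == "F":
        return "frontal"
    if core == "C":
        return "central"
    if core == "P":
        return "parietal"
    if core in ("O", "PO", "POO", "I"):
        return "occipital"
    return None


def default_lobe_map(channel_labels: list[str] | tuple[str, ...] = ESI62_LABELS) -> LobeMap:
    """Build the shipped five-lobe assignment for a montage.

    Unknown labels land in the excluded list; nothing errors.  The result is
    a best-effort reconstruction for extended 10-20 caps and is meant to be
    user-overridable (see :meth:`LobeMap.from_yaml`).
    """
    lobes: dict[str, list[str]] = {name: [] for name in LOBE_ORDER}
    excluded: list[str] = []
    for lab in channel_labels:
        lobe = _classify_label(lab)
        if lobe is None:
            excluded.append(lab)
        else:
            lobes[lobe].append(lab)
    return LobeMap(lobes=lobes, excluded=excluded)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_FORMATS = ("delimited", "npz", "edf", "mat")

_EXT_TO_FORMAT = {
    ".csv": "delimited", ".tsv": "delimited", ".txt": "delimited",
    ".npz": "npz", ".edf": "edf", ".mat": "mat",
}


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise FormatError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext not in _EXT_TO_FORMAT:
        raise FormatError(f"cannot infer format from extension {ext!r}; pass format=")
    return _EXT_TO_FORMAT[ext]


def _read_delimited(path: str) -> np.ndarray:
    for delim in (",", "\t", None):
        try:
            arr = np.loadtxt(path, delimiter=delim, ndmin=2)
        except ValueError:
            continue
        return arr
    raise FormatError(f"{path}: not parseable as a delimited numeric matrix")


def _read_mat(path: str, key: str | None) -> np.ndarray:
    """Read a 2-D array from a MATLAB container (v5 or v7.3)."""
    import h5py
    import scipy.io

    def _numeric_2d(arr: np.ndarray) -> bool:
        # a signal matrix, not a stored scalar like the sampling rate
        return (arr.ndim == 2 and np.issubdtype(arr.dtype, np.number)
                and arr.size > 1)

    if h5py.is_hdf5(path):  # v7.3 layout
        arrays = {}
        with h5py.File(path, "r") as fh:
            def collect(name, obj):
                if hasattr(obj, "shape") and len(obj.shape) == 2:
                    cand = np.asarray(obj[()])
                    if _numeric_2d(cand):
                        # MATLAB stores column-major; transpose back
                        arrays[name] = cand.T
            fh.visititems(collect)
    else:
        try:
            doc = scipy.io.loadmat(path)
        except (OSError, ValueError, NotImplementedError) as exc:
            raise FormatError(f"{path}: not a readable MATLAB container ({exc})") from exc
        arrays = {k: np.asarray(v) for k, v in doc.items()
                  if not k.startswith("__") and _numeric_2d(np.asarray(v))}
    if key is None and len(arrays) > 1 and "eeg" in arrays:
        key = "eeg"  # our own writer's layout
    if key is not None:
        if key not in arrays:
            raise FormatError(f"{path}: no 2-D array named {key!r} (found {sorted(arrays)})")
        return arrays[key]
    if len(arrays) != 1:
        raise FormatError(
            f"{path}: expected exactly one 2-D array, found {sorted(arrays)}; pass key="
        )
    return next(iter(arrays.values()))


def read_recording(
    path: str,
    format: str | None = None,
    fs: float | None = None,
    labels: list[str] | None = None,
    scale: float = 1.0,
    key: str | None = None,
    **metadata: str | None,
) -> Recording:
    """Read a multichannel recording from disk.

    Parameters
    ----------
    path, format
        File location; format inferred from the extension when omitted.
    fs, labels
        Required for formats without embedded metadata (delimited, mat).
        Labels default to ``CH01..CHnn`` when omitted.
    scale
        Multiplier applied to amplitudes; use ``1e6`` for files stored in
        volts so the in-memory unit is microvolts.
    key
        Array name inside a MATLAB container (one-array files need no key).
    """
    fmt = _infer_format(path, format)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")

    if fmt == "delimited":
        data = _read_delimited(path)
    elif fmt == "npz":
        with np.load(path, allow_pickle=False) as doc:
            data = doc["data"]
            fs = float(doc["fs"]) if fs is None else fs
            if labels is None and "channel_labels" in doc:
                labels = [str(s) for s in doc["channel_labels"]]
            for k in ("subject_id", "trial_id", "state_label"):
                if k in doc and metadata.get(k) is None:
                    v = str(doc[k])
                    metadata[k] = None if v == "" else v
    elif fmt == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - mne is preinstalled
            raise FormatError("EDF support requires mne") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne returns volts
        fs = float(raw.info["sfreq"]) if fs is None else fs
        labels = list(raw.ch_names) if labels is None else labels
    elif fmt == "mat":
        data = _read_mat(path, key)
    else:  # pragma: no cover
        raise FormatError(fmt)

    data = np.asarray(data, dtype=float) * scale
    if fs is None:
        raise MetadataError(f"format {fmt!r} carries no sampling rate; pass fs=")
    if labels is None:
        labels = [f"CH{i + 1:02d}" for i in range(data.shape[0])]
    return Recording(data=data, fs=fs, channel_labels=list(labels), **metadata)


def write_recording(rec: Recording, path: str, format: str | None = None) -> str:
    """Write a recording; returns the path.

    The ``npz`` container round-trips bit-exactly; ``delimited`` keeps 10
    significant digits (max abs error below 1e-8 microvolts on unit-scale
    data).  EDF export is not supported.
    """
    fmt = _infer_format(path, format)
    if rec.n_samples == 0:
        raise DataError("refusing to write an empty recording (0 samples)")
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise FormatError(f"destination directory does not exist: {parent}")

    if fmt == "delimited":
        delim = "\t" if path.endswith(".tsv") else ","
        np.savetxt(path, rec.data, fmt="%.10g", delimiter=delim)
    elif fmt == "npz":
        np.savez(
            path,
            data=rec.data,
            fs=rec.fs,
            channel_labels=np.asarray(rec.channel_labels),
            subject_id=rec.subject_id or "",
            trial_id=rec.trial_id or "",
            state_label=rec.state_label or "",
        )
    elif fmt == "mat":
        import scipy.io

        scipy.io.savemat(path, {"eeg": rec.data, "fs": rec.fs,
                                "channel_labels": rec.channel_labels})
    elif fmt == "edf":
        raise FormatError("EDF export is not supported; use the npz container")
    else:  # pragma: no cover
        raise FormatError(fmt)
    return path
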