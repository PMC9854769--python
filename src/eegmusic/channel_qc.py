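"""Amplitude screening for overshooting (corrupt) channels.

Clean scalp EEG lives in the 10-100 microvolt range; electrode leakage and
EMG bleed-through produce channels whose peaks reach 0.6-10 mV.  Screening is
on the per-channel maximum absolute amplitude over the whole trial (matching
the "ranges up to" character of such faults, not their RMS).  The default
threshold of 500 uV sits inside the guaranteed gap between the two regimes
and is exposed everywhere as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, MetadataError
from .recordings_io import Recording

__all__ = [
    "DEFAULT_THRESHOLD_UV",
    "ChannelQCReport",
    "QCSummary",
    "detect_corrupt_channels",
    "qc_summary",
    "mask_channels",
]

DEFAULT_THRESHOLD_UV: float = 500.0


@dataclass
class ChannelQCReport:
    """Per-channel amplitude extrema and corrupt flags for one trial."""

    channel_labels: list[str]
    max_abs_uv: np.ndarray  # per-channel max |x|, microvolts
    threshold_uv: float
    corrupt_flags: np.ndarray  # boolean, flag i <=> max|x_i| > threshold
    subject_id: str | None = None
    trial_id: str | None = None
    state_label: str | None = None

    @property
    def n_corrupt(self) -> int:
        return int(self.corrupt_flags.sum())

    @property
    def corrupt_labels(self) -> list[str]:
        return [self.channel_labels[i] for i in np.flatnonzero(self.corrupt_flags)]

    def to_frame(self) -> pd.DataFrame:
        """One row per channel, serializable as CSV."""
        return pd.DataFrame({
            "channel": self.channel_labels,
            "max_abs_uv": self.max_abs_uv,
            "threshold_uv": self.threshold_uv,
            "corrupt": self.corrupt_flags,
            "subject_id": self.subject_id,
            "trial_id": self.trial_id,
            "state_label": self.state_label,
        })


def detect_corrupt_channels(rec: Recording,
                            threshold_uv: float = DEFAULT_THRESHOLD_UV) -> ChannelQCReport:
    """Flag every channel whose peak absolute amplitude exceeds the threshold."""
    if threshold_uv <= 0:
        raise DataError(f"threshold must be positive, got {threshold_uv}")
    if rec.n_samples == 0 or rec.n_channels == 0:
        raise DataError("cannot screen an empty recording")
    max_abs = np.abs(rec.data).max(axis=1)
    return ChannelQCReport(
        channel_labels=list(rec.channel_labels),
        max_abs_uv=max_abs,
        threshold_uv=float(threshold_uv),
        corrupt_flags=max_abs > threshold_uv,
        subject_id=rec.subject_id,
        trial_id=rec.trial_id,
        state_label=rec.state_label,
    )


@dataclass
class QCSummary:
    """Dataset-level QC: corrupt-trial counts per (state, subject) cell."""

    table: pd.DataFrame  # rows = states, columns = subjects, values = counts
    n_trials: int
    n_corrupt_trials: int

    @property
    def corrupt_trial_fraction(self) -> float:
        return self.n_corrupt_trials / self.n_trials

    def to_json(self) -> dict:
        return {
            "n_trials": self.n_trials,
            "n_corrupt_trials": self.n_corrupt_trials,
            "corrupt_trial_fraction": self.corrupt_trial_fraction,
            "table": {state: {str(sub): int(v) for sub, v in row.items()}
                      for state, row in self.table.iterrows()},
        }


def qc_summary(reports: list[ChannelQCReport]) -> QCSummary:
    """Count trials containing at least one corrupt channel per subject/state."""
    if not reports:
        raise MetadataError("no reports to summarize")
    rows = []
    for rep in reports:
        if rep.subject_id is None or rep.state_label is None:
            raise MetadataError(
                f"report for trial {rep.trial_id!r} lacks subject/state metadata")
        rows.append({"subject": rep.subject_id, "state": rep.state_label,
                     "corrupt": rep.n_corrupt > 0})
    df = pd.DataFrame(rows)
    table = (df.pivot_table(index="state", columns="subject", values="corrupt",
                            aggfunc="sum", fill_value=0)
             .astype(int))
    return QCSummary(table=table, n_trials=len(df),
                     n_corrupt_trials=int(df["corrupt"].sum()))


def mask_channels(rec: Recording, flags: np.ndarray | ChannelQCReport) -> Recording:
    """Drop flagged channel rows (labels filtered consistently)."""
    if isinstance(flags, ChannelQCReport):
        flags = flags.corrupt_flags
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != (rec.n_channels,):
        raise MetadataError(
            f"flag vector length {flags.shape} != channel count {rec.n_channels}")
    if flags.all():
        raise DataError("all channels flagged corrupt; nothing left to analyze")
    keep = ~flags
    labels = [lab for lab, k in zip(rec.channel_labels, keep) if k]
    return rec.with_data(rec.data[keep], labels)
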