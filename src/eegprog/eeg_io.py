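"""Reading and writing EEG epochs.

The native on-disk form is a plain CSV: comment lines carry the sampling
rate and label, the header carries channel names, and each row is one
sample in microvolts.  EDF files can be read when :mod:`mne` is installed
(``pip install eegprog[edf]``); there is no EDF writer here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np

from .eeg_classify import EEGCategory
from .eeg_sim import EEGEpoch

__all__ = ["write_epoch_csv", "read_epoch_csv", "read_epoch_edf"]

PathLike = Union[str, Path]


def write_epoch_csv(epoch: EEGEpoch, path: PathLike) -> None:
    """Serialize an epoch to CSV with metadata comment lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={epoch.fs!r}\n")
        if epoch.true_label is not None:
            fh.write(f"# true_label={EEGCategory(epoch.true_label).value}\n")
        if epoch.start_hour is not None:
            fh.write(f"# start_hour={epoch.start_hour!r}\n")
        fh.write(",".join(epoch.channels) + "\n")
        np.savetxt(fh, epoch.data.T, delimiter=",", fmt="%.6f")


def read_epoch_csv(path: PathLike) -> EEGEpoch:
    """Read an epoch written by :func:`write_epoch_csv`."""
    meta: dict[str, str] = {}
    with Path(path).open() as fh:
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            line = fh.readline()
        channels = [c.strip() for c in line.strip().split(",")]
        data = np.loadtxt(fh, delimiter=",", ndmin=2).T
    label = meta.get("true_label")
    start_hour = meta.get("start_hour")
    return EEGEpoch(
        data,
        fs=float(meta["fs"]),
        channels=channels,
        true_label=EEGCategory(label) if label else None,
        start_hour=float(start_hour) if start_hour else None,
    )


def read_epoch_edf(path: PathLike, *, picks: Optional[list[str]] = None) -> EEGEpoch:
    """Read an epoch from an EDF file (requires the optional ``mne`` extra).

    Channel data are converted from volts to microvolts.  Untested against
    clinical exports in this repository; intended as a convenience for users
    with their own EDF recordings.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF requires mne: pip install eegprog[edf]") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if picks:
        raw = raw.pick(picks)
    return EEGEpoch(raw.get_data() * 1e6, fs=float(raw.info["sfreq"]), channels=list(raw.ch_names))
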