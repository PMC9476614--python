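"""Data containers and on-disk formats.

The native epoch container is an HDF5 file holding the two players' epoched
arrays plus JSON-serializable metadata (sampling rate, channel labels,
condition table).  Keystroke events travel as plain CSV.  Import of standard
EEG formats can be added through :data:`EPOCH_READERS` without touching the
pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from io import StringIO

import h5py
import numpy as np
import pandas as pd

from .montage import CHANNELS

#: Registry for optional standard-format epoch readers: format name -> callable
#: ``(path) -> DyadEpochs``.  The native ``"hdf5"`` reader is always present.
EPOCH_READERS: dict[str, "callable"] = {}

KEYSTROKE_COLUMNS = [
    "pair", "trial", "player", "piece", "familiarity",
    "instruction_self", "instruction_other", "phrase", "position",
    "onset_s", "pitch",
]


@dataclass
class DyadEpochs:
    """Paired epoched EEG of the two players of one dyad.

    ``data1`` and ``data2`` are (n_trials, n_channels, n_samples) arrays with a
    shared, cue-locked time axis.  ``conditions`` carries one row per trial
    (the trial-design columns).  ``keep`` is a per-trial boolean mask standing
    in for interactive artifact-based trial rejection.
    """

    data1: np.ndarray
    data2: np.ndarray
    sfreq: float
    ch_names: list[str]
    times: np.ndarray
    conditions: pd.DataFrame
    keep: np.ndarray = None
    sim_truth: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.data1 = np.asarray(self.data1, float)
        self.data2 = np.asarray(self.data2, float)
        if self.data1.shape != self.data2.shape:
            raise ValueError(
                f"player arrays differ in shape: {self.data1.shape} vs {self.data2.shape}"
            )
        if self.data1.ndim != 3:
            raise ValueError("epoch arrays must be (n_trials, n_channels, n_samples)")
        if self.data1.shape[1] != len(self.ch_names):
            raise ValueError("channel axis does not match channel labels")
        if self.data1.shape[2] != len(self.times):
            raise ValueError("sample axis does not match time axis")
        if len(self.conditions) != self.data1.shape[0]:
            raise ValueError("condition table does not match trial axis")
        if self.keep is None:
            self.keep = np.ones(self.data1.shape[0], bool)
        self.keep = np.asarray(self.keep, bool)

    @property
    def n_trials(self) -> int:
        return self.data1.shape[0]

    def apply_keep(self) -> "DyadEpochs":
        """Drop trials excluded by the keep-mask."""
        k = self.keep
        return DyadEpochs(
            self.data1[k], self.data2[k], self.sfreq, list(self.ch_names),
            self.times, self.conditions.loc[k].reset_index(drop=True),
            np.ones(int(k.sum()), bool), dict(self.sim_truth),
        )

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data1", data=self.data1, compression="gzip")
            f.create_dataset("data2", data=self.data2, compression="gzip")
            f.create_dataset("times", data=self.times)
            f.create_dataset("keep", data=self.keep.astype(np.uint8))
            f.attrs["sfreq"] = float(self.sfreq)
            f.attrs["ch_names"] = json.dumps(list(self.ch_names))
            f.attrs["conditions"] = self.conditions.to_json(orient="split")

    @classmethod
    def load(cls, path) -> "DyadEpochs":
        try:
            with h5py.File(path, "r") as f:
                required = {"data1", "data2", "times", "keep"}
                if not required <= set(f.keys()):
                    raise ValueError(
                        f"not a dyad epoch container (missing {sorted(required - set(f.keys()))})"
                    )
                conditions = pd.read_json(
                    StringIO(f.attrs["conditions"]), orient="split"
                )
                return cls(
                    f["data1"][()], f["data2"][()], float(f.attrs["sfreq"]),
                    json.loads(f.attrs["ch_names"]), f["times"][()],
                    conditions, f["keep"][()].astype(bool),
                )
        except OSError as e:
            raise ValueError(f"cannot read epoch container {path}: {e}") from e


EPOCH_READERS["hdf5"] = DyadEpochs.load


def import_epochs(path, format: str = "hdf5") -> DyadEpochs:
    """Load a :class:`DyadEpochs` container in a registered format."""
    try:
        reader = EPOCH_READERS[format]
    except KeyError:
        raise ValueError(
            f"unsupported epoch format {format!r}; registered: {sorted(EPOCH_READERS)}"
        ) from None
    return reader(path)


def write_keystrokes(df: pd.DataFrame, path) -> None:
    """Write a keystroke event table to CSV (schema :data:`KEYSTROKE_COLUMNS`)."""
    missing = [c for c in KEYSTROKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"keystroke table missing columns {missing}")
    df.to_csv(path, index=False, columns=KEYSTROKE_COLUMNS)


def read_keystrokes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in KEYSTROKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"keystroke CSV missing columns {missing}")
    return df


def default_channels() -> list[str]:
    return list(CHANNELS)
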