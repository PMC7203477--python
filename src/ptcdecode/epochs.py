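"""Epoched EEG data model, on-disk container, and preprocessing transforms.

The universal currency of the package is :class:`EpochDataset`: a
``(n_trials, n_channels, n_timepoints)`` float array of epoched EEG with
per-trial metadata (subject id, trial id, class label).  Two preprocessing
steps are applied before any network sees the data:

* amplitude scaling — divide raw microvolt values by a fixed factor
  (default 20) to bring them approximately into the −1..1 range where
  neural networks train well;
* time-bin averaging — replace consecutive non-overlapping groups of
  samples by their mean (default factor 10, i.e. 250 Hz → 40 ms bins).

Both transforms are linear and commute; they are kept separate for
testability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

#: Columns required in the per-trial metadata table.
METADATA_COLUMNS = ("subject_id", "trial_id", "class_label")

#: On-disk container format version.
FORMAT_VERSION = 1

#: Default stimulus categories of the reference task.
DEFAULT_LABELS = ("face", "scene", "word")


class FormatError(ValueError):
    """Raised when an on-disk container violates the format contract."""


@dataclass
class EpochDataset:
    """Epoched multichannel time-series with per-trial metadata.

    Parameters
    ----------
    data:
        Array of shape ``(n_trials, n_channels, n_timepoints)``.  Units are
        microvolts for raw data, dimensionless after amplitude scaling.
    metadata:
        DataFrame with one row per trial and columns ``subject_id``,
        ``trial_id`` (unique within subject) and ``class_label``.
    sampling_rate:
        Acquisition rate in Hz (of the raw, un-binned signal).
    label_set:
        The declared class labels; ``class_label`` values must come from
        this set.  Defaults to the sorted unique labels present.
    is_binned, bin_width_ms:
        Whether time-bin averaging has been applied, and the resulting bin
        width in milliseconds.
    """

    data: np.ndarray
    metadata: pd.DataFrame
    sampling_rate: float
    label_set: tuple[str, ...] = ()
    is_binned: bool = False
    bin_width_ms: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (trials, channels, timepoints); got shape {self.data.shape}"
            )
        if not self.label_set:
            self.label_set = tuple(sorted(map(str, self.metadata["class_label"].unique())))

    # -- basic queries ----------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    @property
    def subjects(self) -> list:
        """Subject ids in order of first appearance."""
        return list(pd.unique(self.metadata["subject_id"]))

    def class_indices(self, label: str) -> np.ndarray:
        """Row indices of all trials carrying ``label``."""
        return np.flatnonzero((self.metadata["class_label"] == label).to_numpy())

    def subject_indices(self, subject_id) -> np.ndarray:
        return np.flatnonzero((self.metadata["subject_id"] == subject_id).to_numpy())

    def select(self, idx: np.ndarray) -> "EpochDataset":
        """A new dataset restricted to trial rows ``idx`` (order kept)."""
        idx = np.asarray(idx)
        return replace(
            self,
            data=self.data[idx].copy(),
            metadata=self.metadata.iloc[idx].reset_index(drop=True),
        )

    def select_subjects(self, subject_ids) -> "EpochDataset":
        mask = self.metadata["subject_id"].isin(list(subject_ids)).to_numpy()
        return self.select(np.flatnonzero(mask))


@dataclass
class PreprocessConfig:
    """Amplitude divisor and time-binning factor applied before modelling."""

    scale_divisor: float = 20.0
    bin_factor: int = 10

    def __post_init__(self) -> None:
        if self.scale_divisor <= 0:
            raise ValueError("scale_divisor must be > 0")
        if self.bin_factor < 1:
            raise ValueError("bin_factor must be >= 1")


def scale_amplitudes(ds: EpochDataset, divisor: float = 20.0) -> EpochDataset:
    """Divide every sample by ``divisor`` (default 20, µV → roughly −1..1).

    Returns a new dataset; the input is not modified.
    """
    if divisor <= 0:
        raise ValueError(f"divisor must be positive, got {divisor}")
    return replace(ds, data=ds.data / divisor, metadata=ds.metadata.copy())


def bin_time_average(ds: EpochDataset, factor: int = 10) -> EpochDataset:
    """Average consecutive non-overlapping groups of ``factor`` timepoints.

    Output length is ``floor(n_timepoints / factor)``; trailing remainder
    samples are dropped.  The result is flagged binned with
    ``bin_width_ms = 1000 * factor / sampling_rate``.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    if factor > ds.n_timepoints:
        raise ValueError(
            f"factor {factor} exceeds epoch length {ds.n_timepoints}"
        )
    n_bins = ds.n_timepoints // factor
    trimmed = ds.data[:, :, : n_bins * factor]
    binned = trimmed.reshape(ds.n_trials, ds.n_channels, n_bins, factor).mean(axis=3)
    return replace(
        ds,
        data=binned,
        metadata=ds.metadata.copy(),
        is_binned=True,
        bin_width_ms=1000.0 * factor / ds.sampling_rate,
    )


def preprocess(ds: EpochDataset, cfg: PreprocessConfig | None = None) -> EpochDataset:
    """Canonical pipeline: time-bin averaging then amplitude scaling."""
    cfg = cfg or PreprocessConfig()
    return scale_amplitudes(bin_time_average(ds, cfg.bin_factor), cfg.scale_divisor)


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def save_epochs(ds: EpochDataset, path) -> None:
    """Write the dataset to a single HDF5 file.

    Layout: dataset ``epochs`` holds the 3-D array; datasets
    ``meta/subject_id``, ``meta/trial_id``, ``meta/class_label`` hold the
    per-trial table; scalar attributes carry rate, flags and a format
    version.
    """
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["sampling_rate"] = float(ds.sampling_rate)
        f.attrs["is_binned"] = bool(ds.is_binned)
        if ds.bin_width_ms is not None:
            f.attrs["bin_width_ms"] = float(ds.bin_width_ms)
        f.attrs["label_set"] = json.dumps(list(ds.label_set))
        f.create_dataset("epochs", data=ds.data)
        g = f.create_group("meta")
        str_t = h5py.string_dtype(encoding="utf-8")
        g.create_dataset(
            "subject_id", data=ds.metadata["subject_id"].astype(str).to_numpy(), dtype=str_t
        )
        g.create_dataset("trial_id", data=ds.metadata["trial_id"].to_numpy(dtype=np.int64))
        g.create_dataset(
            "class_label", data=ds.metadata["class_label"].astype(str).to_numpy(), dtype=str_t
        )


def load_epochs(path) -> EpochDataset:
    """Read a dataset written by :func:`save_epochs`; validates the format."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise FormatError(f"unknown format version {version!r}")
        if "epochs" not in f:
            raise FormatError("missing 'epochs' dataset")
        data = f["epochs"][()]
        if data.ndim != 3:
            raise FormatError(f"'epochs' must be 3-D, got shape {data.shape}")
        if "meta" not in f:
            raise FormatError("missing 'meta' group")
        meta = {}
        for col in METADATA_COLUMNS:
            if col not in f["meta"]:
                raise FormatError(f"missing metadata column {col!r}")
            raw = f["meta"][col][()]
            if raw.dtype.kind in ("S", "O"):
                raw = np.array([v.decode() if isinstance(v, bytes) else str(v) for v in raw])
            meta[col] = raw
        lengths = {col: len(v) for col, v in meta.items()}
        if any(n != data.shape[0] for n in lengths.values()):
            raise FormatError(
                f"metadata rows {lengths} do not match data with {data.shape[0]} trials"
            )
        metadata = pd.DataFrame(meta)
        return EpochDataset(
            data=data,
            metadata=metadata,
            sampling_rate=float(f.attrs["sampling_rate"]),
            label_set=tuple(json.loads(f.attrs["label_set"])),
            is_binned=bool(f.attrs["is_binned"]),
            bin_width_ms=float(f.attrs["bin_width_ms"]) if "bin_width_ms" in f.attrs else None,
        )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Every invariant violation found in a dataset; empty iff valid."""

    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def to_json(self) -> str:
        return json.dumps({"ok": self.ok, "issues": self.issues}, indent=2)


def validate_dataset(ds: EpochDataset) -> ValidationReport:
    """Check every dataset invariant; reports, never raises."""
    issues: list[str] = []
    if len(ds.metadata) != ds.n_trials:
        issues.append(
            f"metadata has {len(ds.metadata)} rows but data has {ds.n_trials} trials"
        )
    missing = [c for c in METADATA_COLUMNS if c not in ds.metadata.columns]
    if missing:
        issues.append(f"missing metadata columns: {missing}")

    bad = ~np.isfinite(ds.data)
    if bad.any():
        for t, c, b in zip(*np.nonzero(bad)):
            issues.append(f"non-finite value at trial {t}, channel {c}, timepoint {b}")
            if len(issues) > 20:  # cap the listing for pathological inputs
                issues.append("... further non-finite values omitted")
                break

    if not missing and len(ds.metadata) == ds.n_trials:
        unknown = set(map(str, ds.metadata["class_label"])) - set(ds.label_set)
        if unknown:
            issues.append(f"class labels outside declared label set: {sorted(unknown)}")
        dup = ds.metadata.duplicated(subset=["subject_id", "trial_id"])
        for i in np.flatnonzero(dup.to_numpy()):
            row = ds.metadata.iloc[i]
            issues.append(
                f"duplicate trial_id {row['trial_id']} within subject {row['subject_id']}"
            )
    return ValidationReport(issues)
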