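"""Cohort data model and file I/O.

A cohort is an ordered set of subject-level ICA time courses, one matrix of
shape (time points x components) per subject, together with binary diagnostic
labels (0 = patient, 1 = healthy control) and a cohort identifier.  Components
are indexed 0-based and the index order is fixed and shared across a cohort.

On disk, arrays live in an NPY/NPZ or HDF5 container (dataset ``timecourses``,
shape N x T_total x C), subject metadata in a CSV manifest with header
``subject_id,label,cohort_id``, and the component->functional-network
assignment in a CSV with header ``component,network``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "NETWORK_NAMES",
    "TimeCourse",
    "CohortDataset",
    "NetworkMap",
    "WindowedSubject",
    "window_subject",
    "unwindow",
    "zscore_subject",
    "prepare_model_inputs",
    "load_cohort",
    "save_cohort",
    "load_network_map",
    "save_network_map",
    "default_network_map",
]

#: The seven canonical functional networks, in their conventional order.
NETWORK_NAMES = (
    "Subcortical",
    "Auditory",
    "Sensorimotor",
    "Visual",
    "Cognitive Control",
    "Default Mode",
    "Cerebellar",
)

#: Component counts per network for the conventional 53-component template,
#: in NETWORK_NAMES order.  The shipped default assignment is a stand-in for
#: the exact template membership and is always overridable by file.
_DEFAULT_NETWORK_SIZES = (5, 2, 9, 9, 17, 7, 4)


class CohortError(ValueError):
    """Structured error for malformed cohort inputs."""


@dataclass
class TimeCourse:
    """One subject's ICA time courses: rows are time points, columns components."""

    values: np.ndarray  # (T_total, C)
    subject_id: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise CohortError(f"{self.subject_id}: values must be 2-D (time x components)")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise CohortError(f"{self.subject_id}: empty time course")
        if not np.all(np.isfinite(self.values)):
            raise CohortError(f"{self.subject_id}: non-finite entries")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]


@dataclass
class CohortDataset:
    """Ordered subjects + binary labels (0 = patient, 1 = healthy control)."""

    subjects: list[TimeCourse]
    labels: np.ndarray
    cohort_id: str

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.subjects) != len(self.labels):
            raise CohortError(
                f"{self.cohort_id}: {len(self.subjects)} subjects but {len(self.labels)} labels"
            )
        bad = np.setdiff1d(np.unique(self.labels), [0, 1])
        if bad.size:
            raise CohortError(f"{self.cohort_id}: non-binary labels {bad.tolist()}")
        cs = {tc.n_components for tc in self.subjects}
        if len(cs) > 1:
            raise CohortError(f"{self.cohort_id}: inconsistent component counts {sorted(cs)}")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_components(self) -> int:
        return self.subjects[0].n_components

    @property
    def subject_ids(self) -> list[str]:
        return [tc.subject_id for tc in self.subjects]

    def to_array(self) -> np.ndarray:
        """Stack subjects into (N, T_total, C); requires equal lengths."""
        return np.stack([tc.values for tc in self.subjects])

    def subset(self, idx, cohort_id: str | None = None) -> "CohortDataset":
        idx = np.asarray(idx)
        return CohortDataset(
            [self.subjects[i] for i in idx],
            self.labels[idx],
            cohort_id or self.cohort_id,
        )


@dataclass
class NetworkMap:
    """Assignment of every component index 0..C-1 to one of the seven networks."""

    assignment: dict[int, str]
    source_path: str = "<memory>"

    def __post_init__(self):
        unknown = sorted({n for n in self.assignment.values()} - set(NETWORK_NAMES))
        if unknown:
            raise CohortError(f"unknown network names: {unknown}")
        idx = sorted(self.assignment)
        if idx != list(range(len(idx))):
            missing = sorted(set(range(max(idx) + 1)) - set(idx))
            raise CohortError(f"component indices must cover 0..C-1; missing {missing}")

    @property
    def n_components(self) -> int:
        return len(self.assignment)

    @property
    def networks(self) -> tuple[str, ...]:
        """Networks present, in canonical NETWORK_NAMES order."""
        present = set(self.assignment.values())
        return tuple(n for n in NETWORK_NAMES if n in present)

    def components_of(self, network: str) -> np.ndarray:
        if network not in NETWORK_NAMES:
            raise CohortError(f"unknown network name: {network!r}")
        return np.array(sorted(c for c, n in self.assignment.items() if n == network))


@dataclass
class WindowedSubject:
    """Contiguous non-overlapping windows of one subject, trailing tail dropped."""

    windows: np.ndarray  # (K, T, C)
    discarded_tail: int

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


def window_subject(tc: TimeCourse, window_len: int) -> WindowedSubject:
    """Split a time course into K = floor(T_total/window_len) windows.

    Trailing time points that do not fill a whole window are truncated, so a
    140-point scan at window 20 yields exactly 7 windows.
    """
    if window_len < 1:
        raise CohortError("window_len must be >= 1")
    t_total = tc.n_timepoints
    if t_total < window_len:
        raise CohortError(
            f"{tc.subject_id}: series shorter than one window ({t_total} < {window_len})"
        )
    k = t_total // window_len
    tail = t_total - k * window_len
    win = tc.values[: k * window_len].reshape(k, window_len, tc.n_components)
    return WindowedSubject(windows=win, discarded_tail=tail)


def unwindow(ws: WindowedSubject) -> np.ndarray:
    """Concatenate windows back into a (K*T, C) matrix."""
    k, t, c = ws.windows.shape
    return ws.windows.reshape(k * t, c)


def zscore_subject(values: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Per-component z-scoring over time (mean 0, sd 1 within the subject)."""
    mu = values.mean(axis=0, keepdims=True)
    sd = values.std(axis=0, keepdims=True)
    return (values - mu) / np.maximum(sd, eps)


def cohort_scaler(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-component mean and sd pooled over subjects and time points.

    Fit the scaler on training subjects only and apply it everywhere.
    """
    mu = x.mean(axis=(0, 1), keepdims=True)
    sd = np.maximum(x.std(axis=(0, 1), keepdims=True), 1e-12)
    return mu, sd


def prepare_model_inputs(ds: CohortDataset, standardize: str | None = "cohort",
                         scaler: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Stack a cohort into the (N, T_total, C) array the model consumes.

    ``standardize`` selects the input scaling:

    * ``"cohort"`` (default) — per-component z-scoring with mean/sd pooled
      across subjects and time.  Between-subject amplitude differences (the
      clinically meaningful signal) survive; only the component-wise scale is
      normalized for the recurrent model.  A pre-fit ``scaler`` (mean, sd)
      may be passed to avoid using evaluation subjects for the statistics.
    * ``"subject"`` — per-subject, per-component z-scoring, which additionally
      removes each subject's own amplitude; appropriate when site or scaling
      nuisance dominates.
    * ``None`` — raw values.

    Standardization happens here rather than mutating the stored cohort: the
    Mahalanobis balancing stage needs the raw time-averaged activity, which
    z-scoring would annihilate.
    """
    x = ds.to_array()
    if standardize is None:
        return x
    if standardize == "subject":
        return np.stack([zscore_subject(v) for v in x])
    if standardize == "cohort":
        mu, sd = cohort_scaler(x) if scaler is None else scaler
        return (x - mu) / sd
    raise ValueError(f"unknown standardization mode {standardize!r}")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _read_array(array_path: str | os.PathLike) -> np.ndarray:
    path = Path(array_path)
    suffix = path.suffix.lower()
    if suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            if "timecourses" not in f:
                raise CohortError(f"{path}: HDF5 container lacks dataset 'timecourses'")
            arr = f["timecourses"][...]
    elif suffix == ".npz":
        with np.load(path) as z:
            key = "timecourses" if "timecourses" in z else list(z.keys())[0]
            arr = z[key]
    else:
        arr = np.load(path)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 3:
        raise CohortError(f"{path}: expected (N, T_total, C) array, got shape {arr.shape}")
    return arr


def load_cohort(array_path: str | os.PathLike, manifest_path: str | os.PathLike) -> CohortDataset:
    """Load a cohort from an array container plus its CSV manifest.

    Subject order is the manifest order; row i of the manifest describes
    slice i of the array.
    """
    arr = _read_array(array_path)
    manifest = pd.read_csv(manifest_path, dtype={"subject_id": str, "cohort_id": str})
    required = {"subject_id", "label", "cohort_id"}
    if not required.issubset(manifest.columns):
        raise CohortError(f"manifest missing columns {sorted(required - set(manifest.columns))}")
    if len(manifest) != arr.shape[0]:
        raise CohortError(
            f"manifest has {len(manifest)} rows but array holds {arr.shape[0]} subjects"
        )
    labels = manifest["label"].to_numpy()
    bad = [i for i, v in enumerate(labels) if v not in (0, 1)]
    if bad:
        raise CohortError(f"non-binary label in manifest rows {bad}")
    cohort_ids = manifest["cohort_id"].unique()
    subjects = [
        TimeCourse(values=arr[i], subject_id=str(manifest["subject_id"].iloc[i]))
        for i in range(arr.shape[0])
    ]
    return CohortDataset(subjects, labels.astype(np.int64), str(cohort_ids[0]))


def save_cohort(ds: CohortDataset, array_path: str | os.PathLike,
                manifest_path: str | os.PathLike) -> None:
    """Write the cohort as an array container + manifest (inverse of load_cohort)."""
    path = Path(array_path)
    arr = ds.to_array()
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.create_dataset("timecourses", data=arr)
    elif path.suffix.lower() == ".npz":
        np.savez(path, timecourses=arr)
    else:
        np.save(path, arr)
    pd.DataFrame(
        {
            "subject_id": ds.subject_ids,
            "label": ds.labels,
            "cohort_id": [ds.cohort_id] * len(ds),
        }
    ).to_csv(manifest_path, index=False)


def load_network_map(path: str | os.PathLike, C: int) -> NetworkMap:
    """Load a component->network CSV and validate full, unique coverage of 0..C-1."""
    df = pd.read_csv(path)
    if not {"component", "network"}.issubset(df.columns):
        raise CohortError(f"{path}: expected columns component,network")
    comp = df["component"].astype(int).to_numpy()
    dupes = sorted({int(c) for c in comp if (comp == c).sum() > 1})
    if dupes:
        raise CohortError(f"{path}: duplicate component indices {dupes}")
    assignment = {int(c): str(n) for c, n in zip(comp, df["network"])}
    missing = sorted(set(range(C)) - set(assignment))
    extra = sorted(set(assignment) - set(range(C)))
    if missing or extra:
        raise CohortError(f"{path}: missing components {missing}, out-of-range {extra}")
    nm = NetworkMap(assignment=assignment, source_path=str(path))
    return nm


def save_network_map(nm: NetworkMap, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"component": sorted(nm.assignment), "network": [nm.assignment[c] for c in sorted(nm.assignment)]}
    ).to_csv(path, index=False)


def default_network_map(C: int = 53) -> NetworkMap:
    """The shipped stand-in assignment: contiguous index blocks per network.

    Block sizes follow the conventional 53-component template (Subcortical 5,
    Auditory 2, Sensorimotor 9, Visual 9, Cognitive Control 17, Default Mode 7,
    Cerebellar 4).  For other C the blocks are scaled proportionally.  Replace
    by file whenever an authoritative assignment is available.
    """
    if C == 53:
        sizes = _DEFAULT_NETWORK_SIZES
    else:
        raw = np.array(_DEFAULT_NETWORK_SIZES, dtype=float) * C / 53.0
        sizes = np.maximum(1, np.floor(raw)).astype(int)
        # distribute the remainder to the largest networks
        while sizes.sum() < C:
            sizes[np.argmax(raw - sizes)] += 1
        while sizes.sum() > C:
            sizes[np.argmax(sizes)] -= 1
    assignment: dict[int, str] = {}
    c = 0
    for name, n in zip(NETWORK_NAMES, sizes):
        for _ in range(int(n)):
            assignment[c] = name
            c += 1
    return NetworkMap(assignment=assignment, source_path="<default>")
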