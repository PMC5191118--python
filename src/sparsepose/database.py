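"""Movement database: pelvis referencing, downsampling, body-half split,
sensor configurations and feature extraction.

A :class:`MotionDatabase` stores an ordered collection of poses as a dense
array of scalar-first unit quaternions ``(n_poses, n_segments, 4)`` plus a
label table (subject, trial, activity, frame).  The processing pipeline for
raw capture data is:

1. downsample (default factor 10, 240 Hz → 24 Hz);
2. express every segment orientation relative to the pelvis
   (``q' = q_pelvis^-1 ⊗ q``), removing global-heading dependence — the
   pelvis entry becomes the identity;
3. sign-align each segment's quaternion stream frame-to-frame within each
   trial (double-cover continuity);
4. split into upper- and lower-body sub-databases, which are estimated
   independently and recombined into full-body poses.

A :class:`SensorConfiguration` names the five measured segments (always
including the pelvis, which serves as the reference) and partitions the
remaining four into upper- and lower-body input groups.  Because referencing
makes the pelvis quaternion identically the identity, it is excluded from
feature vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import quaternions as qt
from .skeleton import SEGMENTS, Skeleton

__all__ = [
    "LABEL_COLUMNS",
    "UPPER_SEGMENTS",
    "LOWER_SEGMENTS",
    "SensorConfiguration",
    "CONFIGURATIONS",
    "MotionDatabase",
    "pelvis_reference",
    "downsample",
    "build_database",
]

LABEL_COLUMNS = ("subject", "trial", "activity", "frame")

#: Body-half partition (pelvis belongs to both halves as the shared reference).
UPPER_SEGMENTS = (
    "L5", "L3", "T12", "T8", "Neck", "Head",
    "RightShoulder", "RightUpperArm", "RightForearm", "RightHand",
    "LeftShoulder", "LeftUpperArm", "LeftForearm", "LeftHand",
)
LOWER_SEGMENTS = (
    "RightUpperLeg", "RightLowerLeg", "RightFoot", "RightToe",
    "LeftUpperLeg", "LeftLowerLeg", "LeftFoot", "LeftToe",
)


@dataclass(frozen=True)
class SensorConfiguration:
    """A five-sensor placement: the pelvis plus two sensors per body half.

    ``upper_inputs``/``lower_inputs`` are the measured (non-pelvis) segments
    whose orientations form the input feature vector for the corresponding
    body-half estimator.
    """

    name: str
    upper_inputs: tuple
    lower_inputs: tuple

    def __post_init__(self):
        object.__setattr__(self, "upper_inputs", tuple(self.upper_inputs))
        object.__setattr__(self, "lower_inputs", tuple(self.lower_inputs))
        if not self.upper_inputs or not self.lower_inputs:
            raise ValueError("each body-half input group must be nonempty")
        if set(self.upper_inputs) & set(self.lower_inputs):
            raise ValueError("upper and lower input groups must be disjoint")
        for s in self.upper_inputs:
            if s not in UPPER_SEGMENTS:
                raise ValueError(f"{s!r} is not an upper-body segment")
        for s in self.lower_inputs:
            if s not in LOWER_SEGMENTS:
                raise ValueError(f"{s!r} is not a lower-body segment")

    @property
    def measured(self) -> tuple:
        """All measured segments, pelvis (the reference) first."""
        return ("Pelvis",) + self.upper_inputs + self.lower_inputs

    def inputs(self, half: str) -> tuple:
        if half == "upper":
            return self.upper_inputs
        if half == "lower":
            return self.lower_inputs
        raise ValueError(f"half must be 'upper' or 'lower', got {half!r}")

    def outputs(self, half: str) -> tuple:
        """Estimated (unmeasured, non-pelvis) segments of a body half."""
        pool = UPPER_SEGMENTS if half == "upper" else LOWER_SEGMENTS
        if half not in ("upper", "lower"):
            raise ValueError(f"half must be 'upper' or 'lower', got {half!r}")
        return tuple(s for s in pool if s not in self.inputs(half))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "name": self.name,
                    "upper_inputs": list(self.upper_inputs),
                    "lower_inputs": list(self.lower_inputs),
                },
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "SensorConfiguration":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(d["name"], d["upper_inputs"], d["lower_inputs"])


#: Preset five-sensor configurations A–F.  A and E follow their published
#: textual definitions ("pelvis, upper legs, and upper arms"; "pelvis, right
#: upper and lower arm, right upper and lower leg").  B, C, D and F are
#: defined only graphically in the source material; the placements below are
#: documented placeholders (D matches the worked pelvis/lower-arms/lower-legs
#: example) and can be replaced via YAML files.
CONFIGURATIONS = {
    "A": SensorConfiguration(
        "A", ("RightUpperArm", "LeftUpperArm"), ("RightUpperLeg", "LeftUpperLeg")
    ),
    "B": SensorConfiguration(
        "B", ("RightForearm", "LeftForearm"), ("RightUpperLeg", "LeftUpperLeg")
    ),
    "C": SensorConfiguration(
        "C", ("RightUpperArm", "LeftUpperArm"), ("RightLowerLeg", "LeftLowerLeg")
    ),
    "D": SensorConfiguration(
        "D", ("RightForearm", "LeftForearm"), ("RightLowerLeg", "LeftLowerLeg")
    ),
    "E": SensorConfiguration(
        "E", ("RightUpperArm", "RightForearm"), ("RightUpperLeg", "RightLowerLeg")
    ),
    "F": SensorConfiguration(
        "F", ("RightHand", "LeftHand"), ("RightFoot", "LeftFoot")
    ),
}


def get_configuration(config) -> SensorConfiguration:
    if isinstance(config, SensorConfiguration):
        return config
    return CONFIGURATIONS[str(config)]


@dataclass
class MotionDatabase:
    """Ordered pose collection with subject/trial/activity labels.

    Attributes
    ----------
    quaternions : array (n_poses, n_segments, 4)
        Scalar-first unit quaternions.
    labels : DataFrame
        Columns ``subject, trial, activity, frame`` (one row per pose).
    segments : tuple of str
        Segment order of the quaternion axis.
    rate : float
        Sample rate in Hz.
    referenced : bool
        Whether orientations are pelvis-referenced.
    """

    quaternions: np.ndarray
    labels: pd.DataFrame
    segments: tuple = SEGMENTS
    rate: float = 240.0
    referenced: bool = False

    def __post_init__(self):
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        self.segments = tuple(self.segments)
        n = self.quaternions.shape[0]
        if n == 0:
            raise ValueError("database must contain at least one pose")
        if self.quaternions.shape[1:] != (len(self.segments), 4):
            raise ValueError(
                f"quaternion array shape {self.quaternions.shape} does not match "
                f"{len(self.segments)} segments"
            )
        if len(self.labels) != n:
            raise ValueError("labels must have one row per pose")
        missing = set(LABEL_COLUMNS) - set(self.labels.columns)
        if missing:
            raise ValueError(f"labels missing columns {sorted(missing)}")
        self.labels = self.labels.reset_index(drop=True)

    def __len__(self) -> int:
        return self.quaternions.shape[0]

    @property
    def subjects(self) -> list:
        return sorted(self.labels["subject"].unique().tolist())

    def segment_index(self, segment: str) -> int:
        return self.segments.index(segment)

    def segment_quats(self, segment: str) -> np.ndarray:
        return self.quaternions[:, self.segment_index(segment), :]

    def select(self, mask) -> "MotionDatabase":
        mask = np.asarray(mask)
        return replace(
            self,
            quaternions=self.quaternions[mask],
            labels=self.labels.loc[mask].reset_index(drop=True),
        )

    def subset_subjects(self, subjects) -> "MotionDatabase":
        return self.select(self.labels["subject"].isin(list(subjects)).to_numpy())

    # -- pipeline steps ----------------------------------------------------

    def pelvis_referenced(self) -> "MotionDatabase":
        # idempotent: referencing an already-referenced pose is a no-op
        # (the pelvis entry is the identity)
        return replace(
            self,
            quaternions=pelvis_reference(self.quaternions, self.segments),
            referenced=True,
        )

    def downsampled(self, factor: int) -> "MotionDatabase":
        if int(factor) < 1:
            raise ValueError("downsampling factor must be >= 1")
        factor = int(factor)
        keep = []
        for _, idx in self.labels.groupby(["subject", "trial"], sort=False).groups.items():
            idx = np.sort(np.asarray(idx))
            keep.append(idx[::factor])
        keep = np.sort(np.concatenate(keep))
        out = self.select(keep)
        out.rate = self.rate / factor
        return out

    def sign_aligned(self) -> "MotionDatabase":
        """Frame-to-frame sign continuity per segment within each trial."""
        quats = self.quaternions.copy()
        for _, idx in self.labels.groupby(["subject", "trial"], sort=False).groups.items():
            idx = np.sort(np.asarray(idx))
            quats[idx] = qt.sign_continuity(quats[idx], axis=0)
        return replace(self, quaternions=quats)

    def split_upper_lower(self):
        """Split into upper- and lower-body sub-databases (pelvis in both)."""
        both = set(UPPER_SEGMENTS) & set(LOWER_SEGMENTS)
        if both:
            raise ValueError(f"segments assigned to both halves: {sorted(both)}")
        upper = ("Pelvis",) + tuple(s for s in self.segments if s in UPPER_SEGMENTS)
        lower = ("Pelvis",) + tuple(s for s in self.segments if s in LOWER_SEGMENTS)
        out = []
        for segs in (upper, lower):
            idx = [self.segments.index(s) for s in segs]
            out.append(replace(self, quaternions=self.quaternions[:, idx, :], segments=segs))
        return tuple(out)

    # -- learner I/O -------------------------------------------------------

    def features(self, config, half: str) -> np.ndarray:
        """Flattened input feature matrix ``(n, 4 * n_inputs)`` for a half."""
        config = get_configuration(config)
        return self._stack(config.inputs(half))

    def targets(self, config, half: str) -> np.ndarray:
        """Flattened output matrix ``(n, 4 * n_outputs)`` for a half."""
        config = get_configuration(config)
        return self._stack(config.outputs(half))

    def _stack(self, segs) -> np.ndarray:
        for s in segs:
            if s not in self.segments:
                raise ValueError(f"incomplete pose: segment {s!r} absent from database")
        idx = [self.segments.index(s) for s in segs]
        return self.quaternions[:, idx, :].reshape(len(self), 4 * len(segs))

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        cols = {c: self.labels[c].to_numpy() for c in LABEL_COLUMNS}
        flat = self.quaternions.reshape(len(self), -1)
        for i, seg in enumerate(self.segments):
            for j, comp in enumerate("wxyz"):
                cols[f"{seg}_{comp}"] = flat[:, 4 * i + j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, rate: float = 240.0, referenced: bool = False,
        unit_atol: float = 1e-3,
    ) -> "MotionDatabase":
        segs = []
        for c in df.columns:
            if c.endswith("_w"):
                segs.append(c[:-2])
        quats = np.stack(
            [df[[f"{s}_{c}" for c in "wxyz"]].to_numpy(float) for s in segs], axis=1
        )
        norms = np.linalg.norm(quats, axis=-1)
        if np.any(np.abs(norms - 1.0) > unit_atol):
            raise ValueError(
                f"pose file contains non-unit quaternions (tolerance {unit_atol})"
            )
        quats = quats / norms[..., None]
        labels = df[list(LABEL_COLUMNS)].copy()
        return cls(quats, labels, tuple(segs), rate=rate, referenced=referenced)

    @classmethod
    def from_csv(cls, path, rate: float = 240.0, referenced: bool = False) -> "MotionDatabase":
        return cls.from_frame(pd.read_csv(path), rate=rate, referenced=referenced)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("quaternions", data=self.quaternions)
            fh.attrs["segments"] = list(self.segments)
            fh.attrs["rate"] = self.rate
            fh.attrs["referenced"] = self.referenced
            lab = fh.create_group("labels")
            for c in LABEL_COLUMNS:
                col = self.labels[c].to_numpy()
                if col.dtype.kind in "OU":
                    col = col.astype("S")
                lab.create_dataset(c, data=col)

    @classmethod
    def from_hdf5(cls, path) -> "MotionDatabase":
        import h5py

        with h5py.File(path, "r") as fh:
            quats = fh["quaternions"][...]
            segs = tuple(
                s.decode() if isinstance(s, bytes) else str(s) for s in fh.attrs["segments"]
            )
            rate = float(fh.attrs["rate"])
            referenced = bool(fh.attrs["referenced"])
            cols = {}
            for c in LABEL_COLUMNS:
                col = fh["labels"][c][...]
                if col.dtype.kind == "S":
                    col = col.astype(str)
                cols[c] = col
        return cls(quats, pd.DataFrame(cols), segs, rate=rate, referenced=referenced)


def pelvis_reference(quats, segments=SEGMENTS) -> np.ndarray:
    """Express all segment orientations relative to the pelvis.

    ``q'_s = q_pelvis^-1 ⊗ q_s`` for every segment; the pelvis becomes the
    identity.  Idempotent, and invariant under any whole-body rotation
    applied to the raw pose.
    """
    quats = np.asarray(quats, dtype=float)
    segments = tuple(segments)
    if "Pelvis" not in segments:
        raise ValueError("reference segment 'Pelvis' absent from pose")
    i = segments.index("Pelvis")
    pelvis = quats[..., i : i + 1, :]
    if np.any(np.abs(np.linalg.norm(pelvis, axis=-1) - 1.0) > 1e-6):
        raise ValueError("pelvis orientation must be unit norm")
    out = qt.multiply(qt.inverse(pelvis), quats)
    # exact identity for the reference segment itself
    out[..., i, :] = qt.IDENTITY
    return out


def downsample(sequence: np.ndarray, factor: int) -> np.ndarray:
    """Keep every ``factor``-th frame starting at frame 0."""
    if int(factor) < 1:
        raise ValueError("downsampling factor must be >= 1")
    return np.asarray(sequence)[:: int(factor)]


def recombine(upper: MotionDatabase, lower: MotionDatabase, segments=SEGMENTS) -> MotionDatabase:
    """Merge upper- and lower-body sub-databases back into full poses."""
    if len(upper) != len(lower):
        raise ValueError("sub-databases must have equal pose counts")
    segments = tuple(segments)
    n = len(upper)
    quats = np.empty((n, len(segments), 4))
    for k, s in enumerate(segments):
        src = upper if s in upper.segments else lower
        quats[:, k, :] = src.segment_quats(s)
    return MotionDatabase(
        quats, upper.labels.copy(), segments, rate=upper.rate, referenced=upper.referenced
    )


def build_database(raw: MotionDatabase, factor: int = 10) -> MotionDatabase:
    """Raw capture → movement database (downsample, reference, sign-align)."""
    return raw.downsampled(factor).pelvis_referenced().sign_aligned()
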