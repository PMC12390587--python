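"""Data containers and on-disk storage shared by all pipeline stages.

A capture *sample* is a stack of frames from up to three cameras (two NIR,
one RGB) under varying illumination, stored in one HDF5 container with one
group per camera and per-frame metadata as attributes.  Pixel data is
10-bit, carried losslessly in unsigned 16-bit integers.

Conventions: images are row-major with the origin at the top-left corner
(y grows downward); hands are presented fingers-up, so fingertips point
toward the top edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

CAMERAS = ("left", "right", "rgb")
WAVELENGTHS = ("850", "950", "white", "laser")


@dataclass(frozen=True)
class FrameMeta:
    """Per-frame acquisition metadata."""

    camera: str
    wavelength: str
    illumination_state: int = 0

    def __post_init__(self) -> None:
        if self.camera not in CAMERAS:
            raise ValueError(f"unknown camera {self.camera!r}; expected {CAMERAS}")
        if self.wavelength not in WAVELENGTHS:
            raise ValueError(
                f"unknown wavelength {self.wavelength!r}; expected {WAVELENGTHS}"
            )


@dataclass
class HandSample:
    """One hand presentation: ordered frames plus per-frame metadata."""

    frames: list[np.ndarray]
    frame_meta: list[FrameMeta]
    subject_id: str
    hand: str
    sample_index: int = 0
    bit_depth: int = 10

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.hand not in ("LH", "RH"):
            raise ValueError(f"hand must be 'LH' or 'RH', got {self.hand!r}")
        if self.sample_index < 0:
            raise ValueError("sample_index must be >= 0")
        if len(self.frames) != len(self.frame_meta):
            raise ValueError(
                f"{len(self.frames)} frames but {len(self.frame_meta)} meta records"
            )
        per_camera_shape: dict[str, tuple] = {}
        limit = 2**self.bit_depth
        for i, (frame, meta) in enumerate(zip(self.frames, self.frame_meta)):
            if frame.ndim not in (2, 3):
                raise ValueError(f"frame {i}: expected 2-D or 3-channel array")
            shape = frame.shape[:2]
            prev = per_camera_shape.setdefault(meta.camera, shape)
            if prev != shape:
                raise ValueError(
                    f"frame {i}: camera {meta.camera!r} mixes shapes {prev} and {shape}"
                )
            if np.issubdtype(frame.dtype, np.integer) and frame.size:
                if int(frame.max()) >= limit or int(frame.min()) < 0:
                    raise ValueError(
                        f"frame {i}: intensities outside declared {self.bit_depth}-bit range"
                    )

    def frames_for(self, camera: str, wavelength: str | None = None) -> list[int]:
        """Indices of frames from one camera, optionally one wavelength."""
        return [
            i
            for i, m in enumerate(self.frame_meta)
            if m.camera == camera
            and (wavelength is None or m.wavelength == wavelength)
        ]


def write_sample(sample: HandSample, container_path: str | Path) -> Path:
    """Write a sample to an HDF5 container (one group per camera).

    The layout is round-trippable and bit-exact: each frame becomes a
    dataset ``frame_NNN`` under its camera group, with wavelength and
    illumination state stored as dataset attributes and the global frame
    position as ``order`` (frame order across cameras is preserved).
    """
    sample.validate()
    path = Path(container_path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["subject_id"] = sample.subject_id
        f.attrs["hand"] = sample.hand
        f.attrs["sample_index"] = sample.sample_index
        f.attrs["bit_depth"] = sample.bit_depth
        counters: dict[str, int] = {}
        for order, (frame, meta) in enumerate(zip(sample.frames, sample.frame_meta)):
            grp = f.require_group(meta.camera)
            k = counters.get(meta.camera, 0)
            counters[meta.camera] = k + 1
            ds = grp.create_dataset(f"frame_{k:03d}", data=frame)
            ds.attrs["wavelength"] = meta.wavelength
            ds.attrs["illumination_state"] = meta.illumination_state
            ds.attrs["order"] = order
    return path


def read_sample(container_path: str | Path) -> HandSample:
    """Read a sample container written by :func:`write_sample`."""
    path = Path(container_path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise OSError(f"cannot open {path} as an HDF5 container: {exc}") from exc
    with f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported container schema version {version} "
                f"(this reader supports {SCHEMA_VERSION})"
            )
        entries: list[tuple[int, np.ndarray, FrameMeta]] = []
        for camera in f.keys():
            grp = f[camera]
            for name in grp.keys():
                ds = grp[name]
                meta = FrameMeta(
                    camera=camera,
                    wavelength=str(ds.attrs["wavelength"]),
                    illumination_state=int(ds.attrs["illumination_state"]),
                )
                entries.append((int(ds.attrs["order"]), ds[...], meta))
        entries.sort(key=lambda e: e[0])
        return HandSample(
            frames=[e[1] for e in entries],
            frame_meta=[e[2] for e in entries],
            subject_id=str(f.attrs["subject_id"]),
            hand=str(f.attrs["hand"]),
            sample_index=int(f.attrs["sample_index"]),
            bit_depth=int(f.attrs["bit_depth"]),
        )


# ---------------------------------------------------------------------------
# Score tables

SCORE_COLUMNS = [
    "probe_id",
    "enrolled_id",
    "finger_label",
    "protocol_id",
    "score",
    "is_genuine",
]


@dataclass
class ScoreTable:
    """Comparison scores with genuine/impostor labels.

    Thin wrapper over a DataFrame with a fixed schema; the key
    (probe_id, enrolled_id, finger_label, protocol_id) must be unique and
    every score finite.
    """

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=SCORE_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in SCORE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"score table missing columns {missing}")
        self.df = self.df[SCORE_COLUMNS].reset_index(drop=True)
        if len(self.df):
            if not np.all(np.isfinite(self.df["score"].to_numpy(float))):
                raise ValueError("scores must be finite")
            key = self.df[["probe_id", "enrolled_id", "finger_label", "protocol_id"]]
            if key.duplicated().any():
                raise ValueError("duplicate (probe, enrolled, finger, protocol) keys")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def genuine(self) -> np.ndarray:
        return self.df.loc[self.df["is_genuine"], "score"].to_numpy(float)

    @property
    def impostor(self) -> np.ndarray:
        return self.df.loc[~self.df["is_genuine"].astype(bool), "score"].to_numpy(float)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        # %.17g preserves float64 scores exactly through the round-trip
        self.df.to_csv(path, index=False, float_format="%.17g")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreTable":
        df = pd.read_csv(path, dtype={"probe_id": str, "enrolled_id": str})
        df["is_genuine"] = df["is_genuine"].astype(bool)
        return cls(df)
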