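"""Frame synchronization via binary "clap" illumination patterns.

The capture hardware can silently drop a small, non-deterministic number
of frames at the head of a sequence.  To recover alignment, a short
binary illumination pattern (a *clap*) is flashed before and after the
payload frames, preceded by a run of blank frames.  After capture the
per-frame brightness trace is binarized and the two clap occurrences are
located by exact pattern correlation; the gap between them certifies that
no payload frame was lost, and the sequence is trimmed to the payload.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_CODE = (1, 0, 1, 0, 1, 1, 0, 0, 1, 1)


class SyncError(RuntimeError):
    """Clap detection failed (no/ambiguous matches)."""


class DroppedFrameError(SyncError):
    """Inter-clap distance does not match the expected payload length."""


@dataclass(frozen=True)
class ClapPattern:
    code: tuple[int, ...] = DEFAULT_CODE
    preamble_blank_frames: int = 10

    def __post_init__(self) -> None:
        code = np.asarray(self.code)
        if code.ndim != 1 or len(code) != 10:
            raise ValueError("clap code must be a length-10 binary vector")
        if not np.isin(code, (0, 1)).all():
            raise ValueError("clap code must be binary")
        d = np.diff(code)
        if not ((d == 1).any() and (d == -1).any()):
            raise ValueError("clap code must contain both 0->1 and 1->0 transitions")
        if self.preamble_blank_frames < 0:
            raise ValueError("preamble must be non-negative")


@dataclass(frozen=True)
class SyncResult:
    """Recovered alignment: [start_index, end_index) spans the payload."""

    start_index: int
    end_index: int
    frames_dropped_head: int
    complete: bool
    diagnostics: dict = field(default_factory=dict, compare=False)

    @property
    def payload_length(self) -> int:
        return self.end_index - self.start_index


def encode_claps(payload_length: int, pattern: ClapPattern = ClapPattern()) -> np.ndarray:
    """Binary illumination schedule: blanks + clap + payload slots + clap.

    Payload slots are scheduled as illuminated (1); the claps modulate a
    dedicated synchronization source, so payload content does not imitate
    a blank run.
    """
    if payload_length <= 0:
        raise ValueError("payload_length must be positive")
    code = np.asarray(pattern.code, dtype=np.uint8)
    return np.concatenate(
        [
            np.zeros(pattern.preamble_blank_frames, dtype=np.uint8),
            code,
            np.ones(payload_length, dtype=np.uint8),
            code,
        ]
    )


def _binarize(brightness: np.ndarray) -> np.ndarray:
    """Two-cluster (Lloyd) split of the brightness trace; threshold at the
    midpoint of the cluster means.  Invariant under affine rescaling."""
    x = np.asarray(brightness, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise SyncError("constant brightness trace: no clap signal present")
    c0, c1 = lo, hi
    for _ in range(100):
        mid = 0.5 * (c0 + c1)
        low = x <= mid
        n0, n1 = low.sum(), (~low).sum()
        if n0 == 0 or n1 == 0:
            break
        new0, new1 = x[low].mean(), x[~low].mean()
        if new0 == c0 and new1 == c1:
            break
        c0, c1 = new0, new1
    return (x > 0.5 * (c0 + c1)).astype(np.uint8)


def frame_brightness(frames: list[np.ndarray]) -> np.ndarray:
    """Per-frame brightness statistic: mean over the central 50% crop
    (robust to edge vignetting)."""
    out = np.empty(len(frames))
    for i, fr in enumerate(frames):
        h, w = fr.shape[:2]
        out[i] = float(fr[h // 4 : h - h // 4, w // 4 : w - w // 4].mean())
    return out


def detect_claps(
    frame_brightness: np.ndarray,
    pattern: ClapPattern = ClapPattern(),
    expected_payload: int | None = None,
) -> SyncResult:
    """Locate both clap occurrences and trim indices for the payload.

    Parameters
    ----------
    frame_brightness:
        Per-frame brightness trace of the raw (possibly head-truncated)
        sequence.
    expected_payload:
        Number of payload frames scheduled between the claps.  Required to
        certify completeness; the inter-clap distance must equal
        ``len(code) + expected_payload``.

    Raises
    ------
    SyncError
        If the binarized trace contains no or more than two exact clap
        matches.
    DroppedFrameError
        If the claps are found but their spacing shows payload loss.
    """
    bits = _binarize(frame_brightness)
    code = np.asarray(pattern.code, dtype=np.int8)
    n, L = len(bits), len(code)
    if n < L:
        raise SyncError("sequence shorter than one clap")
    # exact binary correlation: windows matching the code in every position
    sig = bits.astype(np.int8) * 2 - 1
    ref = code * 2 - 1
    corr = np.correlate(sig, ref, mode="valid")
    matches = np.flatnonzero(corr == L)
    if len(matches) == 0:
        raise SyncError("no clap pattern found in sequence")
    if len(matches) > 2:
        raise SyncError(f"ambiguous clap detection: {len(matches)} exact matches")
    if len(matches) == 1:
        raise SyncError("only one clap found; cannot certify sequence")
    first, second = int(matches[0]), int(matches[1])
    dropped = pattern.preamble_blank_frames - first
    start, end = first + L, second
    diag = {"first_clap": first, "second_clap": second, "matches": len(matches)}
    if expected_payload is not None and end - start != expected_payload:
        raise DroppedFrameError(
            f"inter-clap payload span is {end - start} frames, "
            f"expected {expected_payload}: frames were dropped mid-sequence"
        )
    complete = expected_payload is None or end - start == expected_payload
    return SyncResult(start, end, dropped, complete, diag)


def trim_payload(frames: list[np.ndarray], result: SyncResult) -> list[np.ndarray]:
    return frames[result.start_index : result.end_index]
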