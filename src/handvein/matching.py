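"""Template comparison by translation-searched cross-correlation.

Two binary maximum-curvature maps are compared by sliding one over the
other (cross-correlation computed in the frequency domain) and counting
overlapping active pixels at every translation within the allowed search
window.  The match score is the peak overlap count normalized by the
smaller of the two active-pixel counts, so identical templates score 1
and templates that cannot overlap score 0.  Rotation is not searched:
finger normalization is assumed to have removed it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .features import VeinTemplate


class MatchError(RuntimeError):
    pass


@dataclass(frozen=True)
class MatchScore:
    score: float
    best_offset: tuple[int, int]  # (dy, dx) applied to the probe
    overlap: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


def _default_shift(shape_a, shape_b, frac: float = 0.2) -> tuple[int, int]:
    rows = 0.5 * (shape_a[0] + shape_b[0])
    cols = 0.5 * (shape_a[1] + shape_b[1])
    return int(round(frac * rows)), int(round(frac * cols))


def overlap_surface(enrolled: np.ndarray, probe: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Integer overlap counts for every translation of the probe.

    Returns (surface, lag0_y, lag0_x): ``surface[lag0_y + dy, lag0_x + dx]``
    is the number of coincident active pixels when the probe is shifted
    by (dy, dx).  Computed via frequency-domain convolution and rounded
    to exact integers.
    """
    a = enrolled.astype(float)
    b = probe.astype(float)
    corr = fftconvolve(a, b[::-1, ::-1], mode="full")
    surface = np.rint(corr).astype(np.int64)
    return surface, probe.shape[0] - 1, probe.shape[1] - 1


def match_templates(
    enrolled: VeinTemplate,
    probe: VeinTemplate,
    max_shift: tuple[int, int] | None = None,
) -> MatchScore:
    """Best-translation overlap score between two templates.

    The search is restricted to |dy| <= max_shift[0], |dx| <= max_shift[1]
    (default: 20% of the mean template extent per axis).  Ties on the
    overlap count are broken toward the smallest |dy|+|dx|, then
    lexicographically, so the result is deterministic and symmetric in
    score: match(a, b).score == match(b, a).score.
    """
    A, B = enrolled.feature_map, probe.feature_map
    for s_a, s_b in zip(A.shape, B.shape):
        if max(s_a, s_b) > 2 * min(s_a, s_b):
            raise MatchError(
                f"template shapes {A.shape} and {B.shape} differ by more than 2x"
            )
    na, nb = enrolled.n_active, probe.n_active
    if na == 0 or nb == 0:
        raise MatchError("cannot match an empty template")
    if max_shift is None:
        max_shift = _default_shift(A.shape, B.shape)

    surface, oy, ox = overlap_surface(A, B)
    dy_lo, dy_hi = -min(max_shift[0], oy), min(max_shift[0], A.shape[0] - 1)
    dx_lo, dx_hi = -min(max_shift[1], ox), min(max_shift[1], A.shape[1] - 1)
    window = surface[oy + dy_lo : oy + dy_hi + 1, ox + dx_lo : ox + dx_hi + 1]

    peak = int(window.max()) if window.size else 0
    if peak <= 0:
        return MatchScore(score=0.0, best_offset=(0, 0), overlap=0)
    ys, xs = np.nonzero(window == peak)
    dys, dxs = ys + dy_lo, xs + dx_lo
    order = np.lexsort((dxs, dys, np.abs(dys) + np.abs(dxs)))
    best = (int(dys[order[0]]), int(dxs[order[0]]))
    return MatchScore(score=peak / min(na, nb), best_offset=best, overlap=peak)


def match_templates_bruteforce(
    enrolled: VeinTemplate,
    probe: VeinTemplate,
    max_shift: tuple[int, int] | None = None,
) -> MatchScore:
    """Exhaustive spatial-domain reference matcher (slow; for validation).

    Counts overlaps by explicit array shifting at every admissible
    translation.  Must agree exactly with :func:`match_templates`.
    """
    A, B = enrolled.feature_map, probe.feature_map
    if max_shift is None:
        max_shift = _default_shift(A.shape, B.shape)
    ha, wa = A.shape
    hb, wb = B.shape
    best_overlap, best_off = 0, (0, 0)
    candidates = []
    for dy in range(-max_shift[0], max_shift[0] + 1):
        for dx in range(-max_shift[1], max_shift[1] + 1):
            # probe pixel (r, c) lands on enrolled pixel (r+dy, c+dx)
            r0, r1 = max(0, dy), min(ha, hb + dy)
            c0, c1 = max(0, dx), min(wa, wb + dx)
            if r0 >= r1 or c0 >= c1:
                continue
            ov = int(
                np.logical_and(
                    A[r0:r1, c0:c1], B[r0 - dy : r1 - dy, c0 - dx : c1 - dx]
                ).sum()
            )
            candidates.append((ov, abs(dy) + abs(dx), dy, dx))
    if candidates:
        best = max(candidates, key=lambda t: (t[0], -t[1], -t[2], -t[3]))
        if best[0] > 0:
            best_overlap, best_off = best[0], (best[2], best[3])
    score = best_overlap / min(enrolled.n_active, probe.n_active)
    return MatchScore(score=score, best_offset=best_off, overlap=best_overlap)
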