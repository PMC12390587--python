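"""Verification protocols, error-rate evaluation and multi-finger fusion.

A verification experiment enrolls one sample per identity and compares
every remaining (probe) sample against its own identity (genuine) and
against three randomly drawn other identities (zero-effort impostors,
ZEI).  Performance is summarized by

    FMR  — % of impostor comparisons accepted (score >= threshold)
    FNMR — % of genuine comparisons rejected
    HTER — 0.5 (FMR + FNMR)

with the operating threshold chosen on a development split so that the
dev FMR does not exceed a target (default 0.1%), then transferred
unchanged to the evaluation split.

For hand-level decisions the three per-finger scores (index, middle,
ring) of each hand probe form a 3-D feature vector; an RBF-kernel SVM is
fit on the dev genuine/ZEI vectors and its continuous decision values
are thresholded with the same dev-FMR rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .core_io import ScoreTable

FUSION_FINGERS = ("index", "middle", "ring")


@dataclass(frozen=True)
class ProtocolDef:
    id: str
    modality: str  # LH | RH
    camera: str  # left | right
    wavelength: str  # 850 | 950

    @property
    def name(self) -> str:
        return f"{self.modality}_{self.camera}_{self.wavelength}"


#: The eight canonical protocols: {LH,RH} x {left,right} x {850,950}.
CANONICAL_PROTOCOLS = tuple(
    ProtocolDef(id=f"P{i + 1}", modality=m, camera=c, wavelength=w)
    for i, (m, c, w) in enumerate(
        product(("LH", "RH"), ("left", "right"), ("850", "950"))
    )
)


@dataclass(frozen=True)
class EvalResult:
    fmr_pct: float
    fnmr_pct: float
    hter_pct: float
    threshold: float
    n_genuine: int
    n_impostor: int

    def __post_init__(self) -> None:
        if abs(self.hter_pct - 0.5 * (self.fmr_pct + self.fnmr_pct)) > 1e-12:
            raise ValueError("HTER must equal 0.5 (FMR + FNMR)")
        for r in (self.fmr_pct, self.fnmr_pct, self.hter_pct):
            if not 0.0 <= r <= 100.0:
                raise ValueError("rates must lie in [0, 100] percent")


@dataclass
class FusionVector:
    scores: np.ndarray  # (3,) index, middle, ring
    hand_probe_id: str
    is_genuine: bool

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float).reshape(-1)
        if s.shape != (3,) or not np.isfinite(s).all():
            raise ValueError("fusion vector needs exactly 3 finite finger scores")
        self.scores = s


@dataclass
class Protocol:
    """Materialized comparison plan for one experiment."""

    enrolled: pd.DataFrame  # one row per enrolled identity sample
    probes: pd.DataFrame
    comparisons: pd.DataFrame  # probe_key, enrolled_identity, is_genuine
    n_excluded: int = 0


def build_protocol(
    manifest: pd.DataFrame,
    seed: int,
    n_zei: int = 3,
) -> Protocol:
    """Construct enrolment/probe sets and the comparison list.

    ``manifest`` has one row per sample with columns ``identity``,
    ``sample_index`` and ``complete`` (four-finger segmentation success).
    Incomplete samples are excluded.  The lowest sample index per
    identity is enrolled; all remaining samples are probes, each compared
    once against its own identity and against ``n_zei`` distinct other
    enrolled identities drawn without replacement using ``seed``.
    """
    required = {"identity", "sample_index", "complete"}
    if missing := required - set(manifest.columns):
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    n_excluded = int((~manifest["complete"].astype(bool)).sum())
    usable = manifest[manifest["complete"].astype(bool)].copy()
    usable = usable.sort_values(["identity", "sample_index"]).reset_index(drop=True)

    enrolled = usable.groupby("identity", sort=True).head(1).reset_index(drop=True)
    enrolled_ids = list(enrolled["identity"])
    if len(enrolled_ids) < n_zei + 1:
        raise ValueError(
            f"need at least {n_zei + 1} enrolled identities to draw {n_zei} "
            f"zero-effort impostors; got {len(enrolled_ids)}"
        )
    enrol_keys = set(zip(enrolled["identity"], enrolled["sample_index"]))
    probes = usable[
        ~usable.apply(
            lambda r: (r["identity"], r["sample_index"]) in enrol_keys, axis=1
        )
    ].reset_index(drop=True)

    rng = np.random.default_rng(seed)
    rows = []
    for _, probe in probes.iterrows():
        pid = probe["identity"]
        key = f"{pid}#{probe['sample_index']}"
        rows.append({"probe_key": key, "probe_identity": pid,
                     "enrolled_identity": pid, "is_genuine": True})
        others = [e for e in enrolled_ids if e != pid]
        for zei in rng.choice(others, size=n_zei, replace=False):
            rows.append({"probe_key": key, "probe_identity": pid,
                         "enrolled_identity": zei, "is_genuine": False})
    comparisons = pd.DataFrame(rows)
    return Protocol(enrolled, probes, comparisons, n_excluded)


def threshold_at_fmr(dev_scores: ScoreTable | np.ndarray, target_fmr_pct: float) -> float:
    """Smallest threshold whose dev-set FMR does not exceed the target.

    The decision rule is accept iff score >= threshold, so FMR is a step
    function of the threshold; candidates are the sorted impostor scores
    themselves plus a value just above the maximum (FMR = 0).
    """
    impostor = (
        dev_scores.impostor
        if isinstance(dev_scores, ScoreTable)
        else np.asarray(dev_scores, dtype=float)
    )
    if impostor.size == 0:
        raise ValueError("need at least one impostor score")
    grid = np.sort(np.unique(impostor))
    n = impostor.size
    for t in grid:
        fmr = 100.0 * (impostor >= t).sum() / n
        if fmr <= target_fmr_pct:
            return float(t)
    return float(np.nextafter(grid[-1], np.inf))


def evaluate(
    scores: ScoreTable | tuple[np.ndarray, np.ndarray], threshold: float
) -> EvalResult:
    """FMR/FNMR/HTER of labeled scores at a fixed threshold."""
    if isinstance(scores, ScoreTable):
        genuine, impostor = scores.genuine, scores.impostor
    else:
        genuine, impostor = (np.asarray(a, dtype=float) for a in scores)
    if genuine.size == 0 or impostor.size == 0:
        raise ValueError("both genuine and impostor scores are required")
    fmr = 100.0 * (impostor >= threshold).sum() / impostor.size
    fnmr = 100.0 * (genuine < threshold).sum() / genuine.size
    return EvalResult(
        fmr_pct=float(fmr),
        fnmr_pct=float(fnmr),
        hter_pct=0.5 * (float(fmr) + float(fnmr)),
        threshold=float(threshold),
        n_genuine=int(genuine.size),
        n_impostor=int(impostor.size),
    )


def hter_pct(fmr_pct: float, fnmr_pct: float) -> float:
    """HTER = 0.5 (FMR + FNMR), in percent."""
    return 0.5 * (fmr_pct + fnmr_pct)


@dataclass
class SvmConfig:
    C: float = 1.0
    gamma: str | float = "scale"
    class_weight: str | None = "balanced"
    normalize: bool = False  # optionally standardize finger scores


def fuse_fingers(
    dev_vectors: list[FusionVector],
    eval_vectors: list[FusionVector],
    target_fmr_pct: float = 0.1,
    svm: SvmConfig | None = None,
    seed: int = 0,
) -> tuple[EvalResult, EvalResult]:
    """Hand-level decisions from 3-finger score vectors via an RBF SVM.

    The classifier is fit on the dev vectors; its signed decision values
    act as classification scores.  The classification-score threshold is
    chosen with the dev-FMR rule and applied to both splits.
    """
    if svm is None:
        svm = SvmConfig()
    X_dev = np.stack([v.scores for v in dev_vectors])
    y_dev = np.array([v.is_genuine for v in dev_vectors])
    X_eval = np.stack([v.scores for v in eval_vectors])
    y_eval = np.array([v.is_genuine for v in eval_vectors])
    if len(np.unique(y_dev)) < 2:
        raise ValueError("dev set must contain both genuine and impostor vectors")
    mu, sd = (X_dev.mean(0), X_dev.std(0) + 1e-12) if svm.normalize else (0.0, 1.0)
    clf = SVC(
        kernel="rbf",
        C=svm.C,
        gamma=svm.gamma,
        class_weight=svm.class_weight,
        random_state=seed,
    )
    clf.fit((X_dev - mu) / sd, y_dev)
    s_dev = clf.decision_function((X_dev - mu) / sd)
    s_eval = clf.decision_function((X_eval - mu) / sd)
    thr = threshold_at_fmr(s_dev[~y_dev], target_fmr_pct)
    # When the dev decision values are separated, every threshold up to the
    # smallest accepted genuine value yields the same dev FMR/FNMR; take the
    # midpoint of that interval (maximum margin) instead of its impostor
    # edge, which transfers far more robustly to the eval split.
    gen_above = s_dev[y_dev][s_dev[y_dev] >= thr]
    if gen_above.size and gen_above.min() > thr:
        thr = 0.5 * (thr + float(gen_above.min()))
    return (
        evaluate((s_dev[y_dev], s_dev[~y_dev]), thr),
        evaluate((s_eval[y_eval], s_eval[~y_eval]), thr),
    )
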