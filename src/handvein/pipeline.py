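"""End-to-end recognition pipeline and the seeded synthetic benchmark.

One sample flows through: segmentation -> anatomical reordering ->
rotation normalization -> vein enhancement -> maximum-curvature template,
one template per finger.  The benchmark renders a population of
synthetic identities (two hands per subject, several samples each),
builds dev/eval verification protocols, compares templates, picks the
operating threshold on the dev split at a target FMR and reports
single-finger and fused-hand error rates on both splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import ScoreTable
from .evaluation import (
    EvalResult,
    FusionVector,
    SvmConfig,
    build_protocol,
    evaluate,
    fuse_fingers,
    threshold_at_fmr,
)
from .features import MCParams, VeinTemplate, enhance_veins, extract_mc
from .matching import match_templates
from .segmentation import (
    SegmentationParams,
    extract_fingers,
    normalize_finger,
    reorder_fingers,
)
from .synth import RenderParams, make_identity, render_hand

FUSION_FINGERS = ("index", "middle", "ring")


def build_templates(
    image: np.ndarray,
    hand: str,
    enhancer: str = "baseline",
    seg_params: SegmentationParams | None = None,
    mc_params: MCParams | None = None,
) -> dict[str, VeinTemplate] | None:
    """Per-finger templates from one hand image, or None when the sample
    fails four-finger segmentation (such samples are excluded upstream)."""
    seg = extract_fingers(image, seg_params)
    if not seg.complete:
        return None
    seg = reorder_fingers(seg, hand)
    templates: dict[str, VeinTemplate] = {}
    try:
        for finger in seg.fingers:
            normalized = normalize_finger(finger)
            enhanced = enhance_veins(normalized, enhancer)
            templates[finger.finger_label] = extract_mc(enhanced, mc_params)
    except ValueError:
        return None
    return templates


@dataclass
class BenchmarkConfig:
    """Default study conditions: 20 subjects x 2 hands x 5 samples."""

    n_subjects: int = 20
    n_samples: int = 5
    hands: tuple[str, ...] = ("LH", "RH")
    seed: int = 0
    render: RenderParams = field(default_factory=RenderParams)
    enhancer: str = "baseline"
    mc: MCParams = field(default_factory=MCParams)
    target_fmr_pct: float = 0.1
    n_zei: int = 3
    svm: SvmConfig = field(default_factory=SvmConfig)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SplitResult:
    single_finger: EvalResult
    fused: EvalResult
    per_finger: dict[str, EvalResult]


@dataclass
class BenchmarkResult:
    dev: SplitResult
    eval: SplitResult
    threshold: float
    scores: dict[str, ScoreTable]  # split -> finger-score table
    manifest: pd.DataFrame
    config: BenchmarkConfig


def _identity_seed(seed: int, subject: int, hand: str) -> int:
    ss = np.random.SeedSequence([seed, subject, 0 if hand == "LH" else 1])
    return int(ss.generate_state(1)[0] % (2**31))


def render_population(config: BenchmarkConfig):
    """Render every sample and build its templates; returns the sample
    manifest and a template store keyed by (identity, sample_index)."""
    manifest_rows = []
    store: dict[tuple[str, int], dict[str, VeinTemplate]] = {}
    for subject in range(config.n_subjects):
        for hand in config.hands:
            identity_id = f"S{subject:03d}_{hand}"
            identity = make_identity(_identity_seed(config.seed, subject, hand), hand)
            for s in range(config.n_samples):
                render = render_hand(identity, config.render, sample_seed=s)
                templates = build_templates(
                    render.image, hand, config.enhancer, mc_params=config.mc
                )
                complete = templates is not None
                if complete:
                    store[(identity_id, s)] = templates
                manifest_rows.append(
                    {
                        "identity": identity_id,
                        "subject": subject,
                        "hand": hand,
                        "sample_index": s,
                        "complete": complete,
                    }
                )
    return pd.DataFrame(manifest_rows), store


def _score_split(
    manifest: pd.DataFrame,
    store,
    config: BenchmarkConfig,
    split_name: str,
    protocol_seed: int,
) -> tuple[ScoreTable, list[FusionVector]]:
    protocol = build_protocol(manifest, seed=protocol_seed, n_zei=config.n_zei)
    enrol_sample = dict(
        zip(protocol.enrolled["identity"], protocol.enrolled["sample_index"])
    )
    rows = []
    vectors = []
    for _, cmp_row in protocol.comparisons.iterrows():
        probe_identity, probe_s = cmp_row["probe_key"].split("#")
        probe_tmpl = store[(probe_identity, int(probe_s))]
        enr_identity = cmp_row["enrolled_identity"]
        enr_tmpl = store[(enr_identity, enrol_sample[enr_identity])]
        finger_scores = []
        for finger in FUSION_FINGERS:
            score = match_templates(enr_tmpl[finger], probe_tmpl[finger]).score
            finger_scores.append(score)
            rows.append(
                {
                    "probe_id": cmp_row["probe_key"],
                    "enrolled_id": enr_identity,
                    "finger_label": finger,
                    "protocol_id": split_name,
                    "score": score,
                    "is_genuine": bool(cmp_row["is_genuine"]),
                }
            )
        vectors.append(
            FusionVector(
                scores=np.array(finger_scores),
                hand_probe_id=f"{cmp_row['probe_key']}|{enr_identity}",
                is_genuine=bool(cmp_row["is_genuine"]),
            )
        )
    return ScoreTable(pd.DataFrame(rows)), vectors


def run_benchmark(config: BenchmarkConfig | None = None) -> BenchmarkResult:
    """Full synthetic verification experiment at the configured conditions.

    Subjects are split in half by sorted id: first half development,
    second half evaluation (each split enrolls and draws its zero-effort
    impostors internally).  The single-finger threshold is set on pooled
    dev finger scores at the target FMR and transferred to eval; fusion
    uses an RBF-SVM over (index, middle, ring) score vectors with the
    same threshold rule applied to its decision values.
    """
    if config is None:
        config = BenchmarkConfig()
    manifest, store = render_population(config)
    half = config.n_subjects // 2
    dev_manifest = manifest[manifest["subject"] < half]
    eval_manifest = manifest[manifest["subject"] >= half]

    dev_scores, dev_vecs = _score_split(dev_manifest, store, config, "dev", config.seed + 101)
    eval_scores, eval_vecs = _score_split(eval_manifest, store, config, "eval", config.seed + 202)

    thr = threshold_at_fmr(dev_scores, config.target_fmr_pct)
    single_dev = evaluate(dev_scores, thr)
    single_eval = evaluate(eval_scores, thr)

    def per_finger(scores: ScoreTable) -> dict[str, EvalResult]:
        out = {}
        for finger in FUSION_FINGERS:
            sub = ScoreTable(scores.df[scores.df["finger_label"] == finger])
            out[finger] = evaluate(sub, thr)
        return out

    fused_dev, fused_eval = fuse_fingers(
        dev_vecs, eval_vecs, config.target_fmr_pct, config.svm, seed=config.seed
    )
    return BenchmarkResult(
        dev=SplitResult(single_dev, fused_dev, per_finger(dev_scores)),
        eval=SplitResult(single_eval, fused_eval, per_finger(eval_scores)),
        threshold=thr,
        scores={"dev": dev_scores, "eval": eval_scores},
        manifest=manifest,
        config=config,
    )
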