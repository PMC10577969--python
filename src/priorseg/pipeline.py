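"""End-to-end orchestration of prior-guided CTV-TB auto-segmentation.

The per-case workflow mirrors the five clinical steps:

1. deformably register the preoperative to the postoperative CT (DVF),
2. warp the preoperative prior EV_1cm into the postoperative frame
   (T-EV_1cm),
3. enhance both CTs inside their prior ROIs and feed the two channels to
   the 3D U-Net,
4. predict the CTV-TB contour on the postoperative CT,
5. evaluate the prediction against the reference contour (DSC, HD).

:func:`run_experiment` runs a cross-validated three-arm comparison on a
phantom cohort: the prior-guided network, the same network without the
postoperative prior (raw postoperative channel), and the traditional
gray-level threshold baseline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

import numpy as np

from .baseline import ThresholdParams, threshold_segment
from .enhancement import EnhancementParams, enhance_roi, normalize_for_network, shift_to_nonnegative
from .metrics import (
    PairedComparison,
    aggregate_report,
    dsc,
    hausdorff,
    paired_compare,
)
from .phantom import PhantomCase, PhantomParams, generate_cohort
from .priors import build_prior_rois, calibrate_margin
from .registration import RegistrationParams, register_deformable, warp_mask
from .unet_model import TrainConfig, build_unet, make_folds, predict, train
from .volumes import BinaryMask, ImageVolume, write_mask

log = logging.getLogger(__name__)

ARMS = ("with_prior", "without_prior", "baseline")


def desk_train_config(**overrides) -> TrainConfig:
    """Training configuration for the CPU-scale phantom grid.

    Keeps the clinical schedule shape (Adam, batch 4, per-epoch learning
    rate drop, weight decay 3e-5) but shrinks the network to the 64x64x16
    grid and raises the learning rate to 0.1 so the small instance-normalized
    model converges within the few dozen optimization steps a small cohort
    provides.
    """
    defaults = dict(
        learning_rate=0.1,
        max_epochs=8,
        base_channels=4,
        depth=2,
        input_shape=(64, 64, 16),
    )
    defaults.update(overrides)
    return TrainConfig(**defaults)


@dataclasses.dataclass
class PipelineConfig:
    """Everything needed to run the cross-validated three-arm experiment."""

    phantom: PhantomParams = dataclasses.field(default_factory=PhantomParams)
    n_cases: int = 24
    k_folds: int = 2
    margin_candidates: tuple = (10.0, 20.0, 30.0)
    ctv_margin_mm: float = 10.0
    registration: RegistrationParams = dataclasses.field(default_factory=RegistrationParams)
    enhancement: EnhancementParams = dataclasses.field(default_factory=EnhancementParams)
    train: TrainConfig = dataclasses.field(default_factory=desk_train_config)
    threshold_hu: float = 40.0
    master_seed: int = 0
    output_dir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclasses.dataclass
class CaseInputs:
    """Per-case intermediates shared by the three arms."""

    case: PhantomCase
    margin_mm: float
    ev_1cm: BinaryMask
    t_ev_1cm: BinaryMask
    pre_enhanced: ImageVolume
    post_enhanced: ImageVolume
    post_raw: ImageVolume  # shifted but unenhanced postoperative channel


def prepare_case(case: PhantomCase, config: PipelineConfig) -> CaseInputs:
    """Steps 1–3: registration, prior transfer, enhancement."""
    margin = calibrate_margin(case.pt, case.pathology, config.margin_candidates)
    _, ev_1cm = build_prior_rois(case.pt, margin, config.ctv_margin_mm)
    dvf = register_deformable(case.postop, case.preop, config.registration)
    t_ev_1cm = warp_mask(ev_1cm, dvf)
    t_ev_1cm = BinaryMask(t_ev_1cm.voxels, t_ev_1cm.spacing, t_ev_1cm.origin, label="T-EV_1cm")

    pre_shift = shift_to_nonnegative(case.preop)
    post_shift = shift_to_nonnegative(case.postop)
    pre_enhanced = enhance_roi(pre_shift, ev_1cm, config.enhancement)
    post_enhanced = enhance_roi(post_shift, t_ev_1cm, config.enhancement)
    return CaseInputs(
        case=case,
        margin_mm=margin,
        ev_1cm=ev_1cm,
        t_ev_1cm=t_ev_1cm,
        pre_enhanced=pre_enhanced,
        post_enhanced=post_enhanced,
        post_raw=post_shift,
    )


def network_input(inputs: CaseInputs, arm: str) -> np.ndarray:
    """Stack the two normalized channels for a learning arm.

    The prior-guided arm uses both enhanced channels; the comparator arm
    replaces the postoperative channel with the raw (unenhanced) scan.
    """
    if arm == "with_prior":
        post = inputs.post_enhanced
    elif arm == "without_prior":
        post = inputs.post_raw
    else:
        raise ValueError(f"not a learning arm: {arm!r}")
    return np.stack(
        [
            normalize_for_network(inputs.pre_enhanced).voxels,
            normalize_for_network(post).voxels,
        ]
    ).astype(np.float32)


def _metric_row(case: PhantomCase, predicted: BinaryMask) -> dict:
    """DSC always defined (0 for an empty prediction); HD NaN when undefined."""
    row = {"case_id": case.case_id}
    if case.ctv_tb.n_foreground == 0:
        row["dsc"] = float("nan")
        row["hd_mm"] = float("nan")
        return row
    if predicted.n_foreground == 0:
        row["dsc"] = 0.0
        row["hd_mm"] = float("nan")
    else:
        row["dsc"] = dsc(predicted, case.ctv_tb)
        row["hd_mm"] = hausdorff(predicted, case.ctv_tb)
    return row


def run_case(
    inputs: CaseInputs,
    config: PipelineConfig,
    network=None,
    arm: str = "with_prior",
) -> tuple[BinaryMask, dict]:
    """Steps 4–5 for a single case: predict and evaluate one arm."""
    case = inputs.case
    if arm == "baseline":
        predicted = threshold_segment(
            case.postop, ThresholdParams(case.breast_post, config.threshold_hu)
        )
    else:
        post = inputs.post_enhanced if arm == "with_prior" else inputs.post_raw
        predicted = predict(network, inputs.pre_enhanced, post)
    row = _metric_row(case, predicted)
    row["arm"] = arm
    if config.output_dir:
        _persist_case(inputs, predicted, config, arm)
    return predicted, row


def _persist_case(inputs, predicted, config, arm):
    case_dir = os.path.join(config.output_dir, inputs.case.case_id)
    os.makedirs(case_dir, exist_ok=True)
    path = os.path.join(case_dir, f"predicted_{arm}.nii.gz")
    write_mask(predicted, path)
    sidecar = {
        "stage": "predict",
        "arm": arm,
        "case_id": inputs.case.case_id,
        "master_seed": config.master_seed,
        "config_hash": config.config_hash(),
        "margin_mm": inputs.margin_mm,
    }
    with open(path + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


@dataclasses.dataclass
class ExperimentReport:
    """Three-arm cross-validated results plus paired comparisons."""

    arms: dict  # arm name -> MetricsReport
    comparisons: dict  # label -> PairedComparison
    fold_assignments: dict
    prior_dsc: dict  # case_id -> DSC of T-EV_1cm vs reference CTV-TB
    config_hash: str = ""

    def summary(self) -> dict:
        out = {}
        for arm, report in self.arms.items():
            for metric, (mean, sd, n) in report.aggregate.items():
                out[f"{arm}.{metric}"] = {"mean": mean, "sd": sd, "n": n}
        pv = [v for v in self.prior_dsc.values()]
        out["prior.dsc"] = {
            "mean": float(np.mean(pv)),
            "sd": float(np.std(pv, ddof=1)) if len(pv) > 1 else 0.0,
            "n": len(pv),
        }
        return out

    def to_json(self, path: str) -> str:
        payload = {
            "summary": self.summary(),
            "comparisons": {k: dataclasses.asdict(v) for k, v in self.comparisons.items()},
            "folds": {str(k): v for k, v in self.fold_assignments.items()},
            "per_case": {arm: r.per_case for arm, r in self.arms.items()},
            "prior_dsc": self.prior_dsc,
            "config_hash": self.config_hash,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, allow_nan=True)
        return str(path)


def _arm_seed(master_seed: int, fold: int, arm: str) -> int:
    return int(
        np.random.SeedSequence([master_seed, fold, ARMS.index(arm)]).generate_state(1)[0]
        % (2 ** 31)
    )


def _paired_defined(rows_a, rows_b, key):
    """Values for cases where the metric is defined in both arms."""
    b_by_id = {r["case_id"]: r for r in rows_b}
    xs, ys = [], []
    for ra in rows_a:
        rb = b_by_id.get(ra["case_id"])
        if rb is None:
            continue
        if np.isfinite(ra[key]) and np.isfinite(rb[key]):
            xs.append(ra[key])
            ys.append(rb[key])
    return xs, ys


def run_experiment(
    cohort: list[PhantomCase] | None, config: PipelineConfig
) -> ExperimentReport:
    """Cross-validated three-arm comparison on a (phantom) cohort.

    For every fold, both learning arms are trained on the remaining folds
    and evaluated on the held-out cases; the threshold baseline needs no
    training. Per-case DSC/HD rows are aggregated per arm and the arms are
    compared pairwise on the cases where both are defined.
    """
    if cohort is None:
        cohort = generate_cohort(
            config.n_cases, dataclasses.replace(config.phantom, seed=config.master_seed)
        )
    if len(cohort) < config.k_folds:
        raise ValueError("cohort smaller than the number of folds")
    ids = [c.case_id for c in cohort]
    folds = make_folds(ids, config.k_folds, config.master_seed)

    log.info("preparing %d cases (registration + priors + enhancement)", len(cohort))
    inputs = {}
    prior_dsc = {}
    for case in cohort:
        t0 = time.time()
        ci = prepare_case(case, config)
        inputs[case.case_id] = ci
        prior_dsc[case.case_id] = dsc(ci.t_ev_1cm, case.ctv_tb)
        log.debug("prepared %s in %.2fs", case.case_id, time.time() - t0)

    rows = {arm: [] for arm in ARMS}
    for fold in range(config.k_folds):
        test_ids = set(folds.fold_ids(fold))
        train_ids = [i for i in ids if i not in test_ids]
        for arm in ("with_prior", "without_prior"):
            cfg = dataclasses.replace(config.train, seed=_arm_seed(config.master_seed, fold, arm))
            net = build_unet(cfg)
            data = [
                (network_input(inputs[i], arm), inputs[i].case.ctv_tb.voxels.astype(np.float32))
                for i in train_ids
            ]
            t0 = time.time()
            net, history = train(net, data, cfg)
            log.info(
                "fold %d arm %s: trained %d cases, loss %.3f -> %.3f (%.1fs)",
                fold, arm, len(data),
                history["epoch_loss"][0], history["epoch_loss"][-1], time.time() - t0,
            )
            for cid in sorted(test_ids):
                _, row = run_case(inputs[cid], config, net, arm)
                rows[arm].append(row)
    for cid in ids:  # baseline is training-free: evaluate every case once
        _, row = run_case(inputs[cid], config, arm="baseline")
        rows["baseline"].append(row)

    arms = {arm: aggregate_report(sorted(r, key=lambda x: x["case_id"])) for arm, r in rows.items()}
    comparisons = {}
    for metric in ("dsc", "hd_mm"):
        for a, b in (("with_prior", "without_prior"), ("with_prior", "baseline")):
            xs, ys = _paired_defined(arms[a].per_case, arms[b].per_case, metric)
            label = f"{metric}:{a}_vs_{b}"
            if len(xs) >= 3:
                comparisons[label] = paired_compare(xs, ys)
            else:
                comparisons[label] = PairedComparison(
                    "degenerate", float("nan"), float("nan"), False, float("nan")
                )
    report = ExperimentReport(arms, comparisons, dict(folds.assignments), prior_dsc,
                              config_hash=config.config_hash())
    if config.output_dir:
        os.makedirs(config.output_dir, exist_ok=True)
        report.to_json(os.path.join(config.output_dir, "experiment_report.json"))
        for arm in ARMS:
            arms[arm].to_csv(os.path.join(config.output_dir, f"per_case_{arm}.csv"))
    return report


def export_overlay(
    postop: ImageVolume,
    predicted: BinaryMask,
    reference: BinaryMask,
    path_prefix: str,
    views: tuple = ("axial", "coronal", "sagittal"),
) -> list[str]:
    """Write mid-slice PNG overlays: predicted contour white, reference black.

    One image per requested view; pixel dimensions equal the slice
    dimensions. Returns the written paths.
    """
    from matplotlib.image import imsave
    from scipy import ndimage as ndi

    if postop.shape != predicted.shape or postop.shape != reference.shape:
        raise ValueError("overlay inputs must share one grid")

    def contour(mask2d):
        return mask2d & ~ndi.binary_erosion(mask2d)

    axes = {"sagittal": 0, "coronal": 1, "axial": 2}
    paths = []
    for view in views:
        ax = axes[view]
        ref_any = np.any(reference.voxels, axis=tuple(i for i in range(3) if i != ax))
        mid = int(np.argwhere(ref_any).mean()) if ref_any.any() else postop.shape[ax] // 2
        sl = [slice(None)] * 3
        sl[ax] = mid
        img = postop.voxels[tuple(sl)].astype(float)
        lo, hi = np.percentile(img, [1, 99])
        gray = np.clip((img - lo) / max(hi - lo, 1e-6), 0, 1)
        rgb = np.stack([gray] * 3, axis=-1)
        rgb[contour(reference.voxels[tuple(sl)])] = [0.0, 0.0, 0.0]
        rgb[contour(predicted.voxels[tuple(sl)])] = [1.0, 1.0, 1.0]
        out = f"{path_prefix}_{view}.png"
        imsave(out, np.rot90(rgb))
        paths.append(out)
    return paths
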