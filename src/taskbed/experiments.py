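"""Study designs: lambda sweeps, depth sweeps, and task-shift experiments.

Every experiment follows the same arm protocol:

1. generate a task's noiseless targets at the full field of view, simulate
   paired low-dose images through the fan-beam pipeline, and crop the ROI;
2. MSE-pretrain the CNN denoiser on the training pairs;
3. fine-tune the last ``n_train`` layers with the hybrid loss at a given
   lambda, with an appended task observer;
4. train an *independent* evaluation observer (SLNN-NO, or the softmax SLNN
   for detection-localization tasks) on the denoised training images, and
   measure AUC on the denoised test images, together with RMSE/SSIM against
   the noiseless targets and the covariance condition ratio of the denoised
   test ensemble.

Matched reference arms share seeds, sample sizes, the pretrained model, and
the observer protocol, so performance gaps between arms are attributable to
the fine-tuning task alone.

The default :data:`TINY` profile is sized for a single CPU; :data:`DESK`
holds the larger reference configuration. All sizes are deliberate
reductions of the study design (tens of thousands of 120x120 images on a
GPU in the original setting) that preserve its structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .containers import ImageEnsemble, TARGET, LOWDOSE, DENOISED
from .phantom import (
    BackgroundModel, SignalModel, LocationLaw, TaskSpec, build_ensemble,
    InvalidConfigurationError,
)
from .imaging import ScannerGeometry, NoiseModel, simulate_lowdose
from .denoiser import (
    DenoiserSpec, DenoiserModel, TrainSettings, build_denoiser, pretrain, apply,
)
from .taskloss import HybridConfig, finetune
from .observers import estimate_stats, train_evaluation_slnn
from .evaluate import empirical_auc, rmse, ssim, covariance_spectrum


class UnsupportedShiftError(ValueError):
    pass


# ---------------------------------------------------------------------------
# scale profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaleProfile:
    """All problem sizes and optimizer settings for one experiment scale."""

    roi_side: int = 32
    full_side: int = 48
    filters: int = 6
    depth: int = 7
    n_train_per_class: int = 128
    n_val_per_class: int = 64
    n_test_per_class: int = 256
    pretrain_epochs: int = 60
    finetune_epochs: int = 20
    observer_epochs: int = 120
    batch_size: int = 32
    learning_rate: float = 3e-3
    observer_learning_rate: float = 3e-3
    n_views: int = 64
    n_detector_elements: int = 96
    detector_element_size: float = 1.5
    incident_flux_I0: float = math.e ** 11
    spectrum_rank: int = 100

    def geometry(self) -> ScannerGeometry:
        return ScannerGeometry(
            n_views=self.n_views,
            n_detector_elements=self.n_detector_elements,
            detector_element_size=self.detector_element_size,
        )

    def noise(self) -> NoiseModel:
        return NoiseModel(self.incident_flux_I0)

    def denoiser_spec(self, depth: int | None = None) -> DenoiserSpec:
        return DenoiserSpec(depth_D=depth or self.depth,
                            filters_per_layer=self.filters)

    def train_settings(self, epochs: int) -> TrainSettings:
        return TrainSettings(learning_rate=self.learning_rate,
                             batch_size=self.batch_size, epochs=epochs)

    def observer_settings(self) -> TrainSettings:
        return TrainSettings(learning_rate=self.observer_learning_rate,
                             batch_size=self.batch_size,
                             epochs=self.observer_epochs)


#: single-CPU profile used by the test suite and the acceptance script
TINY = ScaleProfile()

#: larger reference configuration (hours of CPU time)
DESK = ScaleProfile(
    roi_side=64, full_side=96, filters=64, depth=7,
    n_train_per_class=1000, n_val_per_class=200, n_test_per_class=1000,
    pretrain_epochs=30, finetune_epochs=30, observer_epochs=100,
    learning_rate=1e-4, observer_learning_rate=1e-4,
    n_views=256, n_detector_elements=512, detector_element_size=0.8,
)


# ---------------------------------------------------------------------------
# task builders (locations expressed in full-field coordinates)
# ---------------------------------------------------------------------------

def default_background(profile: ScaleProfile) -> BackgroundModel:
    return BackgroundModel(image_side=profile.full_side)


def default_signal() -> SignalModel:
    return SignalModel()


def make_task(profile: ScaleProfile, location_mode: str = "fixed",
              radius: float = 6.0, n_sites: int = 2,
              site_ring_radius: float = 8.0) -> TaskSpec:
    """Build a task whose signal locations live inside the centred ROI.

    * ``fixed``: the ROI centre;
    * ``uniform-disc``: uniform in a disc of ``radius`` pixels at the centre;
    * ``discrete-sites``: ``n_sites`` sites evenly spaced on a ring of radius
      ``site_ring_radius`` around the centre (detection-localization).
    """
    c = (profile.full_side - 1) / 2.0
    if location_mode == "fixed":
        loc = LocationLaw(mode="fixed", center=(c, c))
        kind = "binary-detection"
    elif location_mode == "uniform-disc":
        loc = LocationLaw(mode="uniform-disc", center=(c, c), radius_r=radius)
        kind = "binary-detection"
    elif location_mode == "discrete-sites":
        angles = 2 * np.pi * np.arange(n_sites) / n_sites
        sites = tuple(
            (c + site_ring_radius * math.sin(a), c + site_ring_radius * math.cos(a))
            for a in angles
        )
        loc = LocationLaw(mode="discrete-sites", sites=sites)
        kind = "detection-localization"
    else:
        raise InvalidConfigurationError(f"unknown location mode {location_mode!r}")
    return TaskSpec(task_kind=kind, background=default_background(profile),
                    signal=default_signal(), location=loc,
                    incident_flux_I0=profile.incident_flux_I0)


# ---------------------------------------------------------------------------
# dataset and arm machinery
# ---------------------------------------------------------------------------

@dataclass
class TaskDatasets:
    train: ImageEnsemble
    val: ImageEnsemble
    test: ImageEnsemble


def generate_datasets(task: TaskSpec, profile: ScaleProfile,
                      seed: int) -> TaskDatasets:
    """Simulate paired (low-dose, target) train/val/test splits for a task."""
    ss = np.random.SeedSequence([seed, 2025])
    seeds = ss.generate_state(6)
    geometry = profile.geometry()
    noise = profile.noise()
    splits = {}
    sizes = {
        "train": profile.n_train_per_class,
        "val": profile.n_val_per_class,
        "test": profile.n_test_per_class,
    }
    for i, (name, n) in enumerate(sizes.items()):
        targets = build_ensemble(task, n, n, seeds[2 * i])
        splits[name] = simulate_lowdose(targets, geometry, noise,
                                        seeds[2 * i + 1],
                                        roi_side=profile.roi_side)
    return TaskDatasets(**splits)


def pretrain_denoiser(data: TaskDatasets, profile: ScaleProfile, seed: int,
                      depth: int | None = None) -> DenoiserModel:
    model = build_denoiser(profile.denoiser_spec(depth), seed)
    settings = replace(profile.train_settings(profile.pretrain_epochs),
                       seed=seed)
    model, _ = pretrain(model, data.train, data.val, settings)
    return model


def evaluate_arm(model: DenoiserModel, data: TaskDatasets,
                 profile: ScaleProfile, seed: int,
                 task_kind: str = "binary-detection") -> dict:
    """Denoise all splits, train the evaluation observer, and score the arm."""
    den = {
        name: apply(model, getattr(data, name).variant(LOWDOSE))
        for name in ("train", "val", "test")
    }
    train_d = data.train.with_variant(DENOISED, den["train"])
    val_d = data.val.with_variant(DENOISED, den["val"])
    obs = train_evaluation_slnn(train_d, val_d, DENOISED, task_kind,
                                profile.observer_settings(), rng_seed=seed)
    stat = obs.detection_statistic(den["test"])
    roc = empirical_auc(stat, (data.test.labels > 0).astype(int))
    targets = data.test.variant(TARGET)
    stats = estimate_stats(den["test"][data.test.labels > 0],
                           den["test"][data.test.labels == 0])
    spectrum = covariance_spectrum(stats, rank_k=profile.spectrum_rank)
    out = {
        "auc": roc.auc,
        "auc_se": roc.se,
        "rmse": rmse(den["test"], targets),
        "ssim": ssim(den["test"], targets),
        "condition_ratio": spectrum.condition_ratio,
    }
    if task_kind == "detection-localization":
        present = data.test.labels > 0
        loc = obs.localize(den["test"][present])
        out["localization_accuracy"] = float(
            np.mean(loc == data.test.labels[present])
        )
    return out


# ---------------------------------------------------------------------------
# experiment plans
# ---------------------------------------------------------------------------

@dataclass
class ExperimentPlan:
    source_task: TaskSpec
    target_task: TaskSpec | None = None  # None: no task-shift
    lambda_grid: tuple = (0.01, 0.1, 0.3, 0.5, 0.7, 0.9, 0.99)
    ntrain_grid: tuple = (3,)
    depth_grid: tuple = (7,)
    seeds: tuple = (0, 1, 2, 3, 4)
    observer_for_training: str = "slnn-no"
    profile: ScaleProfile = field(default_factory=lambda: TINY)

    def manifest(self) -> dict:
        return asdict(self)


def _finetune_arm(model, data, profile, lam, ntrain, observer_kind, seed):
    config = HybridConfig(lambda_weight=lam, n_trainable_layers=ntrain,
                          task_observer_kind=observer_kind)
    settings = replace(profile.train_settings(profile.finetune_epochs),
                       seed=seed)
    tuned, obs, history = finetune(model, config, data.train, data.val,
                                   settings, rng_seed=seed)
    return tuned, obs, history


def run_lambda_sweep(plan: ExperimentPlan) -> pd.DataFrame:
    """Fine-tune and score every (lambda, n_train, seed) arm of the plan.

    A ``pretrained`` row per seed records the reference metrics of the
    non-task-informed model (the n_train = 0 convention).
    """
    profile = plan.profile
    task = plan.source_task
    rows = []
    for seed in plan.seeds:
        data = generate_datasets(task, profile, seed)
        base = pretrain_denoiser(data, profile, seed)
        ref = evaluate_arm(base, data, profile, seed, task.task_kind)
        rows.append({"seed": seed, "lambda": np.nan, "n_train": 0,
                     "arm": "pretrained", **ref})
        for ntrain in plan.ntrain_grid:
            for lam in plan.lambda_grid:
                if ntrain == 0:
                    # frozen denoiser: identical images, identical metrics
                    rows.append({"seed": seed, "lambda": lam, "n_train": 0,
                                 "arm": "finetuned", **ref})
                    continue
                tuned, _, _ = _finetune_arm(
                    base, data, profile, lam, ntrain,
                    plan.observer_for_training, seed,
                )
                res = evaluate_arm(tuned, data, profile, seed, task.task_kind)
                rows.append({"seed": seed, "lambda": lam, "n_train": ntrain,
                             "arm": "finetuned", **res})
    return pd.DataFrame(rows)


def run_depth_sweep(plan: ExperimentPlan, lambda_weight: float = 0.9,
                    n_train: int = 3) -> pd.DataFrame:
    """Pretrained vs fine-tuned AUC for every denoiser depth in the plan."""
    profile = plan.profile
    task = plan.source_task
    rows = []
    for seed in plan.seeds:
        data = generate_datasets(task, profile, seed)
        for depth in plan.depth_grid:
            base = pretrain_denoiser(data, profile, seed, depth=depth)
            pre = evaluate_arm(base, data, profile, seed, task.task_kind)
            tuned, _, _ = _finetune_arm(base, data, profile, lambda_weight,
                                        n_train, plan.observer_for_training,
                                        seed)
            fin = evaluate_arm(tuned, data, profile, seed, task.task_kind)
            rows.append({"seed": seed, "depth": depth,
                         "auc_pretrained": pre["auc"],
                         "auc_finetuned": fin["auc"],
                         "rmse_pretrained": pre["rmse"],
                         "rmse_finetuned": fin["rmse"]})
    return pd.DataFrame(rows)


def _check_location_only_shift(source: TaskSpec, target: TaskSpec) -> None:
    if (source.background != target.background
            or source.signal != target.signal
            or source.incident_flux_I0 != target.incident_flux_I0):
        raise UnsupportedShiftError(
            "task-shift studies support tasks differing in location law only"
        )


def run_task_shift(plan: ExperimentPlan, target_tasks: list[TaskSpec]
                   | None = None, lambda_weight: float = 0.99,
                   n_train: int = 3) -> pd.DataFrame:
    """Shifted vs matched-reference arms for one or more target tasks.

    The shifted arm fine-tunes on the source task and is evaluated on each
    target task; its matched reference fine-tunes directly on the target
    task. Both arms share the seed, the pretrained model, the sample sizes,
    and the evaluation-observer protocol; evaluation observers are always
    trained on the target-task denoised images of the arm being scored.
    """
    profile = plan.profile
    source = plan.source_task
    targets = target_tasks or [plan.target_task or source]
    for t in targets:
        _check_location_only_shift(source, t)
    rows = []
    for seed in plan.seeds:
        source_data = generate_datasets(source, profile, seed)
        base = pretrain_denoiser(source_data, profile, seed)
        shifted_model, _, _ = _finetune_arm(
            base, source_data, profile, lambda_weight, n_train,
            plan.observer_for_training, seed,
        )
        for t_idx, target in enumerate(targets):
            if target == source:
                target_data = source_data
            else:
                target_data = generate_datasets(target, profile, seed)
            res_shift = evaluate_arm(shifted_model, target_data, profile,
                                     seed, target.task_kind)
            ref_model, _, _ = _finetune_arm(
                base, target_data, profile, lambda_weight, n_train,
                plan.observer_for_training, seed,
            )
            res_ref = evaluate_arm(ref_model, target_data, profile, seed,
                                   target.task_kind)
            rows.append({
                "seed": seed, "target_index": t_idx,
                "target_mode": target.location.mode,
                "target_radius": target.location.radius_r,
                "target_sites": target.location.n_sites,
                "auc_shifted": res_shift["auc"],
                "auc_reference": res_ref["auc"],
                "auc_gap": res_ref["auc"] - res_shift["auc"],
            })
    return pd.DataFrame(rows)
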