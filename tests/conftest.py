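"""Shared fixtures.

The heavy, training-dependent checks (lambda sweep, depth sweep, task-shift)
all draw on one session-scoped :class:`Workbench` that lazily generates and
caches datasets, pretrained denoisers, and fine-tuned arms, so the full CNN
pipeline runs once per configuration for the whole suite.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from taskbed.containers import ImageEnsemble, TARGET, LOWDOSE
from taskbed.experiments import (
    TINY, ScaleProfile, make_task, generate_datasets, pretrain_denoiser,
    evaluate_arm, _finetune_arm,
)

#: seeds for all median-over-seeds trend checks
SEEDS = (0, 1, 2, 3, 4)

LAMBDA_GRID = (0.01, 0.1, 0.3, 0.5, 0.7, 0.9, 0.99)

#: tiny-but-real sizes for bookkeeping/contract tests (models untrained)
MICRO = replace(
    TINY, n_train_per_class=24, n_val_per_class=12, n_test_per_class=24,
    pretrain_epochs=2, finetune_epochs=2, observer_epochs=4,
)


class Workbench:
    """Lazily computed, session-cached experiment artifacts."""

    def __init__(self, profile: ScaleProfile = TINY):
        self.profile = profile
        self.sweep_task = make_task(profile, "uniform-disc", radius=6.0)
        self.fixed_task = make_task(profile, "fixed")
        self._cache: dict = {}

    def _get(self, key, build):
        if key not in self._cache:
            self._cache[key] = build()
        return self._cache[key]

    def data(self, task, seed):
        return self._get(("data", task, seed),
                         lambda: generate_datasets(task, self.profile, seed))

    def pretrained(self, task, seed, depth=None):
        return self._get(
            ("pre", task, seed, depth),
            lambda: pretrain_denoiser(self.data(task, seed), self.profile,
                                      seed, depth=depth),
        )

    def pretrained_metrics(self, task, seed, depth=None):
        return self._get(
            ("pre-metrics", task, seed, depth),
            lambda: evaluate_arm(self.pretrained(task, seed, depth),
                                 self.data(task, seed), self.profile, seed,
                                 task.task_kind),
        )

    def finetuned(self, task, seed, lam, ntrain=3, observer="slnn-no",
                  depth=None, pretrain_task=None):
        base_task = pretrain_task or task
        def build():
            model, obs, hist = _finetune_arm(
                self.pretrained(base_task, seed, depth),
                self.data(task, seed),
                self.profile, lam, ntrain, observer, seed,
            )
            return model
        return self._get(
            ("ft", task, seed, lam, ntrain, observer, depth, base_task), build
        )

    def finetuned_metrics(self, task, seed, lam, ntrain=3,
                          observer="slnn-no", depth=None, pretrain_task=None):
        return self._get(
            ("ft-metrics", task, seed, lam, ntrain, observer, depth,
             pretrain_task),
            lambda: evaluate_arm(
                self.finetuned(task, seed, lam, ntrain, observer, depth,
                               pretrain_task),
                self.data(task, seed), self.profile, seed, task.task_kind,
            ),
        )

    # -- composite studies --------------------------------------------------
    def lambda_sweep(self) -> pd.DataFrame:
        """AUC/RMSE/SSIM/condition-ratio over the lambda grid, all seeds."""
        def build():
            rows = []
            for seed in SEEDS:
                pre = self.pretrained_metrics(self.sweep_task, seed)
                rows.append({"seed": seed, "lambda": np.nan,
                             "arm": "pretrained", **pre})
                for lam in LAMBDA_GRID:
                    res = self.finetuned_metrics(self.sweep_task, seed, lam)
                    rows.append({"seed": seed, "lambda": lam,
                                 "arm": "finetuned", **res})
            return pd.DataFrame(rows)
        return self._get(("lambda-sweep",), build)

    def hotelling_loss_arm(self, seed, lam=0.99):
        """Condition ratio of the SLNN-HO fine-tuned arm at large lambda."""
        return self.finetuned_metrics(self.sweep_task, seed, lam,
                                      observer="slnn-ho")

    def depth_sweep(self, depths=(5, 7, 9), lam=0.9) -> pd.DataFrame:
        def build():
            rows = []
            for seed in SEEDS:
                for depth in depths:
                    d = None if depth == self.profile.depth else depth
                    pre = self.pretrained_metrics(self.sweep_task, seed, d)
                    fin = self.finetuned_metrics(self.sweep_task, seed, lam,
                                                 depth=d)
                    rows.append({"seed": seed, "depth": depth,
                                 "auc_pretrained": pre["auc"],
                                 "auc_finetuned": fin["auc"]})
            return pd.DataFrame(rows)
        return self._get(("depth-sweep", depths, lam), build)

    def task_shift(self, radii=(2.0, 4.0, 6.0), lam=0.99) -> pd.DataFrame:
        """Fixed-location source vs uniform-disc targets of growing radius."""
        def build():
            rows = []
            for seed in SEEDS:
                shifted_model = self.finetuned(self.fixed_task, seed, lam)
                for r in radii:
                    target = make_task(self.profile, "uniform-disc", radius=r)
                    tdata = self.data(target, seed)
                    shift = evaluate_arm(shifted_model, tdata, self.profile,
                                         seed, target.task_kind)
                    # matched reference: same seed and pretrained model,
                    # fine-tuned directly on the target task
                    ref = self.finetuned_metrics(
                        target, seed, lam, pretrain_task=self.fixed_task
                    )
                    rows.append({"seed": seed, "radius": r,
                                 "auc_shifted": shift["auc"],
                                 "auc_reference": ref["auc"],
                                 "auc_gap": ref["auc"] - shift["auc"]})
            return pd.DataFrame(rows)
        return self._get(("task-shift", radii, lam), build)


@pytest.fixture(scope="session")
def bench() -> Workbench:
    return Workbench()


@pytest.fixture(scope="session")
def micro_profile() -> ScaleProfile:
    return MICRO


def make_toy_pairs(n_per_class=16, side=16, noise=0.1, seed=0,
                   n_classes=2) -> ImageEnsemble:
    """Paired (target, lowdose) ensemble without the CT pipeline: targets are
    lumpy-like random fields with an additive blob for present images, and
    the low-dose variant adds white noise. Fast fuel for training contracts.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    yy, xx = np.mgrid[0:side, 0:side]
    targets = 0.1 * rng.standard_normal((n, side, side)) + 0.5
    labels = np.zeros(n, dtype=int)
    centers = np.full((n, 2), np.nan)
    for i in range(n_per_class, n):
        j = 1 if n_classes == 2 else 1 + int(rng.integers(n_classes - 1))
        c = side / 2 + (j - 1) * 3
        targets[i] += 0.4 * np.exp(-((yy - c) ** 2 + (xx - c) ** 2) / 4.0)
        labels[i] = j
        centers[i] = (c, c)
    lowdose = targets + noise * rng.standard_normal(targets.shape)
    order = rng.permutation(n)
    return ImageEnsemble(
        {TARGET: targets[order], LOWDOSE: lowdose[order]},
        labels[order], centers[order], {"synthetic": True},
    )
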