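"""Teacher-student knowledge distillation with temperature-scaled soft labels.

A teacher classifier is trained on the large pooled multi-assay set (assay
identity entering as a global one-hot).  Its logits on the task-specific
molecules are temperature-softened into probabilities; the student minimises

    L_S = L_true + lambda * L_soft

where L_true is binary cross-entropy against the hard labels and L_soft is a
divergence between teacher and student soft probabilities at temperature T
(binary KL by default, optionally scaled by T^2 so the soft-gradient magnitude
is independent of T; mean-squared error on logits is the alternative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .chemdata import LabeledRecord
from .macro_pp import (
    MacroPPClassifier,
    MacroPPConfig,
    ModelCheckpoint,
    _BundleCache,
    fit_classifier,
)

__all__ = [
    "DistillConfig",
    "SoftTargets",
    "soft_probability",
    "distill_divergence",
    "student_loss",
    "train_teacher",
    "distill_student",
]

_EPS = 1e-7


@dataclass
class DistillConfig:
    temperature: float = 2.0
    lam: float = 0.5
    divergence: str = "BINARY_KL"  # or MSE_LOGITS
    t_squared_scaling: bool = True

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.divergence not in ("BINARY_KL", "MSE_LOGITS"):
            raise ValueError(f"unknown divergence {self.divergence!r}")


@dataclass
class SoftTargets:
    """Frozen teacher outputs for the student training molecules."""

    logits: np.ndarray
    probabilities: np.ndarray  # sigmoid(logits / T), strictly inside (0, 1)
    temperature: float


def soft_probability(z, temperature: float):
    """Temperature-scaled sigmoid p = sigma(z / T), numerically stable."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    zt = np.asarray(z, dtype=np.float64) / temperature
    out = np.where(
        zt >= 0,
        1.0 / (1.0 + np.exp(-np.clip(zt, None, 500))),
        np.exp(np.clip(zt, -500, None)) / (1.0 + np.exp(np.clip(zt, -500, None))),
    )
    return float(out) if np.isscalar(z) else out


def distill_divergence(p_teacher, p_student, config: DistillConfig | None = None) -> float:
    """Soft-label divergence; zero iff the distributions agree, never negative.

    BINARY_KL: p_t ln(p_t/p_s) + (1-p_t) ln((1-p_t)/(1-p_s)), optionally x T^2.
    Probabilities at exactly 0/1 are clamped to eps = 1e-7 with a warning.
    """
    config = config or DistillConfig()
    p_t = np.asarray(p_teacher, dtype=np.float64)
    p_s = np.asarray(p_student, dtype=np.float64)
    if ((p_t <= 0) | (p_t >= 1) | (p_s <= 0) | (p_s >= 1)).any():
        warnings.warn(f"probabilities at the boundary clamped to eps={_EPS}")
        p_t = np.clip(p_t, _EPS, 1.0 - _EPS)
        p_s = np.clip(p_s, _EPS, 1.0 - _EPS)
    if config.divergence == "MSE_LOGITS":
        z_t = np.log(p_t / (1.0 - p_t))
        z_s = np.log(p_s / (1.0 - p_s))
        val = np.mean((z_t - z_s) ** 2)
    else:
        val = np.mean(
            p_t * np.log(p_t / p_s) + (1.0 - p_t) * np.log((1.0 - p_t) / (1.0 - p_s))
        )
        if config.t_squared_scaling:
            val = val * config.temperature**2
    return float(val)


def student_loss(
    y,
    p_student_hard,
    p_teacher_soft,
    p_student_soft,
    config: DistillConfig | None = None,
) -> float:
    """L_S = BCE(y, p_hard) + lambda * divergence(p_t, p_s at T)."""
    config = config or DistillConfig()
    y = np.asarray(y, dtype=np.float64)
    p = np.clip(np.asarray(p_student_hard, dtype=np.float64), _EPS, 1.0 - _EPS)
    l_true = float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
    l_soft = distill_divergence(p_teacher_soft, p_student_soft, config)
    return l_true + config.lam * l_soft


def train_teacher(
    large: Sequence[LabeledRecord],
    val: Sequence[LabeledRecord],
    config: MacroPPConfig | None = None,
    seed: int = 0,
    cache: _BundleCache | None = None,
) -> tuple[MacroPPClassifier, ModelCheckpoint]:
    """Fit the baseline classifier on the pooled multi-assay set.

    Assay identity is appended as a one-hot global feature so a single teacher
    spans Caco-2 / MDCK / RRCK / PAMPA; a single-assay subset degenerates to a
    constant one-hot and still trains.
    """
    config = config or MacroPPConfig()
    if not config.use_assay_onehot:
        raise ValueError("teacher requires use_assay_onehot=True")
    return fit_classifier(large, val, config, seed=seed, cache=cache)


def distill_student(
    teacher: MacroPPClassifier,
    task_train: Sequence[LabeledRecord],
    task_val: Sequence[LabeledRecord],
    distill_config: DistillConfig | None = None,
    config: MacroPPConfig | None = None,
    seed: int = 0,
    cache: _BundleCache | None = None,
) -> tuple[MacroPPClassifier, ModelCheckpoint, SoftTargets]:
    """Train the distilled student on the task-specific set.

    Teacher logits are computed once for the student's training molecules (the
    teacher stays frozen), then the student minimises hard BCE plus the
    lambda-weighted soft divergence.  With lambda = 0 this reduces exactly to
    the plain task-only classifier: same seed, same parameters bit-for-bit.
    """
    distill_config = distill_config or DistillConfig()
    config = config or MacroPPConfig()
    cache = cache or teacher.cache
    z_teacher = teacher.predict_logits(task_train)
    targets = SoftTargets(
        logits=z_teacher,
        probabilities=np.clip(
            soft_probability(z_teacher, distill_config.temperature), _EPS, 1.0 - _EPS
        ),
        temperature=distill_config.temperature,
    )
    model, ckpt = fit_classifier(
        task_train,
        task_val,
        config,
        seed=seed,
        cache=cache,
        teacher_logits=z_teacher if distill_config.lam > 0 else None,
        distill_config=distill_config if distill_config.lam > 0 else None,
    )
    return model, ckpt, targets
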