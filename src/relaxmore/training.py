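"""Subject-specific self-supervised training of the unrolled reconstructor.

There is no fully sampled reference: the loss compares the re-encoded
per-phase image estimates against the subject's own undersampled k-space,

    L = sum_{t=0..T} gamma_t || U F C x^(t) - f ||_2^2,

with gamma_T = 1 weighting the final phase and a small gamma (1e-4) keeping
the intermediate phases on track.  Training all learnables (step sizes,
thresholds, network weights) with Adam IS the reconstruction — once the loss
has converged for one subject the parameter maps are read off the final
forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .encoding import KSpaceData, forward_encode
from .network import Adam
from .unrolled import (
    ReconResult,
    UnrolledModel,
    _unrolled_forward_t,
    normalization_scale,
)

__all__ = ["TrainConfig", "PRESETS", "multiphase_loss", "train", "warm_start"]

# preset (alpha0, beta0, learning rate) triples per anatomy
PRESETS = {
    "brain": dict(alpha0=0.1, beta0=1e-5, learning_rate=1e-4),
    "knee": dict(alpha0=0.5, beta0=1e-7, learning_rate=1e-4),
    "phantom": dict(alpha0=0.9, beta0=1e-3, learning_rate=5e-4),
}


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``preset`` selects the published (alpha0, beta0, learning-rate) triple
    for brain, knee or phantom data; any field set explicitly overrides its
    preset value.  Network-size fields default to the reference architecture
    (width 32/depth 4 initialization networks, width 64/depth 8 transforms,
    T = 8); smaller values trade accuracy for CPU time.
    """

    preset: str = "brain"
    epochs: int = 10000
    learning_rate: float | None = None
    alpha0: float | None = None
    beta0: float | None = None
    gamma_last: float = 1.0
    gamma_other: float = 1e-4
    n_phases: int = 8
    init_width: int = 32
    init_depth: int = 4
    prox_width: int = 64
    prox_depth: int = 8
    t1_min: float = 1.0
    t1_max: float = 5000.0
    seed: int = 0
    warm_start_path: str | None = None

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; options: {list(PRESETS)}")
        p = PRESETS[self.preset]
        if self.learning_rate is None:
            self.learning_rate = p["learning_rate"]
        if self.alpha0 is None:
            self.alpha0 = p["alpha0"]
        if self.beta0 is None:
            self.beta0 = p["beta0"]
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")

    def gammas(self) -> np.ndarray:
        g = np.full(self.n_phases + 1, self.gamma_other)
        g[-1] = self.gamma_last
        return g

    def build_model(self, n_coils: int, n_flip: int) -> UnrolledModel:
        return UnrolledModel.create(
            n_coils=n_coils,
            n_flip=n_flip,
            n_phases=self.n_phases,
            alpha0=self.alpha0,
            beta0=self.beta0,
            init_width=self.init_width,
            init_depth=self.init_depth,
            prox_width=self.prox_width,
            prox_depth=self.prox_depth,
            t1_min=self.t1_min,
            t1_max=self.t1_max,
            seed=self.seed,
        )


def multiphase_loss(
    result: ReconResult, kdata: KSpaceData, gammas: np.ndarray
) -> float:
    """Weighted multi-phase k-space MSE of a finished reconstruction."""
    gammas = np.asarray(gammas, dtype=np.float64)
    if gammas.size != len(result.x_per_phase):
        raise ValueError(
            f"{gammas.size} weights for {len(result.x_per_phase)} phase outputs"
        )
    total = 0.0
    for g, x in zip(gammas, result.x_per_phase):
        pred = forward_encode(x, kdata.coils, kdata.mask)
        total += float(g) * float(np.sum(np.abs(pred - kdata.f) ** 2))
    return total


def _loss_t(xs, kd: KSpaceData, f_n: np.ndarray, gammas: np.ndarray) -> ad.Tensor:
    from .unrolled import _forward_encode_t

    total = None
    for g, x in zip(gammas, xs):
        resid = ad.sub(_forward_encode_t(x, kd.coils, kd.mask), f_n)
        term = ad.scale(ad.sqnorm(resid), float(g))
        total = term if total is None else ad.add(total, term)
    return total


def train(
    kdata: KSpaceData,
    config: TrainConfig,
    model: UnrolledModel | None = None,
    on_epoch=None,
) -> tuple[UnrolledModel, ReconResult, list[float]]:
    """Optimize all learnables against the multi-phase self-supervised loss.

    Pass ``model`` (e.g. from :func:`warm_start`) to continue from existing
    weights; otherwise a fresh Xavier-initialized model is built from
    ``config.seed``.  Returns (model, final reconstruction, per-epoch loss
    trace).  The trace is reported in normalized k-space units (f scaled to
    unit zero-filled image magnitude).  ``on_epoch(epoch, loss, model)`` is
    called after every epoch when given.
    """
    n_coils, n_flip = kdata.coils.n_coils, kdata.acq.n_flip
    if model is None:
        model = config.build_model(n_coils, n_flip)
    else:
        if model.n_coils != n_coils or model.n_flip != n_flip:
            raise ValueError(
                f"model built for (coils={model.n_coils}, flips={model.n_flip}) "
                f"cannot train on data with (coils={n_coils}, flips={n_flip})"
            )
    gammas = config.gammas()
    scale = normalization_scale(kdata)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    trace: list[float] = []
    for epoch in range(config.epochs):
        opt.zero_grad()
        t1s, i0s, xs, kd = _unrolled_forward_t(kdata, model, scale)
        loss = _loss_t(xs, kd, kd.f, gammas)
        val = float(loss.data)
        if not np.isfinite(val):
            raise RuntimeError(
                f"loss became non-finite at epoch {epoch}: {val!r}; "
                f"alphas={model.alphas()}, betas={model.betas()}, "
                f"last losses={trace[-5:]}"
            )
        ad.backward(loss)
        opt.step()
        trace.append(val)
        if on_epoch is not None:
            on_epoch(epoch, val, model)
    from .unrolled import reconstruct

    result = reconstruct(kdata, model)
    result.loss_trace = list(trace)
    return model, result, trace


def warm_start(checkpoint: dict | str, new_kdata: KSpaceData) -> UnrolledModel:
    """Build a model from a saved checkpoint as the starting point for
    training on another subject's data (transfer learning).

    ``checkpoint`` is either the path of a checkpoint written by
    :func:`relaxmore.io.save_checkpoint` or its loaded dict.  The architecture
    must match the new data's coil and flip-angle counts; mismatches are
    rejected with a field-by-field diff.  Optimizer state is not carried over.
    """
    if isinstance(checkpoint, str):
        from .io import load_checkpoint

        checkpoint = load_checkpoint(checkpoint)
    hyper = checkpoint["hyper"]
    n_coils, n_flip = new_kdata.coils.n_coils, new_kdata.acq.n_flip
    problems = []
    if hyper["n_coils"] != n_coils:
        problems.append(f"n_coils: checkpoint {hyper['n_coils']} != data {n_coils}")
    if hyper["n_flip"] != n_flip:
        problems.append(f"n_flip: checkpoint {hyper['n_flip']} != data {n_flip}")
    if problems:
        raise ValueError("checkpoint/data mismatch:\n  " + "\n  ".join(problems))
    model = UnrolledModel.create(
        **{k: hyper[k] for k in (
            "n_coils", "n_flip", "n_phases", "alpha0", "beta0", "init_width",
            "init_depth", "prox_width", "prox_depth", "t1_min", "t1_max",
            "t1_scale_ms", "seed",
        )}
    )
    model.load_state(checkpoint["state"])
    return model
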