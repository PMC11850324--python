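"""Iterative attention feature fusion of two feature matrices.

The N x D similarity-derived features X and KG-derived features Y are
treated as 1-channel maps, lifted to C channels by a 1x1 projection, gated
by a multiscale channel attention module (sigmoid of a pooled global context
plus a pointwise local context, both through a C -> C/r -> C bottleneck),
fused as a gate-weighted convex combination, and collapsed back to one
channel. Two gating stages are applied: the first-stage fused map drives the
gate that produces the final output (iterative attention fusion).

All forward passes run on :mod:`kgrdr.autodiff` tensors so the parameters
can be trained end-to-end with the downstream predictor.

At initialization the collapse projection is the exact left-inverse of the
lift, so fusing a matrix with itself returns it unchanged and the output is
an elementwise convex combination of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigError, InvalidInputError


@dataclass
class FusionConfig:
    channels: int = 16
    ratio: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.ratio < 1:
            raise ConfigError("ratio must be >= 1")
        if self.channels < 1 or self.channels % self.ratio != 0:
            raise ConfigError(
                f"channels ({self.channels}) must be a positive multiple of ratio ({self.ratio})"
            )


class AttentionFusion:
    """Parameter container + forward passes for (i)AFF.

    Parameters (all autodiff tensors, trainable):
      lift_w/lift_b        1x1 lift from 1 channel to C channels
      collapse_w/collapse_b  1x1 collapse from C channels back to 1
      per gating stage: bottleneck W1 (C/r x C), b1, W2 (C x C/r), b2,
      shared between the global (pooled) and local (pointwise) contexts.
    """

    def __init__(self, config: FusionConfig):
        self.config = config
        C, r = config.channels, config.ratio
        hidden = C // r
        rng = np.random.default_rng(np.random.SeedSequence([config.seed % (2 ** 32), 29]))
        lift_w = rng.standard_normal(C) * 0.5 + 1.0
        self.lift_w = Tensor(lift_w.reshape(C, 1), requires_grad=True)
        self.lift_b = Tensor(np.zeros((C, 1)), requires_grad=True)
        # exact left-inverse of the lift at init: sum_c v_c w_c = 1, biases 0
        self.collapse_w = Tensor((lift_w / (lift_w ** 2).sum()).reshape(1, C), requires_grad=True)
        self.collapse_b = Tensor(np.zeros((1, 1)), requires_grad=True)
        self.stages = []
        for _ in range(2):
            self.stages.append({
                "W1": Tensor(0.1 * rng.standard_normal((hidden, C)), requires_grad=True),
                "b1": Tensor(np.zeros((hidden, 1)), requires_grad=True),
                "W2": Tensor(0.1 * rng.standard_normal((C, hidden)), requires_grad=True),
                "b2": Tensor(np.zeros((C, 1)), requires_grad=True),
            })

    @property
    def params(self) -> list[Tensor]:
        out = [self.lift_w, self.lift_b, self.collapse_w, self.collapse_b]
        for stage in self.stages:
            out.extend(stage.values())
        return out

    # ---- building blocks -------------------------------------------------

    def lift(self, flat: Tensor) -> Tensor:
        """(1, N*D) -> (C, N*D) per-channel affine lift."""
        return self.lift_w @ flat + self.lift_b

    def collapse(self, lifted: Tensor) -> Tensor:
        """(C, N*D) -> (1, N*D) learned channel combination."""
        return self.collapse_w @ lifted + self.collapse_b

    def gate(self, lifted: Tensor, stage: int) -> Tensor:
        """MS-CAM gate in (0,1), same shape as the lifted map."""
        p = self.stages[stage]
        pooled = lifted.mean(axis=1, keepdims=True)  # (C, 1) global context
        global_ctx = p["W2"] @ ad.relu(p["W1"] @ pooled + p["b1"]) + p["b2"]
        local_ctx = p["W2"] @ ad.relu(p["W1"] @ lifted + p["b1"]) + p["b2"]
        return ad.sigmoid(global_ctx + local_ctx)  # broadcast (C,1) + (C,N*D)


def _flatten(F, name: str) -> tuple[Tensor, tuple[int, int]]:
    t = F if isinstance(F, Tensor) else Tensor(np.asarray(F, dtype=np.float64))
    if len(t.shape) != 2:
        raise InvalidInputError(f"{name} must be a 2-D feature matrix")
    n, d = t.shape
    return t.reshape(1, n * d), (n, d)


def channel_lift(F, module: AttentionFusion) -> np.ndarray:
    """Lift an N x D matrix to a (C, N, D) multi-channel map (numpy view)."""
    flat, (n, d) = _flatten(F, "F")
    lifted = module.lift(flat)
    return lifted.data.reshape(module.config.channels, n, d)


def ms_cam(F_lifted: np.ndarray, module: AttentionFusion, stage: int = 0) -> np.ndarray:
    """Gate tensor for an already-lifted (C, N, D) map; entries in (0, 1)."""
    F_lifted = np.asarray(F_lifted, dtype=np.float64)
    if F_lifted.ndim != 3 or F_lifted.shape[0] != module.config.channels:
        raise InvalidInputError("F_lifted must have shape (C, N, D)")
    c, n, d = F_lifted.shape
    gate = module.gate(Tensor(F_lifted.reshape(c, n * d)), stage)
    return gate.data.reshape(c, n, d)


def _fuse(module: AttentionFusion, X, Y) -> tuple[Tensor, tuple, Tensor, Tensor, Tensor]:
    fx, shape_x = _flatten(X, "X")
    fy, shape_y = _flatten(Y, "Y")
    if shape_x != shape_y:
        raise InvalidInputError(f"X shape {shape_x} != Y shape {shape_y}")
    lx = module.lift(fx)
    ly = module.lift(fy)
    gate1 = module.gate(lx + ly, stage=0)
    fused1 = gate1 * lx + (1.0 - gate1) * ly  # X (+) Y in the lifted space
    return fused1, shape_x, lx, ly, gate1


def aff(X, Y, module: AttentionFusion, return_gate: bool = False):
    """Single-stage attention fusion collapsed back to N x D."""
    tensor_in = isinstance(X, Tensor) or isinstance(Y, Tensor)
    fused1, (n, d), _, _, gate1 = _fuse(module, X, Y)
    out = module.collapse(fused1).reshape(n, d)
    if not tensor_in:
        out = out.data
    if return_gate:
        return out, gate1.data.reshape(module.config.channels, n, d)
    return out


def iaff(X, Y, module: AttentionFusion, return_gates: bool = False):
    """Two-stage (iterative) attention fusion.

    The first-stage fused map feeds the second gating stage, whose gate
    reweights the original lifted X and Y. Accepts numpy arrays or autodiff
    tensors; returns the same kind.
    """
    tensor_in = isinstance(X, Tensor) or isinstance(Y, Tensor)
    fused1, (n, d), lx, ly, gate1 = _fuse(module, X, Y)
    gate2 = module.gate(fused1, stage=1)
    fused2 = gate2 * lx + (1.0 - gate2) * ly
    out = module.collapse(fused2).reshape(n, d)
    if return_gates:
        c = module.config.channels
        return out if tensor_in else out.data, (
            gate1.data.reshape(c, n, d),
            gate2.data.reshape(c, n, d),
        )
    return out if tensor_in else out.data


def gate_statistics(gates: np.ndarray) -> dict[str, float]:
    return {"min": float(gates.min()), "mean": float(gates.mean()), "max": float(gates.max())}
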