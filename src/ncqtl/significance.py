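"""Likelihood-ratio (LOD) testing of effects retained by the shrinkage fit.

Each retained effect k is tested profile-style: the full model keeps all
converged estimates; the reduced model sets gamma_k = 0 while holding
beta, sigma^2 and every other effect at their converged values.  Both
are evaluated under the Gaussian residual likelihood

    logL = -(n/2) log(2 pi sigma^2) - ||y - X beta - Z gamma||^2 / (2 sigma^2)

so LR = 2 (logL_full - logL_reduced), clipped at zero, and
LOD = LR / (2 ln 10).  An effect is declared significant when LOD
reaches the threshold (default 2.0, inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ebayes import EBayesFit
from .model_matrix import EffectDescriptor

LOD_SCALE = 2.0 * math.log(10.0)  # LR units per LOD


@dataclass(frozen=True)
class EffectTest:
    descriptor: EffectDescriptor | None
    lr: float
    lod: float

    def significant(self, threshold: float = 2.0) -> bool:
        return self.lod >= threshold


def gaussian_loglik(y: np.ndarray, mean: np.ndarray, sigma2: float) -> float:
    """Gaussian residual log-likelihood at a fixed mean vector and variance."""
    y = np.asarray(y, dtype=float)
    resid = y - mean
    n = y.size
    return -0.5 * n * math.log(2.0 * math.pi * sigma2) - float(resid @ resid) / (2.0 * sigma2)


def lod_for_effect(fit: EBayesFit, k: int, y: np.ndarray, Z: np.ndarray,
                   descriptor: EffectDescriptor | None = None) -> EffectTest:
    """LOD score of effect ``k`` of a converged fit.

    LR = 2 [logL(full) - logL(gamma_k = 0, everything else fixed)];
    negative LR (possible for an over-shrunk coefficient) is clipped to 0.
    """
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if not 0 <= k < len(fit.gamma):
        raise IndexError(f"effect index {k} outside the fitted model")
    resid_full = y - fit.beta - Z @ fit.gamma
    resid_reduced = resid_full + Z[:, k] * fit.gamma[k]
    lr = (float(resid_reduced @ resid_reduced) - float(resid_full @ resid_full)) / fit.sigma2
    lr = max(lr, 0.0)
    return EffectTest(descriptor, lr, lr / LOD_SCALE)


def lod_all_effects(fit: EBayesFit, y: np.ndarray, Z: np.ndarray,
                    descriptors: Sequence[EffectDescriptor] | None = None
                    ) -> list[EffectTest]:
    descriptors = descriptors or [None] * len(fit.gamma)
    return [lod_for_effect(fit, k, y, Z, d) for k, d in enumerate(descriptors)]


def significant_effects(tests: Sequence[EffectTest], threshold: float = 2.0
                        ) -> list[EffectTest]:
    """Tests passing the LOD threshold (inclusive), sorted descending by LOD."""
    if threshold <= 0:
        raise ValueError("LOD threshold must be positive")
    kept = [t for t in tests if t.lod >= threshold]
    return sorted(kept, key=lambda t: -t.lod)
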