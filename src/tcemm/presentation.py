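"""Deterministic stand-in model for MHC class II peptide presentation.

The mismatch derivation needs a rule deciding whether a 9-mer core is
presented by a recipient HLA-DRB1 allele. Trained class II binding
predictors are deliberately not a dependency; instead each DRB1 allele gets
a 9x20 position-weight matrix drawn deterministically from (allele name,
seed), and a core is "presented" when its additive PWM score reaches an
allele threshold calibrated so that a target fraction ``q_bind`` of
uniformly random cores are presented. Weights are keyed by allele *name*
(not sequence) so that registry-version diffs isolate sequence changes, the
way an external predictor's per-allele models persist across database
releases.
"""

from __future__ import annotations

import zlib
from typing import Dict, Protocol

import numpy as np

from .registry import AA_INDEX, AlleleName, AlleleRegistry

__all__ = ["PresentationModel", "DefaultPresentationModel", "default_presentation_model"]

_CALIBRATION_N = 100_000


def encode_cores(cores) -> np.ndarray:
    """Encode an iterable of 9-mer strings as an (n, 9) uint8 index array."""
    arr = np.empty((len(cores), 9), dtype=np.uint8)
    for i, c in enumerate(cores):
        for j, ch in enumerate(c):
            arr[i, j] = AA_INDEX[ch]
    return arr


class PresentationModel(Protocol):
    """Contract: pure deterministic presentation calls per (core, presenter)."""

    def score(self, core: str, presenter: AlleleName) -> float: ...

    def threshold(self, presenter: AlleleName) -> float: ...

    def presented_mask(self, core_idx: np.ndarray, presenter: AlleleName) -> np.ndarray: ...


class DefaultPresentationModel:
    """PWM-based presentation model over a registry's DRB1 alleles.

    Parameters
    ----------
    registry:
        Registry whose DRB1 alleles act as presenters.
    q_bind:
        Target fraction of uniformly random 9-mer cores called presented,
        per presenter. ``0`` and ``1`` are allowed as degenerate settings
        (nothing / everything presented).
    seed:
        Model seed; weights are a pure function of (allele name, seed).
    """

    def __init__(self, registry: AlleleRegistry, q_bind: float, seed: int):
        if not 0.0 <= q_bind <= 1.0:
            raise ValueError("q_bind must be in [0, 1]")
        self.q_bind = float(q_bind)
        self.seed = int(seed)
        self._weights: Dict[AlleleName, np.ndarray] = {}
        self._thresholds: Dict[AlleleName, float] = {}
        cal_rng = np.random.default_rng(
            np.random.SeedSequence([self.seed & 0x7FFFFFFF, zlib.crc32(b"__pwm_calibration__")])
        )
        cal_cores = cal_rng.integers(0, 20, size=(_CALIBRATION_N, 9))
        for name in registry.alleles_at("DRB1"):
            w = self._pwm(name)
            self._weights[name] = w
            if self.q_bind <= 0.0:
                thr = np.inf
            elif self.q_bind >= 1.0:
                thr = -np.inf
            else:
                scores = w[np.arange(9), cal_cores].sum(axis=1)
                thr = float(np.quantile(scores, 1.0 - self.q_bind))
            self._thresholds[name] = thr

    def _pwm(self, name: AlleleName) -> np.ndarray:
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed & 0x7FFFFFFF, zlib.crc32(str(name).encode())])
        )
        return rng.normal(0.0, 1.0, size=(9, 20))

    def _check(self, presenter: AlleleName) -> None:
        if presenter not in self._weights:
            if presenter.locus != "DRB1":
                raise ValueError(f"presenter {presenter} is not an HLA-DRB1 allele")
            raise KeyError(f"DRB1 allele {presenter} unknown to this model")

    def weights(self, presenter: AlleleName) -> np.ndarray:
        self._check(presenter)
        return self._weights[presenter]

    def threshold(self, presenter: AlleleName) -> float:
        self._check(presenter)
        return self._thresholds[presenter]

    def score(self, core: str, presenter: AlleleName) -> float:
        idx = encode_cores([core])
        return float(self.score_batch(idx, presenter)[0])

    def score_batch(self, core_idx: np.ndarray, presenter: AlleleName) -> np.ndarray:
        self._check(presenter)
        w = self._weights[presenter]
        return w[np.arange(9), core_idx].sum(axis=1)

    def presented(self, core: str, presenter: AlleleName) -> bool:
        return bool(self.score(core, presenter) >= self.threshold(presenter))

    def presented_mask(self, core_idx: np.ndarray, presenter: AlleleName) -> np.ndarray:
        if core_idx.shape[0] == 0:
            return np.zeros(0, dtype=bool)
        return self.score_batch(core_idx, presenter) >= self._thresholds[presenter]


def default_presentation_model(
    registry: AlleleRegistry, q_bind: float, seed: int
) -> DefaultPresentationModel:
    """Build the default PWM presentation model (thin functional wrapper)."""
    return DefaultPresentationModel(registry, q_bind, seed)
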