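"""Nucleotide substitution models: JC69, HKY85, GTR, with discrete-Γ rates.

State order is A, C, G, T throughout.  Rate matrices are normalised so the
expected substitution rate at stationarity is one, i.e. branch lengths are in
expected substitutions per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = [
    "ModelError", "SubstitutionModel", "PartitionedModel",
    "rate_matrix", "gamma_rates", "transition_probs", "EigenSystem",
    "JC69", "FAMILIES",
]

FAMILIES = ("JC69", "HKY85", "GTR")
# exchangeability order for GTR: AC, AG, AT, CG, CT, GT
_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


class ModelError(ValueError):
    pass


@dataclass
class SubstitutionModel:
    family: str = "JC69"
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    kappa: float = 2.0
    exchangeabilities: Optional[np.ndarray] = None
    gamma_shape: Optional[float] = None
    n_categories: int = 4

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ModelError(f"unknown model family {self.family!r}")
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.family == "JC69":
            self.freqs = np.full(4, 0.25)
        if self.freqs.shape != (4,) or np.any(self.freqs <= 0):
            raise ModelError("base frequencies must be 4 positive values")
        self.freqs = self.freqs / self.freqs.sum()
        if self.family == "GTR":
            if self.exchangeabilities is None:
                self.exchangeabilities = np.ones(6)
            self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
            if self.exchangeabilities.shape != (6,) or np.any(self.exchangeabilities <= 0):
                raise ModelError("GTR needs 6 positive exchangeabilities")
        if self.family == "HKY85" and self.kappa <= 0:
            raise ModelError("kappa must be positive")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ModelError("gamma shape must be positive")
        if self.n_categories < 1:
            raise ModelError("n_categories must be >= 1")

    @property
    def n_free_params(self) -> int:
        """Free substitution parameters (frequencies counted as empirical)."""
        base = {"JC69": 0, "HKY85": 1, "GTR": 5}[self.family]
        return base + (1 if self.gamma_shape is not None else 0)

    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return gamma_rates(self.gamma_shape, self.n_categories)


def JC69(gamma_shape: Optional[float] = None, n_categories: int = 4) -> SubstitutionModel:
    return SubstitutionModel("JC69", gamma_shape=gamma_shape, n_categories=n_categories)


def rate_matrix(model: SubstitutionModel) -> np.ndarray:
    """Normalised reversible generator Q (rows sum to zero, mean rate 1)."""
    pi = model.freqs
    if model.family == "JC69":
        s = np.ones(6)
    elif model.family == "HKY85":
        s = np.ones(6)
        s[1] = s[4] = model.kappa          # AG and CT are transitions
    else:
        s = model.exchangeabilities
    Q = np.zeros((4, 4))
    for rate, (i, j) in zip(s, _PAIRS):
        Q[i, j] = rate * pi[j]
        Q[j, i] = rate * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))
    return Q / mu


def gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of ``k`` equal-probability bins of a Gamma(α, 1/α) density.

    The discrete approximation of among-site rate variation: bin boundaries
    are the i/k quantiles, the category rate is the conditional mean within
    the bin (an incomplete-gamma identity), and the rates are renormalised to
    mean exactly one.
    """
    if alpha <= 0:
        raise ModelError("alpha must be positive")
    if k < 1:
        raise ModelError("need at least one category")
    if k == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    # E[X | a < X < b] * P(a < X < b) = F_{alpha+1}(b) - F_{alpha+1}(a)
    cdf_hi = gamma_dist.cdf(edges[1:], a=alpha + 1.0, scale=1.0 / alpha)
    cdf_lo = gamma_dist.cdf(edges[:-1], a=alpha + 1.0, scale=1.0 / alpha)
    rates = k * (cdf_hi - cdf_lo)
    return rates / rates.mean()


class EigenSystem:
    """Eigendecomposition of a reversible Q for fast P(t) evaluation.

    With D = diag(π), the symmetrised matrix D^{1/2} Q D^{-1/2} has a real
    spectral decomposition U Λ Uᵀ, and P(t) = D^{-1/2} U e^{Λt} Uᵀ D^{1/2}.
    """

    def __init__(self, Q: np.ndarray, freqs: np.ndarray):
        self.freqs = np.asarray(freqs, dtype=float)
        sq = np.sqrt(self.freqs)
        B = (sq[:, None] * Q) / sq[None, :]
        vals, U = np.linalg.eigh((B + B.T) / 2.0)
        self.eigvals = vals
        self.left = U / sq[:, None]        # D^{-1/2} U   (4x4)
        self.right = U.T * sq[None, :]     # Uᵀ D^{1/2}   (4x4)

    @classmethod
    def from_model(cls, model: SubstitutionModel) -> "EigenSystem":
        return cls(rate_matrix(model), model.freqs)

    def probs(self, t: float) -> np.ndarray:
        if t < 0:
            raise ModelError("branch length must be non-negative")
        P = (self.left * np.exp(self.eigvals * t)) @ self.right
        return np.clip(P, 0.0, None)

    def probs_many(self, ts: np.ndarray) -> np.ndarray:
        """Stacked P(t) for an array of scaled times; shape (len(ts), 4, 4)."""
        E = np.exp(np.multiply.outer(np.asarray(ts, float), self.eigvals))
        return np.clip(np.einsum("ik,ck,kj->cij", self.left, E, self.right),
                       0.0, None)


def transition_probs(model_or_Q, t: float, rate_scale: float = 1.0,
                     freqs: Optional[np.ndarray] = None) -> np.ndarray:
    """P(rate_scale * t) for a model or an explicit reversible generator."""
    if t < 0 or rate_scale < 0:
        raise ModelError("time and rate scale must be non-negative")
    if isinstance(model_or_Q, SubstitutionModel):
        es = EigenSystem.from_model(model_or_Q)
    else:
        Q = np.asarray(model_or_Q, dtype=float)
        if freqs is None:
            # stationary distribution from the left null vector
            vals, vecs = np.linalg.eig(Q.T)
            i = np.argmin(np.abs(vals))
            pi = np.real(vecs[:, i])
            freqs = pi / pi.sum()
        es = EigenSystem(Q, freqs)
    return es.probs(t * rate_scale)


@dataclass
class PartitionedModel:
    """Per-partition substitution models sharing one set of branch lengths.

    ``multipliers`` stretch the shared branch lengths per partition; for
    identifiability their partition-length-weighted mean is kept at one (the
    normalisation is applied by :meth:`normalise`, which rescales branch
    lengths to compensate).
    """

    models: dict[str, SubstitutionModel]
    multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in self.models:
            self.multipliers.setdefault(name, 1.0)
        if any(m <= 0 for m in self.multipliers.values()):
            raise ModelError("rate multipliers must be positive")

    @classmethod
    def single(cls, model: SubstitutionModel, locus_ids) -> "PartitionedModel":
        return cls(models={lid: model for lid in locus_ids})

    def normalise(self, lengths: dict[str, int]) -> float:
        """Rescale multipliers to weighted mean 1; returns the factor by
        which branch lengths must be multiplied to keep likelihood fixed."""
        w = np.array([lengths[k] for k in self.models], dtype=float)
        m = np.array([self.multipliers[k] for k in self.models])
        mean = float((w * m).sum() / w.sum())
        for k in self.multipliers:
            self.multipliers[k] /= mean
        return mean
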