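"""Amino-acid substitution models for simulation and distance estimation.

A model couples a time-reversible 20-state rate matrix (built from a symmetric
exchangeability matrix and stationary frequencies, normalised to one expected
substitution per unit time) with optional discrete-gamma rate heterogeneity
across sites (Yang's k-category mean-of-quantile-interval discretisation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._lg_data import LG_ALPHABET, LG_EXCHANGEABILITIES, LG_FREQUENCIES

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def aa_to_codes(seq: str) -> np.ndarray:
    """Encode an amino-acid string as integer codes; gaps/unknowns become -1."""
    return np.array([_AA_INDEX.get(c, -1) for c in seq.upper()], dtype=np.int64)


def codes_to_aa(codes: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[c] if c >= 0 else "-" for c in codes)


def discrete_gamma_rates(shape: float, k: int = 4) -> np.ndarray:
    """Mean rates of ``k`` equal-probability gamma categories (mean rate 1).

    Category means follow the standard incomplete-gamma construction: the
    mean of the gamma(shape, 1/shape) density over each inter-quantile
    interval, scaled by ``k`` so the overall mean is exactly 1.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be > 0")
    if k < 1:
        raise ValueError("need at least one rate category")
    if k == 1:
        return np.ones(1)
    bounds = gamma_dist.ppf(np.arange(1, k) / k, a=shape, scale=1.0 / shape)
    upper = np.concatenate([bounds, [np.inf]])
    lower = np.concatenate([[0.0], bounds])
    # E[X; a<X<b] for gamma(shape, mean 1) via the regularised lower
    # incomplete gamma of shape+1
    mass_hi = gammainc(shape + 1.0, upper * shape)
    mass_lo = gammainc(shape + 1.0, lower * shape)
    rates = k * (mass_hi - mass_lo)
    return rates / rates.mean() * 1.0


@dataclass
class SubstitutionModel:
    """Reversible amino-acid model with optional +G4 rate heterogeneity.

    Parameters
    ----------
    exchangeabilities
        Symmetric 20x20 matrix of relative exchange rates (diagonal ignored).
    frequencies
        Stationary residue frequencies in ``AMINO_ACIDS`` order; must sum to 1.
    gamma_shape
        Shape of the discrete-gamma distribution of site rates, or ``None``
        for rate homogeneity.
    n_categories
        Number of discrete gamma categories (conventionally 4).
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    gamma_shape: float | None = None
    n_categories: int = 4
    name: str = "custom"

    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] = field(
        init=False, repr=False, default=None
    )

    def __post_init__(self):
        S = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if S.shape != (20, 20):
            raise ValueError("exchangeability matrix must be 20x20")
        if not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("stationary frequencies must sum to 1")
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        # normalise to 1 expected substitution per unit time
        mu = -np.dot(pi, np.diag(Q))
        Q /= mu
        self.rate_matrix = Q
        self.frequencies = pi
        # symmetric similarity transform for a stable eigendecomposition
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)
        evals, evecs = np.linalg.eigh(B)
        left = evecs.T * sq[None, :]          # rows:  U^T diag(sqrt pi)
        right = (evecs.T / sq[None, :]).T     # cols:  diag(1/sqrt pi) U
        self._eig = (evals, right, left)

    @property
    def rates(self) -> np.ndarray:
        """Per-category relative rates (array of length ``n_categories``)."""
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = expm(Q t) for a single rate class."""
        evals, right, left = self._eig
        P = (right * np.exp(evals * t)[None, :]) @ left
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stack of P(t * r_c) over the gamma rate categories."""
        return np.stack([self.transition_matrix(t * r) for r in self.rates])

    def mixture_transition(self, t: float) -> np.ndarray:
        """Equal-weight mixture of P(t * r_c) over the rate categories."""
        evals, right, left = self._eig
        lam = np.exp(np.outer(self.rates, evals) * t)       # (k, 20)
        P = np.einsum("ib,kb,bj->kij", right, lam, left)
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=-1, keepdims=True)
        return P.mean(axis=0)


def lg_model(gamma_shape: float | None = None, n_categories: int = 4,
             frequencies: np.ndarray | None = None) -> SubstitutionModel:
    """The LG empirical model (Le & Gascuel 2008), optionally +F and +G4."""
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = LG_EXCHANGEABILITIES[k]
            k += 1
    pi = np.array(LG_FREQUENCIES)
    # reorder from PAML convention into our alphabet if they differ
    if LG_ALPHABET != AMINO_ACIDS:
        order = [LG_ALPHABET.index(a) for a in AMINO_ACIDS]
        S = S[np.ix_(order, order)]
        pi = pi[order]
    if frequencies is not None:
        pi = np.asarray(frequencies, float)
    return SubstitutionModel(S, pi, gamma_shape, n_categories, name="LG")


def poisson_model(gamma_shape: float | None = None,
                  n_categories: int = 4) -> SubstitutionModel:
    """Equal-rates, equal-frequency 20-state model (the JC analogue)."""
    S = np.ones((20, 20))
    np.fill_diagonal(S, 0.0)
    pi = np.full(20, 0.05)
    return SubstitutionModel(S, pi, gamma_shape, n_categories, name="Poisson")


_MODEL_FACTORIES = {"LG": lg_model, "Poisson": poisson_model}


def get_model(model_id: str, gamma_shape: float | None = None,
              n_categories: int = 4) -> SubstitutionModel:
    try:
        factory = _MODEL_FACTORIES[model_id]
    except KeyError:
        raise ValueError(
            f"unknown substitution model {model_id!r}; "
            f"available: {sorted(_MODEL_FACTORIES)}"
        ) from None
    return factory(gamma_shape=gamma_shape, n_categories=n_categories)
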