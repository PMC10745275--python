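"""Continuous-time substitution models shared by simulation and distances.

Rate matrices are built as Q[a,b] = s[a,b] * pi[b] (a != b) from symmetric
exchangeabilities s and stationary frequencies pi, normalized so the expected
substitution rate at stationarity is 1 (branch lengths are then in expected
substitutions per site). Transition matrices exp(Qt) are computed through the
symmetric eigendecomposition of the reversibly-similar matrix.
"""

from __future__ import annotations

import numpy as np

from ._lg import AA_ALPHABET, LG_EXCHANGEABILITIES_LOWER, LG_FREQUENCIES

__all__ = [
    "DNA_ALPHABET",
    "AA_ALPHABET",
    "make_rate_matrix",
    "jc69_model",
    "lg_model",
    "gtr_model",
    "SpectralModel",
]

DNA_ALPHABET = "ACGT"


def make_rate_matrix(exchangeabilities: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Normalized reversible generator from symmetric s and stationary pi."""
    s = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(freqs, dtype=float)
    if not np.allclose(s, s.T):
        raise ValueError("exchangeability matrix must be symmetric")
    if abs(pi.sum() - 1.0) > 1e-8 or np.any(pi <= 0):
        raise ValueError("frequencies must be positive and sum to 1")
    Q = s * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -np.sum(pi * np.diag(Q))
    return Q / rate


class SpectralModel:
    """Eigendecomposition of a reversible generator for fast exp(Qt)."""

    def __init__(self, Q: np.ndarray, freqs: np.ndarray, alphabet: str):
        self.Q = Q
        self.freqs = np.asarray(freqs, dtype=float)
        self.alphabet = alphabet
        half = np.sqrt(self.freqs)
        sym = (Q * half[:, None]) / half[None, :]
        vals, vecs = np.linalg.eigh((sym + sym.T) / 2.0)
        self._vals = vals
        self._left = vecs / half[:, None]
        self._right = vecs * half[:, None]

    def transition_matrix(self, t: float) -> np.ndarray:
        P = (self._left * np.exp(self._vals * t)) @ self._right.T
        np.clip(P, 1e-300, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def jc69_model() -> SpectralModel:
    """Jukes-Cantor DNA model: equal frequencies, equal exchangeabilities."""
    s = np.ones((4, 4))
    np.fill_diagonal(s, 0.0)
    pi = np.full(4, 0.25)
    return SpectralModel(make_rate_matrix(s, pi), pi, DNA_ALPHABET)


def lg_model(freqs: np.ndarray | None = None) -> SpectralModel:
    """LG amino-acid model; published frequencies unless overridden."""
    s = np.zeros((20, 20))
    idx = 0
    for j in range(20):  # column-major strict lower triangle
        for i in range(j + 1, 20):
            s[i, j] = s[j, i] = LG_EXCHANGEABILITIES_LOWER[idx]
            idx += 1
    pi = np.asarray(LG_FREQUENCIES if freqs is None else freqs, dtype=float)
    pi = pi / pi.sum()
    return SpectralModel(make_rate_matrix(s, pi), pi, AA_ALPHABET)


def gtr_model(exch_upper: np.ndarray, freqs: np.ndarray) -> SpectralModel:
    """General time-reversible DNA model from the 6 upper-triangle rates."""
    exch_upper = np.asarray(exch_upper, dtype=float)
    if exch_upper.shape != (6,):
        raise ValueError("GTR takes 6 exchangeabilities (AC, AG, AT, CG, CT, GT)")
    s = np.zeros((4, 4))
    s[np.triu_indices(4, k=1)] = exch_upper
    s = s + s.T
    pi = np.asarray(freqs, dtype=float)
    return SpectralModel(make_rate_matrix(s, pi), pi, DNA_ALPHABET)
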