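"""Substitution models and their gap-augmented extension.

A standard reversible substitution process on an alphabet ``Σ`` is
extended with a deletion symbol ``ε`` that acts as an absorbing state:
every character is deleted at rate ``μ`` independently of substitutions,
and once deleted it can no longer substitute.  Branch transition
probabilities are matrix exponentials of the extended generator.

Built-in models: JC69, K80(κ), GTR for nucleotides; WAG and LG with
their published frequencies for amino acids (optional frequency
override).  All generators are normalised to one expected substitution
per site per unit branch length before the deletion rate is added, so
branch lengths keep their usual units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from . import _aa_data

__all__ = [
    "SubstModel",
    "ModelError",
    "jc69",
    "k80",
    "gtr",
    "wag",
    "lg",
    "make_model",
    "extend_rate_matrix",
    "DNA",
    "AA",
    "GAP",
]

DNA = "ACGT"
AA = _aa_data.AA_ORDER
GAP = "-"

# IUPAC nucleotide ambiguity -> compatible bases
_DNA_AMBIG = {
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_AA_AMBIG = {"B": "DN", "Z": "EQ", "X": AA}


class ModelError(ValueError):
    """Invalid model specification or rate matrix."""


def extend_rate_matrix(Q: np.ndarray, mu: float) -> np.ndarray:
    """Extend a generator on Σ by an absorbing deletion state.

    The returned ``(s+1)×(s+1)`` generator has deletion rate ``mu`` from
    every character state into ``ε`` and an all-zero ``ε`` row, with
    diagonals adjusted so each row still sums to zero.
    """
    Q = np.asarray(Q, dtype=float)
    s = Q.shape[0]
    if Q.shape != (s, s):
        raise ModelError("rate matrix must be square")
    if not mu > 0:
        raise ModelError("deletion rate mu must be strictly positive")
    if np.max(np.abs(Q.sum(axis=1))) > 1e-8:
        raise ModelError("rate matrix rows must sum to zero")
    Qe = np.zeros((s + 1, s + 1))
    Qe[:s, :s] = Q
    Qe[:s, s] = mu
    Qe[np.arange(s), np.arange(s)] -= mu
    return Qe


@dataclass
class SubstModel:
    """Substitution process on Σ plus its gap-augmented extension.

    Attributes
    ----------
    alphabet : str
        Ordered character states Σ.
    Q : ndarray
        ``|Σ|×|Σ|`` normalised generator (one expected substitution per
        unit time at stationarity).
    pi : ndarray
        Stationary distribution over Σ.
    mu : float
        Deletion rate; defines the absorbing extension.
    """

    alphabet: str
    Q: np.ndarray
    pi: np.ndarray
    mu: float
    name: str = "custom"
    Q_eps: np.ndarray = field(init=False)
    pi_eps: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if abs(self.pi.sum() - 1.0) > 1e-8 or np.any(self.pi < 0):
            raise ModelError("stationary frequencies must be a distribution")
        if np.max(np.abs(self.pi @ self.Q)) > 1e-8:
            raise ModelError("pi is not stationary for Q")
        self.Q_eps = extend_rate_matrix(self.Q, self.mu)
        # Characters are drawn from Σ at insertion; ε carries no mass.
        self.pi_eps = np.concatenate([self.pi, [0.0]])
        self._eig = None
        self._diagonalizable = None
        self._index = {c: i for i, c in enumerate(self.alphabet)}
        self._ambig = _DNA_AMBIG if self.alphabet == DNA else _AA_AMBIG

    # -- alphabet helpers ---------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.alphabet)

    @property
    def gap_code(self) -> int:
        return self.n_states

    def encode(self, symbol: str) -> int:
        """Map a residue or '-' to its state code (gap -> ``n_states``)."""
        if symbol == GAP:
            return self.gap_code
        i = self._index.get(symbol)
        if i is None:
            raise ModelError(f"symbol {symbol!r} is not in the model alphabet")
        return i

    def indicator(self, symbol: str) -> np.ndarray:
        """Leaf partial-likelihood vector over Σ_ε for one observed symbol.

        Unambiguous residues give a one-hot vector; '-' puts all mass on
        the ε component; IUPAC ambiguity codes put a 1 on each compatible
        residue (the usual pruning convention).
        """
        v = np.zeros(self.n_states + 1)
        if symbol == GAP:
            v[-1] = 1.0
            return v
        if symbol in self._index:
            v[self._index[symbol]] = 1.0
            return v
        comp = self._ambig.get(symbol)
        if comp is None:
            raise ModelError(f"symbol {symbol!r} is not in Σ or its ambiguity codes")
        for c in comp:
            v[self._index[c]] = 1.0
        return v

    # -- transition probabilities -------------------------------------

    def transition_probs(self, b: float) -> np.ndarray:
        """Row-stochastic transition matrix exp(b·Q_ε) on Σ_ε.

        Uses the eigendecomposition of Q_ε when it is diagonalizable to
        working precision (Q_ε is not reversible, so no symmetric
        shortcut exists) and falls back to scaling-and-squaring.
        """
        if b < 0:
            raise ModelError("branch length must be non-negative")
        if b == 0:
            return np.eye(self.n_states + 1)
        if self._eig is None:
            w, V = np.linalg.eig(self.Q_eps)
            try:
                Vinv = np.linalg.inv(V)
                self._diagonalizable = (
                    np.linalg.cond(V) < 1e8
                    and np.max(np.abs((V * w) @ Vinv - self.Q_eps)) < 1e-10
                )
            except np.linalg.LinAlgError:
                self._diagonalizable = False
            self._eig = (w, V, Vinv if self._diagonalizable else None)
        w, V, Vinv = self._eig
        if self._diagonalizable:
            P = np.real((V * np.exp(b * w)) @ Vinv)
        else:
            P = expm(b * self.Q_eps)
        np.clip(P, 0.0, 1.0, out=P)
        # renormalise away clipping / roundoff
        P /= P.sum(axis=1, keepdims=True)
        return P


# -- model factories ---------------------------------------------------


def _normalise(R: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Turn exchangeabilities + frequencies into a unit-rate generator."""
    Q = R * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -np.sum(pi * np.diag(Q))
    return Q / rate


def jc69(mu: float) -> SubstModel:
    """Jukes–Cantor nucleotide model: equal rates, uniform frequencies."""
    pi = np.full(4, 0.25)
    R = np.ones((4, 4))
    return SubstModel(DNA, _normalise(R, pi), pi, mu, name="JC69")


def k80(mu: float, kappa: float = 2.0) -> SubstModel:
    """Kimura two-parameter model with transition/transversion ratio κ."""
    if not kappa > 0:
        raise ModelError("kappa must be positive")
    pi = np.full(4, 0.25)
    R = np.ones((4, 4))
    # transitions: A<->G (0,2), C<->T (1,3)
    R[0, 2] = R[2, 0] = R[1, 3] = R[3, 1] = kappa
    return SubstModel(DNA, _normalise(R, pi), pi, mu, name="K80")


def gtr(mu: float, rates, pi) -> SubstModel:
    """General time-reversible nucleotide model.

    ``rates`` are the six exchangeabilities in order AC, AG, AT, CG, CT,
    GT; ``pi`` the four stationary frequencies (A, C, G, T).
    """
    rates = np.asarray(rates, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if rates.shape != (6,) or np.any(rates <= 0):
        raise ModelError("GTR needs 6 positive exchangeabilities")
    if pi.shape != (4,) or abs(pi.sum() - 1) > 1e-8 or np.any(pi <= 0):
        raise ModelError("GTR needs 4 positive frequencies summing to 1")
    R = np.zeros((4, 4))
    R[0, 1] = R[1, 0] = rates[0]
    R[0, 2] = R[2, 0] = rates[1]
    R[0, 3] = R[3, 0] = rates[2]
    R[1, 2] = R[2, 1] = rates[3]
    R[1, 3] = R[3, 1] = rates[4]
    R[2, 3] = R[3, 2] = rates[5]
    return SubstModel(DNA, _normalise(R, pi), pi, mu, name="GTR")


def _empirical_aa(exch, freqs, name: str, mu: float, pi_override=None) -> SubstModel:
    R = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            R[i, j] = R[j, i] = exch[k]
            k += 1
    pi = np.asarray(pi_override if pi_override is not None else freqs, dtype=float)
    if pi.shape != (20,):
        raise ModelError("amino-acid frequency override needs 20 values")
    pi = pi / pi.sum()
    return SubstModel(AA, _normalise(R, pi), pi, mu, name=name)


def wag(mu: float, pi=None) -> SubstModel:
    return _empirical_aa(_aa_data.WAG_EXCH, _aa_data.WAG_FREQS, "WAG", mu, pi)


def lg(mu: float, pi=None) -> SubstModel:
    return _empirical_aa(_aa_data.LG_EXCH, _aa_data.LG_FREQS, "LG", mu, pi)


def make_model(name: str, mu: float, **kwargs) -> SubstModel:
    """Build a model by name: JC69, K80, GTR, WAG or LG."""
    name = name.upper()
    if name == "JC69":
        return jc69(mu)
    if name == "K80":
        return k80(mu, kappa=kwargs.get("kappa", 2.0))
    if name == "GTR":
        if "rates" not in kwargs or "pi" not in kwargs:
            raise ModelError("GTR requires 'rates' and 'pi'")
        return gtr(mu, kwargs["rates"], kwargs["pi"])
    if name == "WAG":
        return wag(mu, kwargs.get("pi"))
    if name == "LG":
        return lg(mu, kwargs.get("pi"))
    raise ModelError(f"unknown model {name!r}")
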