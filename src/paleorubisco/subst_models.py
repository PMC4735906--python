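"""Reversible substitution models and discrete-gamma rate variation.

Supports the empirical LG amino-acid model (exchangeabilities and
stationary frequencies bundled as a plain-text data file in PAML layout),
a symmetric two-state model over {a, g} used for ancestral gap (indel)
reconstruction, and an equal-rates JC-style model on an arbitrary state
count.  Rate matrices are built as Q_ij = s_ij * pi_j, constrained to zero
row sums, and scaled so the expected substitution rate at stationarity is
one, so branch lengths read as expected substitutions per site.

Among-site rate heterogeneity uses Yang's discrete-gamma approximation:
``ncat`` equal-probability categories, each represented by its category
mean, with the overall mean pinned to one.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP_STATES = "ag"

#: sha256 of the bundled LG exchangeability/frequency file.
LG_DATA_SHA256 = "fc32c95bdccb00f3990b577bcdf93b8b31e33b46d6ea11aa92548e7f9eb38674"


class ModelError(ValueError):
    pass


def _load_lg() -> tuple[np.ndarray, np.ndarray]:
    """Parse the bundled PAML-format LG file (lower-triangle + frequencies)."""
    ref = resources.files("paleorubisco.data").joinpath("lg.dat")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != LG_DATA_SHA256:
        raise ModelError(
            f"LG data file checksum mismatch: {digest} != {LG_DATA_SHA256}"
        )
    values = [float(x) for x in raw.decode().split()]
    k = 20
    n_tri = k * (k - 1) // 2
    if len(values) != n_tri + k:
        raise ModelError("LG data file has unexpected size")
    S = np.zeros((k, k))
    idx = 0
    for i in range(1, k):
        for j in range(i):
            S[i, j] = S[j, i] = values[idx]
            idx += 1
    freqs = np.array(values[idx:])
    return S, freqs / freqs.sum()


@dataclass
class TransitionMatrix:
    """Row-stochastic P(t) for one branch length."""

    t: float
    P: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-10):
            raise ModelError("transition matrix rows do not sum to 1")


@dataclass
class SubstModel:
    """A normalized reversible rate matrix with optional gamma rates.

    Attributes
    ----------
    alphabet : str
        Ordered state labels (length k).
    exchangeabilities : (k, k) ndarray
        Symmetric non-negative matrix, zero diagonal.
    frequencies : (k,) ndarray
        Stationary distribution.
    Q : (k, k) ndarray
        Normalized rate matrix (expected rate 1 at stationarity).
    alpha : float or None
        Gamma shape; ``None`` means rate homogeneity.
    category_rates : (ncat,) ndarray
        Equal-probability discrete-gamma category rates, mean 1.
    """

    name: str
    alphabet: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: float | None = None
    ncat: int = 1
    Q: np.ndarray = field(init=False)
    category_rates: np.ndarray = field(init=False)
    _eig: tuple[np.ndarray, np.ndarray, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        k = len(self.alphabet)
        pi = np.asarray(self.frequencies, dtype=float)
        if pi.shape != (k,):
            raise ModelError(
                f"frequencies length {pi.shape} does not match alphabet size {k}"
            )
        if abs(pi.sum() - 1.0) > 1e-6:
            raise ModelError(f"frequencies sum to {pi.sum():.8f}, not 1")
        if np.any(pi <= 0):
            raise ModelError("frequencies must be strictly positive")
        pi = pi / pi.sum()
        S = np.asarray(self.exchangeabilities, dtype=float)
        if S.shape != (k, k) or not np.allclose(S, S.T):
            raise ModelError("exchangeabilities must be a symmetric k x k matrix")
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -(pi * np.diag(Q)).sum()
        if rate <= 0:
            raise ModelError("degenerate rate matrix (zero total rate)")
        Q /= rate
        self.frequencies = pi
        self.Q = Q
        if self.alpha is not None and self.alpha <= 0:
            raise ModelError("gamma shape alpha must be positive")
        if self.ncat < 1:
            raise ModelError("ncat must be >= 1")
        if self.alpha is None:
            self.category_rates = np.ones(1 if self.ncat == 1 else self.ncat)
        else:
            self.category_rates = discretize_gamma(self.alpha, self.ncat)
        # Symmetric eigendecomposition of B = D^{1/2} Q D^{-1/2} (D = diag(pi));
        # reused for every matrix exponential.
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = (B + B.T) / 2.0
        eigval, eigvec = np.linalg.eigh(B)
        self._eig = (eigval, eigvec, sq)

    @property
    def k(self) -> int:
        return len(self.alphabet)

    def state_index(self, symbol: str) -> int:
        try:
            return self.alphabet.index(symbol)
        except ValueError:
            raise ModelError(
                f"symbol {symbol!r} not in model alphabet {self.alphabet!r}"
            ) from None


def build_model(
    name: str,
    frequencies: np.ndarray | str = "model_default",
    alpha: float | None = None,
    ncat: int = 1,
    k: int = 4,
) -> SubstModel:
    """Construct a named substitution model.

    ``LG``: the empirical amino-acid model; `frequencies` may be
    ``"model_default"`` (the published frequencies) or a user simplex,
    e.g. alignment-derived (+F).  ``binary_gap``: symmetric 2-state model
    over {a, g} with equal frequencies, used for gap reconstruction.
    ``JC_k``: equal-rates model on `k` states.
    """
    if name == "LG":
        S, default_pi = _load_lg()
        pi = default_pi if isinstance(frequencies, str) else np.asarray(frequencies)
        return SubstModel("LG", AMINO_ACIDS, S, pi, alpha=alpha, ncat=ncat)
    if name == "binary_gap":
        S = np.array([[0.0, 1.0], [1.0, 0.0]])
        pi = (
            np.full(2, 0.5)
            if isinstance(frequencies, str)
            else np.asarray(frequencies)
        )
        return SubstModel("binary_gap", GAP_STATES, S, pi, alpha=alpha, ncat=ncat)
    if name == "JC_k":
        S = np.ones((k, k)) - np.eye(k)
        pi = (
            np.full(k, 1.0 / k)
            if isinstance(frequencies, str)
            else np.asarray(frequencies)
        )
        labels = "".join(chr(ord("0") + i) if i < 10 else chr(ord("A") + i - 10)
                         for i in range(k))
        return SubstModel("JC_k", labels, S, pi, alpha=alpha, ncat=ncat)
    raise ModelError(f"unknown model {name!r}")


def transition_matrix(model: SubstModel, t: float) -> TransitionMatrix:
    """P(t) = exp(Qt) via the model's symmetric eigendecomposition."""
    if t < 0:
        raise ModelError(f"branch length must be non-negative, got {t}")
    eigval, eigvec, sq = model._eig
    inner = (eigvec * np.exp(eigval * t)) @ eigvec.T
    P = inner / sq[:, None] * sq[None, :]
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return TransitionMatrix(t, P)


def discretize_gamma(alpha: float, ncat: int) -> np.ndarray:
    """Equal-probability discrete-gamma category rates (category means).

    The gamma has shape `alpha` and mean 1.  Category i is the interval
    between the i/ncat and (i+1)/ncat quantiles; its representative rate is
    the conditional mean over that interval, computed from the incomplete
    gamma function with shape alpha+1.  The rates are renormalized so their
    mean is exactly 1 in floating point.
    """
    if alpha <= 0:
        raise ModelError("alpha must be positive")
    if ncat < 1:
        raise ModelError("ncat must be >= 1")
    if ncat == 1:
        return np.ones(1)
    probs = np.arange(1, ncat) / ncat
    bounds = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    # P(X <= b) under shape alpha+1, rate alpha, times ncat, differenced.
    upper = np.concatenate([gammainc(alpha + 1.0, bounds * alpha), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1.0, bounds * alpha)])
    rates = ncat * (upper - lower)
    return rates / rates.mean()
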