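"""q-exponential family and the geometric/exponential null model.

The clustering statistic rests on two distribution families:

* the **geometric null** — in an i.i.d. letter sequence a word of occurrence
  probability ``omega`` has inter-occurrence distances ``P(d) = omega *
  (1-omega)**(d-1)``, whose survival function is exponential with
  characteristic distance ``x0 = 1/|ln(1-omega)|``;
* the **q-exponential (Tsallis) family** ``e_q(x) = [1+(1-q)x]**(1/(1-q))``,
  which generalises the exponential (recovered at ``q=1``) and has a power-law
  tail ``d**(-1/(q-1))`` for ``q>1``.  The entropic index ``q`` fitted to the
  observed survival function of a word's inter-occurrence distances is the
  clustering score: ``q ~ 1`` means random placement, larger ``q`` means
  heavier tails, i.e. stronger clustering.

All functions are pure and accept scalars or numpy arrays in ``x``/``d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QParams",
    "NucleotideComposition",
    "q_exponential",
    "q_logarithm",
    "tsallis_ccdf",
    "word_probability",
    "null_x0",
    "geometric_null_ccdf",
]

#: below this |q-1| the family switches to the exact exp/log limit,
#: avoiding catastrophic cancellation in (1-q).
_Q_ONE_TOL = 1e-12

DNA_LETTERS = ("A", "C", "G", "T")


@dataclass(frozen=True)
class QParams:
    """Parameters of a q-exponential survival curve.

    Attributes
    ----------
    q : float
        Entropic index; must be positive.  ``q=1`` is the exponential limit.
    x0 : float
        Characteristic distance in bp; must be positive.
    """

    q: float
    x0: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.q) and self.q > 0):
            raise ValueError(f"q must be a positive finite number, got {self.q}")
        if not (np.isfinite(self.x0) and self.x0 > 0):
            raise ValueError(f"x0 must be a positive finite number, got {self.x0}")


@dataclass(frozen=True)
class NucleotideComposition:
    """Letter counts and probabilities of a DNA sequence.

    ``counts`` maps each letter (including ``N`` for ambiguous positions) to
    its count; ``length`` is the total sequence length.  Probabilities are
    defined as ``counts[X] / length``.
    """

    counts: dict[str, int]
    length: int
    probs: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("sequence length must be positive")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("letter counts must be non-negative")
        total = sum(self.counts.values())
        if total != self.length:
            raise ValueError(
                f"letter counts sum to {total}, expected length {self.length}"
            )
        object.__setattr__(
            self,
            "probs",
            {x: c / self.length for x, c in self.counts.items()},
        )

    @classmethod
    def from_sequence(cls, sequence: str) -> "NucleotideComposition":
        """Count letters of an (uppercase) sequence string."""
        counts: dict[str, int] = {}
        for ch in sequence:
            counts[ch] = counts.get(ch, 0) + 1
        return cls(counts=counts, length=len(sequence))

    def prob(self, letter: str) -> float:
        return self.probs.get(letter, 0.0)


def _check_finite(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {value}")
    return arr


def q_exponential(x, q: float):
    """Evaluate ``e_q(x)``.

    ``e_q(x) = exp(x)`` for ``q=1``; otherwise ``[1+(1-q)x]**(1/(1-q))`` where
    the bracket is positive and 0 where it is not (the Tsallis cutoff, which
    only bites for ``q<1`` at sufficiently negative ``x``).
    """
    xa = _check_finite("x", x)
    q = float(_check_finite("q", q))
    if q <= 0:
        raise ValueError(f"q must be positive, got {q}")
    scalar = xa.shape == ()
    if abs(q - 1.0) < _Q_ONE_TOL:
        out = np.exp(xa)
        return float(out) if scalar else out
    x1 = np.atleast_1d(xa)
    bracket = 1.0 + (1.0 - q) * x1
    out = np.zeros_like(x1)
    pos = bracket > 0
    # log1p formulation keeps the q -> 1 limit accurate.
    with np.errstate(over="ignore"):
        out[pos] = np.exp(np.log1p((1.0 - q) * x1[pos]) / (1.0 - q))
    return float(out[0]) if scalar else out


def q_logarithm(y, q: float):
    """Evaluate ``ln_q(y) = (y**(1-q) - 1)/(1-q)``, the inverse of ``e_q``.

    Reduces to ``ln(y)`` at ``q=1``.  Defined for ``y > 0`` only.
    """
    ya = _check_finite("y", y)
    q = float(_check_finite("q", q))
    if q <= 0:
        raise ValueError(f"q must be positive, got {q}")
    if np.any(ya <= 0):
        raise ValueError("q_logarithm requires y > 0")
    if abs(q - 1.0) < _Q_ONE_TOL:
        out = np.log(ya)
        return out if out.shape else float(out)
    out = np.expm1((1.0 - q) * np.log(ya)) / (1.0 - q)
    return out if out.shape else float(out)


def tsallis_ccdf(d, params: QParams):
    """Survival function ``P(D >= d) = e_q(-d/x0)`` of the Tsallis law.

    Equals 1 at ``d=0``, is non-increasing in ``d``, and for ``q>1`` decays as
    ``d**(-1/(q-1))`` in the tail.
    """
    da = _check_finite("d", d)
    if np.any(da < 0):
        raise ValueError("distances must be non-negative")
    return q_exponential(-da / params.x0, params.q)


def word_probability(word: str, comp: NucleotideComposition) -> float:
    """Occurrence probability of a word under letter independence.

    The product of its letter probabilities, ``omega_S = prod P(X_i)``.
    Returns 0 if any letter has zero probability in ``comp``.
    """
    if not word:
        raise ValueError("word must be non-empty")
    bad = set(word) - set(DNA_LETTERS)
    if bad:
        raise ValueError(f"word contains non-ACGT letters: {sorted(bad)}")
    omega = 1.0
    for letter in word:
        omega *= comp.prob(letter)
    return omega


def null_x0(omega: float) -> float:
    """Characteristic distance ``1/|ln(1-omega)|`` of the geometric null.

    For small ``omega`` this is approximately ``1/omega`` (large, since word
    probabilities are small).
    """
    omega = float(omega)
    if not (0.0 < omega < 1.0):
        raise ValueError(f"omega must lie in (0, 1), got {omega}")
    return 1.0 / abs(np.log1p(-omega))


def geometric_null_ccdf(d, omega: float):
    """Null survival function ``P(D >= d) = (1-omega)**(d-1)`` for ``d >= 1``.

    This is ``exp(-(d-1)/x0)`` with ``x0 = null_x0(omega)``: the exponential
    form that random (uncorrelated) word placement produces.
    """
    if not (0.0 < omega < 1.0):
        raise ValueError(f"omega must lie in (0, 1), got {omega}")
    da = _check_finite("d", d)
    if np.any(da < 1):
        raise ValueError("distances must be >= 1")
    out = np.power(1.0 - omega, da - 1.0)
    return out if out.shape else float(out)
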