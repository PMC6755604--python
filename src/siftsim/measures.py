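"""Catalog of 44 binary similarity measures on confusion counts.

Every measure is a function of the pairwise confusion table of two
equal-length bitstrings: ``a`` common on-bits, ``b`` on in the first only,
``c`` on in the second only, ``d`` common off-bits, ``p = a+b+c+d``.
Measures whose natural range is not [0, 1] (e.g. correlation-type
coefficients on [-1, 1]) are rescaled with

    s' = (s + alpha) / beta

so that every scaled value lies in [0, 1]. For a handful of measures the
attainable range grows with the fingerprint length, so alpha/beta are
functions of ``p``; the catalog stores them as callables with a scalar fast
path. The bounds used are derived from the formulas and verified by
exhaustive enumeration over all confusion tables at several ``p`` in the
test suite.

Each entry carries two classifications:

* symmetricity — ``S`` if ``d`` is counted equally with ``a``, ``I`` if
  ``d`` is underweighted (including measures where ``d`` enters only
  through ``p``), ``A`` if ``d`` does not appear at all, and ``Q`` for
  correlation-based coefficients;
* metricity — ``M`` if ``1 - s'`` satisfies the metric axioms (triangle
  inequality included), ``N`` otherwise.

Degenerate denominators are resolved by convention: two identical
fingerprints (``b = c = 0``) score the maximum (``s' = 1``) for every
measure; any other zero denominator scores the minimum (``s' = 0``). Every
such event is logged at DEBUG level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import asin, log, pi, sqrt
from typing import Callable, Union

logger = logging.getLogger(__name__)

Scaling = Union[float, Callable[[int], float]]

SYMMETRICITY_CLASSES = ("S", "I", "A", "Q")
METRICITY_CLASSES = ("M", "N")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pairwise bit co-occurrence counts for two equal-length bitstrings.

    ``a``: 1-1, ``b``: 1-0, ``c``: 0-1, ``d``: 0-0; ``p = a + b + c + d``.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {name} must be a non-negative integer, got {v}")
        if self.p < 1:
            raise ValueError("confusion counts must describe at least one bit")

    @property
    def p(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SimilarityMeasure:
    """A named binary similarity coefficient with scaling and class labels."""

    abbrev: str
    name: str
    formula: Callable[[int, int, int, int, int], float]
    alpha: Scaling = 0.0
    beta: Scaling = 1.0
    symmetricity: str = "S"
    metricity: str = "N"
    #: False for directional coefficients where swapping the two
    #: fingerprints (b <-> c) changes the value (Pe1/Pe2, Co1/Co2).
    exchange_symmetric: bool = field(default=True)

    def __post_init__(self) -> None:
        if self.symmetricity not in SYMMETRICITY_CLASSES:
            raise ValueError(f"bad symmetricity {self.symmetricity!r}")
        if self.metricity not in METRICITY_CLASSES:
            raise ValueError(f"bad metricity {self.metricity!r}")

    def alpha_at(self, p: int) -> float:
        return self.alpha(p) if callable(self.alpha) else float(self.alpha)

    def beta_at(self, p: int) -> float:
        beta = self.beta(p) if callable(self.beta) else float(self.beta)
        if beta <= 0:
            raise ValueError(f"{self.abbrev}: beta must be positive, got {beta}")
        return beta


# ---------------------------------------------------------------------------
# formulas (plain-Python arithmetic so zero denominators raise
# ZeroDivisionError and are resolved by the convention below)

def _sm(a, b, c, d, p):
    return (a + d) / p

def _rt(a, b, c, d, p):
    return (a + d) / (p + b + c)

def _jt(a, b, c, d, p):
    return a / (a + b + c)

def _gle(a, b, c, d, p):
    return 2 * a / (2 * a + b + c)

def _rr(a, b, c, d, p):
    return a / p

def _for(a, b, c, d, p):
    return p * a / ((a + b) * (a + c))

def _sim(a, b, c, d, p):
    return a / min(a + b, a + c)

def _bb(a, b, c, d, p):
    return a / max(a + b, a + c)

def _dk(a, b, c, d, p):
    return a / sqrt((a + b) * (a + c))

def _bub(a, b, c, d, p):
    return (sqrt(a * d) + a) / (sqrt(a * d) + a + b + c)

def _kul(a, b, c, d, p):
    return (a / (a + b) + a / (a + c)) / 2

def _ss1(a, b, c, d, p):
    return a / (a + 2 * (b + c))

def _ss2(a, b, c, d, p):
    return 2 * (a + d) / (p + a + d)

def _ss4(a, b, c, d, p):
    return (a / (a + b) + a / (a + c) + d / (d + b) + d / (d + c)) / 4

def _ja(a, b, c, d, p):
    return 3 * a / (3 * a + b + c)

def _fai(a, b, c, d, p):
    return (a + d / 2) / p

def _mou(a, b, c, d, p):
    return 2 * a / (a * (b + c) + 2 * b * c)

def _mic(a, b, c, d, p):
    return 4 * (a * d - b * c) / ((a + d) ** 2 + (b + c) ** 2)

def _rg(a, b, c, d, p):
    return a / (2 * a + b + c) + d / (2 * d + b + c)

def _hd(a, b, c, d, p):
    return (a / (a + b + c) + d / (b + c + d)) / 2

def _yu1(a, b, c, d, p):
    return (a * d - b * c) / (a * d + b * c)

def _yu2(a, b, c, d, p):
    return (sqrt(a * d) - sqrt(b * c)) / (sqrt(a * d) + sqrt(b * c))

def _fos(a, b, c, d, p):
    return p * (a - 0.5) ** 2 / ((a + b) * (a + c))

def _den(a, b, c, d, p):
    return (a * d - b * c) / sqrt(p * (a + b) * (a + c))

def _co1(a, b, c, d, p):
    return (a * d - b * c) / ((a + b) * (b + d))

def _co2(a, b, c, d, p):
    return (a * d - b * c) / ((a + c) * (c + d))

def _dis(a, b, c, d, p):
    return (a * d - b * c) / p ** 2

def _gk(a, b, c, d, p):
    m = min(a, d)
    return (2 * m - b - c) / (2 * m + b + c)

def _gl(a, b, c, d, p):
    return (a + d) / (a + d + (b + c) / 2)

def _gow(a, b, c, d, p):
    return a * d / sqrt((a + b) * (a + c) * (b + d) * (c + d))

def _phi(a, b, c, d, p):
    return (a * d - b * c) / sqrt((a + b) * (a + c) * (b + d) * (c + d))

def _coh(a, b, c, d, p):
    return 2 * (a * d - b * c) / ((a + b) * (b + d) + (a + c) * (c + d))

def _pe1(a, b, c, d, p):
    return (a * d - b * c) / ((a + b) * (c + d))

def _pe2(a, b, c, d, p):
    return (a * d - b * c) / ((a + c) * (b + d))

def _mp(a, b, c, d, p):
    return 2 * (a * d - b * c) / ((a + b) * (c + d) + (a + c) * (b + d))

def _hl(a, b, c, d, p):
    return a * (2 * d + b + c) / (2 * (a + b + c)) + d * (2 * a + b + c) / (2 * (b + c + d))

def _ct1(a, b, c, d, p):
    return log(1 + a + d) / log(1 + p)

def _ct2(a, b, c, d, p):
    return (log(1 + p) - log(1 + b + c)) / log(1 + p)

def _ct3(a, b, c, d, p):
    return log(1 + a) / log(1 + p)

def _ct4(a, b, c, d, p):
    return log(1 + a) / log(1 + a + b + c)

def _ct5(a, b, c, d, p):
    return (log(1 + a * d) - log(1 + b * c)) / log(1 + p ** 2 / 4)

def _ac(a, b, c, d, p):
    return 2 / pi * asin(sqrt((a + d) / p))

def _sor(a, b, c, d, p):
    return a * a / ((a + b) * (a + c))

def _tar(a, b, c, d, p):
    return (p * a - (a + b) * (a + c)) / (p * a + (a + b) * (a + c))


# p-dependent scaling bounds ------------------------------------------------

def _den_alpha(p: int) -> float:
    # minimum is -sqrt(bc/p) maximised at b = c = p/2
    return sqrt(p) / 2

def _den_beta(p: int) -> float:
    # maximum is (p-1)/sqrt(p) at a=1, d=p-1
    return sqrt(p) / 2 + (p - 1) / sqrt(p) if p > 1 else 0.5

def _fos_beta(p: int) -> float:
    # maximum is (p-0.5)^2/p at a=p
    return (p - 0.5) ** 2 / p

def _co_alpha(p: int) -> float:
    # minimum is -(p-1): a=d=0, b=1, c=p-1
    return float(p - 1)

def _co_beta(p: int) -> float:
    return float(p) if p > 1 else 1.0


def _measures() -> tuple[SimilarityMeasure, ...]:
    m = SimilarityMeasure
    return (
        # symmetric --------------------------------------------------------
        m("SM", "simple matching (Sokal-Michener)", _sm, 0, 1, "S", "M"),
        m("RT", "Rogers-Tanimoto", _rt, 0, 1, "S", "M"),
        m("SS2", "Sokal-Sneath 2", _ss2, 0, 1, "S", "N"),
        m("SS4", "Sokal-Sneath 4", _ss4, 0, 1, "S", "N"),
        m("RG", "Rogot-Goldberg", _rg, 0, 1, "S", "N"),
        m("HD", "Hawkins-Dotson", _hd, 0, 1, "S", "N"),
        m("GK", "Goodman-Kruskal", _gk, 1, 2, "S", "N"),
        m("GL", "Gower-Legendre", _gl, 0, 1, "S", "N"),
        m("Gow", "Gower", _gow, 0, 1, "S", "N"),
        m("HL", "Harris-Lahey", _hl, 0, lambda p: float(p), "S", "N"),
        m("CT1", "Consonni-Todeschini 1", _ct1, 0, 1, "S", "N"),
        m("CT2", "Consonni-Todeschini 2", _ct2, 0, 1, "S", "N"),
        m("AC", "Austin-Colwell", _ac, 0, 1, "S", "N"),
        # intermediate (d underweighted, possibly only through p) ----------
        m("BUB", "Baroni-Urbani-Buser", _bub, 0, 1, "I", "N"),
        m("Fai", "Faith", _fai, 0, 1, "I", "N"),
        m("RR", "Russel-Rao", _rr, 0, 1, "I", "M"),
        m("For", "Forbes", _for, 0, lambda p: float(p), "I", "N"),
        m("Fos", "Fossum", _fos, 0, _fos_beta, "I", "N"),
        m("CT3", "Consonni-Todeschini 3", _ct3, 0, 1, "I", "N"),
        # asymmetric (d absent) --------------------------------------------
        m("JT", "Jaccard-Tanimoto", _jt, 0, 1, "A", "M"),
        m("Gle", "Gleason (Dice-Sorensen)", _gle, 0, 1, "A", "N"),
        m("Sim", "Simpson", _sim, 0, 1, "A", "N"),
        m("BB", "Braun-Blanquet", _bb, 0, 1, "A", "N"),
        m("DK", "Driver-Kroeber (Ochiai)", _dk, 0, 1, "A", "N"),
        m("Kul", "Kulczynski", _kul, 0, 1, "A", "N"),
        m("SS1", "Sokal-Sneath 1", _ss1, 0, 1, "A", "M"),
        m("Ja", "Jaccard (3w)", _ja, 0, 1, "A", "N"),
        m("Mou", "Mountford", _mou, 0, 2, "A", "N"),
        m("CT4", "Consonni-Todeschini 4", _ct4, 0, 1, "A", "N"),
        m("Sor", "Sorgenfrei", _sor, 0, 1, "A", "N"),
        # correlation-based ------------------------------------------------
        m("Mic", "Michael", _mic, 1, 2, "Q", "N"),
        m("Yu1", "Yule 1", _yu1, 1, 2, "Q", "N"),
        m("Yu2", "Yule 2", _yu2, 1, 2, "Q", "N"),
        m("Den", "Dennis", _den, _den_alpha, _den_beta, "Q", "N"),
        m("Co1", "Cole 1", _co1, _co_alpha, _co_beta, "Q", "N", exchange_symmetric=False),
        m("Co2", "Cole 2", _co2, _co_alpha, _co_beta, "Q", "N", exchange_symmetric=False),
        m("dis", "dispersion", _dis, 0.25, 0.5, "Q", "N"),
        m("Phi", "Pearson-Heron (phi)", _phi, 1, 2, "Q", "N"),
        m("Coh", "Cohen", _coh, 1, 2, "Q", "N"),
        m("Pe1", "Peirce 1", _pe1, 1, 2, "Q", "N", exchange_symmetric=False),
        m("Pe2", "Peirce 2", _pe2, 1, 2, "Q", "N", exchange_symmetric=False),
        m("MP", "Maxwell-Pilliner", _mp, 1, 2, "Q", "N"),
        m("CT5", "Consonni-Todeschini 5", _ct5, 1, 2, "Q", "N"),
        m("Tar", "Tarwid", _tar, 1, 2, "Q", "N"),
    )


MEASURES: dict[str, SimilarityMeasure] = {m.abbrev: m for m in _measures()}


def list_measures() -> list[SimilarityMeasure]:
    """The full catalog, 44 distinct measures, in catalog order."""
    return list(MEASURES.values())


def get_measure(abbrev: str) -> SimilarityMeasure:
    try:
        return MEASURES[abbrev]
    except KeyError:
        raise KeyError(f"unknown similarity measure {abbrev!r}") from None


# ---------------------------------------------------------------------------
# evaluation


def raw_similarity(measure: SimilarityMeasure, counts: ConfusionCounts) -> float:
    """Raw (unscaled) value of a measure on a confusion table.

    Degenerate cases are resolved by convention on the *scaled* scale and
    reported here on the raw scale: identical fingerprints (b = c = 0) get
    the measure's scaled maximum, other zero denominators its scaled
    minimum. Both events are logged.
    """
    a, b, c, d, p = counts.a, counts.b, counts.c, counts.d, counts.p
    if b == 0 and c == 0:
        logger.debug("%s: identical fingerprints (b=c=0), returning maximum", measure.abbrev)
        return measure.beta_at(p) - measure.alpha_at(p)
    try:
        return measure.formula(a, b, c, d, p)
    except (ZeroDivisionError, ValueError):
        logger.debug("%s: degenerate denominator on %r, returning minimum", measure.abbrev, counts)
        return -measure.alpha_at(p)


def scale_similarity(s: float, measure: SimilarityMeasure, p: int) -> float:
    """Rescale a raw value to [0, 1] via ``(s + alpha) / beta``.

    Values outside [0, 1] by more than 1e-9 indicate a wrong alpha/beta and
    raise; values inside the tolerance are clamped.
    """
    scaled = (s + measure.alpha_at(p)) / measure.beta_at(p)
    if scaled < -1e-9 or scaled > 1 + 1e-9:
        raise RuntimeError(
            f"{measure.abbrev}: scaled value {scaled} outside [0, 1]; "
            "alpha/beta do not cover the measure's range"
        )
    return min(1.0, max(0.0, scaled))


def scaled_similarity(measure: SimilarityMeasure, counts: ConfusionCounts) -> float:
    """Scaled similarity in [0, 1] with the degenerate-case convention."""
    return scale_similarity(raw_similarity(measure, counts), measure, counts.p)
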