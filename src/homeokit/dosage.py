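"""Allele-dosage inference from probe-classified read counts.

Given n_alt reads carrying a deletion allele and n_ref carrying the
reference allele at a locus with m total alleles (e.g. m=6 for three
diploid-behaving gene copies), this module provides:

* Pearson chi-square goodness of fit of (n_alt, n_ref) against a
  hypothesized integer dosage d of m (two categories, df=1, no
  continuity correction);
* maximum-likelihood integer dosage under a binomial read-sampling
  model, with the implied allele ratio in lowest terms;
* ranking of arbitrary candidate dosage configurations by likelihood.

Ambiguous reads are excluded upstream; only classified reads enter N.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import xlogy

from .errors import InputError

SMALL_EXPECTED = 5.0


@dataclass(frozen=True)
class DosageHypothesis:
    """d deletion alleles out of m total at the locus."""

    d: int
    m: int
    label: Optional[str] = None

    def __post_init__(self):
        if self.m < 1:
            raise InputError(f"total allele count m must be >= 1, got {self.m}")
        if not 0 <= self.d <= self.m:
            raise InputError(f"dosage d={self.d} outside [0, {self.m}]")

    @property
    def fraction(self) -> float:
        return self.d / self.m

    @property
    def ratio(self) -> tuple[int, int]:
        """d : (m - d) in lowest integer terms."""
        g = math.gcd(self.d, self.m - self.d) or 1
        return (self.d // g, (self.m - self.d) // g)

    @classmethod
    def parse(cls, text: str, label: Optional[str] = None) -> "DosageHypothesis":
        """Parse a "d/m" string, e.g. "1/6"."""
        try:
            d_s, m_s = text.split("/")
            return cls(int(d_s), int(m_s), label=label)
        except (ValueError, AttributeError) as exc:
            raise InputError(f"cannot parse dosage hypothesis {text!r}") from exc


@dataclass(frozen=True)
class GofResult:
    chi2: float
    df: int
    p: float
    hypothesis: DosageHypothesis
    impossible: bool = False  # boundary hypothesis contradicted by data
    small_expected: bool = False
    exact_binomial_p: Optional[float] = None


@dataclass(frozen=True)
class DosageInference:
    counts: tuple[int, int]  # (n_alt, n_ref)
    m: int
    loglik: np.ndarray  # indexed by d = 0..m
    d_hat: int
    ties: tuple[int, ...]  # all argmax dosages (len > 1 marks a tie)
    implied_ratio: Optional[tuple[int, int]]  # None when ambiguous
    gof: list[GofResult] = field(default_factory=list)

    @property
    def ambiguous(self) -> bool:
        return len(self.ties) > 1


def _binom_loglik(n_alt: int, n_ref: int, frac: float) -> float:
    # xlogy(0, 0) == 0 handles the boundary dosages.
    return float(xlogy(n_alt, frac) + xlogy(n_ref, 1.0 - frac))


def chisq_gof(n_alt: int, n_ref: int, hyp: DosageHypothesis,
              exact_binomial: bool = True) -> GofResult:
    """Pearson chi-square GOF of observed allele counts vs dosage d/m.

    Two categories, df=1, no continuity correction. Boundary hypotheses
    (d=0 or d=m) contradicted by a positive count are flagged impossible
    with p=0. When an expected count falls below 5 a warning is issued
    and, if ``exact_binomial``, an exact binomial p-value is attached.
    """
    if n_alt < 0 or n_ref < 0:
        raise InputError("counts must be non-negative")
    n = n_alt + n_ref
    if n == 0:
        raise InputError("cannot test a hypothesis with zero classified reads")

    if (hyp.d == 0 and n_alt > 0) or (hyp.d == hyp.m and n_ref > 0):
        return GofResult(chi2=math.inf, df=1, p=0.0, hypothesis=hyp, impossible=True)
    if hyp.d == 0 or hyp.d == hyp.m:
        return GofResult(chi2=0.0, df=1, p=1.0, hypothesis=hyp)

    expected = np.array([n * hyp.fraction, n * (1.0 - hyp.fraction)])
    chi2, p = stats.chisquare([n_alt, n_ref], f_exp=expected)

    small = bool(expected.min() < SMALL_EXPECTED)
    exact_p = None
    if small:
        warnings.warn(
            f"expected count below {SMALL_EXPECTED:g} for hypothesis "
            f"{hyp.d}/{hyp.m} (N={n}); chi-square approximation is rough",
            stacklevel=2,
        )
        if exact_binomial:
            exact_p = stats.binomtest(n_alt, n, hyp.fraction).pvalue

    return GofResult(
        chi2=float(chi2), df=1, p=float(p), hypothesis=hyp,
        small_expected=small, exact_binomial_p=exact_p,
    )


def ml_dosage(n_alt: int, n_ref: int, m: int, with_gof: bool = True) -> DosageInference:
    """Maximum-likelihood integer dosage under a binomial read model.

    Evaluates loglik(d) = n_alt*ln(d/m) + n_ref*ln(1-d/m) for d=0..m
    (boundary dosages are impossible unless the matching count is zero).
    Ties are reported, not silently broken.
    """
    if n_alt < 0 or n_ref < 0:
        raise InputError("counts must be non-negative")
    if n_alt + n_ref == 0:
        raise InputError("cannot infer dosage from zero classified reads")
    if m < 1:
        raise InputError(f"total allele count m must be >= 1, got {m}")

    loglik = np.array([_binom_loglik(n_alt, n_ref, d / m) for d in range(m + 1)])
    best = loglik.max()
    # tolerate last-bit float noise so symmetric dosages register as ties
    tol = 1e-12 * max(abs(best), 1.0)
    ties = tuple(int(d) for d in np.flatnonzero(loglik >= best - tol))
    d_hat = ties[0]
    ratio = DosageHypothesis(d_hat, m).ratio if len(ties) == 1 else None

    gof: list[GofResult] = []
    if with_gof:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gof = [
                chisq_gof(n_alt, n_ref, DosageHypothesis(d, m), exact_binomial=False)
                for d in range(m + 1)
            ]

    return DosageInference(
        counts=(n_alt, n_ref), m=m, loglik=loglik, d_hat=d_hat,
        ties=ties, implied_ratio=ratio, gof=gof,
    )


def rank_configurations(counts: tuple[int, int],
                        configs: Sequence[DosageHypothesis]) -> list[dict]:
    """Rank candidate dosage configurations by binomial log-likelihood.

    Returns dicts with keys hypothesis/loglik/gof, sorted by descending
    log-likelihood (stable for exact ties).
    """
    if not configs:
        raise InputError("need at least one configuration")
    n_alt, n_ref = counts
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for hyp in configs:
            rows.append({
                "hypothesis": hyp,
                "loglik": _binom_loglik(n_alt, n_ref, hyp.fraction),
                "gof": chisq_gof(n_alt, n_ref, hyp),
            })
    rows.sort(key=lambda r: -r["loglik"])
    return rows
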