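"""Closed-form kin-selection quantities for the inelastic island model.

All quantities refer to an infinite island model of ``n`` haploid asexual
breeders per patch, a dispersal mortality probability ``c``, a population
mean dispersal rate ``xbar`` and a local density dependence of dispersal
``mu`` (the slope of the dispersal reaction norm at unit relative density).

The central output is the *potential for altruism* ``A``: the threshold
cost-to-benefit ratio C/B below which an indiscriminate altruistic trait is
favoured.  Under density-independent dispersal (``mu = 0``) A collapses to
1/n regardless of ``xbar`` and ``c``; under the evolutionarily stable
positive density-dependent dispersal schedule (``mu = 1 - xbar*``) kin
competition is abolished and A = (r - c^2)/(1 - c^2) > 1/n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConsistencyError, DegenerateError, DomainError

__all__ = [
    "Demography",
    "DispersalRegime",
    "SocialEffects",
    "AnalyticSummary",
    "relatedness",
    "scale_of_competition",
    "mortality_load",
    "potential_general",
    "potential_explicit",
    "hamilton_margin",
    "optimal_dispersal_rate",
    "optimal_dispersal_at_density",
    "optimal_density_slope",
    "potential_under_optimal_dispersal",
    "summarize",
]

_IDENTITY_TOL = 1e-10


@dataclass(frozen=True)
class Demography:
    """Structural parameters of the island model.

    Parameters
    ----------
    n : int
        Breeders per patch (>= 1).
    c : float
        Probability that a dispersing juvenile dies in transit, in [0, 1].
    k : int
        Offspring per breeder (>= 1); only the individual-based simulator
        uses ``k``, the closed forms hold in the large-``k`` limit.
    """

    n: int
    c: float
    k: int = 10

    def __post_init__(self) -> None:
        if not (isinstance(self.n, int) and self.n >= 1):
            raise DomainError(f"n must be an integer >= 1, got {self.n!r}")
        if not 0.0 <= self.c <= 1.0:
            raise DomainError(f"c must lie in [0, 1], got {self.c!r}")
        if not (isinstance(self.k, int) and self.k >= 1):
            raise DomainError(f"k must be an integer >= 1, got {self.k!r}")


@dataclass(frozen=True)
class DispersalRegime:
    """Population-level description of dispersal behaviour.

    ``mean_rate`` is the population-average probability of attempting
    dispersal; ``density_slope`` is the derivative of the dispersal
    reaction norm with respect to relative patch density, evaluated at
    unit density (may be negative).
    """

    mean_rate: float
    density_slope: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_rate <= 1.0:
            raise DomainError(
                f"mean_rate must lie in [0, 1], got {self.mean_rate!r}"
            )


@dataclass(frozen=True)
class SocialEffects:
    """Marginal survival effects of the altruistic trait.

    ``benefit`` (B) is the marginal survival benefit to patch mates,
    ``cost`` (C) the marginal survival cost to the actor, ``baseline``
    (s0) the survival probability of a juvenile in a fully selfish,
    monomorphic population (simulator only).
    """

    benefit: float
    cost: float
    baseline: float = 0.5

    def __post_init__(self) -> None:
        if not self.benefit > 0.0:
            raise DomainError(f"benefit must be > 0, got {self.benefit!r}")
        if not self.cost > 0.0:
            raise DomainError(f"cost must be > 0, got {self.cost!r}")
        if not 0.0 < self.baseline <= 1.0:
            raise DomainError(
                f"baseline must lie in (0, 1], got {self.baseline!r}"
            )


@dataclass(frozen=True)
class AnalyticSummary:
    """Bundle of derived kin-selection quantities at one parameter point."""

    relatedness: float
    scale_of_competition: float
    mortality_load: float
    potential: float
    optimal_mean_dispersal: float
    optimal_dispersal_at_P: float
    relative_density: float


def _check_denominator(c: float, xbar: float) -> None:
    if 1.0 - c * xbar <= 0.0:
        raise DegenerateError(
            f"1 - c*xbar must be positive, got c={c}, xbar={xbar}"
        )


def relatedness(demog: Demography, mean_rate: float) -> float:
    """Whole-group relatedness of a juvenile to her patch's juveniles.

    r = (1 - c x)^2 / [ (1 - x)^2 + x n (1 - c) (2 - (1 + c) x) ]

    with x the population mean dispersal rate.  Not a free parameter:
    it is fully determined by ``n``, ``c`` and ``mean_rate``.
    """
    if not 0.0 <= mean_rate <= 1.0:
        raise DomainError(f"mean_rate must lie in [0, 1], got {mean_rate!r}")
    n, c, x = demog.n, demog.c, mean_rate
    denom = (1.0 - x) ** 2 + x * n * (1.0 - c) * (2.0 - (1.0 + c) * x)
    if denom == 0.0:
        # only reachable at c = 1, x = 1
        raise DegenerateError(
            "relatedness undefined at c = 1 with mean_rate = 1"
        )
    return (1.0 - c * x) ** 2 / denom


def scale_of_competition(regime: DispersalRegime, c: float) -> float:
    """Degree to which altruism-driven density intensifies local competition.

    a = [(1 - x)/(1 - c x)] * [(1 - x - mu)/(1 - c x)].

    Vanishes when ``mu = 1 - x`` (every altruism-induced extra survivor
    disperses away) and when ``x = 1``.
    """
    x, mu = regime.mean_rate, regime.density_slope
    _check_denominator(c, x)
    return (1.0 - x) / (1.0 - c * x) * (1.0 - x - mu) / (1.0 - c * x)


def mortality_load(regime: DispersalRegime, c: float) -> float:
    """Relative marginal increase in dispersal mortality owing to altruism.

    chi = mu c / (1 - c x); zero whenever ``mu = 0`` or ``c = 0``.
    """
    x, mu = regime.mean_rate, regime.density_slope
    _check_denominator(c, x)
    return mu * c / (1.0 - c * x)


def potential_general(r: float, a: float, chi: float) -> float:
    """Potential for altruism from relatedness, competition scale and load.

    A = (r - a r - chi r) / (1 - a r - chi r).

    With ``chi = 0`` this is the classic (r - a r)/(1 - a r); with
    ``a = chi = 0`` it is just ``r``.
    """
    denom = 1.0 - a * r - chi * r
    if denom == 0.0:
        raise DegenerateError("potential undefined: 1 - r(a + chi) = 0")
    return (r - a * r - chi * r) / denom


def potential_explicit(demog: Demography, regime: DispersalRegime) -> float:
    """Demographically explicit potential for altruism.

    A = 1/n + ((n-1)/n) * (1-(1+c)x) mu / [ n x (2-(1+c)x) + (1-(1+c)x) mu ]

    Equal (to float precision) to composing :func:`potential_general` with
    :func:`relatedness`, :func:`scale_of_competition` and
    :func:`mortality_load`.  For ``mu = 0`` this returns exactly ``1/n``
    for every ``x`` and ``c``: density-independent dispersal rate has no
    effect on the threshold (the relatedness and kin-competition effects
    of viscosity cancel).
    """
    n, c = demog.n, demog.c
    x, mu = regime.mean_rate, regime.density_slope
    if mu == 0.0:
        return 1.0 / n
    denom = n * x * (2.0 - (1.0 + c) * x) + (1.0 - (1.0 + c) * x) * mu
    if denom == 0.0:
        raise DegenerateError(
            f"explicit potential undefined at x={x}, mu={mu}, n={n}, c={c}"
        )
    return 1.0 / n + (n - 1) / n * (1.0 - (1.0 + c) * x) * mu / denom


def hamilton_margin(
    effects: SocialEffects, demog: Demography, regime: DispersalRegime
) -> float:
    """Signed left-hand side of the condition for altruism to be favoured.

    -C(1-cx) + B(1-cx)r - (1-x-mu)[(1-x)/(1-cx)](B-C)r - mu c (B-C)r

    Positive exactly when C/B lies below :func:`potential_explicit`.
    The four terms are: the actor's own survival cost, the benefit to
    patch mates weighted by relatedness, the kin-competition cost of the
    extra local survivors, and the dispersal-mortality cost of the extra
    dispersers.
    """
    B, C = effects.benefit, effects.cost
    c = demog.c
    x, mu = regime.mean_rate, regime.density_slope
    _check_denominator(c, x)
    r = relatedness(demog, x)
    return (
        -C * (1.0 - c * x)
        + B * (1.0 - c * x) * r
        - (1.0 - x - mu) * (1.0 - x) / (1.0 - c * x) * (B - C) * r
        - mu * c * (B - C) * r
    )


def optimal_dispersal_rate(demog: Demography) -> float:
    """ESS population mean dispersal rate.

    xbar* = 2 / (1 + 2 c n + sqrt(1 + 4 c^2 n (n - 1))),

    subject to the guard r > c (r evaluated at the ESS itself); returns
    0 when the guard fails, which only happens at c = 1.  At n = 1 this
    is 1/(1 + c); at c = 0 it is 1.
    """
    n, c = demog.n, demog.c
    xs = 2.0 / (1.0 + 2.0 * c * n + math.sqrt(1.0 + 4.0 * c * c * n * (n - 1)))
    if relatedness(demog, xs) <= c:
        return 0.0
    return xs


def optimal_dispersal_at_density(P: float, demog: Demography) -> float:
    """ESS dispersal probability for an individual at relative density P.

    x*_P = clamp(1 - (1 - xbar*)/P, 0, 1): the number of non-dispersers a
    patch retains, P (1 - x*_P), is the same for every patch (constant
    non-disperser principle); patches below the quota emit no dispersers.
    """
    if not P > 0.0:
        raise DomainError(f"relative density P must be > 0, got {P!r}")
    xs = optimal_dispersal_rate(demog)
    return min(1.0, max(0.0, 1.0 - (1.0 - xs) / P))


def optimal_density_slope(demog: Demography) -> float:
    """Slope of the ESS dispersal norm at unit density: mu* = 1 - xbar*."""
    return 1.0 - optimal_dispersal_rate(demog)


def potential_under_optimal_dispersal(demog: Demography) -> float:
    """Potential for altruism when dispersal sits at its density-dependent ESS.

    Evaluates both algebraic forms,

        A = (1 - c xbar*) / (1 + ((n-1)(2 - (1+c) xbar*) - c) xbar*)
        A = (r - c^2) / (1 - c^2),

    asserts their agreement to 1e-10 (guarding against transcription
    errors), and returns the first.  Exceeds 1/n for all 0 < c < 1 and
    n > 1: with optimal density-dependent dispersal, viscosity promotes
    altruism.
    """
    n, c = demog.n, demog.c
    xs = optimal_dispersal_rate(demog)
    a_form = (1.0 - c * xs) / (
        1.0 + ((n - 1) * (2.0 - (1.0 + c) * xs) - c) * xs
    )
    if c >= 1.0:
        return a_form
    r = relatedness(demog, xs)
    r_form = (r - c * c) / (1.0 - c * c)
    if abs(a_form - r_form) > _IDENTITY_TOL:
        raise ConsistencyError(
            f"optimal-dispersal potential forms disagree: {a_form!r} vs "
            f"{r_form!r} at n={n}, c={c}"
        )
    return a_form


def summarize(
    demog: Demography,
    regime: DispersalRegime | None = None,
    P: float = 1.0,
) -> AnalyticSummary:
    """Evaluate every derived quantity at one parameter point.

    When ``regime`` is None the population is placed at its dispersal ESS
    (mean rate xbar*, slope 1 - xbar*).
    """
    if regime is None:
        xs = optimal_dispersal_rate(demog)
        regime = DispersalRegime(mean_rate=xs, density_slope=1.0 - xs)
    return AnalyticSummary(
        relatedness=relatedness(demog, regime.mean_rate),
        scale_of_competition=scale_of_competition(regime, demog.c),
        mortality_load=mortality_load(regime, demog.c),
        potential=potential_explicit(demog, regime),
        optimal_mean_dispersal=optimal_dispersal_rate(demog),
        optimal_dispersal_at_P=optimal_dispersal_at_density(P, demog),
        relative_density=P,
    )
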