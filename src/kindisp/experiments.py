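"""Computational experiments: threshold estimation, parameter sweep, test.

The headline experiment runs one simulation per (n, c) cell of a grid,
records the evolved dispersal rate at unit density, estimates each
population's potential for altruism by bisecting on the cost-to-benefit
ratio, and tests the association between the two with a Monte Carlo
randomization test.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from . import analytics
from .analytics import Demography, SocialEffects
from .errors import DomainError, InconclusiveBracketError
from .simulator import SimConfig, run_simulation
from typing import Callable, Sequence

__all__ = [
    "ExperimentSettings",
    "PotentialEstimate",
    "SweepRecord",
    "RandomizationResult",
    "cell_seed",
    "estimate_potential",
    "run_sweep",
    "permutation_test",
    "figure1d_pipeline",
]

DEFAULT_NS = (1, 2, 3, 5, 10)
DEFAULT_CS = (0.0, 0.2, 0.4, 0.6, 0.8)

#: published-scale population: 5e4 breeders, 2e4 generations (behind --full)
FULL_SCALE = dict(total_breeders=50_000, generations=20_000, burn_in=8000)


@dataclass(frozen=True)
class ExperimentSettings:
    """Scaled-down defaults that keep the full pipeline desk-runnable.

    When ``total_breeders`` is set, the patch count per grid cell is
    ``max(50, total_breeders // n)`` so every cell carries the same
    breeding population (equal drift and equal cost across patch sizes);
    otherwise ``num_patches`` applies as-is.
    """

    num_patches: int = 500
    total_breeders: int | None = None
    generations: int = 2000
    burn_in: int = 800
    k: int = 10
    benefit: float = 0.1
    baseline: float = 0.8
    mutation_prob: float = 0.01
    mutation_sd: float = 0.03
    P_lo: float = 0.8
    P_hi: float = 1.2
    bisection_depth: int = 4
    replicates: int = 3
    ambiguity: float = 0.04
    freeze_dispersal: bool = False
    master_seed: int = 0
    # overrides for the dedicated dispersal-evolution runs; the ESS of the
    # reaction norm equilibrates more slowly than the direction of
    # selection on altruism, so those runs get more time and variance
    ess_generations: int | None = None
    ess_burn_in: int | None = None
    ess_mutation_prob: float | None = None
    # start threshold-direction runs from a dispersal strategy evolved in a
    # dedicated simulation (altruism frozen), so the classified selection
    # direction reflects the dispersal ESS rather than the transient from
    # a flat initial norm
    pre_evolve: bool = True

    def patches_for(self, n: int) -> int:
        if self.total_breeders is not None:
            return max(50, self.total_breeders // n)
        return self.num_patches

    def sim_config(self, n: int, c: float, cost: float, seed: int) -> SimConfig:
        return SimConfig(
            demog=Demography(n=n, c=c, k=self.k),
            effects=SocialEffects(
                benefit=self.benefit, cost=cost, baseline=self.baseline
            ),
            num_patches=self.patches_for(n),
            generations=self.generations,
            burn_in=self.burn_in,
            mutation_prob=self.mutation_prob,
            mutation_sd=self.mutation_sd,
            P_lo=self.P_lo,
            P_hi=self.P_hi,
            seed=seed,
            freeze_dispersal=self.freeze_dispersal,
        )

    def at_full_scale(self) -> "ExperimentSettings":
        return dataclasses.replace(
            self,
            total_breeders=FULL_SCALE["total_breeders"],
            generations=FULL_SCALE["generations"],
            burn_in=FULL_SCALE["burn_in"],
        )


@dataclass(frozen=True)
class PotentialEstimate:
    n: int
    c: float
    A_hat: float
    resolution: float
    runs_used: int
    seed: int


@dataclass(frozen=True)
class SweepRecord:
    n: int
    c: float
    x_hat: float          # evolved mean dispersal at unit density
    mu_hat: float         # evolved reaction-norm slope at unit density
    A_hat: float
    analytic_x_star: float
    analytic_A: float
    seed: int


@dataclass(frozen=True)
class RandomizationResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int
    tail: str = "negative"


def cell_seed(master_seed: int, n: int, c: float, salt: int = 0) -> int:
    """Deterministic per-cell seed, independent across grid cells."""
    mask = (1 << 63) - 1  # SeedSequence entropy must be non-negative
    ss = np.random.SeedSequence(
        entropy=(
            int(master_seed) & mask,
            int(n) & mask,
            int(round(c * 1000)) & mask,
            int(salt) & mask,
        )
    )
    return int(ss.generate_state(1, np.uint64)[0])


def _selection_direction(
    n: int,
    c: float,
    ratio: float,
    settings: ExperimentSettings,
    seed: int,
    norm_init: tuple[float, float] | None = None,
) -> float:
    """Signed strength of selection on altruism at cost ratio C/B.

    Runs one simulation with altruism initialized at 0.5 (and, when given,
    the dispersal norm initialized from a previously evolved strategy but
    still co-evolving) and returns the post-burn-in time average of
    (mean y - 0.5).
    """
    cost = max(ratio * settings.benefit, 1e-12)
    config = settings.sim_config(n, c, cost, seed)
    if norm_init is not None:
        config = dataclasses.replace(
            config, init_norm_lo=norm_init[0], init_norm_hi=norm_init[1]
        )
    result = run_simulation(config)
    return result.mean_of("mean_altruism") - config.init_altruism


def _evolve_dispersal_state(
    n: int, c: float, settings: ExperimentSettings, seed: int
) -> tuple[float, float, tuple[float, float]]:
    """Dispersal-only evolution; returns (x̂(1), μ̂, evolved norm loci)."""
    config = dataclasses.replace(
        settings.sim_config(n, c, cost=1e-9, seed=seed),
        freeze_altruism=True,
        generations=settings.ess_generations or settings.generations,
        burn_in=(
            settings.ess_burn_in
            if settings.ess_burn_in is not None
            else settings.burn_in
        ),
        mutation_prob=(
            settings.ess_mutation_prob
            if settings.ess_mutation_prob is not None
            else settings.mutation_prob
        ),
    )
    result = run_simulation(config)
    lo = min(1.0, max(0.0, result.mean_of("mean_norm_lo")))
    hi = min(1.0, max(0.0, result.mean_of("mean_norm_hi")))
    return (
        result.mean_of("x_at_unit_density"),
        result.mean_of("mu_hat"),
        (lo, hi),
    )


def estimate_potential(
    n: int,
    c: float,
    settings: ExperimentSettings,
    *,
    seed: int | None = None,
    check_bracket: bool = False,
    direction: Callable[..., float] | None = None,
    norm_init: tuple[float, float] | None = None,
) -> PotentialEstimate:
    """Bisect on the cost-to-benefit ratio for the selection threshold.

    At each candidate ratio the direction of selection on altruism is
    classified from one simulation; when the post-burn-in displacement of
    mean altruism is smaller than ``settings.ambiguity`` the cell is
    replicated (up to ``settings.replicates`` runs) and majority-voted.
    The returned ``A_hat`` is the midpoint of the final bracket.

    With ``settings.pre_evolve`` (and no explicit ``norm_init``), dispersal
    is first evolved in a dedicated run and every direction run starts
    from that strategy, so the threshold is measured at the dispersal ESS
    rather than during the transient from a flat norm.
    """
    if settings.bisection_depth < 4:
        raise DomainError("bisection_depth must be >= 4")
    if seed is None:
        seed = cell_seed(settings.master_seed, n, c)
    classify = direction or _selection_direction
    runs = 0
    if norm_init is None and settings.pre_evolve and direction is None:
        runs += 1
        _, _, norm_init = _evolve_dispersal_state(
            n, c, settings, seed + 31
        )

    def vote(ratio: float) -> float:
        nonlocal runs
        votes = []
        for rep in range(settings.replicates):
            runs += 1
            d = classify(
                n, c, ratio, settings, seed + 7919 * (rep + runs),
                norm_init=norm_init,
            )
            votes.append(d)
            if abs(d) >= settings.ambiguity:
                break
        return float(np.sign(sum(np.sign(v) for v in votes))) or -1.0

    lo, hi = 0.0, 1.0
    if check_bracket:
        d_lo, d_hi = vote(lo), vote(hi)
        if d_lo == d_hi:
            raise InconclusiveBracketError(
                f"selection direction identical ({d_lo:+.0f}) at "
                f"C/B = 0 and C/B = 1 for n={n}, c={c}"
            )
    for _ in range(settings.bisection_depth):
        mid = 0.5 * (lo + hi)
        if vote(mid) > 0:   # altruism still favoured: threshold is higher
            lo = mid
        else:
            hi = mid
    return PotentialEstimate(
        n=n,
        c=c,
        A_hat=0.5 * (lo + hi),
        resolution=0.5 * (hi - lo),
        runs_used=runs,
        seed=seed,
    )


def evolve_dispersal(
    n: int, c: float, settings: ExperimentSettings, seed: int
) -> tuple[float, float]:
    """One simulation with altruism frozen; returns evolved (x̂(1), μ̂)."""
    x_hat, mu_hat, _ = _evolve_dispersal_state(n, c, settings, seed)
    return x_hat, mu_hat


def run_sweep(
    ns: Sequence[int] = DEFAULT_NS,
    cs: Sequence[float] = DEFAULT_CS,
    settings: ExperimentSettings | None = None,
) -> list[SweepRecord]:
    """One SweepRecord per (n, c) cell of the grid.

    Per-cell seeds derive deterministically from the master seed so cells
    are independent and individually reproducible.
    """
    settings = settings or ExperimentSettings()
    records = []
    for n in ns:
        for c in cs:
            seed = cell_seed(settings.master_seed, n, c)
            try:
                x_hat, mu_hat, norms = _evolve_dispersal_state(
                    n, c, settings, seed
                )
                est = estimate_potential(
                    n, c, settings, seed=seed + 1, norm_init=norms
                )
            except Exception as exc:  # annotate with cell identity
                raise type(exc)(f"sweep cell n={n}, c={c}: {exc}") from exc
            demog = Demography(n=n, c=c)
            records.append(
                SweepRecord(
                    n=n,
                    c=c,
                    x_hat=x_hat,
                    mu_hat=mu_hat,
                    A_hat=est.A_hat,
                    analytic_x_star=analytics.optimal_dispersal_rate(demog),
                    analytic_A=analytics.potential_under_optimal_dispersal(
                        demog
                    ),
                    seed=seed,
                )
            )
    return records


def permutation_test(
    x_values: Sequence[float],
    A_values: Sequence[float],
    n_permutations: int = 100_000,
    seed: int = 0,
    strata: Sequence[int] | None = None,
) -> RandomizationResult:
    """One-tailed Monte Carlo randomization test for negative association.

    Unstratified (default): the statistic is the Pearson correlation of
    (x, A) and the null shuffles A against fixed x.

    Stratified: ``strata`` labels each point (e.g. by patch size); the
    statistic is the mean of within-stratum Pearson correlations over the
    strata where both variables vary, and the null shuffles A only within
    strata.  This is the appropriate reading of a negative
    dispersal-altruism relationship that holds within each patch size:
    pooling across patch sizes confounds it with the joint decline of
    both quantities in patch size.

    p = (1 + #{stat_perm <= stat_obs}) / (n_permutations + 1), never
    smaller than 1/(n_permutations + 1).
    """
    x = np.asarray(x_values, dtype=float)
    A = np.asarray(A_values, dtype=float)
    if x.shape != A.shape or x.ndim != 1 or x.size < 3:
        raise DomainError("need two equal-length 1-d samples of >= 3 points")
    if np.ptp(x) == 0.0 or np.ptp(A) == 0.0:
        raise DomainError(
            "degenerate variance: a constant sample has no correlation"
        )
    rng = np.random.default_rng(seed)

    if strata is None:
        groups = [np.arange(x.size)]
    else:
        labels = np.asarray(strata)
        if labels.shape != x.shape:
            raise DomainError("strata must label every point")
        groups = [np.flatnonzero(labels == v) for v in np.unique(labels)]
    # keep strata where the correlation is defined (>= 3 points, both
    # variables non-constant); the A multiset per stratum is permutation-
    # invariant, so this selection does not depend on the shuffle
    groups = [
        g for g in groups
        if g.size >= 3 and np.ptp(x[g]) > 0.0 and np.ptp(A[g]) > 0.0
    ]
    if not groups:
        raise DomainError("no stratum with variation in both variables")

    # standardize x and A within each stratum so each within-stratum
    # correlation is a plain dot product
    def standardize(v, g):
        s = v[g]
        return (s - s.mean()) / (s.std() * math.sqrt(s.size))

    xc = [standardize(x, g) for g in groups]
    Ac = [standardize(A, g) for g in groups]
    stat_obs = float(np.mean([xg @ Ag for xg, Ag in zip(xc, Ac)]))

    hits = 0
    chunk = 20_000
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        stat_perm = np.zeros(m)
        for xg, Ag in zip(xc, Ac):
            perms = rng.permuted(np.tile(Ag, (m, 1)), axis=1)
            stat_perm += perms @ xg
        stat_perm /= len(groups)
        hits += int((stat_perm <= stat_obs + 1e-15).sum())
        done += m
    return RandomizationResult(
        statistic=stat_obs,
        p_value=(1 + hits) / (n_permutations + 1),
        n_permutations=n_permutations,
        seed=seed,
    )


@dataclass
class Figure1dResult:
    records: list[SweepRecord]
    test: RandomizationResult
    settings: ExperimentSettings = field(default_factory=ExperimentSettings)


def figure1d_pipeline(
    settings: ExperimentSettings | None = None,
    ns: Sequence[int] = DEFAULT_NS,
    cs: Sequence[float] = DEFAULT_CS,
    n_permutations: int = 100_000,
) -> Figure1dResult:
    """Sweep the grid and test the (x̂(1), Â) association.

    Emits one row per cell with the analytic overlay columns plus the
    randomization-test summary for the negative dispersal-altruism
    relationship.
    """
    settings = settings or ExperimentSettings()
    records = run_sweep(ns, cs, settings)
    # the potential for altruism declines with the dispersal rate *within*
    # each patch size (for n > 1; at n = 1 the potential is identically 1):
    # test the within-patch-size association, permuting within strata
    tested = [r for r in records if r.n > 1] or records
    test = permutation_test(
        [r.x_hat for r in tested],
        [r.A_hat for r in tested],
        n_permutations=n_permutations,
        seed=cell_seed(settings.master_seed, 0, -1.0),
        strata=[r.n for r in tested],
    )
    return Figure1dResult(records=records, test=test, settings=settings)
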