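"""Synthetic cross-experiment and sequence-pair generators.

The cross generator emulates the study design it is meant to stand in
for: seven populations with a fixed COI distance matrix, all 42 ordered
interpopulation crosses plus 7 intra-population controls, and 16
backcross types using F1 hybrid dams.  Mechanism: the species is
arrhenotokous, so each egg is either left unfertilized (developing into a
haploid son) or fertilized (a diploid, female-destined egg that may die
before adulthood).  Both the fertilization-failure probability and the
diploid death probability follow logistic curves in the genetic distance
gd between the two parental populations:

    m(gd) = expit(a_pre + b_pre * gd)      fertilization failure
    v(gd) = expit(a_inv + b_inv * gd)      diploid death
    s(gd) = expit(a_ster + b_ster * gd)    backcross offspring death

Per-female counts are beta-binomial with correlation ``rho``, so
aggregated combination counts are overdispersed relative to binomial —
the property the quasibinomial analysis exists to absorb.  With the
default parameters the logistic curves match the published barrier
models, controls sit at the curves' gd = 0 levels, and combination totals
land in the hundreds of eggs (12-30 replicate pairs laying ~40 eggs each
over the 5-day oviposition window).

A separate helper evolves sequence pairs under the continuous-time K2P
substitution process for testing the distance estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .cross_data import CrossRecord, DistanceMatrix, split_dam_code, table2_fixture

#: the study's 16 backcross types: F1 hybrid dam codes, mother label first
DEFAULT_BACKCROSS_DAMS = (
    "FT", "FI", "FJ", "TF", "TI", "IF", "IT",
    "CIMCN", "CIMK", "CNCIM", "CNK", "KCIM", "KCN",
    "JF", "JCIM", "JCN",
)


@dataclass(frozen=True)
class BarrierParams:
    """Logistic barrier curve: logit(prob) = intercept + slope * gd."""

    intercept: float
    slope: float

    def prob(self, gd: float) -> float:
        return float(expit(self.intercept + self.slope * gd))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults for the cross generator.

    Barrier parameters default to the published gd-only model
    coefficients; replication and fecundity reflect the study's stated
    ranges (12-30 pairs per parental combination, 10-32 per backcross,
    a 5-day oviposition window).  ``rho`` is the within-brood
    beta-binomial correlation generating overdispersion;
    ``hatch_fraction`` splits diploid deaths into dead juveniles
    (hatched) vs unhatched eggs and is an arbitrary convention, since
    only the sum enters any barrier index.
    """

    distances: DistanceMatrix = field(default_factory=table2_fixture)
    prezygotic: BarrierParams = BarrierParams(-1.453, 12.728)
    inviability: BarrierParams = BarrierParams(-1.337, 39.450)
    sterility: BarrierParams = BarrierParams(-1.308, 54.552)
    rho: float = 0.1
    fecundity_mean: float = 40.0
    n_pairs: int | tuple[int, int] = (12, 30)
    n_pairs_backcross: int | tuple[int, int] = (10, 32)
    hatch_fraction: float = 0.7
    male_background_mortality: float = 0.0
    hybrid_male_viability: float = 0.0
    backcross_dams: tuple[str, ...] = DEFAULT_BACKCROSS_DAMS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        if self.fecundity_mean <= 0:
            raise ValueError("fecundity_mean must be positive")
        for p in (self.hatch_fraction, self.male_background_mortality,
                  self.hybrid_male_viability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for np_ in (self.n_pairs, self.n_pairs_backcross):
            lo = np_ if isinstance(np_, int) else np_[0]
            if lo < 1:
                raise ValueError("n_pairs must be >= 1")


def _draw_pairs(setting: int | tuple[int, int], rng: np.random.Generator) -> int:
    if isinstance(setting, int):
        return setting
    lo, hi = setting
    return int(rng.integers(lo, hi + 1))


def beta_binomial(
    n: np.ndarray, m: float, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Beta-binomial draws with mean ``m`` and intra-unit correlation ``rho``.

    rho = 0 degenerates to plain binomial; means 0 or 1 are
    deterministic.  Variance is inflated over binomial by 1 + (n-1) rho.
    """
    n = np.asarray(n)
    if m <= 0.0:
        return np.zeros_like(n)
    if m >= 1.0:
        return n.copy()
    if rho == 0.0:
        return rng.binomial(n, m)
    a = m * (1.0 - rho) / rho
    b = (1.0 - m) * (1.0 - rho) / rho
    p = rng.beta(a, b, size=n.shape)
    return rng.binomial(n, p)


def _assemble(
    female_pop: str, male_pop: str, cross_class: str, dam_code: str,
    n_pairs: int, eggs, sons, daughters, unhatched, dead_juv,
) -> CrossRecord:
    return CrossRecord(
        female_pop=female_pop, male_pop=male_pop, cross_class=cross_class,
        dam_code=dam_code, n_pairs=n_pairs,
        eggs=int(np.sum(eggs)), sons=int(np.sum(sons)),
        daughters=int(np.sum(daughters)), unhatched=int(np.sum(unhatched)),
        dead_juv=int(np.sum(dead_juv)),
    )


def simulate_cross(
    female_pop: str, male_pop: str, gd: float,
    cfg: SimulationConfig, rng: np.random.Generator,
) -> CrossRecord:
    """One parental cross combination, aggregated over replicate pairs.

    Per female: eggs ~ Poisson(fecundity_mean); unfertilized (son) count
    beta-binomial at m(gd); each fertilized egg dies with probability
    v(gd) (beta-binomial across the brood), split into unhatched vs dead
    juvenile by the hatch fraction; survivors are daughters.
    """
    npairs = _draw_pairs(cfg.n_pairs, rng)
    eggs = rng.poisson(cfg.fecundity_mean, size=npairs)
    eggs = np.maximum(eggs, 1)  # an ovipositing female contributes >= 1 egg
    m = cfg.prezygotic.prob(gd)
    v = cfg.inviability.prob(gd)
    sons_u = beta_binomial(eggs, m, cfg.rho, rng)
    fert = eggs - sons_u
    deaths = beta_binomial(fert, v, cfg.rho, rng)
    dead_juv = rng.binomial(deaths, cfg.hatch_fraction)
    unhatched = deaths - dead_juv
    daughters = fert - deaths
    dead_sons = rng.binomial(sons_u, cfg.male_background_mortality)
    sons = sons_u - dead_sons
    cross_class = "control" if female_pop == male_pop else "interpopulation"
    return _assemble(female_pop, male_pop, cross_class, "", npairs,
                     eggs, sons, daughters, unhatched, dead_juv + dead_sons)


def simulate_backcross(
    dam_code: str, gd: float, cfg: SimulationConfig, rng: np.random.Generator,
) -> CrossRecord:
    """One backcross type: F1 hybrid dams crossed to males of the sire population.

    ``gd`` is the distance between the dam's two parental populations.
    Each egg dies with probability s(gd); surviving unfertilized eggs
    become sons only with the hybrid-male viability factor (default 0 for
    genetically distinct parents — hybrid males are hardly viable — and 1
    when the parents are genetically identical); inviable sons are
    recorded as dead juveniles.
    """
    mother, father = split_dam_code(dam_code, cfg.distances.labels)
    npairs = _draw_pairs(cfg.n_pairs_backcross, rng)
    eggs = rng.poisson(cfg.fecundity_mean, size=npairs)
    eggs = np.maximum(eggs, 1)
    s = cfg.sterility.prob(gd)
    deaths = beta_binomial(eggs, s, cfg.rho, rng)
    survivors = eggs - deaths
    m0 = cfg.prezygotic.prob(0.0)  # dam x parental male: control-level fertilization
    sons_u = beta_binomial(survivors, m0, cfg.rho, rng)
    viability = cfg.hybrid_male_viability if gd > 0 else 1.0
    sons = rng.binomial(sons_u, viability)
    inviable_sons = sons_u - sons
    daughters = survivors - sons_u
    dead_juv = rng.binomial(deaths, cfg.hatch_fraction) + inviable_sons
    unhatched = eggs - sons - daughters - dead_juv
    return _assemble(dam_code, father, "backcross", dam_code, npairs,
                     eggs, sons, daughters, unhatched, dead_juv)


def simulate_study(cfg: SimulationConfig | None = None) -> list[CrossRecord]:
    """Full study-layout dataset.

    Defaults produce 49 parental records (7 controls + 42 ordered
    interpopulation combinations over the fixture distance matrix) and 16
    backcross records, in a deterministic order given ``cfg.seed``.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    labels = cfg.distances.labels
    records: list[CrossRecord] = []
    for f in labels:
        records.append(simulate_cross(f, f, 0.0, cfg, rng))
    for f in labels:
        for m_ in labels:
            if f == m_:
                continue
            records.append(simulate_cross(f, m_, cfg.distances.lookup(f, m_), cfg, rng))
    for dam in cfg.backcross_dams:
        mo, fa = split_dam_code(dam, labels)
        records.append(simulate_backcross(dam, cfg.distances.lookup(mo, fa), cfg, rng))
    return records


def with_barriers(cfg: SimulationConfig, **kwargs: BarrierParams) -> SimulationConfig:
    """Convenience: return a config with selected barrier curves replaced."""
    return replace(cfg, **kwargs)


# ---------------------------------------------------------------------------
# K2P sequence-pair evolution


def _k2p_event_probs(alpha_ts: float, beta_tv: float, t: float) -> tuple[float, float, float]:
    """(same, transition, each-transversion) probabilities after divergence t."""
    e4 = np.exp(-4.0 * beta_tv * t)
    e2 = np.exp(-2.0 * (alpha_ts + beta_tv) * t)
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e4
    return 1.0 - p_ts - 2.0 * p_tv, p_ts, p_tv


def _mutate(idx: np.ndarray, alpha_ts: float, beta_tv: float, t: float,
            rng: np.random.Generator) -> np.ndarray:
    p_same, p_ts, p_tv = _k2p_event_probs(alpha_ts, beta_tv, t)
    u = rng.random(idx.shape[0])
    event = np.searchsorted(np.cumsum([p_same, p_ts, p_tv]), u, side="right")
    out = idx.copy()
    out[event == 1] = idx[event == 1] ^ 2            # A<->G, C<->T
    out[event == 2] = (idx[event == 2] + 1) % 4
    out[event == 3] = (idx[event == 3] + 3) % 4
    return out


def evolve_k2p_pair(
    length: int, alpha_ts: float, beta_tv: float, t: float,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Evolve a sequence pair separated by total time ``t`` under K2P.

    ``alpha_ts`` is the instantaneous transition rate, ``beta_tv`` the
    rate to *each* of the two transversion targets, so the expected
    distance is (alpha_ts + 2 beta_tv) * t.  One end is drawn uniform over
    {A,C,G,T}; the other per site from the closed-form K2P transition
    probabilities at divergence t (the process is reversible with uniform
    stationary distribution, so this equals evolving both ends from a
    common ancestor for t/2 each).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if alpha_ts < 0 or beta_tv < 0 or t < 0:
        raise ValueError("rates and time must be non-negative")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    a = rng.integers(0, 4, size=length)
    b = _mutate(a, alpha_ts, beta_tv, t, rng)
    return bases[a].tobytes().decode(), bases[b].tobytes().decode()


def evolve_star_alignment(
    dist: DistanceMatrix, length: int, alpha_ts: float, beta_tv: float,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Evolve one sequence per population on a star phylogeny.

    Each tip descends from a common ancestral sequence along a branch of
    length t_i = (mean distance of population i to the others) / 2 /
    (alpha_ts + 2 beta_tv), so pairwise expected distances only roughly
    emulate the target matrix (a star tree cannot reproduce an arbitrary
    matrix exactly).  A testing/demo aid, not a coalescent simulation.
    """
    rate = alpha_ts + 2.0 * beta_tv
    bases = np.frombuffer(b"ACGT", dtype="S1")
    ancestor = rng.integers(0, 4, size=length)
    n = len(dist.labels)
    out: dict[str, str] = {}
    for i, lab in enumerate(dist.labels):
        mean_d = float(np.sum(dist.d[i])) / max(n - 1, 1)
        t_i = mean_d / 2.0 / rate if rate > 0 else 0.0
        tip = _mutate(ancestor, alpha_ts, beta_tv, t_i, rng)
        out[lab] = bases[tip].tobytes().decode()
    return out
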