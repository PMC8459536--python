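"""Reproductive-isolation indices from offspring counts.

In an arrhenotokous (haplodiploid) species, males develop from unfertilized
eggs and females from fertilized eggs, so the offspring sex ratio exposes
post-mating fertilization failure directly.  Four barrier measures are
computed per cross combination, each as a count pair (k, n):

* prezygotic      — sons / eggs (lack of fertilization)
* inviability     — (unhatched + dead juveniles) / (eggs - sons)
                    (mortality among fertilized, female-destined offspring)
* total           — 1 - daughters / eggs (parental crosses; equals
                    prezygotic + (1 - prezygotic) * inviability exactly)
* sterility       — (unhatched + dead juveniles) / eggs in backcrosses of
                    F1 hybrid females (a slight overestimate because
                    background mortality is not subtracted)

Inviability is undefined for an all-male brood (eggs == sons, a 0/0
ratio); such records are excluded from the inviability model with a
logged warning rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .cross_data import CrossRecord, DistanceMatrix, split_dam_code

logger = logging.getLogger(__name__)

BARRIERS = ("prezygotic", "inviability", "total", "sterility")


@dataclass(frozen=True)
class BarrierObservation:
    """One (k successes, n trials) unit feeding a barrier GLM.

    ``female_pop`` is the maternal population for parental crosses and the
    hybrid dam code for backcrosses; ``gd`` the genetic distance driving
    the barrier (0 for controls).
    """

    barrier: str
    k: int
    n: int
    gd: float
    female_pop: str

    def __post_init__(self) -> None:
        if self.barrier not in BARRIERS:
            raise ValueError(f"unknown barrier {self.barrier!r}")
        if not (0 <= self.k <= self.n):
            raise ValueError(f"need 0 <= k <= n, got k={self.k}, n={self.n}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.gd < 0:
            raise ValueError("genetic distance must be >= 0")

    @property
    def proportion(self) -> float:
        return self.k / self.n


def _parental_only(rec: CrossRecord, what: str) -> None:
    if rec.cross_class == "backcross":
        raise ValueError(f"{what} is defined for parental crosses, not backcrosses")


def prezygotic(rec: CrossRecord, gd: float = 0.0) -> BarrierObservation:
    """Lack-of-fertilization index: sons / eggs."""
    _parental_only(rec, "prezygotic isolation")
    return BarrierObservation("prezygotic", rec.sons, rec.eggs, gd, rec.female_pop)


def inviability(rec: CrossRecord, gd: float = 0.0) -> Optional[BarrierObservation]:
    """Diploid-offspring mortality: (unhatched + dead_juv) / (eggs - sons).

    Returns ``None`` (with a warning) for all-male broods, where the
    denominator is zero and the index is a 0/0 form.
    """
    _parental_only(rec, "hybrid inviability")
    n = rec.eggs - rec.sons
    if n == 0:
        logger.warning(
            "inviability undefined for all-male brood %s x %s (eggs == sons == %d); "
            "record excluded",
            rec.female_pop, rec.male_pop, rec.eggs,
        )
        return None
    return BarrierObservation(
        "inviability", rec.unhatched + rec.dead_juv, n, gd, rec.female_pop
    )


def total_isolation(rec: CrossRecord, gd: float = 0.0) -> BarrierObservation:
    """Total barrier in parental crosses: 1 - daughters / eggs.

    By the accounting identity k = eggs - daughters equals
    sons + unhatched + dead_juv, so this composes the prezygotic and
    inviability stages exactly.
    """
    _parental_only(rec, "total isolation")
    return BarrierObservation(
        "total", rec.eggs - rec.daughters, rec.eggs, gd, rec.female_pop
    )


def sterility(rec: CrossRecord, gd: float = 0.0) -> BarrierObservation:
    """Hybrid-female sterility index: (unhatched + dead_juv) / eggs.

    Defined for backcrosses of F1 hybrid females, and for intra-population
    controls when these are included in the sterility model.  No background
    mortality is subtracted (see :func:`correct_background` for an
    explicitly non-standard corrected variant).
    """
    if rec.cross_class == "interpopulation":
        raise ValueError("sterility is defined for backcrosses and controls only")
    who = rec.dam_code if rec.cross_class == "backcross" else rec.female_pop
    return BarrierObservation(
        "sterility", rec.unhatched + rec.dead_juv, rec.eggs, gd, who
    )


def correct_background(obs: BarrierObservation, rate: float) -> BarrierObservation:
    """Background-mortality-corrected variant of a sterility observation.

    Subtracts an expected ``rate * n`` background deaths from k (floored at
    zero).  This correction is NOT part of the published analysis, which
    deliberately reports the uncorrected overestimate; it is offered as an
    opt-in extension only.
    """
    if not 0 <= rate < 1:
        raise ValueError("background rate must be in [0, 1)")
    k = max(0, obs.k - round(rate * obs.n))
    return BarrierObservation(obs.barrier, k, obs.n, obs.gd, obs.female_pop)


def record_gd(rec: CrossRecord, dist: DistanceMatrix) -> float:
    """Genetic distance relevant to a record's barrier response.

    Controls: 0.  Interpopulation crosses: distance between the two
    parental populations.  Backcrosses: distance between the hybrid dam's
    two parental populations (her degree of hybridity), 0 for dams whose
    parents are genetically identical.
    """
    if rec.cross_class == "control":
        return 0.0
    if rec.cross_class == "backcross":
        mother, father = split_dam_code(rec.dam_code, dist.labels)
        return dist.lookup(mother, father)
    return dist.lookup(rec.female_pop, rec.male_pop)


def observations(
    records: Iterable[CrossRecord],
    dist: DistanceMatrix,
    barrier: str,
    include_controls_in_sterility: bool = True,
) -> list[BarrierObservation]:
    """Build the observation set for one barrier model.

    prezygotic / inviability / total use parental (control +
    interpopulation) records; sterility uses backcrosses plus, by default,
    the intra-population controls.  Undefined inviability records are
    dropped (warned).
    """
    if barrier not in BARRIERS:
        raise ValueError(f"unknown barrier {barrier!r}")
    out: list[BarrierObservation] = []
    for rec in records:
        if barrier == "sterility":
            if rec.cross_class == "interpopulation":
                continue
            if rec.cross_class == "control" and not include_controls_in_sterility:
                continue
            out.append(sterility(rec, record_gd(rec, dist)))
            continue
        if rec.cross_class == "backcross":
            continue
        gd = record_gd(rec, dist)
        if barrier == "prezygotic":
            out.append(prezygotic(rec, gd))
        elif barrier == "total":
            out.append(total_isolation(rec, gd))
        else:
            obs = inviability(rec, gd)
            if obs is not None:
                out.append(obs)
    return out


def indices_table(
    records: Sequence[CrossRecord], dist: DistanceMatrix
) -> pd.DataFrame:
    """Tidy table: one row per (combination, barrier) with k, n, proportion."""
    rows = []
    for rec in records:
        gd = record_gd(rec, dist)
        if rec.cross_class == "backcross":
            obs_list = [sterility(rec, gd)]
        else:
            obs_list = [prezygotic(rec, gd), total_isolation(rec, gd),
                        sterility(rec, gd) if rec.cross_class == "control" else None,
                        inviability(rec, gd)]
        for obs in obs_list:
            if obs is None:
                continue
            rows.append({
                "barrier": obs.barrier,
                "female_pop": obs.female_pop,
                "male_pop": rec.male_pop,
                "cross_class": rec.cross_class,
                "gd": obs.gd,
                "k": obs.k,
                "n": obs.n,
                "proportion": obs.proportion,
            })
    return pd.DataFrame(rows)
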