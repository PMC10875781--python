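"""Stochastic generators emulating the drive experiments.

Three generators mirror the wet experiments end to end so every pipeline
stage can be exercised without laboratory data:

* :func:`simulate_assay` — the single-generation threshold assay: mixed
  founder vials across a ladder of starting frequencies, multinomial
  mating, Poisson offspring, complete hybrid inviability.
* :func:`simulate_mate_choice_trial` — the 4-fly first-to-mate assay.
* :func:`simulate_discrete_generations` — a discrete-generation cage
  trial that reseeds each generation at the realized offspring frequency.

:func:`simulate_control_assay` emulates the negative control — two
interfertile wild-type lines whose cross-line offspring survive and
segregate evenly between labels — which the hybrid-lethal generator
cannot represent.

Design presets reproduce the two published vial layouts: ``vial40``
(20 + 20 founders, 19 starting frequencies from 5% to 95% in 5% steps)
and ``bottle120`` (60 + 60 founders, 10% to 90% in 10% steps).  The
default per-female offspring mean of 3.93 corresponds to the measured
wild-type output of 78.6 adults from 20 females per vial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .fitting import AssayRecord
from .matestats import MatingCountTable
from .model import DriveParams, Trajectory

__all__ = [
    "AssayDesign",
    "PRESETS",
    "vial40_design",
    "bottle120_design",
    "simulate_assay",
    "simulate_control_assay",
    "simulate_mate_choice_trial",
    "simulate_discrete_generations",
]

SeedLike = Union[None, int, np.random.Generator]

#: Mean adult offspring per wild-type female per vial: 78.6 adults / 20 females.
DEFAULT_OFFSPRING_PER_FEMALE = 78.6 / 20.0


@dataclass(frozen=True)
class AssayDesign:
    """Layout of a single-generation drive assay.

    ``mean_offspring_per_female`` is the expected adult offspring of one
    wild-type female mated to a wild-type male (EGI x EGI pairs scale it
    by the fecundity ratio F).
    """

    n_males: int
    n_females: int
    starting_frequencies: tuple
    replicates_per_frequency: int = 1
    mean_offspring_per_female: float = DEFAULT_OFFSPRING_PER_FEMALE

    def __post_init__(self) -> None:
        if self.n_males < 1 or self.n_females < 1:
            raise ValueError("need at least one founder of each sex")
        if self.replicates_per_frequency < 1:
            raise ValueError("need at least one replicate per frequency")
        if self.mean_offspring_per_female <= 0:
            raise ValueError("mean offspring per female must be positive")
        freqs = tuple(float(f) for f in self.starting_frequencies)
        if not freqs or any(not 0.0 < f < 1.0 for f in freqs):
            raise ValueError("starting frequencies must lie strictly in (0, 1)")
        object.__setattr__(self, "starting_frequencies", freqs)


def vial40_design(
    replicates_per_frequency: int = 6,
    mean_offspring_per_female: float = DEFAULT_OFFSPRING_PER_FEMALE,
) -> AssayDesign:
    """40-fly vials: 20 males + 20 females, 5% to 95% EGI in 5% steps."""
    return AssayDesign(
        n_males=20,
        n_females=20,
        starting_frequencies=tuple(np.round(np.arange(0.05, 0.96, 0.05), 2)),
        replicates_per_frequency=replicates_per_frequency,
        mean_offspring_per_female=mean_offspring_per_female,
    )


def bottle120_design(
    replicates_per_frequency: int = 3,
    mean_offspring_per_female: float = DEFAULT_OFFSPRING_PER_FEMALE,
) -> AssayDesign:
    """120-fly bottles: 60 males + 60 females, 10% to 90% EGI in 10% steps."""
    return AssayDesign(
        n_males=60,
        n_females=60,
        starting_frequencies=tuple(np.round(np.arange(0.1, 0.91, 0.1), 1)),
        replicates_per_frequency=replicates_per_frequency,
        mean_offspring_per_female=mean_offspring_per_female,
    )


PRESETS = {"vial40": vial40_design, "bottle120": bottle120_design}


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _founder_split(x0: float, n: int) -> int:
    """Nearest-integer number of EGI founders among n of one sex."""
    return int(round(x0 * n))


def _mating_counts_propensity(
    n_matings: int, x: float, c: float, rng: np.random.Generator
) -> tuple:
    """Pair-type counts (ee, ew, we, ww) drawn from the propensity-weighted
    pairing distribution (cx)^2, cx(1-cx), cx(1-cx), (1-cx)^2."""
    cx = c * x
    if cx > 1.0:
        raise ValueError(
            f"c*x = {cx:.4g} > 1: the propensity pairing distribution is not "
            "a probability distribution; the generator cannot realize it"
        )
    probs = [cx * cx, cx * (1 - cx), cx * (1 - cx), (1 - cx) ** 2]
    ee, ew, we, ww = rng.multinomial(n_matings, probs)
    return int(ee), int(ew), int(we), int(ww)


def _mating_counts_preference(
    n_egi_females: int,
    n_wt_females: int,
    x_male: float,
    params: DriveParams,
    rng: np.random.Generator,
) -> tuple:
    """Each female independently chooses a male genotype with probability
    proportional to (pairing weight x male genotype frequency)."""
    ee = ew = we = ww = 0
    d_egi = params.w1 * x_male + params.w2 * (1.0 - x_male)
    if d_egi > 0:
        p = params.w1 * x_male / d_egi
        ee = int(rng.binomial(n_egi_females, p))
        ew = n_egi_females - ee
    d_wt = params.w3 * x_male + (1.0 - x_male)
    if d_wt > 0:
        p = params.w3 * x_male / d_wt
        we = int(rng.binomial(n_wt_females, p))
        ww = n_wt_females - we
    return ee, ew, we, ww


def _simulate_vial(
    x0: float,
    design: AssayDesign,
    params: DriveParams,
    rng: np.random.Generator,
    replicate: Optional[str] = None,
) -> AssayRecord:
    n_egi_f = _founder_split(x0, design.n_females)
    n_egi_m = _founder_split(x0, design.n_males)
    start_egi = n_egi_f + n_egi_m
    start_wt = design.n_females + design.n_males - start_egi
    lam = design.mean_offspring_per_female

    if params.mode == "propensity" and params.c != 1.0:
        x_realized = start_egi / (start_egi + start_wt)
        ee, ew, we, ww = _mating_counts_propensity(
            design.n_females, x_realized, params.c, rng
        )
    else:
        x_male = n_egi_m / design.n_males
        ee, ew, we, ww = _mating_counts_preference(
            n_egi_f, design.n_females - n_egi_f, x_male, params, rng
        )
    # hybrid pairings (ew, we) leave no adult offspring
    offspring_egi = int(rng.poisson(lam * params.F * ee)) if ee else 0
    offspring_wt = int(rng.poisson(lam * ww)) if ww else 0
    return AssayRecord(
        start_egi=start_egi,
        start_wt=start_wt,
        offspring_egi=offspring_egi,
        offspring_wt=offspring_wt,
        replicate=replicate,
    )


def simulate_assay(
    design: AssayDesign, params: DriveParams, seed: SeedLike = None
) -> list:
    """Simulate one full single-generation drive assay.

    Returns one :class:`AssayRecord` per (starting frequency, replicate).
    Founders are allocated per sex by nearest-integer rounding of the
    nominal frequency; each female mates once; hybrid pairings yield no
    adult offspring; EGI x EGI and wt x wt pairs produce Poisson offspring
    with means ``lambda * F`` and ``lambda``.  Vials that produce no
    offspring are retained with zero counts.
    """
    rng = _rng(seed)
    records = []
    for x0 in design.starting_frequencies:
        for rep in range(design.replicates_per_frequency):
            records.append(
                _simulate_vial(x0, design, params, rng, replicate=f"{x0:g}-{rep + 1}")
            )
    return records


def simulate_control_assay(design: AssayDesign, seed: SeedLike = None) -> list:
    """Simulate the neutral negative control: two interfertile wild-type
    lines with equal fecundity.

    All pairings are viable; cross-line offspring are assigned to either
    parental label with equal probability (Mendelian segregation of a
    neutral line marker), so the expected frequency change is zero at
    every starting frequency.  The first label is stored in the
    ``start_egi``/``offspring_egi`` columns for schema compatibility.
    """
    rng = _rng(seed)
    lam = design.mean_offspring_per_female
    records = []
    for x0 in design.starting_frequencies:
        for rep in range(design.replicates_per_frequency):
            n_a_f = _founder_split(x0, design.n_females)
            n_a_m = _founder_split(x0, design.n_males)
            start_a = n_a_f + n_a_m
            start_b = design.n_females + design.n_males - start_a
            x_male = n_a_m / design.n_males
            # random mate choice, all pairings viable
            aa = int(rng.binomial(n_a_f, x_male))
            ab = n_a_f - aa
            ba = int(rng.binomial(design.n_females - n_a_f, x_male))
            bb = design.n_females - n_a_f - ba
            off_same_a = int(rng.poisson(lam * aa)) if aa else 0
            off_same_b = int(rng.poisson(lam * bb)) if bb else 0
            off_mixed = int(rng.poisson(lam * (ab + ba))) if (ab + ba) else 0
            mixed_a = int(rng.binomial(off_mixed, 0.5)) if off_mixed else 0
            records.append(
                AssayRecord(
                    start_egi=start_a,
                    start_wt=start_b,
                    offspring_egi=off_same_a + mixed_a,
                    offspring_wt=off_same_b + (off_mixed - mixed_a),
                    replicate=f"{x0:g}-{rep + 1}",
                )
            )
    return records


def simulate_mate_choice_trial(
    params: DriveParams, n_trials: int, seed: SeedLike = None
) -> MatingCountTable:
    """Simulate a batch of 4-fly first-to-mate trials.

    Each trial draws the first-mating pair from the four pairings with
    probabilities proportional to (w1, w2, w3, 1); counts are aggregated
    over trials.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    weights = np.array([params.w1, params.w2, params.w3, 1.0])
    if np.all(weights == 0):
        raise ValueError("all pairing weights are zero")
    rng = _rng(seed)
    ee, ew, we, ww = rng.multinomial(n_trials, weights / weights.sum())
    return MatingCountTable(n_ee=int(ee), n_ew=int(ew), n_we=int(we), n_ww=int(ww))


def simulate_discrete_generations(
    x0: float,
    population_size: int,
    params: DriveParams,
    max_generations: int = 50,
    mean_offspring_per_female: float = DEFAULT_OFFSPRING_PER_FEMALE,
    seed: SeedLike = None,
) -> Trajectory:
    """Agent-based discrete-generation cage trial.

    Each generation founds a fresh vial of ``population_size`` flies per
    sex at the current frequency (nearest-integer split per sex), runs one
    single-generation assay, and seeds the next generation at the realized
    offspring frequency.  Terminates at fixation (frequency 1), loss
    (frequency 0), extinction (no offspring at all), or
    ``max_generations``.
    """
    if population_size < 1:
        raise ValueError("population_size must be at least 1")
    if not 0.0 <= x0 <= 1.0:
        raise ValueError("x0 must lie in [0, 1]")
    rng = _rng(seed)
    design = AssayDesign(
        n_males=population_size,
        n_females=population_size,
        starting_frequencies=(0.5,),  # placeholder; vials are run directly
        mean_offspring_per_female=mean_offspring_per_female,
    )
    x = float(x0)
    freqs = [x]
    outcome = "max_generations"
    for _ in range(max_generations):
        if x == 1.0:
            outcome = "fixation"
            break
        if x == 0.0:
            outcome = "loss"
            break
        rec = _simulate_vial(x, design, params, rng)
        if rec.total_offspring == 0:
            outcome = "extinction"
            break
        x = rec.x1
        freqs.append(x)
    else:
        if freqs[-1] == 1.0:
            outcome = "fixation"
        elif freqs[-1] == 0.0:
            outcome = "loss"
    return Trajectory(frequencies=tuple(freqs), outcome=outcome)
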