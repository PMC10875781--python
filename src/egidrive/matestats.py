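"""Statistics for mate-choice tables and the drive-assay scatter.

The 4-fly mate-choice assay places one male and one female of each of two
genotypes in a vial and records the first pair to mate, yielding a 2x2
count table over (female genotype x male genotype).  Departure from random
mating is tested with a Pearson chi-squared statistic against a uniform
25% expectation (p-value by Monte-Carlo simulation of the multinomial
null, as the counts are small), assortativity with Fisher's exact test,
and the table's cell ratios estimate the mate-preference weights of the
drive model.  Quadrant counting and the two-proportion z-test compare a
drive-assay scatter against a neutral control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np
from scipy import stats as sps

from .fitting import AssayRecord

__all__ = [
    "MatingCountTable",
    "QuadrantSummary",
    "CHI_SQUARED_DF",
    "chi_squared_uniform",
    "empirical_p_value",
    "fisher_exact_2x2",
    "estimate_preferences",
    "quadrant_assign",
    "two_proportion_z_test",
]

#: The uniform null over four pairing categories has three degrees of freedom.
CHI_SQUARED_DF = 3

Alternative = Literal["two_sided", "greater", "less"]


@dataclass(frozen=True)
class MatingCountTable:
    """First-mating counts from a dual-choice assay of genotypes A and B.

    Cells are (female x male): ``n_ee`` A x A, ``n_ew`` A-female x B-male,
    ``n_we`` B-female x A-male, ``n_ww`` B x B.  In drive experiments
    genotype A is the engineered (EGI) line and B the wild-type reference.
    """

    n_ee: int
    n_ew: int
    n_we: int
    n_ww: int
    labels: tuple = ("EGI", "wt")

    def __post_init__(self) -> None:
        for name in ("n_ee", "n_ew", "n_we", "n_ww"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def total(self) -> int:
        return self.n_ee + self.n_ew + self.n_we + self.n_ww

    def as_array(self) -> np.ndarray:
        """2x2 array with rows = female genotype (A, B), cols = male."""
        return np.array([[self.n_ee, self.n_ew], [self.n_we, self.n_ww]])


@dataclass(frozen=True)
class QuadrantSummary:
    """Quadrant counts of a (x0, dx) scatter split at dx = 0 and x0 = split_x.

    A: left of split, dx > 0;  B: right of split, dx > 0;
    C: left of split, dx <= 0; D: right of split, dx <= 0.
    B and C are the drive-consistent quadrants (decline below the
    threshold, spread above it).
    """

    a: int
    b: int
    c: int
    d: int
    split_x: float

    @property
    def n_classified(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_drive_consistent(self) -> int:
        return self.b + self.c

    @property
    def fraction_drive_consistent(self) -> float:
        return self.n_drive_consistent / self.n_classified


def chi_squared_uniform(table: MatingCountTable) -> float:
    """Pearson statistic against equal 25% expectation in each cell (df=3)."""
    n = table.total
    if n == 0:
        raise ValueError("cannot test an empty table")
    counts = np.array([table.n_ee, table.n_ew, table.n_we, table.n_ww], dtype=float)
    expected = n / 4.0
    return float(np.sum((counts - expected) ** 2) / expected)


def empirical_p_value(
    observed_stat: float,
    n: int,
    n_sims: int = 100_000,
    seed: Optional[int] = None,
) -> float:
    """Monte-Carlo p-value for the uniform chi-squared test.

    Simulates ``n_sims`` tables of ``n`` matings under the uniform
    multinomial null and returns ``(1 + #{stat_sim >= stat_obs}) /
    (n_sims + 1)`` — the add-one form never returns zero and its floor
    (about ``1/n_sims``) is the smallest attainable p.
    """
    if n < 1 or n_sims < 1:
        raise ValueError("n and n_sims must be positive")
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(n, [0.25] * 4, size=n_sims).astype(float)
    expected = n / 4.0
    stats_sim = np.sum((sims - expected) ** 2, axis=1) / expected
    exceed = int(np.count_nonzero(stats_sim >= observed_stat))
    return (1 + exceed) / (n_sims + 1)


def fisher_exact_2x2(
    table: MatingCountTable, alternative: Alternative = "two_sided"
) -> float:
    """Fisher's exact test on the 2x2 (female x male) count table.

    With margins fixed, ``greater`` tests enrichment of the A x A cell
    (assortative mating pulls same-genotype pairings onto the diagonal);
    ``two_sided`` sums all tables whose point probability does not exceed
    the observed one.  A table with an empty margin carries no information
    and returns p = 1 with a warning.
    """
    arr = table.as_array()
    if arr.sum() == 0 or 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
        warnings.warn(
            "degenerate table (zero margin): Fisher test uninformative, p = 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    scipy_alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}
    try:
        alt = scipy_alt[alternative]
    except KeyError:
        raise ValueError(f"unknown alternative {alternative!r}") from None
    return float(sps.fisher_exact(arr, alternative=alt).pvalue)


def estimate_preferences(table: MatingCountTable) -> tuple:
    """Mate-preference weights (w1, w2, w3) from a 4-fly count table.

    Each weight is the cell count relative to the B x B (wild-type self)
    cell; under the weighted-pairing model at frequency 1/2 — the 4-fly
    design — these ratios are the multinomial maximum-likelihood
    estimates.
    """
    if table.n_ww == 0:
        raise ValueError(
            "preference weights are undefined when the wild-type x wild-type "
            "cell is zero; add explicit pseudocounts if a finite estimate is "
            "required"
        )
    return (
        table.n_ee / table.n_ww,
        table.n_ew / table.n_ww,
        table.n_we / table.n_ww,
    )


def quadrant_assign(
    records: Iterable[AssayRecord], split_x: float
) -> QuadrantSummary:
    """Classify (x0, dx) points into quadrants about dx = 0 and x0 = split_x.

    Ties land deterministically: dx = 0 counts as non-positive and
    x0 = split_x counts as right-of-split.  Records with no offspring
    (undefined dx) are not classified.
    """
    if not 0.0 < split_x < 1.0:
        raise ValueError("split_x must lie strictly inside (0, 1)")
    a = b = c = d = 0
    for r in records:
        if r.total_offspring == 0:
            continue
        left = r.x0 < split_x
        positive = r.dx > 0
        if left and positive:
            a += 1
        elif not left and positive:
            b += 1
        elif left:
            c += 1
        else:
            d += 1
    return QuadrantSummary(a=a, b=b, c=c, d=d, split_x=split_x)


def two_proportion_z_test(k1: int, n1: int, k2: int, n2: int) -> tuple:
    """Pooled two-proportion z-test; returns (z, two-sided p).

    Degenerate pooled proportions (0 or 1) make the statistic undefined;
    those return (0, 1) with a warning.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("successes must lie within [0, n]")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn(
            "pooled proportion is degenerate (all successes or all failures)",
            RuntimeWarning,
            stacklevel=2,
        )
        return (0.0, 1.0)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = 2.0 * float(sps.norm.sf(abs(z)))
    return (float(z), min(p, 1.0))
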