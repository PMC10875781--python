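"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (exact
rational arithmetic, full enumeration) and never calls the code under
test or the library routines it wraps.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_exact_enumeration(a: int, b: int, c: int, d: int, alternative: str) -> Fraction:
    """Fisher's exact p for the 2x2 table [[a, b], [c, d]] by enumerating
    every table with the observed margins, in exact rational arithmetic.

    With margins fixed, the top-left cell k follows a hypergeometric law:
    P(k) = C(r1, k) C(r2, c1 - k) / C(n, c1).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    pmf = {k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom) for k in range(lo, hi + 1)}
    if alternative == "greater":
        return sum(p for k, p in pmf.items() if k >= a)
    if alternative == "less":
        return sum(p for k, p in pmf.items() if k <= a)
    if alternative == "two_sided":
        observed = pmf[a]
        return sum(p for p in pmf.values() if p <= observed)
    raise ValueError(alternative)


def threshold_by_dense_scan(F: float, w1: float = 1.0, n: int = 2_000_000) -> float:
    """Locate the interior zero of F*w1*x^2/(F*w1*x^2 + (1-x)^2) - x by a
    dense linear scan plus linear interpolation (no root-finder reuse)."""
    g = F * w1
    prev_x = prev_d = None
    for i in range(1, n):
        x = i / n
        d = g * x * x / (g * x * x + (1 - x) ** 2) - x
        if prev_d is not None and prev_d < 0 <= d:
            return prev_x + (x - prev_x) * (-prev_d) / (d - prev_d)
        prev_x, prev_d = x, d
    raise RuntimeError("no crossing found")
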