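"""Published measurements for the two EGI *Drosophila melanogaster* lines.

Desk-scale inputs for threshold prediction: mean adult offspring per vial
at 25 C (20 females + 20 males per vial, 10-12 replicates per strain) and
the 4-fly mate-choice first-mating count tables for the engineered lines
A3.7 and N17.1 against the wild-type references Oregon-R and Z30.

Fecundity ratios and preference weights derived from these numbers feed
:func:`egidrive.fitting.predict_threshold_from_components`.
"""

from __future__ import annotations

from .matestats import MatingCountTable

__all__ = [
    "FECUNDITY_MEAN_OFFSPRING_25C",
    "MATE_CHOICE_TABLES",
    "fecundity_ratio",
]

#: Mean adult offspring per vial at 25 C by strain.
FECUNDITY_MEAN_OFFSPRING_25C: dict = {
    "A3.7": 108.1,
    "N17.1": 57.5,
    "OregonR": 78.6,
}

#: First-mating counts from the 4-fly assays, keyed by (EGI line, reference
#: line).  Cell order: (EGI-f x EGI-m, EGI-f x ref-m, ref-f x EGI-m,
#: ref-f x ref-m).
MATE_CHOICE_TABLES: dict = {
    ("A3.7", "OregonR"): MatingCountTable(
        n_ee=17, n_ew=54, n_we=4, n_ww=15, labels=("A3.7", "OregonR")
    ),
    ("N17.1", "OregonR"): MatingCountTable(
        n_ee=52, n_ew=21, n_we=9, n_ww=7, labels=("N17.1", "OregonR")
    ),
    ("A3.7", "Z30"): MatingCountTable(
        n_ee=2, n_ew=25, n_we=2, n_ww=18, labels=("A3.7", "Z30")
    ),
    ("N17.1", "Z30"): MatingCountTable(
        n_ee=15, n_ew=14, n_we=1, n_ww=7, labels=("N17.1", "Z30")
    ),
}


def fecundity_ratio(strain: str, reference: str = "OregonR") -> float:
    """Fecundity of ``strain`` relative to ``reference`` (F of the model)."""
    return (
        FECUNDITY_MEAN_OFFSPRING_25C[strain]
        / FECUNDITY_MEAN_OFFSPRING_25C[reference]
    )
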