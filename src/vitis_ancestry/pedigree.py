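"""Pedigree-based ancestry expectations.

A diploid offspring inherits half of its genome from each parent, so its
expected vinifera percentage is the midparent mean of the two parents'
percentages. These expectations are the classical cross-check for
marker-based ancestry estimates: well-documented cultivar pedigrees give
an arithmetic prediction to compare against the PCA estimate.

Documented worked cases (parent percentages from published estimates):
'Regent' = 'Diana' (pure vinifera, 100%) x 'Chambourcin' (46%) -> 73%;
'Beta' = V. riparia (wild, 0%) x 'Concord' (31%) -> 15.5, reported as 16%;
'Orion'/'Staufer'/'Phoenix' = 'Villard Blanc' (62%) x vinifera (100%) -> 81%.
"""

from __future__ import annotations


def midparent_percent(parent1_percent: float, parent2_percent: float) -> float:
    """Expected offspring vinifera percentage: mean of the parents'."""
    for p in (parent1_percent, parent2_percent):
        if not 0.0 <= p <= 100.0:
            raise ValueError(f"parent percentage {p} outside [0, 100]")
    return (parent1_percent + parent2_percent) / 2.0


def midparent_percent_rounded(parent1_percent: float, parent2_percent: float) -> int:
    """Midparent expectation rounded to a whole percent.

    Half-values round away from zero (15.5 -> 16), matching how such
    expectations are quoted.
    """
    x = midparent_percent(parent1_percent, parent2_percent)
    import math

    return int(math.floor(x + 0.5))


#: (name, parent percentages) for the documented cultivar cross-checks
WORKED_EXAMPLES: dict[str, tuple[float, float]] = {
    "Regent": (100.0, 46.0),           # Diana (vinifera) x Chambourcin
    "Beta": (0.0, 31.0),               # V. riparia x Concord
    "Orion/Staufer/Phoenix": (62.0, 100.0),  # Villard Blanc x vinifera
}
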