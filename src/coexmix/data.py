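"""Bundled reference inputs for the five-chemical household mixture.

The five household chemicals characterized in this workflow, with their
CAS registry numbers and individually established AC90 concentrations
(µM).  Benzyl cinnamate never reduced viability to 90% within the tested
0-2000 µM range, so its entry carries the 1000 µM fallback concentration
with ``not_reached_fallback`` status.  These values are the canonical
worked-example input for the proportional-AC90 mixture design.
"""

from __future__ import annotations

from .mixture import STATUS_ESTIMATED, STATUS_FALLBACK, Ac90Entry, Ac90Table

__all__ = ["HOUSEHOLD_CHEMICALS", "household_ac90_table"]

#: (chemical name, CASRN, AC90 µM, status)
HOUSEHOLD_CHEMICALS: list[tuple[str, str, float, str]] = [
    ("Benzyl cinnamate", "103-41-3", 1000.0, STATUS_FALLBACK),
    ("Butylparaben", "94-26-8", 150.0, STATUS_ESTIMATED),
    ("Decanoic acid", "334-48-5", 1300.0, STATUS_ESTIMATED),
    ("Eugenol", "97-53-0", 150.0, STATUS_ESTIMATED),
    ("Sodium dodecyl sulfate", "151-21-3", 250.0, STATUS_ESTIMATED),
]


def household_ac90_table() -> Ac90Table:
    """AC90 table for the five-chemical household mixture."""
    return Ac90Table(
        {
            name: Ac90Entry(name, ac90, status, casrn)
            for name, casrn, ac90, status in HOUSEHOLD_CHEMICALS
        }
    )
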