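"""Proportional-potency mixture design.

Each chemical enters the mixture at its individual AC90 (the
concentration retaining 90% cell viability) scaled by a common
dimensionless factor i:

    C_i = sum_c AC90_c * i

so component ratios are fixed by relative potency and a single knob
moves the whole mixture up or down the dose axis.  The nominal total
C_i is the sum of the components.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["Ac90Entry", "Ac90Table", "MixtureSpec", "scaled_mixture", "mixture_series",
           "mixture_sheet"]

STATUS_ESTIMATED = "estimated"
STATUS_FALLBACK = "not_reached_fallback"


@dataclass(frozen=True)
class Ac90Entry:
    """One chemical's AC90 concentration with provenance status.

    ``status`` records whether the value came from a converged
    dose-response fit (``estimated``) or from the fallback rule applied
    when viability never drops to 90% in the tested range
    (``not_reached_fallback``); fallback values participate in the
    mixture arithmetic identically.
    """

    chemical: str
    ac90_um: float
    status: str = STATUS_ESTIMATED
    casrn: str = ""

    def __post_init__(self) -> None:
        if self.ac90_um <= 0:
            raise ValueError(f"AC90 for {self.chemical} must be positive, got {self.ac90_um}")
        if self.status not in {STATUS_ESTIMATED, STATUS_FALLBACK}:
            raise ValueError(f"unknown AC90 status {self.status!r}")


class Ac90Table(dict):
    """chemical name -> :class:`Ac90Entry`, canonically iterated alphabetically."""

    @classmethod
    def from_mapping(cls, values: Mapping[str, float], statuses: Mapping[str, str] | None = None,
                     casrns: Mapping[str, str] | None = None) -> "Ac90Table":
        statuses = statuses or {}
        casrns = casrns or {}
        return cls(
            {
                chem: Ac90Entry(chem, float(v), statuses.get(chem, STATUS_ESTIMATED),
                                casrns.get(chem, ""))
                for chem, v in values.items()
            }
        )

    def ordered(self) -> list[Ac90Entry]:
        return [self[c] for c in sorted(self)]


@dataclass
class MixtureSpec:
    """Mixture composition at one scaling factor i (all concentrations in µM)."""

    i: float
    components_um: dict[str, float]  # chemical -> AC90 * i
    statuses: dict[str, str]

    @property
    def total_um(self) -> float:
        return float(sum(self.components_um.values()))

    def as_frame(self) -> pd.DataFrame:
        chems = sorted(self.components_um)
        return pd.DataFrame(
            {
                "chemical": chems,
                "i": self.i,
                "concentration_um": [self.components_um[c] for c in chems],
                "ac90_status": [self.statuses[c] for c in chems],
            }
        )


def scaled_mixture(ac90s: Ac90Table | Mapping[str, Ac90Entry], i: float) -> MixtureSpec:
    """Mixture at scaling factor ``i``: each component at ``AC90 * i`` µM.

    ``i = 1.0`` reproduces the individual AC90s; ``i = 0.2`` puts every
    chemical at one fifth of its AC90.  Raises if ``i <= 0`` or any AC90
    is missing/non-positive, naming the chemical.
    """
    if i <= 0:
        raise ValueError(f"scaling factor i must be > 0, got {i}")
    components: dict[str, float] = {}
    statuses: dict[str, str] = {}
    for chem in sorted(ac90s):
        entry = ac90s[chem]
        if entry is None or entry.ac90_um is None:
            raise ValueError(f"missing AC90 for chemical {chem!r}")
        components[chem] = entry.ac90_um * i
        statuses[chem] = entry.status
    if not components:
        raise ValueError("empty AC90 table")
    return MixtureSpec(i=i, components_um=components, statuses=statuses)


def mixture_series(
    ac90s: Ac90Table | Mapping[str, Ac90Entry], i_values: Sequence[float]
) -> list[MixtureSpec]:
    """One :class:`MixtureSpec` per scaling factor, input order preserved."""
    if not i_values:
        raise ValueError("i_values must be non-empty")
    return [scaled_mixture(ac90s, i) for i in i_values]


def mixture_sheet(
    ac90s: Ac90Table, i_values: Sequence[float], path: str | Path | None = None
) -> pd.DataFrame:
    """Long-format mixture sheet (chemical, CASRN, AC90, status, i, concentration).

    Mirrors the composition-table layout used when reporting proportional
    mixtures; optionally written as CSV.
    """
    rows = []
    for spec in mixture_series(ac90s, i_values):
        for chem in sorted(spec.components_um):
            entry = ac90s[chem]
            rows.append(
                {
                    "chemical": chem,
                    "casrn": entry.casrn,
                    "ac90_um": entry.ac90_um,
                    "ac90_status": entry.status,
                    "i": spec.i,
                    "concentration_um": spec.components_um[chem],
                }
            )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
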