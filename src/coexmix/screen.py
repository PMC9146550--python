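"""Bioactivity screening filters for summary-level high-throughput assay data.

Filters assay summary records (one row per chemical x endpoint, with a
binary hit call, a cytotoxicity-burst Z-score and an AC50) down to
chemicals that are active on the configured endpoint at concentrations
well below the cytotoxicity signal-burst region, then intersects the
survivors with the exposure presence matrix.

The two filters are:

* ``hit_call == 1`` — the chemical was called active on the endpoint;
* ``cytotox_zscore > z_threshold`` (strict) — activity occurs far below
  the cytotoxicity burst.  A missing Z-score means no cytotoxicity was
  observed at all, which by default passes with an audit flag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import PresenceFilterResult, filter_min_categories, normalize_chemical_id

logger = logging.getLogger(__name__)

__all__ = ["ScreenResult", "load_assay_summary", "filter_active_noncytotoxic",
           "intersect_with_exposure"]

#: default column names, following summary-file conventions
DEFAULT_COLUMNS = {
    "id_col": "chemical_id",
    "endpoint_col": "assay_component_endpoint_name",
    "hit_col": "hitc",
    "z_col": "cytotox_z",
    "ac50_col": "ac50",
}


def load_assay_summary(
    path: str | Path,
    endpoint_name: str,
    *,
    id_col: str = "chemical_id",
    endpoint_col: str = "assay_component_endpoint_name",
    hit_col: str = "hitc",
    z_col: str = "cytotox_z",
    ac50_col: str = "ac50",
    continuous_hitc: bool = False,
    hitc_threshold: float = 0.9,
    sep: str | None = None,
) -> pd.DataFrame:
    """Load assay summary records for one endpoint.

    Endpoint matching is exact and case-sensitive (endpoint names are a
    controlled vocabulary).  Non-numeric Z-score / AC50 cells are kept as
    missing with a logged warning.  Hit calls must be exact 0/1 integers
    unless ``continuous_hitc`` maps continuous calls through
    ``hitc_threshold``.

    Returns a DataFrame with columns ``chemical_id, endpoint, hit_call,
    cytotox_zscore, ac50_um``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"assay summary file not found: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=str)
    for col in (id_col, endpoint_col, hit_col):
        if col not in raw.columns:
            raise KeyError(f"assay summary {path} lacks column {col!r}")
    raw = raw[raw[endpoint_col] == endpoint_name]
    if raw.empty:
        raise ValueError(
            f"no rows in {path} match endpoint {endpoint_name!r} (exact, case-sensitive)"
        )

    def _coerce(series: pd.Series, what: str) -> pd.Series:
        out = pd.to_numeric(series, errors="coerce")
        bad = out.isna() & series.notna() & (series.str.strip() != "")
        if bad.any():
            logger.warning("%d non-numeric %s value(s) treated as missing", int(bad.sum()), what)
        return out

    hit = pd.to_numeric(raw[hit_col], errors="coerce")
    if continuous_hitc:
        hit_call = (hit >= hitc_threshold).astype(int)
    else:
        ok = hit.isin([0, 1])
        if not ok.all():
            raise ValueError(
                f"{int((~ok).sum())} hit-call value(s) are not exact 0/1 integers; "
                "set continuous_hitc=True to threshold continuous hit calls"
            )
        hit_call = hit.astype(int)

    out = pd.DataFrame(
        {
            "chemical_id": raw[id_col].map(normalize_chemical_id),
            "endpoint": endpoint_name,
            "hit_call": hit_call.to_numpy(),
            "cytotox_zscore": _coerce(raw[z_col], "Z-score").to_numpy()
            if z_col in raw.columns
            else np.nan,
            "ac50_um": _coerce(raw[ac50_col], "AC50").to_numpy()
            if ac50_col in raw.columns
            else np.nan,
        }
    ).reset_index(drop=True)
    if (out["ac50_um"] <= 0).any():
        raise ValueError("AC50 values must be positive where present")
    logger.info("loaded %d record(s) for endpoint %s", len(out), endpoint_name)
    return out


@dataclass
class ScreenResult:
    """Active-chemical set plus per-chemical filter provenance.

    ``provenance`` has one row per input chemical with boolean
    ``hit_pass``, ``z_pass``, ``missing_z_flag`` and ``active`` columns;
    ``stage_counts`` records the funnel (input -> hit -> hit & z).
    """

    active_chemicals: set[str]
    provenance: pd.DataFrame
    stage_counts: dict[str, int]
    z_threshold: float = 2.0
    missing_z_policy: str = "pass_with_flag"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "z_threshold": self.z_threshold,
            "missing_z_policy": self.missing_z_policy,
            "stage_counts": self.stage_counts,
            "chemicals": json.loads(
                self.provenance.to_json(orient="records")
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def filter_active_noncytotoxic(
    records: pd.DataFrame,
    z_threshold: float = 2.0,
    missing_z_policy: str = "pass_with_flag",
) -> ScreenResult:
    """Apply the hit-call and cytotoxicity Z-score filters.

    A chemical passes iff ``hit_call == 1`` and ``cytotox_zscore >
    z_threshold`` (strict inequality: a Z-score of exactly ``z_threshold``
    fails).  Missing Z-scores pass with a flag under the default policy
    (no observed cytotoxicity implies activity far from the burst region)
    or fail under ``missing_z_policy="fail"``.
    """
    if records.empty:
        raise ValueError("no assay records to filter")
    if missing_z_policy not in {"pass_with_flag", "fail"}:
        raise ValueError(f"unknown missing_z_policy {missing_z_policy!r}")

    z = records["cytotox_zscore"]
    hit_pass = records["hit_call"].astype(int) == 1
    missing = z.isna()
    z_pass = (z > z_threshold).fillna(False)
    if missing_z_policy == "pass_with_flag":
        z_pass = z_pass | missing
    active = hit_pass & z_pass

    prov = pd.DataFrame(
        {
            "chemical_id": records["chemical_id"],
            "hit_call": records["hit_call"].astype(int),
            "cytotox_zscore": z,
            "ac50_um": records.get("ac50_um"),
            "hit_pass": hit_pass,
            "z_pass": z_pass,
            "missing_z_flag": missing & active,
            "active": active,
        }
    ).reset_index(drop=True)
    counts = {
        "input": int(len(records)),
        "hit_call_1": int(hit_pass.sum()),
        "hit_and_noncytotoxic": int(active.sum()),
    }
    logger.info("screen funnel: %s", counts)
    return ScreenResult(
        active_chemicals=set(prov.loc[prov["active"], "chemical_id"]),
        provenance=prov,
        stage_counts=counts,
        z_threshold=z_threshold,
        missing_z_policy=missing_z_policy,
    )


def intersect_with_exposure(
    screen: ScreenResult, m: pd.DataFrame, min_count: int = 2
) -> PresenceFilterResult:
    """Restrict the presence matrix to active chemicals and re-filter.

    After dropping inactive rows the minimum-category filter and the
    all-zero-column drop are re-applied, since removing chemicals can
    empty a category.
    """
    keep = [c for c in m.index if c in screen.active_chemicals]
    if not keep:
        raise ValueError(
            "active chemicals and presence matrix share no identifiers; "
            "check that both sources use the same normalized join key"
        )
    return filter_min_categories(m.loc[keep], min_count=min_count)
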