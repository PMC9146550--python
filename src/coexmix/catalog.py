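"""Exposure-source catalog: list-presence ingestion and the binary presence matrix.

Consumer-product databases record chemical *presence* (not concentration)
across product and use inventories through curated keywords.  This module
ingests such list-presence records, collapses keywords into broader
exposure-source categories via a user-supplied mapping, and builds the
chemical x category 0/1 presence matrix that downstream co-occurrence
clustering consumes.  Chemicals seen in fewer than ``min_count`` distinct
categories are removed because co-occurrence is undefined for them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ListPresenceRecord",
    "PresenceFilterResult",
    "normalize_chemical_id",
    "load_list_presence",
    "load_keyword_map",
    "map_keywords",
    "build_presence_matrix",
    "filter_min_categories",
    "write_presence_matrix",
    "read_presence_matrix",
]


def normalize_chemical_id(raw: str) -> str:
    """Normalize a CASRN or DTXSID join key: trim, uppercase, drop internal spaces.

    Idempotent: ``normalize_chemical_id(normalize_chemical_id(x)) == normalize_chemical_id(x)``.
    """
    return "".join(str(raw).strip().upper().split())


class ListPresenceRecord(NamedTuple):
    """One chemical/keyword presence assertion from a list-presence table."""

    chemical_id: str
    preferred_name: str
    keyword: str


def load_list_presence(
    path: str | Path,
    *,
    id_col: str = "chemical_id",
    name_col: str = "preferred_name",
    keyword_col: str = "keyword",
    sep: str | None = None,
) -> list[ListPresenceRecord]:
    """Read a delimited list-presence table into records.

    Duplicate (chemical, keyword) rows are preserved; deduplication happens
    downstream in :func:`map_keywords`.  Rows with a blank keyword are
    rejected with a logged warning count.

    Parameters
    ----------
    path
        CSV/TSV file with a header row.
    id_col, name_col, keyword_col
        Column names holding the chemical identifier, display name and
        curated keyword.  ``name_col`` is optional in the file; the
        identifier is reused when absent.
    sep
        Field separator; inferred from the file extension when None.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"list-presence file not found: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in (id_col, keyword_col) if c not in df.columns]
    if missing:
        raise KeyError(
            f"list-presence file {path} lacks configured column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    if df.empty:
        raise ValueError(f"list-presence file {path} contains no data rows")

    has_name = name_col in df.columns
    records: list[ListPresenceRecord] = []
    n_blank = 0
    for row in df.itertuples(index=False):
        raw_id = getattr(row, id_col, None) or ""
        keyword = str(getattr(row, keyword_col) or "").strip()
        chem = normalize_chemical_id(raw_id)
        if not chem or not keyword or keyword.lower() == "nan":
            n_blank += 1
            continue
        name = str(getattr(row, name_col)).strip() if has_name else chem
        records.append(ListPresenceRecord(chem, name or chem, keyword))
    if n_blank:
        logger.warning("rejected %d row(s) with blank chemical id or keyword", n_blank)
    logger.info("loaded %d list-presence records from %s", len(records), path)
    return records


def load_keyword_map(path: str | Path, sep: str | None = None) -> dict[str, str]:
    """Read the two-column ``keyword,exposure_source_category`` mapping.

    Keys are case-folded and trimmed so that matching is case-insensitive.
    A keyword mapped to two different categories is an error (the mapping
    must be many-to-one).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"keyword mapping file not found: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"keyword mapping {path} must have two columns")
    kw_col, cat_col = df.columns[:2]
    mapping: dict[str, str] = {}
    for kw, cat in zip(df[kw_col], df[cat_col]):
        key = str(kw).strip().casefold()
        val = str(cat).strip()
        if not key or not val:
            raise ValueError(f"keyword mapping {path} has an empty keyword or category")
        if key in mapping and mapping[key] != val:
            raise ValueError(f"keyword {kw!r} maps to multiple categories")
        mapping[key] = val
    return mapping


def map_keywords(
    records: Iterable[ListPresenceRecord],
    mapping: Mapping[str, str],
    unmapped_policy: str = "drop_with_warning",
) -> list[tuple[str, str]]:
    """Replace each record's keyword by its exposure-source category.

    Exact duplicates of (chemical, category) collapse to one pair, so the
    result is order-invariant and duplication-invariant.  Keyword lookup is
    case-insensitive after trimming.

    ``unmapped_policy`` is ``"drop_with_warning"`` (default) or ``"error"``.
    """
    if unmapped_policy not in {"drop_with_warning", "error"}:
        raise ValueError(f"unknown unmapped_policy {unmapped_policy!r}")
    folded = {str(k).strip().casefold(): v for k, v in mapping.items()}
    pairs: set[tuple[str, str]] = set()
    unmapped: set[str] = set()
    for rec in records:
        key = rec.keyword.strip().casefold()
        cat = folded.get(key)
        if cat is None:
            if unmapped_policy == "error":
                raise KeyError(f"keyword {rec.keyword!r} has no exposure-source category")
            unmapped.add(rec.keyword)
            continue
        pairs.add((rec.chemical_id, cat))
    if unmapped:
        logger.warning(
            "dropped %d unmapped keyword(s): %s",
            len(unmapped),
            ", ".join(sorted(unmapped)[:10]),
        )
    return sorted(pairs)


def build_presence_matrix(pairs: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Build the binary chemical x category presence matrix.

    ``cell(c, s) = 1`` iff the pair (c, s) was observed.  Rows and columns
    are ordered lexicographically so the result is independent of input
    order.
    """
    if not pairs:
        raise ValueError("no (chemical, category) pairs to build a presence matrix from")
    chems = sorted({c for c, _ in pairs})
    cats = sorted({s for _, s in pairs})
    m = pd.DataFrame(0, index=chems, columns=cats, dtype="int8")
    for c, s in pairs:
        m.loc[c, s] = 1
    m.index.name = "chemical_id"
    m.columns.name = "exposure_source_category"
    return m


@dataclass
class PresenceFilterResult:
    """Presence matrix after the minimum-category filter, with provenance."""

    matrix: pd.DataFrame
    removed_chemicals: list[tuple[str, int]] = field(default_factory=list)
    dropped_categories: list[str] = field(default_factory=list)
    min_count: int = 2

    def provenance(self) -> dict:
        return {
            "min_count": self.min_count,
            "n_chemicals_retained": int(self.matrix.shape[0]),
            "n_categories_retained": int(self.matrix.shape[1]),
            "removed_chemicals": [
                {"chemical_id": c, "n_categories": n} for c, n in self.removed_chemicals
            ],
            "dropped_categories": list(self.dropped_categories),
        }


def filter_min_categories(m: pd.DataFrame, min_count: int = 2) -> PresenceFilterResult:
    """Keep chemicals present in at least ``min_count`` distinct categories.

    Columns left with no presence after row removal are dropped: an all-zero
    category has no defined Jaccard distance to anything.  Idempotent.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    _check_binary(m)
    row_sums = m.sum(axis=1)
    keep = row_sums >= min_count
    removed = [(str(c), int(row_sums[c])) for c in m.index[~keep]]
    out = m.loc[keep]
    if out.shape[0] == 0:
        raise ValueError(
            f"no chemical is present in >= {min_count} categories; nothing to analyze"
        )
    col_sums = out.sum(axis=0)
    dropped_cols = [str(c) for c in out.columns[col_sums == 0]]
    out = out.loc[:, col_sums > 0]
    if removed:
        logger.info(
            "min-category filter removed %d chemical(s) with < %d categories",
            len(removed), min_count,
        )
    return PresenceFilterResult(out, removed, dropped_cols, min_count)


def _check_binary(m: pd.DataFrame) -> None:
    if not m.isin([0, 1]).all().all():
        raise ValueError("presence matrix cells must all be 0 or 1")


def write_presence_matrix(
    m: pd.DataFrame, path: str | Path, provenance: dict | None = None
) -> None:
    """Write the matrix as TSV plus an optional JSON provenance sidecar."""
    path = Path(path)
    m.to_csv(path, sep="\t")
    if provenance is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True) + "\n"
        )


def read_presence_matrix(path: str | Path) -> pd.DataFrame:
    m = pd.read_csv(path, sep="\t", index_col=0).astype("int8")
    m.index.name = "chemical_id"
    m.columns.name = "exposure_source_category"
    _check_binary(m)
    return m
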