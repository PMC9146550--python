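"""Cluster prioritization by exposure-source breadth.

Chemical clusters found by co-occurrence analysis are scored by the mean
number of distinct exposure-source categories their members appear in;
the cluster with the broadest average coverage is nominated for mixture
testing.  An optional set of required categories (e.g. household-relevant
sources) demotes clusters touching none of them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .clustering import ClusterSolution

__all__ = ["ClusterSummary", "Prioritization", "summarize_clusters", "prioritize_cluster"]


@dataclass
class ClusterSummary:
    """Per-cluster exposure-source breadth statistics."""

    cluster: int
    members: list[str]
    category_counts: dict[str, int]  # per-member distinct-category count
    mean_categories: float
    categories_covered: list[str]  # categories with >= 1 member present
    annotation: str = ""  # free-text slot for manual subselection notes

    @property
    def n_members(self) -> int:
        return len(self.members)

    def to_dict(self) -> dict:
        return {
            "cluster": self.cluster,
            "n_members": self.n_members,
            "members": self.members,
            "category_counts": self.category_counts,
            "mean_categories": self.mean_categories,
            "categories_covered": self.categories_covered,
            "annotation": self.annotation,
        }


def summarize_clusters(m: pd.DataFrame, sol: ClusterSolution) -> list[ClusterSummary]:
    """One breadth summary per chemical cluster.

    ``mean_categories`` is the arithmetic mean of member row sums, i.e.
    the average number of exposure-source categories a member chemical is
    present in.
    """
    missing = [str(c) for c in m.index if str(c) not in sol.row_labels]
    if missing:
        raise ValueError(f"cluster solution does not cover matrix rows: {missing[:5]}")
    out: list[ClusterSummary] = []
    for cluster in sorted(set(sol.row_labels.values())):
        members = sorted(lbl for lbl, c in sol.row_labels.items() if c == cluster)
        sub = m.loc[members]
        counts = {chem: int(sub.loc[chem].sum()) for chem in members}
        covered = sorted(str(cat) for cat in sub.columns[sub.any(axis=0)])
        out.append(
            ClusterSummary(
                cluster=cluster,
                members=members,
                category_counts=counts,
                mean_categories=float(sub.sum(axis=1).mean()),
                categories_covered=covered,
            )
        )
    return out


def breadth_stats(summaries: Sequence[ClusterSummary]) -> dict[str, float]:
    """Overall mean / min / max of the per-cluster mean category counts."""
    means = [s.mean_categories for s in summaries]
    return {
        "overall_mean": float(sum(means) / len(means)),
        "min": float(min(means)),
        "max": float(max(means)),
    }


@dataclass
class Prioritization:
    """Ranked clusters with the nominated (rank-1) cluster first."""

    ranking: list[ClusterSummary]
    required_categories: list[str] = field(default_factory=list)

    @property
    def selected(self) -> ClusterSummary:
        return self.ranking[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "required_categories": self.required_categories,
            "stats": breadth_stats(self.ranking),
            "ranking": [s.to_dict() for s in self.ranking],
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    def report(self) -> str:
        lines = ["Cluster prioritization (by mean exposure-source count)", ""]
        for rank, s in enumerate(self.ranking, start=1):
            mark = "  <- selected" if rank == 1 else ""
            lines.append(
                f"  rank {rank}: cluster {s.cluster} | {s.n_members} chemicals | "
                f"mean {s.mean_categories:.2f} categories{mark}"
            )
        lines.append("")
        lines.append("Selected cluster members: " + ", ".join(self.selected.members))
        return "\n".join(lines)


def prioritize_cluster(
    summaries: Sequence[ClusterSummary],
    required_categories: Iterable[str] | None = None,
) -> Prioritization:
    """Rank clusters by mean category count, descending.

    Clusters covering at least one of ``required_categories`` (if given)
    rank above clusters covering none, regardless of breadth.  Remaining
    ties break by larger member count, then lower cluster index.  The
    final manual subselection of members within the nominated cluster
    (purchasability, stability) is not modeled; the full member list is
    emitted with an annotation slot instead.
    """
    if not summaries:
        raise ValueError("no cluster summaries to prioritize")
    req = {c.strip().casefold() for c in (required_categories or [])}

    def sort_key(s: ClusterSummary):
        covered = {c.casefold() for c in s.categories_covered}
        hits_required = bool(covered & req) if req else True
        return (not hits_required, -s.mean_categories, -s.n_members, s.cluster)

    ranking = sorted(summaries, key=sort_key)
    return Prioritization(list(ranking), sorted(req))
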