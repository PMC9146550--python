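"""Synthetic datasets with known ground truth for every pipeline stage.

Real inputs to this workflow are database exports (list-presence records,
assay summary files) and wet-lab readouts (viability plates, qPCR Ct
tables).  The generators here emulate each of them with planted
structure so that every stage of the pipeline can be validated against
a known truth:

* a block-structured binary presence matrix (planted row/column blocks),
* an assay summary with a planted active, non-cytotoxic chemical set,
* viability plates drawn from known 4PL curves with analytic AC90s,
* qPCR Ct tables with planted log2 fold changes.

Every generator is a pure function of its parameters and seed:
regeneration with the same arguments is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import ListPresenceRecord
from .doseresponse import four_pl

__all__ = [
    "SyntheticTruth",
    "gen_presence",
    "gen_assay",
    "gen_viability",
    "gen_qpcr",
    "default_viability_params",
    "default_log2fc",
    "simulate_all",
]


@dataclass
class SyntheticTruth:
    """Planted ground truth serialized alongside every generated dataset."""

    seed: int | None = None
    params: dict = field(default_factory=dict)
    row_blocks: dict[str, int] = field(default_factory=dict)
    col_blocks: dict[str, int] = field(default_factory=dict)
    presence: dict[str, list[str]] = field(default_factory=dict)  # chemical -> categories
    active_chemicals: list[str] = field(default_factory=list)
    viability_params: dict[str, dict] = field(default_factory=dict)
    true_ac90: dict[str, float | None] = field(default_factory=dict)
    true_log2fc: dict[str, float] = field(default_factory=dict)  # "condition|gene" keys

    def to_json(self, path: str | Path) -> None:
        payload = {k: v for k, v in self.__dict__.items() if v not in (None, {}, [])}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        data = json.loads(Path(path).read_text())
        truth = cls()
        for k, v in data.items():
            setattr(truth, k, v)
        return truth


def _block_sizes(n: int, blocks: int) -> list[int]:
    base, extra = divmod(n, blocks)
    return [base + (1 if b < extra else 0) for b in range(blocks)]


def _row_block_colsets(n_row_blocks: int, n_col_blocks: int) -> list[set[int]]:
    """Assign each row block a distinct non-empty subset of column blocks.

    Row block r occupies the column blocks in the binary expansion of
    r + 1, so all row-block profiles (and all column-block profiles) are
    distinct and both plantings are identifiable.  Requires
    ``n_row_blocks <= 2**n_col_blocks - 1``.
    """
    if n_row_blocks > 2**n_col_blocks - 1:
        raise ValueError(
            f"{n_row_blocks} row blocks cannot be given distinct column-block "
            f"subsets with only {n_col_blocks} column blocks"
        )
    return [
        {c for c in range(n_col_blocks) if (r + 1) >> c & 1}
        for r in range(n_row_blocks)
    ]


def gen_presence(
    n_chemicals: int = 60,
    n_categories: int = 12,
    n_row_blocks: int = 3,
    n_col_blocks: int = 2,
    p_within: float = 0.9,
    p_between: float = 0.05,
    seed: int = 1,
) -> tuple[list[ListPresenceRecord], dict[str, str], SyntheticTruth]:
    """Planted-block presence structure as raw list-presence records.

    Chemicals are split into ``n_row_blocks`` blocks and categories into
    ``n_col_blocks`` blocks; a cell is 1 with probability ``p_within``
    when the chemical's block occupies the category's block and
    ``p_between`` otherwise.  Rows violating the downstream >= 2-category
    filter are resampled so the planted labels survive filtering.  Each
    category carries 2-5 generated keywords and every presence cell is
    emitted as 1-2 keyword records, exercising the keyword -> category
    mapping and deduplication steps.
    """
    if not 0 <= p_between < p_within <= 1:
        raise ValueError("need 0 <= p_between < p_within <= 1")
    if n_row_blocks > n_chemicals or n_col_blocks > n_categories:
        raise ValueError("more blocks than rows/columns")
    colsets = _row_block_colsets(n_row_blocks, n_col_blocks)
    col_sizes = _block_sizes(n_categories, n_col_blocks)
    min_within = min(
        sum(col_sizes[c] for c in cs) for cs in colsets
    )
    if p_within * min_within + p_between * (n_categories - min_within) < 2:
        raise ValueError(
            "infeasible parameters: expected row sum below the 2-category filter"
        )

    rng = np.random.default_rng(seed)
    chems = [f"CHEM{i:04d}" for i in range(n_chemicals)]
    cats = [f"source {i:02d}" for i in range(n_categories)]
    row_sizes = _block_sizes(n_chemicals, n_row_blocks)
    row_block = np.repeat(np.arange(n_row_blocks), row_sizes)
    col_block = np.repeat(np.arange(n_col_blocks), col_sizes)

    prob = np.empty((n_chemicals, n_categories))
    for i in range(n_chemicals):
        within = np.isin(col_block, list(colsets[row_block[i]]))
        prob[i] = np.where(within, p_within, p_between)
    cells = rng.random((n_chemicals, n_categories)) < prob
    for i in range(n_chemicals):  # guarantee the >= 2 category filter passes
        while cells[i].sum() < 2:
            cells[i] = rng.random(n_categories) < prob[i]

    keywords: dict[str, list[str]] = {
        cat: [f"{cat} keyword {j}" for j in range(int(rng.integers(2, 6)))] for cat in cats
    }
    keyword_map = {kw: cat for cat, kws in keywords.items() for kw in kws}

    records: list[ListPresenceRecord] = []
    for i, chem in enumerate(chems):
        for j in np.flatnonzero(cells[i]):
            cat = cats[j]
            for kw in rng.choice(keywords[cat], size=int(rng.integers(1, 3))):
                records.append(ListPresenceRecord(chem, f"Chemical {i}", str(kw)))

    truth = SyntheticTruth(
        seed=seed,
        params={
            "n_chemicals": n_chemicals,
            "n_categories": n_categories,
            "n_row_blocks": n_row_blocks,
            "n_col_blocks": n_col_blocks,
            "p_within": p_within,
            "p_between": p_between,
        },
        row_blocks={c: int(b) + 1 for c, b in zip(chems, row_block)},
        col_blocks={c: int(b) + 1 for c, b in zip(cats, col_block)},
        presence={chems[i]: [cats[j] for j in np.flatnonzero(cells[i])] for i in range(n_chemicals)},
    )
    return records, keyword_map, truth


def gen_assay(
    n_chemicals: int = 500,
    frac_active: float = 0.08,
    endpoint: str = "ATG_PPARg_TRANS_up",
    seed: int = 1,
    chemical_ids: list[str] | None = None,
    include_boundary_decoy: bool = True,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Assay summary records with a planted active, non-cytotoxic set.

    Planted actives carry ``hit_call = 1`` and a cytotoxicity Z-score
    strictly above 2; decoys are inactive (``hit_call = 0``, any Z) or
    active-but-cytotoxic (``hit_call = 1``, Z <= 2), including one decoy
    pinned at exactly Z = 2.0 to probe the strict inequality.  AC50s are
    log-uniform over (0.1, 100) µM.
    """
    if not 0 <= frac_active <= 1:
        raise ValueError("frac_active must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if chemical_ids is None:
        chemical_ids = [f"CHEM{i:04d}" for i in range(n_chemicals)]
    n_chemicals = len(chemical_ids)
    n_active = int(round(frac_active * n_chemicals))
    active_idx = set(rng.choice(n_chemicals, size=n_active, replace=False).tolist())

    rows = []
    decoy_positions = [i for i in range(n_chemicals) if i not in active_idx]
    boundary = decoy_positions[0] if (include_boundary_decoy and decoy_positions) else None
    for i, chem in enumerate(chemical_ids):
        if i in active_idx:
            hit, z = 1, 2.0 + abs(rng.normal(1.5, 0.75))
        elif i == boundary:
            hit, z = 1, 2.0  # exactly at the threshold: must fail the strict filter
        elif rng.random() < 0.5:
            hit, z = 0, rng.normal(1.0, 1.5)
        else:
            hit, z = 1, 2.0 - abs(rng.normal(1.0, 0.75))
        rows.append(
            {
                "chemical_id": chem,
                "endpoint": endpoint,
                "hit_call": hit,
                "cytotox_zscore": round(float(z), 6),
                "ac50_um": round(float(10 ** rng.uniform(-1, 2)), 6),
            }
        )
    df = pd.DataFrame(rows)
    truth = SyntheticTruth(
        seed=seed,
        params={"n_chemicals": n_chemicals, "frac_active": frac_active, "endpoint": endpoint},
        active_chemicals=sorted(chemical_ids[i] for i in active_idx),
    )
    return df, truth


def default_viability_params(chemicals: list[str] | None = None) -> dict[str, dict]:
    """Five 4PL parameter sets emulating variable household-chemical potency.

    One chemical's curve never drops to 90% viability in the 0-2000 µM
    test range (bottom plateau above 90%), exercising the fallback rule.
    """
    base = [
        {"top": 100.0, "bottom": 95.0, "midpoint_um": 500.0, "hill": 1.5},  # never reaches 90
        {"top": 105.0, "bottom": 5.0, "midpoint_um": 600.0, "hill": 2.0},
        {"top": 110.0, "bottom": 0.0, "midpoint_um": 900.0, "hill": 1.2},
        {"top": 100.0, "bottom": 10.0, "midpoint_um": 300.0, "hill": 2.5},
        {"top": 102.0, "bottom": 0.0, "midpoint_um": 450.0, "hill": 1.0},
    ]
    if chemicals is None:
        chemicals = [f"MIXCHEM{i}" for i in range(5)]
    return {chem: base[i % len(base)] for i, chem in enumerate(chemicals)}


def analytic_ac90(top: float, bottom: float, midpoint_um: float, hill: float,
                  target: float = 90.0) -> float | None:
    """Closed-form dose at ``target``% viability, or None if never crossed."""
    if not bottom < target < top:
        return None
    return float(midpoint_um * ((top - target) / (target - bottom)) ** (1.0 / hill))


def gen_viability(
    true_params: dict[str, dict] | None = None,
    doses: np.ndarray | list[float] | None = None,
    replicates: int = 3,
    sigma_pct: float = 5.0,
    vehicle_mean: float = 1000.0,
    seed: int = 1,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Raw fluorescence viability plates from known 4PL curves.

    Treated signals are ``vehicle_mean * v(d)/100 * (1 + eps)`` with
    multiplicative Gaussian noise of relative SD ``sigma_pct``%; vehicle
    wells (dose 0) read ``vehicle_mean * (1 + eps)``.  The truth stores
    each chemical's parameters and analytic AC90.  Defaults follow the
    bench design: 8 log-spaced doses spanning 1-2000 µM plus vehicle,
    in triplicate.
    """
    if sigma_pct < 0:
        raise ValueError("sigma_pct must be >= 0")
    if true_params is None:
        true_params = default_viability_params()
    if doses is None:
        doses = np.concatenate([[0.0], np.geomspace(1.0, 2000.0, 8)])
    doses = np.asarray(doses, dtype=float)
    if 0.0 not in doses:
        raise ValueError("doses must include 0 (vehicle)")
    rng = np.random.default_rng(seed)
    rows = []
    for chem in sorted(true_params):
        p = true_params[chem]
        for d in doses:
            v = 100.0 if d == 0 else four_pl(d, p["top"], p["bottom"], p["midpoint_um"], p["hill"])
            for rep in range(1, replicates + 1):
                noise = 1.0 + rng.normal(0.0, sigma_pct / 100.0)
                rows.append(
                    {
                        "chemical_id": chem,
                        "dose_um": float(d),
                        "signal": float(vehicle_mean * v / 100.0 * noise),
                        "replicate": rep,
                    }
                )
    truth = SyntheticTruth(
        seed=seed,
        params={"replicates": replicates, "sigma_pct": sigma_pct,
                "vehicle_mean": vehicle_mean, "doses": [float(d) for d in doses]},
        viability_params={c: dict(p) for c, p in true_params.items()},
        true_ac90={c: analytic_ac90(**true_params[c]) for c in true_params},
    )
    return pd.DataFrame(rows), truth


def default_log2fc(conditions: list[str] | None = None) -> dict[tuple[str, str], float]:
    """Planted expression effects: modest individual shifts, larger mixture shift.

    Two target genes are planted (the receptor transcript and a
    downstream target); individual chemical conditions get log2 fold
    changes in the 0.2-1.5 range and the mixture condition a joint
    effect, the pattern this workflow is designed to detect.
    """
    if conditions is None:
        conditions = [f"MIXCHEM{i}" for i in range(5)]
    individual_pparg = [1.24, 0.30, 0.94, 0.50, 0.22]
    individual_insr = [0.40, -0.19, 1.52, 0.30, 0.10]
    out: dict[tuple[str, str], float] = {}
    for i, cond in enumerate(conditions):
        out[(cond, "PPARG")] = individual_pparg[i % 5]
        out[(cond, "INSR")] = individual_insr[i % 5]
    out[("mixture", "PPARG")] = 1.2
    out[("mixture", "INSR")] = 0.67
    return out


def gen_qpcr(
    true_log2fc: dict[tuple[str, str], float] | None = None,
    n_bio: int = 3,
    n_tech: int = 3,
    sigma_ct: float = 0.1,
    base_ct: dict[str, float] | None = None,
    control_label: str = "vehicle",
    housekeeping: str = "GAPDH",
    seed: int = 1,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """qPCR Ct tables with planted log2 fold changes.

    Target Cts are ``base_ct[gene] - log2FC(condition, gene)`` plus a
    per-sample global offset (cancelled exactly by dCt normalization)
    and per-well Gaussian noise of SD ``sigma_ct`` cycles; housekeeping
    Cts sit at their base value plus the same offset and noise.  With
    ``sigma_ct = 0`` the ddCt pipeline recovers the planted effects
    exactly.  The control condition is planted at log2FC = 0.
    """
    if n_bio < 2:
        raise ValueError("n_bio must be >= 2 for downstream testing")
    if true_log2fc is None:
        true_log2fc = default_log2fc()
    if base_ct is None:
        base_ct = {"PPARG": 25.0, "INSR": 27.0, housekeeping: 18.0}
    genes = sorted({g for _, g in true_log2fc})
    conditions = sorted({c for c, _ in true_log2fc})
    rng = np.random.default_rng(seed)
    rows = []
    for cond in [control_label] + conditions:
        for b in range(1, n_bio + 1):
            sample = f"{cond}_b{b}"
            offset = float(rng.normal(0.0, 3.0 * sigma_ct)) if sigma_ct > 0 else 0.0
            for gene in genes + [housekeeping]:
                fc = 0.0 if (cond == control_label or gene == housekeeping) else \
                    true_log2fc.get((cond, gene), 0.0)
                true_ct = base_ct[gene] - fc + offset
                for t in range(1, n_tech + 1):
                    rows.append(
                        {
                            "sample": sample,
                            "condition": cond,
                            "gene": gene,
                            "ct": float(true_ct + rng.normal(0.0, sigma_ct)),
                            "bio_rep": b,
                            "tech_rep": t,
                        }
                    )
    truth = SyntheticTruth(
        seed=seed,
        params={"n_bio": n_bio, "n_tech": n_tech, "sigma_ct": sigma_ct,
                "control_label": control_label, "housekeeping": housekeeping,
                "base_ct": base_ct},
        true_log2fc={f"{c}|{g}": v for (c, g), v in true_log2fc.items()},
    )
    return pd.DataFrame(rows), truth


def simulate_all(seed: int, outdir: str | Path, *,
                 n_mixture_chemicals: int = 5) -> dict[str, Path]:
    """Write the full synthetic fixture suite (plus truth JSON) to a directory.

    Sub-seeds for the four generators are derived deterministically from
    the one master seed.  The viability and qPCR fixtures are generated
    for chemicals drawn from the broadest planted presence block, so the
    downstream prioritization stage finds them, closing the loop from
    co-occurrence planting to wet-lab-style outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s_presence, s_assay, s_via, s_qpcr = (
        int(s) % 2**31 for s in np.random.SeedSequence(seed).generate_state(4)
    )

    records, keyword_map, presence_truth = gen_presence(seed=s_presence)
    rec_path = outdir / "list_presence.csv"
    pd.DataFrame(records, columns=["chemical_id", "preferred_name", "keyword"]).to_csv(
        rec_path, index=False
    )
    map_path = outdir / "keyword_map.csv"
    pd.DataFrame(
        sorted(keyword_map.items()), columns=["keyword", "exposure_source_category"]
    ).to_csv(map_path, index=False)

    chems = sorted(presence_truth.row_blocks)
    assay_df, assay_truth = gen_assay(chemical_ids=chems, frac_active=0.7, seed=s_assay)
    assay_path = outdir / "assay_summary.csv"
    assay_df.rename(
        columns={
            "endpoint": "assay_component_endpoint_name",
            "hit_call": "hitc",
            "cytotox_zscore": "cytotox_z",
            "ac50_um": "ac50",
        }
    ).to_csv(assay_path, index=False)

    # the broadest planted block occupies every column block; pick active members
    colsets = _row_block_colsets(
        presence_truth.params["n_row_blocks"], presence_truth.params["n_col_blocks"]
    )
    broad_block = 1 + max(range(len(colsets)), key=lambda r: len(colsets[r]))
    broad_active = [
        c for c in chems
        if presence_truth.row_blocks[c] == broad_block
        and c in set(assay_truth.active_chemicals)
    ]
    mixture_chems = broad_active[:n_mixture_chemicals]

    via_df, via_truth = gen_viability(
        true_params=default_viability_params(mixture_chems), seed=s_via
    )
    via_path = outdir / "viability.csv"
    via_df.to_csv(via_path, index=False)

    qpcr_df, qpcr_truth = gen_qpcr(true_log2fc=default_log2fc(mixture_chems), seed=s_qpcr)
    qpcr_path = outdir / "qpcr_ct.csv"
    qpcr_df.to_csv(qpcr_path, index=False)

    truth = SyntheticTruth(
        seed=seed,
        params={
            "sub_seeds": {"presence": s_presence, "assay": s_assay,
                          "viability": s_via, "qpcr": s_qpcr},
            "mixture_chemicals": mixture_chems,
            "broad_block": broad_block,
        },
        row_blocks=presence_truth.row_blocks,
        col_blocks=presence_truth.col_blocks,
        active_chemicals=assay_truth.active_chemicals,
        viability_params=via_truth.viability_params,
        true_ac90=via_truth.true_ac90,
        true_log2fc=qpcr_truth.true_log2fc,
    )
    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)
    return {
        "list_presence": rec_path,
        "keyword_map": map_path,
        "assay_summary": assay_path,
        "viability": via_path,
        "qpcr_ct": qpcr_path,
        "truth": truth_path,
    }
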