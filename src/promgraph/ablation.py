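"""Feature-combination ablation harness.

Runs the full pipeline once per feature combination on the *same* split
and seed bundle, reporting Cohen's kappa (and the complete metric report)
per combination and per dataset condition.  Two families of combinations
are supported: local-encoding subsets of {NCP_ND, EIIP, BPB} (with all
embedding scales active) and embedding-scale subsets of
{node, community, global} (with all local parts active).  The classic
harness enumerates all seven non-empty subsets of each family, on a
balanced and on a 1:5 imbalanced condition.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import pandas as pd

from .encoders import LOCAL_PARTS
from .embeddings import SCALE_ORDER
from .io import PromoterDataset
from .pipeline import ExperimentConfig, run_experiment


def all_nonempty_subsets(items: tuple[str, ...]) -> list[tuple[str, ...]]:
    """All non-empty subsets in size-then-lexicographic enumeration order."""
    out: list[tuple[str, ...]] = []
    for r in range(1, len(items) + 1):
        out.extend(combinations(items, r))
    return out


def _with_combo(config: ExperimentConfig, kind: str,
                combo: tuple[str, ...]) -> ExperimentConfig:
    if kind == "local":
        return dataclasses.replace(config, parts=tuple(combo))
    embed = dataclasses.replace(config.embed, scales=tuple(combo))
    return dataclasses.replace(config, embed=embed)


def ablation_run(
    datasets: PromoterDataset | dict[str, PromoterDataset],
    local_combos: list[tuple[str, ...]] | None = None,
    embed_combos: list[tuple[str, ...]] | None = None,
    config: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """Run every requested combination on every dataset condition.

    Returns a long-form table with one row per (family, combination,
    condition): indicator columns per feature part, kappa, and the full
    metric suite.  A failed pipeline run is recorded with ``status``
    "failed" and the harness continues.
    """
    if isinstance(datasets, PromoterDataset):
        datasets = {"balanced": datasets}
    if local_combos is None and embed_combos is None:
        local_combos = all_nonempty_subsets(LOCAL_PARTS)
        embed_combos = all_nonempty_subsets(SCALE_ORDER)
    config = config or ExperimentConfig()

    jobs: list[tuple[str, tuple[str, ...]]] = []
    for combo in local_combos or []:
        jobs.append(("local", tuple(combo)))
    for combo in embed_combos or []:
        jobs.append(("embedding", tuple(combo)))

    rows = []
    for condition, dataset in datasets.items():
        for family, combo in jobs:
            parts_universe = LOCAL_PARTS if family == "local" else SCALE_ORDER
            row: dict = {"family": family, "condition": condition,
                         "combination": "+".join(combo)}
            for part in parts_universe:
                row[part] = int(part in combo)
            try:
                result = run_experiment(dataset, _with_combo(config, family, combo))
                row.update(result.metrics.to_dict() | {"status": "ok"})
                row.pop("counts", None)
            except Exception as exc:  # noqa: BLE001 - harness must continue
                row.update({"status": "failed", "error": str(exc)})
            rows.append(row)
    return pd.DataFrame(rows)


def kappa_table(results: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long-form results into combination x condition kappa."""
    ok = results[results["status"] == "ok"]
    return ok.pivot_table(
        index=["family", "combination"], columns="condition", values="kappa"
    )
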