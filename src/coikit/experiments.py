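"""Taxon-subsampling and mini-barcode simulation series.

Two stress tests of barcode-based classification:

* **taxon subsampling** — random subsets holding 75/50/25/10% of the species
  (all conspecific records of a chosen species are kept together), each
  re-analysed from scratch (distances -> NJ -> bootstrap -> group scoring);
* **mini-barcodes** — the alignment truncated to its first 450/300/200/100
  columns, likewise re-analysed, probing how much identification power short
  fragments retain.

Both emit long-format per-group records plus per-condition summaries; a
species-level uniqueness check reports record pairs from different species
that are identical over the retained columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import distance_matrix
from .monophyly import GroupScore, score_all_groups
from .seqio import Alignment
from .trees import bootstrap_support, neighbor_joining

__all__ = [
    "ExperimentConfig",
    "subsample_species",
    "run_subsampling",
    "truncate_alignment",
    "run_fragment_series",
    "species_uniqueness",
    "summarize_conditions",
]

RESULT_COLUMNS = [
    "condition",
    "replicate",
    "group",
    "level",
    "n_members",
    "monophyletic",
    "support",
    "excluded",
]


@dataclass(frozen=True)
class ExperimentConfig:
    fractions: tuple[float, ...] = (0.75, 0.50, 0.25, 0.10)
    n_subsets: int = 100
    fragment_lengths: tuple[int, ...] = (450, 300, 200, 100)
    bootstrap_reps: int = 1000
    seed: int = 0
    model: str = "k2p"
    support_threshold: float = 90.0

    def __post_init__(self):
        if any(not (0 < f <= 1) for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1]")
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def subsample_species(
    taxonomy: dict[str, tuple[str, str, str]],
    fraction: float,
    rng: np.random.Generator,
) -> list[str]:
    """Sample species uniformly without replacement; keep all their records.

    The species count is ``round(fraction x n_species)`` (half away from
    zero), floored at 3 so a tree can still be built.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    species = sorted({v[0] for v in taxonomy.values()})
    count = max(3, _round_half_away(fraction * len(species)))
    count = min(count, len(species))
    chosen = set(rng.choice(species, size=count, replace=False))
    ids = [i for i, v in taxonomy.items() if v[0] in chosen]
    if len(ids) < 3:
        raise ValueError(f"subset too small ({len(ids)} records)")
    return ids


def _analyse_subset(
    alignment: Alignment,
    taxonomy: dict[str, tuple[str, str, str]],
    model: str,
    bootstrap_reps: int,
    seed: int,
) -> list[GroupScore]:
    matrix = distance_matrix(alignment, model=model)
    if matrix.n_undefined:
        raise RuntimeError(f"{matrix.n_undefined} undefined distances in subset")
    tree = neighbor_joining(matrix)
    annotated, _, _ = bootstrap_support(alignment, model, tree, bootstrap_reps, seed)
    scores = []
    for level in ("genus", "family"):
        scores.extend(score_all_groups(annotated, taxonomy, level))
    return scores


def _rows(condition, replicate, scores: list[GroupScore]) -> list[dict]:
    return [
        {
            "condition": condition,
            "replicate": replicate,
            "group": s.group,
            "level": s.level,
            "n_members": s.n_members,
            "monophyletic": s.monophyletic,
            "support": s.support,
            "excluded": s.excluded,
        }
        for s in scores
    ]


def run_subsampling(
    alignment: Alignment,
    config: ExperimentConfig,
) -> tuple[pd.DataFrame, list[str]]:
    """Taxon-subsampling series: fractions x replicates, each fully re-analysed.

    Returns the long-format results frame and a list of failure messages
    (failed replicates are logged and skipped, the run continues).
    """
    taxonomy = alignment.taxonomy()
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    failures: list[str] = []
    run_idx = 0
    for fraction in config.fractions:
        for rep in range(config.n_subsets):
            run_idx += 1
            boot_seed = config.seed + run_idx * 100_000
            try:
                ids = subsample_species(taxonomy, fraction, rng)
                sub = alignment.subset(ids)
                scores = _analyse_subset(
                    sub, taxonomy, config.model, config.bootstrap_reps, boot_seed
                )
            except Exception as exc:  # logged, run continues
                failures.append(f"fraction={fraction} replicate={rep}: {exc}")
                continue
            rows.extend(_rows(fraction, rep, scores))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS), failures


def truncate_alignment(alignment: Alignment, length: int) -> Alignment:
    """Keep alignment columns 1..length (mini-barcode prefix)."""
    return alignment.truncate(length)


def run_fragment_series(
    alignment: Alignment,
    config: ExperimentConfig,
) -> tuple[pd.DataFrame, list[str]]:
    """Mini-barcode series: one full re-analysis per fragment length."""
    taxonomy = alignment.taxonomy()
    rows: list[dict] = []
    failures: list[str] = []
    for k, length in enumerate(config.fragment_lengths):
        boot_seed = config.seed + (k + 1) * 1_000_000
        try:
            sub = truncate_alignment(alignment, length)
            scores = _analyse_subset(
                sub, taxonomy, config.model, config.bootstrap_reps, boot_seed
            )
        except Exception as exc:
            failures.append(f"length={length}: {exc}")
            continue
        rows.extend(_rows(length, 0, scores))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS), failures


def summarize_conditions(
    results: pd.DataFrame, support_threshold: float = 90.0
) -> pd.DataFrame:
    """Per-condition counts: scored, monophyletic, well-supported, mean support."""
    rows = []
    for (condition, level), grp in results.groupby(["condition", "level"], sort=False):
        scored = grp[~grp["excluded"]]
        mono = scored[scored["monophyletic"] == True]  # noqa: E712
        supported = mono[mono["support"] > support_threshold]
        rows.append(
            {
                "condition": condition,
                "level": level,
                "n_scored": len(scored),
                "n_monophyletic": len(mono),
                "n_supported": len(supported),
                "mean_support": mono["support"].astype(float).mean(),
            }
        )
    return pd.DataFrame(rows)


def species_uniqueness(alignment: Alignment, length: int) -> pd.DataFrame:
    """Record pairs from different species identical over the first ``length``
    columns (collisions), plus pairs with no comparable sites.

    Uniqueness at ``length`` holds iff the returned frame has no
    ``collision`` rows.
    """
    enc = alignment.encoded()[:, :length]
    valid = enc >= 0
    taxonomy = alignment.taxonomy()
    ids = alignment.ids
    rows = []
    n = len(ids)
    for i in range(n - 1):
        both = valid[i] & valid[i + 1 :]
        comparable = both.sum(axis=1)
        diffs = ((enc[i] != enc[i + 1 :]) & both).sum(axis=1)
        for off in range(n - 1 - i):
            j = i + 1 + off
            if taxonomy[ids[i]][0] == taxonomy[ids[j]][0]:
                continue
            if comparable[off] == 0:
                rows.append(
                    {"id_a": ids[i], "id_b": ids[j], "kind": "no_overlap",
                     "comparable": 0, "differences": 0}
                )
            elif diffs[off] == 0:
                rows.append(
                    {"id_a": ids[i], "id_b": ids[j], "kind": "collision",
                     "comparable": int(comparable[off]), "differences": 0}
                )
    return pd.DataFrame(rows, columns=["id_a", "id_b", "kind", "comparable", "differences"])
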