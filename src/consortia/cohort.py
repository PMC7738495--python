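"""Cohort-level aggregation of per-sample consortium selections.

Given the minimal community selected for every metagenome in a cohort, this
module reports, per species: how often it was selected (overall and within
each sample group, e.g. country of origin), and its median 1-based picking
rank over the samples where it made the community.  The core consortium is
the set of species selected in more than a prevalence threshold (default 50%)
of the samples of at least one group.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path
import statistics

import pandas as pd

from .selection import SelectionResult

__all__ = [
    "GroupLabels",
    "GenomeSummary",
    "CohortSummary",
    "read_group_labels",
    "write_group_labels",
    "aggregate_selections",
    "core_consortium",
]

#: Mapping sample_id -> group name (e.g. country of origin).
GroupLabels = Mapping[str, str]


def read_group_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``id``/``group`` TSV into a sample→group mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["id", "group"]:
        raise ValueError(f"{path}: expected columns 'id' and 'group', got {list(df.columns)}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    return dict(zip(df["id"], df["group"]))


def write_group_labels(labels: GroupLabels, path: str | Path) -> None:
    pd.DataFrame({"id": list(labels), "group": list(labels.values())}).to_csv(
        path, sep="\t", index=False
    )


@dataclass(frozen=True)
class GenomeSummary:
    """Selection statistics of one genome across the cohort."""

    genome_id: str
    n_selected_total: int
    prevalence_total: float
    prevalence_by_group: Mapping[str, float]
    median_rank: float | None  # None when never selected


@dataclass(frozen=True)
class CohortSummary:
    """Per-genome prevalence and rank statistics over a whole cohort."""

    n_samples: int
    group_sizes: Mapping[str, int]
    genomes: Mapping[str, GenomeSummary]

    def __getitem__(self, genome_id: str) -> GenomeSummary:
        return self.genomes[genome_id]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per genome, group prevalences as columns."""
        groups = sorted(self.group_sizes)
        rows = []
        for gid, s in sorted(self.genomes.items()):
            row: dict[str, object] = {
                "genome_id": gid,
                "n_selected_total": s.n_selected_total,
                "prevalence_total": s.prevalence_total,
                "median_rank": s.median_rank,
            }
            for g in groups:
                row[f"prevalence_{g}"] = s.prevalence_by_group.get(g, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)


def aggregate_selections(
    results: Sequence[SelectionResult], labels: GroupLabels
) -> CohortSummary:
    """Aggregate per-sample selections into cohort prevalence and rank stats.

    Prevalence counts membership in the knee-truncated community, not the full
    greedy ranking; the median rank of a genome uses its 1-based position in
    ``ranked_genomes``, over exactly those samples where it is in the
    community (midpoint convention for even counts).
    """
    if not results:
        raise ValueError("aggregate_selections needs at least one selection result")
    seen: set[str] = set()
    for r in results:
        if r.sample_id in seen:
            raise ValueError(f"duplicate sample id {r.sample_id!r}")
        seen.add(r.sample_id)
        if r.sample_id not in labels:
            raise ValueError(f"sample {r.sample_id!r} has no group label")

    n_samples = len(results)
    group_sizes: dict[str, int] = {}
    for r in results:
        g = labels[r.sample_id]
        group_sizes[g] = group_sizes.get(g, 0) + 1

    counts: dict[str, int] = {}
    group_counts: dict[str, dict[str, int]] = {}
    ranks: dict[str, list[int]] = {}
    all_genomes: set[str] = set()
    for r in results:
        g = labels[r.sample_id]
        all_genomes.update(r.ranked_genomes)
        for rank, gid in enumerate(r.community, start=1):
            counts[gid] = counts.get(gid, 0) + 1
            group_counts.setdefault(gid, {})[g] = group_counts.setdefault(gid, {}).get(g, 0) + 1
            ranks.setdefault(gid, []).append(rank)

    genomes: dict[str, GenomeSummary] = {}
    for gid in sorted(all_genomes):
        n_sel = counts.get(gid, 0)
        by_group = {
            g: group_counts.get(gid, {}).get(g, 0) / size for g, size in group_sizes.items()
        }
        genomes[gid] = GenomeSummary(
            genome_id=gid,
            n_selected_total=n_sel,
            prevalence_total=n_sel / n_samples,
            prevalence_by_group=by_group,
            median_rank=statistics.median(ranks[gid]) if gid in ranks else None,
        )
    return CohortSummary(n_samples=n_samples, group_sizes=group_sizes, genomes=genomes)


def core_consortium(
    summary: CohortSummary,
    threshold: float = 0.5,
    mode: str = "any_group",
) -> list[str]:
    """Genomes selected in strictly more than ``threshold`` of samples.

    ``mode='any_group'`` requires prevalence > threshold in at least one
    group; ``mode='overall'`` applies the threshold to the whole cohort.
    Output ordered by decreasing overall prevalence, ties lexicographic.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if mode not in ("any_group", "overall"):
        raise ValueError(f"unknown mode {mode!r}; use 'any_group' or 'overall'")
    selected = []
    for gid, s in summary.genomes.items():
        if mode == "overall":
            hit = s.prevalence_total > threshold
        else:
            hit = any(p > threshold for p in s.prevalence_by_group.values())
        if hit:
            selected.append(gid)
    return sorted(selected, key=lambda g: (-summary.genomes[g].prevalence_total, g))
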