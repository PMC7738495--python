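"""Host-ecology statistics: cultured fraction and host-enrichment calls.

Works on relative-abundance tables of amplicon-derived taxa with a host label
per sample (pig, mouse, human, ...).  Three questions are answered downstream
of sequence matching (which is consumed as a precomputed set of matched taxa,
not recomputed here):

* cultured fraction — what percentage of a sample's reads is covered by taxa
  matched to cultured isolates at a stated identity threshold;
* do cultured fractions differ between hosts (Kruskal–Wallis);
* which taxa are enriched in a target host — detected in at least a
  prevalence threshold of its samples (default 20%) and at a higher median
  relative abundance than in *every* other host, by one-sided Wilcoxon
  rank-sum with Benjamini–Hochberg correction pooled over all taxa and
  host comparisons (adjusted p < 0.05).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles import UnknownEntityError

__all__ = [
    "AbundanceTable",
    "MatchSet",
    "HostComparison",
    "read_abundance_table",
    "write_abundance_table",
    "cultured_fraction",
    "cultured_fractions",
    "compare_hosts",
    "bh_adjust",
    "host_enrichment",
]

_ROW_SUM_TOL = 1e-6


@dataclass(frozen=True)
class AbundanceTable:
    """Samples × taxa relative abundances with a host label per sample.

    ``data`` is indexed by sample id with taxon columns; entries are
    fractions, each row summing to at most 1 (plus tolerance).
    """

    data: pd.DataFrame
    host: pd.Series  # sample_id -> host name

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate taxon ids")
        if (self.data.values < -1e-12).any():
            raise ValueError("relative abundances must be non-negative")
        sums = self.data.sum(axis=1)
        if (sums > 1.0 + _ROW_SUM_TOL).any():
            bad = sums[sums > 1.0 + _ROW_SUM_TOL].index.tolist()
            raise ValueError(f"rows exceed total abundance 1: {bad}")
        missing = self.data.index.difference(self.host.index)
        if len(missing):
            raise ValueError(f"samples without host label: {missing.tolist()}")
        object.__setattr__(self, "host", self.host.loc[self.data.index])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def hosts(self) -> list[str]:
        return sorted(self.host.unique())


@dataclass(frozen=True)
class MatchSet:
    """Taxa matched to cultured isolates at a stated sequence-identity level."""

    taxa: frozenset[str]
    identity_threshold: float | None = None  # metadata only, e.g. 0.97

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", frozenset(self.taxa))


def read_abundance_table(path: str | Path) -> AbundanceTable:
    """Read the ``id``/``host``/taxa... TSV layout."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if list(df.columns[:2]) != ["id", "host"]:
        raise ValueError(f"{path}: expected leading columns 'id' and 'host'")
    host = pd.Series(df["host"].values, index=df["id"].values)
    data = df.drop(columns=["id", "host"]).astype(float)
    data.index = pd.Index(df["id"].values)
    return AbundanceTable(data=data, host=host)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    out = table.data.copy()
    out.insert(0, "host", table.host.values)
    out.insert(0, "id", out.index)
    out.to_csv(path, sep="\t", index=False)


def cultured_fraction(table: AbundanceTable, sample_id: str, matched: MatchSet) -> float:
    """Percentage of a sample's relative abundance carried by matched taxa."""
    if sample_id not in table.data.index:
        raise UnknownEntityError(sample_id)
    cols = [t for t in table.taxon_ids if t in matched.taxa]
    return 100.0 * float(table.data.loc[sample_id, cols].sum())


def cultured_fractions(table: AbundanceTable, matched: MatchSet) -> pd.Series:
    """Cultured fraction (percent) of every sample, in table order."""
    cols = [t for t in table.taxon_ids if t in matched.taxa]
    return 100.0 * table.data[cols].sum(axis=1)


@dataclass(frozen=True)
class HostComparison:
    """Kruskal–Wallis comparison of per-sample values across hosts."""

    statistic: float
    p_value: float
    medians: Mapping[str, float]
    q25: Mapping[str, float]
    q75: Mapping[str, float]


def compare_hosts(fractions: Mapping[str, Sequence[float]]) -> HostComparison:
    """Kruskal–Wallis H test (tie-corrected) across ≥2 hosts.

    Also reports the per-host median and quartiles.  If every observation is
    identical the H statistic is 0 and p = 1 by convention (no variation).
    """
    if len(fractions) < 2:
        raise ValueError("need at least two hosts")
    groups = {h: np.asarray(v, dtype=float) for h, v in fractions.items()}
    for h, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"host {h!r} has fewer than two samples")
    medians = {h: float(np.median(v)) for h, v in groups.items()}
    q25 = {h: float(np.percentile(v, 25)) for h, v in groups.items()}
    q75 = {h: float(np.percentile(v, 75)) for h, v in groups.items()}
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0.0:
        return HostComparison(0.0, 1.0, medians, q25, q75)
    h_stat, p = stats.kruskal(*groups.values())
    return HostComparison(float(h_stat), float(p), medians, q25, q75)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def host_enrichment(
    table: AbundanceTable,
    target_host: str,
    prevalence_threshold: float = 0.20,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Call taxa enriched in ``target_host`` relative to every other host.

    A taxon is enriched iff (i) it is detected (abundance > 0) in at least
    ``prevalence_threshold`` of the target host's samples, and (ii) against
    every other host its target-host median abundance is strictly greater and
    the one-sided Wilcoxon rank-sum test (target greater) has BH-adjusted
    p < ``alpha``, where the BH family pools all taxon × comparison tests.

    Returns one row per taxon with per-host prevalence and median columns,
    raw and adjusted p per comparison, and the final ``enriched`` flag.
    """
    hosts = table.hosts
    if target_host not in hosts:
        raise ValueError(f"target host {target_host!r} not present in the table")
    others = [h for h in hosts if h != target_host]
    if not others:
        raise ValueError("need at least one non-target host")
    if not 0.0 <= prevalence_threshold <= 1.0:
        raise ValueError("prevalence_threshold must lie in [0, 1]")

    by_host = {h: table.data.loc[table.host == h] for h in hosts}
    taxa = table.taxon_ids
    out = pd.DataFrame(index=pd.Index(taxa, name="taxon_id"))
    for h in hosts:
        sub = by_host[h]
        out[f"prevalence_{h}"] = (sub > 0).mean(axis=0).values
        out[f"median_{h}"] = sub.median(axis=0).values

    raw: dict[str, list[float]] = {h: [] for h in others}
    for taxon in taxa:
        tvals = by_host[target_host][taxon].values
        for h in others:
            ovals = by_host[h][taxon].values
            if np.ptp(np.concatenate([tvals, ovals])) == 0.0:
                raw[h].append(1.0)  # constant data: no evidence either way
            else:
                raw[h].append(
                    float(stats.mannwhitneyu(tvals, ovals, alternative="greater").pvalue)
                )
    pooled = [raw[h][i] for i in range(len(taxa)) for h in others]
    adjusted = bh_adjust(pooled)
    adj: dict[str, list[float]] = {h: [] for h in others}
    pos = 0
    for _ in taxa:
        for h in others:
            adj[h].append(adjusted[pos])
            pos += 1
    for h in others:
        out[f"p_raw_vs_{h}"] = raw[h]
        out[f"p_adj_vs_{h}"] = adj[h]

    enriched = out[f"prevalence_{target_host}"] >= prevalence_threshold
    for h in others:
        enriched &= out[f"median_{target_host}"] > out[f"median_{h}"]
        enriched &= out[f"p_adj_vs_{h}"] < alpha
    out["enriched"] = enriched
    return out
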