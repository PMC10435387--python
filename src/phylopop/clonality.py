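"""Clonemate and selfed-offspring detection from shared heterozygosity.

The pairwise statistic is the Jaccard fraction of co-called sites that are
heterozygous in both samples over sites heterozygous in either; clonemates
sit near 1, unrelated pairs far below, and a selfed offspring's
heterozygous sites are a ~1/2 subset of its parent's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeTable

__all__ = [
    "RelatednessReport",
    "shared_het",
    "pairwise_shared_het",
    "detect_clones",
    "detect_selfing",
    "build_exclusion_ledger",
]


@dataclass
class SelfingPair:
    parent: str
    descendant: str
    het_containment: float  # fraction of descendant het sites het in parent
    het_ratio: float  # |het(descendant)| / |het(parent)|


@dataclass
class RelatednessReport:
    """Pairwise statistics, groupings and the exclusion ledger."""

    shared_het: Optional[pd.DataFrame] = None
    clone_groups: list[list[str]] = field(default_factory=list)
    selfing_pairs: list[SelfingPair] = field(default_factory=list)
    exclusions: dict[str, str] = field(default_factory=dict)  # sample -> reason
    retained: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sample": s, "status": "excluded", "reason": r}
                for s, r in self.exclusions.items()]
        rows += [{"sample": s, "status": "retained", "reason": ""}
                 for s in self.retained]
        return pd.DataFrame(rows)


def shared_het(
    a: str, b: str, table: GenotypeTable, min_overlap: int = 100
) -> float:
    """|sites het in both| / |sites het in either|, on co-called sites."""
    ia, ib = table.sample_index(a), table.sample_index(b)
    het = table.het_mask()
    called = ~table.missing_mask()
    both_called = called[:, ia] & called[:, ib]
    if int(both_called.sum()) < min_overlap:
        raise ValueError(
            f"samples {a!r} and {b!r} share only {int(both_called.sum())} "
            f"called sites (< {min_overlap})"
        )
    ha = het[:, ia] & both_called
    hb = het[:, ib] & both_called
    union = int((ha | hb).sum())
    if union == 0:
        return 1.0  # no heterozygosity at all: indistinguishable
    return float((ha & hb).sum() / union)


def pairwise_shared_het(
    table: GenotypeTable, min_overlap: int = 100
) -> pd.DataFrame:
    """Symmetric matrix of :func:`shared_het` over all sample pairs."""
    het = table.het_mask().astype(np.float64)
    called = (~table.missing_mask()).astype(np.float64)
    overlap = called.T @ called
    n = table.n_samples
    off_diag = ~np.eye(n, dtype=bool)
    if n > 1 and overlap[off_diag].min() < min_overlap:
        i, j = np.unravel_index(
            np.argmin(np.where(off_diag, overlap, np.inf)), overlap.shape
        )
        raise ValueError(
            f"samples {table.samples[int(i)]!r} and {table.samples[int(j)]!r} "
            f"share only {int(overlap[i, j])} called sites (< {min_overlap})"
        )
    inter = het.T @ het  # both het (het implies called)
    het_in_called = het.T @ called  # (i,j): het in i and called in j
    union = het_in_called + het_in_called.T - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    np.fill_diagonal(out, 1.0)
    return pd.DataFrame(out, index=table.samples, columns=table.samples)


def _genotype_identity(table: GenotypeTable, i: int, j: int) -> float:
    called = ~table.missing_mask()
    both = called[:, i] & called[:, j]
    if not both.any():
        return 0.0
    gi = np.sort(table.genotypes[both, i], axis=1)
    gj = np.sort(table.genotypes[both, j], axis=1)
    return float((gi == gj).all(axis=1).mean())


def detect_clones(
    table: GenotypeTable,
    clone_threshold: float = 0.9,
    error_rate_allowance: float = 0.02,
    min_overlap: int = 100,
    shared: Optional[pd.DataFrame] = None,
) -> list[list[str]]:
    """Single-linkage clone groups from shared heterozygosity + identity.

    A pair is linked when shared_het >= ``clone_threshold`` and overall
    genotype identity >= 1 - ``error_rate_allowance``.  Returns groups of
    size >= 2, each sorted, in first-appearance order.
    """
    if shared is None:
        shared = pairwise_shared_het(table, min_overlap)
    n = table.n_samples
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    sh = shared.to_numpy()
    for i in range(n):
        for j in range(i + 1, n):
            if sh[i, j] >= clone_threshold and _genotype_identity(
                table, i, j
            ) >= 1.0 - error_rate_allowance:
                parent[find(i)] = find(j)
    groups: dict[int, list[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(table.samples[i])
    return [sorted(g) for g in groups.values() if len(g) >= 2]


def clone_representatives(
    table: GenotypeTable, groups: list[list[str]]
) -> dict[str, list[str]]:
    """For each group: representative (highest call rate, ties by name) ->
    excluded members."""
    called = ~table.missing_mask()
    rates = {s: float(called[:, table.sample_index(s)].mean()) for g in groups for s in g}
    out = {}
    for g in groups:
        # highest call rate wins; ties go to the first name alphabetically
        rep = min(g, key=lambda s: (-rates[s], s))
        out[rep] = [s for s in g if s != rep]
    return out


def detect_selfing(
    table: GenotypeTable,
    containment_min: float = 0.99,
    ci_level: float = 0.99,
    clone_groups: Optional[list[list[str]]] = None,
    min_het: int = 20,
) -> list[SelfingPair]:
    """Flag ordered (parent, descendant) pairs consistent with one
    generation of selfing.

    Conditions: (i) >= ``containment_min`` of the descendant's het sites
    are het in the parent; (ii) the het-count ratio lies in the central
    ``ci_level`` binomial interval around 1/2; (iii) the pair is not a
    clone pair.  The sample with fewer het sites is the descendant.
    """
    het = table.het_mask().astype(np.float64)
    called = (~table.missing_mask()).astype(np.float64)
    het_in_called = het.T @ called  # (i,j): het in i, called in j
    inter = het.T @ het
    clone_sets = []
    if clone_groups:
        clone_sets = [set(g) for g in clone_groups]
    alpha = (1.0 - ci_level) / 2.0
    ci_cache: dict[int, tuple[float, float]] = {}
    pairs: list[SelfingPair] = []
    n = table.n_samples
    for i in range(n):
        for j in range(i + 1, n):
            a, b = table.samples[i], table.samples[j]
            if any(a in cs and b in cs for cs in clone_sets):
                continue
            ni, nj = int(het_in_called[i, j]), int(het_in_called[j, i])
            if max(ni, nj) < min_het:
                continue
            # descendant = fewer het sites
            if ni <= nj:
                d_idx, p_idx, nd, np_ = i, j, ni, nj
            else:
                d_idx, p_idx, nd, np_ = j, i, nj, ni
            containment = float(inter[i, j] / nd) if nd else 1.0
            if containment < containment_min:
                continue
            if np_ not in ci_cache:
                ci_cache[np_] = (
                    float(stats.binom.ppf(alpha, np_, 0.5)),
                    float(stats.binom.ppf(1.0 - alpha, np_, 0.5)),
                )
            lo, hi_b = ci_cache[np_]
            if not lo <= nd <= hi_b:
                continue
            pairs.append(
                SelfingPair(
                    parent=table.samples[p_idx],
                    descendant=table.samples[d_idx],
                    het_containment=containment,
                    het_ratio=nd / np_ if np_ else float("nan"),
                )
            )
    return pairs


def build_exclusion_ledger(
    table: GenotypeTable,
    clone_groups: list[list[str]],
    selfing_pairs: list[SelfingPair],
    missing_excluded: list[str],
    shared: Optional[pd.DataFrame] = None,
) -> RelatednessReport:
    """Combine exclusions with priority selfing > clonality > missingness.

    Each excluded sample gets exactly one reason; retained = input -
    excluded.
    """
    exclusions: dict[str, str] = {}
    for p in selfing_pairs:
        exclusions.setdefault(p.descendant, "selfing")
    reps = clone_representatives(table, clone_groups)
    for rep, members in reps.items():
        for m in members:
            exclusions.setdefault(m, "clone")
    for s in missing_excluded:
        exclusions.setdefault(s, "missing")
    retained = [s for s in table.samples if s not in exclusions]
    report = RelatednessReport(
        shared_het=shared,
        clone_groups=clone_groups,
        selfing_pairs=selfing_pairs,
        exclusions=exclusions,
        retained=retained,
    )
    assert len(retained) + len(exclusions) == table.n_samples
    return report
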