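"""Gene presence/absence calling and core/shell/cloud classification."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PresenceRules",
    "call_presence",
    "build_pav_matrix",
    "qc_samples",
    "classify_genes",
    "classify_pav",
]


@dataclass
class PresenceRules:
    """Thresholds of the two presence rules.

    Rule (a): a single alignment with identity and coverage above
    ``single_identity``/``single_coverage``.  Rule (b): hits split across
    at most ``max_scaffolds`` scaffolds whose summed coverage and
    length-weighted identity clear the higher ``split_*`` thresholds.
    """

    single_identity: float = 0.60
    single_coverage: float = 0.60
    split_identity: float = 0.85
    split_coverage: float = 0.85
    max_scaffolds: int = 3


def call_presence(
    hits: Sequence[tuple[str, float, float]],
    rules: Optional[PresenceRules] = None,
) -> bool:
    """Decide presence of one gene in one assembly.

    ``hits`` is a sequence of (scaffold, identity, coverage) rows; coverage
    fractions on distinct scaffolds are treated as non-overlapping.
    """
    rules = rules or PresenceRules()
    if not hits:
        return False
    for _, ident, cov in hits:
        if ident > rules.single_identity and cov > rules.single_coverage:
            return True
    scaffolds = {h[0] for h in hits}
    if len(scaffolds) <= rules.max_scaffolds:
        covs = np.array([h[2] for h in hits], dtype=float)
        idents = np.array([h[1] for h in hits], dtype=float)
        total_cov = min(covs.sum(), 1.0)
        if covs.sum() > 0:
            weighted_ident = float((idents * covs).sum() / covs.sum())
        else:
            weighted_ident = 0.0
        if total_cov > rules.split_coverage and weighted_ident > rules.split_identity:
            return True
    return False


def build_pav_matrix(
    hits: pd.DataFrame,
    rules: Optional[PresenceRules] = None,
    genes: Optional[Sequence[str]] = None,
    samples: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Apply :func:`call_presence` to a hit table (gene, sample, scaffold,
    identity, coverage) and return a boolean genes x samples matrix."""
    rules = rules or PresenceRules()
    genes = list(genes) if genes is not None else sorted(hits["gene"].unique())
    samples = (
        list(samples) if samples is not None else sorted(hits["sample"].unique())
    )
    mat = pd.DataFrame(False, index=genes, columns=samples, dtype=bool)
    for (gene, sample), grp in hits.groupby(["gene", "sample"], sort=False):
        if gene in mat.index and sample in mat.columns:
            rows = list(zip(grp["scaffold"], grp["identity"], grp["coverage"]))
            mat.loc[gene, sample] = call_presence(rows, rules)
    return mat


def qc_samples(
    pav: pd.DataFrame, min_genes: int = 17500
) -> tuple[pd.DataFrame, list[str]]:
    """Drop samples with present-gene count <= ``min_genes`` (strictly
    greater counts are kept)."""
    counts = pav.sum(axis=0)
    excluded = [s for s in pav.columns if counts[s] <= min_genes]
    return pav.drop(columns=excluded), excluded


def classify_genes(
    frequencies: pd.Series,
    fallback_thresholds: tuple[float, float] = (0.15, 0.90),
    max_iter: int = 200,
) -> pd.Series:
    """Deterministic 1-D three-cluster split of per-gene frequencies.

    Lloyd's algorithm with centroids initialised at the 0.1/0.5/0.9
    quantiles; clusters are labelled cloud < shell < core by ascending
    centroid.  With fewer than three distinct frequencies the k-means
    problem is degenerate and fixed thresholds are used instead.
    """
    f = frequencies.to_numpy(dtype=float)
    if ((f < 0) | (f > 1)).any():
        raise ValueError("frequencies must lie in [0, 1]")
    labels = np.empty(f.size, dtype=object)
    if np.unique(f).size < 3:
        lo, hi = fallback_thresholds
        labels[f <= lo] = "cloud"
        labels[(f > lo) & (f < hi)] = "shell"
        labels[f >= hi] = "core"
        return pd.Series(labels, index=frequencies.index, name="class")

    centroids = np.quantile(f, [0.1, 0.5, 0.9])
    for _ in range(max_iter):
        assign = np.argmin(np.abs(f[:, None] - centroids[None, :]), axis=1)
        new = centroids.copy()
        for k in range(3):
            if (assign == k).any():
                new[k] = f[assign == k].mean()
        if np.allclose(new, centroids):
            break
        centroids = new
    order = np.argsort(centroids)
    name_of = {int(order[0]): "cloud", int(order[1]): "shell", int(order[2]): "core"}
    labels[:] = [name_of[int(a)] for a in assign]
    return pd.Series(labels, index=frequencies.index, name="class")


def classify_pav(
    pav: pd.DataFrame,
    min_genes: int = 17500,
    rules: Optional[PresenceRules] = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, list[str]]:
    """Sample QC, observation frequencies and gene classes in one call."""
    kept, excluded = qc_samples(pav, min_genes)
    freq = kept.mean(axis=1)
    classes = classify_genes(freq)
    return kept, freq, classes, excluded
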