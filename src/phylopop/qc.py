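"""Post-calling SNP filter cascade and derived SNP-set operations.

Boundary semantics are strict everywhere: a metric exactly at its threshold
passes.  Missing INFO annotations (e.g. rank sums at sites without
heterozygotes) pass the corresponding criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import ANNOTATION_CLASSES, GenotypeTable, MISSING

__all__ = [
    "FilterConfig",
    "FilterReport",
    "mask_near_variants",
    "apply_hard_filters",
    "mask_genotypes",
    "select_biallelic",
    "intersect_regions",
    "subset_by_annotation",
    "thin_by_distance",
    "sample_missing_filter",
    "run_cascade",
    "pos_to_bed_index",
]


@dataclass
class FilterConfig:
    """Thresholds of the hard-filter cascade (strict inequalities)."""

    indel_window: int = 20
    mq_min: float = 40.0
    fs_max: float = 60.0
    qd_min: float = 10.0
    rank_sum_abs_max: float = 2.5
    sor_max: float = 3.0
    dp_multiplier: float = 2.0
    gq_min: int = 30
    dp_min: int = 10
    thin_distance: int = 3000
    sample_missing_max: float = 0.15

    def validate(self) -> None:
        for name in (
            "mq_min", "fs_max", "qd_min", "rank_sum_abs_max", "sor_max",
            "dp_multiplier",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.thin_distance <= 0:
            raise ValueError("thin_distance must be > 0")
        if self.indel_window < 0:
            raise ValueError("indel_window must be >= 0")


@dataclass
class FilterReport:
    """Per-stage accounting: input = removed + retained at every stage."""

    stages: list[dict] = field(default_factory=list)
    sample_missing_rates: dict[str, float] = field(default_factory=dict)
    excluded_samples: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def add_stage(self, name: str, n_in: int, n_out: int, **extra) -> None:
        self.stages.append(
            {"stage": name, "input": n_in, "removed": n_in - n_out,
             "retained": n_out, **extra}
        )
        self.log.append(f"{name}: {n_in} -> {n_out}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def check(self) -> None:
        for s in self.stages:
            assert s["input"] == s["removed"] + s["retained"], s


def _require_sorted(table: GenotypeTable) -> None:
    s = table.sites
    if len(s) < 2:
        return
    same = s["chrom"].to_numpy()[1:] == s["chrom"].to_numpy()[:-1]
    inc = s["pos"].to_numpy()[1:] >= s["pos"].to_numpy()[:-1]
    if np.any(same & ~inc):
        raise ValueError("site table is not sorted by (chrom, pos)")


def mask_near_variants(table: GenotypeTable, window: int = 20) -> GenotypeTable:
    """Drop SNPs within ``window`` bp (inclusive) of any non-SNP variant."""
    _require_sorted(table)
    s = table.sites
    vt = s["vartype"].to_numpy()
    is_snp = vt == "snp"
    keep = np.ones(len(s), dtype=bool)
    others = s.loc[~is_snp, ["chrom", "pos"]]
    if len(others):
        chrom = s["chrom"].to_numpy()
        pos = s["pos"].to_numpy()
        for oc, op in zip(others["chrom"].to_numpy(), others["pos"].to_numpy()):
            near = is_snp & (chrom == oc) & (np.abs(pos - op) <= window)
            keep &= ~near
    keep |= ~is_snp  # non-SNP records pass through untouched here
    return table.subset_sites(keep)


def apply_hard_filters(
    table: GenotypeTable, config: Optional[FilterConfig] = None
) -> tuple[GenotypeTable, FilterReport]:
    """Site-level hard filters; removal if any criterion fails strictly.

    The DP ceiling is ``dp_multiplier x mean site DP`` of the input table.
    Missing (NaN) metrics pass their criterion.
    """
    config = config or FilterConfig()
    config.validate()
    s = table.sites
    for col in ("MQ", "FS", "QD", "MQRankSum", "ReadPosRankSum", "SOR", "DP"):
        vals = s[col]
        if not pd.api.types.is_numeric_dtype(vals):
            bad = s.loc[pd.to_numeric(vals, errors="coerce").isna() & vals.notna()]
            if len(bad):
                r = bad.iloc[0]
                raise ValueError(
                    f"non-numeric {col} at {r['chrom']}:{r['pos']}"
                )
            s = s.copy()
            s[col] = pd.to_numeric(vals, errors="coerce")

    def _fail(series: pd.Series, cond) -> np.ndarray:
        arr = series.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            f = cond(arr)
        f[np.isnan(arr)] = False
        return f

    dp_ceiling = config.dp_multiplier * float(np.nanmean(s["DP"].to_numpy(dtype=float)))
    fails = {
        "MQ": _fail(s["MQ"], lambda a: a < config.mq_min),
        "FS": _fail(s["FS"], lambda a: a > config.fs_max),
        "QD": _fail(s["QD"], lambda a: a < config.qd_min),
        "MQRankSum": _fail(s["MQRankSum"], lambda a: np.abs(a) > config.rank_sum_abs_max),
        "ReadPosRankSum": _fail(
            s["ReadPosRankSum"], lambda a: np.abs(a) > config.rank_sum_abs_max
        ),
        "SOR": _fail(s["SOR"], lambda a: a > config.sor_max),
        "DP": _fail(s["DP"], lambda a: a > dp_ceiling),
    }
    any_fail = np.zeros(len(s), dtype=bool)
    report = FilterReport()
    for name, f in fails.items():
        any_fail |= f
    report.add_stage(
        "hard_filters", len(s), int((~any_fail).sum()),
        dp_ceiling=dp_ceiling,
        per_criterion={k: int(v.sum()) for k, v in fails.items()},
    )
    return table.subset_sites(~any_fail), report


def mask_genotypes(
    table: GenotypeTable, config: Optional[FilterConfig] = None
) -> GenotypeTable:
    """Set calls to missing on low GQ/DP or allele-depth conflicts."""
    config = config or FilterConfig()
    out = table.copy()
    if out.ad.shape[2] != 2:
        raise ValueError(f"AD arity {out.ad.shape[2]} != 2")
    g0 = out.genotypes[:, :, 0]
    g1 = out.genotypes[:, :, 1]
    called = (g0 != MISSING) & (g1 != MISSING)
    low = (out.gq < config.gq_min) | (out.dp < config.dp_min)
    hom_ref_conflict = (g0 == 0) & (g1 == 0) & (out.ad[:, :, 1] >= 1)
    hom_alt_conflict = (g0 > 0) & (g1 > 0) & (out.ad[:, :, 0] >= 1)
    bad = called & (low | hom_ref_conflict | hom_alt_conflict)
    out.genotypes[bad] = MISSING
    return out


def select_biallelic(table: GenotypeTable) -> GenotypeTable:
    """Keep only SNPs with exactly one ref and one alt allele."""
    s = table.sites
    keep = (s["vartype"].to_numpy() == "snp") & np.array(
        [len(a) == 1 for a in s["alt"]], dtype=bool
    )
    return table.subset_sites(keep)


def pos_to_bed_index(pos_1based: np.ndarray) -> np.ndarray:
    """Central 1-based VCF position -> 0-based BED coordinate conversion."""
    return np.asarray(pos_1based) - 1


def intersect_regions(
    table: GenotypeTable, regions: Sequence[tuple[str, int, int]]
) -> GenotypeTable:
    """Keep sites whose position falls in any 0-based half-open interval."""
    for iv in regions:
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        if end < start or start < 0:
            raise ValueError(f"malformed interval {iv}")
    if not regions:
        return table.subset_sites(np.zeros(table.n_sites, dtype=bool))
    chrom = table.sites["chrom"].to_numpy()
    zero_based = pos_to_bed_index(table.sites["pos"].to_numpy())
    keep = np.zeros(table.n_sites, dtype=bool)
    for c, start, end, *_ in regions:
        keep |= (chrom == c) & (zero_based >= int(start)) & (zero_based < int(end))
    return table.subset_sites(keep)


def subset_by_annotation(
    table: GenotypeTable, annotation: str, drop_missing: bool = False
) -> GenotypeTable:
    """Keep sites of one annotation class; optionally require complete calls."""
    if annotation not in ANNOTATION_CLASSES:
        raise ValueError(
            f"unknown annotation class {annotation!r}; expected one of "
            f"{ANNOTATION_CLASSES}"
        )
    keep = table.sites["annotation"].to_numpy() == annotation
    out = table.subset_sites(keep)
    if drop_missing:
        out = out.subset_sites(~out.missing_mask().any(axis=1))
    return out


def thin_by_distance(table: GenotypeTable, min_distance: int = 3000) -> GenotypeTable:
    """Greedy left-to-right thinning: keep a site iff it is >= min_distance
    from the last kept site on the same chromosome."""
    _require_sorted(table)
    chrom = table.sites["chrom"].to_numpy()
    pos = table.sites["pos"].to_numpy()
    keep = np.zeros(len(pos), dtype=bool)
    last_chrom = None
    last_pos = None
    for i in range(len(pos)):
        if chrom[i] != last_chrom or pos[i] - last_pos >= min_distance:
            keep[i] = True
            last_chrom = chrom[i]
            last_pos = pos[i]
    return table.subset_sites(keep)


def sample_missing_filter(
    table: GenotypeTable, max_rate: float = 0.15
) -> tuple[GenotypeTable, list[str], dict[str, float]]:
    """Drop samples whose missing-call fraction exceeds ``max_rate``."""
    miss = table.missing_mask()
    rates = miss.mean(axis=0) if table.n_sites else np.zeros(table.n_samples)
    rate_map = {s: float(r) for s, r in zip(table.samples, rates)}
    excluded = [s for s, r in rate_map.items() if r > max_rate]
    kept = [s for s in table.samples if s not in set(excluded)]
    return table.subset_samples(kept), excluded, rate_map


def run_cascade(
    table: GenotypeTable,
    config: Optional[FilterConfig] = None,
    core_regions: Optional[Sequence[tuple[str, int, int]]] = None,
) -> tuple[GenotypeTable, FilterReport]:
    """Full post-calling cascade: indel proximity -> hard filters ->
    genotype masking -> biallelic -> (optional) core-region intersection."""
    config = config or FilterConfig()
    config.validate()
    report = FilterReport()

    n0 = table.n_sites
    table = mask_near_variants(table, config.indel_window)
    report.add_stage("near_indel_mask", n0, table.n_sites)

    table, hard = apply_hard_filters(table, config)
    report.stages.extend(hard.stages)
    report.log.extend(hard.log)

    table = mask_genotypes(table, config)
    report.add_stage("genotype_mask", table.n_sites, table.n_sites)

    n0 = table.n_sites
    table = select_biallelic(table)
    report.add_stage("biallelic", n0, table.n_sites)

    if core_regions is not None:
        n0 = table.n_sites
        table = intersect_regions(table, core_regions)
        report.add_stage("core_regions", n0, table.n_sites)

    _, excluded, rates = sample_missing_filter(table, config.sample_missing_max)
    report.sample_missing_rates = rates
    report.excluded_samples = excluded
    report.check()
    return table, report
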