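"""Synthetic data generation for every pipeline stage.

A small internal Hudson-style coalescent engine (independent non-recombining
loci, infinite-sites mutation) produces multi-population diploid genotype
tables under an explicit demographic model.  Companion generators inject
clonemates and selfed offspring, corrupt records so each hard filter has an
exact truth set, and emulate organelle pileups and gene presence/absence
alignment summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    ANNOTATION_CLASSES,
    MISSING,
    ConfigurationError,
    DatasetTruth,
    GenotypeTable,
    SampleTruth,
    SimulatedDataset,
    empty_site_frame,
)

__all__ = [
    "DemographicModel",
    "Split",
    "Pulse",
    "CorruptionSpec",
    "CpPileup",
    "CpSimTruth",
    "simulate_coalescent",
    "inject_clones_and_selfs",
    "corrupt_for_qc",
    "simulate_cp_pileup",
    "simulate_pav",
    "two_population_model",
]

_BASES = np.array(["A", "C", "G", "T"])


# ----------------------------------------------------------------------
# demographic model
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class Split:
    """Backward-in-time merge: lineages of both children move to ``parent``
    at ``time`` (generations before present)."""

    child_a: str
    child_b: str
    time: float
    parent: Optional[str] = None

    @property
    def parent_name(self) -> str:
        return self.parent or f"anc({self.child_a},{self.child_b})"


@dataclass(frozen=True)
class Pulse:
    """Single-generation admixture pulse: forward in time, ``fraction`` of
    ``target``'s genes arrive from ``source`` at ``time``."""

    source: str
    target: str
    time: float
    fraction: float


@dataclass
class DemographicModel:
    """Population tree with sizes, split times, pulses and mutation model.

    ``populations`` maps name -> diploid effective size; ancestral
    populations created by splits default to the first child's size unless
    listed explicitly.
    """

    populations: dict[str, float]
    splits: list[Split] = field(default_factory=list)
    admixture_pulses: list[Pulse] = field(default_factory=list)
    mutation_rate: float = 1e-8
    generation_time: float = 3.0
    locus_spec: tuple[int, int] = (100, 5000)

    def __post_init__(self) -> None:
        self.splits = [s if isinstance(s, Split) else Split(*s) for s in self.splits]
        self.admixture_pulses = [
            p if isinstance(p, Pulse) else Pulse(*p) for p in self.admixture_pulses
        ]
        self.validate()

    def validate(self) -> None:
        if self.mutation_rate < 0:
            raise ConfigurationError("mutation_rate must be >= 0")
        if self.generation_time <= 0:
            raise ConfigurationError("generation_time must be > 0")
        n_loci, locus_length = self.locus_spec
        if n_loci <= 0 or locus_length <= 0:
            raise ConfigurationError("locus_spec entries must be positive")
        for name, ne in self.populations.items():
            if ne <= 0:
                raise ConfigurationError(f"N_e for {name!r} must be > 0")
        for p in self.admixture_pulses:
            if not 0 < p.fraction < 1:
                raise ConfigurationError("admixture fraction must be in (0, 1)")
            if p.time <= 0:
                raise ConfigurationError("pulse time must be > 0")
        # replay the merge sequence to check topological consistency
        alive = set(self.populations)
        last_t = 0.0
        for s in sorted(self.splits, key=lambda s: s.time):
            if s.time <= 0:
                raise ConfigurationError("split times must be strictly positive")
            if s.time < last_t:  # sorted, cannot happen; guard anyway
                raise ConfigurationError("splits out of order")
            for child in (s.child_a, s.child_b):
                if child not in alive:
                    raise ConfigurationError(
                        f"split at t={s.time} references {child!r}, which is not "
                        "an active population at that time"
                    )
            alive -= {s.child_a, s.child_b}
            if s.parent_name in alive:
                raise ConfigurationError(f"duplicate population {s.parent_name!r}")
            alive.add(s.parent_name)
            last_t = s.time
        if self.splits and len(alive) != 1:
            raise ConfigurationError(
                f"splits do not merge all populations into one root: {sorted(alive)}"
            )

    def size_of(self, name: str) -> float:
        if name in self.populations:
            return self.populations[name]
        for s in self.splits:
            if s.parent_name == name:
                return self.size_of(s.child_a)
        raise ConfigurationError(f"unknown population {name!r}")

    def split_times(self) -> dict[str, float]:
        """Map ancestral-node name -> split time in generations."""
        return {s.parent_name: s.time for s in self.splits}


def two_population_model(
    ne: float,
    split_generations: float,
    mutation_rate: float = 1e-8,
    generation_time: float = 3.0,
    n_loci: int = 500,
    locus_length: int = 5000,
) -> DemographicModel:
    """Convenience isolation model: two equal-size populations, one split."""
    return DemographicModel(
        populations={"A": ne, "B": ne},
        splits=[Split("A", "B", split_generations, parent="root")],
        mutation_rate=mutation_rate,
        generation_time=generation_time,
        locus_spec=(n_loci, locus_length),
    )


# ----------------------------------------------------------------------
# coalescent engine
# ----------------------------------------------------------------------
def _simulate_locus_tree(
    rng: np.random.Generator,
    model: DemographicModel,
    leaf_pops: dict[str, list[int]],
) -> tuple[list[float], list[Optional[int]], list[tuple[int, int]]]:
    """Simulate one gene tree; returns (times, parents, children-pairs).

    Leaves are nodes ``0..n-1`` at time 0; internal nodes are appended.
    """
    n_leaves = sum(len(v) for v in leaf_pops.values())
    times: list[float] = [0.0] * n_leaves
    parents: list[Optional[int]] = [None] * n_leaves
    children: list[tuple[int, int]] = [(-1, -1)] * n_leaves

    active: dict[str, list[int]] = {p: list(ids) for p, ids in leaf_pops.items()}
    events: list[tuple[float, str, object]] = []
    for s in model.splits:
        events.append((s.time, "split", s))
    for p in model.admixture_pulses:
        events.append((p.time, "pulse", p))
    events.sort(key=lambda e: (e[0], e[1]))

    t = 0.0
    ev_i = 0
    while True:
        k_total = sum(len(v) for v in active.values())
        if k_total <= 1:
            break
        rates = {
            p: len(v) * (len(v) - 1) / (4.0 * model.size_of(p))
            for p, v in active.items()
            if len(v) >= 2
        }
        total_rate = sum(rates.values())
        t_event = events[ev_i][0] if ev_i < len(events) else math.inf
        dt = rng.exponential(1.0 / total_rate) if total_rate > 0 else math.inf
        if t + dt < t_event:
            t += dt
            # pick the population in which the coalescence happens
            u = rng.random() * total_rate
            acc = 0.0
            pop = next(iter(rates))
            for p, r in rates.items():
                acc += r
                if u <= acc:
                    pop = p
                    break
            lst = active[pop]
            i, j = rng.choice(len(lst), size=2, replace=False)
            a, b = lst[int(i)], lst[int(j)]
            node = len(times)
            times.append(t)
            parents.append(None)
            children.append((a, b))
            parents[a] = node
            parents[b] = node
            active[pop] = [x for x in lst if x not in (a, b)] + [node]
        else:
            if math.isinf(t_event):
                raise ConfigurationError(
                    "remaining lineages are in populations that never merge"
                )
            t = t_event
            _, kind, payload = events[ev_i]
            ev_i += 1
            if kind == "split":
                s: Split = payload  # type: ignore[assignment]
                moved = active.pop(s.child_a, []) + active.pop(s.child_b, [])
                active.setdefault(s.parent_name, []).extend(moved)
            else:
                p: Pulse = payload  # type: ignore[assignment]
                tgt = active.get(p.target, [])
                stay, move = [], []
                for lin in tgt:
                    (move if rng.random() < p.fraction else stay).append(lin)
                if move:
                    active[p.target] = stay
                    active.setdefault(p.source, []).extend(move)
    return times, parents, children


def _drop_mutations(
    rng: np.random.Generator,
    times: list[float],
    parents: list[Optional[int]],
    children: list[tuple[int, int]],
    n_leaves: int,
    mu: float,
    locus_length: int,
) -> list[tuple[int, np.ndarray]]:
    """Infinite-sites mutations; returns sorted (position, derived-leaf mask)."""
    node_ids = [i for i, p in enumerate(parents) if p is not None]
    if not node_ids:
        return []
    lengths = np.array([times[parents[i]] - times[i] for i in node_ids])
    total = float(lengths.sum())
    n_mut = int(rng.poisson(mu * locus_length * total))
    if n_mut == 0:
        return []
    if n_mut > locus_length:
        raise ConfigurationError(
            f"infinite-sites violated: {n_mut} mutations on a "
            f"{locus_length}-bp locus; lower the mutation rate"
        )
    # leaf descendant sets (boolean masks) per node
    masks: dict[int, np.ndarray] = {}

    def leaf_mask(node: int) -> np.ndarray:
        if node in masks:
            return masks[node]
        if node < n_leaves:
            m = np.zeros(n_leaves, dtype=bool)
            m[node] = True
        else:
            a, b = children[node]
            m = leaf_mask(a) | leaf_mask(b)
        masks[node] = m
        return m

    branch_pick = rng.choice(len(node_ids), size=n_mut, p=lengths / total)
    positions = np.sort(rng.choice(locus_length, size=n_mut, replace=False)) + 1
    out = []
    for pos, bi in zip(positions, branch_pick):
        out.append((int(pos), leaf_mask(node_ids[int(bi)]).copy()))
    return out


def simulate_coalescent(
    model: DemographicModel,
    n_samples_per_pop: dict[str, int],
    seed: int,
    annotation_fractions: tuple[float, float, float] = (0.35, 0.35, 0.30),
    mean_depth: int = 30,
) -> SimulatedDataset:
    """Simulate diploid genotypes at ``model.locus_spec`` independent loci.

    Each diploid pairs two haploid lineages sampled from its population.
    Variant records carry passing INFO metrics and clean per-call
    GQ/DP/AD so that only deliberately corrupted records fail QC.
    """
    model.validate()
    for pop, n in n_samples_per_pop.items():
        if n < 1:
            raise ConfigurationError(f"need >= 1 sample for population {pop!r}")
        if pop not in model.populations:
            raise ConfigurationError(f"unknown population {pop!r}")

    rng = np.random.default_rng(seed)
    n_loci, locus_length = model.locus_spec

    sample_ids: list[str] = []
    sample_pops: list[str] = []
    leaf_pops: dict[str, list[int]] = {}
    leaf = 0
    for pop, n in n_samples_per_pop.items():
        ids = []
        for i in range(n):
            sample_ids.append(f"{pop}_{i + 1:02d}")
            sample_pops.append(pop)
            ids.extend([leaf, leaf + 1])
            leaf += 2
        leaf_pops[pop] = ids
    n_leaves = leaf
    n_samples = len(sample_ids)

    chroms: list[str] = []
    positions: list[int] = []
    hap_rows: list[np.ndarray] = []
    for locus in range(n_loci):
        times, parents, children = _simulate_locus_tree(rng, model, leaf_pops)
        muts = _drop_mutations(
            rng, times, parents, children, n_leaves, model.mutation_rate, locus_length
        )
        chrom = f"locus_{locus + 1:05d}"
        for pos, mask in muts:
            if mask.all() or not mask.any():
                continue
            chroms.append(chrom)
            positions.append(pos)
            hap_rows.append(mask)

    n_sites = len(hap_rows)
    haplotypes = (
        np.array(hap_rows, dtype=np.int8)
        if n_sites
        else np.zeros((0, n_leaves), dtype=np.int8)
    )
    genotypes = haplotypes.reshape(n_sites, n_samples, 2)

    sites = empty_site_frame(n_sites)
    sites["chrom"] = chroms
    sites["pos"] = np.array(positions, dtype=np.int64)
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_shift = rng.integers(1, 4, size=n_sites)
    sites["ref"] = _BASES[ref_idx]
    sites["alt"] = [(_BASES[(r + s) % 4],) for r, s in zip(ref_idx, alt_shift)]
    sites["annotation"] = rng.choice(
        list(ANNOTATION_CLASSES), size=n_sites, p=annotation_fractions
    )
    sites["MQ"] = rng.uniform(55.0, 60.0, n_sites)
    sites["FS"] = rng.uniform(0.0, 5.0, n_sites)
    sites["QD"] = rng.uniform(20.0, 34.0, n_sites)
    sites["MQRankSum"] = np.clip(rng.normal(0.0, 0.5, n_sites), -2.0, 2.0)
    sites["ReadPosRankSum"] = np.clip(rng.normal(0.0, 0.5, n_sites), -2.0, 2.0)
    sites["SOR"] = rng.uniform(0.3, 2.0, n_sites)

    dp = rng.poisson(mean_depth, size=(n_sites, n_samples)).astype(np.int32) + 10
    gq = np.full((n_sites, n_samples), 99, dtype=np.int32)
    ad = _consistent_ad(genotypes, dp)
    sites["DP"] = dp.sum(axis=1).astype(float)

    table = GenotypeTable(
        sites=sites,
        genotypes=genotypes,
        gq=gq,
        dp=dp,
        ad=ad,
        samples=sample_ids,
        seq_length=n_loci * locus_length,
    )
    truth = DatasetTruth(
        samples={
            sid: SampleTruth(population=pop)
            for sid, pop in zip(sample_ids, sample_pops)
        }
    )
    return SimulatedDataset(
        genotypes=table,
        truth=truth,
        true_tree_times=model.split_times(),
        seed=seed,
    )


def _consistent_ad(genotypes: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """AD consistent with the genotype: hom-ref (dp,0), hom-alt (0,dp),
    het a near-even split.  Missing calls get (0,0)."""
    n_sites, n_samples, _ = genotypes.shape
    ad = np.zeros((n_sites, n_samples, 2), dtype=np.int32)
    g0 = genotypes[:, :, 0]
    g1 = genotypes[:, :, 1]
    called = (g0 != MISSING) & (g1 != MISSING)
    hom_ref = called & (g0 == 0) & (g1 == 0)
    hom_alt = called & (g0 > 0) & (g1 > 0)
    het = called & ~hom_ref & ~hom_alt
    ad[:, :, 0][hom_ref] = dp[hom_ref]
    ad[:, :, 1][hom_alt] = dp[hom_alt]
    half = dp // 2
    ad[:, :, 0][het] = half[het]
    ad[:, :, 1][het] = (dp - half)[het]
    return ad


# ----------------------------------------------------------------------
# clones and selfed offspring
# ----------------------------------------------------------------------
def inject_clones_and_selfs(
    data: SimulatedDataset,
    n_clonemate_copies: int,
    n_selfed: int,
    genotyping_error_rate: float,
    seed: int,
    clone_sources: Optional[Sequence[str]] = None,
    selfing_parents: Optional[Sequence[str]] = None,
) -> SimulatedDataset:
    """Append clonemate copies and selfed offspring with truth labels.

    Clonemates copy a source genotype with independent per-call flip errors
    at ``genotyping_error_rate``; selfed offspring segregate Mendelianly
    from a single parent (het site -> het w.p. 1/2, else a random
    homozygote).
    """
    if not 0 <= genotyping_error_rate <= 1:
        raise ConfigurationError("genotyping_error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = data.copy()
    table = out.genotypes
    originals = list(table.samples)

    if clone_sources is None:
        if n_clonemate_copies > len(originals):
            raise ConfigurationError("not enough source samples for clones")
        clone_sources = [
            originals[i]
            for i in rng.choice(len(originals), size=n_clonemate_copies, replace=False)
        ]
    if len(clone_sources) != n_clonemate_copies:
        raise ConfigurationError("clone_sources length mismatch")
    if selfing_parents is None:
        pool = [s for s in originals if s not in set(clone_sources)]
        if n_selfed > len(pool):
            raise ConfigurationError("not enough source samples for selfing")
        selfing_parents = [
            pool[i] for i in rng.choice(len(pool), size=n_selfed, replace=False)
        ]
    if len(selfing_parents) != n_selfed:
        raise ConfigurationError("selfing_parents length mismatch")

    new_cols: list[np.ndarray] = []
    new_ids: list[str] = []
    next_group = 1 + max(
        (t.clone_group for t in out.truth.samples.values() if t.clone_group is not None),
        default=-1,
    )
    for k, src in enumerate(clone_sources):
        si = table.sample_index(src)
        g = table.genotypes[:, si].copy()
        g = _apply_genotyping_errors(rng, g, genotyping_error_rate)
        new_id = f"{src}_clone{k + 1}"
        group = out.truth.samples[src].clone_group
        if group is None:
            group = next_group
            next_group += 1
            out.truth.samples[src].clone_group = group
        out.truth.samples[new_id] = SampleTruth(
            population=out.truth.samples[src].population, clone_group=group
        )
        new_cols.append(g)
        new_ids.append(new_id)

    for k, src in enumerate(selfing_parents):
        si = table.sample_index(src)
        g = _self_offspring(rng, table.genotypes[:, si])
        g = _apply_genotyping_errors(rng, g, genotyping_error_rate)
        new_id = f"{src}_self{k + 1}"
        out.truth.samples[new_id] = SampleTruth(
            population=out.truth.samples[src].population, selfed_from=src
        )
        new_cols.append(g)
        new_ids.append(new_id)

    if new_cols:
        add = np.stack(new_cols, axis=1)
        genotypes = np.concatenate([table.genotypes, add], axis=1)
        dp_new = rng.poisson(30, size=(table.n_sites, len(new_ids))).astype(np.int32) + 10
        dp = np.concatenate([table.dp, dp_new], axis=1)
        gq = np.concatenate(
            [table.gq, np.full((table.n_sites, len(new_ids)), 99, dtype=np.int32)],
            axis=1,
        )
        ad = np.concatenate([table.ad, _consistent_ad(add, dp_new)], axis=1)
        out.genotypes = GenotypeTable(
            sites=table.sites,
            genotypes=genotypes,
            gq=gq,
            dp=dp,
            ad=ad,
            samples=originals + new_ids,
            seq_length=table.seq_length,
        )
    return out


def _apply_genotyping_errors(
    rng: np.random.Generator, g: np.ndarray, rate: float
) -> np.ndarray:
    """Flip one random allele of a call with probability ``rate``."""
    if rate <= 0:
        return g
    g = g.copy()
    called = (g != MISSING).all(axis=1)
    hit = called & (rng.random(g.shape[0]) < rate)
    which = rng.integers(0, 2, size=g.shape[0])
    idx = np.flatnonzero(hit)
    g[idx, which[idx]] = 1 - g[idx, which[idx]]
    return g


def _self_offspring(rng: np.random.Generator, parent: np.ndarray) -> np.ndarray:
    """Mendelian selfing of one diploid genotype vector (n_sites, 2)."""
    child = parent.copy()
    het = (parent[:, 0] != parent[:, 1]) & (parent != MISSING).all(axis=1)
    idx = np.flatnonzero(het)
    u = rng.random(idx.size)
    # u < 0.5 -> stay het; else homozygote, each parental allele w.p. 1/2
    hom = idx[u >= 0.5]
    pick = rng.integers(0, 2, size=hom.size)
    allele = parent[hom, pick]
    child[hom, 0] = allele
    child[hom, 1] = allele
    return child


# ----------------------------------------------------------------------
# QC corruption
# ----------------------------------------------------------------------
@dataclass
class CorruptionSpec:
    """Exact per-filter corruption counts (not expected values)."""

    n_mq: int = 0
    n_fs: int = 0
    n_qd: int = 0
    n_mqranksum: int = 0
    n_readposranksum: int = 0
    n_sor: int = 0
    n_dp: int = 0
    n_near_indel: int = 0
    n_multiallelic: int = 0
    n_low_gq: int = 0
    n_low_dp: int = 0
    n_conflicting_ad: int = 0
    n_high_missing_samples: int = 0
    missing_rate: float = 0.25

    def validate(self) -> None:
        for name in (
            "n_mq", "n_fs", "n_qd", "n_mqranksum", "n_readposranksum", "n_sor",
            "n_dp", "n_near_indel", "n_multiallelic", "n_low_gq", "n_low_dp",
            "n_conflicting_ad", "n_high_missing_samples",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.missing_rate <= 1:
            raise ConfigurationError("missing_rate must be in [0, 1]")

    @property
    def site_tags(self) -> dict[str, int]:
        return {
            "mq": self.n_mq,
            "fs": self.n_fs,
            "qd": self.n_qd,
            "mqranksum": self.n_mqranksum,
            "readposranksum": self.n_readposranksum,
            "sor": self.n_sor,
            "dp": self.n_dp,
            "multiallelic": self.n_multiallelic,
            "near_indel": self.n_near_indel,
        }


def corrupt_for_qc(
    data: SimulatedDataset,
    spec: CorruptionSpec,
    seed: int,
    high_missing_candidates: Optional[Sequence[str]] = None,
) -> SimulatedDataset:
    """Corrupt exact numbers of records/calls so each filter has a truth set.

    Every corrupted site carries ``fail_tag`` naming the filter it must
    fail; corrupted calls are recorded in ``truth.masked_calls``; samples
    pushed above the missing-rate ceiling are listed in
    ``truth.high_missing_samples``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    out = data.copy()
    table = out.genotypes
    sites = table.sites

    n_site_targets = sum(spec.site_tags.values())
    clean = np.flatnonzero(sites["fail_tag"].to_numpy() == "")
    if n_site_targets > clean.size:
        raise ConfigurationError("not enough clean sites to corrupt")

    # near-indel targets need genomic isolation so the indel only hits them
    iso = _isolated_sites(sites) if spec.n_near_indel else np.array([], dtype=int)
    iso = np.array([i for i in iso if i in set(clean)], dtype=int)
    if spec.n_near_indel > iso.size:
        raise ConfigurationError("not enough isolated sites for near-indel targets")
    near_idx = iso[rng.choice(iso.size, size=spec.n_near_indel, replace=False)]

    rest_pool = np.array(sorted(set(clean) - set(near_idx.tolist())), dtype=int)
    n_rest = n_site_targets - spec.n_near_indel
    picked = rest_pool[rng.choice(rest_pool.size, size=n_rest, replace=False)]
    cursor = 0
    chosen: dict[str, np.ndarray] = {"near_indel": near_idx}
    for tag, count in spec.site_tags.items():
        if tag == "near_indel":
            continue
        chosen[tag] = picked[cursor : cursor + count]
        cursor += count

    tags = sites["fail_tag"].to_numpy(dtype=object)
    for tag, idx in chosen.items():
        tags[idx] = tag
    sites["fail_tag"] = tags

    sites.loc[chosen["mq"], "MQ"] = rng.uniform(10.0, 39.5, chosen["mq"].size)
    sites.loc[chosen["fs"], "FS"] = rng.uniform(60.5, 120.0, chosen["fs"].size)
    sites.loc[chosen["qd"], "QD"] = rng.uniform(0.5, 9.5, chosen["qd"].size)
    sign = rng.choice([-1.0, 1.0], size=chosen["mqranksum"].size)
    sites.loc[chosen["mqranksum"], "MQRankSum"] = sign * rng.uniform(
        2.6, 6.0, chosen["mqranksum"].size
    )
    sign = rng.choice([-1.0, 1.0], size=chosen["readposranksum"].size)
    sites.loc[chosen["readposranksum"], "ReadPosRankSum"] = sign * rng.uniform(
        2.6, 6.0, chosen["readposranksum"].size
    )
    sites.loc[chosen["sor"], "SOR"] = rng.uniform(3.1, 8.0, chosen["sor"].size)
    sites.loc[chosen["dp"], "DP"] = sites["DP"].mean() * rng.uniform(
        8.0, 12.0, chosen["dp"].size
    )
    alt_col = sites["alt"].to_list()
    for i in chosen["multiallelic"]:
        ref = sites.at[i, "ref"]
        existing = set(alt_col[i]) | {ref}
        extra = next(b for b in _BASES if b not in existing)
        alt_col[i] = tuple(alt_col[i]) + (extra,)
    sites["alt"] = alt_col

    out.genotypes = table  # sites edited in place above
    n_sites, n_samples = table.n_sites, table.n_samples

    # high-missing samples first (exact count, exact missing fraction) so
    # call-level corruption below never lands on an already-missing cell
    if spec.n_high_missing_samples:
        if high_missing_candidates is None:
            pool = np.arange(n_samples)
        else:
            pool = np.array(
                [table.sample_index(s) for s in high_missing_candidates], dtype=int
            )
        if spec.n_high_missing_samples > pool.size:
            raise ConfigurationError("more high-missing samples than candidates")
        js = pool[rng.choice(pool.size, size=spec.n_high_missing_samples, replace=False)]
        n_drop = int(round(spec.missing_rate * n_sites))
        for j in js:
            rows = rng.choice(n_sites, size=n_drop, replace=False)
            table.genotypes[rows, j] = MISSING
            table.ad[rows, j] = 0
        out.truth.high_missing_samples = [table.samples[int(j)] for j in js]

    # genotype-level corruption on untouched sites
    masked: list[tuple[str, int, str]] = []
    still_clean = np.flatnonzero(sites["fail_tag"].to_numpy() == "")
    n_calls = spec.n_low_gq + spec.n_low_dp + spec.n_conflicting_ad
    if n_calls:
        called = ~table.missing_mask()
        cand = [
            (i, j) for i in still_clean for j in range(n_samples) if called[i, j]
        ]
        if n_calls > len(cand):
            raise ConfigurationError("not enough clean calls to corrupt")
        pick = rng.choice(len(cand), size=n_calls, replace=False)
        cells = [cand[int(k)] for k in pick]

        def _record(i: int, j: int) -> None:
            masked.append(
                (str(sites.at[i, "chrom"]), int(sites.at[i, "pos"]), table.samples[j])
            )

        k = 0
        for i, j in cells[: spec.n_low_gq]:
            table.gq[i, j] = rng.integers(0, 30)
            _record(i, j)
        k += spec.n_low_gq
        for i, j in cells[k : k + spec.n_low_dp]:
            d = int(rng.integers(0, 10))
            table.dp[i, j] = d
            g = table.genotypes[i, j]
            if g[0] == 0 and g[1] == 0:
                table.ad[i, j] = (d, 0)
            elif g[0] > 0 and g[1] > 0:
                table.ad[i, j] = (0, d)
            else:
                table.ad[i, j] = (d // 2, d - d // 2)
            _record(i, j)
        k += spec.n_low_dp
        for i, j in cells[k:]:
            g = table.genotypes[i, j]
            if g[0] != g[1]:  # force a homozygote so the AD conflict applies
                table.genotypes[i, j] = (0, 0)
            d = max(int(table.dp[i, j]), 10)
            table.dp[i, j] = d
            minor = int(rng.integers(1, 4))
            if table.genotypes[i, j, 0] == 0:
                table.ad[i, j] = (d - minor, minor)
            else:
                table.ad[i, j] = (minor, d - minor)
            _record(i, j)
    out.truth.masked_calls = masked

    # indel records inserted next to their targets, then re-sorted
    if spec.n_near_indel:
        out.genotypes = _insert_indels(rng, out, near_idx)
    return out


def _isolated_sites(sites: pd.DataFrame, radius: int = 45) -> np.ndarray:
    """Indices of SNPs with no neighbour within ``radius`` bp on the same
    chromosome (so an adjacent indel cannot clip another site)."""
    idx = []
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    vt = sites["vartype"].to_numpy()
    for i in range(len(sites)):
        if vt[i] != "snp":
            continue
        same = (chrom == chrom[i])
        d = np.abs(pos - pos[i])
        d[~same] = radius + 1
        d[i] = radius + 1
        if d.min() > radius and pos[i] > radius:
            idx.append(i)
    return np.array(idx, dtype=int)


def _insert_indels(
    rng: np.random.Generator, data: SimulatedDataset, target_idx: np.ndarray
) -> GenotypeTable:
    table = data.genotypes
    n_samples = table.n_samples
    rows = empty_site_frame(len(target_idx))
    for k, i in enumerate(target_idx):
        offset = int(rng.integers(1, 21))
        rows.loc[k, "chrom"] = table.sites.at[i, "chrom"]
        rows.loc[k, "pos"] = int(table.sites.at[i, "pos"]) - offset
        rows.loc[k, "ref"] = "AT"
        rows.at[k, "alt"] = ("A",)
        rows.loc[k, "vartype"] = "indel"
        rows.loc[k, "fail_tag"] = "indel_record"
    g = np.zeros((len(target_idx), n_samples, 2), dtype=table.genotypes.dtype)
    dp = np.full((len(target_idx), n_samples), 30, dtype=np.int32)
    gq = np.full((len(target_idx), n_samples), 99, dtype=np.int32)
    ad = _consistent_ad(g, dp)
    sites = pd.concat([table.sites, rows], ignore_index=True)
    genotypes = np.concatenate([table.genotypes, g], axis=0)
    order = sites.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    return GenotypeTable(
        sites=sites.iloc[order].reset_index(drop=True),
        genotypes=genotypes[order],
        gq=np.concatenate([table.gq, gq], axis=0)[order],
        dp=np.concatenate([table.dp, dp], axis=0)[order],
        ad=np.concatenate([table.ad, ad], axis=0)[order],
        samples=list(table.samples),
        seq_length=table.seq_length,
    )


# ----------------------------------------------------------------------
# chloroplast pileups
# ----------------------------------------------------------------------
@dataclass
class CpPileup:
    """Per-sample organelle pileup: reference base codes (0..3), coverage
    and per-base read counts for every (1-based) genome position."""

    ref: np.ndarray  # (L,) uint8 codes into ACGT
    coverage: np.ndarray  # (L,) int32
    counts: np.ndarray  # (L, 4) int32

    def __post_init__(self) -> None:
        if (self.counts.sum(axis=1) > self.coverage).any():
            raise ValueError("base counts exceed coverage")

    @property
    def length(self) -> int:
        return self.ref.size


@dataclass
class CpSimTruth:
    """Ground truth for a simulated chloroplast pileup set."""

    variable_positions: list[int]  # 1-based, all callable positions
    microsat_positions: list[int]
    hairpin_positions: list[int]
    masks: list[tuple[int, int, str]]  # 0-based half-open BED rows
    haplotypes: dict[str, str]  # sample -> bases at retained positions
    retained_positions: list[int]


def simulate_cp_pileup(
    genealogy_or_model: Union[DemographicModel, int, Sequence[str]],
    genome_length: int,
    n_variable: int,
    n_microsat_artifacts: int,
    n_hairpin_artifacts: int,
    median_coverage: int,
    seed: int,
    n_haplotypes: Optional[int] = None,
) -> tuple[dict[str, CpPileup], CpSimTruth]:
    """Simulate organelle pileups whose calling + masking outcome is known.

    Every simulated variable position satisfies the calling rules
    (variant-read fraction > 0.5 in carriers, coverage > 0.3 x median);
    artifact positions are genuine calls listed in the mask intervals.
    """
    if n_variable < n_microsat_artifacts + n_hairpin_artifacts:
        raise ConfigurationError("n_variable must cover the artifact counts")
    rng = np.random.default_rng(seed)

    if isinstance(genealogy_or_model, DemographicModel):
        samples = [f"{p}_cp1" for p in genealogy_or_model.populations]
    elif isinstance(genealogy_or_model, int):
        samples = [f"cp_{i + 1:02d}" for i in range(genealogy_or_model)]
    else:
        samples = list(genealogy_or_model)
    n_samples = len(samples)
    if n_samples < 1:
        raise ConfigurationError("need at least one sample")
    k = n_haplotypes or min(8, n_samples)
    k = max(1, min(k, n_samples))

    ref = rng.integers(0, 4, size=genome_length).astype(np.uint8)
    positions = np.sort(rng.choice(genome_length, size=n_variable, replace=False)) + 1
    art = rng.choice(
        n_variable, size=n_microsat_artifacts + n_hairpin_artifacts, replace=False
    )
    micro = np.sort(positions[art[:n_microsat_artifacts]])
    hairpin = np.sort(positions[art[n_microsat_artifacts:]])

    # haplotype matrix over all variable positions; derived allele carried by
    # a random non-empty proper subset of haplotypes (plus hap 0 = reference)
    hap_state = np.zeros((k, n_variable), dtype=bool)
    for j in range(n_variable):
        if k == 1:
            hap_state[0, j] = True  # single haplotype: everyone carries it
            continue
        size = int(rng.integers(1, k))
        carriers = rng.choice(k, size=size, replace=False)
        hap_state[carriers, j] = True
    assignment = {s: i % k for i, s in enumerate(samples)}

    alt_base = (ref[positions - 1] + rng.integers(1, 4, size=n_variable)) % 4

    pileups: dict[str, CpPileup] = {}
    floor = int(0.4 * median_coverage) + 1
    for s in samples:
        cov = rng.poisson(median_coverage, size=genome_length).astype(np.int32)
        cov[positions - 1] = np.maximum(cov[positions - 1], floor)
        counts = np.zeros((genome_length, 4), dtype=np.int32)
        counts[np.arange(genome_length), ref] = cov
        hap = assignment[s]
        carried = np.flatnonzero(hap_state[hap])
        for j in carried:
            p = positions[j] - 1
            c = int(cov[p])
            v = int(rng.binomial(c, 0.95))
            if v * 2 <= c:
                v = int(math.ceil(0.75 * c))
            counts[p] = 0
            counts[p, alt_base[j]] = v
            counts[p, ref[p]] = c - v
        pileups[s] = CpPileup(ref=ref, coverage=cov, counts=counts)

    art_set = set(micro.tolist()) | set(hairpin.tolist())
    retained = [int(p) for p in positions if int(p) not in art_set]
    base_chars = "ACGT"
    haplo_strings = {}
    pos_index = {int(p): j for j, p in enumerate(positions)}
    for s in samples:
        hap = assignment[s]
        chars = []
        for p in retained:
            j = pos_index[p]
            code = alt_base[j] if hap_state[hap, j] else ref[p - 1]
            chars.append(base_chars[int(code)])
        haplo_strings[s] = "".join(chars)

    masks = [(int(p) - 1, int(p), "microsatellite") for p in micro] + [
        (int(p) - 1, int(p), "hairpin_inversion") for p in hairpin
    ]
    truth = CpSimTruth(
        variable_positions=[int(p) for p in positions],
        microsat_positions=[int(p) for p in micro],
        hairpin_positions=[int(p) for p in hairpin],
        masks=masks,
        haplotypes=haplo_strings,
        retained_positions=retained,
    )
    return pileups, truth


# ----------------------------------------------------------------------
# pangenome presence/absence
# ----------------------------------------------------------------------
def simulate_pav(
    n_genes: int,
    class_fractions: tuple[float, float, float],
    n_samples: int,
    seed: int,
    low_quality_samples: int = 0,
    low_quality_keep: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, list[str]]:
    """Alignment-hit records engineered to reproduce a known PAV matrix.

    ``class_fractions`` is (cloud, shell, core) and must sum to 1.  Returns
    (hits, truth presence matrix, truth gene classes, low-quality samples).
    """
    if abs(sum(class_fractions) - 1.0) > 1e-9:
        raise ConfigurationError("class_fractions must sum to 1")
    if low_quality_samples > n_samples:
        raise ConfigurationError("too many low-quality samples")
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    samples = [f"asm_{j + 1:03d}" for j in range(n_samples)]

    n_cloud = int(round(class_fractions[0] * n_genes))
    n_shell = int(round(class_fractions[1] * n_genes))
    n_core = n_genes - n_cloud - n_shell
    classes = pd.Series(
        ["cloud"] * n_cloud + ["shell"] * n_shell + ["core"] * n_core,
        index=genes,
        name="class",
    )

    presence = np.zeros((n_genes, n_samples), dtype=bool)
    for i in range(n_genes):
        cls = classes.iloc[i]
        if cls == "cloud":
            f = rng.uniform(0.0, 0.12)
        elif cls == "shell":
            f = rng.uniform(0.35, 0.65)
        else:
            f = rng.uniform(0.93, 1.0)
        count = int(round(f * n_samples))
        if cls == "cloud":
            count = min(count, max(0, int(0.15 * n_samples)))
        elif cls == "core":
            count = max(count, int(math.ceil(0.9 * n_samples)))
        if count:
            js = rng.choice(n_samples, size=count, replace=False)
            presence[i, js] = True

    low_q = [samples[int(j)] for j in rng.choice(
        n_samples, size=low_quality_samples, replace=False
    )]
    for s in low_q:
        j = samples.index(s)
        have = np.flatnonzero(presence[:, j])
        keep = int(low_quality_keep * have.size)
        drop = rng.choice(have, size=have.size - keep, replace=False)
        presence[drop, j] = False

    rows = []
    for i, gene in enumerate(genes):
        for j, sample in enumerate(samples):
            if presence[i, j]:
                if rng.random() < 0.8:  # rule (a): one strong hit
                    rows.append(
                        (gene, sample, "scaf_1",
                         float(rng.uniform(0.80, 0.999)),
                         float(rng.uniform(0.80, 0.999)))
                    )
                else:  # rule (b): strong hits split over <= 3 scaffolds
                    parts = int(rng.integers(2, 4))
                    covs = rng.dirichlet(np.ones(parts)) * rng.uniform(0.90, 0.999)
                    for p in range(parts):
                        rows.append(
                            (gene, sample, f"scaf_{p + 1}",
                             float(rng.uniform(0.90, 0.999)), float(covs[p]))
                        )
            else:
                if rng.random() < 0.5:  # weak stray hit, fails both rules
                    rows.append(
                        (gene, sample, "scaf_1",
                         float(rng.uniform(0.20, 0.55)),
                         float(rng.uniform(0.05, 0.50)))
                    )
    hits = pd.DataFrame(
        rows, columns=["gene", "sample", "scaffold", "identity", "coverage"]
    )
    truth = pd.DataFrame(presence, index=genes, columns=samples)
    return hits, truth, classes, low_q
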