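"""End-to-end orchestration from a single YAML configuration.

A run is deterministic given (config, seed): every stage draws from a
seed hierarchy spawned from the global seed, and reports carry no
wall-clock provenance.  The synthetic stage caches its output keyed by a
content hash of the generation block so re-runs resume cheaply.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__, clock, clonality, cpdna, io, popstats, presets, qc
from .simulate import (
    CorruptionSpec,
    DemographicModel,
    Pulse,
    Split,
    inject_clones_and_selfs,
    corrupt_for_qc,
    simulate_coalescent,
    simulate_cp_pileup,
)
from .types import ConfigurationError

__all__ = ["validate_config", "run_pipeline", "load_config", "demo_config"]

_STAGES = ("simulate", "qc", "clones", "stats", "cpdna", "dating")


def load_config(path: str | os.PathLike) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def demo_config(seed: int = 1, output_dir: str = "phylopop_run") -> dict:
    """A small synthetic end-to-end configuration reproducing the
    190 -> 153 retained-sample ledger."""
    return {
        "seed": seed,
        "output_dir": output_dir,
        "stages": list(_STAGES),
        "synthetic": {
            "populations": {"P1": 10000, "P2": 10000, "P3": 10000, "P4": 10000},
            "splits": [
                ["P1", "P2", 4000, "anc12"],
                ["P3", "P4", 6000, "anc34"],
                ["anc12", "anc34", 20000, "root"],
            ],
            "mutation_rate": 1e-8,
            "generation_time": presets.GENERATION_TIME_YEARS,
            "n_loci": 120,
            "locus_length": 2000,
            "samples_per_pop": {"P1": 41, "P2": 41, "P3": 41, "P4": 40},
            "n_clonemates": presets.SAMPLES_CLONEMATES,
            "n_selfed": presets.SAMPLES_SELFED,
            "genotyping_error_rate": 0.0,
            "n_high_missing": presets.SAMPLES_HIGH_MISSING,
            "missing_rate": 0.25,
        },
        "qc": {},
        "stats": {"outgroup": "P4", "n_boot": 200, "max_pops": 4},
        "cpdna": {
            "genome_length": 20000,
            "n_variable": 40,
            "n_microsat": 3,
            "n_hairpin": 2,
            "median_coverage": 200,
            "epsilon": 0,
        },
        "dating": {
            "mutation_rate_per_generation": 1e-8,
            "generation_time": presets.GENERATION_TIME_YEARS,
        },
    }


def validate_config(config: dict) -> list[dict]:
    """Schema and cross-field checks; returns structured diagnostics."""
    diags: list[dict] = []

    def fatal(msg: str) -> None:
        diags.append({"level": "fatal", "message": msg})

    def warn(msg: str) -> None:
        diags.append({"level": "warning", "message": msg})

    if "seed" not in config:
        fatal("config requires a global 'seed'")
    stages = config.get("stages", [])
    unknown = [s for s in stages if s not in _STAGES]
    if unknown:
        fatal(f"unknown stages: {unknown}")
    has_synth = "synthetic" in config
    has_real = "inputs" in config
    if has_synth and has_real:
        fatal("exactly one of 'synthetic' or 'inputs' may be active")
    if stages and not (has_synth or has_real):
        fatal("stages requested but neither 'synthetic' nor 'inputs' given")
    if "stats" in stages and not config.get("stats", {}).get("outgroup"):
        fatal("stats stage (D-statistics) requires stats.outgroup")
    thin = config.get("qc", {}).get("thin_distance", 3000)
    if thin is not None and thin <= 0:
        fatal("qc.thin_distance must be > 0")
    synth = config.get("synthetic", {})
    if has_synth:
        rate = synth.get("genotyping_error_rate", 0.0)
        if not 0 <= rate <= 1:
            fatal("synthetic.genotyping_error_rate must be in [0, 1]")
    if "cpdna" in stages:
        cp = config.get("cpdna", {})
        if has_real and not cp.get("masks"):
            fatal("cpdna stage on real inputs requires cpdna.masks")
    if not stages:
        warn("empty stage list: report will contain provenance only")
    return diags


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _build_model(synth: dict) -> DemographicModel:
    splits = []
    for s in synth.get("splits", []):
        if len(s) == 3:
            splits.append(Split(s[0], s[1], float(s[2])))
        else:
            splits.append(Split(s[0], s[1], float(s[2]), parent=s[3]))
    pulses = [Pulse(*p) for p in synth.get("admixture_pulses", [])]
    return DemographicModel(
        populations={k: float(v) for k, v in synth["populations"].items()},
        splits=splits,
        admixture_pulses=pulses,
        mutation_rate=float(synth.get("mutation_rate", 1e-8)),
        generation_time=float(synth.get("generation_time", 3.0)),
        locus_spec=(
            int(synth.get("n_loci", 100)),
            int(synth.get("locus_length", 2000)),
        ),
    )


def run_pipeline(config: dict, force: bool = False) -> dict:
    """Execute the configured stages in dependency order; returns the run
    report (also written to ``<output_dir>/report.json``)."""
    diags = validate_config(config)
    if any(d["level"] == "fatal" for d in diags):
        raise ConfigurationError(
            "; ".join(d["message"] for d in diags if d["level"] == "fatal")
        )
    seed = int(config["seed"])
    out_dir = Path(config.get("output_dir", "phylopop_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", [])
    report: dict = {
        "provenance": {
            "tool": "phylopop",
            "version": __version__,
            "seed": seed,
            "config_hash": _config_hash(config),
        },
        "diagnostics": diags,
        "stages": {},
    }
    seeds = np.random.SeedSequence(seed).spawn(len(_STAGES))
    stage_seed = {
        name: int(ss.generate_state(1)[0] % 2**31)
        for name, ss in zip(_STAGES, seeds)
    }

    dataset = None
    table = None
    pop_map: Optional[dict[str, list[str]]] = None

    if "simulate" in stages:
        synth = config["synthetic"]
        cache_key = _config_hash({"synthetic": synth, "seed": seed})
        vcf_path = out_dir / "simulated.vcf"
        key_path = out_dir / "simulated.hash"
        model = _build_model(synth)
        dataset = simulate_coalescent(
            model,
            {k: int(v) for k, v in synth["samples_per_pop"].items()},
            seed=stage_seed["simulate"],
        )
        dataset = inject_clones_and_selfs(
            dataset,
            n_clonemate_copies=int(synth.get("n_clonemates", 0)),
            n_selfed=int(synth.get("n_selfed", 0)),
            genotyping_error_rate=float(synth.get("genotyping_error_rate", 0.0)),
            seed=stage_seed["simulate"] + 1,
        )
        corr = synth.get("corruption", {})
        spec = CorruptionSpec(
            **corr,
            n_high_missing_samples=int(synth.get("n_high_missing", 0)),
            missing_rate=float(synth.get("missing_rate", 0.25)),
        )
        # keep missing-rate exclusions disjoint from clone/selfing exclusions
        # so the ledger arithmetic is exact
        eligible = [
            sid
            for sid, t in dataset.truth.samples.items()
            if t.clone_group is None and t.selfed_from is None
        ]
        dataset = corrupt_for_qc(
            dataset, spec, seed=stage_seed["simulate"] + 2,
            high_missing_candidates=eligible,
        )
        if force or not (
            key_path.exists() and key_path.read_text() == cache_key
        ):
            io.write_vcf(dataset.genotypes, vcf_path)
            key_path.write_text(cache_key)
        table = dataset.genotypes
        pop_map = {}
        for sid, t in dataset.truth.samples.items():
            pop_map.setdefault(t.population, []).append(sid)
        report["stages"]["simulate"] = {
            "n_sites": table.n_sites,
            "n_samples": table.n_samples,
            "vcf": str(vcf_path),
        }
    elif "inputs" in config:
        table = io.read_vcf(config["inputs"]["vcf"])
        if "population_map" in config["inputs"]:
            pop_map = io.read_population_map(config["inputs"]["population_map"])

    if "qc" in stages:
        cfg = qc.FilterConfig(**config.get("qc", {}))
        table, rep = qc.run_cascade(table, cfg)
        io.write_vcf(table, out_dir / "qc.vcf")
        rep.to_frame().to_csv(out_dir / "filter_report.tsv", sep="\t", index=False)
        report["stages"]["qc"] = {
            "stages": rep.stages,
            "excluded_samples": rep.excluded_samples,
        }

    ledger = None
    if "clones" in stages:
        cfg = qc.FilterConfig(**config.get("qc", {}))
        _, missing_excluded, _rates = qc.sample_missing_filter(
            table, cfg.sample_missing_max
        )
        shared = clonality.pairwise_shared_het(table)
        groups = clonality.detect_clones(table, shared=shared)
        selfs = clonality.detect_selfing(table, clone_groups=groups)
        ledger = clonality.build_exclusion_ledger(
            table, groups, selfs, missing_excluded, shared=shared
        )
        ledger.to_frame().to_csv(out_dir / "sample_ledger.tsv", sep="\t", index=False)
        table = table.subset_samples(ledger.retained)
        if pop_map:
            retained = set(ledger.retained)
            pop_map = {
                p: [s for s in ss if s in retained] for p, ss in pop_map.items()
            }
        report["stages"]["clones"] = {
            "n_clone_groups": len(ledger.clone_groups),
            "n_selfing_pairs": len(ledger.selfing_pairs),
            "n_excluded": len(ledger.exclusions),
            "n_retained": len(ledger.retained),
        }

    if "stats" in stages:
        scfg = config.get("stats", {})
        if pop_map is None:
            raise ConfigurationError("stats stage requires a population map")
        neutral = qc.subset_by_annotation(table, "synonymous", drop_missing=True)
        div = {
            p: float(
                popstats.nucleotide_diversity(neutral, ss, per_chromosome=False).iloc[0]
            )
            for p, ss in pop_map.items()
            if len(ss) >= 1 and neutral.n_sites > 0
        }
        hobs = {
            s: popstats.individual_heterozygosity(table, s) for s in table.samples
        }
        fst_t, fst_p = popstats.fst_matrix(
            table,
            {p: ss for p, ss in pop_map.items() if len(ss) >= 2},
            n_boot=int(scfg.get("n_boot", 200)),
            seed=stage_seed["stats"],
        )
        fst_t.to_csv(out_dir / "fst_theta.tsv", sep="\t")
        fst_p.to_csv(out_dir / "fst_pvalues.tsv", sep="\t")
        trios = popstats.patterson_d_table(
            table, pop_map, outgroup=scfg["outgroup"]
        )
        heat = popstats.d_heatmap_summarize(trios)
        heat.to_csv(out_dir / "d_heatmap.tsv", sep="\t", index=False)
        report["stages"]["stats"] = {
            "pi": div,
            "mean_hobs": float(np.mean(list(hobs.values()))) if hobs else None,
            "fst": fst_t.to_dict(),
            "n_trios": len(trios),
        }

    if "cpdna" in stages:
        ccfg = config.get("cpdna", {})
        pileups, cp_truth = simulate_cp_pileup(
            int(ccfg.get("n_samples", 12)),
            genome_length=int(ccfg.get("genome_length", 20000)),
            n_variable=int(ccfg.get("n_variable", 40)),
            n_microsat_artifacts=int(ccfg.get("n_microsat", 3)),
            n_hairpin_artifacts=int(ccfg.get("n_hairpin", 2)),
            median_coverage=int(ccfg.get("median_coverage", 200)),
            seed=stage_seed["cpdna"],
        )
        positions, calls = cpdna.call_cp_variants(pileups)
        retained, removed = cpdna.apply_masks(positions, cp_truth.masks)
        seqs = {
            s: "".join(calls.loc[s, p] for p in retained) for s in calls.index
        }
        io.write_fasta(seqs, out_dir / "cp_haplotypes.fasta")
        haps = cpdna.collapse_haplotypes(seqs)
        net = cpdna.median_joining_network(
            list(haps["haplotype"]), epsilon=int(ccfg.get("epsilon", 0))
        )
        report["stages"]["cpdna"] = {
            "n_called": len(positions),
            "n_retained": len(retained),
            "removed_by_mask": removed,
            "n_haplotypes": len(haps),
            "network_vertices": net.graph.number_of_nodes(),
            "network_edges": net.graph.number_of_edges(),
        }

    if "dating" in stages:
        dcfg = config.get("dating", {})
        params = clock.ClockParams(
            mutation_rate_per_generation=float(
                dcfg.get("mutation_rate_per_generation", 1e-8)
            ),
            generation_time=float(
                dcfg.get("generation_time", presets.GENERATION_TIME_YEARS)
            ),
        )
        rows = []
        if pop_map and dataset is not None:
            complete = table.subset_sites(~table.missing_mask().any(axis=1))
            pops = [p for p, ss in pop_map.items() if len(ss) >= 2]
            for i, a in enumerate(pops):
                for b in pops[i + 1 :]:
                    t_years = clock.net_divergence_split_time(
                        complete, pop_map[a], pop_map[b], params
                    )
                    rows.append({"pop_a": a, "pop_b": b, "split_years": t_years})
        report["stages"]["dating"] = {"splits": rows}

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
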