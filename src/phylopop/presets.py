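"""Reference constants for the worked examples and demo configurations.

These are the published values of the study system the pipeline was built
around; they parameterise demo runs and recovery benchmarks, never the
algorithms themselves.
"""

from __future__ import annotations

#: organelle quadripartite structure (bp)
CP_INVERTED_REPEAT = 24_127
CP_LARGE_SINGLE_COPY = 83_312
CP_SMALL_SINGLE_COPY = 12_402
CP_GENOME_LENGTH = 143_968  # = 2*IR + LSC + SSC

#: organelle variant bookkeeping
CP_VARIABLE_POSITIONS = 174
CP_MICROSAT_ARTIFACTS = 11
CP_HAIRPIN_ARTIFACTS = 12
CP_RETAINED_SNPS = 151
CP_PARSIMONY_INFORMATIVE = 108

#: organelle clock
CP_MUTATION_RATE_PER_YEAR = 2e-9  # synonymous, per site per year

#: nuclear sample ledger of the demo composition
SAMPLES_TOTAL = 190
SAMPLES_SELFED = 10
SAMPLES_CLONEMATES = 17
SAMPLES_HIGH_MISSING = 10
SAMPLES_RETAINED = 153

#: generation time (years) used for generation <-> year conversions
GENERATION_TIME_YEARS = 3.0

#: divergence times of the four dated colonization nodes (kya)
NODE_TIMES_KYA = {
    "trans_pacific_1": 352.0,
    "trans_pacific_2": 270.0,
    "atlantic_colonization": 243.0,
    "mediterranean_founding": 43.8,
    "nw_ne_atlantic_split": 18.8,
}

#: lognormal node-age calibrations (real-space mean in mya, log-space sd)
CALIBRATION_STAGE1 = (11.154, 0.07)
CALIBRATION_STAGE2 = (0.3564, 0.1)

#: pangenome bookkeeping
PANGENOME_GENES = 20_100
PANGENOME_MIN_GENES = 17_500
PANGENOME_CORE_GENES = 18_717
PANGENOME_CORE_MEAN_FREQUENCY = 0.97


def node_time_generations(node: str,
                          generation_time: float = GENERATION_TIME_YEARS) -> float:
    """Convert a named node time from kya to generations."""
    return NODE_TIMES_KYA[node] * 1000.0 / generation_time
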