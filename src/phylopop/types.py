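"""Core data containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: columns every site table must carry
SITE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "vartype",
    "annotation",
    "MQ",
    "FS",
    "QD",
    "MQRankSum",
    "ReadPosRankSum",
    "SOR",
    "DP",
    "fail_tag",
]

ANNOTATION_CLASSES = ("synonymous", "nonsynonymous", "noncoding")

MISSING = -1


class ConfigurationError(ValueError):
    """Raised when a model or filter configuration is inconsistent."""


@dataclass
class GenotypeTable:
    """Site-by-sample diploid genotype matrix with per-call quality metrics.

    ``genotypes`` has shape ``(n_sites, n_samples, 2)`` with allele codes
    (0 = ref, 1.. = alt, -1 = missing).  ``ad`` stores (ref, alt) read
    depths per call.  ``sites`` is a :class:`pandas.DataFrame` with the
    columns in :data:`SITE_COLUMNS`; ``alt`` holds a tuple of alt alleles.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    gq: np.ndarray
    dp: np.ndarray
    ad: np.ndarray
    samples: list[str]
    seq_length: Optional[int] = None

    def __post_init__(self) -> None:
        n = len(self.sites)
        m = len(self.samples)
        if self.genotypes.shape != (n, m, 2):
            raise ValueError(
                f"genotypes shape {self.genotypes.shape} != ({n}, {m}, 2)"
            )
        for name, arr, shape in (
            ("gq", self.gq, (n, m)),
            ("dp", self.dp, (n, m)),
            ("ad", self.ad, (n, m, 2)),
        ):
            if arr.shape != shape:
                raise ValueError(f"{name} shape {arr.shape} != {shape}")

    # ------------------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(
            sites=self.sites.copy(),
            genotypes=self.genotypes.copy(),
            gq=self.gq.copy(),
            dp=self.dp.copy(),
            ad=self.ad.copy(),
            samples=list(self.samples),
            seq_length=self.seq_length,
        )

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_sites, n_samples)`` array; True where call missing."""
        return (self.genotypes == MISSING).any(axis=2)

    def het_mask(self) -> np.ndarray:
        """True where the call is present and heterozygous."""
        g = self.genotypes
        return (g[:, :, 0] != g[:, :, 1]) & ~self.missing_mask()

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def subset_sites(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeTable(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[idx],
            gq=self.gq[idx],
            dp=self.dp[idx],
            ad=self.ad[idx],
            samples=list(self.samples),
            seq_length=self.seq_length,
        )

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeTable":
        idx = [self.sample_index(s) for s in samples]
        return GenotypeTable(
            sites=self.sites.copy(),
            genotypes=self.genotypes[:, idx],
            gq=self.gq[:, idx],
            dp=self.dp[:, idx],
            ad=self.ad[:, idx],
            samples=list(samples),
            seq_length=self.seq_length,
        )

    def allele_frequencies(self, samples: Optional[Sequence[str]] = None) -> np.ndarray:
        """Alt-allele frequency per site over called alleles (NaN if none)."""
        g = self.genotypes
        if samples is not None:
            idx = [self.sample_index(s) for s in samples]
            g = g[:, idx]
        called = g != MISSING
        n_called = called.sum(axis=(1, 2))
        n_alt = ((g > 0) & called).sum(axis=(1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, n_alt / np.maximum(n_called, 1), np.nan)


@dataclass
class SampleTruth:
    """Ground-truth label for one simulated sample."""

    population: str
    clone_group: Optional[int] = None
    selfed_from: Optional[str] = None


@dataclass
class DatasetTruth:
    """All ground-truth bookkeeping attached to a simulated dataset."""

    samples: dict[str, SampleTruth] = field(default_factory=dict)
    high_missing_samples: list[str] = field(default_factory=list)
    #: calls corrupted below the genotype-quality rules, as (chrom, pos, sample)
    masked_calls: list[tuple[str, int, str]] = field(default_factory=list)
    cp_artifacts: dict[str, list[int]] = field(default_factory=dict)

    def clone_groups(self) -> dict[int, list[str]]:
        groups: dict[int, list[str]] = {}
        for sid, t in self.samples.items():
            if t.clone_group is not None:
                groups.setdefault(t.clone_group, []).append(sid)
        return groups


@dataclass
class SimulatedDataset:
    """A simulated genotype table plus its ground truth."""

    genotypes: GenotypeTable
    truth: DatasetTruth
    true_tree_times: dict[str, float]
    seed: int

    def copy(self) -> "SimulatedDataset":
        truth = DatasetTruth(
            samples={k: replace(v) for k, v in self.truth.samples.items()},
            high_missing_samples=list(self.truth.high_missing_samples),
            masked_calls=list(self.truth.masked_calls),
            cp_artifacts={k: list(v) for k, v in self.truth.cp_artifacts.items()},
        )
        return SimulatedDataset(
            genotypes=self.genotypes.copy(),
            truth=truth,
            true_tree_times=dict(self.true_tree_times),
            seed=self.seed,
        )


def empty_site_frame(n: int = 0) -> pd.DataFrame:
    """A site table with the mandatory columns and ``n`` blank rows."""
    return pd.DataFrame(
        {
            "chrom": [""] * n,
            "pos": np.zeros(n, dtype=np.int64),
            "ref": ["A"] * n,
            "alt": [("T",)] * n,
            "vartype": ["snp"] * n,
            "annotation": ["noncoding"] * n,
            "MQ": np.full(n, 60.0),
            "FS": np.full(n, 1.0),
            "QD": np.full(n, 25.0),
            "MQRankSum": np.zeros(n),
            "ReadPosRankSum": np.zeros(n),
            "SOR": np.full(n, 1.0),
            "DP": np.full(n, 1000.0),
            "fail_tag": [""] * n,
        }
    )
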