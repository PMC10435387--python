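"""Reading and writing of the plain-text interchange formats.

VCF v4.2 (GT:GQ:DP:AD, the hard-filter INFO keys and an ANN annotation
class), BED (0-based half-open), FASTA, per-sample pileup TSVs and
population-map TSVs.  Reading VCF uses cyvcf2.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import CpPileup
from .types import MISSING, GenotypeTable, empty_site_frame

__all__ = [
    "write_vcf",
    "read_vcf",
    "read_bed",
    "write_bed",
    "write_fasta",
    "read_fasta",
    "write_pileup_tsv",
    "read_pileup_tsv",
    "read_population_map",
]

_INFO_KEYS = ["MQ", "FS", "QD", "MQRankSum", "ReadPosRankSum", "SOR", "DP"]

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">
##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric odds ratio">
##INFO=<ID=DP,Number=1,Type=Float,Description="Total depth">
##INFO=<ID=ANN,Number=1,Type=String,Description="Annotation class">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
"""


def write_vcf(table: GenotypeTable, path: str | os.PathLike) -> None:
    """Serialise a genotype table as an uncompressed VCF v4.2 file."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if table.seq_length is not None:
            fh.write(f"##seq_length={table.seq_length}\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        s = table.sites
        for i in range(table.n_sites):
            row = s.iloc[i]
            info = ";".join(
                f"{k}={float(row[k]):.4f}" for k in _INFO_KEYS if pd.notna(row[k])
            )
            info += f";ANN={row['annotation']}"
            alt = ",".join(row["alt"]) if row["alt"] else "."
            cols = [
                str(row["chrom"]), str(int(row["pos"])), ".", str(row["ref"]), alt,
                ".", "PASS", info, "GT:GQ:DP:AD",
            ]
            for j in range(table.n_samples):
                a, b = table.genotypes[i, j]
                gt = "./." if a == MISSING or b == MISSING else f"{a}/{b}"
                ad = f"{table.ad[i, j, 0]},{table.ad[i, j, 1]}"
                cols.append(f"{gt}:{table.gq[i, j]}:{table.dp[i, j]}:{ad}")
            fh.write("\t".join(cols) + "\n")


def read_vcf(path: str | os.PathLike) -> GenotypeTable:
    """Load a VCF into a genotype table (cyvcf2 backend)."""
    from cyvcf2 import VCF

    seq_length: Optional[int] = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##seq_length="):
                seq_length = int(line.strip().split("=", 1)[1])
            if not line.startswith("##"):
                break

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    genos, gqs, dps, ads = [], [], [], []
    for v in vcf:
        alt = tuple(v.ALT)
        if len(v.REF) == 1 and all(len(a) == 1 for a in alt):
            vartype = "snp"
        else:
            vartype = "indel"
        rows.append(
            {
                "chrom": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": alt,
                "vartype": vartype,
                "annotation": v.INFO.get("ANN") or "noncoding",
                "MQ": _num(v.INFO.get("MQ")),
                "FS": _num(v.INFO.get("FS")),
                "QD": _num(v.INFO.get("QD")),
                "MQRankSum": _num(v.INFO.get("MQRankSum")),
                "ReadPosRankSum": _num(v.INFO.get("ReadPosRankSum")),
                "SOR": _num(v.INFO.get("SOR")),
                "DP": _num(v.INFO.get("DP")),
                "fail_tag": "",
            }
        )
        gt = np.array([[g[0], g[1]] for g in v.genotypes], dtype=np.int8)
        gt[gt < 0] = MISSING
        genos.append(gt)
        gq = v.format("GQ")
        gqs.append(
            gq[:, 0].astype(np.int32) if gq is not None
            else np.full(len(samples), 99, np.int32)
        )
        dp = v.format("DP")
        dps.append(
            dp[:, 0].astype(np.int32) if dp is not None
            else np.full(len(samples), 30, np.int32)
        )
        ad = v.format("AD")
        if ad is None:
            ads.append(np.zeros((len(samples), 2), np.int32))
        else:
            ad = ad.astype(np.int32)
            ad[ad < 0] = 0
            ads.append(ad[:, :2])
    n = len(rows)
    sites = pd.DataFrame(rows) if n else empty_site_frame(0)
    return GenotypeTable(
        sites=sites,
        genotypes=np.stack(genos) if n else np.zeros((0, len(samples), 2), np.int8),
        gq=np.stack(gqs) if n else np.zeros((0, len(samples)), np.int32),
        dp=np.stack(dps) if n else np.zeros((0, len(samples)), np.int32),
        ad=np.stack(ads) if n else np.zeros((0, len(samples), 2), np.int32),
        samples=samples,
        seq_length=seq_length,
    )


def _num(x) -> float:
    return float("nan") if x is None else float(x)


# ----------------------------------------------------------------------
def read_bed(path: str | os.PathLike) -> list[tuple[str, int, int, str]]:
    """BED rows as (chrom, start, end, name); name '' when absent."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            name = parts[3] if len(parts) > 3 else ""
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


def write_bed(
    intervals: Sequence[tuple], path: str | os.PathLike
) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


# ----------------------------------------------------------------------
def write_fasta(sequences: dict[str, str], path: str | os.PathLike,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    out: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                out[name] = []
            else:
                if name is None:
                    raise ValueError("FASTA sequence before header")
                out[name].append(line)
    return {k: "".join(v) for k, v in out.items()}


# ----------------------------------------------------------------------
_PILEUP_COLS = ["pos", "ref", "cov", "A", "C", "G", "T"]
_BASE_CHARS = "ACGT"


def write_pileup_tsv(pileup: CpPileup, path: str | os.PathLike) -> None:
    """One row per (1-based) position: pos, ref, cov, A, C, G, T."""
    df = pd.DataFrame(
        {
            "pos": np.arange(1, pileup.length + 1),
            "ref": [_BASE_CHARS[int(b)] for b in pileup.ref],
            "cov": pileup.coverage,
            "A": pileup.counts[:, 0],
            "C": pileup.counts[:, 1],
            "G": pileup.counts[:, 2],
            "T": pileup.counts[:, 3],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path: str | os.PathLike) -> CpPileup:
    df = pd.read_csv(path, sep="\t")
    missing = set(_PILEUP_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup TSV missing columns: {sorted(missing)}")
    ref = np.array([_BASE_CHARS.index(b) for b in df["ref"]], dtype=np.uint8)
    counts = df[["A", "C", "G", "T"]].to_numpy(dtype=np.int32)
    return CpPileup(
        ref=ref, coverage=df["cov"].to_numpy(dtype=np.int32), counts=counts
    )


def read_population_map(path: str | os.PathLike) -> dict[str, list[str]]:
    """TSV of (sample, population) -> {population: [samples]}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"])
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["population"]), []).append(str(row["sample"]))
    return out
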