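"""File formats.

TSV for SNP panels, pool observations and scan statistics; CSV for
germination count tables; BED (0-based half-open, strand '+' for Col-0 /
'-' for Bs-2) and a richer TSV for QTL intervals.  Internal coordinates are
1-based closed; conversion happens only here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .scan import QTLInterval
from .simulate import PoolObservation

__all__ = [
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_pool_tsv",
    "read_pool_tsv",
    "write_scan_tsv",
    "write_qtl_bed",
    "write_qtl_tsv",
    "read_qtl_tsv",
    "read_counts_csv",
]


def write_genotypes_tsv(dosages: np.ndarray, gmap: GeneticMap, path) -> None:
    """Individuals x SNPs Col-0 dosage matrix, SNP ids as header."""
    pd.DataFrame(dosages, columns=gmap.snps["id"]).to_csv(
        path, sep="\t", index_label="individual"
    )


def read_genotypes_tsv(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col="individual").to_numpy(dtype=np.int8)


def write_pool_tsv(pool: PoolObservation, path, snp_ids=None) -> None:
    """Intensity pools: snp_id, pool_id, replicate, dye, signal_col,
    signal_bs.  Frequency pools: snp_id, pool_id, freq."""
    if pool.intensities is not None:
        df = pool.intensities.copy()
        df.insert(1, "pool_id", pool.pool_id)
        df.to_csv(path, sep="\t", index=False)
    elif pool.freq is not None:
        ids = snp_ids if snp_ids is not None else np.arange(pool.freq.size)
        pd.DataFrame(
            {"snp_id": ids, "pool_id": pool.pool_id, "freq": pool.freq}
        ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError("pool has neither frequencies nor intensities")


def read_pool_tsv(path) -> PoolObservation:
    df = pd.read_csv(path, sep="\t")
    pool_id = str(df["pool_id"].iloc[0]) if "pool_id" in df else "pool"
    if "freq" in df.columns:
        return PoolObservation(
            pool_id=pool_id, n_individuals=0, freq=df["freq"].to_numpy()
        )
    return PoolObservation(
        pool_id=pool_id,
        n_individuals=0,
        intensities=df[["snp_id", "replicate", "dye", "signal_col", "signal_bs"]],
    )


def write_scan_tsv(stats: pd.DataFrame, threshold: float, path) -> None:
    out = stats.copy()
    out["significant"] = (out["signed_F"].abs() >= threshold).astype(int)
    out.to_csv(path, sep="\t", index=False)


def write_qtl_bed(intervals: list[QTLInterval], path, names=None) -> None:
    """BED6; scores are |peak F| scaled into 0-1000 as BED requires."""
    if names is None:
        names = [f"qtl{i + 1}" for i in range(len(intervals))]
    peak = max((abs(iv.peak_f) for iv in intervals), default=1.0) or 1.0
    with open(path, "w") as fh:
        for iv, name in zip(intervals, names):
            score = int(round(1000 * abs(iv.peak_f) / peak))
            strand = "+" if iv.direction == "Col-0" else "-"
            fh.write(
                f"{iv.chrom}\t{iv.start_bp - 1}\t{iv.end_bp}\t{name}\t{score}\t{strand}\n"
            )


def write_qtl_tsv(intervals: list[QTLInterval], path, names=None) -> None:
    if names is None:
        names = [f"qtl{i + 1}" for i in range(len(intervals))]
    pd.DataFrame(
        [
            dict(
                name=name, chrom=iv.chrom, start_bp=iv.start_bp, end_bp=iv.end_bp,
                direction=iv.direction, peak_F=iv.peak_f,
                peak_pos_bp=iv.peak_pos_bp, n_significant_snps=iv.n_significant_snps,
            )
            for iv, name in zip(intervals, names)
        ],
        columns=[
            "name", "chrom", "start_bp", "end_bp", "direction", "peak_F",
            "peak_pos_bp", "n_significant_snps",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_qtl_tsv(path) -> list[QTLInterval]:
    df = pd.read_csv(path, sep="\t")
    return [
        QTLInterval(
            chrom=str(r.chrom), start_bp=int(r.start_bp), end_bp=int(r.end_bp),
            direction=str(r.direction), peak_f=float(r.peak_F),
            peak_pos_bp=int(r.peak_pos_bp),
            n_significant_snps=int(r.n_significant_snps),
        )
        for r in df.itertuples()
    ]


def read_counts_csv(path) -> pd.DataFrame:
    """Germination counts: time_hours, count, replicate, accession,
    environment, total_seeds."""
    df = pd.read_csv(path)
    required = {"time_hours", "count", "replicate", "accession", "environment",
                "total_seeds"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns {sorted(missing)}")
    return df
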