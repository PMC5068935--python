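"""Genetic map / SNP panel container.

A :class:`GeneticMap` holds the chromosome layout (physical and genetic
lengths) and the ordered SNP panel used both by the forward simulator and by
the scan.  Genetic positions (cM) are tied to physical positions (bp) through
a per-chromosome constant recombination rate, which is the simplest map
consistent with a Haldane (no-interference) meiosis model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "default_map"]

PANEL_COLUMNS = ["chrom", "pos_bp", "pos_cM", "id"]


@dataclass
class GeneticMap:
    """Chromosome layout plus an ordered biallelic SNP panel.

    Parameters
    ----------
    chromosomes
        List of ``(name, length_bp, length_cM)`` tuples in genome order.
    snps
        DataFrame with columns ``chrom, pos_bp, pos_cM, id``; SNPs must be
        grouped by chromosome in genome order, with strictly increasing
        ``pos_bp`` and non-decreasing ``pos_cM`` within each chromosome.
    """

    chromosomes: list[tuple[str, int, float]]
    snps: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"SNP panel missing columns {missing}")
        self.snps = self.snps.reset_index(drop=True)
        lengths = {name: (lbp, lcm) for name, lbp, lcm in self.chromosomes}
        order = [name for name, _, _ in self.chromosomes]
        seen = self.snps["chrom"].unique().tolist()
        if seen != [c for c in order if c in seen]:
            raise ValueError("SNPs not grouped in chromosome order")
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            if chrom not in lengths:
                raise ValueError(f"SNP on unknown chromosome {chrom!r}")
            pos = grp["pos_bp"].to_numpy()
            cm = grp["pos_cM"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"pos_bp not strictly increasing on {chrom}")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"pos_cM decreasing on {chrom}")
            if pos[0] < 0 or pos[-1] > lengths[chrom][0]:
                raise ValueError(f"pos_bp outside chromosome {chrom}")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _, _ in self.chromosomes]

    def chrom_slices(self) -> dict[str, slice]:
        """Panel index range of each chromosome, in panel order."""
        out: dict[str, slice] = {}
        start = 0
        for chrom, grp in self.snps.groupby("chrom", sort=False):
            out[str(chrom)] = slice(start, start + len(grp))
            start += len(grp)
        return out

    def snp_index(self, chrom: str, pos_bp: float) -> int:
        """Panel index of the SNP nearest to ``pos_bp`` on ``chrom``."""
        sl = self.chrom_slices().get(chrom)
        if sl is None:
            raise ValueError(f"no SNPs on chromosome {chrom!r}")
        pos = self.snps["pos_bp"].to_numpy()[sl]
        return sl.start + int(np.argmin(np.abs(pos - pos_bp)))

    def to_tsv(self, path) -> None:
        self.snps.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, chromosomes=None) -> "GeneticMap":
        snps = pd.read_csv(path, sep="\t")
        if chromosomes is None:
            # infer lengths from the panel extent (positions are inside)
            chromosomes = [
                (str(chrom), int(grp["pos_bp"].max()), float(grp["pos_cM"].max()))
                for chrom, grp in snps.groupby("chrom", sort=False)
            ]
        return cls(chromosomes=chromosomes, snps=snps)


def default_map(
    n_chromosomes: int = 5,
    length_bp: int = 30_000_000,
    cm_per_mb: float = 4.0,
    n_snps: int = 3000,
) -> GeneticMap:
    """Desk-scale stand-in for the 5-chromosome Arabidopsis panel.

    Evenly spaced SNPs, constant recombination rate (default 4 cM/Mbp, about
    120 cM per 30-Mbp chromosome, in the range of the A. thaliana genetic
    map).  The published panel had ~30,389 SNPs; 3000 keeps desk-scale runs
    fast while preserving marker density well below the LD scale of an F3.
    """
    per_chrom = n_snps // n_chromosomes
    length_cm = length_bp / 1e6 * cm_per_mb
    chroms = [(f"Chr{i + 1}", length_bp, length_cm) for i in range(n_chromosomes)]
    frames = []
    for name, lbp, _ in chroms:
        pos = np.linspace(lbp / per_chrom, lbp, per_chrom).round().astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": name,
                    "pos_bp": pos,
                    "pos_cM": pos / 1e6 * cm_per_mb,
                    "id": [f"{name}_snp{j:05d}" for j in range(per_chrom)],
                }
            )
        )
    return GeneticMap(chromosomes=chroms, snps=pd.concat(frames, ignore_index=True))
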