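"""Cross-cohort QTL comparison and run reporting.

Interval arithmetic is 1-based closed throughout (matching how QTL ranges
are quoted in Mbp); BED conversion to 0-based half-open happens only at
file boundaries (see :mod:`germxqtl.io`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scan import QTLInterval

__all__ = [
    "QTLSet",
    "interval_overlap",
    "annotate_intervals",
    "read_gff3_features",
    "summarize_run",
    "name_intervals",
]

logger = logging.getLogger(__name__)


@dataclass
class QTLSet:
    """A labelled, sorted set of called QTL intervals (e.g. ``SaltEarly``)."""

    label: str
    intervals: list[QTLInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start_bp)
        )
        prev: QTLInterval | None = None
        for iv in self.intervals:
            if iv.start_bp > iv.end_bp:
                raise ValueError("interval start must not exceed end")
            if (
                prev is not None
                and iv.chrom == prev.chrom
                and iv.start_bp <= prev.end_bp
            ):
                raise ValueError(f"overlapping intervals within set {self.label!r}")
            prev = iv


def name_intervals(qtl_set: QTLSet) -> list[str]:
    """``<label>Q<chrom index>.<index>`` names, e.g. SaltEarlyQ4.1."""
    names = []
    counter: dict[str, int] = {}
    for iv in qtl_set.intervals:
        cnum = "".join(ch for ch in iv.chrom if ch.isdigit()) or iv.chrom
        counter[cnum] = counter.get(cnum, 0) + 1
        names.append(f"{qtl_set.label}Q{cnum}.{counter[cnum]}")
    return names


def interval_overlap(a: QTLSet, b: QTLSet) -> pd.DataFrame:
    """All overlapping interval pairs between two QTL sets.

    One row per pair with 1-based closed overlap length
    (``min(end) - max(start) + 1``) and a direction-agreement flag.
    """
    rows = []
    names_a = name_intervals(a)
    names_b = name_intervals(b)
    for iv_a, name_a in zip(a.intervals, names_a):
        for iv_b, name_b in zip(b.intervals, names_b):
            if iv_a.chrom != iv_b.chrom:
                continue
            lo = max(iv_a.start_bp, iv_b.start_bp)
            hi = min(iv_a.end_bp, iv_b.end_bp)
            if lo > hi:
                continue
            rows.append(
                dict(
                    name_a=name_a, name_b=name_b, chrom=iv_a.chrom,
                    start_a=iv_a.start_bp, end_a=iv_a.end_bp,
                    start_b=iv_b.start_bp, end_b=iv_b.end_bp,
                    overlap_bp=hi - lo + 1,
                    direction_agreement=iv_a.direction == iv_b.direction,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "name_a", "name_b", "chrom", "start_a", "end_a", "start_b", "end_b",
            "overlap_bp", "direction_agreement",
        ],
    )


def read_gff3_features(path) -> pd.DataFrame:
    """Genomic features from a GFF3 file: chrom, start, end (1-based closed),
    id, name.  Malformed rows are skipped with a logged count."""
    import pyranges as pr

    gr = pr.read_gff3(path)
    df = gr.df
    out = pd.DataFrame(
        {
            "chrom": df["Chromosome"].astype(str),
            "start": df["Start"].astype(int) + 1,  # pyranges is 0-based half-open
            "end": df["End"].astype(int),
            "id": df["ID"] if "ID" in df else pd.Series([None] * len(df)),
            "name": df["Name"] if "Name" in df else pd.Series([None] * len(df)),
        }
    )
    bad = (out["end"] < out["start"]).sum()
    if bad:
        logger.warning("skipped %d malformed feature rows", bad)
        out = out[out["end"] >= out["start"]]
    return out.reset_index(drop=True)


def annotate_intervals(
    qtl_set: QTLSet, features: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Features intersecting each interval (1-based closed intersection;
    a feature touching an interval edge by one bp is reported)."""
    out: dict[str, pd.DataFrame] = {}
    for iv, name in zip(qtl_set.intervals, name_intervals(qtl_set)):
        if features.empty:
            out[name] = features.copy()
            continue
        hit = (
            (features["chrom"] == iv.chrom)
            & (features["start"] <= iv.end_bp)
            & (features["end"] >= iv.start_bp)
        )
        out[name] = features[hit].reset_index(drop=True)
    return out


def _qtl_table(qtl_set: QTLSet) -> str:
    lines = ["name\tchrom\trange_Mbp\tsize_Mbp\tdirection\tpeak_F\tn_snps"]
    for iv, name in zip(qtl_set.intervals, name_intervals(qtl_set)):
        lines.append(
            f"{name}\t{iv.chrom}\t"
            f"{iv.start_bp / 1e6:.2f}-{iv.end_bp / 1e6:.2f}\t"
            f"{(iv.end_bp - iv.start_bp) / 1e6:.2f}\t"
            f"{iv.direction}\t{iv.peak_f:.2f}\t{iv.n_significant_snps}"
        )
    return "\n".join(lines)


def summarize_run(
    qtl_sets: list[QTLSet],
    cohort_sizes: dict[str, list[int]] | None = None,
    kinetics: pd.DataFrame | None = None,
    recovery: pd.DataFrame | None = None,
) -> str:
    """Plain-text report: cohort sizes, per-set QTL tables (sizes in Mbp to
    two decimals), the pairwise overlap matrix, and optional kinetics and
    QTL-recovery tables.  Deterministic for identical inputs."""
    parts: list[str] = ["# X-QTL run summary", ""]
    if cohort_sizes:
        parts.append("## Cohort sizes (individuals per replicate pool)")
        for label in sorted(cohort_sizes):
            sizes = ", ".join(str(s) for s in cohort_sizes[label])
            parts.append(f"{label}: {sizes}")
        parts.append("")
    else:
        parts.append("## Cohort sizes: absent")
        parts.append("")
    parts.append("## QTL intervals")
    if not qtl_sets:
        parts.append("(no QTL sets)")
    for qs in qtl_sets:
        parts.append(f"### {qs.label} ({len(qs.intervals)} intervals)")
        parts.append(_qtl_table(qs))
        parts.append("")
    if len(qtl_sets) > 1:
        parts.append("## Pairwise overlaps")
        for i in range(len(qtl_sets)):
            for j in range(i + 1, len(qtl_sets)):
                ov = interval_overlap(qtl_sets[i], qtl_sets[j])
                parts.append(
                    f"{qtl_sets[i].label} vs {qtl_sets[j].label}: "
                    f"{len(ov)} overlapping pair(s)"
                )
                for _, row in ov.iterrows():
                    agree = "same" if row.direction_agreement else "opposite"
                    parts.append(
                        f"  {row.name_a} x {row.name_b} ({row.chrom}): "
                        f"{row.overlap_bp / 1e6:.2f} Mbp, {agree} direction"
                    )
        parts.append("")
    parts.append("## Kinetics")
    if kinetics is None or kinetics.empty:
        parts.append("absent")
    else:
        parts.append(kinetics.to_csv(sep="\t", index=False, float_format="%.4f").rstrip())
    parts.append("")
    parts.append("## QTL recovery")
    if recovery is None or recovery.empty:
        parts.append("absent")
    else:
        parts.append(recovery.to_csv(sep="\t", index=False).rstrip())
    parts.append("")
    return "\n".join(parts)
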