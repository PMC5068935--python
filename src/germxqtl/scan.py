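"""X-QTL mapping core.

Pooled allele-frequency estimation from dye-swap two-channel intensities
against the random-F2 reference, the sliding-window nested-ANOVA scan
statistic signed by parental direction, genome-wide permutation thresholds
(with window-size selection), and QTL interval calling with the <1 Mbp
merge rule.

Scan statistic
--------------
Within the window of ``w`` consecutive SNPs centred on the focal SNP, the
response is the per-SNP, per-replicate-pool frequency estimate and the
model is a nested ANOVA: selection condition (fixed, selected vs control),
replicate pool nested in condition, and SNP-within-window as the residual
stratum.  The reported F tests the condition effect against the
replicate-within-condition mean square, and carries the sign of the mean
frequency difference (positive = Col-0 bias, negative = Bs-2 bias).
Because both mean squares average over the window, F reduces to a one-way
ANOVA on per-replicate window means, which is how it is computed; the
brute-force sums-of-squares decomposition over the full w x R table gives
the identical value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .simulate import PoolObservation

__all__ = [
    "ScanConfig",
    "QTLInterval",
    "estimate_allele_freq",
    "freq_matrix",
    "window_scan",
    "permutation_threshold",
    "select_window_size",
    "call_qtl",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters: window size (odd SNP count), family-wise alpha,
    permutation count, interval merge distance and RNG seed."""

    window_size: int = 9
    alpha: float = 0.05
    n_permutations: int = 200
    merge_distance_bp: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 3")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.merge_distance_bp <= 0:
            raise ValueError("merge_distance_bp must be > 0")


@dataclass(frozen=True)
class QTLInterval:
    """A called QTL: a run of consecutive significant SNPs (possibly merged
    with nearby same-direction runs)."""

    chrom: str
    start_bp: int
    end_bp: int
    direction: str  # "Col-0" or "Bs-2"
    peak_f: float  # signed F at the peak SNP
    peak_pos_bp: int
    n_significant_snps: int


# ---------------------------------------------------------------------------
# allele-frequency estimation


def _dye_swap_ratio(intensities: pd.DataFrame) -> pd.DataFrame:
    """Per (snp, replicate) geometric mean of the col/bs channel ratio over
    the dye-swap pair; SNPs missing an orientation are dropped."""
    df = intensities
    if np.any(df["signal_col"].to_numpy() <= 0) or np.any(
        df["signal_bs"].to_numpy() <= 0
    ):
        raise ValueError("non-positive intensity")
    df = df.assign(ratio=df["signal_col"] / df["signal_bs"])
    piv = df.pivot_table(
        index=["snp_id", "replicate"], columns="dye", values="ratio", aggfunc="first"
    )
    complete = piv.dropna(subset=["forward", "swapped"])
    n_dropped = len(piv) - len(complete)
    if n_dropped:
        logger.warning("dropped %d snp/replicate pairs missing a dye-swap partner",
                       n_dropped)
    return np.sqrt(complete["forward"] * complete["swapped"]).rename("rho").reset_index()


def estimate_allele_freq(
    obs: PoolObservation,
    ref: PoolObservation,
    ref_freq: float = 0.5,
) -> pd.DataFrame:
    """Col-0 allele-frequency estimates per (snp, replicate).

    Channel ratios are geometric-mean averaged over the dye-swap pair
    (cancelling dye gains), divided by the matching reference-pool ratio
    (cancelling probe affinity), and the resulting odds — relative to the
    reference frequency — converted to a frequency.  A pool identical to the
    reference therefore lands at ``ref_freq`` (0.5 for random F2s).
    Estimates are clamped to [0, 1]; the clamp count is logged.
    """
    if obs.intensities is None or ref.intensities is None:
        raise ValueError("both observations need intensities")
    rho_obs = _dye_swap_ratio(obs.intensities)
    rho_ref = _dye_swap_ratio(ref.intensities).rename(columns={"rho": "rho_ref"})
    merged = rho_obs.merge(rho_ref, on=["snp_id", "replicate"], how="inner")
    odds_ref = ref_freq / (1.0 - ref_freq)
    corrected = merged["rho"] / merged["rho_ref"] * odds_ref
    freq = corrected / (corrected + 1.0)
    n_clamped = int(((freq < 0) | (freq > 1)).sum())
    if n_clamped:
        logger.info("clamped %d frequency estimates to [0, 1]", n_clamped)
    out = merged[["snp_id", "replicate"]].copy()
    out["freq"] = np.clip(freq, 0.0, 1.0)
    return out


def freq_matrix(estimates: pd.DataFrame, gmap: GeneticMap) -> np.ndarray:
    """(n_replicates, n_snps) matrix of estimates in panel order."""
    piv = estimates.pivot_table(index="replicate", columns="snp_id", values="freq")
    missing = [s for s in gmap.snps["id"] if s not in piv.columns]
    if missing:
        raise ValueError(f"estimates missing {len(missing)} panel SNPs")
    return piv[gmap.snps["id"].tolist()].to_numpy()


# ---------------------------------------------------------------------------
# sliding-window scan


def _window_bounds(n: int, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Truncated window [lo, hi) per focal index for one chromosome."""
    h = w // 2
    idx = np.arange(n)
    lo = np.maximum(0, idx - h)
    hi = np.minimum(n, idx + h + 1)
    return lo, hi


def _window_means(mat: np.ndarray, gmap: GeneticMap, w: int) -> np.ndarray:
    """(R, S) per-replicate window-mean frequencies; windows of w SNPs
    centred on each focal SNP, truncated at chromosome ends and never
    spanning chromosomes."""
    out = np.empty_like(mat, dtype=float)
    for chrom, sl in gmap.chrom_slices().items():
        sub = mat[:, sl]
        n = sub.shape[1]
        if w > n:
            logger.warning("window %d exceeds %d SNPs on %s; truncating", w, n, chrom)
        lo, hi = _window_bounds(n, w)
        csum = np.concatenate(
            [np.zeros((sub.shape[0], 1)), np.cumsum(sub, axis=1)], axis=1
        )
        out[:, sl] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
    return out


def _signed_f(
    w_sel: np.ndarray, w_ctrl: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Signed F per focal SNP from per-replicate window means.

    Returns (F, signed difference of condition means).  F = 0 where the
    condition means coincide; +inf where replicates are identical within
    condition but the conditions differ.
    """
    r1, r2 = w_sel.shape[0], w_ctrl.shape[0]
    if r1 < 2 or r2 < 2:
        raise ValueError("need >= 2 replicate estimates per pool")
    m1 = w_sel.mean(axis=0)
    m2 = w_ctrl.mean(axis=0)
    grand = (r1 * m1 + r2 * m2) / (r1 + r2)
    ss_cond = r1 * (m1 - grand) ** 2 + r2 * (m2 - grand) ** 2
    ss_rep = ((w_sel - m1) ** 2).sum(axis=0) + ((w_ctrl - m2) ** 2).sum(axis=0)
    df_rep = r1 + r2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ss_cond / (ss_rep / df_rep)
    f = np.where(ss_cond <= 0.0, 0.0, f)
    return f, m1 - m2


def window_scan(
    sel: np.ndarray,
    ctrl: np.ndarray,
    gmap: GeneticMap,
    cfg: ScanConfig,
) -> pd.DataFrame:
    """Sliding-window nested-ANOVA scan of selected vs control pools.

    ``sel`` and ``ctrl`` are (n_replicates, n_snps) frequency-estimate
    matrices in panel order.  Returns one row per focal SNP with columns
    ``snp_id, chrom, pos_bp, signed_F, window_size``; step is one SNP.
    """
    if sel.shape[1] != gmap.n_snps or ctrl.shape[1] != gmap.n_snps:
        raise ValueError("estimate matrices must cover the SNP panel")
    w_sel = _window_means(sel, gmap, cfg.window_size)
    w_ctrl = _window_means(ctrl, gmap, cfg.window_size)
    f, diff = _signed_f(w_sel, w_ctrl)
    return pd.DataFrame(
        {
            "snp_id": gmap.snps["id"],
            "chrom": gmap.snps["chrom"],
            "pos_bp": gmap.snps["pos_bp"],
            "signed_F": np.sign(diff) * f,
            "window_size": cfg.window_size,
        }
    )


# ---------------------------------------------------------------------------
# permutation threshold


def permutation_threshold(
    sel: np.ndarray,
    ctrl: np.ndarray,
    gmap: GeneticMap,
    cfg: ScanConfig,
    return_null: bool = False,
):
    """Genome-wide significance threshold for |signed F| by permutation.

    Replicate-pool labels (dye-swap pairs stay intact inside a replicate)
    are permuted across the selected/control conditions; each permutation's
    genome-wide max |F| forms the null distribution and the empirical
    (1 - alpha) quantile is the threshold.  Deterministic given cfg.seed.
    """
    r1, r2 = sel.shape[0], ctrl.shape[0]
    r = r1 + r2
    if r < 4:
        raise ValueError("need >= 4 replicate pools in total to permute")
    if math.comb(r, r1) < 3:
        raise ValueError(
            "fewer than 3 distinct label assignments; permutation threshold "
            "is meaningless at this replication level"
        )
    rng = np.random.default_rng(cfg.seed)
    w_all = np.vstack(
        [
            _window_means(sel, gmap, cfg.window_size),
            _window_means(ctrl, gmap, cfg.window_size),
        ]
    )
    base = np.zeros(r, dtype=bool)
    base[:r1] = True
    sumsq = (w_all**2).sum(axis=0)
    grand = w_all.mean(axis=0)
    ss_grand = r * grand**2
    df_rep = r - 2
    maxima = np.empty(cfg.n_permutations)
    for b in range(cfg.n_permutations):
        lab = rng.permutation(base)
        m1 = w_all[lab].mean(axis=0)
        m2 = w_all[~lab].mean(axis=0)
        ss_cond = r1 * m1**2 + r2 * m2**2 - ss_grand
        ss_rep = sumsq - r1 * m1**2 - r2 * m2**2
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(ss_cond <= 0.0, 0.0, ss_cond / (ss_rep / df_rep))
        maxima[b] = np.nanmax(f)
        if (b + 1) % 50 == 0:
            logger.debug("permutation %d/%d", b + 1, cfg.n_permutations)
    # next-higher order statistic: the standard (slightly conservative)
    # permutation convention
    threshold = float(np.quantile(maxima, 1.0 - cfg.alpha, method="higher"))
    return (threshold, maxima) if return_null else threshold


def select_window_size(
    sel: np.ndarray,
    ctrl: np.ndarray,
    gmap: GeneticMap,
    candidates: list[int],
    cfg: ScanConfig,
    rel_tol: float = 0.05,
) -> tuple[int, pd.DataFrame, bool]:
    """Window size by permutation-threshold stability.

    Computes the permutation threshold for each candidate window size and
    returns the smallest one whose threshold differs by less than
    ``rel_tol`` (relative) from the next larger candidate.  If no candidate
    stabilises, the largest is returned with ``stable=False``.
    """
    if any(w < 3 or w % 2 == 0 for w in candidates):
        raise ValueError("candidate window sizes must be odd and >= 3")
    cands = sorted(candidates)
    thresholds = [
        permutation_threshold(sel, ctrl, gmap, replace(cfg, window_size=w))
        for w in cands
    ]
    table = pd.DataFrame({"window_size": cands, "threshold": thresholds})
    chosen, stable = stable_window_size(cands, thresholds, rel_tol)
    return chosen, table, stable


def stable_window_size(
    candidates: list[int], thresholds: list[float], rel_tol: float = 0.05
) -> tuple[int, bool]:
    """Smallest window whose threshold changes by < rel_tol (relative)
    against the next larger candidate; largest candidate with a False flag
    when no candidate stabilises."""
    if len(candidates) == 1:
        return candidates[0], True
    for i in range(len(candidates) - 1):
        if abs(thresholds[i] - thresholds[i + 1]) / thresholds[i + 1] < rel_tol:
            return candidates[i], True
    return candidates[-1], False


# ---------------------------------------------------------------------------
# interval calling


def call_qtl(
    stats: pd.DataFrame,
    threshold: float,
    cfg: ScanConfig,
) -> list[QTLInterval]:
    """QTL intervals from scan statistics.

    Maximal runs of consecutive panel SNPs with |signed F| >= threshold and a
    shared direction become intervals spanning [first SNP bp, last SNP bp];
    adjacent same-direction runs on a chromosome closer than
    ``cfg.merge_distance_bp`` are merged (transitively).  Opposite-direction
    runs are never merged, and an interleaved opposite-direction run blocks
    merging across it.
    """
    if stats.empty:
        raise ValueError("empty scan statistics")
    runs: list[QTLInterval] = []
    for chrom, grp in stats.groupby("chrom", sort=False):
        pos = grp["pos_bp"].to_numpy()
        f = grp["signed_F"].to_numpy()
        sig = np.abs(f) >= threshold
        sign = np.sign(f)
        start = None
        for i in range(len(grp) + 1):
            boundary = (
                i == len(grp)
                or not sig[i]
                or (start is not None and sign[i] != sign[i - 1])
            )
            if start is not None and boundary:
                seg = slice(start, i)
                peak = start + int(np.argmax(np.abs(f[seg])))
                runs.append(
                    QTLInterval(
                        chrom=str(chrom),
                        start_bp=int(pos[start]),
                        end_bp=int(pos[i - 1]),
                        direction="Col-0" if sign[start] > 0 else "Bs-2",
                        peak_f=float(f[peak]),
                        peak_pos_bp=int(pos[peak]),
                        n_significant_snps=i - start,
                    )
                )
                start = None
            if i < len(grp) and sig[i] and start is None:
                start = i
    return _merge_runs(runs, cfg.merge_distance_bp)


def _merge_runs(runs: list[QTLInterval], merge_bp: int) -> list[QTLInterval]:
    merged: list[QTLInterval] = []
    for run in runs:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and run.chrom == prev.chrom
            and run.direction == prev.direction
            and run.start_bp - prev.end_bp < merge_bp
        ):
            peak_from_run = abs(run.peak_f) > abs(prev.peak_f)
            merged[-1] = QTLInterval(
                chrom=prev.chrom,
                start_bp=prev.start_bp,
                end_bp=run.end_bp,
                direction=prev.direction,
                peak_f=run.peak_f if peak_from_run else prev.peak_f,
                peak_pos_bp=run.peak_pos_bp if peak_from_run else prev.peak_pos_bp,
                n_significant_snps=prev.n_significant_snps + run.n_significant_snps,
            )
        else:
            merged.append(run)
    return merged
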