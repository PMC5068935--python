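"""Forward simulation of the X-QTL mapping experiment.

Generates Bs-2 x Col-0 F3 recombinant populations (Haldane meiosis, one
selfing generation), environment-dependent germination times with additive
QTL effects, percentile time-cohorts of germinants, pooled allele
frequencies, and noisy dye-swap two-channel array observations.

Genotypes are coded as the per-SNP dosage of the Col-0 allele
(0 = Bs-2/Bs-2, 1 = heterozygote, 2 = Col-0/Col-0).

Germination-time model
----------------------
``time = baseline_t50 + sum_q effect_q(env) * (dosage_q - 1 + dominance_q *
I[dosage_q == 1]) + eps`` with ``eps`` a zero-mean, right-skewed gamma
deviate (shape ``noise_shape``, SD ``noise_sd_hours``).  Right skew reflects
the declining germination hazard of a stressed seed lot: the germination-
competent fraction germinates in a sharp early burst and the remainder
trickles out over a long tail, which is what produces both the prolonged
15-day germination window and the opposite early/late cohort allele biases
at a censored locus.  ``noise_shape=None`` selects Gaussian noise instead.
Individuals whose time exceeds ``censor_time_hours`` never germinate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMap

__all__ = [
    "QTLEffect",
    "EnvironmentSpec",
    "CohortSpec",
    "PoolObservation",
    "haldane_recombination",
    "simulate_f2_population",
    "simulate_f3_population",
    "assign_germination_times",
    "select_cohorts",
    "pool_allele_frequency",
    "combine_pools",
    "probe_affinities",
    "simulate_hybridization",
    "salt_environment",
    "no_salt_environment",
    "default_cohorts",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class QTLEffect:
    """A simulated germination-time locus.

    ``additive_effect_by_env`` maps environment name to hours added to the
    germination time per Col-0 allele (negative = Col-0 speeds germination).
    An environment absent from the map contributes nothing, which is how a
    cryptic (salt-only) locus is expressed.  ``dominance`` shifts the
    heterozygote by that fraction of the additive effect (-1..1).
    """

    chrom: str
    pos_bp: float
    additive_effect_by_env: dict[str, float]
    dominance: float = 0.0

    def effect(self, env_name: str) -> float:
        return self.additive_effect_by_env.get(env_name, 0.0)


@dataclass(frozen=True)
class EnvironmentSpec:
    """Germination environment: time-scale, dispersion and censoring."""

    name: str
    baseline_t50_hours: float
    noise_sd_hours: float
    censor_time_hours: float
    noise_shape: float | None = 0.7  # gamma shape; None -> Gaussian

    def __post_init__(self) -> None:
        if self.baseline_t50_hours <= 0:
            raise ValueError("baseline_t50_hours must be > 0")
        if self.noise_sd_hours < 0:
            raise ValueError("noise_sd_hours must be >= 0")
        if self.noise_shape is not None and self.noise_shape <= 0:
            raise ValueError("noise_shape must be > 0")


def salt_environment() -> EnvironmentSpec:
    """250 mM NaCl defaults.

    Censor time is the 23% germination quantile of the default mapping
    scenario, so ~23% of seeds germinate within the 15-day scoring window.
    """
    return EnvironmentSpec(
        name="salt_250mM",
        baseline_t50_hours=300.0,
        noise_sd_hours=100.0,
        censor_time_hours=232.0,
        noise_shape=0.7,
    )


def no_salt_environment() -> EnvironmentSpec:
    """Basal-media defaults: fast, near-complete germination."""
    return EnvironmentSpec(
        name="no_salt",
        baseline_t50_hours=40.0,
        noise_sd_hours=8.0,
        censor_time_hours=120.0,
        noise_shape=4.0,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Percentile bounds (fractions of *total seeds*) per cohort label.

    Bounds are half-open ``[lo, hi)`` on the rank/total fraction of
    germinants ordered by germination time.
    """

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        prev_hi = 0.0
        for label, (lo, hi) in self.bounds.items():
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"cohort {label!r}: bad bounds ({lo}, {hi})")
            if lo < prev_hi:
                raise ValueError(f"cohort {label!r} overlaps previous cohort")
            prev_hi = hi


def default_cohorts() -> CohortSpec:
    """Early ~0-5th, medium ~5th-20th, late ~20th-23rd percentile of seeds."""
    return CohortSpec(
        bounds={"early": (0.0, 0.05), "medium": (0.05, 0.20), "late": (0.20, 0.23)}
    )


@dataclass
class PoolObservation:
    """A DNA pool: true per-SNP Col-0 allele frequencies and/or the noisy
    two-channel array intensities measured from it.

    ``intensities`` is a long DataFrame with columns ``snp_id, replicate,
    dye, signal_col, signal_bs`` where ``dye`` is ``forward`` or ``swapped``
    (dye-swap pairing: every replicate carries both orientations).
    """

    pool_id: str
    n_individuals: int
    cohort: str | None = None
    freq: np.ndarray | None = None
    intensities: pd.DataFrame | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# meiosis


def haldane_recombination(d_cm):
    """Haldane map function: recombination fraction for a distance in cM.

    r = (1 - exp(-2 d / 100)) / 2, assuming no crossover interference.
    """
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return r if r.ndim else float(r)


def _meiosis_phases(rec: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, S) boolean phase matrix for n independent meioses.

    ``rec`` holds the S-1 inter-marker recombination fractions.  Under no
    interference, recombination events in disjoint intervals are independent,
    so a gamete is a start phase followed by independent Bernoulli switches.
    """
    s = rec.size + 1
    phases = np.empty((n, s), dtype=bool)
    phases[:, 0] = rng.random(n) < 0.5
    phases[:, 1:] = rng.random((n, s - 1)) < rec
    return np.bitwise_xor.accumulate(phases, axis=1)


def _f1_gametes(rec: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    # F1 is Col/Bs heterozygous everywhere: the gamete is the phase itself
    # (True = Col-0 allele).
    return _meiosis_phases(rec, n, rng)


def _per_chrom_rec(gmap: GeneticMap) -> dict[str, np.ndarray]:
    out = {}
    for chrom, sl in gmap.chrom_slices().items():
        cm = gmap.snps["pos_cM"].to_numpy()[sl]
        out[chrom] = haldane_recombination(np.diff(cm))
    return out


def simulate_f2_population(
    gmap: GeneticMap, n: int, rng: np.random.Generator | int
) -> np.ndarray:
    """(n, n_snps) int8 Col-0 dosages of F2 individuals (one meiosis pair)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = np.empty((n, gmap.n_snps), dtype=np.int8)
    if n == 0:
        return out
    for chrom, sl in gmap.chrom_slices().items():
        rec = haldane_recombination(np.diff(gmap.snps["pos_cM"].to_numpy()[sl]))
        g1 = _f1_gametes(rec, n, rng)
        g2 = _f1_gametes(rec, n, rng)
        out[:, sl] = g1.astype(np.int8) + g2.astype(np.int8)
    return out


def simulate_f3_population(
    gmap: GeneticMap, n: int, rng: np.random.Generator | int
) -> np.ndarray:
    """(n, n_snps) int8 Col-0 dosages of F3 individuals.

    Each individual: two F1 gametes form an F2, which is selfed once (two
    independent meioses over the F2's haplotypes).  No selection between
    generations.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    out = np.empty((n, gmap.n_snps), dtype=np.int8)
    if n == 0:
        return out
    for chrom, sl in gmap.chrom_slices().items():
        rec = haldane_recombination(np.diff(gmap.snps["pos_cM"].to_numpy()[sl]))
        h1 = _f1_gametes(rec, n, rng)  # F2 haplotype 1
        h2 = _f1_gametes(rec, n, rng)  # F2 haplotype 2
        pa = _meiosis_phases(rec, n, rng)
        pb = _meiosis_phases(rec, n, rng)
        gam_a = np.where(pa, h2, h1)
        gam_b = np.where(pb, h2, h1)
        out[:, sl] = gam_a.astype(np.int8) + gam_b.astype(np.int8)
    return out


# ---------------------------------------------------------------------------
# phenotype


def assign_germination_times(
    dosages: np.ndarray,
    qtls: list[QTLEffect],
    env: EnvironmentSpec,
    gmap: GeneticMap,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Germination time in hours per individual; NaN = censored (never
    germinates within the scoring window)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = dosages.shape[0]
    times = np.full(n, env.baseline_t50_hours, dtype=float)
    for q in qtls:
        idx = gmap.snp_index(q.chrom, q.pos_bp)
        d = dosages[:, idx].astype(float)
        eff = q.effect(env.name)
        times += eff * (d - 1.0 + q.dominance * (d == 1))
    if env.noise_sd_hours > 0:
        if env.noise_shape is None:
            times += rng.normal(0.0, env.noise_sd_hours, size=n)
        else:
            k = env.noise_shape
            theta = env.noise_sd_hours / np.sqrt(k)
            times += rng.gamma(k, theta, size=n) - k * theta
    times[times > env.censor_time_hours] = np.nan
    return times


def select_cohorts(
    times: np.ndarray, spec: CohortSpec, total_seeds: int | None = None
) -> dict[str, np.ndarray]:
    """Assign germinants to percentile cohorts of *total seeds*.

    Germinants are ranked by ascending time (ties broken by individual
    index); individual at rank k joins the cohort whose bounds contain
    k / total_seeds.  Censored individuals (NaN times) never join a cohort.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    total = total_seeds if total_seeds is not None else times.size
    germinated = np.flatnonzero(~np.isnan(times))
    if germinated.size == 0:
        warnings.warn("all individuals censored; all cohorts empty")
        return {label: np.empty(0, dtype=int) for label in spec.bounds}
    order = germinated[np.lexsort((germinated, times[germinated]))]
    frac = np.arange(order.size) / total
    return {
        label: order[(frac >= lo) & (frac < hi)]
        for label, (lo, hi) in spec.bounds.items()
    }


# ---------------------------------------------------------------------------
# pooling and hybridization


def pool_allele_frequency(dosages: np.ndarray) -> np.ndarray:
    """Per-SNP Col-0 allele frequency of a pool of diploid genotypes."""
    if dosages.shape[0] == 0:
        raise ValueError("empty pool")
    return dosages.mean(axis=0) / 2.0


def combine_pools(pools: list[PoolObservation]) -> PoolObservation:
    """Mix pools proportionally to their number of individuals.

    Mirrors building the all-germinant pool from the three time cohorts.
    """
    if not pools:
        raise ValueError("no pools to combine")
    sizes = {p.freq.shape for p in pools if p.freq is not None}
    if len(sizes) != 1 or any(p.freq is None for p in pools):
        raise ValueError("pools must share an identical SNP panel")
    n = np.array([p.n_individuals for p in pools], dtype=float)
    freqs = np.stack([p.freq for p in pools])
    return PoolObservation(
        pool_id="+".join(p.pool_id for p in pools),
        n_individuals=int(n.sum()),
        cohort="combined",
        freq=(n[:, None] * freqs).sum(axis=0) / n.sum(),
    )


def probe_affinities(
    n_snps: int, rng: np.random.Generator | int, sd_log: float = 0.3
) -> tuple[np.ndarray, np.ndarray]:
    """Lognormal probe-specific affinities for the two allele probes."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    a_col = np.exp(rng.normal(0.0, sd_log, size=n_snps))
    a_bs = np.exp(rng.normal(0.0, sd_log, size=n_snps))
    return a_col, a_bs


# multiplicative freq floor: a pool fixed for one allele still yields a
# faint cross-hybridization signal on the other probe
_FREQ_FLOOR = 1e-4


def simulate_hybridization(
    freqs: np.ndarray,
    affinity_col: np.ndarray | float,
    affinity_bs: np.ndarray | float,
    noise_cv: float,
    n_replicates: int,
    rng: np.random.Generator | int,
    dye_gains: tuple[float, float] = (1.0, 1.3),
    pool_id: str = "pool",
    snp_ids: np.ndarray | None = None,
    replicate_offset: int = 0,
) -> PoolObservation:
    """Dye-swap two-channel intensities for a pool of known allele freqs.

    Per replicate and dye orientation::

        signal_col = affinity_col * freq       * gain_col * (1 + eps)
        signal_bs  = affinity_bs  * (1 - freq) * gain_bs  * (1 + eps')

    with multiplicative Gaussian noise of CV ``noise_cv``; the two dye gains
    swap between the forward and swapped orientations, so their product over
    a dye-swap pair is orientation-free (the classic dye-swap cancellation).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("freqs must lie in [0, 1]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    f = np.clip(freqs, _FREQ_FLOOR, 1.0 - _FREQ_FLOOR)
    s = f.size
    if snp_ids is None:
        snp_ids = np.array([f"snp{i:05d}" for i in range(s)])
    g1, g2 = dye_gains
    frames = []
    for rep in range(n_replicates):
        for dye, (gc, gb) in (("forward", (g1, g2)), ("swapped", (g2, g1))):
            eps_c = 1.0 + rng.normal(0.0, noise_cv, size=s) if noise_cv else 1.0
            eps_b = 1.0 + rng.normal(0.0, noise_cv, size=s) if noise_cv else 1.0
            frames.append(
                pd.DataFrame(
                    {
                        "snp_id": snp_ids,
                        "replicate": rep + replicate_offset,
                        "dye": dye,
                        "signal_col": affinity_col * f * gc * eps_c,
                        "signal_bs": affinity_bs * (1.0 - f) * gb * eps_b,
                    }
                )
            )
    return PoolObservation(
        pool_id=pool_id,
        n_individuals=0,
        freq=freqs,
        intensities=pd.concat(frames, ignore_index=True),
    )
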