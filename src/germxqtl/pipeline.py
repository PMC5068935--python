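"""End-to-end experiment orchestration.

Wires the forward simulator to the scan: replicate F3 populations per
condition, time-cohort selection under salt, pooling, dye-swap
hybridization against the shared random-F2 reference, allele-frequency
estimation, the windowed scan with permutation threshold, and interval
calling.  Also provides the null-calibration and QTL-recovery harnesses
used to validate the pipeline, and a founder germination-kinetics
generator for the curve-fitting workflow.

Each replicate is an independent selection experiment (its own F3
population), so replicate pools are exchangeable under the null — the
requirement behind the permutation threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genmap import GeneticMap, default_map
from .kinetics import build_cumulative_curve, fit_4phf, t50_from_fit
from .scan import (
    QTLInterval,
    ScanConfig,
    call_qtl,
    estimate_allele_freq,
    freq_matrix,
    permutation_threshold,
    window_scan,
)
from .simulate import (
    CohortSpec,
    EnvironmentSpec,
    PoolObservation,
    QTLEffect,
    assign_germination_times,
    combine_pools,
    default_cohorts,
    no_salt_environment,
    pool_allele_frequency,
    probe_affinities,
    salt_environment,
    select_cohorts,
    simulate_f2_population,
    simulate_f3_population,
    simulate_hybridization,
)

__all__ = [
    "ArrayConfig",
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "scan_condition",
    "end_to_end_recovery",
    "RecoveryReport",
    "founder_kinetics",
]

logger = logging.getLogger(__name__)

# condition labels produced by run_experiment
SALT_COHORT_LABELS = ("early", "medium", "late")


@dataclass(frozen=True)
class ArrayConfig:
    """Two-channel array noise model: multiplicative intensity CV,
    lognormal probe-affinity spread, and the two dye gains."""

    noise_cv: float = 0.05
    affinity_sd_log: float = 0.3
    dye_gains: tuple[float, float] = (1.0, 1.3)


@dataclass(frozen=True)
class ExperimentConfig:
    """Desk-scale defaults for the simulated selection experiment."""

    n_per_pool: int = 2000
    n_replicate_pools: int = 10
    n_reference: int = 2000
    # Control pools are subsampled to this many germinants (default: the
    # expected early-cohort size).  Matching the control pool size to the
    # selected-cohort size keeps the pool-composition variance equal across
    # replicate pools, which is what makes replicate labels exchangeable
    # under the null and the permutation threshold calibrated at desk scale.
    control_pool_size: int | None = None
    qtls: tuple[QTLEffect, ...] = ()
    salt_env: EnvironmentSpec = field(default_factory=salt_environment)
    nosalt_env: EnvironmentSpec = field(default_factory=no_salt_environment)
    cohorts: CohortSpec = field(default_factory=default_cohorts)
    array: ArrayConfig = field(default_factory=ArrayConfig)
    conditions: tuple[str, ...] = ("early", "late", "all", "control", "nosalt_early")


@dataclass
class ExperimentResult:
    gmap: GeneticMap
    config: ExperimentConfig
    estimates: dict[str, np.ndarray]  # condition -> (R, S) estimated freqs
    true_freqs: dict[str, np.ndarray]  # condition -> (R, S) pool truth
    pool_sizes: dict[str, list[int]]
    germinated_fraction_salt: list[float]
    cohort_sizes: dict[str, list[int]]


def _hybridize_and_estimate(
    freq: np.ndarray,
    ref_freq: np.ndarray,
    affinities: tuple[np.ndarray, np.ndarray],
    arr: ArrayConfig,
    gmap: GeneticMap,
    rng: np.random.Generator,
    pool_id: str,
) -> np.ndarray:
    """One dye-swap array: pool channel + reference channel -> (S,) estimate."""
    a_col, a_bs = affinities
    snp_ids = gmap.snps["id"].to_numpy()
    obs = simulate_hybridization(
        freq, a_col, a_bs, arr.noise_cv, 1, rng,
        dye_gains=arr.dye_gains, pool_id=pool_id, snp_ids=snp_ids,
    )
    ref = simulate_hybridization(
        ref_freq, a_col, a_bs, arr.noise_cv, 1, rng,
        dye_gains=arr.dye_gains, pool_id=f"{pool_id}_ref", snp_ids=snp_ids,
    )
    est = estimate_allele_freq(obs, ref)
    return freq_matrix(est, gmap)[0]


def run_experiment(
    config: ExperimentConfig, gmap: GeneticMap | None = None, seed: int = 0
) -> ExperimentResult:
    """Simulate the full selection + pooled-genotyping experiment.

    For each replicate: an F3 population germinated under salt yields the
    early/medium/late percentile cohorts (and their proportional mixture,
    ``all``); an independent F3 population germinated on basal media yields
    the unselected ``control`` pool and, optionally, a ``nosalt_early``
    cohort.  Every pool is hybridized (dye swap) against a single shared
    random-F2 reference pool.
    """
    rng = np.random.default_rng(seed)
    if gmap is None:
        gmap = default_map()
    qtls = list(config.qtls)
    arr = config.array
    affinities = probe_affinities(gmap.n_snps, rng, arr.affinity_sd_log)
    ref_pool = simulate_f2_population(gmap, config.n_reference, rng)
    ref_freq = pool_allele_frequency(ref_pool)

    wanted = set(config.conditions)
    estimates: dict[str, list[np.ndarray]] = {c: [] for c in config.conditions}
    true_freqs: dict[str, list[np.ndarray]] = {c: [] for c in config.conditions}
    pool_sizes: dict[str, list[int]] = {c: [] for c in config.conditions}
    germ_frac: list[float] = []
    cohort_sizes: dict[str, list[int]] = {c: [] for c in SALT_COHORT_LABELS}

    need_salt = wanted & ({"all"} | set(SALT_COHORT_LABELS))
    need_nosalt = wanted & {"control", "nosalt_early"}
    for rep in range(config.n_replicate_pools):
        rep_pools: dict[str, PoolObservation] = {}
        if need_salt:
            pop = simulate_f3_population(gmap, config.n_per_pool, rng)
            times = assign_germination_times(pop, qtls, config.salt_env, gmap, rng)
            germ_frac.append(float(np.mean(~np.isnan(times))))
            cohorts = select_cohorts(times, config.cohorts)
            for label in SALT_COHORT_LABELS:
                ids = cohorts[label]
                cohort_sizes[label].append(len(ids))
                if label in wanted or "all" in wanted:
                    rep_pools[label] = PoolObservation(
                        pool_id=f"salt_{label}_r{rep}",
                        n_individuals=len(ids),
                        cohort=label,
                        freq=pool_allele_frequency(pop[ids]),
                    )
            if "all" in wanted:
                rep_pools["all"] = combine_pools(
                    [rep_pools[c] for c in SALT_COHORT_LABELS]
                )
        if need_nosalt:
            pop = simulate_f3_population(gmap, config.n_per_pool, rng)
            times = assign_germination_times(pop, qtls, config.nosalt_env, gmap, rng)
            germinants = np.flatnonzero(~np.isnan(times))
            if "control" in wanted:
                size = config.control_pool_size
                if size is None:
                    lo, hi = config.cohorts.bounds.get("early", (0.0, 0.05))
                    size = max(2, round((hi - lo) * config.n_per_pool))
                chosen = (
                    rng.choice(germinants, size=size, replace=False)
                    if size < len(germinants)
                    else germinants
                )
                rep_pools["control"] = PoolObservation(
                    pool_id=f"control_r{rep}",
                    n_individuals=len(chosen),
                    freq=pool_allele_frequency(pop[chosen]),
                )
            if "nosalt_early" in wanted:
                ids = select_cohorts(times, config.cohorts)["early"]
                rep_pools["nosalt_early"] = PoolObservation(
                    pool_id=f"nosalt_early_r{rep}",
                    n_individuals=len(ids),
                    cohort="early",
                    freq=pool_allele_frequency(pop[ids]),
                )
        for cond in config.conditions:
            pool = rep_pools[cond]
            est = _hybridize_and_estimate(
                pool.freq, ref_freq, affinities, arr, gmap, rng, pool.pool_id
            )
            estimates[cond].append(est)
            true_freqs[cond].append(pool.freq)
            pool_sizes[cond].append(pool.n_individuals)

    return ExperimentResult(
        gmap=gmap,
        config=config,
        estimates={c: np.vstack(v) for c, v in estimates.items()},
        true_freqs={c: np.vstack(v) for c, v in true_freqs.items()},
        pool_sizes=pool_sizes,
        germinated_fraction_salt=germ_frac,
        cohort_sizes=cohort_sizes,
    )


def scan_condition(
    result: ExperimentResult,
    selected: str,
    cfg: ScanConfig,
    control: str = "control",
) -> tuple[pd.DataFrame, float, list[QTLInterval]]:
    """Scan one selected condition against a control condition."""
    sel = result.estimates[selected]
    ctrl = result.estimates[control]
    stats = window_scan(sel, ctrl, result.gmap, cfg)
    threshold = permutation_threshold(sel, ctrl, result.gmap, cfg)
    intervals = call_qtl(stats, threshold, cfg)
    return stats, threshold, intervals


@dataclass
class RecoveryReport:
    """Per true QTL: whether a called interval covers it, and how far the
    nearest peak landed."""

    intervals: dict[str, list[QTLInterval]]
    thresholds: dict[str, float]
    covered: dict[str, list[bool]]  # condition -> per true QTL
    localization_error_bp: dict[str, list[float]]
    germinated_fraction_salt: float


def end_to_end_recovery(
    config: ExperimentConfig,
    cfg: ScanConfig,
    gmap: GeneticMap | None = None,
    seed: int = 0,
    scans: tuple[str, ...] = ("early",),
) -> RecoveryReport:
    """simulate -> pool -> hybridize -> estimate -> scan -> threshold -> call,
    then compare called intervals with the simulated QTL positions."""
    result = run_experiment(config, gmap=gmap, seed=seed)
    intervals: dict[str, list[QTLInterval]] = {}
    thresholds: dict[str, float] = {}
    covered: dict[str, list[bool]] = {}
    loc_err: dict[str, list[float]] = {}
    for cond in scans:
        _, thr, ivs = scan_condition(result, cond, replace(cfg, seed=cfg.seed + 1))
        intervals[cond] = ivs
        thresholds[cond] = thr
        cov, err = [], []
        for q in config.qtls:
            hits = [
                iv for iv in ivs
                if iv.chrom == q.chrom and iv.start_bp <= q.pos_bp <= iv.end_bp
            ]
            cov.append(bool(hits))
            same_chrom = [iv for iv in ivs if iv.chrom == q.chrom]
            err.append(
                min((abs(iv.peak_pos_bp - q.pos_bp) for iv in same_chrom),
                    default=float("nan"))
            )
        covered[cond] = cov
        loc_err[cond] = err
    frac = float(np.mean(result.germinated_fraction_salt)) if (
        result.germinated_fraction_salt
    ) else float("nan")
    return RecoveryReport(
        intervals=intervals,
        thresholds=thresholds,
        covered=covered,
        localization_error_bp=loc_err,
        germinated_fraction_salt=frac,
    )


def recovery_table(report: RecoveryReport, config: ExperimentConfig) -> pd.DataFrame:
    """Per true QTL x scanned condition: covered flag and peak distance."""
    rows = []
    for cond, cov in report.covered.items():
        for q, c, err in zip(config.qtls, cov, report.localization_error_bp[cond]):
            rows.append(
                dict(condition=cond, chrom=q.chrom, pos_bp=int(q.pos_bp),
                     covered=bool(c), peak_distance_bp=err)
            )
    return pd.DataFrame(
        rows, columns=["condition", "chrom", "pos_bp", "covered", "peak_distance_bp"]
    )


# ---------------------------------------------------------------------------
# founder kinetics


def founder_kinetics(
    seed: int = 0,
    n_seeds: int = 2000,
    n_replicates: int = 3,
    t50_mode: str = "relative",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulated founder-accession germination time courses.

    Bs-2 and Col-0 seed lots scored in triplicate on basal and 250 mM NaCl
    media (6-hourly for 5 d without salt, daily for 15 d with salt).
    Parental germination speeds differ by ~3.4 h without salt and ~54 h
    (2.25 d) under salt — the published founder contrast.  Returns the
    per-interval count table and a per-replicate t50 table (4PHF fits).
    """
    rng = np.random.default_rng(seed)
    envs = {"no_salt": no_salt_environment(), "salt_250mM": salt_environment()}
    # half the parental difference, added/subtracted around the env baseline
    offsets = {
        ("Bs-2", "no_salt"): +1.7, ("Col-0", "no_salt"): -1.7,
        ("Bs-2", "salt_250mM"): +27.0, ("Col-0", "salt_250mM"): -27.0,
    }
    schedules = {
        "no_salt": np.arange(6.0, 126.0, 6.0),
        "salt_250mM": np.arange(24.0, 384.0, 24.0),
    }
    counts_rows = []
    fit_rows = []
    for env_name, env in envs.items():
        grid = schedules[env_name]
        for accession in ("Bs-2", "Col-0"):
            base = env.baseline_t50_hours + offsets[(accession, env_name)]
            # founder plates are scored to the end of the schedule (15 d with
            # salt), unlike the selection experiment's harvest cutoff
            env_a = replace(
                env, baseline_t50_hours=base, censor_time_hours=float(grid[-1])
            )
            for rep in range(n_replicates):
                times = assign_germination_times(
                    np.zeros((n_seeds, 1), dtype=np.int8) + 1, [], env_a,
                    _TRIVIAL_MAP, rng,
                )
                germ = times[~np.isnan(times)]
                edges = np.concatenate([[0.0], grid])
                interval_counts, _ = np.histogram(germ, bins=edges)
                for t, k in zip(grid, interval_counts):
                    counts_rows.append(
                        dict(time_hours=t, count=int(k), replicate=rep,
                             accession=accession, environment=env_name,
                             total_seeds=n_seeds)
                    )
                rec = build_cumulative_curve(
                    grid, interval_counts, n_seeds, accession, env_name, rep
                )
                fit = fit_4phf(rec)
                fit_rows.append(
                    dict(accession=accession, environment=env_name, replicate=rep,
                         y0=fit.y0, a=fit.a, b=fit.b, c=fit.c,
                         converged=fit.converged,
                         t50=t50_from_fit(fit, t50_mode) if fit.converged else np.nan)
                )
    return pd.DataFrame(counts_rows), pd.DataFrame(fit_rows)


# minimal one-SNP map for phenotype-only simulations
_TRIVIAL_MAP = GeneticMap(
    chromosomes=[("Chr1", 1000, 0.004)],
    snps=pd.DataFrame(
        {"chrom": ["Chr1"], "pos_bp": [500], "pos_cM": [0.002], "id": ["snp0"]}
    ),
)
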