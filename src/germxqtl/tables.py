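"""Published founder stage-timing summary statistics.

Cumulative hours for Bs-2 and Col-0 seed lots to reach the four germination
stages (testa rupture, radicle protrusion, cotyledon greening, cotyledon
expansion) on basal and 250 mM NaCl media: per-accession mean and SD over
triplicate plates (~2000 seeds each).  These printed summaries are the
input to the stage-schedule t-tests; cotyledon greening was too transient
to score at 6-h intervals without salt, hence its absence there.
"""

from __future__ import annotations

import pandas as pd

from .kinetics import StageTiming

__all__ = ["founder_stage_timings", "stage_timing_pairs"]

_ROWS = [
    # environment, stage, accession, mean_hours, sd_hours, n
    ("no_salt", "testa_rupture", "Bs-2", 11.789, 0.227, 3),
    ("no_salt", "testa_rupture", "Col-0", 12.043, 0.790, 3),
    ("no_salt", "radicle_protrusion", "Bs-2", 25.836, 0.500, 3),
    ("no_salt", "radicle_protrusion", "Col-0", 23.116, 0.250, 3),
    ("no_salt", "cotyledon_expansion", "Bs-2", 38.761, 0.348, 3),
    ("no_salt", "cotyledon_expansion", "Col-0", 37.419, 0.152, 3),
    ("salt_250mM", "testa_rupture", "Bs-2", 66.133, 1.620, 3),
    ("salt_250mM", "testa_rupture", "Col-0", 55.907, 0.235, 3),
    ("salt_250mM", "radicle_protrusion", "Bs-2", 124.202, 1.687, 3),
    ("salt_250mM", "radicle_protrusion", "Col-0", 106.282, 6.209, 3),
    ("salt_250mM", "cotyledon_greening", "Bs-2", 190.125, 1.957, 3),
    ("salt_250mM", "cotyledon_greening", "Col-0", 171.707, 8.846, 3),
    ("salt_250mM", "cotyledon_expansion", "Bs-2", 214.168, 0.590, 3),
    ("salt_250mM", "cotyledon_expansion", "Col-0", 191.542, 5.125, 3),
]


def founder_stage_timings() -> pd.DataFrame:
    return pd.DataFrame(
        _ROWS,
        columns=["environment", "stage", "accession", "mean_hours", "sd_hours", "n"],
    )


def stage_timing_pairs() -> list[tuple[StageTiming, StageTiming]]:
    """(Bs-2, Col-0) StageTiming pairs per environment and stage."""
    df = founder_stage_timings()
    pairs = []
    for (env, stage), grp in df.groupby(["environment", "stage"], sort=False):
        by_acc = {
            r.accession: StageTiming(
                stage=stage, accession=r.accession, environment=env,
                mean_hours=r.mean_hours, sd_hours=r.sd_hours, n=r.n,
            )
            for r in grp.itertuples()
        }
        pairs.append((by_acc["Bs-2"], by_acc["Col-0"]))
    return pairs
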