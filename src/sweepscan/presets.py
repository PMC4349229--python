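"""Canned desk-scale scenarios used by the validation suite and the
acceptance report.

All population sizes here are rescaled to forward-simulable magnitudes
(N <= 500 diploids) with selection, mutation and recombination boosted
correspondingly; they are validation instruments, not biological estimates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from sweepscan.ihs import ihs_scan, standardize
from sweepscan.pbs import window_scan
from sweepscan.simulate import (
    DemographyModel,
    SweepSpec,
    simulate_forward_wf,
    simulate_neutral_coalescent,
)

SAMPLES = {"breed1": 14, "breed2": 16, "outgroup": 10}

#: demography for the complete-sweep PBS recovery scenario: shallow history,
#: mild bottlenecks (low drift noise), recombination strong enough to confine
#: the sweep footprint to a fraction of the region
COMPLETE_SWEEP_MODEL = DemographyModel(
    N_anc=150, T_dom=80, T_split=40,
    N_bottleneck1=100, D_bottleneck1=10,
    N_bottleneck2=130, D_bottleneck2=2,
    N_breed=150, m=0.0, mu=8e-7, r=3e-6,
)
COMPLETE_SWEEP_REGION = 300_000
COMPLETE_SWEEP_POSITION = 150_000
#: the scan's windows span ~30 kb, so "the sweep window wins" is asserted at
#: footprint resolution: the top window must overlap position +/- this margin
COMPLETE_SWEEP_TOLERANCE = 25_000


def complete_sweep_replicate(seed: int):
    """One complete-sweep replicate: returns (haps, truth). 2Ns = 240."""
    sweep = SweepSpec(
        "breed1", COMPLETE_SWEEP_POSITION, s=0.8, onset_generation=36,
        mode="complete",
    )
    return simulate_forward_wf(
        COMPLETE_SWEEP_MODEL, [sweep], COMPLETE_SWEEP_REGION, SAMPLES,
        seed=seed,
    )


def complete_sweep_top_window(seed: int) -> dict:
    """Simulate, scan, and report whether the genome-wide maximum PBS
    window in the target breed lies at the sweep (footprint tolerance),
    plus whether the sweep locus ranks top-1% in the unselected breed."""
    haps, truth = complete_sweep_replicate(seed)
    scan = window_scan(
        haps, "breed1", "breed2", "outgroup", window_snps=100, step_snps=25
    )
    ok = scan[scan["defined"]]
    top = ok.loc[ok["pbs_breed1"].idxmax()]
    pos = COMPLETE_SWEEP_POSITION
    tol = COMPLETE_SWEEP_TOLERANCE
    at_sweep = ok[(ok["start_pos"] <= pos) & (ok["stop_pos"] >= pos)]
    q99_other = ok["pbs_breed2"].quantile(0.99)
    return {
        "target_hit": bool(
            top["start_pos"] <= pos + tol and top["stop_pos"] >= pos - tol
        ),
        "other_breed_top1pct": bool(
            (at_sweep["pbs_breed2"] > q99_other).any()
        ),
        "final_frequency": truth.sweeps[0]["final_frequency"],
    }


#: demography for the partial-sweep iHS recovery scenario: large breeds and
#: negligible breed bottlenecks keep recent within-breed coalescence (which
#: inflates the ancestral iHH under the 0.05 EHH cutoff) rare; the sweep is
#: young and strong so the derived haplotype dwarfs the background
PARTIAL_SWEEP_MODEL = DemographyModel(
    N_anc=400, T_dom=50, T_split=25,
    N_bottleneck1=400, D_bottleneck1=5,
    N_bottleneck2=400, D_bottleneck2=2,
    N_breed=500, m=0.0, mu=6e-7, r=1.6e-5,
)
PARTIAL_SWEEP_REGION = 300_000
PARTIAL_SWEEP_POSITION = 150_000
PARTIAL_SWEEP_SAMPLES = {"breed1": 40, "breed2": 16, "outgroup": 10}


def partial_sweep_replicate(seed: int):
    """One partial-sweep replicate conditioned on sampling frequency
    0.4-0.6. 2Ns = 3,500 (selection stops at the target frequency)."""
    sweep = SweepSpec(
        "breed1", PARTIAL_SWEEP_POSITION, s=3.5, onset_generation=6,
        mode="partial", target_frequency=0.5,
    )
    return simulate_forward_wf(
        PARTIAL_SWEEP_MODEL, [sweep], PARTIAL_SWEEP_REGION,
        PARTIAL_SWEEP_SAMPLES, seed=seed, freq_tolerance=0.1,
    )


def partial_sweep_rank(seed: int, check_other: bool = True) -> dict:
    """Simulate one partial-sweep replicate and report the |iHS| rank of
    the core nearest the selected site: whether it reaches the top 1%
    (``target_hit``) and top 10% (``target_top10``) in the target breed,
    and the top 1% in the unselected breed (``other_hit``)."""
    haps, truth = partial_sweep_replicate(seed)
    out: dict = {"final_frequency": truth.sweeps[0]["final_frequency"]}
    for breed, key in (("breed1", "target_hit"), ("breed2", "other_hit")):
        if breed == "breed2" and not check_other:
            continue
        table = standardize(
            ihs_scan(haps, breed, "outgroup"), keep_truncated=True
        ).dropna(subset=["abs_ihs"])
        if table.empty:
            out[key] = False
            continue
        nearest = (table["pos"] - PARTIAL_SWEEP_POSITION).abs().idxmin()
        score = table.loc[nearest, "abs_ihs"]
        out[key] = bool(score >= table["abs_ihs"].quantile(0.99))
        if breed == "breed1":
            out["target_top10"] = bool(
                score >= table["abs_ihs"].quantile(0.90)
            )
    return out


#: neutral three-population demography used for the iHS standardization
#: check: enough per-replicate diversity for a few hundred eligible cores
NEUTRAL_IHS_MODEL = DemographyModel(
    N_anc=300, T_dom=80, T_split=40,
    N_bottleneck1=250, D_bottleneck1=8,
    N_bottleneck2=250, D_bottleneck2=2,
    N_breed=350, m=0.0, mu=6e-7, r=8e-6,
)


def neutral_ihs_cores(
    n_cores: int, seed: int, region_length: int = 300_000
) -> pd.DataFrame:
    """Pool raw iHS records from neutral forward replicates (one simulated
    'chromosome' each) until at least ``n_cores`` eligible cores exist."""
    rng = np.random.default_rng(seed)
    tables = []
    total = 0
    chrom = 0
    while total < n_cores:
        rep_seed = int(rng.integers(2**31 - 1))
        haps, _ = simulate_forward_wf(
            NEUTRAL_IHS_MODEL, [], region_length,
            {"breed1": 25, "breed2": 16, "outgroup": 10}, seed=rep_seed,
        )
        raw = ihs_scan(haps, "breed1", "outgroup")
        raw["chrom"] = str(chrom)
        chrom += 1
        tables.append(raw)
        total += len(raw)
    return pd.concat(tables, ignore_index=True)


#: H-statistic comparison: the neutral no-recombination coalescent under a
#: two-bottleneck demography versus a forward scenario with severe breed
#: bottlenecks ending near the present plus strong between-breed admixture
H_NEUTRAL_MODEL = DemographyModel(
    N_anc=1000, T_dom=500, T_split=120,
    N_bottleneck1=150, D_bottleneck1=80,
    N_bottleneck2=100, D_bottleneck2=40,
    N_breed=400, m=0.001, mu=1e-6, r=0.0,
)
H_BOTTLENECK_ADMIX_MODEL = DemographyModel(
    N_anc=300, T_dom=80, T_split=45,
    N_bottleneck1=20, D_bottleneck1=15,
    N_bottleneck2=5, D_bottleneck2=40,
    N_breed=50, m=0.08, mu=8e-7, r=1e-8,
)


def h_values_neutral(n_replicates: int, seed: int, theta: float = 40.0):
    from sweepscan.core import h_windows

    values: list[int] = []
    reps = simulate_neutral_coalescent(
        H_NEUTRAL_MODEL, SAMPLES, theta=theta, n_replicates=n_replicates,
        seed=seed,
    )
    for r in reps:
        for pop in ("breed1", "breed2"):
            try:
                values.extend(h_windows(r, pop, 30)["H"].tolist())
            except ValueError:
                pass
    return values


def h_values_bottleneck_admixture(
    n_replicates: int, seed: int, region_length: int = 400_000
):
    from sweepscan.core import h_windows

    rng = np.random.default_rng(seed)
    values: list[int] = []
    for _ in range(n_replicates):
        haps, _ = simulate_forward_wf(
            H_BOTTLENECK_ADMIX_MODEL, [], region_length, SAMPLES,
            seed=int(rng.integers(2**31 - 1)),
        )
        for pop in ("breed1", "breed2"):
            try:
                values.extend(h_windows(haps, pop, 30)["H"].tolist())
            except ValueError:
                pass
    return values
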