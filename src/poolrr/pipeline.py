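"""High-level workflows: simulate pools, calibrate the correction model,
and estimate adjusted pool genetic maps and windowed recombination rates.

These functions wire the lower-level modules together in the order the
method runs (simulate -> pool -> K factors -> raw map -> calibration ->
adjusted map -> windows) and are what the command-line interface and the
reproduction script call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import adjust, pgm, popsim, windows


def simulate_pooled_af(
    tmap: pd.DataFrame,
    n_genotypes: int,
    depth: int,
    rng: np.random.Generator,
    pop_type: str = "F2",
    selfing_generations: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One pooled sample: subsample markers, simulate, pool.

    Returns (allele-frequency track, true-map subset actually genotyped).
    """
    sub = popsim.subsample_markers(tmap, depth, rng)
    if pop_type == "F2":
        g = popsim.simulate_f2_population(sub, n_genotypes, rng)
    elif pop_type == "RIL":
        g = popsim.simulate_ril(sub, n_genotypes, selfing_generations, rng)
    else:
        raise ValueError(f"unknown population type {pop_type!r}")
    return popsim.pool_allele_frequency(g), sub


@dataclass
class EstimateResult:
    """Everything `estimate` produces for one sample."""

    pgm_map: pd.DataFrame  # raw cumulative K map
    npgm_map: pd.DataFrame  # calibrated map (cM)
    pairs: pd.DataFrame  # K / K' per adjacent pair
    windows: pd.DataFrame  # windowed RR from the nPGM
    adj_start: float
    n_snps: int
    filter_report: pgm.FilterReport


def estimate_npgm(
    af_track: pd.DataFrame,
    n_genotypes: int,
    model: adjust.AdjustmentModel | None = None,
    pop_type: str = "F2",
    allow_ril_heuristic: bool = False,
    max_missing: float = 0.10,
    min_dist_bp: int = 2,
    window_mb: float = 50.0,
    slide_frac: float = 0.5,
    min_pairs: int = 2,
    window_stat: str = "mean",
) -> EstimateResult:
    """Full pool-map estimation from an allele-frequency track.

    Filters markers, computes K factors, cumulates the raw PGM, predicts the
    depth/size correction from the (supplied or shipped) non-linear model,
    rescales to the nPGM and summarizes windowed recombination rates.
    Windows average the interval rates by default: the pool map's
    per-interval rates are zero-inflated (an interval with no observed
    allele-frequency change contributes K = 0), so the window median can
    collapse to zero in sparse-recombination regimes where the mean stays
    informative.
    """
    if model is None:
        model = adjust.default_model()
    scale = adjust.check_population_type(model, pop_type, allow_ril_heuristic)
    filtered, report = pgm.filter_markers(af_track, max_missing=max_missing)
    pairs = pgm.compute_k(filtered, min_dist_bp=min_dist_bp)
    raw_map = pgm.build_pgm(pairs, af_track=filtered)
    n_snps = len(filtered)
    adj = adjust.predict_adj(model, n_snps, n_genotypes) * scale
    pairs = adjust.apply_adjustment(pairs, adj)
    npgm_map = pgm.build_pgm(pairs, use_adjusted=True, af_track=filtered)
    intervals = windows.pairwise_rr(npgm_map)
    win = windows.window_rr(
        intervals,
        window_mb=window_mb,
        slide_frac=slide_frac,
        min_pairs=min_pairs,
        stat=window_stat,
    )
    return EstimateResult(
        pgm_map=raw_map,
        npgm_map=npgm_map,
        pairs=pairs,
        windows=win,
        adj_start=adj,
        n_snps=n_snps,
        filter_report=report,
    )


def simulate_calibration_table(
    tmap: pd.DataFrame,
    depths: list[int],
    sizes: list[int],
    replicates: int = 5,
    seed: int = 0,
    pop_type: str = "F2",
) -> pd.DataFrame:
    """Calibration rows over a depth x size x replicate simulation grid.

    For every combination a fresh population is simulated from the true map,
    pooled, mapped, and its observed correction factor
    adj_start = ML_ref / ML_PGM recorded; ML_ref is the genetic length of
    the marker subset actually genotyped.
    """
    popsim.validate_map(tmap)
    rows = []
    rep_counter = 0
    for depth in depths:
        for size in sizes:
            for _ in range(replicates):
                rng = np.random.default_rng([seed, rep_counter])
                rep_counter += 1
                af, sub = simulate_pooled_af(tmap, size, depth, rng, pop_type)
                filtered, _ = pgm.filter_markers(af)
                pairs = pgm.compute_k(filtered)
                raw_map = pgm.build_pgm(pairs)
                ml_pgm = pgm.map_length(raw_map)
                ml_ref = float(sub.groupby("chrom")["cM"].max().sum())
                rows.append(
                    {
                        "n_snps": depth,
                        "n_genotypes": size,
                        "ml_ref": ml_ref,
                        "ml_pgm": ml_pgm,
                        "adj_start": adjust.adj_start_observed(ml_ref, ml_pgm),
                    }
                )
    return pd.DataFrame(rows, columns=adjust.CALIBRATION_COLUMNS)


def calibrate(
    tmap: pd.DataFrame,
    depths: list[int],
    sizes: list[int],
    replicates: int = 5,
    seed: int = 0,
    pop_type: str = "F2",
) -> tuple[adjust.AdjustmentModel, adjust.LinearAdjModel, pd.DataFrame]:
    """Fit the non-linear (and, for comparison, linear) correction model.

    Returns (non-linear model, linear model, calibration table); the
    non-linear model carries AIC/log-likelihood diagnostics and is the one
    applied downstream.
    """
    table = simulate_calibration_table(
        tmap, depths, sizes, replicates=replicates, seed=seed, pop_type=pop_type
    )
    nls = adjust.fit_nls(table, population_type=pop_type)
    linear = adjust.fit_linear(table)
    return nls, linear, table
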