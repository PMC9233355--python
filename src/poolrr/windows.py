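"""Windowed recombination rates (cM/MB) and comparison statistics.

A genetic map (pool map, Haldane map or reference map) is first turned into
per-interval recombination rates — map distance over physical distance for
each adjacent marker pair — and then summarized in sliding windows (default
50 MB, sliding by half a window). Tracks from different methods are compared
window-by-window with Pearson/Spearman correlation and RMSE; because the
pool-map calibration is a pure rescaling, those correlations are invariant
to it.

Also provided is a simple general-recombination-effect (GRE) estimator: a
fixed-effects least-squares decomposition of per-population genome-wide RR
into additive parental contributions across a crossing design. This is a
main-effects stand-in, not a G-BLUP.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

RR_WINDOW_COLUMNS = ["chrom", "start_bp", "end_bp", "rr", "n_pairs", "partial"]


def pairwise_rr(gmap: pd.DataFrame) -> pd.DataFrame:
    """Per-interval recombination rate from a map (chrom, pos_bp, map_pos).

    RR = delta map position (cM) / (delta bp / 1e6), anchored at the
    interval's physical midpoint.
    """
    frames = []
    for chrom, grp in gmap.groupby("chrom", sort=False):
        bp = grp["pos_bp"].to_numpy(np.int64)
        pos = grp["map_pos"].to_numpy(float)
        if len(bp) < 2:
            continue
        dbp = np.diff(bp)
        if np.any(dbp <= 0):
            raise ValueError(f"map positions not strictly increasing in bp on {chrom}")
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "left_bp": bp[:-1],
                    "right_bp": bp[1:],
                    "mid_bp": (bp[:-1] + bp[1:]) / 2.0,
                    "rr": np.diff(pos) / (dbp / 1e6),
                }
            )
        )
    if not frames:
        raise ValueError("no chromosome has two or more markers")
    return pd.concat(frames, ignore_index=True)


def _window_starts(chrom_len: int, window_bp: int, step_bp: int) -> list[tuple[int, int, bool]]:
    """(start, end, partial) triples tiling [0, chrom_len)."""
    out = []
    start = 0
    while start + window_bp <= chrom_len:
        out.append((start, start + window_bp, False))
        start += step_bp
    covered_end = out[-1][1] if out else 0
    if covered_end < chrom_len:
        out.append((start, chrom_len, True))  # terminal partial window
    return out


def window_rr(
    intervals: pd.DataFrame,
    window_mb: float = 50.0,
    slide_frac: float = 0.5,
    min_pairs: int = 2,
    stat: str = "median",
    anchor: str = "midpoint",
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Sliding-window summary of per-interval recombination rates.

    Windows of window_mb megabases tile each chromosome with step
    slide_frac * window; an interval contributes to every window containing
    its anchor (physical midpoint by default, left marker with
    anchor='left'). The window statistic is the median (or mean) of the
    contributing interval RRs; windows with fewer than min_pairs
    contributors report a missing RR. A trailing partial window is kept and
    flagged. Chromosome length defaults to the last marker position.
    """
    if window_mb <= 0:
        raise ValueError("window size must be positive")
    if not 0 < slide_frac <= 1:
        raise ValueError("slide_frac must be in (0, 1]")
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    if anchor not in ("midpoint", "left"):
        raise ValueError("anchor must be 'midpoint' or 'left'")
    window_bp = int(round(window_mb * 1e6))
    step_bp = max(int(round(window_bp * slide_frac)), 1)
    agg = np.median if stat == "median" else np.mean

    rows = []
    for chrom, grp in intervals.groupby("chrom", sort=False):
        pos = grp["mid_bp"].to_numpy(float) if anchor == "midpoint" else grp[
            "left_bp"
        ].to_numpy(float)
        rr = grp["rr"].to_numpy(float)
        chrom_len = int(
            chrom_lengths[chrom]
            if chrom_lengths is not None
            else grp["right_bp"].max()
        )
        for start, end, partial in _window_starts(chrom_len, window_bp, step_bp):
            inside = (pos >= start) & (pos < end)
            n = int(inside.sum())
            rows.append(
                {
                    "chrom": chrom,
                    "start_bp": start,
                    "end_bp": end,
                    "rr": float(agg(rr[inside]))
                    if n >= max(min_pairs, 1)
                    else np.nan,
                    "n_pairs": n,
                    "partial": partial,
                }
            )
    return pd.DataFrame(rows, columns=RR_WINDOW_COLUMNS)


def compare_rr(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Pearson, Spearman, RMSE and n over windows matched by (chrom, start).

    Windows missing on either side are excluded; fewer than 3 matched
    windows is an error.
    """
    merged = a.merge(b, on=["chrom", "start_bp"], suffixes=("_a", "_b"))
    merged = merged.dropna(subset=["rr_a", "rr_b"])
    n = len(merged)
    if n < 3:
        raise ValueError(f"only {n} matched windows with data; need at least 3")
    x = merged["rr_a"].to_numpy(float)
    y = merged["rr_b"].to_numpy(float)
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    return {"pearson": pearson, "spearman": spearman, "rmse": rmse, "n": n}


def _connected(parents1, parents2) -> bool:
    """Whether the crossing design links all parents (union-find)."""
    parent_ids = {p: i for i, p in enumerate(sorted(set(parents1) | set(parents2)))}
    root = list(range(len(parent_ids)))

    def find(i):
        while root[i] != i:
            root[i] = root[root[i]]
            i = root[i]
        return i

    for p, q in zip(parents1, parents2):
        ri, rj = find(parent_ids[p]), find(parent_ids[q])
        root[ri] = rj
    return len({find(i) for i in range(len(parent_ids))}) == 1


def gre_estimate(pop_table: pd.DataFrame) -> pd.DataFrame:
    """Per-parent general recombination effects from per-population RR.

    Fits RR_pop = mu + effect(parent1) + effect(parent2) by least squares
    with a sum-to-zero constraint on the effects (minimum-norm solution,
    re-centered). Input columns: parent1, parent2, rr. The crossing design
    must connect all parents. Returns a parent/effect table sorted by
    effect, with the intercept in DataFrame.attrs['mu'].
    """
    for col in ("parent1", "parent2", "rr"):
        if col not in pop_table.columns:
            raise ValueError(f"population table lacks column {col!r}")
    if (pop_table["parent1"] == pop_table["parent2"]).any():
        raise ValueError("each population must link two distinct parents")
    parents = sorted(set(pop_table["parent1"]) | set(pop_table["parent2"]))
    if not _connected(pop_table["parent1"], pop_table["parent2"]):
        raise ValueError("crossing design is disconnected; effects not estimable")
    pidx = {p: i for i, p in enumerate(parents)}
    n, p = len(pop_table), len(parents)
    X = np.zeros((n, p + 1))
    X[:, 0] = 1.0
    for row, (p1, p2) in enumerate(zip(pop_table["parent1"], pop_table["parent2"])):
        X[row, 1 + pidx[p1]] += 1.0
        X[row, 1 + pidx[p2]] += 1.0
    y = pop_table["rr"].to_numpy(float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)  # minimum-norm solution
    mu, eff = beta[0], beta[1:]
    shift = eff.mean()  # re-center to sum-to-zero effects
    eff = eff - shift
    mu = mu + 2 * shift
    out = (
        pd.DataFrame({"parent": parents, "effect": eff})
        .sort_values("effect", ascending=False)
        .reset_index(drop=True)
    )
    out.attrs["mu"] = float(mu)
    return out
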