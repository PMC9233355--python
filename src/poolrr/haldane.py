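"""Haldane genetic map (HGM) from individual genotypes — the baseline method.

Given a physically ordered F2 genotype matrix, each adjacent marker pair's
recombination fraction r is estimated by maximum likelihood (EM) over the
nine two-locus dosage classes, accounting for the phase ambiguity of double
heterozygotes and a small symmetric genotyping-error probability. Haldane's
mapping function d = -50 * ln(1 - 2r) cM then converts fractions to
distances, which cumulate into the per-chromosome map.

This is a two-point chain on a fixed physical marker order — order
estimation and multipoint likelihood are deliberately out of scope, since
physical positions pin the order.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .popsim import MISSING, GenotypeMatrix

RF_COLUMNS = ["chrom", "left_bp", "right_bp", "rf", "n_informative", "loglik"]

#: upper clamp keeping Haldane distances finite
R_MAX = 0.4999
#: minimum jointly called individuals for an interval estimate
MIN_INFORMATIVE = 10

# --- two-locus F2 machinery -------------------------------------------------
# Gamete haplotypes at a marker pair: (0,0), (0,1), (1,0), (1,1); the middle
# two are recombinant. An F2 individual is an ordered pair of independent
# gametes (16 combos); its dosage pair is the allele sum per locus.
_GAMETES = np.array([(0, 0), (0, 1), (1, 0), (1, 1)])
_REC = np.array([0, 1, 1, 0])
_T1, _T2 = np.meshgrid(np.arange(4), np.arange(4), indexing="ij")
_T1, _T2 = _T1.ravel(), _T2.ravel()
_D1 = _GAMETES[_T1, 0] + _GAMETES[_T2, 0]  # dosage at left locus per combo
_D2 = _GAMETES[_T1, 1] + _GAMETES[_T2, 1]  # dosage at right locus per combo
_NREC = _REC[_T1] + _REC[_T2]  # recombinant gametes per combo, {0,1,2}


def _emission_matrix(error_prob: float) -> np.ndarray:
    """P(observed dosage | true dosage) with symmetric misclassification."""
    e = error_prob
    E = np.full((3, 3), e / 2.0)
    np.fill_diagonal(E, 1.0 - e)
    return E


def _class_combo_weights(error_prob: float) -> np.ndarray:
    """(9, 16) matrix: emission weight of each gamete combo for each observed
    dosage-pair class (classes indexed o1*3 + o2)."""
    E = _emission_matrix(error_prob)
    o1, o2 = np.divmod(np.arange(9), 3)
    return E[o1[:, None], _D1[None, :]] * E[o2[:, None], _D2[None, :]]


def _combo_probs(r: np.ndarray) -> np.ndarray:
    """(n, 16) combo probabilities for a vector of recombination fractions."""
    r = r[:, None]
    return ((1.0 - r) / 2.0) ** (2 - _NREC) * (r / 2.0) ** _NREC


def _em_rf(
    counts: np.ndarray,
    error_prob: float,
    max_iter: int = 2000,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized EM over many 9-class tables; returns (r_hat, loglik).

    The E-step computes, per table, the expected number of recombinant
    gametes given the current r (the double-heterozygote class splits
    between the 0- and 2-recombinant phases); the M-step divides by the
    number of scored gametes (2 per individual).
    """
    counts = np.asarray(counts, float)
    if counts.ndim == 1:
        counts = counts[None, :]
    n_pair = counts.shape[0]
    n_ind = counts.sum(axis=1)
    em = _class_combo_weights(error_prob)  # (9, 16)
    r = np.full(n_pair, 0.25)
    for _ in range(max_iter):
        pc = _combo_probs(r)  # (n, 16)
        w = pc[:, None, :] * em[None, :, :]  # (n, 9, 16)
        q = w.sum(axis=2)  # (n, 9)
        with np.errstate(invalid="ignore", divide="ignore"):
            post_rec = np.where(q > 0, (w * _NREC).sum(axis=2) / q, 0.0)
        e_rec = (counts * post_rec).sum(axis=1)
        r_new = np.clip(e_rec / (2.0 * n_ind), 1e-12, R_MAX)
        done = np.max(np.abs(r_new - r)) < tol
        r = r_new
        if done:
            break
    q = (_combo_probs(r)[:, None, :] * em[None, :, :]).sum(axis=2)
    with np.errstate(divide="ignore"):
        ll = np.where(counts > 0, counts * np.log(q), 0.0).sum(axis=1)
    return r, ll


def est_rf_adjacent(g: GenotypeMatrix, error_prob: float = 0.0001) -> pd.DataFrame:
    """ML recombination fractions for all physically adjacent marker pairs.

    Pairs with fewer than 10 jointly called individuals get a missing
    estimate (the interval is later chained as zero length, with a warning).
    """
    if not 0.0 <= error_prob < 0.5:
        raise ValueError("error_prob must be in [0, 0.5)")
    d = g.dosage
    markers = g.markers.reset_index(drop=True)  # align index with dosage columns
    rows = []
    for chrom, grp in markers.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if len(idx) < 2:
            continue
        left, right = idx[:-1], idx[1:]
        d1, d2 = d[:, left], d[:, right]
        ok = (d1 != MISSING) & (d2 != MISSING)
        code = d1 * 3 + d2
        counts = np.stack(
            [((code == k) & ok).sum(axis=0) for k in range(9)], axis=1
        ).astype(float)
        n_inf = counts.sum(axis=1)
        rf = np.full(len(left), np.nan)
        ll = np.full(len(left), np.nan)
        enough = n_inf >= MIN_INFORMATIVE
        if (~enough).any():
            warnings.warn(
                f"{int((~enough).sum())} interval(s) on {chrom} with fewer than "
                f"{MIN_INFORMATIVE} informative individuals: estimate skipped",
                stacklevel=2,
            )
        if enough.any():
            rf[enough], ll[enough] = _em_rf(counts[enough], error_prob)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "left_bp": grp["pos_bp"].to_numpy()[:-1],
                    "right_bp": grp["pos_bp"].to_numpy()[1:],
                    "rf": rf,
                    "n_informative": n_inf.astype(int),
                    "loglik": ll,
                }
            )
        )
    if not rows:
        raise ValueError("no chromosome has two or more markers")
    return pd.concat(rows, ignore_index=True)


def haldane_distance(r, clamp: bool = False):
    """Haldane map distance d = -50 * ln(1 - 2r) in centiMorgans.

    r must lie in [0, 0.5); with clamp=True values at or above 0.5 are
    clamped to R_MAX with a warning instead of raising.
    """
    r = np.asarray(r, float)
    if np.any(r < 0):
        raise ValueError("recombination fraction must be non-negative")
    if np.any(r >= 0.5):
        if not clamp:
            raise ValueError("recombination fraction must be < 0.5")
        warnings.warn(f"recombination fractions clamped to {R_MAX}", stacklevel=2)
        r = np.minimum(r, R_MAX)
    d = -50.0 * np.log(1.0 - 2.0 * r)
    return float(d) if d.ndim == 0 else d


def inverse_haldane(d):
    """Recombination fraction from a Haldane distance in cM."""
    d = np.asarray(d, float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    r = (1.0 - np.exp(-d / 50.0)) / 2.0
    return float(r) if r.ndim == 0 else r


def build_hgm(rfs: pd.DataFrame) -> pd.DataFrame:
    """Chain adjacent-interval Haldane distances into a genetic map.

    Missing interval estimates are interpolated as zero length with a
    warning. Output columns match the pool-map layout (chrom, pos_bp,
    map_pos in cM) for direct comparison.
    """
    frames = []
    n_missing = int(rfs["rf"].isna().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} interval(s) without an estimate chained as zero length",
            stacklevel=2,
        )
    for chrom, grp in rfs.groupby("chrom", sort=False):
        r = np.nan_to_num(grp["rf"].to_numpy(float), nan=0.0)
        d = haldane_distance(np.minimum(r, R_MAX))
        bp = np.concatenate([[grp["left_bp"].iloc[0]], grp["right_bp"].to_numpy()])
        pos = np.concatenate([[0.0], np.cumsum(np.atleast_1d(d))])
        frames.append(pd.DataFrame({"chrom": chrom, "pos_bp": bp, "map_pos": pos}))
    return pd.concat(frames, ignore_index=True)
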