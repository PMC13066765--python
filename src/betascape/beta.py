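"""Abundance-based beta diversity: Bray-Curtis partition and Raup-Crick nulls.

``pairwise_bray`` decomposes Bray-Curtis dissimilarity into balanced-variation
and abundance-gradient components; ``multi_site_partition`` is the multiple-
site analogue (sums of the pairwise A, min, max quantities), which reduces
exactly to the pairwise form for two sites.  ``raup_crick_pair`` standardises
the observed dissimilarity against a null that fixes each community's richness
and total abundance while drawing composition from a species pool.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import DomainError


def _as_counts(v) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise DomainError("count vectors must be 1-D")
    if np.any(arr < 0):
        raise DomainError("counts must be non-negative")
    return arr


def pairwise_bray(x, y) -> tuple[float, float, float, float, float, float]:
    """Bray-Curtis dissimilarity and its decomposition for one pair.

    Returns (d, d_balanced, d_gradient, A, B, C) where A = sum of per-species
    minima, B and C the site-specific surpluses, d = (B+C)/(2A+B+C),
    d_balanced = min(B,C)/(A+min(B,C)) and d_gradient = d - d_balanced.
    """
    x, y = _as_counts(x), _as_counts(y)
    if x.shape != y.shape:
        raise DomainError("count vectors must share a species set")
    m = np.minimum(x, y)
    A = float(m.sum())
    B = float((x - m).sum())
    C = float((y - m).sum())
    if A + B + C == 0:
        raise DomainError("both communities are empty")
    d = (B + C) / (2 * A + B + C)
    mn = min(B, C)
    d_bal = mn / (A + mn) if (A + mn) > 0 else 0.0
    return d, d_bal, d - d_bal, A, B, C


def multi_site_partition(matrix) -> tuple[float, float, float]:
    """Multiple-site Bray-Curtis partition (total, balanced, gradient).

    Sums A, min(B,C) and max(B,C) over all unordered site pairs:
    total = (Smin+Smax)/(2*SA+Smin+Smax), balanced = Smin/(SA+Smin).
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise DomainError("need a sites x species matrix with >= 2 rows")
    if np.any(M < 0):
        raise DomainError("counts must be non-negative")
    if np.any(M.sum(axis=1) == 0):
        raise DomainError("matrix contains an all-zero row")
    SA = Smin = Smax = 0.0
    for j, k in combinations(range(M.shape[0]), 2):
        m = np.minimum(M[j], M[k])
        A = m.sum()
        b = (M[j] - m).sum()
        c = (M[k] - m).sum()
        SA += A
        Smin += min(b, c)
        Smax += max(b, c)
    if 2 * SA + Smin + Smax == 0:
        raise DomainError("degenerate matrix")
    total = (Smin + Smax) / (2 * SA + Smin + Smax)
    balanced = Smin / (SA + Smin) if (SA + Smin) > 0 else 0.0
    return float(total), float(balanced), float(total - balanced)


def _null_communities(
    richness: int,
    total: int,
    pool_freq: np.ndarray,
    pool_relabund: np.ndarray,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n_reps null communities: richness species without replacement with
    probability proportional to pool_freq, then a multinomial of ``total``
    individuals over the drawn species with probability proportional to
    pool_relabund.  Returns an (n_reps, S) count matrix."""
    S = pool_freq.size
    candidates = np.flatnonzero(pool_freq > 0)
    if richness > candidates.size:
        raise DomainError(
            f"community richness {richness} exceeds pool richness {candidates.size}"
        )
    # Gumbel-top-k == weighted sampling without replacement proportional to freq
    with np.errstate(divide="ignore"):
        logw = np.log(pool_freq)
    keys = logw[None, :] + rng.gumbel(size=(n_reps, S))
    chosen = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    P = pool_relabund[chosen].astype(float)
    sums = P.sum(axis=1, keepdims=True)
    P = np.where(sums > 0, P, 1.0)  # degenerate slice: uniform over chosen
    P /= P.sum(axis=1, keepdims=True)
    drawn = rng.multinomial(total, P)  # batched over replicate rows
    out = np.zeros((n_reps, S), dtype=float)
    np.put_along_axis(out, chosen, drawn, axis=1)
    return out


def _bray_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise plain Bray-Curtis between matched rows of X and Y."""
    m = np.minimum(X, Y)
    A = m.sum(axis=1)
    B = (X - m).sum(axis=1)
    C = (Y - m).sum(axis=1)
    return (B + C) / (2 * A + B + C)


def raup_crick_pair(
    x,
    y,
    pool_freq,
    pool_relabund,
    n_reps: int = 999,
    seed: int | np.random.Generator = 0,
) -> float:
    """Abundance-based Raup-Crick index in [-1, 1] for one community pair.

    rc = 2 * [(#{d* < d_obs} + 0.5 * #{d* = d_obs}) / n_reps] - 1, where d*
    are Bray-Curtis dissimilarities of null community pairs drawn from the
    pool with each community's richness and total abundance held fixed.
    """
    x, y = _as_counts(x), _as_counts(y)
    pool_freq = np.asarray(pool_freq, dtype=float)
    pool_relabund = np.asarray(pool_relabund, dtype=float)
    if not (x.size == y.size == pool_freq.size == pool_relabund.size):
        raise DomainError("pool vectors must match the species dimension")
    if n_reps < 1:
        raise DomainError("n_reps must be >= 1")
    for v in (x, y):
        present = v > 0
        if not present.any():
            raise DomainError("communities must contain at least one species")
        if np.any(pool_freq[present] <= 0):
            raise DomainError("pool is missing a species present in the pair")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d_obs = pairwise_bray(x, y)[0]
    xs = _null_communities(int((x > 0).sum()), int(round(x.sum())), pool_freq, pool_relabund, n_reps, rng)
    ys = _null_communities(int((y > 0).sum()), int(round(y.sum())), pool_freq, pool_relabund, n_reps, rng)
    d_null = _bray_rows(xs, ys)
    less = np.count_nonzero(d_null < d_obs - 1e-12)
    ties = np.count_nonzero(np.abs(d_null - d_obs) <= 1e-12)
    return float(2.0 * ((less + 0.5 * ties) / n_reps) - 1.0)


@dataclass
class BetaDiversityResult:
    beta_total: float
    beta_balanced: float
    beta_gradient: float
    rc_raw: float
    rc_rescaled: float
    n_null_reps: int
    seed: int


def pool_from_matrix(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(occurrence frequency, pooled relative abundance) from a sites x species matrix."""
    M = np.asarray(matrix, dtype=float)
    freq = (M > 0).mean(axis=0)
    totals = M.sum(axis=0)
    relabund = totals / totals.sum()
    return freq, relabund


def landscape_beta(
    matrix, n_reps: int = 999, seed: int = 0, compute_rc: bool = True
) -> BetaDiversityResult:
    """Multi-site partition plus the mean pairwise Raup-Crick index for one
    landscape, with the null pool built from the landscape's own inventories."""
    M = np.asarray(matrix, dtype=float)
    total, balanced, gradient = multi_site_partition(M)
    rc_raw = float("nan")
    if compute_rc:
        freq, relabund = pool_from_matrix(M)
        rng = np.random.default_rng(seed)
        vals = [
            raup_crick_pair(M[j], M[k], freq, relabund, n_reps, rng)
            for j, k in combinations(range(M.shape[0]), 2)
        ]
        rc_raw = float(np.mean(vals))
    return BetaDiversityResult(
        beta_total=total,
        beta_balanced=balanced,
        beta_gradient=gradient,
        rc_raw=rc_raw,
        rc_rescaled=(rc_raw + 1.0) / 2.0,
        n_null_reps=n_reps,
        seed=seed,
    )


def beta_table(
    abundances: pd.DataFrame,
    membership: pd.DataFrame,
    n_reps: int = 999,
    seed: int = 0,
    compute_rc: bool = True,
) -> pd.DataFrame:
    """Per-landscape beta diversity table from a wide abundance matrix and a
    membership table (columns landscape_id, inventory_id)."""
    rows = []
    for lid, grp in membership.groupby("landscape_id", sort=True):
        sub = abundances.loc[grp["inventory_id"]]
        sub = sub.loc[:, (sub.sum(axis=0) > 0)]
        # landscape-level seeds derive from the master seed and the id so that
        # adding landscapes does not perturb existing results
        sub_seed = np.random.SeedSequence(
            [seed, zlib.crc32(str(lid).encode())]
        ).generate_state(1)[0]
        res = landscape_beta(sub.to_numpy(), n_reps=n_reps, seed=int(sub_seed), compute_rc=compute_rc)
        rows.append(
            {
                "landscape_id": lid,
                "beta_total": res.beta_total,
                "beta_balanced": res.beta_balanced,
                "beta_gradient": res.beta_gradient,
                "rc_raw": res.rc_raw,
                "rc_rescaled": res.rc_rescaled,
                "n_null_reps": res.n_null_reps,
                "seed": res.seed,
            }
        )
    return pd.DataFrame(rows)
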