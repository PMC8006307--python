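"""Per-SNP association statistics for two-bulk segregant analysis.

Four statistics are computed from the 2x2 allele-by-bulk count table at each
site: the SNP-index difference between bulks (delta), the likelihood-ratio
G statistic, the Euclidean distance between the bulks' base-frequency
vectors, and the two-tailed Fisher exact test p-value.

Conventions
-----------
* The SNP-index of a bulk is the fraction of its reads carrying the
  tolerant-parent allele when parental origins are known (the simulator
  writes the tolerant allele as ALT), so delta > 0 means the tolerant
  allele is enriched in the tolerant bulk.
* G uses natural logarithms; zero cells contribute zero.
* ED is the raw distance in four-base frequency space (max sqrt(2) for a
  fully diverged biallelic site); an optional power k returns ED**k.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "snp_index",
    "delta_index",
    "g_statistic",
    "euclidean_distance",
    "ed_from_counts",
    "fisher_two_tailed",
    "compute_stats",
]

#: relative tolerance for probability ties in the two-tailed Fisher sum
_FISHER_TIE_TOL = 1e-12


def snp_index(ref_depth: float, alt_depth: float) -> float:
    """Fraction of reads carrying the alt (tolerant-parent) allele."""
    total = ref_depth + alt_depth
    if total <= 0:
        raise ValueError("SNP-index undefined at zero total depth")
    return float(alt_depth) / float(total)


def delta_index(index_t: float, index_s: float) -> float:
    """SNP-index difference, tolerant bulk minus sensitive bulk."""
    return index_t - index_s


def g_statistic(a: float, b: float, c: float, d: float) -> float:
    """Likelihood-ratio G for the 2x2 table [[a, b], [c, d]].

    Rows are bulks, columns alleles. G = 2 * sum n_i ln(n_i / nhat_i) with
    nhat the expectation under row/column independence; equivalently
    2 * n * MI(nats) of the empirical joint distribution.
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    if (row == 0).any():
        raise ValueError("each bulk needs positive total depth")
    col = obs.sum(axis=0)
    n = obs.sum()
    exp = np.outer(row, col) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    return float(max(2.0 * terms.sum(), 0.0))


def euclidean_distance(
    freqs_t: np.ndarray, freqs_s: np.ndarray, k: float = 1.0
) -> float:
    """Distance between two four-base frequency vectors, raised to power k.

    k = 1 is the raw distance; larger powers (classically k = 4) suppress
    low-level noise relative to true divergence.
    """
    ft = np.asarray(freqs_t, dtype=float)
    fs = np.asarray(freqs_s, dtype=float)
    for v in (ft, fs):
        if abs(v.sum() - 1.0) > 1e-6:
            raise ValueError("frequency vector must sum to 1")
    ed = float(np.sqrt(((ft - fs) ** 2).sum()))
    return ed**k


def ed_from_counts(
    t_ref: float, t_alt: float, s_ref: float, s_alt: float, k: float = 1.0
) -> float:
    """ED for a biallelic site embedded in four-base frequency space."""
    ft = np.array([t_ref, t_alt, 0.0, 0.0], dtype=float)
    fs = np.array([s_ref, s_alt, 0.0, 0.0], dtype=float)
    ft /= ft.sum()
    fs /= fs.sum()
    return euclidean_distance(ft, fs, k=k)


def _hypergeom_logpmf_support(
    r1: int, c1: int, n: int
) -> Tuple[np.ndarray, int]:
    """Log-pmf of the hypergeometric cell 'a' over its whole support."""
    kmin = max(0, r1 + c1 - n)
    kmax = min(r1, c1)
    ks = np.arange(kmin, kmax + 1)
    logp = (
        gammaln(r1 + 1)
        - gammaln(ks + 1)
        - gammaln(r1 - ks + 1)
        + gammaln(n - r1 + 1)
        - gammaln(c1 - ks + 1)
        - gammaln(n - r1 - c1 + ks + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    return logp, kmin


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums the conditional (hypergeometric) probabilities of every table with
    the same margins whose probability does not exceed the observed table's,
    with a small relative tolerance for floating-point ties.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    r1, c1 = a + b, a + c
    logp, kmin = _hypergeom_logpmf_support(r1, c1, n)
    p = np.exp(logp)
    p_obs = p[a - kmin]
    total = p[p <= p_obs * (1.0 + _FISHER_TIE_TOL)].sum()
    return float(min(total, 1.0))


def _fisher_many(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray
) -> np.ndarray:
    out = np.ones(len(a), dtype=float)
    for i in range(len(a)):
        n = a[i] + b[i] + c[i] + d[i]
        if n == 0:
            out[i] = np.nan
            continue
        out[i] = fisher_two_tailed(int(a[i]), int(b[i]), int(c[i]), int(d[i]))
    return out


def compute_stats(
    counts: pd.DataFrame,
    min_depth: int = 10,
    ed_power: float = 1.0,
) -> pd.DataFrame:
    """All four statistics per site from a pooled-counts table.

    ``counts`` needs columns chrom, pos, t_ref, t_alt, s_ref, s_alt with the
    alt allele oriented to the tolerant parent (as written by the simulator
    and the VCF reader). Sites where either pool's total depth falls below
    ``min_depth`` are dropped: shallow pools make every statistic unstable
    and real pipelines apply the same guard.
    """
    df = counts.copy()
    t_tot = df["t_ref"] + df["t_alt"]
    s_tot = df["s_ref"] + df["s_alt"]
    keep = (t_tot >= min_depth) & (s_tot >= min_depth)
    df = df.loc[keep].reset_index(drop=True)
    t_tot = t_tot[keep].to_numpy(dtype=float)
    s_tot = s_tot[keep].to_numpy(dtype=float)
    ta = df["t_alt"].to_numpy(dtype=float)
    sa = df["s_alt"].to_numpy(dtype=float)
    tr = df["t_ref"].to_numpy(dtype=float)
    sr = df["s_ref"].to_numpy(dtype=float)

    index_t = ta / t_tot
    index_s = sa / s_tot
    delta = index_t - index_s

    # vectorized G over all sites
    n = t_tot + s_tot
    g = np.zeros(len(df))
    for obs, rtot, ctot in (
        (tr, t_tot, tr + sr),
        (ta, t_tot, ta + sa),
        (sr, s_tot, tr + sr),
        (sa, s_tot, ta + sa),
    ):
        exp = rtot * ctot / n
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
        g += term
    g = np.maximum(2.0 * g, 0.0)

    ed = np.sqrt((index_t - index_s) ** 2 + ((1 - index_t) - (1 - index_s)) ** 2)
    ed = ed**ed_power

    fisher_p = _fisher_many(
        df["t_ref"].to_numpy(int),
        df["t_alt"].to_numpy(int),
        df["s_ref"].to_numpy(int),
        df["s_alt"].to_numpy(int),
    )

    out = df[["chrom", "pos"]].copy()
    out["index_t"] = index_t
    out["index_s"] = index_s
    out["delta"] = delta
    out["g"] = g
    out["ed"] = ed
    out["fisher_p"] = np.clip(fisher_p, np.nextafter(0, 1), 1.0)
    out["t_depth"] = t_tot
    out["s_depth"] = s_tot
    return out
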