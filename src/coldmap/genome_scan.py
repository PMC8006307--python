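"""Window smoothing, null thresholds, region calling, and consensus.

The per-SNP statistics are smoothed on a sliding-window grid (default 1 Mb
windows every 20 kb). Significance is declared per window against either a
genome-wide empirical quantile (95/99%) or, for the SNP-index difference, a
depth-aware Monte-Carlo null band. Significant windows are merged into
candidate regions per method, and the final QTL interval is the
intersection of the four methods' regions ("consensus").

Method names used throughout: ``delta`` (SNP-index difference), ``g``
(tricube-smoothed G, i.e. G'), ``ed`` (Euclidean distance), ``fisher``
(mean -log10 p).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

METHODS = ("delta", "g", "ed", "fisher")

#: track column holding each method's windowed value
METHOD_COLUMNS = {
    "delta": "delta",
    "g": "g_prime",
    "ed": "ed",
    "fisher": "fisher_neglog10p",
}


@dataclass(frozen=True)
class CandidateRegion:
    """One method's significant interval (1-based closed coordinates)."""

    method: str
    chrom: str
    start: int
    end: int
    peak: float
    confidence: float

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ConsensusRegion:
    """Cross-method intersection interval with the supporting peaks."""

    chrom: str
    start: int
    end: int
    methods: Tuple[str, ...]
    peaks: Dict[str, float] = field(default_factory=dict, hash=False, compare=False)

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def width_mb(self) -> float:
        return self.width / 1e6


def make_windows(
    chrom_lengths: Dict[str, int],
    window_size: int = 1_000_000,
    step: int = 20_000,
) -> pd.DataFrame:
    """Sliding-window grid [k*step + 1, k*step + window], clipped at ends."""
    if not (window_size >= step > 0):
        raise ValueError("need window_size >= step > 0")
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(1, length + 1, step, dtype=np.int64)
        ends = np.minimum(starts + window_size - 1, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def smooth_track(
    stats: pd.DataFrame,
    windows: pd.DataFrame,
    min_snps: int = 5,
) -> pd.DataFrame:
    """Window-smooth the four statistics.

    delta and ED are unweighted window means; G' is the tricube-weighted
    mean of G with weights (1 - (d/h)^3)^3 (d = distance to the window
    center, h = half window); the Fisher track is the window mean of
    -log10 p (also reported back-transformed). Windows supported by fewer
    than ``min_snps`` SNPs are set missing.
    """
    out = windows.copy().reset_index(drop=True)
    n_win = len(out)
    cols = {
        "n_snps": np.zeros(n_win, dtype=np.int64),
        "delta": np.full(n_win, np.nan),
        "g_prime": np.full(n_win, np.nan),
        "ed": np.full(n_win, np.nan),
        "fisher_neglog10p": np.full(n_win, np.nan),
        "t_depth": np.full(n_win, np.nan),
        "s_depth": np.full(n_win, np.nan),
    }
    for chrom, wsub in out.groupby("chrom", sort=False):
        ssub = stats.loc[stats["chrom"] == chrom]
        ssub = ssub.sort_values("pos", kind="mergesort")
        pos = ssub["pos"].to_numpy()
        if len(pos) == 0:
            continue
        delta = ssub["delta"].to_numpy(dtype=float)
        g = ssub["g"].to_numpy(dtype=float)
        ed = ssub["ed"].to_numpy(dtype=float)
        nlp = -np.log10(ssub["fisher_p"].to_numpy(dtype=float))
        t_dep = ssub.get("t_depth", pd.Series(np.nan, index=ssub.index)).to_numpy(
            dtype=float
        )
        s_dep = ssub.get("s_depth", pd.Series(np.nan, index=ssub.index)).to_numpy(
            dtype=float
        )
        starts = wsub["start"].to_numpy()
        ends = wsub["end"].to_numpy()
        i0 = np.searchsorted(pos, starts, side="left")
        i1 = np.searchsorted(pos, ends, side="right")

        csum = {
            name: np.concatenate(([0.0], np.cumsum(arr)))
            for name, arr in (
                ("delta", delta),
                ("ed", ed),
                ("nlp", nlp),
                ("t", t_dep),
                ("s", s_dep),
            )
        }
        counts = i1 - i0
        idx = wsub.index.to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            for name, col in (
                ("delta", "delta"),
                ("ed", "ed"),
                ("nlp", "fisher_neglog10p"),
                ("t", "t_depth"),
                ("s", "s_depth"),
            ):
                vals = (csum[name][i1] - csum[name][i0]) / counts
                cols[col][idx] = vals
        cols["n_snps"][idx] = counts

        # tricube-weighted G' per window
        centers = (starts + ends) / 2.0
        half = (ends - starts + 1) / 2.0
        gp = np.full(len(idx), np.nan)
        for j in range(len(idx)):
            lo, hi = i0[j], i1[j]
            if hi <= lo:
                continue
            d = np.abs(pos[lo:hi] - centers[j])
            w = (1.0 - np.minimum(d / half[j], 1.0) ** 3) ** 3
            wsum = w.sum()
            if wsum > 0:
                gp[j] = float((w * g[lo:hi]).sum() / wsum)
            else:
                gp[j] = float(np.mean(g[lo:hi]))
        cols["g_prime"][idx] = gp

    for name, arr in cols.items():
        out[name] = arr
    low = out["n_snps"] < min_snps
    out.loc[low, ["delta", "g_prime", "ed", "fisher_neglog10p"]] = np.nan
    out["fisher_p"] = 10.0 ** (-out["fisher_neglog10p"])
    return out


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank quantile: the ceil(q*n)-th smallest value."""
    vals = np.sort(np.asarray(values, dtype=float))
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError("no values")
    k = max(int(np.ceil(q * len(vals))), 1)
    return float(vals[k - 1])


@dataclass
class DeltaBandTable:
    """Depth-indexed symmetric null bands for |delta|, with interpolation."""

    depths: np.ndarray
    bands: Dict[float, np.ndarray]  # confidence -> band per depth

    def lookup(self, depth: np.ndarray, confidence: float) -> np.ndarray:
        if confidence not in self.bands:
            raise KeyError(f"no band tabulated at confidence {confidence}")
        return np.interp(depth, self.depths, self.bands[confidence])


def delta_null_band(
    bulk_size: int,
    depth: int,
    n_sim: int = 10_000,
    confidence: float = 0.95,
    seed: int = 0,
) -> float:
    """Monte-Carlo null quantile of |delta| for given bulk size and depth.

    Under H0 each bulk's allele frequency is drawn from 2*bulk_size fair
    F2 allele draws, then reads are Binomial(depth, freq); the band is the
    two-sided ``confidence`` quantile of |index_T - index_S|.
    """
    import warnings

    if bulk_size < 1 or depth < 1:
        raise ValueError("bulk_size and depth must be >= 1")
    if n_sim < 1000:
        warnings.warn("n_sim < 1000 gives unstable null bands", stacklevel=2)
    rng = np.random.default_rng(seed)
    m = 2 * bulk_size
    deltas = np.empty(n_sim)
    f_t = rng.binomial(m, 0.5, size=n_sim) / m
    f_s = rng.binomial(m, 0.5, size=n_sim) / m
    idx_t = rng.binomial(depth, f_t) / depth
    idx_s = rng.binomial(depth, f_s) / depth
    deltas = np.abs(idx_t - idx_s)
    return nearest_rank_quantile(deltas, confidence)


def build_delta_band_table(
    bulk_size: int,
    depths: Sequence[int] = (10, 20, 30, 50, 75, 100, 150, 200, 300),
    confidences: Sequence[float] = (0.95, 0.99),
    n_sim: int = 10_000,
    seed: int = 0,
) -> DeltaBandTable:
    bands = {
        conf: np.array(
            [
                delta_null_band(bulk_size, d, n_sim=n_sim, confidence=conf, seed=seed + i)
                for i, d in enumerate(depths)
            ]
        )
        for conf in confidences
    }
    return DeltaBandTable(depths=np.asarray(depths, dtype=float), bands=bands)


@dataclass
class ThresholdSet:
    """Per-method thresholds at each confidence, plus an optional delta band."""

    values: Dict[str, Dict[float, float]]
    delta_band: Optional[DeltaBandTable] = None

    def get(self, method: str, confidence: float) -> float:
        return self.values[method][confidence]


def empirical_thresholds(
    track: pd.DataFrame,
    confidences: Sequence[float] = (0.95, 0.99),
    min_windows: int = 100,
) -> ThresholdSet:
    """Genome-wide empirical quantiles of each method's windowed statistic.

    The upper tail is used for every method (|delta| for the SNP-index
    difference, whose extremes are two-sided).
    """
    values: Dict[str, Dict[float, float]] = {}
    for method in METHODS:
        col = METHOD_COLUMNS[method]
        vals = track[col].to_numpy(dtype=float)
        if method == "delta":
            vals = np.abs(vals)
        vals = vals[~np.isnan(vals)]
        if len(vals) < min_windows:
            raise ValueError(
                f"only {len(vals)} non-missing windows for {method}; need {min_windows}"
            )
        values[method] = {c: nearest_rank_quantile(vals, c) for c in confidences}
    return ThresholdSet(values=values)


def call_regions(
    track: pd.DataFrame,
    method: str,
    thresholds: ThresholdSet,
    confidence: float,
    min_region: int = 100_000,
    gap_windows: int = 1,
    use_delta_band: bool = True,
) -> List[CandidateRegion]:
    """Merge windows exceeding the method's threshold into maximal regions.

    Runs of significant windows tolerate gaps of up to ``gap_windows``
    non-significant windows; regions narrower than ``min_region`` bp are
    dropped. The delta method compares |delta| either against the
    depth-aware Monte-Carlo band (when available) or the empirical quantile.
    """
    col = METHOD_COLUMNS[method]
    regions: List[CandidateRegion] = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("start", kind="mergesort")
        vals = sub[col].to_numpy(dtype=float)
        score = np.abs(vals) if method == "delta" else vals
        if method == "delta" and use_delta_band and thresholds.delta_band is not None:
            depth = np.fmin(
                sub["t_depth"].to_numpy(dtype=float),
                sub["s_depth"].to_numpy(dtype=float),
            )
            thr = thresholds.delta_band.lookup(depth, confidence)
        else:
            thr = np.full(len(sub), thresholds.get(method, confidence))
        sig = np.where(np.isnan(score), False, score > thr)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()

        i = 0
        n = len(sig)
        while i < n:
            if not sig[i]:
                i += 1
                continue
            j = i
            last_sig = i
            while j + 1 < n:
                if sig[j + 1]:
                    j += 1
                    last_sig = j
                elif j + 1 - last_sig <= gap_windows and np.any(
                    sig[j + 2 : j + 2 + gap_windows]
                ):
                    j += 1
                else:
                    break
            run = slice(i, last_sig + 1)
            run_vals = vals[run]
            run_score = score[run]
            k = int(np.nanargmax(run_score))
            region = CandidateRegion(
                method=method,
                chrom=chrom,
                start=int(starts[run][0]),
                end=int(ends[run][-1]),
                peak=float(run_vals[k]),
                confidence=confidence,
            )
            if region.width >= min_region:
                regions.append(region)
            i = last_sig + 1
    return regions


def _interval_intersection(
    sets: Sequence[List[Tuple[int, int]]]
) -> List[Tuple[int, int]]:
    """Intersection of unions of 1-based closed intervals."""
    current = sorted(sets[0])
    for other in sets[1:]:
        other = sorted(other)
        merged = []
        for a_start, a_end in current:
            for b_start, b_end in other:
                lo, hi = max(a_start, b_start), min(a_end, b_end)
                if lo <= hi:
                    merged.append((lo, hi))
        current = sorted(merged)
        if not current:
            return []
    return current


def intersect_regions(
    regions_by_method: Dict[str, List[CandidateRegion]],
    required_methods: Optional[Sequence[str]] = None,
) -> List[ConsensusRegion]:
    """Per-chromosome interval intersection across the required methods.

    A consensus region exists only where every required method has a
    significant region; its peaks record, per method, the peak of the
    supporting region that contains it.
    """
    methods = tuple(required_methods) if required_methods else tuple(regions_by_method)
    chroms: List[str] = []
    for m in methods:
        for r in regions_by_method.get(m, []):
            if r.chrom not in chroms:
                chroms.append(r.chrom)
    out: List[ConsensusRegion] = []
    for chrom in chroms:
        per_method = []
        ok = True
        for m in methods:
            ivals = [
                (r.start, r.end)
                for r in regions_by_method.get(m, [])
                if r.chrom == chrom
            ]
            if not ivals:
                ok = False
                break
            per_method.append(ivals)
        if not ok:
            continue
        for lo, hi in _interval_intersection(per_method):
            peaks = {}
            for m in methods:
                for r in regions_by_method.get(m, []):
                    if r.chrom == chrom and r.start <= hi and r.end >= lo:
                        peaks[m] = r.peak
                        break
            region = ConsensusRegion(
                chrom=chrom, start=lo, end=hi, methods=methods, peaks=peaks
            )
            _assert_contained(region, regions_by_method)
            out.append(region)
    return out


def _assert_contained(
    region: ConsensusRegion, regions_by_method: Dict[str, List[CandidateRegion]]
) -> None:
    # consensus must be a subset of some supporting region of every method
    for m in region.methods:
        if not any(
            r.chrom == region.chrom and r.start <= region.start and r.end >= region.end
            for r in regions_by_method.get(m, [])
        ):
            raise AssertionError(
                f"consensus {region.chrom}:{region.start}-{region.end} "
                f"not contained in any {m} region"
            )


def regions_table(
    regions_by_method: Dict[str, List[CandidateRegion]],
    consensus: Sequence[ConsensusRegion],
) -> pd.DataFrame:
    """Flat report: one row per method region, with the overlap interval."""
    rows = []
    for method, regions in regions_by_method.items():
        for r in regions:
            overlap = ""
            for c in consensus:
                if c.chrom == r.chrom and c.start <= r.end and c.end >= r.start:
                    overlap = f"{(c.start - 1) / 1e6:.2f}-{c.end / 1e6:.2f}"
                    break
            rows.append(
                {
                    "method": method,
                    "confidence": r.confidence,
                    "chrom": r.chrom,
                    "start": r.start,
                    "end": r.end,
                    "peak": r.peak,
                    "overlap_mb": overlap,
                }
            )
    return pd.DataFrame(rows)
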