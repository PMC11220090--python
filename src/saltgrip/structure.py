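"""Contact-map analytics: O/E normalization, insulation, pileups and APA.

Conventions.  The expected signal e(d) is the mean count at diagonal offset d,
so O/E is self-normalizing per distance.  The insulation score of bin b is the
mean count in the diamond {i in (b-w, b], j in (b, b+w]}, reported as log2 of
its ratio to the chromosome-wide mean diamond score: LOWER score = stronger
boundary.  Boundary weakening therefore shows up as a positive score delta.
Per-loop APA strength is the mean O/E over the center 3x3 pixels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats

from .core import ContactMatrix, GenomicInterval


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, ContactMatrix):
        return m.matrix
    return np.asarray(m, dtype=float)


def expected_by_distance(m) -> tuple[np.ndarray, np.ndarray]:
    """Mean contact count per diagonal offset, plus the normalized P(s) curve.

    Returns (e, p) where e[d] = mean over bins of M[i, i+d] and p = e / sum(e).
    """
    mat = _as_matrix(m)
    n = mat.shape[0]
    if n == 0:
        raise ValueError("empty contact matrix")
    e = np.array([np.mean(np.diagonal(mat, d)) for d in range(n)])
    total = e.sum()
    p = e / total if total > 0 else np.zeros_like(e)
    return e, p


def oe_normalize(m) -> np.ndarray:
    """Observed-over-expected matrix; cells at distances with e(d)=0 are NaN."""
    mat = _as_matrix(m)
    e, _ = expected_by_distance(mat)
    n = mat.shape[0]
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    denom = e[d]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(denom > 0, mat / np.where(denom > 0, denom, 1.0), np.nan)
    return oe


def insulation_score(m, window_bins: int = 5) -> np.ndarray:
    """Diamond insulation score per bin (log2 vs chromosome mean).

    Edge bins within ``window_bins`` of either end are NaN.  Lower = more
    insulated (stronger boundary) under this convention.
    """
    mat = _as_matrix(m)
    n = mat.shape[0]
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    if n < 3 * window_bins:
        raise ValueError("matrix too small for the insulation window")
    w = window_bins
    raw = np.full(n, np.nan)
    for b in range(w, n - w):
        raw[b] = mat[b - w + 1 : b + 1, b + 1 : b + w + 1].mean()
    valid = np.isfinite(raw) & (raw > 0)
    mean_raw = np.nanmean(raw[np.isfinite(raw)])
    if not np.isfinite(mean_raw) or mean_raw <= 0:
        raise ValueError("degenerate matrix: zero mean diamond score")
    out = np.full(n, np.nan)
    out[valid] = np.log2(raw[valid] / mean_raw)
    return out


def find_boundaries(scores: np.ndarray, prominence: float = 0.2) -> np.ndarray:
    """Local minima of the insulation score with at least ``prominence``
    depth (on the log2 scale)."""
    filled = np.where(np.isfinite(scores), scores, np.nanmax(scores[np.isfinite(scores)]))
    minima, _ = _signal.find_peaks(-filled, prominence=prominence)
    return minima


def boundary_delta_test(
    is_a: np.ndarray,
    is_b: np.ndarray,
    groups: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Per-group paired test of insulation-score change between conditions.

    delta(b) = IS_B(b) - IS_A(b) at each boundary bin; the one-sided paired
    t-test targets weakening (delta > 0 under the lower-is-stronger
    convention).  Groups with zero delta variance surface p = NaN explicitly.
    """
    is_a = np.asarray(is_a, dtype=float)
    is_b = np.asarray(is_b, dtype=float)
    if is_a.shape != is_b.shape:
        raise ValueError("insulation tracks must cover the same bins")
    rows = []
    for name, bins in groups.items():
        bins = np.asarray(bins, dtype=int)
        if len(bins) < 2:
            raise ValueError(f"group {name!r} needs >= 2 boundaries")
        delta = is_b[bins] - is_a[bins]
        if not np.isfinite(delta).all():
            raise ValueError(f"group {name!r} hits edge bins with undefined scores")
        sd = delta.std(ddof=1)
        if sd == 0:
            t_stat, pval = np.nan, (1.0 if np.allclose(delta, 0) else np.nan)
        else:
            t_stat = delta.mean() / (sd / np.sqrt(len(delta)))
            pval = float(stats.t.sf(t_stat, df=len(delta) - 1))
        rows.append(
            {
                "group": name,
                "n": len(delta),
                "mean_delta": float(delta.mean()),
                "t": t_stat,
                "p_value": pval,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def local_pileup(
    oe: np.ndarray, centers: np.ndarray, flank_bins: int
) -> np.ndarray:
    """NaN-aware mean of O/E submatrices centered on the diagonal at each
    center bin.  Windows falling outside the matrix are skipped; all out of
    range is an error."""
    oe = np.asarray(oe, dtype=float)
    n = oe.shape[0]
    f = flank_bins
    stack = []
    for c in np.asarray(centers, dtype=int):
        if c - f < 0 or c + f + 1 > n:
            continue
        stack.append(oe[c - f : c + f + 1, c - f : c + f + 1])
    if not stack:
        raise ValueError("all pileup windows fall outside the matrix")
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.stack(stack), axis=0)


def apa(
    oe: np.ndarray,
    loops: pd.DataFrame,
    flank_bins: int = 20,
) -> dict:
    """Aggregate peak analysis over loop pixel neighborhoods.

    loops needs bin_i < bin_j columns.  Returns the aggregate (2*flank+1)^2
    map, per-loop center scores (mean O/E over the center 3x3), and the count
    of loops skipped for falling too close to the matrix edge.
    """
    if not len(loops):
        raise ValueError("no loops supplied")
    oe = np.asarray(oe, dtype=float)
    n = oe.shape[0]
    f = flank_bins
    stack, scores, keep_idx = [], [], []
    for row in loops.itertuples():
        i, j = int(row.bin_i), int(row.bin_j)
        if i >= j:
            raise ValueError("loops must satisfy bin_i < bin_j")
        if i - f < 0 or j + f + 1 > n:
            continue
        sub = oe[i - f : i + f + 1, j - f : j + f + 1]
        stack.append(sub)
        scores.append(float(np.nanmean(oe[i - 1 : i + 2, j - 1 : j + 2])))
        keep_idx.append(row.Index)
    skipped = len(loops) - len(stack)
    if not stack:
        raise ValueError("every loop fell too close to the matrix edge")
    with np.errstate(invalid="ignore"):
        agg = np.nanmean(np.stack(stack), axis=0)
    return {
        "map": agg,
        "scores": pd.Series(scores, index=keep_idx, name="apa_score"),
        "skipped": skipped,
    }


def apa_group_test(scores_x: pd.Series, scores_y: pd.Series) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two groups' loop scores."""
    return float(stats.ranksums(scores_x.to_numpy(), scores_y.to_numpy()).pvalue)


def positional_enrichment(
    sites: list[GenomicInterval] | pd.DataFrame,
    domains: list[GenomicInterval] | pd.DataFrame,
    n_bins: int = 100,
    pad_bins: int = 10,
) -> np.ndarray:
    """Per-bin count of overlapping site centers per 1000 domains.

    Each domain is scaled to ``n_bins`` interior bins plus ``pad_bins``
    flanking bins on each side, each flank bin as wide as an interior bin
    (domain_length / n_bins).  Index pad_bins is the first interior bin (the
    domain start).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")

    def _frame(x, what):
        if isinstance(x, pd.DataFrame):
            return x
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in x],
                "start": [iv.start for iv in x],
                "end": [iv.end for iv in x],
            }
        )

    site_df = _frame(sites, "sites")
    dom_df = _frame(domains, "domains")
    if not len(dom_df):
        raise ValueError("domains must be non-empty")
    if ((dom_df["end"] - dom_df["start"]) <= 0).any():
        raise ValueError("zero-length domain")
    total_bins = n_bins + 2 * pad_bins
    counts = np.zeros(total_bins)
    centers = ((site_df["start"] + site_df["end"]) // 2).to_numpy()
    chroms = site_df["chrom"].to_numpy()
    for dom in dom_df.itertuples(index=False):
        width = (dom.end - dom.start) / n_bins
        ext_start = dom.start - pad_bins * width
        sel = chroms == dom.chrom
        rel = (centers[sel] - ext_start) / width
        idx = np.floor(rel).astype(int)
        ok = (idx >= 0) & (idx < total_bins)
        np.add.at(counts, idx[ok], 1.0)
    return counts * 1000.0 / len(dom_df)
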