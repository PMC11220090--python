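"""Per-motif signal quantification, peak calling and salt-series classification.

The peak caller is a transparent Poisson model: per-bin counts are tested
against the larger of the chromosome-wide mean and a local (10 kb) mean,
BH-corrected, and significant bins merged.  It replaces a model-based caller
because the analyses downstream only need reproducible peak sets with a
controlled type-I property on the Poisson synthetic data.

Salt-nesting classes follow the perturbation-series logic: N1 sites keep
occupancy at all three salt stringencies, N2 at the lower two, N3 only at the
lowest; X sites appear only in crosslinked (X-ChIP) peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import FragmentSet, SignalTrack


@dataclass
class PeakSet:
    """Called peaks for one condition: merged intervals with summit + score."""

    condition: str
    frame: pd.DataFrame  # chrom, start, end, summit, score

    def __len__(self) -> int:
        return len(self.frame)

    def membership(self, chroms: np.ndarray, points: np.ndarray) -> np.ndarray:
        """True where point (bp) falls inside a peak of this set."""
        out = np.zeros(len(points), dtype=bool)
        for chrom, grp in self.frame.groupby("chrom"):
            sel = chroms == chrom
            if not sel.any():
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
            idx = np.searchsorted(starts, points[sel], side="right") - 1
            ok = idx >= 0
            hit = np.zeros(sel.sum(), dtype=bool)
            hit[ok] = points[sel][ok] < ends[idx[ok]]
            out[sel] = hit
        return out


def quantify_signal_matrix(
    libraries: dict[str, FragmentSet | list[FragmentSet]],
    motifs: pd.DataFrame,
    window: int = 80,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """RPM fragment counts in motif center +/- window/2, per condition.

    Replicate lists are pooled by concatenation before normalization.  Returns
    a motifs x conditions DataFrame indexed by motif_id, columns in the order
    given (callers pass increasing stringency first).
    """
    if window < (motifs["end"] - motifs["start"]).max():
        raise ValueError("window must be >= motif width")
    centers = ((motifs["start"] + motifs["end"]) // 2).to_numpy()
    chroms = motifs["chrom"].to_numpy()
    half = window // 2
    win_start = centers - half
    win_end = centers + half
    if (win_start < 0).any():
        raise ValueError("motif window extends past the chromosome start")
    if chrom_sizes:
        sizes = np.array([chrom_sizes[c] for c in chroms])
        if (win_end > sizes).any():
            raise ValueError("motif window extends past the chromosome end")
    out = {}
    for cond, libs in libraries.items():
        frags = (
            FragmentSet.concat(libs, condition=cond)
            if isinstance(libs, list)
            else libs
        )
        if frags.total == 0:
            raise ValueError(f"empty library for condition {cond!r}")
        counts = np.zeros(len(motifs))
        for chrom, grp in frags.frame.groupby("chrom"):
            sel = chroms == chrom
            if not sel.any():
                continue
            starts = np.sort(grp["start"].to_numpy())
            ends = np.sort(grp["end"].to_numpy())
            # overlap count = #(start < win_end) - #(end <= win_start)
            n_start = np.searchsorted(starts, win_end[sel], side="left")
            n_end = np.searchsorted(ends, win_start[sel], side="right")
            counts[sel] = n_start - n_end
        out[cond] = counts * 1e6 / frags.total
    return pd.DataFrame(out, index=motifs["motif_id"].to_numpy())


def call_peaks(
    track: SignalTrack,
    q_cut: float = 0.01,
    merge_gap: int = 100,
    local_window: int = 10_000,
) -> PeakSet:
    """Poisson peak caller on a raw binned count track.

    Per bin, a one-sided Poisson p-value against max(global mean, local mean
    over ``local_window`` bp) is BH-adjusted; bins at q <= q_cut are merged
    when closer than ``merge_gap`` bp, with the argmax bin as summit.
    """
    if track.normalization != "raw":
        raise ValueError("peak calling requires a raw count track")
    if not (0.0 < q_cut < 1.0):
        raise ValueError("q_cut must be in (0, 1)")
    all_p = []
    per_chrom = {}
    for chrom, vals in track.values.items():
        if not len(vals):
            continue
        global_mean = vals.mean()
        w = max(local_window // track.bin, 1)
        from scipy.ndimage import uniform_filter1d

        local_mean = uniform_filter1d(vals, size=w, mode="nearest")
        lam = np.maximum(global_mean, local_mean)
        pvals = stats.poisson.sf(vals - 1, lam)
        per_chrom[chrom] = pvals
        all_p.append(pvals)
    if not all_p or all(
        not np.any(track.values[c]) for c in track.values
    ):
        return PeakSet(condition="", frame=_empty_peaks())
    flat = np.concatenate(all_p)
    qvals = multipletests(flat, method="fdr_bh")[1]
    rows = []
    pos = 0
    gap_bins = max(merge_gap // track.bin, 1)
    for chrom, pvals in per_chrom.items():
        q = qvals[pos : pos + len(pvals)]
        pos += len(pvals)
        sig = np.flatnonzero(q <= q_cut)
        if not len(sig):
            continue
        breaks = np.flatnonzero(np.diff(sig) > gap_bins)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(sig) - 1]])
        vals = track.values[chrom]
        for a, b in zip(starts, ends):
            b0, b1 = sig[a], sig[b]
            summit_bin = b0 + int(np.argmax(vals[b0 : b1 + 1]))
            rows.append(
                (
                    chrom,
                    int(b0) * track.bin,
                    (int(b1) + 1) * track.bin,
                    summit_bin * track.bin + track.bin // 2,
                    float(vals[summit_bin]),
                )
            )
    frame = (
        pd.DataFrame(rows, columns=["chrom", "start", "end", "summit", "score"])
        if rows
        else _empty_peaks()
    )
    return PeakSet(condition="", frame=frame)


def _empty_peaks() -> pd.DataFrame:
    return pd.DataFrame(columns=["chrom", "start", "end", "summit", "score"])


def classify_salt_nesting(
    peaks: dict[str, PeakSet],
    xchip: PeakSet,
    motifs: pd.DataFrame,
    salt_order: list[str] | None = None,
) -> tuple[pd.Series, dict]:
    """Classify motifs into N1/N2/N3/X/none from salt-series + X-ChIP peaks.

    Membership is motif center within a peak interval.  N1 = in all three salt
    peak sets; N2 = low+mid only; N3 = low only; X = only in X-ChIP peaks.
    Nesting violations (present at a higher salt but absent at a lower one)
    are counted in the report and classified by the highest salt reached.
    """
    order = salt_order or list(peaks)
    if len(order) != 3:
        raise ValueError("exactly three native salt conditions are required")
    centers = ((motifs["start"] + motifs["end"]) // 2).to_numpy()
    chroms = motifs["chrom"].to_numpy()
    member = np.stack(
        [peaks[cond].membership(chroms, centers) for cond in order], axis=1
    )
    in_x = xchip.membership(chroms, centers)
    n_in = member.sum(axis=1)
    highest = np.where(
        member[:, 2], 3, np.where(member[:, 1], 2, np.where(member[:, 0], 1, 0))
    )
    # nesting-consistent membership count equals the highest salt reached
    violations = highest != n_in
    labels = np.full(len(motifs), "none", dtype=object)
    labels[highest == 3] = "N1"
    labels[highest == 2] = "N2"
    labels[highest == 1] = "N3"
    labels[(highest == 0) & in_x] = "X"
    report = {
        "nesting_violations": int(violations.sum()),
        "violation_motifs": motifs.loc[violations, "motif_id"].tolist(),
    }
    return pd.Series(labels, index=motifs["motif_id"].to_numpy()), report


def differential_sites(
    counts_a: pd.Series,
    counts_b: pd.Series,
    fdr_cut: float = 0.05,
    lfc_cut: float = 1.0,
) -> pd.DataFrame:
    """Classify motifs as lost/stable/gained between conditions A and B.

    Raw per-motif fragment counts are compared by a two-sided binomial test of
    B against the library-size expectation (count_b | n=a+b, p=depth_b/depth),
    BH-corrected.  Significant sites with log2FC <= -lfc_cut are lost, with
    log2FC >= +lfc_cut gained, else stable.  Defaults: FDR < 0.05, |log2FC| >= 1.
    """
    counts_a, counts_b = counts_a.align(counts_b, join="inner")
    tot_a, tot_b = float(counts_a.sum()), float(counts_b.sum())
    if tot_a == 0 or tot_b == 0:
        raise ValueError("zero total count in one condition")
    a = counts_a.to_numpy(dtype=float)
    b = counts_b.to_numpy(dtype=float)
    p0 = tot_b / (tot_a + tot_b)
    n = (a + b).astype(int)
    pvals = np.ones(len(n))
    nonzero = n > 0
    for i in np.flatnonzero(nonzero):
        pvals[i] = stats.binomtest(int(b[i]), int(n[i]), p0).pvalue
    qvals = multipletests(pvals, method="fdr_bh")[1]
    # depth-scaled fold change with half-count continuity correction at zeros
    rate_a = np.where(a > 0, a, 0.5) / tot_a
    rate_b = np.where(b > 0, b, 0.5) / tot_b
    lfc = np.log2(rate_b / rate_a)
    status = np.full(len(n), "stable", dtype=object)
    status[(qvals <= fdr_cut) & (lfc <= -lfc_cut)] = "lost"
    status[(qvals <= fdr_cut) & (lfc >= lfc_cut)] = "gained"
    return pd.DataFrame(
        {
            "count_a": a,
            "count_b": b,
            "log2fc": lfc,
            "p_value": pvals,
            "q_value": qvals,
            "status": status,
        },
        index=counts_a.index,
    )
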