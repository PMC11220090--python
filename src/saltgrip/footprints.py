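"""V-plot footprint analysis and strand-oriented fragment-end pileups.

A V-plot is the 2-D histogram of fragment length against the offset of the
fragment midpoint from a site center.  Protein-bound sites protect a short
footprint, so spanning fragments pile up inside the "V" (length >= twice the
absolute offset) while digestion carves out the vacancy around it.  Fragment
midpoints of even-length fragments round down; this single convention is used
everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FragmentSet, GenomicInterval


@dataclass
class VPlot:
    """counts[length-1, offset+F] over lengths 1..Lmax, offsets -F..+F."""

    counts: np.ndarray
    lmax: int
    flank: int
    n_sites: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def lengths(self) -> np.ndarray:
        return np.arange(1, self.lmax + 1)

    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def modal_length(self) -> int:
        """Fragment length with the largest marginal count."""
        marg = self.counts.sum(axis=1)
        return int(np.argmax(marg)) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.lengths(), columns=self.offsets())

    def plot(self, ax=None, **imshow_kw):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.imshow(
            self.counts, origin="lower", aspect="auto",
            extent=(-self.flank - 0.5, self.flank + 0.5, 0.5, self.lmax + 0.5),
            **imshow_kw,
        )
        ax.set_xlabel("midpoint offset from site center (bp)")
        ax.set_ylabel("fragment length (bp)")
        return ax


def _site_centers(sites) -> pd.DataFrame:
    if isinstance(sites, pd.DataFrame):
        frame = sites
        centers = ((frame["start"] + frame["end"]) // 2).to_numpy()
        chroms = frame["chrom"].to_numpy()
    else:
        centers = np.array([s.center for s in sites])
        chroms = np.array([s.chrom for s in sites])
    return pd.DataFrame({"chrom": chroms, "center": centers})


def compute_vplot(
    frags: FragmentSet,
    sites: list[GenomicInterval] | pd.DataFrame,
    lmax: int = 120,
    flank: int = 100,
) -> VPlot:
    """Accumulate (length, midpoint-offset) counts over all (fragment, site)
    pairs with |midpoint - center| <= flank and length <= lmax."""
    if lmax < 1 or flank < 1:
        raise ValueError("lmax and flank must be >= 1")
    site_df = _site_centers(sites)
    if not len(site_df):
        raise ValueError("sites must be non-empty")
    counts = np.zeros((lmax, 2 * flank + 1), dtype=np.int64)
    for chrom, grp in frags.frame.groupby("chrom"):
        centers = np.sort(
            site_df.loc[site_df["chrom"] == chrom, "center"].to_numpy()
        )
        if not len(centers):
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        mids = (starts + ends) // 2
        lengths = ends - starts
        ok = lengths <= lmax
        mids, lengths = mids[ok], lengths[ok]
        lo = np.searchsorted(centers, mids - flank, side="left")
        hi = np.searchsorted(centers, mids + flank, side="right")
        n_pairs = hi - lo
        frag_idx = np.repeat(np.arange(len(mids)), n_pairs)
        site_idx = np.concatenate(
            [np.arange(a, b) for a, b in zip(lo, hi)]
        ) if len(mids) else np.empty(0, dtype=int)
        offs = mids[frag_idx] - centers[site_idx]
        keep = np.abs(offs) <= flank
        np.add.at(counts, (lengths[frag_idx][keep] - 1, offs[keep] + flank), 1)
    return VPlot(counts=counts, lmax=lmax, flank=flank, n_sites=len(site_df))


def inside_v_fraction(vp: VPlot, lv: int = 120) -> float:
    """Fraction of plotted fragments inside the V triangle: fragments that span
    the site center (length >= 2|offset|) with length <= lv."""
    if lv > vp.lmax:
        raise ValueError("lv must not exceed the V-plot's lmax")
    total = vp.counts.sum()
    if total == 0:
        raise ValueError("empty V-plot: inside-V fraction undefined")
    lengths = vp.lengths()[:, None]
    offsets = vp.offsets()[None, :]
    mask = (lengths >= 2 * np.abs(offsets)) & (lengths <= lv)
    return float(vp.counts[mask].sum() / total)


def fragment_length_histogram(frags: FragmentSet) -> dict[int, int]:
    """Exact multiset histogram of fragment lengths."""
    if frags.total == 0:
        raise ValueError("empty fragment set")
    vals, cnts = np.unique(frags.lengths(), return_counts=True)
    return {int(v): int(c) for v, c in zip(vals, cnts)}


@dataclass
class EndProfile:
    """Scaled 5'/3' fragment-end pileups over offsets -F..+F around motifs.

    Profiles are RPM-normalized then divided by the half-mean of the summed
    (5'+3') profile over the 2F window, so that after scaling the mean of
    (5'+3') over the window is exactly 2.
    """

    five: np.ndarray
    three: np.ndarray
    flank: int
    scale: float

    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets(), "five_prime": self.five, "three_prime": self.three}
        )


def end_pileup_scaled(
    frags: FragmentSet,
    motifs: pd.DataFrame,
    flank: int = 100,
    lcap: int = 120,
) -> EndProfile:
    """Oriented digestion-boundary profile around motif centers.

    Fragments of length <= lcap whose nearest motif center lies within
    ``flank`` are kept; for minus-strand motifs the 5'/3' roles are swapped
    and offsets negated, so all fragments share the motif orientation.  The 3'
    end is the last covered base of the half-open interval.  Nearest-motif
    ties break toward the smaller genomic coordinate.
    """
    if "strand" not in motifs.columns:
        raise ValueError("motif frame must carry a strand column")
    five = np.zeros(2 * flank + 1)
    three = np.zeros(2 * flank + 1)
    kept = 0
    for chrom, grp in frags.frame.groupby("chrom"):
        sub = motifs[motifs["chrom"] == chrom]
        if not len(sub):
            continue
        order = np.argsort(((sub["start"] + sub["end"]) // 2).to_numpy(), kind="stable")
        centers = ((sub["start"] + sub["end"]) // 2).to_numpy()[order]
        strands = sub["strand"].to_numpy()[order]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        lengths = ends - starts
        ok = lengths <= lcap
        starts, ends = starts[ok], ends[ok]
        mids = (starts + ends) // 2
        # nearest center, ties toward the smaller coordinate
        pos = np.searchsorted(centers, mids)
        left = np.clip(pos - 1, 0, len(centers) - 1)
        right = np.clip(pos, 0, len(centers) - 1)
        dl = np.abs(mids - centers[left])
        dr = np.abs(mids - centers[right])
        nearest = np.where(dl <= dr, left, right)
        near_c = centers[nearest]
        keep = np.abs(mids - near_c) <= flank
        starts, ends, near = starts[keep], ends[keep], nearest[keep]
        near_c = near_c[keep]
        minus = strands[near] == "-"
        o5 = np.where(minus, -(ends - 1 - near_c), starts - near_c)
        o3 = np.where(minus, -(starts - near_c), ends - 1 - near_c)
        for off, arr in ((o5, five), (o3, three)):
            inw = np.abs(off) <= flank
            np.add.at(arr, off[inw] + flank, 1.0)
        kept += int(keep.sum())
    if kept == 0:
        raise ValueError("no fragment passed the end-pileup filters")
    rpm = 1e6 / frags.total
    five *= rpm
    three *= rpm
    scale = float((five + three).mean() / 2.0)
    if scale <= 0:
        raise ValueError("degenerate end profile: zero total signal in window")
    return EndProfile(five=five / scale, three=three / scale, flank=flank, scale=scale)
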