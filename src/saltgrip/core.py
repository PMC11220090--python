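"""Core in-memory containers shared across the pipeline.

All genomic coordinates are 0-based, half-open ``[start, end)`` — the single
dialect used everywhere in this package.  Fragments are unstranded; strand
enters only through motif orientation at analysis time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded interval on a named chromosome (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Midpoint, rounding down for even lengths (fixed convention)."""
        return (self.start + self.end) // 2


_FRAG_COLS = ["chrom", "start", "end"]


class FragmentSet:
    """Sequenced fragment intervals for one library/condition.

    Parameters
    ----------
    frame : DataFrame with columns chrom, start, end (0-based half-open).
    condition : library label, e.g. ``"75mM"`` or ``"xchip"``.
    """

    def __init__(self, frame: pd.DataFrame, condition: str = "") -> None:
        missing = [c for c in _FRAG_COLS if c not in frame.columns]
        if missing:
            raise ValueError(f"fragment frame missing columns {missing}")
        frame = frame[_FRAG_COLS].reset_index(drop=True)
        if len(frame):
            starts = frame["start"].to_numpy()
            ends = frame["end"].to_numpy()
            if (starts < 0).any() or (starts >= ends).any():
                bad = int(np.argmax((starts < 0) | (starts >= ends)))
                raise ValueError(f"invalid fragment at row {bad}")
        self.frame = frame
        self.condition = condition

    @property
    def total(self) -> int:
        return len(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    def lengths(self) -> np.ndarray:
        return (self.frame["end"] - self.frame["start"]).to_numpy()

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(c, int(s), int(e))
            for c, s, e in self.frame.itertuples(index=False)
        ]

    @classmethod
    def concat(cls, sets: list["FragmentSet"], condition: str = "") -> "FragmentSet":
        """Pool replicate libraries before normalization."""
        frames = [s.frame for s in sets]
        return cls(pd.concat(frames, ignore_index=True), condition=condition)


@dataclass
class SignalTrack:
    """Binned per-chromosome signal values.

    values maps chromosome name to a float array of per-bin values; bin is the
    bin width in bp; normalization is ``"raw"`` or ``"RPM"``.
    """

    values: dict[str, np.ndarray]
    bin: int
    normalization: str = "raw"

    def __post_init__(self) -> None:
        if self.bin < 1:
            raise ValueError("bin width must be >= 1")
        if self.normalization not in ("raw", "RPM"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite signal values on {chrom}")
            if self.normalization == "raw" and (arr < 0).any():
                raise ValueError(f"negative raw counts on {chrom}")
            self.values[chrom] = arr


@dataclass
class ContactMatrix:
    """Binned symmetric chromatin-contact counts for one chromosome.

    matrix is dense and symmetric; weights holds optional balancing weights
    (reserved for real data; synthetic matrices have uniform coverage).
    """

    chrom: str
    resolution: int
    matrix: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("contact matrix must be symmetric")
        if (m < 0).any():
            raise ValueError("contact counts must be >= 0")
        self.matrix = m
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (m.shape[0],):
                raise ValueError("weights length must match matrix size")
            if np.any(w[np.isfinite(w)] <= 0):
                raise ValueError("weights must be > 0 where defined")
            self.weights = w

    @property
    def nbins(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside synthetic data.

    motifs: one row per motif (motif_id, retention, transient, has_U, has_D).
    boundaries: boundary bin index, anchor motif id (-1 if none), depth.
    loops: anchor bins, anchor motif id, baseline strength.
    """

    motifs: pd.DataFrame
    boundaries: pd.DataFrame = field(default_factory=pd.DataFrame)
    loops: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        req = {"motif_id", "retention", "transient", "has_U", "has_D"}
        missing = req - set(self.motifs.columns)
        if missing:
            raise ValueError(f"truth table missing columns {sorted(missing)}")
        r = self.motifs["retention"].to_numpy(dtype=float)
        t = self.motifs["transient"].to_numpy(dtype=float)
        if not (np.isfinite(r).all() and np.isfinite(t).all()):
            raise ValueError("retention/transient must be finite")
        if (r < 0).any() or (r > 1).any():
            raise ValueError("retention must lie in [0, 1]")
        if (t < 0).any():
            raise ValueError("transient rate must be >= 0")
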