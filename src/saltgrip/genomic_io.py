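"""Readers/writers and coverage primitives for the standard formats used here.

BED is parsed strictly: malformed lines raise with the offending line number
rather than being coerced.  Contact matrices travel as sparse triplet TSV with
a header line declaring resolution, chromosome and bin count.
"""

from __future__ import annotations

import io as _stdio
import os
import re

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ContactMatrix, FragmentSet, GenomicInterval, SignalTrack, STRANDS


class BedParseError(ValueError):
    pass


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED3/BED6 into GenomicInterval records (strict parsing)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            strand = "."
            if len(fields) >= 6:
                strand = fields[5]
                if strand not in STRANDS:
                    raise BedParseError(
                        f"{path}: line {lineno}: unknown strand {strand!r}"
                    )
            try:
                out.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: list[GenomicInterval], path: str | os.PathLike) -> None:
    """Write BED6 (name='.', score=0)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def read_fragments(path: str | os.PathLike, condition: str = "") -> FragmentSet:
    ivs = read_bed(path)
    frame = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in ivs],
            "start": [iv.start for iv in ivs],
            "end": [iv.end for iv in ivs],
        }
    )
    return FragmentSet(frame, condition=condition)


def write_fragments(frags: FragmentSet, path: str | os.PathLike) -> None:
    # valid (possibly empty) BED even for depth-0 libraries
    frags.frame.to_csv(path, sep="\t", header=False, index=False)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# coverage


def compute_coverage(
    frags: FragmentSet,
    bin: int = 1,
    normalize: bool = False,
    chrom_sizes: dict[str, int] | None = None,
) -> SignalTrack:
    """Per-bin fragment overlap counts, optionally scaled to reads per million.

    A fragment contributes 1 to every bin it overlaps.  The RPM denominator is
    the library's retained fragment count, fixed at read time.
    """
    if bin < 1:
        raise ValueError("bin width must be >= 1")
    if normalize and frags.total == 0:
        raise ValueError("cannot RPM-normalize an empty fragment library")
    sizes: dict[str, int] = dict(chrom_sizes or {})
    if not sizes:
        for chrom, grp in frags.frame.groupby("chrom"):
            sizes[chrom] = int(grp["end"].max())
    values: dict[str, np.ndarray] = {}
    for chrom, size in sizes.items():
        nbins = (size + bin - 1) // bin
        arr = np.zeros(nbins + 1)
        grp = frags.frame[frags.frame["chrom"] == chrom]
        if len(grp):
            b0 = grp["start"].to_numpy() // bin
            b1 = (grp["end"].to_numpy() - 1) // bin  # inclusive last bin
            b1 = np.minimum(b1, nbins - 1)
            np.add.at(arr, b0, 1.0)
            np.add.at(arr, b1 + 1, -1.0)
        values[chrom] = np.cumsum(arr[:-1])
    if normalize:
        scale = 1e6 / frags.total
        values = {c: v * scale for c, v in values.items()}
    return SignalTrack(values, bin=bin, normalization="RPM" if normalize else "raw")


def write_bedgraph(track: SignalTrack, path: str | os.PathLike) -> None:
    """0-based half-open bedGraph, one line per non-zero run of bins."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            vals = track.values[chrom]
            if not len(vals):
                continue
            # run-length encode constant stretches
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(vals)]])
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    fh.write(
                        f"{chrom}\t{s * track.bin}\t{e * track.bin}\t{v:.6g}\n"
                    )


# ---------------------------------------------------------------------------
# contact triplet TSV

_HEADER_RE = re.compile(
    r"^#\s*resolution=(\d+)\s+chrom=(\S+)\s+nbins=(\d+)\s*$"
)


def read_contact_tsv(path: str | os.PathLike) -> ContactMatrix:
    """Read a sparse triplet TSV into a dense symmetric ContactMatrix.

    The first line must be ``# resolution=<bp> chrom=<name> nbins=<n>``.
    Missing pairs are 0; i>j triplets are folded into the upper triangle and
    duplicate (i, j) entries are summed.
    """
    with open(path) as fh:
        header = fh.readline()
        m = _HEADER_RE.match(header.strip())
        if not m:
            raise ValueError(f"{path}: missing or malformed contact header line")
        resolution, chrom, nbins = int(m.group(1)), m.group(2), int(m.group(3))
        body = fh.read()
    mat = np.zeros((nbins, nbins))
    if body.strip():
        trip = pd.read_csv(
            _stdio.StringIO(body), sep="\t", header=None,
            names=["i", "j", "count"],
        )
        ii = trip["i"].to_numpy(dtype=int)
        jj = trip["j"].to_numpy(dtype=int)
        cc = trip["count"].to_numpy(dtype=float)
        if (ii < 0).any() or (jj < 0).any() or (ii >= nbins).any() or (jj >= nbins).any():
            raise ValueError(f"{path}: triplet index outside [0, {nbins})")
        lo, hi = np.minimum(ii, jj), np.maximum(ii, jj)
        np.add.at(mat, (lo, hi), cc)
        mat = mat + np.triu(mat, 1).T
    return ContactMatrix(chrom=chrom, resolution=resolution, matrix=mat)


def write_contact_tsv(cm: ContactMatrix, path: str | os.PathLike) -> None:
    """Write the upper triangle (incl. diagonal) as sparse triplets."""
    with open(path, "w") as fh:
        fh.write(f"# resolution={cm.resolution} chrom={cm.chrom} nbins={cm.nbins}\n")
        iu, ju = np.triu_indices(cm.nbins)
        vals = cm.matrix[iu, ju]
        nz = vals != 0
        for i, j, v in zip(iu[nz], ju[nz], vals[nz]):
            fh.write(f"{i}\t{j}\t{v:.10g}\n")
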