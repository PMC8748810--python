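"""Library-size-normalised binned coverage (RPM) and TSS metaprofiles.

Reads are supplied as intervals; coverage is fractional by base-pair overlap
with each bin, so a read straddling two 10-bp bins contributes to both in
proportion.  Bin values are reads-per-million: (overlapping read-bp /
bin_size) × 1e6 / library_size, which makes one fully-contained read of
exactly bin_size length in a library of one million reads equal 1.0 RPM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .intervals import GeneModel, GenomicInterval, IntervalSet

__all__ = [
    "SignalTrack",
    "binned_rpm",
    "median_track",
    "region_signal",
    "tss_metaprofile",
    "read_bedgraph",
    "write_bedgraph",
]


@dataclass
class SignalTrack:
    assembly: dict[str, int]
    bin_size: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def n_bins(self, chrom: str) -> int:
        return -(-self.assembly[chrom] // self.bin_size)  # ceil division

    def total_mass(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))


def binned_rpm(
    read_intervals: IntervalSet,
    bin_size: int = 10,
    library_size: int | None = None,
) -> SignalTrack:
    """Bin read coverage and scale to reads-per-million.

    ``library_size`` defaults to the number of reads supplied; passing the
    true sequenced library size reproduces the scaling of coverage tools that
    normalise by 1e6 / library_size.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if library_size is None:
        library_size = len(read_intervals)
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    scale = 1e6 / (library_size * bin_size)
    track = SignalTrack(dict(read_intervals.assembly), bin_size)
    by_chrom = read_intervals.by_chrom()
    for chrom, length in track.assembly.items():
        nb = track.n_bins(chrom)
        reads = by_chrom.get(chrom, [])
        if not reads:
            track.values[chrom] = np.zeros(nb)
            continue
        # per-base coverage via +1/-1 difference array, then bin sums
        diff = np.zeros(nb * bin_size + 1)
        starts = np.fromiter((iv.start for iv in reads), dtype=np.int64, count=len(reads))
        ends = np.fromiter((iv.end for iv in reads), dtype=np.int64, count=len(reads))
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
        cov = np.cumsum(diff[:-1])
        track.values[chrom] = cov.reshape(nb, bin_size).sum(axis=1) * scale
    return track


def median_track(tracks: Sequence[SignalTrack]) -> SignalTrack:
    """Bin-wise median across replicate tracks (computed before any region
    summarisation, so per-region medians see the combined signal)."""
    if not tracks:
        raise ValueError("no tracks")
    first = tracks[0]
    for t in tracks[1:]:
        if t.bin_size != first.bin_size or t.assembly != first.assembly:
            raise ValueError("tracks differ in bin size or assembly")
    out = SignalTrack(dict(first.assembly), first.bin_size)
    for chrom in first.assembly:
        out.values[chrom] = np.median(
            np.stack([t.values[chrom] for t in tracks]), axis=0
        )
    return out


def region_signal(
    track: SignalTrack, region: GenomicInterval, stat: str = "median"
) -> float:
    """Summary statistic over the bins intersecting a region."""
    if region.chrom not in track.values:
        raise ValueError(f"chromosome {region.chrom!r} not in track")
    b0 = region.start // track.bin_size
    b1 = -(-region.end // track.bin_size)
    vals = track.values[region.chrom][b0:b1]
    if stat == "median":
        return float(np.median(vals))
    if stat == "mean":
        return float(np.mean(vals))
    raise ValueError(f"unknown stat {stat!r}")


def tss_metaprofile(
    track: SignalTrack,
    genes: Sequence[GeneModel],
    window: int = 1000,
    stat: str = "median",
) -> tuple[np.ndarray, np.ndarray, int]:
    """Strand-oriented signal profile around TSSs.

    Returns (offsets, profile, n_excluded): per offset bin in
    [−window, +window), the statistic across all usable TSSs, with − strand
    profiles reversed so upstream is always left.  TSSs whose window leaves
    the chromosome are excluded and counted.
    """
    bs = track.bin_size
    if window % bs != 0:
        raise ValueError(f"window ({window}) must be a multiple of bin_size ({bs})")
    half = window // bs
    rows = []
    excluded = 0
    for g in genes:
        if g.chrom not in track.values:
            excluded += 1
            continue
        center = g.tss // bs
        nb = len(track.values[g.chrom])
        if center - half < 0 or center + half > nb:
            excluded += 1
            continue
        row = track.values[g.chrom][center - half : center + half]
        if g.strand == "-":
            row = row[::-1]
        rows.append(row)
    if not rows:
        raise ValueError("no usable TSSs within chromosome bounds")
    mat = np.stack(rows)
    if stat == "median":
        profile = np.median(mat, axis=0)
    elif stat == "mean":
        profile = mat.mean(axis=0)
    else:
        raise ValueError(f"unknown stat {stat!r}")
    offsets = (np.arange(-half, half) * bs).astype(int)
    return offsets, profile, excluded


def write_bedgraph(track: SignalTrack, path: str | Path, header: str | None = None) -> None:
    """Write non-zero bins as bedGraph (chrom, start, end, value)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        bs = track.bin_size
        for chrom in sorted(track.values):
            vals = track.values[chrom]
            length = track.assembly[chrom]
            for b in np.nonzero(vals)[0]:
                start = int(b) * bs
                fh.write(f"{chrom}\t{start}\t{min(start + bs, length)}\t{vals[b]:.6g}\n")


def read_bedgraph(
    path: str | Path, assembly: Mapping[str, int], bin_size: int
) -> SignalTrack:
    track = SignalTrack(dict(assembly), bin_size)
    for chrom, length in assembly.items():
        track.values[chrom] = np.zeros(-(-length // bin_size))
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")
            start = int(s)
            if int(e) - start > bin_size or start % bin_size != 0:
                raise ValueError(f"{path}:{lineno}: record not aligned to {bin_size}-bp bins")
            track.values[chrom][start // bin_size] = float(v)
    return track
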