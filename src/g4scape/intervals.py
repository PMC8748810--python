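"""Genomic interval algebra and I/O.

Coordinates are 0-based, half-open everywhere (BED native).  An
:class:`IntervalSet` is bound to an assembly (a chrom → length map) so that
out-of-range records are rejected at parse time rather than deep inside an
analysis.  Book-ended intervals ([0,5) and [5,10)) merge into one segment,
matching ``bedtools merge`` defaults; consensus segments produced by coverage
thresholding are therefore maximal contiguous runs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "GeneModel",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "read_gtf_genes",
    "merge",
    "k_of_n_consensus",
    "overlap_count",
    "overlap_percent",
    "venn3_counts",
    "promoter_windows",
]


class BedParseError(ValueError):
    """Raised on a malformed BED/TSV line; carries the 1-based line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    score: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """A sorted collection of intervals on one assembly.

    The constructor sorts and validates against the assembly; it does not
    merge.  Call :func:`merge` (or ``.merged()``) to obtain the disjoint
    representation required by the classification and consensus operations.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        assembly: Mapping[str, int],
        name: str = "",
    ):
        self.name = name
        self.assembly = dict(assembly)
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        for iv in ivs:
            length = self.assembly.get(iv.chrom)
            if length is None:
                raise ValueError(
                    f"chromosome {iv.chrom!r} absent from assembly "
                    f"(known: {sorted(self.assembly)})"
                )
            if iv.end > length:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {length}"
                )
        self.intervals: list[GenomicInterval] = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return [
            (iv.chrom, iv.start, iv.end) for iv in self.intervals
        ] == [(iv.chrom, iv.start, iv.end) for iv in other.intervals]

    def __repr__(self) -> str:
        return f"IntervalSet({self.name!r}, n={len(self)})"

    def total_bp(self) -> int:
        """Covered base pairs (on the merged representation)."""
        return sum(len(iv) for iv in merge(self).intervals)

    def merged(self) -> "IntervalSet":
        return merge(self)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def dedup(self) -> "IntervalSet":
        """Drop exact duplicate coordinates (peak callers emit unique regions)."""
        seen: set[tuple[str, int, int]] = set()
        keep = []
        for iv in self.intervals:
            key = (iv.chrom, iv.start, iv.end)
            if key not in seen:
                seen.add(key)
                keep.append(iv)
        return IntervalSet(keep, self.assembly, self.name)


@dataclass(frozen=True)
class GeneModel:
    """Gene anchored at its strand-aware transcription start site.

    ``tss`` is the first transcribed base: transcript start on the + strand,
    transcript end − 1 on the − strand (0-based).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    biotype: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")


# ---------------------------------------------------------------------------
# I/O


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                sizes[parts[0]] = int(parts[1])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bed(
    path: str | Path, assembly: Mapping[str, int], name: str | None = None
) -> IntervalSet:
    """Read a BED3+ file into a sorted :class:`IntervalSet`.

    Column 5 (0-based index 4) is kept as the score when parseable; any
    further columns are ignored.  Lines starting with ``#``, ``track`` or
    ``browser`` are skipped.
    """
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if chrom not in assembly:
                raise BedParseError(
                    f"{path}:{lineno}: chromosome {chrom!r} not in assembly"
                )
            score = None
            if len(parts) >= 5:
                try:
                    score = float(parts[4])
                except ValueError:
                    score = None
            try:
                intervals.append(GenomicInterval(chrom, start, end, score))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals, assembly, name or Path(path).stem)


def write_bed(iset: IntervalSet, path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for iv in iset:
            if iv.score is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{iv.score:g}\n")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a TSV with columns gene_id, chrom, strand, tss (header optional)."""
    genes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "gene_id":  # header row
                continue
            if len(parts) < 4:
                raise BedParseError(f"{path}:{lineno}: expected >=4 columns")
            try:
                tss = int(parts[3])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer TSS") from exc
            biotype = parts[4] if len(parts) > 4 else None
            genes.append(GeneModel(parts[0], parts[1], parts[2], tss, biotype))
    return genes


_GTF_GENE_ID = re.compile(r'gene_id "([^"]+)"')
_GTF_BIOTYPE = re.compile(r'gene_(?:bio)?type "([^"]+)"')


def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Extract gene records from a GTF (1-based inclusive → 0-based half-open).

    Only ``gene`` feature rows are consulted; the TSS is the annotated gene
    start on + and gene end − 1 on −.
    """
    genes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise BedParseError(f"{path}:{lineno}: expected 9 GTF columns")
            if parts[2] != "gene":
                continue
            chrom, start1, end1, strand, attrs = (
                parts[0],
                parts[3],
                parts[4],
                parts[6],
                parts[8],
            )
            m = _GTF_GENE_ID.search(attrs)
            if m is None:
                raise BedParseError(f"{path}:{lineno}: missing gene_id attribute")
            start0 = int(start1) - 1
            end0 = int(end1)  # inclusive end → exclusive
            tss = start0 if strand == "+" else end0 - 1
            bm = _GTF_BIOTYPE.search(attrs)
            genes.append(
                GeneModel(m.group(1), chrom, strand, tss, bm.group(1) if bm else None)
            )
    return genes


# ---------------------------------------------------------------------------
# Algebra


def merge(iset: IntervalSet) -> IntervalSet:
    """Union of coverage as disjoint intervals; book-ended runs are joined."""
    out: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = None, 0, 0
    for iv in iset.intervals:
        if iv.chrom == cur_chrom and iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            if cur_chrom is not None:
                out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    if cur_chrom is not None:
        out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return IntervalSet(out, iset.assembly, iset.name)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base-pair intersection of two sets (both merged internally)."""
    am, bm = merge(a).by_chrom(), merge(b).by_chrom()
    out = []
    for chrom in sorted(set(am) & set(bm)):
        ai, bi = am[chrom], bm[chrom]
        i = j = 0
        while i < len(ai) and j < len(bi):
            lo = max(ai[i].start, bi[j].start)
            hi = min(ai[i].end, bi[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if ai[i].end <= bi[j].end:
                i += 1
            else:
                j += 1
    return IntervalSet(out, a.assembly, f"{a.name}&{b.name}")


def k_of_n_consensus(sets: Sequence[IntervalSet], k: int) -> IntervalSet:
    """Segments covered by at least k of the n input sets.

    multiIntersectBed semantics: partition the genome at every breakpoint of
    every (merged) input, keep segments whose set-count is >= k, then merge
    adjacent survivors.  With k = 1 this degenerates to the union.
    """
    if not sets:
        raise ValueError("need at least one interval set")
    if not (1 <= k <= len(sets)):
        raise ValueError(f"k={k} outside 1..{len(sets)}")
    assembly = sets[0].assembly
    # sweep-line over +1/-1 coverage events per chromosome
    events: dict[str, list[tuple[int, int]]] = {}
    for s in sets:
        for iv in merge(s).intervals:
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events[iv.chrom].append((iv.end, -1))
    out = []
    for chrom in sorted(events):
        evs = sorted(events[chrom])
        depth = 0
        seg_start = None
        i = 0
        while i < len(evs):
            pos = evs[i][0]
            while i < len(evs) and evs[i][0] == pos:
                depth += evs[i][1]
                i += 1
            if depth >= k and seg_start is None:
                seg_start = pos
            elif depth < k and seg_start is not None:
                if pos > seg_start:
                    out.append(GenomicInterval(chrom, seg_start, pos))
                seg_start = None
    name = f"consensus_{k}of{len(sets)}"
    return merge(IntervalSet(out, assembly, name))


def _overlap_mask(a: IntervalSet, b: IntervalSet) -> list[bool]:
    """Per-interval of a: does it overlap >=1 bp of merged b?"""
    bm = merge(b).by_chrom()
    import bisect

    starts = {c: [iv.start for iv in ivs] for c, ivs in bm.items()}
    ends = {c: [iv.end for iv in ivs] for c, ivs in bm.items()}
    mask = []
    for iv in a.intervals:
        hit = False
        if iv.chrom in bm:
            # first merged interval with end > iv.start
            idx = bisect.bisect_right(ends[iv.chrom], iv.start)
            if idx < len(starts[iv.chrom]) and starts[iv.chrom][idx] < iv.end:
                hit = True
        mask.append(hit)
    return mask


def overlap_count(a: IntervalSet, b: IntervalSet) -> int:
    """Number of intervals of a with >=1 bp overlap in b (intersect -u style).

    Exact duplicate coordinates in a are counted once.
    """
    return sum(_overlap_mask(a.dedup(), b))


def overlap_percent(count: int, total: int) -> float | None:
    """Percentage of overlapping intervals; None when total is zero."""
    if total == 0:
        return None
    return 100.0 * count / total


def venn3_counts(
    a: IntervalSet, b: IntervalSet, c: IntervalSet
) -> dict[str, dict[str, int]]:
    """Three-way overlap tallies reported per set.

    Each interval of each set is classified once by its membership pattern —
    a 3-character key over (a, b, c) with '1' where coverage overlaps.  Because
    a single interval of one set may straddle several intervals of another,
    region counts for shared patterns can legitimately differ between the
    contributing sets; the per-set tallies are reported side by side instead of
    forcing one number.
    """
    sets = {"a": a.dedup(), "b": b.dedup(), "c": c.dedup()}
    patterns = ["100", "010", "001", "110", "101", "011", "111"]
    result: dict[str, dict[str, int]] = {p: {} for p in patterns}
    others = {"a": ("b", "c"), "b": ("a", "c"), "c": ("a", "b")}
    pos = {"a": 0, "b": 1, "c": 2}
    for label, iset in sets.items():
        o1, o2 = others[label]
        m1 = _overlap_mask(iset, sets[o1])
        m2 = _overlap_mask(iset, sets[o2])
        tallies = {p: 0 for p in patterns}
        for h1, h2 in zip(m1, m2):
            bits = ["0", "0", "0"]
            bits[pos[label]] = "1"
            if h1:
                bits[pos[o1]] = "1"
            if h2:
                bits[pos[o2]] = "1"
            tallies["".join(bits)] += 1
        for p in patterns:
            if p[pos[label]] == "1":
                result[p][label] = tallies[p]
    return result


def promoter_windows(
    genes: Sequence[GeneModel],
    assembly: Mapping[str, int],
    flank: int = 1000,
) -> tuple[IntervalSet, dict[str, GenomicInterval]]:
    """Symmetric promoter windows around each strand-aware TSS.

    The window is [tss − flank, tss + flank + 1): 2·flank + 1 bp including the
    TSS base itself, clipped at chromosome bounds.  Returns the window set and
    a gene_id → window mapping for annotation joins.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    out = []
    mapping: dict[str, GenomicInterval] = {}
    for g in genes:
        length = assembly.get(g.chrom)
        if length is None:
            raise ValueError(f"chromosome {g.chrom!r} of gene {g.gene_id} not in assembly")
        if not (0 <= g.tss < length):
            raise ValueError(
                f"TSS {g.tss} of gene {g.gene_id} outside {g.chrom} (length {length})"
            )
        start = max(0, g.tss - flank)
        end = min(length, g.tss + flank + 1)
        iv = GenomicInterval(g.chrom, start, end)
        out.append(iv)
        mapping[g.gene_id] = iv
    return IntervalSet(out, assembly, "promoters"), mapping
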