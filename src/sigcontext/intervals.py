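"""Genome representation, context annotations, and binned feature tracks.

Coordinate conventions, applied everywhere in the package:

* BED intervals are 0-based, half-open ``[start, end)``.
* Mutation / point positions are 1-based; the conversion happens in exactly
  one place, :func:`assign_points` (a 1-based point ``p`` is a member of an
  interval iff the 0-based index ``p - 1`` falls in ``[start, end)``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeIndex",
    "ContextAnnotation",
    "BinnedTrack",
    "load_intervals",
    "binarize_to_bins",
    "assign_points",
]


class GenomeIndex:
    """Ordered chromosome names and lengths, with optional FASTA-backed sequence.

    Parameters
    ----------
    chrom_lengths
        Mapping of chromosome name to length in bases (order preserved).
    sequence_source
        Either ``None`` (no sequence available), a mapping of chromosome name
        to an uppercase sequence string, or a path to an (indexed) FASTA file.
    """

    def __init__(
        self,
        chrom_lengths: Mapping[str, int],
        sequence_source: Mapping[str, str] | str | Path | None = None,
    ):
        if len(set(chrom_lengths)) != len(chrom_lengths):
            raise ValueError("chromosome names must be unique")
        for name, length in chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self.chrom_names: list[str] = list(chrom_lengths)
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths)
        self._fasta = None
        self._seqs: dict[str, str] | None = None
        if sequence_source is None:
            pass
        elif isinstance(sequence_source, (str, Path)):
            from pyfaidx import Fasta

            self._fasta = Fasta(str(sequence_source), sequence_always_upper=True)
        else:
            self._seqs = {c: str(s).upper() for c, s in sequence_source.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        from pyfaidx import Fasta

        fa = Fasta(str(path), sequence_always_upper=True)
        idx = cls({name: len(fa[name]) for name in fa.keys()})
        idx._fasta = fa
        return idx

    @property
    def has_sequence(self) -> bool:
        return self._fasta is not None or self._seqs is not None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the uppercase sequence for 0-based half-open ``[start, end)``.

        Out-of-bounds flanks are padded with ``N`` so trinucleotide lookups at
        chromosome edges stay well-defined.
        """
        length = self.length(chrom)
        left_pad = max(0, -start)
        right_pad = max(0, end - length)
        s, e = max(0, start), min(end, length)
        if self._seqs is not None:
            core = self._seqs[chrom][s:e]
        elif self._fasta is not None:
            core = str(self._fasta[chrom][s:e])
        else:
            raise ValueError("GenomeIndex has no sequence source")
        seq = "N" * left_pad + core.upper() + "N" * right_pad
        if any(b not in "ACGTN" for b in set(seq)):
            # IUPAC ambiguity codes collapse to N: they are unclassifiable anyway
            seq = "".join(b if b in "ACGTN" else "N" for b in seq)
        return seq

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


def _merge_intervals(ivals: Iterable[tuple[int, int]]) -> np.ndarray:
    """Sort and merge overlapping/adjacent [start, end) pairs into an (n, 2) array."""
    arr = sorted(ivals)
    merged: list[list[int]] = []
    for s, e in arr:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64).reshape(-1, 2)


@dataclass
class ContextAnnotation:
    """A named set of genomic intervals (one context label), merged and sorted.

    ``intervals`` maps chromosome -> (n, 2) int64 array of 0-based half-open
    [start, end) rows, non-overlapping and sorted by start.
    """

    label: str
    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_tuples(
        cls,
        label: str,
        tuples: Iterable[tuple[str, int, int]],
        genome: GenomeIndex | None = None,
    ) -> "ContextAnnotation":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in tuples:
            if start >= end:
                raise ValueError(f"start >= end in interval ({chrom}, {start}, {end})")
            if start < 0:
                raise ValueError(f"negative start in interval ({chrom}, {start}, {end})")
            if genome is not None:
                if chrom not in genome:
                    raise KeyError(f"unknown chromosome {chrom!r}")
                if end > genome.length(chrom):
                    raise ValueError(
                        f"interval ({chrom}, {start}, {end}) beyond chromosome "
                        f"length {genome.length(chrom)}"
                    )
            by_chrom.setdefault(chrom, []).append((start, end))
        return cls(label, {c: _merge_intervals(v) for c, v in by_chrom.items()})

    def total_length(self) -> int:
        return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in self.intervals.values()))

    def n_intervals(self) -> int:
        return int(sum(len(arr) for arr in self.intervals.values()))

    def iter_tuples(self):
        for chrom in self.intervals:
            for s, e in self.intervals[chrom]:
                yield chrom, int(s), int(e)

    def complement(self, genome: GenomeIndex, label: str | None = None) -> "ContextAnnotation":
        """Every base of the genome not covered by this annotation."""
        out: dict[str, np.ndarray] = {}
        for chrom in genome.chrom_names:
            L = genome.length(chrom)
            arr = self.intervals.get(chrom, np.empty((0, 2), dtype=np.int64))
            gaps = []
            prev = 0
            for s, e in arr:
                if s > prev:
                    gaps.append((prev, s))
                prev = max(prev, int(e))
            if prev < L:
                gaps.append((prev, L))
            if gaps:
                out[chrom] = np.array(gaps, dtype=np.int64)
        return ContextAnnotation(label or f"not_{self.label}", out)

    def intersect(self, other: "ContextAnnotation", label: str | None = None) -> "ContextAnnotation":
        out: dict[str, np.ndarray] = {}
        for chrom in self.intervals:
            if chrom not in other.intervals:
                continue
            a, b = self.intervals[chrom], other.intervals[chrom]
            rows = []
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    rows.append((int(s), int(e)))
                if a[i, 1] < b[j, 1]:
                    i += 1
                else:
                    j += 1
            if rows:
                out[chrom] = np.array(rows, dtype=np.int64)
        return ContextAnnotation(label or f"{self.label}&{other.label}", out)

    def subtract(self, other: "ContextAnnotation", genome: GenomeIndex, label: str | None = None) -> "ContextAnnotation":
        return self.intersect(other.complement(genome), label or self.label)

    def to_bed(self, path: str | Path, with_label: bool = True) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for s, e in self.intervals[chrom]:
                    if with_label:
                        fh.write(f"{chrom}\t{s}\t{e}\t{self.label}\n")
                    else:
                        fh.write(f"{chrom}\t{s}\t{e}\n")


@dataclass
class BinnedTrack:
    """Per-bin values along each chromosome at a fixed bin size.

    ``values[chrom]`` has ``ceil(chrom_length / bin_size)`` entries; binary
    tracks contain only 0/1.
    """

    feature_name: str
    bin_size: int
    values: dict[str, np.ndarray]

    def n_bins(self) -> int:
        return int(sum(len(v) for v in self.values.values()))

    def is_binary(self) -> bool:
        return all(np.isin(v, (0, 1)).all() for v in self.values.values())

    def concat(self, chrom_order: Sequence[str] | None = None) -> np.ndarray:
        order = list(chrom_order) if chrom_order is not None else list(self.values)
        return np.concatenate([self.values[c] for c in order])

    def bin_annotation(self, mask_value=1, label: str | None = None) -> ContextAnnotation:
        """Intervals covering the bins whose value equals ``mask_value``."""
        tuples = []
        for chrom, vals in self.values.items():
            idx = np.flatnonzero(vals == mask_value)
            for i in idx:
                tuples.append((chrom, int(i) * self.bin_size, (int(i) + 1) * self.bin_size))
        ann = ContextAnnotation.from_tuples(label or self.feature_name, tuples) if tuples else ContextAnnotation(label or self.feature_name, {})
        return ann

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.values):
                for i, v in enumerate(self.values[chrom]):
                    fh.write(f"{chrom}\t{i * self.bin_size}\t{(i + 1) * self.bin_size}\t{v:g}\n")


def n_bins_for(length: int, bin_size: int) -> int:
    return math.ceil(length / bin_size)


def load_intervals(
    path: str | Path,
    genome: GenomeIndex | None = None,
    label: str | None = None,
    label_from_column: bool = False,
) -> ContextAnnotation | dict[str, ContextAnnotation]:
    """Read a BED3/BED4 file into one (or several) merged annotations.

    With ``label_from_column=True`` the 4th column partitions rows into one
    annotation per distinct name and a dict is returned; otherwise a single
    annotation is built, labelled by ``label`` or the file stem.
    """
    path = Path(path)
    rows: list[tuple[str, int, int, str]] = []
    default_label = label or path.stem
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns, got {len(parts)}")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = parts[3] if (label_from_column and len(parts) >= 4) else default_label
            rows.append((chrom, start, end, name))
    if label_from_column:
        groups: dict[str, list[tuple[str, int, int]]] = {}
        for chrom, s, e, name in rows:
            groups.setdefault(name, []).append((chrom, s, e))
        return {
            name: ContextAnnotation.from_tuples(name, tup, genome)
            for name, tup in groups.items()
        }
    return ContextAnnotation.from_tuples(default_label, [(c, s, e) for c, s, e, _ in rows], genome)


def binarize_to_bins(
    annotation: ContextAnnotation,
    genome: GenomeIndex,
    bin_size: int,
    rule: str = "any_overlap",
) -> BinnedTrack:
    """Project an annotation onto fixed-size bins as a 0/1 track.

    ``rule="any_overlap"`` marks a bin if any base overlaps; ``rule="majority"``
    requires strictly more than half of the bin covered (a truncated terminal
    bin is judged against its actual width).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if rule not in ("any_overlap", "majority"):
        raise ValueError(f"unknown rule {rule!r}")
    values: dict[str, np.ndarray] = {}
    for chrom in genome.chrom_names:
        L = genome.length(chrom)
        nb = n_bins_for(L, bin_size)
        cov = np.zeros(nb, dtype=np.int64)  # covered bases per bin
        for s, e in annotation.intervals.get(chrom, np.empty((0, 2), dtype=np.int64)):
            b0, b1 = int(s) // bin_size, (int(e) - 1) // bin_size
            for b in range(b0, b1 + 1):
                bs, be = b * bin_size, min((b + 1) * bin_size, L)
                cov[b] += max(0, min(int(e), be) - max(int(s), bs))
        if rule == "any_overlap":
            vals = (cov > 0).astype(np.int8)
        else:
            widths = np.minimum((np.arange(nb) + 1) * bin_size, L) - np.arange(nb) * bin_size
            vals = (cov * 2 > widths).astype(np.int8)
        values[chrom] = vals
    return BinnedTrack(annotation.label, bin_size, values)


def assign_points(
    positions: Sequence[tuple[str, int]],
    annotation: ContextAnnotation,
    genome: GenomeIndex | None = None,
) -> np.ndarray:
    """Membership flags for 1-based points against 0-based half-open intervals.

    Point ``p`` is a member iff ``start <= p - 1 < end``. If ``genome`` is
    given, chromosomes absent from it raise ``KeyError`` listing them; a
    chromosome merely absent from the annotation is non-member.
    """
    if genome is not None:
        unknown = sorted({c for c, _ in positions if c not in genome})
        if unknown:
            raise KeyError(f"unknown chromosome(s): {', '.join(unknown)}")
    out = np.zeros(len(positions), dtype=bool)
    # group queries by chromosome, then binary-search the merged starts
    by_chrom: dict[str, list[int]] = {}
    for i, (chrom, pos) in enumerate(positions):
        by_chrom.setdefault(chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        arr = annotation.intervals.get(chrom)
        if arr is None or len(arr) == 0:
            continue
        pts = np.array([positions[i][1] - 1 for i in idxs], dtype=np.int64)
        j = np.searchsorted(arr[:, 0], pts, side="right") - 1
        ok = (j >= 0) & (pts < arr[np.clip(j, 0, None), 1])
        for k, i in enumerate(idxs):
            out[i] = bool(ok[k])
    return out
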