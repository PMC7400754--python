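"""Somatic substitutions and 96-category trinucleotide catalogs.

Substitutions are normalized to the pyrimidine strand: a mutation at a purine
reference base is reverse-complemented (trinucleotide reversed and
complemented, alt complemented), so every mutation falls into one of the 96
COSMIC categories ``X[R>A]Y`` with R in {C, T}.

Category order is the canonical COSMIC order: substitution classes
C>A, C>G, C>T, T>A, T>C, T>G; within each class the 5' flank cycles A,C,G,T
slowest, then the 3' flank A,C,G,T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import ContextAnnotation, GenomeIndex, assign_points

logger = logging.getLogger(__name__)

__all__ = [
    "Mutation",
    "TrinucCatalog",
    "CATEGORIES_96",
    "SUBSTITUTION_CLASSES",
    "normalize_substitution",
    "build_catalog",
    "partition_mutations",
    "filter_samples",
    "read_mutations_tsv",
    "read_mutations_vcf",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 trinucleotide substitution categories in canonical COSMIC order.
CATEGORIES_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in "ACGT"
    for three in "ACGT"
)
_CAT_INDEX = {c: i for i, c in enumerate(CATEGORIES_96)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Mutation:
    """One somatic single-base substitution (1-based position)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"ref/alt must be single bases in ACGT, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")


class UnclassifiableError(ValueError):
    """Raised when a trinucleotide contains N (no defined category)."""


def normalize_substitution(trinuc: str, ref: str, alt: str) -> str:
    """Map a substitution in its trinucleotide context to its COSMIC category.

    ``trinuc`` is the 3-mer centered on the reference base. Purine references
    are reverse-complemented onto the pyrimidine strand.

    >>> normalize_substitution("ACA", "C", "T")
    'A[C>T]A'
    >>> normalize_substitution("AGC", "G", "T")
    'G[C>A]T'
    """
    trinuc = trinuc.upper()
    ref, alt = ref.upper(), alt.upper()
    if len(trinuc) != 3 or trinuc[1] != ref:
        raise ValueError(f"trinucleotide {trinuc!r} does not center on ref {ref!r}")
    if "N" in trinuc or ref == "N" or alt == "N":
        raise UnclassifiableError(f"N in trinucleotide {trinuc!r}")
    if ref in "AG":  # purine: flip to the pyrimidine strand
        trinuc = revcomp(trinuc)
        ref = trinuc[1]
        alt = alt.translate(_COMPLEMENT)
    return f"{trinuc[0]}[{ref}>{alt}]{trinuc[2]}"


@dataclass
class TrinucCatalog:
    """96-long count vector for one (sample, context) in canonical order."""

    sample_id: str
    context_label: str = "genome"
    counts: np.ndarray = field(default_factory=lambda: np.zeros(96, dtype=np.int64))
    n_unclassifiable: int = 0
    n_ref_mismatch: int = 0

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError(f"catalog must have exactly 96 categories, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CATEGORIES_96), name=self.sample_id)

    def __add__(self, other: "TrinucCatalog") -> "TrinucCatalog":
        return TrinucCatalog(
            self.sample_id if self.sample_id == other.sample_id else f"{self.sample_id}+{other.sample_id}",
            self.context_label if self.context_label == other.context_label else "merged",
            self.counts + other.counts,
            self.n_unclassifiable + other.n_unclassifiable,
            self.n_ref_mismatch + other.n_ref_mismatch,
        )


def build_catalog(
    mutations: Iterable[Mutation],
    genome: GenomeIndex,
    sample_id: str | None = None,
    context_label: str = "genome",
    on_ref_mismatch: str = "skip",
) -> TrinucCatalog:
    """Count mutations of one sample into the 96 trinucleotide categories.

    Mutations whose trinucleotide contains N are skipped and tallied in
    ``n_unclassifiable``. A reference-base mismatch against the genome is
    skipped with a warning (``on_ref_mismatch="skip"``) or raises
    (``on_ref_mismatch="error"``).
    """
    if on_ref_mismatch not in ("skip", "error"):
        raise ValueError(f"on_ref_mismatch must be 'skip' or 'error', got {on_ref_mismatch!r}")
    counts = np.zeros(96, dtype=np.int64)
    n_unclass = 0
    n_mismatch = 0
    sid = sample_id
    for mut in mutations:
        if sid is None:
            sid = mut.sample_id
        trinuc = genome.fetch(mut.chrom, mut.pos - 2, mut.pos + 1)
        if trinuc[1] != mut.ref:
            if trinuc[1] == "N":
                n_unclass += 1
                continue
            if on_ref_mismatch == "error":
                raise ValueError(
                    f"ref mismatch at {mut.chrom}:{mut.pos}: genome has {trinuc[1]}, record says {mut.ref}"
                )
            n_mismatch += 1
            continue
        try:
            cat = normalize_substitution(trinuc, mut.ref, mut.alt)
        except UnclassifiableError:
            n_unclass += 1
            continue
        counts[_CAT_INDEX[cat]] += 1
    if n_unclass or n_mismatch:
        logger.warning(
            "catalog %s/%s: skipped %d unclassifiable (N) and %d ref-mismatch mutations",
            sid, context_label, n_unclass, n_mismatch,
        )
    return TrinucCatalog(sid or "sample", context_label, counts, n_unclass, n_mismatch)


def group_by_sample(mutations: Iterable[Mutation]) -> dict[str, list[Mutation]]:
    out: dict[str, list[Mutation]] = {}
    for m in mutations:
        out.setdefault(m.sample_id, []).append(m)
    return out


def partition_mutations(
    mutations: Sequence[Mutation],
    annotations: Sequence[ContextAnnotation],
) -> dict[str, list[Mutation]]:
    """Subset mutations by context label; a mutation may land in several contexts.

    Returns ``{context_label: [mutations inside that context]}``, preserving
    input order within each subset.
    """
    positions = [(m.chrom, m.pos) for m in mutations]
    out: dict[str, list[Mutation]] = {}
    for ann in annotations:
        flags = assign_points(positions, ann)
        subset = [m for m, f in zip(mutations, flags) if f]
        out[ann.label] = subset
        logger.info("context %s: %d / %d mutations", ann.label, len(subset), len(mutations))
    return out


def filter_samples(
    mutations_by_sample: Mapping[str, Sequence[Mutation]],
    min_count: int = 500,
) -> dict[str, list[Mutation]]:
    """Drop samples with fewer than ``min_count`` genome-wide mutations.

    The boundary is retained: a sample with exactly ``min_count`` passes.
    """
    kept = {s: list(m) for s, m in mutations_by_sample.items() if len(m) >= min_count}
    dropped = sorted(set(mutations_by_sample) - set(kept))
    if dropped:
        logger.info("filter_samples: dropped %d samples below %d mutations", len(dropped), min_count)
    return kept


# ---------------------------------------------------------------------------
# I/O


def read_mutations_tsv(path: str | Path, sample_col: str = "sample") -> list[Mutation]:
    """Read a tabular mutation list with columns sample, chrom, pos, ref, alt."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    cols = {c.lower(): c for c in df.columns}
    required = [sample_col, "chrom", "pos", "ref", "alt"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    muts = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        rec = {k.lower(): v for k, v in zip(df.columns, row)}
        ref, alt = str(rec["ref"]).upper(), str(rec["alt"]).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT" or ref == alt:
            n_skipped += 1
            continue
        muts.append(Mutation(str(rec[sample_col]), str(rec["chrom"]), int(rec["pos"]), ref, alt))
    if n_skipped:
        logger.warning("%s: skipped %d non-SNV / malformed records", path, n_skipped)
    return muts


def read_mutations_vcf(path: str | Path, sample_id: str | None = None) -> list[Mutation]:
    """Read SNVs from a (plain-text) VCF; multi-allelic and indel records are skipped.

    The sample identity comes from ``sample_id`` if given, else from the first
    genotype column name, else from the file stem.
    """
    muts: list[Mutation] = []
    n_skipped = 0
    default_sample = sample_id
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.rstrip("\n").split("\t")
                if default_sample is None and len(fields) > 9:
                    default_sample = fields[9]
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                continue
            chrom, pos, _, ref, alt = parts[0], parts[1], parts[2], parts[3].upper(), parts[4].upper()
            if len(ref) != 1 or len(alt) != 1 or "," in alt or ref not in "ACGT" or alt not in "ACGT":
                n_skipped += 1
                continue
            muts.append(Mutation(default_sample or Path(path).stem, chrom, int(pos), ref, alt))
    if n_skipped:
        logger.warning("%s: skipped %d multi-allelic/indel records", path, n_skipped)
    return muts


_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def count_trinucleotides(
    genome: GenomeIndex,
    annotation: ContextAnnotation | None = None,
) -> np.ndarray:
    """Occurrences of each pyrimidine-strand trinucleotide, expanded to 96 categories.

    Counts the 32 pyrimidine-centered trinucleotides (purine-centered sites
    are reverse-complemented) genome-wide or within an annotation; each count
    is repeated for the 3 substitution categories sharing that trinucleotide,
    yielding a 96-vector aligned with :data:`CATEGORIES_96`.
    """
    counts32: dict[str, int] = {}
    regions = (
        list(annotation.iter_tuples())
        if annotation is not None
        else [(c, 0, genome.length(c)) for c in genome.chrom_names]
    )
    tri32 = [f"{a}{c}{b}" for c in "CT" for a in "ACGT" for b in "ACGT"]
    code32 = {16 * "ACGT".index(t[0]) + 4 * "ACGT".index(t[1]) + "ACGT".index(t[2]): t for t in tri32}
    acc = np.zeros(64, dtype=np.int64)
    for chrom, s, e in regions:
        lo, hi = max(int(s), 1), min(int(e), genome.length(chrom) - 1)
        if hi <= lo:
            continue
        seq = genome.fetch(chrom, lo - 1, hi + 1)
        codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)
        c0, c1, c2 = codes[:-2], codes[1:-1], codes[2:]
        ok = (c0 >= 0) & (c1 >= 0) & (c2 >= 0)
        tri = c0 * 16 + c1 * 4 + c2
        rc = (3 - c2) * 16 + (3 - c1) * 4 + (3 - c0)
        tri = np.where((c1 == 0) | (c1 == 2), rc, tri)
        acc += np.bincount(tri[ok], minlength=64)
    counts32 = {t: int(acc[code]) for code, t in code32.items()}
    return np.array([counts32[c[0] + c[2] + c[6]] for c in CATEGORIES_96], dtype=np.int64)


def trinucleotide_abundance(
    genome: GenomeIndex,
    context: ContextAnnotation,
) -> np.ndarray:
    """Context-to-genome trinucleotide frequency ratios (96-vector, > 0).

    Dividing a context catalog by this vector corrects exposures for the
    context's sequence composition differing from the genome's.
    """
    ctx = count_trinucleotides(genome, context).astype(float)
    gen = count_trinucleotides(genome).astype(float)
    if (ctx == 0).any():
        raise ValueError("context lacks some trinucleotides; abundance undefined")
    return (ctx / ctx.sum()) / (gen / gen.sum())


def catalogs_to_frame(catalogs: Sequence[TrinucCatalog]) -> pd.DataFrame:
    """96-row DataFrame (categories × samples) for signature-tool interchange."""
    data = {c.sample_id: c.counts for c in catalogs}
    return pd.DataFrame(data, index=list(CATEGORIES_96))
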