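"""Synthetic inputs with planted ground truth for every pipeline stage.

Every generator is a pure function of its configuration and seed: the same
(config, seed) yields byte-identical output. The defaults describe a toy
genome (2 chromosomes x 2 Mb, 10 kb bins, 6 binary features, 5 planted HMM
states, cohorts of tens of samples) small enough that full parameter-recovery
runs finish in seconds to minutes on one CPU.

What is emulated: mutation cohorts drawn from known per-context signature
mixtures; binary epigenomic tracks emitted by a planted Bernoulli HMM;
Repli-seq-like waves built from known origin positions (so timing, fork
direction and speed have analytic truth); expression tables with planted
tertile shifts and SV counts monotone in a signature's weight.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import CATEGORIES_96, Mutation, revcomp
from .hmm import MREModel
from .intervals import BinnedTrack, ContextAnnotation, GenomeIndex
from .refit import SignatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "simulate_tracks",
    "simulate_repliseq",
    "simulate_cohort",
    "simulate_expression_and_sv",
    "synthetic_signatures",
]

#: the 32 pyrimidine-centered trinucleotides (central base C or T)
PYR_TRINUCS: tuple[str, ...] = tuple(
    f"{a}{c}{b}" for c in "CT" for a in "ACGT" for b in "ACGT"
)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic world; ``seed`` is mandatory (no unseeded runs)."""

    seed: int
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    bin_size: int = 10_000
    # HMM truth
    n_states: int = 5
    n_features: int = 6
    self_transition: float = 0.95
    emission_contrast: float = 0.85  # "on" features emit at this rate, others at 1 - rate
    # replication truth
    origins_per_chrom: int = 4
    origin_sigma: float = 150_000.0
    wave_amplitude: float = 2.0
    wave_baseline: float = -1.0
    repliseq_noise: float = 0.0
    # cohort truth
    n_samples: int = 30
    mutations_per_sample: int = 2000
    mixture_map: dict[str, dict[str, float]] = field(default_factory=dict)
    # expression / SV truth
    expression_shift: float = 1.0
    sv_noise: float = 0.05

    def __post_init__(self):
        if self.chrom_length < 10_000:
            raise ValueError("chromosome length must be >= 10 kb")
        for ctx, mix in self.mixture_map.items():
            total = sum(mix.values())
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(f"mixture for context {ctx!r} sums to {total}, not 1")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


# ---------------------------------------------------------------------------
# genome


def simulate_genome(
    config: SimulationConfig,
    fasta_path: str | Path | None = None,
    gc: float = 0.5,
) -> GenomeIndex:
    """Seeded i.i.d. genome; guarantees every pyrimidine-centered trinucleotide occurs.

    Bases are drawn with GC fraction ``gc`` (a skewed value exercises the
    abundance-correction path downstream). If any of the 32 pyrimidine
    trinucleotides is absent, it is patched into a deterministic position so
    all 96 categories are realizable.
    """
    rng = _rng(config, 1)
    p_gc = gc / 2.0
    probs = [(1 - gc) / 2, p_gc, p_gc, (1 - gc) / 2]  # A, C, G, T
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    for chrom in config.chrom_names():
        arr = rng.choice(bases, size=config.chrom_length, p=probs)
        seq = "".join(arr)
        # patch in any missing pyrimidine trinucleotide (vanishing probability
        # at Mb scale, but the guarantee must be unconditional)
        present = {seq[i : i + 3] for i in range(len(seq) - 2)}
        missing = [t for t in PYR_TRINUCS if t not in present and revcomp(t) not in present]
        for k, tri in enumerate(missing):
            at = 100 + 5 * k
            seq = seq[:at] + tri + seq[at + 3 :]
        seqs[chrom] = seq
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for chrom, seq in seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
    return GenomeIndex({c: len(s) for c, s in seqs.items()}, seqs)


# ---------------------------------------------------------------------------
# planted HMM tracks


def planted_hmm(config: SimulationConfig) -> MREModel:
    """The ground-truth HMM: sticky chain, one block of 'on' features per state."""
    K, F = config.n_states, config.n_features
    transition = np.full((K, K), (1 - config.self_transition) / max(K - 1, 1))
    np.fill_diagonal(transition, config.self_transition if K > 1 else 1.0)
    hi, lo = config.emission_contrast, 1 - config.emission_contrast
    emission = np.full((K, F), lo)
    for s in range(K):
        # state s switches on a contiguous block of features, wrapping around
        for j in range(max(1, F // K)):
            emission[s, (s + j) % F] = hi
    initial = np.full(K, 1.0 / K)
    return MREModel(initial, transition, emission)


def simulate_tracks(
    config: SimulationConfig,
    model: MREModel | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], MREModel]:
    """Sample per-chromosome state paths and Bernoulli feature emissions.

    Returns (observations, true_paths, model): observations maps chromosome
    to a (bins, F) 0/1 matrix, true_paths to the planted 1-based state labels.
    """
    model = model or planted_hmm(config)
    rng = _rng(config, 2)
    K = model.n_states
    n_bins = config.chrom_length // config.bin_size
    obs: dict[str, np.ndarray] = {}
    paths: dict[str, np.ndarray] = {}
    for chrom in config.chrom_names():
        path = np.empty(n_bins, dtype=np.int64)
        path[0] = rng.choice(K, p=model.initial)
        for t in range(1, n_bins):
            path[t] = rng.choice(K, p=model.transition[path[t - 1]])
        u = rng.random((n_bins, model.n_features))
        obs[chrom] = (u < model.emission[path]).astype(np.int8)
        paths[chrom] = path + 1
    return obs, paths, model


def tracks_to_binned(
    observations: Mapping[str, np.ndarray],
    bin_size: int,
    feature_names: Sequence[str] | None = None,
) -> list[BinnedTrack]:
    """Split a per-chromosome (bins, F) observation dict into one track per feature."""
    F = next(iter(observations.values())).shape[1]
    names = list(feature_names) if feature_names else [f"f{i}" for i in range(F)]
    return [
        BinnedTrack(names[f], bin_size, {c: np.asarray(m)[:, f].astype(np.int8) for c, m in observations.items()})
        for f in range(F)
    ]


# ---------------------------------------------------------------------------
# Repli-seq waves


def simulate_repliseq(
    config: SimulationConfig,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict[str, dict[str, np.ndarray]]]:
    """Replication-timing waves from planted origins, with analytic truth.

    The noiseless signal is a sum of Gaussian bumps centered on the origins
    (early peaks) on a negative baseline. Truth labels per bin come from the
    noiseless curve: timing = sign, direction = sign of the analytic
    derivative (left where positive), speed = |derivative| below/at-or-above
    its genome-wide median (fast/slow). Returns (positions, noisy_values,
    truth) where truth[chrom] holds 'timing', 'direction', 'speed' and
    'origins'.
    """
    rng = _rng(config, 3)
    positions: dict[str, np.ndarray] = {}
    values: dict[str, np.ndarray] = {}
    truth: dict[str, dict[str, np.ndarray]] = {}
    clean_grad_all: list[np.ndarray] = []
    clean_all: dict[str, np.ndarray] = {}
    grad_all: dict[str, np.ndarray] = {}
    for chrom in config.chrom_names():
        n_bins = config.chrom_length // config.bin_size
        x = (np.arange(n_bins) + 0.5) * config.bin_size
        # evenly spaced origins, jittered
        spacing = config.chrom_length / (config.origins_per_chrom + 1)
        origins = spacing * (np.arange(config.origins_per_chrom) + 1)
        origins = origins + rng.uniform(-0.1, 0.1, size=len(origins)) * spacing
        clean = np.full(len(x), config.wave_baseline)
        grad = np.zeros(len(x))
        for o in origins:
            z = (x - o) / config.origin_sigma
            bump = config.wave_amplitude * np.exp(-0.5 * z**2)
            clean = clean + bump
            grad = grad + bump * (-(x - o) / config.origin_sigma**2)
        noise = rng.normal(0, config.repliseq_noise, size=len(x)) if config.repliseq_noise > 0 else 0.0
        positions[chrom] = x
        values[chrom] = clean + noise
        clean_all[chrom] = clean
        grad_all[chrom] = grad
        clean_grad_all.append(np.abs(grad))
        truth[chrom] = {"origins": origins}
    med = float(np.median(np.concatenate(clean_grad_all)))
    for chrom in config.chrom_names():
        g = grad_all[chrom]
        truth[chrom]["timing"] = np.where(clean_all[chrom] > 0, "early", "late")
        direction = np.full(len(g), "none", dtype=object)
        direction[g > 0] = "left"
        direction[g < 0] = "right"
        truth[chrom]["direction"] = direction.astype(str)
        truth[chrom]["speed"] = np.where(np.abs(g) < med, "fast", "slow")
        truth[chrom]["clean"] = clean_all[chrom]
        truth[chrom]["gradient"] = g
    return positions, values, truth


# ---------------------------------------------------------------------------
# signatures and cohorts


def synthetic_signatures(
    n_signatures: int = 10,
    seed: int = 0,
    concentration: float = 0.08,
) -> SignatureMatrix:
    """Well-separated synthetic signatures: sparse Dirichlet draws over 96 categories.

    A small ``concentration`` makes each signature load on few categories, so
    distinct signatures are nearly orthogonal and exposures are identifiable.
    """
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.full(96, concentration), size=n_signatures)
    probs = np.clip(probs, 1e-12, None)
    probs /= probs.sum(axis=1, keepdims=True)
    names = [f"SYN{i + 1}" for i in range(n_signatures)]
    return SignatureMatrix(names, probs)


_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _tri_code(t: str) -> int:
    return 16 * "ACGT".index(t[0]) + 4 * "ACGT".index(t[1]) + "ACGT".index(t[2])


class _SiteIndex:
    """1-based genomic positions realizing each pyrimidine trinucleotide.

    A site whose plus-strand trinucleotide has a purine center is indexed
    under its reverse complement (the pyrimidine strand), matching the
    catalog normalization.
    """

    def __init__(self, genome: GenomeIndex, annotation: ContextAnnotation):
        self.chrom_names: list[str] = []
        chunks_chrom: dict[str, list[np.ndarray]] = {t: [] for t in PYR_TRINUCS}
        chunks_pos: dict[str, list[np.ndarray]] = {t: [] for t in PYR_TRINUCS}
        code_to_tri = {_tri_code(t): t for t in PYR_TRINUCS}
        for chrom, s, e in annotation.iter_tuples():
            if chrom not in self.chrom_names:
                self.chrom_names.append(chrom)
            ci = self.chrom_names.index(chrom)
            lo = max(int(s), 1)
            hi = min(int(e), genome.length(chrom) - 1)
            if hi <= lo:
                continue
            seq = genome.fetch(chrom, lo - 1, hi + 1)
            codes = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)
            c0, c1, c2 = codes[:-2], codes[1:-1], codes[2:]
            ok = (c0 >= 0) & (c1 >= 0) & (c2 >= 0)
            tri = c0 * 16 + c1 * 4 + c2
            rc = (3 - c2) * 16 + (3 - c1) * 4 + (3 - c0)
            purine_center = (c1 == 0) | (c1 == 2)  # A or G on the plus strand
            tri = np.where(purine_center, rc, tri)
            pos = lo + 1 + np.arange(len(tri), dtype=np.int64)  # 1-based centers
            for code, t in code_to_tri.items():
                mask = ok & (tri == code)
                if mask.any():
                    p = pos[mask]
                    chunks_pos[t].append(p)
                    chunks_chrom[t].append(np.full(len(p), ci, dtype=np.int32))
        self.positions = {
            t: (np.concatenate(v) if v else np.empty(0, dtype=np.int64))
            for t, v in chunks_pos.items()
        }
        self.chrom_ids = {
            t: (np.concatenate(v) if v else np.empty(0, dtype=np.int32))
            for t, v in chunks_chrom.items()
        }

    def n_sites(self, tri: str) -> int:
        return len(self.positions[tri])

    def sample(self, tri: str, rng: np.random.Generator) -> tuple[str, int]:
        k = int(rng.integers(self.n_sites(tri)))
        return self.chrom_names[self.chrom_ids[tri][k]], int(self.positions[tri][k])


def simulate_cohort(
    config: SimulationConfig,
    genome: GenomeIndex,
    annotations: Sequence[ContextAnnotation],
    signatures: SignatureMatrix,
) -> tuple[list[Mutation], pd.DataFrame]:
    """Draw a mutation cohort from known per-context signature mixtures.

    For each mutation: a context is chosen in proportion to its genomic
    share, a signature from that context's planted mixture, one of the 96
    categories from the signature's spectrum, and a uniformly random genomic
    site inside the context whose (pyrimidine-strand) trinucleotide realizes
    that category; the strand determines ref/alt. A category with no matching
    site in the context is resampled (logged).

    Returns the mutation list and the planted truth as a tidy frame
    (sample, context, signature, weight).
    """
    if not config.mixture_map:
        raise ValueError("config.mixture_map is empty")
    labels = [a.label for a in annotations]
    missing = set(config.mixture_map) - set(labels)
    if missing:
        raise ValueError(f"mixture_map contexts without annotation: {sorted(missing)}")
    anns = {a.label: a for a in annotations}
    rng = _rng(config, 4)
    shares = np.array([anns[c].total_length() for c in config.mixture_map], dtype=float)
    shares /= shares.sum()
    ctx_names = list(config.mixture_map)
    site_indexes = {c: _SiteIndex(genome, anns[c]) for c in ctx_names}
    sig_idx = {n: i for i, n in enumerate(signatures.signature_names)}

    cat_trinuc = [c[0] + c[2] + c[6] for c in CATEGORIES_96]  # e.g. A[C>T]G -> "ACG"
    cat_alt = [c[4] for c in CATEGORIES_96]

    # per-context spectra with unrealizable categories (no site) zeroed out;
    # this is the vectorized equivalent of resample-until-placeable
    n_dropped = 0
    usable: dict[tuple[str, str], np.ndarray] = {}
    for ctx in ctx_names:
        sites = site_indexes[ctx]
        has_site = np.array([sites.n_sites(t) > 0 for t in cat_trinuc])
        for sig in config.mixture_map[ctx]:
            spec = signatures.probabilities[sig_idx[sig]].copy()
            n_dropped += int((~has_site & (spec > 0)).sum())
            spec[~has_site] = 0.0
            if spec.sum() == 0:
                raise RuntimeError(f"no placeable category for {sig} in context {ctx!r}")
            usable[(ctx, sig)] = spec / spec.sum()
    if n_dropped:
        logger.info("simulate_cohort: %d signature categories lack sites, resampled", n_dropped)

    mutations: list[Mutation] = []
    for si in range(config.n_samples):
        sample = f"S{si + 1:03d}"
        n = config.mutations_per_sample
        ctx_draw = rng.choice(len(ctx_names), size=n, p=shares)
        records: list[tuple[str, int, int]] = []  # (chrom, pos, category)
        for ci, ctx in enumerate(ctx_names):
            n_ctx = int((ctx_draw == ci).sum())
            if n_ctx == 0:
                continue
            mix = config.mixture_map[ctx]
            sig_names_ctx = list(mix)
            sig_draw = rng.choice(
                len(sig_names_ctx), size=n_ctx, p=np.array(list(mix.values()))
            )
            sites = site_indexes[ctx]
            for gi, sig in enumerate(sig_names_ctx):
                n_sig = int((sig_draw == gi).sum())
                if n_sig == 0:
                    continue
                cats = rng.choice(96, size=n_sig, p=usable[(ctx, sig)])
                for cat, count in zip(*np.unique(cats, return_counts=True)):
                    tri = cat_trinuc[cat]
                    ks = rng.integers(sites.n_sites(tri), size=count)
                    for k in ks:
                        records.append(
                            (
                                sites.chrom_names[sites.chrom_ids[tri][k]],
                                int(sites.positions[tri][k]),
                                int(cat),
                            )
                        )
        for chrom, pos, cat in records:
            plus_tri = genome.fetch(chrom, pos - 2, pos + 1)
            if plus_tri[1] in "CT":  # pyrimidine already on plus strand
                ref, alt = plus_tri[1], cat_alt[cat]
            else:
                ref, alt = plus_tri[1], revcomp(cat_alt[cat])
            mutations.append(Mutation(sample, chrom, pos, ref, alt))

    rows = []
    for si in range(config.n_samples):
        sample = f"S{si + 1:03d}"
        for ctx, mix in config.mixture_map.items():
            for sig, w in mix.items():
                rows.append((sample, ctx, sig, w))
    truth = pd.DataFrame(rows, columns=["sample", "context", "signature", "weight"])
    return mutations, truth


def simulate_expression_and_sv(
    config: SimulationConfig,
    sample_weights: Mapping[str, float],
) -> pd.DataFrame:
    """Expression with planted tertile shifts and SV counts monotone in weight.

    ``sample_weights`` maps sample id to its planted genome-wide weight of
    the signature of interest. Expression = shift * weight + noise (so a zero
    ``expression_shift`` plants the null); SV count = a seeded noisy monotone
    function of the weight.
    """
    rng = _rng(config, 5)
    samples = list(sample_weights)
    w = np.array([sample_weights[s] for s in samples], dtype=float)
    expression = config.expression_shift * w + rng.normal(0, 0.1, size=len(w))
    sv = np.maximum(0, 100.0 * w + rng.normal(0, 100.0 * config.sv_noise, size=len(w)))
    return pd.DataFrame(
        {"sample": samples, "expression": expression, "sv_count": np.round(sv).astype(int)}
    )


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> None:
    obj = truth.to_dict(orient="records")
    Path(path).write_text(json.dumps(obj, indent=1))
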