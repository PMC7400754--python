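"""End-to-end orchestration: contexts -> catalogs -> exposures -> statistics.

`run_context_analysis` reproduces the core analysis flow: filter samples by
genome-wide mutation count, partition mutations into contexts, build a
96-category catalog per (sample, context), refit signature exposures against
the reference matrix, and compare exposures between context pairs with the
Wilcoxon signed-rank test and the rank-biserial W/R effect size.

`run_mre_analysis` trains the composite-state HMM on binarized tracks,
decodes per cell type, computes feature enrichments, and (optionally) feeds
the per-state bin annotations back through the context machinery.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .catalog import Mutation, build_catalog, filter_samples, group_by_sample, partition_mutations
from .hmm import MREModel, StateAnnotation, decode_states, enrichment_scores, train_mre
from .intervals import BinnedTrack, ContextAnnotation, GenomeIndex
from .refit import ExposureVector, SignatureMatrix, exposures_to_frame, refit_exposures
from .stats import bh_fdr, compare_contexts

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_context_analysis", "run_mre_analysis", "context_exposure_table"]


@dataclass
class RunConfig:
    """Parameters of a pipeline run; paths are optional when objects are passed."""

    seed: int = 0
    min_mutations: int = 500
    min_context_mutations: int = 50
    cutoff: float = 0.06
    bin_size: int = 10_000
    spar: float = 0.2
    n_states: int = 20
    solver: str = "greedy"
    out_dir: str | Path | None = None

    def manifest(self, **extra) -> dict:
        m = {
            "version": __version__,
            "seed": self.seed,
            "min_mutations": self.min_mutations,
            "min_context_mutations": self.min_context_mutations,
            "cutoff": self.cutoff,
            "bin_size": self.bin_size,
            "spar": self.spar,
            "n_states": self.n_states,
            "solver": self.solver,
        }
        m.update(extra)
        return m


def context_exposure_table(
    mutations: Sequence[Mutation],
    genome: GenomeIndex,
    annotations: Sequence[ContextAnnotation],
    signatures: SignatureMatrix,
    config: RunConfig | None = None,
    include_genome_wide: bool = True,
) -> pd.DataFrame:
    """Long-format (sample, context, signature, weight, n_mutations) exposures.

    Samples below the genome-wide mutation threshold are dropped; a
    (sample, context) cell with fewer than ``min_context_mutations``
    classifiable mutations is skipped (logged) rather than fitted on noise.
    """
    cfg = config or RunConfig()
    by_sample = filter_samples(group_by_sample(mutations), cfg.min_mutations)
    if not by_sample:
        raise ValueError("no samples pass the mutation-count filter")
    exposures: list[ExposureVector] = []
    n_mut: dict[tuple[str, str], int] = {}
    ordered_samples = sorted(by_sample)
    for context_label, subset_all in _iter_context_subsets(
        by_sample, ordered_samples, annotations, include_genome_wide
    ):
        for sample in ordered_samples:
            muts = subset_all.get(sample, [])
            if len(muts) < cfg.min_context_mutations:
                logger.info(
                    "skipping %s/%s: %d mutations < %d",
                    sample, context_label, len(muts), cfg.min_context_mutations,
                )
                continue
            cat = build_catalog(muts, genome, sample_id=sample, context_label=context_label)
            if cat.total == 0:
                continue
            exposures.append(
                refit_exposures(cat, signatures, cutoff=cfg.cutoff, solver=cfg.solver)
            )
            n_mut[(sample, context_label)] = cat.total
    table = exposures_to_frame(exposures)
    table["n_mutations"] = [
        n_mut.get((s, c), 0) for s, c in zip(table["sample"], table["context"])
    ]
    return table


def _iter_context_subsets(by_sample, ordered_samples, annotations, include_genome_wide):
    all_muts = [m for s in ordered_samples for m in by_sample[s]]
    if include_genome_wide:
        yield "genome", {s: list(by_sample[s]) for s in ordered_samples}
    partitioned = partition_mutations(all_muts, list(annotations))
    for label, subset in partitioned.items():
        yield label, group_by_sample(subset)


def run_context_analysis(
    mutations: Sequence[Mutation],
    genome: GenomeIndex,
    annotations: Sequence[ContextAnnotation],
    signatures: SignatureMatrix,
    comparisons: Sequence[tuple[str, str, str]] = (),
    config: RunConfig | None = None,
) -> dict:
    """Full exposure-and-comparison run.

    ``comparisons`` lists (signature, context_a, context_b) triples; each is
    tested with the paired signed-rank test and the W/R effect size, and the
    p-values are BH-adjusted jointly. Returns a dict with the exposure table,
    the comparison results frame, and a manifest; writes TSV/JSON under
    ``config.out_dir`` when set.
    """
    cfg = config or RunConfig()
    table = context_exposure_table(mutations, genome, annotations, signatures, cfg)
    rows = []
    for sig, ctx_a, ctx_b in comparisons:
        res = compare_contexts(table, sig, ctx_a, ctx_b, paired=True)
        rows.append((f"{sig}:{ctx_a}-vs-{ctx_b}", res["statistic"], res["p"],
                     res["effect_size"], res["n"]))
    results = pd.DataFrame(rows, columns=["comparison", "statistic", "p", "effect_size", "n"])
    if len(results):
        results["p_adjusted"] = bh_fdr(results["p"].to_numpy())
    manifest = cfg.manifest(
        n_samples=int(table["sample"].nunique()),
        contexts=sorted(table["context"].unique().tolist()),
        signatures=signatures.signature_names,
    )
    out = {"exposures": table, "comparisons": results, "manifest": manifest}
    if cfg.out_dir is not None:
        out_dir = Path(cfg.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "exposures.tsv", sep="\t", index=False)
        results.to_csv(out_dir / "comparisons.tsv", sep="\t", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def run_mre_analysis(
    observations_by_cell_type: Mapping[str, Mapping[str, np.ndarray]],
    K: int,
    tracks: Sequence[BinnedTrack] | None = None,
    config: RunConfig | None = None,
    feature_names: Sequence[str] | None = None,
) -> dict:
    """Train the MRE HMM jointly, decode each cell type, score enrichments.

    ``observations_by_cell_type`` maps cell type -> chromosome -> (bins, F)
    binary matrix. Returns the model, per-cell-type annotations, and (when
    ``tracks`` are given) the per-cell-type fold-enrichment tables.
    """
    cfg = config or RunConfig()
    model: MREModel = train_mre(
        [observations_by_cell_type[ct] for ct in observations_by_cell_type],
        K=K,
        seed=cfg.seed,
        feature_names=feature_names,
    )
    annotations: dict[str, StateAnnotation] = {}
    enrichments: dict[str, np.ndarray] = {}
    for ct, obs in observations_by_cell_type.items():
        ann = decode_states(model, dict(obs), cell_type=ct, bin_size=cfg.bin_size)
        annotations[ct] = ann
        if tracks is not None:
            enrichments[ct] = enrichment_scores(ann, list(tracks))
    out = {"model": model, "annotations": annotations, "enrichments": enrichments}
    if cfg.out_dir is not None:
        out_dir = Path(cfg.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        model.to_json(out_dir / "mre_model.json")
        for ct, ann in annotations.items():
            ann.to_bed(out_dir / f"mre_states_{ct}.bed")
    return out
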