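"""Signature-exposure refitting against a fixed reference signature matrix.

The default solver reproduces the greedy iterative scheme popularized by
deconstructSigs: starting from zero raw weights, repeatedly find the signature
whose optimal single-weight update most reduces the sum-of-squares error
between the (renormalized) weighted signature mixture and the observed
catalog fraction vector, stopping when the best achievable improvement falls
below a threshold. Weights below a fraction cutoff (default 0.06 of the
total) are zeroed, and the residual mass is reported as "unassigned".

An exact non-negative least-squares mode (``solver="nnls"``) is available and
must agree with the greedy fit on clean mixtures; the test suite uses it as
the independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .catalog import CATEGORIES_96, TrinucCatalog

__all__ = [
    "SignatureMatrix",
    "ExposureVector",
    "refit_exposures",
    "signature_burden",
    "cosine_similarity",
    "read_signature_tsv",
]


@dataclass
class SignatureMatrix:
    """Reference signatures: each row a probability vector over the 96 categories."""

    signature_names: list[str]
    probabilities: np.ndarray  # (S, 96)
    categories: tuple[str, ...] = CATEGORIES_96

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        S = len(self.signature_names)
        if self.probabilities.shape != (S, 96):
            raise ValueError(
                f"probabilities must be ({S}, 96), got {self.probabilities.shape}"
            )
        if (self.probabilities < 0).any():
            raise ValueError("negative signature probabilities")
        sums = self.probabilities.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = [self.signature_names[i] for i in np.flatnonzero(~np.isclose(sums, 1.0, atol=1e-6))]
            raise ValueError(f"signature rows must sum to 1: {bad}")
        if tuple(self.categories) != CATEGORIES_96:
            # reorder columns into canonical order by category name
            idx = [list(self.categories).index(c) for c in CATEGORIES_96]
            self.probabilities = self.probabilities[:, idx]
            self.categories = CATEGORIES_96

    @property
    def n_signatures(self) -> int:
        return len(self.signature_names)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probabilities.T, index=list(CATEGORIES_96), columns=self.signature_names)


@dataclass
class ExposureVector:
    """Fitted per-sample signature weights (fractions of 1) plus residual."""

    sample_id: str
    context_label: str
    weights: dict[str, float] = field(default_factory=dict)
    unassigned: float = 0.0
    sse: float = float("nan")

    def __post_init__(self):
        for name, w in self.weights.items():
            if w < 0:
                raise ValueError(f"negative weight for {name}")
        total = sum(self.weights.values())
        if total > 1 + 1e-9:
            raise ValueError(f"weights sum to {total} > 1")

    def weight(self, name: str) -> float:
        return self.weights.get(name, 0.0)

    def as_array(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.weights.get(n, 0.0) for n in names])


def _mixture_error(P: np.ndarray, raw: np.ndarray, target: np.ndarray) -> float:
    """SSE between the raw-weight mixture (no renormalization) and the target."""
    d = raw @ P - target
    return float(d @ d)


def _greedy_fit(P: np.ndarray, target: np.ndarray, tol: float, max_rounds: int) -> np.ndarray:
    """Greedy coordinate-wise fit in raw-weight space.

    Each round finds the signature whose optimal single-weight update (1-D
    bounded minimization of the SSE against the unnormalized weighted sum)
    most reduces the error, and applies it; stops when the best relative
    improvement drops below ``tol``. The caller normalizes the raw weights
    to fractions afterwards.
    """
    S = P.shape[0]
    raw = np.zeros(S)
    err = _mixture_error(P, raw, target)
    base = raw @ P - target
    for _ in range(max_rounds):
        best_err, best_s, best_w = err, -1, 0.0
        for s in range(S):
            # analytic 1-D optimum: err(w) is a parabola in w
            # d(w) = base - raw[s]*P[s] + w*P[s]
            resid = base - raw[s] * P[s]
            denom = P[s] @ P[s]
            w_opt = max(0.0, float(-(resid @ P[s]) / denom))
            e = _mixture_error(P, _with(raw, s, w_opt), target)
            if e < best_err - 1e-15:
                best_err, best_s, best_w = e, s, w_opt
        if best_s < 0 or err - best_err < tol * max(err, 1e-12):
            break
        raw[best_s] = best_w
        err = best_err
        base = raw @ P - target
    return raw


def _with(raw: np.ndarray, s: int, w: float) -> np.ndarray:
    out = raw.copy()
    out[s] = w
    return out


def refit_exposures(
    catalog: TrinucCatalog,
    signatures: SignatureMatrix,
    cutoff: float = 0.06,
    abundance: np.ndarray | None = None,
    solver: str = "greedy",
    tol: float = 1e-3,
    max_rounds: int = 1000,
) -> ExposureVector:
    """Estimate per-signature exposure fractions for one catalog.

    Parameters
    ----------
    catalog
        96-category mutation counts; must be non-empty.
    signatures
        Reference signature matrix.
    cutoff
        Fitted fractions below this value are set to exactly 0 (the residual
        goes to ``unassigned``).
    abundance
        Optional 96-vector of context-to-genome trinucleotide abundance
        ratios; when given, catalog fractions are divided by it and
        renormalized before fitting (corrects for sequence-composition
        differences of a sub-genomic context).
    solver
        ``"greedy"`` (iterative 1-D updates, the default) or ``"nnls"``
        (exact non-negative least squares on the fraction vector, then
        normalized to fractions).
    """
    if catalog.total == 0:
        raise ValueError("empty catalog")
    if solver not in ("greedy", "nnls"):
        raise ValueError(f"unknown solver {solver!r}")
    target = catalog.counts.astype(float)
    if abundance is not None:
        abundance = np.asarray(abundance, dtype=float)
        if abundance.shape != (96,):
            raise ValueError("abundance must be a 96-vector")
        if (abundance <= 0).any():
            raise ValueError("abundance ratios must be positive")
        target = target / abundance
    target = target / target.sum()
    P = signatures.probabilities

    if solver == "greedy":
        raw = _greedy_fit(P, target, tol=tol, max_rounds=max_rounds)
    else:
        raw, _ = nnls(P.T, target)
    total = raw.sum()
    fracs = raw / total if total > 0 else raw
    fracs[fracs < cutoff] = 0.0
    weights = {n: float(w) for n, w in zip(signatures.signature_names, fracs) if w > 0}
    sse = _mixture_error(P, fracs, target) if fracs.sum() > 0 else float(np.sum(target**2))
    return ExposureVector(
        sample_id=catalog.sample_id,
        context_label=catalog.context_label,
        weights=weights,
        unassigned=float(1.0 - fracs.sum()),
        sse=sse,
    )


def signature_burden(
    exposure: ExposureVector,
    n_mutations: int,
    context_length: int,
) -> dict[str, float]:
    """Mutations/Mb attributed to each signature: weight × n / (length/1e6)."""
    if context_length <= 0:
        raise ValueError("context_length must be positive")
    rate = n_mutations / (context_length / 1e6)
    return {name: w * rate for name, w in exposure.weights.items()}


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two spectra: a.b / (|a||b|)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def read_signature_tsv(path: str | Path) -> SignatureMatrix:
    """Read a COSMIC-layout signature TSV (96 category rows × signature columns).

    Both v2 ("Somatic Mutation Type" / "Substitution Type" + "Trinucleotide"
    triplet columns) and v3 ("Type" column with A[C>A]A names) dialects are
    accepted, as is a plain first-column index of category names.
    """
    df = pd.read_csv(path, sep="\t")
    cols_lower = {c.lower(): c for c in df.columns}
    if "type" in cols_lower:
        cat_col = cols_lower["type"]
        df = df.set_index(cat_col)
    elif "somatic mutation type" in cols_lower:
        df = df.set_index(cols_lower["somatic mutation type"])
        df = df.drop(columns=[c for c in df.columns
                              if c.lower() in ("substitution type", "trinucleotide")])
    elif "substitution type" in cols_lower and "trinucleotide" in cols_lower:
        sub = df[cols_lower["substitution type"]]
        tri = df[cols_lower["trinucleotide"]]
        names = [f"{t[0]}[{s}]{t[2]}" for s, t in zip(sub, tri)]
        df = df.drop(columns=[cols_lower["substitution type"], cols_lower["trinucleotide"]])
        df.index = names
    else:
        df = df.set_index(df.columns[0])
    df = df.apply(pd.to_numeric)
    missing = set(CATEGORIES_96) - set(df.index)
    if missing:
        raise ValueError(f"{path}: missing categories, e.g. {sorted(missing)[:3]}")
    df = df.loc[list(CATEGORIES_96)]
    return SignatureMatrix(list(df.columns), df.to_numpy().T)


def write_signature_tsv(signatures: SignatureMatrix, path: str | Path) -> None:
    frame = signatures.as_frame()
    frame.index.name = "Type"
    frame.to_csv(path, sep="\t")


def exposures_to_frame(exposures: Sequence[ExposureVector]) -> pd.DataFrame:
    """Long-format table (sample, context, signature, weight)."""
    rows = []
    for e in exposures:
        for name, w in sorted(e.weights.items()):
            rows.append((e.sample_id, e.context_label, name, w))
        rows.append((e.sample_id, e.context_label, "unassigned", e.unassigned))
    return pd.DataFrame(rows, columns=["sample", "context", "signature", "weight"])
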