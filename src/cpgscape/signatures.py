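"""96-channel trinucleotide spectra and constrained signature decomposition.

The spectrum counts single-base substitutions in their trinucleotide
context, collapsed so the mutated base is a pyrimidine: 6 substitution
classes (C>A, C>G, C>T, T>A, T>C, T>G) x 16 flank combinations = 96
channels, ordered as in the COSMIC v2 convention.

Decomposition expresses a normalized spectrum as a nonnegative mixture of
fixed signature probability vectors.  The fit is nonnegativity-constrained
least squares (unconstrained regression can return negative exposures,
which are meaningless as mutation fractions; an unconstrained mode exists
for comparison).  Signatures explaining less than the pruning threshold
(default 1%) of the mutations are dropped and the fit repeated on the
retained subset, iterating to a fixed point.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .genome import GenomeSequence, trinucleotide_context

log = logging.getLogger(__name__)

__all__ = [
    "CONTEXTS_96",
    "SUBSTITUTION_CLASSES",
    "MutationSpectrum",
    "SignatureMatrix",
    "DecompositionResult",
    "build_spectrum",
    "decompose",
    "synthetic_signatures",
]

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_FLANKS = "ACGT"

#: channel labels like "A[C>T]G", grouped by substitution class then 5' then 3' flank
CONTEXTS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in _FLANKS
    for three in _FLANKS
)
_CHANNEL_INDEX = {lab: i for i, lab in enumerate(CONTEXTS_96)}


def channel_of(context: str, substitution: str) -> int:
    """Channel index of a pyrimidine-collapsed (3-mer, class) pair."""
    return _CHANNEL_INDEX[f"{context[0]}[{substitution}]{context[2]}"]


@dataclass
class MutationSpectrum:
    counts: np.ndarray = field(default_factory=lambda: np.zeros(96))
    n_skipped: int = 0  # events with N-containing context

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have exactly 96 channels")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be nonnegative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def normalized(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return self.counts / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"context": CONTEXTS_96, "count": self.counts})

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class SignatureMatrix:
    """96 x K matrix of signature probability vectors (columns sum to 1)."""

    def __init__(self, matrix: pd.DataFrame) -> None:
        if list(matrix.index) != list(CONTEXTS_96):
            matrix = matrix.reindex(CONTEXTS_96)
            if matrix.isna().any().any():
                raise ValueError("signature matrix rows must cover the 96 contexts")
        if (matrix.values < 0).any():
            raise ValueError("signature matrix must be nonnegative")
        sums = matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("every signature column must sum to 1")
        self.df = matrix

    @property
    def names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    @classmethod
    def from_tsv(cls, path: str) -> "SignatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def to_tsv(self, path: str) -> None:
        self.df.to_csv(path, sep="\t", index_label="context", float_format="%.10g")


@dataclass
class DecompositionResult:
    weights: pd.Series  # nonnegative, over retained signatures, summing to ~1
    residual_norm: float
    full_weights: pd.Series
    full_residual_norm: float
    pruned: list[str]

    def to_json(self, path: str) -> None:
        payload = {
            "weights": {k: float(v) for k, v in self.weights.items()},
            "residual_norm": self.residual_norm,
            "full_residual_norm": self.full_residual_norm,
            "pruned": self.pruned,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def build_spectrum(events, genome: GenomeSequence) -> MutationSpectrum:
    """Tally rare substitution events into the 96 channels.

    The reference allele is treated as ancestral (the rationale for
    restricting to rare variants: recently arisen, so the reference is
    almost surely the ancestral state).  Events whose context contains N are
    skipped and counted.
    """
    counts = np.zeros(96)
    skipped = 0
    for ev in events:
        try:
            res = trinucleotide_context(genome, ev.chrom, ev.pos, ev.ref, ev.alt)
        except (KeyError, IndexError):
            skipped += 1
            continue
        if res is None:
            skipped += 1
            continue
        context, sub = res
        counts[channel_of(context, sub)] += 1
    return MutationSpectrum(counts, n_skipped=skipped)


def _fit(S: np.ndarray, p: np.ndarray, constrained: bool) -> tuple[np.ndarray, float]:
    if constrained:
        w, rnorm = nnls(S, p)
    else:
        w, *_ = np.linalg.lstsq(S, p, rcond=None)
        rnorm = float(np.linalg.norm(S @ w - p))
    return w, float(rnorm)


def decompose(
    spectrum: MutationSpectrum,
    signatures: SignatureMatrix,
    prune_threshold: float = 0.01,
    constrained: bool = True,
) -> DecompositionResult:
    """Fit a spectrum as a nonnegative signature mixture with >=1% pruning.

    The spectrum is normalized to a probability vector, fit against all
    signature columns, and the weights renormalized to sum to 1.  Signatures
    explaining less than ``prune_threshold`` of the mutations are dropped
    and the fit repeated on the survivors until no weight falls below the
    threshold (at most K rounds).  The residual after pruning can only be at
    least the full-fit residual; both are reported.
    """
    if len(signatures.names) == 0:
        raise ValueError("signature matrix has no columns")
    p = spectrum.normalized()
    S = signatures.values
    names = signatures.names

    w_full, r_full = _fit(S, p, constrained)
    if w_full.sum() > 0:
        w_full = w_full / w_full.sum()
    full = pd.Series(w_full, index=names)

    active = list(names)
    while True:
        S_act = signatures.df[active].to_numpy()
        w, rnorm = _fit(S_act, p, constrained)
        if w.sum() > 0:
            w = w / w.sum()
        low = [a for a, wi in zip(active, w) if wi < prune_threshold]
        if not low or len(low) == len(active):
            break
        active = [a for a in active if a not in low]
    weights = pd.Series(w, index=active)
    pruned = [n for n in names if n not in active]
    return DecompositionResult(
        weights=weights,
        residual_norm=rnorm,
        full_weights=full,
        full_residual_norm=r_full,
        pruned=pruned,
    )


def synthetic_signatures(n_signatures: int = 30, seed: int = 2020) -> SignatureMatrix:
    """A synthetic stand-in signature matrix in the COSMIC v2 layout.

    Thirty columns over the 96 channels.  Column "Signature 1" emulates the
    spontaneous-deamination process: most of its mass on the N[C>T]G
    channels.  "Signature 5" is a flat background.  The remaining columns
    are reproducible sparse random profiles.  This matrix is *synthetic* —
    deterministic from the seed and suitable for testing and demonstration,
    not a substitute for a curated reference catalogue.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for k in range(1, n_signatures + 1):
        name = f"Signature {k}"
        if k == 1:
            col = np.full(96, 0.15 / 92)
            for five in _FLANKS:
                col[channel_of(f"{five}CG", "C>T")] = 0.85 / 4
        elif k == 5:
            col = np.full(96, 1.0 / 96)
        else:
            col = rng.dirichlet(np.full(96, 0.08))
        cols[name] = col / col.sum()
    df = pd.DataFrame(cols, index=list(CONTEXTS_96))
    return SignatureMatrix(df)
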