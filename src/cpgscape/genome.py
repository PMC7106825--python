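"""Reference-genome access and CpG dinucleotide enumeration.

A CpG "site" throughout this package is the dinucleotide, keyed by the
0-based coordinate of its C on the plus strand.  The palindromic G on the
opposite strand is *not* a separate site: a G>A observation at ``pos`` and a
C>T observation at ``pos - 1`` describe the same mutable unit.

Coordinates are 0-based, half-open (BED arithmetic) everywhere; VCF input
is converted on ingestion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeSequence",
    "CpGSite",
    "revcomp",
    "cpg_positions",
    "enumerate_cpg_sites",
    "trinucleotide_context",
    "normalize_substitution",
    "CONVENTIONAL_CHROM_RE",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: autosomes 1-22 plus X and Y, with or without a "chr" prefix
CONVENTIONAL_CHROM_RE = re.compile(r"^(chr)?([1-9]|1[0-9]|2[0-2]|X|Y)$")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_conventional_chrom(name: str) -> bool:
    return CONVENTIONAL_CHROM_RE.match(name) is not None


class GenomeSequence:
    """Uppercase random access to a reference, restricted to conventional chromosomes.

    Backed either by an in-memory ``{chrom: sequence}`` mapping or by an
    indexed FASTA (via :mod:`pyfaidx`).  Soft-masked (lowercase) sequence is
    uppercased before any matching; hard-masked ``N`` never matches a CpG.
    """

    def __init__(
        self,
        seqs: Mapping[str, str],
        conventional_only: bool = True,
    ) -> None:
        self._seqs: dict[str, str] = {}
        for name, seq in seqs.items():
            if conventional_only and not is_conventional_chrom(name):
                continue
            self._seqs[name] = str(seq).upper()
        self.chrom_names: list[str] = list(self._seqs)

    @classmethod
    def from_fasta(cls, path: str, conventional_only: bool = True) -> "GenomeSequence":
        import pyfaidx

        fa = pyfaidx.Fasta(path, as_raw=True, sequence_always_upper=True)
        keys = [k for k in fa.keys() if not conventional_only or is_conventional_chrom(k)]
        return cls({k: str(fa[k][:]) for k in keys}, conventional_only=conventional_only)

    # -- accessors --------------------------------------------------------
    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        self._check(chrom)
        return len(self._seqs[chrom])

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def chrom_seq(self, chrom: str) -> str:
        """Full uppercase sequence of one chromosome."""
        self._check(chrom)
        return self._seqs[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``[start, end)`` (0-based half-open); out-of-bounds is an error."""
        self._check(chrom)
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(
                f"region {chrom}:{start}-{end} outside chromosome bounds (length {len(seq)})"
            )
        return seq[start:end]

    def _check(self, chrom: str) -> None:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}; available: {self.chrom_names}")


@dataclass
class CpGSite:
    """One CpG dinucleotide keyed by the plus-strand C position."""

    chrom: str
    pos: int
    in_cgi: bool = False
    cgi_class: str | None = None
    signed_distance: float | None = None
    coding_overlap: bool = False
    methyl_beta: float | None = None


def cpg_positions(genome: GenomeSequence, chrom: str) -> np.ndarray:
    """0-based positions of every CpG anchor (the C) on ``chrom``, in order.

    Overlap-free by construction at the dinucleotide level but "CGCG" yields
    anchors 0 and 2; positions containing N never match.
    """
    seq = genome.chrom_seq(chrom)
    if len(seq) < 2:
        return np.empty(0, dtype=np.int64)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    hits = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    return np.nonzero(hits)[0].astype(np.int64)


def enumerate_cpg_sites(
    genome: GenomeSequence, chroms: Sequence[str] | None = None
) -> Iterator[CpGSite]:
    """Yield every CpG site in coordinate order, chromosome by chromosome."""
    for chrom in chroms if chroms is not None else genome.chrom_names:
        if chrom not in genome:
            raise KeyError(f"unknown chromosome {chrom!r}")
        for pos in cpg_positions(genome, chrom):
            yield CpGSite(chrom, int(pos))


_PYRIMIDINES = frozenset("CT")
_BASES = frozenset("ACGT")


class ContextSkip(Exception):
    """Signal (not raised by default) used to tag N-containing contexts."""


def normalize_substitution(trimer: str, ref: str, alt: str) -> tuple[str, str] | None:
    """Collapse a substitution in its 3-mer context onto the 96-channel convention.

    ``trimer`` is the plus-strand 3-mer with the mutated base central.  If the
    reference base is a purine, both the context and the change are
    reverse-complemented so the reported channel has a pyrimidine reference
    (the standard trinucleotide-spectrum convention).  Returns
    ``(context, "C>T"-style class)`` or ``None`` if the context contains a
    base outside ACGT.
    """
    trimer = trimer.upper()
    ref = ref.upper()
    alt = alt.upper()
    if len(trimer) != 3 or trimer[1] != ref:
        raise ValueError(f"trimer {trimer!r} does not have ref {ref!r} central")
    if ref == alt or alt not in _BASES:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if any(b not in _BASES for b in trimer):
        return None
    if ref not in _PYRIMIDINES:
        trimer = revcomp(trimer)
        ref = revcomp(ref)
        alt = revcomp(alt)
    return trimer, f"{ref}>{alt}"


def trinucleotide_context(
    genome: GenomeSequence, chrom: str, pos: int, ref: str, alt: str
) -> tuple[str, str] | None:
    """96-channel ``(context, class)`` of a substitution at ``chrom:pos``.

    Returns ``None`` for contexts containing N (a flagged skip, not an
    error).  Raises if ``ref`` disagrees with the genome or the position has
    no two flanking bases.
    """
    if pos - 1 < 0 or pos + 2 > genome.length(chrom):
        raise IndexError(f"position {chrom}:{pos} has no trinucleotide context")
    trimer = genome.fetch(chrom, pos - 1, pos + 2)
    if trimer[1] != ref.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: genome has {trimer[1]!r}, event says {ref!r}"
        )
    return normalize_substitution(trimer, ref, alt)
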