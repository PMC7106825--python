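"""Consequence-primed site enumeration vs a full-transcript translation oracle."""

import numpy as np
import pandas as pd
import pytest

from cpgscape.consequence import (
    ac_spectrum,
    classify_codon_change,
    cross_with_observed,
    enumerate_primed_sites,
)
from cpgscape.genes import GeneModel, cds_intervals
from cpgscape.genome import revcomp
from cpgscape.synthetic import _make_gene
from cpgscape.variants import VariantEvent

from .conftest import make_genome


@pytest.mark.parametrize(
    "before,after,expected",
    [
        ("CGA", "TGA", "NONSENSE"),
        ("ACG", "ACA", "SILENT"),      # Thr -> Thr
        ("CGC", "TGC", "MISSENSE"),    # Arg -> Cys
        ("TGA", "TAA", "SILENT"),      # stop -> stop
        ("TGG", "TGA", "NONSENSE"),    # Trp -> stop
    ],
)
def test_codon_change_classification(before, after, expected):
    assert classify_codon_change(before, after)[0] == expected


def test_stop_loss_counted_as_missense_but_flagged():
    cons, stop_loss = classify_codon_change("TGA", "CGA")
    assert cons == "MISSENSE" and stop_loss


def _translate(seq: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(seq).translate())


def _oracle_consequences(genome, gene):
    """Independent oracle: rebuild the transcript, substitute, translate both."""
    seq = genome.chrom_seq(gene.chrom)
    pieces = "".join(seq[s:e] for s, e in cds_intervals(gene))
    cds = revcomp(pieces) if gene.strand == "-" else pieces
    out = {}
    genomic = []
    for s, e in cds_intervals(gene):
        genomic.extend(range(s, e))
    if gene.strand == "-":
        genomic = genomic[::-1]
    p0 = _translate(cds)
    for i, p in enumerate(genomic):
        base = seq[p]
        if base == "C" and seq[p : p + 2] == "CG":
            pass
        elif base == "G" and p >= 1 and seq[p - 1 : p + 1] == "CG":
            pass
        else:
            continue
        t_alt = {"C": "T", "G": "A"}[cds[i]]
        p1 = _translate(cds[:i] + t_alt + cds[i + 1 :])
        if p0 == p1:
            out[p] = "SILENT"
        elif any(b == "*" and a != "*" for a, b in zip(p0, p1)):
            out[p] = "NONSENSE"
        else:
            out[p] = "MISSENSE"
    return out


def test_enumeration_agrees_with_translation_oracle_on_random_genes(rng):
    """Codon-level classification vs end-to-end translate-and-diff, both strands,
    multi-exon genes with junction-spanning codons."""
    for trial in range(40):
        L = 6000
        seq = "".join(rng.choice(list("ACGT"), size=L))
        strand = "+" if trial % 2 == 0 else "-"
        tss = 1000 if strand == "+" else 5000
        gene = _make_gene(f"g{trial}", "chr1", strand, tss, rng)
        genome = make_genome(chr1=seq)
        primed = enumerate_primed_sites(genome, [gene], beta_min=None, collapse=False)
        oracle = _oracle_consequences(genome, gene)
        got = dict(zip(primed["pos"], primed["consequence"]))
        assert got == oracle


def test_strand_duality_of_consequence_counts(rng):
    """Opposite-strand genes on the reverse-complement genome give identical
    consequence counts."""
    L = 5000
    seq = "".join(rng.choice(list("ACGT"), size=L))
    gene = _make_gene("g", "chr1", "+", 500, rng)
    fwd = enumerate_primed_sites(make_genome(chr1=seq), [gene], beta_min=None)
    mirror = GeneModel(
        "g", "chr1", "-", L - gene.tx_end, L - gene.tx_start,
        L - gene.cds_end, L - gene.cds_start,
        [(L - e, L - s) for s, e in reversed(gene.exons)],
    )
    rev = enumerate_primed_sites(make_genome(chr1=revcomp(seq)), [mirror], beta_min=None)
    assert (
        fwd["consequence"].value_counts().to_dict()
        == rev["consequence"].value_counts().to_dict()
    )


def test_beta_threshold_filters_sites():
    seq = "ATGCGATAA"  # codon CGA at positions 3-5
    genome = make_genome(chr1=seq)
    gene = GeneModel("g", "chr1", "+", 0, 9, 0, 9, [(0, 9)])
    beta = pd.DataFrame({"chrom": ["chr1"], "pos": [3], "beta": [0.9]})
    hyper = enumerate_primed_sites(genome, [gene], site_beta=beta, beta_min=0.67)
    assert set(hyper["pos"]) == {3, 4}  # both bases of the hyper dinucleotide
    hypo = enumerate_primed_sites(
        genome, [gene], site_beta=beta.assign(beta=0.2), beta_min=0.67
    )
    assert len(hypo) == 0
    unfiltered = enumerate_primed_sites(genome, [gene], beta_min=None)
    assert set(unfiltered["pos"]) == {3, 4}
    # C>T at codon offset 0 of CGA -> TGA
    row = unfiltered[unfiltered.pos == 3].iloc[0]
    assert (row.ref, row.alt, row.consequence) == ("C", "T", "NONSENSE")


def test_cross_with_observed_matches_exact_events():
    primed = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"], "pos": [3, 4], "ref": ["C", "G"],
            "alt": ["T", "A"], "consequence": ["NONSENSE", "MISSENSE"],
        }
    )
    events = [
        VariantEvent("chr1", 3, "C", "T", ac=1, af=0.001),
        VariantEvent("chr1", 4, "G", "C", ac=5, af=0.01),  # mismatching alt
    ]
    out = cross_with_observed(primed, events)
    assert out.loc[out.pos == 3, "observed"].iloc[0]
    assert out.loc[out.pos == 3, "ac"].iloc[0] == 1
    assert not out.loc[out.pos == 4, "observed"].iloc[0]


def test_ac_spectrum_proportions():
    df = pd.DataFrame(
        {
            "consequence": ["SILENT"] * 4 + ["NONSENSE"] * 2,
            "observed": [True] * 4 + [True, False],
            "ac": [1.0, 1.0, 6.0, 6.0, 1.0, np.nan],
        }
    )
    out = ac_spectrum(df).set_index(["consequence", "ac_bin"])
    assert out.loc[("SILENT", "AC=1"), "proportion"] == pytest.approx(0.5)
    assert out.loc[("SILENT", "AC>5"), "proportion"] == pytest.approx(0.5)
    assert out.loc[("NONSENSE", "AC=1"), "proportion"] == pytest.approx(1.0)
    sums = out.reset_index().groupby("consequence")["proportion"].sum()
    assert np.allclose(sums, 1.0)
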