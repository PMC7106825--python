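"""Island calling vs a brute-force window oracle, classification, distances."""

import numpy as np
import pytest

from cpgscape.cgi import (
    call_cgis,
    classify_cgis,
    derive_shores,
    gardiner_garden_stats,
    load_cgis_bed,
    signed_distances,
)
from cpgscape.genes import GeneModel

from .conftest import make_genome


def bruteforce_call(seq: str, window: int = 200):
    """Independent oracle: score every window, merge, re-score merged segments."""
    qual = []
    for s in range(0, len(seq) - window + 1):
        w = seq[s : s + window]
        c, g, cpg = w.count("C"), w.count("G"), w.count("CG")
        gc = (c + g) / window
        oe = cpg * window / (c * g) if c and g else 0.0
        if gc >= 0.5 and oe > 0.6:
            qual.append([s, s + window])
    merged = []
    for s, e in qual:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        seg = seq[s:e]
        c, g, cpg = seg.count("C"), seg.count("G"), seg.count("CG")
        gc = (c + g) / (e - s)
        oe = cpg * (e - s) / (c * g) if c and g else 0.0
        if gc >= 0.5 and oe > 0.6 and (e - s) > 200:
            out.append((s, e))
    return out


def _blocky_sequence(rng, n_blocks=20, block=500):
    """Composition-varying sequence so some windows qualify and some fail."""
    parts = []
    for _ in range(n_blocks):
        gc = rng.uniform(0.3, 0.8)
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        parts.append("".join(rng.choice(list("ACGT"), size=block, p=p)))
    return "".join(parts)


def test_saturated_cg_repeat_is_one_island():
    seq = "CG" * 150
    g = make_genome(chr1=seq)
    islands = call_cgis(g)
    assert len(islands) == 1
    isl = islands[0]
    assert (isl.start, isl.end) == (0, 300)
    assert isl.gc_fraction == 1.0
    assert isl.obs_exp_ratio == pytest.approx((150 * 300) / (150 * 150))


def test_poly_a_has_no_island():
    g = make_genome(chr1="A" * 300)
    assert call_cgis(g) == []


def test_planted_island_recovered_within_window_slack(rng):
    gc_bg, gc_isl = 0.40, 0.70
    bg = "".join(rng.choice(list("ACGT"), size=1000,
                            p=[(1 - gc_bg) / 2, gc_bg / 2, gc_bg / 2, (1 - gc_bg) / 2]))
    # deplete background CpGs so obs/exp fails outside the insert
    bg = bg.replace("CG", "CA")
    isl = "".join(rng.choice(list("ACGT"), size=400,
                             p=[(1 - gc_isl) / 2, gc_isl / 2, gc_isl / 2, (1 - gc_isl) / 2]))
    seq = bg[:500] + isl + bg[500:]
    called = call_cgis(make_genome(chr1=seq))
    assert len(called) == 1
    s, e = called[0].start, called[0].end
    assert abs(s - 500) < 200 and abs(e - 900) < 200
    assert bruteforce_call(seq) == [(s, e)]


def test_caller_matches_bruteforce_on_varied_sequences(rng):
    for _ in range(8):
        seq = _blocky_sequence(rng, n_blocks=10, block=400)
        got = [(i.start, i.end) for i in call_cgis(make_genome(chr1=seq))]
        assert got == bruteforce_call(seq)


def test_called_islands_pass_criteria_when_rescored(rng):
    seq = _blocky_sequence(rng)
    g = make_genome(chr1=seq)
    for isl in call_cgis(g):
        gc, oe = gardiner_garden_stats(seq[isl.start : isl.end])
        assert gc >= 0.5 and oe > 0.6 and isl.length > 200


def test_no_recheck_keeps_raw_unions(rng):
    seq = _blocky_sequence(rng)
    g = make_genome(chr1=seq)
    raw = call_cgis(g, recheck=False)
    checked = call_cgis(g, recheck=True)
    spans = {(i.start, i.end) for i in raw}
    assert {(i.start, i.end) for i in checked} <= spans


def test_short_chromosome_skipped_with_warning(caplog):
    g = make_genome(chr1="CG" * 50)  # 100 bp < window
    with caplog.at_level("WARNING"):
        assert call_cgis(g) == []
    assert "shorter than window" in caplog.text


# --- BED ingestion ---------------------------------------------------------


def test_load_bed_sorts_and_merges(tmp_path):
    bed = tmp_path / "cgi.bed"
    bed.write_text("chr1\t100\t300\nchr1\t250\t400\nchr2\t0\t500\n")
    islands = load_cgis_bed(str(bed))
    assert [(i.chrom, i.start, i.end) for i in islands] == [
        ("chr1", 100, 400),
        ("chr2", 0, 500),
    ]


def test_load_bed_errors_and_unknown_chrom(tmp_path, caplog):
    bad = tmp_path / "bad.bed"
    bad.write_text("chr1\t100\n")
    with pytest.raises(ValueError, match=":1"):
        load_cgis_bed(str(bad))
    rev = tmp_path / "rev.bed"
    rev.write_text("chr1\t300\t100\n")
    with pytest.raises(ValueError, match="end <= start"):
        load_cgis_bed(str(rev))
    drop = tmp_path / "drop.bed"
    drop.write_text("chr1\t0\t300\nchr9\t0\t300\n")
    g = make_genome(chr1="A" * 400)
    with caplog.at_level("WARNING"):
        islands = load_cgis_bed(str(drop), g)
    assert len(islands) == 1 and "chr9" in caplog.text


# --- classification --------------------------------------------------------


def _cgi(chrom, start, end):
    from cpgscape.cgi import CpGIsland

    return CpGIsland(chrom, start, end)


def test_classification_rules():
    coding = GeneModel("c", "chr1", "+", 1000, 8000, 1200, 7800, [(1000, 8000)])
    # TSS window hit
    isl = _cgi("chr1", 950, 1300)
    assert classify_cgis([isl], [coding])[0].cgi_class == "TSS_CODING"
    # body hit only
    isl = _cgi("chr1", 5000, 5400)
    assert classify_cgis([isl], [coding])[0].cgi_class == "INTRAGENIC_CODING"
    # no gene at all
    isl = _cgi("chr1", 20000, 20400)
    assert classify_cgis([isl], [coding])[0].cgi_class == "INTERGENIC"
    assert classify_cgis([_cgi("chr1", 0, 300)], [])[0].cgi_class == "INTERGENIC"


def test_tss_hit_outranks_body_hit_from_same_gene():
    coding = GeneModel("c", "chr1", "+", 1000, 8000, 1200, 7800, [(1000, 8000)])
    isl = _cgi("chr1", 950, 1300)  # overlaps both the TSS window and the body
    assert classify_cgis([isl], [coding])[0].cgi_class == "TSS_CODING"


def test_distinct_labels_from_different_genes_give_misc():
    coding = GeneModel("c", "chr1", "+", 1000, 4000, 1100, 3900, [(1000, 4000)])
    noncod = GeneModel("n", "chr1", "+", 500, 2000, 500, 500, [(500, 2000)])
    isl = _cgi("chr1", 950, 1300)  # coding TSS + noncoding body
    assert classify_cgis([isl], [coding, noncod])[0].cgi_class == "MISC"


def test_minus_strand_tss_is_tx_end():
    gene = GeneModel("m", "chr1", "-", 1000, 5000, 1100, 4900, [(1000, 5000)])
    isl = _cgi("chr1", 4950, 5200)  # overlaps tss=4999 +/- 100
    assert classify_cgis([isl], [gene])[0].cgi_class == "TSS_CODING"


def test_classification_is_a_partition(rng):
    genes = [
        GeneModel("a", "chr1", "+", 1000, 4000, 1100, 3900, [(1000, 4000)]),
        GeneModel("b", "chr1", "-", 6000, 9000, 6000, 6000, [(6000, 9000)]),
    ]
    islands = [_cgi("chr1", int(s), int(s) + 300) for s in rng.integers(0, 12000, size=30)]
    classify_cgis(islands, genes)
    assert all(i.cgi_class is not None for i in islands)


# --- distances and shores --------------------------------------------------


def test_signed_distance_convention():
    cgis = [_cgi("chr1", 1000, 1500)]
    d, idx = signed_distances(np.array([800, 1600, 1200]), cgis)
    assert d[0] == -200
    assert d[1] == 100
    assert np.isnan(d[2]) and idx[2] == 0  # inside: IN_CGI marker


def test_distance_tie_breaks_to_lower_coordinate_island():
    cgis = [_cgi("chr1", 0, 100), _cgi("chr1", 300, 400)]
    d, idx = signed_distances(np.array([200]), cgis)  # 100 from both borders
    assert idx[0] == 0 and d[0] == 100


def test_distance_missing_when_no_islands():
    d, idx = signed_distances(np.array([5, 10]), [])
    assert np.isnan(d).all() and (idx == -1).all()


def test_mirror_antisymmetry_of_distances(rng):
    """Mirroring the chromosome maps outside-site distances d -> -d - 2
    (the dinucleotide anchor shifts by 2 under reverse complement)."""
    L = 10_000
    cgis = [_cgi("chr1", 2000, 2600), _cgi("chr1", 6000, 6500)]
    mirrored = [_cgi("chr1", L - 6500, L - 6000), _cgi("chr1", L - 2600, L - 2000)]
    pos = rng.integers(0, L - 2, size=400)
    d, _ = signed_distances(np.sort(pos), cgis)
    dm, _ = signed_distances(np.sort(L - 2 - pos), mirrored)
    dm = dm[::-1]  # back into the original site order
    both = ~np.isnan(d) & ~np.isnan(dm)
    assert np.all(dm[both] == -d[both] - 2)


def test_shores_clipped_at_neighbours_and_ends():
    cgis = [_cgi("chr1", 500, 1000), _cgi("chr1", 2000, 2500)]
    shores = derive_shores(cgis, {"chr1": 3000}, width=2000)
    spans = {(s.side, s.start, s.end) for s in shores}
    assert ("left", 0, 500) in spans  # clipped at chromosome start
    assert ("right", 1000, 2000) in spans  # clipped at the neighbour island
    assert ("left", 1000, 2000) in spans
    assert ("right", 2500, 3000) in spans  # clipped at chromosome end
    for s in shores:
        assert s.end <= s.parent.start or s.start >= s.parent.end
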