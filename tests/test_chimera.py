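"""Local alignment, self-homology, TM heuristic and the 0-4 rubric."""

import numpy as np
import pytest

from chimorf.chimera import (ChimeraHit, SelfHomologySearcher, TMPrediction,
                             annotate_hit_feature, find_self_homology,
                             nearest_gene, predict_tm_helices,
                             score_candidate, smith_waterman)
from chimorf.orfs import OrfRecord, scan_orfs
from chimorf.seqio import GeneFeature, GenomeSequence, revcomp
from conftest import random_seq

# --- Smith-Waterman --------------------------------------------------------


def gotoh_oracle(a, b, match=2, mismatch=-3, gap_open=-5, gap_extend=-2):
    """Independent affine-gap local-alignment score (plain DP, no traceback)."""
    NEG = -10**9
    m, n = len(a), len(b)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def test_identical_twenty_mers():
    aln = smith_waterman("ACGTACGTACGTACGTACGT", "ACGTACGTACGTACGTACGT")
    assert (aln.score, aln.identity_pct, aln.match_length) == (40, 100, 20)
    assert (aln.subject_start, aln.subject_stop) == (1, 20)


def test_disjoint_alphabets_score_at_most_single_match():
    aln = smith_waterman("AAAA", "CCCC")
    assert aln is None
    aln = smith_waterman("AAAA", "CCAC")
    assert aln is not None and aln.score <= 2


def test_n_never_matches():
    assert smith_waterman("NNNN", "NNNN") is None


def test_gap_costs_are_affine():
    # bridging a 2 bp insertion costs open+extend = 7, leaving 12*2-7
    aln = smith_waterman("AAAAAATTTTTT", "AAAAAAGGTTTTTT")
    assert aln.score == 12 * 2 - 5 - 2
    assert aln.columns == 14 and aln.matches == 12


def test_matches_exhaustive_oracle_on_short_strings():
    rng = np.random.default_rng(10)
    for _ in range(300):
        a = random_seq(rng, int(rng.integers(1, 13)))
        b = random_seq(rng, int(rng.integers(1, 13)))
        aln = smith_waterman(a, b)
        got = aln.score if aln else 0
        assert got == gotoh_oracle(a, b), (a, b)


def test_alignment_score_is_self_consistent():
    """Recomputing the score from matches/columns bounds the reported one."""
    rng = np.random.default_rng(11)
    for _ in range(50):
        a = random_seq(rng, 40)
        b = random_seq(rng, 60)
        aln = smith_waterman(a, b)
        if aln is None:
            continue
        mismatch_and_gap = aln.columns - aln.matches
        assert aln.score <= 2 * aln.matches
        assert aln.score >= 2 * aln.matches - 5 * mismatch_and_gap


# --- self-homology ---------------------------------------------------------


def _genome_with_copy(rng, frag_len, reverse=False):
    """An ORF-bearing genome whose ORF carries an exact distal copy.

    The copy is fenced by N runs: N never matches, so the optimal local
    alignment ends exactly at the planted copy on either strand.
    """
    stops = ("TAA", "TAG", "TGA")
    codons = []
    while len(codons) < 110:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in stops:
            codons.append(c)
    orf_nt = "ATG" + "".join(codons) + "TAA"
    frag = orf_nt[30:30 + frag_len]
    left = random_seq(rng, 2000)
    right = random_seq(rng, 2000)
    if frag_len:
        insert = "NNNNNN" + (revcomp(frag) if reverse else frag) + "NNNNNN"
    else:
        insert = ""
    seq = left + "TAA" + orf_nt + right + insert + random_seq(rng, 500)
    g = GenomeSequence("g", seq, circular=False)
    orf_start = len(left) + 3 + 1
    orf = OrfRecord("q", orf_start, orf_start + len(orf_nt) - 1, "+", 0,
                    len(orf_nt), "")
    frag_start = len(left) + 3 + len(orf_nt) + 2000 + 7
    return g, orf, (frag_start, frag_start + frag_len - 1)


def test_unique_orf_has_no_hits():
    rng = np.random.default_rng(12)
    g, orf, _ = _genome_with_copy(rng, 0)
    assert find_self_homology(orf, g) == []


def test_planted_forward_copy_found_exactly():
    rng = np.random.default_rng(13)
    g, orf, (fs, fe) = _genome_with_copy(rng, 60)
    (hit,) = find_self_homology(orf, g)
    assert (hit.subject_start, hit.subject_stop) == (fs, fe)
    assert hit.match_length == 60 and hit.identity_pct == 100


def test_planted_reverse_copy_uses_descending_coordinates():
    rng = np.random.default_rng(14)
    g, orf, (fs, fe) = _genome_with_copy(rng, 72, reverse=True)
    (hit,) = find_self_homology(orf, g)
    assert hit.subject_start > hit.subject_stop  # reverse-strand convention
    assert (hit.subject_stop, hit.subject_start) == (fs, fe)
    assert hit.match_length == 72 and hit.identity_pct == 100


def test_twenty_bp_hit_passes_sixteen_bp_floor():
    rng = np.random.default_rng(15)
    g, orf, (fs, fe) = _genome_with_copy(rng, 20)
    (hit,) = find_self_homology(orf, g)
    assert hit.match_length == fe - fs + 1 == 20
    assert hit.identity_pct == 100


def test_short_copies_fail_the_floor():
    rng = np.random.default_rng(16)
    g, orf, _ = _genome_with_copy(rng, 12)
    assert find_self_homology(orf, g) == []


def test_self_locus_never_reported(default_fixture):
    genome, _, truth, _ = default_fixture
    searcher = SelfHomologySearcher(genome)
    for orf, _, _, _ in truth.planted_orfs:
        for hit in find_self_homology(orf, genome, searcher=searcher):
            lo, hi = hit.interval()
            assert hi < orf.start or lo > orf.stop


def test_hit_feature_annotation():
    feats = [GeneFeature("atp1", "protein", 1000, 2000, "+"),
             GeneFeature("nad4", "protein", 1900, 2900, "+")]
    orf_loci = [OrfRecord("o1", 5000, 5500, "+", 0, 501, "")]
    h = ChimeraHit("q", 1100, 1200, 100, 50)
    assert annotate_hit_feature(h, feats, 10000).subject_feature == "atp1"
    h = ChimeraHit("q", 1950, 2050, 100, 50)  # larger overlap with nad4
    assert annotate_hit_feature(h, feats, 10000).subject_feature == "nad4"
    h = ChimeraHit("q", 5100, 5200, 100, 50)
    assert annotate_hit_feature(h, feats, 10000, orf_loci).subject_feature == "ORF"
    h = ChimeraHit("q", 8000, 8100, 100, 50)
    assert annotate_hit_feature(h, feats, 10000, orf_loci).subject_feature == "—"


# --- transmembrane heuristic ----------------------------------------------


def test_hydrophilic_peptide_has_no_helix():
    assert predict_tm_helices("D" * 30).helix_count == 0


def test_single_hydrophobic_stretch_is_one_helix():
    pep = "D" * 10 + "L" * 25 + "D" * 10
    tm = predict_tm_helices(pep)
    assert tm.helix_count == 1
    # direct window-mean check: every marked window overlaps the L stretch
    for s, e in tm.segments:
        assert e >= 11 and s <= 45


def test_two_separated_stretches_are_two_helices():
    pep = "L" * 25 + "D" * 30 + "L" * 25
    assert predict_tm_helices(pep).helix_count == 2


def test_non_standard_residue_reported_with_position():
    with pytest.raises(ValueError, match="position 3"):
        predict_tm_helices("ADXDD")


def test_threshold_window_mean():
    # alanine (1.8) exceeds the 1.6 default; one aspartate dilutes the
    # 19-mer window mean to (18*1.8 - 3.5)/19 = 1.52 < 1.6
    assert predict_tm_helices("A" * 19).helix_count == 1
    assert predict_tm_helices("A" * 18 + "D").helix_count == 0


# --- proximity and scoring -------------------------------------------------


def _orf(start, stop):
    return OrfRecord(f"o{start}", start, stop, "+", 0, stop - start + 1, "")


def test_nearest_gene_overlap_and_range():
    feats = [GeneFeature("nad7", "protein", 900, 1800, "+"),
             GeneFeature("cox3", "protein", 9000, 9600, "+")]
    assert nearest_gene(_orf(1500, 2200), feats, 20000) == ("nad7", 0)
    assert nearest_gene(_orf(2300, 2900), feats, 20000) == ("nad7", 499)
    assert nearest_gene(_orf(4000, 4600), feats, 20000) is None  # > 1 kb


def test_nearest_gene_across_circular_origin():
    feats = [GeneFeature("atp9", "protein", 19000, 19500, "+")]
    # gene ends 500 bp before the ORF start, measured across the origin
    assert nearest_gene(_orf(1, 600), feats, 20000) == ("atp9", 500)
    assert nearest_gene(_orf(1, 600), feats, 20000, circular=False) is None


def test_score_components_and_retention():
    orf = _orf(100, 500)
    hit_orf = ChimeraHit("o100", 5000, 5100, 98, 50, "ORF")
    hit_atp = ChimeraHit("o100", 6000, 6050, 100, 50, "atp9")
    tm1 = TMPrediction(1, [(1, 19)])
    tm0 = TMPrediction(0, [])
    # the printed-table row-1 composition: ORF hit, nearby gene, one helix
    s = score_candidate(orf, [hit_orf], tm1, ("cox3", 120))
    assert (s.parts_of_other, s.proximity, s.hydrophobic, s.atp_bonus) == \
        (1, 1, 1, 0)
    assert s.total == 3 and s.retained
    s = score_candidate(orf, [], tm0, None)
    assert s.total == 0 and not s.retained
    s = score_candidate(orf, [hit_atp], tm1, ("nad5", 10))
    assert s.total == 4 and s.retained
    s = score_candidate(orf, [hit_atp], tm0, None)
    assert s.total == 2 and not s.retained


def test_planted_candidates_score_as_constructed(default_fixture):
    genome, feats, truth, _ = default_fixture
    searcher = SelfHomologySearcher(genome)
    all_orfs = scan_orfs(genome)
    for orf, donor, donor_iv, expected in truth.planted_orfs:
        hits = find_self_homology(orf, genome, searcher=searcher)
        for h in hits:
            annotate_hit_feature(h, feats, genome.length, all_orfs)
        s = score_candidate(orf, hits, predict_tm_helices(orf.peptide),
                            nearest_gene(orf, feats, genome.length))
        assert s.total == expected
        # the reported hit points at the planted donor fragment locus
        # (boundaries may drift a base or two where flanks happen to align)
        def covers(h):
            lo, hi = h.interval()
            overlap = min(hi, donor_iv[1]) - max(lo, donor_iv[0]) + 1
            return overlap >= donor_iv[1] - donor_iv[0] - 1 and \
                h.identity_pct >= 95
        assert any(covers(h) for h in hits)
    for orf in truth.planted_decoys:
        hits = find_self_homology(orf, genome, searcher=searcher)
        s = score_candidate(orf, hits, predict_tm_helices(orf.peptide),
                            nearest_gene(orf, feats, genome.length))
        # decoys can never satisfy the constructed components; a chance
        # sequence coincidence may contribute at most the parts-of-other
        # point, which cannot reach the >= 3 retention bar
        assert (s.hydrophobic, s.proximity, s.atp_bonus) == (0, 0, 0)
        assert s.total <= 1 and not s.retained
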