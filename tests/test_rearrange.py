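"""Anchor indexing, chaining, breakpoint calling and read support."""

import numpy as np
import pytest

from chimorf.rearrange import (Breakpoint, build_anchor_index,
                               call_breakpoints, chain_anchors,
                               filter_by_read_support)
from chimorf.seqio import GenomeSequence, revcomp
from chimorf.simulate import derive_rearranged, generate_reference, simulate_reads
from conftest import random_seq


def test_index_excludes_repeats():
    # every k-mer of a doubled sequence occurs twice, so none is indexed;
    # the unrepeated flank remains indexable
    rng = np.random.default_rng(0)
    repeat = random_seq(rng, 40)
    flank = random_seq(rng, 40)
    ref = GenomeSequence("r", repeat * 2 + flank, circular=False)
    idx = build_anchor_index(ref, 11)
    for kmer, pos in idx.index.items():
        # k-mers fully inside either repeat copy occur twice -> excluded
        assert not (pos <= 30 or 41 <= pos <= 70)
    ref_unique = GenomeSequence("r", repeat + flank, circular=False)
    assert len(build_anchor_index(ref_unique, 11)) > len(idx)


def test_index_k_validation(linear_genome):
    g = linear_genome(random_seq(np.random.default_rng(1), 100))
    for bad_k in (10, 33, 20):
        with pytest.raises(ValueError):
            build_anchor_index(g, bad_k)


def test_index_density_on_random_sequence(linear_genome):
    g = linear_genome(random_seq(np.random.default_rng(2), 10_000))
    idx = build_anchor_index(g, 21)
    n_positions = g.length - 20
    assert len(idx) >= 0.99 * n_positions
    # brute-force uniqueness check on a sample of indexed k-mers
    items = sorted(idx.index.items())[:50]
    for kmer, pos in items:
        assert g.seq[pos - 1:pos + 20] == kmer
        assert g.seq.count(kmer) + g.seq.count(revcomp(kmer)) == 1


def test_index_spans_circular_origin():
    rng = np.random.default_rng(3)
    seq = random_seq(rng, 200)
    g = GenomeSequence("c", seq, circular=True)
    idx = build_anchor_index(g, 21)
    wrap_kmer = seq[-10:] + seq[:11]
    if wrap_kmer in idx.index:
        assert idx.index[wrap_kmer] == 191


def test_identity_query_single_chain(linear_genome):
    seq = random_seq(np.random.default_rng(4), 5000)
    ref = linear_genome(seq)
    idx = build_anchor_index(ref, 21)
    chains = chain_anchors(linear_genome(seq), idx)
    assert len(chains) == 1
    c = chains[0]
    assert c.orientation == "forward"
    assert c.query_end - c.query_start + 1 >= 5000 - 2 * 20
    assert call_breakpoints(chains, "self", 5000, circular=False) == []


def test_no_shared_kmers_no_chains(linear_genome):
    ref = linear_genome("A" * 30 + random_seq(np.random.default_rng(5), 1000))
    idx = build_anchor_index(ref, 21)
    q = linear_genome(random_seq(np.random.default_rng(6), 500))
    assert chain_anchors(q, idx) == []


def test_planted_inversion_three_chains_and_two_breakpoints(linear_genome):
    rng = np.random.default_rng(7)
    seq = random_seq(rng, 9000)
    ref = linear_genome(seq)
    idx = build_anchor_index(ref, 21)
    q = seq[:3000] + revcomp(seq[3000:6000]) + seq[6000:]
    chains = chain_anchors(linear_genome(q), idx)
    assert [c.orientation for c in chains] == ["forward", "reverse", "forward"]
    bps = call_breakpoints(chains, "cmp", 9000, circular=False)
    assert len(bps) == 2
    assert all(b.kind == "inversion_junction" for b in bps)
    for b, true_pos in zip(bps, (3000, 6000)):
        assert abs(b.ref_pos - true_pos) <= 20  # within k-1


def test_chain_anchors_are_exactly_the_colinear_matches(linear_genome):
    """On a toy reference every unique shared k-mer lands in the one chain."""
    rng = np.random.default_rng(8)
    seq = random_seq(rng, 300)
    ref = linear_genome(seq)
    idx = build_anchor_index(ref, 11)
    (chain,) = chain_anchors(linear_genome(seq), idx, min_anchors=3)
    expected = sorted(pos for kmer, pos in idx.index.items())
    assert [a.ref_pos for a in chain.anchors] == expected
    assert [a.query_pos for a in chain.anchors] == expected


def test_planted_translocation_junctions(default_fixture):
    genome, _, _, _ = default_fixture
    der, truth = derive_rearranged(
        genome, 99, [{"kind": "translocation", "start": 40001, "stop": 45000,
                      "insert_after": 70000}])
    idx = build_anchor_index(genome, 21)
    bps = call_breakpoints(chain_anchors(der, idx), "cmp", genome.length)
    for tb in truth.planted_breakpoints:
        assert min(abs(b.ref_pos - tb.ref_pos) for b in bps) <= 20


def test_symmetry_of_breakpoint_sets(linear_genome):
    """A vs B and B vs A junctions correspond within k-1 bp."""
    rng = np.random.default_rng(9)
    a_seq = random_seq(rng, 12000)
    a = GenomeSequence("a", a_seq, circular=True)
    b, _ = derive_rearranged(a, 10, [{"kind": "inversion", "start": 4001,
                                      "stop": 8000}])
    bps_ab = call_breakpoints(chain_anchors(b, build_anchor_index(a, 21)),
                              "x", a.length)
    bps_ba = call_breakpoints(chain_anchors(a, build_anchor_index(b, 21)),
                              "x", b.length)
    assert len(bps_ab) == len(bps_ba) == 2
    for p in bps_ab:
        assert min(abs(p.ref_pos - q.ref_pos) for q in bps_ba) <= 20


def test_no_false_positives_on_identity_many_seeds():
    for seed in range(100):
        seq = random_seq(np.random.default_rng(seed), 2000)
        g = GenomeSequence(f"g{seed}", seq, circular=True)
        idx = build_anchor_index(g, 21)
        assert call_breakpoints(chain_anchors(g, idx), "self", g.length) == []


@pytest.fixture(scope="module")
def support_fixture():
    g, _ = generate_reference(11, length=40_000, n_genes=8)
    der, _ = derive_rearranged(g, 12, [{"kind": "inversion",
                                        "start": 12001, "stop": 20000}])
    idx = build_anchor_index(g, 21)
    bps = call_breakpoints(chain_anchors(der, idx), "cmp", g.length)
    n = int(23 * g.length / 400)  # ~23x
    return g, der, idx, bps, n


class TestReadSupport:
    def fresh(self, bps):
        return [Breakpoint(b.ref_pos, b.kind, 1.0, b.comparator_id)
                for b in bps]

    def test_derived_reads_full_support(self, support_fixture):
        g, der, idx, bps, n = support_fixture
        kept = filter_by_read_support(self.fresh(bps),
                                      simulate_reads(der, 13, n), idx)
        assert len(kept) == len(bps) == 2
        assert all(b.support_fraction == 1.0 for b in kept)

    def test_reference_reads_zero_support(self, support_fixture):
        g, der, idx, bps, n = support_fixture
        fresh = self.fresh(bps)
        kept = filter_by_read_support(fresh, simulate_reads(g, 14, n), idx)
        assert kept == []
        assert all(b.support_fraction == 0.0 for b in fresh)

    def test_mixture_rejected_at_strict_threshold(self, support_fixture):
        g, der, idx, bps, n = support_fixture
        mix = simulate_reads(der, 13, n) + simulate_reads(g, 14, n)
        fresh = self.fresh(bps)
        kept = filter_by_read_support(fresh, mix, idx)
        # diluted support sits strictly between the pure-read extremes and
        # fails the strict >60% retention rule
        for b in fresh:
            assert 0.0 < b.support_fraction < 1.0
            assert b.support_fraction <= 0.6
        assert kept == []

    def test_breakpoint_with_no_reads_dropped(self, support_fixture, caplog):
        g, der, idx, bps, n = support_fixture
        kept = filter_by_read_support(self.fresh(bps), [], idx)
        assert kept == []
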