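from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seedbin as sb
from seedbin.overlap import OverlapGraph

from conftest import make_reads

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)
read_lists = st.lists(
    st.text(alphabet="ACGT", min_size=10, max_size=40), min_size=2, max_size=12
)


@pytest.mark.parametrize(
    "seq,rc",
    [("AAAA", "TTTT"), ("ACCC", "GGGT"), ("GCGC", "GCGC"), ("CCTAA", "TTAGG")],
)
def test_reverse_complement(seq, rc):
    assert sb.reverse_complement(seq) == rc


def test_reverse_complement_rejects_n():
    with pytest.raises(ValueError):
        sb.reverse_complement("ACGN")


@pytest.mark.parametrize(
    "kmer,canon",
    [("TTTT", "AAAA"), ("ACGT", "ACGT"), ("GGGT", "ACCC")],
)
def test_canonical_form(kmer, canon):
    assert sb.canonical_form(kmer) == canon


@given(dna)
def test_canonical_form_strand_symmetric(seq):
    assert sb.canonical_form(seq) == sb.canonical_form(sb.reverse_complement(seq))


def test_extract_qmers_examples():
    assert sb.extract_qmers("CCTAA", 5) == {"CCTAA"}
    assert sb.extract_qmers("CCT", 5) == set()
    assert sb.extract_qmers("AAGAA", 3, canonical=False) == {"AAG", "AGA", "GAA"}


def test_extract_qmers_skips_n_windows():
    assert sb.extract_qmers("AANAA", 2, canonical=False) == {"AA"}


def test_shared_qmer_count_examples():
    p4 = sb.OverlapParams(q=4, m=1, canonical=False)
    p5 = sb.OverlapParams(q=5, m=1, canonical=False)
    assert sb.shared_qmer_count("CCTAA", "AAGTG", p4) == 0
    assert sb.shared_qmer_count("CCTAAG", "CTAAGT", p5) == 1
    # identical reads with all-distinct windows share every window
    seq = "ACGTACCGGTTAACG"
    p = sb.OverlapParams(q=6, m=1, canonical=False)
    assert sb.shared_qmer_count(seq, seq, p) == len(seq) - 6 + 1


def test_overlaps_threshold_boundary():
    # 10-base shared block: windows of q=4 give 7 shared q-mers
    a = "ACCGGTTACA" + "TTTTTT"
    b = "GGGGGG" + "ACCGGTTACA"
    p0 = sb.OverlapParams(q=4, m=0, canonical=False)
    assert sb.shared_qmer_count(a, b, p0) == 7
    assert sb.overlaps(a, b, sb.OverlapParams(q=4, m=7, canonical=False))
    assert not sb.overlaps(a, b, sb.OverlapParams(q=4, m=8, canonical=False))


def test_m_zero_floored_to_one():
    p = sb.OverlapParams(q=4, m=0)
    assert p.threshold == 1
    assert not sb.overlaps("AAAATTTT", "GGCCGGCC", p)


def test_graph_disjoint_reads_no_edges():
    reads = make_reads(["AAAAAAAA", "CCCCCCCC", "ACACACAC"])
    g = sb.build_overlap_graph(reads, sb.OverlapParams(q=8, m=1))
    assert g.n_edges == 0


def test_graph_two_copies_length_40():
    seq = "AGCTTCGGATACGATCCGTAGGCTAACGTTAGCCATAGGC"
    assert len(seq) == 40
    reads = make_reads([seq, seq])
    g = sb.build_overlap_graph(reads, sb.OverlapParams(q=30, m=5))
    assert g.n_edges == 1
    assert g.shared_count(0, 1) == 11  # 40 - 30 + 1 windows


def _brute_force_graph(reads, params):
    n = len(reads)
    edges = {}
    for u, v in combinations(range(n), 2):
        c = sb.shared_qmer_count(reads[u], reads[v], params)
        if c >= params.threshold:
            edges[(u, v)] = c
    return OverlapGraph(n, edges)


@settings(deadline=None, max_examples=40)
@given(read_lists, st.integers(1, 3), st.booleans())
def test_index_graph_equals_all_pairs_oracle(seqs, m, canonical):
    reads = make_reads(seqs)
    params = sb.OverlapParams(q=8, m=m, canonical=canonical)
    fast = sb.build_overlap_graph(reads, params)
    brute = _brute_force_graph(reads, params)
    assert fast.edges() == brute.edges()


@settings(deadline=None, max_examples=30)
@given(read_lists)
def test_edge_set_monotone_in_m(seqs):
    reads = make_reads(seqs)
    e = {
        m: {(u, v) for u, v, _ in
            sb.build_overlap_graph(reads, sb.OverlapParams(q=8, m=m)).edges()}
        for m in (1, 2, 3)
    }
    assert e[3] <= e[2] <= e[1]


@settings(deadline=None, max_examples=30)
@given(read_lists, st.data())
def test_canonical_graph_invariant_to_read_strand(seqs, data):
    reads = make_reads(seqs)
    flip = [data.draw(st.booleans()) for _ in seqs]
    flipped = make_reads(
        [sb.reverse_complement(s) if f else s for s, f in zip(seqs, flip)]
    )
    params = sb.OverlapParams(q=8, m=1, canonical=True)
    g1 = sb.build_overlap_graph(reads, params)
    g2 = sb.build_overlap_graph(flipped, params)
    assert [(u, v) for u, v, _ in g1.edges()] == [(u, v) for u, v, _ in g2.edges()]


def test_graph_symmetry_and_no_self_edges(two_species_sim):
    reads, _ = two_species_sim
    subset = sb.ReadSet(list(reads)[:100])
    g = sb.build_overlap_graph(subset, sb.OverlapParams())
    for u, v, _ in g.edges():
        assert u != v
        assert g.has_edge(u, v) and g.has_edge(v, u)
        assert u in g.neighbors(v) and v in g.neighbors(u)


def test_edgelist_dump(tmp_path):
    reads = make_reads(["ACGTACGTAC", "ACGTACGTAC"])
    g = sb.build_overlap_graph(reads, sb.OverlapParams(q=8, m=1))
    p = tmp_path / "edges.tsv"
    g.write_edgelist(p)
    # 3 shared canonical 8-mers (ACGTACGT and GTACGTAC are palindromic)
    assert p.read_text() == "0\t1\t3\n"
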