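from itertools import combinations

import numpy as np
import pytest

import seedbin as sb


def test_degenerate_model_all_a():
    t = np.array([[1.0, 0.0, 0.0, 0.0]])
    spec = sb.SpeciesSpec("a", 50, t, order=0)
    assert sb.generate_genome(spec, rng=0) == "A" * 50


def test_genome_length_exact():
    spec = sb.SpeciesSpec("x", 1234, sb.random_markov(2, rng=0), order=2)
    assert len(sb.generate_genome(spec, rng=1)) == 1234


def test_dinucleotide_frequencies_match_transition_model():
    rng = np.random.default_rng(0)
    t = sb.random_markov(order=1, rng=rng, alpha=1.0)
    spec = sb.SpeciesSpec("x", 100_000, t, order=1)
    g = sb.generate_genome(spec, rng=rng)
    idx = {b: i for i, b in enumerate("ACGT")}
    counts = np.zeros((4, 4))
    for a, b in zip(g, g[1:]):
        counts[idx[a], idx[b]] += 1
    empirical = counts / counts.sum(axis=1, keepdims=True)
    assert np.abs(empirical - t).max() < 0.02


def test_sample_reads_error_free_are_genome_substrings():
    spec = sb.SpeciesSpec("x", 2000, sb.random_markov(2, rng=0))
    g = sb.generate_genome(spec, rng=0)
    reads = sb.sample_reads(
        g, 50, 80, rng=1, species_label="x", error_rate=0.0
    )
    assert len(reads) == 50
    for r in reads:
        window = g[r.truth.start : r.truth.end]
        assert r.seq in (window, sb.reverse_complement(window))
        assert r.truth.end - r.truth.start == 80


def test_sample_reads_substitutions_at_expected_rate():
    spec = sb.SpeciesSpec("x", 20_000, sb.random_markov(2, rng=5))
    g = sb.generate_genome(spec, rng=5)
    reads = sb.sample_reads(
        g, 10, 1000, rng=0, species_label="x", error_rate=0.1
    )

    def hamming(a, b):
        return sum(x != y for x, y in zip(a, b))

    # substitutions always change the base, so the distance to the true
    # strand counts errors exactly
    diffs = sum(
        min(
            hamming(r.seq, g[r.truth.start : r.truth.end]),
            hamming(r.seq, sb.reverse_complement(g[r.truth.start : r.truth.end])),
        )
        for r in reads
    )
    rate = diffs / sum(r.length for r in reads)
    assert 0.08 < rate < 0.12


def test_paired_mode_emits_mate_suffixes():
    spec = sb.SpeciesSpec("x", 3000, sb.random_markov(2, rng=0))
    g = sb.generate_genome(spec, rng=0)
    reads = sb.sample_reads(
        g, 10, 80, rng=1, species_label="x", error_rate=0.0, paired=True
    )
    assert len(reads) == 20
    assert sum(r.id.endswith("/1") for r in reads) == 10
    assert sum(r.id.endswith("/2") for r in reads) == 10
    for r1, r2 in zip(reads[::2], reads[1::2]):
        window = g[r2.truth.start : r2.truth.end]
        assert r2.seq == sb.reverse_complement(window)
        assert r1.truth.start < r2.truth.start


def test_coverage_count_identity():
    sp = sb.SpeciesSpec("x", 4000, sb.random_markov(2, rng=0))
    spec = sb.SimulationSpec(
        species=[sp], read_length=80, coverage=3.0, error_rate=0.0, rng_seed=0
    )
    reads, _ = sb.simulate(spec)
    assert len(reads) == round(3.0 * 4000 / 80)


def test_abundance_apportionment():
    sp1, sp2 = sb.divergent_species_pair(2000, rng=0, abundance_weights=(1, 4))
    spec = sb.SimulationSpec(
        species=[sp1, sp2], read_length=80, n_reads=100, error_rate=0.0, rng_seed=0
    )
    reads, _ = sb.simulate(spec)
    counts = {}
    for r in reads:
        counts[r.truth.species_label] = counts.get(r.truth.species_label, 0) + 1
    assert counts == {"sp1": 20, "sp2": 80}


def test_simulation_spec_validation():
    sp = sb.SpeciesSpec("x", 2000, sb.random_markov(2, rng=0))
    with pytest.raises(ValueError):
        sb.SimulationSpec(species=[sp])  # neither n_reads nor coverage
    with pytest.raises(ValueError):
        sb.SimulationSpec(species=[sp], n_reads=10, coverage=2.0)


def test_true_overlap_examples():
    def read(genome, start, end):
        return sb.Read(
            f"{genome}:{start}", "A" * (end - start),
            truth=sb.ReadTruth("sp", genome, start, end),
        )

    assert sb.true_overlap(read("g1", 1, 6), read("g1", 4, 9))
    assert not sb.true_overlap(read("g1", 1, 6), read("g1", 7, 12))
    assert not sb.true_overlap(read("g1", 1, 6), read("g2", 1, 6))
    with pytest.raises(ValueError):
        sb.true_overlap(sb.Read("x", "AAAA"), read("g1", 0, 4))


def test_grouping_precision_examples():
    reads = sb.ReadSet(
        [
            sb.Read(f"r{i}", "AAAA", truth=sb.ReadTruth("a" if i < 9 else "b", "g", 0, 4))
            for i in range(10)
        ]
        + [
            sb.Read(f"s{i}", "AAAA", truth=sb.ReadTruth("b", "g", 0, 4))
            for i in range(10)
        ]
    )
    mixed = sb.Group(0, tuple(range(10)), (0,), tuple(range(1, 10)))
    singles = [sb.Group(1 + j, (10 + j,), (10 + j,), ()) for j in range(10)]
    assert sb.grouping_precision([mixed] + singles, reads) == pytest.approx(0.95)
    # pure groups give 1.0; order permutation does not matter
    assert sb.grouping_precision(list(reversed(singles)), reads) == 1.0


def test_nonoverlapping_sampler_intervals_disjoint():
    spec = sb.SpeciesSpec("x", 20_000, sb.random_markov(2, rng=0))
    g = sb.generate_genome(spec, rng=0)
    reads = sb.sample_nonoverlapping_reads(
        g, 60, 150, rng=1, species_label="x"
    )
    assert len(reads) == 60
    ivs = sorted((r.truth.start, r.truth.end) for r in reads)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        assert e1 <= s2
    assert all(r.seq == g[r.truth.start : r.truth.end] for r in reads)


def test_cross_species_edges_rare(two_species_sim):
    reads, _ = two_species_sim
    graph = sb.build_overlap_graph(reads, sb.OverlapParams(q=30, m=5))
    read_list = list(reads)
    cross = sum(
        read_list[u].truth.species_label != read_list[v].truth.species_label
        for u, v, _ in graph.edges()
    )
    assert graph.n_edges > 0
    assert cross / graph.n_edges < 0.02


def test_truly_overlapping_reads_detected():
    # same-strand reads sharing >= q + m - 1 = 34 genome bases must overlap
    spec = sb.SpeciesSpec("x", 2000, sb.random_markov(2, rng=3))
    g = sb.generate_genome(spec, rng=3)
    params = sb.OverlapParams(q=30, m=5)
    rng = np.random.default_rng(0)
    for _ in range(20):
        s = int(rng.integers(0, 2000 - 120))
        shift = int(rng.integers(0, 80 - 34 + 1))
        a, b = g[s : s + 80], g[s + shift : s + shift + 80]
        assert sb.overlaps(a, b, params)


def test_seed_reads_mostly_truly_nonoverlapping():
    # deep coverage so seeds grow toward the 9000 bp cap: residual true
    # overlaps (pairs overlapping by < q + m - 1 bases, invisible to the
    # shared-q-mer criterion) are then a small fraction of all seed pairs
    sp = sb.SpeciesSpec("x", 6000, sb.random_markov(2, rng=0))
    spec = sb.SimulationSpec(
        species=[sp], read_length=80, coverage=12.0, error_rate=0.0, rng_seed=0
    )
    reads, _ = sb.simulate(spec)
    graph = sb.build_overlap_graph(reads, sb.OverlapParams(q=30, m=5))
    groups = sb.build_groups(graph, reads, s_max=9000, rng=0)
    read_list = list(reads)
    pairs = 0
    overlapping = 0
    for g in groups:
        for i, j in combinations(g.seed, 2):
            pairs += 1
            if sb.true_overlap(read_list[i], read_list[j]):
                overlapping += 1
    assert pairs > 0
    assert overlapping / pairs < 0.05
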