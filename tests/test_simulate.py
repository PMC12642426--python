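"""Simulator: shearing, assembly order, duplications, reads, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import arraykit.simulate as sim
from arraykit._seq import random_dna, revcomp
from arraykit.adjacency import TypeSequence, adjacency_statistic
from arraykit.records import ReferenceRecord


class TestShearGenome:
    def test_bounds_and_single_fragment(self, small_refs, small_shear):
        g = small_refs["pseudo_stuffer"]
        with pytest.raises(ValueError):
            sim.shear_genome(g, small_shear, 0, seed=1)
        (f,) = sim.shear_genome(g, small_shear, 1, seed=1)
        assert 0 <= f.source_start < f.source_end <= len(g)
        assert small_shear.min_len <= f.length <= small_shear.max_len

    def test_length_distribution_matches_truncated_cdf(self, small_refs, small_shear):
        g = small_refs["pseudo_stuffer"]
        frags = sim.shear_genome(g, small_shear, 10_000, seed=2)
        frac = np.mean([f.length < 1000 for f in frags])
        assert abs(frac - small_shear.fraction_below(1000)) < 0.03

    def test_default_emulates_sub_kb_bulk(self):
        # ~91.5% of carrier fragments under 1 kb with default parameters
        assert abs(sim.ShearParams().fraction_below(1000) - 0.915) < 0.02

    def test_seed_determinism(self, small_refs, small_shear):
        g = small_refs["pseudo_stuffer"]
        a = sim.shear_genome(g, small_shear, 500, seed=3)
        b = sim.shear_genome(g, small_shear, 500, seed=3)
        assert a == b

    def test_max_len_exceeding_genome_is_error(self, small_refs):
        with pytest.raises(ValueError, match="exceeds genome length"):
            sim.shear_genome(
                small_refs["pseudo_stuffer"], sim.ShearParams(max_len=10**7), 5, seed=1
            )


def _tiny_two_class_mix(n, seed, w=None):
    rng = np.random.default_rng(99)
    a = ReferenceRecord("tgA", random_dna(60, rng), "transgene")
    b = ReferenceRecord("selB", random_dna(50, rng), "selection")
    return sim.InjectionMix(
        entries=[sim.MixEntry(a, 1.0), sim.MixEntry(b, 1.0)],
        n_fragments=n,
        clustering_weight=w or {},
        seed=seed,
    )


class TestAssembleArray:
    def test_counts_within_binomial_interval(self):
        mix = _tiny_two_class_mix(4000, seed=5)
        _, truth = sim.assemble_array(mix)
        n_a = sum(f.source_class == "transgene" for f in truth.fragments)
        # binomial 99% interval around n/2
        half, sd = 2000, np.sqrt(4000 * 0.25)
        assert abs(n_a - half) < 2.58 * sd

    def test_w1_order_matches_exchangeable_null(self):
        """At w=1 the order statistic follows the exhaustive multiset null
        (checked on N=6 against full enumeration)."""
        from arraykit.adjacency import exhaustive_test

        counts = {"A": 3, "B": 3}
        rng = np.random.default_rng(17)
        # exact pmf of S under uniform multiset ordering
        import itertools

        orderings = set(itertools.permutations("AAABBB"))
        exact = np.zeros(6)
        for o in orderings:
            s = adjacency_statistic(TypeSequence.from_labels(list(o)), "A")
            exact[s] += 1
        exact /= exact.sum()
        draws = np.zeros(6)
        n_rep = 4000
        for _ in range(n_rep):
            labs = sim.sample_class_order(counts, None, rng)
            draws[adjacency_statistic(TypeSequence.from_labels(labs), "A")] += 1
        from scipy.stats import chisquare

        mask = exact > 0
        stat, p = chisquare(draws[mask], exact[mask] * n_rep)
        assert p > 0.001

    def test_clustering_raises_adjacency(self):
        """w=50 on one class beats the w=1 expectation in >=99/100 runs."""
        rng = np.random.default_rng(23)
        counts = {"sel": 20, "stuf": 40}
        n = sum(counts.values())
        m = counts["sel"]
        expected_null = m * (m - 1) / n  # E[S] for a linear exchangeable order
        wins = 0
        for _ in range(100):
            labs = sim.sample_class_order(counts, {"sel": 50.0}, rng)
            s = adjacency_statistic(TypeSequence.from_labels(labs), "sel")
            wins += s > expected_null
        assert wins >= 99

    def test_truth_tiling_byte_equality(self, small_sim, small_refs):
        assert small_sim.truth.sequence(small_refs) == small_sim.array_seq

    def test_determinism(self, small_refs, small_shear):
        mix = sim.default_mix(small_refs, n_fragments=50, seed=7,
                              shear_params=small_shear)
        s1, t1 = sim.assemble_array(mix)
        s2, t2 = sim.assemble_array(mix)
        assert s1 == s2 and t1.fragments == t2.fragments

    def test_empty_mix_rejected(self):
        with pytest.raises(ValueError, match="no entries"):
            sim.InjectionMix(entries=[], n_fragments=5)

    def test_canonical_truth_has_no_left_extension(self, small_sim, small_refs):
        """Every interior boundary is left-aligned: the right-hand fragment
        cannot be extended one base leftward within its source."""
        frags = small_sim.truth.fragments
        seq = small_sim.array_seq
        offs = small_sim.truth.starts()
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for i in range(1, len(frags)):
            f = frags[i]
            src = small_refs[f.source_id].seq
            if f.strand == "+":
                if f.source_start == 0:
                    continue
                incoming = src[f.source_start - 1]
            else:
                if f.source_end == len(src):
                    continue
                incoming = comp[src[f.source_end]]
            assert incoming != seq[int(offs[i]) - 1]


class TestDuplications:
    def test_zero_events_identity(self, small_sim, small_refs):
        seq, truth = sim.apply_duplications(
            small_sim.array_seq, small_sim.truth, small_refs, 0, seed=1
        )
        assert seq == small_sim.array_seq and truth is small_sim.truth

    def test_single_event_grows_by_copy_length(self, small_refs, small_shear):
        mix = sim.default_mix(small_refs, n_fragments=150, seed=31,
                              shear_params=small_shear)
        seq, truth = sim.assemble_array(mix)
        seq2, truth2 = sim.apply_duplications(
            seq, truth, small_refs, 1, length_range=(5_000, 8_000), seed=2
        )
        (ev,) = truth2.duplications
        assert len(seq2) == len(seq) + ev.length
        assert ev.length >= 5_000
        # the copy is an exact repeat of its origin
        assert seq2[ev.copy[0] : ev.copy[1]] == seq2[ev.origin[0] : ev.origin[1]]
        assert truth2.sequence(small_refs) == seq2

    def test_oversized_event_is_error(self, small_sim, small_refs):
        with pytest.raises(ValueError, match="exceeds array length"):
            sim.apply_duplications(
                small_sim.array_seq, small_sim.truth, small_refs, 1,
                length_range=(10**9, 10**9), seed=1,
            )


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self, rng):
        g = random_dna(4000, rng)
        pairs, truth = sim.simulate_reads(g, 100, 300, 20, 50, 0.0, seed=4)
        for rid, r1, r2 in pairs:
            s, e = truth[rid]
            assert r1 == g[s : s + 100]
            assert r2 == revcomp(g[e - 100 : e])

    def test_coverage_calibration(self, rng):
        g = random_dna(30_000, rng)
        depth, rl = 30, 100
        n_pairs = int(depth * len(g) / (2 * rl))
        pairs, truth = sim.simulate_reads(g, rl, 300, 30, n_pairs, 0.0, seed=5)
        cov = np.zeros(len(g))
        for rid, _, _ in pairs:
            s, e = truth[rid]
            cov[s : s + rl] += 1
            cov[e - rl : e] += 1
        assert abs(cov.mean() - depth) / depth < 0.10

    def test_seed_determinism_bytes(self, rng, tmp_path):
        from arraykit.io import write_fastq_pairs

        g = random_dna(2000, rng)
        files = []
        for run in ("a", "b"):
            pairs, _ = sim.simulate_reads(g, 80, 250, 25, 20, 0.01, seed=6)
            p1, p2 = tmp_path / f"{run}_1.fq", tmp_path / f"{run}_2.fq"
            write_fastq_pairs(pairs, p1, p2)
            files.append((p1.read_bytes(), p2.read_bytes()))
        assert files[0] == files[1]

    def test_short_genome_is_error(self, rng):
        with pytest.raises(ValueError, match="shorter than"):
            sim.simulate_reads(random_dna(100, rng), 50, 300, 10, 5, 0.0, seed=1)


class TestIntegrationStage:
    def test_junctions_recorded_and_flanked(self, small_sim, small_refs):
        from arraykit.attsites import derive_lr, find_att_sites

        sites = sim.default_att_sites()
        attL, attR = derive_lr(sites["attB"], sites["attP"])
        hits = find_att_sites(small_sim.integrated_seq, [attL, attR], 0, "int")
        jl, jr = small_sim.junctions
        assert [(h.kind, h.start) for h in hits] == [("L", jl.start), ("R", jr.start)]
        host = small_refs["host_chr"]
        assert len(small_sim.integrated_seq) == len(host) + len(small_sim.array_seq)


@settings(max_examples=20, deadline=None)
@given(n=st.integers(2, 40), seed=st.integers(0, 2**20))
def test_truth_tiling_property(n, seed):
    """Any mix size/seed: truth fragments tile the emitted array exactly."""
    rng = np.random.default_rng(7)
    stuffer = ReferenceRecord("st", random_dna(5000, rng), "stuffer")
    tg = ReferenceRecord("tg", random_dna(300, rng), "transgene")
    mix = sim.InjectionMix(
        entries=[sim.MixEntry(stuffer, 3.0), sim.MixEntry(tg, 1.0)],
        n_fragments=n,
        shear_params=sim.ShearParams(min_len=30, max_len=400),
        truncation_prob=0.2,
        seed=seed,
    )
    seq, truth = sim.assemble_array(mix)
    assert truth.sequence({"st": stuffer, "tg": tg}) == seq
    offs = truth.starts()
    assert int(offs[-1]) == len(seq)
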