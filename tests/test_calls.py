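"""Exact-match mapper, SAM round trip, evidence collection, call clustering."""

import numpy as np
import pysam
import pytest

import arraykit.simulate as sim
from arraykit._seq import random_dna, revcomp
from arraykit.calls import (
    SplitEvidence,
    cluster_calls,
    collect_evidence,
    naive_map,
)
from arraykit.io import write_sam


@pytest.fixture(scope="module")
def two_refs():
    rng = np.random.default_rng(71)
    return {"chrI": random_dna(8000, rng), "plasmid": random_dna(3000, rng)}


class TestNaiveMap:
    def test_exact_substring_placed(self, two_refs):
        r1 = two_refs["chrI"][1000:1150]
        r2 = revcomp(two_refs["chrI"][1250:1400])
        header, recs = naive_map([("p0", r1, r2)], two_refs)
        prim = [r for r in recs if not r.is_unmapped]
        assert len(prim) == 2
        assert prim[0].reference_name == "chrI"
        assert prim[0].reference_start == 1000
        assert prim[1].reference_start == 1250 and prim[1].is_reverse

    def test_junction_read_split_with_complementary_clips(self, two_refs):
        junction = two_refs["chrI"][500:580] + two_refs["plasmid"][2000:2070]
        mate = revcomp(two_refs["plasmid"][2200:2350])
        header, recs = naive_map([("j0", junction, mate)], two_refs)
        first = [r for r in recs if r.is_read1]
        assert len(first) == 2
        prim = next(r for r in first if not r.is_supplementary)
        supp = next(r for r in first if r.is_supplementary)
        assert {prim.reference_name, supp.reference_name} == {"chrI", "plasmid"}
        # complementary soft-clips tile the read
        cl = sorted([prim.cigarstring, supp.cigarstring])
        assert cl == sorted(["80M70S", "80S70M"])
        assert prim.has_tag("SA") and supp.has_tag("SA")

    def test_absent_read_unmapped(self, two_refs, rng):
        alien = random_dna(150, rng)
        header, recs = naive_map([("a0", alien, alien)], two_refs)
        assert all(r.is_unmapped for r in recs)

    def test_ambiguous_read_unmapped_not_misplaced(self, rng):
        block = random_dna(400, rng)
        refs = {"r1": block + random_dna(400, rng), "r2": block + random_dna(400, rng)}
        read = block[50:200]
        header, recs = naive_map([("x0", read, read)], refs)
        assert all(r.is_unmapped for r in recs)

    def test_sam_round_trip(self, two_refs, tmp_path):
        g = two_refs["chrI"]
        pairs, _ = sim.simulate_reads(g, 100, 300, 20, 40, 0.0, seed=9)
        header, recs = naive_map(pairs, two_refs)
        path = tmp_path / "out.sam"
        write_sam(header, recs, path)
        with pysam.AlignmentFile(str(path), "r") as af:
            back = list(af)
        assert len(back) == len(recs)
        for rec in back:
            if rec.is_unmapped:
                continue
            # CIGAR consumes exactly the stored sequence
            q = sum(l for op, l in rec.cigartuples if op in (0, 1, 4))
            assert q == len(rec.query_sequence)
            assert rec.reference_start >= 0


class TestCollectEvidence:
    def test_host_only_pair_yields_nothing(self, two_refs):
        g = two_refs["chrI"]
        pairs, _ = sim.simulate_reads(g, 100, 300, 20, 30, 0.0, seed=3)
        header, recs = naive_map(pairs, two_refs)
        ev = collect_evidence((header, recs), {"chrI"}, {"plasmid"})
        assert ev == []

    def test_unassigned_reference_is_error(self, two_refs):
        header, recs = naive_map(
            [("p0", two_refs["chrI"][:150], revcomp(two_refs["chrI"][200:350]))],
            two_refs,
        )
        with pytest.raises(ValueError, match="neither host nor payload"):
            collect_evidence((header, recs), {"chrI"}, set())

    def test_overlapping_sets_error(self, two_refs):
        header, recs = naive_map([], two_refs)
        with pytest.raises(ValueError, match="both host and payload"):
            collect_evidence((header, recs), {"chrI"}, {"chrI", "plasmid"})

    def test_split_read_becomes_evidence(self, two_refs):
        junction = two_refs["chrI"][500:580] + two_refs["plasmid"][2000:2070]
        mate = revcomp(two_refs["plasmid"][2100:2250])
        header, recs = naive_map([("j0", junction, mate)], two_refs)
        ev = collect_evidence((header, recs), {"chrI"}, {"plasmid"})
        split = [e for e in ev if e.source == "split"]
        assert len(split) == 1
        e = split[0]
        assert (e.host_chrom, e.side) == ("chrI", "left")
        assert e.host_pos == 580
        assert e.payload_id == "plasmid"

    def test_discordant_pair_evidence(self, two_refs):
        r1 = two_refs["chrI"][3000:3150]
        r2 = revcomp(two_refs["plasmid"][100:250])
        header, recs = naive_map([("d0", r1, r2)], two_refs)
        ev = collect_evidence((header, recs), {"chrI"}, {"plasmid"})
        assert [e.source for e in ev] == ["discordant"]
        assert ev[0].side == "left" and ev[0].host_pos == 3150

    def test_split_only_flag(self, two_refs):
        r1 = two_refs["chrI"][3000:3150]
        r2 = revcomp(two_refs["plasmid"][100:250])
        header, recs = naive_map([("d0", r1, r2)], two_refs)
        ev = collect_evidence((header, recs), {"chrI"}, {"plasmid"},
                              use_pairs=False)
        assert ev == []


def _ev(pos, side="left", rid="r"):
    return SplitEvidence(rid, "chrI", pos, "+", "plasmid", 0, side, "split")


class TestClusterCalls:
    def test_tight_cluster(self):
        calls = cluster_calls([_ev(100 + i * 20, rid=f"r{i}") for i in range(5)])
        assert len(calls) == 1
        c = calls[0]
        assert (c.start, c.end, c.support) == (100, 180, 5)

    def test_min_support(self):
        assert cluster_calls([_ev(1), _ev(5)], min_support=3) == []

    def test_window_splits_clusters(self):
        evs = [_ev(p, rid=f"r{p}") for p in (0, 100, 200, 5000, 5100, 5200)]
        calls = cluster_calls(evs, window=500, min_support=3)
        assert len(calls) == 2
        assert {c.start for c in calls} == {0, 5000}

    def test_sides_called_separately(self):
        evs = [_ev(100 + i, "left", f"l{i}") for i in range(4)] + [
            _ev(120 + i, "right", f"r{i}") for i in range(4)
        ]
        calls = cluster_calls(evs)
        assert len(calls) == 2
        assert {c.side for c in calls} == {"left", "right"}

    def test_bad_window(self):
        with pytest.raises(ValueError, match="window"):
            cluster_calls([], window=0)


class TestEndToEnd:
    def test_integration_recovered_and_control_clean(self, small_refs, small_shear):
        mix = sim.default_mix(small_refs, n_fragments=80, seed=904,
                              shear_params=small_shear)
        res = sim.simulate_run(mix, references=small_refs)
        maprefs = {r.id: r.seq for r in small_refs.values()}
        host_names = {"host_chr"}
        payload_names = set(maprefs) - host_names
        n_pairs = int(30 * len(res.integrated_seq) / 300)
        pairs, _ = sim.simulate_reads(res.integrated_seq, 150, 400, 40,
                                      n_pairs, 0.0, seed=905)
        header, recs = naive_map(pairs, maprefs)
        ev = collect_evidence((header, recs), host_names, payload_names)
        calls = cluster_calls(ev)
        attb = small_refs["host_chr"].atts[0]
        locus = attb[1]
        assert len(calls) >= 2
        for c in calls[:2]:
            assert c.host_chrom == "host_chr"
            assert abs((c.start + c.end) / 2 - locus) <= 500

        # control: reads from the naked host genome produce no calls
        cpairs, _ = sim.simulate_reads(small_refs["host_chr"].seq, 150, 400, 40,
                                       2000, 0.0, seed=906)
        h2, r2 = naive_map(cpairs, maprefs)
        ev2 = collect_evidence((h2, r2), host_names, payload_names)
        assert cluster_calls(ev2) == []
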