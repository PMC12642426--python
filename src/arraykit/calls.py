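"""Insertion-site calling from short reads split between host and payload.

Array integrations are located by mapping paired-end reads against a
combined reference — the host chromosomes plus the payload sequences from
the injection mix — and collecting reads whose alignments bridge the two
name sets: split reads (primary + supplementary alignments of one mate on
host and payload, with a soft clip of at least ``min_clip`` on the
junction-facing side) and discordant pairs (mates mapping to host and
payload respectively). Evidence positions are clustered per host breakpoint
flank by single linkage within a window; the attL-side and attR-side flanks
of one integration therefore produce two calls at (nearly) the same host
locus, mirroring how breakend sides are reported for structural variants.

``naive_map`` is an exact-match k-mer-anchored mapper guaranteed only for
error-free reads; it exists so the simulated pipeline is self-contained and
bit-reproducible. Real data should be aligned externally and fed in as SAM.
SAM records use the standard 1-based convention on disk via :mod:`pysam`;
everything internal stays 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from arraykit._seq import (
    kmer_code_at,
    kmer_codes,
    match_left_extension,
    match_right_extension,
    revcomp,
)


# ---------------------------------------------------------------------------
# evidence / call records


@dataclass
class SplitEvidence:
    """One read (or pair) bridging a host chromosome and a payload."""

    read_id: str
    host_chrom: str
    host_pos: int
    host_strand: str
    payload_id: str
    payload_pos: int
    side: str        #: 'left' = host lies left of the junction
    source: str      #: 'split' | 'discordant'


@dataclass
class InsertionCall:
    """A clustered host-genome breakpoint flank supported by evidence."""

    host_chrom: str
    start: int
    end: int
    support: int
    payloads: tuple[str, ...]
    left_support: int
    right_support: int
    side: str


# ---------------------------------------------------------------------------
# minimal exact mapper


class _FwdIndex:
    """Sorted k-mer index over the forward strand of each reference."""

    def __init__(self, refs: dict[str, str], k: int):
        self.k = k
        self.names = list(refs)
        self.seqs = refs
        codes_all, ridx_all, pos_all = [], [], []
        for ri, name in enumerate(self.names):
            codes, valid = kmer_codes(refs[name], k)
            sel = np.flatnonzero(valid)
            codes_all.append(codes[sel])
            ridx_all.append(np.full(sel.size, ri, dtype=np.int32))
            pos_all.append(sel.astype(np.int64))
        codes = np.concatenate(codes_all) if codes_all else np.empty(0, np.uint64)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.ridx = (np.concatenate(ridx_all) if ridx_all else np.empty(0, np.int32))[order]
        self.pos = (np.concatenate(pos_all) if pos_all else np.empty(0, np.int64))[order]

    def lookup(self, code) -> list[tuple[str, int]]:
        code = np.uint64(code)
        lo = int(np.searchsorted(self.codes, code, side="left"))
        hi = int(np.searchsorted(self.codes, code, side="right"))
        return [(self.names[int(self.ridx[i])], int(self.pos[i]))
                for i in range(lo, hi)]


@dataclass
class _Piece:
    ref: str
    ref_start: int
    read_start: int
    length: int

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length


def _best_prefix(index: _FwdIndex, seq: str) -> _Piece | None:
    """Longest unique exact match anchored at the read's first k bases."""
    k = index.k
    code = kmer_code_at(seq, 0, k)
    if code is None:
        return None
    best: list[_Piece] = []
    for ref, pos in index.lookup(code):
        m = k + match_right_extension(index.seqs[ref], pos + k, seq, k)
        p = _Piece(ref, pos, 0, m)
        if not best or p.length > best[0].length:
            best = [p]
        elif p.length == best[0].length:
            best.append(p)
    if len(best) != 1:
        return None  # absent or ambiguous: never misplace
    return best[0]


def _best_suffix(index: _FwdIndex, seq: str) -> _Piece | None:
    k = index.k
    if len(seq) < k:
        return None
    code = kmer_code_at(seq, len(seq) - k, k)
    if code is None:
        return None
    best: list[_Piece] = []
    for ref, pos in index.lookup(code):
        m = k + match_left_extension(index.seqs[ref], pos, seq, len(seq) - k)
        p = _Piece(ref, pos + k - m, len(seq) - m, m)
        if not best or p.length > best[0].length:
            best = [p]
        elif p.length == best[0].length:
            best.append(p)
    if len(best) != 1:
        return None
    return best[0]


@dataclass
class _Mapping:
    """Oriented placement of one read: primary piece + optional split."""

    reverse: bool
    seq: str                      # stored (oriented) sequence
    primary: _Piece
    supplementary: _Piece | None
    covered: int


def _map_oriented(index: _FwdIndex, seq: str, max_unexplained: int) -> _Mapping | None:
    pre = _best_prefix(index, seq)
    if pre is not None and pre.length == len(seq):
        return _Mapping(False, seq, pre, None, len(seq))
    suf = _best_suffix(index, seq)
    if pre is not None and suf is not None:
        gap = len(seq) - pre.length - suf.length
        if gap <= -len(seq) + 1:  # pieces are the same full-length match
            suf = None
        elif gap <= max_unexplained:
            if gap < 0:  # junction micro-homology: trim the shorter piece
                if pre.length >= suf.length:
                    suf = _Piece(suf.ref, suf.ref_start - gap, suf.read_start - gap,
                                 suf.length + gap)
                else:
                    pre = _Piece(pre.ref, pre.ref_start, 0, pre.length + gap)
            prim, supp = (pre, suf) if pre.length >= suf.length else (suf, pre)
            if supp.length > 0:
                return _Mapping(False, seq, prim, supp, prim.length + supp.length)
    best = None
    for p in (pre, suf):
        if p is not None and (best is None or p.length > best.length):
            best = p
    if best is None:
        return None
    return _Mapping(False, seq, best, None, best.length)


def _map_read(index: _FwdIndex, read: str, max_unexplained: int) -> _Mapping | None:
    fwd = _map_oriented(index, read, max_unexplained)
    rev = _map_oriented(index, revcomp(read), max_unexplained)
    if fwd is not None and (rev is None or fwd.covered >= rev.covered):
        return fwd
    if rev is not None and (fwd is None or rev.covered > fwd.covered):
        rev.reverse = True
        return rev
    return None


def _cigar(piece: _Piece, read_len: int) -> str:
    left = piece.read_start
    right = read_len - piece.read_start - piece.length
    return (f"{left}S" if left else "") + f"{piece.length}M" + (
        f"{right}S" if right else ""
    )


def naive_map(
    pairs: list[tuple[str, str, str]],
    references: dict[str, str],
    k: int = 21,
    max_unexplained: int = 50,
) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment]]:
    """Map error-free read pairs by unique exact k-mer anchoring.

    Junction-spanning reads yield a primary plus a supplementary record
    with complementary soft clips; reads whose best anchor is not unique
    are reported unmapped, never misplaced. ``max_unexplained`` tolerates a
    short middle stretch matching neither side (e.g. the residual att arm
    between host- and payload-derived sequence at an integration junction).

    Returns a pysam header and records; write them with
    :func:`arraykit.io.write_sam`.
    """
    if k < 15:
        raise ValueError("k must be >= 15")
    index = _FwdIndex(references, k)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": len(s)} for n, s in references.items()],
        }
    )
    tid = {n: i for i, n in enumerate(references)}
    records: list[pysam.AlignedSegment] = []

    for rid, r1, r2 in pairs:
        maps = [_map_read(index, r, max_unexplained) for r in (r1, r2)]
        for mi, (m, raw) in enumerate(zip(maps, (r1, r2))):
            mate = maps[1 - mi]
            flag_base = 0x1 | (0x40 if mi == 0 else 0x80)
            if mate is None:
                flag_base |= 0x8
            elif mate.reverse:
                flag_base |= 0x20
            if m is None:
                rec = pysam.AlignedSegment(header)
                rec.query_name = rid
                rec.flag = flag_base | 0x4
                rec.query_sequence = raw
                if mate is not None:
                    rec.next_reference_id = tid[mate.primary.ref]
                    rec.next_reference_start = mate.primary.ref_start
                records.append(rec)
                continue
            pieces = [(m.primary, False)]
            if m.supplementary is not None:
                pieces.append((m.supplementary, True))
            proper = (
                mate is not None
                and m.supplementary is None
                and mate.supplementary is None
                and mate.primary.ref == m.primary.ref
                and mate.reverse != m.reverse
            )
            sa_parts = {
                id(p): f"{p.ref},{p.ref_start + 1},{'-' if m.reverse else '+'},"
                       f"{_cigar(p, len(m.seq))},60,0;"
                for p, _ in pieces
            }
            for piece, is_supp in pieces:
                rec = pysam.AlignedSegment(header)
                rec.query_name = rid
                flag = flag_base
                if m.reverse:
                    flag |= 0x10
                if is_supp:
                    flag |= 0x800
                if proper:
                    flag |= 0x2
                rec.flag = flag
                rec.reference_id = tid[piece.ref]
                rec.reference_start = piece.ref_start
                rec.mapping_quality = 60
                rec.cigarstring = _cigar(piece, len(m.seq))
                rec.query_sequence = m.seq
                if mate is not None:
                    rec.next_reference_id = tid[mate.primary.ref]
                    rec.next_reference_start = mate.primary.ref_start
                if m.supplementary is not None:
                    other = [p for p, _ in pieces if p is not piece]
                    rec.set_tag("SA", "".join(sa_parts[id(p)] for p in other))
                records.append(rec)
    return header, records


# ---------------------------------------------------------------------------
# evidence collection


def _clips(rec: pysam.AlignedSegment) -> tuple[int, int]:
    ct = rec.cigartuples or []
    left = ct[0][1] if ct and ct[0][0] in (4, 5) else 0
    right = ct[-1][1] if ct and ct[-1][0] in (4, 5) else 0
    return left, right


def collect_evidence(
    alignments,
    host_names: set[str],
    payload_names: set[str],
    min_clip: int = 20,
    use_pairs: bool = True,
) -> list[SplitEvidence]:
    """Extract host/payload bridging evidence from SAM alignments.

    *alignments* is a SAM path or a ``(header, records)`` tuple as returned
    by :func:`naive_map`. Every reference name in the header must belong to
    exactly one of *host_names* / *payload_names*. With ``use_pairs=False``
    only split-read evidence is collected.
    """
    host_names, payload_names = set(host_names), set(payload_names)
    both = host_names & payload_names
    if both:
        raise ValueError(f"references in both host and payload sets: {sorted(both)}")

    if isinstance(alignments, (str, Path)):
        af = pysam.AlignmentFile(str(alignments), "r", check_sq=True)
        if not af.header.to_dict().get("SQ"):
            raise ValueError(f"SAM file {alignments} has no header @SQ lines")
        refs = list(af.references)
        records = list(af)
        af.close()
    else:
        header, records = alignments
        refs = list(header.references)
    for name in refs:
        if name not in host_names and name not in payload_names:
            raise ValueError(
                f"reference {name!r} assigned to neither host nor payload"
            )

    by_mate: dict[tuple[str, int], list[pysam.AlignedSegment]] = {}
    for rec in records:
        if rec.is_unmapped:
            continue
        mate_no = 1 if rec.is_read2 else 0
        by_mate.setdefault((rec.query_name, mate_no), []).append(rec)

    evidence: list[SplitEvidence] = []
    split_qnames: set[str] = set()
    for (qname, _mate), recs in by_mate.items():
        primaries = [r for r in recs if not r.is_supplementary]
        supps = [r for r in recs if r.is_supplementary]
        if not primaries or not supps:
            continue
        prim = primaries[0]
        for supp in supps:
            sides = {prim.reference_name: prim, supp.reference_name: supp}
            host_recs = [r for n, r in sides.items() if n in host_names]
            payl_recs = [r for n, r in sides.items() if n in payload_names]
            if not host_recs or not payl_recs:
                continue
            h, p = host_recs[0], payl_recs[0]
            lclip, rclip = _clips(h)
            if rclip >= min_clip and rclip >= lclip:
                side, pos = "left", h.reference_end
            elif lclip >= min_clip:
                side, pos = "right", h.reference_start
            else:
                continue
            evidence.append(
                SplitEvidence(
                    qname, h.reference_name, int(pos),
                    "-" if h.is_reverse else "+",
                    p.reference_name, int(p.reference_start), side, "split",
                )
            )
            split_qnames.add(qname)

    if use_pairs:
        prim_by_read: dict[str, dict[int, pysam.AlignedSegment]] = {}
        for (qname, mate_no), recs in by_mate.items():
            for r in recs:
                if not r.is_supplementary:
                    prim_by_read.setdefault(qname, {})[mate_no] = r
        for qname, mates in prim_by_read.items():
            if len(mates) != 2 or qname in split_qnames:
                continue
            r0, r1 = mates[0], mates[1]
            names = {r0.reference_name, r1.reference_name}
            if not (names & host_names and names & payload_names):
                continue
            h = r0 if r0.reference_name in host_names else r1
            p = r1 if h is r0 else r0
            if h.is_reverse:
                side, pos = "right", h.reference_start
            else:
                side, pos = "left", h.reference_end
            evidence.append(
                SplitEvidence(
                    qname, h.reference_name, int(pos),
                    "-" if h.is_reverse else "+",
                    p.reference_name, int(p.reference_start), side, "discordant",
                )
            )
    return evidence


def cluster_calls(
    evidence: list[SplitEvidence],
    window: int = 500,
    min_support: int = 3,
) -> list[InsertionCall]:
    """Single-linkage clustering of evidence into insertion calls.

    Evidence is grouped per host chromosome and junction side; positions
    within *window* of their neighbour join the same cluster. Clusters with
    fewer than *min_support* reads are dropped; output is sorted by support
    descending.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    groups: dict[tuple[str, str], list[SplitEvidence]] = {}
    for ev in evidence:
        groups.setdefault((ev.host_chrom, ev.side), []).append(ev)
    calls: list[InsertionCall] = []
    for (chrom, side), evs in groups.items():
        evs.sort(key=lambda e: e.host_pos)
        cluster: list[SplitEvidence] = []
        for ev in evs + [None]:
            if ev is not None and (not cluster or ev.host_pos - cluster[-1].host_pos <= window):
                cluster.append(ev)
                continue
            if len(cluster) >= min_support:
                calls.append(
                    InsertionCall(
                        chrom,
                        cluster[0].host_pos,
                        cluster[-1].host_pos,
                        len(cluster),
                        tuple(sorted({e.payload_id for e in cluster})),
                        sum(e.side == "left" for e in cluster),
                        sum(e.side == "right" for e in cluster),
                        side,
                    )
                )
            cluster = [ev] if ev is not None else []
    calls.sort(key=lambda c: (-c.support, c.host_chrom, c.start))
    return calls
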