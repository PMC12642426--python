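"""Detection of large duplicated regions within and between array contigs.

Assemblies of concatemer arrays carry multi-fragment segmental duplications
that confound contig resolution; the published filter for calling them is
length > 50 kb with mapping quality > 50. This module reproduces that
pipeline self-containedly: contigs are compared all-vs-all (and against
themselves, off-diagonal) by shared-k-mer anchoring on a common diagonal,
chained, then extended to maximal exact matches. Because no external
aligner is invoked there is no MAPQ; instead each hit carries an internal
*uniqueness* score on the same 0-60 scale — 60 when an interval has a
single equally good partner, dropping MAPQ-style (``-10 log10(1 - 1/m)``)
to ~3 when two partners tie and to 0 in the limit — so the published
strict-threshold semantics (> 50 kb, > 50) carry over. External alignments
with a real quality column can be loaded instead via ``hits_from_paf``.

High-multiplicity k-mers (scattered transgene copies) are skipped during
anchoring, as an aligner's repeat masking would; exact extension across the
chained anchors restores full event boundaries regardless. Matching is
forward-strand: duplications arising from re-ligation of array segments are
direct repeats, and inverted-repeat detection is out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from arraykit._seq import kmer_codes, match_left_extension, match_right_extension


@dataclass
class RepeatHit:
    """A maximal exact match between two contig intervals (forward strand)."""

    contig_a: str
    start_a: int
    end_a: int
    contig_b: str
    start_b: int
    end_b: int
    identity: float = 1.0
    quality: int = 60

    @property
    def length(self) -> int:
        return self.end_a - self.start_a


@dataclass
class DuplicatedRegion:
    """A retained duplicated region pair after filtering."""

    contig_a: str
    interval_a: tuple[int, int]
    contig_b: str
    interval_b: tuple[int, int]
    length: int
    identity: float
    quality: int


def self_compare(
    contigs: dict[str, str],
    anchor_k: int = 21,
    max_gap: int = 10_000,
    max_occ: int = 20,
) -> list[RepeatHit]:
    """All maximal chained-and-extended exact matches between contig pairs.

    Includes a contig against itself (off-diagonal only). Anchors are
    shared ``anchor_k``-mers occurring at most ``max_occ`` times in total;
    anchor pairs on a common diagonal within ``max_gap`` are chained, and
    each chain is extended outward to its maximal exact match. Chains that
    extend to the same interval pair are deduplicated.
    """
    if anchor_k < 15:
        raise ValueError("anchor_k must be >= 15")
    names = list(contigs)
    codes_all, cidx_all, pos_all = [], [], []
    for ci, name in enumerate(names):
        codes, valid = kmer_codes(contigs[name], anchor_k)
        sel = np.flatnonzero(valid)
        codes_all.append(codes[sel])
        cidx_all.append(np.full(sel.size, ci, dtype=np.int32))
        pos_all.append(sel.astype(np.int64))
    if not codes_all:
        return []
    codes = np.concatenate(codes_all)
    cidx = np.concatenate(cidx_all)
    pos = np.concatenate(pos_all)

    order = np.argsort(codes, kind="stable")
    codes, cidx, pos = codes[order], cidx[order], pos[order]

    # group boundaries of equal codes
    breaks = np.flatnonzero(np.diff(codes) != 0) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [codes.size]])

    gsize = ends - starts
    # all index pairs within shared-k-mer groups, vectorised per group size
    a_idx_parts, b_idx_parts = [], []
    for g in range(2, max_occ + 1):
        gs = starts[gsize == g]
        if gs.size == 0:
            continue
        members = gs[:, None] + np.arange(g)[None, :]  # (n_groups, g)
        iu, ju = np.triu_indices(g, k=1)
        a_idx_parts.append(members[:, iu].ravel())
        b_idx_parts.append(members[:, ju].ravel())
    if not a_idx_parts:
        return []
    ai = np.concatenate(a_idx_parts)
    bi = np.concatenate(b_idx_parts)
    a_c, a_p = cidx[ai].astype(np.int64), pos[ai]
    b_c, b_p = cidx[bi].astype(np.int64), pos[bi]
    swap = (a_c > b_c) | ((a_c == b_c) & (a_p > b_p))
    pa_c = np.where(swap, b_c, a_c)
    pa_p = np.where(swap, b_p, a_p)
    pb_c = np.where(swap, a_c, b_c)
    pb_p = np.where(swap, a_p, b_p)

    diag = pb_p - pa_p
    key = np.lexsort((pa_p, diag, pb_c, pa_c))
    pa_c, pa_p, pb_c, pb_p, diag = (
        pa_c[key], pa_p[key], pb_c[key], pb_p[key], diag[key]
    )
    same_group = (
        (np.diff(pa_c) == 0) & (np.diff(pb_c) == 0) & (np.diff(diag) == 0)
        & (np.diff(pa_p) <= max_gap)
    )
    run_starts = np.concatenate([[0], np.flatnonzero(~same_group) + 1])
    run_ends = np.concatenate([np.flatnonzero(~same_group) + 1, [pa_c.size]])

    seen: set[tuple] = set()
    hits: list[RepeatHit] = []
    for s, e in zip(run_starts, run_ends):
        ca, cb = names[int(pa_c[s])], names[int(pb_c[s])]
        a0, a1 = int(pa_p[s]), int(pa_p[e - 1]) + anchor_k
        b0 = int(pb_p[s])
        seq_a, seq_b = contigs[ca], contigs[cb]
        ext_l = match_left_extension(seq_a, a0, seq_b, b0)
        span = a1 - a0
        ext_r = match_right_extension(seq_a, a0 + span, seq_b, b0 + span)
        sa, ea = a0 - ext_l, a1 + ext_r
        sb = b0 - ext_l
        eb = sb + (ea - sa)
        if ca == cb and sa == sb:
            continue  # trivial self-diagonal
        key_t = (ca, sa, ea, cb, sb, eb)
        if key_t in seen:
            continue
        seen.add(key_t)
        hits.append(RepeatHit(ca, sa, ea, cb, sb, eb))

    _score_uniqueness(hits)
    hits.sort(key=lambda h: (-h.length, h.contig_a, h.start_a))
    return hits


def _overlap_frac(s1, e1, s2, e2) -> float:
    inter = max(0, min(e1, e2) - max(s1, s2))
    shorter = min(e1 - s1, e2 - s2)
    return inter / shorter if shorter else 0.0


def _score_uniqueness(hits: list[RepeatHit]) -> None:
    """Assign MAPQ-like uniqueness scores (see module docstring).

    A hit *o* is an alternative partner of *h* when it has comparable
    length (within 5%) and one of its intervals overlaps one of *h*'s by at
    least 90% of the shorter — i.e. the same stretch of sequence has more
    than one equally good home. Candidates are found through per-contig
    interval trees.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for idx, h in enumerate(hits):
        for contig, s, e in ((h.contig_a, h.start_a, h.end_a),
                             (h.contig_b, h.start_b, h.end_b)):
            if e > s:
                trees.setdefault(contig, IntervalTree()).addi(s, e, idx)
    for h in hits:
        partner_ids: set[int] = set()
        for contig, hs, he in ((h.contig_a, h.start_a, h.end_a),
                               (h.contig_b, h.start_b, h.end_b)):
            for iv in trees.get(contig, IntervalTree()).overlap(hs, he):
                o = hits[iv.data]
                if o is h:
                    continue
                if abs(o.length - h.length) > 0.05 * max(h.length, 1):
                    continue
                if _overlap_frac(iv.begin, iv.end, hs, he) >= 0.9:
                    partner_ids.add(iv.data)
        partners = 1 + len(partner_ids)
        if partners == 1:
            h.quality = 60
        else:
            h.quality = int(round(-10.0 * math.log10(1.0 - 1.0 / partners)))


def filter_repeats(
    hits: list[RepeatHit],
    min_len: int = 50_000,
    min_quality: int = 50,
) -> list[DuplicatedRegion]:
    """Apply the published repeat filters with strict inequalities.

    A hit is retained iff ``length > min_len`` and ``quality > min_quality``
    (strict, matching the "longer than 50 kb" / "greater than 50" wording).
    Reciprocal pairs are deduplicated; output is sorted by length
    descending.
    """
    if min_len < 0 or min_quality < 0:
        raise ValueError("thresholds must be >= 0")
    seen = set()
    out = []
    for h in hits:
        if not (h.length > min_len and h.quality > min_quality):
            continue
        a = (h.contig_a, h.start_a, h.end_a)
        b = (h.contig_b, h.start_b, h.end_b)
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        out.append(
            DuplicatedRegion(
                h.contig_a, (h.start_a, h.end_a),
                h.contig_b, (h.start_b, h.end_b),
                h.length, h.identity, h.quality,
            )
        )
    out.sort(key=lambda r: -r.length)
    return out


def hits_from_paf(path) -> list[RepeatHit]:
    """Load contig-vs-contig alignments from a PAF-like TSV with a quality
    column (column 12), as produced by an external aligner."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qname, qs, qe = f[0], int(f[2]), int(f[3])
            tname, ts, te = f[5], int(f[7]), int(f[8])
            nmatch, alen, mapq = int(f[9]), int(f[10]), int(f[11])
            if qname == tname and qs == ts and qe == te:
                continue
            out.append(
                RepeatHit(qname, qs, qe, tname, ts, te,
                          identity=(nmatch / alen if alen else 0.0), quality=mapq)
            )
    return out
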