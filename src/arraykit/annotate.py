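"""Decompose array contigs into source-derived fragments; composition stats.

The annotator segments each contig into maximal exact matches against the
source references (both strands), scanning right to left: at the current
segment end it anchors the terminal ``min_anchor``-mer in a packed k-mer
index of the references and extends the match leftward as far as it goes,
choosing the longest extension (ties by leftmost source coordinate). This
produces the unique segmentation whose boundaries are left-aligned within
junction micro-homology — the same canonical form the simulator's truth
uses — so on error-free contigs annotation equals truth fragment for
fragment.

The alignment model is substitution-free exact matching because the default
synthetic inputs are error-free; for real, noisy contigs use an external
aligner and load its output through :func:`annotations_from_paf`.

Composition statistics follow the quantities reported for sequenced arrays:
per-class base fractions, per-source full-length fragment counts, fragment
length summaries, donor ("stuffer") genome coverage, and the per-base
copy-number spectrum with the fraction of donor bases present fewer than
``k`` times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from arraykit._seq import kmer_codes, match_left_extension, revcomp
from arraykit.records import FragmentAnnotation, ReferenceRecord, check_unique_ids


# ---------------------------------------------------------------------------
# reference k-mer index


class _RefIndex:
    """Sorted-array k-mer index over both strands of every reference."""

    def __init__(self, references: list[ReferenceRecord], k: int):
        self.k = k
        self.seqs: list[tuple[str, str, str]] = []  # (ref_id, strand, strand_seq)
        codes_all, seq_idx_all, pos_all = [], [], []
        for rec in references:
            for strand, seq in (("+", rec.seq), ("-", revcomp(rec.seq))):
                if len(seq) < k:
                    continue
                codes, valid = kmer_codes(seq, k)
                idx = len(self.seqs)
                self.seqs.append((rec.id, strand, seq))
                sel = np.flatnonzero(valid)
                codes_all.append(codes[sel])
                seq_idx_all.append(np.full(sel.size, idx, dtype=np.int32))
                pos_all.append(sel.astype(np.int64))
        if codes_all:
            codes = np.concatenate(codes_all)
            order = np.argsort(codes, kind="stable")
            self.codes = codes[order]
            self.seq_idx = np.concatenate(seq_idx_all)[order]
            self.pos = np.concatenate(pos_all)[order]
        else:  # all references shorter than k
            self.codes = np.empty(0, dtype=np.uint64)
            self.seq_idx = np.empty(0, dtype=np.int32)
            self.pos = np.empty(0, dtype=np.int64)

    def lookup(self, code) -> list[tuple[int, int]]:
        code = np.uint64(code)
        lo = int(np.searchsorted(self.codes, code, side="left"))
        hi = int(np.searchsorted(self.codes, code, side="right"))
        return [(int(self.seq_idx[i]), int(self.pos[i])) for i in range(lo, hi)]


# ---------------------------------------------------------------------------
# annotation


def annotate_contigs(
    contigs: dict[str, str],
    references: list[ReferenceRecord] | dict[str, ReferenceRecord],
    min_anchor: int = 25,
    min_identity: float = 1.0,
) -> list[FragmentAnnotation]:
    """Segment contigs into source fragments by maximal exact matching.

    Parameters
    ----------
    contigs : dict
        contig id -> sequence.
    references : list or dict of ReferenceRecord
        Source sequences; ids must be unique. Host-class references are
        allowed (useful when annotating an integrated molecule).
    min_anchor : int
        Anchor k-mer size and the minimum annotatable fragment length.
        Fragments shorter than this are left unannotated.
    min_identity : float
        Annotations below this identity are dropped. The internal exact
        matcher only emits identity 1.0; the parameter matters for
        externally loaded alignments re-filtered with the same contract.
    """
    if isinstance(references, dict):
        references = list(references.values())
    if not references:
        raise ValueError("references must be non-empty")
    if not 11 <= min_anchor <= 32:
        raise ValueError("min_anchor must be in [11, 32]")
    check_unique_ids(references)

    index = _RefIndex(references, min_anchor)
    k = min_anchor
    out: list[FragmentAnnotation] = []

    for contig_id, cseq in contigs.items():
        e = len(cseq)
        anns: list[FragmentAnnotation] = []
        ccodes, cvalid = kmer_codes(cseq, k)
        while e >= k:
            if not cvalid[e - k]:
                e -= 1
                continue
            placements = index.lookup(ccodes[e - k])
            if not placements:
                e -= 1
                continue
            best = None
            for seq_i, pos in placements:
                ref_id, strand, sseq = index.seqs[seq_i]
                ext = match_left_extension(cseq, e - k, sseq, pos)
                length = k + ext
                ss_start, ss_end = pos - ext, pos + k
                if strand == "+":
                    src = (ss_start, ss_end)
                else:
                    L = len(sseq)
                    src = (L - ss_end, L - ss_start)
                cand = (length, -src[0], strand == "+", ref_id, src)
                # longest first; then leftmost source coordinate; then +
                if best is None or (cand[0], cand[1], cand[2], cand[3]) > (
                    best[0], best[1], best[2], best[3]
                ):
                    best = cand + (strand,)
            length, _, _, ref_id, src, strand = best
            anns.append(
                FragmentAnnotation(
                    contig_id, e - length, e, strand, ref_id, src[0], src[1]
                )
            )
            e -= length
        anns.reverse()
        out.extend(a for a in anns if a.identity >= min_identity)
    out.sort(key=lambda a: (a.contig_id, a.start))
    return out


def annotations_from_paf(path, min_identity: float = 0.0) -> list[FragmentAnnotation]:
    """Load externally produced alignments from a PAF-like TSV.

    Columns 1-12 of minimap2-style PAF are read (query = contig,
    target = source). Because annotations model substitution-only placements,
    alignments whose query and target spans differ (indels) are squared up by
    trimming the longer span at its end.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qname, qstart, qend = f[0], int(f[2]), int(f[3])
            strand, tname, tstart, tend = f[4], f[5], int(f[7]), int(f[8])
            nmatch, alen = int(f[9]), int(f[10])
            span = min(qend - qstart, tend - tstart)
            ident = nmatch / alen if alen else 0.0
            if ident < min_identity or span <= 0:
                continue
            out.append(
                FragmentAnnotation(
                    qname, qstart, qstart + span, strand, tname,
                    tstart, tstart + span, identity=max(min(ident, 1.0), 1e-9),
                )
            )
    out.sort(key=lambda a: (a.contig_id, a.start))
    return out


def classify_full_length(
    annotations: list[FragmentAnnotation],
    references: list[ReferenceRecord] | dict[str, ReferenceRecord],
    min_cov: float = 0.98,
) -> list[FragmentAnnotation]:
    """Set ``full_length`` on each annotation.

    A transgene or selection fragment is full-length when its source
    interval covers at least ``min_cov`` of the reference; stuffer and host
    fragments are never full-length (they are arbitrary genome windows, so
    the notion does not apply).
    """
    if not 0.0 < min_cov <= 1.0:
        raise ValueError("min_cov must be in (0, 1]")
    refs = {r.id: r for r in (references.values() if isinstance(references, dict)
                              else references)}
    for a in annotations:
        rec = refs[a.source_id]
        if rec.source_class in ("transgene", "selection"):
            a.full_length = (a.source_end - a.source_start) >= min_cov * len(rec)
        else:
            a.full_length = False
    return annotations


# ---------------------------------------------------------------------------
# composition report


@dataclass
class CompositionReport:
    """Architecture statistics of an annotated array."""

    total_bases: int
    class_base_fraction: dict[str, float]
    unannotated_fraction: float
    fragment_counts: dict[str, int]
    full_length_counts: dict[str, int]
    class_fragment_counts: dict[str, int]
    stuffer_len_min: int | None
    stuffer_len_max: int | None
    stuffer_fraction_below_1kb: float | None
    stuffer_coverage_fraction: float
    copy_number_hist: dict[int, int] = field(default_factory=dict)
    fraction_below_k: float = 0.0
    k_threshold: int = 5

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["copy_number_hist"] = {str(k): v for k, v in self.copy_number_hist.items()}
        return d


def composition_report(
    annotations: list[FragmentAnnotation],
    contigs: dict[str, str],
    references: list[ReferenceRecord] | dict[str, ReferenceRecord],
    k_threshold: int = 5,
) -> CompositionReport:
    """Compute the composition statistics of an annotated array.

    Base fractions are over total contig length; stuffer coverage is the
    union of stuffer source intervals divided by total stuffer genome
    length; the copy-number spectrum counts, per stuffer-genome base, how
    many annotations cover it (uncovered bases count with multiplicity 0 in
    the below-``k`` fraction, and every annotation counts — including those
    inside detected duplications).
    """
    refs = {r.id: r for r in (references.values() if isinstance(references, dict)
                              else references)}
    total = sum(len(s) for s in contigs.values())
    if total == 0:
        raise ValueError("contigs are empty")

    by_contig: dict[str, list[FragmentAnnotation]] = {}
    for a in annotations:
        if a.contig_id not in contigs:
            raise ValueError(f"annotation on unknown contig {a.contig_id!r}")
        if a.start < 0 or a.end > len(contigs[a.contig_id]):
            raise ValueError(
                f"annotation {a.source_id} at {a.contig_id}:{a.start}-{a.end} "
                "exceeds contig bounds"
            )
        by_contig.setdefault(a.contig_id, []).append(a)

    class_bases: dict[str, int] = {}
    annotated = 0
    for cid, anns in by_contig.items():
        anns.sort(key=lambda a: a.start)
        prev_end = 0
        for a in anns:
            if a.start < prev_end:
                raise ValueError(f"overlapping annotations on contig {cid!r}")
            prev_end = a.end
            cls = refs[a.source_id].source_class
            class_bases[cls] = class_bases.get(cls, 0) + a.length
            annotated += a.length

    class_frac = {c: b / total for c, b in sorted(class_bases.items())}
    unannotated = (total - annotated) / total

    frag_counts: dict[str, int] = {}
    full_counts: dict[str, int] = {}
    class_counts: dict[str, int] = {}
    for a in annotations:
        frag_counts[a.source_id] = frag_counts.get(a.source_id, 0) + 1
        cls = refs[a.source_id].source_class
        class_counts[cls] = class_counts.get(cls, 0) + 1
        if a.full_length:
            full_counts[a.source_id] = full_counts.get(a.source_id, 0) + 1

    stuffer_ids = [rid for rid, r in refs.items() if r.source_class == "stuffer"]
    stuffer_anns = [a for a in annotations if a.source_id in set(stuffer_ids)]
    if stuffer_anns:
        lens = np.fromiter((a.length for a in stuffer_anns), dtype=np.int64)
        s_min, s_max = int(lens.min()), int(lens.max())
        s_below = float((lens < 1000).mean())
    else:
        s_min = s_max = None
        s_below = None

    stuffer_total = sum(len(refs[rid]) for rid in stuffer_ids)
    covered = 0
    hist: dict[int, int] = {}
    frac_below_k = 0.0
    if stuffer_total:
        offs = {}
        off = 0
        for rid in stuffer_ids:
            offs[rid] = off
            off += len(refs[rid])
        diff = np.zeros(stuffer_total + 1, dtype=np.int64)
        for a in stuffer_anns:
            diff[offs[a.source_id] + a.source_start] += 1
            diff[offs[a.source_id] + a.source_end] -= 1
        mult = np.cumsum(diff[:-1])
        covered = int((mult > 0).sum())
        counts = np.bincount(mult)
        hist = {int(m): int(c) for m, c in enumerate(counts) if c}
        frac_below_k = float((mult < k_threshold).mean())

    return CompositionReport(
        total_bases=total,
        class_base_fraction=class_frac,
        unannotated_fraction=unannotated,
        fragment_counts=dict(sorted(frag_counts.items())),
        full_length_counts=dict(sorted(full_counts.items())),
        class_fragment_counts=dict(sorted(class_counts.items())),
        stuffer_len_min=s_min,
        stuffer_len_max=s_max,
        stuffer_fraction_below_1kb=s_below,
        stuffer_coverage_fraction=(covered / stuffer_total) if stuffer_total else 0.0,
        copy_number_hist=hist,
        fraction_below_k=frac_below_k,
        k_threshold=k_threshold,
    )
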