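"""Ground-truthed simulator of transgene-array assembly and integration.

The generative model mirrors how extrachromosomal arrays form from an
injected mix of linear DNA: transgene and selection-marker fragments (the
marker carries an attP site), plus carrier "stuffer" DNA sheared from a
donor genome. Fragments concatenate end-to-end in random orientation. The
default composition — 827 fragments at class weights 558 stuffer : 238
selection : 31 transgene, with the bulk of stuffer fragments under 1 kb —
matches the architecture reported for sequenced integrated arrays of this
kind.

Assembly order is a conditional Markov preference: class counts are drawn
first (multinomial in the class weights), then the order is built
sequentially, weighting each remaining class by ``w`` when it repeats the
previous fragment's class. ``w = 1`` makes the order an exactly uniform
permutation of the multiset — i.e. the null hypothesis of the adjacency
permutation test — while ``w > 1`` produces same-class clustering at fixed
composition.

Post-assembly, large segmental duplications copy contiguous runs of whole
fragments and insert them at fragment boundaries; finally the circular array
is integrated into a host molecule at its single attB via
:func:`arraykit.attsites.integrate`.

Fragment boundaries in the emitted truth are **left-aligned within junction
micro-homology**: when the first base(s) of a fragment happen to equal the
bases that would extend the previous fragment's source, the boundary is
ambiguous at the sequence level (the same convention VCF uses for indel
placement). Truth and annotation share this canonical form; the emitted
sequence is unchanged by it.

All randomness flows from a single seed via :mod:`arraykit._seeds`.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.integrate
import scipy.stats

from arraykit._seeds import stage_rng
from arraykit._seq import random_dna, revcomp
from arraykit.attsites import AttSiteDef, AttSiteHit, integrate
from arraykit.records import FragmentAnnotation, ReferenceRecord, check_unique_ids

_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


# ---------------------------------------------------------------------------
# configuration dataclasses


@dataclass(frozen=True)
class ShearParams:
    """Length distribution for sheared stuffer fragments.

    A log-normal truncated to ``[min_len, max_len]``. The defaults
    (``mu=5.5``, ``sigma=1.0``, bounds 40..100000 bp) put ~91.7% of fragment
    lengths under 1 kb with a tail reaching tens of kb, emulating sheared
    genomic carrier DNA.
    """

    mu: float = 5.5
    sigma: float = 1.0
    min_len: int = 40
    max_len: int = 100_000

    def __post_init__(self):
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")

    def _dist(self):
        return scipy.stats.lognorm(s=self.sigma, scale=math.exp(self.mu))

    def fraction_below(self, x: float) -> float:
        """Truncated-CDF probability that a fragment is shorter than *x*."""
        d = self._dist()
        lo, hi = d.cdf(self.min_len), d.cdf(self.max_len)
        return float(np.clip((d.cdf(x) - lo) / (hi - lo), 0.0, 1.0))

    def mean_length(self) -> float:
        """Mean fragment length under the truncated distribution."""
        d = self._dist()
        lo, hi = d.cdf(self.min_len), d.cdf(self.max_len)
        val, _ = scipy.integrate.quad(
            lambda x: x * d.pdf(x), self.min_len, self.max_len, limit=200
        )
        return val / (hi - lo)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw *n* integer lengths by rejection from the truncated law."""
        out = np.empty(0, dtype=np.int64)
        while out.size < n:
            draw = rng.lognormal(self.mu, self.sigma, size=max(n * 2, 64))
            keep = draw[(draw >= self.min_len) & (draw <= self.max_len)]
            out = np.concatenate([out, keep.astype(np.int64)])
        return out[:n]


@dataclass(frozen=True)
class MixEntry:
    """One component of the injection mix."""

    record: ReferenceRecord
    weight: float
    topology: str = "linear"

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError("mix entry weights must be > 0")
        if self.topology not in ("linear", "circular"):
            raise ValueError("topology must be 'linear' or 'circular'")


@dataclass
class InjectionMix:
    """Everything needed to assemble one array.

    ``clustering_weight`` maps a source class to its same-class repeat
    preference w >= 1; classes absent from the map use w = 1 (fully random
    assortment). ``truncation_prob`` is the chance a transgene/selection
    fragment is incorporated incompletely.
    """

    entries: list[MixEntry]
    n_fragments: int
    shear_params: ShearParams = field(default_factory=ShearParams)
    clustering_weight: dict[str, float] = field(default_factory=dict)
    truncation_prob: float = 0.0
    n_duplications: int = 0
    duplication_length: tuple[int, int] = (50_000, 120_000)
    seed: int = 0

    def __post_init__(self):
        if not self.entries:
            raise ValueError("injection mix has no entries")
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be >= 1")
        for w in self.clustering_weight.values():
            if w < 1:
                raise ValueError("clustering weights must be >= 1")
        check_unique_ids(e.record for e in self.entries)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class FragmentTruth:
    """One placed fragment: which source interval, in which orientation."""

    source_id: str
    source_start: int
    source_end: int
    strand: str
    source_class: str

    @property
    def length(self) -> int:
        return self.source_end - self.source_start


@dataclass
class DuplicationEvent:
    """A post-assembly segmental duplication, in final contig coordinates."""

    origin: tuple[int, int]
    copy: tuple[int, int]
    insert_point: int

    @property
    def length(self) -> int:
        return self.copy[1] - self.copy[0]


@dataclass
class ArrayTruth:
    """Complete ground truth for one simulated array contig."""

    contig_id: str
    fragments: list[FragmentTruth]
    circular: bool = True
    duplications: list[DuplicationEvent] = field(default_factory=list)
    att_positions: list[AttSiteHit] = field(default_factory=list)
    junctions: tuple[AttSiteHit, AttSiteHit] | None = None

    def starts(self) -> np.ndarray:
        """Cumulative contig start of each fragment."""
        lens = np.fromiter((f.length for f in self.fragments), dtype=np.int64)
        return np.concatenate([[0], np.cumsum(lens)])

    def labels(self) -> list[str]:
        return [f.source_class for f in self.fragments]

    def sequence(self, references: dict[str, ReferenceRecord] | list) -> str:
        """Reconstruct the contig sequence from the truth fragments."""
        refs = _as_ref_map(references)
        parts = []
        for f in self.fragments:
            s = refs[f.source_id].seq[f.source_start : f.source_end]
            parts.append(s if f.strand == "+" else revcomp(s))
        return "".join(parts)

    def annotations(self) -> list[FragmentAnnotation]:
        """The truth expressed as the annotation set an ideal annotator
        should recover (same coordinates, same canonical boundaries)."""
        offs = self.starts()
        return [
            FragmentAnnotation(
                self.contig_id, int(offs[i]), int(offs[i + 1]), f.strand,
                f.source_id, f.source_start, f.source_end,
            )
            for i, f in enumerate(self.fragments)
        ]


def _as_ref_map(references) -> dict[str, ReferenceRecord]:
    if isinstance(references, dict):
        return references
    return {r.id: r for r in references}


# ---------------------------------------------------------------------------
# shearing


def shear_genome(
    genome: ReferenceRecord,
    shear_params: ShearParams,
    n_fragments: int,
    seed: int | np.random.Generator = 0,
) -> list[FragmentTruth]:
    """Shear a donor genome into random fragments.

    Lengths follow the truncated log-normal of *shear_params*; start
    positions are uniform over valid placements; strands are uniform.
    Identical seeds give identical fragment lists.
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if shear_params.max_len > len(genome):
        raise ValueError(
            f"shear max_len {shear_params.max_len} exceeds genome length {len(genome)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = shear_params.sample(n_fragments, rng)
    starts = rng.integers(0, len(genome) - lengths + 1)
    strands = rng.choice(np.array(["+", "-"]), size=n_fragments)
    return [
        FragmentTruth(genome.id, int(s), int(s + L), str(st), genome.source_class)
        for s, L, st in zip(starts, lengths, strands)
    ]


# ---------------------------------------------------------------------------
# ordering model


def sample_class_order(
    counts: dict[str, int],
    clustering_weight: dict[str, float] | None,
    rng: np.random.Generator,
) -> list[str]:
    """Order a fixed multiset of class labels with same-class preference.

    Sequentially draws the next class with probability proportional to its
    remaining count, multiplied by its clustering weight when it equals the
    previous class. With all weights 1 this is an exactly uniform shuffle of
    the multiset (the exchangeable null of the adjacency permutation test).
    """
    w = dict(clustering_weight or {})
    classes = [c for c in counts if counts[c] > 0]
    remaining = {c: counts[c] for c in classes}
    out: list[str] = []
    prev = None
    n = sum(remaining.values())
    for _ in range(n):
        weights = np.array(
            [
                remaining[c] * (w.get(c, 1.0) if c == prev else 1.0)
                for c in classes
            ],
            dtype=float,
        )
        probs = weights / weights.sum()
        idx = rng.choice(len(classes), p=probs)
        c = classes[idx]
        out.append(c)
        remaining[c] -= 1
        if remaining[c] == 0:
            remaining.pop(c)
            classes.remove(c)
        prev = c
    return out


# ---------------------------------------------------------------------------
# assembly


def _canonicalize_junctions(
    fragments: list[FragmentTruth], refs: dict[str, ReferenceRecord]
) -> None:
    """Left-align fragment boundaries within junction micro-homology.

    At each junction, while the right-hand fragment can be extended one base
    leftward in its own source and that base equals the placed base it would
    replace, the boundary moves left. Deterministic, sequence-preserving,
    and shared with the annotator's segmentation convention.
    """
    for i in range(1, len(fragments)):
        prev, cur = fragments[i - 1], fragments[i]
        prev_seq = refs[prev.source_id].seq
        cur_seq = refs[cur.source_id].seq
        while prev.length > 1:
            if prev.strand == "+":
                placed = prev_seq[prev.source_end - 1]
            else:
                placed = _COMP1[prev_seq[prev.source_start]]
            if cur.strand == "+":
                if cur.source_start == 0:
                    break
                incoming = cur_seq[cur.source_start - 1]
            else:
                if cur.source_end == len(cur_seq):
                    break
                incoming = _COMP1[cur_seq[cur.source_end]]
            if incoming != placed:
                break
            if cur.strand == "+":
                cur.source_start -= 1
            else:
                cur.source_end += 1
            if prev.strand == "+":
                prev.source_end -= 1
            else:
                prev.source_start += 1


def assemble_array(
    mix: InjectionMix, contig_id: str = "array"
) -> tuple[str, ArrayTruth]:
    """Assemble one circular array from the injection mix.

    Returns the array sequence (linear string flagged circular in the truth)
    and the complete :class:`ArrayTruth`. Duplication events configured in
    the mix are *not* applied here; see :func:`apply_duplications`.
    """
    rng = stage_rng(mix.seed, "assemble")
    refs = {e.record.id: e.record for e in mix.entries}

    by_class: dict[str, list[MixEntry]] = {}
    for e in mix.entries:
        by_class.setdefault(e.record.source_class, []).append(e)
    class_weights = {c: sum(e.weight for e in es) for c, es in by_class.items()}

    classes = sorted(class_weights)
    probs = np.array([class_weights[c] for c in classes], dtype=float)
    probs /= probs.sum()
    count_draw = rng.multinomial(mix.n_fragments, probs)
    counts = {c: int(k) for c, k in zip(classes, count_draw)}

    order = sample_class_order(counts, mix.clustering_weight, rng)

    # pre-draw stuffer fragments in one deterministic batch
    stuffer_pool: list[FragmentTruth] = []
    n_stuffer = sum(1 for c in order if c == "stuffer")
    if n_stuffer:
        stuffer_entries = by_class.get("stuffer", [])
        if not stuffer_entries:
            raise ValueError("order requests stuffer fragments but mix has none")
        # split between stuffer genomes by weight
        sw = np.array([e.weight for e in stuffer_entries], dtype=float)
        alloc = rng.multinomial(n_stuffer, sw / sw.sum())
        for e, k in zip(stuffer_entries, alloc):
            if k:
                stuffer_pool.extend(shear_genome(e.record, mix.shear_params, int(k), rng))
        rng.shuffle(stuffer_pool)

    fragments: list[FragmentTruth] = []
    si = 0
    for c in order:
        if c == "stuffer":
            frag = stuffer_pool[si]
            si += 1
        else:
            entries = by_class[c]
            ws = np.array([e.weight for e in entries], dtype=float)
            rec = entries[rng.choice(len(entries), p=ws / ws.sum())].record
            s, e_ = 0, len(rec)
            if mix.truncation_prob > 0 and rng.random() < mix.truncation_prob:
                frac = rng.uniform(0.3, 0.95)
                keep = max(int(frac * len(rec)), 30)
                if rng.random() < 0.5:
                    s, e_ = 0, keep
                else:
                    s, e_ = len(rec) - keep, len(rec)
            strand = "+" if rng.random() < 0.5 else "-"
            frag = FragmentTruth(rec.id, s, e_, strand, c)
        fragments.append(frag)

    _canonicalize_junctions(fragments, refs)
    truth = ArrayTruth(contig_id, fragments, circular=True)
    return truth.sequence(refs), truth


# ---------------------------------------------------------------------------
# duplications


def apply_duplications(
    array_seq: str,
    truth: ArrayTruth,
    references,
    n_events: int,
    length_range: tuple[int, int] = (50_000, 120_000),
    seed: int | np.random.Generator = 0,
    _max_tries: int = 20_000,
) -> tuple[str, ArrayTruth]:
    """Plant segmental duplications that copy runs of whole fragments.

    Each event copies a contiguous run of fragments totalling at least a
    target length drawn uniformly from *length_range* and inserts the copy
    at a fragment boundary. Event origins are mutually disjoint and no
    insertion point falls strictly inside an origin, so every origin/copy
    pair remains an exact repeat in the final array. Recorded coordinates
    are final contig coordinates.
    """
    refs = _as_ref_map(references)
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if n_events == 0:
        return array_seq, truth
    if length_range[0] > len(array_seq):
        raise ValueError(
            f"duplication length {length_range[0]} exceeds array length {len(array_seq)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    frags = truth.fragments
    nf = len(frags)
    lens = np.fromiter((f.length for f in frags), dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lens)])

    # choose disjoint origin runs of whole fragments
    chosen: list[tuple[int, int]] = []  # fragment index ranges [i, j)
    tries = 0
    while len(chosen) < n_events:
        tries += 1
        if tries > _max_tries:
            raise ValueError(
                "could not place disjoint duplication origins; array too small "
                "for the requested events"
            )
        target = rng.integers(length_range[0], length_range[1] + 1)
        i = int(rng.integers(0, nf))
        j = int(np.searchsorted(cum, cum[i] + target, side="left"))
        if j > nf or cum[j] - cum[i] < target:
            continue
        if any(not (j <= a or b <= i) for a, b in chosen):
            continue
        chosen.append((i, j))

    # insertion boundaries: fragment boundary indices not inside any origin
    events = []
    for (i, j) in chosen:
        while True:
            b = int(rng.integers(0, nf + 1))
            if all(not (a < b < bb) for a, bb in chosen):
                break
        events.append({"range": (i, j), "boundary": b})

    origin_objs = {k: frags[i:j] for k, ev in enumerate(events)
                   for (i, j) in [ev["range"]]}
    copy_objs = {k: [copy.deepcopy(f) for f in origin_objs[k]] for k in origin_objs}

    new_frags = list(frags)
    for k, ev in sorted(enumerate(events), key=lambda kv: -kv[1]["boundary"]):
        b = ev["boundary"]
        new_frags[b:b] = copy_objs[k]

    _canonicalize_junctions(new_frags, refs)

    # final coordinates via object identity
    pos = {}
    off = 0
    for f in new_frags:
        pos[id(f)] = (off, off + f.length)
        off += f.length

    dup_events = []
    for k, ev in enumerate(events):
        o = origin_objs[k]
        c = copy_objs[k]
        origin_iv = (pos[id(o[0])][0], pos[id(o[-1])][1])
        copy_iv = (pos[id(c[0])][0], pos[id(c[-1])][1])
        dup_events.append(DuplicationEvent(origin_iv, copy_iv, copy_iv[0]))
    dup_events.sort(key=lambda d: d.copy)

    new_truth = ArrayTruth(
        truth.contig_id, new_frags, circular=truth.circular, duplications=dup_events
    )
    return new_truth.sequence(refs), new_truth


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    genome: str,
    read_len: int = 150,
    insert_mean: float = 400.0,
    insert_sd: float = 40.0,
    n_pairs: int = 1000,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[list[tuple[str, str, str]], dict[str, tuple[int, int]]]:
    """Simulate paired-end reads from a linear genome.

    Returns ``(pairs, truth)`` where each pair is ``(read_id, r1, r2)`` (r2
    reverse-complemented, FR orientation) and truth maps read id to the
    0-based fragment interval of origin. With ``error_rate = 0`` both mates
    are exact (reverse-complemented) substrings of the genome.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    if insert_mean > len(genome):
        raise ValueError(
            f"genome length {len(genome)} shorter than mean insert {insert_mean}"
        )
    if read_len > len(genome):
        raise ValueError("genome shorter than the read length")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    inserts = np.clip(
        np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(np.int64),
        read_len,
        len(genome),
    )
    starts = rng.integers(0, len(genome) - inserts + 1)
    pairs = []
    truth = {}
    bases = np.array(list("ACGT"))
    for idx, (s, ins) in enumerate(zip(starts, inserts)):
        s, ins = int(s), int(ins)
        r1 = genome[s : s + read_len]
        r2 = revcomp(genome[s + ins - read_len : s + ins])
        if error_rate > 0:
            r1 = _mutate(r1, error_rate, rng, bases)
            r2 = _mutate(r2, error_rate, rng, bases)
        rid = f"rp{idx:07d}"
        pairs.append((rid, r1, r2))
        truth[rid] = (s, s + ins)
    return pairs, truth


def _mutate(read: str, rate: float, rng: np.random.Generator, bases) -> str:
    arr = np.array(list(read))
    hit = rng.random(arr.size) < rate
    if hit.any():
        arr[hit] = bases[rng.integers(0, 4, size=int(hit.sum()))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# copy-number sampling model (closed-form prediction)


def expected_fraction_below(
    shear_params: ShearParams, genome_len: int, n_fragments: int, k: int
) -> float:
    """Closed-form expected fraction of donor-genome bases present fewer
    than *k* times when *n_fragments* fragments are sheared from it.

    A base is covered by one fragment with probability
    ``E[L / (G - L + 1)]`` (uniform start positions); per-base multiplicity
    is then Binomial(n, p), i.e. the equal-p Poisson-binomial of the
    sampling model. Edge effects (bases within one fragment length of the
    genome ends) are ignored; they are O(E[L]/G).
    """
    d = shear_params._dist()
    lo, hi = d.cdf(shear_params.min_len), d.cdf(shear_params.max_len)
    val, _ = scipy.integrate.quad(
        lambda L: d.pdf(L) * (L / (genome_len - L + 1)),
        shear_params.min_len,
        min(shear_params.max_len, genome_len),
        limit=200,
    )
    p = val / (hi - lo)
    return float(scipy.stats.binom.cdf(k - 1, n_fragments, p))


# ---------------------------------------------------------------------------
# default synthetic references and end-to-end convenience


#: Synthetic att site definitions (arm/core sequences are arbitrary but
#: fixed; real experiments should supply their own via ``load_att_config``).
def default_att_sites() -> dict[str, AttSiteDef]:
    attB = AttSiteDef("B", "TGCGGGTGCCAGGGCG", "TT", "GCCCGGGAGCCCCCGG")
    attP = AttSiteDef("P", "GTGCCCCAACTGGGGTAA", "TT", "GATATGAAAGCCCCGGGC")
    return {"attB": attB, "attP": attP}


def make_references(
    seed: int = 0,
    stuffer_len: int = 1_000_000,
    host_len: int = 120_000,
    transgene_len: int = 2_500,
    selection_len: int = 1_600,
) -> dict[str, ReferenceRecord]:
    """Build the default synthetic reference set.

    * ``pseudo_stuffer`` — a seeded random donor genome standing in for
      sheared carrier gDNA (a real genome FASTA may be substituted).
    * ``yfp_tg`` — a transgene fragment.
    * ``hygR_attP`` — a selection-marker fragment with an attP appended.
    * ``host_chr`` — a host chromosome with a single central attB.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA11]))
    sites = default_att_sites()
    attB, attP = sites["attB"], sites["attP"]

    stuffer = ReferenceRecord("pseudo_stuffer", random_dna(stuffer_len, rng), "stuffer")
    transgene = ReferenceRecord("yfp_tg", random_dna(transgene_len, rng), "transgene")

    # attP sits inside the marker fragment (as on a circular plasmid opened
    # for PCR), so integration junctions stay contiguous with this reference
    b1 = int(selection_len * 0.6)
    sel_seq = (
        random_dna(b1, rng) + attP.seq + random_dna(selection_len - b1, rng)
    )
    selection = ReferenceRecord(
        "hygR_attP", sel_seq, "selection",
        atts=(("P", b1, b1 + len(attP), "+"),),
    )

    half = host_len // 2
    host_seq = random_dna(half, rng) + attB.seq + random_dna(host_len - half, rng)
    host = ReferenceRecord(
        "host_chr", host_seq, "host", atts=(("B", half, half + len(attB), "+"),)
    )
    return {r.id: r for r in (stuffer, transgene, selection, host)}


def default_mix(
    references: dict[str, ReferenceRecord],
    n_fragments: int = 827,
    clustering_weight: dict[str, float] | None = None,
    seed: int = 0,
    **kwargs,
) -> InjectionMix:
    """Injection mix at the default array composition (558:238:31)."""
    return InjectionMix(
        entries=[
            MixEntry(references["pseudo_stuffer"], 558.0),
            MixEntry(references["hygR_attP"], 238.0),
            MixEntry(references["yfp_tg"], 31.0),
        ],
        n_fragments=n_fragments,
        clustering_weight=clustering_weight or {},
        seed=seed,
        **kwargs,
    )


@dataclass
class SimulationResult:
    """Bundle of everything one simulated run produced."""

    references: dict[str, ReferenceRecord]
    mix: InjectionMix
    array_seq: str
    truth: ArrayTruth
    integrated_seq: str | None = None
    junctions: tuple[AttSiteHit, AttSiteHit] | None = None


def simulate_run(
    mix: InjectionMix,
    references: dict[str, ReferenceRecord] | None = None,
    integrate_into_host: bool = True,
    attP_choice: str = "random",
    att_sites: dict[str, AttSiteDef] | None = None,
) -> SimulationResult:
    """Assemble, duplicate and (optionally) integrate one array."""
    refs = dict(references or {})
    for e in mix.entries:
        refs.setdefault(e.record.id, e.record)
    array_seq, truth = assemble_array(mix)
    if mix.n_duplications:
        array_seq, truth = apply_duplications(
            array_seq, truth, refs, mix.n_duplications, mix.duplication_length,
            seed=stage_rng(mix.seed, "duplicate"),
        )
    result = SimulationResult(refs, mix, array_seq, truth)

    if integrate_into_host:
        hosts = [r for r in refs.values() if r.source_class == "host"]
        if len(hosts) != 1:
            raise ValueError("integration requested but references contain "
                             f"{len(hosts)} host records")
        host = hosts[0]
        sites = att_sites or default_att_sites()
        from arraykit.attsites import find_att_sites

        p_hits = find_att_sites(array_seq, [sites["attP"]], 0, truth.contig_id)
        if not p_hits:
            raise ValueError("assembled array contains no attP site; add a "
                             "selection entry carrying one")
        rng = stage_rng(mix.seed, "integrate")
        idx = int(rng.integers(0, len(p_hits))) if attP_choice == "random" else 0
        integrated, junctions = integrate(
            host.seq, array_seq, sites["attB"], sites["attP"],
            chosen_attP_index=idx, host_id=host.id,
        )
        result.integrated_seq = integrated
        result.junctions = junctions
        truth.att_positions = p_hits
        truth.junctions = junctions
    return result
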