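"""attB/attP site algebra and sequence-level serine-integrase recombination.

A serine integrase (PhiC31 in the motivating system) recombines a single
attB site in the host genome with one attP site on a circular DNA molecule.
The reaction is unidirectional and swaps the site arms around a shared
crossover core, producing attL and attR junctions:

    attB = B_left + core + B_right        attL = B_left + core + P_right
    attP = P_left + core + P_right        attR = P_left + core + B_right

Integrating a circle at its attP therefore inserts the whole circle into the
host, flanked by attL and attR, with every base conserved. No canonical att
sequences are hard-coded: site definitions are user-supplied (see
``arraykit.simulate.default_att_sites`` for documented synthetic defaults and
``load_att_config`` for the YAML interchange format).

Coordinates are 0-based half-open; minus-strand hits are reported in forward
coordinates. Site matching allows substitutions only (no indels) because att
sites are short and indel tolerance invites spurious hits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from arraykit._seq import revcomp, seq_to_u8, validate_dna

ATT_KINDS = ("B", "P", "L", "R")


@dataclass(frozen=True)
class AttSiteDef:
    """One att site: left arm + crossover core + right arm."""

    kind: str
    left_arm: str
    core: str
    right_arm: str

    def __post_init__(self):
        if self.kind not in ATT_KINDS:
            raise ValueError(f"att kind must be one of {ATT_KINDS}, got {self.kind!r}")
        for part, name in [(self.left_arm, "left_arm"), (self.core, "core"),
                           (self.right_arm, "right_arm")]:
            validate_dna(part, name=f"att{self.kind} {name}")
        if not self.core:
            raise ValueError("core must be non-empty")

    @property
    def seq(self) -> str:
        return self.left_arm + self.core + self.right_arm

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AttSiteHit:
    """A located att site occurrence on a contig (forward coordinates)."""

    kind: str
    contig_id: str
    start: int
    end: int
    strand: str
    mismatches: int


def derive_lr(attB: AttSiteDef, attP: AttSiteDef) -> tuple[AttSiteDef, AttSiteDef]:
    """Arm-swap attB x attP into the (attL, attR) product sites.

    attL keeps attB's left arm and acquires attP's right arm; attR is the
    complementary swap. Total arm bases are conserved. Raises ``ValueError``
    if the kinds are wrong or the cores differ (recombination requires an
    identical crossover core).
    """
    if attB.kind != "B" or attP.kind != "P":
        raise ValueError(
            f"derive_lr expects (attB, attP), got kinds ({attB.kind}, {attP.kind})"
        )
    if attB.core != attP.core:
        raise ValueError(
            f"core mismatch: attB core {attB.core!r} != attP core {attP.core!r}"
        )
    attL = AttSiteDef("L", attB.left_arm, attB.core, attP.right_arm)
    attR = AttSiteDef("R", attP.left_arm, attP.core, attB.right_arm)
    return attL, attR


def _scan_pattern(arr: np.ndarray, pattern: str, max_mismatch: int) -> np.ndarray:
    """Start positions where *pattern* matches with <= max_mismatch
    substitutions (N in the subject always counts as a mismatch)."""
    pat = seq_to_u8(pattern)
    m = len(pat)
    n = len(arr)
    if n < m:
        return np.empty(0, dtype=np.intp)
    w = n - m + 1
    mism = np.zeros(w, dtype=np.int32)
    for j in range(m):
        mism += arr[j : j + w] != pat[j]
    return np.flatnonzero(mism <= max_mismatch)


def find_att_sites(
    seq: str,
    defs: list[AttSiteDef],
    max_mismatch: int = 0,
    contig_id: str = "seq",
) -> list[AttSiteHit]:
    """Scan both strands of *seq* for every site definition.

    Returns hits sorted by start position; overlapping hits of different
    kinds are all reported. Minus-strand hits give the forward-strand
    interval that reverse-complements to the site.
    """
    if not defs:
        raise ValueError("defs must be non-empty")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    validate_dna(seq, name=contig_id)
    arr = seq_to_u8(seq.upper())
    hits: list[AttSiteHit] = []
    for d in defs:
        site = d.seq.upper()
        fwd = _scan_pattern(arr, site, max_mismatch)
        rev = _scan_pattern(arr, revcomp(site), max_mismatch)
        for pos in fwd:
            hits.append(AttSiteHit(d.kind, contig_id, int(pos), int(pos) + len(site),
                                   "+", _count_mm(seq, int(pos), site)))
        rc = revcomp(site)
        for pos in rev:
            # palindromic definitions would double-report; keep the + call
            if site == rc and pos in fwd:
                continue
            hits.append(AttSiteHit(d.kind, contig_id, int(pos), int(pos) + len(site),
                                   "-", _count_mm(seq, int(pos), rc)))
    hits.sort(key=lambda h: (h.start, h.kind, h.strand))
    return hits


def _count_mm(seq: str, pos: int, pattern: str) -> int:
    window = seq[pos : pos + len(pattern)].upper()
    return sum(a != b for a, b in zip(window, pattern))


def integrate(
    host: str,
    array: str,
    attB: AttSiteDef,
    attP: AttSiteDef,
    chosen_attP_index: int = 0,
    max_mismatch: int = 0,
    host_id: str = "host",
) -> tuple[str, tuple[AttSiteHit, AttSiteHit]]:
    """Integrate a circular *array* into a linear *host* at its single attB.

    The array string is treated as circular: it is opened at the chosen attP
    and spliced into the host, replacing attB with attL ... attR. The product
    length equals ``len(host) + len(array)`` exactly and removing the
    inserted span re-fuses the arms back into the original host.

    Raises ``ValueError`` when the host carries zero attB copies (the
    integration-dead, mutated-site failure mode), more than one, or when the
    array has no attP.
    """
    b_hits = find_att_sites(host, [attB], max_mismatch, contig_id=host_id)
    if len(b_hits) == 0:
        raise ValueError(
            "no attB site found in host (site absent or mutated beyond "
            f"max_mismatch={max_mismatch}); integration impossible"
        )
    if len(b_hits) > 1:
        raise ValueError(f"host contains {len(b_hits)} attB sites; expected exactly 1")
    bh = b_hits[0]
    if bh.strand == "-":
        raise ValueError(
            "host attB lies on the minus strand; reverse-complement the host first"
        )

    p_hits = [h for h in find_att_sites(array, [attP], max_mismatch, "array")]
    if not p_hits:
        raise ValueError("no attP site found in array; integration impossible")
    try:
        ph = p_hits[chosen_attP_index]
    except IndexError:
        raise ValueError(
            f"chosen_attP_index {chosen_attP_index} out of range "
            f"({len(p_hits)} attP hits)"
        ) from None
    if ph.strand == "-":
        # orientation of a circle is arbitrary; flip it so attP reads forward
        flipped = revcomp(array)
        new_start = len(array) - ph.end
        array = flipped
        cand = [h for h in find_att_sites(array, [attP], max_mismatch, "array")
                if h.start == new_start and h.strand == "+"]
        if not cand:  # pragma: no cover - defensive
            raise RuntimeError("attP lost after reverse complement")
        ph = cand[0]

    lb, lc, lp = len(attB.left_arm), len(attB.core), len(attP.left_arm)
    if len(attP.core) != lc or attB.core.upper() != attP.core.upper():
        raise ValueError("attB and attP cores differ; recombination impossible")

    # observed (possibly mismatched) site copies, split at the core boundary
    attL_seq = host[bh.start : bh.start + lb + lc] + array[ph.start + lp + lc : ph.end]
    attR_seq = array[ph.start : ph.start + lp + lc] + host[bh.start + lb + lc : bh.end]
    opened = array[ph.end :] + array[: ph.start]

    integrated = host[: bh.start] + attL_seq + opened + attR_seq + host[bh.end :]

    attL_hit = AttSiteHit("L", host_id, bh.start, bh.start + len(attL_seq), "+", 0)
    r_start = bh.start + len(attL_seq) + len(opened)
    attR_hit = AttSiteHit("R", host_id, r_start, r_start + len(attR_seq), "+", 0)
    return integrated, (attL_hit, attR_hit)


def load_att_config(path) -> dict[str, AttSiteDef]:
    """Read att site definitions from a small YAML key-value file.

    Format: top-level keys are site names; each maps to ``kind``,
    ``left_arm``, ``core``, ``right_arm``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        name: AttSiteDef(d["kind"], d["left_arm"], d["core"], d["right_arm"])
        for name, d in raw.items()
    }


def save_att_config(defs: dict[str, AttSiteDef], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                name: {
                    "kind": d.kind,
                    "left_arm": d.left_arm,
                    "core": d.core,
                    "right_arm": d.right_arm,
                }
                for name, d in defs.items()
            },
            fh,
            sort_keys=True,
        )
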