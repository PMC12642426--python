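"""File interchange: FASTA/FASTQ, GFF3, BED/BEDPE, SAM and JSON reports.

All writers take the package's 0-based half-open internal coordinates and
emit the convention of each format (GFF3 1-based closed, BED 0-based
half-open, SAM 1-based via pysam).
"""

from __future__ import annotations

import json
from pathlib import Path

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from arraykit.records import FragmentAnnotation, ReferenceRecord


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence dict."""
    out = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in out:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            out[rec.id] = str(rec.seq).upper()
    except ValueError as exc:
        raise ValueError(f"malformed FASTA {path}: {exc}") from exc
    if not out:
        raise ValueError(f"no FASTA records parsed from {path} (line 1)")
    return out


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=n, description="") for n, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_references(path, class_map: dict[str, str]) -> list[ReferenceRecord]:
    """Read reference FASTA, assigning each id its source class from
    *class_map* (id -> transgene|selection|stuffer|host)."""
    seqs = read_fasta(path)
    missing = set(seqs) - set(class_map)
    if missing:
        raise ValueError(f"no source class given for references: {sorted(missing)}")
    return [ReferenceRecord(n, s, class_map[n]) for n, s in seqs.items()]


def write_fastq_pairs(pairs, path1, path2) -> None:
    """Write ``(id, r1, r2)`` tuples as two FASTQ files (constant quality)."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rid, r1, r2 in pairs:
            f1.write(f"@{rid}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{rid}/2\n{r2}\n+\n{'I' * len(r2)}\n")


def read_fastq_pairs(path1, path2) -> list[tuple[str, str, str]]:
    r1s = list(SeqIO.parse(str(path1), "fastq"))
    r2s = list(SeqIO.parse(str(path2), "fastq"))
    if len(r1s) != len(r2s):
        raise ValueError("paired FASTQ files differ in record count")
    pairs = []
    for a, b in zip(r1s, r2s):
        rid = a.id.rsplit("/", 1)[0]
        pairs.append((rid, str(a.seq).upper(), str(b.seq).upper()))
    return pairs


# ---------------------------------------------------------------------------
# GFF3 / BED


def write_annotations_gff3(annotations: list[FragmentAnnotation], path,
                           source: str = "arraykit") -> None:
    """Fragment annotations as GFF3 ``match`` features (source id, source
    interval and identity in the attributes column)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, a in enumerate(annotations):
            attrs = (
                f"ID=frag{i:06d};Name={a.source_id};"
                f"source_start={a.source_start};source_end={a.source_end};"
                f"identity={a.identity:.6g};full_length={a.full_length}"
            )
            fh.write(
                f"{a.contig_id}\t{source}\tmatch\t{a.start + 1}\t{a.end}\t"
                f"{a.identity:.4g}\t{a.strand}\t.\t{attrs}\n"
            )


def read_annotations_gff3(path) -> list[FragmentAnnotation]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            fl = attrs.get("full_length", "None")
            out.append(
                FragmentAnnotation(
                    f[0], int(f[3]) - 1, int(f[4]), f[6], attrs["Name"],
                    int(attrs["source_start"]), int(attrs["source_end"]),
                    identity=float(attrs.get("identity", 1.0)),
                    full_length=None if fl == "None" else fl == "True",
                )
            )
    return out


def write_truth_gff3(truth, path) -> None:
    """Simulator ground truth as GFF3: fragment features plus duplication
    origin/copy features."""
    offs = truth.starts()
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(truth.fragments):
            attrs = (
                f"ID=truth{i:06d};Name={f.source_id};class={f.source_class};"
                f"source_start={f.source_start};source_end={f.source_end}"
            )
            fh.write(
                f"{truth.contig_id}\tarraykit_sim\tfragment\t{int(offs[i]) + 1}\t"
                f"{int(offs[i + 1])}\t.\t{f.strand}\t.\t{attrs}\n"
            )
        for j, d in enumerate(truth.duplications):
            fh.write(
                f"{truth.contig_id}\tarraykit_sim\tduplication_origin\t"
                f"{d.origin[0] + 1}\t{d.origin[1]}\t.\t+\t.\tID=dup{j:03d}o\n"
            )
            fh.write(
                f"{truth.contig_id}\tarraykit_sim\tduplication_copy\t"
                f"{d.copy[0] + 1}\t{d.copy[1]}\t.\t+\t.\t"
                f"ID=dup{j:03d}c;origin={d.origin[0]}-{d.origin[1]}\n"
            )


def write_att_hits_bed6(hits, path) -> None:
    """att-site hits as BED6 (name = kind, score = mismatches)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.contig_id}\t{h.start}\t{h.end}\tatt{h.kind}\t"
                f"{h.mismatches}\t{h.strand}\n"
            )


def write_annotations_bed12(annotations: list[FragmentAnnotation], path) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(
                f"{a.contig_id}\t{a.start}\t{a.end}\t{a.source_id}\t"
                f"{round(1000 * a.identity)}\t{a.strand}\t{a.start}\t{a.end}\t"
                f"0,0,0\t1\t{a.length},\t0,\n"
            )


def write_regions_bedpe(regions, path) -> None:
    """Duplicated regions as BEDPE (one line per interval pair)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.contig_a}\t{r.interval_a[0]}\t{r.interval_a[1]}\t"
                f"{r.contig_b}\t{r.interval_b[0]}\t{r.interval_b[1]}\t"
                f"dup\t{r.quality}\t+\t+\n"
            )


def write_calls_bedpe(calls, path) -> None:
    """Insertion calls as BEDPE host-interval lines (payload ids in name)."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.host_chrom}\t{c.start}\t{max(c.end, c.start + 1)}\t"
                f".\t-1\t-1\t{','.join(c.payloads)}\t{c.support}\t.\t.\n"
            )


def write_link_table(regions, path) -> None:
    """Circos-style link table (contig, start, end, partner coordinates)."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tpartner_contig\tpartner_start\tpartner_end\n")
        for r in regions:
            fh.write(
                f"{r.contig_a}\t{r.interval_a[0]}\t{r.interval_a[1]}\t"
                f"{r.contig_b}\t{r.interval_b[0]}\t{r.interval_b[1]}\n"
            )


# ---------------------------------------------------------------------------
# SAM / JSON


def write_sam(header: pysam.AlignmentHeader, records, path) -> None:
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            out.write(rec)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def dataclass_list_json(items) -> list[dict]:
    out = []
    for it in items:
        d = dict(it.__dict__)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        out.append(d)
    return out
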