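"""Readers and writers for the standard formats the pipeline consumes.

VCF 4.2 in/out through pysam, BED3 regions, FASTA/FASTQ reads through
Biopython, and tab-separated report tables through pandas.

VCF dialect notes
-----------------
Internally everything is 0-based half-open; VCF POS is 1-based, so
``start = POS - 1``. Caller dialects differ on allele padding and on the
sign of SVLEN for deletions: both padded (``len(ALT) == SVLEN + 1``) and
unpadded alleles are accepted on read, and SVLEN is stored as a positive
length. Symbolic alleles (``<DEL>``, ``<INS>``) are accepted with empty
sequences. On write, records carry INFO keys SVTYPE, SVLEN, END, SUPP
(comma-joined platform labels) and HAP (comma-joined haplotype labels),
plus a single-sample GT column for the genotype.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import PLATFORMS, Callset, RegionSet, SVRecord

_SYMBOLIC = re.compile(r"^<(\w+)(:[\w:]+)?>$")


class SVVCFError(ValueError):
    """Raised for a VCF that cannot be parsed at all."""


@dataclass
class RecordError:
    """A non-fatal per-record parse problem, collected into Callset.meta."""

    record_id: str
    pos: str
    message: str


def _svtype_of(rec) -> str | None:
    svtype = _info_get(rec, "SVTYPE")
    if isinstance(svtype, (tuple, list)):
        svtype = svtype[0] if svtype else None
    if svtype is not None:
        return str(svtype)
    alt = rec.alts[0] if rec.alts else None
    if alt is None:
        return None
    m = _SYMBOLIC.match(alt)
    if m:
        return m.group(1)
    if len(alt) > len(rec.ref):
        return "INS"
    if len(alt) < len(rec.ref):
        return "DEL"
    return None


def _scalar(value):
    if isinstance(value, (tuple, list)):
        return value[0] if value else None
    return value


def _info_get(rec, key):
    # pysam raises ValueError("Invalid header") for keys the header does
    # not declare; treat those as simply absent
    try:
        return rec.info.get(key)
    except (KeyError, ValueError):
        return None


def _genotype_of(rec) -> str:
    if not rec.samples:
        return "unknown"
    gt = rec.samples[0].get("GT")
    if gt is None:
        return "unknown"
    alleles = {a for a in gt if a is not None}
    if alleles == {0, 1}:
        return "het"
    if alleles == {1}:
        return "hom"
    return "unknown"


def _strip_pad(seq: str, svlen: int) -> str:
    """Recover the SV allele from a possibly padded VCF allele string."""
    if len(seq) == svlen:
        return seq
    if len(seq) == svlen + 1:
        return seq[1:]
    return seq[1:] if len(seq) > svlen else seq


def read_sv_vcf(path: str, label: str) -> Callset:
    """Read DEL/INS records from a VCF into a sorted Callset.

    Records of other SVTYPEs are skipped (count in ``meta['skipped']``);
    per-record inconsistencies (e.g. END disagreeing with SVLEN) are
    collected into ``meta['errors']`` rather than aborting the read.
    If a record carries no SUPP INFO, its support set is initialised to
    ``{label}`` when the label is a known platform, else left empty.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise SVVCFError(f"cannot parse VCF {path}: {exc}") from exc

    records: list[SVRecord] = []
    errors: list[RecordError] = []
    skipped = 0
    with vcf:
        for i, rec in enumerate(vcf):
            rid = rec.id or f"{label}_{i}"
            svtype = _svtype_of(rec)
            if svtype not in ("DEL", "INS"):
                skipped += 1
                continue
            try:
                records.append(_parse_record(rec, rid, label, svtype, errors))
            except ValueError as exc:
                errors.append(RecordError(rid, f"{rec.chrom}:{rec.pos}", str(exc)))
    cs = Callset(label, records, {"skipped": skipped, "errors": errors})
    return cs.sort()


def _parse_record(rec, rid, label, svtype, errors) -> SVRecord:
    start = rec.start  # pysam is already 0-based
    svlen = _scalar(_info_get(rec, "SVLEN"))
    ref = rec.ref or ""
    alt = rec.alts[0] if rec.alts else ""
    symbolic = bool(_SYMBOLIC.match(alt))
    if svlen is None:
        if svtype == "DEL":
            svlen = (rec.stop - start) if symbolic else (len(ref) - len(alt))
        else:
            svlen = len(alt) - len(ref)
        if svlen <= 0:
            raise ValueError("cannot determine SVLEN")
    svlen = abs(int(svlen))
    if svlen < 1:
        raise ValueError(f"non-positive SVLEN {svlen}")

    if svtype == "DEL" and rec.stop - start > 1:
        # explicit or allele-derived END; tolerate the 1 bp padding-base ambiguity
        if rec.stop - start not in (svlen, svlen + 1):
            errors.append(
                RecordError(
                    rid,
                    f"{rec.chrom}:{rec.pos}",
                    f"END implies length {rec.stop - start}, SVLEN says {svlen}",
                )
            )

    alt_seq = _strip_pad(alt, svlen) if (svtype == "INS" and not symbolic) else ""
    # REF may carry the deleted allele even when ALT is the symbolic <DEL>
    ref_seq = _strip_pad(ref, svlen) if (svtype == "DEL" and len(ref) >= svlen) else ""

    supp = _info_get(rec, "SUPP")
    if supp:
        support = set(supp) if isinstance(supp, tuple) else set(str(supp).split(","))
    else:
        support = {label} if label in PLATFORMS else set()
    hap = _info_get(rec, "HAP")
    hap_support = (
        (set(hap) if isinstance(hap, tuple) else set(str(hap).split(","))) if hap else set()
    )

    sv = SVRecord(
        id=rid,
        chrom=rec.chrom,
        start=start,
        svtype=svtype,
        svlen=svlen,
        alt_seq=alt_seq,
        ref_seq=ref_seq,
        support=support,
        hap_support=hap_support,
        genotype=_genotype_of(rec),
    )
    sv.validate()
    return sv


def _build_header(callset: Callset) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length (bp)">')
    header.add_line('##INFO=<ID=SUPP,Number=.,Type=String,Description="Supporting platforms">')
    header.add_line(
        '##INFO=<ID=HAP,Number=.,Type=String,Description="Supporting haplotype assemblies">'
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in callset.chroms():
        header.contigs.add(chrom)
    header.add_sample("SAMPLE")
    return header


_GT = {"het": (0, 1), "hom": (1, 1), "unknown": (None, None)}


def write_sv_vcf(callset: Callset, path: str) -> None:
    """Write a Callset as VCF 4.2; round-trips through read_sv_vcf."""
    if not callset.is_sorted():
        raise ValueError("callset must be sorted before writing")
    header = _build_header(callset)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for sv in callset:
            if sv.svtype == "DEL":
                ref = sv.ref_seq or "N"
                alt = "<DEL>"
            else:
                ref = "N"
                alt = sv.alt_seq or "<INS>"
            want_stop = sv.start + sv.svlen if sv.svtype == "DEL" else sv.start + 1
            rec = out.new_record(
                contig=sv.chrom,
                start=sv.start,
                stop=want_stop,
                alleles=(ref, alt),
                id=sv.id,
                filter="PASS",
            )
            rec.info["SVTYPE"] = sv.svtype
            rec.info["SVLEN"] = sv.svlen if sv.svtype == "INS" else -sv.svlen
            if sv.support:
                rec.info["SUPP"] = ",".join(sorted(sv.support))
            if sv.hap_support:
                rec.info["HAP"] = ",".join(sorted(sv.hap_support))
            if rec.stop != want_stop:  # only emit END when alleles don't imply it
                rec.stop = want_stop
            rec.samples["SAMPLE"]["GT"] = _GT[sv.genotype]
            out.write(rec)


def read_bed(path: str, label: str = "") -> RegionSet:
    """Read a BED3+ file (0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            intervals.append((chrom, start, end))
    return RegionSet(intervals, label or str(path))


def write_bed(rs: RegionSet, path: str, names: list | None = None) -> None:
    """Write BED3 (or BED4 when per-interval names are supplied)."""
    with open(path, "w") as fh:
        for i, (chrom, s, e) in enumerate(rs.intervals):
            if names is not None:
                fh.write(f"{chrom}\t{s}\t{e}\t{names[i]}\n")
            else:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def normalize_regions(rs: RegionSet) -> RegionSet:
    """Merge overlapping/adjacent intervals per chromosome (functional API)."""
    return rs.normalize()


def read_fastx(path: str) -> list:
    """Read FASTA or FASTQ into (id, sequence) tuples."""
    fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]


def write_fasta(reads, path: str) -> None:
    """Write (id, sequence) pairs (or objects with .id/.seq) as FASTA."""
    records = []
    for r in reads:
        rid, seq = (r.id, r.seq) if hasattr(r, "seq") else r
        records.append(SeqRecord(Seq(seq), id=rid, description=""))
    SeqIO.write(records, str(path), "fasta")
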