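"""VCF and BED I/O.

Reading uses cyvcf2 (raw INFO access keeps the END -> SVLEN -> REF-length
fallback chain explicit); writing uses pysam.  VCF positions are 1-based and
END is inclusive; BED is 0-based half-open.  Internally everything is
flattened, 0-based, inclusive.
"""

from __future__ import annotations

import logging

import pysam
from cyvcf2 import VCF

from svfuse.core import SV_TYPES, Call, Callset
from svfuse.errors import DataError
from svfuse.genome import Genome
from svfuse.intervals import merge

log = logging.getLogger(__name__)

_SYMBOLIC_ALTS = {f"<{t}>" for t in SV_TYPES} | {"<DEL:ME>", "<DUP:TANDEM>", "<CNV>"}


def _first(value):
    """cyvcf2 returns tuples for Number=. INFO fields; take the first entry."""
    if isinstance(value, (tuple, list)):
        return value[0] if value else None
    return value


def _resolve_record(rec) -> tuple[str, int, int, str] | None:
    """Return (sv_type, pos0, end0, a_seq) or None when not derivable."""
    sv_type = rec.INFO.get("SVTYPE")
    alt = rec.ALT[0] if rec.ALT else None
    if sv_type is None and alt and alt.startswith("<") and alt.endswith(">"):
        sv_type = alt[1:-1].split(":")[0]
    if sv_type not in SV_TYPES:
        return None
    pos0 = rec.POS - 1
    end_info = _first(rec.INFO.get("END"))
    svlen = _first(rec.INFO.get("SVLEN"))
    symbolic = alt is None or (alt.startswith("<") and alt.endswith(">"))
    if end_info is not None:
        end0 = int(end_info) - 1
    elif svlen is not None:
        end0 = pos0 + abs(int(svlen)) - 1
    elif not symbolic and len(rec.REF) > 1:
        end0 = pos0 + len(rec.REF) - 1
    elif sv_type == "INS" and not symbolic:
        end0 = pos0
    else:
        return None
    a_seq = ""
    if sv_type == "INS" and alt and not symbolic:
        a_seq = alt
    return sv_type, pos0, max(pos0, end0), a_seq


def read_vcf(path, caller_id: int, genome: Genome, sample_id: str = "") -> Callset:
    """Load one caller's VCF into a flattened :class:`Callset`.

    Records whose end position cannot be derived (no END, no SVLEN, symbolic
    ALT) and records on contigs absent from ``genome`` are skipped and
    counted — never guessed.
    """
    try:
        vcf = VCF(str(path))
    except OSError as exc:
        raise DataError(f"cannot read VCF {path}: {exc}") from exc
    if not sample_id:
        sample_id = vcf.samples[0] if vcf.samples else ""
    calls = []
    skipped_end = skipped_contig = 0
    for rec in vcf:
        if rec.CHROM not in genome:
            skipped_contig += 1
            continue
        resolved = _resolve_record(rec)
        if resolved is None:
            skipped_end += 1
            continue
        sv_type, pos0, end0, a_seq = resolved
        contig_len = genome.length_of(rec.CHROM)
        end0 = min(end0, contig_len - 1)
        calls.append(
            Call(
                s_start=genome.flatten(rec.CHROM, pos0),
                s_end=genome.flatten(rec.CHROM, end0),
                sv_type=sv_type,
                a_seq=a_seq,
                caller_id=caller_id,
                filter_value=rec.FILTER if rec.FILTER is not None else ".",
                sample_id=sample_id,
            )
        )
    vcf.close()
    if skipped_end or skipped_contig:
        log.warning(
            "read_vcf %s: skipped %d record(s) with no derivable end, "
            "%d on contigs absent from the genome",
            path, skipped_end, skipped_contig,
        )
    return Callset(caller_id, sample_id, calls)


def _vcf_header(genome: Genome, sample_id: str) -> pysam.VariantHeader:
    hdr = pysam.VariantHeader()
    for name, length in genome.contigs:
        hdr.contigs.add(name, length=length)
    hdr.info.add("SVTYPE", 1, "String", "Type of structural variant")
    hdr.info.add("END", 1, "Integer", "End position of the variant (inclusive)")
    hdr.info.add("SVLEN", 1, "Integer", "Length of the variant")
    hdr.info.add("SVEX", 1, "Float", "Fused group expectation value")
    hdr.info.add("SVMETHOD", 1, "String", "Comma-joined supporting caller ids")
    hdr.formats.add("GT", 1, "String", "Genotype")
    for t in SV_TYPES:
        hdr.add_meta("ALT", items=[("ID", t), ("Description", f"{t} structural variant")])
    hdr.add_sample(sample_id or "SAMPLE")
    return hdr


def write_vcf(callset: Callset, genome: Genome, path, annotations=None) -> None:
    """Write a sorted callset as VCF 4.2 with symbolic ALT alleles.

    ``annotations`` optionally maps call index -> dict with ``expectation``
    (float) and ``callers`` (iterable of int) to fill SVEX / SVMETHOD.
    Genotypes are emitted as the ``./1`` placeholder.
    """
    annotations = annotations or {}
    hdr = _vcf_header(genome, callset.sample_id)
    try:
        out = pysam.VariantFile(str(path), "w", header=hdr)
    except OSError as exc:
        raise DataError(f"cannot write VCF {path}: {exc}") from exc
    with out:
        for idx, c in enumerate(callset):
            contig, pos0 = genome.unflatten(c.s_start)
            _, end0 = genome.unflatten(c.s_end)
            # htslib derives END for symbolic alleles as POS + |SVLEN|
            # (padding-base semantics); emit the SVLEN consistent with the
            # inclusive POS..END span so END survives the round trip exactly
            svlen = end0 - pos0
            rec = out.new_record(
                contig=contig,
                start=pos0,
                stop=end0 + 1,
                alleles=("N", f"<{c.sv_type}>"),
                id=f"svfuse_{idx}",
            )
            rec.info["SVTYPE"] = c.sv_type
            rec.info["SVLEN"] = -svlen if c.sv_type == "DEL" else svlen
            ann = annotations.get(idx)
            if ann:
                if "expectation" in ann:
                    rec.info["SVEX"] = float(ann["expectation"])
                if "callers" in ann:
                    rec.info["SVMETHOD"] = ",".join(str(i) for i in sorted(ann["callers"]))
            rec.samples[0]["GT"] = (None, 1)
            out.write(rec)


def read_bed_mask(path, genome: Genome) -> list[tuple[int, int]]:
    """Read a BED3+ exclusion mask into sorted, merged flattened intervals."""
    raw = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError:
                raise DataError(f"{path}:{lineno}: non-integer BED coordinates") from None
            if end <= start:
                raise DataError(f"{path}:{lineno}: empty or inverted BED interval")
            if chrom not in genome:
                log.warning("%s:%d: contig %s absent from genome, skipped", path, lineno, chrom)
                continue
            fs = genome.flatten(chrom, start)
            fe = genome.flatten(chrom, min(end, genome.length_of(chrom)) - 1)
            raw.append((fs, fe))
    return merge(raw)
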