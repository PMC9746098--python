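"""Readers and writers for SV call sets (VCF 4.2) and region files (BED3).

Two VCF dialects are understood: symbolic ALT records (``<DEL>``, ``<DUP>``,
``<INS>``, ``<INV>``) with END/SVLEN INFO keys, and breakend (BND) records with
bracketed ALT alleles.  Paired intra-chromosomal breakends whose bracket
patterns agree are normalized to DEL/DUP/INV; mates on different chromosomes
collapse to a single TRA record; everything else stays BND.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pysam

from .core import (
    Breakend,
    CallSet,
    GenomicRegionSet,
    MIN_SV_SIZE,
    Provenance,
    SVRecord,
    chrom_sort_key,
)

#: reserved INFO key used by the simulator to carry truth labels
TRUTH_INFO_KEY = "TRUTH_ID"

_BND_ALT_RE = re.compile(
    r"^(?P<pre>[ACGTNacgtn.]*)(?P<b1>[\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>[0-9]+)"
    r"(?P<b2>[\[\]])(?P<post>[ACGTNacgtn.]*)$"
)

# bracket pattern -> implied intra-chromosomal type, keyed by the orientation
# pair (orient at lower breakend, orient at higher breakend)
_ORIENT_TO_TYPE = {
    ("+", "-"): "DEL",
    ("-", "+"): "DUP",
    ("+", "+"): "INV",
    ("-", "-"): "INV",
}


def _parse_bnd_alt(alt: str):
    """Return (orient_here, orient_mate, mate_chrom, mate_pos) or None."""
    m = _BND_ALT_RE.match(alt)
    if not m:
        return None
    orient_here = "+" if m.group("pre") else "-"
    orient_mate = "+" if m.group("b1") == "]" else "-"
    return orient_here, orient_mate, m.group("chrom"), int(m.group("pos"))


def _bnd_alt(ref: str, orient_here: str, orient_mate: str, mate_chrom: str, mate_pos: int) -> str:
    p = f"{mate_chrom}:{mate_pos}"
    if orient_here == "+":
        return f"{ref}]{p}]" if orient_mate == "+" else f"{ref}[{p}["
    return f"]{p}]{ref}" if orient_mate == "+" else f"[{p}[{ref}"


@dataclass
class _RawBreakend:
    rec_id: str
    chrom: str
    pos: int
    orient_here: str
    orient_mate: str
    mate_chrom: str
    mate_pos: int
    mate_id: str | None
    filter: str
    info: dict


def read_sv_vcf(
    path,
    provenance: Provenance,
    require_pass: bool = True,
    min_size: int = MIN_SV_SIZE,
) -> CallSet:
    """Read a VCF into a :class:`CallSet`.

    Record-level problems (malformed ALT, missing END/SVLEN) do not abort the
    parse; they are collected in ``callset.stats['errors']`` with the record
    index.  ``stats`` also reports how many records were dropped by the PASS
    filter, the size floor, and exact-coordinate deduplication, so that
    parsed + rejected always equals the input record count.
    """
    records: list[SVRecord] = []
    breakends: list[_RawBreakend] = []
    errors: list[tuple[int, str]] = []
    n_input = n_filtered = n_subthreshold = 0

    with pysam.VariantFile(str(path)) as vf:
        for idx, rec in enumerate(vf, start=1):
            n_input += 1
            filters = list(rec.filter.keys())
            filt = ";".join(filters) if filters else "PASS"
            if require_pass and filt not in ("PASS", "."):
                n_filtered += 1
                continue
            try:
                parsed = _parse_record(rec, idx, filt)
            except ValueError as exc:
                errors.append((idx, str(exc)))
                continue
            if isinstance(parsed, _RawBreakend):
                breakends.append(parsed)
            else:
                if not parsed.is_translocation_like and parsed.size < min_size:
                    n_subthreshold += 1
                    continue
                records.append(parsed)

    records.extend(_pair_breakends(breakends))

    seen: set = set()
    deduped: list[SVRecord] = []
    for rec in sorted(records, key=SVRecord.sort_key):
        key = rec.coord_key()
        if key in seen:
            continue
        seen.add(key)
        deduped.append(rec)

    cs = CallSet(provenance=provenance, records=deduped)
    cs.stats = {
        "input_records": n_input,
        "parsed": len(deduped),
        "errors": errors,
        "filtered_non_pass": n_filtered,
        "sub_threshold": n_subthreshold,
        "deduplicated": len(records) - len(deduped),
        "unpaired_breakends": sum(
            1 for r in deduped if r.svtype in ("TRA", "BND")
        ),
    }
    return cs


def _parse_record(rec, idx: int, filt: str):
    info = dict(rec.info)
    svtype = info.get("SVTYPE")
    alt = rec.alts[0] if rec.alts else None
    if alt is None:
        raise ValueError("missing ALT allele")

    extra = {TRUTH_INFO_KEY: info[TRUTH_INFO_KEY]} if TRUTH_INFO_KEY in info else {}
    rec_id = rec.id or f"rec{idx}"

    bnd = _parse_bnd_alt(alt)
    if bnd is not None:
        o_here, o_mate, mchrom, mpos = bnd
        mate_id = info.get("MATEID")
        if isinstance(mate_id, tuple):
            mate_id = mate_id[0]
        return _RawBreakend(
            rec_id, rec.contig, rec.pos, o_here, o_mate, mchrom, mpos,
            mate_id, filt, extra,
        )

    if not (alt.startswith("<") and alt.endswith(">")):
        raise ValueError(f"unsupported ALT {alt!r}")
    sym = alt[1:-1].split(":")[0]
    if svtype is None:
        svtype = sym
    if sym not in ("DEL", "DUP", "INS", "INV", "TRA", "BND"):
        raise ValueError(f"unsupported symbolic ALT {alt!r}")

    svlen = info.get("SVLEN")
    if isinstance(svlen, tuple):
        svlen = svlen[0]
    end = info.get("END", rec.stop if rec.stop > rec.pos else None)

    if svtype in ("TRA", "BND") and "CHR2" in info:
        # Delly/Sniffles translocation dialect: CHR2 + END give the mate
        if end is None:
            raise ValueError("TRA record lacks END")
        b1 = Breakend(rec.contig, rec.pos)
        b2 = Breakend(str(info["CHR2"]), int(end))
        svt = "TRA" if b1.chrom != b2.chrom else "BND"
        return SVRecord(rec_id, svt, b1, b2, filter=filt, info=extra)

    if sym == "INS":
        if svlen is None:
            raise ValueError("INS record lacks SVLEN")
        b1 = Breakend(rec.contig, rec.pos)
        return SVRecord(rec_id, "INS", b1, b1, size=abs(int(svlen)), filter=filt, info=extra)

    if sym in ("DEL", "DUP", "INV"):
        if end is None:
            if svlen is None:
                raise ValueError(f"{sym} record lacks both END and SVLEN")
            end = rec.pos + abs(int(svlen))
        b1 = Breakend(rec.contig, rec.pos)
        b2 = Breakend(rec.contig, int(end))
        return SVRecord(rec_id, sym, b1, b2, filter=filt, info=extra)

    raise ValueError(f"cannot interpret symbolic {sym} without bracket mates")


def _pair_breakends(raws: list[_RawBreakend]) -> list[SVRecord]:
    """Collapse mate pairs; normalize agreeing intra-chromosomal pairs."""
    by_id = {r.rec_id: r for r in raws}
    by_coord: dict = {}
    for r in raws:
        by_coord.setdefault((r.chrom, r.pos), []).append(r)

    out: list[SVRecord] = []
    used: set[str] = set()
    for r in raws:
        if r.rec_id in used:
            continue
        mate = None
        if r.mate_id and r.mate_id in by_id and r.mate_id not in used:
            mate = by_id[r.mate_id]
        else:
            for cand in by_coord.get((r.mate_chrom, r.mate_pos), []):
                if (
                    cand.rec_id not in used
                    and cand.rec_id != r.rec_id
                    and (cand.mate_chrom, cand.mate_pos) == (r.chrom, r.pos)
                ):
                    mate = cand
                    break
        used.add(r.rec_id)
        b_here = Breakend(r.chrom, r.pos, r.orient_here)
        if mate is None:
            b_mate = Breakend(r.mate_chrom, r.mate_pos, r.orient_mate)
            svt = "TRA" if r.chrom != r.mate_chrom else "BND"
            out.append(SVRecord(r.rec_id, svt, b_here, b_mate, filter=r.filter, info=r.info))
            continue
        used.add(mate.rec_id)
        b_mate = Breakend(mate.chrom, mate.pos, mate.orient_here)
        base_id = r.rec_id
        for suffix in ("_1", "_2", "_bnd1", "_bnd2"):
            if base_id.endswith(suffix):
                base_id = base_id[: -len(suffix)]
                break
        info = {**mate.info, **r.info}
        if r.chrom != mate.chrom:
            out.append(SVRecord(base_id, "TRA", b_here, b_mate, filter=r.filter, info=info))
            continue
        lo, hi = sorted([b_here, b_mate], key=Breakend.sort_key)
        # the two mate lines describe one junction; they agree when each
        # declares the other's orientation correctly
        mates_agree = (
            r.orient_mate == mate.orient_here and mate.orient_mate == r.orient_here
        )
        implied = _ORIENT_TO_TYPE.get((lo.orient, hi.orient))
        if mates_agree and implied is not None and lo.pos != hi.pos:
            out.append(SVRecord(base_id, implied, lo, hi, filter=r.filter, info=info))
        else:
            out.append(SVRecord(base_id, "BND", lo, hi, filter=r.filter, info=info))
    return out


_HEADER_INFO_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">',
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="ID of mate breakend">',
    f'##INFO=<ID={TRUTH_INFO_KEY},Number=1,Type=String,Description="Simulated truth label">',
]


def write_sv_vcf(callset: CallSet, path) -> str:
    """Write a call set as VCF 4.2.

    DEL/DUP/INS/INV go out as symbolic ALT records with END/SVLEN; TRA as a
    breakend mate pair; BND as a single unpaired breakend line.  Records are
    position sorted.  The output carries no timestamps so reruns are
    byte-identical.
    """
    header = pysam.VariantHeader()
    for line in _HEADER_INFO_LINES:
        header.add_line(line)
    header.add_line('##FILTER=<ID=LowQual,Description="Low quality call">')
    chroms = sorted(
        {r.bnd1.chrom for r in callset.records}
        | {r.bnd2.chrom for r in callset.records},
        key=chrom_sort_key,
    )
    for chrom in chroms:
        header.add_line(f"##contig=<ID={chrom}>")

    lines = []
    for rec in sorted(callset.records, key=SVRecord.sort_key):
        lines.extend(_format_record(rec))
    lines.sort(key=lambda t: t[0])

    with open(path, "w") as fh:
        fh.write(str(header))
        for _, line in lines:
            fh.write(line + "\n")
    return str(path)


def _info_str(parts: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in parts.items() if v is not None)


def _format_record(rec: SVRecord):
    filt = rec.filter if rec.filter else "PASS"
    truth = rec.info.get(TRUTH_INFO_KEY)
    key1 = (chrom_sort_key(rec.bnd1.chrom), rec.bnd1.pos)
    if rec.svtype in ("DEL", "DUP", "INV", "INS"):
        svlen = -rec.size if rec.svtype == "DEL" else rec.size
        end = rec.bnd1.pos if rec.svtype == "INS" else rec.bnd2.pos
        info = _info_str(
            {"SVTYPE": rec.svtype, "END": end, "SVLEN": svlen, TRUTH_INFO_KEY: truth}
        )
        line = (
            f"{rec.bnd1.chrom}\t{rec.bnd1.pos}\t{rec.id}\tN\t<{rec.svtype}>\t.\t"
            f"{filt}\t{info}"
        )
        return [(key1, line)]
    o1 = rec.bnd1.orient or "+"
    o2 = rec.bnd2.orient or "-"
    if rec.svtype == "BND":
        alt = _bnd_alt("N", o1, o2, rec.bnd2.chrom, rec.bnd2.pos)
        info = _info_str({"SVTYPE": "BND", TRUTH_INFO_KEY: truth})
        line = f"{rec.bnd1.chrom}\t{rec.bnd1.pos}\t{rec.id}\tN\t{alt}\t.\t{filt}\t{info}"
        return [(key1, line)]
    # TRA: mate pair
    id1, id2 = f"{rec.id}_1", f"{rec.id}_2"
    alt1 = _bnd_alt("N", o1, o2, rec.bnd2.chrom, rec.bnd2.pos)
    alt2 = _bnd_alt("N", o2, o1, rec.bnd1.chrom, rec.bnd1.pos)
    info1 = _info_str({"SVTYPE": "BND", "MATEID": id2, TRUTH_INFO_KEY: truth})
    info2 = _info_str({"SVTYPE": "BND", "MATEID": id1, TRUTH_INFO_KEY: truth})
    key2 = (chrom_sort_key(rec.bnd2.chrom), rec.bnd2.pos)
    return [
        (key1, f"{rec.bnd1.chrom}\t{rec.bnd1.pos}\t{id1}\tN\t{alt1}\t.\t{filt}\t{info1}"),
        (key2, f"{rec.bnd2.chrom}\t{rec.bnd2.pos}\t{id2}\tN\t{alt2}\t.\t{filt}\t{info2}"),
    ]


def read_bed_regions(path, label: str = "") -> GenomicRegionSet:
    """Read a BED3+ file (0-based half-open) into a region set.

    Malformed rows (too few columns, non-numeric bounds, start >= end) are
    skipped; the reject count is available as ``regions.n_rejected``.
    """
    rows = []
    n_rejected = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                if start >= end:
                    raise ValueError
            except (ValueError, IndexError):
                n_rejected += 1
                continue
            rows.append((chrom, start, end))
    regions = GenomicRegionSet(rows, label=label)
    regions.n_rejected = n_rejected
    return regions


def write_bed_regions(regions: GenomicRegionSet, path) -> str:
    with open(path, "w") as fh:
        for chrom, start, end in sorted(
            regions.regions, key=lambda r: (chrom_sort_key(r[0]), r[1])
        ):
            fh.write(f"{chrom}\t{start}\t{end}\n")
    return str(path)
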