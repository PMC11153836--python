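"""Parsing of variant files (VCF 4.1/4.2, txt, BED-like, AnnotSV TSV) into
normalized :class:`Variant` records, variant-type classification, and the
maximum-length filter.

Every reader converts to 0-based half-open coordinates at parse time.
Supported perturbation types are SNPs, small indels, and the structural
classes DEL, DUP (tandem), INV, and BND (breakend rearrangements with VCF
bracket notation). Insertions and CNVs given only as symbolic tags are
classified unsupported because the replacement sequence is not provided by
upstream variant callers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import pysam

__all__ = [
    "Variant",
    "BreakendMate",
    "FilterReport",
    "VariantParseError",
    "read_vcf",
    "read_table",
    "read_variants",
    "classify",
    "filter_by_limit",
    "variant_length",
    "default_limit",
    "write_bed_like",
    "write_rejected",
    "INDEL_SV_THRESHOLD",
    "ORIENTATIONS",
]

logger = logging.getLogger(__name__)

#: length-change cutoff (bp) between "small indel" and structural variant
INDEL_SV_THRESHOLD = 50

#: the four VCF breakend bracket orientations
ORIENTATIONS = ("t[p[", "t]p]", "]p]t", "[p[t")

_SYMBOLIC_MAP = {"DEL": "DEL", "DUP": "DUP", "INV": "INV", "INS": "INS"}
_LITERAL_RE = re.compile(r"^[ACGTNacgtn]+$")
_BND_RE = re.compile(
    r"^(?P<lead>[ACGTNacgtn]*)(?P<b1>[\[\]])(?P<loc>[^\[\]:]+):(?P<pos>\d+)"
    r"(?P<b2>[\[\]])(?P<trail>[ACGTNacgtn]*)$"
)


class VariantParseError(ValueError):
    """Raised for structurally malformed variant records."""


@dataclass
class BreakendMate:
    """The partner locus of a breakend junction.

    ``pos`` is the 0-based offset of the mate breakend base; ``orientation``
    is one of the four VCF bracket forms in :data:`ORIENTATIONS`;
    ``inserted`` holds any untemplated bases at the junction.
    """

    chrom: str
    pos: int
    orientation: str
    inserted: str = ""


@dataclass
class Variant:
    """One normalized perturbation.

    For literal records (SNP/indel) ``ref_allele`` and ``alt`` are base
    strings and ``end = start + len(ref_allele)``. For symbolic records
    ``alt`` keeps the tag (e.g. ``<DEL>``) and [start, end) spans the
    affected interval. ``svlen`` is the signed net length change of the
    edited sequence.
    """

    id: str
    chrom: str
    start: int
    end: int
    ref_allele: str | None
    alt: str
    sv_type: str
    svlen: int
    bnd_mate: BreakendMate | None = None

    def __post_init__(self) -> None:
        if self.sv_type in ("DEL", "DUP", "INV") and not self.start < self.end:
            raise VariantParseError(
                f"{self.id}: start must be < end for {self.sv_type}"
            )


@dataclass
class FilterReport:
    """Partition of an input variant list into kept and rejected records.

    Rejection reasons: ``exceeds_limit``, ``unsupported_type``,
    ``malformed``, ``off_chromosome``.
    """

    kept: list[Variant] = field(default_factory=list)
    rejected: list[tuple[Variant, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.kept) + len(self.rejected)


def classify(v: Variant) -> str:
    """Categorize a parsed variant by how it can be incorporated.

    Returns one of SNP / INDEL / DEL / DUP / INV / BND, or ``"unsupported"``
    for symbolic insertions and CNVs whose replacement sequence is unknown.
    """
    if v.sv_type == "BND":
        return "BND"
    if v.alt.startswith("<"):
        return v.sv_type if v.sv_type in ("DEL", "DUP", "INV") else "unsupported"
    if (
        v.ref_allele is not None
        and len(v.ref_allele) == 1
        and len(v.alt) == 1
    ):
        return "SNP"
    return "INDEL"


def _classify_literal(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    return "INDEL"


def parse_breakend_alt(alt: str, ref: str) -> BreakendMate:
    """Parse a VCF bracketed breakend ALT string into mate coordinates,
    orientation, and inserted bases. ``ref`` is the record's REF allele."""
    m = _BND_RE.match(alt)
    if m is None or m.group("b1") != m.group("b2"):
        raise VariantParseError(f"malformed breakend ALT {alt!r}")
    lead, trail = m.group("lead"), m.group("trail")
    bracket = m.group("b1")
    mate_chrom = m.group("loc")
    mate_pos = int(m.group("pos")) - 1  # 1-based in the ALT string
    if lead and not trail:
        if not lead.upper().startswith(ref.upper()):
            raise VariantParseError(f"breakend ALT {alt!r} does not start with REF")
        inserted = lead[len(ref):].upper()
        orientation = "t[p[" if bracket == "[" else "t]p]"
    elif trail and not lead:
        if not trail.upper().endswith(ref.upper()):
            raise VariantParseError(f"breakend ALT {alt!r} does not end with REF")
        inserted = trail[: len(trail) - len(ref)].upper()
        orientation = "[p[t" if bracket == "[" else "]p]t"
    else:
        raise VariantParseError(f"breakend ALT {alt!r}: bases on both sides")
    return BreakendMate(mate_chrom, mate_pos, orientation, inserted)


def _check_vcf_version(path: Path) -> None:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        first = fh.readline().strip()
    if first not in ("##fileformat=VCFv4.1", "##fileformat=VCFv4.2"):
        raise VariantParseError(
            f"{path}: expected ##fileformat=VCFv4.1 or VCFv4.2, got {first!r}"
        )


def _pair_breakends(
    raw: list[tuple[Variant, str | None]],
) -> list[Variant]:
    """Pair raw breakend records into single canonical Variants.

    Mates are matched by MATEID when present, otherwise by reciprocal
    coordinates. The lexicographically smaller breakend (chrom, pos, id) is
    canonical. Unpaired breakends are returned with ``bnd_mate=None`` so the
    filter can reject them as malformed.
    """
    by_id = {v.id: (v, mate_id) for v, mate_id in raw}
    out: list[Variant] = []
    consumed: set[str] = set()
    for v, mate_id in raw:
        if v.id in consumed:
            continue
        partner: Variant | None = None
        if mate_id is not None and mate_id in by_id:
            cand = by_id[mate_id][0]
            if cand.id != v.id:
                partner = cand
        if partner is None and mate_id is None:
            for w, _ in raw:
                if w.id in consumed or w.id == v.id or w.bnd_mate is None:
                    continue
                if (
                    w.chrom == v.bnd_mate.chrom
                    and w.pos0 == v.bnd_mate.pos
                    and w.bnd_mate.chrom == v.chrom
                    and w.bnd_mate.pos == v.pos0
                ):
                    partner = w
                    break
        if partner is None:
            out.append(replace(v, bnd_mate=None))
            consumed.add(v.id)
            continue
        consumed.update((v.id, partner.id))
        canon = min(
            (v, partner), key=lambda x: (x.chrom, x.start, x.id)
        )
        out.append(canon)
    return out


def read_vcf(path: str | Path) -> list[Variant]:
    """Read a VCF 4.1/4.2 (plain or bgzipped) into normalized Variants.

    Multi-allelic lines are split into one Variant per ALT (perturbations
    are incorporated one at a time downstream). Breakend mate pairs collapse
    into a single Variant; unpaired breakends are kept with ``bnd_mate=None``
    and rejected as malformed by :func:`filter_by_limit`.
    """
    path = Path(path)
    _check_vcf_version(path)
    variants: list[Variant] = []
    bnd_raw: list[tuple[Variant, str | None]] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            start = rec.pos - 1  # pysam rec.pos is 1-based
            ref = (rec.ref or "").upper()
            rec_id = rec.id
            for i, alt in enumerate(rec.alts or ()):
                if rec_id is None:
                    vid = f"{rec.chrom}_{rec.pos}_{i}"
                elif len(rec.alts) > 1:
                    vid = f"{rec_id}_{i}"
                else:
                    vid = rec_id
                if "[" in alt or "]" in alt:
                    mate = parse_breakend_alt(alt, ref)
                    v = Variant(
                        id=vid, chrom=rec.chrom, start=start, end=start + 1,
                        ref_allele=ref, alt=alt.upper(), sv_type="BND",
                        svlen=len(mate.inserted), bnd_mate=mate,
                    )
                    v.pos0 = start  # type: ignore[attr-defined]
                    try:
                        mate_ids = rec.info.get("MATEID", None)
                    except (KeyError, ValueError):
                        mate_ids = None
                    mate_id = None
                    if mate_ids is not None:
                        mate_id = (
                            mate_ids[0] if isinstance(mate_ids, tuple) else mate_ids
                        )
                    bnd_raw.append((v, mate_id))
                elif alt.startswith("<"):
                    tag = alt.strip("<>").split(":")[0].upper()
                    sv_type = _SYMBOLIC_MAP.get(tag, tag)
                    end, svlen = _symbolic_extent(rec, start, sv_type)
                    variants.append(
                        Variant(
                            id=vid, chrom=rec.chrom, start=start, end=end,
                            ref_allele=ref or None, alt=f"<{tag}>",
                            sv_type=sv_type, svlen=svlen,
                        )
                    )
                elif _LITERAL_RE.match(alt):
                    a = alt.upper()
                    variants.append(
                        Variant(
                            id=vid, chrom=rec.chrom, start=start,
                            end=start + len(ref), ref_allele=ref, alt=a,
                            sv_type=_classify_literal(ref, a),
                            svlen=len(a) - len(ref),
                        )
                    )
                else:
                    raise VariantParseError(
                        f"{path}: unparseable ALT {alt!r} at {rec.chrom}:{rec.pos}"
                    )
    variants.extend(_pair_breakends(bnd_raw))
    return variants


def _symbolic_extent(rec, start: int, sv_type: str) -> tuple[int, int]:
    """Resolve [start, end) and svlen for a symbolic record from END/SVLEN.

    END (1-based inclusive) equals the 0-based exclusive end directly; pysam
    exposes it as ``rec.stop``. When END is absent, fall back to |SVLEN|.
    When both are present and disagree, END wins (it is positional; SVLEN is
    derived) and a warning is logged.
    """
    # read END from the raw record text: robust to VCFs whose headers do
    # not declare INFO/END as Integer (pysam then ignores it for rec.stop)
    end_m = re.search(r"[\t;]END=(\d+)", str(rec))
    try:
        svlen_info = rec.info.get("SVLEN", None)
    except (KeyError, ValueError):  # SVLEN absent and undeclared in header
        svlen_info = None
    if isinstance(svlen_info, tuple):
        svlen_info = svlen_info[0]
    if end_m:
        end = int(end_m.group(1))  # 1-based inclusive == 0-based exclusive
        if end < start + 1:
            raise VariantParseError(f"{rec.chrom}:{rec.pos}: END < POS")
    elif svlen_info is not None:
        end = start + abs(int(svlen_info))
    else:
        raise VariantParseError(
            f"{rec.chrom}:{rec.pos}: symbolic ALT needs INFO/END or SVLEN"
        )
    span = end - start
    if sv_type == "DEL":
        svlen = -span
    elif sv_type == "DUP":
        svlen = span  # tandem duplication adds one extra copy
    elif sv_type == "INV":
        svlen = 0
    else:  # INS and unknown CNV-like tags: net change unknown without sequence
        svlen = int(svlen_info) if svlen_info is not None else 0
    if svlen_info is not None and end_m and sv_type in ("DEL", "DUP"):
        if abs(int(svlen_info)) != span:
            logger.warning(
                "%s:%d SVLEN=%s disagrees with END-derived span %d; using END",
                rec.chrom, rec.pos, svlen_info, span,
            )
    return end, svlen


def _variant_from_symbolic(
    vid: str, chrom: str, start: int, end: int, sv_type: str
) -> Variant:
    svlen = {"DEL": -(end - start), "DUP": end - start, "INV": 0}.get(sv_type, 0)
    return Variant(
        id=vid, chrom=chrom, start=start, end=end, ref_allele=None,
        alt=f"<{sv_type}>", sv_type=sv_type, svlen=svlen,
    )


def read_table(path: str | Path, dialect: str) -> list[Variant]:
    """Read a non-VCF variant table. Dialects:

    - ``txt``: whitespace-delimited ``chrom pos_1based ref alt`` (literal
      alleles only).
    - ``bed_like``: tab/whitespace ``chrom start end sv_type [alt] [id]``
      with 0-based half-open coordinates. ``alt`` may be literal bases or a
      bracketed breakend string (which also encodes the mate).
    - ``annotsv_tsv``: header-keyed TSV with at least SV_chrom, SV_start,
      SV_end, SV_type (1-based inclusive coordinates, AnnotSV convention).

    All dialects produce Variant records field-identical to the equivalent
    VCF content.
    """
    path = Path(path)
    if dialect == "txt":
        return _read_txt(path)
    if dialect == "bed_like":
        return _read_bed_like(path)
    if dialect == "annotsv_tsv":
        return _read_annotsv(path)
    raise VariantParseError(f"unknown dialect {dialect!r}")


def _read_txt(path: Path) -> list[Variant]:
    rows = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#", dtype=str,
        names=["chrom", "pos", "ref", "alt"],
    )
    if len(rows) and not rows.iloc[0]["pos"].isdigit():
        rows = rows.iloc[1:]  # tolerate a header line
    out = []
    for i, row in rows.iterrows():
        start = int(row["pos"]) - 1
        ref, alt = row["ref"].upper(), row["alt"].upper()
        if not (_LITERAL_RE.match(ref) and _LITERAL_RE.match(alt)):
            raise VariantParseError(f"{path}: txt dialect needs literal alleles")
        out.append(
            Variant(
                id=f"{row['chrom']}_{row['pos']}_{i}", chrom=row["chrom"],
                start=start, end=start + len(ref), ref_allele=ref, alt=alt,
                sv_type=_classify_literal(ref, alt), svlen=len(alt) - len(ref),
            )
        )
    return out


def _read_bed_like(path: Path) -> list[Variant]:
    rows = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#", dtype=str,
    )
    if rows.shape[1] < 4:
        raise VariantParseError(f"{path}: bed_like needs >= 4 columns")
    out: list[Variant] = []
    for i, row in rows.iterrows():
        chrom, start, end, sv_type = row[0], int(row[1]), int(row[2]), row[3].upper()
        alt = row[4] if rows.shape[1] > 4 and pd.notna(row[4]) else None
        vid = (
            row[5]
            if rows.shape[1] > 5 and pd.notna(row[5])
            else f"{chrom}_{start}_{i}"
        )
        if alt in (".", ""):
            alt = None
        if sv_type == "BND":
            # bed_like stores one row per junction: the full bracket ALT
            # (which encodes mate, orientation, and inserted bases) at the
            # canonical breakend. The REF base t is the ALT's flanking base.
            if alt is None:
                raise VariantParseError(f"{path}: BND rows need the ALT column")
            lead = re.match(r"^[ACGTNacgtn]+", alt)
            trail = re.search(r"[ACGTNacgtn]+$", alt)
            if lead is None and trail is None:
                raise VariantParseError(f"{path}: bad breakend ALT {alt!r}")
            t = (lead.group(0)[0] if lead else trail.group(0)[-1]).upper()
            mate = parse_breakend_alt(alt, t)
            out.append(
                Variant(
                    id=vid, chrom=chrom, start=start, end=start + 1,
                    ref_allele=t, alt=alt.upper(), sv_type="BND",
                    svlen=len(mate.inserted), bnd_mate=mate,
                )
            )
        elif sv_type in ("DEL", "DUP", "INV", "INS") and (
            alt is None or alt.startswith("<")
        ):
            out.append(_variant_from_symbolic(vid, chrom, start, end, sv_type))
        else:
            if alt is None or not _LITERAL_RE.match(alt):
                raise VariantParseError(
                    f"{path}: sv_type {sv_type} needs a literal alt column"
                )
            ref = row[6] if rows.shape[1] > 6 and pd.notna(row[6]) else None
            alt = alt.upper()
            ref = ref.upper() if ref else None
            out.append(
                Variant(
                    id=vid, chrom=chrom, start=start, end=end,
                    ref_allele=ref, alt=alt,
                    sv_type=sv_type if sv_type in ("SNP", "INDEL")
                    else _classify_literal(ref or "N" * (end - start), alt),
                    svlen=len(alt) - (end - start),
                )
            )
    return out


def _read_annotsv(path: Path) -> list[Variant]:
    rows = pd.read_csv(path, sep="\t", dtype=str)
    required = {"SV_chrom", "SV_start", "SV_end", "SV_type"}
    missing = required - set(rows.columns)
    if missing:
        raise VariantParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in rows.iterrows():
        sv_type = row["SV_type"].upper()
        start = int(row["SV_start"]) - 1  # AnnotSV is 1-based inclusive
        end = int(row["SV_end"])
        vid = row.get("AnnotSV_ID") or f"{row['SV_chrom']}_{row['SV_start']}_{i}"
        out.append(
            _variant_from_symbolic(vid, row["SV_chrom"], start, end, sv_type)
            if sv_type in ("DEL", "DUP", "INV", "INS")
            else Variant(
                id=vid, chrom=row["SV_chrom"], start=start, end=end,
                ref_allele=None, alt=f"<{sv_type}>", sv_type=sv_type, svlen=0,
            )
        )
    return out


def read_variants(path: str | Path, fmt: str) -> list[Variant]:
    """Dispatch on format name: vcf | txt | bed | annotsv."""
    fmt = {"bed": "bed_like", "annotsv": "annotsv_tsv"}.get(fmt, fmt)
    if fmt == "vcf":
        return read_vcf(path)
    return read_table(path, fmt)


def variant_length(v: Variant) -> int:
    """Length used against the maximum-variant-length limit: |svlen| for
    length-changing types, end-start for inversions, 0 for SNPs."""
    if v.sv_type == "SNP":
        return 0
    if v.sv_type == "INV":
        return v.end - v.start
    return abs(v.svlen)


def default_limit(seq_len: int) -> int:
    """Default maximum variant length: two thirds of the output length."""
    return (2 * seq_len) // 3


def filter_by_limit(
    variants: list[Variant], seq_len: int, limit: int | None = None
) -> FilterReport:
    """Partition variants into kept and rejected.

    Rejections: unsupported types (symbolic INS/CNV), malformed records
    (unpaired breakends), and variants longer than the effective limit
    (``limit`` if given, else two thirds of ``seq_len``).
    """
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    eff = limit if limit is not None else default_limit(seq_len)
    report = FilterReport()
    for v in variants:
        if v.sv_type == "BND" and v.bnd_mate is None:
            report.rejected.append((v, "malformed"))
        elif classify(v) == "unsupported":
            report.rejected.append((v, "unsupported_type"))
        elif variant_length(v) > eff:
            report.rejected.append((v, "exceeds_limit"))
        else:
            report.kept.append(v)
    return report


def write_bed_like(variants: list[Variant], out_path: str | Path) -> Path:
    """Write variants in the bed_like dialect (chrom, start, end, sv_type,
    alt, id, ref); re-reading reproduces the records."""
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        for v in variants:
            alt = "." if (v.alt.startswith("<") and v.sv_type != "BND") else v.alt
            ref = v.ref_allele or "."
            fh.write(
                "\t".join(
                    [v.chrom, str(v.start), str(v.end), v.sv_type, alt, v.id, ref]
                )
                + "\n"
            )
    return out_path


def write_rejected(report: FilterReport, out_path: str | Path) -> Path:
    """Write the rejected-variant report as TSV:
    id, chrom, start, end, sv_type, reason."""
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        fh.write("id\tchrom\tstart\tend\tsv_type\treason\n")
        for v, reason in report.rejected:
            fh.write(
                f"{v.id}\t{v.chrom}\t{v.start}\t{v.end}\t{v.sv_type}\t{reason}\n"
            )
    return out_path
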