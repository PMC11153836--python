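"""Construction of fixed-length REF/ALT sequence pairs around one variant.

The perturbation is centered (on the midpoint of its reference footprint) in
a window of ``seq_len`` bases; ``shift`` slides the window right (positive)
or left (negative), which moves the variant left/right within the emitted
sequence. Windows never cross chromosome-arm boundaries: a window that would
overhang an arm end is slid back inside (``clamped``), never truncated or
N-padded, so every emitted sequence is real genomic sequence of exactly
``seq_len`` bases — the fixed-length input contract of sequence-to-profile
models.

ALT sequences are computed in *edited-arm coordinates*: conceptually the arm
with the variant spliced in, materialized by piecewise fetches so memory
stays O(seq_len). Net length changes are absorbed by re-balancing the flanks
symmetrically (the odd base comes from the right flank), so REF and ALT
windows share as much flanking sequence as possible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .reference_genome import ArmTable, GenomeHandle
from .variant_io import Variant, classify

__all__ = [
    "WindowError",
    "UnsupportedVariantError",
    "Window",
    "SequencePair",
    "revcomp",
    "build_window",
    "incorporate",
    "fuse_breakend",
    "write_pairs",
    "read_pairs",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_LOCAL_LEFT = ("t[p[", "t]p]")  # orientations whose local flank is upstream


class WindowError(ValueError):
    """A window cannot be placed for this variant (e.g. arm too short)."""

    def __init__(self, message: str, reason: str = "off_chromosome"):
        super().__init__(message)
        self.reason = reason


class UnsupportedVariantError(ValueError):
    """The variant class cannot be incorporated (no literal sequence)."""


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N} (case-preserving)."""
    bad = set(seq) - set("ACGTNacgtn")
    if bad:
        raise ValueError(f"invalid characters for revcomp: {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Window:
    """Provenance of one extraction window (forward-genome coordinates of
    the fetched span; ``rc`` marks that the stored sequence is the reverse
    complement of this span)."""

    chrom: str
    start: int
    end: int
    requested_shift: int
    clamped: bool
    rc: bool = False


@dataclass
class SequencePair:
    """Fixed-length REF/ALT sequences for one variant.

    ``ref_seqs`` holds one sequence (two for breakends: local and mate
    windows). ``*_rel_pos`` give the 0-based offset of the variant (or
    junction) within each sequence, in the sequence's own orientation.
    ``ref_footprint``/``alt_footprint`` are the bp extents of the variant in
    the respective frames (0 for a pure deletion in ALT). For breakends,
    ``bnd_sides[i]`` says which flank of the fused ALT sequence
    ``ref_seqs[i]`` aligns with and ``ins_len`` is the untemplated-junction
    length.
    """

    variant_id: str
    sv_type: str
    ref_seqs: list[str]
    alt_seq: str
    ref_rel_pos: list[int]
    alt_rel_pos: int
    revcomp: bool
    windows: list[Window]
    alt_window: Window
    seq_len: int
    shift: int
    ref_footprint: int = 0
    alt_footprint: int = 0
    bnd_sides: list[str] | None = None
    ins_len: int = 0


def _arm_for(v: Variant, arms: ArmTable, chrom: str, pos: int, seq_len: int):
    arm = arms.arm_of(chrom, pos)
    if arm is None:
        raise WindowError(f"{v.id}: position {chrom}:{pos} falls in no arm")
    a, b = arm
    if b - a < seq_len:
        raise WindowError(
            f"{v.id}: arm {chrom}:{a}-{b} shorter than seq_len {seq_len}"
        )
    return a, b


def build_window(
    v: Variant, seq_len: int, shift: int, genome: GenomeHandle, arms: ArmTable
) -> Window:
    """Place the REF-frame window: variant midpoint at the center, slid by
    ``shift``, then clamped inside the containing chromosome arm."""
    if seq_len % 2:
        raise ValueError("seq_len must be even")
    if abs(shift) >= seq_len // 2:
        raise ValueError("|shift| must be < seq_len/2")
    mid = (v.start + v.end) // 2
    a, b = _arm_for(v, arms, v.chrom, mid, seq_len)
    w0 = mid - seq_len // 2 + shift
    ws = min(max(w0, a), b - seq_len)
    return Window(v.chrom, ws, ws + seq_len, shift, clamped=ws != w0)


def _replacement(v: Variant, genome: GenomeHandle) -> tuple[int, int, str]:
    """The edit as (start, end, replacement string) in genome coordinates."""
    if v.sv_type in ("SNP", "INDEL"):
        s, e = v.start, v.end
        file_ref = v.ref_allele
        actual = genome.fetch(v.chrom, s, e)
        if file_ref is not None and file_ref != actual:
            logger.warning(
                "%s: REF allele %r does not match genome %r at %s:%d; "
                "using file alleles", v.id, file_ref, actual, v.chrom, s,
            )
        return s, e, v.alt
    span = genome.fetch(v.chrom, v.start, v.end)
    if v.sv_type == "DEL":
        return v.start, v.end, ""
    if v.sv_type == "DUP":
        return v.start, v.end, span + span  # tandem: second copy follows first
    if v.sv_type == "INV":
        return v.start, v.end, revcomp(span)
    raise UnsupportedVariantError(f"{v.id}: cannot incorporate {v.sv_type}")


def _edited_window(
    genome: GenomeHandle,
    chrom: str,
    arm_start: int,
    s: int,
    e: int,
    repl: str,
    wa: int,
    seq_len: int,
) -> str:
    """Extract ``E[wa : wa+seq_len]`` where E is the edited arm
    ``genome[arm_start:s] + repl + genome[e:arm_end]``, without building E."""
    out: list[str] = []
    x0, x1 = wa, wa + seq_len
    rs, re_ = s - arm_start, s - arm_start + len(repl)
    lo, hi = x0, min(x1, rs)
    if hi > lo:
        out.append(genome.fetch(chrom, arm_start + lo, arm_start + hi))
    lo, hi = max(x0, rs), min(x1, re_)
    if hi > lo:
        out.append(repl[lo - rs : hi - rs])
    lo, hi = max(x0, re_), x1
    if hi > lo:
        out.append(genome.fetch(chrom, e + (lo - re_), e + (hi - re_)))
    return "".join(out)


def incorporate(
    v: Variant,
    seq_len: int,
    shift: int,
    revcomp_flag: bool,
    genome: GenomeHandle,
    arms: ArmTable,
) -> SequencePair:
    """Produce the fixed-length REF/ALT pair for one variant.

    Dispatches breakends to :func:`fuse_breakend`. Raises
    :class:`UnsupportedVariantError` for symbolic insertions/CNVs and
    :class:`WindowError` when no valid window exists.
    """
    kind = classify(v)
    if kind == "unsupported":
        raise UnsupportedVariantError(f"{v.id}: type {v.sv_type} unsupported")
    if kind == "BND":
        return fuse_breakend(v, seq_len, shift, genome, arms, revcomp_flag)

    win = build_window(v, seq_len, shift, genome, arms)
    s, e, repl = _replacement(v, genome)
    ref_seq = genome.fetch(v.chrom, win.start, win.end)
    # offset of the variant start in the window; may fall outside [0, seq_len)
    # when a large replacement plus shift overhangs the window — the window
    # content itself is always well-defined
    ref_rel = s - win.start

    svlen = len(repl) - (e - s)
    # flank re-balancing: net deletions borrow |svlen| extra flank bp split
    # symmetrically (odd base from the right); net insertions trim likewise
    if svlen >= 0:
        lf_alt = ref_rel - svlen // 2
    else:
        lf_alt = ref_rel + (-svlen) // 2
    arm_a, arm_b = _arm_for(v, arms, v.chrom, (v.start + v.end) // 2, seq_len)
    len_edited = (arm_b - arm_a) + svlen
    if len_edited < seq_len:
        raise WindowError(f"{v.id}: edited arm shorter than seq_len")
    wa0 = (s - arm_a) - lf_alt
    wa = min(max(wa0, 0), len_edited - seq_len)
    alt_seq = _edited_window(genome, v.chrom, arm_a, s, e, repl, wa, seq_len)
    alt_rel = (s - arm_a) - wa

    pair = SequencePair(
        variant_id=v.id,
        sv_type=v.sv_type,
        ref_seqs=[ref_seq],
        alt_seq=alt_seq,
        ref_rel_pos=[ref_rel],
        alt_rel_pos=alt_rel,
        revcomp=False,
        windows=[win],
        alt_window=Window(
            v.chrom, arm_a + wa, arm_a + wa + seq_len, shift, wa != wa0
        ),
        seq_len=seq_len,
        shift=shift,
        ref_footprint=e - s,
        alt_footprint=len(repl),
    )
    if revcomp_flag:
        pair = _revcomp_pair(pair)
    return pair


def _revcomp_pair(pair: SequencePair) -> SequencePair:
    """Reverse-complement all sequences in place, remapping relative
    positions into the flipped coordinate frame."""
    L = pair.seq_len
    pair.ref_seqs = [revcomp(s) for s in pair.ref_seqs]
    pair.alt_seq = revcomp(pair.alt_seq)
    if pair.sv_type == "BND":
        jstart = pair.alt_rel_pos + pair.ins_len  # old start of right segment
        new_j = L - jstart
        pair.ref_rel_pos = [new_j for _ in pair.ref_rel_pos]
        pair.alt_rel_pos = new_j
        pair.bnd_sides = [
            {"left": "right", "right": "left"}[s] for s in (pair.bnd_sides or [])
        ]
    else:
        pair.ref_rel_pos = [
            L - p - pair.ref_footprint for p in pair.ref_rel_pos
        ]
        pair.alt_rel_pos = L - pair.alt_rel_pos - pair.alt_footprint
    for w in pair.windows:
        w.rc = not w.rc
    pair.alt_window.rc = not pair.alt_window.rc
    pair.revcomp = not pair.revcomp
    return pair


def fuse_breakend(
    v: Variant,
    seq_len: int,
    shift: int,
    genome: GenomeHandle,
    arms: ArmTable,
    revcomp_flag: bool = False,
) -> SequencePair:
    """Build the fused ALT sequence for a breakend junction plus the two
    REF windows (local and mate breakend).

    The ALT is ``left_segment + inserted + right_segment`` with the
    segments chosen and oriented by the VCF bracket orientation. Each REF
    window is defined as the unique ``seq_len`` window (reverse-complemented
    for orientations that read the mate in reverse) that agrees
    base-for-base with the ALT on the corresponding flank segment, so
    REF/ALT bins align exactly on each side of the junction. ``ref_seqs``
    holds [local, mate] in that oriented frame; ``windows`` record the
    forward-genome spans with ``rc`` flags.
    """
    if seq_len % 2:
        raise ValueError("seq_len must be even")
    mate = v.bnd_mate
    if mate is None:
        raise WindowError(f"{v.id}: breakend has no mate", "malformed")
    ins = mate.inserted
    ins_len = len(ins)
    L = seq_len
    p1, c1 = v.start, v.chrom
    p2, c2 = mate.pos, mate.chrom
    o = mate.orientation
    local_left = o in _LOCAL_LEFT

    a1, b1 = _arm_for(v, arms, c1, p1, seq_len)
    a2, b2 = _arm_for(v, arms, c2, p2, seq_len)

    # forward-genome window start as a function of left_len l: start = c + m*l
    if local_left:
        local_c, local_m, local_rc = p1 + 1, -1, False
    else:
        local_c, local_m, local_rc = p1 - ins_len, -1, False
    if o == "t[p[":
        mate_c, mate_m, mate_rc = p2 - ins_len, -1, False
    elif o == "t]p]":
        mate_c, mate_m, mate_rc = p2 + ins_len - L + 1, +1, True
    elif o == "]p]t":
        mate_c, mate_m, mate_rc = p2 + 1, -1, False
    elif o == "[p[t":
        mate_c, mate_m, mate_rc = p2 - L, +1, True
    else:
        raise WindowError(f"{v.id}: unknown orientation {o!r}", "malformed")

    def feasible(c: int, m: int, a: int, b: int) -> tuple[int, int]:
        # a <= c + m*l and c + m*l + L <= b
        if m == 1:
            return a - c, (b - L) - c
        return c - (b - L), c - a

    lo1, hi1 = feasible(local_c, local_m, a1, b1)
    lo2, hi2 = feasible(mate_c, mate_m, a2, b2)
    lo = max(lo1, lo2, 1)
    hi = min(hi1, hi2, L - ins_len - 1)
    if lo > hi:
        raise WindowError(f"{v.id}: no feasible junction placement in arms")
    desired = L // 2 - shift
    left_len = min(max(desired, lo), hi)
    clamped = left_len != desired
    jstart = left_len + ins_len

    def oriented(chrom: str, c: int, m: int, rc: bool) -> tuple[str, Window]:
        start = c + m * left_len
        seq = genome.fetch(chrom, start, start + L)
        if rc:
            seq = revcomp(seq)
        return seq, Window(chrom, start, start + L, shift, clamped, rc=rc)

    local_seq, local_win = oriented(c1, local_c, local_m, local_rc)
    mate_seq, mate_win = oriented(c2, mate_c, mate_m, mate_rc)

    # REF check on the breakend base t
    if v.ref_allele:
        actual = genome.fetch(c1, p1, p1 + 1)
        if actual != v.ref_allele.upper():
            logger.warning(
                "%s: breakend REF %r does not match genome %r at %s:%d",
                v.id, v.ref_allele, actual, c1, p1,
            )

    left_source = local_seq if local_left else mate_seq
    right_source = mate_seq if local_left else local_seq
    alt_seq = left_source[:left_len] + ins.upper() + right_source[jstart:]
    assert len(alt_seq) == L

    pair = SequencePair(
        variant_id=v.id,
        sv_type="BND",
        ref_seqs=[local_seq, mate_seq],
        alt_seq=alt_seq,
        ref_rel_pos=[left_len, left_len],
        alt_rel_pos=left_len,
        revcomp=False,
        windows=[local_win, mate_win],
        alt_window=Window(c1, local_win.start, local_win.end, shift, clamped),
        seq_len=seq_len,
        shift=shift,
        ref_footprint=0,
        alt_footprint=ins_len,
        bnd_sides=["left", "right"] if local_left else ["right", "left"],
        ins_len=ins_len,
    )
    if revcomp_flag:
        pair = _revcomp_pair(pair)
    return pair


def _pair_key(pair: SequencePair) -> str:
    return f"{pair.variant_id}|{pair.shift}|{int(pair.revcomp)}"


def _records(pair: SequencePair):
    for i, (seq, win, rel) in enumerate(
        zip(pair.ref_seqs, pair.windows, pair.ref_rel_pos)
    ):
        yield ("REF" if i == 0 else "REF2", seq, win, rel)
    yield ("ALT", pair.alt_seq, pair.alt_window, pair.alt_rel_pos)


def write_pairs(pairs: list[SequencePair], out_path: str | Path) -> Path:
    """Write sequence pairs as FASTA plus a metadata TSV sidecar.

    Header grammar (bit-exact):
    ``>{variant_id}|{role}|{chrom}:{start}-{end}|relpos={n}|shift={s}|rc={0|1}``
    with roles REF, REF2 (breekend mate window), and ALT. The sidecar
    ``<out>.tsv`` repeats the header fields plus the scoring metadata
    (sv_type, footprints, breakend side, inserted length).
    """
    out_path = Path(out_path)
    tsv_path = out_path.with_suffix(".tsv")
    with open(out_path, "w") as fa, open(tsv_path, "w") as tsv:
        tsv.write(
            "pair_key\tvariant_id\trole\tchrom\tstart\tend\trelpos\tshift\trc\t"
            "sv_type\tref_footprint\talt_footprint\tside\tins_len\tseq_len\n"
        )
        for pair in pairs:
            for j, (role, seq, win, rel) in enumerate(_records(pair)):
                rc = 1 if (pair.revcomp if role == "ALT" else win.rc) else 0
                fa.write(
                    f">{pair.variant_id}|{role}|{win.chrom}:{win.start}-"
                    f"{win.end}|relpos={rel}|shift={pair.shift}|rc={rc}\n"
                )
                fa.write(seq + "\n")
                side = ""
                if pair.bnd_sides is not None and role != "ALT":
                    side = pair.bnd_sides[j]
                tsv.write(
                    "\t".join(
                        str(x)
                        for x in (
                            _pair_key(pair), pair.variant_id, role, win.chrom,
                            win.start, win.end, rel, pair.shift, rc,
                            pair.sv_type, pair.ref_footprint,
                            pair.alt_footprint, side, pair.ins_len,
                            pair.seq_len,
                        )
                    )
                    + "\n"
                )
    return out_path


def read_pairs(fasta_path: str | Path) -> list[SequencePair]:
    """Re-read pairs written by :func:`write_pairs` (FASTA + TSV sidecar),
    reconstructing SequencePair objects ready for scoring."""
    fasta_path = Path(fasta_path)
    tsv_path = fasta_path.with_suffix(".tsv")
    seqs: dict[tuple[str, str], str] = {}
    order: list[str] = []
    with open(fasta_path) as fh:
        header = None
        chunks: list[str] = []
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    seqs[header] = "".join(chunks)
                header = line[1:]
                chunks = []
            else:
                chunks.append(line)
        if header is not None:
            seqs[header] = "".join(chunks)

    import pandas as pd

    meta = pd.read_csv(tsv_path, sep="\t", dtype={"side": str}, keep_default_na=False)
    pairs: list[SequencePair] = []
    for _, grp in meta.groupby("pair_key", sort=False):
        grp = grp.set_index("role")
        vid = grp["variant_id"].iloc[0]
        sv_type = grp["sv_type"].iloc[0]
        seq_len = int(grp["seq_len"].iloc[0])

        def rec(role: str):
            row = grp.loc[role]
            key = (
                f"{vid}|{role}|{row['chrom']}:{row['start']}-{row['end']}|"
                f"relpos={row['relpos']}|shift={row['shift']}|rc={row['rc']}"
            )
            if key not in seqs:
                raise ValueError(f"FASTA record missing for {key!r}")
            win = Window(
                row["chrom"], int(row["start"]), int(row["end"]),
                int(row["shift"]), clamped=False, rc=bool(int(row["rc"])),
            )
            return seqs[key], win, int(row["relpos"])

        roles = [r for r in ("REF", "REF2") if r in grp.index]
        ref = [rec(r) for r in roles]
        alt_seq, alt_win, alt_rel = rec("ALT")
        sides = None
        if sv_type == "BND":
            sides = [grp.loc[r, "side"] for r in roles]
        pairs.append(
            SequencePair(
                variant_id=str(vid),
                sv_type=sv_type,
                ref_seqs=[r[0] for r in ref],
                alt_seq=alt_seq,
                ref_rel_pos=[r[2] for r in ref],
                alt_rel_pos=alt_rel,
                revcomp=bool(int(grp.loc["ALT", "rc"])),
                windows=[r[1] for r in ref],
                alt_window=alt_win,
                seq_len=seq_len,
                shift=int(grp.loc["ALT", "shift"]),
                ref_footprint=int(grp["ref_footprint"].iloc[0]),
                alt_footprint=int(grp["alt_footprint"].iloc[0]),
                bnd_sides=sides,
                ins_len=int(grp["ins_len"].iloc[0]),
            )
        )
    return pairs
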