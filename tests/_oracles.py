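"""Independent oracles used by the test suite.

These deliberately take the naive route — edit the whole chromosome string,
then cut the window out of it — so they share no code with the piecewise
window arithmetic they check.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def edited_chromosome(chrom_seq: str, v) -> str:
    """Whole-chromosome string after applying one variant."""
    s, e = v.start, v.end
    if v.sv_type in ("SNP", "INDEL"):
        repl = v.alt
    elif v.sv_type == "DEL":
        repl = ""
    elif v.sv_type == "DUP":
        repl = chrom_seq[s:e] * 2
    elif v.sv_type == "INV":
        repl = naive_revcomp(chrom_seq[s:e])
    else:
        raise ValueError(v.sv_type)
    return chrom_seq[:s] + repl + chrom_seq[e:]


def oracle_windows(chrom_seq: str, v, seq_len: int, shift: int):
    """Expected (ref_seq, alt_seq) for a single-arm chromosome: naive string
    edit, then window extraction with symmetric flank re-balancing."""
    s, e = v.start, v.end
    if v.sv_type in ("SNP", "INDEL"):
        repl = v.alt
    elif v.sv_type == "DEL":
        repl = ""
    elif v.sv_type == "DUP":
        repl = chrom_seq[s:e] * 2
    elif v.sv_type == "INV":
        repl = naive_revcomp(chrom_seq[s:e])
    else:
        raise ValueError(v.sv_type)
    n = len(chrom_seq)
    mid = (s + e) // 2
    w0 = mid - seq_len // 2 + shift
    ws = min(max(w0, 0), n - seq_len)
    ref = chrom_seq[ws : ws + seq_len]

    edited = chrom_seq[:s] + repl + chrom_seq[e:]
    svlen = len(repl) - (e - s)
    lf = s - ws
    lf_alt = lf - svlen // 2 if svlen >= 0 else lf + (-svlen) // 2
    wa = min(max(s - lf_alt, 0), len(edited) - seq_len)
    alt = edited[wa : wa + seq_len]
    return ref, alt


def random_variant(rng, chrom: str, chrom_len: int, seq_len: int, genome):
    """Draw one supported variant with its footprint safely inside the
    chromosome. Lengths stay under the default limit for seq_len."""
    from ismkit.variant_io import Variant

    max_len = (2 * seq_len) // 3
    sv_type = rng.choice(["SNP", "INDEL", "DEL", "DUP", "INV"])
    margin = seq_len
    if sv_type == "SNP":
        pos = int(rng.integers(margin, chrom_len - margin))
        ref = genome.fetch(chrom, pos, pos + 1)
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return Variant(f"fz_{pos}", chrom, pos, pos + 1, ref, alt, "SNP", 0)
    if sv_type == "INDEL":
        ref_len = int(rng.integers(1, 40))
        alt_len = int(rng.integers(1, 40))
        pos = int(rng.integers(margin, chrom_len - margin))
        ref = genome.fetch(chrom, pos, pos + ref_len)
        alt = "".join(rng.choice(list("ACGT"), size=alt_len))
        return Variant(
            f"fz_{pos}", chrom, pos, pos + ref_len, ref, alt, "INDEL",
            alt_len - ref_len,
        )
    span = int(rng.integers(2, max_len))
    pos = int(rng.integers(margin, chrom_len - margin - span))
    svlen = {"DEL": -span, "DUP": span, "INV": 0}[sv_type]
    return Variant(
        f"fz_{pos}", chrom, pos, pos + span, None, f"<{sv_type}>", sv_type, svlen
    )
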