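"""Indexed reference-genome access, chromosome-arm intervals, and toy fixtures.

All coordinates in this package are 0-based half-open. Conversion from the
1-based conventions of VCF and AnnotSV files happens exactly once, at parse
time in :mod:`ismkit.variant_io`; everything downstream of that point can
assume Python-slice semantics.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pyfaidx import Fasta

__all__ = [
    "GenomeError",
    "GenomeHandle",
    "ArmTable",
    "load_fasta",
    "arm_of",
    "make_toy_genome",
]

_VALID_BASES = frozenset("ACGTNacgtn")


class GenomeError(ValueError):
    """Raised for unreadable, malformed, or out-of-range genome access."""


def _validate_fasta(path: Path) -> None:
    """Stream the file once: check record names are unique and bases are IUPAC
    {A,C,G,T,N} (either case). Raises GenomeError on the first violation."""
    names: set[str] = set()
    with open(path) as fh:
        saw_record = False
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                saw_record = True
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise GenomeError(f"{path}:{lineno}: empty record name")
                if name in names:
                    raise GenomeError(f"{path}:{lineno}: duplicate record name {name!r}")
                names.add(name)
            else:
                if not saw_record:
                    raise GenomeError(f"{path}:{lineno}: sequence before first header")
                bad = set(line) - _VALID_BASES
                if bad:
                    raise GenomeError(
                        f"{path}:{lineno}: non-IUPAC characters {sorted(bad)!r}"
                    )
    if not names:
        raise GenomeError(f"{path}: no FASTA records found")


class GenomeHandle:
    """Random access to an (indexed) multi-record FASTA.

    Sequences are returned uppercase; soft-masked (lowercase) bases carry no
    special meaning here. Unknown chromosomes and out-of-range spans raise
    :class:`GenomeError` rather than returning truncated or empty output.
    """

    def __init__(self, path: str | Path):
        path = Path(path)
        if not path.exists():
            raise GenomeError(f"FASTA not found: {path}")
        _validate_fasta(path)
        self._fasta = Fasta(str(path), sequence_always_upper=True, rebuild=True)
        self.chrom_names: list[str] = list(self._fasta.keys())
        self.chrom_lengths: dict[str, int] = {
            name: len(self._fasta[name]) for name in self.chrom_names
        }

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the uppercase sequence of ``chrom[start:end]`` (0-based
        half-open). The result has length exactly ``end - start``."""
        if chrom not in self.chrom_lengths:
            raise GenomeError(f"unknown chromosome {chrom!r}")
        n = self.chrom_lengths[chrom]
        if not (0 <= start <= end <= n):
            raise GenomeError(
                f"span {chrom}:{start}-{end} out of range (length {n})"
            )
        if start == end:
            return ""
        seq = str(self._fasta[chrom][start:end])
        # pyfaidx guarantees the span given the bounds check above
        assert len(seq) == end - start
        return seq


def load_fasta(path: str | Path) -> GenomeHandle:
    """Open a FASTA (wrapped or unwrapped) for indexed access."""
    return GenomeHandle(path)


@dataclass
class ArmTable:
    """Chromosome-arm intervals (0-based half-open), used to keep extraction
    windows away from centromeres/telomeres: windows must fit entirely within
    one arm, because model predictions near sequence edges are less accurate.

    ``arms`` maps chrom -> sorted list of (start, end, name). Positions that
    fall in no interval (e.g. acrocentric gaps) map to "no arm".
    """

    arms: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, ivals in self.arms.items():
            ivals.sort()
            prev_end = -1
            for start, end, _ in ivals:
                if start < 0 or end <= start:
                    raise GenomeError(f"bad arm interval {chrom}:{start}-{end}")
                if start < prev_end:
                    raise GenomeError(f"overlapping arm intervals on {chrom}")
                prev_end = end

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ArmTable":
        """Read a 4-column TSV: chrom, arm_start, arm_end, arm_name."""
        arms: dict[str, list[tuple[int, int, str]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise GenomeError(f"arm table line needs 4 columns: {line!r}")
                chrom, start, end, name = fields[:4]
                arms.setdefault(chrom, []).append((int(start), int(end), name))
        return cls(arms)

    @classmethod
    def whole_chromosomes(cls, genome: GenomeHandle) -> "ArmTable":
        """Fallback when no centromere annotation exists (e.g. toy genomes):
        each chromosome is a single arm."""
        return cls({c: [(0, n, c)] for c, n in genome.chrom_lengths.items()})

    def arm_of(self, chrom: str, pos: int) -> tuple[int, int] | None:
        """The unique (start, end) arm interval containing ``pos``, or None."""
        ivals = self.arms.get(chrom)
        if not ivals:
            return None
        i = bisect.bisect_right([iv[0] for iv in ivals], pos) - 1
        if i < 0:
            return None
        start, end, _ = ivals[i]
        return (start, end) if start <= pos < end else None


def arm_of(arms: ArmTable, chrom: str, pos: int) -> tuple[int, int] | None:
    return arms.arm_of(chrom, pos)


def make_toy_genome(
    spec: dict[str, int],
    seed: int,
    out_path: str | Path,
    line_width: int = 60,
) -> Path:
    """Write a deterministic random FASTA with the given chromosome lengths.

    The same (spec, seed) always yields a byte-identical file; the content
    round-trips through :func:`load_fasta`.
    """
    out_path = Path(out_path)
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    with open(out_path, "w") as fh:
        for chrom, length in spec.items():
            if length < 1:
                raise GenomeError(f"chromosome {chrom!r} length must be >= 1")
            seq = "".join(alphabet[rng.integers(0, 4, size=length)])
            fh.write(f">{chrom}\n")
            for i in range(0, length, line_width):
                fh.write(seq[i : i + line_width] + "\n")
    return out_path
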