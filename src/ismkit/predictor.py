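"""Model contract for sequence-to-contact-map predictors, plus a small
deterministic stand-in predictor used throughout the test pipeline.

Real genome-folding models (Akita-class networks: ~1 Mb input, ~2 kb bins,
edge bins cropped) plug in behind :class:`PredictorSpec`/``predict``; the
package never hard-codes any trained model's geometry. The toy predictor is
a closed-form map over per-bin CG-dinucleotide content: cheap, exactly
reproducible, local (an edit inside bin k only touches row/column k), and
revcomp-covariant — exactly the properties needed to validate the masking,
alignment, and augmentation machinery downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

__all__ = ["PredictorSpec", "ContactMap", "Predictor", "ToyCGPredictor", "toy_predict"]

#: entries within this many bins of the diagonal are undefined (masked)
DIAGONAL_MASK_BINS = 2

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class PredictorSpec:
    """Geometry of a sequence-to-map model: input length (bp), bin width
    (bp), and the number of bins cropped from each map edge."""

    required_seq_len: int
    bin_size: int
    cropped_bins: int = 0

    def __post_init__(self) -> None:
        if self.required_seq_len % self.bin_size:
            raise ValueError("required_seq_len must be divisible by bin_size")
        if self.map_dim < 2:
            raise ValueError("map_dim must be >= 2")

    @property
    def map_dim(self) -> int:
        return self.required_seq_len // self.bin_size - 2 * self.cropped_bins


@dataclass
class ContactMap:
    """Square log(obs/exp) contact matrix.

    ``values`` uses NaN for undefined entries (the near-diagonal mask and
    anything a model leaves unpredicted). ``genomic_start`` is the 0-based
    coordinate of bin 0 (after cropping) in the frame of the sequence's
    window; ``variant_bin`` is the bin index the variant falls in and
    ``variant_rel`` its bp interval relative to bin 0, both None for plain
    windows.
    """

    values: np.ndarray
    bin_size: int
    genomic_start: int = 0
    variant_bin: int | None = None
    variant_rel: tuple[int, int] | None = None

    @property
    def map_dim(self) -> int:
        return self.values.shape[0]

    @property
    def mask(self) -> np.ndarray:
        """Boolean matrix, True where the entry is undefined."""
        return np.isnan(self.values)


class Predictor(Protocol):
    """Anything that turns a sequence of ``spec.required_seq_len`` bases
    into a ContactMap."""

    spec: PredictorSpec

    def predict(self, seq: str) -> ContactMap: ...


def toy_predict(seq: str, bin_size: int, cropped_bins: int = 0) -> ContactMap:
    """Closed-form toy contact map.

    With n = len(seq)/bin_size bins and f_i = (# of "CG" dinucleotides fully
    inside bin i)/bin_size::

        values[i, j] = -|i - j|/n + f_i * f_j   for |i - j| >= 2
        values[i, j] = NaN (masked)             for |i - j| < 2

    then ``cropped_bins`` bins are removed from each edge. The distance term
    mimics contact decay with genomic separation; the f_i f_j term gives a
    sequence-dependent outer-product structure that is exactly local to the
    edited bin.
    """
    if len(seq) % bin_size:
        raise ValueError("sequence length must be divisible by bin_size")
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)!r}")
    n = len(seq) // bin_size
    f = np.array(
        [seq[i * bin_size : (i + 1) * bin_size].count("CG") for i in range(n)],
        dtype=float,
    ) / bin_size
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    values = -dist / n + np.outer(f, f)
    values[dist < DIAGONAL_MASK_BINS] = np.nan
    c = cropped_bins
    if c:
        values = values[c:-c, c:-c]
    return ContactMap(values=values, bin_size=bin_size)


@dataclass
class ToyCGPredictor:
    """Deterministic CG-content predictor satisfying the model contract."""

    seq_len: int
    bin_size: int
    cropped_bins: int = 0
    spec: PredictorSpec = field(init=False)

    def __post_init__(self) -> None:
        self.spec = PredictorSpec(self.seq_len, self.bin_size, self.cropped_bins)

    def predict(self, seq: str) -> ContactMap:
        if len(seq) != self.spec.required_seq_len:
            raise ValueError(
                f"sequence length {len(seq)} != required "
                f"{self.spec.required_seq_len}"
            )
        return toy_predict(seq, self.bin_size, self.cropped_bins)
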