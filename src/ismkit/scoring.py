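"""Disruption scoring of REF vs ALT predicted contact maps.

Length-changing variants leave the two maps covering different genomic
content: a deletion's bins exist only in the REF map, a tandem duplication's
second copy only in the ALT map. :func:`mask_align` removes those rows and
columns (plus the compensating window-edge bins of the other map) so the
remaining matrices compare homologous flanking bins index-for-index; all
metrics then operate on the defined (unmasked) upper-triangle entries of
that aligned pair.

Thirteen predefined metrics are registered; the defaults are the two most
common map-comparison measures, mean squared error and Spearman rank
correlation. Error-type metrics read "higher = more disruption"; correlation
metrics are reported raw with polarity flagged in the registry, so a named
statistic is never silently transformed.

Scores can be averaged over input augmentations (±1 bp window shifts and
the reverse complement by default) to damp model positional artifacts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import stats

from .mutator import SequencePair, incorporate
from .predictor import ContactMap, Predictor

__all__ = [
    "AlignedMapPair",
    "DisruptionTrack",
    "AugmentationSpec",
    "ScoreRecord",
    "DEFAULT_AUGMENTATION",
    "DEFAULT_METRICS",
    "METRICS",
    "MetricInfo",
    "mask_align",
    "score",
    "disruption_track",
    "predict_pair",
    "score_sequence_pair",
    "augment_scores",
    "score_bnd",
    "write_scores",
    "write_track",
    "write_map",
]

#: half-width (bins) of the variant-local window for local_* metrics
LOCAL_WINDOW_BINS = 8
#: diamond half-width (bins) for insulation profiles
INSULATION_WINDOW_BINS = 3
#: lookahead/lookback (bins) for directionality index
DI_WINDOW_BINS = 3
#: diagonal offsets closer than this are masked by the toy predictor
_DIAG_MIN = 2


class ScoringError(ValueError):
    pass


@dataclass
class AlignedMapPair:
    """REF/ALT matrices on a common index frame after un-padding/masking.

    ``removed_bins`` records which bins were dropped from which map as
    (which_map, [indices]) in the pre-removal index frame. Entries undefined
    in either matrix are NaN in both (joint mask).
    """

    ref_values: np.ndarray
    alt_values: np.ndarray
    removed_bins: list[tuple[str, list[int]]]
    bin_size: int
    genomic_start: int = 0
    variant_bin: int | None = None

    def __post_init__(self) -> None:
        if self.ref_values.shape != self.alt_values.shape:
            raise ScoringError("aligned matrices must share dimensions")
        joint = np.isnan(self.ref_values) | np.isnan(self.alt_values)
        self.ref_values = np.where(joint, np.nan, self.ref_values)
        self.alt_values = np.where(joint, np.nan, self.alt_values)

    @property
    def m(self) -> int:
        return self.ref_values.shape[0]


@dataclass
class DisruptionTrack:
    """Per-bin local disagreement (mean squared difference per row)."""

    values: np.ndarray
    bin_size: int
    genomic_start: int = 0


@dataclass
class AugmentationSpec:
    """Ordered (shift_bp, revcomp) augmentations whose scores are averaged."""

    augmentations: list[tuple[int, bool]]

    def __post_init__(self) -> None:
        if not self.augmentations:
            raise ScoringError("augmentation spec must be non-empty")


DEFAULT_AUGMENTATION = AugmentationSpec(
    [(0, False), (-1, False), (1, False), (0, True)]
)


@dataclass
class ScoreRecord:
    """Per-variant metric results with the per-augmentation breakdown.

    ``values[metric]`` is the arithmetic mean of
    ``per_augmentation[k][metric]`` over augmentations.
    """

    variant_id: str
    values: dict[str, float]
    per_augmentation: list[dict[str, float]]
    augmentation: AugmentationSpec


# ---------------------------------------------------------------------------
# alignment


def _bins_overlapping(
    rel_lo: int, rel_hi: int, bin_size: int, m: int
) -> list[int]:
    """Bins whose half-open bp interval intersects [rel_lo, rel_hi) by >= 1 bp."""
    if rel_hi <= rel_lo:
        return []
    b0 = max(0, rel_lo // bin_size)
    b1 = min(m, -(-rel_hi // bin_size))
    return list(range(b0, b1))


def _drop(values: np.ndarray, bins: list[int]) -> np.ndarray:
    return np.delete(np.delete(values, bins, axis=0), bins, axis=1)


def mask_align(
    ref_map: ContactMap,
    alt_map: ContactMap,
    v,
    reverse: bool = False,
) -> AlignedMapPair:
    """Align REF and ALT maps onto a common index frame.

    DEL: the deleted bins never existed in the ALT genome — drop them from
    the REF map and drop the same number of compensating edge bins from the
    ALT map (whose window's flanks extend further by exactly the deleted
    length, split symmetrically). DUP: mirror image — drop the second-copy
    bins from the ALT map and edge bins from the REF map. Balanced variants
    (SNP, sub-bin indels, INV): no removal, masks intersected.

    ``v`` only needs an ``sv_type`` attribute. ``reverse`` says the maps were
    predicted on reverse-complemented windows, which mirrors the edge split
    and the duplicate-copy position.
    """
    if ref_map.bin_size != alt_map.bin_size:
        raise ScoringError("bin_size mismatch between maps")
    if ref_map.map_dim != alt_map.map_dim:
        raise ScoringError("map dimension mismatch")
    m = ref_map.map_dim
    bs = ref_map.bin_size
    removed: list[tuple[str, list[int]]] = []
    rv, av = ref_map.values, alt_map.values

    sv_type = getattr(v, "sv_type")
    if sv_type == "DEL" and ref_map.variant_rel is not None:
        bins = _bins_overlapping(*ref_map.variant_rel, bs, m)
        if len(bins) >= m:
            raise ScoringError("variant span exceeds the map")
        if bins:
            d = len(bins)
            la = (d - d // 2) if reverse else d // 2
            edge = list(range(la)) + list(range(m - (d - la), m))
            rv = _drop(rv, bins)
            av = _drop(av, edge)
            removed = [("ref", bins), ("alt", edge)]
    elif sv_type == "DUP" and alt_map.variant_rel is not None:
        lo, hi = alt_map.variant_rel
        copy_len = (hi - lo) // 2
        # drop the genomically-second copy: right half forward, left half
        # in a reverse-complemented frame
        span = (lo, lo + copy_len) if reverse else (lo + copy_len, hi)
        bins = _bins_overlapping(span[0], span[1], bs, m)
        if len(bins) >= m:
            raise ScoringError("variant span exceeds the map")
        if bins:
            d = len(bins)
            la = (d - d // 2) if reverse else d // 2
            edge = list(range(la)) + list(range(m - (d - la), m))
            av = _drop(av, bins)
            rv = _drop(rv, edge)
            removed = [("alt", bins), ("ref", edge)]

    mm = rv.shape[0]
    if ref_map.variant_bin is not None:
        vb = int(np.clip(ref_map.variant_bin, 0, mm - 1))
    else:
        vb = mm // 2
    return AlignedMapPair(
        ref_values=rv,
        alt_values=av,
        removed_bins=removed,
        bin_size=bs,
        genomic_start=ref_map.genomic_start,
        variant_bin=vb,
    )


# ---------------------------------------------------------------------------
# metric registry


def _defined_ut(pair: AlignedMapPair) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(pair.m, k=1)
    r, a = pair.ref_values[iu], pair.alt_values[iu]
    ok = np.isfinite(r) & np.isfinite(a)
    return r[ok], a[ok]


def _mse(pair):
    r, a = _defined_ut(pair)
    return float(np.mean((r - a) ** 2))


def _spearman(pair):
    r, a = _defined_ut(pair)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(r, a).statistic
    return float(rho)


def _pearson(pair):
    r, a = _defined_ut(pair)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.pearsonr(r, a).statistic
    return float(rho)


def _mae(pair):
    r, a = _defined_ut(pair)
    return float(np.mean(np.abs(r - a)))


def _l2(pair):
    r, a = _defined_ut(pair)
    return float(np.sqrt(np.sum((r - a) ** 2)))


def _max_abs(pair):
    r, a = _defined_ut(pair)
    return float(np.max(np.abs(r - a)))


def _local_ut(pair: AlignedMapPair, w: int) -> tuple[np.ndarray, np.ndarray]:
    vb = pair.variant_bin if pair.variant_bin is not None else pair.m // 2
    lo, hi = max(0, vb - w), min(pair.m, vb + w + 1)
    sub_r = pair.ref_values[lo:hi, lo:hi]
    sub_a = pair.alt_values[lo:hi, lo:hi]
    iu = np.triu_indices(hi - lo, k=1)
    r, a = sub_r[iu], sub_a[iu]
    ok = np.isfinite(r) & np.isfinite(a)
    return r[ok], a[ok]


def _local_mse(pair):
    r, a = _local_ut(pair, LOCAL_WINDOW_BINS)
    if r.size == 0:
        return float("nan")
    return float(np.mean((r - a) ** 2))


def _local_spearman(pair):
    r, a = _local_ut(pair, LOCAL_WINDOW_BINS)
    if r.size < 2:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.spearmanr(r, a).statistic)


def _insulation_profile(values: np.ndarray, w: int) -> np.ndarray:
    m = values.shape[0]
    out = np.full(m, np.nan)
    for i in range(w, m - w):
        block = values[i - w : i, i : i + w]
        if np.isfinite(block).any():
            out[i] = np.nanmean(block)
    return out


def _insulation_diff(pair):
    w = INSULATION_WINDOW_BINS
    ri = _insulation_profile(pair.ref_values, w)
    ai = _insulation_profile(pair.alt_values, w)
    ok = np.isfinite(ri) & np.isfinite(ai)
    if not ok.any():
        return float("nan")
    return float(np.mean(np.abs(ri[ok] - ai[ok])))


def _di_profile(values: np.ndarray, w: int) -> np.ndarray:
    m = values.shape[0]
    out = np.full(m, np.nan)
    for i in range(m):
        right = values[i, i + _DIAG_MIN : i + _DIAG_MIN + w]
        left = values[i, max(0, i - _DIAG_MIN - w + 1) : max(0, i - _DIAG_MIN + 1)]
        if np.isfinite(right).any() and np.isfinite(left).any():
            out[i] = np.nanmean(right) - np.nanmean(left)
    return out


def _di_diff(pair):
    rd = _di_profile(pair.ref_values, DI_WINDOW_BINS)
    ad = _di_profile(pair.alt_values, DI_WINDOW_BINS)
    ok = np.isfinite(rd) & np.isfinite(ad)
    if not ok.any():
        return float("nan")
    return float(np.mean(np.abs(rd[ok] - ad[ok])))


def _decay_diff(pair):
    diffs = []
    for k in range(_DIAG_MIN, pair.m):
        r = np.diagonal(pair.ref_values, k)
        a = np.diagonal(pair.alt_values, k)
        ok = np.isfinite(r) & np.isfinite(a)
        if ok.any():
            diffs.append(abs(float(np.mean(r[ok]) - np.mean(a[ok]))))
    return float(np.mean(diffs)) if diffs else float("nan")


def _track_values(pair: AlignedMapPair) -> np.ndarray:
    d = (pair.ref_values - pair.alt_values) ** 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        track = np.nanmean(d, axis=1)
    return np.nan_to_num(track, nan=0.0)


def _track_max(pair):
    return float(np.max(_track_values(pair)))


def _track_rank(pair):
    track = _track_values(pair)
    if track.size < 2:
        return 0.0
    vb = pair.variant_bin if pair.variant_bin is not None else pair.m // 2
    ranks = stats.rankdata(track, method="average")
    return float((ranks[vb] - 1) / (track.size - 1))


@dataclass(frozen=True)
class MetricInfo:
    name: str
    func: Callable[[AlignedMapPair], float]
    higher_is_more_disruptive: bool
    description: str


#: the 13 predefined disruption metrics; mse and spearman are the defaults
METRICS: dict[str, MetricInfo] = {
    m.name: m
    for m in [
        MetricInfo("mse", _mse, True, "mean squared error over defined entries"),
        MetricInfo("spearman", _spearman, False, "Spearman rank correlation"),
        MetricInfo("pearson", _pearson, False, "Pearson correlation"),
        MetricInfo("mae", _mae, True, "mean absolute error"),
        MetricInfo("l2", _l2, True, "L2 norm of the difference"),
        MetricInfo("max_abs", _max_abs, True, "maximum absolute bin difference"),
        MetricInfo(
            "local_mse", _local_mse, True,
            f"mse within ±{LOCAL_WINDOW_BINS} bins of the variant",
        ),
        MetricInfo(
            "local_spearman", _local_spearman, False,
            f"Spearman within ±{LOCAL_WINDOW_BINS} bins of the variant",
        ),
        MetricInfo(
            "insulation_diff", _insulation_diff, True,
            "mean |Δ| of diamond-window insulation profiles",
        ),
        MetricInfo(
            "di_diff", _di_diff, True, "mean |Δ| of directionality index"
        ),
        MetricInfo(
            "decay_diff", _decay_diff, True,
            "mean |Δ| of per-diagonal contact decay",
        ),
        MetricInfo("track_max", _track_max, True, "maximum of the disruption track"),
        MetricInfo(
            "track_rank", _track_rank, True,
            "normalized rank of the variant bin in the disruption track",
        ),
    ]
}

DEFAULT_METRICS = ["mse", "spearman"]


def score(pair: AlignedMapPair, metric: str) -> float:
    """Evaluate one registered metric on an aligned pair."""
    if metric not in METRICS:
        raise ScoringError(f"unknown metric {metric!r}")
    r, _ = _defined_ut(pair)
    if r.size == 0:
        raise ScoringError("all entries masked; nothing to score")
    return METRICS[metric].func(pair)


def disruption_track(pair: AlignedMapPair) -> DisruptionTrack:
    """Per-bin disruption: mean over defined columns of the squared
    REF-ALT difference in that row."""
    return DisruptionTrack(
        values=_track_values(pair),
        bin_size=pair.bin_size,
        genomic_start=pair.genomic_start,
    )


# ---------------------------------------------------------------------------
# pipeline: sequence pair -> maps -> scores


def predict_pair(
    pair: SequencePair, predictor: Predictor
) -> tuple[list[ContactMap], ContactMap]:
    """Run the predictor on all sequences of a pair and attach per-map
    metadata (genomic start of bin 0, variant bin, variant bp interval)."""
    crop_bp = predictor.spec.cropped_bins * predictor.spec.bin_size
    bs = predictor.spec.bin_size

    def annotate(cmap: ContactMap, win_start: int, rel: int, footprint: int):
        cmap.genomic_start = win_start + crop_bp
        cmap.variant_rel = (rel - crop_bp, rel - crop_bp + footprint)
        cmap.variant_bin = int(
            np.clip((rel - crop_bp) // bs, 0, cmap.map_dim - 1)
        )
        return cmap

    ref_maps = [
        annotate(
            predictor.predict(seq), win.start, rel, pair.ref_footprint
        )
        for seq, win, rel in zip(pair.ref_seqs, pair.windows, pair.ref_rel_pos)
    ]
    alt_map = annotate(
        predictor.predict(pair.alt_seq),
        pair.alt_window.start,
        pair.alt_rel_pos,
        pair.alt_footprint,
    )
    return ref_maps, alt_map


def score_sequence_pair(
    pair: SequencePair,
    predictor: Predictor,
    metrics: list[str] | None = None,
) -> dict[str, float]:
    """Predict, align, and score one sequence pair (one augmentation)."""
    metrics = metrics or DEFAULT_METRICS
    if pair.sv_type == "BND":
        return _score_bnd_pair(pair, predictor, metrics)
    ref_maps, alt_map = predict_pair(pair, predictor)
    aligned = mask_align(ref_maps[0], alt_map, pair, reverse=pair.revcomp)
    return {m: score(aligned, m) for m in metrics}


def aligned_pair(
    pair: SequencePair, predictor: Predictor
) -> AlignedMapPair:
    """Convenience: the aligned map pair for a non-BND sequence pair."""
    ref_maps, alt_map = predict_pair(pair, predictor)
    return mask_align(ref_maps[0], alt_map, pair, reverse=pair.revcomp)


def _bnd_half_pairs(
    pair: SequencePair, predictor: Predictor
) -> list[AlignedMapPair]:
    """One masked AlignedMapPair per junction flank.

    Each REF window was constructed to agree base-for-base with the fused
    ALT on its flank, so indices align directly; everything outside the
    flank's square block — including the inter-flank quadrants, which have
    no REF counterpart — is masked out.
    """
    bs = predictor.spec.bin_size
    crop_bp = predictor.spec.cropped_bins * bs
    ref_maps, alt_map = predict_pair(pair, predictor)
    m = alt_map.map_dim
    jrel = pair.alt_rel_pos - crop_bp
    jb_left = max(0, min(m, jrel // bs))  # bins fully left of the junction
    jb_right = max(0, min(m, -(-(jrel + pair.ins_len) // bs)))
    out = []
    for ref_map, side in zip(ref_maps, pair.bnd_sides or []):
        sel = (
            np.arange(0, jb_left) if side == "left" else np.arange(jb_right, m)
        )
        rv = np.full((m, m), np.nan)
        av = np.full((m, m), np.nan)
        if sel.size:
            ix = np.ix_(sel, sel)
            rv[ix] = ref_map.values[ix]
            av[ix] = alt_map.values[ix]
        vb = int(np.clip(jb_left, 0, m - 1))
        out.append(
            AlignedMapPair(
                ref_values=rv,
                alt_values=av,
                removed_bins=[],
                bin_size=bs,
                genomic_start=alt_map.genomic_start,
                variant_bin=vb,
            )
        )
    return out


def bnd_combined_pair(
    pair: SequencePair, predictor: Predictor
) -> AlignedMapPair:
    """Union of the two BND half comparisons in one masked matrix pair
    (left flank block vs local REF, right flank block vs mate REF); used
    for disruption tracks and map dumps. Inter-flank quadrants stay masked."""
    halves = _bnd_half_pairs(pair, predictor)
    rv = np.full(halves[0].ref_values.shape, np.nan)
    av = np.full_like(rv, np.nan)
    for half in halves:
        ok = np.isfinite(half.ref_values)
        rv[ok] = half.ref_values[ok]
        av[ok] = half.alt_values[ok]
    return AlignedMapPair(
        ref_values=rv, alt_values=av, removed_bins=[],
        bin_size=halves[0].bin_size, genomic_start=halves[0].genomic_start,
        variant_bin=halves[0].variant_bin,
    )


def _score_bnd_pair(
    pair: SequencePair, predictor: Predictor, metrics: list[str]
) -> dict[str, float]:
    """Defined-entry-weighted combination of the two half-map comparisons."""
    halves = _bnd_half_pairs(pair, predictor)
    acc = {m: 0.0 for m in metrics}
    wsum = 0
    for half in halves:
        r, _ = _defined_ut(half)
        w = int(r.size)
        if w == 0:
            continue
        for m in metrics:
            acc[m] += w * METRICS[m].func(half)
        wsum += w
    if wsum == 0:
        raise ScoringError(f"{pair.variant_id}: no defined entries in any flank")
    return {m: acc[m] / wsum for m in metrics}


def augment_scores(
    v,
    spec: AugmentationSpec,
    metrics: list[str],
    seq_len: int,
    predictor: Predictor,
    genome,
    arms,
    shift: int = 0,
) -> ScoreRecord:
    """Score one variant under every augmentation and average.

    Augmentation shifts add to the base ``shift``. A failing augmentation
    fails the variant — means stay comparable across perturbations.
    """
    per_aug: list[dict[str, float]] = []
    for aug_shift, aug_rc in spec.augmentations:
        pair = incorporate(v, seq_len, shift + aug_shift, aug_rc, genome, arms)
        per_aug.append(score_sequence_pair(pair, predictor, metrics))
    values = {
        m: float(np.mean([a[m] for a in per_aug])) for m in metrics
    }
    return ScoreRecord(
        variant_id=v.id, values=values, per_augmentation=per_aug,
        augmentation=spec,
    )


def score_bnd(
    v,
    seq_len: int,
    predictor: Predictor,
    genome,
    arms,
    metrics: list[str] | None = None,
    shift: int = 0,
    revcomp: bool = False,
) -> ScoreRecord:
    """Score a single breakend variant (one augmentation)."""
    from .mutator import fuse_breakend

    metrics = metrics or DEFAULT_METRICS
    pair = fuse_breakend(v, seq_len, shift, genome, arms, revcomp)
    vals = _score_bnd_pair(pair, predictor, metrics)
    return ScoreRecord(
        variant_id=v.id, values=vals, per_augmentation=[vals],
        augmentation=AugmentationSpec([(shift, revcomp)]),
    )


# ---------------------------------------------------------------------------
# output


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def write_scores(
    records: list[ScoreRecord],
    out_path: str | Path,
    metrics: list[str] | None = None,
    include_augmentations: bool = False,
) -> Path:
    """Write a scores TSV: variant_id, one column per metric, optionally one
    column per (metric, augmentation)."""
    out_path = Path(out_path)
    if metrics is None:
        metrics = list(records[0].values.keys()) if records else DEFAULT_METRICS
    cols = ["variant_id"] + list(metrics)
    aug_cols: list[tuple[str, int, int, bool]] = []
    if include_augmentations and records:
        for m in metrics:
            for k, (sh, rc) in enumerate(records[0].augmentation.augmentations):
                aug_cols.append((m, k, sh, rc))
        cols += [f"{m}|shift={sh},rc={int(rc)}" for m, _, sh, rc in aug_cols]
    with open(out_path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            row = [rec.variant_id] + [_fmt(rec.values[m]) for m in metrics]
            row += [
                _fmt(rec.per_augmentation[k][m]) for m, k, _, _ in aug_cols
            ]
            fh.write("\t".join(row) + "\n")
    return out_path


def write_track(
    track: DisruptionTrack, chrom: str, out_path: str | Path
) -> Path:
    """Write a disruption track as BedGraph (chrom, bin_start, bin_end, value)."""
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        for i, val in enumerate(track.values):
            start = track.genomic_start + i * track.bin_size
            fh.write(f"{chrom}\t{start}\t{start + track.bin_size}\t{_fmt(val)}\n")
    return out_path


def write_map(cmap: ContactMap, out_prefix: str | Path) -> Path:
    """Dump a map as a dense whitespace matrix plus a JSON metadata sidecar."""
    out_prefix = Path(out_prefix)
    mat_path = Path(f"{out_prefix}.mat.txt")
    np.savetxt(mat_path, cmap.values, fmt="%.8g")
    meta = {
        "bin_size": cmap.bin_size,
        "genomic_start": cmap.genomic_start,
        "variant_bin": cmap.variant_bin,
        "mask_width_bins": _DIAG_MIN,
        "map_dim": cmap.map_dim,
    }
    with open(f"{out_prefix}.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return mat_path
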