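"""Batched end-to-end runs: variants -> sequence pairs -> disruption scores.

Two entry points mirror the two halves of the workflow:

- :func:`run_sequences` incorporates each variant and writes the FASTA of
  fixed-length REF/ALT pairs plus a metadata TSV and a rejected-variant TSV.
- :func:`run_scores` predicts contact maps and writes a scores TSV
  (optionally per-variant map dumps and disruption tracks), either fused
  from a variant file or from pre-generated sequences written by
  :func:`run_sequences`.

Both stream the variant list in batches of ``batch_rows``; batching affects
peak memory only, never the outputs, which are byte-identical across batch
sizes and runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import scoring
from .mutator import (
    SequencePair,
    UnsupportedVariantError,
    WindowError,
    incorporate,
    read_pairs,
    write_pairs,
)
from .predictor import Predictor, ToyCGPredictor
from .reference_genome import ArmTable, load_fasta
from .scoring import (
    DEFAULT_METRICS,
    AugmentationSpec,
    ScoreRecord,
    augment_scores,
    score_sequence_pair,
    write_scores,
)
from .variant_io import FilterReport, filter_by_limit, read_variants, write_rejected

__all__ = ["RunConfig", "run_sequences", "run_scores"]

logger = logging.getLogger(__name__)

_REVCOMP_MODES = ("none", "add", "only")
_OUTPUTS = ("seq", "scores", "maps", "tracks")


@dataclass
class RunConfig:
    """Validated parameters for a run. ``validate()`` returns every problem
    at once so a misconfigured run fails before any work starts."""

    input: str | None = None
    fmt: str = "vcf"
    genome: str | None = None
    arms: str | None = None
    sequences: str | None = None  # pre-generated pairs FASTA (scoring only)
    seq_len: int = 384
    shifts: list[int] = field(default_factory=lambda: [0])
    limit: int | None = None
    revcomp_mode: str = "none"
    augment: AugmentationSpec | None = None
    metrics: list[str] = field(default_factory=lambda: list(DEFAULT_METRICS))
    batch_rows: int = 1000
    bin_size: int = 32
    cropped_bins: int = 1
    outputs: list[str] = field(default_factory=lambda: ["seq", "scores"])
    out_dir: str = "."
    seed: int | None = None  # fixture generation only

    def validate(self, scoring_run: bool = False) -> list[str]:
        errors = []
        if self.sequences is None:
            if self.input is None:
                errors.append("an input variant file is required")
            if self.genome is None:
                errors.append("a reference genome FASTA is required")
            if self.fmt not in ("vcf", "txt", "bed", "annotsv"):
                errors.append(f"unknown input format {self.fmt!r}")
        if self.seq_len < 2 or self.seq_len % 2:
            errors.append("seq_len must be even and >= 2")
        if self.batch_rows < 1:
            errors.append("batch_rows must be >= 1")
        if self.revcomp_mode not in _REVCOMP_MODES:
            errors.append(f"revcomp mode must be one of {_REVCOMP_MODES}")
        for s in self.shifts:
            if abs(s) >= self.seq_len // 2:
                errors.append(f"|shift| {s} must be < seq_len/2")
        bad = set(self.outputs) - set(_OUTPUTS)
        if bad:
            errors.append(f"unknown outputs {sorted(bad)}")
        if scoring_run:
            if self.seq_len % self.bin_size:
                errors.append("seq_len must be divisible by bin_size")
            elif self.seq_len < 2 * self.bin_size:
                errors.append("seq_len must be >= 2 * bin_size")
            unknown = set(self.metrics) - set(scoring.METRICS)
            if unknown:
                errors.append(f"unknown metrics {sorted(unknown)}")
            if self.augment is not None and self.sequences is not None:
                errors.append(
                    "augmentation needs variant+genome input, not "
                    "pre-generated sequences"
                )
        return errors

    def require_valid(self, scoring_run: bool = False) -> None:
        errors = self.validate(scoring_run)
        if errors:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))


def _load_inputs(cfg: RunConfig):
    genome = load_fasta(cfg.genome)
    arms = (
        ArmTable.from_tsv(cfg.arms)
        if cfg.arms
        else ArmTable.whole_chromosomes(genome)
    )
    variants = read_variants(cfg.input, cfg.fmt)
    return genome, arms, variants


def _batches(items: list, size: int):
    for i in range(0, len(items), size):
        yield items[i : i + size]


def _rc_flags(mode: str) -> list[bool]:
    return {"none": [False], "only": [True], "add": [False, True]}[mode]


def _log_variant(v, action: str, reason: str = "") -> None:
    logger.info(
        "variant=%s type=%s action=%s%s",
        v.id, v.sv_type, action, f" reason={reason}" if reason else "",
    )


def _incorporate_all(
    cfg: RunConfig, genome, arms, report: FilterReport
) -> list[SequencePair]:
    """Incorporate every kept variant for every (shift, revcomp) combination,
    demoting window failures to rejections."""
    pairs: list[SequencePair] = []
    still_kept = []
    for batch in _batches(report.kept, cfg.batch_rows):
        for v in batch:
            try:
                made = [
                    incorporate(v, cfg.seq_len, s, rc, genome, arms)
                    for s in cfg.shifts
                    for rc in _rc_flags(cfg.revcomp_mode)
                ]
            except WindowError as exc:
                report.rejected.append((v, exc.reason))
                _log_variant(v, "rejected", exc.reason)
                continue
            except UnsupportedVariantError:
                report.rejected.append((v, "unsupported_type"))
                _log_variant(v, "rejected", "unsupported_type")
                continue
            pairs.extend(made)
            still_kept.append(v)
            _log_variant(v, "incorporated")
    report.kept = still_kept
    return pairs


def run_sequences(cfg: RunConfig) -> dict[str, Path]:
    """Generate sequence pairs for every processable variant.

    Writes ``sequences.fa`` + ``sequences.tsv`` (pairs), ``rejected.tsv``,
    and ``summary.json`` into ``cfg.out_dir``. Returns the paths keyed by
    role. Raises if no variant could be processed.
    """
    cfg.require_valid()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome, arms, variants = _load_inputs(cfg)
    report = filter_by_limit(variants, cfg.seq_len, cfg.limit)
    for v, reason in report.rejected:
        _log_variant(v, "rejected", reason)
    pairs = _incorporate_all(cfg, genome, arms, report)

    fa_path = write_pairs(pairs, out_dir / "sequences.fa")
    rej_path = write_rejected(report, out_dir / "rejected.tsv")
    summary = {
        "input_variants": len(report),
        "processed": len(report.kept),
        "rejected": len(report.rejected),
        "pairs_written": len(pairs),
        "seq_len": cfg.seq_len,
        "shifts": cfg.shifts,
        "revcomp": cfg.revcomp_mode,
    }
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
    if not pairs:
        raise RuntimeError("no variant could be processed")
    return {
        "fasta": fa_path,
        "metadata": fa_path.with_suffix(".tsv"),
        "rejected": rej_path,
        "summary": summary_path,
    }


def _make_predictor(cfg: RunConfig, seq_len: int) -> Predictor:
    return ToyCGPredictor(seq_len, cfg.bin_size, cfg.cropped_bins)


def _record_ids(pairs: list[SequencePair]) -> list[str]:
    """One stable id per pair: the bare variant id when unique in this run,
    otherwise variant|shift|rc."""
    counts: dict[str, int] = {}
    for p in pairs:
        counts[p.variant_id] = counts.get(p.variant_id, 0) + 1
    return [
        p.variant_id
        if counts[p.variant_id] == 1
        else f"{p.variant_id}|{p.shift}|{int(p.revcomp)}"
        for p in pairs
    ]


def _emit_optional_outputs(
    cfg: RunConfig,
    out_dir: Path,
    rec_id: str,
    pair: SequencePair,
    predictor: Predictor,
) -> None:
    want_maps = "maps" in cfg.outputs
    want_tracks = "tracks" in cfg.outputs
    if not (want_maps or want_tracks):
        return
    if pair.sv_type == "BND":
        aligned = scoring.bnd_combined_pair(pair, predictor)
    else:
        aligned = scoring.aligned_pair(pair, predictor)
    safe = rec_id.replace("|", "_").replace(":", "_")
    if want_maps:
        ref_maps, alt_map = scoring.predict_pair(pair, predictor)
        scoring.write_map(ref_maps[0], out_dir / f"{safe}.ref")
        scoring.write_map(alt_map, out_dir / f"{safe}.alt")
    if want_tracks:
        track = scoring.disruption_track(aligned)
        scoring.write_track(track, pair.windows[0].chrom, out_dir / f"{safe}.track.bedgraph")


def run_scores(cfg: RunConfig) -> dict[str, Path]:
    """Score variants for 3D-genome disruption.

    Input is either a variant file + genome (fused path) or a pre-generated
    sequence FASTA with its metadata TSV (``cfg.sequences``). Scores TSV is
    always written; per-variant maps and disruption tracks only when
    requested in ``cfg.outputs``. The fused path without augmentation
    produces scores identical to generating sequences first and scoring
    them.
    """
    cfg.require_valid(scoring_run=True)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records: list[ScoreRecord] = []
    rej_path = None

    if cfg.sequences is not None:
        pairs = read_pairs(cfg.sequences)
        if pairs and len(pairs[0].alt_seq) != cfg.seq_len:
            raise ValueError(
                f"pre-generated sequences have length {len(pairs[0].alt_seq)}"
                f" but seq_len is {cfg.seq_len}"
            )
        predictor = _make_predictor(cfg, cfg.seq_len)
        for rec_id, pair in zip(_record_ids(pairs), pairs):
            vals = score_sequence_pair(pair, predictor, cfg.metrics)
            records.append(
                ScoreRecord(
                    variant_id=rec_id, values=vals, per_augmentation=[vals],
                    augmentation=AugmentationSpec([(pair.shift, pair.revcomp)]),
                )
            )
            _emit_optional_outputs(cfg, out_dir, rec_id, pair, predictor)
    else:
        genome, arms, variants = _load_inputs(cfg)
        report = filter_by_limit(variants, cfg.seq_len, cfg.limit)
        predictor = _make_predictor(cfg, cfg.seq_len)
        if cfg.augment is not None:
            for batch in _batches(report.kept, cfg.batch_rows):
                for v in batch:
                    try:
                        rec = augment_scores(
                            v, cfg.augment, cfg.metrics, cfg.seq_len,
                            predictor, genome, arms, shift=cfg.shifts[0],
                        )
                    except WindowError as exc:
                        report.rejected.append((v, exc.reason))
                        _log_variant(v, "rejected", exc.reason)
                        continue
                    records.append(rec)
                    _log_variant(v, "scored")
        else:
            pairs = _incorporate_all(cfg, genome, arms, report)
            for rec_id, pair in zip(_record_ids(pairs), pairs):
                vals = score_sequence_pair(pair, predictor, cfg.metrics)
                records.append(
                    ScoreRecord(
                        variant_id=rec_id, values=vals,
                        per_augmentation=[vals],
                        augmentation=AugmentationSpec(
                            [(pair.shift, pair.revcomp)]
                        ),
                    )
                )
                _emit_optional_outputs(cfg, out_dir, rec_id, pair, predictor)
        rej_path = write_rejected(report, out_dir / "rejected.tsv")

    scores_path = write_scores(
        records, out_dir / "scores.tsv", metrics=cfg.metrics,
        include_augmentations=cfg.augment is not None,
    )
    out = {"scores": scores_path}
    if rej_path is not None:
        out["rejected"] = rej_path
    return out
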