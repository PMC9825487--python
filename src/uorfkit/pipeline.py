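"""One-command pipeline: annotate → candidates → P-sites → QC → call → variants.

The pipeline is deterministic: identical configuration (and inputs) yields
byte-identical output files, and a machine-readable run manifest records
inputs, parameters, package version and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

from . import __version__
from .active_calling import (
    DEFAULT_MIN_READS,
    DEFAULT_PERIODICITY_ALPHA,
    DEFAULT_SCORE_THRESHOLD,
    call_sample,
    write_calls_tsv,
)
from .qc import SIZE_GATE_MIN_READS, evaluate_library
from .ribo_io import (
    DEFAULT_LENGTH_FILTER,
    OffsetTable,
    build_psite_profiles,
    estimate_offsets,
    load_alignments,
)
from .transcript_model import parse_annotation
from .uorf_discovery import (
    DEFAULT_START_CODONS,
    collapse_isoforms,
    enumerate_candidates,
    write_candidates_tsv,
)
from .variant_annotation import (
    annotate_effect,
    extract_utr5_variants,
    write_effects_tsv,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    annotation: str = ""
    genome: str = ""
    alignments: str = ""  # BAM/SAM or P-site TSV
    alignment_space: str = "transcript"
    vcf: str = ""
    offset_table: str = ""  # optional user-supplied offsets
    output_dir: str = "uorfkit_out"
    start_codons: tuple[str, ...] = DEFAULT_START_CODONS
    min_len_nt: int = 18
    length_filter_min: int = 27
    length_filter_max: int = 32
    score_threshold: float = DEFAULT_SCORE_THRESHOLD
    periodicity_alpha: float = DEFAULT_PERIODICITY_ALPHA
    min_reads: int = DEFAULT_MIN_READS
    qc_min_reads: int = SIZE_GATE_MIN_READS
    sample_id: str = "sample1"
    seed: int = 0
    force: bool = False

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Flat key=value config file; unknown keys are an error."""
        cfg = cls()
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise PipelineError(f"config line {i}: expected key=value, got {line!r}")
                key, value = (x.strip() for x in line.split("=", 1))
                if not hasattr(cfg, key):
                    raise PipelineError(f"config line {i}: unknown key {key!r}")
                current = getattr(cfg, key)
                if isinstance(current, bool):
                    setattr(cfg, key, value.lower() in ("1", "true", "yes"))
                elif isinstance(current, int):
                    setattr(cfg, key, int(value))
                elif isinstance(current, float):
                    setattr(cfg, key, float(value))
                elif isinstance(current, tuple):
                    setattr(cfg, key, tuple(v.strip().upper() for v in value.split(",")))
                else:
                    setattr(cfg, key, value)
        return cfg

    @property
    def length_filter(self) -> range:
        return range(self.length_filter_min, self.length_filter_max + 1)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run manifest.

    Stages run in order: annotation parsing, candidate enumeration, P-site
    profiling, QC, active calling, and (when a VCF is supplied) variant
    annotation.  A failed QC gate halts before calling unless
    ``config.force`` is set.
    """
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {},
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
            if k not in ("annotation", "genome", "alignments", "vcf", "output_dir", "offset_table")
        },
        "outputs": {},
        "stages": [],
    }
    for key in ("annotation", "genome", "alignments", "vcf", "offset_table"):
        path = getattr(config, key)
        if path:
            manifest["inputs"][key] = {"path": path, "sha256": _sha256(path)}

    # stage: annotate
    try:
        records = parse_annotation(config.annotation, config.genome)
    except Exception as exc:
        raise PipelineError(f"annotate: {exc}") from exc
    models = {m.transcript_id: m for m, _ in records}
    seqs = {s.transcript_id: s for _, s in records}
    manifest["stages"].append({"stage": "annotate", "n_transcripts": len(models)})

    # stage: candidates
    try:
        candidates = []
        for tid in sorted(models):
            if models[tid].has_utr5:
                candidates.extend(
                    enumerate_candidates(
                        models[tid], seqs[tid], config.start_codons, config.min_len_nt
                    )
                )
        collapsed = collapse_isoforms(candidates)
    except Exception as exc:
        raise PipelineError(f"candidates: {exc}") from exc
    cand_path = os.path.join(out, "candidates.tsv")
    write_candidates_tsv(collapsed, cand_path)
    manifest["outputs"]["candidates"] = os.path.basename(cand_path)
    manifest["stages"].append(
        {"stage": "candidates", "n_candidates": len(candidates), "n_collapsed": len(collapsed)}
    )

    profiles = None
    if config.alignments:
        # stage: psites
        try:
            hits, drop_stats = load_alignments(config.alignments, config.alignment_space, models)
            if config.offset_table:
                offsets = OffsetTable.read_tsv(config.offset_table)
            else:
                offsets = estimate_offsets(hits, models, lengths=config.length_filter)
            profiles = build_psite_profiles(hits, offsets, models, config.length_filter)
        except Exception as exc:
            raise PipelineError(f"psites: {exc}") from exc
        off_path = os.path.join(out, "offsets.tsv")
        offsets.write_tsv(off_path)
        manifest["outputs"]["offsets"] = os.path.basename(off_path)
        manifest["stages"].append(
            {
                "stage": "psites",
                "n_hits": len(hits),
                "dropped": drop_stats,
                "n_profiled_transcripts": len(profiles),
            }
        )

        # stage: qc
        try:
            fasta_for_size = (
                config.alignments if config.alignments.endswith((".fa", ".fasta")) else None
            )
            report = evaluate_library(
                hits,
                profiles,
                models,
                fasta_path=fasta_for_size,
                size_min_reads=config.qc_min_reads,
            )
        except Exception as exc:
            raise PipelineError(f"qc: {exc}") from exc
        qc_path = os.path.join(out, "qc.json")
        report.write_json(qc_path)
        manifest["outputs"]["qc"] = os.path.basename(qc_path)
        manifest["stages"].append({"stage": "qc", "pass": report.passed, "gates": report.gates})
        if not report.passed and not config.force:
            _write_manifest(manifest, out)
            raise PipelineError(
                "qc: QC gate failed (" + "; ".join(report.reasons.values()) + ")"
            )

        # stage: call
        try:
            calls = call_sample(
                collapsed,
                profiles,
                models,
                min_reads=config.min_reads,
                alpha=config.periodicity_alpha,
                threshold=config.score_threshold,
                sample_id=config.sample_id,
            )
        except Exception as exc:
            raise PipelineError(f"call: {exc}") from exc
        calls_path = os.path.join(out, "calls.tsv")
        write_calls_tsv(calls, calls_path)
        manifest["outputs"]["calls"] = os.path.basename(calls_path)
        manifest["stages"].append(
            {"stage": "call", "n_calls": len(calls), "n_active": sum(c.active for c in calls)}
        )

    if config.vcf:
        # stage: variants
        try:
            variants, var_stats = extract_utr5_variants(config.vcf, models)
            effects = []
            for v in variants:
                model = models[v.transcript_id]
                cands = [c for c in candidates if c.transcript_id == v.transcript_id]
                effects.extend(
                    annotate_effect(
                        v, model, seqs[v.transcript_id], cands,
                        config.start_codons, config.min_len_nt,
                    )
                )
        except Exception as exc:
            raise PipelineError(f"variants: {exc}") from exc
        eff_path = os.path.join(out, "variant_effects.tsv")
        write_effects_tsv(effects, {v.variant_id: v for v in variants}, eff_path)
        manifest["outputs"]["variant_effects"] = os.path.basename(eff_path)
        manifest["stages"].append(
            {
                "stage": "variants",
                "n_utr5_variants": len(variants),
                "n_effects": len(effects),
                "dropped": var_stats,
            }
        )

    _write_manifest(manifest, out)
    return manifest


def _jsonify(obj):
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_manifest(manifest: dict, out_dir: str) -> None:
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")
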