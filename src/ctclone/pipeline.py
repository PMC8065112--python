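"""Full-pipeline orchestration: filter -> pathogenicity -> clonality ->
copy number -> associations -> signatures, with deterministic TSV outputs.

Every output table carries ``# key=value`` metadata headers recording the
tool version, the seed and a hash of the run parameters; no timestamps are
written, so a rerun with an identical configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .clonality import clonality_table
from .copy_number import adjust_cohort
from .io import (
    Cohort,
    classify_cohort,
    filter_germline,
    read_annotation_resources,
    read_cohort,
    write_cohort,
    write_table,
)
from .signatures import (
    aggregate_clonal_subclonal,
    bootstrap_exposures,
    compare_conditions,
    fit_exposures,
    read_signature_matrix,
    synthetic_signatures,
)
from .stats import cooccurrence_matrix

logger = logging.getLogger("ctclone")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in its message."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    variants: str
    clinical: str
    cn: str | None = None
    hotspots: str | None = None
    oncogenic: str | None = None
    recurrence: str | None = None
    signature_matrix: str | None = None  # None -> built-in synthetic reference set
    out_dir: str = "ctclone_out"
    seed: int = 0
    vaf_scale: str = "percent"
    vaf_center: float = 50.0
    vaf_halfwidth: float = 2.0
    pop_af_threshold: float = 0.001
    recurrence_min: int = 3
    min_incidence: float = 0.05
    cn_gene: str = "HER2"
    cn_threshold: float = 2.0
    discard_threshold: float = 0.06
    bootstrap_iterations: int = 200
    bootstrap_fraction: float = 0.9
    signature_subtypes: tuple = ("HR+HER2-", "TNBC")
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("variants", "clinical", "cn", "hotspots", "oncogenic",
                     "recurrence", "signature_matrix"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "signature_subtypes" in raw:
            raw["signature_subtypes"] = tuple(raw["signature_subtypes"])
        return cls(**raw)

    def metadata(self) -> dict:
        params = asdict(self)
        # only analysis-relevant parameters enter the hash: the same inputs
        # and settings give identical outputs wherever they are written
        params.pop("out_dir", None)
        params.pop("log_level", None)
        digest = hashlib.sha256(
            json.dumps(params, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        return {"tool": f"ctclone {__version__}", "seed": self.seed, "params_sha256": digest}


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return decorator


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis pipeline; returns the output paths.

    Inputs are never mutated; everything is written under
    ``config.out_dir``.  Stage failures raise :class:`PipelineError` naming
    the stage.
    """
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = config.metadata()
    outputs: dict[str, Path] = {}

    cohort = _load(config)
    cohort, removed = _filter(config, cohort)
    outputs["removed_germline"] = out / "removed_germline.tsv"
    removed_cohort = Cohort()
    from .io import PatientProfile  # avoid polluting the module namespace

    for v in removed:
        if v.patient_id not in removed_cohort:
            removed_cohort.add(PatientProfile(patient_id=v.patient_id))
        removed_cohort[v.patient_id].variants.append(v)
    write_table(removed_cohort.variants_frame(), outputs["removed_germline"], meta)

    if config.hotspots and config.oncogenic and config.recurrence:
        cohort = _classify(config, cohort)
    outputs["variants_filtered"] = out / "variants_filtered.tsv"
    outputs["clinical"] = out / "clinical.tsv"
    outputs["cn"] = out / "cn.tsv"
    write_cohort(cohort, outputs["variants_filtered"], outputs["clinical"], outputs["cn"], meta)

    outputs["clonality"] = out / "clonality.tsv"
    ct = _clonality(cohort)
    write_table(ct, outputs["clonality"], meta)

    cn_table = _copy_number(config, cohort)
    if not cn_table.empty:
        outputs["copy_number"] = out / "copy_number_adjusted.tsv"
        write_table(cn_table, outputs["copy_number"], meta)

    assoc = _associations(config, cohort)
    if assoc is not None:
        outputs["cooccurrence"] = out / "cooccurrence.tsv"
        write_table(assoc, outputs["cooccurrence"], meta)

    sig_table = _signatures(config, cohort)
    if sig_table is not None:
        outputs["signatures"] = out / "signature_comparison.tsv"
        write_table(sig_table, outputs["signatures"], meta)

    logger.info("pipeline complete: %d outputs under %s", len(outputs), out)
    return outputs


@_stage("load")
def _load(config: RunConfig) -> Cohort:
    return read_cohort(config.variants, config.clinical, config.cn, vaf_scale=config.vaf_scale)


@_stage("germline-filter")
def _filter(config: RunConfig, cohort: Cohort):
    return filter_germline(
        cohort, config.vaf_center, config.vaf_halfwidth, config.pop_af_threshold
    )


@_stage("pathogenicity")
def _classify(config: RunConfig, cohort: Cohort) -> Cohort:
    resources = read_annotation_resources(config.hotspots, config.oncogenic, config.recurrence)
    return classify_cohort(cohort, resources, config.recurrence_min)


@_stage("clonality")
def _clonality(cohort: Cohort):
    return clonality_table(cohort)


@_stage("copy-number")
def _copy_number(config: RunConfig, cohort: Cohort):
    return adjust_cohort(cohort, config.cn_gene, config.cn_threshold)


@_stage("associations")
def _associations(config: RunConfig, cohort: Cohort):
    try:
        return cooccurrence_matrix(cohort, config.min_incidence, pathogenic_only=False)
    except ValueError as exc:
        logger.warning("skipping co-occurrence: %s", exc)
        return None


@_stage("signatures")
def _signatures(config: RunConfig, cohort: Cohort):
    import pandas as pd

    signatures = (
        read_signature_matrix(config.signature_matrix)
        if config.signature_matrix
        else synthetic_signatures()
    )
    frames = []
    for subtype in config.signature_subtypes:
        sets = aggregate_clonal_subclonal(cohort, subtype)
        if len(sets.clonal) < 10 or len(sets.subclonal) < 10:
            logger.warning(
                "skipping signatures for %s: sets too small (%d clonal, %d subclonal)",
                subtype, len(sets.clonal), len(sets.subclonal),
            )
            continue
        boot_clonal = bootstrap_exposures(
            sets.clonal, signatures, config.bootstrap_iterations,
            config.bootstrap_fraction, seed=config.seed,
            discard_threshold=config.discard_threshold,
        )
        boot_subclonal = bootstrap_exposures(
            sets.subclonal, signatures, config.bootstrap_iterations,
            config.bootstrap_fraction, seed=config.seed + 1,
            discard_threshold=config.discard_threshold,
        )
        comparison = compare_conditions(boot_clonal, boot_subclonal)
        comparison.insert(0, "subtype", subtype)
        full_clonal = fit_exposures(sets.clonal.catalogue(), signatures,
                                    config.discard_threshold)
        full_subclonal = fit_exposures(sets.subclonal.catalogue(), signatures,
                                       config.discard_threshold)
        comparison["full_fit_clonal"] = full_clonal.weights.to_numpy()
        comparison["full_fit_subclonal"] = full_subclonal.weights.to_numpy()
        frames.append(comparison)
    if not frames:
        return None
    return pd.concat(frames, ignore_index=True)
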