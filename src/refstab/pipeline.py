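"""Pipeline orchestration: one config drives the full validation workflow.

A :class:`PipelineConfig` (YAML on disk) names an input — a wide Ct CSV
plus annotation CSV, or a simulation design — a set of cohorts (filters
on treatment group and tissue location), the stability methods to run,
and optional relative-expression analyses. :func:`run_pipeline` writes,
per cohort, the per-method stability tables, the comprehensive-ranking
report, gene summaries, and expression reports, plus a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import refstab
from refstab.aggregate import METHOD_ORDER, rank_table
from refstab.ct_data import (
    CtMatrix,
    SampleAnnotation,
    complete_case,
    load_ct_table,
    summarize,
    summaries_to_frame,
)
from refstab.expression import delta_delta_ct, group_anova
from refstab.stability import bestkeeper, delta_ct_stability, genorm, normfinder
from refstab.synthetic import default_design, load_design, simulate_ct

__all__ = ["PipelineConfig", "CohortSpec", "validate_config", "run_pipeline"]

logger = logging.getLogger("refstab")

_METHOD_FUNCS = {
    "delta_ct": lambda ct, ann: delta_ct_stability(ct),
    "genorm": lambda ct, ann: genorm(ct),
    "normfinder": lambda ct, ann: normfinder(ct),
    "bestkeeper": lambda ct, ann: bestkeeper(ct),
}


@dataclass
class CohortSpec:
    """A named sample filter: which groups and locations enter an analysis."""

    name: str
    groups: list[str] | None = None  # None = all
    locations: list[str] | None = None


@dataclass
class ExpressionSpec:
    goi: str
    refs: list[str]
    control_group: str


@dataclass
class PipelineConfig:
    input_ct: str | None = None  # wide Ct CSV
    input_annotations: str | None = None
    simulate: str | None = None  # "default" or a design YAML path
    cohorts: list[CohortSpec] = field(default_factory=lambda: [CohortSpec("all")])
    methods: list[str] = field(default_factory=lambda: list(METHOD_ORDER))
    genorm_efficiencies: str | None = None  # CSV gene,amplification
    expression: list[ExpressionSpec] = field(default_factory=list)
    output_dir: str = "refstab_out"
    seed: int = 0
    log_level: str = "INFO"


def validate_config(source: str | Path | dict) -> tuple[PipelineConfig | None, list[str]]:
    """Parse and validate a pipeline config; returns (config, errors).

    All violations are collected (never fail-on-first); the config is
    ``None`` whenever the error list is non-empty.
    """
    if isinstance(source, dict):
        raw = source
    else:
        try:
            raw = yaml.safe_load(Path(source).read_text())
        except (OSError, yaml.YAMLError) as exc:
            return None, [f"cannot read config: {exc}"]
    if not isinstance(raw, dict):
        return None, ["config must be a mapping"]

    errors: list[str] = []
    known = {
        "input_ct", "input_annotations", "simulate", "cohorts", "methods",
        "genorm_efficiencies", "expression", "output_dir", "seed", "log_level",
    }
    for key in set(raw) - known:
        errors.append(f"unknown config key {key!r} (allowed: {sorted(known)})")

    methods = raw.get("methods", list(METHOD_ORDER))
    if not isinstance(methods, list) or not methods:
        errors.append("methods must be a non-empty list")
        methods = list(METHOD_ORDER)
    for m in methods:
        if m not in METHOD_ORDER:
            errors.append(f"unknown method {m!r} (allowed: {list(METHOD_ORDER)})")

    cohorts_raw = raw.get("cohorts", [{"name": "all"}])
    cohorts: list[CohortSpec] = []
    names: set[str] = set()
    if not isinstance(cohorts_raw, list):
        errors.append("cohorts must be a list")
    else:
        for c in cohorts_raw:
            if not isinstance(c, dict) or "name" not in c:
                errors.append(f"each cohort needs a 'name': {c!r}")
                continue
            if c["name"] in names:
                errors.append(f"duplicate cohort name {c['name']!r}")
            names.add(c["name"])
            extra = set(c) - {"name", "groups", "locations"}
            if extra:
                errors.append(f"cohort {c['name']!r}: unknown keys {sorted(extra)}")
            cohorts.append(
                CohortSpec(c["name"], c.get("groups"), c.get("locations"))
            )

    expr: list[ExpressionSpec] = []
    for e in raw.get("expression", []) or []:
        need = {"goi", "refs", "control_group"}
        if not isinstance(e, dict) or not need <= set(e):
            errors.append(f"expression entries need keys {sorted(need)}: {e!r}")
            continue
        refs = e["refs"] if isinstance(e["refs"], list) else [e["refs"]]
        expr.append(ExpressionSpec(e["goi"], refs, e["control_group"]))

    has_input = raw.get("input_ct") is not None
    has_sim = raw.get("simulate") is not None
    if has_input == has_sim:
        errors.append("exactly one of input_ct or simulate must be given")
    if has_input and raw.get("input_annotations") is None:
        errors.append("input_ct requires input_annotations")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed must be an integer")
        seed = 0

    if errors:
        return None, errors
    return (
        PipelineConfig(
            input_ct=raw.get("input_ct"),
            input_annotations=raw.get("input_annotations"),
            simulate=raw.get("simulate"),
            cohorts=cohorts,
            methods=methods,
            genorm_efficiencies=raw.get("genorm_efficiencies"),
            expression=expr,
            output_dir=raw.get("output_dir", "refstab_out"),
            seed=seed,
            log_level=raw.get("log_level", "INFO"),
        ),
        [],
    )


def _resolve_input(config: PipelineConfig) -> tuple[CtMatrix, list[SampleAnnotation]]:
    if config.simulate is not None:
        design = (
            default_design(seed=config.seed)
            if config.simulate == "default"
            else load_design(config.simulate)
        )
        ds = simulate_ct(design, seed=config.seed)
        return ds.ct, ds.annotations
    ct, ann = load_ct_table(
        config.input_ct, layout="wide", annotation_source=config.input_annotations
    )
    return ct, ann


def _filter_cohort(
    ct: CtMatrix, annotations: list[SampleAnnotation], cohort: CohortSpec
) -> tuple[CtMatrix, list[SampleAnnotation]]:
    by_id = {a.sample_id: a for a in annotations}
    keep = [
        s
        for s in ct.sample_ids
        if (cohort.groups is None or by_id[s].group in cohort.groups)
        and (cohort.locations is None or by_id[s].location in cohort.locations)
    ]
    if not keep:
        raise ValueError(f"cohort {cohort.name!r} selects no samples")
    return ct.subset(samples=keep), [by_id[s] for s in keep]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured workflow; returns the run manifest."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ct, annotations = _resolve_input(config)
    logger.info("input: %d samples × %d genes", ct.n_samples, ct.n_genes)

    vocab_groups = sorted({a.group for a in annotations})
    vocab_locations = sorted({a.location for a in annotations})
    for cohort in config.cohorts:
        for g in cohort.groups or []:
            if g not in vocab_groups:
                raise ValueError(
                    f"cohort {cohort.name!r}: unknown group {g!r} (have {vocab_groups})"
                )
        for loc in cohort.locations or []:
            if loc not in vocab_locations:
                raise ValueError(
                    f"cohort {cohort.name!r}: unknown location {loc!r} "
                    f"(have {vocab_locations})"
                )

    efficiencies = None
    if config.genorm_efficiencies:
        eff = pd.read_csv(config.genorm_efficiencies)
        efficiencies = dict(zip(eff["gene"], eff["amplification"].astype(float)))

    written: list[str] = []

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        written.append(name)

    for cohort in config.cohorts:
        sub, sub_ann = _filter_cohort(ct, annotations, cohort)
        complete, removed = complete_case(sub)
        logger.info(
            "cohort %s: %d samples (%d removed as incomplete), %d genes",
            cohort.name, complete.n_samples, len(removed), complete.n_genes,
        )
        results = []
        for m in config.methods:
            if m == "genorm" and efficiencies is not None:
                res = genorm(complete, efficiencies=efficiencies)
            else:
                res = _METHOD_FUNCS[m](complete, sub_ann)
            results.append(res)
            _write(res.to_frame(), f"{cohort.name}_{m}.csv")
        if set(config.methods) == set(METHOD_ORDER):
            _write(rank_table(results), f"{cohort.name}_comprehensive.csv")
        _write(
            summaries_to_frame(summarize(sub, sub_ann, stratify_by="location"))
            if len({a.location for a in sub_ann}) > 1
            else summaries_to_frame(summarize(sub)),
            f"{cohort.name}_gene_summary.csv",
        )

    for spec in config.expression:
        res = delta_delta_ct(
            ct, spec.goi, spec.refs, spec.control_group, annotations
        )
        comparisons = group_anova(res)
        ref_tag = "+".join(spec.refs)
        _write(res.per_group, f"expression_{spec.goi}_vs_{ref_tag}_groups.csv")
        _write(comparisons, f"expression_{spec.goi}_vs_{ref_tag}_tests.csv")

    manifest = {
        "refstab_version": refstab.__version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(
                {
                    "input_ct": config.input_ct,
                    "simulate": config.simulate,
                    "cohorts": [[c.name, c.groups, c.locations] for c in config.cohorts],
                    "methods": config.methods,
                    "seed": config.seed,
                },
                sort_keys=True,
            ).encode()
        ).hexdigest(),
        "n_samples": ct.n_samples,
        "n_genes": ct.n_genes,
        "outputs": written,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
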