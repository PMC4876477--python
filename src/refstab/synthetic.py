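"""Seeded generator of synthetic Ct datasets with known ground truth.

Generative model for sample s, gene g:

    Ct(s, g) = baseline_g + u_s + sum(matching effect shifts) + eps_sg

where ``u_s ~ Normal(0, sample_effect_sd²)`` is a shared per-sample
loading/RNA-input effect (it is what makes stable genes co-vary, giving
the stability algorithms their signal) and
``eps_sg ~ Normal(0, noise_sd_g²)`` is gene-specific technical noise on
the Ct (log) scale. Effects are additive cycle shifts keyed on
(gene, group, location), with ``"*"`` as a wildcard.

The default design mirrors a five-reference-gene validation study in
preterm lamb lung tissue: six treatment groups (unventilated control NI
plus ventilation strategies V1–V5) × two tissue locations
(non-dependent, gravity-dependent), n = 10 animals per cell, and an
RPS29 expression drop (+1.78 cycles) in gravity-dependent tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from refstab.ct_data import CtMatrix, SampleAnnotation

__all__ = [
    "GeneSpec",
    "Effect",
    "SimulationDesign",
    "SimulatedDataset",
    "default_design",
    "unstable_benchmark_design",
    "simulate_ct",
    "simulate_dilution_series",
    "save_design",
    "load_design",
]


@dataclass(frozen=True)
class GeneSpec:
    """One simulated gene: baseline Ct (cycles) and technical noise SD (cycles)."""

    gene_id: str
    baseline_ct: float
    noise_sd: float


@dataclass(frozen=True)
class Effect:
    """Additive Ct shift for a gene in matching (group, location) cells.

    ``group`` / ``location`` may be ``"*"`` to match every level.
    Positive shifts mean later threshold crossing, i.e. lower expression.
    """

    gene_id: str
    group: str
    location: str
    shift: float


@dataclass
class SimulationDesign:
    """Full generative specification for a synthetic Ct dataset."""

    genes: list[GeneSpec]
    groups: list[tuple[str, int]]  # (group_id, n per location)
    locations: list[str]
    sample_effect_sd: float = 0.5
    effects: list[Effect] = field(default_factory=list)
    seed: int = 0
    censor_at: float | None = None  # optional max-cycle censoring, off by default

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in design")
        if self.sample_effect_sd < 0:
            raise ValueError("sample_effect_sd must be ≥ 0")
        for g in self.genes:
            if g.noise_sd < 0:
                raise ValueError(f"noise_sd for {g.gene_id} must be ≥ 0")
        for _, n in self.groups:
            if n < 1:
                raise ValueError("group sizes must be ≥ 1")
        known_g = {gid for gid, _ in self.groups} | {"*"}
        known_l = set(self.locations) | {"*"}
        for e in self.effects:
            if e.group not in known_g or e.location not in known_l:
                raise ValueError(f"effect {e} references unknown group/location")
            if e.gene_id not in set(ids):
                raise ValueError(f"effect {e} references unknown gene")

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.groups) * len(self.locations)


@dataclass
class SimulatedDataset:
    """A simulated Ct matrix, its annotations, and the design that generated it."""

    ct: CtMatrix
    annotations: list[SampleAnnotation]
    truth: SimulationDesign


#: Table of per-gene baseline Ct means and SDs (non-dependent lung tissue)
#: used by :func:`default_design`.
DEFAULT_GENE_PARAMS = [
    ("18S", 12.36, 1.139),
    ("GAPDH", 27.42, 1.170),
    ("ACTB", 26.12, 1.858),
    ("TOP1", 27.86, 1.366),
    ("RPS29", 37.19, 1.641),
]

#: RPS29 gravity-dependent baseline is 38.97 cycles: a +1.78-cycle shift.
RPS29_LOCATION_SHIFT = 1.78

GROUPS = ["NI", "V1", "V2", "V3", "V4", "V5"]
LOCATIONS = ["non-dependent", "gravity-dependent"]


def default_design(seed: int = 0) -> SimulationDesign:
    """The study-default design: five reference genes, 6 groups × 2 locations.

    Baselines and noise SDs follow the observed per-gene Ct means/SDs in
    non-dependent tissue; RPS29 gains +1.78 cycles in gravity-dependent
    tissue; n = 10 per group×location cell; shared per-sample loading
    effect SD 0.5 cycles.
    """
    return SimulationDesign(
        genes=[GeneSpec(g, b, s) for g, b, s in DEFAULT_GENE_PARAMS],
        groups=[(g, 10) for g in GROUPS],
        locations=list(LOCATIONS),
        sample_effect_sd=0.5,
        effects=[Effect("RPS29", "*", "gravity-dependent", RPS29_LOCATION_SHIFT)],
        seed=seed,
    )


def unstable_benchmark_design(shift: float = 3.0, noise_sd: float = 0.5) -> SimulationDesign:
    """The parameter-recovery benchmark: one designed-unstable gene.

    Keeps the default design's structure (six groups × two locations,
    n = 10 per cell, shared loading effect 0.5 cycles, RPS29 location
    shift) but homogenises candidate technical noise at ``noise_sd``
    cycles and adds a gene "UNSTB" carrying a ``shift``-cycle expression
    change in half the treatment groups (V3–V5). With the default
    3-cycle shift the injected gene's marginal Ct variance
    (0.5² + 3²/4 = 2.5) dominates every candidate's, so all four
    stability methods should rank it last.
    """
    base = default_design()
    genes = [GeneSpec(g.gene_id, g.baseline_ct, noise_sd) for g in base.genes]
    genes.append(GeneSpec("UNSTB", 25.0, noise_sd))
    return SimulationDesign(
        genes=genes,
        groups=base.groups,
        locations=base.locations,
        sample_effect_sd=base.sample_effect_sd,
        effects=base.effects
        + [Effect("UNSTB", g, "*", shift) for g in ("V3", "V4", "V5")],
        seed=base.seed,
    )


def _effect_total(design: SimulationDesign, gene: str, group: str, location: str) -> float:
    total = 0.0
    for e in design.effects:
        if (
            e.gene_id == gene
            and e.group in ("*", group)
            and e.location in ("*", location)
        ):
            total += e.shift
    return total


def simulate_ct(
    design: SimulationDesign, seed: int | None = None
) -> SimulatedDataset:
    """Draw one Ct dataset from the design's generative model (reproducible)."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    sample_ids: list[str] = []
    ann: list[SampleAnnotation] = []
    cells: list[tuple[str, str]] = []
    for location in design.locations:
        for group, n in design.groups:
            for i in range(n):
                sid = f"{group}_{location}_{i + 1:02d}"
                sample_ids.append(sid)
                ann.append(SampleAnnotation(sid, group, location))
                cells.append((group, location))

    n_samples = len(sample_ids)
    genes = [g.gene_id for g in design.genes]
    u = rng.normal(0.0, design.sample_effect_sd, size=n_samples)
    values = np.empty((n_samples, len(genes)))
    for j, gs in enumerate(design.genes):
        eps = rng.normal(0.0, gs.noise_sd, size=n_samples)
        shifts = np.array(
            [_effect_total(design, gs.gene_id, grp, loc) for grp, loc in cells]
        )
        values[:, j] = gs.baseline_ct + u + shifts + eps
    if design.censor_at is not None:
        values[values > design.censor_at] = np.nan
    ct = CtMatrix(values, sample_ids, genes)
    return SimulatedDataset(ct=ct, annotations=ann, truth=design)


def simulate_dilution_series(
    true_efficiency_pct: float,
    intercept_ct: float,
    dilution_log10_steps: Sequence[float],
    replicate_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 2,
) -> np.ndarray:
    """Simulate a standard-curve dilution series with known efficiency.

    Ct at log10 dilution x is ``intercept − x / log10(1 + E/100) + noise``
    (so the slope is ``−1/log10(amplification)``), with ``n_replicates``
    technical replicates per dilution point. Returns an array of rows
    (log10_dilution, ct).
    """
    if not 0 < true_efficiency_pct <= 150:
        raise ValueError("true_efficiency_pct must be in (0, 150]")
    steps = list(dilution_log10_steps)
    if len(steps) < 3:
        raise ValueError("need at least 3 dilution points for a standard curve")
    rng = np.random.default_rng(seed)
    slope = -1.0 / np.log10(1.0 + true_efficiency_pct / 100.0)
    rows = []
    for x in steps:
        for _ in range(n_replicates):
            ct = intercept_ct + slope * x + rng.normal(0.0, replicate_sd)
            rows.append((x, ct))
    return np.array(rows)


# ---------------------------------------------------------------------------
# Design (de)serialisation — plain-text YAML config


def save_design(design: SimulationDesign, path: str | Path) -> None:
    payload = {
        "genes": [asdict(g) for g in design.genes],
        "groups": [{"group_id": g, "n_per_location": n} for g, n in design.groups],
        "locations": list(design.locations),
        "sample_effect_sd": design.sample_effect_sd,
        "effects": [asdict(e) for e in design.effects],
        "seed": design.seed,
        "censor_at": design.censor_at,
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_design(path: str | Path) -> SimulationDesign:
    payload = yaml.safe_load(Path(path).read_text())
    return SimulationDesign(
        genes=[GeneSpec(**g) for g in payload["genes"]],
        groups=[(g["group_id"], int(g["n_per_location"])) for g in payload["groups"]],
        locations=list(payload["locations"]),
        sample_effect_sd=float(payload.get("sample_effect_sd", 0.5)),
        effects=[Effect(**e) for e in payload.get("effects", [])],
        seed=int(payload.get("seed", 0)),
        censor_at=payload.get("censor_at"),
    )
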