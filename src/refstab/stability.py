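"""The four reference-gene stability algorithms.

All four operate on a complete-case Ct matrix (no missing values; see
:func:`refstab.ct_data.complete_case`) and return a
:class:`StabilityResult` whose per-gene statistic is *lower = more
stable*, with dense ascending ranks (ties share a rank).

* comparative delta-Ct — a gene's statistic is the mean, over all other
  candidates, of the sample SD of their pairwise Ct differences.
* geNorm — average pairwise variation M of log2 expression ratios, with
  step-wise exclusion of the least stable gene until the best pair
  remains; the final pair shares rank 1.
* NormFinder — model-based decomposition of sample-centred Ct values
  into per-gene technical variance (and, in grouped mode, systematic
  between-group differences).
* BestKeeper — per-gene Ct dispersion plus Pearson correlation with the
  BestKeeper index (the per-sample geometric mean of all candidates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from refstab.ct_data import CtMatrix, SampleAnnotation

__all__ = [
    "StabilityResult",
    "pairwise_delta_ct_sd",
    "delta_ct_stability",
    "genorm",
    "normfinder",
    "bestkeeper",
    "dense_ranks",
]

_TIE_TOL = 1e-9


@dataclass
class StabilityResult:
    """One method's per-gene stability statistics and dense ranks."""

    method: str
    per_gene: dict[str, float]
    ranks: dict[str, int]
    aux: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.per_gene, key=lambda g: (self.ranks[g], g))
        return pd.DataFrame(
            {
                "gene": genes,
                "statistic": [self.per_gene[g] for g in genes],
                "rank": [self.ranks[g] for g in genes],
            }
        )


def dense_ranks(stats_by_gene: Mapping[str, float], tol: float = _TIE_TOL) -> dict[str, int]:
    """Ascending dense ranks; values within ``tol`` (relative) share a rank."""
    items = sorted(stats_by_gene.items(), key=lambda kv: (kv[1], kv[0]))
    ranks: dict[str, int] = {}
    rank = 0
    prev = None
    for gene, value in items:
        if prev is None or abs(value - prev) > tol * max(1.0, abs(prev)):
            rank += 1
        ranks[gene] = rank
        prev = value
    return ranks


def _require_complete(ct: CtMatrix, min_samples: int = 3, min_genes: int = 2) -> None:
    if np.isnan(ct.values).any():
        raise ValueError(
            "Ct matrix contains missing values; apply complete_case() first"
        )
    if ct.n_samples < min_samples:
        raise ValueError(f"need ≥ {min_samples} samples, got {ct.n_samples}")
    if ct.n_genes < min_genes:
        raise ValueError(f"need ≥ {min_genes} genes, got {ct.n_genes}")


# ---------------------------------------------------------------------------
# Comparative delta-Ct


def pairwise_delta_ct_sd(ct: CtMatrix) -> pd.DataFrame:
    """Symmetric gene × gene matrix of SD(Ct_j − Ct_k) over samples (n−1)."""
    _require_complete(ct)
    v = ct.values
    k = ct.n_genes
    out = np.zeros((k, k))
    for j in range(k):
        diffs = v[:, [j]] - v  # n_samples × k matrix of Ct_j − Ct_k
        out[j, :] = diffs.std(axis=0, ddof=1)
    np.fill_diagonal(out, 0.0)
    return pd.DataFrame(out, index=ct.gene_ids, columns=ct.gene_ids)


def delta_ct_stability(ct: CtMatrix) -> StabilityResult:
    """Comparative delta-Ct method: mean pairwise-difference SD per gene."""
    sd = pairwise_delta_ct_sd(ct)
    k = ct.n_genes
    stat = {
        g: float((sd.loc[g].sum()) / (k - 1))  # diagonal is 0
        for g in ct.gene_ids
    }
    return StabilityResult(
        method="delta_ct",
        per_gene=stat,
        ranks=dense_ranks(stat),
        aux={"pairwise_sd": sd},
    )


# ---------------------------------------------------------------------------
# geNorm


def _log2_quantities(ct: CtMatrix, amplification: Mapping[str, float]) -> np.ndarray:
    """log2 relative quantities: q_sj = A_j^(min_s Ct_sj − Ct_sj)."""
    v = ct.values
    log2a = np.array([np.log2(amplification[g]) for g in ct.gene_ids])
    return (v.min(axis=0, keepdims=True) - v) * log2a


def _genorm_m(log2q: np.ndarray) -> np.ndarray:
    """M_j = mean over k≠j of SD over samples of log2(q_j/q_k)."""
    k = log2q.shape[1]
    vmat = np.zeros((k, k))
    for j in range(k):
        vmat[j, :] = (log2q[:, [j]] - log2q).std(axis=0, ddof=1)
    return vmat.sum(axis=1) / (k - 1)


def genorm(
    ct: CtMatrix,
    efficiencies: Mapping[str, float] | None = None,
) -> StabilityResult:
    """geNorm M values with step-wise exclusion of the least stable gene.

    ``efficiencies`` maps gene id → amplification factor (fold per
    cycle); by default every gene is assumed to double per cycle
    (amplification 2.0), under which Ct differences are log2 expression
    ratios directly.

    The reported statistic for each gene is its M value at the step of
    its elimination; the final pair shares the final-step M and rank 1.
    Remaining ranks follow reverse elimination order (dense, equal M
    values share a rank).
    """
    _require_complete(ct)
    amp = dict.fromkeys(ct.gene_ids, 2.0)
    if efficiencies:
        unknown = set(efficiencies) - set(ct.gene_ids)
        if unknown:
            raise ValueError(f"efficiencies given for unknown genes: {sorted(unknown)}")
        amp.update(efficiencies)
    if any(a <= 1.0 for a in amp.values()):
        raise ValueError("amplification factors must be > 1")

    log2q = _log2_quantities(ct, amp)
    genes = list(ct.gene_ids)

    if ct.n_genes < 3:
        warnings.warn(
            "geNorm needs ≥ 3 genes for step-wise exclusion; "
            "reporting the single pairwise variation",
            stacklevel=2,
        )
        m = _genorm_m(log2q)
        stat = {g: float(m[i]) for i, g in enumerate(genes)}
        return StabilityResult(
            method="genorm",
            per_gene=stat,
            ranks=dict.fromkeys(genes, 1),
            aux={"elimination_order": [], "steps": []},
        )

    remaining = list(genes)
    cols = {g: i for i, g in enumerate(genes)}
    eliminated: list[str] = []
    stat: dict[str, float] = {}
    steps: list[dict[str, float]] = []
    while len(remaining) > 2:
        sub = log2q[:, [cols[g] for g in remaining]]
        m = _genorm_m(sub)
        step_m = {g: float(m[i]) for i, g in enumerate(remaining)}
        steps.append(step_m)
        # highest M leaves; ties broken to the lexicographically last gene
        worst = max(remaining, key=lambda g: (step_m[g], g))
        stat[worst] = step_m[worst]
        eliminated.append(worst)
        remaining.remove(worst)

    # final pair: both genes share the pair's variation as their M
    sub = log2q[:, [cols[g] for g in remaining]]
    final_m = float(_genorm_m(sub)[0])
    steps.append(dict.fromkeys(remaining, final_m))
    for g in remaining:
        stat[g] = final_m

    # ranks: final pair first, then reverse elimination order; equal
    # statistics merge into a shared dense rank
    ordering = sorted(remaining) + list(reversed(eliminated))
    ranks: dict[str, int] = {}
    rank = 0
    prev = None
    for g in ordering:
        if prev is None or abs(stat[g] - prev) > _TIE_TOL * max(1.0, abs(prev)):
            rank += 1
        ranks[g] = rank
        prev = stat[g]

    aux = {
        "elimination_order": eliminated,
        "final_pair": sorted(remaining),
        "steps": steps,
        "pairwise_variation": _normalization_factor_variation(log2q, genes, ranks),
    }
    return StabilityResult(method="genorm", per_gene=stat, ranks=ranks, aux=aux)


def _normalization_factor_variation(
    log2q: np.ndarray, genes: list[str], ranks: Mapping[str, int]
) -> dict[str, float]:
    """geNorm V_{n/n+1}: SD of log2 ratio of normalization factors built
    from the n and n+1 most stable genes (reported only, no cutoff rule)."""
    order = sorted(genes, key=lambda g: (ranks[g], g))
    cols = {g: i for i, g in enumerate(genes)}
    out: dict[str, float] = {}
    for n in range(2, len(order)):
        nf_n = log2q[:, [cols[g] for g in order[:n]]].mean(axis=1)
        nf_n1 = log2q[:, [cols[g] for g in order[: n + 1]]].mean(axis=1)
        out[f"V{n}/{n + 1}"] = float((nf_n - nf_n1).std(ddof=1))
    return out


# ---------------------------------------------------------------------------
# NormFinder


def _normfinder_sigma2(d: np.ndarray) -> np.ndarray:
    """Per-gene technical variance from sample-centred values.

    With n genes, centring makes Var(d_j) = sigma²_j·(n−2)/n + Σsigma²/n²;
    summing over genes gives Σsigma² = n/(n−1)·Σv, which closes the system:

        sigma²_j = n/(n−2) · [v_j − Σv / (n(n−1))]

    Negative estimates (possible at small sample counts) truncate to 0.
    """
    n = d.shape[1]
    v = d.var(axis=0, ddof=1)
    sigma2 = (n / (n - 2)) * (v - v.sum() / (n * (n - 1)))
    return np.maximum(sigma2, 0.0)


def normfinder(
    ct: CtMatrix,
    annotations: Sequence[SampleAnnotation] | None = None,
    mode: str = "ungrouped",
) -> StabilityResult:
    """NormFinder stability values on Ct (log-scale) data.

    Ungrouped (default): each sample is centred across genes and the
    per-gene technical variance is estimated from the centred values;
    the statistic is its square root. Grouped: the same decomposition is
    applied within each group and combined with the systematic
    between-group expression differences,

        stability_j = mean over groups of (|gamma_jg| + sqrt(sigma²_jg / m_g))

    where gamma_jg is the group's deviation of the gene's centred mean.
    """
    _require_complete(ct, min_genes=3)
    if mode not in ("ungrouped", "grouped"):
        raise ValueError(f"mode must be 'ungrouped' or 'grouped', got {mode!r}")
    y = ct.values
    d = y - y.mean(axis=1, keepdims=True)  # centre each sample across genes

    if mode == "ungrouped":
        sigma2 = _normfinder_sigma2(d)
        stat = {g: float(np.sqrt(sigma2[j])) for j, g in enumerate(ct.gene_ids)}
        aux = {"sigma2": dict(zip(ct.gene_ids, sigma2.tolist()))}
        return StabilityResult("normfinder", stat, dense_ranks(stat), aux)

    if annotations is None:
        raise ValueError("grouped mode requires annotations")
    by_sample = {a.sample_id: a.group for a in annotations}
    absent = [s for s in ct.sample_ids if s not in by_sample]
    if absent:
        raise ValueError(f"no annotation for sample(s): {absent}")
    labels = np.array([by_sample[s] for s in ct.sample_ids])
    groups = list(dict.fromkeys(labels))
    if len(groups) < 2:
        raise ValueError("grouped mode requires ≥ 2 groups")
    sizes = {g: int((labels == g).sum()) for g in groups}
    small = [g for g, m in sizes.items() if m < 3]
    if small:
        raise ValueError(f"grouped mode requires ≥ 3 samples per group; too small: {small}")

    k = ct.n_genes
    sigma2_g = np.empty((len(groups), k))
    dbar_g = np.empty((len(groups), k))
    for gi, grp in enumerate(groups):
        block = d[labels == grp, :]
        sigma2_g[gi] = _normfinder_sigma2(block)
        dbar_g[gi] = block.mean(axis=0)
    gamma = dbar_g - dbar_g.mean(axis=0, keepdims=True)
    m = np.array([sizes[g] for g in groups], dtype=float)[:, None]
    per_group = np.abs(gamma) + np.sqrt(sigma2_g / m)
    combined = per_group.mean(axis=0)
    stat = {g: float(combined[j]) for j, g in enumerate(ct.gene_ids)}
    aux = {
        "groups": groups,
        "intra_sigma2": pd.DataFrame(sigma2_g, index=groups, columns=ct.gene_ids),
        "inter_gamma": pd.DataFrame(gamma, index=groups, columns=ct.gene_ids),
    }
    return StabilityResult("normfinder", stat, dense_ranks(stat), aux)


# ---------------------------------------------------------------------------
# BestKeeper


def bestkeeper(ct: CtMatrix, sd_variant: str = "sample_sd") -> StabilityResult:
    """BestKeeper: Ct dispersion per gene plus correlation with the index.

    The BestKeeper index is the per-sample geometric mean of all
    candidate Ct values. The ranking statistic is the gene's Ct
    dispersion — the sample SD (n−1) by default, or the mean absolute
    deviation from the arithmetic mean with ``sd_variant="mean_abs_dev"``
    (the original BestKeeper convention). Genes with dispersion ≥ 1
    cycle are flagged unstable in ``aux``.
    """
    _require_complete(ct)
    if sd_variant not in ("sample_sd", "mean_abs_dev"):
        raise ValueError(f"unknown sd_variant {sd_variant!r}")
    v = ct.values
    if np.any(v <= 0):
        raise ValueError("BestKeeper requires strictly positive Ct values")

    index = np.exp(np.log(v).mean(axis=1))  # per-sample geometric mean
    rows = []
    stat: dict[str, float] = {}
    for j, g in enumerate(ct.gene_ids):
        col = v[:, j]
        am = float(col.mean())
        gm = float(np.exp(np.log(col).mean()))
        sd = float(col.std(ddof=1))
        mad = float(np.abs(col - am).mean())
        disp = sd if sd_variant == "sample_sd" else mad
        if np.allclose(col, col[0]):
            r, p = (1.0, 0.0) if np.ptp(index) == 0 else (np.nan, np.nan)
        else:
            r, p = sps.pearsonr(col, index)
        stat[g] = disp
        rows.append(
            {
                "gene": g,
                "geo_mean": gm,
                "ar_mean": am,
                "min": float(col.min()),
                "max": float(col.max()),
                "sd": sd,
                "mean_abs_dev": mad,
                "cv_pct": 100.0 * disp / am,
                "r_vs_index": float(r) if np.isfinite(r) else np.nan,
                "p_vs_index": float(p) if np.isfinite(p) else np.nan,
            }
        )
    aux = {
        "index": pd.Series(index, index=ct.sample_ids, name="bestkeeper_index"),
        "descriptives": pd.DataFrame(rows).set_index("gene"),
        "unstable": [g for g, s in stat.items() if s >= 1.0],
        "sd_variant": sd_variant,
    }
    return StabilityResult("bestkeeper", stat, dense_ranks(stat), aux)
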