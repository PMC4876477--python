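"""Relative expression by the 2^-ddCt (Livak) method with group statistics.

For a gene of interest (GOI) normalised to one or more reference genes:

    dCt_s  = Ct_goi,s − Ct_ref,s        (multiple refs: arithmetic mean Ct,
                                         i.e. geometric-mean normalisation
                                         on the quantity scale)
    ddCt_s = dCt_s − mean(dCt over control-group samples)
    fold_s = 2^(−ddCt_s)

Group summaries are mean ± SEM of per-sample fold changes; comparisons
are a one-way ANOVA across groups plus each-group-vs-control tests with
Holm adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from refstab.ct_data import CtMatrix, SampleAnnotation

__all__ = ["ExpressionResult", "delta_delta_ct", "group_anova", "location_compare"]


@dataclass
class ExpressionResult:
    """Per-sample and per-group 2^-ddCt results for one GOI/reference pairing."""

    goi: str
    refs: list[str]
    control_group: str
    per_sample: pd.DataFrame  # sample, group, delta_ct, ddct, fold
    per_group: pd.DataFrame  # group, n, mean_fold, sem_fold
    comparisons: pd.DataFrame = field(default_factory=pd.DataFrame)
    degenerate: bool = False  # goi carries no variation relative to refs


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def delta_delta_ct(
    ct: CtMatrix,
    goi: str,
    refs: str | Sequence[str],
    control_group: str,
    annotations: Sequence[SampleAnnotation],
    efficiencies: dict[str, float] | None = None,
) -> ExpressionResult:
    """Relative expression of ``goi`` vs ``refs``, calibrated to ``control_group``.

    Samples with a missing Ct in the GOI or any reference are dropped.
    With ``efficiencies`` (gene → amplification factor), the
    efficiency-corrected fold ``A_goi^(−dCt_goi) / A_ref^(−dCt_ref)``
    generalisation is used; the default is the classical 2^-ddCt.
    """
    refs = [refs] if isinstance(refs, str) else list(refs)
    if goi in refs:
        raise ValueError("gene of interest cannot be one of its reference genes")
    for g in [goi, *refs]:
        if g not in ct.gene_ids:
            raise ValueError(f"gene {g!r} not in Ct matrix")
    group_of = {a.sample_id: a.group for a in annotations}
    absent = [s for s in ct.sample_ids if s not in group_of]
    if absent:
        raise ValueError(f"no annotation for sample(s): {absent}")

    goi_ct = ct.gene(goi)
    ref_ct = np.column_stack([ct.gene(r) for r in refs]).mean(axis=1)
    keep = ~np.isnan(goi_ct) & ~np.isnan(ref_ct)
    samples = [s for s, k in zip(ct.sample_ids, keep) if k]
    if not samples:
        raise ValueError("no sample has complete GOI and reference Ct values")
    dct = goi_ct[keep] - ref_ct[keep]
    groups = np.array([group_of[s] for s in samples])
    in_control = groups == control_group
    if not in_control.any():
        raise ValueError(f"control group {control_group!r} empty after filtering")
    ddct = dct - dct[in_control].mean()
    fold = np.power(2.0, -ddct)

    degenerate = bool(np.ptp(dct) < 1e-12)
    if degenerate:
        warnings.warn(
            "gene of interest carries no variation relative to the references; "
            "all fold changes are 1 and group tests are meaningless",
            stacklevel=2,
        )

    per_sample = pd.DataFrame(
        {"sample": samples, "group": groups, "delta_ct": dct, "ddct": ddct, "fold": fold}
    )
    rows = []
    for grp in dict.fromkeys(groups):
        f = fold[groups == grp]
        rows.append(
            {
                "group": grp,
                "n": len(f),
                "mean_fold": float(f.mean()),
                "sem_fold": float(f.std(ddof=1) / np.sqrt(len(f))) if len(f) > 1 else np.nan,
            }
        )
    result = ExpressionResult(
        goi=goi,
        refs=refs,
        control_group=control_group,
        per_sample=per_sample,
        per_group=pd.DataFrame(rows),
        degenerate=degenerate,
    )
    if efficiencies:
        # efficiency-corrected fold (Pfaffl-style): per-gene amplification
        # factors replace the assumed doubling
        a_goi = efficiencies.get(goi, 2.0)
        a_ref = {r: efficiencies.get(r, 2.0) for r in refs}
        goi_rel = np.power(a_goi, -(goi_ct[keep] - goi_ct[keep][in_control].mean()))
        ref_rel = np.ones_like(goi_rel)
        for r in refs:
            col = ct.gene(r)[keep]
            ref_rel = ref_rel * np.power(a_ref[r], -(col - col[in_control].mean()))
        ref_rel = np.power(ref_rel, 1.0 / len(refs))
        result.per_sample["fold_eff_corrected"] = goi_rel / ref_rel
    return result


def group_anova(
    result: ExpressionResult,
    scale: str = "fold",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA across groups plus each-group-vs-control Holm-adjusted tests.

    ``scale="fold"`` (default) tests the per-sample fold changes as
    reported; ``scale="log"`` tests ddCt values, on which the Gaussian
    ANOVA assumptions hold exactly under Gaussian Ct noise. Groups with
    fewer than two samples are excluded with a warning. The returned
    frame has the omnibus ANOVA row first, then one row per non-control
    group with Welch t p-values, Holm-adjusted p, and significance stars
    (α tiers 0.05 / 0.01 / 0.001).
    """
    if scale not in ("fold", "log"):
        raise ValueError("scale must be 'fold' or 'log'")
    col = "fold" if scale == "fold" else "ddct"
    df = result.per_sample
    sizes = df.groupby("group", sort=False).size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"groups excluded with n < 2: {small}", stacklevel=2)
        df = df[~df["group"].isin(small)]
    groups = list(dict.fromkeys(df["group"]))
    if len(groups) < 2:
        raise ValueError("ANOVA needs ≥ 2 groups with n ≥ 2")
    if result.degenerate:
        return pd.DataFrame(
            [{"comparison": "anova", "statistic": np.nan, "p_value": np.nan,
              "adjusted_p": np.nan, "stars": "", "note": "degenerate: no variation"}]
        )

    arrays = [df.loc[df["group"] == g, col].to_numpy() for g in groups]
    f_stat, f_p = sps.f_oneway(*arrays)
    rows = [
        {
            "comparison": "anova",
            "statistic": float(f_stat),
            "p_value": float(f_p),
            "adjusted_p": np.nan,
            "stars": _stars(float(f_p)),
        }
    ]
    control = result.control_group
    others = [g for g in groups if g != control]
    if control in groups and others:
        ctrl = df.loc[df["group"] == control, col].to_numpy()
        raw = []
        for g in others:
            t, p = sps.ttest_ind(
                df.loc[df["group"] == g, col].to_numpy(), ctrl, equal_var=False
            )
            raw.append((g, float(t), float(p)))
        adj = multipletests([p for _, _, p in raw], alpha=alpha, method="holm")[1]
        for (g, t, p), ap in zip(raw, adj):
            rows.append(
                {
                    "comparison": f"{g} vs {control}",
                    "statistic": t,
                    "p_value": p,
                    "adjusted_p": float(ap),
                    "stars": _stars(float(ap)),
                }
            )
    out = pd.DataFrame(rows)
    result.comparisons = out
    return out


def location_compare(
    ct: CtMatrix,
    annotations: Sequence[SampleAnnotation],
    gene: str,
    locations: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Within each treatment group, compare a gene's Ct between the two
    tissue locations (two-sided Welch t-test) with box-plot summaries.

    Returns one row per treatment group with n, quartiles, min/max per
    location arm and the Welch p-value. Groups where either arm has
    fewer than two usable samples are skipped with a warning.
    """
    if gene not in ct.gene_ids:
        raise ValueError(f"gene {gene!r} not in Ct matrix")
    ann = {a.sample_id: a for a in annotations}
    absent = [s for s in ct.sample_ids if s not in ann]
    if absent:
        raise ValueError(f"no annotation for sample(s): {absent}")
    col = ct.gene(gene)
    df = pd.DataFrame(
        {
            "ct": col,
            "group": [ann[s].group for s in ct.sample_ids],
            "location": [ann[s].location for s in ct.sample_ids],
        }
    ).dropna(subset=["ct"])
    if locations is None:
        locs = list(dict.fromkeys(df["location"]))
        if len(locs) != 2:
            raise ValueError(f"expected exactly 2 locations, found {locs}")
        locations = (locs[0], locs[1])

    rows = []
    for grp in dict.fromkeys(df["group"]):
        arms = {
            loc: df.loc[(df["group"] == grp) & (df["location"] == loc), "ct"].to_numpy()
            for loc in locations
        }
        if any(len(v) < 2 for v in arms.values()):
            warnings.warn(f"group {grp!r} skipped: a location arm has n < 2", stacklevel=2)
            continue
        a, b = arms[locations[0]], arms[locations[1]]
        if np.ptp(np.concatenate([a, b])) < 1e-12:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(a, b, equal_var=False)
        row = {"group": grp, "gene": gene, "t_statistic": float(t), "p_value": float(p),
               "stars": _stars(float(p))}
        for loc, v in arms.items():
            q1, q2, q3 = np.percentile(v, [25, 50, 75])
            row.update(
                {
                    f"n ({loc})": len(v),
                    f"median ({loc})": float(q2),
                    f"q1 ({loc})": float(q1),
                    f"q3 ({loc})": float(q3),
                    f"min ({loc})": float(v.min()),
                    f"max ({loc})": float(v.max()),
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
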