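"""qPCR relative expression.

Amplification efficiency per gene comes from a pooled-cDNA standard
dilution curve (E = 10^(−1/slope) of Ct vs log10 input).  Relative
quantities use the efficiency-corrected Ct method against each gene's
minimum observed Ct, normalized to the mean relative quantity of three
reference genes.  Stage differences are assessed by one-way ANOVA with
Tukey HSD letters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .protein_stats import _anova_fit, tukey_letters

DEFAULT_REFERENCE_GENES = ("ACT", "EF1", "GAPDH")
EFFICIENCY_BAND = (1.0, 2.2)


@dataclass
class StandardCurve:
    gene: str
    dilutions: list[float]
    cts: list[float]
    slope: float  # cycles per log10(quantity)
    intercept: float
    efficiency: float  # fold amplification per cycle
    r_squared: float


def fit_standard_curve(dilutions, cts, gene: str = "") -> StandardCurve:
    """Least-squares of Ct on log10(relative input); E = 10^(−1/slope)."""
    dilutions = np.asarray(dilutions, dtype=float)
    cts = np.asarray(cts, dtype=float)
    if dilutions.size < 3:
        raise ValueError("need at least 3 dilution points")
    if np.any(dilutions <= 0):
        raise ValueError("dilutions must be positive")
    fit = stats.linregress(np.log10(dilutions), cts)
    if fit.slope >= 0:
        raise ValueError(
            f"invalid standard curve for {gene!r}: non-negative slope "
            f"({fit.slope:.3f}); Ct must fall with input"
        )
    efficiency = 10.0 ** (-1.0 / fit.slope)
    if not EFFICIENCY_BAND[0] < efficiency <= EFFICIENCY_BAND[1]:
        warnings.warn(
            f"efficiency {efficiency:.3f} for {gene!r} outside plausibility "
            f"band {EFFICIENCY_BAND}"
        )
    return StandardCurve(
        gene=gene, dilutions=dilutions.tolist(), cts=cts.tolist(),
        slope=float(fit.slope), intercept=float(fit.intercept),
        efficiency=float(efficiency), r_squared=float(fit.rvalue**2),
    )


def relative_quantity(ct: float, ct_min: float, efficiency: float) -> float:
    """Efficiency-corrected relative quantity: E^(Ct_min − Ct)."""
    if not EFFICIENCY_BAND[0] < efficiency <= EFFICIENCY_BAND[1]:
        raise ValueError(f"efficiency {efficiency} outside {EFFICIENCY_BAND}")
    if not np.isfinite(ct):
        raise ValueError("Ct must be finite")
    return float(efficiency ** (ct_min - ct))


def relative_expression(
    ct_target: float,
    e_target: float,
    ct_refs: list[float],
    e_refs: list[float],
    ct_target_min: float | None = None,
    ct_ref_mins: list[float] | None = None,
    ref_mean: str = "arithmetic",
) -> float:
    """Normalized expression of one sample.

    Q_g = E_g^(Ct_min,g − Ct_g) per gene; the target quantity is divided
    by the (arithmetic by default, optionally geometric) mean of the
    three reference-gene quantities.
    """
    if len(ct_refs) != len(e_refs):
        raise ValueError("reference Cts and efficiencies must align")
    if ct_target_min is None:
        ct_target_min = ct_target
    if ct_ref_mins is None:
        ct_ref_mins = list(ct_refs)
    q_target = relative_quantity(ct_target, ct_target_min, e_target)
    q_refs = [relative_quantity(ct, ct_min, e)
              for ct, ct_min, e in zip(ct_refs, ct_ref_mins, e_refs)]
    if ref_mean == "arithmetic":
        denom = float(np.mean(q_refs))
    elif ref_mean == "geometric":
        denom = float(stats.gmean(q_refs))
    else:
        raise ValueError("ref_mean must be 'arithmetic' or 'geometric'")
    return q_target / denom


def fit_all_standard_curves(ct_table: pd.DataFrame) -> dict[str, StandardCurve]:
    """Fit one standard curve per gene from the ``is_standard`` rows."""
    curves = {}
    standards = ct_table[ct_table["is_standard"].astype(bool)]
    for gene, grp in standards.groupby("gene", sort=False):
        means = grp.groupby("dilution")["ct"].mean()
        curves[gene] = fit_standard_curve(means.index.to_numpy(),
                                          means.to_numpy(), gene=gene)
    return curves


def expression_table(
    ct_table: pd.DataFrame,
    target_genes: list[str],
    reference_genes: tuple[str, ...] = DEFAULT_REFERENCE_GENES,
    ref_mean: str = "arithmetic",
    efficiencies: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-sample normalized expression for every target gene.

    Ct table columns: run, gene, sample, stage, ct, is_standard,
    dilution.  Efficiencies default to per-gene standard curves fitted
    from the same table.  Samples missing any reference Ct are dropped
    with a warning.
    """
    samples = ct_table[~ct_table["is_standard"].astype(bool)]
    if efficiencies is None:
        curves = fit_all_standard_curves(ct_table)
        efficiencies = {g: c.efficiency for g, c in curves.items()}
    ct_wide = samples.pivot_table(index=["sample", "stage"], columns="gene",
                                  values="ct")
    ct_mins = ct_wide.min(axis=0)
    records = []
    for (sample, stage), row in ct_wide.iterrows():
        ref_cts = [row.get(g, np.nan) for g in reference_genes]
        if any(not np.isfinite(ct) for ct in ref_cts):
            warnings.warn(f"dropping sample {sample}: missing reference Ct")
            continue
        for gene in target_genes:
            ct = row.get(gene, np.nan)
            if not np.isfinite(ct):
                continue
            expr = relative_expression(
                ct, efficiencies[gene],
                ref_cts, [efficiencies[g] for g in reference_genes],
                ct_target_min=float(ct_mins[gene]),
                ct_ref_mins=[float(ct_mins[g]) for g in reference_genes],
                ref_mean=ref_mean,
            )
            records.append(dict(gene=gene, sample=sample, stage=stage,
                                expression=expr))
    return pd.DataFrame.from_records(records)


def stage_anova(
    expression: pd.DataFrame,
    value_col: str = "expression",
    stage_col: str = "stage",
    stage_order: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA across stages with Tukey HSD compact letters.

    Returns one row per stage: mean, se, n, letter, plus the ANOVA
    p-value (identical across rows).
    """
    stages = stage_order or list(dict.fromkeys(expression[stage_col]))
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    groups = [expression.loc[expression[stage_col] == s, value_col].dropna()
              for s in stages]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least 2 replicates per stage")
    means, cov, resid_df, ns = _anova_fit(
        expression.dropna(subset=[value_col]), stages, value_col, stage_col
    )
    with np.errstate(invalid="ignore"):
        _, p_value = stats.f_oneway(*[g.to_numpy() for g in groups])
    if not np.isfinite(p_value):  # zero within-group variance
        p_value = 0.0 if len(set(np.round(means, 12))) > 1 else 1.0
    letters = tukey_letters(means, cov, resid_df, alpha=alpha)
    return pd.DataFrame([
        dict(stage=s, mean=float(m),
             se=float(g.std(ddof=1) / np.sqrt(len(g))), n=len(g),
             letter=letter, p_anova=float(p_value))
        for s, m, g, letter in zip(stages, means, groups, letters)
    ])


def expression_profiles(
    ct_table: pd.DataFrame,
    target_genes: list[str],
    reference_genes: tuple[str, ...] = DEFAULT_REFERENCE_GENES,
    stage_order: list[str] | None = None,
    ref_mean: str = "arithmetic",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene stage profiles (mean, se, n, letter) from a Ct table."""
    expr = expression_table(ct_table, target_genes, reference_genes,
                            ref_mean=ref_mean)
    frames = []
    for gene, grp in expr.groupby("gene", sort=False):
        stats_frame = stage_anova(grp, stage_order=stage_order, alpha=alpha)
        stats_frame.insert(0, "gene", gene)
        frames.append(stats_frame)
    return pd.concat(frames, ignore_index=True)
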