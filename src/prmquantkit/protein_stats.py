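"""Peptide-to-protein roll-up.

Proteins observed through several peptides are summarized with a linear
mixed model: ripening stage is a fixed categorical factor, peptide a
random factor, and sample a random factor capturing that the peptides
are repeated measures on the same fruit.  Single-peptide proteins reduce
to a classical one-way ANOVA.  Stage comparisons use Tukey's HSD with a
compact letter display.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM


@dataclass
class StageEstimate:
    stage: str
    estimate: float
    se: float | None
    n: int
    letter: str = ""


@dataclass
class ProteinAbundanceProfile:
    protein: str
    stages: list[StageEstimate]
    model_used: str  # 'mixed' | 'anova' | 'anova-fallback'
    notes: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dict(protein=self.protein, stage=s.stage, estimate=s.estimate,
                  se=s.se, n=s.n, letter=s.letter, model_used=self.model_used)
             for s in self.stages]
        )


# ---------------------------------------------------------------------------
# Compact letter display
# ---------------------------------------------------------------------------


def _compact_letters(k: int, significant: set[tuple[int, int]],
                     order: np.ndarray) -> list[str]:
    """Insert-and-absorb compact letter display.

    ``significant`` holds index pairs that differ; groups sharing a
    letter are exactly those never declared different.  ``order`` gives
    the display order (descending estimate) so letters read contiguously.
    """
    classes: list[set[int]] = [set(range(k))]
    for i, j in significant:
        new_classes: list[set[int]] = []
        for cls in classes:
            if i in cls and j in cls:
                new_classes.append(cls - {i})
                new_classes.append(cls - {j})
            else:
                new_classes.append(cls)
        # absorb subsets
        classes = []
        for cls in sorted(new_classes, key=len, reverse=True):
            if cls and not any(cls <= kept for kept in classes):
                classes.append(cls)
    # sort classes by the best-ranked member so the alphabet is contiguous
    rank = {g: r for r, g in enumerate(order)}
    classes.sort(key=lambda cls: min(rank[g] for g in cls))
    letters = [""] * k
    for letter, cls in zip(string.ascii_lowercase, classes):
        for g in cls:
            letters[g] += letter
    return ["".join(sorted(s)) for s in letters]


def tukey_letters(
    estimates: np.ndarray,
    covariance: np.ndarray,
    df: float,
    alpha: float = 0.05,
) -> list[str]:
    """All-pairs Tukey HSD letters from estimates and their covariance.

    A pair differs when |Δ|/SE(Δ) exceeds q(1−α; k, df)/√2.  Zero
    SE(Δ) with unequal estimates counts as significant (exact
    separation); with equal estimates it does not.
    """
    estimates = np.asarray(estimates, dtype=float)
    covariance = np.atleast_2d(np.asarray(covariance, dtype=float))
    k = estimates.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    if df <= 0 or not np.isfinite(df):
        raise ValueError("positive finite degrees of freedom required")
    q_crit = stats.studentized_range.ppf(1 - alpha, k, df)
    significant: set[tuple[int, int]] = set()
    for i in range(k):
        for j in range(i + 1, k):
            var_diff = covariance[i, i] + covariance[j, j] - 2 * covariance[i, j]
            diff = abs(estimates[i] - estimates[j])
            if var_diff <= 0:
                if diff > 1e-12:
                    significant.add((i, j))
                continue
            if diff / np.sqrt(var_diff) > q_crit / np.sqrt(2):
                significant.add((i, j))
    order = np.argsort(-estimates, kind="stable")
    return _compact_letters(k, significant, order)


# ---------------------------------------------------------------------------
# Summaries and models
# ---------------------------------------------------------------------------


def summarize_profile(
    quantities: pd.DataFrame,
    value_col: str = "fmol_per_ug",
    stage_col: str = "stage",
    stage_order: list[str] | None = None,
) -> pd.DataFrame:
    """Per-stage mean ± SE over biological replicates.

    SE = sd/√n; with a single replicate the SE is reported missing.
    """
    if stage_col not in quantities or value_col not in quantities:
        raise KeyError("missing stage or value column")
    rows = []
    stages = stage_order or list(dict.fromkeys(quantities[stage_col]))
    for stage in stages:
        vals = quantities.loc[quantities[stage_col] == stage, value_col].dropna()
        n = len(vals)
        se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append(dict(stage=stage, mean=float(vals.mean()) if n else np.nan,
                         se=se, n=n))
    return pd.DataFrame(rows)


def _anova_fit(df: pd.DataFrame, stages: list[str], value_col: str,
               stage_col: str) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """One-way ANOVA: stage means, covariance from pooled MSE, residual df."""
    groups = [df.loc[df[stage_col] == s, value_col].to_numpy() for s in stages]
    ns = np.array([g.size for g in groups])
    if np.any(ns == 0):
        raise ValueError("every stage needs at least one observation")
    means = np.array([g.mean() for g in groups])
    resid_df = int(ns.sum() - len(stages))
    if resid_df <= 0:
        raise ValueError("no residual degrees of freedom")
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    mse = sse / resid_df
    cov = np.diag(mse / ns)
    return means, cov, resid_df, ns


def _mixed_fit(df: pd.DataFrame, stages: list[str], value_col: str,
               stage_col: str):
    """Crossed random intercepts for peptide and sample via variance
    components; returns marginal stage means and their covariance."""
    data = df.copy()
    data["_one"] = 1
    data[stage_col] = pd.Categorical(data[stage_col], categories=stages)
    formula = f"{value_col} ~ C({stage_col})"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            formula, data=data, groups="_one", re_formula="0",
            vc_formula={"peptide": "0 + C(peptide)", "sample": "0 + C(sample)"},
        )
        result = model.fit(reml=True, method="lbfgs", maxiter=200)
    beta = np.asarray(result.fe_params)
    cov_beta = np.asarray(result.cov_params())[: beta.size, : beta.size]
    k = len(stages)
    contrast = np.zeros((k, beta.size))
    contrast[:, 0] = 1.0
    for i in range(1, k):
        contrast[i, i] = 1.0  # treatment coding against stages[0]
    estimates = contrast @ beta
    cov = contrast @ cov_beta @ contrast.T
    return estimates, cov, result


def fit_protein_model(
    quantities: pd.DataFrame,
    protein: str = "",
    value_col: str = "fmol_per_ug",
    stage_col: str = "stage",
    stage_order: list[str] | None = None,
    alpha: float = 0.05,
) -> ProteinAbundanceProfile:
    """Fit the stage model for one protein's peptide-level quantities.

    Expects columns ``stage``, ``peptide``, ``sample`` and the value
    column; rows with missing values (quantification failures) are
    dropped per (sample, peptide).  Routes to one-way ANOVA for a single
    peptide, otherwise to the mixed model; non-convergence falls back to
    ANOVA on per-sample peptide means.
    """
    df = quantities.dropna(subset=[value_col]).copy()
    if df.empty:
        raise ValueError(f"no quantifiable observations for {protein!r}")
    stages = stage_order or list(dict.fromkeys(df[stage_col]))
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    n_peptides = df["peptide"].nunique() if "peptide" in df else 1
    notes: list[str] = []

    if n_peptides == 1:
        means, cov, resid_df, ns = _anova_fit(df, stages, value_col, stage_col)
        model_used = "anova"
    else:
        try:
            means, cov, result = _mixed_fit(df, stages, value_col, stage_col)
            # a False converged flag with finite estimates usually means a
            # variance component sits at its zero boundary; keep the fit
            if not (np.all(np.isfinite(means)) and np.all(np.isfinite(cov))):
                raise RuntimeError("mixed model produced non-finite estimates")
            if not bool(getattr(result, "converged", True)):
                notes.append("variance component at boundary (flagged by optimizer)")
            ns = np.array([
                df.loc[df[stage_col] == s, "sample"].nunique() for s in stages
            ])
            # residual df: conservative observation-based approximation
            resid_df = len(df) - len(stages) - (n_peptides - 1)
            model_used = "mixed"
        except Exception as exc:  # noqa: BLE001 - any optimizer failure
            notes.append(f"mixed model failed ({exc}); ANOVA on peptide means")
            collapsed = (
                df.groupby(["sample", stage_col], sort=False)[value_col]
                .mean().reset_index()
            )
            means, cov, resid_df, ns = _anova_fit(collapsed, stages,
                                                  value_col, stage_col)
            model_used = "anova-fallback"

    letters = tukey_letters(means, cov, resid_df, alpha=alpha)
    ses = np.sqrt(np.clip(np.diag(cov), 0, None))
    return ProteinAbundanceProfile(
        protein=protein,
        stages=[
            StageEstimate(stage=s, estimate=float(m), se=float(se),
                          n=int(n), letter=letter)
            for s, m, se, n, letter in zip(stages, means, ses, ns, letters)
        ],
        model_used=model_used,
        notes=notes,
    )


def roll_up(
    quant_table: pd.DataFrame,
    stage_order: list[str] | None = None,
    alpha: float = 0.05,
    exclude_removed: bool = True,
) -> pd.DataFrame:
    """Roll the peptide-quantity table up to per-protein stage profiles."""
    df = quant_table.copy()
    if exclude_removed and "decision" in df:
        df = df[df["decision"] != "removed"]
    frames = []
    for protein, grp in df.groupby("protein", sort=False):
        try:
            profile = fit_protein_model(grp, protein=protein,
                                        stage_order=stage_order, alpha=alpha)
        except ValueError as exc:
            warnings.warn(f"skipping {protein}: {exc}")
            continue
        frames.append(profile.as_frame())
    if not frames:
        return pd.DataFrame(
            columns=["protein", "stage", "estimate", "se", "n", "letter",
                     "model_used"]
        )
    return pd.concat(frames, ignore_index=True)
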