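"""PRM quantification: XIC extraction, AUC integration, transition-group
scoring, decoy-based q-values, q-value gating, single-point-calibration
absolute quantification and dilution-series linearity.

Identification follows three observables — retention-time agreement,
precursor mass error below 5 ppm, and co-elution/relative-intensity
consistency of the transition group — combined into a fixed-weight
composite score.  q-values come from a target/decoy score comparison
rather than a semi-supervised learner; the two downstream gates (0.01
and 0.05) are all the pipeline consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assay_design import AssayPanel, PanelRow, transition_mz
from .simdata import SimulatedRun

PPM_GATE = 5.0
Q_KEEP = 0.01
Q_REMOVE = 0.05
RT_WINDOW_MIN = 5.0
PRECURSOR_HALF_WINDOW_DA = 1.0  # "2 m/z selection window"
PRODUCT_TOLERANCE_DA = 0.5

#: Composite-score weights (retention time, mass error, co-elution,
#: relative-intensity dot product).  The identification criteria are
#: fixed; the weights are a tunable implementation choice.
DEFAULT_SCORE_WEIGHTS = {"rt": 0.2, "ppm": 0.3, "coelution": 0.3, "dotp": 0.2}


@dataclass
class XIC:
    """One extracted ion chromatogram."""

    peptide: str
    isotope: str
    transition: str
    times: np.ndarray
    intensities: np.ndarray
    mz_window: tuple[float, float]  # (center, half-width)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class TransitionGroupScore:
    peptide: str
    rt_delta_min: float
    mass_error_ppm: float
    coelution_r: float
    intensity_dotp: float
    composite: float
    q_value: float | None = None
    decision: str | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class PeptideQuantity:
    peptide: str
    sample_id: str
    auc_light: float
    auc_heavy: float
    ratio: float | None
    spike_fmol: float
    abundance_fmol_per_ug: float | None
    failure: str | None = None


@dataclass
class DilutionFit:
    peptide: str
    levels: list[float]
    corrected_responses: list[float]
    slope: float
    intercept: float
    r_squared: float
    excluded_levels: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# XIC extraction & integration
# ---------------------------------------------------------------------------


def extract_xic(
    run: SimulatedRun,
    panel: AssayPanel,
    peptide: str,
    isotope: str,
    transition: str,
    mz_tolerance: float | None = None,
    rt_window_min: float = RT_WINDOW_MIN,
) -> XIC:
    """Extract the trace for one transition, restricted to the scheduled
    RT window and to the m/z tolerance.

    Precursor (``p``) transitions use the 2 m/z selection window (±1 Da);
    product ions use the 0.5 Da ion-match tolerance.  A trace whose
    recorded m/z falls outside the window yields a zero-length XIC, not
    an error.
    """
    row = panel.row_for(peptide)
    key = (peptide, isotope, transition)
    if key not in run.traces:
        raise KeyError(f"no trace for {key} in run {run.run_id}")
    tdef = next((t for t in row.transitions if t.label == transition), None)
    if tdef is None:
        raise KeyError(f"transition {transition!r} not in panel for {peptide}")
    if mz_tolerance is None:
        mz_tolerance = (PRECURSOR_HALF_WINDOW_DA if tdef.ion_type == "p"
                        else PRODUCT_TOLERANCE_DA)
    if mz_tolerance <= 0:
        raise ValueError("mz_tolerance must be positive")
    theoretical = transition_mz(peptide, tdef, row.charge, heavy=isotope == "heavy")
    observed = run.trace_mz[key]
    times, intens = run.traces[key]
    if abs(observed - theoretical) > mz_tolerance:
        times, intens = np.empty(0), np.empty(0)
    else:
        lo = (row.rt_min - rt_window_min) * 60.0
        hi = (row.rt_min + rt_window_min) * 60.0
        mask = (times >= lo) & (times <= hi)
        times, intens = times[mask], intens[mask]
    return XIC(peptide, isotope, transition, times, intens,
               mz_window=(theoretical, mz_tolerance))


def integrate_auc(xic: XIC, boundaries: tuple[float, float] | None = None) -> float:
    """Trapezoidal area of an XIC, optionally between boundaries (s)."""
    if len(xic) == 0:
        return 0.0
    times, intens = xic.times, xic.intensities
    if boundaries is not None:
        start, end = boundaries
        if start >= end:
            raise ValueError("boundary start must precede end")
        mask = (times >= start) & (times <= end)
        times, intens = times[mask], intens[mask]
        if times.size == 0:
            return 0.0
    return float(np.trapezoid(intens, times))


def apex_time(xic: XIC) -> float | None:
    """Apex RT by quadratic interpolation around the maximum sample."""
    if len(xic) == 0 or np.all(xic.intensities <= 0):
        return None
    i = int(np.argmax(xic.intensities))
    if 0 < i < len(xic) - 1:
        y0, y1, y2 = xic.intensities[i - 1 : i + 2]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            shift = 0.5 * (y0 - y2) / denom
            dt = xic.times[i + 1] - xic.times[i]
            return float(xic.times[i] + shift * dt)
    return float(xic.times[i])


# ---------------------------------------------------------------------------
# Scoring & q-values
# ---------------------------------------------------------------------------


def fit_peak_boundaries(
    times: np.ndarray,
    intensities: np.ndarray,
    n_sigma: float = 3.0,
) -> tuple[float, float] | None:
    """Integration boundaries apex ± n·σ from a (summed) trace.

    The apex is refined by quadratic interpolation; σ comes from the
    full width at half maximum (FWHM / 2.3548).  Returns None when the
    trace carries no signal.
    """
    if times.size == 0 or np.all(intensities <= 0):
        return None
    i = int(np.argmax(intensities))
    apex_t = times[i]
    if 0 < i < times.size - 1:
        y0, y1, y2 = intensities[i - 1 : i + 2]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            apex_t = times[i] + 0.5 * (y0 - y2) / denom * (times[i + 1] - times[i])
    half = intensities[i] / 2.0
    above = intensities >= half
    left = i
    while left > 0 and above[left - 1]:
        left -= 1
    right = i
    while right < times.size - 1 and above[right + 1]:
        right += 1
    fwhm = times[right] - times[left]
    if fwhm <= 0:
        return None
    sigma = fwhm / 2.3548200450309493
    return (float(apex_t - n_sigma * sigma), float(apex_t + n_sigma * sigma))


def _mean_pairwise_pearson(xics: list[XIC]) -> float | None:
    traces = [x.intensities for x in xics if len(x) > 1]
    if len(traces) < 2:
        return None
    rs = []
    for i in range(len(traces)):
        for j in range(i + 1, len(traces)):
            a, b = traces[i], traces[j]
            if np.std(a) == 0 or np.std(b) == 0:
                continue
            rs.append(float(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(rs)) if rs else None


def score_transition_group(
    light_xics: list[XIC],
    heavy_xics: list[XIC] | None,
    panel_row: PanelRow,
    reference_fractions: list[float] | None = None,
    observed_precursor_mz: float | None = None,
    weights: dict[str, float] | None = None,
) -> TransitionGroupScore:
    """Score one candidate identification.

    Reference relative intensities come from the heavy (spiked) traces
    when available, else from ``reference_fractions``.  Sub-scores are
    each mapped to [0, 1] (higher = better) and combined by a weighted
    sum; degenerate all-zero traces score 0 and are flagged.
    """
    if len(light_xics) < 2:
        raise ValueError("need at least 2 transitions per isotope")
    weights = weights or DEFAULT_SCORE_WEIGHTS
    flags: list[str] = []

    apices = [apex_time(x) for x in light_xics]
    apices = [a for a in apices if a is not None]
    if apices:
        rt_delta = abs(float(np.median(apices)) / 60.0 - panel_row.rt_min)
    else:
        rt_delta = RT_WINDOW_MIN
        flags.append("no-signal")

    theoretical = panel_row.light_mz
    observed = observed_precursor_mz if observed_precursor_mz is not None else theoretical
    mass_error_ppm = abs(observed - theoretical) / theoretical * 1e6

    coelution = _mean_pairwise_pearson(light_xics)
    if coelution is None:
        coelution = 0.0
        flags.append("coelution-undefined")

    observed_areas = np.array([integrate_auc(x) for x in light_xics])
    if heavy_xics is not None:
        reference = np.array([integrate_auc(x) for x in heavy_xics])
    elif reference_fractions is not None:
        reference = np.asarray(reference_fractions, dtype=float)
    else:
        reference = np.ones_like(observed_areas)
    no, nr = np.linalg.norm(observed_areas), np.linalg.norm(reference)
    if no == 0 or nr == 0:
        dotp = 0.0
        flags.append("dotp-undefined")
    else:
        dotp = float(observed_areas @ reference / (no * nr))

    rt_score = max(0.0, 1.0 - rt_delta / RT_WINDOW_MIN)
    ppm_score = max(0.0, 1.0 - mass_error_ppm / PPM_GATE)
    composite = (weights["rt"] * rt_score + weights["ppm"] * ppm_score
                 + weights["coelution"] * max(coelution, 0.0)
                 + weights["dotp"] * dotp)
    return TransitionGroupScore(
        peptide=panel_row.peptide,
        rt_delta_min=rt_delta,
        mass_error_ppm=mass_error_ppm,
        coelution_r=coelution,
        intensity_dotp=dotp,
        composite=composite,
        flags=flags,
    )


def passes_identification_gates(score: TransitionGroupScore) -> bool:
    """The hard identification rule: <5 ppm, inside the RT window, co-eluting."""
    return (score.mass_error_ppm < PPM_GATE
            and score.rt_delta_min < RT_WINDOW_MIN
            and score.coelution_r > 0.5)


def estimate_q_values(target_scores: list[float], decoy_scores: list[float]) -> list[float]:
    """Target-decoy q-values.

    For each target score s, FDR(s) = #{decoys ≥ s} / max(1, #{targets ≥ s});
    the q-value is the running minimum of FDR over decreasing score, so it
    is monotone non-increasing in the score.
    """
    if not target_scores:
        return []
    if not decoy_scores:
        raise ValueError(
            "no decoy scores: generate decoys (shuffled-sequence or "
            "second-best-peak) before estimating q-values"
        )
    targets = np.asarray(target_scores, dtype=float)
    sorted_targets = np.sort(targets)
    decoys = np.sort(np.asarray(decoy_scores, dtype=float))
    thresholds = np.unique(targets)  # ascending candidate cut-offs
    n_decoys_ge = decoys.size - np.searchsorted(decoys, thresholds, side="left")
    n_targets_ge = targets.size - np.searchsorted(sorted_targets, thresholds,
                                                  side="left")
    fdr = n_decoys_ge / np.maximum(1, n_targets_ge)
    # q(s) = min FDR over any threshold that still accepts s (t <= s)
    q_at_threshold = np.minimum(np.minimum.accumulate(fdr), 1.0)
    idx = np.searchsorted(thresholds, targets)
    return q_at_threshold[idx].tolist()


def apply_q_filter(q_values: list[float], strict: bool = False) -> list[str]:
    """Map q-values to decisions.

    q < 0.01 → ``kept``; 0.01 ≤ q ≤ 0.05 → ``flagged`` (kept by default,
    removed under ``strict``); q > 0.05 → ``removed``.
    """
    decisions = []
    for q in q_values:
        if q < Q_KEEP:
            decisions.append("kept")
        elif q <= Q_REMOVE:
            decisions.append("removed" if strict else "flagged")
        else:
            decisions.append("removed")
    return decisions


def make_decoy_scores(
    runs: list[SimulatedRun],
    panel: AssayPanel,
    seed: int = 0,
    rt_shift_min: float = 3.0,
) -> list[float]:
    """Decoy scores from deliberately wrong extractions.

    Each decoy scores a transition group against a shuffled transition
    order (breaking the relative-intensity pattern) at an RT offset
    (breaking the scheduled-time match), mimicking the second-best-peak
    idea without a learner.
    """
    rng = np.random.default_rng(seed)
    scores = []
    for run in runs:
        for row in panel:
            xics = [extract_xic(run, panel, row.peptide, "light", t.label)
                    for t in row.transitions]
            if len(xics) < 2:
                continue
            shuffled = list(xics)
            rng.shuffle(shuffled)
            decoy_row_rt = row.rt_min + rt_shift_min * rng.choice([-1.0, 1.0])
            decoy_row = PanelRow(
                protein_id=row.protein_id, peptide=row.peptide,
                labeled_peptide=row.labeled_peptide, light_mz=row.light_mz,
                heavy_mz=row.heavy_mz, charge=row.charge,
                transitions=row.transitions, rt_min=decoy_row_rt,
                spike_fmol=row.spike_fmol,
            )
            reference = [integrate_auc(x) for x in xics][::-1]
            score = score_transition_group(
                shuffled, None, decoy_row, reference_fractions=reference,
                observed_precursor_mz=row.light_mz * (1 + 20e-6),
            )
            scores.append(score.composite)
    return scores


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------


def quantify_single_point(
    auc_light: float,
    auc_heavy: float,
    spike_fmol: float,
    injected_ug: float = 1.0,
) -> float:
    """Single-point calibration: (light/heavy AUC ratio) × spike / μg."""
    if spike_fmol <= 0:
        raise QuantificationFailure("no labeled peptide spiked: cannot calibrate")
    if injected_ug <= 0:
        raise ValueError("injected amount must be positive")
    if auc_heavy <= 0:
        raise QuantificationFailure("no heavy signal: cannot calibrate")
    return (auc_light / auc_heavy) * spike_fmol / injected_ug


class QuantificationFailure(ValueError):
    """Raised when a peptide cannot be quantified (e.g. zero heavy AUC)."""


def quantify_run(
    run: SimulatedRun,
    panel: AssayPanel,
    q_values: dict[str, float] | None = None,
) -> list[PeptideQuantity]:
    """Quantify every panel peptide in one run.

    Sums trapezoidal AUC over the panel's quantifier transitions for the
    endogenous and heavy traces and applies single-point calibration.
    A zero heavy AUC produces an explicit failure record rather than a
    silent drop.
    """
    out = []
    for row in panel:
        light = [extract_xic(run, panel, row.peptide, "light", t.label)
                 for t in row.transitions]
        heavy = [extract_xic(run, panel, row.peptide, "heavy", t.label)
                 for t in row.transitions]
        # shared boundaries (apex ± 3σ) fitted on the combined group:
        # light and heavy isotopologues co-elute
        pooled = [x for x in light + heavy if len(x)]
        boundaries = None
        if pooled:
            times = pooled[0].times
            if all(len(x) == times.size for x in pooled):
                summed = np.sum([x.intensities for x in pooled], axis=0)
                boundaries = fit_peak_boundaries(times, summed)
        auc_light = sum(integrate_auc(x, boundaries) for x in light if len(x))
        auc_heavy = sum(integrate_auc(x, boundaries) for x in heavy if len(x))
        spike = run.spiked.get(row.peptide, row.spike_fmol)
        try:
            abundance = quantify_single_point(auc_light, auc_heavy, spike,
                                              run.injected_ug)
            ratio = auc_light / auc_heavy
            failure = None
        except QuantificationFailure as exc:
            abundance, ratio, failure = None, None, str(exc)
        out.append(PeptideQuantity(
            peptide=row.peptide, sample_id=run.run_id,
            auc_light=auc_light, auc_heavy=auc_heavy, ratio=ratio,
            spike_fmol=spike, abundance_fmol_per_ug=abundance, failure=failure,
        ))
    return out


def quantify_runs(
    runs: list[SimulatedRun],
    panel: AssayPanel,
    with_q_values: bool = True,
    strict: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Quantify a set of runs into the peptide-quantity table.

    Columns: sample, stage, replicate, protein, peptide, auc_light,
    auc_heavy, ratio, fmol_per_ug, q_value, decision, failure.
    """
    protein_of = {row.peptide: row.protein_id for row in panel}
    records = []
    target_scores: list[float] = []
    score_index: list[int] = []
    for run in runs:
        quantities = quantify_run(run, panel)
        for q in quantities:
            row = panel.row_for(q.peptide)
            rec = dict(
                sample=q.sample_id, stage=run.stage, replicate=run.replicate,
                protein=protein_of[q.peptide], peptide=q.peptide,
                auc_light=q.auc_light, auc_heavy=q.auc_heavy, ratio=q.ratio,
                fmol_per_ug=q.abundance_fmol_per_ug, failure=q.failure,
                q_value=np.nan, decision="kept",
            )
            if with_q_values:
                light = [extract_xic(run, panel, q.peptide, "light", t.label)
                         for t in row.transitions]
                heavy = [extract_xic(run, panel, q.peptide, "heavy", t.label)
                         for t in row.transitions]
                score = score_transition_group(light, heavy, row)
                target_scores.append(score.composite)
                score_index.append(len(records))
            records.append(rec)
    frame = pd.DataFrame.from_records(records)
    if with_q_values and target_scores:
        decoys = make_decoy_scores(runs, panel, seed=seed)
        qs = estimate_q_values(target_scores, decoys)
        decisions = apply_q_filter(qs, strict=strict)
        for i, q, d in zip(score_index, qs, decisions):
            frame.loc[i, "q_value"] = q
            frame.loc[i, "decision"] = d
    return frame


# ---------------------------------------------------------------------------
# Dilution series
# ---------------------------------------------------------------------------


def evaluate_dilution_linearity(
    series: list[tuple[float, float, float]],
    peptide: str = "",
) -> DilutionFit:
    """OLS fit of run-corrected heavy response on spike level.

    Each run's response is auc_heavy / auc_light: the endogenous signal
    is constant across the series and acts as the run-to-run normalizer.
    Runs with zero light AUC (no normalizer) or zero level (no heavy
    signal expected) are excluded.
    """
    usable: list[tuple[float, float]] = []
    excluded: list[float] = []
    for level, auc_heavy, auc_light in series:
        if level <= 0:
            excluded.append(level)
            continue
        if auc_light <= 0:
            warnings.warn(f"excluding level {level}: zero endogenous AUC")
            excluded.append(level)
            continue
        usable.append((level, auc_heavy / auc_light))
    if len(usable) < 3:
        raise ValueError("need at least 3 usable non-zero levels")
    levels = np.array([u[0] for u in usable])
    responses = np.array([u[1] for u in usable])
    fit = stats.linregress(levels, responses)
    return DilutionFit(
        peptide=peptide,
        levels=levels.tolist(),
        corrected_responses=responses.tolist(),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 0.0,
    )


def choose_spike_level(
    series: list[tuple[float, float]],
    endogenous_auc: float,
) -> float:
    """Pick the tested spike level whose heavy AUC is closest to the
    endogenous AUC on a log scale; ties resolve to the lower level."""
    candidates = [(level, auc) for level, auc in series if auc > 0 and level > 0]
    if not candidates:
        raise ValueError("no usable spike levels")
    if endogenous_auc <= 0:
        raise ValueError("endogenous AUC must be positive")
    log_target = np.log(endogenous_auc)
    best = min(
        candidates,
        key=lambda c: (abs(np.log(c[1]) - log_target), c[0]),
    )
    return best[0]
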