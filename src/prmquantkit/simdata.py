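"""Seeded synthetic-data generators.

Produces PRM runs (co-eluting light/heavy Gaussian transition groups
with known ground-truth amounts), spike dilution series, qPCR plates
with standard curves, and paired mean±SE stage profiles — everything the
downstream quantification, statistics and correlation stages consume,
with the truth recorded so recovery can be checked.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .assay_design import AssayPanel, transition_mz

DEFAULT_STAGES = ("MG", "BR", "OR", "R")
DEFAULT_SPIKE_LEVELS = (0.0, 1.0, 5.0, 10.0, 100.0, 200.0)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic PRM instrument."""

    stages: tuple[str, ...] = DEFAULT_STAGES
    replicates_per_stage: int = 6
    rt_sigma: float = 2.55  # seconds (~6 s FWHM)
    rt_jitter_sd: float = 1.0  # seconds
    noise_sd: float = 0.0  # intensity units
    mz_error_ppm_sd: float = 0.0
    response_factor: float = 1000.0  # intensity·s per fmol
    sampling_interval: float = 0.5  # seconds
    trace_halfwidth: float = 20.0  # seconds either side of apex
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rt_sigma", "rt_jitter_sd", "noise_sd", "mz_error_ppm_sd",
                     "response_factor", "sampling_interval"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicates_per_stage < 1:
            raise ValueError("replicates_per_stage must be >= 1")


@dataclass
class GroundTruth:
    """Hidden truth behind a set of simulated runs.

    ``abundances`` maps protein -> stage -> true fmol per μg.
    ``yields`` maps peptide -> digestion yield in [0, 1].
    ``fractions`` maps peptide -> per-transition relative intensity
    (one entry per panel transition, summing to 1).
    """

    abundances: dict[str, dict[str, float]]
    yields: dict[str, float]
    fractions: dict[str, list[float]]

    def __post_init__(self) -> None:
        for protein, per_stage in self.abundances.items():
            for stage, v in per_stage.items():
                if v < 0:
                    raise ValueError(f"negative abundance for {protein}/{stage}")
        for pep, y in self.yields.items():
            if not 0 <= y <= 1:
                raise ValueError(f"yield for {pep} outside [0, 1]")
        for pep, fr in self.fractions.items():
            if abs(sum(fr) - 1.0) > 1e-6:
                raise ValueError(f"fractions for {pep} do not sum to 1")


@dataclass
class TraceKey:
    peptide: str
    isotope: str  # 'light' | 'heavy'
    transition: str

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.peptide, self.isotope, self.transition)


@dataclass
class SimulatedRun:
    """One synthetic injection: transition traces plus spike metadata."""

    run_id: str
    traces: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]]
    trace_mz: dict[tuple[str, str, str], float]
    spiked: dict[str, float]
    injected_ug: float = 1.0
    stage: str | None = None
    replicate: int | None = None
    truth_fmol: dict[str, float] = field(default_factory=dict)

    def trace(self, peptide: str, isotope: str, transition: str):
        return self.traces[(peptide, isotope, transition)]


def default_ground_truth(
    panel: AssayPanel,
    seed: int = 0,
    stages: tuple[str, ...] = DEFAULT_STAGES,
    abundance_range: tuple[float, float] = (0.5, 40.0),
    yield_preset: str = "uniform",
) -> GroundTruth:
    """Random but seeded truth for a panel.

    ``yield_preset='uniform'`` gives every peptide yield 1.0;
    ``'discordant'`` cycles yields {1.0, 0.5, 0.25} across the peptides
    of each protein, emulating position-dependent digestion efficiency.
    """
    rng = np.random.default_rng(seed)
    abundances: dict[str, dict[str, float]] = {}
    for protein in panel.proteins:
        abundances[protein] = {
            stage: float(rng.uniform(*abundance_range)) for stage in stages
        }
    yields: dict[str, float] = {}
    discordant_cycle = (1.0, 0.5, 0.25)
    counters: dict[str, int] = {}
    for row in panel:
        if yield_preset == "discordant":
            i = counters.get(row.protein_id, 0)
            counters[row.protein_id] = i + 1
            yields[row.peptide] = discordant_cycle[i % 3]
        else:
            yields[row.peptide] = 1.0
    fractions = {
        row.peptide: [float(x) for x in rng.dirichlet(np.full(len(row.transitions), 5.0))]
        for row in panel
    }
    return GroundTruth(abundances=abundances, yields=yields, fractions=fractions)


def _gaussian_trace(times: np.ndarray, apex: float, sigma: float,
                    amplitude: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((times - apex) / sigma) ** 2)


def simulate_run(
    config: SimulationConfig,
    truth: GroundTruth,
    panel: AssayPanel,
    seed: int,
    stage: str | None = None,
    replicate: int | None = None,
    run_id: str | None = None,
    spiked: dict[str, float] | None = None,
) -> SimulatedRun:
    """Simulate one PRM injection over every panel peptide.

    Each transition trace is a Gaussian peak centred at the scheduled RT
    plus a per-peptide jitter shared by the light and heavy isotopes
    (isotopologues co-elute by construction), scaled by the transition's
    relative intensity fraction, with additive Gaussian noise truncated
    at zero.  Light amplitude follows true abundance × digestion yield;
    heavy amplitude follows the spiked amount.
    """
    rng = np.random.default_rng(seed)
    stage = stage or config.stages[0]
    if spiked is None:
        spiked = {row.peptide: row.spike_fmol for row in panel}
    for pep, amount in spiked.items():
        if amount < 0:
            raise ValueError(f"negative spike for {pep}")

    traces: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]] = {}
    trace_mz: dict[tuple[str, str, str], float] = {}
    truth_fmol: dict[str, float] = {}
    for row in panel:
        if row.protein_id not in truth.abundances:
            raise KeyError(f"no ground truth for protein {row.protein_id}")
        true_fmol = truth.abundances[row.protein_id][stage]
        yield_factor = truth.yields[row.peptide]
        truth_fmol[row.peptide] = true_fmol * yield_factor
        rt_s = row.rt_min * 60.0
        jitter = rng.normal(0.0, config.rt_jitter_sd) if config.rt_jitter_sd else 0.0
        apex = rt_s + jitter
        times = np.arange(
            rt_s - config.trace_halfwidth,
            rt_s + config.trace_halfwidth + config.sampling_interval / 2,
            config.sampling_interval,
        )
        area_light = config.response_factor * true_fmol * yield_factor
        area_heavy = config.response_factor * spiked.get(row.peptide, 0.0)
        norm = config.rt_sigma * np.sqrt(2 * np.pi)
        for isotope, area in (("light", area_light), ("heavy", area_heavy)):
            for t, frac in zip(row.transitions, truth.fractions[row.peptide]):
                amplitude = area * frac / norm
                signal = _gaussian_trace(times, apex, config.rt_sigma, amplitude)
                if config.noise_sd:
                    signal = signal + rng.normal(0.0, config.noise_sd, signal.shape)
                signal = np.clip(signal, 0.0, None)
                key = (row.peptide, isotope, t.label)
                traces[key] = (times.copy(), signal)
                mz = transition_mz(row.peptide, t, row.charge,
                                   heavy=isotope == "heavy")
                if config.mz_error_ppm_sd:
                    mz *= 1.0 + rng.normal(0.0, config.mz_error_ppm_sd) * 1e-6
                trace_mz[key] = mz
    return SimulatedRun(
        run_id=run_id or f"{stage}_{replicate if replicate is not None else 0}",
        traces=traces,
        trace_mz=trace_mz,
        spiked=dict(spiked),
        stage=stage,
        replicate=replicate,
        truth_fmol=truth_fmol,
    )


def simulate_experiment(
    config: SimulationConfig,
    truth: GroundTruth,
    panel: AssayPanel,
    seed: int | None = None,
) -> list[SimulatedRun]:
    """Full design: every stage × replicate, deterministic in the seed."""
    base_seed = config.seed if seed is None else seed
    root = np.random.default_rng(base_seed)
    runs = []
    for stage in config.stages:
        for rep in range(1, config.replicates_per_stage + 1):
            runs.append(
                simulate_run(
                    config, truth, panel,
                    seed=int(root.integers(0, 2**31 - 1)),
                    stage=stage, replicate=rep,
                    run_id=f"{stage}_{rep}",
                )
            )
    return runs


def simulate_spike_series(
    config: SimulationConfig,
    panel: AssayPanel,
    endogenous_fmol: dict[str, float],
    levels: tuple[float, ...] = DEFAULT_SPIKE_LEVELS,
    seed: int = 0,
    truth: GroundTruth | None = None,
) -> list[SimulatedRun]:
    """Dilution series: one run per heavy spike level, fixed endogenous."""
    if any(level < 0 for level in levels):
        raise ValueError("spike levels must be non-negative")
    if truth is None:
        truth = GroundTruth(
            abundances={
                row.protein_id: {s: endogenous_fmol.get(row.peptide, 0.0)
                                 for s in config.stages}
                for row in panel
            },
            yields={row.peptide: 1.0 for row in panel},
            fractions=default_ground_truth(panel, seed=seed).fractions,
        )
    root = np.random.default_rng(seed)
    runs = []
    for level in levels:
        runs.append(
            simulate_run(
                config, truth, panel,
                seed=int(root.integers(0, 2**31 - 1)),
                run_id=f"spike_{level:g}",
                spiked={row.peptide: level for row in panel},
            )
        )
    return runs


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------


@dataclass
class QpcrGroundTruth:
    """True expression, efficiencies and noise level behind a qPCR plate."""

    expression: dict[str, dict[str, float]]  # gene -> stage -> relative quantity
    efficiencies: dict[str, float]  # gene -> E in (1, 2]
    reference_genes: tuple[str, str, str] = ("ACT", "EF1", "GAPDH")
    ct_noise_sd: float = 0.0
    base_ct: float = 20.0

    def __post_init__(self) -> None:
        for gene, e in self.efficiencies.items():
            if not 1.0 < e <= 2.0:
                raise ValueError(f"efficiency for {gene} must be in (1, 2]")
        for ref in self.reference_genes:
            levels = self.expression.get(ref)
            if levels is not None and len(set(levels.values())) > 1:
                raise ValueError(f"reference gene {ref} must be constant across stages")


def default_qpcr_truth(
    target_genes: list[str],
    seed: int = 0,
    stages: tuple[str, ...] = DEFAULT_STAGES,
    ct_noise_sd: float = 0.0,
) -> QpcrGroundTruth:
    rng = np.random.default_rng(seed)
    refs = ("ACT", "EF1", "GAPDH")
    expression: dict[str, dict[str, float]] = {}
    for gene in target_genes:
        expression[gene] = {
            stage: float(rng.uniform(0.1, 4.0)) for stage in stages
        }
    for ref in refs:
        expression[ref] = {stage: 1.0 for stage in stages}
    efficiencies = {
        gene: float(rng.uniform(1.85, 2.0)) for gene in [*target_genes, *refs]
    }
    return QpcrGroundTruth(
        expression=expression,
        efficiencies=efficiencies,
        reference_genes=refs,
        ct_noise_sd=ct_noise_sd,
    )


def simulate_qpcr(
    qtruth: QpcrGroundTruth,
    stages: tuple[str, ...] = DEFAULT_STAGES,
    replicates: int = 6,
    seed: int = 0,
    standard_dilutions: tuple[float, ...] = (1.0, 0.1, 0.01, 0.001),
) -> pd.DataFrame:
    """Simulate Ct values for samples plus a pooled-cDNA standard curve.

    Ct = base_ct − log_E(relative quantity) + noise.  Each gene also gets
    one standard dilution series (``is_standard`` rows) for efficiency
    estimation.
    """
    rng = np.random.default_rng(seed)
    records = []
    for gene, e in qtruth.efficiencies.items():
        if e <= 1.0:
            raise ValueError(f"efficiency for {gene} must exceed 1")
        log_e = np.log(e)
        for stage in stages:
            q = qtruth.expression[gene][stage]
            for rep in range(1, replicates + 1):
                ct = qtruth.base_ct - np.log(q) / log_e
                if qtruth.ct_noise_sd:
                    ct += rng.normal(0.0, qtruth.ct_noise_sd)
                records.append(
                    dict(run=1, gene=gene, sample=f"{stage}_{rep}", stage=stage,
                         ct=float(ct), is_standard=False, dilution=np.nan)
                )
        for dilution in standard_dilutions:
            ct = qtruth.base_ct - np.log(dilution) / log_e
            if qtruth.ct_noise_sd:
                ct += rng.normal(0.0, qtruth.ct_noise_sd)
            records.append(
                dict(run=1, gene=gene, sample=f"std_{dilution:g}", stage="standard",
                     ct=float(ct), is_standard=True, dilution=dilution)
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Paired mean±SE profiles
# ---------------------------------------------------------------------------


def simulate_profiles(
    true_r: float,
    n_stages: int = 4,
    se_scale: float = 0.1,
    seed: int = 0,
    stages: tuple[str, ...] | None = None,
):
    """Two mean±SE stage profiles whose latent means correlate at ``true_r``.

    Returns a pair of dicts with keys ``stages``, ``means``, ``ses``.
    With two stages any sample correlation is ±1; a warning is issued.
    """
    if not -1.0 <= true_r <= 1.0:
        raise ValueError("true_r must lie in [-1, 1]")
    if n_stages == 2:
        warnings.warn("2-point profiles have degenerate (always ±1) correlation")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_stages)
    noise = rng.standard_normal(n_stages)
    if abs(true_r) == 1.0:
        y = np.sign(true_r) * x
    else:
        # residualize so the construction controls the latent correlation
        noise = noise - noise.mean()
        x_c = x - x.mean()
        noise = noise - (noise @ x_c) / (x_c @ x_c) * x_c
        nx = np.linalg.norm(x_c)
        nn = np.linalg.norm(noise)
        y = true_r * x_c / nx + np.sqrt(1 - true_r**2) * noise / max(nn, 1e-12)
    labels = tuple(stages) if stages else tuple(
        DEFAULT_STAGES[:n_stages] if n_stages <= 4
        else [f"S{i+1}" for i in range(n_stages)]
    )
    ses_a = np.abs(rng.normal(0.0, se_scale, n_stages)) if se_scale else np.zeros(n_stages)
    ses_b = np.abs(rng.normal(0.0, se_scale, n_stages)) if se_scale else np.zeros(n_stages)
    a = dict(stages=labels, means=x + 10.0, ses=ses_a)
    b = dict(stages=labels, means=y * np.std(x) + 10.0, ses=ses_b)
    return a, b


# ---------------------------------------------------------------------------
# IO: long-format trace CSV + JSON truth sidecar
# ---------------------------------------------------------------------------


def runs_to_frame(runs: list[SimulatedRun]) -> pd.DataFrame:
    """Long format: run_id, peptide, isotope, transition, time_s, intensity."""
    chunks = []
    for run in runs:
        for (pep, isotope, transition), (times, intens) in run.traces.items():
            chunks.append(pd.DataFrame({
                "run_id": run.run_id,
                "stage": run.stage,
                "replicate": run.replicate,
                "peptide": pep,
                "isotope": isotope,
                "transition": transition,
                "time_s": times,
                "intensity": intens,
                "mz": run.trace_mz[(pep, isotope, transition)],
            }))
    return pd.concat(chunks, ignore_index=True)


def save_runs(runs: list[SimulatedRun], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    runs_to_frame(runs).to_csv(directory / "traces.csv", index=False)
    meta = {
        run.run_id: dict(stage=run.stage, replicate=run.replicate,
                         spiked=run.spiked, injected_ug=run.injected_ug,
                         truth_fmol=run.truth_fmol)
        for run in runs
    }
    (directory / "runs.json").write_text(json.dumps(meta, indent=2))


def load_runs(directory: str | Path) -> list[SimulatedRun]:
    directory = Path(directory)
    frame = pd.read_csv(directory / "traces.csv")
    meta = json.loads((directory / "runs.json").read_text())
    runs = []
    for run_id, grp in frame.groupby("run_id", sort=False):
        traces = {}
        trace_mz = {}
        for (pep, isotope, transition), sub in grp.groupby(
            ["peptide", "isotope", "transition"], sort=False
        ):
            key = (pep, isotope, transition)
            traces[key] = (sub["time_s"].to_numpy(), sub["intensity"].to_numpy())
            trace_mz[key] = float(sub["mz"].iloc[0])
        info = meta[str(run_id)]
        runs.append(SimulatedRun(
            run_id=str(run_id), traces=traces, trace_mz=trace_mz,
            spiked=info["spiked"], injected_ug=info.get("injected_ug", 1.0),
            stage=info.get("stage"), replicate=info.get("replicate"),
            truth_fmol=info.get("truth_fmol", {}),
        ))
    return runs


def save_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(truth), indent=2))


def load_truth(path: str | Path) -> GroundTruth:
    return GroundTruth(**json.loads(Path(path).read_text()))
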