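"""Seeded synthetic-assay generators.

No raw instrument data are deposited for the four assay designs the
pipeline consumes, so each generator emulates one assay at the level the
fitting stages ingest (occupancy fractions, internal-standard-corrected
AUCs, fluorescence traces, viability fractions), with the concentration
panels and sampling schedules of the original experiments:

* MS occupancy plates: probe at 20/40/80/160 uM, two biological
  parallels, sampled to labelling saturation (minutes for the reactive
  acrylamide/chloroacetamide compounds, hours for the slow imidazole-
  and aziridine-carboxamides);
* GSH surrogate reactivity: 250 uM compound with/without 5 mM GSH,
  sampled at 0/1/2/4/8/12/24/48/72 h, duplicate;
* MANT-GDP exchange: 30 s cadence over 60 min, with RAS-SOS1 and
  RAS-only control wells, three independent experiments;
* cell viability: six-point 5x dilution from 100 uM, 3 replicates x 3
  experiments.

All randomness flows from the design's integer seed through
``numpy.random.default_rng``; a fixed seed gives byte-identical output.
Generation starts at the occupancy/AUC level - no spectra or
chromatograms are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import reference_data as ref
from .kinetics import TwoStepParams, analytic_kobs, occupancy_curve, simulate_two_step_ode

__all__ = [
    "AssayDesign",
    "occupancy_design",
    "gsh_design",
    "exchange_design",
    "viability_design",
    "generate_occupancy_plate",
    "generate_gsh_series",
    "generate_exchange_traces",
    "generate_viability_plate",
    "generate_study",
]

# occupancy sampling schedules: the published incubation series (reactive
# acrylamide/chloroacetamide chemistries in minutes, slow carboxamides in
# hours; two hour-scale variants were used)
_OCC_SCHEDULES_S = {
    "fast": np.array([0.5, 2.0, 5.0, 15.0, 60.0]) * 60.0,  # minutes
    "slow_a": np.array([1.0, 2.5, 4.5, 8.5, 24.0]) * 3600.0,  # hours
    "slow_b": np.array([1.0, 2.0, 4.5, 17.0, 24.0]) * 3600.0,
}

GSH_TIMES_H = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 48.0, 72.0])

#: uncatalysed and SOS1-catalysed exchange rates framing the assay window (s^-1)
EXCHANGE_RATE_RAS_ONLY = 2e-5
EXCHANGE_RATE_RAS_SOS = 1.5e-3


@dataclass(frozen=True)
class AssayDesign:
    """Concentration panel, sampling schedule and noise model of one assay.

    ``noise_model`` is ``"gaussian"`` (additive, sd in response units) or
    ``"lognormal"`` (multiplicative, sd of the log).  ``replicates``
    are within-experiment wells; ``experiments`` independent repeats.
    """

    concentrations: tuple  # M
    times: tuple  # s or h depending on the assay
    replicates: int = 2
    experiments: int = 1
    noise_model: str = "gaussian"
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.experiments < 1:
            raise ValueError("replicate and experiment counts must be >= 1")
        if self.noise_model not in ("gaussian", "lognormal"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_(self, **kwargs) -> "AssayDesign":
        return replace(self, **kwargs)


def occupancy_design(schedule: str = "fast", seed: int = 0,
                     noise_sd: float = 0.02) -> AssayDesign:
    """MS occupancy design: 20/40/80/160 uM probe, duplicate, class schedule."""
    return AssayDesign(
        concentrations=(20e-6, 40e-6, 80e-6, 160e-6),
        times=tuple(_OCC_SCHEDULES_S[schedule]),
        replicates=2,
        noise_model="gaussian",
        noise_sd=noise_sd,
        seed=seed,
    )


def gsh_design(seed: int = 0, noise_sd: float = 0.05) -> AssayDesign:
    """GSH reactivity design: 0-72 h schedule, duplicate, lognormal AUC noise."""
    return AssayDesign(
        concentrations=(250e-6,),
        times=tuple(GSH_TIMES_H),
        replicates=2,
        noise_model="lognormal",
        noise_sd=noise_sd,
        seed=seed,
    )


def exchange_design(seed: int = 0, noise_sd: float = 0.01) -> AssayDesign:
    """Exchange-assay design: 30 s cadence x 60 min, 7-point 5x dilution.

    Noise sd is a fraction of the fluorescence amplitude.
    """
    concs = tuple(125e-6 / 5.0 ** i for i in range(7))  # 125 uM ... 8 nM
    return AssayDesign(
        concentrations=concs,
        times=tuple(np.arange(0.0, 3601.0, 30.0)),
        replicates=1,
        experiments=3,
        noise_model="gaussian",
        noise_sd=noise_sd,
        seed=seed,
    )


def viability_design(seed: int = 0, noise_sd: float = 0.05) -> AssayDesign:
    """Cell viability design: 100 uM down to 32 nM (5x), 3 x 3 replication."""
    return AssayDesign(
        concentrations=(100e-6, 20e-6, 4e-6, 0.8e-6, 0.16e-6, 0.032e-6),
        times=(),
        replicates=3,
        experiments=3,
        noise_model="gaussian",
        noise_sd=noise_sd,
        seed=seed,
    )


def generate_occupancy_plate(
    params: TwoStepParams,
    design: AssayDesign,
    compound_id: str = "cpd",
    plateau: float = 0.95,
    use_ode: bool = False,
    E0: float = 2e-6,
) -> pd.DataFrame:
    """Simulate one MS target-occupancy plate.

    Occupancy follows the analytic one-phase curve at
    ``analytic_kobs(params, c)`` (or, with ``use_ode=True``, the
    mass-action adduct fraction as a cross-validation mode), plus
    additive Gaussian noise clipped to [0, 1].

    Returns a tidy frame: compound, conc_uM, replicate, time_s, occupancy.
    """
    rng = design.rng()
    times = np.asarray(design.times, dtype=float)
    rows = []
    for conc in design.concentrations:
        if use_ode:
            k_1 = 1e5  # fast recognition; K_I fixes k_minus1
            traj = simulate_two_step_ode(
                k_1, k_1 * params.K_I, params.k_inact, E0, conc,
                times if times[0] > 0 else times + 1e-9,
            )
            clean = plateau * traj.adduct_fraction
        else:
            clean = occupancy_curve(analytic_kobs(params, conc), plateau, times)
        for rep in range(1, design.replicates + 1):
            noisy = clean + rng.normal(0.0, design.noise_sd, size=times.shape) \
                if design.noise_sd > 0 else clean.copy()
            noisy = np.clip(noisy, 0.0, 1.0)
            rows.append(pd.DataFrame({
                "compound": compound_id,
                "conc_uM": conc * 1e6,
                "replicate": f"r{rep}",
                "time_s": times,
                "occupancy": noisy,
            }))
    return pd.concat(rows, ignore_index=True)


def generate_gsh_series(
    k_deg: float,
    k_gsh: float,
    design: AssayDesign,
    compound_id: str = "cpd",
    auc0: float = 1e6,
) -> pd.DataFrame:
    """Simulate paired HPLC AUC decay series (blank vs +GSH).

    The blank arm decays at the aqueous degradation rate ``k_deg``
    (h^-1), the GSH arm at ``k_deg + k_gsh``; noise is multiplicative
    lognormal on AUC.  Returns: compound, arm, replicate, time_h, auc.
    """
    if k_deg < 0 or k_gsh < 0:
        raise ValueError("rates must be >= 0")
    rng = design.rng()
    times = np.asarray(design.times, dtype=float)
    rows = []
    for arm, rate in (("blank", k_deg), ("gsh", k_deg + k_gsh)):
        clean = auc0 * np.exp(-rate * times)
        for rep in range(1, design.replicates + 1):
            noisy = clean * np.exp(rng.normal(0.0, design.noise_sd, size=times.shape)) \
                if design.noise_sd > 0 else clean.copy()
            rows.append(pd.DataFrame({
                "compound": compound_id,
                "arm": arm,
                "replicate": f"r{rep}",
                "time_h": times,
                "auc": noisy,
            }))
    return pd.concat(rows, ignore_index=True)


def generate_exchange_traces(
    ic50: float,
    design: AssayDesign,
    compound_id: str = "cpd",
    hill: float = 1.0,
    f0: float = 1.0,
    f_inf: float = 0.2,
) -> pd.DataFrame:
    """Simulate MANT-GDP exchange fluorescence traces.

    Each sample well exchanges at a rate interpolated between the
    RAS-only (fully inhibited) and RAS-SOS1 (uninhibited) control rates
    by a logistic in compound concentration; the trace is a single
    exponential fluorescence decay at that rate plus Gaussian noise
    scaled to the amplitude.  Control wells are included per experiment.

    Returns: well, role, conc_uM, experiment, time_s, fluorescence.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be > 0")
    rng = design.rng()
    times = np.asarray(design.times, dtype=float)
    amplitude = abs(f0 - f_inf)
    sd = design.noise_sd * amplitude

    def trace(rate: float) -> np.ndarray:
        clean = f_inf + (f0 - f_inf) * np.exp(-rate * times)
        return clean + rng.normal(0.0, sd, size=times.shape) if sd > 0 else clean

    span = EXCHANGE_RATE_RAS_SOS - EXCHANGE_RATE_RAS_ONLY
    rows = []
    for exp in range(1, design.experiments + 1):
        rows.append(pd.DataFrame({
            "well": f"e{exp}_ras_sos", "role": "ras_sos", "conc_uM": 0.0,
            "experiment": exp, "time_s": times,
            "fluorescence": trace(EXCHANGE_RATE_RAS_SOS),
        }))
        rows.append(pd.DataFrame({
            "well": f"e{exp}_ras_only", "role": "ras_only", "conc_uM": 0.0,
            "experiment": exp, "time_s": times,
            "fluorescence": trace(EXCHANGE_RATE_RAS_ONLY),
        }))
        for i, conc in enumerate(design.concentrations):
            activity = 1.0 / (1.0 + (conc / ic50) ** hill)
            rate = EXCHANGE_RATE_RAS_ONLY + span * activity
            for rep in range(1, design.replicates + 1):
                rows.append(pd.DataFrame({
                    "well": f"e{exp}_c{i}_r{rep}", "role": "sample",
                    "conc_uM": conc * 1e6, "experiment": exp, "time_s": times,
                    "fluorescence": trace(rate),
                }))
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "compound", compound_id)
    return out


def generate_viability_plate(
    ic50_per_line: dict[str, float],
    design: AssayDesign,
    compound_id: str = "cpd",
    hill: float = 1.0,
) -> pd.DataFrame:
    """Simulate an MTT viability plate for one compound across cell lines.

    ``ic50_per_line`` maps cell line -> IC50 (M).  Viability is a
    logistic from 1 (vehicle) to 0 (full kill) with Gaussian noise,
    clipped below at 0.  Returns: cell_line, compound, conc_uM,
    experiment, replicate, viability.
    """
    rng = design.rng()
    concs = np.asarray(design.concentrations, dtype=float)
    rows = []
    for line, ic50 in ic50_per_line.items():
        if ic50 <= 0:
            raise ValueError(f"IC50 for {line} must be > 0")
        clean = 1.0 / (1.0 + (concs / ic50) ** hill)
        for exp in range(1, design.experiments + 1):
            for rep in range(1, design.replicates + 1):
                noisy = clean + rng.normal(0.0, design.noise_sd, size=concs.shape) \
                    if design.noise_sd > 0 else clean.copy()
                rows.append(pd.DataFrame({
                    "cell_line": line,
                    "compound": compound_id,
                    "conc_uM": concs * 1e6,
                    "experiment": exp,
                    "replicate": f"r{rep}",
                    "viability": np.clip(noisy, 0.0, None),
                }))
    return pd.concat(rows, ignore_index=True)


def generate_study(
    seed: int = 0,
    occupancy_noise_sd: float = 0.02,
    gsh_noise_sd: float = 0.05,
    exchange_noise_sd: float = 0.01,
    viability_noise_sd: float = 0.05,
    k_deg: float = 0.005,
) -> dict[str, pd.DataFrame]:
    """Materialise a complete nine-compound synthetic study.

    Uses the published kinetic constants of the compound panel as
    ground-truth generator inputs; ``k_deg`` (h^-1) is a nominal slow
    aqueous degradation shared by all compounds (per-compound rates are
    unpublished).  Censored GSH half-lives are generated with zero GSH
    reactivity.  Returns {"occupancy", "reactivity", "traces",
    "viability"} tidy frames.
    """
    rng = np.random.default_rng(seed)

    def subseed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    occ, gsh, traces, via = [], [], [], []
    for cpd in ref.COMPOUNDS:
        row = ref.KINETICS[cpd]
        params = TwoStepParams(K_I=row["KI_um"] * 1e-6,
                               k_inact=row["kinact_mili"] * 1e-3)
        sched = ref.OCCUPANCY_SCHEDULE_CLASS[cpd]
        occ.append(generate_occupancy_plate(
            params,
            occupancy_design(sched, seed=subseed(), noise_sd=occupancy_noise_sd),
            compound_id=cpd,
        ))
        k_gsh = 0.0 if row["t_half_gsh_h"] is None else np.log(2.0) / row["t_half_gsh_h"]
        gsh.append(generate_gsh_series(
            k_deg, k_gsh, gsh_design(seed=subseed(), noise_sd=gsh_noise_sd),
            compound_id=cpd,
        ))
        traces.append(generate_exchange_traces(
            row["ic50_um"] * 1e-6,
            exchange_design(seed=subseed(), noise_sd=exchange_noise_sd),
            compound_id=cpd,
        ))
        via.append(generate_viability_plate(
            {line: ref.CELL_IC50_UM[line][cpd] * 1e-6 for line in ref.CELL_IC50_UM},
            viability_design(seed=subseed(), noise_sd=viability_noise_sd),
            compound_id=cpd,
        ))
    return {
        "occupancy": pd.concat(occ, ignore_index=True),
        "reactivity": pd.concat(gsh, ignore_index=True),
        "traces": pd.concat(traces, ignore_index=True),
        "viability": pd.concat(via, ignore_index=True),
    }
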