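"""Study orchestration: tidy assay CSVs in, publication-style tables out.

``run_pipeline`` sequences the stages — occupancy time courses to k_obs,
the k_obs-concentration hyperbola to (K_I, k_inact), AUC decays to
GSH half-lives, fluorescence traces to exchange IC50s, viability plates
to cellular IC50s and selectivity factors — and then applies the
free-energy transforms.  Parameters are fitted per replicate (or per
independent experiment) and aggregated as mean +/- sample SD; derived
energies are computed per replicate before averaging.  Per-compound
failures are isolated: a compound that cannot be fitted is reported
with an error note and the run continues.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import fitting
from .fitting import aggregate_replicates, correct_gsh_rate, fit_ic50
from .thermo import ThermoContext, binding_free_energy, eyring_barrier, gsh_barrier

logger = logging.getLogger("covkin")

__all__ = ["StudyConfig", "StudyReport", "run_pipeline", "render_tables", "round_half_even"]


class StudyConfig(BaseModel):
    """Declarative study configuration (unknown keys are rejected)."""

    model_config = ConfigDict(extra="forbid")

    occupancy_csv: str | None = None
    reactivity_csv: str | None = None
    traces_csv: str | None = None
    viability_csv: str | None = None
    output_dir: str = "covkin_out"
    seed: int = 0
    temperature_K: float = 298.15
    gsh_total_mM: float = 5.0
    ph: float = 7.4
    gsh_pka: float = 8.7
    wt_cell_line: str = "LCLC-103H"
    energy_decimals: int = 1
    ratio_decimals: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def thermo_context(self) -> ThermoContext:
        return ThermoContext(
            T=self.temperature_K,
            gsh_total=self.gsh_total_mM * 1e-3,
            pH=self.ph,
            pKa_gsh=self.gsh_pka,
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class StudyReport:
    """All per-compound results of one pipeline run."""

    kinetics: pd.DataFrame  # half-lives, IC50s, K_I, k_inact, efficiency
    energies: pd.DataFrame  # dG_bind and the two Eyring barriers
    cell_ic50: pd.DataFrame  # per cell line IC50s
    selectivity: pd.DataFrame  # wt/mutant ratios
    errors: dict[str, str] = field(default_factory=dict)
    config_hash: str = ""
    seed: int = 0


# ---------------------------------------------------------------------------
# per-assay reductions
# ---------------------------------------------------------------------------

def fit_occupancy_table(df: pd.DataFrame) -> pd.DataFrame:
    """Occupancy plates -> per-compound (K_I, k_inact) with replicate SDs.

    Expects columns compound, conc_uM, replicate, time_s, occupancy.
    Fits k_obs per (replicate, concentration), then the saturation
    hyperbola per replicate, then aggregates across replicates.
    """
    out = []
    for cpd, per_cpd in df.groupby("compound", sort=False):
        kis, kinacts, flags = [], [], []
        for rep, per_rep in per_cpd.groupby("replicate", sort=False):
            ests = []
            for conc_um, per_conc in per_rep.groupby("conc_uM", sort=False):
                est = fitting.fit_one_phase(
                    per_conc["time_s"].to_numpy(),
                    per_conc["occupancy"].to_numpy(),
                    conc=conc_um * 1e-6,
                )
                ests.append(est)
            fit = fitting.fit_kobs_vs_conc(ests)
            kis.append(fit.K_I)
            kinacts.append(fit.k_inact)
            if fit.poorly_determined:
                flags.append(f"{rep}: K_I poorly determined")
            if not fit.converged:
                flags.append(f"{rep}: non-convergent")
        ki_m, ki_sd = aggregate_replicates(kis)
        kin_m, kin_sd = aggregate_replicates(kinacts)
        effs = [k / K for k, K in zip(kinacts, kis)]
        eff_m, eff_sd = aggregate_replicates(effs)
        out.append(dict(
            compound=cpd, n_replicates=len(kis),
            KI_uM=ki_m * 1e6, KI_uM_sd=None if ki_sd is None else ki_sd * 1e6,
            kinact_s=kin_m, kinact_s_sd=kin_sd,
            kinact_over_KI=eff_m, kinact_over_KI_sd=eff_sd,
            flags="; ".join(flags),
        ))
    return pd.DataFrame(out)


def fit_reactivity_table(df: pd.DataFrame) -> pd.DataFrame:
    """Paired AUC decays -> per-compound corrected GSH half-life.

    Expects columns compound, arm (blank|gsh), replicate, time_h, auc.
    Rates are fitted per replicate; the compound is censored (">72 h")
    when the replicate-mean k_GSH does not exceed the assay horizon.
    """
    out = []
    for cpd, per_cpd in df.groupby("compound", sort=False):
        results = []
        reps = sorted(set(per_cpd["replicate"])) if "replicate" in per_cpd else [None]
        for rep in reps:
            sub = per_cpd if rep is None else per_cpd[per_cpd["replicate"] == rep]
            blank = sub[sub["arm"] == "blank"]
            gsh = sub[sub["arm"] == "gsh"]
            k_deg = fitting.fit_log_linear_rate(blank["time_h"].to_numpy(),
                                                blank["auc"].to_numpy())
            k_app = fitting.fit_log_linear_rate(gsh["time_h"].to_numpy(),
                                                gsh["auc"].to_numpy())
            results.append(correct_gsh_rate(k_app, k_deg))
        k_gsh_m, k_gsh_sd = aggregate_replicates([r.k_gsh for r in results])
        censored = k_gsh_m <= np.log(2.0) / fitting.GSH_CENSOR_HORIZON_H
        t_half = fitting.GSH_CENSOR_HORIZON_H if censored else float(np.log(2.0) / k_gsh_m)
        t_halves = [r.t_half_gsh for r in results]
        _, t_half_sd = aggregate_replicates(t_halves)
        out.append(dict(
            compound=cpd, n_replicates=len(results),
            k_deg=float(np.mean([r.k_deg for r in results])),
            k_gsh=k_gsh_m, k_gsh_sd=k_gsh_sd,
            t_half_gsh_h=t_half,
            t_half_gsh_h_sd=None if censored else t_half_sd,
            censored=censored,
        ))
    return pd.DataFrame(out)


def fit_traces_table(df: pd.DataFrame) -> pd.DataFrame:
    """Exchange traces -> per-compound IC50 of nucleotide-exchange inhibition.

    Expects columns compound, well, role (sample|ras_sos|ras_only),
    conc_uM, experiment, time_s, fluorescence.  Rates are fitted per
    well, normalised to the same experiment's controls, and the IC50 is
    fitted per experiment then aggregated.
    """
    out = []
    for cpd, per_cpd in df.groupby("compound", sort=False):
        ic50s = []
        flags = []
        for exp, per_exp in per_cpd.groupby("experiment", sort=False):
            rates = {}
            for well, per_well in per_exp.groupby("well", sort=False):
                rates[well] = (
                    fitting.fit_exponential_trace(per_well["time_s"].to_numpy(),
                                                  per_well["fluorescence"].to_numpy()),
                    per_well["role"].iloc[0],
                    per_well["conc_uM"].iloc[0],
                )
            sos = [r for r, role, _ in rates.values() if role == "ras_sos"]
            only = [r for r, role, _ in rates.values() if role == "ras_only"]
            if not sos or not only:
                raise ValueError(f"{cpd}: experiment {exp} lacks control wells")
            concs, activities = [], []
            for rate, role, conc_um in rates.values():
                if role != "sample":
                    continue
                concs.append(conc_um * 1e-6)
                activities.append(fitting.normalize_exchange_rates(
                    rate, float(np.mean(sos)), float(np.mean(only))))
            dr = fit_ic50(np.array(concs), np.array(activities))
            ic50s.append(dr.ic50)
            if dr.censored:
                flags.append(f"e{exp}: IC50 censored {dr.censored}")
        m, sd = aggregate_replicates(ic50s)
        out.append(dict(
            compound=cpd, n_experiments=len(ic50s),
            IC50_uM=m * 1e6, IC50_uM_sd=None if sd is None else sd * 1e6,
            flags="; ".join(flags),
        ))
    return pd.DataFrame(out)


def fit_viability_table(df: pd.DataFrame, wt_cell_line: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Viability plates -> per cell-line IC50s and mutant-selectivity factors.

    Expects columns cell_line, compound, conc_uM, experiment (optional),
    replicate, viability.  IC50 is fitted per independent experiment and
    aggregated; selectivity is IC50(wt line) / IC50(G12C line) on the
    aggregated means.
    """
    rows = []
    group_cols = ["compound", "cell_line"]
    for (cpd, line), sub in df.groupby(group_cols, sort=False):
        ic50s = []
        exps = sorted(set(sub["experiment"])) if "experiment" in sub else [None]
        for exp in exps:
            per_exp = sub if exp is None else sub[sub["experiment"] == exp]
            dr = fit_ic50(per_exp["conc_uM"].to_numpy() * 1e-6,
                          per_exp["viability"].to_numpy())
            ic50s.append(dr.ic50)
        m, sd = aggregate_replicates(ic50s)
        rows.append(dict(compound=cpd, cell_line=line, IC50_uM=m * 1e6,
                         IC50_uM_sd=None if sd is None else sd * 1e6,
                         n_experiments=len(ic50s)))
    cell = pd.DataFrame(rows)
    sel_rows = []
    for cpd, sub in cell.groupby("compound", sort=False):
        wt = sub[sub["cell_line"] == wt_cell_line]
        if wt.empty:
            continue
        wt_ic50 = float(wt["IC50_uM"].iloc[0])
        for _, r in sub[sub["cell_line"] != wt_cell_line].iterrows():
            sel_rows.append(dict(
                compound=cpd, cell_line=r["cell_line"],
                selectivity=wt_ic50 / float(r["IC50_uM"]),
            ))
    return cell, pd.DataFrame(sel_rows)


def derive_energies(
    kinetics: pd.DataFrame,
    reactivity: pd.DataFrame | None,
    ctx: ThermoContext,
) -> pd.DataFrame:
    """Free-energy transforms of the fitted kinetics (mean-level inputs)."""
    react = None if reactivity is None else reactivity.set_index("compound")
    rows = []
    for _, r in kinetics.iterrows():
        cpd = r["compound"]
        dg_bind = binding_free_energy(r["KI_uM"] * 1e-6, ctx)
        dg_target = eyring_barrier(r["kinact_s"], ctx) if r["kinact_s"] > 0 else np.nan
        dg_gsh, censored = np.nan, False
        if react is not None and cpd in react.index:
            rr = react.loc[cpd]
            dg_gsh, censored = gsh_barrier(float(rr["t_half_gsh_h"]), ctx,
                                           censored=bool(rr["censored"]))
        rows.append(dict(
            compound=cpd, dG_bind=dg_bind, dG_barrier_gsh=dg_gsh,
            dG_barrier_target=dg_target, gsh_censored=censored,
        ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _isolate(stage, errors: dict[str, str], label: str):
    try:
        return stage()
    except Exception as exc:  # per-stage isolation; the run continues
        logger.error("%s failed: %s", label, exc)
        errors[label] = str(exc)
        return None


def run_pipeline(config: StudyConfig) -> StudyReport:
    """Run every configured stage and derive the energy table."""
    chash = config.config_hash()
    logger.info("covkin run: config=%s seed=%d", chash, config.seed)
    errors: dict[str, str] = {}
    ctx = config.thermo_context()

    def read(path):
        return pd.read_csv(path)

    kinetics = pd.DataFrame(columns=["compound", "KI_uM", "kinact_s", "kinact_over_KI"])
    reactivity = None
    if config.occupancy_csv:
        occ = read(config.occupancy_csv)
        if occ.empty:
            warnings.warn("occupancy input contains zero compounds")
        else:
            res = _isolate(lambda: fit_occupancy_table(occ), errors, "occupancy")
            if res is not None:
                kinetics = res
    if config.reactivity_csv:
        res = _isolate(lambda: fit_reactivity_table(read(config.reactivity_csv)),
                       errors, "reactivity")
        reactivity = res
    traces = None
    if config.traces_csv:
        traces = _isolate(lambda: fit_traces_table(read(config.traces_csv)),
                          errors, "traces")
    cell = sel = pd.DataFrame()
    if config.viability_csv:
        res = _isolate(
            lambda: fit_viability_table(read(config.viability_csv), config.wt_cell_line),
            errors, "viability")
        if res is not None:
            cell, sel = res

    # merge half-lives and exchange IC50s into the kinetics table
    if reactivity is not None and not kinetics.empty:
        kinetics = kinetics.merge(
            reactivity[["compound", "t_half_gsh_h", "t_half_gsh_h_sd", "censored"]],
            on="compound", how="left")
    if traces is not None and not kinetics.empty:
        kinetics = kinetics.merge(
            traces[["compound", "IC50_uM", "IC50_uM_sd"]], on="compound", how="left")

    energies = pd.DataFrame()
    if not kinetics.empty:
        energies = derive_energies(kinetics, reactivity, ctx)

    if kinetics.empty:
        warnings.warn("report contains zero compounds")
    return StudyReport(kinetics=kinetics, energies=energies, cell_ic50=cell,
                       selectivity=sel, errors=errors, config_hash=chash,
                       seed=config.seed)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def round_half_even(value: float, decimals: int) -> str:
    """Banker's rounding on the decimal representation (18.85 -> '18.8')."""
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_EVEN))


def _pm(mean: float, sd: float | None, decimals: int) -> str:
    if mean is None or (isinstance(mean, float) and np.isnan(mean)):
        return ""
    s = round_half_even(mean, decimals)
    if sd is None or (isinstance(sd, float) and np.isnan(sd)):
        return s
    return f"{s} ± {round_half_even(sd, decimals)}"


def render_tables(report: StudyReport, outdir: str | Path) -> dict[str, Path]:
    """Write CSV + JSON (unrounded) and plain-text (printed-style) tables.

    Censored GSH entries render as ">72" (half-life) and ">20.1"-style
    bounds (barrier).  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    frames = {
        "kinetics": report.kinetics,
        "energies": report.energies,
        "cell_ic50": report.cell_ic50,
        "selectivity": report.selectivity,
    }
    for name, frame in frames.items():
        p = outdir / f"{name}.csv"
        frame.to_csv(p, index=False)
        paths[name] = p

    payload = {
        "config_hash": report.config_hash,
        "seed": report.seed,
        "errors": report.errors,
        **{name: json.loads(frame.to_json(orient="records"))
           for name, frame in frames.items()},
    }
    jp = outdir / "report.json"
    jp.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    paths["json"] = jp

    lines = ["covalent inhibition summary", ""]
    for _, r in report.kinetics.iterrows():
        t_half = ">72" if r.get("censored") else (
            "" if "t_half_gsh_h" not in r or pd.isna(r.get("t_half_gsh_h"))
            else _pm(r["t_half_gsh_h"], r.get("t_half_gsh_h_sd"), 0))
        ic50 = _pm(r.get("IC50_uM", np.nan), r.get("IC50_uM_sd"), 3) \
            if "IC50_uM" in r else ""
        kinact_mili = None if pd.isna(r["kinact_s"]) else r["kinact_s"] * 1e3
        ksd = r.get("kinact_s_sd")
        lines.append(
            f"{r['compound']}: t1/2(GSH) {t_half} h | IC50 {ic50} uM | "
            f"K_I {_pm(r['KI_uM'], r.get('KI_uM_sd'), 1)} uM | "
            f"k_inact {_pm(kinact_mili, None if ksd is None or pd.isna(ksd) else ksd * 1e3, 1)} e-3/s | "
            f"kinact/KI {_pm(r['kinact_over_KI'], r.get('kinact_over_KI_sd'), 1)} /M/s"
        )
    if not report.energies.empty:
        lines += ["", "free energies (kcal/mol)"]
        for _, r in report.energies.iterrows():
            gsh = (f">{round_half_even(r['dG_barrier_gsh'], 1)}"
                   if r["gsh_censored"] else
                   ("" if pd.isna(r["dG_barrier_gsh"])
                    else round_half_even(r["dG_barrier_gsh"], 1)))
            lines.append(
                f"{r['compound']}: dG_bind {round_half_even(r['dG_bind'], 1)} | "
                f"dG# GSH {gsh} | "
                f"dG# target {round_half_even(r['dG_barrier_target'], 1)}"
            )
    tp = outdir / "summary.txt"
    tp.write_text("\n".join(lines) + "\n")
    paths["text"] = tp
    return paths
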