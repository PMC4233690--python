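"""Experiment-level entry points chaining the component modules.

``run_experiment`` executes one of the packaged experiment designs end to
end: generate the synthetic population once, fit the per-scenario sentence
distributions, run the scenario ensembles (contagious or spontaneous-only),
derive recidivism statistics, and write population/event/prevalence/
recidivism CSVs, a provenance JSON and summary plots into the output
directory.  Re-running with the same spec reproduces the CSVs byte for
byte.
"""

from __future__ import annotations

import logging
import pathlib
import time

from .config import ExperimentSpec, provenance_record, write_provenance
from .engine import CompiledNetwork, EpidemicConfig, compare_ensembles, run_ensemble
from .lifetable import LifeTable
from .nullmodel import NullConfig, tune_spontaneous_rate
from .ode import bifurcation_sweep, calibrate_mean_rate, critical_sentence, \
    steady_state_prevalence
from .population import generate_population
from .recidivism import compute_recidivism_tables, extract_release_records
from .sentencing import fit_negative_binomial
from .transmission import SurveyTable

log = logging.getLogger("incarsis")


def _sentence_dists(spec: ExperimentSpec) -> dict:
    return {sc.name: fit_negative_binomial(sc.sentence_mean,
                                           sc.sentence_median, sc.name)
            for sc in spec.scenarios}


def _clock_maps(population, epoch: int):
    ag = population.agents
    birth = dict(zip(ag["id"], (ag["birth_year"] - epoch) * 12))
    death = dict(zip(ag["id"], (ag["death_year"] - epoch) * 12))
    return birth, death


def run_experiment(spec: ExperimentSpec, make_plots: bool = True) -> pathlib.Path:
    """Execute the experiment described by ``spec``; returns the output dir."""
    spec.validate()
    out = pathlib.Path(spec.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    log.info("experiment=%s seed=%d out=%s", spec.experiment, spec.base_seed, out)

    life_table = (LifeTable.from_csv(spec.life_table_csv)
                  if spec.life_table_csv else LifeTable.default())
    survey = (SurveyTable.from_csv(spec.survey_csv)
              if spec.survey_csv else SurveyTable.default())
    rate_table = survey.derive_monthly(spec.calibration_sentence)
    rate_table.to_csv(out / "monthly_rates.csv")
    survey.to_csv(out / "survey_table.csv")

    population = generate_population(spec.population, life_table,
                                     seed=spec.base_seed)
    population.to_csv(out / "agents.csv", out / "ties.csv")
    log.info("population: %d agents, %d ties (%.1fs)",
             population.n_agents, population.n_ties, time.time() - t0)
    epoch = spec.population.burn_in
    birth_m, death_m = _clock_maps(population, epoch)
    dists = _sentence_dists(spec)

    extra = {"sentence_distributions": {k: d.to_dict() for k, d in dists.items()},
             "population_size": population.n_agents,
             "population_ties": population.n_ties}

    if spec.experiment == "ode_analysis":
        p = spec.ode_p
        sweep = bifurcation_sweep(p)
        sweep.to_csv(out / "ode_bifurcation.csv", index=False)
        results = {
            "p": p, "critical_sentence": critical_sentence(p),
            "steady_states": {name: steady_state_prevalence(p, d.mean())
                              for name, d in dists.items()},
        }
        extra["ode"] = results
        write_provenance(provenance_record(spec, extra), out / "provenance.json")
        if make_plots:
            from .plotting import plot_bifurcation
            plot_bifurcation(sweep, {n: d.mean() for n, d in dists.items()},
                             out / "ode_bifurcation.png")
        return out

    tuned_rate = None
    if spec.experiment == "null_control":
        anchor = spec.scenarios[0]
        ncfg = NullConfig(sentence_dist=dists[anchor.name],
                          init_prevalence=anchor.init_prevalence,
                          horizon=spec.horizon,
                          min_incarcerable_age=spec.min_incarcerable_age,
                          epidemic_start_year=epoch)
        tuned_rate = tune_spontaneous_rate(
            population, ncfg, spec.target_prevalence, spec.tolerance,
            n_replicates=spec.tuning_replicates, base_seed=spec.base_seed + 10_000)
        extra["tuned_spontaneous_rate"] = tuned_rate
        log.info("tuned spontaneous rate: %.6f", tuned_rate)

    net = CompiledNetwork(population, rate_table,
                          min_incarcerable_age=spec.min_incarcerable_age,
                          adult_child_age=spec.adult_child_age,
                          epidemic_start_year=epoch)
    ensembles = {}
    for i, sc in enumerate(spec.scenarios):
        if spec.experiment == "null_control":
            cfg = EpidemicConfig(
                sentence_dist=dists[sc.name], rate_table=None,
                init_prevalence=sc.init_prevalence, horizon=spec.horizon,
                n_replicates=spec.n_replicates,
                min_incarcerable_age=spec.min_incarcerable_age,
                epidemic_start_year=epoch, spontaneous_rate=tuned_rate)
            ens = run_ensemble(population, cfg,
                               base_seed=spec.base_seed + 1000 * (i + 1))
        else:
            cfg = EpidemicConfig(
                sentence_dist=dists[sc.name], rate_table=rate_table,
                init_prevalence=sc.init_prevalence, horizon=spec.horizon,
                n_replicates=spec.n_replicates,
                min_incarcerable_age=spec.min_incarcerable_age,
                adult_child_age=spec.adult_child_age,
                epidemic_start_year=epoch)
            ens = run_ensemble(net, cfg,
                               base_seed=spec.base_seed + 1000 * (i + 1))
        ensembles[sc.name] = ens
        ens.events.to_csv(out / f"events_{sc.name}.csv", index=False)
        ens.prevalence_frame().to_csv(out / f"prevalence_{sc.name}.csv", index=False)
        ens.summary().to_csv(out / f"summary_{sc.name}.csv", index=False)
        log.info("scenario %s: final mean prevalence %.4f%%",
                 sc.name, 100 * ens.final_mean_prevalence)
        records = extract_release_records(ens.events, spec.horizon,
                                          birth_months=birth_m,
                                          death_months=death_m)
        if records["followup_complete"].any():
            tables = compute_recidivism_tables(records)
            tables.to_csv(out / f"recidivism_{sc.name}")
        else:
            log.warning("scenario %s: no complete-followup releases", sc.name)

    if len(spec.scenarios) == 2:
        a, b = (ensembles[sc.name] for sc in spec.scenarios)
        compare_ensembles(a.prevalence, b.prevalence).to_csv(
            out / "prevalence_welch_pvalues.csv", index=False)

    pooled = calibrate_mean_rate([e.events for e in ensembles.values()]) \
        if spec.experiment != "null_control" else None
    if pooled is not None:
        extra["calibrated_mean_rate"] = pooled
        bifurcation_sweep(pooled).to_csv(out / "ode_bifurcation.csv", index=False)
    write_provenance(provenance_record(spec, extra), out / "provenance.json")

    if make_plots:
        from .plotting import plot_prevalence_bands, plot_recidivism_panels
        plot_prevalence_bands({n: e.summary() for n, e in ensembles.items()},
                              out / "prevalence.png")
        for sc in spec.scenarios:
            d = out / f"recidivism_{sc.name}"
            if d.exists():
                plot_recidivism_panels(d, out / f"recidivism_{sc.name}.png")
    log.info("done in %.1fs", time.time() - t0)
    return out
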