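"""End-to-end pipeline: simulate → cohort → estimates → model → PSA/DSA.

All randomness descends from one root seed, split per stage with
``numpy.random.SeedSequence``, and every run writes a manifest (package
version, stage seeds, config hash) so any output can be reproduced from the
manifest alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from . import __version__
from .cohort import build_cohort, write_cohort
from .config import RunConfig, parameters_from_config
from .incidence import detect_events, estimate_fatality, estimate_incidence, write_estimates
from .markov import run_base_case
from .params import ModelParameters, parameters_from_estimates
from .sensitivity import build_distributions, ceac, one_way_dsa, run_psa, scatter_table
from .synthetic import generate_population, write_ground_truth

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage_seeds(root_seed: int) -> Dict[str, int]:
    children = np.random.SeedSequence(root_seed).spawn(2)
    # keep derived seeds small enough for external tools
    return {
        "generator": int(children[0].generate_state(1)[0] % (2**31 - 1)),
        "psa": int(children[1].generate_state(1)[0] % (2**31 - 1)),
    }


def run_all(config: RunConfig, out_dir, seed: int = 0, psa_n_iter: Optional[int] = None) -> Dict:
    """Run the full chain and write all artifact tables under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(seed)
    summary: Dict = {"seed": seed, "stage_seeds": seeds}

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    name = stage("simulate-data")
    try:
        from dataclasses import replace

        gen_cfg = replace(config.generator, seed=seeds["generator"])
        dataset = generate_population(gen_cfg)
        claims_dir = out / "claims"
        dataset.write(claims_dir)
        write_ground_truth(gen_cfg, claims_dir)
    except Exception as exc:
        raise StageError(f"{name}: {exc}") from exc

    name = stage("build-cohort")
    try:
        cohort, attrition = build_cohort(dataset, config.codemap, config.window)
        write_cohort(cohort, attrition, out)
        summary["cohort_size"] = len(cohort)
        summary["attrition"] = attrition
    except Exception as exc:
        raise StageError(f"{name}: {exc}") from exc

    name = stage("estimate-params")
    try:
        events = detect_events(cohort, dataset.visits)
        incidence = estimate_incidence(cohort, events)
        fatality = estimate_fatality(events, dataset.patients)
        write_estimates(incidence, fatality, out)
    except Exception as exc:
        raise StageError(f"{name}: {exc}") from exc

    name = stage("run-base-case")
    try:
        mp = parameters_from_config(config)
        if mp is None:
            mp = parameters_from_estimates(
                incidence, fatality,
                settings=config.settings,
                post_event_costs=config.post_event_costs,
            )
            mp = ModelParameters(
                settings=mp.settings,
                incidence=mp.incidence,
                fatality=mp.fatality,
                drug_utilities=config.drug_utilities,
                event_utilities=config.event_utilities,
                medication_costs=config.medication_costs,
                event_costs=config.event_costs,
                post_event_costs=config.post_event_costs,
                fatality_counts=mp.fatality_counts,
                incidence_counts=mp.incidence_counts,
            )
        base_case, traces = run_base_case(mp.strategies(), mp.settings, mp.reference)
        base_case.to_csv(out / "base_case.csv", index=False)
        for drug, trace in traces.items():
            trace.to_frame().to_csv(out / f"trace_{drug}.csv", index=False)
        summary["base_case"] = base_case.to_dict("records")
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"{name}: {exc}") from exc

    name = stage("run-psa")
    try:
        dists = build_distributions(
            mp,
            cost_cv=config.psa_cost_cv,
            event_utility_cv=config.psa_event_utility_cv,
            drug_utility_cv=config.psa_drug_utility_cv,
        )
        n_iter = psa_n_iter if psa_n_iter is not None else config.psa_n_iter
        psa = run_psa(mp, dists, n_iter=n_iter, seed=seeds["psa"])
        psa.iterations.to_csv(out / "psa_iterations.csv", index=False)
        psa.summary.to_csv(out / "psa_summary.csv", index=False)
        ceac_table = ceac(psa.iterations, reference=mp.reference)
        ceac_table.to_csv(out / "ceac.csv", index=False)
        scatter_table(psa).to_csv(out / "scatter.csv", index=False)
        summary["psa_rejected_draws"] = psa.rejected_draws
        summary["p_cost_effective_at_wtp"] = psa.probability_cost_effective().to_dict()
    except Exception as exc:
        raise StageError(f"{name}: {exc}") from exc

    name = stage("run-dsa")
    try:
        tornado = one_way_dsa(mp, dists, reference=mp.reference)
        tornado.to_csv(out / "tornado.csv", index=False)
    except Exception as exc:
        raise StageError(f"{name}: {exc}") from exc

    manifest = {
        "package": "afcea",
        "version": __version__,
        "seed": seed,
        "stage_seeds": seeds,
        "config_hash": config.config_hash(),
        "outputs": sorted(
            p.name for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    summary["manifest"] = manifest
    return summary
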