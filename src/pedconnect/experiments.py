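"""Replicated simulation experiments: parameter recovery and error control.

These drive the full inference chain (simulate → assign at posterior > 0.95 →
pedigree → connectivity / fitness) on reduced-size populations and compare
the estimates against the generating parameters:

* **connectivity recovery** — does the estimated between-patch rate sit
  inside the exact binomial 95% CI of the configured pollen migration
  probability ``m_pollen``?
* **fitness recovery** — with a migrant fecundity multiplier of 2, does the
  negative-binomial rate ratio land near 2?
* **false-triad control** — with every parent sampled, what fraction of
  retained triads is not the true parent pair?
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import demofit
from .connectivity import connectivity_stats, events_from_pedigree, events_to_frame
from .genotype_io import qc_filter, records_to_frame
from .parentage import AssignmentConfig, assign_parents
from .pedigree import PedigreeGraph
from .simdata import SimConfig, simulate

logger = logging.getLogger(__name__)

#: reduced-population replicate settings: ~1,000 plants per replicate keeps a
#: replicate around a second while leaving hundreds of triads; the per-patch
#: cap bounds the stochastic growth so replicate sizes stay comparable
REPLICATE_SIM = dict(founders_per_patch=10, n_years=10, capacity_per_patch=40)


def _run_chain(sim_kwargs: dict, seed: int, assignment: AssignmentConfig | None = None):
    cfg = SimConfig(rng_seed=seed, **sim_kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        genotypes, records, truth = simulate(cfg)
    rec = records_to_frame(records)
    g, _ = qc_filter(genotypes)
    rec = rec.loc[g.ids]
    result = assign_parents(g, rec, assignment or AssignmentConfig())
    ped = PedigreeGraph.from_assignments(result, rec)
    return cfg, g, rec, truth, result, ped


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI for a proportion."""
    alpha = 1.0 - level
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def connectivity_recovery(
    m_pollen: float,
    n_replicates: int = 50,
    seed: int = 0,
    sim_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Estimate between-patch connectivity on replicate simulations.

    One row per replicate: retained triad count, between-patch count, the
    estimated rate, the exact binomial 95% CI and whether it covers the
    configured ``m_pollen``.
    """
    sim_kwargs = dict(REPLICATE_SIM, **(sim_kwargs or {}), m_pollen=m_pollen)
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    rows = []
    for r, s in enumerate(seeds):
        *_, ped = _run_chain(sim_kwargs, int(s))
        extraction = events_from_pedigree(ped)
        report = connectivity_stats(extraction.events)
        lo, hi = clopper_pearson(report.n_between, report.n_total)
        rows.append(
            {
                "replicate": r,
                "n_triads": report.n_total,
                "n_between": report.n_between,
                "estimate": report.n_between / report.n_total,
                "ci_low": lo,
                "ci_high": hi,
                "covers_m": lo <= m_pollen <= hi,
            }
        )
        logger.debug("connectivity replicate %d: %s", r, rows[-1])
    return pd.DataFrame(rows)


def fitness_recovery(
    rate_ratio: float = 2.0,
    n_replicates: int = 50,
    seed: int = 0,
    m_pollen: float = 0.25,
    sim_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Recover the migrant/resident rate ratio from replicate simulations.

    The generator applies ``rate_ratio`` as the migrant fecundity multiplier;
    a high ``m_pollen`` keeps both status groups populated at reduced sizes.
    """
    sim_kwargs = dict(
        REPLICATE_SIM,
        founders_per_patch=12,
        **(sim_kwargs or {}),
        m_pollen=m_pollen,
        migrant_fecundity_multiplier=rate_ratio,
    )
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    rows = []
    for r, s in enumerate(seeds):
        *_, rec, truth, result, ped = _run_chain(sim_kwargs, int(s))
        events = events_to_frame(events_from_pedigree(ped).events)
        records = demofit.fitness_records(ped, events, last_years_excluded=2)
        try:
            model = demofit.fitness_model(records)
            rows.append(
                {
                    "replicate": r,
                    "n_records": len(records),
                    "n_migrant": int((records["status"] == "migrant").sum()),
                    "rate_ratio": model.rate_ratio,
                    "p_value": model.p_value,
                }
            )
        except (ValueError, demofit.ModelConvergenceError) as exc:
            logger.warning("fitness replicate %d unusable: %s", r, exc)
            rows.append(
                {
                    "replicate": r, "n_records": len(records),
                    "n_migrant": int((records["status"] == "migrant").sum()),
                    "rate_ratio": np.nan, "p_value": np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class FalseTriadReport:
    n_triads: int
    n_false: int

    @property
    def rate(self) -> float:
        return self.n_false / self.n_triads if self.n_triads else float("nan")


def false_triad_rate(
    seed: int = 0, error_rate: float = 0.01, sim_kwargs: dict | None = None
) -> FalseTriadReport:
    """Fraction of retained triads that are not the true parent pair, with
    full parental sampling and the given genotyping error rate."""
    sim_kwargs = dict(
        REPLICATE_SIM, **(sim_kwargs or {}), genotyping_error_rate=error_rate
    )
    *_, truth, result, _ = _run_chain(
        sim_kwargs, seed, AssignmentConfig(error_rate=error_rate)
    )
    triads = result.triads()
    n_false = sum(
        1
        for a in triads
        if {a.parent1, a.parent2} != set(truth.pedigree.get(a.offspring, ()))
    )
    return FalseTriadReport(n_triads=len(triads), n_false=n_false)
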