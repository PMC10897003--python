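"""Perturbation experiments over fixed-seed virtual cohorts.

Four parameter-change families model candidate disease mechanisms:

* ``gaba_weights``    -- joint scaling of the inhibitory weights J_EI and
  J_II (local GABAergic inhibition), 100% down to 60%;
* ``glut_drive_to_I`` -- scaling of J_IE (local glutamatergic drive onto
  inhibitory cells), 100% down to 60%;
* ``global_coupling`` -- scaling of K_gl (inter-regional coupling), 100%
  down to 60%;
* ``noise_level``     -- scaling of sigma_ou (global background noise),
  100% up to 140%.

A virtual cohort is a list of master seeds (default 40); the same seeds are
re-used in every condition so conditions differ only through the perturbed
parameter.  Each condition run yields per-subject connectivity/dynamics
reports that are compared to the default condition with mean differences,
Hedges' g and label-permutation p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd

from .network import (Connectome, GlobalParams, PopulationParams,
                      SimulationOutput, simulate)
from .hemodynamics import HemoParams, bold_from_rates
from .metrics import MetricsReport, Partition, metrics_report
from .stats import compare_groups, hedges_g, paired_permutation_test
from .transfer_tables import TransferTables

log = logging.getLogger(__name__)

FAMILY_RANGES = {
    "gaba_weights": (0.6, 1.0),
    "glut_drive_to_I": (0.6, 1.0),
    "global_coupling": (0.6, 1.0),
    "noise_level": (1.0, 1.4),
}

COMPARISON_MEASURES = ("gbc_global", "gbc_sensory", "gbc_association",
                       "mean_R", "metastability")

__all__ = [
    "PerturbationSpec",
    "VirtualCohort",
    "FAMILY_RANGES",
    "COMPARISON_MEASURES",
    "apply_perturbation",
    "run_condition",
    "compare_to_default",
    "evolutionary_fit",
    "make_fc_objective",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """One perturbation family with its scale factors (1.0 = reference)."""

    family: str
    scales: tuple = (1.0, 0.95, 0.9, 0.85, 0.8)
    allow_out_of_range: bool = False

    def __post_init__(self):
        if self.family not in FAMILY_RANGES:
            raise ValueError(f"unknown family '{self.family}', expected one of "
                             f"{sorted(FAMILY_RANGES)}")
        if 1.0 not in self.scales:
            raise ValueError("scales must include the reference 1.0")
        lo, hi = FAMILY_RANGES[self.family]
        if not self.allow_out_of_range:
            for s in self.scales:
                if not lo <= s <= hi:
                    raise ValueError(
                        f"scale {s} outside the {self.family} range "
                        f"[{lo}, {hi}] (pass allow_out_of_range to override)")


@dataclass
class VirtualCohort:
    """Fixed-seed virtual subjects sharing a connectome and parameters."""

    connectome: Connectome
    tables: TransferTables
    partition: Partition
    pop: PopulationParams = field(default_factory=PopulationParams)
    glob: GlobalParams = field(default_factory=GlobalParams)
    hemo: HemoParams = field(default_factory=HemoParams)
    seeds: tuple = tuple(range(40))
    TR: float = 2.0


def apply_perturbation(pop: PopulationParams, glob: GlobalParams,
                       family: str, scale: float):
    """Return (pop', glob') with the family's parameter(s) scaled."""
    if family == "gaba_weights":
        return replace(pop, J_EI=pop.J_EI * scale, J_II=pop.J_II * scale), glob
    if family == "glut_drive_to_I":
        return replace(pop, J_IE=pop.J_IE * scale), glob
    if family == "global_coupling":
        return pop, replace(glob, K_gl=glob.K_gl * scale)
    if family == "noise_level":
        return pop, replace(glob, sigma_ou=glob.sigma_ou * scale)
    raise ValueError(f"unknown family '{family}'")


def run_subject(cohort: VirtualCohort, pop: PopulationParams,
                glob: GlobalParams, seed: int) -> MetricsReport:
    out: SimulationOutput = simulate(cohort.connectome, pop, glob, seed,
                                     cohort.tables)
    bold = bold_from_rates(out.rate_E, out.output_step_ms, cohort.hemo,
                           TR_s=cohort.TR)
    return metrics_report(bold, cohort.TR, cohort.partition)


def run_condition(cohort: VirtualCohort, perturbation: PerturbationSpec | str,
                  scale: float):
    """Simulate every virtual subject under one perturbed condition.

    Returns a list of per-subject :class:`MetricsReport`.  A simulation abort
    for any seed fails the whole condition with that seed recorded.
    """
    family = perturbation.family if isinstance(perturbation, PerturbationSpec) \
        else perturbation
    spec = perturbation if isinstance(perturbation, PerturbationSpec) \
        else PerturbationSpec(family=family, scales=(1.0, scale)
                              if scale != 1.0 else (1.0,))
    if scale not in spec.scales:
        raise ValueError(f"scale {scale} not declared in the perturbation spec")
    pop, glob = apply_perturbation(cohort.pop, cohort.glob, family, scale)
    reports = []
    for seed in cohort.seeds:
        try:
            reports.append(run_subject(cohort, pop, glob, seed))
        except FloatingPointError as exc:
            raise RuntimeError(
                f"condition ({family}, scale={scale}) failed for virtual "
                f"subject seed={seed}: {exc}") from exc
    return reports


def compare_to_default(default_reports, condition_reports,
                       measures=COMPARISON_MEASURES, n_perm: int = 5000,
                       seed: int = 0) -> pd.DataFrame:
    """Default-vs-condition comparison rows for the headline measures.

    Emits both sign conventions explicitly: ``mean_default_minus_perturbed``
    (the table-caption convention) and ``mean_perturbed_minus_default``.
    Hedges' g is computed as default minus perturbed in pooled-SD units.
    Two permutation p-values are reported: ``p_perm`` from the two-sample
    label permutation (the published tables' convention) and
    ``p_perm_paired`` from the sign-flip test that exploits the fixed virtual
    subjects, i.e. the same noise seeds in both conditions.
    """
    rows = []
    paired = len(default_reports) == len(condition_reports)
    for m in measures:
        x = np.asarray([r.flat()[m] for r in default_reports], dtype=float)
        y = np.asarray([r.flat()[m] for r in condition_reports], dtype=float)
        cmp_ = compare_groups(x, y, measure=m, method="permutation",
                              n_perm=n_perm, seed=seed)
        rows.append({
            "measure": m,
            "mean_default_minus_perturbed": cmp_.mean_difference,
            "mean_perturbed_minus_default": -cmp_.mean_difference,
            "hedges_g": cmp_.hedges_g,
            "ci95_low": cmp_.ci95_low,
            "ci95_high": cmp_.ci95_high,
            "p_perm": cmp_.p_value,
            "p_perm_paired": paired_permutation_test(x, y, n_perm=n_perm,
                                                     seed=seed)
            if paired else np.nan,
            "n_default": cmp_.n1,
            "n_condition": cmp_.n2,
            "n_permutations": cmp_.n_permutations,
        })
    return pd.DataFrame(rows)


def evolutionary_fit(objective, bounds, n_init: int = 160, n_pop: int = 80,
                     n_gen: int = 100, seed: int = 0, maximize: bool = True):
    """Population-based evolutionary search within box bounds.

    A rank-selection (mu+lambda) evolution strategy: uniform initialization of
    ``n_init`` individuals, tournament parent selection, per-dimension
    arithmetic crossover, decaying Gaussian mutation, and elitist truncation
    to ``n_pop``.  Individuals whose objective evaluation fails are discarded
    with a log entry.  Deterministic under ``seed``.

    Returns dict with ``best_params``, ``best_value`` and ``trace`` (the
    best-so-far objective per generation).
    """
    rng = np.random.default_rng(seed)
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    ndim = len(bounds)
    sign = 1.0 if maximize else -1.0

    def evaluate(xs):
        vals = []
        ok = []
        for x in xs:
            try:
                v = float(objective(x))
            except Exception as exc:  # noqa: BLE001 - individual failure only
                log.warning("objective failed for %s: %s", x, exc)
                continue
            if not np.isfinite(v):
                log.warning("objective non-finite for %s", x)
                continue
            vals.append(sign * v)
            ok.append(x)
        return np.asarray(ok), np.asarray(vals)

    pop_x = lo + (hi - lo) * rng.random((n_init, ndim))
    pop_x, pop_v = evaluate(pop_x)
    if len(pop_x) == 0:
        raise RuntimeError("objective failed for every initial individual")
    order = np.argsort(-pop_v)[:n_pop]
    pop_x, pop_v = pop_x[order], pop_v[order]
    trace = [sign * pop_v[0]]

    for gen in range(n_gen):
        sigma = 0.2 * (hi - lo) * (0.9 ** gen)
        children = np.empty((n_pop, ndim))
        for c in range(n_pop):
            cand = rng.integers(0, len(pop_x), size=3)
            p1 = pop_x[cand[np.argmax(pop_v[cand])]]
            cand = rng.integers(0, len(pop_x), size=3)
            p2 = pop_x[cand[np.argmax(pop_v[cand])]]
            u = rng.random(ndim)
            child = u * p1 + (1.0 - u) * p2
            child = child + rng.normal(0.0, sigma)
            children[c] = np.clip(child, lo, hi)
        ch_x, ch_v = evaluate(children)
        if len(ch_x):
            all_x = np.vstack([pop_x, ch_x])
            all_v = np.concatenate([pop_v, ch_v])
            order = np.argsort(-all_v)[:n_pop]
            pop_x, pop_v = all_x[order], all_v[order]
        trace.append(sign * pop_v[0])
    return {"best_params": pop_x[0], "best_value": sign * pop_v[0],
            "trace": np.asarray(trace)}


def make_fc_objective(cohort: VirtualCohort, target_FC: np.ndarray,
                      param_names=("mu_E_ext", "sigma_ou"),
                      seed: int = 0):
    """Objective: Pearson correlation between simulated and target FC.

    ``param_names`` select which population/global parameters the optimizer
    controls; FC correlation is computed over the upper triangle.
    """
    iu = np.triu_indices(target_FC.shape[0], k=1)
    tvec = np.asarray(target_FC)[iu]

    def objective(x):
        pop, glob = cohort.pop, cohort.glob
        for name, val in zip(param_names, x):
            if hasattr(pop, name):
                pop = replace(pop, **{name: float(val)})
            elif hasattr(glob, name):
                glob = replace(glob, **{name: float(val)})
            else:
                raise ValueError(f"unknown parameter '{name}'")
        rep = run_subject(cohort, pop, glob, seed)
        svec = rep.FC[iu]
        return float(np.corrcoef(tvec, svec)[0, 1])

    return objective
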