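"""Replicated simulation studies validating estimation and screening.

These runners reproduce the two validation designs end to end: repeated
data generation, full maximum-likelihood fits, delta-method intervals, and
(for the composition design) table-wide screening with BH adjustment.
They are what the acceptance checks and the reproducibility script execute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import InteractionSpec
from .effects import EffectSpec, effects_ci
from .estimation import fit_mle
from .likelihood import QuadratureSpec
from .screen import evaluate, screen_taxa
from .simulate import (
    Setting1Config,
    Setting2Config,
    simulate_setting1,
    simulate_setting2,
    table1_params,
)

#: Analysis model of the univariate study: the abundance interaction is
#: excluded (the generating design sets it to zero and the reported
#: parameter set does not include it).
SETTING1_INTERACTIONS = InteractionSpec(indicator=True, abundance=False)

#: Analysis model of the composition screening study: no exposure-mediator
#: interaction terms (allowed by the marginal outcome model; including them
#: only inflates the effect variances under this design).
SETTING2_INTERACTIONS = InteractionSpec(indicator=False, abundance=False)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


@dataclass
class CoverageStudy:
    """Replicated-fit summary for one univariate scenario."""

    coverage_pct: dict            # effect -> % of 95% CIs covering truth
    mean_estimate: dict           # effect -> mean point estimate
    true_value: dict              # effect -> generating truth
    rel_bias_pct: dict            # effect -> 100 * (mean - truth) / truth
    empirical_se: dict
    mean_estimated_se: dict
    n_converged: int
    n_reps: int


def coverage_study(n_reps: int = 100, n: int = 200, seed: int = 0,
                   scenario: str = "low",
                   quad: QuadratureSpec = QuadratureSpec()) -> CoverageStudy:
    """Fit ``n_reps`` simulated datasets; summarize CI coverage and bias."""
    truth_params = table1_params(scenario)
    seeds = _child_seeds(seed, n_reps)
    spec = EffectSpec(x1=0.0, x2=1.0)
    effects = ("nie1", "nie2", "nie")
    covers = {e: 0 for e in effects}
    ests = {e: [] for e in effects}
    ses = {e: [] for e in effects}
    n_conv = 0
    truths = {}
    for s in seeds:
        data, _, true_eff = simulate_setting1(
            Setting1Config(n=n, seed=int(s), params=truth_params))
        if not truths:
            truths = {e: true_eff[e].estimate for e in effects}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = fit_mle(data, quad=quad, interactions=SETTING1_INTERACTIONS)
        if not fit.converged:
            continue
        try:
            est = effects_ci(fit, spec)
        except Exception:
            continue
        n_conv += 1
        for e in effects:
            ests[e].append(est[e].estimate)
            ses[e].append(est[e].se)
            if est[e].ci_low <= truths[e] <= est[e].ci_high:
                covers[e] += 1
    return CoverageStudy(
        coverage_pct={e: 100.0 * covers[e] / n_conv for e in effects},
        mean_estimate={e: float(np.mean(ests[e])) for e in effects},
        true_value=truths,
        rel_bias_pct={e: 100.0 * (float(np.mean(ests[e])) - truths[e])
                      / truths[e] for e in effects},
        empirical_se={e: float(np.std(ests[e], ddof=1)) for e in effects},
        mean_estimated_se={e: float(np.mean(ses[e])) for e in effects},
        n_converged=n_conv, n_reps=n_reps,
    )


@dataclass
class ScreeningStudy:
    """Aggregated confusion counts over replicated composition screens."""

    counts: dict                  # effect -> dict(tp, fp, tn, fn)
    recall: dict
    precision: dict
    f1: dict
    mean_relative_abundance: np.ndarray
    n_reps: int

    @staticmethod
    def _rates(tp, fp, fn):
        recall = tp / (tp + fn) if (tp + fn) else float("nan")
        precision = 1.0 if fp == 0 else tp / (tp + fp)
        f1 = (2 * recall * precision / (recall + precision)
              if (recall + precision) else float("nan"))
        return recall, precision, f1


def screening_study(n_reps: int = 100, n: int = 200, seed: int = 0,
                    fdr: float = 0.20,
                    quad: QuadratureSpec = QuadratureSpec()) -> ScreeningStudy:
    """Screen ``n_reps`` five-taxon composition datasets at the target FDR."""
    seeds = _child_seeds(seed, n_reps)
    spec = EffectSpec(x1=0.0, x2=1.0)
    agg = {e: {"tp": 0, "fp": 0, "tn": 0, "fn": 0} for e in ("nie1", "nie2")}
    ra_sum = None
    n_obs = 0
    for s in seeds:
        comp, y, x, lib, labels = simulate_setting2(
            Setting2Config(n=n, seed=int(s)))
        ra_sum = comp.sum(axis=0) if ra_sum is None else ra_sum + comp.sum(axis=0)
        n_obs += comp.shape[0]
        res = screen_taxa(comp, y, x, lib, spec, fdr=fdr, quad=quad,
                          interactions=SETTING2_INTERACTIONS)
        report = evaluate(res, labels)
        for e in ("nie1", "nie2"):
            agg[e]["tp"] += report[e].tp
            agg[e]["fp"] += report[e].fp
            agg[e]["tn"] += report[e].tn
            agg[e]["fn"] += report[e].fn
    recall, precision, f1 = {}, {}, {}
    for e, c in agg.items():
        recall[e], precision[e], f1[e] = ScreeningStudy._rates(
            c["tp"], c["fp"], c["fn"])
    return ScreeningStudy(counts=agg, recall=recall, precision=precision,
                          f1=f1, mean_relative_abundance=ra_sum / n_obs,
                          n_reps=n_reps)


__all__ = ["CoverageStudy", "ScreeningStudy", "coverage_study",
           "screening_study", "SETTING1_INTERACTIONS", "SETTING2_INTERACTIONS"]
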