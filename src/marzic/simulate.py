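"""Synthetic-data generators for validating the mediation model.

Two designs are provided.

**Setting 1 (univariate ZIB).**  A single taxon's relative abundance is
drawn from the zero-inflated Beta model itself, the outcome from the linear
outcome model using the TRUE latent abundance, and the observed abundance
passes through the limit-of-detection (LOD) rule: a value is recorded as
zero whenever its expected read count ``M * L`` falls below one read.
False zeros therefore corrupt only the observed mediator, which is exactly
the situation in which methods that ignore detection failure become biased.
Library sizes default to log-uniform draws over the range 31,607-911,652
reads; an empirical list of depths can be supplied instead.

**Setting 2 (zero-inflated Dirichlet-multinomial).**  A full composition is
generated per subject: presence indicators for designated zero-inflated
taxa (logit-linked in exposure), a Dirichlet draw over the present taxa,
multinomial read counts at the library size, and relative abundances as
counts over depth.  An absent taxon's concentration mass is absorbed by a
designated "absorber" taxon (taxon 1 by default), so that the marginal
mean abundances of all remaining taxa are exactly unaffected by the
exposure; only the absorber and the exposure-linked taxa mediate.  The
outcome depends on the first two taxa (abundance of both, presence of the
second, and exposure interactions).

Also provided is the marginal-coefficient identity for the no-zeros
Dirichlet outcome model, used as a property-test utility: the coefficients
of the regression of Y on a single taxon are closed-form functions of the
full-model coefficients and Dirichlet means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core import (
    MediationDataset,
    ModelParams,
    OutcomeParams,
    ZIBParams,
)
from .effects import EffectEstimates, EffectSpec, effects_point

#: Library-size range printed for the motivating mouse study.
DEFAULT_LIB_RANGE = (31607, 911652)


def table1_params(scenario: str = "low") -> ModelParams:
    """Generating truth for the two setting-1 scenarios.

    ``low`` gives a rare taxon (mean positive abundance ~0.0025, subject to
    LOD false zeros); ``high`` an abundant one (mean positive abundance
    ~0.27-0.35, never below detection).
    """
    if scenario not in ("low", "high"):
        raise ValueError("scenario must be 'low' or 'high'")
    alpha0 = -6.20 if scenario == "low" else -1.00
    return ModelParams(
        outcome=OutcomeParams(beta0=-2.0, beta1=100.0, beta2=4.0,
                              beta3=5.0, beta4=3.0, beta5=0.0, delta=1.0),
        mediator=ZIBParams(alpha0=alpha0, alpha1=0.40, phi=50.0,
                           gamma0=-1.16, gamma1=-0.50),
    )


def apply_lod(m_true, lib_size):
    """Limit-of-detection rule: observe 0 whenever ``m_true * L < 1``.

    Accepts scalars or arrays; a true zero stays zero for any depth.
    """
    m = np.asarray(m_true, dtype=float)
    L = np.asarray(lib_size, dtype=float)
    out = np.where(m * L < 1.0, 0.0, m)
    if out.ndim == 0:
        return float(out)
    return out


def _draw_lib_sizes(rng: np.random.Generator, n: int,
                    lib_size_range: tuple[int, int],
                    lib_size_mode: str,
                    lib_sizes: Optional[Sequence[int]]) -> np.ndarray:
    if lib_size_mode == "log-uniform":
        lo, hi = lib_size_range
        if not (0 < lo <= hi):
            raise ValueError("library-size range must be positive and ordered")
        return np.floor(np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)))
    if lib_size_mode == "empirical-list":
        if lib_sizes is None or len(lib_sizes) == 0:
            raise ValueError("lib_size_mode='empirical-list' requires lib_sizes")
        return np.asarray(lib_sizes, float)[rng.integers(0, len(lib_sizes), n)]
    raise ValueError(f"unknown lib_size_mode {lib_size_mode!r}")


@dataclass
class Setting1Config:
    """Univariate ZIB design: exposure Bernoulli(0.5), LOD false zeros."""

    n: int = 200
    params: ModelParams = field(default_factory=table1_params)
    lib_size_range: tuple[int, int] = DEFAULT_LIB_RANGE
    lib_size_mode: str = "log-uniform"
    lib_sizes: Optional[Sequence[int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")


def simulate_setting1(
    cfg: Setting1Config,
) -> tuple[MediationDataset, ModelParams, EffectEstimates]:
    """Generate one setting-1 dataset; returns (data, truth, true effects).

    The outcome uses the true latent abundance and its indicator; only the
    observed mediator is subjected to the LOD rule.
    """
    rng = np.random.default_rng(cfg.seed)
    med = cfg.params.mediator
    out = cfg.params.outcome

    x = rng.binomial(1, 0.5, size=cfg.n).astype(float)
    lib = _draw_lib_sizes(rng, cfg.n, cfg.lib_size_range,
                          cfg.lib_size_mode, cfg.lib_sizes)

    mu = expit(med.alpha0 + med.alpha1 * x)
    dz = expit(med.gamma0 + med.gamma1 * x)
    present = rng.random(cfg.n) >= dz
    m_true = np.zeros(cfg.n)
    if present.any():
        a = mu[present] * med.phi
        b = (1.0 - mu[present]) * med.phi
        m_true[present] = rng.beta(a, b)

    ind = (m_true > 0).astype(float)
    y_mean = (out.beta0 + out.beta1 * m_true + out.beta2 * ind
              + out.beta3 * x + out.beta4 * x * ind + out.beta5 * x * m_true)
    y = y_mean + out.delta * rng.standard_normal(cfg.n)

    m_obs = apply_lod(m_true, lib)
    data = MediationDataset.from_arrays(y, m_obs, lib, x)
    true_effects = effects_point(cfg.params, EffectSpec(x1=0.0, x2=1.0))
    return data, cfg.params, true_effects


# ---------------------------------------------------------------------------
# Setting 2: zero-inflated Dirichlet-multinomial composition
# ---------------------------------------------------------------------------

def five_taxon_concentrations(
    mean_targets: Sequence[float] = (0.196, 0.250, 0.220, 0.146, 0.188),
    absence_prob: tuple[float, float] = (0.28, 0.03),
    total: float = 50.0,
) -> np.ndarray:
    """Dirichlet concentrations hitting the target marginal means exactly.

    The second taxon is zero-inflated with absence probability
    ``absence_prob[x]`` at exposure ``x``; when absent, its concentration
    mass is absorbed by the first taxon (an ecological competitor filling
    the niche).  Under that mechanism the marginal means of taxa 3..K+1
    never depend on the exposure, while the first two taxa's means move in
    exact opposition: ``E[M2(x)] = pi(x)*q2`` and ``E[M1(x)] = q1 +
    (1-pi(x))*q2`` with ``pi(x)`` the presence probability.  Shares are
    solved so the exposure-averaged means equal ``mean_targets``.
    Returns one concentration vector summing to ``total``.
    """
    t = np.asarray(mean_targets, float)
    if t.size < 3:
        raise ValueError("need at least 3 taxa")
    if not np.isclose(t.sum(), 1.0, atol=1e-6):
        raise ValueError("mean targets must sum to 1")
    d0, d1 = absence_prob
    pi_bar = 1.0 - 0.5 * (d0 + d1)
    q2 = t[1] / pi_bar          # present-world share of the ZI taxon
    q1 = t[0] + t[1] - q2       # closure: taxon 1 holds the rest
    if q1 <= 0:
        raise ValueError("targets leave no mass for the first taxon")
    return total * np.concatenate([[q1, q2], t[2:]])


@dataclass
class Setting2Config:
    """Composition design: presence model, Dirichlet, multinomial counts.

    ``concentrations`` / ``concentrations_x1`` are the per-taxon Dirichlet
    concentrations at exposure 0 and 1 (interpolated linearly for
    intermediate exposures).  ``presence_logits`` maps zero-inflated taxon
    indices to the ``(g0, g1)`` of their absence-probability logit.  When a
    taxon is absent its concentration mass moves to ``absorber`` (set
    ``absorber=None`` to renormalize over the present taxa instead).  The
    outcome is::

        Y = b0 + b11*M1 + b12*M2 + b2*1(M2>0) + b3*X + b4*X*1(M2>0)
            + b5*X*M2 + eps,   eps ~ N(0, sigma^2)

    The defaults implement the five-taxon design of
    :func:`five_taxon_concentrations`: only the first two taxa carry an
    abundance-mediation path and only the second a presence path.
    """

    n: int = 200
    concentrations: np.ndarray = field(
        default_factory=five_taxon_concentrations)
    concentrations_x1: Optional[np.ndarray] = None
    presence_logits: dict = field(
        default_factory=lambda: {1: (float(logit(0.28)),
                                     float(logit(0.03) - logit(0.28)))})
    absorber: Optional[int] = 0
    outcome_coefficients: tuple = (1.0, 80.0, 2.0, 3.0, 1.0, 1.0, 1.0)
    sigma: float = 1.0
    lib_size_range: tuple[int, int] = DEFAULT_LIB_RANGE
    lib_size_mode: str = "log-uniform"
    lib_sizes: Optional[Sequence[int]] = None
    seed: int = 0
    max_redraws: int = 100

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, float)
        if self.concentrations_x1 is None:
            self.concentrations_x1 = self.concentrations.copy()
        self.concentrations_x1 = np.asarray(self.concentrations_x1, float)
        if np.any(self.concentrations <= 0) or np.any(self.concentrations_x1 <= 0):
            raise ValueError("concentrations must be positive")
        if self.concentrations.size < 2:
            raise ValueError("need at least 2 taxa")
        if self.concentrations_x1.shape != self.concentrations.shape:
            raise ValueError("concentrations_x1 must match concentrations")

    def concentrations_at(self, x: float) -> np.ndarray:
        return self.concentrations + x * (self.concentrations_x1
                                          - self.concentrations)


def _mean_abundances(cfg: Setting2Config, x: float) -> np.ndarray:
    """Exact marginal mean composition at exposure ``x``.

    Enumerates the presence patterns of the zero-inflated taxa (each
    pattern's Dirichlet renormalizes over the present taxa) and averages
    the conditional means.
    """
    from itertools import product as iproduct

    conc = cfg.concentrations_at(x)
    K1 = conc.size
    zi = sorted(cfg.presence_logits)
    means = np.zeros(K1)
    for pattern in iproduct([0, 1], repeat=len(zi)):
        prob = 1.0
        c = conc.copy()
        for j, absent in zip(zi, pattern):
            g0, g1 = cfg.presence_logits[j]
            dz = expit(g0 + g1 * x)
            prob *= dz if absent else 1.0 - dz
            if absent:
                if cfg.absorber is not None:
                    c[cfg.absorber] += c[j]
                c[j] = 0.0
        if c.sum() > 0:
            means += prob * c / c.sum()
    return means


def setting2_truth_labels(cfg: Setting2Config) -> pd.DataFrame:
    """Per-taxon indicators of a nonzero abundance / presence mediation path.

    The abundance path (NIE1) is active when the taxon's marginal mean
    abundance differs between the exposure levels (computed exactly by
    presence-pattern enumeration).  The presence path (NIE2) is active for
    a taxon whose presence probability depends on exposure AND whose
    presence indicator enters the outcome (the second taxon).
    """
    K1 = cfg.concentrations.size
    diff = _mean_abundances(cfg, 1.0) - _mean_abundances(cfg, 0.0)
    nie1 = np.abs(diff) > 1e-9
    nie2 = np.zeros(K1, bool)
    for j, (g0, g1) in cfg.presence_logits.items():
        if g1 != 0.0 and j == 1:
            nie2[j] = True
    return pd.DataFrame({
        "taxon": [f"taxon{j + 1}" for j in range(K1)],
        "nie1_nonzero": nie1,
        "nie2_nonzero": nie2,
    })


def simulate_setting2(
    cfg: Setting2Config,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, pd.DataFrame]:
    """Generate one composition dataset.

    Returns ``(composition, y, x, lib, labels)`` where ``composition`` is
    the n x (K+1) relative-abundance matrix derived from multinomial counts
    (rows sum to 1), and ``labels`` the per-taxon truth indicators.
    """
    rng = np.random.default_rng(cfg.seed)
    K1 = cfg.concentrations.size
    x = rng.binomial(1, 0.5, size=cfg.n).astype(float)
    lib = _draw_lib_sizes(rng, cfg.n, cfg.lib_size_range,
                          cfg.lib_size_mode, cfg.lib_sizes)

    composition = np.zeros((cfg.n, K1))
    for i in range(cfg.n):
        conc_x = cfg.concentrations_at(x[i])
        for _ in range(cfg.max_redraws):
            conc = conc_x.copy()
            for j, (g0, g1) in cfg.presence_logits.items():
                if rng.random() < expit(g0 + g1 * x[i]):
                    if cfg.absorber is not None:
                        conc[cfg.absorber] += conc[j]
                    conc[j] = 0.0
            present = conc > 0
            if present.any():
                break
        else:
            raise RuntimeError("could not draw a subject with any taxon present")
        p = np.zeros(K1)
        p[present] = rng.dirichlet(conc[present])
        counts = rng.multinomial(int(lib[i]), p)
        composition[i] = counts / lib[i]

    b0, b11, b12, b2, b3, b4, b5 = cfg.outcome_coefficients
    m1 = composition[:, 0]
    m2 = composition[:, 1]
    ind2 = (m2 > 0).astype(float)
    y = (b0 + b11 * m1 + b12 * m2 + b2 * ind2 + b3 * x
         + b4 * x * ind2 + b5 * x * m2
         + cfg.sigma * rng.standard_normal(cfg.n))
    return composition, y, x, lib, setting2_truth_labels(cfg)


# ---------------------------------------------------------------------------
# Marginal-coefficient identity for the no-zeros Dirichlet outcome model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FullModelSpec:
    """Full compositional outcome model with Dirichlet mediators.

    ``Y = sum_k betas[k]*M_k + beta_x*X + sum_k inter[k]*X*M_k + eps`` with
    ``M ~ Dirichlet(dirichlet_means * dispersion)``.
    """

    betas: tuple
    inter: tuple
    beta_x: float
    dirichlet_means: tuple
    dispersion: float = 1.0

    def __post_init__(self) -> None:
        mu = np.asarray(self.dirichlet_means, float)
        if not np.isclose(mu.sum(), 1.0, atol=1e-8):
            raise ValueError("dirichlet_means must sum to 1")
        if len(self.betas) != mu.size or len(self.inter) != mu.size:
            raise ValueError("betas/inter must match dirichlet_means length")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive")


def marginal_coeffs(spec: FullModelSpec, j: int) -> tuple[float, float, float, float]:
    """Marginal regression coefficients of Y on taxon ``j`` (1-based).

    Because the composition closes to 1, the full model implies a
    single-taxon marginal association with closed-form coefficients:
    the intercept is the concentration-weighted mean of the other taxa's
    coefficients, the taxon slope the excess of its own coefficient over
    that mean, and similarly for the exposure and interaction terms.
    """
    mu = np.asarray(spec.dirichlet_means, float)
    betas = np.asarray(spec.betas, float)
    inter = np.asarray(spec.inter, float)
    K1 = mu.size
    if not (1 <= j <= K1):
        raise ValueError(f"taxon index must lie in 1..{K1}, got {j}")
    k = j - 1
    others = np.arange(K1) != k
    denom = mu[others].sum()
    if denom == 0:
        raise ValueError("remaining Dirichlet mass is zero")
    b0s = float(betas[others] @ mu[others] / denom)
    b1s = float(betas[k] - b0s)
    wmean_inter = float(inter[others] @ mu[others] / denom)
    b2s = float(spec.beta_x + wmean_inter)
    b3s = float(inter[k] - wmean_inter)
    return b0s, b1s, b2s, b3s


# ---------------------------------------------------------------------------
# Plain-text writers
# ---------------------------------------------------------------------------

def write_feature_table(path, composition: np.ndarray,
                        taxa: Optional[Sequence[str]] = None,
                        samples: Optional[Sequence[str]] = None) -> None:
    """Write a samples x taxa relative-abundance TSV."""
    n, K1 = composition.shape
    taxa = list(taxa) if taxa is not None else [f"taxon{j+1}" for j in range(K1)]
    samples = (list(samples) if samples is not None
               else [f"sample{i+1}" for i in range(n)])
    df = pd.DataFrame(composition, index=pd.Index(samples, name="sample_id"),
                      columns=taxa)
    df.to_csv(path, sep="\t")


def write_metadata(path, y: np.ndarray, x: np.ndarray, lib: np.ndarray,
                   samples: Optional[Sequence[str]] = None) -> None:
    """Write the per-sample metadata TSV (outcome, exposure, library size)."""
    n = len(y)
    samples = (list(samples) if samples is not None
               else [f"sample{i+1}" for i in range(n)])
    pd.DataFrame({
        "sample_id": samples,
        "outcome": y,
        "exposure": x,
        "lib_size": np.asarray(lib, int),
    }).to_csv(path, sep="\t", index=False)


def write_truth_labels(path, labels: pd.DataFrame) -> None:
    labels.to_csv(path, sep="\t", index=False)


__all__ = [
    "DEFAULT_LIB_RANGE", "table1_params", "apply_lod",
    "Setting1Config", "simulate_setting1",
    "Setting2Config", "simulate_setting2", "setting2_truth_labels",
    "FullModelSpec", "marginal_coeffs",
    "write_feature_table", "write_metadata", "write_truth_labels",
]
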