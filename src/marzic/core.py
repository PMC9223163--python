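"""Domain types, link functions and the zero-inflated Beta (ZIB) density.

The mediator model for a single taxon's relative abundance M is a mixture of
a point mass ``Delta`` at zero (absence) and a ``Beta(mu*phi, (1-mu)*phi)``
distribution on (0, 1) (abundance when present).  Both mixture parameters are
linked to the exposure X on the logit scale::

    logit(mu)    = alpha0 + alpha1 * X
    logit(Delta) = gamma0 + gamma1 * X

The continuous outcome Y follows a linear model in the mediator, its
presence indicator, the exposure and their interactions::

    Y = b0 + b1*M + b2*1(M>0) + b3*X + b4*X*1(M>0) + b5*X*M + eps,
    eps ~ N(0, delta^2)

with ``delta`` a residual standard deviation.  Everything downstream
(likelihood, estimation, effect decomposition, screening) consumes the types
defined here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import betaln, expit

#: Canonical parameter ordering used everywhere a flat vector is needed
#: (gradients, observed information, delta-method covariance).
PARAM_NAMES: tuple[str, ...] = (
    "beta0", "beta1", "beta2", "beta3", "beta4", "beta5",
    "delta", "alpha0", "alpha1", "phi", "gamma0", "gamma1",
)

N_PARAMS = len(PARAM_NAMES)

#: Index of each parameter in the canonical ordering.
PARAM_INDEX = {name: i for i, name in enumerate(PARAM_NAMES)}

# Clamp for relative abundances at the upper edge of the Beta support.
_M_UPPER_CLAMP = 1.0 - 1e-10


class MarzicError(Exception):
    """Base class for errors raised by this package."""


@dataclass(frozen=True)
class ZIBParams:
    """Marginal mediator model: logit-linked mean, zero probability, dispersion.

    Parameters
    ----------
    alpha0, alpha1
        Intercept and exposure slope of the logit link for the Beta mean.
    gamma0, gamma1
        Intercept and exposure slope of the logit link for the point mass
        at zero (probability of structural absence).
    phi
        Beta dispersion (precision); the Beta shape parameters are
        ``mu*phi`` and ``(1-mu)*phi``.  Must be positive.
    """

    alpha0: float
    alpha1: float
    gamma0: float
    gamma1: float
    phi: float

    def __post_init__(self) -> None:
        if not self.phi > 0:
            raise ValueError(f"phi must be > 0, got {self.phi}")

    def mu(self, x: float) -> float:
        return float(expit(self.alpha0 + self.alpha1 * x))

    def delta_zero(self, x: float) -> float:
        return float(expit(self.gamma0 + self.gamma1 * x))


@dataclass(frozen=True)
class OutcomeParams:
    """Coefficients of the outcome regression and its residual scale.

    ``beta0..beta5`` multiply ``(1, M, 1(M>0), X, X*1(M>0), X*M)``;
    ``delta`` is the residual standard deviation (> 0).
    """

    beta0: float
    beta1: float
    beta2: float
    beta3: float
    beta4: float
    beta5: float
    delta: float

    def __post_init__(self) -> None:
        if not self.delta > 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")

    @property
    def betas(self) -> np.ndarray:
        return np.array(
            [self.beta0, self.beta1, self.beta2, self.beta3, self.beta4, self.beta5]
        )


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set: outcome regression plus ZIB mediator model.

    The flat-vector representation follows :data:`PARAM_NAMES`
    (beta0..beta5, delta, alpha0, alpha1, phi, gamma0, gamma1) and is stable
    across fitting, observed-information and delta-method computations.
    """

    outcome: OutcomeParams
    mediator: ZIBParams

    def to_vector(self) -> np.ndarray:
        o, m = self.outcome, self.mediator
        return np.array(
            [o.beta0, o.beta1, o.beta2, o.beta3, o.beta4, o.beta5, o.delta,
             m.alpha0, m.alpha1, m.phi, m.gamma0, m.gamma1]
        )

    @staticmethod
    def from_vector(theta: Sequence[float]) -> "ModelParams":
        t = np.asarray(theta, dtype=float)
        if t.shape != (N_PARAMS,):
            raise ValueError(f"expected length-{N_PARAMS} vector, got shape {t.shape}")
        return ModelParams(
            outcome=OutcomeParams(*t[:7]),
            mediator=ZIBParams(alpha0=t[7], alpha1=t[8], phi=t[9],
                               gamma0=t[10], gamma1=t[11]),
        )


@dataclass(frozen=True)
class InteractionSpec:
    """Which exposure-by-mediator interaction terms enter the outcome model.

    ``indicator`` toggles ``beta4`` (X * presence indicator), ``abundance``
    toggles ``beta5`` (X * relative abundance).  A disabled term has its
    coefficient fixed at 0 and is removed from the information matrix.
    """

    indicator: bool = True
    abundance: bool = True

    @staticmethod
    def from_keyword(kw: str) -> "InteractionSpec":
        table = {
            "both": InteractionSpec(True, True),
            "indicator": InteractionSpec(True, False),
            "abundance": InteractionSpec(False, True),
            "none": InteractionSpec(False, False),
        }
        try:
            return table[kw]
        except KeyError:
            raise ValueError(
                f"unknown interaction keyword {kw!r}; expected one of {sorted(table)}"
            ) from None


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's observed data for a single taxon.

    ``m_obs`` is the observed relative abundance (0 when the taxon is not
    detected), ``r`` its presence indicator, ``lib_size`` the sequencing
    depth and ``x`` the exposure.  ``r == 1`` exactly when ``m_obs > 0``.
    """

    y: float
    m_obs: float
    r: int
    lib_size: float
    x: float

    def __post_init__(self) -> None:
        if self.m_obs < 0:
            raise ValueError(f"m_obs must be >= 0, got {self.m_obs}")
        if self.m_obs >= 1.0:
            warnings.warn(
                "relative abundance >= 1 clamped to the Beta support",
                RuntimeWarning, stacklevel=2,
            )
            object.__setattr__(self, "m_obs", _M_UPPER_CLAMP)
        if self.r != (1 if self.m_obs > 0 else 0):
            raise ValueError(
                f"presence indicator r={self.r} inconsistent with m_obs={self.m_obs}"
            )
        if not self.lib_size > 0:
            raise ValueError(f"lib_size must be positive, got {self.lib_size}")


@dataclass
class MediationDataset:
    """Aligned observations (y, m*, r, L, x) for one taxon.

    ``context`` optionally carries the full n x (K+1) relative-abundance
    matrix the taxon was taken from; rows must sum to 1 within 1e-6.
    """

    records: list[SubjectRecord]
    context: Optional[np.ndarray] = None
    taxon: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise ValueError("dataset must contain at least one record")
        if self.context is not None:
            ctx = np.asarray(self.context, dtype=float)
            sums = ctx.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError("composition rows must sum to 1 within 1e-6")
            self.context = ctx

    def __len__(self) -> int:
        return len(self.records)

    @staticmethod
    def from_arrays(
        y: Sequence[float],
        m_obs: Sequence[float],
        lib_size: Sequence[float],
        x: Sequence[float],
        context: Optional[np.ndarray] = None,
        taxon: Optional[str] = None,
    ) -> "MediationDataset":
        y = np.asarray(y, float)
        m = np.asarray(m_obs, float)
        L = np.asarray(lib_size, float)
        x = np.asarray(x, float)
        if not (y.shape == m.shape == L.shape == x.shape):
            raise ValueError("y, m_obs, lib_size, x must have equal lengths")
        recs = [
            SubjectRecord(y=float(yi), m_obs=float(mi), r=int(mi > 0),
                          lib_size=float(Li), x=float(xi))
            for yi, mi, Li, xi in zip(y, m, L, x)
        ]
        return MediationDataset(records=recs, context=context, taxon=taxon)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (y, m_obs, r, lib_size, x) as flat float arrays."""
        n = len(self.records)
        out = np.empty((5, n))
        for i, rec in enumerate(self.records):
            out[:, i] = (rec.y, rec.m_obs, rec.r, rec.lib_size, rec.x)
        y, m, r, L, x = out
        return y, m, r, L, x


# ---------------------------------------------------------------------------
# Elementary model functions
# ---------------------------------------------------------------------------

def zib_moments(params: ZIBParams, x: float) -> tuple[float, float, float, float]:
    """Moments of the ZIB mediator at exposure ``x``.

    Returns ``(mu, delta_zero, mean_m, prob_positive)`` where ``mu`` is the
    Beta mean of the positive part, ``delta_zero`` the point mass at zero,
    ``prob_positive = 1 - delta_zero`` and
    ``mean_m = prob_positive * mu`` the overall mean including the point
    mass.
    """
    mu = params.mu(x)
    dz = params.delta_zero(x)
    prob_pos = 1.0 - dz
    return mu, dz, prob_pos * mu, prob_pos


def beta_logpdf(m: np.ndarray | float, mu: np.ndarray | float,
                phi: float) -> np.ndarray | float:
    """Log-density of Beta(mu*phi, (1-mu)*phi) at ``m`` in (0, 1)."""
    a = mu * phi
    b = (1.0 - mu) * phi
    return (a - 1.0) * np.log(m) + (b - 1.0) * np.log1p(-m) - betaln(a, b)


def zib_logpdf(m: float, params: ZIBParams, x: float) -> float:
    """Log-density of the ZIB mixture at ``m`` in [0, 1).

    Returns ``log Delta(x)`` at ``m == 0`` and
    ``log(1 - Delta(x)) + Beta log-density`` for positive ``m``.
    """
    if not (0.0 <= m < 1.0):
        raise ValueError(f"m must lie in [0, 1), got {m}")
    dz = params.delta_zero(x)
    if m == 0.0:
        with np.errstate(divide="ignore"):
            return float(np.log(dz))
    mu = params.mu(x)
    with np.errstate(divide="ignore"):
        return float(np.log1p(-dz) + beta_logpdf(m, mu, params.phi))


def outcome_mean(params: OutcomeParams, m: float, x: float) -> float:
    """Mean outcome ``b0 + b1*m + b2*1(m>0) + b3*x + b4*x*1(m>0) + b5*x*m``."""
    if not (0.0 <= m < 1.0):
        raise ValueError(f"m must lie in [0, 1), got {m}")
    ind = 1.0 if m > 0 else 0.0
    return (params.beta0 + params.beta1 * m + params.beta2 * ind
            + params.beta3 * x + params.beta4 * x * ind + params.beta5 * x * m)


def free_param_mask(
    has_zeros: bool, interactions: InteractionSpec = InteractionSpec()
) -> np.ndarray:
    """Boolean mask over :data:`PARAM_NAMES` selecting the free parameters.

    When the data contain no observed zeros the zero-model is not
    identifiable; ``gamma0, gamma1`` and the indicator-linked coefficients
    ``beta2, beta4`` are dropped.  Interaction toggles additionally fix
    ``beta4`` and/or ``beta5`` at zero.
    """
    mask = np.ones(N_PARAMS, dtype=bool)
    if not interactions.indicator:
        mask[PARAM_INDEX["beta4"]] = False
    if not interactions.abundance:
        mask[PARAM_INDEX["beta5"]] = False
    if not has_zeros:
        for name in ("beta2", "beta4", "gamma0", "gamma1"):
            mask[PARAM_INDEX[name]] = False
    return mask


__all__ = [
    "PARAM_NAMES", "PARAM_INDEX", "N_PARAMS", "MarzicError",
    "ZIBParams", "OutcomeParams", "ModelParams", "InteractionSpec",
    "SubjectRecord", "MediationDataset",
    "zib_moments", "zib_logpdf", "beta_logpdf", "outcome_mean",
    "free_param_mask",
]
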