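"""Equilibrium isolation-with-migration theory for rate mixing.

Two haploid populations of size ``N`` exchange genes at rate ``m`` per
lineage per generation and accumulate substitutions at population-specific
rates ``mu1`` and ``mu2``.  At migration-drift equilibrium the relative
divergence is ``FST = 1/(1 + 4Nm)``, and the observed rate ratio ``r``
(ratio of expected derived-allele counts exclusive to each lineage of a
cross-population pair) is a function of ``FST`` parameterized singly by the
true rate ratio ``r0 = mu2/mu1``:

    r = (1 + r0 + FST*(r0 - 1)) / (1 + r0 - FST*(r0 - 1))

This module provides that relation, the 6-state pair coalescent generator it
derives from, sojourn-time computations by three independent routes, the
recurrent-mutation corrections that bias the D3/D4 site-pattern statistics,
and weighted least-squares estimation of ``r0`` from binned (FST, r) data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad_vec
from scipy.linalg import expm
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "IMParameters",
    "SojournTimes",
    "RecurrentMutationParams",
    "RateFit",
    "PAIR_STATES",
    "fst_equilibrium",
    "m_from_fst",
    "rate_matrix",
    "sojourn_times",
    "r_from_fst",
    "fst_linear_approx",
    "r_from_sojourn",
    "d3_observed",
    "d4_observed",
    "fit_r0",
]

#: State order of the pair coalescent chain: lineage locations left/right of
#: the bar denote population 1/2; 0 marks the coalesced pair.
PAIR_STATES = ("1|2", "2|1", "12|", "|12", "0|", "|0")


@dataclass(frozen=True)
class IMParameters:
    """Parameters of the equilibrium two-population IM model.

    N : haploid population size (both populations)
    m : per-generation, per-lineage gene-flow rate
    mu1, mu2 : substitution rates in populations 1 and 2
    """

    N: float
    m: float
    mu1: float = 1.0
    mu2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("N", "m", "mu1", "mu2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def r0(self) -> float:
        return self.mu2 / self.mu1

    @property
    def fst(self) -> float:
        return fst_equilibrium(self.N, self.m)


@dataclass(frozen=True)
class SojournTimes:
    """Expected pre-coalescence sojourn times S_{i|j} of a cross-population pair.

    ``s_ij`` is the expected time the (uncoalesced) lineage sampled in
    population j spends in population i, integrated to infinity.
    """

    s11: float
    s22: float
    s12: float
    s21: float

    def as_array(self) -> np.ndarray:
        return np.array([[self.s11, self.s12], [self.s21, self.s22]])


def fst_equilibrium(N: float, m: float) -> float:
    """Equilibrium relative divergence of the symmetric two-deme IM model."""
    if N <= 0 or m <= 0:
        raise ValueError("N and m must be positive")
    return 1.0 / (1.0 + 4.0 * N * m)


def m_from_fst(fst: float, N: float) -> float:
    """Gene-flow rate giving equilibrium divergence ``fst`` (inverse of Eq. above)."""
    if not 0 < fst < 1:
        raise ValueError("fst must be in (0, 1)")
    return (1.0 - fst) / (4.0 * N * fst)


def rate_matrix(N: float, m: float) -> np.ndarray:
    """Generator A of the 6-state pair chain (columns sum to zero; dp/dt = A p).

    States ordered as :data:`PAIR_STATES`.  Migration moves one lineage at
    rate m; a co-located pair coalesces at rate 1/N, after which the single
    surviving lineage keeps migrating.
    """
    if N <= 0 or m <= 0:
        raise ValueError("N and m must be positive")
    c = 1.0 / N
    return np.array(
        [
            [-2 * m, 0.0, m, m, 0.0, 0.0],
            [0.0, -2 * m, m, m, 0.0, 0.0],
            [m, m, -2 * m - c, 0.0, 0.0, 0.0],
            [m, m, 0.0, -2 * m - c, 0.0, 0.0],
            [0.0, 0.0, c, 0.0, -m, m],
            [0.0, 0.0, 0.0, c, m, -m],
        ]
    )


# Indicator rows picking, among the four uncoalesced states, the states in
# which the focal lineage sits in population 1 (resp. 2), for a pair started
# in state (1|2).  These are the weight vectors of the sojourn integrals.
_W_SAME = np.array([1.0, 0.0, 0.0, 1.0])   # S_{1|1} = S_{2|2}
_W_CROSS = np.array([0.0, 1.0, 1.0, 0.0])  # S_{2|1} = S_{1|2}
_E_START = np.array([1.0, 0.0, 0.0, 0.0])  # pair sampled one per population


def _sojourn_closed(N: float, m: float) -> tuple[float, float]:
    return (1.0 + 2.0 * N * m) / (2.0 * m), float(N)


def _sojourn_linear(N: float, m: float) -> tuple[float, float]:
    # Integral of exp(B t) over [0, inf) is -inv(B) on the transient block.
    B = rate_matrix(N, m)[:4, :4]
    green = np.linalg.solve(-B, _E_START)
    return float(_W_SAME @ green), float(_W_CROSS @ green)


def _sojourn_quadrature(N: float, m: float, rtol: float = 1e-10) -> tuple[float, float]:
    B = rate_matrix(N, m)[:4, :4]
    # Tail bound from the slowest decay mode of the transient block.
    rate = -np.max(np.linalg.eigvals(B).real)
    if rate <= 0:
        raise RuntimeError("transient block is not dissipative; cannot integrate")
    horizon = -np.log(1e-14) / rate
    val, err = quad_vec(lambda t: expm(B * t) @ _E_START, 0.0, horizon, epsrel=rtol)
    if not np.all(np.isfinite(val)):
        raise RuntimeError(f"sojourn quadrature failed to converge (err={err})")
    return float(_W_SAME @ val), float(_W_CROSS @ val)


def sojourn_times(N: float, m: float, method: str = "closed") -> SojournTimes:
    """Sojourn times of the cross-population pair, by one of three routes.

    method="closed"     : S_{1|1} = (1 + 2Nm)/(2m), S_{2|1} = N
    method="linear"     : solve the transient linear system (-B)^{-1} e
    method="quadrature" : adaptive quadrature of the matrix exponential
    "numeric" is accepted as an alias for "linear".
    """
    if N <= 0 or m <= 0:
        raise ValueError("N and m must be positive")
    if method == "numeric":
        method = "linear"
    if method == "closed":
        same, cross = _sojourn_closed(N, m)
    elif method == "linear":
        same, cross = _sojourn_linear(N, m)
    elif method == "quadrature":
        same, cross = _sojourn_quadrature(N, m)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SojournTimes(s11=same, s22=same, s12=cross, s21=cross)


def r_from_fst(fst, r0: float):
    """Observed rate ratio as a function of relative divergence.

    Accepts scalar or array ``fst`` in [0, 1].  Strictly increasing in FST
    for r0 > 1 and strictly decreasing for r0 < 1.
    """
    fst = np.asarray(fst, dtype=float)
    if np.any((fst < 0) | (fst > 1)):
        raise ValueError("fst must lie in [0, 1]")
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    d = fst * (r0 - 1.0)
    out = (1.0 + r0 + d) / (1.0 + r0 - d)
    return float(out) if out.ndim == 0 else out


def fst_linear_approx(r, r0: float):
    """Small-(r0-1) linearization: FST ~= (r - 1)/(r0 - 1)."""
    if r0 == 1.0:
        raise ValueError("linear approximation undefined at r0 = 1")
    r = np.asarray(r, dtype=float)
    out = (r - 1.0) / (r0 - 1.0)
    return float(out) if out.ndim == 0 else out


def r_from_sojourn(N: float, m: float, mu1: float, mu2: float,
                   method: str = "closed") -> float:
    """Rate ratio assembled from sojourn times: (mu2 S22 + mu1 S12)/(mu1 S11 + mu2 S21).

    Algebraically identical to ``r_from_fst(1/(1+4Nm), mu2/mu1)``.
    """
    s = sojourn_times(N, m, method=method)
    return (mu2 * s.s22 + mu1 * s.s12) / (mu1 * s.s11 + mu2 * s.s21)


@dataclass(frozen=True)
class RecurrentMutationParams:
    """Recurrent-mutation model for outgroup site patterns.

    p1, p2 : per-site probabilities that outgroups O1, O2 carry a recurrent
             mutation (p2 is ignored by the 3-taxon correction)
    c      : probability a recurrent mutation re-creates the focal derived allele
    d3_true : the uncorrupted asymmetry (n1 - n2)/(n1 + n2), negative when the
              second focal lineage substitutes faster
    """

    p1: float
    c: float
    d3_true: float
    p2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "c"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 <= self.d3_true <= 1.0:
            raise ValueError("d3_true must lie in [-1, 1]")
        if self.p2 and self.p2 < self.p1:
            warnings.warn(
                "p2 < p1: recurrent mutation is usually more frequent in the "
                "more distant outgroup", stacklevel=3,
            )


def d3_observed(params: RecurrentMutationParams, approximate: bool = False) -> float:
    """Three-taxon asymmetry after recurrent mutation in the outgroup.

    Exact: D3 = D3_true * (1 - (c+1) p1) / (1 + (c-1) p1); the small-p1
    approximation is (1 - 2 c p1) * D3_true.
    """
    if approximate:
        return (1.0 - 2.0 * params.c * params.p1) * params.d3_true
    num = 1.0 - (params.c + 1.0) * params.p1
    den = 1.0 + (params.c - 1.0) * params.p1
    return params.d3_true * num / den


def d4_observed(params: RecurrentMutationParams) -> float:
    """Four-taxon asymmetry generated purely by recurrent outgroup mutation.

    D4 = D3_true * (p2 - p1)/(p2 + p1); negative whenever p2 > p1 and the
    true asymmetry is negative, i.e. a gene-flow-free route to a significant
    ABBA-BABA statistic.
    """
    if params.p1 + params.p2 <= 0:
        raise ValueError("d4_observed requires p1 + p2 > 0")
    return params.d3_true * (params.p2 - params.p1) / (params.p2 + params.p1)


@dataclass
class RateFit:
    """Result of fitting r0 to binned (FST, r) observations."""

    r0_hat: float
    se: float
    fitted: np.ndarray
    residuals: np.ndarray
    residual_norm: float
    n_bins: int
    weights: np.ndarray = field(repr=False, default=None)


def _wls_gradient(r0: float, fst: np.ndarray, r: np.ndarray, w: np.ndarray) -> float:
    # d/dr0 of sum w (r - f(fst; r0))^2, up to factor -2
    d = fst * (r0 - 1.0)
    u = 1.0 + r0 + d
    v = 1.0 + r0 - d
    f = u / v
    fprime = ((1.0 + fst) * v - (1.0 - fst) * u) / v**2
    return float(np.sum(w * (r - f) * fprime))


def fit_r0(
    fst,
    r,
    se=None,
    bounds: tuple[float, float] = (0.1, 10.0),
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
) -> RateFit:
    """Weighted least-squares fit of the r-FST curve, returning r0 and its SE.

    Weights are 1/se^2; bins with missing or zero SE receive the median
    weight (unweighted if no SEs are given).  The 1-D profile is solved by
    bisection on the normal equation (the model is monotone in r0), and the
    SE comes from bootstrap resampling over bins.
    """
    fst = np.asarray(fst, dtype=float)
    r = np.asarray(r, dtype=float)
    keep = np.isfinite(fst) & np.isfinite(r)
    fst, r = fst[keep], r[keep]
    if fst.size < 2:
        raise ValueError("need at least 2 usable (fst, r) bins")
    if np.ptp(fst) == 0:
        raise ValueError("no variation in fst across bins")
    if se is None:
        w = np.ones_like(r)
    else:
        se = np.asarray(se, dtype=float)[keep]
        with np.errstate(divide="ignore"):
            w = 1.0 / se**2
        bad = ~np.isfinite(w) | (w <= 0)
        if bad.all():
            w = np.ones_like(r)
        elif bad.any():
            w = np.where(bad, np.median(w[~bad]), w)

    def solve(fst_s, r_s, w_s):
        lo, hi = bounds
        glo = _wls_gradient(lo, fst_s, r_s, w_s)
        ghi = _wls_gradient(hi, fst_s, r_s, w_s)
        if glo == 0.0:
            return lo
        if ghi == 0.0:
            return hi
        if np.sign(glo) != np.sign(ghi):
            return brentq(_wls_gradient, lo, hi, args=(fst_s, r_s, w_s), xtol=1e-12)
        # No interior stationary point: minimize on the boundary-aware profile.
        res = minimize_scalar(
            lambda x: float(np.sum(w_s * (r_s - r_from_fst(fst_s, x)) ** 2)),
            bounds=bounds, method="bounded",
        )
        return float(res.x)

    r0_hat = solve(fst, r, w)
    fitted = r_from_fst(fst, r0_hat)
    residuals = r - fitted

    if rng is None:
        rng = np.random.default_rng(0)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, fst.size, size=fst.size)
        if np.ptp(fst[idx]) == 0:
            continue
        boots.append(solve(fst[idx], r[idx], w[idx]))
    se_hat = float(np.std(boots, ddof=1)) if len(boots) > 1 else float("nan")

    return RateFit(
        r0_hat=float(r0_hat),
        se=se_hat,
        fitted=fitted,
        residuals=residuals,
        residual_norm=float(np.sqrt(np.sum(w * residuals**2))),
        n_bins=int(fst.size),
        weights=w,
    )
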