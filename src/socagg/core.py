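"""The decomposition model core.

A litter cohort's carbon is split over five pools x(t) = (A, W, E, N, H)
(kg C m^-2) obeying the linear system

    dx/dt = M x + b,

where b is the annual litter input (kg C m^-2 yr^-1) and M is a 5x5 rate
matrix. Decomposition rates are the reference rates scaled by a
dimensionless climate modifier

    f(T, P) = exp(beta1 T + beta2 T^2) * (1 - exp(gamma P)),

with T the (annual-mean or sinusoid-resolved monthly) temperature in degC
and P the annual precipitation in metres, and — for woody litter — by a
size modifier h(d) = min(1, (1 + phi1 d + phi2 d^2)^r) that slows
decomposition of 2 cm and 10 cm material. Because climate is piecewise
constant year by year, the annual step is solved exactly with a matrix
exponential rather than by sub-annual numerical integration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .params import ParameterSet

__all__ = [
    "ClimateRecord", "SoilState", "SingularMatrixError",
    "climate_modifier", "precipitation_sensitivity", "size_modifier",
    "build_rate_matrix", "step_annual", "step_annual_with_flux",
    "steady_state",
]

MM_PER_M = 1000.0
COND_LIMIT = 1e12


class SingularMatrixError(np.linalg.LinAlgError):
    """Raised when a rate matrix is singular or numerically near-singular."""


@dataclass(frozen=True)
class ClimateRecord:
    """One year of climate input.

    ``mat`` is the mean annual temperature (degC), ``t_min``/``t_max`` the
    lowest and highest monthly mean temperatures (degC), ``precip`` the
    annual precipitation in mm.
    """

    year: int
    mat: float
    t_min: float
    t_max: float
    precip: float

    def __post_init__(self) -> None:
        if self.precip < 0:
            raise ValueError(f"negative precipitation: {self.precip}")
        if not self.t_min <= self.mat <= self.t_max:
            raise ValueError(
                f"need t_min <= mat <= t_max, got "
                f"{self.t_min}, {self.mat}, {self.t_max}"
            )


@dataclass(frozen=True)
class SoilState:
    """The five-pool carbon vector (A, W, E, N, H), kg C m^-2."""

    pools: np.ndarray

    def __post_init__(self) -> None:
        pools = np.asarray(self.pools, dtype=float)
        if pools.shape != (5,):
            raise ValueError(f"pools must be a 5-vector, got {pools.shape}")
        object.__setattr__(self, "pools", pools)

    @property
    def total(self) -> float:
        """Total stock, kg C m^-2."""
        return float(self.pools.sum())


# ---------------------------------------------------------------------------
# modifiers

def climate_modifier(climate: ClimateRecord, params: ParameterSet,
                     use_sinusoid: bool = False) -> float:
    """Dimensionless climate-dependence factor for the decomposition rates.

    With ``use_sinusoid`` the temperature response exp(beta1 T + beta2 T^2)
    is averaged over twelve monthly temperatures reconstructed from the
    annual mean and the monthly extremes with a sinusoid of amplitude
    (t_max - t_min)/2; otherwise the annual mean is used directly.
    Precipitation enters in metres.
    """
    if climate.precip < 0:
        raise ValueError("negative precipitation")
    p_m = climate.precip / MM_PER_M
    if use_sinusoid:
        months = np.arange(1, 13)
        amplitude = (climate.t_max - climate.t_min) / 2.0
        t = climate.mat + amplitude * np.sin(2 * np.pi * months / 12.0)
        t_term = float(np.mean(np.exp(params.beta1 * t + params.beta2 * t**2)))
    else:
        t = climate.mat
        t_term = float(np.exp(params.beta1 * t + params.beta2 * t**2))
    return t_term * (1.0 - float(np.exp(params.gamma * p_m)))


def climate_modifier_vec(mat, t_min, t_max, precip_mm, params: ParameterSet,
                         use_sinusoid: bool = False) -> np.ndarray:
    """Vectorized :func:`climate_modifier` over aligned climate arrays."""
    mat = np.asarray(mat, dtype=float)
    precip_mm = np.asarray(precip_mm, dtype=float)
    if np.any(precip_mm < 0):
        raise ValueError("negative precipitation")
    p_m = precip_mm / MM_PER_M
    if use_sinusoid:
        months = np.arange(1, 13)
        amplitude = (np.asarray(t_max, dtype=float)
                     - np.asarray(t_min, dtype=float)) / 2.0
        t = mat[..., None] + amplitude[..., None] * np.sin(2 * np.pi * months / 12.0)
        t_term = np.mean(np.exp(params.beta1 * t + params.beta2 * t**2), axis=-1)
    else:
        t_term = np.exp(params.beta1 * mat + params.beta2 * mat**2)
    return t_term * (1.0 - np.exp(params.gamma * p_m))


def precipitation_sensitivity(mat: float, precip_mm: float,
                              params: ParameterSet) -> float:
    """Relative precipitation sensitivity d ln f / dP (per metre).

    The factor approaches an asymptote in precipitation, so its *relative*
    response per unit precipitation is the natural measure of how sensitive
    it still is at a given P; the temperature term cancels.
    """
    p = precip_mm / MM_PER_M
    e = np.exp(params.gamma * p)
    return float(-params.gamma * e / (1.0 - e))


def size_modifier(diameter_cm: float, params: ParameterSet) -> float:
    """Woody-size modifier h(d) in (0, 1]; h(0) = 1 (non-woody litter)."""
    if diameter_cm < 0:
        raise ValueError(f"negative diameter: {diameter_cm}")
    if diameter_cm == 0:
        return 1.0
    base = 1.0 + params.size_phi1 * diameter_cm + params.size_phi2 * diameter_cm**2
    if base <= 0:
        raise ValueError(
            f"size modifier undefined at d={diameter_cm} cm for these coefficients"
        )
    return float(min(1.0, base ** params.size_r))


# ---------------------------------------------------------------------------
# rate matrix and annual stepping

def build_rate_matrix(params: ParameterSet, climate_factor: float,
                      size_factor: float = 1.0) -> np.ndarray:
    """5x5 rate matrix M (yr^-1).

    Labile rates are alpha_i * climate_factor * size_factor; the humus rate
    is alpha_h * climate_factor (woody-size features do not apply to humus).
    Column i carries -k_i on the diagonal and the mass flows k_i * p(i->j)
    off-diagonal; the column deficit is the mass lost to the atmosphere.
    """
    if not (np.isfinite(climate_factor) and np.isfinite(size_factor)):
        raise ValueError("non-finite rate modifier")
    if climate_factor < 0 or size_factor < 0:
        raise ValueError("rate modifiers must be >= 0")
    k_lab = params.alphas[:4] * climate_factor * size_factor
    k_h = params.alpha_h * climate_factor
    m = np.zeros((5, 5))
    m[:4, :4] = params.flow_fractions.T * k_lab[np.newaxis, :]
    np.fill_diagonal(m[:4, :4], -k_lab)
    m[4, :4] = params.humus_fraction * k_lab
    m[4, 4] = -k_h
    return m


def _augmented_step(matrix: np.ndarray, x: np.ndarray,
                    b: np.ndarray) -> np.ndarray:
    """x(1) = e^M x + (int_0^1 e^(M s) ds) b via one augmented exponential.

    Valid for singular and non-singular M alike (no explicit inverse).
    """
    aug = np.zeros((6, 6))
    aug[:5, :5] = matrix
    aug[:5, 5] = b
    e = expm(aug)
    return e[:5, :5] @ x + e[:5, 5]


def step_annual(state: SoilState, annual_input: np.ndarray,
                matrix: np.ndarray) -> SoilState:
    """Advance the pools one year under constant input and climate.

    Exact solution of dx/dt = M x + b over a unit time step. Off-diagonal
    entries of M are non-negative, so non-negative states stay non-negative.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("non-finite entries in rate matrix")
    b = np.asarray(annual_input, dtype=float)
    return SoilState(_augmented_step(matrix, state.pools, b))


def step_annual_with_flux(state: SoilState, annual_input: np.ndarray,
                          matrix: np.ndarray) -> tuple[SoilState, float]:
    """Annual step plus the mass exported to the atmosphere during the year.

    The export is the integrated outflux -1^T M x(s) ds, computed from the
    time-integral of the state obtained with a doubly augmented exponential;
    it closes the per-step mass balance
    ``total(t+1) - total(t) = input - export`` to machine precision.
    """
    matrix = np.asarray(matrix, dtype=float)
    b = np.asarray(annual_input, dtype=float)
    x = state.pools
    # blocks: d/ds [x, y, z] with y' = x (state integral), z' = 1
    aug = np.zeros((11, 11))
    aug[:5, :5] = matrix
    aug[:5, 5:10] = 0.0
    aug[5:10, :5] = np.eye(5)
    aug[:5, 10] = b
    e = expm(aug)
    x1 = e[:5, :5] @ x + e[:5, 10]
    x_int = e[5:10, :5] @ x + e[5:10, 10]  # int_0^1 x(s) ds
    export = float(-(matrix.sum(axis=0) @ x_int))
    return SoilState(x1), export


def steady_state(params: ParameterSet, climate_factor: float,
                 size_factor: float, annual_input: np.ndarray) -> SoilState:
    """Analytic steady state x* solving M x* + b = 0.

    Equals the long-run limit of repeated :func:`step_annual`. Raises
    :class:`SingularMatrixError` when M is singular or has condition number
    above 1e12 (e.g. a zero decomposition rate) instead of returning a
    meaningless solution.
    """
    m = build_rate_matrix(params, climate_factor, size_factor)
    if climate_factor == 0:
        raise SingularMatrixError("zero climate factor: no steady state")
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        raise SingularMatrixError(f"rate matrix ill-conditioned (cond={cond:.2e})")
    b = np.asarray(annual_input, dtype=float)
    return SoilState(np.linalg.solve(m, -b))
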