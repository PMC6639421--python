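"""Adherence chains to dosing histories to plasma concentration profiles.

Closed-form linear compartment models (one- or two-compartment disposition
with first-order absorption) are superposed over the dose times implied by a
daily adherence chain, illustrating how covariate-driven adherence patterns
translate into time below a protective plasma concentration threshold.  The
conventional threshold for plasma tenofovir is 40 ng/mL and the nominal dose
300 mg; both are configurable.

The shipped :data:`ILLUSTRATIVE_TFV_PARAMS` set is an illustrative,
tenofovir-like parameterization for demonstration and testing only — it is
not a fitted population model, and quantitative work must supply explicit
parameters (bioavailability is folded into the apparent clearance/volumes;
prodrug conversion is not modelled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError
from .markov_model import MarkovParams, transition_matrix
from .ntt_diagnostics import simulate_chain

PROTECTIVE_THRESHOLD_NG_ML = 40.0
DEFAULT_DOSE_MG = 300.0

#: Rate constants closer than this (relative) use the ka == ke limit branch.
_RATE_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class PKParams:
    """Apparent parameters of a linear oral-absorption compartment model.

    ka in 1/h; clearances in L/h; volumes in L; dose in mg.  ``q`` and ``vp``
    switch on peripheral distribution (two-compartment disposition).
    """

    ka: float
    cl_f: float
    v_f: float
    q: float | None = None
    vp: float | None = None
    dose_mg: float = DEFAULT_DOSE_MG
    illustrative: bool = False

    def __post_init__(self):
        for name in ("ka", "cl_f", "v_f", "dose_mg"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"PK parameter {name} must be > 0")
        if (self.q is None) != (self.vp is None):
            raise ConfigurationError("two-compartment form needs both q and vp")
        if self.q is not None and (self.q <= 0 or self.vp <= 0):
            raise ConfigurationError("q and vp must be > 0")

    @property
    def n_compartments(self) -> int:
        return 2 if self.q is not None else 1


#: Illustrative tenofovir-like parameter set (NOT a fitted population model).
ILLUSTRATIVE_TFV_PARAMS = PKParams(
    ka=1.0, cl_f=42.0, v_f=380.0, q=180.0, vp=560.0,
    dose_mg=DEFAULT_DOSE_MG, illustrative=True,
)


@dataclass
class DoseHistory:
    """Ordered dose times (hours from start) and amounts (mg)."""

    times: np.ndarray
    amounts: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.amounts = np.asarray(self.amounts, dtype=float)
        if self.times.shape != self.amounts.shape:
            raise DataError("dose times and amounts must be aligned")
        if len(self.times) and (np.diff(self.times) < 0).any():
            raise DataError("dose times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ConcentrationProfile:
    """Plasma concentration (ng/mL) on a strictly increasing time grid (h)."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if len(self.times) < 1 or (np.diff(self.times) <= 0).any():
            raise DataError("time grid must be non-empty and strictly increasing")
        if (self.concentrations < -1e-9).any():
            raise DataError("negative concentrations")


def chain_to_doses(chain, dose_time_of_day: float = 8.0,
                   dose_mg: float = DEFAULT_DOSE_MG) -> DoseHistory:
    """One dose at (day x 24 + dose_time_of_day) h for every state-1 day."""
    chain = np.asarray(chain)
    if chain.size == 0:
        raise DataError("empty adherence chain")
    days = np.flatnonzero(chain == 1)
    return DoseHistory(days * 24.0 + dose_time_of_day,
                       np.full(len(days), float(dose_mg)))


def _single_dose_ngml(tau: np.ndarray, dose_mg: float, p: PKParams) -> np.ndarray:
    """Concentration after one oral dose at tau >= 0 (vectorized; ng/mL)."""
    tau = np.maximum(tau, 0.0)
    ka = p.ka
    if p.n_compartments == 1:
        ke = p.cl_f / p.v_f
        if abs(ka - ke) <= _RATE_TIE_RTOL * max(ka, ke):
            c = dose_mg * ka * tau * np.exp(-ka * tau) / p.v_f
        else:
            c = (dose_mg * ka / (p.v_f * (ka - ke))
                 * (np.exp(-ke * tau) - np.exp(-ka * tau)))
    else:
        k10 = p.cl_f / p.v_f
        k12 = p.q / p.v_f
        k21 = p.q / p.vp
        ssum = k10 + k12 + k21
        disc = np.sqrt(max(ssum * ssum - 4.0 * k10 * k21, 0.0))
        alpha = (ssum + disc) / 2.0
        beta = (ssum - disc) / 2.0
        c = np.zeros_like(tau)
        # biexponential macro-coefficients; degenerate rate ties fall back to
        # the limit of the distinct-rate formula via a tiny symmetric split
        for lam_self, lam_others in ((alpha, (beta, ka)), (beta, (alpha, ka)),
                                     (ka, (alpha, beta))):
            denom = np.prod([o - lam_self for o in lam_others])
            if abs(denom) <= _RATE_TIE_RTOL * max(alpha, beta, ka) ** 2:
                raise ConfigurationError(
                    "degenerate rate constants in two-compartment model; "
                    "perturb ka/q/vp slightly")
            c = c + (k21 - lam_self) / denom * np.exp(-lam_self * tau)
        c = dose_mg * ka / p.v_f * c
    return 1000.0 * np.maximum(c, 0.0)      # mg/L -> ng/mL


def simulate_profile(doses: DoseHistory, params: PKParams,
                     grid: np.ndarray) -> ConcentrationProfile:
    """Superposition of closed-form single-dose solutions on a time grid."""
    grid = np.asarray(grid, dtype=float)
    conc = np.zeros_like(grid)
    for t0, amt in zip(doses.times, doses.amounts):
        conc += _single_dose_ngml(grid - t0, amt, params)
    return ConcentrationProfile(grid, conc)


@dataclass
class ThresholdMetrics:
    """Time-below-threshold summary of one concentration profile."""

    fraction_below: float
    longest_below_h: float
    first_below_h: float | None       # first time C drops strictly below
    first_above_h: float | None       # first time C reaches/exceeds threshold


def threshold_metrics(profile: ConcentrationProfile,
                      threshold: float = PROTECTIVE_THRESHOLD_NG_ML) -> ThresholdMetrics:
    """Interval accounting of time spent strictly below a threshold.

    The profile is treated as piecewise linear between grid points; segment
    crossings are located by interpolation.  A value exactly at the threshold
    counts as *not* below.
    """
    t, c = profile.times, profile.concentrations
    if len(t) < 2:
        below = bool(c[0] < threshold)
        return ThresholdMetrics(float(below), 0.0,
                                t[0] if below else None,
                                None if below else t[0])
    total = t[-1] - t[0]
    below_time = 0.0
    longest = 0.0
    run = 0.0
    first_below = None
    first_above = None
    if c[0] < threshold:
        first_below = float(t[0])
    else:
        first_above = float(t[0])
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c0, c1 = c[i], c[i + 1]
        b0, b1 = c0 < threshold, c1 < threshold
        if b0 and b1:
            seg_below = dt
        elif not b0 and not b1:
            seg_below = 0.0
        else:
            x = (threshold - c0) / (c1 - c0)    # crossing fraction in [0,1]
            seg_below = dt * (1.0 - x) if b1 else dt * x
            t_cross = t[i] + x * dt
            if b1 and first_below is None:
                first_below = float(t_cross)
            if not b1 and first_above is None:
                first_above = float(t_cross)
        if seg_below == dt:
            run += dt
        elif seg_below == 0.0:
            longest = max(longest, run)
            run = 0.0
        elif b1:                                # enters below mid-segment
            longest = max(longest, run)
            run = seg_below
        else:                                   # leaves below mid-segment
            run += seg_below
            longest = max(longest, run)
            run = 0.0
        below_time += seg_below
    longest = max(longest, run)
    return ThresholdMetrics(
        fraction_below=float(below_time / total) if total > 0 else 0.0,
        longest_below_h=float(longest),
        first_below_h=first_below,
        first_above_h=first_above,
    )


def covariate_profile_panel(
    params: MarkovParams,
    covariate: str,
    *,
    pk: PKParams,
    length_days: int = 30,
    dose_time_of_day: float = 8.0,
    grid_step_h: float = 0.5,
    reference: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> dict[int, dict]:
    """Typical-subject adherence chain and PK profile per covariate category.

    For each category (0 and 1 of the indicator) the typical (eta = 0)
    transition matrix is built with the covariate at that value and all other
    covariates at the reference vector (default 0), a chain of
    ``length_days`` is simulated, converted to doses, and the concentration
    profile computed.  Returns {category: {"matrix", "chain", "doses",
    "profile", "metrics"}}; dose markers are the dose times in ``doses``.
    """
    if covariate not in params.beta01 and covariate not in params.beta10:
        raise ConfigurationError(
            f"covariate {covariate!r} has no effect in the supplied parameters")
    if rng is None:
        rng = np.random.default_rng(seed)
    grid = np.arange(0.0, length_days * 24.0 + grid_step_h, grid_step_h)
    names = set(params.beta01) | set(params.beta10)
    base = {n: 0.0 for n in names}
    if reference:
        base.update(reference)
    out: dict[int, dict] = {}
    for category in (0, 1):
        cov = dict(base)
        cov[covariate] = float(category)
        matrix = transition_matrix(params, cov)
        chain = simulate_chain(matrix, length_days, initial_state=1, rng=rng)
        doses = chain_to_doses(chain, dose_time_of_day, pk.dose_mg)
        profile = simulate_profile(doses, pk, grid)
        out[category] = {
            "matrix": matrix,
            "chain": chain,
            "doses": doses,
            "profile": profile,
            "metrics": threshold_metrics(profile),
        }
    return out
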