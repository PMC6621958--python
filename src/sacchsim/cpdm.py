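"""Continuum-particle bookkeeping for the conversion distribution n(x).

A continuum particle is 1 g of solids in its initial unreacted state; a
stage's solids are represented by Lagrangian cohorts (count concentration,
conversion x), one cohort per feed event, whose conversions advance
continuously.  The total hydrolysis rate of a stage is the sum of the
modified HCH-1 rate over cohorts, each evaluated with its own substrate
concentration and conversion but with the shared stage glucose and the full
shared enzyme pool — the unique convention under which a single-cohort
system reduces exactly to the validated batch model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple

import numpy as np
from scipy.integrate import solve_ivp

from .kinetics import E_FLOOR, GX_FLOOR, KineticParameters

__all__ = [
    "GLUCAN_FRACTION",
    "HYDRATION_FACTOR",
    "ContinuumCohort",
    "ConversionDistribution",
    "cohort_substrate",
    "cohort_rates",
    "total_rate",
    "advance_distribution",
    "stage_conversion",
    "consolidate",
]

#: g glucan per g dry alpha-cellulose (compositional analysis; the remaining
#: xylan and minor components are treated as inert dry mass).
GLUCAN_FRACTION = 0.785

#: g glucose per g glucan hydrolysed (180/162; water adds mass on hydrolysis).
HYDRATION_FACTOR = 180.0 / 162.0


class ContinuumCohort(NamedTuple):
    """One cohort: ``count_conc`` particles (g initial solids) per L liquid
    at common conversion ``x``."""

    count_conc: float
    x: float


@dataclass
class ConversionDistribution:
    """Discretised conversion distribution of the solids in one vessel.

    ``counts[i]`` is the particle concentration (particle/L, numerically
    g initial solids per L liquid) of the cohort at conversion ``xs[i]``.
    """

    counts: np.ndarray
    xs: np.ndarray
    substrate_glucan_fraction: float = GLUCAN_FRACTION
    hydration_factor: float = HYDRATION_FACTOR

    def __post_init__(self) -> None:
        self.counts = np.atleast_1d(np.asarray(self.counts, dtype=float))
        self.xs = np.atleast_1d(np.asarray(self.xs, dtype=float))
        if self.counts.shape != self.xs.shape:
            raise ValueError("counts and xs must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("cohort count concentrations must be >= 0")
        if np.any((self.xs < 0) | (self.xs > 1)):
            raise ValueError("cohort conversions must lie in [0, 1]")

    @classmethod
    def from_cohorts(cls, cohorts: Iterable[ContinuumCohort],
                     **meta) -> "ConversionDistribution":
        cohorts = list(cohorts)
        return cls(np.array([c.count_conc for c in cohorts]),
                   np.array([c.x for c in cohorts]), **meta)

    @classmethod
    def empty(cls, **meta) -> "ConversionDistribution":
        return cls(np.empty(0), np.empty(0), **meta)

    @property
    def cohorts(self) -> list[ContinuumCohort]:
        return [ContinuumCohort(c, x) for c, x in zip(self.counts, self.xs)]

    @property
    def n0(self) -> float:
        """Total particle concentration (particle/L)."""
        return float(self.counts.sum())

    @property
    def substrate_concs(self) -> np.ndarray:
        """Per-cohort unreacted substrate as equivalent glucose (g/L)."""
        return (self.counts * (1.0 - self.xs)
                * self.substrate_glucan_fraction * self.hydration_factor)

    @property
    def equivalent_glucose(self) -> float:
        """Total unreacted equivalent glucose (g/L) across cohorts."""
        return float(self.substrate_concs.sum())


def cohort_substrate(cohort: ContinuumCohort,
                     dist: ConversionDistribution) -> float:
    """Unreacted substrate of one cohort as equivalent glucose (g/L)."""
    return (cohort.count_conc * (1.0 - cohort.x)
            * dist.substrate_glucan_fraction * dist.hydration_factor)


def cohort_rates(gx: np.ndarray, xs: np.ndarray, G1: float, E: float,
                 p: KineticParameters) -> np.ndarray:
    """Per-cohort hydrolysis rates (g/L per time unit), shared enzyme pool.

    The stage's cohorts compete for one enzyme pool, so the rate law's
    saturation denominator is evaluated once for the whole distribution —
    with the total substrate concentration and the substrate-weighted
    adsorption term — and the resulting rate is apportioned over cohorts by
    their reactivity-weighted substrate, kappa(x_i)*Gx_i.  A single cohort
    therefore reduces exactly to the batch rate law, and splitting a cohort
    into equal parts at the same conversion leaves the total rate unchanged.
    """
    rates = np.zeros_like(gx)
    if E <= E_FLOOR:
        return rates
    live = gx > GX_FLOOR
    gx_tot = float(gx[live].sum())
    if gx_tot <= GX_FLOOR:
        return rates
    g = gx[live]
    xv = np.clip(xs[live], 0.0, 1.0)
    kappa = p.k3 / (1.0 + xv ** p.k4) ** p.k5 + p.k6
    # substrate-weighted lumped adsorption over the distribution
    ads_shape = 1.0 / (1.0 + np.exp(-p.a2 * xv + p.a3))
    alpha = p.a1 * G1 / E * float(np.sum(g * ads_shape)) / gx_tot
    epsE = p.epsilon * E
    b = gx_tot - alpha - epsE
    phi = (b + np.sqrt(b * b + 4.0 * alpha * gx_tot)) / (2.0 * gx_tot)
    i = 1.0 / (1.0 + p.beta1 * G1)
    denom = alpha + phi * gx_tot + epsE
    rates[live] = kappa * g * E * i / denom
    return rates


def total_rate(dist: ConversionDistribution, G1: float, E: float,
               p: KineticParameters = KineticParameters()) -> float:
    """Total glucose production rate (g/L per time unit) of a stage."""
    if G1 < 0 or E < 0:
        raise ValueError("G1 and E must be >= 0")
    if dist.counts.size == 0:
        return 0.0
    return float(np.sum(cohort_rates(dist.substrate_concs, dist.xs,
                                     G1, E, p)))


def advance_distribution(dist: ConversionDistribution, G1: float, E: float,
                         E0: float, duration: float,
                         p: KineticParameters = KineticParameters(),
                         rtol: float = 1e-8, atol: float = 1e-10,
                         method: str = "LSODA",
                         ) -> tuple[ConversionDistribution, float, float]:
    """Co-integrate cohort conversions, glucose and enzyme over ``duration`` h.

    Per cohort dx/dt = (cohort rate)/(equivalent glucose per particle count),
    dG1/dt is the total rate, dE/dt follows the enzyme stability model with
    the window-fixed reference ``E0``.  Returns the advanced distribution and
    the final glucose / active-enzyme concentrations.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    live = dist.counts > 0
    counts = dist.counts[live]
    xs0 = dist.xs[live]
    gf_hf = dist.substrate_glucan_fraction * dist.hydration_factor
    eq_per_x = counts * gf_hf  # g equivalent glucose per unit conversion
    k1h, k2h = p.decay_per_hour
    hpu = p.hours_per_unit
    m = counts.size

    if m == 0:
        # no solids: enzyme still relaxes toward its decay fixed point
        enz = _decay_only(E, E0, duration, k1h, k2h)
        return replace(dist), G1, enz

    def rhs(t, y):
        x = np.clip(y[:m], 0.0, 1.0)
        g1 = max(y[m], 0.0)
        e = max(y[m + 1], 0.0)
        gx = eq_per_x * (1.0 - x)
        r = cohort_rates(gx, x, g1, e, p) / hpu  # per hour
        dx = np.where(eq_per_x > 0, r / np.where(eq_per_x > 0, eq_per_x, 1.0),
                      0.0)
        de = -k1h * e + k2h * (E0 - e) * E0
        return np.concatenate([dx, [r.sum(), de]])

    y0 = np.concatenate([xs0, [G1, E]])
    sol = solve_ivp(rhs, (0.0, duration), y0, method=method,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"distribution ODE integration failed: {sol.message}")
    yf = sol.y[:, -1]
    new_xs = dist.xs.copy()
    new_xs[live] = np.clip(yf[:m], 0.0, 1.0)
    new_dist = replace(dist, counts=dist.counts.copy(), xs=new_xs)
    return new_dist, float(max(yf[m], 0.0)), float(max(yf[m + 1], 0.0))


def _decay_only(E: float, E0: float, duration: float,
                k1h: float, k2h: float) -> float:
    """Closed-form solution of the linear decay ODE over one window."""
    if E0 <= 0 or E <= 0:
        return max(E, 0.0)
    lam = k1h + k2h * E0
    e_star = k2h * E0 ** 2 / lam
    return float(e_star + (E - e_star) * np.exp(-lam * duration))


def stage_conversion(dist: ConversionDistribution) -> float:
    """Count-weighted mean conversion of the distribution, in percent."""
    if dist.n0 <= 0:
        raise ValueError("stage conversion undefined for empty distribution")
    return float(np.average(dist.xs, weights=dist.counts) * 100.0)


def consolidate(dist: ConversionDistribution, x_tol: float = 1e-3,
                exhausted_x: float = 0.9995,
                min_frac: float = 1e-12) -> ConversionDistribution:
    """Merge near-identical cohorts, conserving particle count and mean x.

    Cohorts beyond ``exhausted_x`` collapse into one; cohorts closer than
    ``x_tol`` in conversion merge; cohorts below ``min_frac`` of the total
    count merge into their nearest neighbour.  Keeps the Lagrangian cohort
    list bounded during long runs without touching any mass ledger.
    """
    if dist.counts.size <= 1:
        return dist
    order = np.argsort(dist.xs)
    xs = dist.xs[order]
    counts = dist.counts[order]
    total = counts.sum()
    out_x: list[float] = []
    out_c: list[float] = []
    for x, c in zip(xs, counts):
        if c == 0.0:
            continue
        tiny = total > 0 and c < min_frac * total
        if out_x and (x - out_x[-1] <= x_tol
                      or min(x, out_x[-1]) >= exhausted_x or tiny):
            cs = out_c[-1] + c
            out_x[-1] = (out_x[-1] * out_c[-1] + x * c) / cs
            out_c[-1] = cs
        else:
            out_x.append(float(x))
            out_c.append(float(c))
    if not out_x:
        return replace(dist, counts=np.empty(0), xs=np.empty(0))
    return replace(dist, counts=np.array(out_c), xs=np.array(out_x))
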