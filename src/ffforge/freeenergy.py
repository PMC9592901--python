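"""Alchemical lambda schedules and Bennett Acceptance Ratio estimation.

Solvation free energies are computed by decoupling a ligand from solvent in
two legs — Coulomb interactions first (uniform lambda spacing), then van
der Waals (non-uniform spacing, denser near full decoupling) — and
estimating each adjacent-state free-energy difference with the Bennett
Acceptance Ratio (BAR).  BAR solves the self-consistent balance

    < 1 / (1 + exp[ M + beta(dU_ij - dG) ]) >_i
        = < 1 / (1 + exp[ -M + beta(dU_ji + dG) ]) >_j ,

where dU are potential-energy differences sampled in the two neighbouring
states, beta = 1/kT, and M = ln(n_i/n_j) accounts for unequal sample
counts (M = 0 for equal samples).  The left side is monotone increasing
and the right side decreasing in dG, so the root is unique whenever the
two work distributions overlap; it is found by bracketed root-finding to
1e-8 kcal/mol.  Only the estimator and schedule live here — generating the
dU samples (the MD engine's job) is out of scope, and sample files are
plain two-column text (direction, dU).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

#: Gas constant in kcal/(mol K).
R_KCAL = 0.0019872041
DEFAULT_TEMPERATURE_K = 298.0

#: Non-uniform van der Waals decoupling points (fraction decoupled).
DEFAULT_VDW_LAMBDAS = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.65, 0.7,
                       0.75, 0.8, 0.85, 0.9, 0.95, 1.0)
DEFAULT_COULOMB_STEP = 0.25


def beta_for(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Reciprocal thermal energy, mol/kcal."""
    return 1.0 / (R_KCAL * temperature_k)


# --------------------------------------------------------------------------
# Lambda schedule
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LambdaSchedule:
    coulomb: tuple[float, ...]
    vdw: tuple[float, ...]

    @property
    def n_windows(self) -> int:
        return len(self.coulomb) + len(self.vdw)

    @property
    def window_pairs(self) -> list[tuple[str, float, float]]:
        """Adjacent-state pairs per leg, each starting from the coupled state."""
        pairs = []
        prev = 0.0
        for lam in self.coulomb:
            if lam > 0.0:
                pairs.append(("coulomb", prev, lam))
            prev = lam
        prev = 0.0
        for lam in self.vdw:
            pairs.append(("vdw", prev, lam))
            prev = lam
        return pairs


def build_lambda_schedule(coulomb_step: float = DEFAULT_COULOMB_STEP,
                          vdw_values=DEFAULT_VDW_LAMBDAS) -> LambdaSchedule:
    """Default: 5 Coulomb states (0, 0.25, ..., 1) + 15 vdW = 20 windows."""
    if not (0.0 < coulomb_step <= 1.0):
        raise ValueError("coulomb_step must be in (0, 1]")
    n = int(round(1.0 / coulomb_step))
    coulomb = tuple(round(i * coulomb_step, 10) for i in range(n + 1))
    vdw = tuple(float(v) for v in vdw_values)
    if any(b <= a for a, b in zip(vdw, vdw[1:])):
        raise ValueError("vdw lambda values must be strictly increasing")
    if not vdw or abs(vdw[-1] - 1.0) > 1e-12:
        raise ValueError("vdw leg must end at 1.0")
    return LambdaSchedule(coulomb=coulomb, vdw=vdw)


# --------------------------------------------------------------------------
# BAR estimator
# --------------------------------------------------------------------------

@dataclass
class EnergyDifferenceSamples:
    """Forward dU_ij (sampled in i) and reverse dU_ji (sampled in j), kcal/mol."""

    forward: np.ndarray
    reverse: np.ndarray
    beta: float = field(default_factory=beta_for)

    def __post_init__(self):
        self.forward = np.asarray(self.forward, dtype=float).ravel()
        self.reverse = np.asarray(self.reverse, dtype=float).ravel()
        if self.forward.size == 0 or self.reverse.size == 0:
            raise ValueError("both sample directions must be non-empty")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass
class FreeEnergyResult:
    dg: float                     # kcal/mol
    standard_error: float         # kcal/mol
    windows: list = field(default_factory=list)


def _bar_imbalance(dg: float, s: EnergyDifferenceSamples, m_off: float) -> float:
    b = s.beta
    lhs = float(np.sum(expit(-(m_off + b * (s.forward - dg)))))
    rhs = float(np.sum(expit(-(-m_off + b * (s.reverse + dg)))))
    return lhs - rhs


def bar_estimate(samples: EnergyDifferenceSamples) -> FreeEnergyResult:
    """Solve the BAR self-consistency for dG with asymptotic standard error.

    Raises "insufficient overlap" when the imbalance function has no sign
    change within a wide bracket around the one-sided estimates (the two
    work distributions do not overlap).
    """
    s = samples
    b = s.beta
    n_f, n_r = s.forward.size, s.reverse.size
    m_off = math.log(n_f / n_r)

    # one-sided exponential-averaging estimates bound the search region
    dg_f = -(logsumexp(-b * s.forward) - math.log(n_f)) / b
    dg_r = (logsumexp(-b * s.reverse) - math.log(n_r)) / b
    lo, hi = min(dg_f, dg_r), max(dg_f, dg_r)
    span = max(hi - lo, 1.0)
    lo -= 10.0 * span
    hi += 10.0 * span
    f_lo, f_hi = (_bar_imbalance(x, s, m_off) for x in (lo, hi))
    tries = 0
    while f_lo * f_hi > 0 and tries < 60:
        lo -= span
        hi += span
        span *= 2.0
        f_lo, f_hi = (_bar_imbalance(x, s, m_off) for x in (lo, hi))
        tries += 1
    if f_lo * f_hi > 0:
        raise ValueError("insufficient overlap")
    dg = brentq(_bar_imbalance, lo, hi, args=(s, m_off), xtol=1e-10)

    # Bennett asymptotic variance from the Fermi weights at the solution
    f_f = expit(-(m_off + b * (s.forward - dg)))
    f_r = expit(-(-m_off + b * (s.reverse + dg)))
    if np.mean(f_f) <= 0.0 or np.mean(f_r) <= 0.0:
        # the balance underflowed to 0 = 0: distributions do not overlap
        raise ValueError("insufficient overlap")
    var = ((np.mean(f_f ** 2) / np.mean(f_f) ** 2 - 1.0) / n_f
           + (np.mean(f_r ** 2) / np.mean(f_r) ** 2 - 1.0) / n_r)
    se = math.sqrt(max(var, 0.0)) / b
    return FreeEnergyResult(dg=float(dg), standard_error=se)


def total_solvation_dg(window_results: list[FreeEnergyResult]
                       ) -> FreeEnergyResult:
    """Decoupling convention: dG_solv = -sum(window dG); errors in quadrature."""
    if not window_results:
        raise ValueError("at least one window required")
    dg = -sum(r.dg for r in window_results)
    se = math.sqrt(sum(r.standard_error ** 2 for r in window_results))
    return FreeEnergyResult(dg=dg, standard_error=se,
                            windows=list(window_results))


# --------------------------------------------------------------------------
# Synthetic work distributions and sample I/O
# --------------------------------------------------------------------------

def gaussian_work_samples(mu: float, sigma: float, n: int, seed: int,
                          beta: float | None = None) -> EnergyDifferenceSamples:
    """Fluctuation-relation-consistent Gaussian work samples.

    Forward dU ~ N(mu, sigma^2); the reverse distribution implied by the
    Crooks relation for Gaussian work is dU_ji ~ N(-mu + beta sigma^2,
    sigma^2), and the exact free energy is dG = mu - beta sigma^2 / 2.
    """
    beta = beta if beta is not None else beta_for()
    rng = np.random.default_rng(seed)
    fwd = rng.normal(mu, sigma, n)
    rev = rng.normal(-mu + beta * sigma ** 2, sigma, n)
    return EnergyDifferenceSamples(forward=fwd, reverse=rev, beta=beta)


def gaussian_true_dg(mu: float, sigma: float,
                     beta: float | None = None) -> float:
    beta = beta if beta is not None else beta_for()
    return mu - beta * sigma ** 2 / 2.0


def read_window_samples(path: str,
                        beta: float | None = None) -> EnergyDifferenceSamples:
    """Two-column text: direction (F/R) and dU in kcal/mol."""
    fwd, rev = [], []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            d, v = line.split()[:2]
            (fwd if d.upper().startswith("F") else rev).append(float(v))
    return EnergyDifferenceSamples(
        forward=np.array(fwd), reverse=np.array(rev),
        beta=beta if beta is not None else beta_for())
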