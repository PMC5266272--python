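"""Two-pool heterodimer synthesis–assembly–degradation model.

A subunit A (e.g. the GTPase of a tight heterodimer) partitions into two
pools: an *unstable* free-monomer pool degraded quickly (rate
``d_free``) and a *stable* complex-bound pool degraded slowly
(``d_complex``). Mass-action dynamics with first-order degradation:

    dA/dt = N_A s_A - d_free_A A - k_on A B + k_off C
    dB/dt = N_B s_B - d_free_B B - k_on A B + k_off C
    dC/dt = k_on A B - k_off C - d_complex C

where ``N_X`` are gene copy numbers and ``s_X`` per-copy synthesis
fluxes. Because stoichiometric excess of one subunit enlarges its
unstable pool, total A responds sub-proportionally to its own gene
dosage (dosage compensation) and rises with partner dosage.

A genomically tagged copy is kinetically identical to untagged chains,
so tagged levels are simply the ``tagged_copies_A / N_A`` share of the
totals; no separate tagged equations are needed. The tagged-total
observable corresponds to a denaturing blot, the tagged-complex
observable to a native gel.

Steady states have a closed form: eliminating C through the effective
association rate ``k_eff = k_on d_complex / (k_off + d_complex)`` leaves
a single quadratic in the scarcer monomer. An ODE-relaxation fallback
covers degenerate parameter corners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .densitometry import DecaySeries, estimate_half_life

__all__ = [
    "HeterodimerModel",
    "SteadyState",
    "steady_state",
    "perturb",
    "fold_change",
    "simulate_chx",
    "flux_limit_fold",
    "fit_parameters",
    "default_model",
    "PERTURBATION_KINDS",
    "OBSERVABLES",
]

PERTURBATION_KINDS = (
    "multicopy_self",
    "multicopy_partner",
    "partner_deletion",
    "proteasome_defect",
)
OBSERVABLES = ("tagged_total_A", "tagged_complex", "total_A")

_ABS_TOL = 1e-10  # absolute tolerance on steady-state concentrations
_REL_RESID = 1e-9  # relative flux-balance residual accepted at steady state


@dataclass(frozen=True)
class HeterodimerModel:
    """Rate constants, gene dosage and tag bookkeeping.

    Units are arbitrary concentration (AU) and reciprocal hours; only
    ratios matter for fold changes. ``d_free_* >= d_complex`` encodes
    the stabilization of a monomer upon complex formation; the inverted
    ordering is permitted (for limit tests) but is not the modeled
    biology.
    """

    s_a: float = 1.5
    s_b: float = 1.0
    n_a: float = 1.0
    n_b: float = 1.0
    d_free_a: float = 5.0
    d_free_b: float = 5.0
    d_complex: float = 1.0
    k_on: float = 100.0
    k_off: float = 0.0
    tagged_copies_a: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "s_a", "s_b", "n_a", "n_b",
            "d_free_a", "d_free_b", "d_complex", "k_on", "k_off",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0 <= self.tagged_copies_a <= max(self.n_a, self.tagged_copies_a)):
            raise ValueError("tagged_copies_a must be nonnegative")
        if self.n_a > 0 and self.tagged_copies_a > self.n_a:
            raise ValueError("tagged_copies_a cannot exceed n_a")

    @property
    def tagged_share(self) -> float:
        """Fraction of A chains carrying the tag."""
        return self.tagged_copies_a / self.n_a if self.n_a > 0 else 0.0


@dataclass(frozen=True)
class SteadyState:
    """Steady-state pools (AU) with tagged-species bookkeeping."""

    a_free: float
    b_free: float
    complex: float
    tagged_a_free: float
    tagged_complex: float

    @property
    def total_a(self) -> float:
        return self.a_free + self.complex

    @property
    def tagged_total_a(self) -> float:
        return self.tagged_a_free + self.tagged_complex

    def observable(self, name: str) -> float:
        if name == "tagged_total_A":
            return self.tagged_total_a
        if name == "tagged_complex":
            return self.tagged_complex
        if name == "total_A":
            return self.total_a
        raise ValueError(f"unknown observable {name!r}")


def _rhs(t: float, y: np.ndarray, m: HeterodimerModel) -> list[float]:
    a, b, c = y
    assoc = m.k_on * a * b - m.k_off * c
    return [
        m.n_a * m.s_a - m.d_free_a * a - assoc,
        m.n_b * m.s_b - m.d_free_b * b - assoc,
        assoc - m.d_complex * c,
    ]


def _residual_ok(m: HeterodimerModel, a: float, b: float, c: float) -> bool:
    res = np.abs(_rhs(0.0, np.array([a, b, c]), m))
    scale = max(m.n_a * m.s_a, m.n_b * m.s_b, 1.0)
    return bool(np.all(res <= _REL_RESID * scale + _ABS_TOL))


def _closed_form(m: HeterodimerModel) -> tuple[float, float, float] | None:
    """Quadratic steady state; None when the reduction degenerates."""
    if m.d_complex == 0 and m.k_on > 0 and m.k_off == 0:
        return None  # complex accumulates without bound unless fluxes vanish
    k_eff = (
        m.k_on * m.d_complex / (m.k_off + m.d_complex)
        if (m.k_off + m.d_complex) > 0
        else 0.0
    )
    fa, fb = m.n_a * m.s_a, m.n_b * m.s_b
    if fa == 0 and fb == 0:
        return (0.0, 0.0, 0.0)
    if m.k_on == 0:
        if m.d_free_a <= 0 or m.d_free_b <= 0:
            return None
        return (fa / m.d_free_a, fb / m.d_free_b, 0.0)
    if m.d_free_a <= 0:
        return None
    # A = (fa - fb + d_free_b B) / d_free_a from the difference of the
    # monomer balances; substitute into the B balance.
    delta = fa - fb
    qa = k_eff * m.d_free_b / m.d_free_a
    qb = m.d_free_b + k_eff * delta / m.d_free_a
    qc = -fb
    if qa == 0:
        if qb <= 0:
            return None
        b = -qc / qb
    else:
        disc = qb * qb - 4 * qa * qc
        if disc < 0:
            return None
        b = (-qb + math.sqrt(disc)) / (2 * qa)
    if b < 0:
        return None
    a = (delta + m.d_free_b * b) / m.d_free_a
    if a < 0:
        return None
    c = m.k_on * a * b / (m.k_off + m.d_complex) if (m.k_off + m.d_complex) else 0.0
    return (a, b, c)


def _relax_to_steady(m: HeterodimerModel) -> tuple[float, float, float]:
    """ODE relaxation fallback from an order-of-magnitude initial guess."""
    rates = [r for r in (m.d_free_a, m.d_free_b, m.d_complex, m.k_off) if r > 0]
    slowest = min(rates) if rates else 1.0
    horizon = 50.0 / slowest
    y0 = [0.0, 0.0, 0.0]
    sol = solve_ivp(
        _rhs, (0.0, horizon), y0, args=(m,), method="LSODA",
        rtol=1e-10, atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"steady-state integration failed: {sol.message}")
    a, b, c = sol.y[:, -1]
    if not _residual_ok(m, a, b, c):
        res = _rhs(0.0, sol.y[:, -1], m)
        raise RuntimeError(f"steady state did not converge; residual fluxes {res}")
    return float(a), float(b), float(c)


def steady_state(model: HeterodimerModel) -> SteadyState:
    """Nonnegative steady state of the assembly–degradation system.

    Solved in closed form (a quadratic in free B) whenever the reduction
    is non-degenerate, otherwise by ODE relaxation; the returned state
    satisfies flux balance to a relative residual of 1e-9.
    """
    sol = _closed_form(model)
    if sol is None or not _residual_ok(model, *sol):
        sol = _relax_to_steady(model)
    a, b, c = sol
    share = model.tagged_share
    return SteadyState(a, b, c, a * share, c * share)


def perturb(model: HeterodimerModel, kind: str, value: float | None = None) -> HeterodimerModel:
    """Return a perturbed copy of the model.

    ``multicopy_self(N)`` / ``multicopy_partner(N)`` set the gene copy
    number of A / B to N (the tagged genomic copy count is untouched).
    ``partner_deletion`` zeroes the partner synthesis flux.
    ``proteasome_defect(f)`` moves both free-pool degradation rates
    toward the complex rate: ``d_free <- d_complex + f (d_free -
    d_complex)``; f=0 is a complete defect (no stability difference
    left), f=1 no defect.
    """
    if kind == "multicopy_self":
        if value is None or value < 1:
            raise ValueError("multicopy_self requires N >= 1")
        return replace(model, n_a=float(value))
    if kind == "multicopy_partner":
        if value is None or value < 1:
            raise ValueError("multicopy_partner requires N >= 1")
        return replace(model, n_b=float(value))
    if kind == "partner_deletion":
        return replace(model, n_b=0.0)
    if kind == "proteasome_defect":
        if value is None or not (0 <= value <= 1):
            raise ValueError("proteasome_defect requires f in [0, 1]")
        dc = model.d_complex
        return replace(
            model,
            d_free_a=dc + value * (model.d_free_a - dc),
            d_free_b=dc + value * (model.d_free_b - dc),
        )
    raise ValueError(f"unknown perturbation kind {kind!r}")


def parse_perturbation(spec: str) -> tuple[str, float | None]:
    """Parse ``"kind"`` or ``"kind:value"`` perturbation strings."""
    kind, _, raw = spec.partition(":")
    if kind not in PERTURBATION_KINDS:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    return kind, (float(raw) if raw else None)


def fold_change(
    model: HeterodimerModel,
    perturbation: HeterodimerModel | str | tuple[str, float | None],
    observable: str = "tagged_total_A",
) -> float:
    """Observable at the perturbed steady state over the baseline.

    ``perturbation`` may be an already-perturbed model, a ``(kind,
    value)`` pair, or a ``"kind:value"`` string.
    """
    if isinstance(perturbation, HeterodimerModel):
        perturbed = perturbation
    else:
        if isinstance(perturbation, str):
            kind, value = parse_perturbation(perturbation)
        else:
            kind, value = perturbation
        perturbed = perturb(model, kind, value)
    base = steady_state(model).observable(observable)
    if base == 0:
        raise ValueError(f"baseline observable {observable} is zero")
    return steady_state(perturbed).observable(observable) / base


def simulate_chx(
    model: HeterodimerModel,
    times: Sequence[float],
    observable: str = "tagged_total_A",
) -> DecaySeries:
    """Cycloheximide-chase simulation of the tagged observable.

    Synthesis is set to zero at t=0 with the pre-treatment steady state
    as initial condition; the decay of the observable is integrated and
    normalized to time 0. Half-life is the log-linear estimate used for
    experimental chase data (``None`` when no decay).
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must start at 0 and increase strictly")
    ss = steady_state(model)
    chased = replace(model, s_a=0.0, s_b=0.0)
    y0 = [ss.a_free, ss.b_free, ss.complex]
    sol = solve_ivp(
        _rhs, (0.0, float(t[-1]) if t[-1] > 0 else 1.0), y0, args=(chased,),
        t_eval=t, method="LSODA", rtol=1e-10, atol=1e-13,
    )
    if not sol.success:
        raise RuntimeError(f"CHX integration failed: {sol.message}")
    share = model.tagged_share
    if observable == "tagged_total_A":
        series = (sol.y[0] + sol.y[2]) * share
    elif observable == "tagged_complex":
        series = sol.y[2] * share
    elif observable == "total_A":
        series = sol.y[0] + sol.y[2]
    else:
        raise ValueError(f"unknown observable {observable!r}")
    if series[0] <= 0:
        raise ValueError("observable is zero at time 0")
    rel = series / series[0]
    half = None
    if t.size >= 3 and np.all(rel > 0):
        half = estimate_half_life(t, rel)
    return DecaySeries(tuple(t.tolist()), tuple(rel.tolist()), half)


def flux_limit_fold(n: float, s_a: float, s_b: float, d_f: float, d_c: float) -> float:
    """Closed-form tagged-total fold change in the fast-association limit.

    For ``k_on -> inf``, ``k_off = 0`` and A synthesized in excess
    (``N s_A >= s_B``), complex formation consumes the whole partner
    flux, free A carries the surplus, and

        fold(N) = [s_B/(N d_c) + (N s_A - s_B)/(N d_f)]
                  / [s_B/d_c + (s_A - s_B)/d_f].

    Serves as an independent analytic oracle for the numeric solver.
    """
    if n * s_a < s_b or s_a < s_b:
        raise ValueError("flux-limit formula requires s_A >= s_B at both dosages")
    if d_f <= 0 or d_c <= 0 or s_b < 0:
        raise ValueError("rates must be positive")
    num = s_b / (n * d_c) + (n * s_a - s_b) / (n * d_f)
    den = s_b / d_c + (s_a - s_b) / d_f
    return num / den


_FREE_PARAMS = ("s_ratio", "d_ratio", "k_on")
_START_GRID = {
    "s_ratio": (0.5, 1.5, 4.0),
    "d_ratio": (2.0, 5.0, 20.0),
    "k_on": (10.0, 100.0, 1000.0),
}


def _apply_params(base: HeterodimerModel, names: Sequence[str], logvals: np.ndarray) -> HeterodimerModel:
    vals = dict(zip(names, np.exp(logvals)))
    m = base
    if "s_ratio" in vals:
        m = replace(m, s_a=vals["s_ratio"] * m.s_b)
    if "d_ratio" in vals:
        m = replace(
            m,
            d_free_a=vals["d_ratio"] * m.d_complex,
            d_free_b=vals["d_ratio"] * m.d_complex,
        )
    if "k_on" in vals:
        m = replace(m, k_on=vals["k_on"])
    return m


def fit_parameters(
    observations: Iterable[tuple[str, str, float]],
    fixed: HeterodimerModel,
    free: Sequence[str] = ("s_ratio", "d_ratio"),
) -> dict:
    """Least-squares fit of model ratios to perturbation fold changes.

    ``observations`` are ``(perturbation_spec, observable, fold)``
    triples (e.g. ``("multicopy_self:20", "tagged_total_A", 0.38)``).
    Free parameters are any of ``s_ratio`` (s_A/s_B), ``d_ratio``
    (d_free/d_complex, applied to both subunits) and ``k_on``; everything
    else is pinned by ``fixed``. Residuals are in log-fold space; a fixed
    multi-start grid guards against local minima.

    Returns the fitted model, the fitted ratios, residuals, and the
    converged flag.
    """
    obs = list(observations)
    free = tuple(free)
    for name in free:
        if name not in _FREE_PARAMS:
            raise ValueError(f"unknown free parameter {name!r}")
    if len(obs) < len(free):
        raise ValueError(
            f"under-determined fit: {len(obs)} observation(s) for "
            f"free parameters {list(free)}"
        )
    if any(f <= 0 for _, _, f in obs):
        raise ValueError("observed folds must be positive")

    def residuals(logvals: np.ndarray) -> np.ndarray:
        m = _apply_params(fixed, free, logvals)
        out = np.empty(len(obs))
        for i, (pspec, observable, fold) in enumerate(obs):
            try:
                pred = fold_change(m, pspec, observable)
            except (ValueError, RuntimeError):
                return np.full(len(obs), 1e6)
            if pred <= 0:
                return np.full(len(obs), 1e6)
            out[i] = math.log(pred) - math.log(fold)
        return out

    starts = [np.log([_START_GRID[n][i] for n in free]) for i in range(3)]
    best = None
    for x0 in starts:
        res = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
        if best is None or res.cost < best.cost:
            best = res
    fitted = _apply_params(fixed, free, best.x)
    ratios = dict(zip(free, np.exp(best.x)))
    return {
        "model": fitted,
        "params": ratios,
        "residuals": best.fun,
        "converged": bool(best.success and np.all(np.abs(best.fun) < 1e3)),
    }


def default_model() -> HeterodimerModel:
    """The shipped default calibration (loaded from the packaged config)."""
    from .config import load_model, packaged_default_path

    return load_model(packaged_default_path())
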