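"""Global protected-area effectiveness algebra.

Site-level biodiversity inside (``i``) and outside (``o``) protected areas
is expressed as a proportion of its value under pristine conditions. Given

* the inside/outside ratio ``rho = i/o`` (aggregated over land uses with
  global land-area weights),
* the protected fraction of terrestrial area ``a``, and
* the global average proportional loss of site-level biodiversity relative
  to pristine, ``r``,

the global state identity ``1 - r = a*i + (1 - a)*o`` pins down ``i`` and
``o``, and effectiveness is ``e = 1 - (1 - i)/(1 - o)``: 0 when protected
sites are no better than unprotected ones, 1 (100%) when they match
pristine sites, unbounded on both sides.

All quantities are proportions internally; percentages appear only at I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EffectivenessInputs",
    "EffectivenessResult",
    "weighted_ratio",
    "solve_io",
    "effectiveness",
    "scenario_effectiveness",
    "required_area",
    "effectiveness_analysis",
    "monte_carlo_ci",
]

_WEIGHT_TOL = 1e-9


@dataclass
class EffectivenessInputs:
    """Inputs to the effectiveness algebra (all proportions, not %)."""

    land_use_ratios: dict[str, float]  # inside/outside ratio per land use
    weights: dict[str, float]  # share of global terrestrial area per land use
    a: float  # protected fraction of land, in [0, 1)
    r: float  # global average proportional biodiversity loss, < 1
    scenario_ratio: float | None = None  # rho* under restrictive management

    def __post_init__(self) -> None:
        if set(self.land_use_ratios) != set(self.weights):
            raise ValueError("land_use_ratios and weights must share keys")
        if any(not v > 0 for v in self.land_use_ratios.values()):
            raise ValueError("all land-use ratios must be > 0")
        w = np.array(list(self.weights.values()), dtype=float)
        if abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"weights must sum to 1 (got {w.sum():.12f})")
        if not 0.0 <= self.a < 1.0:
            raise ValueError("protected fraction a must be in [0, 1)")
        if not self.r < 1.0:
            raise ValueError("loss r must be < 1")
        if self.scenario_ratio is not None and not self.scenario_ratio > 0:
            raise ValueError("scenario ratio must be > 0")


@dataclass
class EffectivenessResult:
    rho: float
    i: float
    o: float
    e: float
    e_scenario: float | None = None
    required_a: float | None = None
    details: dict = field(default_factory=dict)


def weighted_ratio(
    land_use_ratios: dict[str, float],
    weights: dict[str, float],
    *,
    method: str = "arithmetic",
    outside_levels: dict[str, float] | None = None,
) -> float:
    """Aggregate per-land-use inside/outside ratios to one global ratio.

    ``method="arithmetic"`` (default) takes the area-weighted arithmetic
    mean of the ratios. ``method="ratio_of_means"`` forms the ratio of the
    area-weighted inside and outside biodiversity levels,
    ``sum(w_l i_l) / sum(w_l o_l)``; it needs relative outside levels per
    land use (``outside_levels``, any common scale) and collapses onto the
    arithmetic mean when those are equal.
    """
    if set(land_use_ratios) != set(weights):
        raise ValueError("ratios and weights must share keys")
    keys = list(land_use_ratios)
    w = np.array([weights[k] for k in keys], dtype=float)
    rho = np.array([land_use_ratios[k] for k in keys], dtype=float)
    if abs(w.sum() - 1.0) > _WEIGHT_TOL:
        raise ValueError(f"weights must sum to 1 (got {w.sum():.12f})")
    if np.any(rho <= 0):
        raise ValueError("all ratios must be > 0")
    if method == "arithmetic":
        return float(np.sum(w * rho))
    if method == "ratio_of_means":
        if outside_levels is None:
            o_l = np.ones_like(rho)
        else:
            o_l = np.array([outside_levels[k] for k in keys], dtype=float)
            if np.any(o_l <= 0):
                raise ValueError("outside levels must be > 0")
        return float(np.sum(w * rho * o_l) / np.sum(w * o_l))
    raise ValueError(f"unknown aggregation method {method!r}")


def solve_io(rho: float, a: float, r: float) -> tuple[float, float]:
    """Solve the global-state identity for (i, o) given ``rho = i/o``.

    ``o = (1 - r) / (1 + a (rho - 1))``, ``i = rho * o``; the pair satisfies
    ``a*i + (1 - a)*o = 1 - r`` exactly.
    """
    denom = 1.0 + a * (rho - 1.0)
    if not denom > 0:
        raise ValueError("infeasible inputs: 1 + a(rho - 1) must be > 0")
    o = (1.0 - r) / denom
    return rho * o, o


def effectiveness(i: float, o: float) -> float:
    """``e = 1 - (1 - i)/(1 - o)``; unbounded on both sides of [0, 1]."""
    if o == 1.0:
        raise ZeroDivisionError("effectiveness undefined when o = 1 (pristine outside)")
    return 1.0 - (1.0 - i) / (1.0 - o)


def scenario_effectiveness(rho_star: float, a: float, r: float) -> float:
    """Effectiveness if all protected areas achieved ratio ``rho_star``.

    Re-solves the global-state identity at the scenario ratio (the global
    state ``1 - r`` held fixed) and evaluates ``e`` on the scenario pair.
    """
    i_s, o_s = solve_io(rho_star, a, r)
    return effectiveness(i_s, o_s)


def required_area(
    rho: float,
    rho_star: float,
    a: float,
    r: float,
    *,
    hold: str = "outside",
) -> float:
    """Protected fraction needed to match the restrictive-scenario outcome.

    The restrictive scenario raises the inside level to ``rho_star * o``.
    With ``hold="outside"`` (default) the current outside level ``o`` is
    held fixed, giving a scenario global level
    ``G* = a*rho_star*o + (1 - a)*o``; the required fraction with the
    *current* per-site levels (i, o) then solves
    ``a' * i + (1 - a') * o = G*``, i.e. ``a' = (G* - o)/(i - o)``.
    With ``hold="state"`` the identity is instead re-solved keeping the
    global state ``1 - r`` fixed, under which the outcome level equals
    ``1 - r`` by construction and ``a'`` = ``a`` always; it is exposed only
    for completeness.
    """
    i, o = solve_io(rho, a, r)
    if hold == "state":
        return a
    if hold != "outside":
        raise ValueError(f"unknown hold convention {hold!r}")
    g_star = a * rho_star * o + (1.0 - a) * o
    if i == o:
        if abs(g_star - o) < 1e-12:
            return a
        raise ValueError("required area infeasible: i == o but target level differs")
    return (g_star - o) / (i - o)


def effectiveness_analysis(inputs: EffectivenessInputs,
                           *, method: str = "arithmetic") -> EffectivenessResult:
    """Full algebra on one set of inputs: rho, (i, o), e, scenario, a'."""
    rho = weighted_ratio(inputs.land_use_ratios, inputs.weights, method=method)
    i, o = solve_io(rho, inputs.a, inputs.r)
    e = effectiveness(i, o)
    res = EffectivenessResult(rho=rho, i=i, o=o, e=e)
    if inputs.scenario_ratio is not None:
        res.e_scenario = scenario_effectiveness(inputs.scenario_ratio, inputs.a, inputs.r)
        res.required_a = required_area(rho, inputs.scenario_ratio, inputs.a, inputs.r)
    return res


def monte_carlo_ci(
    log_ratios: dict[str, float],
    log_ratio_ses: dict[str, float],
    weights: dict[str, float],
    a: float,
    r: float,
    *,
    scenario_log_ratio: float | None = None,
    scenario_log_ratio_se: float | None = None,
    n_draws: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """Parametric Monte-Carlo uncertainty for e (and optionally e*, a').

    Per-land-use log ratios are drawn independently from normal sampling
    distributions on the link scale; each draw is pushed through the full
    algebra. Returns point estimates with equal-tailed interval bounds.
    """
    rng = np.random.default_rng(seed)
    keys = list(log_ratios)
    mu = np.array([log_ratios[k] for k in keys])
    se = np.array([log_ratio_ses[k] for k in keys])
    w = np.array([weights[k] for k in keys])
    if abs(w.sum() - 1.0) > _WEIGHT_TOL:
        raise ValueError("weights must sum to 1")
    draws = np.exp(mu + se * rng.standard_normal((n_draws, len(keys))))
    rho_d = draws @ w
    denom = 1.0 + a * (rho_d - 1.0)
    ok = denom > 0
    o_d = np.where(ok, (1.0 - r) / np.where(ok, denom, 1.0), np.nan)
    i_d = rho_d * o_d
    e_d = 1.0 - (1.0 - i_d) / (1.0 - o_d)
    alpha = (1.0 - level) / 2.0
    out = {
        "e": _summ(e_d, alpha),
        "rho": _summ(rho_d, alpha),
        "n_draws": int(n_draws),
        "n_infeasible": int(np.sum(~ok)),
    }
    if scenario_log_ratio is not None:
        se_s = scenario_log_ratio_se or 0.0
        rho_s = np.exp(scenario_log_ratio + se_s * rng.standard_normal(n_draws))
        den_s = 1.0 + a * (rho_s - 1.0)
        o_s = (1.0 - r) / den_s
        i_s = rho_s * o_s
        e_s = 1.0 - (1.0 - i_s) / (1.0 - o_s)
        g_star = a * rho_s * o_d + (1.0 - a) * o_d
        with np.errstate(divide="ignore", invalid="ignore"):
            a_req = (g_star - o_d) / (i_d - o_d)
        out["e_scenario"] = _summ(e_s, alpha)
        out["required_a"] = _summ(a_req, alpha)
    return out


def _summ(x: np.ndarray, alpha: float) -> dict:
    x = x[np.isfinite(x)]
    return {
        "mean": float(np.mean(x)),
        "median": float(np.median(x)),
        "lo": float(np.quantile(x, alpha)),
        "hi": float(np.quantile(x, 1.0 - alpha)),
    }
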