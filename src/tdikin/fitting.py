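"""Global least-squares fitting of mechanism rate constants to progress curves.

The estimator repeatedly integrates the mechanism ODEs and minimises the
sum of squared residuals between simulated and observed detected signal,
simultaneously over all curves ("global fitting of progress curves").
Because full time courses carry pre-steady-state information, the
microscopic binding rates kon/koff of a slow inhibitor are identifiable
here even though initial-velocity analysis cannot see them.

The case-study analysis is two-staged, mirroring how the enzyme must be
characterised before its inhibition can be:

* stage 1 (:func:`fit_stage1`): the sequential-addition product-inhibition
  experiment fixes the hydrolysis parameters - the apparent bimolecular
  constant k1 (= kcat/Km), the catalytic constant k2 (= kcat) and the
  product off-rate k4, with the product on-rate k3 pinned at the diffusion
  limit so that only the ratio k4/k3 (the product Ki) is asserted.
* stage 2 (:func:`fit_stage2`): with the stage-1 constants frozen, the
  inhibited series determines the inhibitor on/off rates k5/k6 (and,
  following the original analysis, the per-curve substrate and shared
  enzyme concentrations within +/-20% of nominal).

Rate parameters are optimised in log space by default (they span ~10
decades); residuals are computed on the detected-signal scale, unweighted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .assays import AssayDesign, EllmanParams, ProgressCurve, _prune_species
from .mechanisms import Mechanism, build_scheme
from .simulate import IntegratorOptions, Phase, run_protocol

__all__ = [
    "FitParameter",
    "FitCurve",
    "FitSpec",
    "GlobalFitResult",
    "global_fit",
    "fit_stage1",
    "fit_stage2",
    "profile_uncertainty",
    "fit_curves_from_progress",
]

RANK_DEFICIENT_COND = 1e8


@dataclass(frozen=True)
class FitParameter:
    """One free parameter: a rate label, ``"e0"`` (shared enzyme
    concentration scale) or ``"s0:<curve index>"`` (per-curve substrate
    scale).  Concentration scales multiply the nominal value, so a guess of
    1.0 with bounds (0.8, 1.2) means nominal +/-20%."""

    name: str
    guess: float
    lower: float = 1e-12
    upper: float = 1e12
    log: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.lower < self.upper):
            raise ValueError(f"bounds for {self.name!r} must be positive and ordered")
        if not (self.lower <= self.guess <= self.upper):
            raise ValueError(f"guess for {self.name!r} outside bounds")


@dataclass(frozen=True)
class FitCurve:
    """One observed progress curve plus the protocol that produced it.

    ``times``/``signal`` are the data (signal in M or absorbance units per
    ``detection``); ``additions`` are (time, {species: conc}) events after
    t = 0 for sequential-addition protocols.  ``preincubation_s`` > 0 means
    enzyme and inhibitor were equilibrated before the recorded reaction
    started (substrate-initiated); otherwise all reagents mix at t = 0.
    """

    times: np.ndarray
    signal: np.ndarray
    e0: float
    s0: float = 0.0
    i0: float = 0.0
    p0: float = 0.0
    preincubation_s: float = 0.0
    additions: tuple[tuple[float, Mapping[str, float]], ...] = ()
    detection: str = "concentration"
    ellman: EllmanParams = EllmanParams()

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.shape != y.shape or t.ndim != 1 or t.size < 2:
            raise ValueError("times and signal must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0) or t[0] < 0:
            raise ValueError("times must be strictly increasing and non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signal", y)

    @property
    def scale(self) -> float:
        """Signal-to-concentration factor (1 for concentration data)."""
        if self.detection == "absorbance":
            return self.ellman.epsilon * self.ellman.path_cm
        return 1.0


@dataclass
class FitSpec:
    """Everything :func:`global_fit` needs.

    ``fixed_rates`` and the free rate parameters must together cover every
    rate label of the mechanism; free and fixed sets must not overlap.
    """

    mechanism: Mechanism
    fixed_rates: Mapping[str, float]
    parameters: Sequence[FitParameter]
    curves: Sequence[FitCurve]
    detected_species: str = "P"
    options: IntegratorOptions = field(default_factory=IntegratorOptions)

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValueError("at least one curve is required")
        free_rates = {p.name for p in self.parameters if not _is_conc_param(p.name)}
        overlap = free_rates & set(self.fixed_rates)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        labels = set(self.mechanism.rate_labels)
        missing = labels - free_rates - set(self.fixed_rates)
        if missing:
            raise ValueError(f"rate labels neither free nor fixed: {sorted(missing)}")
        unknown = free_rates - labels
        if unknown:
            raise ValueError(f"free parameters not in mechanism: {sorted(unknown)}")
        for p in self.parameters:
            if p.name.startswith("s0:"):
                idx = int(p.name.split(":")[1])
                if not (0 <= idx < len(self.curves)):
                    raise ValueError(f"parameter {p.name!r} indexes a missing curve")


def _is_conc_param(name: str) -> bool:
    return name == "e0" or name.startswith("s0:")


@dataclass
class GlobalFitResult:
    """Estimates and diagnostics of a global progress-curve fit.

    Derived quantities (Ki = k6/k5, product Ki = k4/k3, kcat, kcat/Km,
    residence time) are always recomputed from the estimates on access,
    never stored independently.
    """

    estimates: dict[str, float]
    standard_errors: dict[str, float]
    fixed: dict[str, float]
    rss: float
    per_curve_rms: list[float]
    n_points: int
    n_free: int
    nfev: int
    converged: bool
    condition_number: float
    message: str = ""

    @property
    def rank_deficient(self) -> bool:
        return not np.isfinite(self.condition_number) or self.condition_number > RANK_DEFICIENT_COND

    def rate(self, label: str) -> float:
        if label in self.estimates:
            return self.estimates[label]
        return self.fixed[label]

    def derived(self) -> dict[str, float]:
        out: dict[str, float] = {}
        have = lambda *ls: all(l in self.estimates or l in self.fixed for l in ls)
        if have("k1"):
            out["kcat_over_Km_M_per_s"] = self.rate("k1")
        if have("k2"):
            out["kcat_per_s"] = self.rate("k2")
        if have("k1", "k2"):
            out["Km_M"] = self.rate("k2") / self.rate("k1")
        if have("k3", "k4"):
            out["Ki_product_M"] = self.rate("k4") / self.rate("k3")
        if have("k5", "k6"):
            out["Ki_M"] = self.rate("k6") / self.rate("k5")
            out["kon_M_per_s"] = self.rate("k5")
            out["koff_per_s"] = self.rate("k6")
            out["residence_time_s"] = 1.0 / self.rate("k6")
        return out

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "standard_errors": self.standard_errors,
            "fixed": self.fixed,
            "derived": self.derived(),
            "rss": self.rss,
            "per_curve_rms": self.per_curve_rms,
            "n_points": self.n_points,
            "n_free": self.n_free,
            "nfev": self.nfev,
            "converged": self.converged,
            "condition_number": self.condition_number,
            "rank_deficient": self.rank_deficient,
            "message": self.message,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Simulation of one fit curve
# ---------------------------------------------------------------------------

def simulate_fit_curve(
    mechanism: Mechanism,
    rates: Mapping[str, float],
    fc: FitCurve,
    detected_species: str = "P",
    e0_scale: float = 1.0,
    s0_scale: float = 1.0,
    options: IntegratorOptions = IntegratorOptions(),
) -> np.ndarray:
    """Model signal at the curve's sample times for the given parameters."""
    e0 = fc.e0 * e0_scale
    s0 = fc.s0 * s0_scale
    phases: list[Phase] = []
    if fc.preincubation_s > 0:
        init = {"E": e0, "I": fc.i0}
        phases.append(Phase(fc.preincubation_s))
        start_add = {"S": s0, "P": fc.p0}
    else:
        init = {"E": e0, "I": fc.i0, "S": s0, "P": fc.p0}
        start_add = {}
    # split the recorded window at addition events
    bounds = [0.0] + [t for t, _ in fc.additions] + [float(fc.times[-1])]
    adds = [start_add] + [dict(a) for _, a in fc.additions]
    for j in range(len(bounds) - 1):
        lo, hi = bounds[j], bounds[j + 1]
        if hi <= lo:
            raise ValueError("addition times must be increasing and inside the record")
        m = (fc.times >= lo) & (fc.times <= hi if j == len(bounds) - 2 else fc.times < hi)
        add = {sp: c * (s0_scale if sp == "S" else 1.0) for sp, c in adds[j].items()}
        phases.append(Phase(hi - lo, _prune_species(mechanism, add), t_eval=fc.times[m] - lo))
    traj = run_protocol(
        mechanism, rates, phases, init=_prune_species(mechanism, init), options=options
    )
    y = traj[detected_species]
    n = len(fc.times)
    return y[-n:] * fc.scale


# ---------------------------------------------------------------------------
# Global fit
# ---------------------------------------------------------------------------

def _pack(spec: FitSpec):
    x0, lo, hi = [], [], []
    for p in spec.parameters:
        if p.log:
            x0.append(math.log(p.guess)); lo.append(math.log(p.lower)); hi.append(math.log(p.upper))
        else:
            x0.append(p.guess); lo.append(p.lower); hi.append(p.upper)
    return np.array(x0), (np.array(lo), np.array(hi))


def _unpack(spec: FitSpec, x: np.ndarray) -> dict[str, float]:
    out = {}
    for p, v in zip(spec.parameters, x):
        out[p.name] = math.exp(v) if p.log else float(v)
    return out


def _residuals(spec: FitSpec, values: Mapping[str, float]) -> np.ndarray:
    rates = dict(spec.fixed_rates)
    for name, v in values.items():
        if not _is_conc_param(name):
            rates[name] = v
    e0_scale = values.get("e0", 1.0)
    res = []
    for i, fc in enumerate(spec.curves):
        s0_scale = values.get(f"s0:{i}", 1.0)
        model = simulate_fit_curve(
            spec.mechanism, rates, fc, spec.detected_species,
            e0_scale=e0_scale, s0_scale=s0_scale, options=spec.options,
        )
        res.append(model - fc.signal)
    return np.concatenate(res)


def global_fit(spec: FitSpec) -> GlobalFitResult:
    """Trust-region nonlinear least squares over all curves simultaneously.

    Deterministic given identical inputs and guesses.  Approximate standard
    errors come from the Jacobian at the optimum; a Jacobian condition
    number above 1e8 flags a structurally unidentifiable combination.
    """
    x0, bounds = _pack(spec)

    def fun(x: np.ndarray) -> np.ndarray:
        return _residuals(spec, _unpack(spec, x))

    sol = least_squares(
        fun, x0, bounds=bounds, method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    values = _unpack(spec, sol.x)
    rss = float(2.0 * sol.cost)
    n = sum(len(fc.times) for fc in spec.curves)
    m = len(spec.parameters)
    # standard errors in natural parameter units from the (possibly log-space)
    # Jacobian: se(p) = p * se(log p)
    J = sol.jac
    sv = np.linalg.svd(J, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
    ses: dict[str, float] = {}
    if n > m and rss > 0 and np.all(sv > 0):
        s2 = rss / (n - m)
        cov = np.linalg.inv(J.T @ J) * s2
        for j, p in enumerate(spec.parameters):
            se = math.sqrt(cov[j, j])
            ses[p.name] = values[p.name] * se if p.log else se
    else:
        ses = {p.name: 0.0 for p in spec.parameters}
    # per-curve RMS
    resid = fun(sol.x)
    rms, k = [], 0
    for fc in spec.curves:
        r = resid[k : k + len(fc.times)]
        rms.append(float(np.sqrt(np.mean(r**2))))
        k += len(fc.times)
    at_bound = [
        p.name
        for p, xv, l, u in zip(spec.parameters, sol.x, *bounds)
        if xv - l < 1e-9 or u - xv < 1e-9
    ]
    msg = sol.message
    if at_bound:
        msg += f"; parameters at bound: {at_bound}"
    return GlobalFitResult(
        estimates=values,
        standard_errors=ses,
        fixed=dict(spec.fixed_rates),
        rss=rss,
        per_curve_rms=rms,
        n_points=n,
        n_free=m,
        nfev=int(sol.nfev),
        converged=bool(sol.success),
        condition_number=cond,
        message=msg,
    )


# ---------------------------------------------------------------------------
# The two-stage case-study analysis
# ---------------------------------------------------------------------------

def _perturbed(value: float, factor: float) -> float:
    return value * factor


def fit_stage1(
    curves: Sequence[FitCurve],
    k3_fixed: float = 2.0e8,
    guesses: Mapping[str, float] | None = None,
    options: IntegratorOptions = IntegratorOptions(),
) -> GlobalFitResult:
    """Hydrolysis + product-inhibition fit of the sequential-addition series.

    Frees k1 (kcat/Km), k2 (kcat) and the product off-rate k4; k3 is fixed
    at the diffusion limit so only the product Ki = k4/k3 is meaningful.
    """
    mech = build_scheme("slyke_cullen_product")
    g = {"k1": 1e8, "k2": 1e3, "k4": 1e3}
    g.update(guesses or {})
    params = [
        FitParameter("k1", g["k1"], 1e4, 1e12),
        FitParameter("k2", g["k2"], 1e-2, 1e8),
        FitParameter("k4", g["k4"], 1e-4, 1e10),
    ]
    spec = FitSpec(
        mechanism=mech,
        fixed_rates={"k3": k3_fixed},
        parameters=params,
        curves=list(curves),
        options=options,
    )
    return global_fit(spec)


def fit_stage2(
    curves: Sequence[FitCurve],
    stage1: GlobalFitResult | Mapping[str, float],
    guesses: Mapping[str, float] | None = None,
    fit_s0: bool = True,
    fit_e0: bool = True,
    conc_bound: float = 0.2,
    options: IntegratorOptions = IntegratorOptions(),
) -> GlobalFitResult:
    """Inhibitor fit of the inhibited series with stage-1 constants frozen.

    Frees the inhibitor on/off rates k5/k6 and, by default, the per-curve
    substrate and shared enzyme concentration scales within
    ``+/- conc_bound`` of nominal.  Requires at least one curve with
    inhibitor present; warns through the result flags when k5/k6 are
    unidentifiable (no inhibitor information).
    """
    if isinstance(stage1, GlobalFitResult):
        fixed = {l: stage1.rate(l) for l in ("k1", "k2", "k3", "k4")}
    else:
        missing = [l for l in ("k1", "k2", "k3", "k4") if l not in stage1]
        if missing:
            raise ValueError(f"stage-1 constants missing: {missing}")
        fixed = {l: float(stage1[l]) for l in ("k1", "k2", "k3", "k4")}
    if not any(fc.i0 > 0 for fc in curves):
        raise ValueError(
            "stage-2 needs inhibited curves: k5/k6 are unidentifiable with i0 = 0 only"
        )
    g = {"k5": 1e6, "k6": 1e-2}
    g.update(guesses or {})
    params = [
        FitParameter("k5", g["k5"], 1e2, 1e10),
        FitParameter("k6", g["k6"], 1e-7, 1e3),
    ]
    if fit_e0:
        params.append(FitParameter("e0", 1.0, 1 - conc_bound, 1 + conc_bound, log=False))
    if fit_s0:
        for i, fc in enumerate(curves):
            if fc.s0 > 0:
                params.append(
                    FitParameter(f"s0:{i}", 1.0, 1 - conc_bound, 1 + conc_bound, log=False)
                )
    spec = FitSpec(
        mechanism=build_scheme("slyke_cullen_product_inhibitor"),
        fixed_rates=fixed,
        parameters=params,
        curves=list(curves),
        options=options,
    )
    return global_fit(spec)


def profile_uncertainty(
    spec: FitSpec,
    result: GlobalFitResult,
    parameter: str,
    grid: Sequence[float],
) -> list[tuple[float, float]]:
    """1-D profile of the residual norm: re-optimise all other free
    parameters at each grid value of ``parameter``.

    Returns (value, rss) pairs; for an identifiable parameter the profile
    is monotone away from the optimum.
    """
    if parameter not in {p.name for p in spec.parameters}:
        raise ValueError(f"{parameter!r} is not a free parameter of the spec")
    out = []
    for v in grid:
        others = []
        for p in spec.parameters:
            if p.name == parameter:
                continue
            guess = result.estimates.get(p.name, p.guess)
            guess = min(max(guess, p.lower), p.upper)
            others.append(replace(p, guess=guess))
        sub = FitSpec(
            mechanism=spec.mechanism,
            fixed_rates=(
                dict(spec.fixed_rates) | {parameter: float(v)}
                if not _is_conc_param(parameter)
                else dict(spec.fixed_rates)
            ),
            parameters=others,
            curves=spec.curves,
            detected_species=spec.detected_species,
            options=spec.options,
        )
        if _is_conc_param(parameter):
            raise NotImplementedError("profiling concentration scales is not supported")
        res = global_fit(sub)
        out.append((float(v), res.rss))
    return out


# ---------------------------------------------------------------------------
# Bridging assay designs to fit curves
# ---------------------------------------------------------------------------

def fit_curves_from_progress(
    curves: Sequence[ProgressCurve],
    design: AssayDesign,
) -> list[FitCurve]:
    """Wrap generated/observed progress curves with their protocol metadata."""
    out = []
    for c in curves:
        if design.sequential:
            n = len(design.s0_list)
            additions = tuple(
                (j * design.duration_s, {"S": design.s0_list[j]}) for j in range(1, n)
            )
            s0 = design.s0_list[0]
        else:
            additions = ()
            s0 = c.s0
        out.append(
            FitCurve(
                times=c.time_s,
                signal=c.signal,
                e0=design.e0,
                s0=s0,
                i0=c.i0,
                p0=design.p0,
                preincubation_s=(
                    design.preincubation_s if design.order == "substrate_initiated" else 0.0
                ),
                additions=additions,
                detection=c.detection,
                ellman=design.ellman,
            )
        )
    return out
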