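"""Synthetic assay generation: designs -> simulated progress curves.

Two families of experiments are emulated:

* The simulated pre-incubation study: a hypothetical enzyme with
  Km = 10 uM and kcat = 1000 1/s (explicit ES complex, kon 1e8 M^-1 s^-1,
  koff 1 1/s) inhibited by competitive inhibitors sharing Ki = 1 uM but
  differing in k_off.  The enzyme (100 pM) is pre-incubated with the
  inhibitor for 1e6 s, the reaction is started with substrate, and the
  first 10 s are lost to instrument dead time.

* The Torpedo californica acetylcholinesterase / galantamine Ellman
  assays: hydrolysis of acetylthiocholine monitored at 412 nm through the
  thiocholine-TNB chromophore (epsilon 13,600 M^-1 cm^-1), with
  enzyme-initiated and substrate-initiated inhibition series, a
  sequential-addition product-inhibition series, and the long
  progress-curve series used for global fitting.

Order-of-addition semantics: enzyme-initiated means every reagent is
present, complex-free, at t = 0 (mixing is instantaneous); substrate-
initiated means enzyme and inhibitor are first equilibrated for the
pre-incubation time, then substrate is added at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .mechanisms import Mechanism, RateConstantSet, build_scheme
from .simulate import IntegratorOptions, Phase, run_protocol

__all__ = [
    "AssayDesign",
    "EllmanParams",
    "NoiseModel",
    "ProgressCurve",
    "fig3_design",
    "gal_design",
    "tcache_reference_rates",
    "generate_curves",
    "to_absorbance",
    "to_concentration",
    "curves_to_frame",
    "frame_to_curves",
]

MICRO = 1e-6
NANO = 1e-9
PICO = 1e-12


@dataclass(frozen=True)
class EllmanParams:
    """Beer-Lambert conversion for the thiocholine-TNB chromophore at 412 nm."""

    epsilon: float = 13600.0  # M^-1 cm^-1
    path_cm: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.path_cm <= 0:
            raise ValueError("extinction coefficient and path length must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise on the detected signal.

    ``sd_abs`` is an absolute standard deviation on the signal scale
    (absorbance units when detection is absorbance); ``cv`` a relative one.
    The two combine in quadrature.  Identical seed => identical dataset,
    independent of generation order (per-curve child seeds are derived from
    the master seed and the condition identity, not from call order).
    """

    sd_abs: float = 0.0
    cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_abs < 0 or self.cv < 0:
            raise ValueError("noise magnitudes must be non-negative")

    @property
    def silent(self) -> bool:
        return self.sd_abs == 0.0 and self.cv == 0.0

    def rng_for(self, s0: float, i0: float, replicate: int) -> np.random.Generator:
        key = (
            int(self.seed) % (2**63),
            int(replicate),
            int(round(s0 / PICO)) % (2**63),
            int(round(i0 / PICO)) % (2**63),
        )
        return np.random.default_rng(np.random.SeedSequence(key))

    def apply(self, signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.silent:
            return signal
        sd = np.sqrt(self.sd_abs**2 + (self.cv * np.abs(signal)) ** 2)
        return signal + rng.normal(0.0, 1.0, size=signal.shape) * sd


@dataclass(frozen=True)
class ProgressCurve:
    """A sampled reaction time course with its condition metadata.

    ``signal`` is in M when ``detection == "concentration"`` and in
    absorbance units when ``detection == "absorbance"``.
    """

    time_s: np.ndarray
    signal: np.ndarray
    s0: float
    i0: float
    replicate: int = 0
    detection: str = "concentration"
    ellman: EllmanParams | None = None
    p0: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("time_s and signal must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "signal", y)


@dataclass(frozen=True)
class AssayDesign:
    """Concentrations, order of addition and sampling for one experiment.

    ``sequential`` marks designs in which the entries of ``s0_list`` are
    consecutive substrate additions to the same cuvette (one long curve)
    rather than independent conditions; ``duration_s`` is then the length
    of each addition phase.
    """

    e0: float
    s0_list: tuple[float, ...]
    i0_list: tuple[float, ...]
    order: str = "enzyme_initiated"
    p0: float = 0.0
    preincubation_s: float = 0.0
    dead_time_s: float = 10.0
    duration_s: float = 60.0
    sample_dt_s: float = 0.5
    replicates: int = 1
    detection: str = "concentration"
    ellman: EllmanParams = EllmanParams()
    sequential: bool = False
    velocity_window_s: float = 10.0

    def __post_init__(self) -> None:
        if self.e0 < 0 or self.p0 < 0 or min(self.s0_list, default=0) < 0 or min(self.i0_list, default=0) < 0:
            raise ValueError("concentrations must be non-negative")
        if self.order not in ("enzyme_initiated", "substrate_initiated"):
            raise ValueError("order must be enzyme_initiated or substrate_initiated")
        if self.detection not in ("concentration", "absorbance"):
            raise ValueError("detection must be concentration or absorbance")
        if self.duration_s <= self.dead_time_s and not self.sequential:
            raise ValueError("duration must exceed the dead time")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.sample_dt_s <= 0 or self.duration_s <= 0:
            raise ValueError("sampling interval and duration must be positive")

    def conditions(self):
        for i0 in self.i0_list:
            for s0 in self.s0_list:
                for rep in range(self.replicates):
                    yield s0, i0, rep


# ---------------------------------------------------------------------------
# Built-in designs
# ---------------------------------------------------------------------------

# Simulated pre-incubation study (Km 10 uM, kcat 1000 1/s, Ki 1 uM).
FIG3_S0_UM = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0, 150.0, 200.0)
FIG3_I0_UM = (0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0)
KI_TRUE = 1e-6  # M, koff/kon held fixed across the koff scan

# TcAChE / galantamine Ellman-assay grids.
GAL_S0_UM = (10.0, 20.0, 50.0, 100.0, 200.0)

# Reference rate constants for the TcAChE scheme (van Slyke-Cullen with
# product inhibition and the one-step galantamine binding step): k1 is the
# apparent bimolecular constant kcat/Km, k2 the catalytic constant, k3/k4
# product binding with k3 pinned to the diffusion limit, k5/k6 the
# galantamine on/off microscopic rates.
TCACHE_K1 = 3.73e8        # M^-1 s^-1 (kcat/Km)
TCACHE_K2 = 2965.0        # s^-1 (kcat)
TCACHE_K3 = 2.0e8         # M^-1 s^-1 (diffusion-limited product on-rate)
TCACHE_KI_PRODUCT = 21.54e-6   # M, thiocholine-TNB competitive Ki
TCACHE_K5 = 1.9e6         # M^-1 s^-1 (galantamine kon)
TCACHE_KI_GAL = 8.45e-9   # M (galantamine Ki = k6/k5)


def tcache_reference_rates(include_inhibitor: bool = True) -> RateConstantSet:
    """Reference rate constants for the TcAChE hydrolysis scheme."""
    rates = RateConstantSet(
        k1=TCACHE_K1,
        k2=TCACHE_K2,
        k3=TCACHE_K3,
        k4=TCACHE_K3 * TCACHE_KI_PRODUCT,
    )
    if include_inhibitor:
        rates["k5"] = TCACHE_K5
        rates["k6"] = TCACHE_K5 * TCACHE_KI_GAL
    return rates


def fig3_design(k_off: float) -> tuple[Mechanism, RateConstantSet, AssayDesign]:
    """Design of the simulated pre-incubation experiment for one k_off.

    The inhibitor on-rate is slaved to ``k_off / Ki`` with Ki = 1 uM, so
    every point of the k_off scan shares the same equilibrium potency and
    differs only in binding kinetics.
    """
    if not (1e-5 * (1 - 1e-9) <= k_off <= 1e3 * (1 + 1e-9)):
        raise ValueError("k_off must lie in [1e-5, 1e3] 1/s")
    mech = build_scheme("competitive_mm")
    rates = RateConstantSet(
        kon_s=1e8, koff_s=1.0, kcat=1000.0, kon_i=k_off / KI_TRUE, koff_i=k_off
    )
    design = AssayDesign(
        e0=100 * PICO,
        s0_list=tuple(s * MICRO for s in FIG3_S0_UM),
        i0_list=tuple(i * MICRO for i in FIG3_I0_UM),
        order="substrate_initiated",
        preincubation_s=1e6,
        dead_time_s=10.0,
        duration_s=20.0,
        sample_dt_s=0.5,
        detection="concentration",
    )
    return mech, rates, design


def gal_design(variant: str) -> AssayDesign:
    """Built-in TcAChE/galantamine assay designs.

    ``enzyme_initiated``     200 pM enzyme, GAL 0-400 nM, 60 s, no pre-incubation.
    ``substrate_initiated``  50 pM enzyme, GAL 0-30 nM, 20 min pre-incubation.
    ``product_series``       five sequential 35 uM substrate additions in one
                             cuvette (accumulated product 0 -> 175 uM).
    ``gal_fit_series``       50 uM substrate, GAL 0-180 nM, monitored 33 min.
    """
    s0 = tuple(s * MICRO for s in GAL_S0_UM)
    if variant == "enzyme_initiated":
        return AssayDesign(
            e0=200 * PICO,
            s0_list=s0,
            i0_list=tuple(i * NANO for i in (0.0, 50.0, 100.0, 200.0, 400.0)),
            order="enzyme_initiated",
            dead_time_s=0.0,
            duration_s=60.0,
            detection="absorbance",
        )
    if variant == "substrate_initiated":
        return AssayDesign(
            e0=50 * PICO,
            s0_list=s0,
            i0_list=tuple(i * NANO for i in (0.0, 5.0, 10.0, 20.0, 30.0)),
            order="substrate_initiated",
            preincubation_s=1200.0,
            dead_time_s=0.0,
            duration_s=60.0,
            detection="absorbance",
        )
    if variant == "product_series":
        return AssayDesign(
            e0=200 * PICO,
            s0_list=(35 * MICRO,) * 5,
            i0_list=(0.0,),
            order="enzyme_initiated",
            dead_time_s=0.0,
            duration_s=600.0,  # per addition; each reaction completes well within
            sample_dt_s=2.0,
            detection="absorbance",
            sequential=True,
        )
    if variant == "gal_fit_series":
        return AssayDesign(
            e0=200 * PICO,
            s0_list=(50 * MICRO,),
            i0_list=tuple(i * NANO for i in (0.0, 15.0, 30.0, 60.0, 120.0, 180.0)),
            order="enzyme_initiated",
            dead_time_s=0.0,
            duration_s=1980.0,
            sample_dt_s=3.0,
            detection="absorbance",
        )
    raise ValueError(
        "unknown variant; valid: enzyme_initiated, substrate_initiated, "
        "product_series, gal_fit_series"
    )


# ---------------------------------------------------------------------------
# Detection conversion
# ---------------------------------------------------------------------------

def to_absorbance(curve: ProgressCurve, ellman: EllmanParams | None = None) -> ProgressCurve:
    """Convert a concentration trace to absorbance, A = epsilon * l * [P]."""
    if curve.detection != "concentration":
        raise ValueError("curve is not in concentration units")
    ep = ellman or curve.ellman or EllmanParams()
    return replace(
        curve,
        signal=curve.signal * ep.epsilon * ep.path_cm,
        detection="absorbance",
        ellman=ep,
    )


def to_concentration(curve: ProgressCurve, ellman: EllmanParams | None = None) -> ProgressCurve:
    """Convert an absorbance trace back to product concentration (M)."""
    if curve.detection != "absorbance":
        raise ValueError("curve is not in absorbance units")
    ep = ellman or curve.ellman
    if ep is None:
        raise ValueError("no Ellman parameters attached to the curve")
    return replace(
        curve,
        signal=curve.signal / (ep.epsilon * ep.path_cm),
        detection="concentration",
        ellman=ep,
    )


# ---------------------------------------------------------------------------
# Curve generation
# ---------------------------------------------------------------------------

def _prune_species(mechanism: Mechanism, conc: dict[str, float]) -> dict[str, float]:
    """Drop zero entries for species the scheme does not contain."""
    out = {}
    for sp, c in conc.items():
        if sp in mechanism.species:
            out[sp] = c
        elif c != 0.0:
            raise ValueError(
                f"species {sp!r} at {c:.3e} M is not in scheme {mechanism.name!r}"
            )
    return out


def _reaction_grid(design: AssayDesign) -> np.ndarray:
    n = int(round(design.duration_s / design.sample_dt_s))
    return np.linspace(0.0, n * design.sample_dt_s, n + 1)


def _protocol_for(
    design: AssayDesign, s0: float, i0: float, t_eval: np.ndarray
) -> tuple[dict[str, float], list[Phase]]:
    if design.sequential:
        init = {"E": design.e0, "I": i0, "P": design.p0}
        phases = [Phase(design.duration_s, {"S": s}, t_eval=t_eval) for s in design.s0_list]
        return init, phases
    if design.order == "enzyme_initiated":
        init = {"E": design.e0, "I": i0, "S": s0, "P": design.p0}
        return init, [Phase(design.duration_s, t_eval=t_eval)]
    init = {"E": design.e0, "I": i0}
    phases = [
        Phase(design.preincubation_s),
        Phase(design.duration_s, {"S": s0, "P": design.p0}, t_eval=t_eval),
    ]
    return init, phases


def generate_curves(
    design: AssayDesign,
    mechanism: Mechanism,
    rates: RateConstantSet,
    noise: NoiseModel = NoiseModel(),
    detected_species: str = "P",
    options: IntegratorOptions = IntegratorOptions(),
) -> list[ProgressCurve]:
    """Simulate every condition of a design into progress curves.

    Time zero of each returned curve is the start of the monitored reaction
    (after any pre-incubation).  For sequential designs the single long
    multi-addition trajectory is returned per replicate, with global time.
    """
    if detected_species not in mechanism.species:
        raise ValueError(
            f"detected species {detected_species!r} not in scheme {mechanism.name!r}"
        )
    t_eval = _reaction_grid(design)
    curves: list[ProgressCurve] = []
    cache: dict[tuple[float, float], tuple[np.ndarray, np.ndarray]] = {}
    iterator = (
        ((design.s0_list[0], i0, rep) for i0 in design.i0_list for rep in range(design.replicates))
        if design.sequential
        else design.conditions()
    )
    for s0, i0, rep in iterator:
        key = (s0, i0)
        if key in cache:
            t, p = cache[key]
        else:
            init, phases = _protocol_for(design, s0, i0, t_eval)
            init = _prune_species(mechanism, init)
            phases = [
                Phase(p.duration, _prune_species(mechanism, dict(p.additions)), p.t_eval)
                for p in phases
            ]
            try:
                traj = run_protocol(mechanism, rates, phases, init=init, options=options)
            except Exception as exc:  # annotate the failing condition
                raise RuntimeError(
                    f"simulation failed at s0={s0:.3e} M, i0={i0:.3e} M: {exc}"
                ) from exc
            t = traj.t
            p = traj[detected_species]
            if design.order == "substrate_initiated" and not design.sequential:
                # keep only the reaction phase, rebased so substrate addition is t=0
                t, p = t[-len(t_eval):] - design.preincubation_s, p[-len(t_eval):]
            if design.sequential:
                # drop duplicated phase-boundary samples, keep global time
                keep = np.concatenate([[True], np.diff(t) > 0])
                t, p = t[keep], p[keep]
            cache[key] = (t, p)
        curve = ProgressCurve(
            time_s=t.copy(),
            signal=p.copy(),
            s0=s0,
            i0=i0,
            replicate=rep,
            detection="concentration",
            ellman=design.ellman,
            p0=design.p0,
        )
        if design.detection == "absorbance":
            curve = to_absorbance(curve, design.ellman)
        if not noise.silent:
            rng = noise.rng_for(s0, i0, rep)
            curve = replace(curve, signal=noise.apply(curve.signal, rng))
        curves.append(curve)
    return curves


# ---------------------------------------------------------------------------
# Tidy-table I/O
# ---------------------------------------------------------------------------

def curves_to_frame(curves: Sequence[ProgressCurve]) -> pd.DataFrame:
    """Long-format table: time_s, signal, s0_M, i0_M, replicate, detection."""
    parts = []
    for c in curves:
        parts.append(
            pd.DataFrame(
                {
                    "time_s": c.time_s,
                    "signal": c.signal,
                    "s0_M": c.s0,
                    "i0_M": c.i0,
                    "replicate": c.replicate,
                    "detection": c.detection,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def frame_to_curves(df: pd.DataFrame, ellman: EllmanParams | None = None) -> list[ProgressCurve]:
    curves = []
    for (s0, i0, rep, det), g in df.groupby(["s0_M", "i0_M", "replicate", "detection"], sort=True):
        g = g.sort_values("time_s")
        curves.append(
            ProgressCurve(
                time_s=g["time_s"].to_numpy(),
                signal=g["signal"].to_numpy(),
                s0=float(s0),
                i0=float(i0),
                replicate=int(rep),
                detection=str(det),
                ellman=ellman,
            )
        )
    return curves
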