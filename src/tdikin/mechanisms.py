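"""Mass-action reaction networks for enzyme-inhibition kinetics.

A :class:`Mechanism` is a named list of species and elementary steps.  Each
step is uni- or bimolecular with a symbolic rate label; numeric values are
supplied separately through a :class:`RateConstantSet` so the same scheme can
be simulated under many parameterisations (e.g. a scan over the inhibitor
off-rate).

Four schemes used throughout the package are built in:

``competitive_mm``
    E + S <=> ES -> E + P, plus E + I <=> EI.  The textbook competitive
    scheme with an explicit Michaelis complex.
``mixed_mm``
    As above plus ES + I <=> ESI (uncompetitive component).
``slyke_cullen_product``
    The van Slyke-Cullen two-step hydrolysis E + S -> EA + P, EA -> E + A,
    with competitive product inhibition E + P <=> EP.  This is the
    acetylcholinesterase / Ellman-assay scheme: P is thiocholine-TNB (the
    detected chromophore), A is acetate, EA the acylated enzyme.
``slyke_cullen_product_inhibitor``
    As above plus a one-step competitive inhibitor E + I <=> EI
    (galantamine in the case study).

Rate labels follow the field's convention for the hydrolysis scheme:
k1 (apparent bimolecular constant, = kcat/Km), k2 (catalytic constant,
= kcat), k3/k4 (product on/off), k5/k6 (inhibitor on/off, = kon/koff).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "Step",
    "Mechanism",
    "RateConstantSet",
    "build_scheme",
    "derivatives",
    "BUILTIN_SCHEMES",
]


@dataclass(frozen=True)
class Step:
    """One elementary, directed mass-action step.

    Parameters
    ----------
    reactants, products
        Maps species label -> stoichiometry (positive integers).
    rate_label
        Symbolic name of the rate constant (resolved at simulation time).
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_label: str

    def __post_init__(self) -> None:
        for side in (self.reactants, self.products):
            for sp, nu in side.items():
                if not (isinstance(nu, (int, np.integer)) and nu > 0):
                    raise ValueError(
                        f"stoichiometry of {sp!r} in step {self.rate_label!r} "
                        f"must be a positive integer, got {nu!r}"
                    )
        if self.order not in (1, 2):
            raise ValueError(
                f"step {self.rate_label!r} has molecularity {self.order}; "
                "only uni- and bimolecular steps are supported"
            )

    @property
    def order(self) -> int:
        """Molecularity: total reactant stoichiometry (1 or 2)."""
        return int(sum(self.reactants.values()))


@dataclass(frozen=True)
class Mechanism:
    """A named mass-action reaction network."""

    name: str
    species: tuple[str, ...]
    steps: tuple[Step, ...]

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species labels")
        labels = [st.rate_label for st in self.steps]
        if len(set(labels)) != len(labels):
            raise ValueError("rate labels must be unique per directed step")
        known = set(self.species)
        for st in self.steps:
            for sp in (*st.reactants, *st.products):
                if sp not in known:
                    raise ValueError(
                        f"step {st.rate_label!r} references unknown species {sp!r}"
                    )

    @property
    def rate_labels(self) -> tuple[str, ...]:
        return tuple(st.rate_label for st in self.steps)

    def index(self, species: str) -> int:
        return self.species.index(species)

    def stoichiometric_matrix(self) -> np.ndarray:
        """Net stoichiometric matrix N (n_species x n_steps)."""
        n = np.zeros((len(self.species), len(self.steps)))
        for j, st in enumerate(self.steps):
            for sp, nu in st.reactants.items():
                n[self.index(sp), j] -= nu
            for sp, nu in st.products.items():
                n[self.index(sp), j] += nu
        return n

    def conserved_moieties(self, rtol: float = 1e-10) -> np.ndarray:
        """Basis of the left null space of N: rows are conservation vectors.

        For the built-in schemes these span total enzyme and total
        substrate-derived material.
        """
        n = self.stoichiometric_matrix()
        u, s, _ = np.linalg.svd(n)
        rank = int(np.sum(s > rtol * (s[0] if s.size else 1.0)))
        return u[:, rank:].T

    def compile(self, rates: "RateConstantSet | Mapping[str, float]"):
        return CompiledMechanism(self, rates)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "species": list(self.species),
            "steps": [
                {
                    "reactants": dict(st.reactants),
                    "products": dict(st.products),
                    "rate": st.rate_label,
                }
                for st in self.steps
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Mechanism":
        return cls(
            name=d.get("name", "mechanism"),
            species=tuple(d["species"]),
            steps=tuple(
                Step(s["reactants"], s["products"], s["rate"]) for s in d["steps"]
            ),
        )


class RateConstantSet(dict):
    """Map of rate label -> value (first order: s^-1, second order: M^-1 s^-1).

    A thin dict subclass that validates positivity and exposes the derived
    quantities of the built-in schemes (Km, Ki = koff/kon, Vmax = kcat*e0,
    residence time tau = 1/koff).
    """

    def __init__(self, values: Mapping[str, float] | None = None, **kw: float):
        super().__init__()
        merged = dict(values or {})
        merged.update(kw)
        for k, v in merged.items():
            self[k] = v

    def __setitem__(self, key: str, value: float) -> None:
        value = float(value)
        if not np.isfinite(value) or value <= 0.0:
            raise ValueError(f"rate constant {key!r} must be positive and finite, got {value}")
        super().__setitem__(key, value)

    # -- derived quantities ------------------------------------------------
    def ki(self, on: str = "k5", off: str = "k6") -> float:
        """Inhibition dissociation constant koff/kon (M)."""
        return self[off] / self[on]

    def km(self, on: str = "kon_s", off: str = "koff_s", cat: str = "kcat") -> float:
        """Michaelis constant (koff + kcat)/kon for the explicit-ES scheme (M)."""
        return (self[off] + self[cat]) / self[on]

    def vmax(self, e0: float, cat: str = "kcat") -> float:
        """Limiting rate kcat * e0 (M/s)."""
        return self[cat] * e0

    def residence_time(self, off: str = "k6") -> float:
        """Mean lifetime of the inhibited complex, 1/koff (s)."""
        return 1.0 / self[off]


# ---------------------------------------------------------------------------
# Built-in schemes
# ---------------------------------------------------------------------------

def _rev(reactants: dict, products: dict, fwd: str, rev: str) -> list[Step]:
    return [Step(reactants, products, fwd), Step(products, reactants, rev)]


def _competitive_mm() -> Mechanism:
    steps = [
        *_rev({"E": 1, "S": 1}, {"ES": 1}, "kon_s", "koff_s"),
        Step({"ES": 1}, {"E": 1, "P": 1}, "kcat"),
        *_rev({"E": 1, "I": 1}, {"EI": 1}, "kon_i", "koff_i"),
    ]
    return Mechanism("competitive_mm", ("E", "S", "ES", "P", "I", "EI"), tuple(steps))


def _mixed_mm() -> Mechanism:
    base = _competitive_mm()
    steps = list(base.steps) + _rev({"ES": 1, "I": 1}, {"ESI": 1}, "kon_i2", "koff_i2")
    return Mechanism("mixed_mm", base.species + ("ESI",), tuple(steps))


def _slyke_cullen_product() -> Mechanism:
    steps = [
        Step({"E": 1, "S": 1}, {"EA": 1, "P": 1}, "k1"),
        Step({"EA": 1}, {"E": 1, "A": 1}, "k2"),
        *_rev({"E": 1, "P": 1}, {"EP": 1}, "k3", "k4"),
    ]
    return Mechanism(
        "slyke_cullen_product", ("E", "S", "EA", "P", "A", "EP"), tuple(steps)
    )


def _slyke_cullen_product_inhibitor() -> Mechanism:
    base = _slyke_cullen_product()
    steps = list(base.steps) + _rev({"E": 1, "I": 1}, {"EI": 1}, "k5", "k6")
    return Mechanism(
        "slyke_cullen_product_inhibitor", base.species + ("I", "EI"), tuple(steps)
    )


BUILTIN_SCHEMES = {
    "competitive_mm": _competitive_mm,
    "mixed_mm": _mixed_mm,
    "slyke_cullen_product": _slyke_cullen_product,
    "slyke_cullen_product_inhibitor": _slyke_cullen_product_inhibitor,
}


def build_scheme(name: str) -> Mechanism:
    """Return one of the built-in mechanisms by name.

    Raises
    ------
    ValueError
        If ``name`` is not a built-in; the message lists the valid names.
    """
    try:
        factory = BUILTIN_SCHEMES[name]
    except KeyError:
        raise ValueError(
            f"unknown scheme {name!r}; valid names: {sorted(BUILTIN_SCHEMES)}"
        ) from None
    return factory()


# ---------------------------------------------------------------------------
# Compiled right-hand side
# ---------------------------------------------------------------------------

class CompiledMechanism:
    """Mechanism + numeric rates compiled to vectorised rhs and Jacobian.

    The Jacobian is analytic (mass action is polynomial), which lets the
    stiff integrator take large steps over the 10 decades of rates the
    built-in schemes span.
    """

    def __init__(self, mechanism: Mechanism, rates: Mapping[str, float]):
        self.mechanism = mechanism
        missing = [l for l in mechanism.rate_labels if l not in rates]
        if missing:
            raise KeyError(f"missing rate constants: {missing}")
        self.k = np.array([float(rates[l]) for l in mechanism.rate_labels])
        if np.any(~np.isfinite(self.k)) or np.any(self.k < 0):
            raise ValueError("rate constants must be finite and non-negative")
        self.n = mechanism.stoichiometric_matrix()
        # reactant index/stoichiometry lists per step
        self._r_idx: list[np.ndarray] = []
        self._r_st: list[np.ndarray] = []
        for st in mechanism.steps:
            idx = np.array([mechanism.index(sp) for sp in st.reactants], dtype=int)
            sto = np.array([st.reactants[sp] for sp in st.reactants], dtype=int)
            self._r_idx.append(idx)
            self._r_st.append(sto)

    def fluxes(self, y: np.ndarray) -> np.ndarray:
        v = self.k.copy()
        for j, (idx, sto) in enumerate(zip(self._r_idx, self._r_st)):
            for i, m in zip(idx, sto):
                v[j] *= y[i] if m == 1 else y[i] ** m
        return v

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return self.n @ self.fluxes(y)

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        nsp = len(self.mechanism.species)
        dv = np.zeros((len(self.k), nsp))
        for j, (idx, sto) in enumerate(zip(self._r_idx, self._r_st)):
            for pos, (i, m) in enumerate(zip(idx, sto)):
                d = self.k[j] * (m * y[i] ** (m - 1) if m > 1 else 1.0)
                for q, (i2, m2) in enumerate(zip(idx, sto)):
                    if q != pos:
                        d *= y[i2] ** m2
                dv[j, i] += d
        return self.n @ dv


def derivatives(
    mechanism: Mechanism,
    rates: Mapping[str, float],
    state: Mapping[str, float],
    neg_tol: float = 0.0,
) -> dict[str, float]:
    """Exact mass-action time derivatives (M/s) for a state given as a dict.

    ``d[X]/dt = sum over steps of nu_X * k * prod(reactant concentrations)``.
    Concentrations more negative than ``-neg_tol`` are rejected.
    """
    y = np.zeros(len(mechanism.species))
    for sp, c in state.items():
        if sp not in mechanism.species:
            raise KeyError(f"unknown species {sp!r}")
        c = float(c)
        if not np.isfinite(c):
            raise ValueError(f"non-finite concentration for {sp!r}")
        if c < -neg_tol:
            raise ValueError(f"negative concentration for {sp!r}: {c}")
        y[mechanism.index(sp)] = c
    dy = CompiledMechanism(mechanism, rates).rhs(0.0, y)
    return {sp: float(dy[i]) for i, sp in enumerate(mechanism.species)}
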