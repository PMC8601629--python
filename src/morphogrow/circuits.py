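"""Regulatory circuits of secreted diffusible chemicals.

A circuit is a set of chemicals, each with a baseline secretion rate and an
optional list of secretion regulators (Hill links), plus a list of growth
links that gate the cell growth rate.  All quantities are the dimensionless
rescaled parameters of the model: lengths by √(D/γ) of the reference
chemical, concentrations by the relevant growth threshold.

Hill regulation uses very steep exponents (|n| = 100 by default) so each link
acts as a threshold function: an inhibitor link (n < 0) switches its target
off above the threshold, an activator link (n > 0) switches it on.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

DEFAULT_HILL_N = 100.0
_K_FLOOR = 1e-12


class CircuitError(ValueError):
    """Raised for malformed circuits or incomplete concentration vectors."""


def hill(c, K: float, n: float):
    """Hill function c^n / (K^n + c^n), evaluated stably in log space.

    Equal to expit(n·(ln c − ln K)), which avoids overflow at |n| = 100.
    ``n = 0`` means the chemical does not participate and returns exactly 1.
    Accepts scalars or arrays of concentrations; values must be ≥ 0.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise CircuitError("negative concentration passed to hill()")
    if n == 0:
        out = np.ones_like(c)
        return out if out.ndim else float(out)
    K = max(float(K), _K_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = n * (np.log(c) - np.log(K))
    # c == 0: log -> -inf; n<0 gives +inf (no inhibitor -> 1), n>0 gives 0
    t = np.where(c == 0, -np.sign(n) * np.inf, t)
    out = expit(t)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SecretionLink:
    """Hill regulation of one chemical's secretion by another."""

    regulator: str
    Ks: float                       # rescaled secretion threshold K̃s
    n: float = -DEFAULT_HILL_N      # negative: inhibits secretion

    def __post_init__(self):
        if self.Ks <= 0:
            raise CircuitError("secretion threshold Ks must be positive")


@dataclass(frozen=True)
class GrowthLink:
    """Hill regulation of the growth rate by one chemical.

    ``modifiers`` lists (chemical, coefficient a) pairs that linearly lower
    the effective growth threshold: K_eff = Kg·max(1 − Σ a·c̃_mod, 0).  The
    named schemes fold a into the rescaled concentration, so a = 1 there.
    """

    regulator: str
    Kg: float = 1.0
    n: float = -DEFAULT_HILL_N      # negative: growth inhibitor
    modifiers: tuple = ()           # ((chemical, a), ...)

    def __post_init__(self):
        if self.Kg <= 0:
            raise CircuitError("growth threshold Kg must be positive")
        object.__setattr__(self, "modifiers", tuple((str(m), float(a)) for m, a in self.modifiers))


@dataclass(frozen=True)
class Chemical:
    """One secreted diffusible chemical, with its secretion regulation.

    ``b`` (≤ 0) linearly reduces the maximum secretion rate with the
    concentration of ``b_regulator``: μ̃_max = mu0·max(1 + b·c̃_reg, 0).
    ``gamma_r`` is the rescaled degradation ratio (1 for the reference
    chemical).
    """

    name: str
    mu0: float
    gamma_r: float = 1.0
    secretion_links: tuple = ()
    b: float = 0.0
    b_regulator: str | None = None

    def __post_init__(self):
        if self.mu0 < 0:
            raise CircuitError(f"chemical {self.name!r}: mu0 must be >= 0")
        if self.gamma_r <= 0:
            raise CircuitError(f"chemical {self.name!r}: gamma_r must be > 0")
        if self.b > 0:
            raise CircuitError(f"chemical {self.name!r}: b must be <= 0")
        if self.b != 0 and self.b_regulator is None:
            raise CircuitError(f"chemical {self.name!r}: b set without b_regulator")
        object.__setattr__(self, "secretion_links", tuple(self.secretion_links))


@dataclass(frozen=True)
class Circuit:
    """Ordered chemicals plus the growth links gating the cell growth rate."""

    chemicals: tuple = ()
    growth_links: tuple = ()
    name: str = "custom"

    def __post_init__(self):
        object.__setattr__(self, "chemicals", tuple(self.chemicals))
        object.__setattr__(self, "growth_links", tuple(self.growth_links))
        names = [ch.name for ch in self.chemicals]
        if len(set(names)) != len(names):
            raise CircuitError("duplicate chemical names")
        known = set(names)
        for ch in self.chemicals:
            for link in ch.secretion_links:
                if link.regulator not in known:
                    raise CircuitError(f"unknown secretion regulator {link.regulator!r}")
            if ch.b_regulator is not None and ch.b_regulator not in known:
                raise CircuitError(f"unknown b regulator {ch.b_regulator!r}")
        for gl in self.growth_links:
            if gl.regulator not in known:
                raise CircuitError(f"unknown growth regulator {gl.regulator!r}")
            for m, _ in gl.modifiers:
                if m not in known:
                    raise CircuitError(f"unknown threshold modifier {m!r}")
        self.secretion_order()  # raises on cycles

    def chemical(self, name: str) -> Chemical:
        for ch in self.chemicals:
            if ch.name == name:
                return ch
        raise CircuitError(f"no chemical named {name!r}")

    def secretion_order(self) -> list:
        """Chemical names in dependency order; cyclic circuits are rejected."""
        deps = {}
        for ch in self.chemicals:
            d = {link.regulator for link in ch.secretion_links}
            if ch.b_regulator is not None:
                d.add(ch.b_regulator)
            deps[ch.name] = d
        try:
            order = list(graphlib.TopologicalSorter(deps).static_order())
        except graphlib.CycleError as e:
            raise CircuitError("cyclic secretion dependencies are not supported") from e
        return order


def _require(c_vec: Mapping, names) -> None:
    for nm in names:
        if nm not in c_vec:
            raise CircuitError(f"missing concentration entry for {nm!r}")


def secretion_rate(circuit: Circuit, chemical: str, c_vec: Mapping):
    """Secretion rate μ̃ of one chemical given local concentrations.

    μ̃ = mu0 · max(1 + b·c̃_breg, 0) · Π hill(c̃_j | K̃s_j, n_j) over the
    chemical's secretion links.  ``c_vec`` maps names to scalars or arrays.
    """
    ch = circuit.chemical(chemical)
    need = [l.regulator for l in ch.secretion_links]
    if ch.b_regulator is not None:
        need.append(ch.b_regulator)
    _require(c_vec, need)
    rate = ch.mu0
    if ch.b_regulator is not None:
        rate = rate * np.maximum(1.0 + ch.b * np.asarray(c_vec[ch.b_regulator], dtype=float), 0.0)
    for link in ch.secretion_links:
        rate = rate * hill(c_vec[link.regulator], link.Ks, link.n)
    return rate


def growth_rate(circuit: Circuit, c_vec: Mapping):
    """Cell growth rate g ∈ [0, 1] given local concentrations.

    g = Π hill(c̃_j | K_eff_j, n_j) over growth links, with the effective
    threshold K_eff = Kg·max(1 − Σ a·c̃_mod, 0) lowered by any threshold
    modifiers (clamped at 0: a negative threshold is meaningless and simply
    shuts growth off wherever the inhibitor is present).
    """
    need = [gl.regulator for gl in circuit.growth_links]
    for gl in circuit.growth_links:
        need.extend(m for m, _ in gl.modifiers)
    _require(c_vec, need)
    g = None
    for gl in circuit.growth_links:
        if gl.modifiers:
            red = sum(a * np.asarray(c_vec[m], dtype=float) for m, a in gl.modifiers)
            K_eff = gl.Kg * np.maximum(1.0 - red, 0.0)
            c = np.asarray(c_vec[gl.regulator], dtype=float)
            K_eff_b = np.broadcast_to(np.maximum(K_eff, _K_FLOOR), c.shape) if np.ndim(c) else max(float(K_eff), _K_FLOOR)
            if np.ndim(c):
                factor = np.empty_like(c)
                flat_c = c.ravel()
                flat_K = np.asarray(K_eff_b).ravel()
                # hill() takes a scalar K; evaluate via the logistic form directly
                with np.errstate(divide="ignore", invalid="ignore"):
                    t = gl.n * (np.log(flat_c) - np.log(flat_K))
                t = np.where(flat_c == 0, -np.sign(gl.n) * np.inf, t)
                factor = expit(t).reshape(c.shape)
            else:
                factor = hill(c, float(K_eff_b), gl.n)
        else:
            factor = hill(c_vec[gl.regulator], gl.Kg, gl.n)
        g = factor if g is None else g * factor
    if g is None:  # no growth regulation: uniform maximal growth
        shapes = [np.shape(v) for v in c_vec.values()]
        shape = next((s for s in shapes if s), None)
        return np.ones(shape) if shape else 1.0
    return g


# ---------------------------------------------------------------------------
# named schemes
# ---------------------------------------------------------------------------

def build_named_scheme(name: str, params: Mapping | None = None) -> Circuit:
    """Construct one of the standard regulatory schemes.

    ``none``
        no chemicals; g ≡ 1 everywhere.
    ``single_inhibitor(mu_X)``
        X secreted constitutively, inhibits growth above c̃X = 1.
    ``two_inhibitors(mu_X, mu_Y0, Ks, gamma_r)``
        X as above and also inhibits the secretion of a second growth
        inhibitor Y (secreted at mu_Y0 where c̃X < Ks, degradation gamma_r).
    ``threshold_regulator(mu_X, mu_Y0, Ks, gamma_r, b)``
        X inhibits growth; Y (secreted where c̃X < Ks, with secretion
        maximum reduced by c̃X through b ≤ 0) lowers X's growth threshold
        linearly: K_eff = 1 − c̃Y.
    ``activator_s2(mu_X0, mu_Y, gamma_r)``
        Y constitutive; Y inhibits the secretion of the growth activator X;
        growth requires c̃X > 1.
    ``inhibitor_cascade(q, mu, Ks, gamma_r)``
        chain of q growth inhibitors; chemical i is secreted only where all
        chemicals 1..i−1 are below their secretion thresholds.
    """
    p = dict(params or {})

    def take(key, default=None):
        if key in p:
            return float(p.pop(key))
        if default is None:
            raise CircuitError(f"scheme {name!r} requires parameter {key!r}")
        return float(default)

    if name == "none":
        return Circuit(name="none")

    if name == "single_inhibitor":
        mu_X = take("mu_X")
        circ = Circuit(
            chemicals=(Chemical("X", mu0=mu_X, gamma_r=1.0),),
            growth_links=(GrowthLink("X", Kg=1.0, n=-DEFAULT_HILL_N),),
            name=name,
        )
    elif name == "two_inhibitors":
        mu_X, mu_Y0 = take("mu_X"), take("mu_Y0")
        Ks, gr = take("Ks", 1.0), take("gamma_r", 1.0)
        circ = Circuit(
            chemicals=(
                Chemical("X", mu0=mu_X, gamma_r=1.0),
                Chemical("Y", mu0=mu_Y0, gamma_r=gr,
                         secretion_links=(SecretionLink("X", Ks=Ks),)),
            ),
            growth_links=(GrowthLink("X"), GrowthLink("Y")),
            name=name,
        )
    elif name == "threshold_regulator":
        mu_X, mu_Y0 = take("mu_X"), take("mu_Y0")
        Ks, gr, b = take("Ks", 0.9), take("gamma_r", 0.2), take("b", 0.0)
        breg = "X" if b != 0 else None
        circ = Circuit(
            chemicals=(
                Chemical("X", mu0=mu_X, gamma_r=1.0),
                Chemical("Y", mu0=mu_Y0, gamma_r=gr,
                         secretion_links=(SecretionLink("X", Ks=Ks),),
                         b=b, b_regulator=breg),
            ),
            growth_links=(GrowthLink("X", modifiers=(("Y", 1.0),)),),
            name=name,
        )
    elif name == "activator_s2":
        mu_X0, mu_Y = take("mu_X0"), take("mu_Y")
        gr = take("gamma_r", 0.5)
        circ = Circuit(
            chemicals=(
                Chemical("Y", mu0=mu_Y, gamma_r=gr),
                Chemical("X", mu0=mu_X0, gamma_r=1.0,
                         secretion_links=(SecretionLink("Y", Ks=1.0),)),
            ),
            growth_links=(GrowthLink("X", Kg=1.0, n=+DEFAULT_HILL_N),),
            name=name,
        )
    elif name == "inhibitor_cascade":
        q = int(p.pop("q", 0))
        if q < 1:
            raise CircuitError("inhibitor_cascade requires q >= 1")
        mu = p.pop("mu", None)
        if mu is None:
            raise CircuitError("inhibitor_cascade requires 'mu' (list of q rates)")
        mu = [float(v) for v in np.atleast_1d(mu)]
        if len(mu) != q:
            raise CircuitError("inhibitor_cascade: len(mu) must equal q")
        Ks = p.pop("Ks", 1.0)
        Ks = [float(v) for v in (np.full(q, Ks) if np.ndim(Ks) == 0 else np.atleast_1d(Ks))]
        gr = p.pop("gamma_r", 1.0)
        gr = [float(v) for v in (np.full(q, gr) if np.ndim(gr) == 0 else np.atleast_1d(gr))]
        gr[0] = 1.0  # reference chemical
        names = [f"I{i+1}" if q > 2 else "XY"[i] for i in range(q)]
        if q >= 1:
            names[0] = "X"
        if q >= 2:
            names[1] = "Y"
        chems, glinks = [], []
        for i in range(q):
            links = tuple(SecretionLink(names[j], Ks=Ks[j]) for j in range(i))
            chems.append(Chemical(names[i], mu0=mu[i], gamma_r=gr[i], secretion_links=links))
            glinks.append(GrowthLink(names[i]))
        circ = Circuit(chemicals=tuple(chems), growth_links=tuple(glinks), name=f"{name}({q})")
    else:
        raise CircuitError(f"unknown scheme name: {name!r}")

    if p:
        raise CircuitError(f"unused parameters for scheme {name!r}: {sorted(p)}")
    return circ
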