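"""Steady-state reaction–diffusion fields on the unbounded plane.

Each chemical obeys ∇̃²c̃ + μ̃(x) − γr·c̃ = 0 with sources supported inside
the cluster and c̃ → 0 far away.  This is the modified Helmholtz equation;
its 2D free-space Green's function is G(r) = (1/2π)·K₀(√γr·r), so the
solution is the convolution c̃(x) = ∫ μ̃(y)·G(|x−y|) dA(y), evaluated here by
midpoint quadrature over the interior mesh.

The logarithmic singularity of K₀ at r = 0 is regularized by replacing the
kernel, whenever a target lies inside a source cell's equivalent disk
(radius r_e = √(w/π)), with the kernel's exact mean over that disk:
⟨G⟩ = (1 − √γr·r_e·K₁(√γr·r_e)) / (π·γr·r_e²).  This keeps the diagonal
(self) term finite and preserves the quadrature's convergence order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import k0, k1

from . import circuits as _circuits
from .circuits import Circuit
from .geometry import InteriorMesh


class FieldError(ValueError):
    """Raised for invalid sources or meshes."""


def greens_kernel(r, gamma_r: float):
    """Free-space Green's function (1/2π)·K₀(√γr·r) of (∇² − γr) in 2D.

    Diverges logarithmically at r = 0; the quadrature handles that case with
    the disk-mean rule (see module docstring).  Total mass ∫G·2πr dr = 1/γr.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise FieldError("negative distance")
    if gamma_r <= 0:
        raise FieldError("gamma_r must be positive")
    with np.errstate(divide="ignore"):
        out = k0(np.sqrt(gamma_r) * r) / (2.0 * np.pi)
    return out if out.ndim else float(out)


def _disk_mean_kernel(gamma_r: float, r_e: np.ndarray) -> np.ndarray:
    """Mean of G over a disk of radius r_e centered on the source node."""
    kap = np.sqrt(gamma_r)
    return (1.0 - kap * r_e * k1(kap * r_e)) / (np.pi * gamma_r * r_e**2)


def _kernel_sum(targets: np.ndarray, nodes: np.ndarray, weights: np.ndarray,
                source: np.ndarray, gamma_r: float) -> np.ndarray:
    """Σ_j w_j·μ_j·G(|x − x_j|) with the disk-mean regularization."""
    r = cdist(targets, nodes)
    kap = np.sqrt(gamma_r)
    with np.errstate(divide="ignore"):
        G = k0(kap * r) / (2.0 * np.pi)
    r_e = np.sqrt(weights / np.pi)
    near = r < r_e[None, :]
    if np.any(near):
        mean_vals = _disk_mean_kernel(gamma_r, r_e)
        G = np.where(near, mean_vals[None, :], G)
    return G @ (weights * source)


def solve_concentration(mesh: InteriorMesh, source: np.ndarray, gamma_r: float,
                        targets: np.ndarray | None = None) -> np.ndarray:
    """Concentration of one chemical from its per-node secretion rates.

    Returns c̃ at ``targets`` (defaults to the mesh nodes themselves, where
    the self term uses the disk-mean rule).
    """
    if len(mesh) == 0:
        raise FieldError("empty mesh")
    source = np.asarray(source, dtype=float)
    if source.shape != (len(mesh),):
        raise FieldError("source must have one value per mesh node")
    if np.any(source < 0):
        raise FieldError("secretion rates must be non-negative")
    if targets is None:
        targets = mesh.nodes
    return _kernel_sum(np.asarray(targets, dtype=float), mesh.nodes,
                       mesh.weights, source, gamma_r)


@dataclass(frozen=True)
class ConcentrationFields:
    """Per-chemical steady-state fields on a mesh, evaluable anywhere.

    ``values[name]`` are node concentrations; ``sources[name]`` the per-node
    secretion rates that generated them (kept so the field can be evaluated
    at arbitrary query points with the same kernel sum).
    """

    mesh: InteriorMesh
    values: dict
    sources: dict
    gammas: dict

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[name]

    def evaluate(self, name: str, points: np.ndarray) -> np.ndarray:
        """Evaluate chemical ``name`` at arbitrary (x̃, ỹ) query points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return _kernel_sum(pts, self.mesh.nodes, self.mesh.weights,
                           self.sources[name], self.gammas[name])


def solve_circuit_fields(circuit: Circuit, mesh: InteriorMesh) -> ConcentrationFields:
    """Solve all chemicals of a circuit in secretion-dependency order.

    Each chemical's per-node source is its secretion rate evaluated on the
    already-computed upstream fields (feedforward circuits only; cycles are
    rejected by the circuit itself).
    """
    values: dict = {}
    sources: dict = {}
    gammas: dict = {}
    for name in circuit.secretion_order():
        ch = circuit.chemical(name)
        mu = _circuits.secretion_rate(circuit, name, values)
        mu = np.broadcast_to(np.asarray(mu, dtype=float), (len(mesh),)).copy()
        values[name] = solve_concentration(mesh, mu, ch.gamma_r)
        sources[name] = mu
        gammas[name] = ch.gamma_r
    return ConcentrationFields(mesh=mesh, values=values, sources=sources, gammas=gammas)


def growth_field(circuit: Circuit, fields: ConcentrationFields) -> np.ndarray:
    """Per-node growth rate g ∈ [0, 1] from the solved fields."""
    if not circuit.growth_links:
        return np.ones(len(fields.mesh))
    g = _circuits.growth_rate(circuit, fields.values)
    return np.broadcast_to(np.asarray(g, dtype=float), (len(fields.mesh),)).copy()
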