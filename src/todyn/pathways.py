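"""Potential-energy paths and minimum-energy crossing points.

Implements linear interpolation in internal coordinates (LIIC) between anchor
geometries with a mass-weighted path coordinate, relaxed scans along one
coordinate, and penalty-function optimisation of minimum-energy crossing
points (MECPs) that needs only state energies and gradients — no nonadiabatic
coupling vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .constants import HARTREE_EV
from .surfaces import SurfaceModel, adiabatize, adiabatic_gradient

__all__ = ["PathProfile", "MECPResult", "liic_path", "relaxed_scan",
           "optimize_mecp", "minimize_state"]


@dataclass
class PathProfile:
    """A sequence of geometries with mass-weighted path coordinate and energies.

    ``energies`` maps a manifold name (``"singlet"``/``"triplet"``) to an
    array of shape (n_points, n_states_in_manifold); ``anchors`` maps point
    indices to labels (minima, MECPs).
    """

    coords: np.ndarray          # (n_points, n_coords)
    path_coord: np.ndarray      # (n_points,) in amu^0.5 · Å
    energies: dict
    anchors: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.path_coord[0] != 0.0:
            raise ValueError("path coordinate must start at 0")
        if np.any(np.diff(self.path_coord) < 0):
            raise ValueError("path coordinate must be nondecreasing")

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: path coordinate, per-state energies, anchor labels."""
        data = {"path_coord_amu05_A": self.path_coord}
        for manifold, e in self.energies.items():
            prefix = "S" if manifold == "singlet" else "T"
            shift = 0 if manifold == "singlet" else 1
            for k in range(e.shape[1]):
                data[f"E_{prefix}{k + shift}_eV"] = e[:, k]
        labels = [""] * len(self.path_coord)
        for i, lab in self.anchors.items():
            labels[i] = lab
        data["anchor_label"] = labels
        return pd.DataFrame(data)


@dataclass
class MECPResult:
    """Converged minimum-energy crossing point between two surfaces."""

    geometry: np.ndarray
    pair: tuple
    energy: float               # mean of the two state energies, eV
    gap: float                  # final |E_i - E_j|, eV
    barrier: float | None       # energy relative to a reference minimum, eV
    converged: bool
    trace: list = field(default_factory=list)


def _mass_weighted_length(model: SurfaceModel, a: np.ndarray, b: np.ndarray) -> float:
    d = b - a
    return float(np.sqrt(np.sum(model.masses * d * d)))


def _evaluate_energies(model: SurfaceModel, coords: np.ndarray, manifolds) -> dict:
    out = {}
    for manifold in manifolds:
        if manifold == "triplet" and len(model.triplet_indices) == 0:
            continue
        rows = [adiabatize(model, q, manifold=manifold).energies for q in coords]
        out[manifold] = np.array(rows)
    return out


def liic_path(model: SurfaceModel, anchors, n_per_segment: int = 10,
              labels=None, manifolds=("singlet", "triplet")) -> PathProfile:
    """LIIC profile through ``anchors`` with ``n_per_segment`` interior points.

    Each segment is interpolated linearly per internal coordinate and the
    path coordinate accumulates the mass-weighted Euclidean length
    ``sqrt(Σ_i m_i Δq_i²)`` between consecutive points.
    """
    anchors = [model.coords_of(a) for a in anchors]
    if len(anchors) < 2:
        raise ValueError("need at least two anchor geometries")
    points = [anchors[0]]
    anchor_idx = {0: (labels[0] if labels else "anchor0")}
    for k in range(len(anchors) - 1):
        a, b = anchors[k], anchors[k + 1]
        for j in range(1, n_per_segment + 1):
            t = j / (n_per_segment + 1)
            points.append(a + t * (b - a))
        points.append(b.copy())
        anchor_idx[len(points) - 1] = labels[k + 1] if labels else f"anchor{k + 1}"
    coords = np.array(points)
    s = np.zeros(len(coords))
    for i in range(1, len(coords)):
        s[i] = s[i - 1] + _mass_weighted_length(model, coords[i - 1], coords[i])
    energies = _evaluate_energies(model, coords, manifolds)
    return PathProfile(coords=coords, path_coord=s, energies=energies, anchors=anchor_idx)


def minimize_state(model: SurfaceModel, q0, state: int = 0, manifold: str = "singlet",
                   gtol: float = 1e-7, frozen: dict | None = None):
    """Minimise one adiabatic surface; returns (geometry, energy).

    ``frozen`` maps coordinate indices to fixed values (used by relaxed scans).
    """
    q0 = model.coords_of(q0).copy()
    frozen = frozen or {}
    free = [i for i in range(model.n_coords) if i not in frozen]
    if not free:
        raise ValueError("no free coordinates to optimise")

    def assemble(x):
        q = q0.copy()
        q[free] = x
        for i, v in frozen.items():
            q[i] = v
        return q

    def fun(x):
        q = assemble(x)
        ad = adiabatize(model, q, manifold=manifold)
        g = adiabatic_gradient(model, q, state, manifold=manifold, adiabatic=ad)
        return float(ad.energies[state]), g[free]

    res = minimize(fun, q0[free], jac=True, method="L-BFGS-B",
                   options={"gtol": gtol, "maxiter": 500})
    q = assemble(res.x)
    return q, float(res.fun)


def relaxed_scan(model: SurfaceModel, state: int, scan_coord: str, values,
                 q0, manifold: str = "singlet", gtol: float = 1e-6) -> PathProfile:
    """Relaxed scan: minimise all other coordinates on one adiabatic surface.

    Each scan point is warm-started from the previous relaxed geometry;
    points whose inner minimisation stalls are flagged in ``anchors`` but the
    scan continues.
    """
    if scan_coord not in model.coord_names:
        raise ValueError(f"unknown scan coordinate {scan_coord!r}; "
                         f"available: {model.coord_names}")
    ci = model.coord_names.index(scan_coord)
    q = model.coords_of(q0).copy()
    coords = []
    flags = {}
    for k, v in enumerate(values):
        try:
            q, _ = minimize_state(model, q, state=state, manifold=manifold,
                                  gtol=gtol, frozen={ci: float(v)})
        except Exception:
            flags[k] = "not-converged"
        coords.append(q.copy())
    coords = np.array(coords)
    s = np.zeros(len(coords))
    for i in range(1, len(coords)):
        s[i] = s[i - 1] + _mass_weighted_length(model, coords[i - 1], coords[i])
    energies = _evaluate_energies(model, coords, ("singlet", "triplet"))
    return PathProfile(coords=coords, path_coord=s, energies=energies, anchors=flags)


def optimize_mecp(model: SurfaceModel, pair, q0, reference_energy: float | None = None,
                  sigma0: float = 3.5, alpha_hartree: float = 0.02,
                  gap_tol: float = 1e-3, grad_tol: float = 1e-3,
                  max_outer: int = 30, bounds=None) -> MECPResult:
    """Penalty-function MECP optimisation without nonadiabatic couplings.

    Minimises ``F_σ = (E_i+E_j)/2 + σ·ΔE²/(|ΔE|+α)`` with a smoothing
    parameter α (default 0.02 Hartree) and doubles the penalty strength σ
    until the gap drops below ``gap_tol`` (eV) and the mean-energy gradient
    projected onto the seam is below ``grad_tol`` (eV/Å).

    ``pair`` is two ``(manifold, state_index)`` tuples, e.g.
    ``(("singlet", 1), ("singlet", 0))`` for the S1/S0 seam.  Optional
    per-coordinate ``bounds`` keep the search inside one seam basin when a
    crossing seam has several local minima; they must not be active at the
    converged point.
    """
    (man_i, st_i), (man_j, st_j) = pair
    if (man_i, st_i) == (man_j, st_j):
        raise ValueError("MECP requires two distinct states")
    alpha = alpha_hartree * HARTREE_EV
    q = model.coords_of(q0).copy()
    if not np.all(np.isfinite(q)):
        raise ValueError("start geometry must be finite")
    sigma = float(sigma0)
    trace = []

    def eval_states(qq):
        ad_i = adiabatize(model, qq, manifold=man_i)
        ad_j = ad_i if man_j == man_i else adiabatize(model, qq, manifold=man_j)
        ei = float(ad_i.energies[st_i])
        ej = float(ad_j.energies[st_j])
        gi = adiabatic_gradient(model, qq, st_i, manifold=man_i, adiabatic=ad_i)
        gj = adiabatic_gradient(model, qq, st_j, manifold=man_j, adiabatic=ad_j)
        return ei, ej, gi, gj

    lo_b = hi_b = None
    if bounds is not None:
        lo_b = np.array([-np.inf if b is None or b[0] is None else b[0] for b in bounds])
        hi_b = np.array([np.inf if b is None or b[1] is None else b[1] for b in bounds])

    def clip(qq):
        return np.clip(qq, lo_b, hi_b) if bounds is not None else qq

    def refine_on_seam(qq, max_iter=400, eta=0.02):
        """Polish: Newton steps back onto the seam + projected-gradient descent
        of the mean energy along it (the stiff penalty valley limits L-BFGS)."""
        for _ in range(max_iter):
            ei, ej, gi, gj = eval_states(qq)
            u = ei - ej
            dvec = gi - gj
            nd2 = float(dvec @ dvec)
            if nd2 == 0:
                break
            gmean = 0.5 * (gi + gj)
            gseam = gmean - (gmean @ dvec) / nd2 * dvec
            if abs(u) < 0.1 * gap_tol and np.linalg.norm(gseam) < 0.5 * grad_tol:
                break
            qq = clip(qq - u * dvec / nd2 - eta * gseam)
        return qq

    converged = False
    for _ in range(max_outer):
        def penalty(x, _sigma=sigma):
            ei, ej, gi, gj = eval_states(x)
            u = ei - ej
            f = 0.5 * (ei + ej) + _sigma * u * u / (abs(u) + alpha)
            du = (2.0 * u * (abs(u) + alpha) - u * u * np.sign(u)) / (abs(u) + alpha) ** 2
            g = 0.5 * (gi + gj) + _sigma * du * (gi - gj)
            return f, g

        res = minimize(penalty, q, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"gtol": 1e-8, "maxiter": 400})
        q = res.x
        ei, ej, gi, gj = eval_states(q)
        if abs(ei - ej) < 10 * gap_tol:
            q = refine_on_seam(q)
            ei, ej, gi, gj = eval_states(q)
        gap = abs(ei - ej)
        gmean = 0.5 * (gi + gj)
        dvec = gi - gj
        nd = np.linalg.norm(dvec)
        if nd > 0:
            seam_grad = gmean - (gmean @ dvec) / nd**2 * dvec
        else:
            seam_grad = gmean
        trace.append({"sigma": sigma, "gap": gap,
                      "seam_grad": float(np.linalg.norm(seam_grad))})
        if gap < gap_tol and np.linalg.norm(seam_grad) < grad_tol:
            converged = True
            break
        sigma *= 2.0

    energy = 0.5 * (ei + ej)
    if not converged:
        raise RuntimeError(
            f"MECP optimisation did not converge: gap={gap:.4e} eV after "
            f"{len(trace)} penalty cycles (trace: {trace[-3:]})")
    barrier = None if reference_energy is None else energy - reference_energy
    return MECPResult(geometry=q, pair=tuple(pair), energy=float(energy),
                      gap=float(gap), barrier=barrier, converged=converged,
                      trace=trace)
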