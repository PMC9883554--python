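"""Closed-form reference solutions used to gate the numerical solver.

Two fixtures:

* :func:`slab_solution` — a 1-D stack of layers between two full-face plate
  electrodes (series impedance; exact per-layer E, J, Q and complex power);
* :func:`layered_sphere_solution` — an N-layer concentric sphere driven by
  two opposed polar-cap current patches, solved as a Legendre series with
  per-shell radial coefficients matched by continuity of potential and
  normal current.

Both are independent of the finite-volume discretization and serve as the
ground-truth surface for accuracy gates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.special import eval_legendre


@dataclass(frozen=True)
class SlabStack:
    """Ordered stack of layers between plate electrodes.

    ``layers`` is a sequence of (thickness_m, complex admittivity S/m) from
    the driven plate to the grounded plate; ``voltage`` is applied across
    the whole stack over cross-section ``area`` (m^2).
    """

    layers: Tuple[Tuple[float, complex], ...]
    voltage: float = 80.0
    area: float = 1.0

    def __post_init__(self):
        if len(self.layers) == 0:
            raise ValueError("slab stack needs at least one layer")
        for d, _ in self.layers:
            if d <= 0:
                raise ValueError(f"layer thickness must be > 0, got {d}")


@dataclass(frozen=True)
class SlabSolution:
    E: Tuple[complex, ...]  # per-layer field, V/m
    J: complex  # uniform current density, A/m^2
    Q: Tuple[float, ...]  # per-layer heating, W/m^3
    impedance: complex  # ohms
    power: complex  # complex power 1/2 V conj(I), W


def slab_solution(stack: SlabStack) -> SlabSolution:
    """Exact series solution of the layered 1-D slab."""
    kappas = [complex(k) for _, k in stack.layers]
    if any(k == 0 for k in kappas):
        if any(k != 0 for k in kappas):
            return SlabSolution(
                E=tuple(0.0j for _ in kappas),
                J=0.0j,
                Q=tuple(0.0 for _ in kappas),
                impedance=complex(np.inf),
                power=0.0j,
            )
        raise ValueError("all-zero admittivity stack has no solution")
    Z = sum(d / (k * stack.area) for (d, _), k in zip(stack.layers, kappas))
    J = stack.voltage / (Z * stack.area)
    E = tuple(J / k for k in kappas)
    Q = tuple(0.5 * float(np.real(J * np.conj(e))) for e in E)
    power = 0.5 * stack.voltage * np.conj(J * stack.area)
    return SlabSolution(E=E, J=J, Q=Q, impedance=Z, power=power)


# ---------------------------------------------------------------------------
# layered sphere
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LayeredSphere:
    """Concentric shells driven by opposed polar-cap current patches.

    ``radii`` are outer radii of the shells in meters, strictly decreasing;
    shell k occupies ``radii[k+1] <= r <= radii[k]`` (the innermost fills to
    the center).  A total current ``current`` (A) enters uniformly over the
    north polar cap (half-angle ``cap_half_angle_deg``) and leaves over the
    mirrored south cap.  ``order`` truncates the Legendre series.
    """

    radii: Tuple[float, ...]
    kappas: Tuple[complex, ...]
    current: float = 1e-3
    cap_half_angle_deg: float = 10.0
    order: int = 120
    swap_caps: bool = False

    def __post_init__(self):
        r = self.radii
        if len(r) != len(self.kappas):
            raise ValueError("radii and kappas must have equal length")
        if any(a <= b for a, b in zip(r, r[1:])) or any(x <= 0 for x in r):
            raise ValueError(f"radii must be positive and strictly decreasing, got {r}")
        if self.order < 1:
            raise ValueError("series order must be >= 1")

    @property
    def cap_current_density(self) -> float:
        """Uniform inward current density on each cap, A/m^2."""
        alpha = np.deg2rad(self.cap_half_angle_deg)
        cap_area = 2 * np.pi * self.radii[0] ** 2 * (1 - np.cos(alpha))
        return self.current / cap_area


def _cap_flux_coefficients(sph: LayeredSphere) -> np.ndarray:
    """Legendre coefficients j_l of the prescribed radial flux at r = R1.

    The antisymmetric cap pair excites odd degrees only:
    ``j_l = J0 * (P_{l-1}(c) - P_{l+1}(c))`` with ``c = cos(alpha)``.
    """
    c = np.cos(np.deg2rad(sph.cap_half_angle_deg))
    J0 = sph.cap_current_density * (-1.0 if sph.swap_caps else 1.0)
    L = sph.order
    jl = np.zeros(L + 1)
    for l in range(1, L + 1, 2):
        jl[l] = J0 * (eval_legendre(l - 1, c) - eval_legendre(l + 1, c))
    return jl


def _radial_coefficients(sph: LayeredSphere) -> Tuple[np.ndarray, np.ndarray]:
    """Per-shell (A_l, B_l) such that phi_k = A r'^l + B r'^{-l-1}, r' = r/R1."""
    R1 = sph.radii[0]
    rs = np.asarray(sph.radii) / R1
    ks = np.asarray(sph.kappas, dtype=complex)
    N = len(rs)
    jl = _cap_flux_coefficients(sph)
    L = sph.order
    A = np.zeros((L + 1, N), dtype=complex)
    B = np.zeros((L + 1, N), dtype=complex)
    for l in range(1, L + 1, 2):
        # unknowns: A_1, B_1, ..., A_{N-1}, B_{N-1}, A_N  (B_N = 0)
        n_unk = 2 * N - 1
        M = np.zeros((n_unk, n_unk), dtype=complex)
        rhs = np.zeros(n_unk, dtype=complex)

        def col_A(k):
            return 2 * k

        def col_B(k):
            return 2 * k + 1  # only valid for k < N-1

        # outer Neumann: kappa_1 * dphi/dr (r=R1) = j_l ; d/dr = (1/R1) d/dr'
        M[0, col_A(0)] = ks[0] * l / R1
        M[0, col_B(0)] = -ks[0] * (l + 1) / R1
        rhs[0] = jl[l]
        row = 1
        for k in range(N - 1):
            rb = rs[k + 1]  # interface between shell k and k+1 (scaled)
            pl = rb**l
            pm = rb ** (-(l + 1))
            # potential continuity
            M[row, col_A(k)] = pl
            if k < N - 1:
                M[row, col_B(k)] = pm
            M[row, col_A(k + 1)] = -pl
            if k + 1 < N - 1:
                M[row, col_B(k + 1)] = -pm
            row += 1
            # normal current continuity
            dpl = l * rb ** (l - 1)
            dpm = -(l + 1) * rb ** (-(l + 2))
            M[row, col_A(k)] = ks[k] * dpl
            M[row, col_B(k)] = ks[k] * dpm
            M[row, col_A(k + 1)] = -ks[k + 1] * dpl
            if k + 1 < N - 1:
                M[row, col_B(k + 1)] = -ks[k + 1] * dpm
            row += 1
        try:
            sol = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise RuntimeError(f"sphere series system singular at degree l={l}: {exc}") from exc
        if not np.all(np.isfinite(sol)):
            raise RuntimeError(f"sphere series coefficients not finite at degree l={l}")
        for k in range(N):
            A[l, k] = sol[col_A(k)]
            if k < N - 1:
                B[l, k] = sol[col_B(k)]
    return A, B


def layered_sphere_solution(
    sph: LayeredSphere,
    points: np.ndarray,
    return_bound: bool = False,
):
    """Series potential at ``points`` (shape (n, 3), meters, inside R1).

    Returns the potential array, and optionally an estimate of the
    truncation error (magnitude of the last retained odd degree's
    contribution, point-wise maximum).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must have shape (n, 3)")
    R1 = sph.radii[0]
    r = np.linalg.norm(pts, axis=1)
    if np.any(r > R1 * (1 + 1e-9)):
        raise ValueError("evaluation points must lie inside the outer radius")
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = np.where(r > 0, pts[:, 2] / np.maximum(r, 1e-300), 1.0)
    cos_t = np.clip(cos_t, -1.0, 1.0)
    rp = r / R1

    A, B = _radial_coefficients(sph)
    radii_scaled = np.asarray(sph.radii) / R1
    # shell index per point: first shell whose inner radius <= r
    shell = np.zeros(len(pts), dtype=int)
    for k in range(1, len(radii_scaled)):
        shell[rp <= radii_scaled[k] + 1e-12] = k

    phi = np.zeros(len(pts), dtype=complex)
    last_term = np.zeros(len(pts))
    N = len(sph.radii)
    for l in range(1, sph.order + 1, 2):
        P = eval_legendre(l, cos_t)
        term = np.zeros(len(pts), dtype=complex)
        for k in range(N):
            m = shell == k
            if not m.any():
                continue
            rr = rp[m]
            rad = A[l, k] * rr**l
            if k < N - 1:
                with np.errstate(divide="ignore"):
                    rad = rad + B[l, k] * np.where(rr > 0, rr ** (-(l + 1)), 0.0)
            term[m] = rad
        contrib = term * P
        phi += contrib
        last_term = np.abs(contrib)
    if np.all(phi == 0) and np.any(_cap_flux_coefficients(sph) != 0):
        raise RuntimeError("series evaluated to zero; non-convergent parameters")
    if return_bound:
        return phi, float(last_term.max())
    return phi


def homogeneous_sphere_potential(
    radius: float,
    kappa: complex,
    current: float,
    cap_half_angle_deg: float,
    points: np.ndarray,
    order: int = 120,
) -> np.ndarray:
    """Closed form for the uniform sphere (independent of the layered path).

    ``phi = sum_l j_l R / (kappa l) (r/R)^l P_l(cos theta)`` with the cap
    flux coefficients j_l; used to check the degenerate layering case.
    """
    sph = LayeredSphere(
        radii=(radius,), kappas=(kappa,), current=current,
        cap_half_angle_deg=cap_half_angle_deg, order=order,
    )
    jl = _cap_flux_coefficients(sph)
    pts = np.asarray(points, dtype=float)
    r = np.linalg.norm(pts, axis=1)
    cos_t = np.clip(np.where(r > 0, pts[:, 2] / np.maximum(r, 1e-300), 1.0), -1, 1)
    rp = r / radius
    phi = np.zeros(len(pts), dtype=complex)
    for l in range(1, order + 1, 2):
        phi += jl[l] * radius / (kappa * l) * rp**l * eval_legendre(l, cos_t)
    return phi


def cap_potential_difference(sph: LayeredSphere) -> complex:
    """Potential difference between the two cap centers on the surface."""
    R1 = sph.radii[0]
    pts = np.array([[0.0, 0.0, R1], [0.0, 0.0, -R1]])
    phi = layered_sphere_solution(sph, pts)
    return complex(phi[0] - phi[1])


# ---------------------------------------------------------------------------
# numerical cross-validation helpers
# ---------------------------------------------------------------------------


def sphere_cap_neumann_faces(ph, sph: LayeredSphere):
    """Boundary-face currents on a voxelized sphere mimicking the cap drive.

    For every domain-boundary face whose centroid lies within a cap's
    angular window, the prescribed inward current equals the cap current
    density times the face area projected onto the local radial direction
    (so the stair-stepped surface carries the correct total current).  A
    final proportional correction zeroes the net injected current exactly.
    """
    from .em_solver import BoundaryFaces, _lo_hi

    mask = ph.domain_mask()
    shape = mask.shape
    dx = ph.spacing * 1e-3
    area = dx * dx
    alpha = np.deg2rad(sph.cap_half_angle_deg)
    J0 = sph.cap_current_density * (-1.0 if sph.swap_caps else 1.0)
    x, y, z = ph.coords()
    coords = np.stack(np.broadcast_arrays(x, y, z), axis=-1) * 1e-3  # m

    voxs, axs, sds, vals = [], [], [], []
    for a in range(3):
        for side in (1, -1):
            nb_outside = np.ones(shape, dtype=bool)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if side == 1:
                dst[a] = slice(None, -1)
                src[a] = slice(1, None)
            else:
                dst[a] = slice(1, None)
                src[a] = slice(None, -1)
            nb_outside[tuple(dst)] = ~mask[tuple(src)]
            sel = mask & nb_outside
            if not sel.any():
                continue
            fc = coords[sel].copy()
            fc[:, a] += side * dx / 2.0
            rn = np.linalg.norm(fc, axis=1)
            cos_t = np.clip(fc[:, 2] / np.maximum(rn, 1e-300), -1, 1)
            theta = np.arccos(cos_t)
            sign = np.where(theta <= alpha, 1.0, np.where(theta >= np.pi - alpha, -1.0, 0.0))
            proj = np.clip(side * fc[:, a] / np.maximum(rn, 1e-300), 0.0, None)
            I = sign * J0 * area * proj
            nz = I != 0
            if not nz.any():
                continue
            flat = np.flatnonzero(sel.ravel())[nz]
            voxs.append(flat)
            axs.append(np.full(flat.shape, a))
            sds.append(np.full(flat.shape, side))
            vals.append(I[nz].astype(complex))
    vox = np.concatenate(voxs)
    val = np.concatenate(vals)
    # rescale each cap so its staircase carries exactly +-I (the projected
    # area of the voxelized cap differs from the spherical cap by O(dx))
    I = sph.current * (-1.0 if sph.swap_caps else 1.0)
    pos, neg = val.real > 0, val.real < 0
    val[pos] *= I / val[pos].sum()
    val[neg] *= -I / val[neg].sum()
    return BoundaryFaces(vox, np.concatenate(axs), np.concatenate(sds), val)


def to_point_table(points: np.ndarray, phi: np.ndarray):
    """Oracle output as a tidy table (meters, volts)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "x_m": points[:, 0],
            "y_m": points[:, 1],
            "z_m": points[:, 2],
            "phi_real_V": np.real(phi),
            "phi_imag_V": np.imag(phi),
        }
    )


def load_sphere_fixture(path) -> LayeredSphere:
    """Read a sphere fixture definition from JSON."""
    d = json.loads(Path(path).read_text())
    kappas = tuple(complex(k[0], k[1]) if isinstance(k, (list, tuple)) else complex(k) for k in d["kappas"])
    return LayeredSphere(
        radii=tuple(float(r) for r in d["radii_m"]),
        kappas=kappas,
        current=float(d.get("current_A", 1e-3)),
        cap_half_angle_deg=float(d.get("cap_half_angle_deg", 10.0)),
        order=int(d.get("order", 120)),
    )
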