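"""Dose and thermogenesis metrics.

Implements the volumetric Joule heating map ``Q = 1/2 Re(J . E*)``, per-gel
heating-power summaries, per-tissue field statistics (reported in V/cm),
above-threshold volumes (ATV) of the tumor shell, and the power-normalized
field strength ``E_normalized = E2 * sqrt(W1 / W2)`` used to compare cases
at equal maximum gel heating power.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .em_solver import FieldSolution
from .synthetic_phantom import (
    BRAIN_CODES,
    HYDROGEL,
    LABEL_CODES,
    VoxelPhantom,
)
from .tissue_model import TissueTable

V_PER_M_TO_V_PER_CM = 1e-2


class EmptyMaskError(ValueError):
    def __init__(self, name: str):
        super().__init__(f"tissue mask {name!r} is empty")
        self.name = name


@dataclass
class HeatingMap:
    """Volumetric heating power per voxel, W/m^3."""

    Q: np.ndarray
    spacing: float  # mm

    def voxel_volume_m3(self) -> float:
        return float((self.spacing * 1e-3) ** 3)

    def total_power(self) -> float:
        """Domain-integrated real dissipated power, W."""
        return float(np.nansum(self.Q) * self.voxel_volume_m3())


def joule_heating(sol: FieldSolution, props: TissueTable = None, ph: VoxelPhantom = None) -> HeatingMap:
    """Joule heating ``Q = 1/2 Re(J . E*)`` per voxel (W/m^3).

    Equals ``1/2 sigma |E|^2`` wherever the admittivity is real; is zero in
    non-conductive tissue (electrode body, air at DC).  When the solution
    carries the solver's half-cell-integrated dissipation density (set by
    ``attach_fields``), that map is used: it evaluates the same integrand
    face-by-face, reduces to the voxel formula in uniform fields, and its
    domain integral matches the electrode input power exactly.  Otherwise
    the voxel-centered fields are used directly.  ``props``/``ph`` are
    accepted for interface symmetry but not needed: J is stored on the
    solution.
    """
    if getattr(sol, "Q_density", None) is not None:
        return HeatingMap(Q=sol.Q_density.copy(), spacing=sol.spacing)
    if sol.E is None or sol.J is None:
        raise ValueError("solution carries no fields; call attach_fields first")
    Q = 0.5 * np.real(np.einsum("...c,...c->...", sol.J, np.conj(sol.E)))
    Q[~sol.mask] = 0.0
    # clip tiny negative round-off; Q is nonnegative by construction
    np.clip(Q, 0.0, None, out=Q)
    return HeatingMap(Q=Q, spacing=sol.spacing)


def gel_power_stats(Q: HeatingMap, ph: VoxelPhantom, arrays=None) -> pd.DataFrame:
    """Per-gel-pad heating statistics.

    Returns one row per gel pad with the pad's max and mean volumetric
    heating power (W/m^3) and integrated power (W).  Rows are ordered by gel
    id, so ties in any downstream argmax resolve to the lowest id.
    """
    gel = ph.labels == HYDROGEL
    if not gel.any():
        raise EmptyMaskError("hydrogel")
    vol = Q.voxel_volume_m3()
    rows = []
    for gid in np.unique(ph.gel_id[gel]):
        m = gel & (ph.gel_id == gid)
        q = Q.Q[m]
        rows.append(
            {
                "gel_id": int(gid),
                "array": 0 if gid < 9 else 1,
                "n_voxels": int(m.sum()),
                "max_Q_W_per_m3": float(q.max()),
                "mean_Q_W_per_m3": float(q.mean()),
                "power_W": float(q.sum() * vol),
            }
        )
    return pd.DataFrame(rows).sort_values("gel_id", ignore_index=True)


def max_gel_heating(gel_table: pd.DataFrame) -> float:
    """W_max: maximum over gel pads of the pad-wise maximum Q (W/m^3)."""
    return float(gel_table["max_Q_W_per_m3"].max())


def _resolve_mask(ph: VoxelPhantom, tissue: Union[str, np.ndarray]) -> np.ndarray:
    if isinstance(tissue, np.ndarray):
        return tissue
    if tissue == "brain":
        return np.isin(ph.labels, BRAIN_CODES)
    return ph.labels == LABEL_CODES[tissue]


def tissue_field_stats(
    sol: FieldSolution,
    ph: VoxelPhantom,
    tissues: Sequence[str] = ("tumor_core", "tumor_shell", "brain"),
) -> Dict[str, Dict[str, float]]:
    """Volume-weighted mean and max |E| per tissue, in V/cm.

    ``"brain"`` denotes the union of gray matter, white matter and CSF.
    """
    emag = sol.e_magnitude() * V_PER_M_TO_V_PER_CM
    out: Dict[str, Dict[str, float]] = {}
    for t in tissues:
        m = _resolve_mask(ph, t)
        if not m.any():
            raise EmptyMaskError(t if isinstance(t, str) else "custom")
        vals = emag[m]
        out[str(t)] = {
            "mean_V_per_cm": float(vals.mean()),
            "max_V_per_cm": float(vals.max()),
        }
    return out


def atv(
    sol_or_emag: Union[FieldSolution, np.ndarray],
    shell_mask: np.ndarray,
    threshold: float,
) -> float:
    """Percent of the shell volume with |E| >= threshold (V/cm, inclusive)."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    if not shell_mask.any():
        raise EmptyMaskError("tumor_shell")
    if isinstance(sol_or_emag, FieldSolution):
        emag = sol_or_emag.e_magnitude() * V_PER_M_TO_V_PER_CM
    else:
        emag = np.asarray(sol_or_emag, dtype=float)
    vals = emag[shell_mask]
    return 100.0 * float((vals >= threshold).sum()) / float(vals.size)


def normalized_field_strength(E2: float, W1: float, W2: float) -> float:
    """Power-normalized field strength ``E2 * sqrt(W1 / W2)``.

    ``W1``/``W2`` are the maximum per-gel heating powers of the benchmark
    (intact) and evaluated cases; when ``E2`` is the evaluated case's mean
    shell field relative to the benchmark, the result is a fraction of the
    benchmark (multiply by 100 for percent).
    """
    if not (W1 > 0) or not (W2 > 0):
        raise ValueError(f"heating powers must be > 0, got W1={W1}, W2={W2}")
    if E2 < 0:
        raise ValueError(f"E2 must be >= 0, got {E2}")
    return float(E2 * np.sqrt(W1 / W2))


@dataclass
class CaseSummary:
    """All reported metrics for one simulated case."""

    case: str
    field_stats: Dict[str, Dict[str, float]]
    atv_percent: Dict[str, float]
    gel_table: List[dict]
    W_max: float
    E_norm_percent: Optional[float] = None
    solver_info: dict = field(default_factory=dict)
    voxel_counts: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "case": self.case,
            "field_stats": self.field_stats,
            "atv_percent": self.atv_percent,
            "gel_table": self.gel_table,
            "W_max_W_per_m3": self.W_max,
            "E_norm_percent": self.E_norm_percent,
            "solver_info": self.solver_info,
            "voxel_counts": self.voxel_counts,
        }

    def gel_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.gel_table)


def summarize_case(
    case: str,
    sol: FieldSolution,
    ph: VoxelPhantom,
    thresholds: Sequence[float] = (1.0, 2.5),
) -> CaseSummary:
    """Bundle the standard per-case metrics into a :class:`CaseSummary`."""
    stats = tissue_field_stats(sol, ph)
    shell = ph.mask("tumor_shell")
    atvs = {f"{t:g}": atv(sol, shell, t) for t in thresholds}
    Q = joule_heating(sol)
    gels = gel_power_stats(Q, ph)
    counts = {
        name: int((ph.labels == code).sum())
        for name, code in LABEL_CODES.items()
        if code != 0 and (ph.labels == code).any()
    }
    return CaseSummary(
        case=case,
        field_stats=stats,
        atv_percent=atvs,
        gel_table=gels.to_dict(orient="records"),
        W_max=max_gel_heating(gels),
        solver_info=dict(sol.info, residual=sol.residual),
        voxel_counts=counts,
    )
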