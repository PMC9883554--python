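"""Three-case study orchestration (intact / defect / insulated).

Builds the phantom for each case from one shared configuration, solves the
field, computes the case metrics, and assembles the comparison table with
the power-normalized field strength of each case relative to the intact
baseline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd

from . import metrics, synthetic_phantom
from .em_solver import ContactFilm, FieldSolution, SolverConfig, input_power, solve_case_fields
from .metrics import CaseSummary, normalized_field_strength, summarize_case
from .synthetic_phantom import PhantomConfig, VoxelPhantom, _load_config_dict
from .tissue_model import TissueTable

log = logging.getLogger(__name__)

CASES = ("intact", "defect", "insulated")


class StudyConfigError(ValueError):
    pass


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to run and compare the three cases."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    film: ContactFilm = field(default_factory=ContactFilm)
    thresholds: Tuple[float, ...] = (1.0, 2.5)
    cases: Tuple[str, ...] = CASES
    out_dir: Optional[str] = None
    seed: Optional[int] = None
    name: str = "study"

    def validate(self) -> None:
        unknown = set(self.cases) - set(CASES)
        if unknown:
            raise StudyConfigError(f"unknown cases {sorted(unknown)}; valid: {CASES}")
        if "insulated" in self.cases and self.phantom.defect_diameter <= 0:
            raise StudyConfigError("the insulated case requires defect geometry (defect_diameter > 0)")
        self.phantom.validate()

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "phantom": self.phantom.to_dict(),
            "solver": {
                "applied_voltage": self.solver.applied_voltage,
                "frequency": self.solver.freq.frequency,
                "rel_tol": self.solver.rel_tol,
                "max_iter": self.solver.max_iter,
                "mode": self.solver.mode,
            },
            "film": {
                "thickness": self.film.thickness,
                "eps_r": self.film.eps_r,
                "sigma": self.film.sigma,
            },
            "thresholds": list(self.thresholds),
            "cases": list(self.cases),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        from .tissue_model import FrequencySpec

        phantom = PhantomConfig.from_dict(d.get("phantom", {}))
        s = d.get("solver", {})
        solver = SolverConfig(
            applied_voltage=float(s.get("applied_voltage", 80.0)),
            freq=FrequencySpec(float(s.get("frequency", 200_000.0))),
            rel_tol=float(s.get("rel_tol", 1e-8)),
            max_iter=int(s.get("max_iter", 50_000)),
            mode=str(s.get("mode", "auto")),
        )
        f = d.get("film", {})
        film = ContactFilm(
            thickness=float(f.get("thickness", 1e-6)),
            eps_r=float(f.get("eps_r", 2.2)),
            sigma=float(f.get("sigma", 0.0)),
        )
        return cls(
            phantom=phantom,
            solver=solver,
            film=film,
            thresholds=tuple(float(t) for t in d.get("thresholds", (1.0, 2.5))),
            cases=tuple(d.get("cases", CASES)),
            out_dir=d.get("out_dir"),
            seed=d.get("seed"),
            name=str(d.get("name", "study")),
        )

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "StudyConfig":
        return cls.from_dict(_load_config_dict(path))


def fixture_config(name: str, spacing: Optional[float] = None, **overrides) -> StudyConfig:
    """Load one of the packaged study fixtures.

    ``name`` is ``"superficial"`` (tumor under the defect-side array) or
    ``"deep"`` (near-center tumor, same skull window and arrays).
    """
    fname = f"fixture_{name}.json"
    try:
        text = resources.files("ttfdose.data").joinpath(fname).read_text()
    except FileNotFoundError:
        raise StudyConfigError(f"unknown fixture {name!r}; expected 'superficial' or 'deep'") from None
    cfg = StudyConfig.from_dict(json.loads(text))
    cfg = replace(cfg, name=name)
    if spacing is not None:
        cfg = replace(cfg, phantom=replace(cfg.phantom, spacing=spacing))
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def build_case_phantom(cfg: StudyConfig, case: str) -> VoxelPhantom:
    """Phantom for one case: tumor always; defect and film per case."""
    pcfg = cfg.phantom
    if cfg.seed is not None:
        pcfg = replace(pcfg, seed=cfg.seed)
    ph = synthetic_phantom.build_head_phantom(pcfg)
    ph = synthetic_phantom.embed_tumor(ph)
    if case in ("defect", "insulated"):
        ph = synthetic_phantom.apply_skull_defect(ph)
    insulate = True if case == "insulated" else None
    ph, _spec = synthetic_phantom.place_arrays(ph, pcfg.montage, insulate=insulate)
    return ph


def run_case(
    cfg: StudyConfig,
    case: str,
    props: Optional[TissueTable] = None,
    return_artifacts: bool = False,
):
    """Build, solve and summarize one case.

    With ``return_artifacts=True`` also returns ``(phantom, system,
    solution)`` for downstream export or inspection.
    """
    if case not in CASES:
        raise StudyConfigError(f"unknown case {case!r}; valid: {CASES}")
    cfg.validate()
    props = props or TissueTable.default()
    log.info("[%s/%s] building phantom", cfg.name, case)
    ph = build_case_phantom(cfg, case)
    film = cfg.film if case == "insulated" else None
    log.info("[%s/%s] solving", cfg.name, case)
    system, sol = solve_case_fields(ph, props, cfg.solver, film=film)
    summary = summarize_case(case, sol, ph, thresholds=cfg.thresholds)
    P_in = input_power(system, sol)
    Q_int = metrics.joule_heating(sol).total_power()
    summary.solver_info["input_power_W"] = float(P_in.real)
    summary.solver_info["integrated_Q_W"] = Q_int
    log.info(
        "[%s/%s] W_max=%.3e W/m^3, mean shell |E|=%.3f V/cm, P_in=%.4f W, Q_int=%.4f W",
        cfg.name,
        case,
        summary.W_max,
        summary.field_stats["tumor_shell"]["mean_V_per_cm"],
        P_in.real,
        Q_int,
    )
    if return_artifacts:
        return summary, (ph, system, sol)
    return summary


@dataclass
class ComparisonTable:
    """One :class:`CaseSummary` per case plus the normalized-field column."""

    name: str
    summaries: Dict[str, CaseSummary]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "cases": {c: s.to_dict() for c, s in self.summaries.items()},
        }

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for case in CASES:
            if case not in self.summaries:
                continue
            s = self.summaries[case]
            row = {"case": case}
            for tissue, st in s.field_stats.items():
                row[f"{tissue}_mean_V_per_cm"] = st["mean_V_per_cm"]
                row[f"{tissue}_max_V_per_cm"] = st["max_V_per_cm"]
            for t, v in s.atv_percent.items():
                row[f"ATV_{t}_percent"] = v
            row["W_max_W_per_m3"] = s.W_max
            row["E_norm_percent"] = s.E_norm_percent
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, index=False)


def compare_cases(
    cfg: StudyConfig,
    props: Optional[TissueTable] = None,
) -> ComparisonTable:
    """Run the configured cases and normalize each against the intact one."""
    cfg.validate()
    if "intact" not in cfg.cases:
        raise StudyConfigError("compare_cases requires the intact case as the benchmark")
    props = props or TissueTable.default()
    summaries: Dict[str, CaseSummary] = {}
    for case in cfg.cases:
        summaries[case] = run_case(cfg, case, props=props)
    intact = summaries["intact"]
    W1 = intact.W_max
    e_ref = intact.field_stats["tumor_shell"]["mean_V_per_cm"]
    for case, s in summaries.items():
        e2_rel = s.field_stats["tumor_shell"]["mean_V_per_cm"] / e_ref
        s.E_norm_percent = 100.0 * normalized_field_strength(e2_rel, W1, s.W_max)
    # exact identity for the benchmark row
    intact.E_norm_percent = 100.0
    return ComparisonTable(name=cfg.name, summaries=summaries)


# ---------------------------------------------------------------------------
# volume export
# ---------------------------------------------------------------------------


def export_case_volumes(
    ph: VoxelPhantom,
    sol: FieldSolution,
    out_dir: Union[str, Path],
    prefix: str = "case",
) -> Dict[str, str]:
    """Write labels, |E| (V/cm) and Q (W/m^3) as NIfTI volumes."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = ph.affine()
    paths = {}
    vols = {
        "labels": ph.labels.astype(np.int16),
        "E_V_per_cm": (sol.e_magnitude() * 1e-2).astype(np.float32),
        "Q_W_per_m3": metrics.joule_heating(sol).Q.astype(np.float32),
        "phi_real_V": np.nan_to_num(sol.phi.real).astype(np.float32),
    }
    for key, data in vols.items():
        p = out_dir / f"{prefix}_{key}.nii"
        nib.save(nib.Nifti1Image(data, aff), str(p))
        paths[key] = str(p)
    return paths
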