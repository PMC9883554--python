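"""Synthetic voxel head phantoms.

Builds concentric-layer head phantoms (scalp / skull / CSF / gray matter /
white matter) on an isotropic voxel grid, embeds a two-compartment tumor
(low-conductivity shell around a high-conductivity necrotic core), opens an
optional cylindrical skull window refilled with scalp tissue, and places two
opposed 3x3 transducer arrays with hydrogel pads conforming to the scalp.

Coordinate conventions: voxel indices are 0-based; physical coordinates are
voxel centers in millimetres; the head is centered on the physical origin
and the grid is mirror-symmetric about it.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np

try:
    import yaml
except ImportError:  # pragma: no cover
    yaml = None

log = logging.getLogger(__name__)

# Integer label codes used in the voxel volume (documented in the README).
OUTSIDE = 0
SCALP = 1
SKULL = 2
CSF = 3
GRAY_MATTER = 4
WHITE_MATTER = 5
TUMOR_SHELL = 6
TUMOR_CORE = 7
HYDROGEL = 8
ELECTRODE = 9
AIR = 10

LABEL_CODES = {
    "outside": OUTSIDE,
    "scalp": SCALP,
    "skull": SKULL,
    "csf": CSF,
    "gray_matter": GRAY_MATTER,
    "white_matter": WHITE_MATTER,
    "tumor_shell": TUMOR_SHELL,
    "tumor_core": TUMOR_CORE,
    "hydrogel": HYDROGEL,
    "electrode": ELECTRODE,
    "air": AIR,
}
CODE_LABELS = {v: k for k, v in LABEL_CODES.items()}

BRAIN_CODES = (CSF, GRAY_MATTER, WHITE_MATTER)


class PhantomConfigError(ValueError):
    """Invalid phantom geometry configuration."""


class PlacementError(RuntimeError):
    """Transducer arrays cannot be placed without overlap."""


@dataclass(frozen=True)
class PhantomConfig:
    """Geometric description of a synthetic head phantom.

    Radii are outer radii of the concentric layers, in millimetres, and must
    be strictly decreasing inward (scalp > skull > csf > gm > wm).
    """

    scalp_radius: float = 92.0
    skull_radius: float = 85.0
    csf_radius: float = 78.0
    gm_radius: float = 75.0
    wm_radius: float = 60.0
    spacing: float = 2.0
    tumor_center: Tuple[float, float, float] = (55.0, 0.0, 0.0)
    tumor_core_radius: float = 12.0
    tumor_shell_thickness: float = 6.0
    defect_diameter: float = 50.0
    defect_axis: Tuple[float, float, float] = (1.0, 0.0, 0.0)
    montage: str = "LR"
    transducer_radius: float = 10.0
    transducer_height: float = 1.0
    gel_radius: float = 12.5
    gel_thickness: float = 1.0
    transducer_pitch_mm: float = 30.0
    seed: Optional[int] = None

    @property
    def layer_radii(self) -> Tuple[float, ...]:
        return (
            self.scalp_radius,
            self.skull_radius,
            self.csf_radius,
            self.gm_radius,
            self.wm_radius,
        )

    def validate(self) -> None:
        r = self.layer_radii
        if any(not np.isfinite(x) or x <= 0 for x in r):
            raise PhantomConfigError(f"layer radii must be positive, got {r}")
        if any(a <= b for a, b in zip(r[1:], r[2:])) or r[0] <= r[1]:
            raise PhantomConfigError(f"layer radii must be strictly decreasing, got {r}")
        if self.spacing <= 0:
            raise PhantomConfigError(f"spacing must be > 0, got {self.spacing}")
        if self.tumor_shell_thickness <= 0:
            raise PhantomConfigError("tumor shell thickness must be > 0")
        if self.tumor_core_radius < 0:
            raise PhantomConfigError("tumor core radius must be >= 0")
        reach = float(np.linalg.norm(self.tumor_center)) + self.tumor_core_radius + self.tumor_shell_thickness
        if reach > self.gm_radius:
            raise PhantomConfigError(
                f"tumor (reach {reach:.1f} mm) extends outside the brain compartment (gm radius {self.gm_radius} mm)"
            )
        if self.montage not in ("LR", "AP"):
            raise PhantomConfigError(f"montage must be 'LR' or 'AP', got {self.montage!r}")

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["tumor_center"] = list(self.tumor_center)
        d["defect_axis"] = list(self.defect_axis)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        for k in ("tumor_center", "defect_axis"):
            if k in d:
                d[k] = tuple(float(x) for x in d[k])
        return cls(**d)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "PhantomConfig":
        return cls.from_dict(_load_config_dict(path))

    def to_file(self, path: Union[str, Path]) -> None:
        _dump_config_dict(self.to_dict(), path)


def _load_config_dict(path: Union[str, Path]) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        if yaml is None:  # pragma: no cover
            raise RuntimeError("pyyaml is required for YAML configs")
        return yaml.safe_load(text)
    return json.loads(text)


def _dump_config_dict(d: dict, path: Union[str, Path]) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        if yaml is None:  # pragma: no cover
            raise RuntimeError("pyyaml is required for YAML configs")
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    else:
        path.write_text(json.dumps(d, indent=2, sort_keys=True))


@dataclass(frozen=True)
class ArraySpec:
    """Geometry and electrical role of the 2 x (3x3) transducer arrays.

    Array 0 faces the positive montage axis (the defect/tumor side in the
    shipped fixtures) and is driven at the applied voltage; array 1 is the
    opposed ground array.  Transducer ids run 0..8 (array 0) and 9..17
    (array 1); gel pads share the transducer id of the disc above them.
    """

    montage: str
    transducer_centers: np.ndarray  # (18, 3) mm, on the scalp surface
    axes: np.ndarray  # (18, 3) unit outward axis per transducer
    transducer_radius: float = 10.0
    transducer_height: float = 1.0
    gel_radius: float = 12.5
    gel_thickness: float = 1.0
    roles: Tuple[str, str] = ("active", "ground")

    def array_of(self, tid: int) -> int:
        return 0 if tid < 9 else 1

    def role_of(self, tid: int) -> str:
        return self.roles[self.array_of(tid)]


@dataclass
class VoxelPhantom:
    """A 3-D integer label volume plus array/defect annotations.

    ``labels`` uses the codes in :data:`LABEL_CODES`; ``spacing`` is the
    isotropic voxel edge in mm; ``origin`` is the physical coordinate of the
    center of voxel (0, 0, 0) in mm.
    """

    labels: np.ndarray
    spacing: float
    origin: np.ndarray
    defect_mask: np.ndarray = None
    gel_id: np.ndarray = None  # per-voxel transducer id of gel pads, -1 elsewhere
    transducer_id: np.ndarray = None  # per-voxel transducer id of electrode discs
    insulation_flags: np.ndarray = None  # (18,) bool
    array_spec: Optional[ArraySpec] = None
    config: Optional[PhantomConfig] = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int16)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.defect_mask is None:
            self.defect_mask = np.zeros(self.labels.shape, dtype=bool)
        if self.gel_id is None:
            self.gel_id = np.full(self.labels.shape, -1, dtype=np.int16)
        if self.transducer_id is None:
            self.transducer_id = np.full(self.labels.shape, -1, dtype=np.int16)
        if self.insulation_flags is None:
            self.insulation_flags = np.zeros(18, dtype=bool)

    # -- geometry helpers --------------------------------------------------

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    def coords(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical voxel-center coordinate grids (mm), broadcastable."""
        axes = [self.origin[a] + self.spacing * np.arange(self.shape[a]) for a in range(3)]
        return np.meshgrid(*axes, indexing="ij", sparse=True)

    def radius(self) -> np.ndarray:
        x, y, z = self.coords()
        return np.sqrt(x**2 + y**2 + z**2)

    def domain_mask(self) -> np.ndarray:
        """Voxels belonging to the computational domain (not outside)."""
        return self.labels != OUTSIDE

    def mask(self, label: Union[str, int]) -> np.ndarray:
        code = LABEL_CODES[label] if isinstance(label, str) else int(label)
        return self.labels == code

    def brain_mask(self) -> np.ndarray:
        return np.isin(self.labels, BRAIN_CODES)

    def voxel_volume_mm3(self) -> float:
        return float(self.spacing**3)

    def copy(self) -> "VoxelPhantom":
        return VoxelPhantom(
            labels=self.labels.copy(),
            spacing=self.spacing,
            origin=self.origin.copy(),
            defect_mask=self.defect_mask.copy(),
            gel_id=self.gel_id.copy(),
            transducer_id=self.transducer_id.copy(),
            insulation_flags=self.insulation_flags.copy(),
            array_spec=self.array_spec,
            config=self.config,
        )

    # -- NIfTI interoperability -------------------------------------------

    def affine(self) -> np.ndarray:
        aff = np.diag([self.spacing] * 3 + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path: Union[str, Path]) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), self.affine()), str(path))

    @classmethod
    def from_nifti(cls, path: Union[str, Path], spacing: float = None) -> "VoxelPhantom":
        import nibabel as nib

        img = nib.load(str(path))
        aff = img.affine
        steps = np.sqrt((aff[:3, :3] ** 2).sum(axis=0))
        if not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError(f"anisotropic voxel spacing not supported: {steps}")
        sp = float(steps[0]) if spacing is None else spacing
        labels = np.asanyarray(img.dataobj).astype(np.int16)
        return cls(labels=labels, spacing=sp, origin=aff[:3, 3].copy())


# ---------------------------------------------------------------------------
# construction operations
# ---------------------------------------------------------------------------


def _symmetric_grid(extent_mm: float, spacing: float):
    """Odd-sized grid symmetric about the origin covering +-extent_mm."""
    half = int(np.ceil(extent_mm / spacing))
    n = 2 * half + 1
    origin = np.array([-half * spacing] * 3)
    return n, origin


def build_head_phantom(cfg: PhantomConfig) -> VoxelPhantom:
    """Voxelize the concentric-layer head described by ``cfg``.

    Voxels whose centers fall outside the scalp sphere are labeled
    ``outside`` and excluded from the computational domain.  The tumor of
    ``cfg`` is *not* embedded here; use :func:`embed_tumor`.
    """
    cfg.validate()
    # margin for gel + electrode voxels added later by place_arrays
    pad = 2 * cfg.spacing + cfg.gel_thickness + cfg.transducer_height
    n, origin = _symmetric_grid(cfg.scalp_radius + pad, cfg.spacing)
    ph = VoxelPhantom(
        labels=np.zeros((n, n, n), dtype=np.int16),
        spacing=cfg.spacing,
        origin=origin,
        config=cfg,
    )
    r = ph.radius()
    labels = ph.labels
    labels[r <= cfg.scalp_radius] = SCALP
    labels[r <= cfg.skull_radius] = SKULL
    labels[r <= cfg.csf_radius] = CSF
    labels[r <= cfg.gm_radius] = GRAY_MATTER
    labels[r <= cfg.wm_radius] = WHITE_MATTER
    log.info(
        "phantom grid %s spacing %.2f mm, %d domain voxels",
        labels.shape,
        cfg.spacing,
        int((labels != OUTSIDE).sum()),
    )
    return ph


def embed_tumor(
    ph: VoxelPhantom,
    center: Sequence[float] = None,
    r_core: float = None,
    t_shell: float = None,
) -> VoxelPhantom:
    """Embed a two-compartment spherical tumor, overwriting brain tissue.

    Voxels closer than ``r_core`` to ``center`` become tumor core; voxels in
    ``[r_core, r_core + t_shell)`` become tumor shell.  Overlap with existing
    tissue is resolved in favor of the tumor, but the tumor ball must lie
    entirely within the gray/white-matter compartment.
    """
    cfg = ph.config
    if center is None:
        center = cfg.tumor_center
        if cfg.seed is not None:
            rng = np.random.default_rng(cfg.seed)
            center = tuple(
                np.asarray(center, float) + rng.uniform(-0.25, 0.25, 3) * ph.spacing
            )
    if r_core is None:
        r_core = cfg.tumor_core_radius
    if t_shell is None:
        t_shell = cfg.tumor_shell_thickness
    if t_shell <= 0:
        raise PhantomConfigError("tumor shell thickness must be > 0")
    center = np.asarray(center, dtype=float)
    x, y, z = ph.coords()
    d = np.sqrt((x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2)
    ball = d < (r_core + t_shell)
    allowed = (GRAY_MATTER, WHITE_MATTER, TUMOR_SHELL, TUMOR_CORE)
    bad = ball & ~np.isin(ph.labels, allowed)
    if bad.any():
        codes = sorted({CODE_LABELS[int(c)] for c in np.unique(ph.labels[bad])})
        raise PhantomConfigError(f"tumor ball extends outside the brain compartment into {codes}")
    out = ph.copy()
    out.labels[ball] = TUMOR_SHELL
    out.labels[d < r_core] = TUMOR_CORE
    return out


def apply_skull_defect(
    ph: VoxelPhantom,
    axis_center: Sequence[float] = None,
    diameter: float = None,
) -> VoxelPhantom:
    """Open a cylindrical skull window and refill it with scalp tissue.

    The window is a cylinder of the given ``diameter`` whose axis runs from
    the head center through ``axis_center``; skull voxels inside it and on
    the ``axis_center`` side are relabeled scalp and recorded in
    ``defect_mask``.  ``diameter <= 0`` is a no-op with a warning.
    """
    cfg = ph.config
    if axis_center is None:
        axis_center = cfg.defect_axis if cfg is not None else (1.0, 0.0, 0.0)
    if diameter is None:
        diameter = cfg.defect_diameter if cfg is not None else 50.0
    if diameter <= 0:
        warnings.warn("skull-defect diameter <= 0; phantom left unchanged", stacklevel=2)
        return ph.copy()
    u = np.asarray(axis_center, dtype=float)
    nu = np.linalg.norm(u)
    if nu == 0:
        raise PhantomConfigError("defect axis must be a nonzero direction")
    u = u / nu
    x, y, z = ph.coords()
    proj = x * u[0] + y * u[1] + z * u[2]
    perp2 = (x**2 + y**2 + z**2) - proj**2
    window = (proj > 0) & (perp2 < (diameter / 2.0) ** 2) & (ph.labels == SKULL)
    if not window.any():
        raise PhantomConfigError("defect cylinder does not intersect the skull layer")
    out = ph.copy()
    out.labels[window] = SCALP
    out.defect_mask = out.defect_mask | window
    log.info("skull defect: %d voxels converted skull -> scalp", int(window.sum()))
    return out


def _rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit ``axis``."""
    k = np.asarray(axis, float)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _array_axes(montage: str, pitch_rad: float) -> np.ndarray:
    """Unit outward axes of the 18 transducers (array 0 then array 1)."""
    base = np.array([1.0, 0, 0]) if montage == "LR" else np.array([0, 1.0, 0])
    t1 = np.array([0, 1.0, 0]) if montage == "LR" else np.array([1.0, 0, 0])
    t2 = np.array([0, 0, 1.0])
    axes = []
    for sign in (1.0, -1.0):
        u0 = sign * base
        for i in (-1, 0, 1):
            for j in (-1, 0, 1):
                R = _rotation(t1, i * pitch_rad) @ _rotation(t2, j * pitch_rad)
                axes.append(R @ u0)
    return np.asarray(axes)


def place_arrays(
    ph: VoxelPhantom,
    montage: str = None,
    insulate: Union[Sequence[bool], bool, None] = None,
) -> Tuple[VoxelPhantom, ArraySpec]:
    """Place two opposed 3x3 transducer arrays with hydrogel pads.

    Gel discs conform to the voxelized scalp surface; electrode discs sit on
    top of the gel.  Gel/electrode thicknesses are realized as
    ``max(1, round(t / spacing))`` voxel layers so that thin layers survive
    coarse grids.  ``insulate`` sets per-transducer insulation flags: a
    boolean sequence of length 18, ``True`` (all 9 defect-side transducers of
    array 0), or ``None``/``False`` (no insulation).
    """
    cfg = ph.config
    if montage is None:
        montage = cfg.montage if cfg is not None else "LR"
    if montage not in ("LR", "AP"):
        raise PhantomConfigError(f"montage must be 'LR' or 'AP', got {montage!r}")
    gr = cfg.gel_radius if cfg else 12.5
    gt = cfg.gel_thickness if cfg else 1.0
    tr = cfg.transducer_radius if cfg else 10.0
    th = cfg.transducer_height if cfg else 1.0
    pitch_mm = cfg.transducer_pitch_mm if cfg else 30.0
    scalp_r = cfg.scalp_radius if cfg else float(ph.radius()[ph.labels == SCALP].max())

    pitch = pitch_mm / scalp_r
    axes = _array_axes(montage, pitch)

    # non-overlap check: closest pair of same-array pads, arc distance on scalp
    for a0 in (0, 9):
        sub = axes[a0 : a0 + 9]
        dots = np.clip(sub @ sub.T, -1, 1)
        ang = np.arccos(dots)
        np.fill_diagonal(ang, np.inf)
        if (scalp_r * ang.min()) <= 2 * gr:
            raise PlacementError(
                f"transducer pitch {pitch_mm} mm places gel pads (radius {gr} mm) in overlap"
            )

    flags = np.zeros(18, dtype=bool)
    if insulate is True:
        flags[:9] = True
    elif insulate is not None and insulate is not False:
        flags = np.asarray(insulate, dtype=bool)
        if flags.shape != (18,):
            raise PhantomConfigError("insulate must be a length-18 boolean sequence")

    out = ph.copy()
    x, y, z = out.coords()
    r = out.radius()
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = np.stack(np.broadcast_arrays(x / r, y / r, z / r), axis=-1)
    dirs[~np.isfinite(dirs)] = 0.0

    n_g = max(1, int(round(gt / out.spacing)))
    n_e = max(1, int(round(th / out.spacing)))
    outside = out.labels == OUTSIDE
    shell_idx = np.floor((r - scalp_r) / out.spacing).astype(int)

    # nearest transducer (per array) by angular distance
    for a0 in (0, 9):
        sub = axes[a0 : a0 + 9]  # (9, 3)
        cosang = np.clip(np.einsum("...c,kc->...k", dirs, sub), -1, 1)
        k_best = np.argmax(cosang, axis=-1)
        arc = scalp_r * np.arccos(np.take_along_axis(cosang, k_best[..., None], axis=-1)[..., 0])
        tid = (a0 + k_best).astype(np.int16)

        gel_band = outside & (shell_idx >= 0) & (shell_idx < n_g) & (arc <= gr)
        ele_band = outside & (shell_idx >= n_g) & (shell_idx < n_g + n_e) & (arc <= tr)
        out.labels[gel_band] = HYDROGEL
        out.gel_id[gel_band] = tid[gel_band]
        out.labels[ele_band] = ELECTRODE
        out.transducer_id[ele_band] = tid[ele_band]

    _prune_pads(out)

    if not (out.labels == HYDROGEL).any() or not (out.labels == ELECTRODE).any():
        raise PlacementError("array placement produced no gel/electrode voxels")

    spec = ArraySpec(
        montage=montage,
        transducer_centers=axes * scalp_r,
        axes=axes,
        transducer_radius=tr,
        transducer_height=th,
        gel_radius=gr,
        gel_thickness=gt,
    )
    out.array_spec = spec
    out.insulation_flags = flags
    counts = [int((out.gel_id == t).sum()) for t in range(18)]
    log.info("arrays placed: %d gel voxels, %d electrode voxels (per-pad min %d)",
             int((out.labels == HYDROGEL).sum()), int((out.labels == ELECTRODE).sum()), min(counts))
    return out, spec


def _face_adjacent(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Voxels of ``mask_a`` sharing a face with a voxel of ``mask_b``."""
    hit = np.zeros_like(mask_a)
    for a in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[a] = slice(None, -1)
        hi[a] = slice(1, None)
        lo, hi = tuple(lo), tuple(hi)
        hit[lo] |= mask_a[lo] & mask_b[hi]
        hit[hi] |= mask_a[hi] & mask_b[lo]
    return hit


def _prune_pads(ph: VoxelPhantom) -> None:
    """Enforce pad adjacency invariants in place.

    Gel voxels must connect (face-wise, through gel) to the scalp; electrode
    voxels must sit face-adjacent to a gel voxel.  Stair-stepping of the
    spherical scalp surface can strand a few candidate voxels; they are
    dropped back to ``outside``.
    """
    from scipy import ndimage

    gel = ph.labels == HYDROGEL
    scalp = ph.labels == SCALP
    seed = _face_adjacent(gel, scalp)
    structure = ndimage.generate_binary_structure(3, 1)  # faces only
    lab, n = ndimage.label(gel, structure=structure)
    keep_components = np.unique(lab[seed])
    keep_components = keep_components[keep_components > 0]
    keep = np.isin(lab, keep_components)
    drop_gel = gel & ~keep
    ph.labels[drop_gel] = OUTSIDE
    ph.gel_id[drop_gel] = -1

    gel = ph.labels == HYDROGEL
    ele = ph.labels == ELECTRODE
    keep_e = _face_adjacent(ele, gel)
    drop_e = ele & ~keep_e
    ph.labels[drop_e] = OUTSIDE
    ph.transducer_id[drop_e] = -1


def build_slab_phantom(
    layer_labels: Sequence[Union[str, int]],
    layer_voxels: Sequence[int],
    nx: int,
    ny: int,
    spacing: float,
) -> VoxelPhantom:
    """A rectangular layered slab along z (test/oracle fixture geometry).

    Every voxel belongs to the domain; drive it through explicit Dirichlet
    faces on the z boundaries (see :mod:`ttfdose.em_solver`).
    """
    codes = [LABEL_CODES[l] if isinstance(l, str) else int(l) for l in layer_labels]
    if len(codes) != len(layer_voxels):
        raise PhantomConfigError("layer_labels and layer_voxels must have equal length")
    nz = int(sum(layer_voxels))
    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    z0 = 0
    for c, nv in zip(codes, layer_voxels):
        labels[:, :, z0 : z0 + nv] = c
        z0 += nv
    origin = -0.5 * spacing * (np.array([nx, ny, nz]) - 1)
    return VoxelPhantom(labels=labels, spacing=spacing, origin=origin)


def build_sphere_phantom(
    radii_mm: Sequence[float],
    layer_labels: Sequence[Union[str, int]],
    spacing: float,
) -> VoxelPhantom:
    """Concentric-sphere fixture (radii strictly decreasing, mm)."""
    radii = [float(r) for r in radii_mm]
    if any(a <= b for a, b in zip(radii, radii[1:])):
        raise PhantomConfigError(f"sphere radii must be strictly decreasing, got {radii}")
    if len(radii) != len(layer_labels):
        raise PhantomConfigError("radii and labels must have equal length")
    n, origin = _symmetric_grid(radii[0] + spacing, spacing)
    ph = VoxelPhantom(labels=np.zeros((n, n, n), dtype=np.int16), spacing=spacing, origin=origin)
    r = ph.radius()
    for rad, lab in zip(radii, layer_labels):
        code = LABEL_CODES[lab] if isinstance(lab, str) else int(lab)
        ph.labels[r <= rad] = code
    return ph
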