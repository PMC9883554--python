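# ttfdose

Voxel-phantom modelling of tumor-treating fields (TTFields): synthetic head
phantoms with a two-compartment tumor, an optional craniectomy (skull window
refilled with scalp), and two opposed 3×3 transducer arrays; a quasi-static
complex-admittivity finite-volume solver; and the dose / thermogenesis
metrics used to compare the intact-skull, defective-skull and insulated
cases (per-tissue field statistics, above-threshold volumes, per-gel Joule
heating, and the power-normalized field strength).

## What it does

1. **`tissue_model`** — electrical property table (conductivity σ, relative
   permittivity εr per tissue class) and the complex admittivity
   κ = σ + iωε0εr at the working frequency (default 200 kHz,
   ε0 = 8.8541878128×10⁻¹² F/m). The table is packaged as CSV and can be
   overridden per tissue.
2. **`synthetic_phantom`** — concentric-sphere head phantoms
   (scalp/skull/CSF/GM/WM), spherical tumor with a low-conductivity shell
   and a high-conductivity necrotic core, cylindrical skull defect refilled
   with scalp, and voxelized hydrogel pads + electrode discs conforming to
   the scalp on both sides of a LR or AP montage. NIfTI I/O for label
   volumes.
3. **`em_solver`** — cell-centered 7-point finite-volume discretization of
   ∇·(κ∇φ) = 0 with harmonic-mean face admittivities, Dirichlet excitation
   on the outward electrode faces (80 V / ground), zero-flux elsewhere, and
   an optional thin-film contact-impedance condition
   Y = (σf + iωε0εrf)/df replacing the transducer–gel coupling of insulated
   transducers. Direct sparse solve for small systems, diagonally-scaled
   CG/BiCGSTAB above that.
4. **`metrics`** — Joule heating Q = ½ Re(J·E*), per-gel-pad heating
   statistics and W_max, per-tissue mean/max |E| in V/cm ("brain" =
   GM∪WM∪CSF), above-threshold volume (ATV, % of tumor shell ≥ threshold,
   defaults 1.0 and 2.5 V/cm), and the power-normalized field strength
   E_norm = E2·√(W1/W2).
5. **`analytic_oracle`** — closed-form layered-slab and Legendre-series
   layered-sphere solutions used as ground truth for solver validation.
6. **`pipeline`** — three-case orchestration (intact / defect / insulated),
   comparison table with E_norm per case relative to intact, CLI.

## CLI

```bash
ttfdose build   --fixture superficial --case defect --out out/   # labels → NIfTI
ttfdose solve   --fixture superficial --case defect --out out/   # fields + summary
ttfdose compare --fixture deep --out out/                        # 3-case table
ttfdose oracle  --out out/                                       # analytic gates
```

`--config path.json|yaml` accepts a full study configuration (see
`StudyConfig.to_dict()` for the schema); `--spacing`, `--montage`, `--seed`
override it. Two study fixtures ship with the package:

* **superficial** — full-scale head (scalp radius 92 mm), tumor centered
  55 mm from the head center under the defect-side array;
* **deep** — same head and defect, tumor centered 15 mm from the center.

Both use a 20 mm skull window aligned with the array axis and 60 V applied,
chosen so the three cases sit in the sensitive (non-saturated) regime of the
ATV metric at 2 mm voxels.

## Voxel label codes

| code | label        | code | label        |
|------|--------------|------|--------------|
| 0    | outside      | 6    | tumor_shell  |
| 1    | scalp        | 7    | tumor_core   |
| 2    | skull        | 8    | hydrogel     |
| 3    | csf          | 9    | electrode    |
| 4    | gray_matter  | 10   | air          |
| 5    | white_matter |      |              |

## Conventions

* Geometry in mm (voxel centers, 0-based indices, head centered at the
  physical origin); solver internals in SI; field magnitudes reported in
  V/cm (|E| = phasor amplitude √Σ|E_c|²).
* Per-voxel E is reconstructed from face potentials consistent with the
  face currents (reduces to central differences in homogeneous regions,
  one-sided at domain boundaries); the Joule-heating map is integrated per
  half-cell so that its domain integral equals the electrode input power
  exactly.
* All 9 transducers of an array share one potential; insulation flags are
  per transducer (default: all 9 defect-side transducers).
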