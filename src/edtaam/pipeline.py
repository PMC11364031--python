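"""End-to-end comparison of scattering-factor models on one dataset.

Mirrors the comparative-refinement workflow used in electron-diffraction
charge-density studies: refine the same starting model against the same
F^2 data under a list of scattering models (IAM neutral, charged IAM,
multipole/TAAM, hybrid metal/ligand partitions, .tsc tables), then collect
R factors, goodness of fit, resolution-shell R1 with locked parameters,
displacement-ellipsoid statistics, model RMSDs against a reference, and
difference-map / fractal-dimension diagnostics into one report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .crystal import CrystalStructure, ReflectionSet
from .refine import (RefinementConfig, RefinementResult, ellipsoid_ratios,
                     optimize_weights, refine_lsq, rmsd_models, shell_r1)
from .structure_factors import (HybridProvider, MultipoleProvider,
                                SphericalProvider)

__all__ = ["ComparisonConfig", "ComparisonReport", "run_comparison",
           "standard_variants", "expand_to_p1", "residual_map"]

DEFAULT_SHELLS = (8.65, 2.0, 0.85)


@dataclass
class ComparisonConfig:
    shells: tuple = DEFAULT_SHELLS
    weights: tuple | str = "auto"     # (a, b) or "auto"
    start_weights: tuple = (0.05, 0.5)
    fallback_weights: tuple = (0.2, 0.0)
    f_obs_sigma_cut: float = 4.0
    map_divisions: int = 4            # grid spacing = d_min / divisions
    n_weight_cycles: int = 2


@dataclass
class VariantResult:
    name: str
    result: RefinementResult | None
    shells: list = field(default_factory=list)
    ellipsoid_mean: float = float("nan")
    rmsd_coord: float = float("nan")
    rmsd_bond: float = float("nan")
    map_max: float = float("nan")
    map_min: float = float("nan")
    fractal_width: float = float("nan")
    fractal_curve: tuple | None = None
    error: str | None = None


@dataclass
class ComparisonReport:
    variants: list
    config: ComparisonConfig

    def to_rows(self):
        rows = []
        for v in self.variants:
            if v.result is None:
                rows.append(dict(model=v.name, error=v.error))
                continue
            r = v.result
            row = dict(model=v.name,
                       r1_strong=r.r1_strong, r1_all=r.r1_all,
                       goof=r.goof, wr2=r.wr2,
                       n_reflections=r.n_reflections, n_strong=r.n_strong,
                       n_params=r.n_params,
                       weight_a=r.weights[0], weight_b=r.weights[1],
                       scale=r.scale,
                       ellipsoid_r1_r3=v.ellipsoid_mean,
                       rmsd_coord=v.rmsd_coord, rmsd_bond=v.rmsd_bond,
                       map_max=v.map_max, map_min=v.map_min,
                       fractal_width=v.fractal_width)
            for sh in v.shells:
                tag = f"{sh['d_max']:g}-{sh['d_min']:g}"
                row[f"r1_strong[{tag}]"] = sh["r1_strong"]
                row[f"n_strong[{tag}]"] = sh["n_strong"]
            rows.append(row)
        return rows

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.to_rows())

    def variant(self, name: str) -> VariantResult:
        for v in self.variants:
            if v.name == name:
                return v
        raise KeyError(name)


def standard_variants(structure: CrystalStructure,
                      taam_models=None, taam_rotations=None,
                      include=("iam", "iam-fe3", "taam")):
    """Named provider set for the comparison pipeline.

    iam / iam-fe2 / iam-fe3: Slater-family spherical electron factors,
    neutral or with formal metal charges balanced by O^0.5-;
    taam: full multipole models; taam-ligand: hybrid with the metal kept
    spherical neutral (part 1) and multipole ligands (part 2).
    """
    from .synthetic import electron_iam_curves

    out = {}
    for name in include:
        if name == "iam":
            out[name] = SphericalProvider(electron_iam_curves(structure))
        elif name == "iam-fe2":
            out[name] = SphericalProvider(
                electron_iam_curves(structure, {"Fe": 2, "O": -0.5}))
        elif name == "iam-fe3":
            out[name] = SphericalProvider(
                electron_iam_curves(structure, {"Fe": 3, "O": -0.5}))
        elif name == "taam":
            out[name] = MultipoleProvider(taam_models, taam_rotations,
                                          "electron")
        elif name == "taam-ligand":
            spherical = SphericalProvider(electron_iam_curves(structure))
            out[name] = HybridProvider({
                1: spherical,
                2: MultipoleProvider(taam_models, taam_rotations,
                                     "electron")})
        else:
            raise KeyError(f"unknown variant {name!r}")
    return out


def expand_to_p1(hkl, values, spacegroup):
    """Expand unique reflections to the full symmetry-equivalent set.

    F(h R) = F(h) exp(-2 pi i h.t); duplicates keep the first occurrence.
    """
    hkl = np.atleast_2d(np.asarray(hkl, int))
    values = np.asarray(values, complex)
    out_h, out_f, seen = [], [], set()
    for o in range(spacegroup.n_ops):
        R = spacegroup.rotations[o]
        t = spacegroup.translations[o]
        h_op = np.rint(hkl @ R).astype(int)
        ph = np.exp(-2j * np.pi * (hkl @ t))
        for h, f in zip(h_op, values * ph):
            key = tuple(int(v) for v in h)
            if key in seen:
                continue
            seen.add(key)
            out_h.append(key)
            out_f.append(f)
    return np.array(out_h), np.array(out_f)


def residual_map(reflections: ReflectionSet, result: RefinementResult,
                 structure: CrystalStructure, divisions: int = 4,
                 unit: str = "1/A^2"):
    """F_obs - F_calc difference map with model phases, over one unit cell."""
    from .maps import difference_map

    fc = result.f_calc
    k = result.scale
    fo = np.sqrt(np.maximum(reflections.f2, 0.0) / max(k, 1e-30))
    phases = np.where(np.abs(fc) > 0, fc / np.abs(np.where(
        np.abs(fc) > 0, fc, 1.0)), 1.0)
    coeff = (fo - np.abs(fc)) * phases
    hkl_full, coeff_full = expand_to_p1(reflections.hkl, coeff,
                                        structure.spacegroup)
    d_min = float(np.min(reflections.d))
    spacing = d_min / divisions
    shape = [int(np.ceil(l / spacing)) for l in
             (structure.cell.a, structure.cell.b, structure.cell.c)]
    return difference_map(hkl_full, coeff_full, structure.cell, shape,
                          unit=unit)


def run_comparison(start: CrystalStructure, reflections: ReflectionSet,
                   providers: dict, config: ComparisonConfig | None = None,
                   reference: CrystalStructure | None = None
                   ) -> ComparisonReport:
    """Refine every variant from the same start model and collect statistics.

    A failing variant is recorded in the report with its error message and
    does not abort the remaining variants.
    """
    from .maps import fractal_dimension_plot, map_extrema

    config = config or ComparisonConfig()
    variants = []
    for name, provider in providers.items():
        try:
            variants.append(_run_variant(name, provider, start, reflections,
                                         config, reference))
        except Exception as exc:  # recorded, not raised
            variants.append(VariantResult(name=name, result=None,
                                          error=f"{type(exc).__name__}: {exc}"))
    return ComparisonReport(variants=variants, config=config)


def _run_variant(name, provider, start, reflections, config, reference
                 ) -> VariantResult:
    from .maps import fractal_dimension_plot, map_extrema

    if config.weights == "auto":
        a0, b0 = config.start_weights
    else:
        a0, b0 = config.weights
    cfg = RefinementConfig(weight_a=a0, weight_b=b0,
                           f_obs_sigma_cut=config.f_obs_sigma_cut,
                           n_weight_cycles=config.n_weight_cycles)
    res = refine_lsq(start, reflections, provider, cfg)
    if config.weights == "auto":
        a, b, _, ok = optimize_weights(reflections.f2, reflections.sigma,
                                       np.abs(res.f_calc) ** 2, res.scale,
                                       res.n_params, d=reflections.d)
        if not ok:
            a, b = config.fallback_weights
        cfg2 = RefinementConfig(weight_a=a, weight_b=b,
                                f_obs_sigma_cut=config.f_obs_sigma_cut,
                                n_weight_cycles=config.n_weight_cycles)
        res = refine_lsq(start, reflections, provider, cfg2)
    v = VariantResult(name=name, result=res)
    v.shells = shell_r1(reflections, np.abs(res.f_calc) ** 2, res.scale,
                        config.shells, cut=config.f_obs_sigma_cut)
    _, v.ellipsoid_mean, _ = ellipsoid_ratios(res.structure)
    if reference is not None:
        try:
            v.rmsd_coord, v.rmsd_bond = rmsd_models(res.structure, reference)
        except ValueError:
            pass
    grid = residual_map(reflections, res, res.structure,
                        divisions=config.map_divisions)
    v.map_max, v.map_min, _, _ = map_extrema(grid)
    levels, df, width = fractal_dimension_plot(grid)
    v.fractal_width = width
    v.fractal_curve = (levels, df)
    return v
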