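"""CSV/JSON readers and writers for every pipeline artifact.

Spectra travel as long-format CSV with one row per (condition, wavelength,
temperature) grid point and the exact header

    concentration_mg_ml,pH,ionic_strength_mM,wavelength_nm,temperature_C,intensity

Temperatures are Celsius in files and Kelvin inside the fitting code; the
conversion happens here and nowhere else.  Ground truth and fit results get
their own CSVs; run configurations and trained models are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .network import TrainOptions
from .synthetic import (Condition, GeneratorSpec, SpectralSurface)
from .twostate import FitResult, TwoStateParams

__all__ = [
    "SPECTRA_COLUMNS",
    "RunConfig",
    "write_spectra_csv",
    "read_spectra_csv",
    "write_ground_truth_csv",
    "read_ground_truth_csv",
    "write_fit_results_csv",
    "spec_to_json",
    "spec_from_json",
]

SPECTRA_COLUMNS = ["concentration_mg_ml", "pH", "ionic_strength_mM",
                   "wavelength_nm", "temperature_C", "intensity"]

CONDITION_COLUMNS = SPECTRA_COLUMNS[:3]

TRUTH_COLUMNS = CONDITION_COLUMNS + ["wavelength_nm", "I_N", "a", "I_D", "b",
                                     "Tm_K", "dHvh_J_mol"]

FIT_COLUMNS = CONDITION_COLUMNS + ["wavelength_nm", "Tm_K", "Tm_se",
                                   "dHvh_J_mol", "dHvh_se", "rss", "converged"]


def write_spectra_csv(surfaces: Sequence[SpectralSurface], path) -> None:
    """Long-format spectra: one row per grid point, temperatures in °C."""
    frames = []
    for surf in surfaces:
        t, wl = np.meshgrid(surf.temperatures_c, surf.wavelengths_nm,
                            indexing="ij")
        frames.append(pd.DataFrame({
            "concentration_mg_ml": surf.condition.concentration,
            "pH": surf.condition.pH,
            "ionic_strength_mM": surf.condition.ionic_strength,
            "wavelength_nm": wl.ravel(),
            "temperature_C": t.ravel(),
            "intensity": surf.intensity.ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spectra_csv(path) -> List[SpectralSurface]:
    """Rebuild surfaces from long-format CSV, order-independently.

    Validates the header, numeric cells, duplicate grid points and grid
    raggedness, naming rows/conditions in the diagnostics.
    """
    df = pd.read_csv(path)
    missing = [c for c in SPECTRA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in SPECTRA_COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            rows = list((df.index[bad | df[col].isna()] + 2)[:5])
            raise ValueError(
                f"{path}: non-numeric or empty cells in column {col!r} "
                f"(file rows {rows})")
    dup = df.duplicated(subset=SPECTRA_COLUMNS[:5])
    if dup.any():
        rows = list((df.index[dup] + 2)[:5])
        raise ValueError(f"{path}: duplicate (condition, wavelength, "
                         f"temperature) rows (file rows {rows})")

    surfaces = []
    for key, grp in df.groupby(CONDITION_COLUMNS, sort=True):
        cond = Condition(*map(float, key))
        pivot = grp.pivot(index="temperature_C", columns="wavelength_nm",
                          values="intensity")
        if pivot.isna().any().any():
            raise ValueError(
                f"{path}: ragged grid for condition {cond.as_tuple()} — "
                f"not every (wavelength, temperature) combination is present")
        surfaces.append(SpectralSurface(
            condition=cond,
            temperatures_c=pivot.index.to_numpy(dtype=float),
            wavelengths_nm=pivot.columns.to_numpy(dtype=float),
            intensity=pivot.to_numpy(dtype=float),
        ))
    return surfaces


def write_ground_truth_csv(surfaces: Sequence[SpectralSurface], path) -> None:
    """Sidecar with the per-(condition, wavelength) true model parameters."""
    rows = []
    for surf in surfaces:
        if surf.ground_truth is None:
            continue
        for wl, p in surf.ground_truth.items():
            rows.append({
                "concentration_mg_ml": surf.condition.concentration,
                "pH": surf.condition.pH,
                "ionic_strength_mM": surf.condition.ionic_strength,
                "wavelength_nm": wl,
                "I_N": p.I_N, "a": p.a, "I_D": p.I_D, "b": p.b,
                "Tm_K": p.Tm, "dHvh_J_mol": p.dHvh,
            })
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, index=False)


def read_ground_truth_csv(path) -> Dict[tuple, TwoStateParams]:
    """(condition tuple, wavelength) → true parameters."""
    df = pd.read_csv(path)
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    out = {}
    for _, r in df.iterrows():
        key = (r["concentration_mg_ml"], r["pH"], r["ionic_strength_mM"],
               r["wavelength_nm"])
        out[key] = TwoStateParams(I_N=r["I_N"], a=r["a"], I_D=r["I_D"],
                                  b=r["b"], Tm=r["Tm_K"],
                                  dHvh=r["dHvh_J_mol"])
    return out


def write_fit_results_csv(results: Dict[tuple, FitResult], path) -> None:
    """Fit results keyed by (concentration, pH, IS, wavelength)."""
    rows = []
    for (c, ph, is_, wl), fit in results.items():
        rows.append({
            "concentration_mg_ml": c, "pH": ph, "ionic_strength_mM": is_,
            "wavelength_nm": wl,
            "Tm_K": fit.params.Tm,
            "Tm_se": fit.standard_errors.get("Tm", np.nan),
            "dHvh_J_mol": fit.params.dHvh,
            "dHvh_se": fit.standard_errors.get("dHvh", np.nan),
            "rss": fit.residual_sum_of_squares,
            "converged": fit.converged,
        })
    pd.DataFrame(rows, columns=FIT_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RunConfig:
    """A self-describing run: generator settings, experiment choices and one
    named seed per stochastic stage."""

    noise_cv: float = 0.015
    concentrations: tuple = None
    phs: tuple = None
    ionic_strengths: tuple = None
    input_ranges: tuple = ("20-50",)
    split: str = "holdout"           # or "kfold"
    kfold_k: int = 6
    truncation_window: tuple = (330.0, 363.0)
    output_dir: str = "results"
    generator_seed: int = 1
    split_seed: int = 1              # used by kfold only
    network_seed: int = 1
    max_epochs: int = 1000
    goal_mse: float = 20000.0
    max_validation_failures: int = 10

    def generator_spec(self) -> GeneratorSpec:
        kwargs = dict(noise_cv=self.noise_cv, seed=self.generator_seed)
        if self.concentrations is not None:
            kwargs["concentrations"] = tuple(self.concentrations)
        if self.phs is not None:
            kwargs["phs"] = tuple(self.phs)
        if self.ionic_strengths is not None:
            kwargs["ionic_strengths"] = tuple(self.ionic_strengths)
        return GeneratorSpec(**kwargs)

    def train_options(self) -> TrainOptions:
        return TrainOptions(max_epochs=self.max_epochs,
                            goal_mse=self.goal_mse,
                            max_validation_failures=self.max_validation_failures,
                            seed=self.network_seed)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        doc = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**doc)
        for name in ("concentrations", "phs", "ionic_strengths",
                     "input_ranges", "truncation_window"):
            v = getattr(cfg, name)
            if v is not None:
                setattr(cfg, name, tuple(v))
        return cfg

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())


def spec_to_json(spec: GeneratorSpec) -> str:
    """Serialize a generator spec built from the default rules.

    Custom rule callables are not serializable; only the numeric settings
    travel, and loading restores the default rules.
    """
    return json.dumps({
        "noise_cv": spec.noise_cv,
        "seed": spec.seed,
        "concentrations": list(spec.concentrations),
        "phs": list(spec.phs),
        "ionic_strengths": list(spec.ionic_strengths),
        "temperatures_c": spec.temperatures_c.tolist(),
        "wavelengths_nm": spec.wavelengths_nm.tolist(),
    }, indent=2)


def spec_from_json(text: str) -> GeneratorSpec:
    doc = json.loads(text)
    return GeneratorSpec(
        noise_cv=doc["noise_cv"], seed=doc["seed"],
        concentrations=tuple(doc["concentrations"]),
        phs=tuple(doc["phs"]),
        ionic_strengths=tuple(doc["ionic_strengths"]),
        temperatures_c=np.array(doc["temperatures_c"]),
        wavelengths_nm=np.array(doc["wavelengths_nm"]),
    )
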