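"""From spectral surfaces to melting-temperature recovery.

One training record per (condition, wavelength) melting curve: the network
inputs are native-baseline intensities from a chosen temperature window
(optionally plus concentration, pH, ionic strength and wavelength) and the
targets are the 20 intensities of the 52–90 °C transition/denatured region.
Predicted high-temperature sections are stitched onto the experimental
20–50 °C baseline, the stitched 36-point curves are truncated and fitted
with the same two-state model as the experimental curves, and the two Tm
sets are compared by parity regression and RMSE.

Splitting follows the study design: a fixed condition-level holdout
(36 training / 9 validation / 9 test conditions — 1512/378/378 records on
the default grid), with two alternative rotations that together use every
condition exactly once for validation and once for test; and a seeded
k = 6 k-fold alternative (six folds of 378 records).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from . import network as nn
from .synthetic import Condition, GeneratorSpec, SpectralSurface, generate_dataset
from .twostate import (DEFAULT_WINDOW, FitResult, UnfoldingCurve,
                       celsius_to_kelvin, fit_two_state, two_state_intensity)

__all__ = [
    "InputRange",
    "INPUT_RANGES",
    "TrainingRecord",
    "ParityStats",
    "EvalReport",
    "ExperimentResult",
    "assemble_records",
    "holdout_split",
    "kfold_split",
    "kfold_assignment",
    "predict_high_temperature",
    "stitch_curve",
    "rmse_percent",
    "evaluate_tm_parity",
    "records_to_matrices",
    "train_on_records",
    "run_tm_recovery",
    "run_experiment",
]

#: Temperature grids of the study design, °C.
BASELINE_TEMPS_C = np.arange(20.0, 50.0 + 1e-9, 2.0)   # 16 points
TARGET_TEMPS_C = np.arange(52.0, 90.0 + 1e-9, 2.0)     # 20 points

#: Wavelength at which Tm is extracted from fitted curves.
TM_WAVELENGTH = 340.0


@dataclass(frozen=True)
class InputRange:
    """A native-baseline input window for the network."""

    label: str
    t_low: float   # °C, inclusive
    t_high: float  # °C, inclusive
    include_metadata: bool = True

    @property
    def temperatures_c(self) -> np.ndarray:
        grid = BASELINE_TEMPS_C
        return grid[(grid >= self.t_low - 1e-9) & (grid <= self.t_high + 1e-9)]

    @property
    def n_baseline_points(self) -> int:
        return self.temperatures_c.size

    @property
    def n_features(self) -> int:
        return self.n_baseline_points + (4 if self.include_metadata else 0)


#: The experiment matrix: five scanning windows plus the baseline-only model.
INPUT_RANGES: Dict[str, InputRange] = {
    "20-50": InputRange("20-50", 20.0, 50.0, True),
    "20-40": InputRange("20-40", 20.0, 40.0, True),
    "20-30": InputRange("20-30", 20.0, 30.0, True),
    "30-40": InputRange("30-40", 30.0, 40.0, True),
    "40-50": InputRange("40-50", 40.0, 50.0, True),
    "baseline-only": InputRange("baseline-only", 20.0, 50.0, False),
}


@dataclass
class TrainingRecord:
    """One (condition, wavelength) curve prepared for the network."""

    condition: Condition
    wavelength: float
    features: np.ndarray        # input-range intensities (+ metadata)
    targets: np.ndarray         # 20 intensities at 52–90 °C
    baseline: np.ndarray        # full 16-point 20–50 °C baseline, for stitching
    split: Optional[str] = None  # train / validation / test


def _grid_indices(grid: np.ndarray, wanted: np.ndarray, what: str,
                  condition: Condition, wavelength=None) -> np.ndarray:
    dist = np.abs(grid[None, :] - np.asarray(wanted)[:, None])
    idx = dist.argmin(axis=1)
    if np.any(dist[np.arange(len(wanted)), idx] > 1e-6):
        where = f"condition {condition.as_tuple()}"
        if wavelength is not None:
            where += f", wavelength {wavelength} nm"
        raise ValueError(f"missing {what} grid points for {where}")
    return idx


def assemble_records(surfaces: Sequence[SpectralSurface],
                     input_range: InputRange) -> List[TrainingRecord]:
    """One record per (condition, wavelength).

    For the 20–50 °C metadata variant: 16 baseline intensities + the four
    condition descriptors (concentration, pH, ionic strength, wavelength)
    = 20 features; targets are the 20 intensities at 52–90 °C.
    """
    records = []
    for surf in surfaces:
        cond = surf.condition
        base_idx = _grid_indices(surf.temperatures_c, BASELINE_TEMPS_C,
                                 "baseline temperature", cond)
        feat_idx = _grid_indices(surf.temperatures_c,
                                 input_range.temperatures_c,
                                 "input-window temperature", cond)
        targ_idx = _grid_indices(surf.temperatures_c, TARGET_TEMPS_C,
                                 "target temperature", cond)
        for j, wl in enumerate(surf.wavelengths_nm):
            col = surf.intensity[:, j]
            feats = col[feat_idx]
            if input_range.include_metadata:
                feats = np.concatenate([
                    feats,
                    [cond.concentration, cond.pH, cond.ionic_strength, wl],
                ])
            records.append(TrainingRecord(
                condition=cond,
                wavelength=float(wl),
                features=feats.astype(float),
                targets=col[targ_idx].astype(float),
                baseline=col[base_idx].astype(float),
            ))
    return records


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

#: Condition-level holdout of the study: which concentration of each
#: low (1/5/10) and high (20/50/100 mg/mL) triple is held out, per buffer.
#: Values are (validation_or_test_concentration, label) pairs; all other
#: concentrations of the triple train.
_LOW = (1.0, 5.0, 10.0)
_HIGH = (20.0, 50.0, 100.0)

#: (pH, IS) → {concentration: label} for held-out conditions (rotation 0).
_HOLDOUT_TABLE: Dict[Tuple[float, float], Dict[float, str]] = {
    (4.5, 30.0): {1.0: "validation", 20.0: "test"},
    (4.5, 100.0): {5.0: "test", 50.0: "validation"},
    (4.5, 200.0): {10.0: "validation", 100.0: "test"},
    (5.5, 30.0): {1.0: "test", 20.0: "validation"},
    (5.5, 100.0): {5.0: "validation", 50.0: "test"},
    (5.5, 200.0): {10.0: "test", 100.0: "validation"},
    (7.0, 30.0): {1.0: "validation", 20.0: "test"},
    (7.0, 100.0): {5.0: "test", 50.0: "validation"},
    (7.0, 200.0): {10.0: "validation", 100.0: "test"},
}


def holdout_condition_label(condition: Condition, rotation: int = 0) -> str:
    """Split label of one condition under the fixed holdout design.

    ``rotation`` ∈ {0, 1, 2} cycles which member of each concentration
    triple is held out; the three rotations together use every condition
    exactly once for validation/test.
    """
    key = (condition.pH, condition.ionic_strength)
    if key not in _HOLDOUT_TABLE:
        raise KeyError(f"condition {condition.as_tuple()} is not on the "
                       f"holdout design grid")
    c = condition.concentration
    triple = _LOW if c in _LOW else _HIGH if c in _HIGH else None
    if triple is None:
        raise KeyError(f"concentration {c} mg/mL is not on the design grid")
    # under rotation r, the condition at index i takes the role the condition
    # at index (i - r) mod 3 has in the base table
    i = triple.index(c)
    base_c = triple[(i - rotation) % 3]
    return _HOLDOUT_TABLE[key].get(base_c, "train")


def holdout_split(records: Sequence[TrainingRecord],
                  rotation: int = 0) -> List[TrainingRecord]:
    """Label records by the fixed condition-level holdout (36/9/9 conditions,
    1512/378/378 records on the default grid).  All wavelengths of a
    condition share its label."""
    out = []
    for rec in records:
        out.append(replace(rec, split=holdout_condition_label(rec.condition,
                                                              rotation)))
    return out


def kfold_split(records: Sequence[TrainingRecord], k: int = 6,
                seed: int = 0) -> np.ndarray:
    """Seeded random partition into k folds whose sizes differ by ≤ 1.

    Returns the fold index of each record.  ``k < 3`` is rejected: a run
    needs disjoint train/validation/test material.
    """
    if k < 3:
        raise ValueError("k must be at least 3 (train/validation/test)")
    n = len(records)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    # contiguous chunks of the permutation; sizes differ by at most one
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    start = 0
    for f, size in enumerate(sizes):
        folds[perm[start:start + size]] = f
        start += size
    return folds


def kfold_assignment(records: Sequence[TrainingRecord], folds: np.ndarray,
                     run: int, k: int = 6) -> List[TrainingRecord]:
    """Split labels for rotation ``run``: fold ``run`` validates, fold
    ``(run+1) mod k`` tests, the rest train.  Over the k runs each fold is
    validation exactly once and test exactly once."""
    labels = np.full(len(records), "train", dtype=object)
    labels[folds == run % k] = "validation"
    labels[folds == (run + 1) % k] = "test"
    return [replace(rec, split=lab) for rec, lab in zip(records, labels)]


# ---------------------------------------------------------------------------
# Prediction, stitching, metrics
# ---------------------------------------------------------------------------

def records_to_matrices(records: Sequence[TrainingRecord],
                        split: Optional[str] = None
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """(X, Y) matrices, optionally restricted to one split label."""
    sel = [r for r in records if split is None or r.split == split]
    if not sel:
        raise ValueError(f"no records with split={split!r}")
    return (np.vstack([r.features for r in sel]),
            np.vstack([r.targets for r in sel]))


def predict_high_temperature(net: nn.NetworkModel,
                             record: TrainingRecord) -> np.ndarray:
    """Descaled 20-point 52–90 °C intensity prediction for one record."""
    if record.features.size != net.n_in:
        raise ValueError(
            f"record has {record.features.size} features, network expects "
            f"{net.n_in}")
    return nn.predict(net, record.features[None, :])[0]


def stitch_curve(record: TrainingRecord,
                 prediction: np.ndarray) -> UnfoldingCurve:
    """Experimental 20–50 °C baseline + predicted 52–90 °C section.

    Always uses the full 16-point experimental baseline, regardless of how
    narrow the network's input window was; only the model input shrinks.
    Returns a 36-point curve on the Kelvin scale, ready for fitting.
    """
    prediction = np.asarray(prediction, dtype=float)
    if prediction.size != TARGET_TEMPS_C.size:
        raise ValueError(f"prediction must have {TARGET_TEMPS_C.size} points")
    if record.baseline.size != BASELINE_TEMPS_C.size:
        raise ValueError("record lacks the full 20–50 °C baseline")
    temps_c = np.concatenate([BASELINE_TEMPS_C, TARGET_TEMPS_C])
    if np.any(np.diff(temps_c) <= 0):
        raise ValueError("baseline and prediction grids overlap")
    return UnfoldingCurve(
        temperatures=celsius_to_kelvin(temps_c),
        intensities=np.concatenate([record.baseline, prediction]),
        wavelength=record.wavelength,
        condition=record.condition,
    )


def rmse_percent(predicted: np.ndarray, experimental: np.ndarray,
                 fit: FitResult) -> float:
    """Prediction error over 52–90 °C as a percentage of the fitted
    experimental intensity at Tm.

    ``predicted`` and ``experimental`` are the 20-point 52–90 °C intensity
    vectors; ``fit`` is the two-state fit of the experimental curve, whose
    model intensity evaluated at its own Tm is the denominator.
    """
    predicted = np.asarray(predicted, dtype=float)
    experimental = np.asarray(experimental, dtype=float)
    if predicted.shape != experimental.shape:
        raise ValueError("curves must share the 52–90 °C grid")
    tm = fit.params.Tm
    support = celsius_to_kelvin(np.array([BASELINE_TEMPS_C[0],
                                          TARGET_TEMPS_C[-1]]))
    if not (support[0] <= tm <= support[1]):
        raise ValueError(f"Tm {tm:.1f} K outside the curve support")
    denom = float(two_state_intensity(fit.params, tm))
    rmse = float(np.sqrt(np.mean((predicted - experimental) ** 2)))
    return 100.0 * rmse / denom


@dataclass
class ParityStats:
    """Agreement between experimental and model-derived Tm values."""

    rmse: float          # °C
    slope: float         # OLS slope of Tm_ML vs Tm_Ex
    slope_se: float
    r_squared: float
    n: int


def _parity(tm_ex: np.ndarray, tm_ml: np.ndarray) -> ParityStats:
    if tm_ex.size != tm_ml.size:
        raise ValueError("paired Tm lists must have equal length")
    if tm_ex.size < 2:
        raise ValueError("need at least two pairs for a parity fit")
    rmse = float(np.sqrt(np.mean((tm_ml - tm_ex) ** 2)))
    res = stats.linregress(tm_ex, tm_ml)
    return ParityStats(rmse=rmse, slope=float(res.slope),
                       slope_se=float(res.stderr),
                       r_squared=float(res.rvalue ** 2), n=int(tm_ex.size))


def evaluate_tm_parity(tm_experimental: np.ndarray, tm_predicted: np.ndarray,
                       subsets: Optional[Sequence[str]] = None
                       ) -> Dict[str, ParityStats]:
    """Parity statistics (RMSE °C, OLS slope ± SE, R²) for the full set and,
    if ``subsets`` labels are given, for the validation and test subsets."""
    tm_ex = np.asarray(tm_experimental, dtype=float)
    tm_ml = np.asarray(tm_predicted, dtype=float)
    out = {"all": _parity(tm_ex, tm_ml)}
    if subsets is not None:
        labels = np.asarray(subsets)
        if labels.size != tm_ex.size:
            raise ValueError("subset labels must match the Tm pairs")
        for name in ("validation", "test"):
            mask = labels == name
            if mask.sum() >= 2:
                out[name] = _parity(tm_ex[mask], tm_ml[mask])
    return out


@dataclass
class EvalReport:
    """Per-condition prediction quality and Tm parity for one model."""

    input_range: str
    rmse_percent: Dict[Condition, float]
    parity: Dict[str, ParityStats]
    tm_experimental: Dict[Condition, float]   # °C, fit of measured curve
    tm_predicted: Dict[Condition, float]      # °C, fit of stitched curve
    tm_true: Dict[Condition, float]           # °C, generator ground truth

    @property
    def median_rmse_percent(self) -> float:
        return float(np.median(list(self.rmse_percent.values())))


@dataclass
class ExperimentResult:
    """Everything produced by one train/predict/fit cycle."""

    report: EvalReport
    net: nn.NetworkModel
    history: nn.TrainHistory
    records: List[TrainingRecord]


def train_on_records(records: Sequence[TrainingRecord],
                     opts: nn.TrainOptions, n_hidden: int = 20,
                     ) -> Tuple[nn.NetworkModel, nn.TrainHistory]:
    """Initialize and LM-train a network on labelled records.

    Scalings are fitted inside :func:`network.train_network` on the training
    split only; validation drives early stopping; the test columns are
    recorded but inert.
    """
    train = records_to_matrices(records, "train")
    val = records_to_matrices(records, "validation")
    test = records_to_matrices(records, "test")
    net = nn.initialize_network(train[0].shape[1], n_hidden,
                                train[1].shape[1], seed=opts.seed)
    return nn.train_network(net, train, val, test, opts)


def run_tm_recovery(spec: GeneratorSpec,
                    input_range: InputRange = INPUT_RANGES["20-50"],
                    opts: Optional[nn.TrainOptions] = None,
                    surfaces: Optional[Sequence[SpectralSurface]] = None,
                    window=DEFAULT_WINDOW,
                    rotation: int = 0,
                    ) -> ExperimentResult:
    """Full pipeline for one input range on one synthetic dataset.

    Generate (or reuse) the surfaces, assemble and holdout-split the
    records, train, predict every condition's 340 nm curve, stitch, truncate
    and fit both the stitched and the measured curves, and evaluate RMSE%
    and Tm parity over all conditions.
    """
    if opts is None:
        opts = nn.TrainOptions(seed=spec.seed)
    if surfaces is None:
        surfaces = generate_dataset(spec)
    records = holdout_split(assemble_records(surfaces, input_range), rotation)
    net, history = train_on_records(records, opts)

    by_condition = {}
    for rec in records:
        if abs(rec.wavelength - TM_WAVELENGTH) < 1e-6:
            by_condition[rec.condition] = rec

    rmse_pct, tm_ex, tm_ml, tm_true, labels = {}, {}, {}, {}, {}
    for surf in surfaces:
        cond = surf.condition
        rec = by_condition[cond]
        prediction = predict_high_temperature(net, rec)
        experimental = np.concatenate([rec.baseline, rec.targets])

        exp_curve = UnfoldingCurve(
            temperatures=celsius_to_kelvin(
                np.concatenate([BASELINE_TEMPS_C, TARGET_TEMPS_C])),
            intensities=experimental,
            wavelength=TM_WAVELENGTH, condition=cond)
        fit_exp = fit_two_state(exp_curve, window=window)
        fit_ml = fit_two_state(stitch_curve(rec, prediction), window=window)

        rmse_pct[cond] = rmse_percent(prediction, rec.targets, fit_exp)
        tm_ex[cond] = fit_exp.params.Tm - 273.15
        tm_ml[cond] = fit_ml.params.Tm - 273.15
        if surf.ground_truth is not None:
            tm_true[cond] = surf.ground_truth[TM_WAVELENGTH].Tm - 273.15
        labels[cond] = rec.split

    conds = [s.condition for s in surfaces]
    parity = evaluate_tm_parity(
        np.array([tm_ex[c] for c in conds]),
        np.array([tm_ml[c] for c in conds]),
        [labels[c] for c in conds])

    report = EvalReport(
        input_range=input_range.label,
        rmse_percent=rmse_pct,
        parity=parity,
        tm_experimental=tm_ex,
        tm_predicted=tm_ml,
        tm_true=tm_true,
    )
    return ExperimentResult(report=report, net=net, history=history,
                            records=records)


def run_experiment(spec: GeneratorSpec,
                   input_ranges: Optional[Sequence[str]] = None,
                   opts: Optional[nn.TrainOptions] = None,
                   ) -> Dict[str, ExperimentResult]:
    """The full experiment matrix: each input range trained and evaluated
    identically on the same dataset.  Deterministic given the spec and
    option seeds."""
    if input_ranges is None:
        input_ranges = list(INPUT_RANGES)
    surfaces = generate_dataset(spec)
    out = {}
    for label in input_ranges:
        out[label] = run_tm_recovery(spec, INPUT_RANGES[label], opts=opts,
                                     surfaces=surfaces)
    return out
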