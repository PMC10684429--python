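"""pH determination from fitted mixture weights.

The measurement chain is strictly ratiometric: a mixture fit yields the
weights of the deprotonated and protonated MOPS components, their ratio is
mapped to a concentration ratio through a single calibration factor ``k``
(least squares through the origin), and the pH follows from the
temperature-dependent pKa of MOPS together with the base-10 logarithm of
the concentration ratio.  Activity-coefficient corrections exist here only
as diagnostics for simulation studies; the prediction path never applies
them.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import OutOfRangeError, ValidationError
from .hard_model import (
    CompositeModel,
    MixtureFitResult,
    fit_mixture,
    load_composite,
    save_composite,
    component_to_dict,
)
from .spectra_io import RamanSpectrum

__all__ = [
    "WATER",
    "MOPSH",
    "MOPS_MINUS",
    "PENICILLIN_G",
    "TEMPERATURE_RANGE",
    "WORKING_RANGE_HALFWIDTH",
    "CalibrationPoint",
    "CalibrationModel",
    "PhPrediction",
    "pka_mops",
    "ph_from_ratio",
    "ratio_from_ph",
    "zeta_ratio_of",
    "calibrate",
    "predict_ph",
    "rmse",
    "loo_crossval",
    "debye_huckel_log_gamma",
    "activity_corrected_ph",
    "save_calibration",
    "load_calibration",
]

# canonical component names used across the package
WATER = "water"
MOPSH = "MOPSH"
MOPS_MINUS = "MOPS-"
PENICILLIN_G = "penicillin_g"

TEMPERATURE_RANGE = (273.15, 373.15)

# predictions further than this from pKa(T) are flagged as outside the
# effective working range of the buffer (~pH 6 to 8 around neutral pKa)
WORKING_RANGE_HALFWIDTH = 1.3

_ZETA_FLOOR_FACTOR = 1e-12


def pka_mops(temperature: float) -> float:
    """pKa of MOPS at `temperature` (kelvin), Roy-type empirical form.

    pKa(T) = 814.077/T + 9.865 - 0.9501 * ln(T)
    """
    lo, hi = TEMPERATURE_RANGE
    if not lo <= temperature <= hi:
        raise ValidationError(f"temperature {temperature} K outside [{lo}, {hi}]")
    return 814.077 / temperature + 9.865 - 0.9501 * math.log(temperature)


def ph_from_ratio(conc_ratio: float, temperature: float) -> float:
    """pH = pKa(T) + log10(c_MOPS- / c_MOPSH)."""
    if conc_ratio <= 0:
        raise ValidationError(f"concentration ratio must be > 0, got {conc_ratio}")
    return pka_mops(temperature) + math.log10(conc_ratio)


def ratio_from_ph(ph: float, temperature: float) -> float:
    """Inverse of :func:`ph_from_ratio`: 10**(pH - pKa(T))."""
    return 10.0 ** (ph - pka_mops(temperature))


def zeta_ratio_of(fit: MixtureFitResult) -> float:
    """zeta_MOPS- / zeta_MOPSH from a mixture fit."""
    try:
        z_minus = fit.weights[MOPS_MINUS]
        z_h = fit.weights[MOPSH]
    except KeyError as exc:
        raise ValidationError(f"fit lacks weight for component {exc}") from exc
    if z_h <= max(_ZETA_FLOOR_FACTOR * z_minus, 0.0) or z_h == 0.0:
        raise OutOfRangeError(
            "protonated-species weight is (numerically) zero: pH above working range"
        )
    return z_minus / z_h


@dataclass(frozen=True)
class CalibrationPoint:
    zeta_ratio: float
    conc_ratio: float
    temperature: float
    reference_ph: float


@dataclass
class CalibrationModel:
    """Calibration factor k mapping weight ratios to concentration ratios."""

    k: float
    composite: CompositeModel | None = None
    calibration_points: list[CalibrationPoint] = field(default_factory=list)
    created_at: str = ""

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValidationError(f"calibration factor must be > 0, got {self.k}")
        if self.calibration_points and len(self.calibration_points) < 2:
            raise ValidationError("a fitted calibration needs >= 2 points")


@dataclass
class PhPrediction:
    ph: float
    zeta_ratio: float
    conc_ratio: float
    pka: float
    temperature: float
    fit: MixtureFitResult | None = None
    in_working_range: bool = True

    def __post_init__(self) -> None:
        if self.zeta_ratio < 0 or self.conc_ratio < 0:
            raise ValidationError("ratios must be >= 0")


def _fit_k(zeta: np.ndarray, conc: np.ndarray, weights: np.ndarray | None) -> float:
    w = np.ones_like(zeta) if weights is None else np.asarray(weights, dtype=float)
    denom = float(np.sum(w * zeta * zeta))
    if denom <= 0:
        raise ValidationError("degenerate calibration data (all zeta ratios zero)")
    return float(np.sum(w * zeta * conc) / denom)


def calibrate(
    points: Sequence[tuple[MixtureFitResult, float, float]],
    *,
    composite: CompositeModel | None = None,
    weighted: bool = False,
    reference_ph_sd: float = 0.05,
) -> CalibrationModel:
    """Fit the calibration factor k from (fit, reference_ph, temperature) points.

    The reference concentration ratio of each point is computed from its
    reference pH; k minimizes sum (conc_ratio - k * zeta_ratio)^2 through
    the origin.  With ``weighted=True`` the residuals are weighted by the
    inverse variance of the concentration ratio propagated from the
    reference electrode error `reference_ph_sd`.
    """
    if len(points) < 2:
        raise ValidationError(f"calibration needs >= 2 points, got {len(points)}")
    records = []
    for fit, ref_ph, temp in points:
        z = zeta_ratio_of(fit)
        c = ratio_from_ph(ref_ph, temp)
        records.append(CalibrationPoint(z, c, temp, ref_ph))
    zeta = np.array([p.zeta_ratio for p in records])
    conc = np.array([p.conc_ratio for p in records])
    weights = None
    if weighted:
        # var(conc_ratio) ~ (ln10 * conc_ratio * sigma_pH)^2
        weights = 1.0 / (math.log(10.0) * conc * reference_ph_sd) ** 2
    k = _fit_k(zeta, conc, weights)
    return CalibrationModel(
        k=k,
        composite=composite,
        calibration_points=records,
        created_at=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )


def predict_ph(
    spectrum: RamanSpectrum,
    calibration: CalibrationModel,
    temperature: float,
    *,
    composite: CompositeModel | None = None,
) -> PhPrediction:
    """Fit the composite model to `spectrum` and convert the weight ratio to pH.

    The prediction is invariant under uniform intensity scaling of the
    spectrum and under addition of an exact linear baseline (both are
    absorbed by the mixture fit).
    """
    model = composite or calibration.composite
    if model is None:
        raise ValidationError("no composite model attached to the calibration")
    fit = fit_mixture(model, spectrum)
    z = zeta_ratio_of(fit)
    conc_ratio = calibration.k * z
    pka = pka_mops(temperature)
    ph = ph_from_ratio(conc_ratio, temperature)
    in_range = abs(ph - pka) <= WORKING_RANGE_HALFWIDTH
    return PhPrediction(
        ph=ph,
        zeta_ratio=z,
        conc_ratio=conc_ratio,
        pka=pka,
        temperature=temperature,
        fit=fit,
        in_working_range=in_range,
    )


def rmse(predicted: Iterable[float], reference: Iterable[float]) -> float:
    """Root-mean-square error between two equal-length pH vectors."""
    p = np.asarray(list(predicted), dtype=float)
    r = np.asarray(list(reference), dtype=float)
    if p.size != r.size:
        raise ValidationError(f"length mismatch: {p.size} vs {r.size}")
    if p.size == 0:
        raise ValidationError("empty input")
    return float(np.sqrt(np.mean((p - r) ** 2)))


def loo_crossval(points: Sequence[CalibrationPoint], *, weighted: bool = False) -> float:
    """Leave-one-out cross-validated RMSE of the ratiometric calibration.

    Each point in turn is held out, k is refitted on the remainder, and the
    held-out pH is predicted from its zeta ratio at its own temperature.
    """
    if len(points) < 3:
        raise ValidationError(f"cross-validation needs >= 3 points, got {len(points)}")
    zeta = np.array([p.zeta_ratio for p in points])
    conc = np.array([p.conc_ratio for p in points])
    predictions, references = [], []
    for i, p in enumerate(points):
        mask = np.ones(len(points), dtype=bool)
        mask[i] = False
        weights = None
        if weighted:
            weights = 1.0 / (math.log(10.0) * conc[mask] * 0.05) ** 2
        k = _fit_k(zeta[mask], conc[mask], weights)
        predictions.append(ph_from_ratio(k * p.zeta_ratio, p.temperature))
        references.append(p.reference_ph)
    return rmse(predictions, references)


# ---------------------------------------------------------------------------
# activity diagnostics (simulation-only; never used by predict_ph)
# ---------------------------------------------------------------------------


def debye_huckel_log_gamma(A: float, z: int, I: float, B: float, b: float) -> float:
    """Extended Debye-Hueckel log10 activity coefficient.

    log10(gamma) = -A z^2 sqrt(I) / (1 + B sqrt(I)) + b I
    """
    if I < 0:
        raise ValidationError(f"ionic strength must be >= 0, got {I}")
    sqrt_i = math.sqrt(I)
    return -A * z * z * sqrt_i / (1.0 + B * sqrt_i) + b * I


def activity_corrected_ph(
    concentration_ph: float,
    I: float,
    *,
    A: float = 0.51,
    B: float = 1.5,
    b_anion: float = 0.0,
    b_neutral: float = 0.0,
) -> float:
    """Concentration-based pH plus the log-ratio of activity coefficients.

    The deprotonated species carries charge -1; the protonated species is
    neutral, so its ionic term vanishes and only its salting coefficient
    `b_neutral` contributes.  This quantifies the error of neglecting the
    activity ratio; it is a diagnostic and is deliberately not part of the
    prediction path.
    """
    log_gamma_minus = debye_huckel_log_gamma(A, 1, I, B, b_anion)
    log_gamma_neutral = debye_huckel_log_gamma(A, 0, I, B, b_neutral)
    return concentration_ph + log_gamma_minus - log_gamma_neutral


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_calibration(model: CalibrationModel, path: str | Path) -> None:
    data = {
        "k": model.k,
        "created_at": model.created_at,
        "calibration_points": [
            {
                "zeta_ratio": p.zeta_ratio,
                "conc_ratio": p.conc_ratio,
                "temperature": p.temperature,
                "reference_ph": p.reference_ph,
            }
            for p in model.calibration_points
        ],
    }
    if model.composite is not None:
        data["composite"] = {
            "fit_window": list(model.composite.fit_window),
            "baseline_order": model.composite.baseline_order,
            "components": [component_to_dict(c) for c in model.composite.components],
        }
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def load_calibration(path: str | Path) -> CalibrationModel:
    from .hard_model import _load_json, component_from_dict

    data = _load_json(Path(path))
    composite = None
    if "composite" in data:
        composite = CompositeModel(
            components=[component_from_dict(c) for c in data["composite"]["components"]],
            fit_window=tuple(data["composite"]["fit_window"]),
            baseline_order=int(data["composite"].get("baseline_order", 1)),
        )
    points = [
        CalibrationPoint(
            zeta_ratio=float(p["zeta_ratio"]),
            conc_ratio=float(p["conc_ratio"]),
            temperature=float(p["temperature"]),
            reference_ph=float(p["reference_ph"]),
        )
        for p in data.get("calibration_points", [])
    ]
    return CalibrationModel(
        k=float(data["k"]),
        composite=composite,
        calibration_points=points,
        created_at=str(data.get("created_at", "")),
    )
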