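"""Hard spectral models: pseudo-Voigt peaks, pure components and mixtures.

A pure-component model is a sum of pseudo-Voigt peaks

    I(nu) = h * [eta * exp(-4 ln2 (nu-nu0)^2 / w^2)
                 + (1-eta) / (1 + 4 (nu-nu0)^2 / w^2)]

with apex height ``h``, position ``nu0``, a single full width at half
maximum ``w`` shared by the Gaussian and Lorentzian parts, and Gaussian
fraction ``eta``.  A mixture spectrum is the weighted sum of its component
models plus a linear baseline; selected peak parameters (typically the
water peaks' position and linewidth) stay free during mixture fitting to
absorb temperature and ionic-strength effects on the solvent band.

The mixture fit separates the problem: the non-negative component weights
and the (sign-free) baseline are solved by bounded linear least squares
inside every evaluation of the nonlinear residual over the free peak
parameters (variable projection).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares, lsq_linear

from .exceptions import ParseError, ValidationError
from .spectra_io import RamanSpectrum, crop

__all__ = [
    "PseudoVoigtPeak",
    "FreeParameter",
    "PureComponentModel",
    "CompositeModel",
    "MixtureFitResult",
    "eval_peak",
    "eval_component",
    "eval_mixture",
    "fit_mixture",
    "component_to_dict",
    "component_from_dict",
    "save_component",
    "load_component",
    "save_composite",
    "load_composite",
]

_FOUR_LN2 = 4.0 * math.log(2.0)
_PEAK_PARAMETERS = ("height", "position", "fwhm", "gaussian_fraction")

# default freedom granted to a free parameter when no explicit bounds are
# stored: position may move +-20 cm^-1, linewidth may scale within x[0.5, 2]
_POSITION_SLACK = 20.0
_FWHM_SCALE = (0.5, 2.0)


@dataclass(frozen=True)
class PseudoVoigtPeak:
    """One height-normalized pseudo-Voigt line."""

    height: float
    position: float
    fwhm: float
    gaussian_fraction: float

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValidationError(f"height must be >= 0, got {self.height}")
        if self.fwhm <= 0:
            raise ValidationError(f"fwhm must be > 0, got {self.fwhm}")
        if not 0.0 <= self.gaussian_fraction <= 1.0:
            raise ValidationError(
                f"gaussian_fraction must lie in [0, 1], got {self.gaussian_fraction}"
            )


@dataclass(frozen=True)
class FreeParameter:
    """A (peak, parameter) pair allowed to vary during mixture fitting."""

    peak: int
    parameter: str
    bounds: tuple[float, float] | None = None  # absolute; None -> default rule

    def __post_init__(self) -> None:
        if self.parameter not in _PEAK_PARAMETERS:
            raise ValidationError(f"unknown peak parameter {self.parameter!r}")


@dataclass
class PureComponentModel:
    name: str
    peaks: list[PseudoVoigtPeak]
    free_parameters: list[FreeParameter] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValidationError(f"component {self.name!r} has no peaks")
        for fp in self.free_parameters:
            if not 0 <= fp.peak < len(self.peaks):
                raise ValidationError(
                    f"free parameter references peak {fp.peak} of "
                    f"{len(self.peaks)}-peak component {self.name!r}"
                )

    def parameter_bounds(self, fp: FreeParameter) -> tuple[float, float]:
        """Absolute fit bounds for a free parameter."""
        if fp.bounds is not None:
            return fp.bounds
        value = getattr(self.peaks[fp.peak], fp.parameter)
        if fp.parameter == "position":
            return (value - _POSITION_SLACK, value + _POSITION_SLACK)
        if fp.parameter == "fwhm":
            return (value * _FWHM_SCALE[0], value * _FWHM_SCALE[1])
        if fp.parameter == "gaussian_fraction":
            return (0.0, 1.0)
        return (0.0, np.inf)  # height


@dataclass
class CompositeModel:
    """An ordered set of component models sharing a fit window and baseline."""

    components: list[PureComponentModel]
    fit_window: tuple[float, float]
    baseline_order: int = 1

    def __post_init__(self) -> None:
        if not self.components:
            raise ValidationError("a composite model needs >= 1 component")
        lo, hi = self.fit_window
        if not lo < hi:
            raise ValidationError(f"fit window must satisfy lo < hi, got {self.fit_window}")
        if self.baseline_order != 1:
            raise ValidationError("only a linear baseline (order 1) is supported")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate component names: {names}")

    def component(self, name: str) -> PureComponentModel:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass
class MixtureFitResult:
    weights: dict[str, float]
    baseline: tuple[float, float]  # (intercept, slope) in counts, counts/cm^-1
    adjusted_parameters: dict[tuple[str, int, str], float]
    residual_rms: float
    converged: bool
    nfev: int = 0

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise ValidationError("mixture weights must be >= 0")
        if self.residual_rms < 0:
            raise ValidationError("residual_rms must be >= 0")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def eval_peak(peak: PseudoVoigtPeak, wavenumbers: np.ndarray) -> np.ndarray:
    nu = np.asarray(wavenumbers, dtype=float)
    u2 = np.square((nu - peak.position) / peak.fwhm)
    gauss = np.exp(-_FOUR_LN2 * u2)
    lorentz = 1.0 / (1.0 + 4.0 * u2)
    eta = peak.gaussian_fraction
    return peak.height * (eta * gauss + (1.0 - eta) * lorentz)


def eval_component(model: PureComponentModel, wavenumbers: np.ndarray) -> np.ndarray:
    nu = np.asarray(wavenumbers, dtype=float)
    out = np.zeros_like(nu)
    for peak in model.peaks:
        out += eval_peak(peak, nu)
    return out


def _apply_adjustments(
    model: PureComponentModel,
    adjustments: Mapping[tuple[str, int, str], float] | None,
) -> PureComponentModel:
    if not adjustments:
        return model
    relevant = {
        (i, p): v for (name, i, p), v in adjustments.items() if name == model.name
    }
    if not relevant:
        return model
    peaks = list(model.peaks)
    for (i, pname), value in relevant.items():
        if not 0 <= i < len(peaks):
            raise ValidationError(
                f"adjustment targets peak {i} of component {model.name!r}"
            )
        peaks[i] = replace(peaks[i], **{pname: value})
    return replace(model, peaks=peaks)


def eval_mixture(
    model: CompositeModel,
    weights: Mapping[str, float],
    baseline: tuple[float, float],
    adjusted_parameters: Mapping[tuple[str, int, str], float] | None,
    wavenumbers: np.ndarray,
) -> np.ndarray:
    """Evaluate ``sum_i zeta_i * component_i + intercept + slope * nu``."""
    nu = np.asarray(wavenumbers, dtype=float)
    missing = [c.name for c in model.components if c.name not in weights]
    if missing:
        raise ValidationError(f"missing weights for components: {missing}")
    intercept, slope = baseline
    out = intercept + slope * nu
    for comp in model.components:
        adjusted = _apply_adjustments(comp, adjusted_parameters)
        out = out + weights[comp.name] * eval_component(adjusted, nu)
    return out


# ---------------------------------------------------------------------------
# mixture fitting (variable projection)
# ---------------------------------------------------------------------------


def _solve_linear(
    columns: np.ndarray, t: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, tuple[float, float], np.ndarray]:
    """Solve y ~ columns @ w + a + b*t with w >= 0, (a, b) free.

    `t` is the centred/scaled abscissa used for conditioning; the returned
    baseline is in `t` units.
    """
    m = columns.shape[1]
    design = np.column_stack([columns, np.ones_like(t), t])
    lower = np.concatenate([np.zeros(m), [-np.inf, -np.inf]])
    upper = np.full(m + 2, np.inf)
    sol = lsq_linear(design, y, bounds=(lower, upper), method="bvls")
    coeffs = sol.x
    fitted = design @ coeffs
    return coeffs[:m], (coeffs[m], coeffs[m + 1]), y - fitted


def fit_mixture(
    model: CompositeModel,
    spectrum: RamanSpectrum,
    *,
    max_nfev: int = 400,
    xtol: float = 1e-14,
    ftol: float = 1e-14,
) -> MixtureFitResult:
    """Fit the composite model to a spectrum over the model's fit window.

    Component weights and the linear baseline are solved by bounded linear
    least squares; the declared free peak parameters are optimized by
    trust-region nonlinear least squares around them.
    """
    lo, hi = model.fit_window
    window = crop(spectrum, lo, hi)
    nu = window.wavenumber
    y = window.intensity
    centre = 0.5 * (nu[0] + nu[-1])
    halfspan = max(0.5 * (nu[-1] - nu[0]), 1.0)
    t = (nu - centre) / halfspan

    free: list[tuple[int, FreeParameter, float, float, float]] = []
    for ci, comp in enumerate(model.components):
        for fp in comp.free_parameters:
            blo, bhi = comp.parameter_bounds(fp)
            x0 = getattr(comp.peaks[fp.peak], fp.parameter)
            free.append((ci, fp, min(max(x0, blo), bhi), blo, bhi))

    static_cols = np.empty((nu.size, len(model.components)))
    dynamic = {ci for ci, *_ in free}
    for ci, comp in enumerate(model.components):
        if ci not in dynamic:
            static_cols[:, ci] = eval_component(comp, nu)

    def columns_for(theta: np.ndarray) -> np.ndarray:
        cols = static_cols.copy()
        by_comp: dict[int, dict[int, dict[str, float]]] = {}
        for (ci, fp, *_), value in zip(free, theta):
            by_comp.setdefault(ci, {}).setdefault(fp.peak, {})[fp.parameter] = value
        for ci in dynamic:
            comp = model.components[ci]
            peaks = list(comp.peaks)
            for pi, changes in by_comp.get(ci, {}).items():
                peaks[pi] = replace(peaks[pi], **changes)
            cols[:, ci] = eval_component(replace(comp, peaks=peaks), nu)
        return cols

    nfev = 0

    def residual(theta: np.ndarray) -> np.ndarray:
        nonlocal nfev
        nfev += 1
        _, _, r = _solve_linear(columns_for(theta), t, y)
        return r

    converged = True
    if free:
        x0 = np.array([f[2] for f in free])
        bounds = (np.array([f[3] for f in free]), np.array([f[4] for f in free]))
        scale = np.maximum(np.abs(x0), 1.0)
        result = least_squares(
            residual,
            x0,
            bounds=bounds,
            x_scale=scale,
            xtol=xtol,
            ftol=ftol,
            gtol=1e-14,
            max_nfev=max_nfev,
            method="trf",
        )
        theta = result.x
        converged = bool(result.status > 0) and np.all(np.isfinite(result.fun))
    else:
        theta = np.empty(0)

    weights_arr, (a, b), r = _solve_linear(columns_for(theta), t, y)
    # convert baseline back from the conditioned abscissa t = (nu-c)/s
    slope = b / halfspan
    intercept = a - b * centre / halfspan
    adjusted = {
        (model.components[ci].name, fp.peak, fp.parameter): float(v)
        for (ci, fp, *_), v in zip(free, theta)
    }
    return MixtureFitResult(
        weights={c.name: float(w) for c, w in zip(model.components, weights_arr)},
        baseline=(float(intercept), float(slope)),
        adjusted_parameters=adjusted,
        residual_rms=float(np.sqrt(np.mean(r**2))),
        converged=converged,
        nfev=nfev,
    )


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------


def component_to_dict(model: PureComponentModel) -> dict:
    return {
        "name": model.name,
        "peaks": [
            {
                "height": p.height,
                "position_cm1": p.position,
                "fwhm_cm1": p.fwhm,
                "gaussian_fraction": p.gaussian_fraction,
            }
            for p in model.peaks
        ],
        "free_parameters": [
            {
                "peak": fp.peak,
                "parameter": fp.parameter,
                **({"bounds": list(fp.bounds)} if fp.bounds is not None else {}),
            }
            for fp in model.free_parameters
        ],
        **({"metadata": model.metadata} if model.metadata else {}),
    }


def component_from_dict(data: Mapping) -> PureComponentModel:
    try:
        peaks = [
            PseudoVoigtPeak(
                height=float(p["height"]),
                position=float(p["position_cm1"]),
                fwhm=float(p["fwhm_cm1"]),
                gaussian_fraction=float(p["gaussian_fraction"]),
            )
            for p in data["peaks"]
        ]
        free = [
            FreeParameter(
                peak=int(fp["peak"]),
                parameter=str(fp["parameter"]),
                bounds=tuple(fp["bounds"]) if fp.get("bounds") is not None else None,
            )
            for fp in data.get("free_parameters", [])
        ]
    except (KeyError, TypeError) as exc:
        raise ValidationError(f"malformed component model record: {exc}") from exc
    return PureComponentModel(
        name=str(data["name"]),
        peaks=peaks,
        free_parameters=free,
        metadata=dict(data.get("metadata", {})),
    )


def save_component(model: PureComponentModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(component_to_dict(model), indent=2) + "\n")


def _load_json(path: Path) -> dict:
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc


def load_component(path: str | Path) -> PureComponentModel:
    return component_from_dict(_load_json(Path(path)))


def save_composite(model: CompositeModel, path: str | Path) -> None:
    data = {
        "fit_window": list(model.fit_window),
        "baseline_order": model.baseline_order,
        "components": [component_to_dict(c) for c in model.components],
    }
    Path(path).write_text(json.dumps(data, indent=2) + "\n")


def load_composite(path: str | Path) -> CompositeModel:
    path = Path(path)
    data = _load_json(path)
    components = []
    for entry in data["components"]:
        if isinstance(entry, str):  # reference to a component model file
            components.append(load_component(path.parent / entry))
        else:
            components.append(component_from_dict(entry))
    return CompositeModel(
        components=components,
        fit_window=tuple(data["fit_window"]),
        baseline_order=int(data.get("baseline_order", 1)),
    )
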