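"""Construction of pure-component hard models from spectra.

Two routes exist: direct peak fitting of a (pseudo-)pure spectrum, and
complemental hard modeling (CHM), which co-fits a known component model
(typically water) against a binary aqueous spectrum and attributes the
remainder to new peaks of the unknown solute.

Both routes share the same engine: peak heights, the known-component
weight and the linear baseline are solved linearly (non-negative for
heights/weights) inside a bounded trust-region optimization of the
nonlinear peak parameters, and peaks are added greedily at the residual
maximum until the residual target is met.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares, lsq_linear
from scipy.signal import find_peaks

from .exceptions import DegenerateInputError, ValidationError
from .hard_model import (
    FreeParameter,
    PseudoVoigtPeak,
    PureComponentModel,
    eval_component,
    eval_peak,
)
from .ph_probe import pka_mops
from .spectra_io import RamanSpectrum

__all__ = [
    "PeakFitConfig",
    "fit_pure_component",
    "complemental_hard_modeling",
    "protonation_endpoint_check",
]

logger = logging.getLogger(__name__)

_MAX_PEAKS = 64
_MIN_FWHM = 1.0


@dataclass(frozen=True)
class PeakFitConfig:
    """Controls for peak fitting and automatic peak addition.

    n_peaks=None lets the fitter add peaks greedily at the residual maximum
    until the RMS residual drops below ``residual_threshold * max(intensity)``,
    the relative residual improvement falls below `tolerance`, or the cap
    is reached.
    """

    n_peaks: int | None = None
    max_iterations: int = 200
    tolerance: float = 1e-3
    residual_threshold: float = 0.005
    seed: int = 0
    max_auto_peaks: int = 16

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be > 0")
        if self.n_peaks is not None and not 1 <= self.n_peaks <= _MAX_PEAKS:
            raise ValidationError(f"n_peaks must be in [1, {_MAX_PEAKS}]")
        if not 1 <= self.max_auto_peaks <= _MAX_PEAKS:
            raise ValidationError(f"max_auto_peaks must be in [1, {_MAX_PEAKS}]")


# ---------------------------------------------------------------------------
# shared variable-projection engine
# ---------------------------------------------------------------------------


def _unit_peak_column(
    nu: np.ndarray, position: float, fwhm: float, eta: float
) -> np.ndarray:
    return eval_peak(PseudoVoigtPeak(1.0, position, fwhm, eta), nu)


class _PeakProblem:
    """Joint fit of free-height peaks (+ optional rigid known component).

    Nonlinear parameters: (position, fwhm, eta) per new peak, plus any free
    parameters of the known component.  Linear parameters: peak heights and
    the known-component weight (non-negative) and a linear baseline (free).
    """

    def __init__(
        self,
        nu: np.ndarray,
        y: np.ndarray,
        known: PureComponentModel | None = None,
    ) -> None:
        self.nu = nu
        self.y = y
        self.known = known
        self.known_free: list[FreeParameter] = (
            list(known.free_parameters) if known is not None else []
        )
        centre = 0.5 * (nu[0] + nu[-1])
        halfspan = max(0.5 * (nu[-1] - nu[0]), 1.0)
        self.t = (nu - centre) / halfspan
        self._centre, self._halfspan = centre, halfspan
        self.window = (float(nu[0]), float(nu[-1]))

    # -- parameter packing: theta = [known free..., (pos, fwhm, eta) * n] --

    def pack(self, peaks: Sequence[PseudoVoigtPeak]) -> np.ndarray:
        head = [
            getattr(self.known.peaks[fp.peak], fp.parameter) for fp in self.known_free
        ]
        body = []
        for p in peaks:
            body += [p.position, p.fwhm, p.gaussian_fraction]
        return np.array(head + body)

    def bounds(self, n_peaks: int) -> tuple[np.ndarray, np.ndarray]:
        lo_list, hi_list = [], []
        for fp in self.known_free:
            blo, bhi = self.known.parameter_bounds(fp)
            lo_list.append(blo)
            hi_list.append(bhi)
        wlo, whi = self.window
        span = whi - wlo
        for _ in range(n_peaks):
            lo_list += [wlo, _MIN_FWHM, 0.0]
            hi_list += [whi, span, 1.0]
        return np.array(lo_list), np.array(hi_list)

    def design(self, theta: np.ndarray, n_peaks: int) -> np.ndarray:
        nk = len(self.known_free)
        cols = []
        if self.known is not None:
            peaks = list(self.known.peaks)
            for fp, value in zip(self.known_free, theta[:nk]):
                peaks[fp.peak] = replace(peaks[fp.peak], **{fp.parameter: value})
            cols.append(eval_component(replace(self.known, peaks=peaks), self.nu))
        for j in range(n_peaks):
            pos, fwhm, eta = theta[nk + 3 * j : nk + 3 * j + 3]
            cols.append(_unit_peak_column(self.nu, pos, max(fwhm, _MIN_FWHM), eta))
        return (
            np.column_stack(cols) if cols else np.empty((self.nu.size, 0))
        )

    def solve_linear(self, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        m = A.shape[1]
        design = np.column_stack([A, np.ones_like(self.t), self.t])
        lower = np.concatenate([np.zeros(m), [-np.inf, -np.inf]])
        sol = lsq_linear(design, self.y, bounds=(lower, np.full(m + 2, np.inf)), method="bvls")
        return sol.x, self.y - design @ sol.x

    def residual(self, theta: np.ndarray, n_peaks: int) -> np.ndarray:
        _, r = self.solve_linear(self.design(theta, n_peaks))
        return r

    def optimize(
        self, peaks: list[PseudoVoigtPeak], config: PeakFitConfig
    ) -> tuple[list[PseudoVoigtPeak], float, float, np.ndarray, bool]:
        """Refine all parameters; returns (peaks, known_weight, rms, residual, ok)."""
        n = len(peaks)
        theta0 = self.pack(peaks)
        lo, hi = self.bounds(n)
        theta0 = np.clip(theta0, lo, hi)
        ok = True
        if theta0.size:
            result = least_squares(
                self.residual,
                theta0,
                bounds=(lo, hi),
                args=(n,),
                x_scale=np.maximum(np.abs(theta0), 1.0),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=config.max_iterations * max(theta0.size, 1),
                method="trf",
            )
            theta = result.x
            ok = bool(result.status > 0)
        else:
            theta = theta0
        coeffs, r = self.solve_linear(self.design(theta, n))
        nk = len(self.known_free)
        offset = 1 if self.known is not None else 0
        known_weight = float(coeffs[0]) if self.known is not None else 0.0
        new_peaks = []
        for j in range(n):
            pos, fwhm, eta = theta[nk + 3 * j : nk + 3 * j + 3]
            height = float(coeffs[offset + j])
            new_peaks.append(PseudoVoigtPeak(height, float(pos), float(fwhm), float(eta)))
        # record the known component's fitted free parameters
        if self.known is not None and nk:
            fitted = {
                (fp.peak, fp.parameter): float(v)
                for fp, v in zip(self.known_free, theta[:nk])
            }
        else:
            fitted = {}
        self.fitted_known_parameters = fitted
        rms = float(np.sqrt(np.mean(r**2)))
        return new_peaks, known_weight, rms, r, ok


def _initial_positions(
    nu: np.ndarray, y: np.ndarray, n_wanted: int
) -> list[tuple[float, float]]:
    """Detect candidate (position, fwhm) pairs from local maxima.

    The spectrum is baseline-flattened by the straight line through its
    endpoints; the initial FWHM is half the distance to the nearest other
    detected maximum (floored).
    """
    baseline = np.interp(nu, [nu[0], nu[-1]], [y[0], y[-1]])
    flat = y - baseline
    idx, _ = find_peaks(flat)
    if idx.size == 0:
        idx = np.array([int(np.argmax(flat))])
    order = np.argsort(flat[idx])[::-1]
    idx = idx[order][:n_wanted]
    positions = nu[idx]
    out = []
    for p in positions:
        others = positions[positions != p]
        if others.size:
            fwhm = max(0.5 * float(np.min(np.abs(others - p))), 4.0)
        else:
            fwhm = max((nu[-1] - nu[0]) / 10.0, 4.0)
        out.append((float(p), fwhm))
    return out


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def fit_pure_component(
    spectrum: RamanSpectrum, config: PeakFitConfig, name: str
) -> PureComponentModel:
    """Fit a sum of pseudo-Voigt peaks (plus a linear baseline) to a spectrum.

    With ``config.n_peaks`` set, exactly that many peaks are used; otherwise
    peaks are added greedily at the residual maximum.  Convergence status
    and the final RMS residual are recorded in the returned model's
    ``metadata``; failure to reach the residual target is flagged, not
    raised.
    """
    y = spectrum.intensity
    ymax = float(np.max(np.abs(y)))
    if ymax == 0:
        raise ValidationError("all-zero spectrum")
    nu = spectrum.wavenumber
    problem = _PeakProblem(nu, y)
    target = config.residual_threshold * ymax

    if config.n_peaks is not None:
        seeds = _initial_positions(nu, y, config.n_peaks)
        peaks = [PseudoVoigtPeak(1.0, p, w, 0.5) for p, w in seeds]
        while len(peaks) < config.n_peaks:  # top up at residual maxima
            fitted, _, _, r, _ = problem.optimize(peaks, config)
            j = int(np.argmax(np.abs(r)))
            peaks = fitted + [PseudoVoigtPeak(1.0, float(nu[j]), 8.0, 0.5)]
        peaks, _, rms, _, ok = problem.optimize(peaks, config)
    else:
        peaks, rms, ok = _greedy_addition(problem, config, target)

    converged = ok and rms <= target
    model = PureComponentModel(
        name=name,
        peaks=sorted(peaks, key=lambda p: p.position),
        metadata={"converged": converged, "residual_rms": rms},
    )
    return model


def _greedy_addition(
    problem: _PeakProblem, config: PeakFitConfig, target: float
) -> tuple[list[PseudoVoigtPeak], float, bool]:
    cap = config.n_peaks or config.max_auto_peaks
    seeds = _initial_positions(problem.nu, problem.y, 1)
    peaks = [PseudoVoigtPeak(1.0, seeds[0][0], seeds[0][1], 0.5)]
    peaks, _, rms, r, ok = problem.optimize(peaks, config)
    while rms > target and len(peaks) < cap:
        j = int(np.argmax(np.abs(r)))
        trial = peaks + [PseudoVoigtPeak(1.0, float(problem.nu[j]), 8.0, 0.5)]
        trial, _, new_rms, new_r, ok = problem.optimize(trial, config)
        if rms > 0 and (rms - new_rms) / rms < config.tolerance:
            break
        peaks, rms, r = trial, new_rms, new_r
    return peaks, rms, ok


def complemental_hard_modeling(
    binary_spectrum: RamanSpectrum,
    known: PureComponentModel,
    config: PeakFitConfig,
    name: str,
) -> PureComponentModel:
    """Extract the unknown solute model from a binary spectrum by CHM.

    The known model (weight, free parameters) and a linear baseline are
    co-fitted with new peaks added greedily for the unknown; the returned
    model holds only the new peaks.  If the known model alone already
    explains the spectrum to within the residual target, the input is
    degenerate and an error is raised.
    """
    y = binary_spectrum.intensity
    ymax = float(np.max(np.abs(y)))
    if ymax == 0:
        raise ValidationError("all-zero spectrum")
    nu = binary_spectrum.wavenumber
    problem = _PeakProblem(nu, y, known=known)
    target = config.residual_threshold * ymax

    _, _, rms0, r0, _ = problem.optimize([], config)
    if rms0 <= target:
        raise DegenerateInputError(
            f"known component {known.name!r} alone explains the spectrum "
            f"(rms {rms0:.3g} <= target {target:.3g}); no unknown to extract"
        )

    cap = config.n_peaks or config.max_auto_peaks
    peaks: list[PseudoVoigtPeak] = []
    rms, r = rms0, r0
    while rms > target and len(peaks) < cap:
        j = int(np.argmax(np.abs(r)))
        trial = peaks + [PseudoVoigtPeak(1.0, float(nu[j]), 8.0, 0.5)]
        trial, _, new_rms, new_r, _ = problem.optimize(trial, config)
        if rms > 0 and (rms - new_rms) / rms < config.tolerance:
            break
        peaks, rms, r = trial, new_rms, new_r

    peaks, known_weight, rms, _, ok = problem.optimize(peaks, config)
    if not peaks or all(p.height <= 1e-12 * ymax for p in peaks):
        raise DegenerateInputError("no significant unknown component found")

    for p in peaks:
        for kp in known.peaks:
            if abs(p.position - kp.position) <= kp.fwhm:
                logger.warning(
                    "CHM peak at %.1f cm^-1 lies within one FWHM of known peak "
                    "at %.1f cm^-1; residual structure may be misattributed",
                    p.position,
                    kp.position,
                )
    return PureComponentModel(
        name=name,
        peaks=sorted(peaks, key=lambda p: p.position),
        metadata={
            "converged": ok and rms <= target,
            "residual_rms": rms,
            "known_weight": known_weight,
            "known_component": known.name,
        },
    )


def protonation_endpoint_check(
    ph: float, species: str, temperature: float
) -> float:
    """Equilibrium fraction of the requested MOPS species at a given pH.

    Used to verify that endpoint spectra (pH ~2 or ~12) are effectively
    pure before building single-species models; >= 0.999 counts as pure.
    """
    if not 0.0 <= ph <= 14.0:
        raise ValidationError(f"pH {ph} outside [0, 14]")
    pka = pka_mops(temperature)
    if species == "protonated":
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    if species == "deprotonated":
        return 1.0 / (1.0 + 10.0 ** (pka - ph))
    raise ValidationError(f"species must be 'protonated' or 'deprotonated', got {species!r}")
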