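"""Reading, writing and slicing of 1-D Raman spectra.

Canonical in-memory representation: strictly increasing wavenumber axis in
cm^-1 with intensities in arbitrary counts.  Two on-disk formats are
supported:

* two-column CSV (comma, tab or semicolon separated, optional header row)
  with metadata carried in ``#``-prefixed ``key=value`` comment lines;
* a plain-AFFN subset of JCAMP-DX: ``XYPOINTS=(XY..XY)`` and
  ``XYDATA=(X++(Y..Y))`` records are read, ``XYPOINTS`` is written.

Files with a decreasing axis are silently reversed on read.  Temperatures
are stored in kelvin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .exceptions import ParseError, ValidationError

__all__ = [
    "RamanSpectrum",
    "SpectrumSeries",
    "read_spectrum",
    "write_spectrum",
    "crop",
]

_TEMPERATURE_BOUNDS = (273.15, 373.15)


@dataclass
class RamanSpectrum:
    """A single Raman spectrum plus acquisition metadata.

    Parameters
    ----------
    wavenumber : array-like
        Strictly increasing axis in cm^-1 (length >= 2).
    intensity : array-like
        Intensities in arbitrary counts, same length as `wavenumber`.
    temperature : float, optional
        Sample temperature in kelvin.
    reference_ph : float, optional
        pH measured by a reference electrode, if available.
    label : str
        Free-text identifier.
    """

    wavenumber: np.ndarray
    intensity: np.ndarray
    temperature: float | None = None
    reference_ph: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.ndim != 1 or self.intensity.ndim != 1:
            raise ValidationError("wavenumber and intensity must be 1-D")
        if self.wavenumber.size != self.intensity.size:
            raise ValidationError(
                f"length mismatch: {self.wavenumber.size} wavenumbers vs "
                f"{self.intensity.size} intensities"
            )
        if self.wavenumber.size < 2:
            raise ValidationError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.wavenumber) > 0):
            raise ValidationError("wavenumber axis must be strictly increasing")
        if self.temperature is not None:
            lo, hi = _TEMPERATURE_BOUNDS
            if not lo <= self.temperature <= hi:
                raise ValidationError(
                    f"temperature {self.temperature} K outside [{lo}, {hi}]"
                )

    def __len__(self) -> int:
        return int(self.wavenumber.size)

    def scaled(self, factor: float) -> "RamanSpectrum":
        """Return a copy with all intensities multiplied by `factor`."""
        return replace(self, intensity=self.intensity * factor)


@dataclass
class SpectrumSeries:
    """An ordered collection of spectra sharing one wavenumber grid."""

    spectra: list[RamanSpectrum]
    label: str = ""
    timestamps: np.ndarray | None = None  # seconds

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValidationError("a SpectrumSeries must contain spectra")
        grid = self.spectra[0].wavenumber
        for i, s in enumerate(self.spectra[1:], start=1):
            if s.wavenumber.shape != grid.shape or not np.array_equal(
                s.wavenumber, grid
            ):
                raise ValidationError(f"spectrum {i} is on a different grid")
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.size != len(self.spectra):
                raise ValidationError("one timestamp per spectrum required")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------

_CSV_SPLIT = re.compile(r"[,\t;]|\s+")

_META_KEYS = {
    "temperature_k": "temperature",
    "reference_ph": "reference_ph",
    "label": "label",
}


def _parse_csv(lines: Sequence[str], origin: str) -> RamanSpectrum:
    meta: dict[str, object] = {}
    xs: list[float] = []
    ys: list[float] = []
    header_candidate = True  # only the first non-comment row may be a header
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                key = key.strip().lower()
                if key in _META_KEYS:
                    attr = _META_KEYS[key]
                    meta[attr] = value.strip() if attr == "label" else float(value)
            continue
        tokens = [t for t in _CSV_SPLIT.split(line) if t]
        if len(tokens) < 2:
            raise ParseError(f"{origin}: line {lineno}: expected two columns")
        try:
            x, y = float(tokens[0]), float(tokens[1])
        except ValueError:
            if header_candidate and _looks_like_header(tokens):
                header_candidate = False
                continue  # single header row
            raise ParseError(
                f"{origin}: line {lineno}: could not parse {line!r} as numbers"
            ) from None
        header_candidate = False
        xs.append(x)
        ys.append(y)
    if len(xs) < 2:
        raise ParseError(f"{origin}: fewer than 2 data rows")
    return _canonicalize(np.array(xs), np.array(ys), meta, origin)


def _looks_like_header(tokens: Sequence[str]) -> bool:
    # a header row starts with a non-numeric column name; a data row with a
    # corrupt second field ("2700,abc") is an error, not a header
    try:
        float(tokens[0])
    except ValueError:
        return True
    return False


def _canonicalize(
    x: np.ndarray, y: np.ndarray, meta: dict, origin: str
) -> RamanSpectrum:
    if x.size >= 2 and x[0] > x[-1]:
        x, y = x[::-1], y[::-1]
    if not np.all(np.diff(x) > 0):
        raise ValidationError(f"{origin}: wavenumber axis not monotone")
    return RamanSpectrum(x, y, **meta)


def _format_csv(spectrum: RamanSpectrum) -> str:
    lines = []
    if spectrum.label:
        lines.append(f"# label = {spectrum.label}")
    if spectrum.temperature is not None:
        lines.append(f"# temperature_k = {spectrum.temperature!r}")
    if spectrum.reference_ph is not None:
        lines.append(f"# reference_ph = {spectrum.reference_ph!r}")
    lines.append("wavenumber_cm-1,intensity")
    for x, y in zip(spectrum.wavenumber, spectrum.intensity):
        lines.append(f"{float(x)!r},{float(y)!r}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# JCAMP-DX (plain-AFFN subset)
# ---------------------------------------------------------------------------


def _parse_jcamp(lines: Sequence[str], origin: str) -> RamanSpectrum:
    meta: dict[str, object] = {}
    records: dict[str, str] = {}
    data_mode: str | None = None
    data_lines: list[tuple[int, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("$$", 1)[0].rstrip()
        if not line.strip():
            continue
        if line.startswith("##"):
            label, _, value = line[2:].partition("=")
            label = label.strip().upper().replace(" ", "")
            value = value.strip()
            records[label] = value
            if label in ("XYPOINTS", "XYDATA"):
                data_mode = label
            elif data_mode is not None and label == "END":
                data_mode = None
            elif data_mode is not None:
                data_mode = None  # any other record terminates the table
            continue
        if data_mode is not None:
            data_lines.append((lineno, line))
    if data_mode is None and not data_lines:
        raise ParseError(f"{origin}: no XYDATA or XYPOINTS record found")

    xfactor = float(records.get("XFACTOR", 1.0))
    yfactor = float(records.get("YFACTOR", 1.0))
    if "$TEMPERATUREK" in records:
        meta["temperature"] = float(records["$TEMPERATUREK"])
    if "$REFERENCEPH" in records:
        meta["reference_ph"] = float(records["$REFERENCEPH"])
    if "TITLE" in records and records["TITLE"]:
        meta["label"] = records["TITLE"]

    xs: list[float] = []
    ys: list[float] = []
    if "XYPOINTS" in records:
        for lineno, line in data_lines:
            for pair in line.split(";"):
                pair = pair.strip()
                if not pair:
                    continue
                tokens = [t for t in re.split(r"[,\s]+", pair) if t]
                if len(tokens) != 2:
                    raise ParseError(
                        f"{origin}: line {lineno}: bad XY pair {pair!r}"
                    )
                try:
                    xs.append(float(tokens[0]) * xfactor)
                    ys.append(float(tokens[1]) * yfactor)
                except ValueError:
                    raise ParseError(
                        f"{origin}: line {lineno}: bad XY pair {pair!r}"
                    ) from None
    else:  # XYDATA=(X++(Y..Y))
        for lineno, line in data_lines:
            tokens = [t for t in re.split(r"[,\s]+", line.strip()) if t]
            try:
                values = [float(t) for t in tokens]
            except ValueError:
                raise ParseError(
                    f"{origin}: line {lineno}: non-numeric XYDATA token"
                ) from None
            if len(values) < 2:
                raise ParseError(f"{origin}: line {lineno}: XYDATA row too short")
            x0 = values[0] * xfactor
            yrow = values[1:]
            xs.extend(_xydata_axis(x0, len(yrow), records, xfactor))
            ys.extend(v * yfactor for v in yrow)
    if len(xs) < 2:
        raise ParseError(f"{origin}: fewer than 2 data points")
    return _canonicalize(np.array(xs), np.array(ys), meta, origin)


def _xydata_axis(x0: float, n: int, records: dict, xfactor: float) -> list[float]:
    if "DELTAX" in records:
        dx = float(records["DELTAX"])
    else:
        first = float(records.get("FIRSTX", x0))
        last = float(records.get("LASTX", x0))
        npts = int(float(records.get("NPOINTS", n)))
        dx = (last - first) / (npts - 1) if npts > 1 else 1.0
    return [x0 + i * dx for i in range(n)]


def _format_jcamp(spectrum: RamanSpectrum) -> str:
    lines = [
        f"##TITLE={spectrum.label}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=RAMAN SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ARBITRARY UNITS",
    ]
    if spectrum.temperature is not None:
        lines.append(f"##$TEMPERATUREK={spectrum.temperature!r}")
    if spectrum.reference_ph is not None:
        lines.append(f"##$REFERENCEPH={spectrum.reference_ph!r}")
    lines += [
        f"##NPOINTS={len(spectrum)}",
        f"##FIRSTX={float(spectrum.wavenumber[0])!r}",
        f"##LASTX={float(spectrum.wavenumber[-1])!r}",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        "##XYPOINTS=(XY..XY)",
    ]
    for x, y in zip(spectrum.wavenumber, spectrum.intensity):
        lines.append(f"{float(x)!r}, {float(y)!r}")
    lines.append("##END=")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
        if fmt not in ("csv", "jcamp"):
            raise ValidationError(f"unknown format {format!r}")
        return fmt
    if path.suffix.lower() in (".jdx", ".dx", ".jcamp"):
        return "jcamp"
    return "csv"


def read_spectrum(path: str | Path, format: str | None = None) -> RamanSpectrum:
    """Read a spectrum from `path`.

    `format` is ``"csv"`` or ``"jcamp"``; when omitted it is inferred from
    the file extension (``.jdx``/``.dx``/``.jcamp`` -> JCAMP, else CSV).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    fmt = _infer_format(path, format)
    if fmt == "jcamp":
        return _parse_jcamp(lines, str(path))
    return _parse_csv(lines, str(path))


def write_spectrum(
    spectrum: RamanSpectrum, path: str | Path, format: str | None = None
) -> None:
    """Write `spectrum` to `path` in CSV or JCAMP-DX (XYPOINTS) form."""
    path = Path(path)
    fmt = _infer_format(path, format)
    text = _format_jcamp(spectrum) if fmt == "jcamp" else _format_csv(spectrum)
    path.write_text(text)


def crop(spectrum: RamanSpectrum, lo: float, hi: float) -> RamanSpectrum:
    """Return the samples with ``lo <= wavenumber <= hi`` (closed interval)."""
    if not lo < hi:
        raise ValidationError(f"need lo < hi, got [{lo}, {hi}]")
    mask = (spectrum.wavenumber >= lo) & (spectrum.wavenumber <= hi)
    if mask.sum() < 2:
        raise ValidationError(
            f"crop window [{lo}, {hi}] overlaps fewer than 2 samples of the "
            f"axis [{spectrum.wavenumber[0]}, {spectrum.wavenumber[-1]}]"
        )
    return replace(
        spectrum,
        wavenumber=spectrum.wavenumber[mask],
        intensity=spectrum.intensity[mask],
    )
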