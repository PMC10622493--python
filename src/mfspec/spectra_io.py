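"""Reading, validation and resampling of FTIR absorbance spectra.

A :class:`Spectrum` is a pair of equal-length arrays — wavenumber (cm^-1)
and absorbance (AU) — plus free-form string metadata (sample id, cell-line
label, mixing fraction, ...).  Spectra are stored in *descending* wavenumber
order, the mid-IR plotting convention (4000 -> 650 cm^-1); readers accept
either orientation and normalize on ingest.

Two text formats are supported:

* CSV/TSV: two numeric columns, optional ``#``-prefixed header lines that
  carry metadata as ``key=value``.
* A JCAMP-DX subset: single-block ``##XYDATA=(X++(Y..Y))`` (AFFN) and
  ``##XYPOINTS=(XY..XY)`` dialects, honouring XFACTOR/YFACTOR.  Compressed
  dialects (DIFDUP etc.) are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Spectrum",
    "SpectrumError",
    "read_spectrum",
    "write_spectrum",
    "crop_to_range",
    "resample_uniform",
]


class SpectrumError(ValueError):
    """Raised when spectral data violate the Spectrum invariants."""


@dataclass
class Spectrum:
    """An absorbance spectrum on a strictly monotone wavenumber axis.

    Parameters
    ----------
    wavenumbers
        Wavenumber axis in cm^-1, strictly monotone in either direction;
        stored descending.
    absorbance
        Absorbance in AU, same length, all finite.
    meta
        Free-form string metadata (e.g. ``sample``, ``line``, ``phi``).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.ndim != 1 or a.ndim != 1 or w.size != a.size:
            raise SpectrumError("wavenumbers and absorbance must be 1-D and equal length")
        if w.size < 2:
            raise SpectrumError("a spectrum needs at least 2 points")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(a))):
            raise SpectrumError("non-finite value (NaN/Inf) in spectrum")
        dw = np.diff(w)
        if np.all(dw > 0):  # ascending on input -> flip to canonical order
            w, a = w[::-1].copy(), a[::-1].copy()
        elif not np.all(dw < 0):
            raise SpectrumError("wavenumbers must be strictly monotone")
        self.wavenumbers = w
        self.absorbance = a

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def wmin(self) -> float:
        return float(self.wavenumbers[-1])

    @property
    def wmax(self) -> float:
        return float(self.wavenumbers[0])

    def copy(self, **meta_updates) -> "Spectrum":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(self.wavenumbers.copy(), self.absorbance.copy(), meta)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_META_RE = re.compile(r"^#\s*([^=\s]+)\s*=\s*(.*?)\s*$")


def _read_csv(path: Path) -> Spectrum:
    meta: dict = {}
    w, a = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _META_RE.match(line)
            if m:
                meta[m.group(1)] = m.group(2)
            continue
        parts = line.split(",") if "," in line else line.split()
        if len(parts) < 2:
            raise SpectrumError(f"{path}:{lineno}: expected two columns, got {line!r}")
        try:
            w.append(float(parts[0]))
            a.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumError(f"{path}:{lineno}: non-numeric value in {line!r}") from exc
    if not w:
        raise SpectrumError(f"{path}: no data rows")
    return Spectrum(np.array(w), np.array(a), meta)


_NUM_RE = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def _read_jcamp(path: Path) -> Spectrum:
    """Parse a single-block JCAMP-DX file (AFFN XYDATA or XYPOINTS)."""
    header: dict = {}
    mode = None  # "xydata" | "xypoints"
    data_lines: list[str] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XYDATA":
                mode = "xydata"
            elif key == "XYPOINTS":
                mode = "xypoints"
            elif key == "END":
                break
            else:
                header[key] = value
        elif mode is not None and line:
            data_lines.append(line)
    if mode is None:
        raise SpectrumError(f"{path}: no XYDATA/XYPOINTS block found")

    xfac = float(header.get("XFACTOR", 1.0))
    yfac = float(header.get("YFACTOR", 1.0))
    meta = {}
    for k in ("TITLE", "XUNITS", "YUNITS"):
        if k in header:
            meta[k.lower()] = header[k]

    if mode == "xypoints":
        nums = [float(t) for line in data_lines for t in _NUM_RE.findall(line)]
        if len(nums) % 2:
            raise SpectrumError(f"{path}: odd token count in XYPOINTS block")
        arr = np.array(nums).reshape(-1, 2)
        return Spectrum(arr[:, 0] * xfac, arr[:, 1] * yfac, meta)

    # XYDATA=(X++(Y..Y)): each line starts with an X value, then Y values
    # spaced by DELTAX (derived from FIRSTX/LASTX/NPOINTS when absent).
    if "DELTAX" in header:
        deltax = float(header["DELTAX"])
    else:
        try:
            first = float(header["FIRSTX"])
            last = float(header["LASTX"])
            npts = int(float(header["NPOINTS"]))
        except KeyError as exc:
            raise SpectrumError(f"{path}: XYDATA needs DELTAX or FIRSTX/LASTX/NPOINTS") from exc
        deltax = (last - first) / (npts - 1)
    w, a = [], []
    for line in data_lines:
        nums = [float(t) for t in _NUM_RE.findall(line)]
        if len(nums) < 2:
            raise SpectrumError(f"{path}: short XYDATA line {line!r}")
        x0 = nums[0] * xfac
        for i, y in enumerate(nums[1:]):
            w.append(x0 + i * deltax * xfac)
            a.append(y * yfac)
    return Spectrum(np.array(w), np.array(a), meta)


def read_spectrum(path, format: str | None = None) -> Spectrum:
    """Read a spectrum from ``path``.

    ``format`` is ``"csv"`` or ``"jcamp-dx"``; when ``None`` it is inferred
    from the suffix (``.dx``/``.jdx``/``.jcamp`` -> JCAMP, else CSV).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "jcamp-dx" if path.suffix.lower() in {".dx", ".jdx", ".jcamp"} else "csv"
    if format == "csv":
        return _read_csv(path)
    if format in {"jcamp-dx", "jcamp", "jdx"}:
        return _read_jcamp(path)
    raise ValueError(f"unknown spectrum format {format!r}")


def write_spectrum(s: Spectrum, path, format: str = "csv") -> None:
    """Write ``s`` as two-column CSV with meta in ``# key=value`` headers."""
    if format != "csv":
        raise ValueError(f"unsupported output format {format!r}")
    path = Path(path)
    lines = [f"# {k}={v}" for k, v in s.meta.items()]
    lines += [f"{w:.12g},{a:.12g}" for w, a in zip(s.wavenumbers, s.absorbance)]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# axis operations
# ---------------------------------------------------------------------------

def crop_to_range(s: Spectrum, wmin: float, wmax: float) -> Spectrum:
    """Keep only points with wavenumber in [wmin, wmax]."""
    if not wmin < wmax:
        raise ValueError("wmin must be < wmax")
    keep = (s.wavenumbers >= wmin) & (s.wavenumbers <= wmax)
    if keep.sum() < 2:
        raise SpectrumError(
            f"crop range [{wmin}, {wmax}] leaves fewer than 2 points "
            f"of a spectrum spanning [{s.wmin}, {s.wmax}]"
        )
    return Spectrum(s.wavenumbers[keep], s.absorbance[keep], dict(s.meta))


def resample_uniform(s: Spectrum, n_points: int) -> Spectrum:
    """Resample onto a uniform wavenumber grid spanning the same range.

    Linear interpolation; endpoints are preserved exactly.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    grid = np.linspace(s.wmax, s.wmin, n_points)  # descending
    # np.interp needs ascending abscissae
    asc_w = s.wavenumbers[::-1]
    asc_a = s.absorbance[::-1]
    vals = np.interp(grid[::-1], asc_w, asc_a)[::-1]
    return Spectrum(grid, vals, dict(s.meta))
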