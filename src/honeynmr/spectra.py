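"""Processed 1D 1H-NMR spectra: data model, file I/O and TMSP referencing.

Spectra are already-processed absorption spectra (ppm axis plus real
intensities).  Two on-disk dialects are supported: two-column delimited text
(ppm, intensity) and single-block JCAMP-DX with plain-number (AFFN)
``XYDATA=(X++(Y..Y))`` tables.  Axes are stored ascending internally
regardless of file order; chemical shifts are relative to TMSP = 0 ppm.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import SpectrumFormatError


@dataclass
class Spectrum:
    """A processed 1D spectrum with its referencing state and sample metadata."""

    ppm: np.ndarray
    intensity: np.ndarray
    referenced: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumFormatError("ppm and intensity must be 1-D")
        if self.ppm.shape != self.intensity.shape:
            raise SpectrumFormatError(
                f"length mismatch: {self.ppm.size} ppm vs {self.intensity.size} intensities"
            )
        if self.ppm.size < 2:
            raise SpectrumFormatError("spectrum needs at least two points")
        if not np.all(np.isfinite(self.intensity)) or not np.all(np.isfinite(self.ppm)):
            raise SpectrumFormatError("non-finite values in spectrum")
        diffs = np.diff(self.ppm)
        if np.all(diffs < 0):  # stored descending on disk: flip to ascending
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(diffs > 0):
            raise SpectrumFormatError("ppm axis must be strictly monotone")

    @property
    def grid_step(self) -> float:
        """Median axis spacing (exact spacing for uniform grids)."""
        return float(np.median(np.diff(self.ppm)))

    def copy(self) -> "Spectrum":
        return Spectrum(self.ppm.copy(), self.intensity.copy(), self.referenced, dict(self.meta))


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------


def read_spectrum(path: str | Path, dialect: str = "two_column_text") -> Spectrum:
    """Read a spectrum file.  ``referenced`` is always False after load."""
    path = Path(path)
    if dialect == "two_column_text":
        return _read_two_column(path)
    if dialect == "jcamp_dx":
        return _read_jcamp(path)
    raise ValueError(f"unknown spectrum dialect: {dialect!r}")


def write_spectrum(s: Spectrum, path: str | Path, dialect: str = "two_column_text") -> None:
    path = Path(path)
    if dialect == "two_column_text":
        lines = [f"{float(x)!r}\t{float(y)!r}" for x, y in zip(s.ppm, s.intensity)]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif dialect == "jcamp_dx":
        _write_jcamp(s, path)
    else:
        raise ValueError(f"unknown spectrum dialect: {dialect!r}")


def _read_two_column(path: Path) -> Spectrum:
    xs, ys = [], []
    for ln, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[,\t ]+", line)
        if len(parts) < 2:
            raise SpectrumFormatError(f"{path}:{ln}: expected two columns, got {line!r}")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumFormatError(f"{path}:{ln}: {exc}") from exc
    if len(set(xs)) != len(xs):
        raise SpectrumFormatError(f"{path}: duplicated ppm value(s)")
    return Spectrum(np.array(xs), np.array(ys), referenced=False, meta={"source": str(path)})


_LDR_RE = re.compile(r"^##(?P<key>[^=]+)=(?P<value>.*)$")


def _read_jcamp(path: Path) -> Spectrum:
    """Minimal single-block JCAMP-DX reader (AFFN XYDATA only)."""
    headers: dict[str, str] = {}
    y_raw: list[float] = []
    x_checks: list[tuple[int, float]] = []
    in_xydata = False
    for raw in path.read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("$$"):
            continue
        m = _LDR_RE.match(line)
        if m:
            key = m.group("key").strip().upper().replace(" ", "")
            headers[key] = m.group("value").strip()
            if key == "XYDATA":
                in_xydata = True
            elif key == "END":
                in_xydata = False
            elif in_xydata:
                in_xydata = False
            continue
        if in_xydata:
            parts = line.split()
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise SpectrumFormatError(f"{path}: bad XYDATA line {line!r}") from exc
            if len(vals) < 2:
                raise SpectrumFormatError(f"{path}: XYDATA line with no Y values")
            x_checks.append((len(y_raw), vals[0]))
            y_raw.extend(vals[1:])
    for key in ("FIRSTX", "LASTX", "NPOINTS"):
        if key not in headers:
            raise SpectrumFormatError(f"{path}: missing ##{key}=")
    n = int(float(headers["NPOINTS"]))
    if n != len(y_raw):
        raise SpectrumFormatError(
            f"{path}: NPOINTS={n} but {len(y_raw)} Y values found"
        )
    firstx = float(headers["FIRSTX"])
    lastx = float(headers["LASTX"])
    xfac = float(headers.get("XFACTOR", "1"))
    yfac = float(headers.get("YFACTOR", "1"))
    ppm = np.linspace(firstx, lastx, n) * xfac
    intensity = np.array(y_raw) * yfac
    meta = {"source": str(path)}
    if "TITLE" in headers:
        meta["sample_id"] = headers["TITLE"]
    return Spectrum(ppm, intensity, referenced=False, meta=meta)


def _write_jcamp(s: Spectrum, path: Path) -> None:
    n = s.ppm.size
    lines = [
        f"##TITLE={s.meta.get('sample_id', 'honeynmr spectrum')}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        "##XFACTOR=1",
        "##YFACTOR=1",
        f"##FIRSTX={float(s.ppm[0])!r}",
        f"##LASTX={float(s.ppm[-1])!r}",
        f"##NPOINTS={n}",
        f"##FIRSTY={float(s.intensity[0])!r}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 4
    for i in range(0, n, per_line):
        ys = " ".join(repr(float(v)) for v in s.intensity[i : i + per_line])
        lines.append(f"{float(s.ppm[i])!r} {ys}")
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Referencing
# ---------------------------------------------------------------------------


def reference_spectrum(
    s: Spectrum,
    search_window: tuple[float, float] = (-0.1, 0.1),
    ref_ppm: float = 0.0,
) -> Spectrum:
    """Shift the axis so the tallest point in ``search_window`` sits at ``ref_ppm``.

    Intensities are untouched.  A flat window (no unique maximum) is resolved
    to the candidate nearest ``ref_ppm`` with a warning.  Idempotent to within
    one grid step.
    """
    lo, hi = search_window
    if not lo < hi:
        raise ValueError("search_window must be an increasing (lo, hi) interval")
    mask = (s.ppm >= lo) & (s.ppm <= hi)
    if not mask.any():
        raise ValueError(
            f"search window [{lo}, {hi}] contains no axis points "
            f"(axis spans [{s.ppm[0]}, {s.ppm[-1]}])"
        )
    idx = np.flatnonzero(mask)
    vals = s.intensity[idx]
    top = vals.max()
    winners = idx[vals == top]
    if winners.size > 1:
        warnings.warn(
            "no unique maximum in the referencing window; "
            "tie broken to the point nearest the reference shift",
            stacklevel=2,
        )
        winners = winners[np.argsort(np.abs(s.ppm[winners] - ref_ppm), kind="stable")]
    apex = winners[0]
    shift = ref_ppm - s.ppm[apex]
    return Spectrum(s.ppm + shift, s.intensity.copy(), referenced=True, meta=dict(s.meta))
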