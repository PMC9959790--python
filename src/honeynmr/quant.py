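"""Internal-standard quantitation: spectra -> per-sample concentrations.

Peak areas are plain sums of the intensity values at the grid points inside
each integration region (inclusive endpoints; no baseline fit, no
deconvolution).  The molar concentration of analyte a is

    C_a (mM) = (A_a / N_eff,a) / (A_TMSP / 9) * C_TMSP * s_a

where A_a is the (possibly multi-region) summed area, N_eff,a the effective
proton count the region(s) represent per molecule, s_a the back-calculation
scaling factor (inverse alpha-anomer fraction for sugars quantified on the
H-1alpha resonance alone, 1 otherwise), and C_TMSP the verified internal
standard concentration (0.966 mM by default).  Mass concentrations follow
from the sample mass and solvent volume:

    mg/kg = C_a * MW_a * V_mL / (mass_mg * 1e-3)      (= C_a * MW_a * 20
                                                       at the 50 mg / 1 mL
                                                       preparation defaults)
    g/100 g = mg/kg / 1e4

LOQ flags annotate values below the panel LOQ; they never censor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CalibrationError
from .panel import AnalytePanel, AnalyteDefinition, IntegrationRegion, loq_mgkg  # noqa: F401 (re-export)
from .spectra import Spectrum


@dataclass
class QuantResult:
    """Per-sample quantitation output (one replicate, or a replicate average)."""

    sample_id: str
    concentrations: dict[str, float]        # in each analyte's unit_class
    raw_mM: dict[str, float]
    loq_flags: dict[str, bool]
    tmsp_area: float
    replicate: int | None = None
    per_analyte_sd: dict[str, float] | None = None
    units: dict[str, str] = field(default_factory=dict)


def integrate_region(s: Spectrum, r: IntegrationRegion) -> float:
    """Sum of intensities at grid points with ppm_min <= ppm <= ppm_max."""
    if not s.referenced:
        raise CalibrationError("spectrum must be referenced before integration")
    if r.ppm_min < s.ppm[0] or r.ppm_max > s.ppm[-1]:
        raise ValueError(
            f"region [{r.ppm_min}, {r.ppm_max}] outside axis "
            f"[{s.ppm[0]}, {s.ppm[-1]}]"
        )
    lo = np.searchsorted(s.ppm, r.ppm_min, side="left")
    hi = np.searchsorted(s.ppm, r.ppm_max, side="right")
    return float(s.intensity[lo:hi].sum())


def quantify(s: Spectrum, panel: AnalytePanel) -> QuantResult:
    """Quantify every panel analyte in one referenced spectrum."""
    mass_mg = float(s.meta.get("sample_mass_mg", 50.0))
    volume_mL = float(s.meta.get("solvent_volume_mL", 1.0))
    if mass_mg <= 0 or volume_mL <= 0:
        raise ValueError("sample_mass_mg and solvent_volume_mL must be > 0")

    ist = panel.internal_standard
    a_tmsp = integrate_region(s, ist.regions[0])
    if a_tmsp <= 0:
        raise CalibrationError(f"TMSP area must be > 0 (got {a_tmsp})")
    n_tmsp = ist.regions[0].n_protons_effective  # 9 protons
    mM_to_mgkg = volume_mL / (mass_mg * 1e-3)

    concentrations, raw_mM, flags, units = {}, {}, {}, {}
    for analyte in panel.analytes:
        regions = panel.effective_regions(analyte)
        area = sum(integrate_region(s, r) for r in regions)
        n_eff = sum(r.n_protons_effective for r in regions)
        scales = {r.scaling_factor for r in regions}
        if len(scales) != 1:
            raise NotImplementedError(
                f"{analyte.analyte_id!r}: summed regions with differing scaling factors"
            )
        c_mM = (area / n_eff) / (a_tmsp / n_tmsp) * panel.is_concentration_mM * scales.pop()
        c_mM = max(c_mM, 0.0)
        c_mgkg = c_mM * analyte.molecular_weight * mM_to_mgkg
        value = c_mgkg / 1e4 if analyte.unit_class == "g_per_100g" else c_mgkg
        concentrations[analyte.analyte_id] = value
        raw_mM[analyte.analyte_id] = c_mM
        flags[analyte.analyte_id] = c_mgkg < analyte.loq
        units[analyte.analyte_id] = analyte.unit_class
    return QuantResult(
        sample_id=str(s.meta.get("sample_id", "")),
        concentrations=concentrations,
        raw_mM=raw_mM,
        loq_flags=flags,
        tmsp_area=a_tmsp,
        replicate=s.meta.get("replicate"),
        units=units,
    )


def average_triplicates(results: list[QuantResult], panel: AnalytePanel) -> QuantResult:
    """Average replicate quantitation results for one sample.

    Arithmetic mean per analyte with the sample standard deviation (n-1)
    attached; LOQ flags re-evaluated on the mean.  Single replicates carry no
    standard deviation.
    """
    if not results:
        raise ValueError("no results to average")
    ids = {r.sample_id for r in results}
    if len(ids) != 1:
        raise ValueError(f"mixed sample ids: {sorted(ids)}")
    analytes = list(results[0].concentrations)
    means, sds, flags, raw = {}, {}, {}, {}
    for aid in analytes:
        vals = np.array([r.concentrations[aid] for r in results])
        raw_vals = np.array([r.raw_mM[aid] for r in results])
        means[aid] = float(vals.mean())
        raw[aid] = float(raw_vals.mean())
        sds[aid] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        analyte = panel.analyte(aid)
        mgkg = means[aid] * (1e4 if analyte.unit_class == "g_per_100g" else 1.0)
        flags[aid] = mgkg < analyte.loq
    return QuantResult(
        sample_id=results[0].sample_id,
        concentrations=means,
        raw_mM=raw,
        loq_flags=flags,
        tmsp_area=float(np.mean([r.tmsp_area for r in results])),
        replicate=None,
        per_analyte_sd=sds if len(results) > 1 else None,
        units=dict(results[0].units),
    )


def frequency_distribution(
    values,
    bin_width: float = 0.01,
    loq: float | None = None,
) -> pd.DataFrame:
    """Histogram of a concentration vector in relative-width bins.

    ``bin_width`` is a fraction of the observed range (0.01 -> 100 bins
    spanning [min, max]).  Bins lying entirely at or below ``loq`` are
    flagged ``below_loq``.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value vector")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        warnings.warn("all values equal; returning a single bin")
        edges = np.array([vmin, vmax])
    else:
        n_bins = max(1, int(round(1.0 / bin_width)))
        edges = np.linspace(vmin, vmax, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges) if edges.size > 1 and vmin != vmax else (
        np.array([values.size]), None)
    if vmin == vmax:
        lows, highs = np.array([vmin]), np.array([vmax])
    else:
        lows, highs = edges[:-1], edges[1:]
    below = highs <= loq if loq is not None else np.zeros(len(lows), dtype=bool)
    return pd.DataFrame(
        {"bin_low": lows, "bin_high": highs, "count": counts, "below_loq": below}
    )
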