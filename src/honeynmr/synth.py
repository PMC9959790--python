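"""Synthetic data generation: forward-simulated mixture spectra and
class-structured concentration cohorts.

Two generators are provided.

* :func:`simulate_spectrum` builds a processed absorption spectrum from the
  analyte panel and a known concentration map: one Lorentzian singlet per
  integration region, amplitude normalised so that the analytic integral of
  the peak *over its own region* equals ``concentration_mM *
  n_protons_effective / scaling_factor`` (in ppm-area units, one global
  proportionality constant shared with the TMSP singlet).  This is the exact
  forward model of the internal-standard quantitation, so quantifying a
  noiseless simulated spectrum must recover the inputs.

* :func:`simulate_cohort` draws a samples x analytes concentration matrix
  with a binary class structure emulating a geographic-origin survey: by
  default 424 samples of which 105 are the positive (Canadian) class, with
  trigonelline elevated more than two-fold in the positive class (most
  positive samples above 20 mg/kg), proline elevated, and ethanol, succinate,
  MGDH, MGMH, leptosperin, HPLA, 1,3-butanediol, lactate, alanine and
  phenylalanine below half the negative-class mean.  All means and CVs are
  synthetic repo constants — the surveyed concentrations were never deposited
  — chosen to reproduce the qualitative marker structure, not the real values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import AnalytePanel, default_panel
from .spectra import Spectrum


@dataclass
class LineshapeParams:
    """Lorentzian lineshape and grid parameters for the spectrum simulator."""

    linewidth_hz: float = 1.0          # FWHM
    spectrometer_mhz: float = 700.15
    points: int = 2 ** 15
    ppm_min: float = -0.5
    ppm_max: float = 9.5
    noise_sd: float = 0.0              # fraction of the TMSP apex height
    baseline_coeffs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.points < 1024:
            raise ValueError("points must be >= 1024")
        if self.linewidth_hz <= 0:
            raise ValueError("linewidth_hz must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def hwhm_ppm(self) -> float:
        return (self.linewidth_hz / 2.0) / self.spectrometer_mhz


def simulate_spectrum(
    panel: AnalytePanel,
    concentrations_mM: dict[str, float],
    shape: LineshapeParams | None = None,
    seed: int = 0,
) -> Spectrum:
    """Forward-simulate a referenced mixture spectrum with known concentrations.

    TMSP is always present at ``panel.is_concentration_mM`` (a ``"tmsp"`` key
    in the map overrides it).  Gaussian noise with sd ``noise_sd x TMSP apex``
    and then the baseline polynomial are added last.
    """
    shape = shape or LineshapeParams()
    conc = dict(concentrations_mM)
    tmsp_mM = float(conc.pop("tmsp", panel.is_concentration_mM))
    for aid, c in conc.items():
        panel.analyte(aid)  # KeyError if unknown
        if c < 0:
            raise ValueError(f"negative concentration for {aid!r}: {c}")
    if tmsp_mM <= 0:
        raise ValueError("TMSP concentration must be > 0")

    ppm = np.linspace(shape.ppm_min, shape.ppm_max, shape.points)
    gamma = shape.hwhm_ppm

    # One centered Lorentzian singlet per active region.  Amplitudes are
    # obtained by solving a linear system so that the *measured* area of every
    # region -- including the tails every other peak leaks into it -- equals
    # concentration_mM * n_protons_effective / scaling_factor (ppm-area units,
    # one global proportionality constant shared with TMSP).  This makes the
    # simulator the exact forward model of sum-over-region integration.
    regions, targets = [], []

    def stage(region, conc_mM: float) -> None:
        if region.ppm_min < shape.ppm_min or region.ppm_max > shape.ppm_max:
            raise ValueError(
                f"region [{region.ppm_min}, {region.ppm_max}] for "
                f"{region.analyte_id!r} lies outside the simulated grid"
            )
        regions.append(region)
        targets.append(conc_mM * region.n_protons_effective / region.scaling_factor)

    stage(panel.internal_standard.regions[0], tmsp_mM)
    for aid, c_mM in conc.items():
        if c_mM == 0.0:
            continue
        analyte = panel.analyte(aid)
        for region in panel.effective_regions(analyte):
            stage(region, float(c_mM))

    centers = np.array([r.center for r in regions])
    lows = np.array([r.ppm_min for r in regions])
    highs = np.array([r.ppm_max for r in regions])
    # M[i, j] = integral over region i of a unit-amplitude peak centered in region j
    M = gamma * (
        np.arctan((highs[:, None] - centers[None, :]) / gamma)
        - np.arctan((lows[:, None] - centers[None, :]) / gamma)
    )
    amps = np.linalg.solve(M, np.asarray(targets))
    y = (amps[None, :] * gamma ** 2 / ((ppm[:, None] - centers[None, :]) ** 2 + gamma ** 2)).sum(axis=1)
    tmsp_apex = float(amps[0])

    if shape.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y += rng.normal(0.0, shape.noise_sd * tmsp_apex, size=y.shape)
    if shape.baseline_coeffs:
        y += np.polynomial.polynomial.polyval(ppm, np.asarray(shape.baseline_coeffs))

    meta = {"sample_mass_mg": 50.0, "solvent_volume_mL": 1.0, "sample_id": "synthetic"}
    return Spectrum(ppm, y, referenced=True, meta=meta)


def simulate_replicates(
    concentrations: dict[str, float],
    cv: float,
    k: int,
    seed: int = 0,
) -> list[dict[str, float]]:
    """k analytical replicates: each entry scaled by (1 + eps), eps ~ N(0, cv), floored at 0."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(k):
        eps = rng.normal(0.0, cv, size=len(concentrations)) if cv > 0 else np.zeros(len(concentrations))
        out.append(
            {aid: max(0.0, v * (1.0 + e)) for (aid, v), e in zip(concentrations.items(), eps)}
        )
    return out


# ---------------------------------------------------------------------------
# Concentration cohorts
# ---------------------------------------------------------------------------

#: Synthetic per-analyte cohort location parameters (positive-class mean,
#: negative-class mean, coefficient of variation).  Units follow each
#: analyte's reporting unit (g/100 g for fructose and glucose, mg/kg else).
DEFAULT_COHORT_EFFECTS: dict[str, tuple[float, float, float]] = {
    "hmf":             (35.0,   60.0,  0.6),
    "trigonelline":    (35.0,    8.0,  0.35),
    "formate":         (40.0,   50.0,  0.6),
    "leptosperin":     (8.0,    20.0,  0.6),
    "methyl_syringate":(10.0,   18.0,  0.6),
    "pla":             (30.0,   45.0,  0.6),
    "phenylalanine":   (12.0,   30.0,  0.6),
    "hpla":            (12.0,   30.0,  0.6),
    "tyrosine":        (18.0,   28.0,  0.6),
    "maltose":         (14000., 18000., 0.5),
    "sucrose":         (3000.,  6000., 0.6),
    "kojibiose":       (8000.,  10000., 0.5),
    "nigerose":        (5000.,  6500., 0.5),
    "turanose":        (10000., 12000., 0.5),
    "trehalose":       (800.0,  820.0, 0.6),
    "dha":             (50.0,   80.0,  0.6),
    "fructose":        (39.0,   40.0,  0.08),
    "glucose":         (33.0,   31.0,  0.10),
    "citrate":         (150.0,  180.0, 0.5),
    "malate":          (250.0,  300.0, 0.5),
    "succinate":       (40.0,   90.0,  0.6),
    "mgmh":            (10.0,   25.0,  0.6),
    "proline":         (600.0,  280.0, 0.35),
    "acetate":         (120.0,  160.0, 0.6),
    "quercitol":       (60.0,   90.0,  0.6),
    "alanine":         (80.0,   180.0, 0.6),
    "lactate":         (40.0,   100.0, 0.6),
    "mgdh":            (8.0,    20.0,  0.6),
    "threonine":       (30.0,   45.0,  0.6),
    "ethanol":         (30.0,   90.0,  0.40),
    "butanediol_13":   (70.0,   160.0, 0.6),
    "valine":          (25.0,   40.0,  0.6),
    "isoleucine":      (20.0,   21.0,  0.6),
}


@dataclass
class CohortDesign:
    """Design of a two-class synthetic concentration cohort."""

    n_positive: int = 105
    n_negative: int = 319
    analyte_means_positive: dict[str, float] = field(
        default_factory=lambda: {k: v[0] for k, v in DEFAULT_COHORT_EFFECTS.items()}
    )
    analyte_means_negative: dict[str, float] = field(
        default_factory=lambda: {k: v[1] for k, v in DEFAULT_COHORT_EFFECTS.items()}
    )
    dispersion: dict[str, float] = field(
        default_factory=lambda: {k: v[2] for k, v in DEFAULT_COHORT_EFFECTS.items()}
    )
    correlation: np.ndarray | None = None
    distribution: str = "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive + self.n_negative < 2:
            raise ValueError("need at least two samples")
        if self.distribution not in ("lognormal", "truncated_normal"):
            raise ValueError("distribution must be 'lognormal' or 'truncated_normal'")
        if set(self.analyte_means_positive) != set(self.analyte_means_negative):
            raise ValueError("positive/negative mean maps must cover the same analytes")
        for label, means in (
            ("positive", self.analyte_means_positive),
            ("negative", self.analyte_means_negative),
        ):
            bad = [k for k, v in means.items() if v <= 0]
            if bad:
                raise ValueError(f"non-positive {label}-class mean(s) for {bad}")

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.analyte_means_positive)


@dataclass
class ConcentrationMatrix:
    """Samples x analytes concentrations with LOQ flags and sample metadata."""

    values: pd.DataFrame
    units: dict[str, str]
    loq_flags: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("negative concentrations")
        if len(self.values) != len(self.sample_meta):
            raise ValueError("values/sample_meta row mismatch")
        if self.loq_flags.shape != self.values.shape:
            raise ValueError("loq_flags shape mismatch")

    @property
    def labels(self) -> np.ndarray:
        """0/1 class vector (1 = positive class)."""
        return (self.sample_meta["class_label"].to_numpy() == "positive").astype(int)


def _draw_class(
    rng: np.random.Generator,
    n: int,
    means: np.ndarray,
    cvs: np.ndarray,
    corr: np.ndarray | None,
    distribution: str,
) -> np.ndarray:
    p = means.size
    if corr is not None:
        corr = np.asarray(corr, dtype=float)
        if corr.shape != (p, p):
            raise ValueError("correlation matrix has wrong shape")
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ValueError("correlation matrix is not positive definite") from exc
        z = rng.standard_normal((n, p)) @ chol.T
    else:
        z = rng.standard_normal((n, p))
    if distribution == "lognormal":
        sigma2 = np.log1p(cvs ** 2)
        mu = np.log(means) - sigma2 / 2.0
        return np.exp(mu + np.sqrt(sigma2) * z)
    # truncated normal: N(mean, cv*mean) clipped at zero
    return np.clip(means + cvs * means * z, 0.0, None)


def simulate_cohort(
    design: CohortDesign | None = None,
    panel: AnalytePanel | None = None,
) -> ConcentrationMatrix:
    """Draw a reproducible two-class concentration cohort.

    LOQ flags are evaluated against the panel's per-analyte LOQ (mg/kg),
    converting g/100 g columns as needed; flagged values are retained, never
    censored.
    """
    design = design or CohortDesign()
    panel = panel or default_panel()
    rng = np.random.default_rng(design.seed)
    ids = design.analyte_ids
    m_pos = np.array([design.analyte_means_positive[a] for a in ids])
    m_neg = np.array([design.analyte_means_negative[a] for a in ids])
    cvs = np.array([design.dispersion.get(a, 0.0) for a in ids])

    pos = _draw_class(rng, design.n_positive, m_pos, cvs, design.correlation, design.distribution)
    neg = _draw_class(rng, design.n_negative, m_neg, cvs, design.correlation, design.distribution)
    values = np.vstack([pos, neg])
    n = design.n_positive + design.n_negative
    index = [f"S{i:04d}" for i in range(1, n + 1)]
    df = pd.DataFrame(values, index=index, columns=ids)

    units, flags = {}, {}
    for aid in ids:
        try:
            analyte = panel.analyte(aid)
            units[aid] = analyte.unit_class
            factor = 1e4 if analyte.unit_class == "g_per_100g" else 1.0
            flags[aid] = df[aid] * factor < analyte.loq
        except KeyError:
            units[aid] = "mg_per_kg"
            flags[aid] = pd.Series(False, index=df.index)
            warnings.warn(f"analyte {aid!r} not in panel; LOQ flags set to False")
    meta = pd.DataFrame(
        {
            "class_label": ["positive"] * design.n_positive + ["negative"] * design.n_negative,
            "country": ["Canada"] * design.n_positive + ["Other"] * design.n_negative,
            "floral": ["unknown"] * n,
            "replicate_group": index,
        },
        index=index,
    )
    return ConcentrationMatrix(df, units, pd.DataFrame(flags), meta)
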