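"""Analyte panel for targeted quantitative 1H-NMR of honey.

The panel registers, for each of the 33 quantified honey components, the
spectral integration regions (ppm windows), the effective number of protons
each region represents per molecule of analyte, a back-calculation scaling
factor (e.g. the inverse alpha-anomer fraction when only the H-1alpha
resonance of a reducing sugar is integrated), the molecular weight, the
reporting unit and the limit of quantification (LOQ).  TMSP — the 9-proton
internal chemical-shift and concentration standard at 0.0 ppm — is carried
alongside the analytes.

The shipped default panel encodes the integration windows that are fixed by
the method (the fructose tautomer triplet of regions, the glucose H-4 window
at 3.41 ppm, the minor-sugar anomeric windows inside 5.15-5.55 ppm, TMSP at
0.0 ppm).  Every other window, anomeric ratio, multiplicity penalty and the
resulting LOQ is a documented synthetic placeholder: the authoritative
laboratory values were never published, so the defaults are chosen to be
chemically plausible and mutually non-overlapping, and every value can be
overridden through a user-supplied panel file.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .exceptions import PanelValidationError

UNIT_CLASSES = ("g_per_100g", "mg_per_kg")
COMBINE_RULES = ("single_region", "sum_regions")

#: Equilibrium tautomer fractions of free fructose in aqueous solution.
DEFAULT_TAUTOMER_FRACTIONS = {
    "beta_pyranose": 0.682,
    "beta_furanose": 0.223,
    "alpha_furanose": 0.063,
    "alpha_pyranose_plus_keto": 0.032,
}


@dataclass(frozen=True)
class IntegrationRegion:
    """A ppm window whose point-sum quantifies (part of) one analyte."""

    analyte_id: str
    ppm_min: float
    ppm_max: float
    n_protons_effective: float
    scaling_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.ppm_min < self.ppm_max:
            raise PanelValidationError(
                f"region for {self.analyte_id!r}: ppm_min ({self.ppm_min}) must be "
                f"< ppm_max ({self.ppm_max})"
            )
        if self.n_protons_effective <= 0:
            raise PanelValidationError(
                f"region for {self.analyte_id!r}: n_protons_effective must be > 0"
            )
        if self.scaling_factor <= 0:
            raise PanelValidationError(
                f"region for {self.analyte_id!r}: scaling_factor must be > 0"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.ppm_min + self.ppm_max)

    @property
    def width(self) -> float:
        return self.ppm_max - self.ppm_min


@dataclass(frozen=True)
class AnalyteDefinition:
    """One quantified honey component."""

    analyte_id: str
    name: str
    numbering: int
    molecular_weight: float
    regions: tuple[IntegrationRegion, ...]
    unit_class: str = "mg_per_kg"
    loq: float = 0.0  # mg/kg
    combine_rule: str = "single_region"

    def __post_init__(self) -> None:
        if not self.regions:
            raise PanelValidationError(f"{self.analyte_id!r}: at least one region required")
        if self.molecular_weight <= 0:
            raise PanelValidationError(f"{self.analyte_id!r}: molecular_weight must be > 0")
        if self.loq <= 0:
            raise PanelValidationError(f"{self.analyte_id!r}: loq must be > 0")
        if self.unit_class not in UNIT_CLASSES:
            raise PanelValidationError(
                f"{self.analyte_id!r}: unit_class must be one of {UNIT_CLASSES}"
            )
        if self.combine_rule not in COMBINE_RULES:
            raise PanelValidationError(
                f"{self.analyte_id!r}: combine_rule must be one of {COMBINE_RULES}"
            )
        if self.combine_rule == "single_region" and len(self.regions) != 1:
            raise PanelValidationError(
                f"{self.analyte_id!r}: single_region rule but {len(self.regions)} regions"
            )


@dataclass
class AnalytePanel:
    """The full analyte registry plus internal-standard configuration."""

    analytes: list[AnalyteDefinition]
    internal_standard: AnalyteDefinition
    is_concentration_mM: float = 0.966
    tautomer_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TAUTOMER_FRACTIONS)
    )
    #: "tautomer": fructose N_eff = sum of tautomer-derived region proton
    #: equivalents (default 2.618); "nominal2": force the nominal total of 2.0.
    fructose_proton_mode: str = "tautomer"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [a.analyte_id for a in self.analytes]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PanelValidationError(f"duplicate analyte_id(s): {sorted(dupes)}")
        if self.internal_standard.analyte_id in ids:
            raise PanelValidationError("internal standard shares an id with an analyte")
        if self.is_concentration_mM <= 0:
            raise PanelValidationError("is_concentration_mM must be > 0")
        total = sum(self.tautomer_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise PanelValidationError(
                f"tautomer fractions must sum to 1.0 (got {total!r})"
            )
        if self.fructose_proton_mode not in ("tautomer", "nominal2"):
            raise PanelValidationError(
                "fructose_proton_mode must be 'tautomer' or 'nominal2'"
            )

    # -- lookup -----------------------------------------------------------
    @property
    def analyte_ids(self) -> list[str]:
        return [a.analyte_id for a in self.analytes]

    def analyte(self, analyte_id: str) -> AnalyteDefinition:
        for a in self.analytes:
            if a.analyte_id == analyte_id:
                return a
        if analyte_id == self.internal_standard.analyte_id:
            return self.internal_standard
        raise KeyError(analyte_id)

    def effective_regions(self, analyte: AnalyteDefinition) -> tuple[IntegrationRegion, ...]:
        """Regions with proton counts adjusted for the fructose proton mode.

        Under ``nominal2`` the fructose regions are rescaled so their proton
        equivalents sum to exactly 2.0 while keeping the relative split; all
        other analytes are returned unchanged.
        """
        if (
            self.fructose_proton_mode == "nominal2"
            and analyte.analyte_id == "fructose"
            and analyte.combine_rule == "sum_regions"
        ):
            total = sum(r.n_protons_effective for r in analyte.regions)
            factor = 2.0 / total
            return tuple(
                replace(r, n_protons_effective=r.n_protons_effective * factor)
                for r in analyte.regions
            )
        return analyte.regions

    def effective_protons(self, analyte: AnalyteDefinition) -> float:
        return sum(r.n_protons_effective for r in self.effective_regions(analyte))


# ---------------------------------------------------------------------------
# LOQ helper (also exposed by the quantitation module)
# ---------------------------------------------------------------------------


def loq_mgkg(
    base_mM: float,
    n_protons_region: float,
    multiplicity_penalty: float,
    mw: float,
    mass_mg: float = 50.0,
    volume_mL: float = 1.0,
) -> float:
    """Per-analyte LOQ in mg/kg from the base single-proton molar LOQ.

    ``base_mM`` is the molar concentration of a one-proton singlet giving
    S/N = 10:1 (0.01 mM for the reference configuration); the LOQ worsens
    with signal multiplicity and improves with the number of protons the
    integration region represents.
    """
    for name, v in (
        ("base_mM", base_mM),
        ("n_protons_region", n_protons_region),
        ("multiplicity_penalty", multiplicity_penalty),
        ("mw", mw),
        ("mass_mg", mass_mg),
        ("volume_mL", volume_mL),
    ):
        if v <= 0:
            raise PanelValidationError(f"loq_mgkg: {name} must be > 0 (got {v})")
    c_mM = base_mM * multiplicity_penalty / n_protons_region
    return c_mM * mw * volume_mL / (mass_mg * 1e-3)


# ---------------------------------------------------------------------------
# Default panel
# ---------------------------------------------------------------------------

# (analyte_id, name, numbering, MW g/mol, unit_class, combine_rule,
#  loq_spec, [(ppm_min, ppm_max, n_protons_effective, scaling_factor), ...])
# loq_spec: ("direct", mg/kg) or ("formula", n_protons_region, penalty).
# Regions not fixed by the method description are synthetic placeholders at
# plausible shifts, laid out to be mutually disjoint.
_MINOR_SUGAR_SCALE = 2.5  # placeholder 1/alpha-fraction (alpha ~= 0.40)

_DEFAULT_ROWS = [
    ("hmf", "5-HMF", 1, 126.11, "mg_per_kg", "single_region", ("formula", 1, 1), [(9.44, 9.48, 1.0, 1.0)]),
    ("trigonelline", "Trigonelline", 2, 137.14, "mg_per_kg", "single_region", ("formula", 1, 1), [(9.10, 9.14, 1.0, 1.0)]),
    ("formate", "Formate", 3, 46.03, "mg_per_kg", "single_region", ("formula", 1, 1), [(8.43, 8.47, 1.0, 1.0)]),
    ("leptosperin", "Leptosperin", 4, 536.48, "mg_per_kg", "single_region", ("formula", 2, 3), [(7.30, 7.34, 2.0, 1.0)]),
    ("methyl_syringate", "Methyl syringate", 5, 212.20, "mg_per_kg", "single_region", ("formula", 2, 1), [(7.18, 7.22, 2.0, 1.0)]),
    ("pla", "Phenyllactate (PLA)", 6, 166.17, "mg_per_kg", "single_region", ("formula", 2, 5), [(7.24, 7.28, 2.0, 1.0)]),
    ("phenylalanine", "Phenylalanine", 7, 165.19, "mg_per_kg", "single_region", ("formula", 2, 5), [(7.40, 7.44, 2.0, 1.0)]),
    ("hpla", "p-Hydroxyphenyllactate (HPLA)", 8, 182.17, "mg_per_kg", "single_region", ("formula", 2, 3), [(7.10, 7.14, 2.0, 1.0)]),
    ("tyrosine", "Tyrosine", 9, 181.19, "mg_per_kg", "single_region", ("formula", 2, 3), [(6.88, 6.92, 2.0, 1.0)]),
    ("maltose", "Maltose", 10, 342.30, "mg_per_kg", "single_region", ("formula", 1, 3), [(5.355, 5.385, 1.0, _MINOR_SUGAR_SCALE)]),
    ("sucrose", "Sucrose", 11, 342.30, "mg_per_kg", "single_region", ("formula", 1, 3), [(5.39, 5.42, 1.0, 1.0)]),
    ("kojibiose", "Kojibiose", 12, 342.30, "mg_per_kg", "single_region", ("formula", 1, 3), [(5.43, 5.46, 1.0, _MINOR_SUGAR_SCALE)]),
    ("nigerose", "Nigerose", 13, 342.30, "mg_per_kg", "single_region", ("formula", 1, 3), [(5.32, 5.35, 1.0, _MINOR_SUGAR_SCALE)]),
    ("turanose", "Turanose", 14, 342.30, "mg_per_kg", "single_region", ("formula", 1, 3), [(5.28, 5.31, 1.0, _MINOR_SUGAR_SCALE)]),
    ("trehalose", "Trehalose", 15, 342.30, "mg_per_kg", "single_region", ("formula", 2, 3), [(5.185, 5.215, 2.0, 1.0)]),
    ("dha", "Dihydroxyacetone (DHA)", 16, 90.08, "mg_per_kg", "single_region", ("formula", 4, 1), [(4.40, 4.44, 4.0, 1.0)]),
    # Fructose: three tautomer regions; proton equivalents filled in from the
    # panel tautomer fractions by _fructose_regions().
    ("fructose", "Fructose", 17, 180.16, "g_per_100g", "sum_regions", ("formula", 2, 5), None),
    ("glucose", "Glucose", 18, 180.16, "g_per_100g", "single_region", ("formula", 1, 5), [(3.39, 3.43, 1.0, 1.0)]),
    ("citrate", "Citrate", 19, 192.12, "mg_per_kg", "single_region", ("formula", 2, 4), [(2.52, 2.58, 2.0, 1.0)]),
    ("malate", "Malate", 20, 134.09, "mg_per_kg", "single_region", ("formula", 1, 4), [(4.28, 4.32, 1.0, 1.0)]),
    ("succinate", "Succinate", 21, 118.09, "mg_per_kg", "single_region", ("formula", 4, 1), [(2.39, 2.43, 4.0, 1.0)]),
    ("mgmh", "Methylglyoxal monohydrate (MGMH)", 22, 90.08, "mg_per_kg", "single_region", ("formula", 3, 1), [(2.28, 2.32, 3.0, 1.0)]),
    ("proline", "Proline", 23, 115.13, "mg_per_kg", "single_region", ("direct", 230.0), [(1.98, 2.06, 2.0, 1.0)]),
    ("acetate", "Acetate", 24, 60.05, "mg_per_kg", "single_region", ("formula", 3, 1), [(1.90, 1.94, 3.0, 1.0)]),
    ("quercitol", "proto-Quercitol", 25, 164.16, "mg_per_kg", "single_region", ("formula", 1, 4), [(3.50, 3.54, 1.0, 1.0)]),
    ("alanine", "Alanine", 26, 89.09, "mg_per_kg", "single_region", ("formula", 3, 2), [(1.46, 1.50, 3.0, 1.0)]),
    ("lactate", "Lactate", 27, 90.08, "mg_per_kg", "single_region", ("formula", 3, 2), [(1.31, 1.35, 3.0, 1.0)]),
    ("mgdh", "Methylglyoxal dihydrate (MGDH)", 28, 108.09, "mg_per_kg", "single_region", ("formula", 3, 1), [(1.37, 1.41, 3.0, 1.0)]),
    ("threonine", "Threonine", 29, 119.12, "mg_per_kg", "single_region", ("formula", 3, 2), [(1.25, 1.29, 3.0, 1.0)]),
    ("ethanol", "Ethanol", 30, 46.07, "mg_per_kg", "single_region", ("formula", 3, 3), [(1.15, 1.19, 3.0, 1.0)]),
    ("butanediol_13", "1,3-Butanediol", 31, 90.12, "mg_per_kg", "single_region", ("formula", 3, 2), [(1.10, 1.14, 3.0, 1.0)]),
    ("valine", "Valine", 32, 117.15, "mg_per_kg", "single_region", ("formula", 3, 2), [(1.02, 1.06, 3.0, 1.0)]),
    ("isoleucine", "Isoleucine", 33, 131.17, "mg_per_kg", "single_region", ("formula", 3, 3), [(0.92, 0.96, 3.0, 1.0)]),
]


def _fructose_regions(fractions: dict[str, float]) -> list[tuple[float, float, float, float]]:
    """Fructose region proton equivalents from the tautomer equilibrium.

    4.098-4.130 ppm: beta-furanose H3 + H4 and alpha-furanose H3;
    4.013-4.050 ppm: beta-pyranose H6 (CH2, two protons);
    3.985-4.013 ppm: beta-pyranose H5 and alpha-furanose H4.
    """
    bp = fractions["beta_pyranose"]
    bf = fractions["beta_furanose"]
    af = fractions["alpha_furanose"]
    return [
        (4.098, 4.130, 2.0 * bf + af, 1.0),
        (4.013, 4.050, 2.0 * bp, 1.0),
        (3.985, 4.013, bp + af, 1.0),
    ]


def default_panel(
    is_concentration_mM: float = 0.966,
    fructose_proton_mode: str = "tautomer",
) -> AnalytePanel:
    """Build the shipped 33-analyte default panel plus the TMSP standard."""
    fractions = dict(DEFAULT_TAUTOMER_FRACTIONS)
    analytes = []
    for aid, name, num, mw, unit, rule, loq_spec, regions in _DEFAULT_ROWS:
        if regions is None:  # fructose
            regions = _fructose_regions(fractions)
        if loq_spec[0] == "direct":
            loq = float(loq_spec[1])
        else:
            _, n_h, penalty = loq_spec
            loq = loq_mgkg(0.01, n_h, penalty, mw)
        analytes.append(
            AnalyteDefinition(
                analyte_id=aid,
                name=name,
                numbering=num,
                molecular_weight=mw,
                regions=tuple(IntegrationRegion(aid, *r) for r in regions),
                unit_class=unit,
                loq=loq,
                combine_rule=rule,
            )
        )
    tmsp = AnalyteDefinition(
        analyte_id="tmsp",
        name="TMSP (internal standard)",
        numbering=0,
        molecular_weight=172.27,
        regions=(IntegrationRegion("tmsp", -0.02, 0.02, 9.0, 1.0),),
        unit_class="mg_per_kg",
        loq=1e-6,
        combine_rule="single_region",
    )
    return AnalytePanel(
        analytes=analytes,
        internal_standard=tmsp,
        is_concentration_mM=is_concentration_mM,
        tautomer_fractions=fractions,
        fructose_proton_mode=fructose_proton_mode,
    )


# ---------------------------------------------------------------------------
# Panel I/O: structured config (YAML) and delimited table (CSV)
# ---------------------------------------------------------------------------

_CSV_FIELDS = [
    "analyte_id", "name", "numbering", "molecular_weight", "unit_class",
    "loq_mgkg", "combine_rule", "ppm_min", "ppm_max", "n_protons_effective",
    "scaling_factor",
]


def _analyte_to_dict(a: AnalyteDefinition) -> dict:
    return {
        "analyte_id": a.analyte_id,
        "name": a.name,
        "numbering": a.numbering,
        "molecular_weight": a.molecular_weight,
        "unit_class": a.unit_class,
        "loq_mgkg": a.loq,
        "combine_rule": a.combine_rule,
        "regions": [
            {
                "ppm_min": r.ppm_min,
                "ppm_max": r.ppm_max,
                "n_protons_effective": r.n_protons_effective,
                "scaling_factor": r.scaling_factor,
            }
            for r in a.regions
        ],
    }


def _analyte_from_dict(d: dict) -> AnalyteDefinition:
    required = {"analyte_id", "name", "numbering", "molecular_weight",
                "unit_class", "loq_mgkg", "combine_rule", "regions"}
    missing = required - set(d)
    if missing:
        raise PanelValidationError(f"analyte entry missing field(s): {sorted(missing)}")
    regions = tuple(
        IntegrationRegion(
            d["analyte_id"],
            float(r["ppm_min"]),
            float(r["ppm_max"]),
            float(r["n_protons_effective"]),
            float(r.get("scaling_factor", 1.0)),
        )
        for r in d["regions"]
    )
    return AnalyteDefinition(
        analyte_id=str(d["analyte_id"]),
        name=str(d["name"]),
        numbering=int(d["numbering"]),
        molecular_weight=float(d["molecular_weight"]),
        regions=regions,
        unit_class=str(d["unit_class"]),
        loq=float(d["loq_mgkg"]),
        combine_rule=str(d["combine_rule"]),
    )


def write_panel(panel: AnalytePanel, path: str | Path, format: str = "structured_config") -> None:
    """Write a panel as YAML (``structured_config``) or CSV (``delimited_table``)."""
    path = Path(path)
    if format == "structured_config":
        doc = {
            "is_concentration_mM": panel.is_concentration_mM,
            "tautomer_fractions": dict(panel.tautomer_fractions),
            "fructose_proton_mode": panel.fructose_proton_mode,
            "internal_standard": _analyte_to_dict(panel.internal_standard),
            "analytes": [_analyte_to_dict(a) for a in panel.analytes],
        }
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")
    elif format == "delimited_table":
        buf = io.StringIO()
        buf.write(f"#is_concentration_mM={panel.is_concentration_mM!r}\n")
        for k, v in panel.tautomer_fractions.items():
            buf.write(f"#tautomer_fraction:{k}={v!r}\n")
        buf.write(f"#fructose_proton_mode={panel.fructose_proton_mode}\n")
        writer = csv.DictWriter(buf, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for a in [panel.internal_standard, *panel.analytes]:
            for r in a.regions:
                writer.writerow(
                    {
                        "analyte_id": a.analyte_id,
                        "name": a.name,
                        "numbering": a.numbering,
                        "molecular_weight": repr(a.molecular_weight),
                        "unit_class": a.unit_class,
                        "loq_mgkg": repr(a.loq),
                        "combine_rule": a.combine_rule,
                        "ppm_min": repr(r.ppm_min),
                        "ppm_max": repr(r.ppm_max),
                        "n_protons_effective": repr(r.n_protons_effective),
                        "scaling_factor": repr(r.scaling_factor),
                    }
                )
        path.write_text(buf.getvalue(), encoding="utf-8")
    else:
        raise ValueError(f"unknown panel format: {format!r}")


def load_panel(path: str | Path, format: str = "structured_config") -> AnalytePanel:
    """Read a panel written by :func:`write_panel` (or hand-edited)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "structured_config":
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
        for key in ("internal_standard", "analytes"):
            if key not in doc:
                raise PanelValidationError(f"panel file missing key: {key!r}")
        return AnalytePanel(
            analytes=[_analyte_from_dict(d) for d in doc["analytes"]],
            internal_standard=_analyte_from_dict(doc["internal_standard"]),
            is_concentration_mM=float(doc.get("is_concentration_mM", 0.966)),
            tautomer_fractions={
                k: float(v)
                for k, v in doc.get(
                    "tautomer_fractions", DEFAULT_TAUTOMER_FRACTIONS
                ).items()
            },
            fructose_proton_mode=str(doc.get("fructose_proton_mode", "tautomer")),
        )
    elif format == "delimited_table":
        meta: dict[str, str] = {}
        rows = []
        with path.open(encoding="utf-8") as fh:
            data_lines = []
            for line in fh:
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key] = val
                else:
                    data_lines.append(line)
        reader = csv.DictReader(data_lines)
        for row in reader:
            if reader.fieldnames is None or set(_CSV_FIELDS) - set(reader.fieldnames):
                raise PanelValidationError(
                    f"panel table missing column(s): "
                    f"{sorted(set(_CSV_FIELDS) - set(reader.fieldnames or []))}"
                )
            rows.append(row)
        by_id: dict[str, dict] = {}
        order: list[str] = []
        for row in rows:
            aid = row["analyte_id"]
            if aid not in by_id:
                order.append(aid)
                by_id[aid] = {
                    "analyte_id": aid,
                    "name": row["name"],
                    "numbering": row["numbering"],
                    "molecular_weight": row["molecular_weight"],
                    "unit_class": row["unit_class"],
                    "loq_mgkg": row["loq_mgkg"],
                    "combine_rule": row["combine_rule"],
                    "regions": [],
                }
            by_id[aid]["regions"].append(
                {
                    "ppm_min": row["ppm_min"],
                    "ppm_max": row["ppm_max"],
                    "n_protons_effective": row["n_protons_effective"],
                    "scaling_factor": row["scaling_factor"],
                }
            )
        if "tmsp" not in by_id:
            raise PanelValidationError("panel table has no 'tmsp' internal-standard rows")
        tmsp = _analyte_from_dict(by_id.pop("tmsp"))
        order.remove("tmsp")
        fractions = {
            k.split(":", 1)[1]: float(v)
            for k, v in meta.items()
            if k.startswith("tautomer_fraction:")
        } or dict(DEFAULT_TAUTOMER_FRACTIONS)
        return AnalytePanel(
            analytes=[_analyte_from_dict(by_id[aid]) for aid in order],
            internal_standard=tmsp,
            is_concentration_mM=float(meta.get("is_concentration_mM", 0.966)),
            tautomer_fractions=fractions,
            fructose_proton_mode=meta.get("fructose_proton_mode", "tautomer"),
        )
    else:
        raise ValueError(f"unknown panel format: {format!r}")
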