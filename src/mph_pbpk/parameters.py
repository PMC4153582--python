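"""Parameter registries, allometric scaling and pediatric physiology.

All model constants live in editable YAML registries shipped with the
package (``registry/``).  Internal units are fixed: amounts in µg,
concentrations in µg/L (≡ ng/mL), time in h, volumes in L, flows in L/h.
Rate-capacity coefficients scale as BW^0.75 and first-order rate
coefficients as BW^-0.25 across body sizes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import yaml

__all__ = [
    "PartitionSet",
    "PhysiologicalParams",
    "EnantiomerKinetics",
    "PopulationModel",
    "scale_allometric",
    "intrinsic_clearance",
    "interp_anchors",
    "pediatric_physiology",
    "load_population",
    "load_registry",
    "ivive_vmax_coefficient",
    "POPULATION_KEYS",
]

_REGISTRY_DIR = importlib.resources.files("mph_pbpk") / "registry"

#: (species, age_class) -> kinetics registry key
POPULATION_KEYS = {
    ("human", "adult"): "adult_human",
    ("human", "child"): "child",
    ("rhesus", "adult"): "adult_monkey",
    ("rhesus", "juvenile"): "juvenile_monkey",
}

FLOW_CLOSURE_TOL = 1e-12


class RegistryError(KeyError):
    """Unknown population/route combination or malformed registry entry."""


def load_registry(name: str, path: str | Path | None = None) -> dict:
    """Load a parameter registry (``partition``, ``physiology``,
    ``kinetics`` or ``pediatric``) from the packaged YAML, or from an
    override path."""
    if path is None:
        path = _REGISTRY_DIR / f"{name}.yaml"
    with open(str(path), "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or not data:
        raise RegistryError(f"registry {name!r} is empty or malformed")
    return data


def _sexed(value, sex: str) -> float:
    """Resolve a male/female pair (``{M: x, F: y}``) or scalar."""
    if isinstance(value, dict):
        try:
            return float(value[sex])
        except KeyError as exc:
            raise RegistryError(f"no entry for sex {sex!r} in {value!r}") from exc
    return float(value)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PartitionSet:
    """Tissue:plasma equilibrium partition coefficients (dimensionless)."""

    Pfat: float = 1.79
    Pbrain: float = 6.07
    Prich: float = 5.66
    Pslow: float = 2.47
    Pgonads: float = 3.12
    Pheart: float = 2.19
    Pliver: float = 5.66

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"partition coefficient {name} must be > 0")

    @classmethod
    def from_registry(cls, path: str | Path | None = None) -> "PartitionSet":
        return cls(**load_registry("partition", path))


@dataclass(frozen=True)
class PhysiologicalParams:
    """Body weight, cardiac output and fractional flows/volumes.

    ``QRC``/``QSC`` and ``VRC``/``VSC`` are the richly and slowly perfused
    complements.  They are stored explicitly so that a sensitivity
    perturbation can target them directly, but :meth:`with_closure`
    computes them from the closure identities
    ``QRC = 0.76 - QLC - QGC - QBC``, ``QSC = 0.24 - QFC - QHC``,
    ``VRC = 0.33 - VLC - VPC - VGC - VBC``, ``VSC = 0.60 - VFC - VHC``.
    """

    BW: float  # kg
    QCC: float  # L/h/kg^0.75
    QFC: float
    QLC: float
    QBC: float
    QHC: float
    QGC: float
    QRC: float
    QSC: float
    VPC: float
    VFC: float
    VLC: float
    VBC: float
    VHC: float
    VGC: float
    VRC: float
    VSC: float
    sex: Literal["M", "F"] = "M"

    @classmethod
    def with_closure(cls, BW, QCC, QFC, QLC, QBC, QHC, QGC,
                     VPC, VFC, VLC, VBC, VHC, VGC, sex="M"):
        if BW <= 0:
            raise ValueError("body weight must be positive")
        return cls(
            BW=BW, QCC=QCC, QFC=QFC, QLC=QLC, QBC=QBC, QHC=QHC, QGC=QGC,
            QRC=0.76 - QLC - QGC - QBC,
            QSC=0.24 - QFC - QHC,
            VPC=VPC, VFC=VFC, VLC=VLC, VBC=VBC, VHC=VHC, VGC=VGC,
            VRC=0.33 - VLC - VPC - VGC - VBC,
            VSC=0.60 - VFC - VHC,
            sex=sex,
        )

    def validate(self) -> None:
        fracs = {n: getattr(self, n) for n in
                 ("QFC", "QLC", "QBC", "QHC", "QGC", "QRC", "QSC",
                  "VPC", "VFC", "VLC", "VBC", "VHC", "VGC", "VRC", "VSC")}
        for name, v in fracs.items():
            if not 0 < v < 1:
                raise ValueError(f"fraction {name}={v} outside (0, 1)")
        if abs(self.flow_total() - 1.0) > FLOW_CLOSURE_TOL:
            raise ValueError("fractional blood flows do not sum to 1")
        if abs(self.VRC - (0.33 - self.VLC - self.VPC - self.VGC - self.VBC)) > FLOW_CLOSURE_TOL:
            raise ValueError("richly perfused volume closure violated")
        if abs(self.VSC - (0.60 - self.VFC - self.VHC)) > FLOW_CLOSURE_TOL:
            raise ValueError("slowly perfused volume closure violated")

    def flow_total(self) -> float:
        return (self.QFC + self.QLC + self.QBC + self.QHC + self.QGC
                + self.QRC + self.QSC)

    @property
    def cardiac_output(self) -> float:
        """Total cardiac output, L/h."""
        return scale_allometric(self.QCC, self.BW, 0.75)

    @classmethod
    def from_registry(cls, key: str, BW: float, sex: str = "M",
                      path: str | Path | None = None) -> "PhysiologicalParams":
        reg = load_registry("physiology", path)
        try:
            entry = reg[key]
        except KeyError as exc:
            raise RegistryError(
                f"unknown physiology key {key!r}; valid: {sorted(reg)}") from exc
        flows = {k: _sexed(v, sex) for k, v in entry["flows"].items()}
        vols = {k: _sexed(v, sex) for k, v in entry["volumes"].items()}
        return cls.with_closure(BW=BW, QCC=float(entry["QCC"]),
                                **flows, **vols, sex=sex)


@dataclass(frozen=True)
class EnantiomerKinetics:
    """Chemical-specific constants for one MPH enantiomer and its RA.

    ``Kmliver_inhibitor`` is the Michaelis constant of the partner
    enantiomer, used as the competitive-inhibition constant in the
    hepatic hydrolysis term.
    """

    Kmliver: float            # µg/L
    VmaxliverC: float         # µg/h/kg^0.75
    KmetC: float              # L/h/kg^0.75
    VbodyC: float             # L/kg
    Ku_RAC: float             # L/h/kg^0.75
    GEC: float = 0.0          # 1/h/kg^-0.25 (oral)
    K3C: float = 0.0          # 1/h/kg^-0.25 (oral)
    K5C: float = 0.0          # 1/h/kg^0.75 (oral)
    F: float = 0.8            # hydrolysed fraction of gut metabolism
    Kmliver_inhibitor: float = field(default=0.0)

    def __post_init__(self):
        if self.Kmliver <= 0:
            raise ValueError("Kmliver must be > 0")
        if not 0.0 <= self.F <= 1.0:
            raise ValueError("F must lie in [0, 1]")
        if self.K5C < 0:
            raise ValueError("K5C must be >= 0")


@dataclass(frozen=True)
class PopulationModel:
    """A fully resolved population: physiology, partitions and paired
    d/l kinetics for one dosing route."""

    species: Literal["human", "rhesus"]
    age_class: Literal["adult", "child", "juvenile"]
    route: Literal["iv", "oral"]
    physio: PhysiologicalParams
    partition: PartitionSet
    kinetics_d: EnantiomerKinetics
    kinetics_l: EnantiomerKinetics
    age: float | None = None

    @property
    def BW(self) -> float:
        return self.physio.BW

    def replace(self, **changes) -> "PopulationModel":
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# operations


def scale_allometric(coefficient: float, BW: float, exponent: float) -> float:
    """Scale an allometric coefficient to an absolute value at body
    weight ``BW`` (kg): ``coefficient * BW**exponent``.

    Capacity-type coefficients use exponent 0.75, first-order rate
    coefficients use -0.25.
    """
    if BW <= 0:
        raise ValueError("body weight must be positive")
    return coefficient * BW ** exponent


def intrinsic_clearance(kin: EnantiomerKinetics, BW: float) -> float:
    """Hepatic intrinsic clearance Vmax/Km, per kg body weight (L/h/kg)."""
    if BW <= 0:
        raise ValueError("body weight must be positive")
    if kin.Kmliver <= 0:
        raise ZeroDivisionError("Kmliver must be > 0 for intrinsic clearance")
    vmax = scale_allometric(kin.VmaxliverC, BW, 0.75)  # µg/h
    return (vmax / kin.Kmliver) / BW


def interp_anchors(anchors, x: float, mode: str = "piecewise-linear") -> float:
    """Evaluate a tabulated growth function.

    ``piecewise-linear``: anchors are sorted ``(x, y)`` pairs; linear
    interpolation inside the range, flat extrapolation outside.
    ``banded``: anchors are ``(lo, hi, y)`` bands; the band value applies
    inside ``[lo, hi]``; a point in a gap resolves to the nearer band.
    """
    if not anchors:
        raise RegistryError("empty anchor table")
    if mode == "piecewise-linear":
        pts = sorted((float(a), float(b)) for a, b in anchors)
        if x <= pts[0][0]:
            return pts[0][1]
        if x >= pts[-1][0]:
            return pts[-1][1]
        for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
            if x0 <= x <= x1:
                return y0 + (y1 - y0) * (x - x0) / (x1 - x0)
        raise AssertionError("unreachable")
    if mode == "banded":
        bands = sorted((float(lo), float(hi), float(y)) for lo, hi, y in anchors)
        for lo, hi, y in bands:
            if lo <= x <= hi:
                return y
        # gaps / out of range: nearest band edge
        best = min(bands, key=lambda b: min(abs(x - b[0]), abs(x - b[1])))
        return best[2]
    raise ValueError(f"unknown interpolation mode {mode!r}")


def pediatric_physiology(age: float, sex: str, BW: float,
                         path: str | Path | None = None) -> PhysiologicalParams:
    """Child physiology (ages 4-15) from the pediatric growth registry.

    Adipose volume comes from piecewise-linear age anchors; liver blood
    flow from age-banded values; heart, fat and gonad flow fractions
    adopt the adult percentages of cardiac output.  Cardiac output, brain
    blood flow and the remaining fractional volumes follow the registry
    defaults (adult scaling) unless overridden.
    """
    if not 4.0 <= age <= 15.0:
        raise ValueError(f"age {age} outside the supported 4-15 yr range")
    if BW <= 0:
        raise ValueError("body weight must be positive")
    reg = load_registry("pediatric", path)

    fat_L = interp_anchors(reg["fat_volume_L"], age, mode="piecewise-linear")
    VFC = fat_L / BW

    co = reg["cardiac_output"]
    if co.get("mode") == "regression":
        c = co["coefficients"]
        QC = c["intercept"] + c["slope"] * age  # L/h
        QCC = QC / BW ** 0.75
    else:  # adult_allometric default
        QCC = float(co["QCC"])
        QC = QCC * BW ** 0.75

    liver_flow_L_h = interp_anchors(
        reg["liver_flow_mL_per_min"], age, mode="banded") * 60.0 / 1000.0
    QLC = liver_flow_L_h / QC

    bf = reg["brain_flow"]
    if bf.get("mode") == "regression":
        c = bf["coefficients"]
        QBC = (c["intercept"] + c["slope"] * age) / QC
    else:
        QBC = float(bf["QBC"])

    VPC = float(reg["plasma_volume"]["VPC"])
    vols = {k: _sexed(v, sex) for k, v in reg["adult_fraction_volumes"].items()}
    flows = {k: _sexed(v, sex) for k, v in reg["adult_fraction_flows"].items()}

    return PhysiologicalParams.with_closure(
        BW=BW, QCC=QCC, QLC=QLC, QBC=QBC, VPC=VPC, VFC=VFC,
        **flows, **vols, sex=sex)


def load_population(species: str, age_class: str, sex: str = "M",
                    route: str = "oral", BW: float | None = None,
                    age: float | None = None,
                    kinetics_path: str | Path | None = None,
                    physiology_path: str | Path | None = None,
                    partition_path: str | Path | None = None,
                    pediatric_path: str | Path | None = None) -> PopulationModel:
    """Resolve a population model from the registries.

    ``(species, age_class, route)`` must name one of the parameterized
    populations: adult human (iv/oral), child (oral), adult rhesus
    (iv/oral), juvenile rhesus (iv/oral).  ``BW`` is the study-specific
    body weight in kg; children additionally need ``age`` (years).
    """
    try:
        key = POPULATION_KEYS[(species, age_class)]
    except KeyError:
        raise RegistryError(
            f"unknown population ({species!r}, {age_class!r}); valid: "
            f"{sorted(POPULATION_KEYS)}") from None
    kin_reg = load_registry("kinetics", kinetics_path)
    routes = kin_reg[key]
    if route not in routes:
        raise RegistryError(
            f"route {route!r} not parameterized for {key}; valid: {sorted(routes)}")
    if BW is None:
        raise ValueError("body weight BW (kg) is required")

    if key == "child":
        if age is None:
            raise ValueError("age (years) is required for the child model")
        physio = pediatric_physiology(age, sex, BW, path=pediatric_path)
    else:
        phys_key = "adult_human" if key == "adult_human" else "monkey"
        physio = PhysiologicalParams.from_registry(phys_key, BW, sex,
                                                   path=physiology_path)
    physio.validate()

    raw_d = dict(routes[route]["d"])
    raw_l = dict(routes[route]["l"])
    kin_d = EnantiomerKinetics(**raw_d, Kmliver_inhibitor=raw_l["Kmliver"])
    kin_l = EnantiomerKinetics(**raw_l, Kmliver_inhibitor=raw_d["Kmliver"])

    return PopulationModel(
        species=species, age_class=age_class, route=route, physio=physio,
        partition=PartitionSet.from_registry(partition_path),
        kinetics_d=kin_d, kinetics_l=kin_l, age=age)


def ivive_vmax_coefficient(vitro_rate_ng_h_mg: float,
                           protein_mg_per_g_liver: float = 39.19,
                           liver_g: float = 2060.0,
                           relative_activity_factor: float = 0.22,
                           BW: float = (74.8 + 84.02) / 2) -> float:
    """In vitro-in vivo extrapolation of a hepatic Vmax coefficient.

    Converts an in vitro maximal velocity (ng/h/mg microsomal protein)
    to a whole-liver capacity via microsomal protein content and liver
    mass, bridges recombinant-enzyme to native-microsome activity with a
    relative activity factor, and normalizes to µg/h/kg^0.75.  The final
    model coefficients applied a further ~1.5-fold manual adjustment on
    top of these initial estimates.
    """
    if min(vitro_rate_ng_h_mg, protein_mg_per_g_liver, liver_g,
           relative_activity_factor, BW) < 0 or BW <= 0:
        raise ValueError("IVIVE inputs must be positive")
    vmax_ug_h = (vitro_rate_ng_h_mg * protein_mg_per_g_liver * liver_g
                 * relative_activity_factor) / 1000.0
    return vmax_ug_h / BW ** 0.75
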