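"""Local sensitivity analysis via normalized sensitivity coefficients.

Each model parameter is increased by 1% with all others held fixed and
the normalized sensitivity coefficient

    NSC(t) = [(O(1.01 P) - O(P)) / O(P)] / 0.01

is evaluated on the plasma-concentration time course over 24 h after a
single oral 0.3 mg/kg dose.  When a primary flow or volume fraction is
perturbed, the richly/slowly perfused complement re-absorbs the change
so the circulatory closure is preserved; perturbing a complement
fraction itself is applied directly.  Parameters whose maximum |NSC|
over the 24-h grid exceeds 0.1 are classified as sensitive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .model import ExposureSchedule, simulate
from .parameters import PopulationModel, pediatric_physiology

__all__ = [
    "NSCResult",
    "perturb_population",
    "nsc_timecourse",
    "classify_sensitive",
    "PARAMETER_GROUPS",
]

SENSITIVE_THRESHOLD = 0.1

#: parameter -> group, mirroring the physiological / partition / chemical split
PARAMETER_GROUPS = {
    **{p: "physiological" for p in
       ("QCC", "QFC", "QLC", "QBC", "QHC", "QGC", "QRC", "QSC",
        "VPC", "VFC", "VLC", "VBC", "VHC", "VGC", "VRC", "VSC",
        "BW", "Age")},
    **{p: "partition" for p in
       ("Pfat", "Pbrain", "Prich", "Pslow", "Pgonads", "Pheart", "Pliver")},
    **{p: "chemical" for p in
       ("Kmliverd", "Kmliverl", "VmaxliverdC", "VmaxliverlC",
        "KmetdC", "KmetlC", "GEdC", "GElC", "K3dC", "K3lC",
        "K5dC", "K5lC", "Fd", "Fl", "VbodydC", "VbodylC",
        "Ku_RAdC", "Ku_RAlC")},
}

#: which complement absorbs a compensated flow/volume perturbation
_FLOW_COMPENSATED = {"QLC": "QRC", "QGC": "QRC", "QBC": "QRC",
                     "QFC": "QSC", "QHC": "QSC"}
_VOL_COMPENSATED = {"VLC": "VRC", "VPC": "VRC", "VGC": "VRC", "VBC": "VRC",
                    "VFC": "VSC", "VHC": "VSC"}


@dataclass(frozen=True)
class NSCResult:
    """NSC time course for one parameter and one output."""

    parameter: str
    group: str
    t: np.ndarray
    nsc: np.ndarray          # NaN where the baseline output is zero
    max_abs_nsc: float
    sensitive: bool


def _perturb_kinetics(kin, field_name: str, factor: float):
    return replace(kin, **{field_name: getattr(kin, field_name) * factor})


def perturb_population(pop: PopulationModel, parameter: str,
                       factor: float) -> PopulationModel:
    """Return a copy of ``pop`` with one parameter scaled by ``factor``.

    Chemical parameters carry a d/l suffix (e.g. ``VmaxliverdC``,
    ``K3lC``); physiological fractions are compensated per the closure
    convention; ``BW`` rescales the whole body (and any mg/kg dose
    resolved from it); ``Age`` rebuilds the pediatric physiology.
    """
    ph = pop.physio
    if parameter == "BW":
        new_ph = replace(ph, BW=ph.BW * factor)
        return pop.replace(physio=new_ph)
    if parameter == "Age":
        if pop.age is None:
            raise ValueError("Age perturbation requires a child population")
        new_ph = pediatric_physiology(pop.age * factor, ph.sex, ph.BW)
        return pop.replace(physio=new_ph, age=pop.age * factor)
    if parameter in ("QCC",) or parameter in _FLOW_COMPENSATED \
            or parameter in _VOL_COMPENSATED \
            or parameter in ("QRC", "QSC", "VRC", "VSC"):
        changes = {}
        old = getattr(ph, parameter)
        delta = old * (factor - 1.0)
        changes[parameter] = old + delta
        comp = _FLOW_COMPENSATED.get(parameter) or _VOL_COMPENSATED.get(parameter)
        if comp is not None:
            changes[comp] = getattr(ph, comp) - delta
        return pop.replace(physio=replace(ph, **changes))
    if parameter.startswith("P") and hasattr(pop.partition, parameter):
        new_part = replace(pop.partition,
                           **{parameter: getattr(pop.partition, parameter) * factor})
        return pop.replace(partition=new_part)
    # chemical parameters: strip the enantiomer tag
    for tag, attr in (("d", "kinetics_d"), ("l", "kinetics_l")):
        for fld, pname in (("Kmliver", f"Kmliver{tag}"),
                           ("VmaxliverC", f"Vmaxliver{tag}C"),
                           ("KmetC", f"Kmet{tag}C"),
                           ("GEC", f"GE{tag}C"),
                           ("K3C", f"K3{tag}C"),
                           ("K5C", f"K5{tag}C"),
                           ("F", f"F{tag}"),
                           ("VbodyC", f"Vbody{tag}C"),
                           ("Ku_RAC", f"Ku_RA{tag}C")):
            if parameter == pname:
                kin = _perturb_kinetics(getattr(pop, attr), fld, factor)
                other = {"kinetics_d": pop.kinetics_d,
                         "kinetics_l": pop.kinetics_l}
                other[attr] = kin
                # keep the cross-referenced inhibition constants in sync
                if fld == "Kmliver":
                    partner = "kinetics_l" if tag == "d" else "kinetics_d"
                    other[partner] = replace(other[partner],
                                             Kmliver_inhibitor=kin.Kmliver)
                return pop.replace(**other)
    raise KeyError(f"unknown model parameter {parameter!r}")


def nsc_timecourse(pop: PopulationModel, schedule: ExposureSchedule,
                   parameter: str, output: str = "total",
                   t_end: float = 24.0, n_points: int = 97,
                   delta: float = 0.01, rtol: float = 1e-8,
                   _baseline=None) -> NSCResult:
    """Forward-difference NSC(t) of the plasma MPH concentration
    (``output`` = "total" or "d") with respect to one parameter.

    ``_baseline`` may carry a precomputed baseline output series to
    avoid re-simulating it for every parameter.
    """
    grid = np.linspace(0.0, t_end, n_points)

    def output_series(p):
        traj = simulate(p, schedule, t_end, rtol=rtol,
                        points_per_hour=max(8, int((n_points - 1) / t_end)))
        conc = traj.conc_plasma(output)
        return np.interp(grid, traj.t, conc)

    base = output_series(pop) if _baseline is None else np.asarray(_baseline)
    pert = output_series(perturb_population(pop, parameter, 1.0 + delta))
    with np.errstate(divide="ignore", invalid="ignore"):
        nsc = ((pert - base) / base) / delta
    zero = base <= 0.0
    if np.any(zero):
        warnings.warn(
            f"baseline output is zero at {int(zero.sum())} grid points; "
            "NSC masked there", RuntimeWarning, stacklevel=2)
        nsc = np.where(zero, np.nan, nsc)
    max_abs = float(np.nanmax(np.abs(nsc))) if np.any(~zero) else 0.0
    return NSCResult(parameter=parameter,
                     group=PARAMETER_GROUPS.get(parameter, "other"),
                     t=grid, nsc=nsc, max_abs_nsc=max_abs,
                     sensitive=max_abs > SENSITIVE_THRESHOLD)


def baseline_output(pop: PopulationModel, schedule: ExposureSchedule,
                    output: str = "total", t_end: float = 24.0,
                    n_points: int = 97, rtol: float = 1e-8) -> np.ndarray:
    """Baseline output series on the NSC grid, for reuse across parameters."""
    grid = np.linspace(0.0, t_end, n_points)
    traj = simulate(pop, schedule, t_end, rtol=rtol,
                    points_per_hour=max(8, int((n_points - 1) / t_end)))
    return np.interp(grid, traj.t, traj.conc_plasma(output))


def classify_sensitive(results) -> dict:
    """Partition sensitive parameters (max |NSC| > 0.1) into the
    physiological / partition / chemical groups."""
    out = {"physiological": [], "partition": [], "chemical": [], "other": []}
    for r in results:
        if r.sensitive:
            out[r.group].append(r.parameter)
    return {k: sorted(v) for k, v in out.items() if v}
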