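"""Label-free quantification from top-3-isotope extracted-ion chromatograms.

The XIC of a glycan ion sums, in every MS1 scan, the intensities
matched at the m/z of its three most probable aggregated isotope peaks
(the top-3-isotope quantification idea: better signal-to-noise than a
single-isotope trace).  Compositional isomers share one theoretical m/z
and appear as separate chromatographic peaks, detected by an
apex-outward walk: the apex is the highest point, the boundary extends
while intensity stays at or above a fraction of the apex (default 50%)
and then on to the nearest local minimum on each side.  Peak areas are
trapezoidal integrals of intensity over time, summed across charge
states and adducts per isomer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotate import AnnotatedGlycan, _theoretical_envelope
from .calibrate import CalibrationModel, rt_to_gui
from .compositions import GlycanComposition
from .config import Config
from .constants import ADDUCT_MASS
from .msio import BucketIndex, Run

__all__ = [
    "XICTrace",
    "IsomerPeak",
    "CompositionQuant",
    "build_xic",
    "detect_peaks",
    "integrate",
    "quantify_run",
]


@dataclass
class XICTrace:
    composition: GlycanComposition
    charge: int
    adduct: str
    rts: np.ndarray  # minutes, strictly ascending, one per MS1 scan
    intensities: np.ndarray  # combined top-3-isotope intensity


@dataclass
class IsomerPeak:
    apex_rt: float
    apex_intensity: float
    left_rt: float
    right_rt: float
    area: float  # intensity * minutes
    gui: float | None = None


@dataclass
class CompositionQuant:
    composition: GlycanComposition
    isomers: list[IsomerPeak]
    total_area: float


def build_xic(
    run: Run,
    index: BucketIndex,
    comp: GlycanComposition,
    charge: int,
    adduct: str = "proton",
    cfg: Config | None = None,
) -> XICTrace:
    """Dense per-scan trace of combined top-3 isotope intensity.

    Scans with no matched peak contribute 0, so the trace always spans
    every MS1 scan of the run.
    """
    cfg = cfg or Config()
    probs, masses, _ = _theoretical_envelope(
        comp, cfg.derivatization, cfg.reduced_end, cfg.n_isotope_peaks
    )
    top3 = np.argsort(probs)[::-1][:3]
    ms1 = run.ms1_spectra()
    pos: dict[int, int] = {}  # run-spectrum index -> ms1 ordinal
    k = 0
    for si, s in enumerate(run.spectra):
        if s.ms_level == 1:
            pos[si] = k
            k += 1
    intens = np.zeros(len(ms1))
    for i in top3:
        target = (masses[i] + charge * ADDUCT_MASS[adduct]) / charge
        tol = cfg.tol_da(target)
        # nearest in-tolerance peak per scan
        best: dict[int, tuple[float, float]] = {}  # scan -> (distance, intensity)
        for pmz, pint, si, _ in index.query(target, tol):
            k = pos.get(si)
            if k is None:
                continue
            d = abs(pmz - target)
            if k not in best or d < best[k][0]:
                best[k] = (d, pint)
        for k, (_, pint) in best.items():
            intens[k] += pint
    return XICTrace(
        composition=comp,
        charge=charge,
        adduct=adduct,
        rts=np.array([s.rt for s in ms1]),
        intensities=intens,
    )


def detect_peaks(
    trace: XICTrace, boundary_cutoff: float = 0.5, min_apex: float = 0.0
) -> list[IsomerPeak]:
    """Detect isomer peaks in an XIC by the apex-outward algorithm.

    Iteratively: take the highest unassigned point as apex; walk
    outward while intensity >= boundary_cutoff * apex; extend each side
    to the nearest local minimum (stop at the first point whose next
    outward neighbor is not lower); mark the span assigned.  Repeats
    for remaining apexes above ``min_apex``.  Returned peaks are
    disjoint and ordered by apex rt.
    """
    if not 0 < boundary_cutoff < 1:
        raise ValueError("boundary_cutoff must be in (0, 1)")
    y = np.asarray(trace.intensities, dtype=float)
    x = np.asarray(trace.rts, dtype=float)
    n = len(y)
    if n == 0:
        raise ValueError("empty XIC trace")
    assigned = np.zeros(n, dtype=bool)
    peaks: list[IsomerPeak] = []
    while True:
        cand = np.where(~assigned & (y > max(min_apex, 0.0)))[0]
        if len(cand) == 0:
            break
        apex = int(cand[np.argmax(y[cand])])
        if y[apex] <= 0:
            break
        floor = boundary_cutoff * y[apex]
        left = apex
        while left - 1 >= 0 and not assigned[left - 1] and y[left - 1] >= floor:
            left -= 1
        while left - 1 >= 0 and not assigned[left - 1] and y[left - 1] < y[left]:
            left -= 1
        right = apex
        while right + 1 < n and not assigned[right + 1] and y[right + 1] >= floor:
            right += 1
        while right + 1 < n and not assigned[right + 1] and y[right + 1] < y[right]:
            right += 1
        assigned[left : right + 1] = True
        peaks.append(
            IsomerPeak(
                apex_rt=float(x[apex]),
                apex_intensity=float(y[apex]),
                left_rt=float(x[left]),
                right_rt=float(x[right]),
                area=integrate(trace, float(x[left]), float(x[right])),
            )
        )
    peaks.sort(key=lambda p: p.apex_rt)
    return peaks


def integrate(
    trace: XICTrace, left_rt: float, right_rt: float, mode: str = "trapezoid"
) -> float:
    """Area (intensity * minutes) between inclusive rt bounds.

    ``mode="sum"`` instead returns the raw intensity sum over the
    bounded scans (unit: intensity counts), mirroring a plain
    sum-over-scans definition of area.
    """
    if right_rt < left_rt:
        raise ValueError(f"inverted integration bounds [{left_rt}, {right_rt}]")
    sel = (trace.rts >= left_rt) & (trace.rts <= right_rt)
    y = trace.intensities[sel]
    x = trace.rts[sel]
    if len(y) < 2:
        return 0.0
    if mode == "sum":
        return float(np.sum(y))
    if mode != "trapezoid":
        raise ValueError(f"unknown area mode {mode!r}")
    return float(np.trapezoid(y, x))


def quantify_run(
    annotations: list[AnnotatedGlycan],
    run: Run,
    index: BucketIndex,
    model: CalibrationModel,
    cfg: Config | None = None,
) -> list[CompositionQuant]:
    """Per-composition isomer quantification across charges and adducts.

    For every composition with at least one annotation, an XIC is built
    for each annotated (charge, adduct), isomer peaks are detected per
    trace, and peaks whose apexes fall within ``cfg.isomer_rt_window``
    minutes across traces are treated as the same isomer: their areas
    are summed and the apex of the most intense trace defines the
    isomer's rt and calibrated GUI.  The composition's total area is
    the sum over its isomers.
    """
    cfg = cfg or Config()
    if not annotations:
        raise ValueError("no annotations to quantify")
    by_comp: dict[GlycanComposition, set[tuple[int, str]]] = {}
    for a in annotations:
        by_comp.setdefault(a.composition, set()).add((a.charge, a.adduct))
    out: list[CompositionQuant] = []
    for comp in sorted(by_comp, key=str):
        all_peaks: list[IsomerPeak] = []
        for z, adduct in sorted(by_comp[comp]):
            trace = build_xic(run, index, comp, z, adduct, cfg)
            for p in detect_peaks(trace, cfg.boundary_cutoff, cfg.min_apex):
                if cfg.area_mode == "sum":
                    p.area = integrate(trace, p.left_rt, p.right_rt, mode="sum")
                all_peaks.append(p)
        isomers = _merge_isomers(all_peaks, cfg.isomer_rt_window)
        for p in isomers:
            p.gui = float(rt_to_gui(model, p.apex_rt))
        out.append(
            CompositionQuant(
                composition=comp,
                isomers=isomers,
                total_area=float(sum(p.area for p in isomers)),
            )
        )
    return out


def _merge_isomers(peaks: list[IsomerPeak], rt_window: float) -> list[IsomerPeak]:
    """Greedy apex-rt clustering of per-trace peaks into isomers."""
    merged: list[IsomerPeak] = []
    for p in sorted(peaks, key=lambda q: -q.apex_intensity):
        home = None
        for m in merged:
            if abs(m.apex_rt - p.apex_rt) <= rt_window:
                home = m
                break
        if home is None:
            merged.append(
                IsomerPeak(p.apex_rt, p.apex_intensity, p.left_rt, p.right_rt, p.area)
            )
        else:
            home.area += p.area
            home.left_rt = min(home.left_rt, p.left_rt)
            home.right_rt = max(home.right_rt, p.right_rt)
    merged.sort(key=lambda q: q.apex_rt)
    return merged
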