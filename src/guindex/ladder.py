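"""Dextrin-ladder detection and glucose-unit assignment.

The spiked permethylated dextrin ladder (GU 2-12 by default) is located
by matching each scan's peaks against the theoretical m/z of each
rung's most abundant isotope ion at every configured charge and adduct.
Because noise and overlapping envelopes produce spurious matches, the
final rung-to-retention-time assignment is resolved by a dynamic
program over the elution-order constraint: a longer glucan never elutes
before a shorter one, and true rung peaks are more intense than false
ones, so the maximum-total-intensity non-decreasing GU path through the
scans is the most likely assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .compositions import dextrin_formula
from .config import Config
from .isotopes import envelope, envelope_mz
from .msio import BucketIndex, Run

__all__ = ["LadderObservation", "LadderAssignment", "extract_ladder_candidates", "assign_ladder"]


@dataclass(frozen=True)
class LadderObservation:
    """One candidate rung match in one scan (max intensity over charges/adducts)."""

    gu: int
    rt: float  # minutes
    intensity: float
    scan_id: str
    charge: int


@dataclass
class LadderAssignment:
    """Chosen retention time and supporting intensity per glucose unit."""

    rt_by_gu: dict[int, float]
    intensity_by_gu: dict[int, float]
    path: list[tuple[float, int]] = field(default_factory=list)  # (rt, gu) per scan

    def fit_points(self) -> list[tuple[float, int]]:
        """(rt, gu) pairs for calibration, ascending in gu."""
        return [(self.rt_by_gu[g], g) for g in sorted(self.rt_by_gu)]


def extract_ladder_candidates(
    run: Run, index: BucketIndex, cfg: Config
) -> list[LadderObservation]:
    """Match rung anchor ions across the run.

    For each GU and each MS1 scan at most one observation is kept: the
    most intense peak matching the rung's most abundant isotope ion over
    all configured charges and adducts, within the ppm tolerance.
    """
    # best[(spectrum_index, gu)] = (intensity, charge)
    best: dict[tuple[int, int], tuple[float, int]] = {}
    for gu in range(cfg.gu_min, cfg.gu_max + 1):
        env = envelope(dextrin_formula(gu), cfg.n_isotope_peaks)
        for z in range(1, cfg.max_charge + 1):
            for adduct in cfg.adducts:
                anchor = float(envelope_mz(env, z, adduct)[env.most_abundant_index])
                for _, inten, si, _ in index.query(anchor, cfg.tol_da(anchor)):
                    if inten <= cfg.min_ladder_intensity:
                        continue
                    key = (si, gu)
                    if key not in best or inten > best[key][0]:
                        best[key] = (inten, z)
    out = []
    for (si, gu), (inten, z) in sorted(best.items()):
        spec = run.spectra[si]
        out.append(LadderObservation(gu, spec.rt, inten, spec.scan_id, z))
    out.sort(key=lambda o: (o.rt, o.gu))
    return out


def assign_ladder(observations: list[LadderObservation]) -> LadderAssignment:
    """Resolve rung retention times by dynamic programming.

    Scans are visited in rt order; the state is the rung the ladder is
    currently eluting.  score[i][u] = intensity(i, u) + max over j <= u
    of score[i-1][j], so the traceback is the non-decreasing GU sequence
    of maximal total matched intensity (ties broken toward staying on
    the same rung, giving contiguous elution blocks).  Each rung's final
    retention time is the scan of highest matched intensity among the
    scans the path assigns to it; rungs never observed on the path are
    omitted with a warning.
    """
    if not observations:
        raise ValueError("no ladder observations to assign")
    rts = sorted({o.rt for o in observations})
    gus = sorted({o.gu for o in observations})
    rt_ix = {t: i for i, t in enumerate(rts)}
    gu_ix = {g: u for u, g in enumerate(gus)}
    n_t, n_u = len(rts), len(gus)
    inten = np.zeros((n_t, n_u))
    for o in observations:
        i, u = rt_ix[o.rt], gu_ix[o.gu]
        inten[i, u] = max(inten[i, u], o.intensity)

    score = np.zeros((n_t, n_u))
    prev = np.zeros((n_t, n_u), dtype=int)
    score[0] = inten[0]
    prev[0] = np.arange(n_u)
    for i in range(1, n_t):
        best_j = 0  # argmax of score[i-1, :u+1], earliest on ties
        for u in range(n_u):
            if score[i - 1, u] > score[i - 1, best_j]:
                best_j = u
            # prefer the same-rung predecessor when it ties the prefix max
            j = u if score[i - 1, u] >= score[i - 1, best_j] else best_j
            score[i, u] = inten[i, u] + score[i - 1, j]
            prev[i, u] = j

    path_u = np.zeros(n_t, dtype=int)
    path_u[-1] = int(np.argmax(score[-1]))
    for i in range(n_t - 1, 0, -1):
        path_u[i - 1] = prev[i, path_u[i]]

    rt_by_gu: dict[int, float] = {}
    int_by_gu: dict[int, float] = {}
    for i, u in enumerate(path_u):
        g = gus[u]
        v = inten[i, u]
        if v > 0 and (g not in int_by_gu or v > int_by_gu[g]):
            rt_by_gu[g] = rts[i]
            int_by_gu[g] = float(v)
    missing = [g for g in gus if g not in rt_by_gu]
    if missing:
        warnings.warn(
            f"glucose units {missing} had observations but were not supported "
            "by the optimal elution path; omitted from the assignment",
            stacklevel=2,
        )
    return LadderAssignment(
        rt_by_gu=rt_by_gu,
        intensity_by_gu=int_by_gu,
        path=[(rts[i], gus[path_u[i]]) for i in range(n_t)],
    )
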