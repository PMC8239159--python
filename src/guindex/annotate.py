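"""N-glycan annotation by isotope-envelope matching.

For every candidate composition, charge and adduct the search anchor is
the most abundant aggregated isotope ion — the peak most likely to be
observed when the glycan is present.  When the anchor matches a scan
peak within tolerance, the match is extended to the neighboring
aggregated positions (spacing 1.00335/z) and the observed intensities
are scored against the theoretical envelope with the Pearson
correlation coefficient, which is invariant to linear transformation of
the intensities.  Matches scoring at or above the cutoff (default 0.9)
become annotations carrying the calibrated GUI of their scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .calibrate import CalibrationModel, rt_to_gui
from .compositions import GlycanComposition, enumerate_glycans, glycan_formula
from .config import Config
from .constants import ADDUCT_MASS, NEUTRON_SPACING
from .isotopes import envelope
from .msio import BucketIndex, Run, Spectrum

__all__ = ["EnvelopeMatch", "AnnotatedGlycan", "match_envelope", "score_match", "annotate_run"]

#: Envelope length for scoring: theoretical peaks covering this much
#: cumulative probability, but never fewer than MIN_ENVELOPE_PEAKS.
ENVELOPE_COVERAGE = 0.999
MIN_ENVELOPE_PEAKS = 3


@dataclass(frozen=True)
class EnvelopeMatch:
    """Aligned theoretical/observed intensity vectors for one anchor hit."""

    theoretical: np.ndarray
    observed: np.ndarray  # 0.0 where no peak fell within tolerance
    anchor_mz: float
    matched_peaks: int  # positions with an observed peak


@dataclass(frozen=True)
class AnnotatedGlycan:
    composition: GlycanComposition
    charge: int
    adduct: str
    scan_id: str
    rt: float
    score: float
    gui: float
    matched_mz: float  # observed anchor m/z


@lru_cache(maxsize=None)
def _theoretical_envelope(
    comp: GlycanComposition, derivatization: str, reduced_end: bool, n_peaks: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """(probabilities, centroid masses, scored length) for a composition."""
    env = envelope(glycan_formula(comp, derivatization, reduced_end), n_peaks)
    cum = np.cumsum(env.probabilities)
    k = int(np.searchsorted(cum, ENVELOPE_COVERAGE)) + 1
    k = max(k, MIN_ENVELOPE_PEAKS, env.most_abundant_index + 1)
    k = min(k, len(env))
    return env.probabilities[:k], env.centroid_masses[:k], k


def match_envelope(
    spectrum: Spectrum,
    comp: GlycanComposition,
    charge: int,
    adduct: str = "proton",
    tol_ppm: float = 10.0,
    derivatization: str = "permethylated",
    reduced_end: bool = False,
    n_peaks: int = 10,
) -> EnvelopeMatch | None:
    """Match one composition's envelope in one centroided scan.

    Returns None when the most abundant isotope ion has no peak within
    tolerance (the anchor rule); otherwise pairs every theoretical
    aggregated position with the nearest in-tolerance observed peak,
    recording 0 intensity where none exists.
    """
    probs, masses, k = _theoretical_envelope(comp, derivatization, reduced_end, n_peaks)
    anchor_idx = int(np.argmax(probs))
    adduct_mass = ADDUCT_MASS[adduct]
    anchor_mz = (masses[anchor_idx] + charge * adduct_mass) / charge
    tol = tol_ppm * 1e-6 * anchor_mz
    j = spectrum.nearest_peak(anchor_mz, tol)
    if j is None:
        return None
    observed_anchor_mz = float(spectrum.mz[j])
    observed = np.zeros(k)
    for i in range(k):
        # neighbors sit at the aggregated-peak spacing from the observed anchor
        target = observed_anchor_mz + (i - anchor_idx) * NEUTRON_SPACING / charge
        p = spectrum.nearest_peak(target, tol)
        if p is not None:
            observed[i] = spectrum.intensity[p]
    return EnvelopeMatch(
        theoretical=probs.copy(),
        observed=observed,
        anchor_mz=observed_anchor_mz,
        matched_peaks=int(np.count_nonzero(observed)),
    )


def score_match(match: EnvelopeMatch) -> float | None:
    """Pearson correlation of theoretical vs observed envelope intensities.

    None (match rejected) when either vector has zero variance, where
    the correlation is undefined.
    """
    t, o = match.theoretical, match.observed
    if len(t) < 2 or np.ptp(t) == 0 or np.ptp(o) == 0:
        return None
    tc = t - t.mean()
    oc = o - o.mean()
    return float(np.dot(tc, oc) / np.sqrt(np.dot(tc, tc) * np.dot(oc, oc)))


def annotate_run(
    run: Run,
    index: BucketIndex,
    model: CalibrationModel,
    cfg: Config,
    compositions: list[GlycanComposition] | None = None,
) -> list[AnnotatedGlycan]:
    """Annotate every MS1 scan of a run against the composition space.

    One annotation is produced per (composition, charge, adduct, scan)
    whose envelope scores at or above ``cfg.score_cutoff`` (signed
    comparison; negative correlations are never clipped).  Output order
    is deterministic: composition string, rt, charge, adduct.
    """
    if compositions is None:
        compositions = enumerate_glycans(cfg.bounds)
    out: list[AnnotatedGlycan] = []
    for comp in compositions:
        probs, masses, _ = _theoretical_envelope(
            comp, cfg.derivatization, cfg.reduced_end, cfg.n_isotope_peaks
        )
        anchor_idx = int(np.argmax(probs))
        for z in range(1, cfg.max_charge + 1):
            for adduct in cfg.adducts:
                anchor = (masses[anchor_idx] + z * ADDUCT_MASS[adduct]) / z
                hits = index.query(anchor, cfg.tol_da(anchor))
                for si in sorted({h[2] for h in hits}):
                    spec = run.spectra[si]
                    m = match_envelope(
                        spec, comp, z, adduct,
                        tol_ppm=cfg.tol_ppm,
                        derivatization=cfg.derivatization,
                        reduced_end=cfg.reduced_end,
                        n_peaks=cfg.n_isotope_peaks,
                    )
                    if m is None:
                        continue
                    r = score_match(m)
                    if r is None or r < cfg.score_cutoff:
                        continue
                    out.append(
                        AnnotatedGlycan(
                            composition=comp,
                            charge=z,
                            adduct=adduct,
                            scan_id=spec.scan_id,
                            rt=spec.rt,
                            score=r,
                            gui=float(rt_to_gui(model, spec.rt)),
                            matched_mz=m.anchor_mz,
                        )
                    )
    out.sort(key=lambda a: (str(a.composition), a.rt, a.charge, a.adduct))
    return out
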