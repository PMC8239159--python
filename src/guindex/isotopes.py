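"""Aggregated isotopic distributions via the BRAIN polynomial recursion.

The aggregated distribution groups isotopologues by nucleon-number
offset from the monoisotopic variant (A, A+1, A+2, ...), matching
unit-resolved LC-MS practice.  For a formula with v_e atoms of element
e whose isotope abundances form the generating polynomial
Q_e(x) = sum_j P_ej x^j, the molecule's polynomial is
Q(x) = prod_e Q_e(x)^{v_e} and the aggregated probabilities are its
coefficients.  They are obtained without expanding the product through
Newton-Girard identities on the power sums of the inverse roots of the
per-element polynomials; centroid masses come from a companion power
series (the mass-weighted element polynomial divided by Q_e).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .compositions import ElementalFormula, GlycanComposition, glycan_formula
from .constants import ADDUCT_MASS, ISOTOPES

__all__ = ["IsotopeEnvelope", "envelope", "most_abundant_mz", "envelope_mz"]

DEFAULT_N_PEAKS = 10


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Aggregated isotope envelope of one elemental formula."""

    probabilities: np.ndarray  # per aggregated peak, monoisotopic first
    centroid_masses: np.ndarray  # Da, probability-weighted within each peak

    @property
    def most_abundant_index(self) -> int:
        return int(np.argmax(self.probabilities))

    def __len__(self) -> int:
        return len(self.probabilities)


@lru_cache(maxsize=None)
def _element_series(el: str, n_terms: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom inverse-root power sums psi_l and mass series c_k.

    psi_l = sum over roots r of Q_el of r^{-l}, l = 1..n_terms-1.
    c = power series of M_el(x)/Q_el(x) where M_el is the mass-weighted
    abundance polynomial; both enter the molecule-level recursions
    scaled by the atom count.
    """
    iso = ISOTOPES[el]
    a = np.array([p for _, p in iso], dtype=float)  # Q_el coefficients
    b = np.array([m * p for m, p in iso], dtype=float)  # M_el coefficients
    # inverse-root power sums (roots may be complex conjugates; sums real)
    psi = np.zeros(n_terms, dtype=float)
    if len(a) > 1:
        roots = np.roots(a[::-1])
        inv = 1.0 / roots
        acc = np.ones_like(inv)
        for l in range(1, n_terms):
            acc = acc * inv
            psi[l] = float(np.sum(acc).real)
    # series of M/Q by long division
    c = np.zeros(n_terms, dtype=float)
    c[0] = b[0] / a[0]
    for k in range(1, n_terms):
        s = b[k] if k < len(b) else 0.0
        for i in range(1, min(k, len(a) - 1) + 1):
            s -= a[i] * c[k - i]
        c[k] = s / a[0]
    return psi, c


def envelope(formula: ElementalFormula, n_peaks: int = DEFAULT_N_PEAKS) -> IsotopeEnvelope:
    """First ``n_peaks`` aggregated isotope peaks of ``formula``.

    Probabilities follow the Newton-Girard recursion
    j*q_j = -sum_{l=1..j} psi_l q_{j-l} with psi_l accumulated over
    elements; centroid masses are W(x)/Q(x) coefficients as described
    in the module docstring.  The empty formula yields the degenerate
    single peak (probability 1, mass 0).
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    counts = formula.as_dict()
    if not counts:
        return IsotopeEnvelope(np.array([1.0]), np.array([0.0]))

    psi = np.zeros(n_peaks, dtype=float)
    mass_series = np.zeros(n_peaks, dtype=float)
    q0 = 1.0
    for el, v in counts.items():
        e_psi, e_c = _element_series(el, n_peaks)
        psi += v * e_psi
        mass_series += v * e_c
        q0 *= ISOTOPES[el][0][1] ** v

    q = np.zeros(n_peaks, dtype=float)
    q[0] = q0
    for j in range(1, n_peaks):
        q[j] = -np.dot(psi[1 : j + 1], q[j - 1 :: -1][: j]) / j
    q = np.maximum(q, 0.0)  # guard tiny negative round-off in the tail

    # w_j = sum of probability*mass over aggregate j: W = Q * mass_series
    w = np.zeros(n_peaks, dtype=float)
    for j in range(n_peaks):
        w[j] = np.dot(q[: j + 1], mass_series[j::-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        masses = np.where(q > 0, w / np.where(q > 0, q, 1.0), 0.0)
    return IsotopeEnvelope(q, masses)


def envelope_mz(
    env: IsotopeEnvelope, charge: int, adduct: str = "proton"
) -> np.ndarray:
    """m/z (Th) of each aggregated peak for the [M+z·adduct]^z+ ion."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (env.centroid_masses + charge * ADDUCT_MASS[adduct]) / charge


def most_abundant_mz(
    comp: GlycanComposition | ElementalFormula,
    charge: int,
    adduct: str = "proton",
    derivatization: str = "permethylated",
    n_peaks: int = DEFAULT_N_PEAKS,
) -> float:
    """m/z of the most probable aggregated isotope peak (the search anchor)."""
    formula = (
        comp
        if isinstance(comp, ElementalFormula)
        else glycan_formula(comp, derivatization)
    )
    env = envelope(formula, n_peaks)
    return float(envelope_mz(env, charge, adduct)[env.most_abundant_index])
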