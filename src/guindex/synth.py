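"""Synthetic LC-MS run generation for end-to-end testing and demos.

A synthetic run emulates a permethylated-glycomics acquisition with a
spiked dextrin ladder: MS1 scans on a regular retention-time grid, each
planted species contributing its aggregated isotope envelope scaled by
a Gaussian elution profile, ladder rungs placed on a smooth monotone
GU→rt curve, and uniform-m/z decoy peaks with log-normal intensities.
Every run is deterministic under its seed and is accompanied by a
ground-truth manifest (planted species, retention times, heights,
analytic areas) against which pipeline output can be compared.

What this emulates — and what it does not: chromatographic peaks are
ideal Gaussians, envelopes are exact, and decoys are uncorrelated
point noise.  Real data adds peak tailing, chemical background with
isotope structure, charge-state interference and detector saturation,
none of which are modeled here.
"""

from __future__ import annotations

import base64
import json
import math
import struct
import xml.etree.ElementTree as ET
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .compositions import GlycanComposition, dextrin_formula, glycan_formula
from .isotopes import envelope, envelope_mz
from .msio import Run, Spectrum

__all__ = [
    "PlantedGlycan",
    "SynthSpec",
    "default_gu_curve",
    "generate_run",
    "write_mzml",
    "write_manifest",
    "manifest",
    "default_spec",
]

#: Increasing cubic mapping rt (minutes) → GUI, chosen so GU 2–12 spans
#: roughly 10–56 min, the regime of a typical C18 permethylated-glycan
#: gradient.  The generator places rungs on its inverse.
DEFAULT_GU_CUBIC = (0.3, 0.16, 8.0e-4, 2.0e-6)


def gui_of_rt(rt: float, coeffs: tuple[float, ...] = DEFAULT_GU_CUBIC) -> float:
    return float(np.polynomial.polynomial.polyval(rt, coeffs))


def default_gu_curve(gu: float, coeffs: tuple[float, ...] = DEFAULT_GU_CUBIC) -> float:
    """rt (minutes) at which the default GUI curve reaches ``gu``."""
    return float(brentq(lambda t: gui_of_rt(t, coeffs) - gu, 0.0, 500.0))


@dataclass(frozen=True)
class PlantedGlycan:
    """One planted glycan elution peak (one compositional isomer)."""

    composition: GlycanComposition
    charges: tuple[int, ...] = (1,)
    adduct: str = "proton"
    apex_rt: float | None = None  # minutes; or give target_gui
    target_gui: float | None = None
    height: float = 5.0e5  # anchor-isotope apex intensity per charge
    sigma: float = 0.1  # chromatographic width, minutes

    def resolved_apex(self, gu_curve) -> float:
        if self.apex_rt is not None:
            return self.apex_rt
        if self.target_gui is None:
            raise ValueError("planted glycan needs apex_rt or target_gui")
        return gu_curve(self.target_gui)


@dataclass
class SynthSpec:
    """Everything needed to generate one deterministic synthetic run."""

    gu_range: tuple[int, int] = (2, 12)
    gu_curve: object = default_gu_curve  # monotone GU → rt (minutes)
    ladder_height: float = 1.0e6  # GU-2 rung anchor apex intensity
    ladder_decay: float = 0.75  # per-GU height factor (higher rungs weaker)
    ladder_sigma: float = 0.12  # minutes
    glycans: tuple[PlantedGlycan, ...] = ()
    noise_density: float = 0.0  # mean decoy peaks per scan (Poisson)
    noise_intensity: float = 0.0  # decoy log-normal median intensity
    noise_sigma_log: float = 0.5  # log-normal shape of decoy intensities
    noise_mz_range: tuple[float, float] = (300.0, 2000.0)
    rt_range: tuple[float, float] = (8.0, 58.0)
    scan_interval: float = 0.05  # minutes
    seed: int = 0
    envelope_coverage: float = 0.999  # per-species envelope truncation

    def __post_init__(self):
        if self.rt_range[1] <= self.rt_range[0]:
            raise ValueError("invalid rt range")
        if self.scan_interval <= 0:
            raise ValueError("scan interval must be positive")


def default_spec(seed: int = 0, **overrides) -> SynthSpec:
    """The package's standard demo run: full ladder, five glycans, decoys.

    Two of the five compositions are planted as GUI-targeted species
    (GUI 5.0 and 7.0) exercising the calibration round trip; the others
    cover multi-charge, fucosylated and sialylated cases.  Near-isobaric
    anchor collisions with other enumerated compositions exist but score
    below the Pearson cutoff (see the methods note).
    """
    glycans = (
        PlantedGlycan(GlycanComposition(2, 3, 0, 0), (1,), "proton", target_gui=5.0, height=6.0e5),
        PlantedGlycan(GlycanComposition(2, 5, 0, 0), (1,), "proton", target_gui=7.0, height=5.0e5),
        PlantedGlycan(GlycanComposition(4, 5, 0, 0), (1, 2), "proton", apex_rt=30.0, height=4.0e5),
        PlantedGlycan(GlycanComposition(4, 5, 1, 0), (2,), "proton", apex_rt=36.0, height=3.5e5),
        PlantedGlycan(GlycanComposition(4, 5, 0, 2), (2,), "proton", apex_rt=42.0, height=3.0e5),
    )
    base = SynthSpec(
        glycans=glycans,
        noise_density=5.0,
        noise_intensity=0.2 * 1.0e6 * 0.75 ** 10,  # 20% of the weakest rung
        seed=seed,
    )
    return replace(base, **overrides) if overrides else base


def _species_ions(spec: SynthSpec):
    """Yield (apex_rt, sigma, per-ion m/z array, per-ion apex intensities, label)."""
    gu_lo, gu_hi = spec.gu_range
    for gu in range(gu_lo, gu_hi + 1):
        env = envelope(dextrin_formula(gu))
        h = spec.ladder_height * spec.ladder_decay ** (gu - gu_lo)
        yield (
            spec.gu_curve(gu),
            spec.ladder_sigma,
            envelope_mz(env, 1, "proton"),
            h * env.probabilities / env.probabilities.max(),
            f"GU{gu}",
        )
    for g in spec.glycans:
        env = envelope(glycan_formula(g.composition))
        apex = g.resolved_apex(spec.gu_curve)
        for z in g.charges:
            yield (
                apex,
                g.sigma,
                envelope_mz(env, z, g.adduct),
                g.height * env.probabilities / env.probabilities.max(),
                f"{g.composition}/z{z}",
            )


def generate_run(spec: SynthSpec) -> Run:
    """Deterministically synthesize the MS1 run described by ``spec``."""
    rt_lo, rt_hi = spec.rt_range
    n_scans = int(round((rt_hi - rt_lo) / spec.scan_interval)) + 1
    rts = rt_lo + spec.scan_interval * np.arange(n_scans)
    species = list(_species_ions(spec))
    for apex, _, _, _, label in species:
        if not rt_lo <= apex <= rt_hi:
            raise ValueError(f"planted species {label} apex {apex:.2f} min outside rt range")
    rng = np.random.default_rng(spec.seed)
    spectra = []
    for i, rt in enumerate(rts):
        mzs: list[float] = []
        ints: list[float] = []
        for apex, sigma, ion_mz, ion_apex, _ in species:
            if abs(rt - apex) > 5 * sigma:
                continue
            g = math.exp(-0.5 * ((rt - apex) / sigma) ** 2)
            keep = ion_apex * g > 1.0  # drop sub-count envelope tails
            mzs.extend(ion_mz[keep])
            ints.extend(ion_apex[keep] * g)
        n_noise = rng.poisson(spec.noise_density) if spec.noise_density > 0 else 0
        if n_noise:
            mzs.extend(rng.uniform(*spec.noise_mz_range, size=n_noise))
            ints.extend(
                spec.noise_intensity
                * np.exp(rng.normal(0.0, spec.noise_sigma_log, size=n_noise))
            )
        mz_arr = np.asarray(mzs)
        int_arr = np.asarray(ints)
        order = np.argsort(mz_arr)
        mz_arr, int_arr = mz_arr[order], int_arr[order]
        # coincident m/z values (envelope overlap) merge into one peak
        if len(mz_arr) > 1:
            same = np.isclose(np.diff(mz_arr), 0.0, atol=1e-9)
            if same.any():
                keep_idx = np.concatenate([[True], ~same])
                groups = np.cumsum(keep_idx) - 1
                merged_int = np.zeros(groups[-1] + 1)
                np.add.at(merged_int, groups, int_arr)
                mz_arr = mz_arr[keep_idx]
                int_arr = merged_int
        spectra.append(
            Spectrum(
                scan_id=f"scan={i + 1}",
                rt=float(rt),
                ms_level=1,
                mz=mz_arr,
                intensity=int_arr,
            )
        )
    return Run(spectra=spectra, metadata={"synthetic": True, "seed": spec.seed})


def manifest(spec: SynthSpec) -> dict:
    """Ground truth for a spec: planted rts, heights, analytic areas.

    The analytic top-3 area of a Gaussian isomer is
    h·σ·√(2π)·(Σ top-3 probabilities)/p_anchor per charge state.
    """
    gu_lo, gu_hi = spec.gu_range
    rungs = []
    for gu in range(gu_lo, gu_hi + 1):
        rungs.append(
            {
                "gu": gu,
                "rt": spec.gu_curve(gu),
                "height": spec.ladder_height * spec.ladder_decay ** (gu - gu_lo),
            }
        )
    glycans = []
    for g in spec.glycans:
        env = envelope(glycan_formula(g.composition))
        p = np.sort(env.probabilities)[::-1]
        top3_frac = float(p[:3].sum() / p[0])
        apex = g.resolved_apex(spec.gu_curve)
        glycans.append(
            {
                "composition": str(g.composition),
                "charges": list(g.charges),
                "adduct": g.adduct,
                "apex_rt": apex,
                "gui": gui_of_rt(apex) if spec.gu_curve is default_gu_curve else None,
                "height": g.height,
                "sigma": g.sigma,
                "analytic_area_per_charge": g.height * g.sigma * math.sqrt(2 * math.pi) * top3_frac,
                "analytic_total_area": len(g.charges)
                * g.height
                * g.sigma
                * math.sqrt(2 * math.pi)
                * top3_frac,
            }
        )
    return {
        "seed": spec.seed,
        "rt_range": list(spec.rt_range),
        "scan_interval": spec.scan_interval,
        "ladder": rungs,
        "glycans": glycans,
    }


def write_manifest(spec: SynthSpec, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(manifest(spec), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# mzML writing (minimal PSI-standard document, 64-bit uncompressed arrays)

_NS = "http://psi.hupo.org/ms/mzml"


def _cv(parent, accession, name, value="", unit=None):
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": str(value)}
    if unit is not None:
        attrs.update(
            {"unitCvRef": "UO", "unitAccession": unit[0], "unitName": unit[1]}
        )
    ET.SubElement(parent, "cvParam", attrs)


def _binary_array(parent, data: np.ndarray, accession: str, name: str):
    payload = base64.b64encode(
        struct.pack(f"<{len(data)}d", *map(float, data))
    ).decode("ascii")
    bda = ET.SubElement(parent, "binaryDataArray", {"encodedLength": str(len(payload))})
    _cv(bda, "MS:1000523", "64-bit float")
    _cv(bda, "MS:1000576", "no compression")
    _cv(bda, accession, name)
    ET.SubElement(bda, "binary").text = payload


def write_mzml(run: Run, path: str) -> None:
    """Write ``run`` as mzML, losslessly round-trippable via read_mzml."""
    ET.register_namespace("", _NS)
    root = ET.Element(f"{{{_NS}}}mzML", {"version": "1.1.0"})
    cv_list = ET.SubElement(root, "cvList", {"count": "2"})
    ET.SubElement(cv_list, "cv", {"id": "MS", "fullName": "PSI-MS", "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"})
    ET.SubElement(cv_list, "cv", {"id": "UO", "fullName": "UNIT-ONTOLOGY", "URI": "https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"})
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    softlist = ET.SubElement(root, "softwareList", {"count": "1"})
    ET.SubElement(softlist, "software", {"id": "guindex", "version": "0.1.0"})
    iconf = ET.SubElement(root, "instrumentConfigurationList", {"count": "1"})
    ET.SubElement(iconf, "instrumentConfiguration", {"id": "IC1"})
    dplist = ET.SubElement(root, "dataProcessingList", {"count": "1"})
    dp = ET.SubElement(dplist, "dataProcessing", {"id": "DP1"})
    ET.SubElement(dp, "processingMethod", {"order": "1", "softwareRef": "guindex"})
    mzrun = ET.SubElement(
        root, "run", {"id": "synthetic", "defaultInstrumentConfigurationRef": "IC1"}
    )
    slist = ET.SubElement(
        mzrun,
        "spectrumList",
        {"count": str(len(run.spectra)), "defaultDataProcessingRef": "DP1"},
    )
    for i, s in enumerate(run.spectra):
        sp = ET.SubElement(
            slist,
            "spectrum",
            {"index": str(i), "id": s.scan_id, "defaultArrayLength": str(len(s.mz))},
        )
        _cv(sp, "MS:1000511", "ms level", s.ms_level)
        _cv(sp, "MS:1000579" if s.ms_level == 1 else "MS:1000580",
            "MS1 spectrum" if s.ms_level == 1 else "MSn spectrum")
        _cv(sp, "MS:1000128" if s.is_profile else "MS:1000127",
            "profile spectrum" if s.is_profile else "centroid spectrum")
        scan_list = ET.SubElement(sp, "scanList", {"count": "1"})
        _cv(scan_list, "MS:1000795", "no combination")
        scan = ET.SubElement(scan_list, "scan")
        _cv(scan, "MS:1000016", "scan start time", repr(s.rt), unit=("UO:0000031", "minute"))
        arrays = ET.SubElement(sp, "binaryDataArrayList", {"count": "2"})
        _binary_array(arrays, s.mz, "MS:1000514", "m/z array")
        _binary_array(arrays, s.intensity, "MS:1000515", "intensity array")
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")
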