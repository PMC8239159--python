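"""mzML reading, spectrum preprocessing and fast m/z lookup.

Input is standard PSI mzML (vendor raw files must be converted
upstream, e.g. with msconvert).  The reader is a focused stream parser
for the spectrum-level subset of the standard actually needed here:
MS level, scan start time (second or minute units), centroid/profile
flag, and binary m/z / intensity arrays in 32- or 64-bit float with
zlib or no compression.  Internally m/z is in Thomson and retention
time in minutes regardless of the file's declared unit.  Peak lists
live in parallel numpy arrays sorted ascending by m/z.
"""

from __future__ import annotations

import base64
import math
import zlib
import xml.etree.ElementTree as ET
from collections import defaultdict
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .constants import NEUTRON_SPACING

__all__ = [
    "Peak",
    "Spectrum",
    "Run",
    "BucketIndex",
    "read_mzml",
    "centroid",
    "derive_charge",
    "build_index",
]


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass
class Spectrum:
    """One scan: (m/z, intensity) arrays sorted ascending by m/z."""

    scan_id: str
    rt: float  # minutes
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    is_profile: bool = False

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if len(self.mz) > 1 and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    def __len__(self) -> int:
        return len(self.mz)

    def nearest_peak(self, m: float, tol: float) -> int | None:
        """Index of the peak nearest ``m`` within ``tol`` Th, else None."""
        if len(self.mz) == 0:
            return None
        j = int(np.searchsorted(self.mz, m))
        best, dist = None, tol
        for k in (j - 1, j):
            if 0 <= k < len(self.mz):
                d = abs(self.mz[k] - m)
                if d <= dist:
                    best, dist = k, d
        return best


@dataclass
class Run:
    """A whole LC-MS acquisition: spectra sorted ascending by rt."""

    spectra: list[Spectrum]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.spectra = sorted(self.spectra, key=lambda s: s.rt)

    def ms1_spectra(self) -> list[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda_elem) -> np.ndarray:
    """Decode one <binaryDataArray>: base64, optional zlib, 32/64-bit float."""
    dtype = "<f8"
    compressed = False
    payload = ""
    for child in bda_elem:
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":  # 32-bit float
                dtype = "<f4"
            elif acc == "MS:1000523":  # 64-bit float
                dtype = "<f8"
            elif acc == "MS:1000574":  # zlib compression
                compressed = True
        elif name == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(elem) -> Spectrum:
    ms_level = 1
    is_profile = False
    rt = 0.0
    mz_arr = np.array([])
    int_arr = np.array([])
    for cv in elem.iter():
        if _local(cv.tag) != "cvParam":
            continue
        acc = cv.get("accession", "")
        if acc == "MS:1000511":
            ms_level = int(cv.get("value", "1"))
        elif acc == "MS:1000128":
            is_profile = True
        elif acc == "MS:1000016":
            rt = float(cv.get("value", "0"))
            unit = (cv.get("unitName") or cv.get("unitAccession") or "").lower()
            if "second" in unit or unit == "uo:0000010":
                rt /= 60.0
    for bda_list in elem:
        if _local(bda_list.tag) != "binaryDataArrayList":
            continue
        for bda in bda_list:
            if _local(bda.tag) != "binaryDataArray":
                continue
            accs = {c.get("accession") for c in bda if _local(c.tag) == "cvParam"}
            data = _decode_binary_array(bda)
            if "MS:1000514" in accs:
                mz_arr = data
            elif "MS:1000515" in accs:
                int_arr = data
    return Spectrum(
        scan_id=elem.get("id", ""),
        rt=rt,
        ms_level=ms_level,
        mz=mz_arr,
        intensity=int_arr,
        is_profile=is_profile,
    )


def read_mzml(path: str) -> Run:
    """Read an mzML file into a Run (spectra re-sorted by rt).

    MS2+ scans are retained in the Run but excluded from annotation by
    downstream stages.  Profile spectra are flagged for centroiding.
    """
    spectra = []
    try:
        saw_mzml_root = False
        for event, elem in ET.iterparse(str(path), events=("start", "end")):
            if event == "start":
                if _local(elem.tag) in ("mzML", "indexedmzML"):
                    saw_mzml_root = True
                continue
            if _local(elem.tag) == "spectrum":
                spec = _parse_spectrum(elem)
                if not spec.scan_id:
                    spec.scan_id = f"scan={len(spectra) + 1}"
                spectra.append(spec)
                elem.clear()
        if not saw_mzml_root:
            raise ValueError("no <mzML> root element found")
    except Exception as exc:  # noqa: BLE001 - surface file context
        raise IOError(f"cannot read mzML file {path!r}: {exc}") from exc
    return Run(spectra=spectra, metadata={"source": str(path)})


def centroid(spectrum: Spectrum) -> Spectrum:
    """Reduce a profile spectrum to centroided sticks.

    Each contiguous above-zero region is split at its internal local
    minima; every local maximum yields one stick whose m/z is the
    intensity-weighted centroid of its sub-region and whose intensity
    is the sub-region maximum.  Centroided input is returned unchanged,
    making the operation idempotent.
    """
    if not spectrum.is_profile:
        return spectrum
    mzs, ints = spectrum.mz, spectrum.intensity
    out_mz: list[float] = []
    out_int: list[float] = []
    n = len(mzs)
    i = 0
    while i < n:
        if ints[i] <= 0:
            i += 1
            continue
        j = i
        while j + 1 < n and ints[j + 1] > 0:
            j += 1
        # split [i, j] at local minima
        start = i
        for k in range(i + 1, j):
            if ints[k] < ints[k - 1] and ints[k] <= ints[k + 1]:
                _emit_centroid(mzs, ints, start, k - 1, out_mz, out_int)
                start = k
        _emit_centroid(mzs, ints, start, j, out_mz, out_int)
        i = j + 1
    return Spectrum(
        scan_id=spectrum.scan_id,
        rt=spectrum.rt,
        ms_level=spectrum.ms_level,
        mz=np.array(out_mz),
        intensity=np.array(out_int),
        is_profile=False,
    )


def _emit_centroid(mzs, ints, a, b, out_mz, out_int):
    w = ints[a : b + 1]
    out_mz.append(float(np.dot(mzs[a : b + 1], w) / w.sum()))
    out_int.append(float(w.max()))


def derive_charge(
    spectrum: Spectrum,
    peak: Peak,
    max_charge: int = 3,
    tol: float = 0.01,
) -> int | None:
    """Charge from the isotope-companion spacing test.

    Looks for a companion peak at mz + 1.00335/z; the largest z in
    [1, max_charge] with a companion wins (a z=2 envelope also shows
    1 Th spacings, so denser spacing is the more specific evidence).
    Returns None when no companion is found.
    """
    if not 1 <= max_charge <= 10:
        raise ValueError("max_charge must be in [1, 10]")
    for z in range(max_charge, 0, -1):
        if spectrum.nearest_peak(peak.mz + NEUTRON_SPACING / z, tol) is not None:
            return z
    return None


class BucketIndex:
    """Hash-bucket index over every MS1 peak of a run.

    Peaks land in bucket floor(mz / bucket_width); a tolerance query
    inspects the bucket span covering [m - tol, m + tol] (at most 3
    buckets when bucket_width >= tol) and returns exactly the peaks a
    linear scan would.
    """

    def __init__(self, run: Run, bucket_width: float):
        if bucket_width <= 0:
            raise ValueError("bucket_width must be positive")
        self.bucket_width = bucket_width
        self.run = run
        self._buckets: dict[int, list[tuple[float, float, int, int]]] = defaultdict(list)
        self._ms1_indices: list[int] = []
        for si, spec in enumerate(run.spectra):
            if spec.ms_level != 1:
                continue
            self._ms1_indices.append(si)
            for pi, m in enumerate(spec.mz):
                self._buckets[int(m // bucket_width)].append(
                    (float(m), float(spec.intensity[pi]), si, pi)
                )

    def query(self, m: float, tol: float) -> list[tuple[float, float, int, int]]:
        """All MS1 peaks with |mz - m| <= tol as (mz, intensity, spectrum_index, peak_index)."""
        if tol < 0:
            raise ValueError("tolerance must be >= 0")
        lo = int(math.floor((m - tol) / self.bucket_width))
        hi = int(math.floor((m + tol) / self.bucket_width))
        hits = []
        for b in range(lo, hi + 1):
            for rec in self._buckets.get(b, ()):
                if abs(rec[0] - m) <= tol:
                    hits.append(rec)
        hits.sort(key=lambda r: (r[2], r[3]))
        return hits


def build_index(run: Run, bucket_width: float) -> BucketIndex:
    """Index every MS1 peak of ``run`` for tolerance queries."""
    return BucketIndex(run, bucket_width)
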