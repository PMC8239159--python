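"""Shared fixtures: small synthetic runs and pipeline stages.

Everything is generated programmatically; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from guindex.calibrate import fit
from guindex.config import Config
from guindex.ladder import assign_ladder, extract_ladder_candidates
from guindex.msio import Run, Spectrum, build_index
from guindex.synth import PlantedGlycan, SynthSpec, default_spec, generate_run
from guindex.compositions import GlycanComposition


@pytest.fixture(scope="session")
def cfg() -> Config:
    return Config()


@pytest.fixture(scope="session")
def small_spec() -> SynthSpec:
    """Ladder GU 2-5 plus one glycan in a short, noise-free window."""
    return SynthSpec(
        gu_range=(2, 5),
        rt_range=(8.0, 28.0),
        glycans=(
            PlantedGlycan(GlycanComposition(2, 3, 0, 0), (1,), "proton", apex_rt=20.0, height=5e5),
        ),
        noise_density=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_run(small_spec) -> Run:
    return generate_run(small_spec)


@pytest.fixture(scope="session")
def small_index(small_run, cfg):
    return build_index(small_run, cfg.tol_da(2000.0))


@pytest.fixture(scope="session")
def small_model(small_run, small_index, cfg):
    obs = extract_ladder_candidates(small_run, small_index, cfg)
    return fit(assign_ladder(obs).fit_points(), "polynomial", 3)


@pytest.fixture(scope="session")
def default_run_noisy():
    """The generator's standard demo run (ladder, 5 glycans, decoys)."""
    return generate_run(default_spec(seed=5))


def make_spectrum(mz, intensity, rt=10.0, ms_level=1, is_profile=False, scan_id="s1"):
    return Spectrum(
        scan_id=scan_id,
        rt=rt,
        ms_level=ms_level,
        mz=np.asarray(mz, dtype=float),
        intensity=np.asarray(intensity, dtype=float),
        is_profile=is_profile,
    )


@pytest.fixture
def spectrum_factory():
    return make_spectrum
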