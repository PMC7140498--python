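"""Shared fixtures: synthetic libraries generated once per session."""

from __future__ import annotations

import pytest

from cytostab.halflife import HalfLife, classify_stability
from cytostab.standardize import CompoundRecord
from cytostab.synthetic import SimConfig, plant_matched_pairs


def record(
    smiles: str,
    t_half: float,
    inchikey: str | None = None,
    capped: bool = False,
    species: str = "human",
) -> CompoundRecord:
    """Build a CompoundRecord directly (tests that don't exercise standardization)."""
    h = HalfLife(120.0 if capped else t_half, capped)
    return CompoundRecord(
        inchikey=inchikey or smiles,
        smiles_std=smiles,
        t_half=h.value,
        capped=h.capped,
        stability_class=classify_stability(h),
        species=species,
    )


@pytest.fixture(scope="session")
def small_library():
    """~70-compound planted library for fast MMPA/apply unit tests."""
    cfg = SimConfig(
        n_series=6, series_size_range=(10, 14), baseline_log_sigma=0.3, seed=5
    )
    return plant_matched_pairs(cfg)


@pytest.fixture(scope="session")
def rule_only_library():
    """Planted fold-4 rule against assay-like noise only (no structural drift).

    40 scaffold series, every series carrying the aryl-aldehyde analogue and
    its amide swap partner; 10% measurement CV. The regime of the transform
    recovery oracle.
    """
    cfg = SimConfig(
        n_series=40,
        baseline_log_sigma=0.15,
        structure_frac=0.0,
        noise_cv=0.10,
        seed=11,
    )
    return plant_matched_pairs(cfg)


@pytest.fixture(scope="session")
def structural_library():
    """Structure-determined stability at n≈1100, 25% unstable prevalence."""
    cfg = SimConfig(n_series=40, seed=7)
    return plant_matched_pairs(cfg)
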