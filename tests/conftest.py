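"""Shared fixtures: synthetic archetypes and panels, generated at test time."""

from __future__ import annotations

import pytest

from sgrtyping.annotate import AnnotatorParams, annotate, decompose_units
from sgrtyping.simulate import (
    ARCHETYPES,
    MutationModel,
    PanelConfig,
    build_archetype,
    generate_panel,
)


@pytest.fixture(scope="session")
def archetype_records():
    """One freshly built amplicon per subgroup architecture."""
    return {name: build_archetype(spec, seed=42) for name, spec in ARCHETYPES.items()}


@pytest.fixture(scope="session")
def archetype_profiles(archetype_records):
    return {name: annotate(rec) for name, rec in archetype_records.items()}


@pytest.fixture(scope="session")
def small_panel():
    """A 16-leaf panel under the default mutation model."""
    return generate_panel(PanelConfig(n_A=8, n_B=8, seed=11, model=MutationModel(seed=11)))


@pytest.fixture(scope="session")
def small_panel_annotated(small_panel):
    params = AnnotatorParams()
    profiles = [annotate(r, params) for r in small_panel.records]
    decs = {
        r.id: decompose_units(r, p, params)
        for r, p in zip(small_panel.records, profiles)
    }
    return profiles, decs
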