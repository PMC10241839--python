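"""Shared fixtures: phantoms and a reference template bundle.

Heavy objects are session-scoped so registration-based tests share one
phantom geometry.
"""

from __future__ import annotations

import numpy as np
import pytest

from lesionloc.atlas import dilate_parcellation
from lesionloc.imaging import ct_preprocess
from lesionloc.phantom import PhantomSpec, make_phantom, ventricle_ids
from lesionloc.template import TemplateBundle


@pytest.fixture(scope="session")
def spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Coarser grid for registration unit tests (faster, same physics)."""
    return PhantomSpec(shape=(48, 48, 48), spacing=(2.5, 2.5, 2.5))


@pytest.fixture(scope="session")
def phantom(spec):
    """(scan, parcellation, brain_mask) of the canonical phantom."""
    return make_phantom(spec)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_phantom(small_spec)


@pytest.fixture(scope="session")
def ideal_bundle(spec, phantom) -> TemplateBundle:
    """Bundle whose template is the canonical phantom with its exact
    parcellation — isolates localiser accuracy from template-building and
    atlas-propagation error."""
    scan, parc, mask = phantom
    return TemplateBundle(
        template=ct_preprocess(scan),
        parcellation=dilate_parcellation(parc, 10.0),
        brain_mask=mask,
        ventricle_ids=ventricle_ids(parc),
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230529)
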