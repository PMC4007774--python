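import numpy as np
import pytest

from iconalign import (
    ROOT,
    FixtureSimilarity,
    Icon,
    Primitive,
    PrimitiveHierarchy,
    default_components,
)


@pytest.fixture
def components():
    return default_components()


@pytest.fixture
def tiny_hierarchy():
    """root -> {A -> {B, C}, D}, all central pictograms."""
    prims = [
        Primitive("A", "A", "central-pictogram", ROOT),
        Primitive("B", "B", "central-pictogram", "A"),
        Primitive("C", "C", "central-pictogram", "A"),
        Primitive("D", "D", "central-pictogram", ROOT),
    ]
    return PrimitiveHierarchy(prims)


@pytest.fixture
def thyroid_hierarchy():
    """The demonstration-pair hierarchy, built in code (independent of the
    packaged fixture files)."""
    prims = [
        Primitive("current-condition", "Current condition", "central-color", ROOT),
        Primitive("disease", "Disease", "shape", ROOT),
        Primitive("anatomy", "Anatomy", "central-pictogram", ROOT),
        Primitive("endocrine-system", "Endocrine system", "central-pictogram", "anatomy"),
        Primitive("thyroid", "Thyroid", "central-pictogram", "endocrine-system"),
        Primitive("process", "Process", "top-right-pictogram", ROOT),
        Primitive("inflammation", "Inflammation", "top-right-pictogram", "process"),
        Primitive("topright-neutral", "Neutral", "top-right-color", ROOT),
    ]
    return PrimitiveHierarchy(prims)


@pytest.fixture
def thyroid_icons():
    """The broad (endocrine system) and narrow (thyroid + inflammation)
    icons for the same subacute-thyroiditis concept."""
    mesh = Icon(
        "icon_mesh",
        {
            "central-color": {"current-condition"},
            "shape": {"disease"},
            "central-pictogram": {"endocrine-system"},
        },
    )
    icd = Icon(
        "icon_icd",
        {
            "central-color": {"current-condition"},
            "shape": {"disease"},
            "central-pictogram": {"thyroid"},
            "top-right-pictogram": {"inflammation"},
        },
    )
    return mesh, icd


@pytest.fixture
def thyroid_sim():
    return FixtureSimilarity(
        {("endocrine-system", "thyroid"): 0.85, ("disease", "inflammation"): 0.35},
        default=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240311)
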