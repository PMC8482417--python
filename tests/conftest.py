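import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_template():
    from phytomer3d.synthetic import generate_phytomer_template

    return generate_phytomer_template("below_ear")


@pytest.fixture(scope="session")
def leaf_component(default_template):
    return default_template.components["leaf"]


@pytest.fixture(scope="session")
def small_db(tmp_path_factory):
    """Four-cultivar synthetic template database, one template per type."""
    from phytomer3d.synthetic import default_profiles, generate_template_database

    root = tmp_path_factory.mktemp("db")
    return generate_template_database(default_profiles(), per_type=1, seed=7, out_dir=root)


@pytest.fixture(scope="session")
def solo_db(tmp_path_factory):
    """Database holding exactly one leaf-bearing template."""
    from phytomer3d.database import TemplateDB
    from phytomer3d.synthetic import (
        default_params_for_type,
        generate_phytomer_template,
        morphology_of,
    )

    root = tmp_path_factory.mktemp("solo_db")
    db = TemplateDB.create(root)
    params = default_params_for_type("below_ear")
    tpl = generate_phytomer_template("below_ear", params)
    db.add_entry(tpl, "solo-below_ear-000", morphology=morphology_of(params))
    db.save()
    return db


@pytest.fixture(scope="session")
def cylinder_cloud():
    """2000 points on a cylinder surface: radius 1 cm, length 20 cm, +Z axis."""
    rng = np.random.default_rng(0)
    n = 2000
    z = rng.uniform(0, 20, n)
    th = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([np.cos(th), np.sin(th), z])


def flat_leaf_phytomer(z, size=100.0, index=1, offset=(0.0, 0.0)):
    """Square horizontal leaf (two triangles) with a distant dummy internode."""
    from phytomer3d.core import Component, ComponentParams, Phytomer, SemanticMesh, Skeleton

    x0, y0 = offset
    v = np.array(
        [[x0, y0, z], [x0 + size, y0, z], [x0 + size, y0 + size, z], [x0, y0 + size, z]]
    )
    f = np.array([[0, 1, 2], [0, 2, 3]])
    leaf = Component(SemanticMesh(v, f), Skeleton(v[:2], "leaf"), ComponentParams("leaf"))
    iv = np.array([[900.0, 900.0, z], [901.0, 900.0, z], [900.0, 901.0, z]])
    inter = Component(
        SemanticMesh(iv, np.array([[0, 1, 2]])),
        Skeleton(np.array([[900.0, 900.0, z], [900.0, 900.0, z + 1.0]]), "internode"),
        ComponentParams("internode"),
    )
    return Phytomer("below_ear", {"leaf": leaf, "internode": inter}, index)
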