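import pytest

from fociq import (FieldGeometry, SceneConfig, compartment_counts,
                   example_scene, generate_field, segment_nuclei)

FULL_GEOMETRY = FieldGeometry()


@pytest.fixture(scope="session")
def quarter_geom():
    """Quarter-area field (same pixel scale); keeps image tests fast while
    presets preserve spatial densities."""
    return FieldGeometry(width_px=694, height_px=520)


@pytest.fixture(scope="session")
def wt_field(quarter_geom):
    return generate_field(example_scene("wt", geometry=quarter_geom, seed=101))


@pytest.fixture(scope="session")
def mdx_field(quarter_geom):
    return generate_field(example_scene("mdx", geometry=quarter_geom, seed=102))


@pytest.fixture(scope="session")
def wt_summary(wt_field):
    mask = segment_nuclei(wt_field.images["dapi"])
    return compartment_counts(
        {"5p": wt_field.images["5p"], "3p": wt_field.images["3p"]},
        mask, wt_field.config.geometry)


@pytest.fixture(scope="session")
def mdx_summary(mdx_field):
    mask = segment_nuclei(mdx_field.images["dapi"])
    return compartment_counts(
        {"5p": mdx_field.images["5p"], "3p": mdx_field.images["3p"]},
        mask, mdx_field.config.geometry)


@pytest.fixture(scope="session")
def cohort_result(quarter_geom):
    """Simulated two-genotype cohort: 4 animals per genotype, 4 fields each."""
    from fociq import AnimalConfig, CohortConfig, run_pipeline
    animals = tuple(
        AnimalConfig(f"{g}{i + 1}", g, example_scene(g, geometry=quarter_geom),
                     n_fields=4)
        for g in ("wt", "mdx") for i in range(4))
    return run_pipeline(CohortConfig(animals, seed=11))


def clean_scene(geometry, **overrides):
    """Noise-free, well-separated scene for exactness tests."""
    defaults = dict(geometry=geometry, background_au=(2.0, 0.0),
                    photons_per_au=None, min_separation_um=4.0,
                    n_nuclei=40.0, n_pairs=30.0, n_orphan_5p=40.0,
                    n_orphan_3p=40.0, n_large_foci=10.0, seed=0)
    defaults.update(overrides)
    return SceneConfig(**defaults)
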