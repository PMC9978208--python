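import numpy as np
import pytest

import statebias as sb


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Self-contained offline fixture: annotations, conformers, segment maps."""
    out = tmp_path_factory.mktemp("fixture")
    sb.make_annotation_fixture(
        out, n_active=12, n_inactive=12, n_kinase_variants=12, seed=7
    )
    return out


@pytest.fixture(scope="session")
def records(fixture_dir):
    return sb.load_annotations(
        sb.AnnotationSource("fixture", str(fixture_dir / "annotations.tsv"))
    )


@pytest.fixture(scope="session")
def gpcr_records(records):
    return [r for r in records if r.is_gpcr]


@pytest.fixture(scope="session")
def kinase_records(records):
    return [r for r in records if r.is_kinase]


@pytest.fixture(scope="session")
def conformer_pair():
    """(active, inactive, segments) toy GPCR pair with a 4 Å TM6 swing."""
    return sb.make_conformer_pair(sb.ConformerSpec(seed=7))


@pytest.fixture(scope="session")
def kinase_library():
    """(library, segments): toy kinase conformers for each (a_loop, ac_H)."""
    return sb.make_kinase_library(seed=7)


@pytest.fixture(scope="session")
def kinase_reference_library(kinase_library):
    library, _ = kinase_library
    return [
        (coords, {"a_loop": a_loop, "ac_helix": ac_helix})
        for (a_loop, ac_helix), coords in library.items()
    ]


@pytest.fixture(scope="session")
def toy_msa(gpcr_records):
    return sb.make_toy_msa(len(gpcr_records[0].sequence), depth=64, seed=7)


@pytest.fixture(scope="session")
def kinase_msa(kinase_records):
    return sb.make_toy_msa(len(kinase_records[0].sequence), depth=32, seed=8)


def random_cloud(rng, n=10, spread=8.0):
    return rng.normal(0.0, spread, (n, 3))


def as_coords(xyz, start=1):
    xyz = np.asarray(xyz, float)
    return sb.StructureCoords(
        np.arange(start, start + xyz.shape[0]), xyz, source="test"
    )
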