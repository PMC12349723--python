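import pytest

from pgpscreen import (LigandLibrary, LigandRecord, compute_properties,
                       example_target_manifest)


@pytest.fixture
def small_library():
    """Six parseable drug-like-ish molecules with descriptors populated."""
    recs = [
        LigandRecord("ethanol", "CCO"),
        LigandRecord("benzene", "c1ccccc1"),
        LigandRecord("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
        LigandRecord("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
        LigandRecord("ibuprofen", "CC(C)Cc1ccc(cc1)C(C)C(=O)O"),
        LigandRecord("naproxen", "COc1ccc2cc(ccc2c1)C(C)C(=O)O"),
    ]
    return compute_properties(LigandLibrary(recs))


@pytest.fixture
def manifest14():
    """The 14-box multi-conformation receptor manifest."""
    return example_target_manifest()


@pytest.fixture
def manifest_small(manifest14):
    """Three conformation pair groups with 1 DBD + 2 NBD boxes each."""
    keep = {"open_dbd", "open_nbd_1", "open_nbd_2",
            "transition_dbd", "transition_nbd_1", "transition_nbd_2",
            "closed_dbd", "closed_nbd_1", "closed_nbd_2"}
    return [t for t in manifest14 if t.target_id in keep]
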