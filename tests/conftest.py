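import numpy as np
import pytest

from v6pipe.fileio import (
    ManifestEntry,
    ReferenceDB,
    ReferenceRecord,
    SampleManifest,
    TagRecord,
    TaxonomyPath,
)


def make_ref(ref_id, seq, taxonomy, cluster=None):
    return ReferenceRecord(
        ref_id=ref_id,
        sequence=seq,
        taxonomy=TaxonomyPath.from_string(taxonomy),
        cluster_label=cluster,
    )


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_manifest():
    return SampleManifest(
        [
            ManifestEntry("a1", "adult", "spongeA", 1),
            ManifestEntry("a2", "adult", "spongeA", 2),
            ManifestEntry("l1", "larvae", "spongeA", 1),
            ManifestEntry("w1", "seawater", "", 1),
            ManifestEntry("w2", "seawater", "", 2),
        ]
    )


@pytest.fixture
def tiny_db():
    """Five references across two phyla, one labelled cluster."""
    rng = np.random.default_rng(7)
    base = random_dna(rng, 120)
    other = random_dna(rng, 120)
    near = base[:60] + "A" + base[61:]
    return ReferenceDB(
        [
            make_ref("R1", base, "PhyA;ClsA;OrdA;FamA;GenA", cluster="SC01"),
            make_ref("R2", near, "PhyA;ClsA;OrdA;FamA;GenA", cluster="SC01"),
            make_ref("R3", base[:50] + other[50:], "PhyA;ClsA;OrdB;FamB;GenB"),
            make_ref("R4", other, "PhyB;ClsB;OrdC;FamC;GenC"),
            make_ref("R5", other[:100] + base[100:], "PhyB;ClsB;OrdC;FamC;GenD"),
        ]
    )


@pytest.fixture
def tag_factory():
    counter = [0]

    def make(sequence, sample_id="s1", tag_id=None):
        counter[0] += 1
        return TagRecord(tag_id or f"t{counter[0]:04d}", sample_id, sequence)

    return make
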