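import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from exomekit import synthetic_fixtures as sf
from exomekit import variant_concord as vc
from exomekit.reference_io import consolidate_targets

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FIXTURE_SEED = 11


@pytest.fixture(scope="session")
def spec():
    return sf.FixtureSpec(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def reference(spec):
    return sf.simulate_reference(spec)


@pytest.fixture(scope="session")
def fixture_pair(spec, reference):
    genome, features = reference
    return sf.simulate_platform_pair(spec, genome, features)


@pytest.fixture(scope="session")
def fixture_files(spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    return sf.generate(spec, out)


@pytest.fixture(scope="session")
def analyzed_pair(reference, fixture_files):
    """Fixture call sets run through the full comparison pipeline:
    classify -> filter -> annotate -> restrict."""
    from exomekit import reference_io as rio

    genome, features = reference
    targets = consolidate_targets(features)
    recs_a = vc.load_vcf(fixture_files["vcf_a"])
    recs_b = vc.load_vcf(fixture_files["vcf_b"])
    pair = vc.PlatformPair("WES", "WGS", recs_a, recs_b)
    vc.classify_shared(pair)
    ann = vc.load_annotations(fixture_files["annotations_tsv"])
    for recs in (pair.variants_a, pair.variants_b):
        vc.apply_hard_filters(recs)
        vc.annotate(recs, ann)
    pair.variants_a = vc.restrict_to_targets(pair.variants_a, targets, 2)
    pair.variants_b = vc.restrict_to_targets(pair.variants_b, targets, 2)
    return pair


@pytest.fixture()
def rng():
    return np.random.default_rng(FIXTURE_SEED)


def random_genome(rng, lengths):
    bases = np.array(list("ACGT"))
    return {
        name: "".join(bases[rng.integers(0, 4, n)]) for name, n in lengths.items()
    }
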