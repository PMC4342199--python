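import pytest

from genoreport.fixtures import (
    SyntheticCaseSpec,
    generate_case,
    load_table1,
)


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def replay_bundle(tmp_path_factory, table1):
    """Synthetic case with every packaged fixture finding planted."""
    outdir = tmp_path_factory.mktemp("replay")
    spec = SyntheticCaseSpec(
        seed=11,
        n_background_variants=300,
        planted=table1,
        case_id="REPLAY",
    )
    return generate_case(spec, str(outdir))


@pytest.fixture(scope="session")
def replay_result(replay_bundle):
    from genoreport.pipeline import run_case

    return run_case(
        str(replay_bundle.vcf_path),
        str(replay_bundle.resources_dir),
        case_id="REPLAY",
    )
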