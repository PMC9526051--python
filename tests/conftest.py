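import pytest

from trafficlines import cli_io, load_catalog


@pytest.fixture(scope="session")
def catalog_lines():
    """The packaged published catalog, loaded once per session."""
    return load_catalog()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The deterministic generated fixture set (mini catalog, counts, designs)."""
    outdir = tmp_path_factory.mktemp("fixtures")
    cli_io.generate_fixtures(outdir, seed=0)
    return outdir


def by_line_id(catalog, line_id):
    return next(ln for ln in catalog if ln.line_id == line_id)
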