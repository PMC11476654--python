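import pytest

from mitocomp.genome import load_reference_table
from mitocomp.simulate import default_mitospec, gen_mitogenome


@pytest.fixture(scope="session")
def reference_table():
    """Bundled L. atlanticus annotation geometry (38 features, 16,789 bp)."""
    return load_reference_table()


@pytest.fixture(scope="session")
def synthetic_genome():
    """One synthetic mitogenome realized from the reference geometry."""
    return gen_mitogenome(default_mitospec(seed=1))
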