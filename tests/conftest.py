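import pytest

from tecensus.annotation_io import Taxonomy
from tecensus.synthetic_data import build_world, default_config

OUT_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


@pytest.fixture(scope="session")
def taxonomy():
    return Taxonomy.default()


@pytest.fixture(scope="session")
def noiseless_world():
    return build_world(default_config(seed=11))


@pytest.fixture
def write_out(tmp_path):
    """Write RepeatMasker .out content (header + given record lines) to a file."""

    def _write(*records, name="fixture.out", header=OUT_HEADER):
        path = tmp_path / name
        path.write_text(header + "".join(line + "\n" for line in records))
        return path

    return _write
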