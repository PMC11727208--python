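import pytest

from sulfoglyco import parse_composition, parse_topology

#: Core-fucosylated mono-sulfated biantennary N-glycan: the most abundant
#: sulfated structure in thyroid tissue, with a 3-O-sulfate on the terminal
#: galactose of one antenna.
SULFO_BIANTENNARY_TOPOLOGY = (
    "GlcNAc(Fuc)(GlcNAc(Man(Man(GlcNAc(Gal[S3])))(Man(GlcNAc(Gal)))))"
)


@pytest.fixture
def sulfo_biantennary():
    return parse_topology(SULFO_BIANTENNARY_TOPOLOGY)


@pytest.fixture
def oligomannose_series():
    return [parse_composition(f"Hex{n}HexNAc2") for n in range(5, 10)]
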