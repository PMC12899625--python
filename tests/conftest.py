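import pytest

from sirnakit.core import RnaStrand, SirnaDuplex, reverse_complement


def duplex_from_sense(sense_seq: str, target_start: int = 1, name: str = "d") -> SirnaDuplex:
    """Canonical 21/21 duplex: antisense = reverse complement of the window."""
    sense = RnaStrand(sense_seq, name=f"{name}_S")
    antisense = reverse_complement(RnaStrand(sense_seq, name=f"{name}_aS"))
    return SirnaDuplex(sense=sense, antisense=antisense,
                       target_start=target_start, name=name)


#: published 21-mer strands of the siPCSK9_2 duplex (plain sequences)
SIPCSK9_2_AS = "AUAAAUGUCUGCUUGCUUGGG"
SIPCSK9_2_S = "CAAGCAAGCAGACAUUUAUCU"

#: the corresponding 2'-OMe/2'-F antisense design (mN/fN notation)
SIPCSK9_2_12_AS_NOTATION = "mAfUmAfAmAfUmGmUmCmUmGfCmUfUmGfCmUfUmGfGmG"


@pytest.fixture
def engineered_site_duplex():
    from sirnakit.fixtures import ALL_CRITERIA_SITE

    return duplex_from_sense(ALL_CRITERIA_SITE, target_start=100, name="site")
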