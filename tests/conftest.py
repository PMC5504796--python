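import pytest

from lipidrules.chem import FattyAcyl
from lipidrules.library import build_library, default_classes


@pytest.fixture(scope="session")
def pc_class():
    return default_classes()["PC"]


@pytest.fixture(scope="session")
def pc38_6_isomer_library(pc_class):
    """Formate-adduct entries for the two PC(38:6) isomers used throughout
    the co-elution scenarios."""
    chains = [
        (FattyAcyl(16, 0), FattyAcyl(22, 6)),
        (FattyAcyl(18, 2), FattyAcyl(20, 4)),
    ]
    return build_library(pc_class, chains, ["[M+HCO2]-"])
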