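import pytest

from drugsig.chem import Compound, Fingerprint
from drugsig.scoring import BindingSite, Protein


def fp(*bits):
    return Fingerprint(frozenset(bits))


def compound(cid, *bits, name=""):
    return Compound(id=cid, name=name, fingerprint=fp(*bits))


def protein(pid, *sites):
    return Protein(id=pid, sites=[
        BindingSite(site_id=f"s{i}", bsscore=bs, ligand=ligand)
        for i, (bs, ligand) in enumerate(sites)
    ])


@pytest.fixture
def toy_library():
    """Three compounds over a tiny fingerprint universe."""
    return [
        compound("amp", 1, 2, 3),
        compound("bup", 2, 3, 4),
        compound("cip", 7, 8),
    ]
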