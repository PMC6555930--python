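"""Chemical fingerprints and fingerprint similarity.

A fingerprint is a finite set of non-negative integer pattern indices
(substructure keys).  Chemical similarity between a compound and a
binding-site native ligand is the Tanimoto coefficient over these sets;
throughout the package this quantity is called the *OBscore*, after the
substructure-fingerprint comparison step of the scoring pipeline.

Fingerprints may be supplied precomputed (the default, and the only mode
the core pipeline needs) or derived from SMILES through a pluggable
backend.  The SMILES backends delegate to RDKit and are optional: nothing
else in the package imports chemistry code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

__all__ = [
    "Fingerprint",
    "Compound",
    "FingerprintError",
    "tanimoto",
    "fingerprint_from_smiles",
    "obscore",
    "available_backends",
]


class FingerprintError(ValueError):
    """Raised for unparseable SMILES or malformed fingerprint encodings."""


@dataclass(frozen=True)
class Fingerprint:
    """A substructure fingerprint: a set of non-negative pattern indices.

    Set semantics — no duplicates, order-free, possibly empty.  The
    on-disk encoding is a comma-separated list of sorted indices.
    """

    bits: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        bits = frozenset(int(b) for b in self.bits)
        if any(b < 0 for b in bits):
            raise FingerprintError("fingerprint indices must be non-negative")
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return len(self.bits)

    def __bool__(self) -> bool:
        return bool(self.bits)

    def __iter__(self):
        return iter(self.bits)

    @classmethod
    def from_string(cls, text: str) -> "Fingerprint":
        """Parse the on-disk encoding: sorted, comma-separated, unique indices.

        An empty string denotes the empty fingerprint.  Unsorted or
        duplicated indices are rejected — the encoding is canonical so
        files diff cleanly.
        """
        text = text.strip()
        if not text:
            return cls(frozenset())
        try:
            values = [int(tok) for tok in text.split(",")]
        except ValueError as exc:
            raise FingerprintError(f"malformed fingerprint {text!r}: {exc}") from None
        if any(v < 0 for v in values):
            raise FingerprintError(f"negative index in fingerprint {text!r}")
        if values != sorted(set(values)):
            raise FingerprintError(
                f"fingerprint {text!r} must be sorted and duplicate-free"
            )
        return cls(frozenset(values))

    def to_string(self) -> str:
        return ",".join(str(b) for b in sorted(self.bits))


@dataclass
class Compound:
    """A drug-like small molecule with an identifier and a fingerprint."""

    id: str
    name: str = ""
    smiles: Optional[str] = None
    fingerprint: Optional[Fingerprint] = None

    def require_fingerprint(self) -> Fingerprint:
        if self.fingerprint is None:
            raise FingerprintError(f"compound {self.id!r} has no fingerprint")
        return self.fingerprint


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) similarity |a∩b| / |a∪b| in [0, 1].

    Both-empty is defined as 0: two featureless molecules carry no
    evidence of similarity.
    """
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def obscore(compound: Compound, ligand: Fingerprint) -> float:
    """Chemical similarity of a compound to a binding-site native ligand.

    Defined as the Tanimoto coefficient between the compound's
    substructure fingerprint and the ligand's.  Raises
    :class:`FingerprintError` if the compound has no fingerprint.
    """
    return tanimoto(compound.require_fingerprint(), ligand)


# --- SMILES fingerprint backends (optional; require RDKit) ----------------


def _require_rdkit():
    try:
        from rdkit import Chem, RDLogger

        RDLogger.DisableLog("rdApp.*")
        return Chem
    except ImportError as exc:  # pragma: no cover - rdkit is an extra
        raise FingerprintError(
            "SMILES fingerprinting requires the 'rdkit' extra"
        ) from exc


def _parse_smiles(smiles: str):
    Chem = _require_rdkit()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FingerprintError(f"unparseable SMILES: {smiles!r}")
    return mol


def _morgan_backend(smiles: str) -> Fingerprint:
    """Morgan circular fingerprint, radius 2, folded to 2048 bits."""
    mol = _parse_smiles(smiles)
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(frozenset(bv.GetOnBits()))


def _pattern_backend(smiles: str) -> Fingerprint:
    """RDKit topological pattern fingerprint folded to 2048 bits."""
    mol = _parse_smiles(smiles)
    Chem = _require_rdkit()
    bv = Chem.PatternFingerprint(mol, fpSize=2048)
    return Fingerprint(frozenset(bv.GetOnBits()))


_BACKENDS: dict[str, Callable[[str], Fingerprint]] = {
    "morgan": _morgan_backend,
    "pattern": _pattern_backend,
}


def available_backends() -> Iterable[str]:
    return sorted(_BACKENDS)


def fingerprint_from_smiles(smiles: str, scheme: str = "morgan") -> Fingerprint:
    """Compute a substructure fingerprint from a SMILES string.

    Deterministic for a given (smiles, scheme); SMILES spellings of the
    same molecule yield identical fingerprints under the same backend.
    ``scheme`` selects the backend ('morgan' or 'pattern').
    """
    try:
        backend = _BACKENDS[scheme]
    except KeyError:
        raise FingerprintError(
            f"unknown fingerprint scheme {scheme!r}; choose from {sorted(_BACKENDS)}"
        ) from None
    return backend(smiles)
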