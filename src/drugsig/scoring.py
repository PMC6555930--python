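"""Compound-proteome interaction matrices under four scoring schemes.

Each protein carries a list of predicted binding sites; a site pairs a
prediction-confidence value (the *BSscore*) with the substructure
fingerprint of its native ligand.  A compound-protein interaction score
combines the compound↔ligand chemical similarity (OBscore) with the
BSscore in one of four ways:

``best_ob``
    highest OBscore over the protein's site ligands;
``best_bs``
    OBscore against the ligand of the single highest-confidence site;
``best_ob_plus_bs``
    highest per-site sum OBscore + BSscore;
``best_ob_times_bs``
    highest per-site product OBscore × BSscore.

Proteins with no predicted sites score 0 under every scheme (no
interaction evidence).  Rows of the resulting matrix are the compounds'
*proteome interaction signatures*.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import Compound, Fingerprint, obscore

__all__ = [
    "BindingSite",
    "Protein",
    "InteractionMatrix",
    "SCHEMES",
    "score_best_ob",
    "score_best_bs",
    "score_best_ob_plus_bs",
    "score_best_ob_times_bs",
    "score_pair",
    "normalize_bsscores",
    "build_interaction_matrix",
    "count_all_zero_signatures",
]

SCHEMES = ("best_ob", "best_bs", "best_ob_plus_bs", "best_ob_times_bs")


@dataclass(frozen=True)
class BindingSite:
    """A predicted binding site: confidence score plus native-ligand fingerprint."""

    site_id: str
    bsscore: float
    ligand: Fingerprint = field(default_factory=Fingerprint)

    def __post_init__(self) -> None:
        if self.bsscore < 0:
            raise ValueError(f"site {self.site_id!r}: bsscore must be >= 0")


@dataclass
class Protein:
    """A protein with an ordered list of predicted binding sites."""

    id: str
    sites: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(ids) != len(set(ids)):
            raise ValueError(f"protein {self.id!r} has duplicate site ids")


def score_best_ob(compound: Compound, protein: Protein) -> float:
    """Highest OBscore between the compound and any site ligand; 0 if no sites."""
    if not protein.sites:
        return 0.0
    return max(obscore(compound, s.ligand) for s in protein.sites)


def score_best_bs(compound: Compound, protein: Protein) -> float:
    """OBscore against the highest-BSscore site's ligand; 0 if no sites.

    Ties on BSscore are broken by input order (first site wins), so the
    result is deterministic for a fixed site table.
    """
    if not protein.sites:
        return 0.0
    best = max(protein.sites, key=lambda s: s.bsscore)  # max keeps first on ties
    return obscore(compound, best.ligand)


def score_best_ob_plus_bs(compound: Compound, protein: Protein) -> float:
    """Highest per-site OBscore + BSscore; 0 if no sites."""
    if not protein.sites:
        return 0.0
    return max(obscore(compound, s.ligand) + s.bsscore for s in protein.sites)


def score_best_ob_times_bs(compound: Compound, protein: Protein) -> float:
    """Highest per-site OBscore × BSscore; 0 if no sites."""
    if not protein.sites:
        return 0.0
    return max(obscore(compound, s.ligand) * s.bsscore for s in protein.sites)


_SCORERS = {
    "best_ob": score_best_ob,
    "best_bs": score_best_bs,
    "best_ob_plus_bs": score_best_ob_plus_bs,
    "best_ob_times_bs": score_best_ob_times_bs,
}


def score_pair(compound: Compound, protein: Protein, scheme: str) -> float:
    try:
        scorer = _SCORERS[scheme]
    except KeyError:
        raise ValueError(
            f"unknown scoring scheme {scheme!r}; choose from {SCHEMES}"
        ) from None
    return scorer(compound, protein)


def normalize_bsscores(proteins: Sequence[Protein]) -> list:
    """Min-max rescale BSscores to [0, 1] across the whole site table.

    Keeps the sum/product schemes scale-balanced against the
    unit-interval OBscore.  A zero-range (constant) score column maps to
    1.0 when positive, 0.0 when identically zero.  Returns new Protein
    objects; the input is untouched.
    """
    scores = [s.bsscore for p in proteins for s in p.sites]
    if not scores:
        return [replace_protein(p, p.sites) for p in proteins]
    lo, hi = min(scores), max(scores)
    if hi == lo:
        def rescale(v: float) -> float:
            return 1.0 if v > 0 else 0.0
    else:
        def rescale(v: float) -> float:
            return (v - lo) / (hi - lo)
    out = []
    for p in proteins:
        sites = [replace(s, bsscore=rescale(s.bsscore)) for s in p.sites]
        out.append(replace_protein(p, sites))
    return out


def replace_protein(protein: Protein, sites: list) -> Protein:
    return Protein(id=protein.id, sites=list(sites))


@dataclass
class InteractionMatrix:
    """Dense compounds × proteins score matrix.

    Row i is compound i's proteome interaction signature.  ``scheme``
    records how the scores were produced ('external' for matrices loaded
    from disk or filled by a null model).
    """

    compound_ids: list
    protein_ids: list
    scores: np.ndarray
    scheme: str = "external"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.compound_ids), len(self.protein_ids)):
            raise ValueError(
                f"score matrix shape {self.scores.shape} does not match "
                f"{len(self.compound_ids)} compounds × {len(self.protein_ids)} proteins"
            )
        if np.any(self.scores < 0):
            raise ValueError("interaction scores must be non-negative")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("duplicate compound ids in matrix")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def signature(self, compound_id: str) -> np.ndarray:
        return self.scores[self.compound_ids.index(compound_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=pd.Index(self.compound_ids, name="compound_id"),
            columns=self.protein_ids,
        )


def build_interaction_matrix(
    compounds: Sequence[Compound],
    proteins: Sequence[Protein],
    scheme: str,
    normalize_bsscore: bool = True,
) -> InteractionMatrix:
    """Populate the compound-proteome interaction matrix under one scheme.

    With ``normalize_bsscore`` (default) BSscores are min-max rescaled to
    [0, 1] over the whole site table before scoring.  Deterministic for
    fixed inputs.
    """
    if not compounds or not proteins:
        raise ValueError("compound and protein libraries must be non-empty")
    if scheme not in _SCORERS:
        raise ValueError(f"unknown scoring scheme {scheme!r}; choose from {SCHEMES}")
    if normalize_bsscore:
        proteins = normalize_bsscores(proteins)
    scores = np.empty((len(compounds), len(proteins)), dtype=float)
    for i, c in enumerate(compounds):
        for j, p in enumerate(proteins):
            scores[i, j] = score_pair(c, p, scheme)
    return InteractionMatrix(
        compound_ids=[c.id for c in compounds],
        protein_ids=[p.id for p in proteins],
        scores=scores,
        scheme=scheme,
    )


def count_all_zero_signatures(matrix: InteractionMatrix):
    """Count compounds whose entire interaction signature is exactly zero.

    All-zero signatures are degenerate for RMSD ranking (they tie at
    distance 0 with each other), so the pipeline reports them as a
    diagnostic rather than dropping them.  Returns (count, compound ids).
    """
    mask = np.all(matrix.scores == 0.0, axis=1)
    ids = [cid for cid, z in zip(matrix.compound_ids, mask) if z]
    return len(ids), ids
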