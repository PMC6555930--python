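"""Synthetic scenario generator with a tunable planted chemical signal.

Generates complete pipeline inputs — a compound library, a binding-site
table and a drug-indication mapping — in which drugs approved for the
same indication share a chemical *scaffold*: a fixed set of fingerprint
bits.  Signal strength is controlled by two dials:

``noise_flip_prob``
    every bit of the fingerprint universe is flipped independently with
    this probability, applied on top of each molecule's base set.  At 0
    the drugs of an indication are bit-identical to their scaffold; at
    0.5 every fingerprint is a uniform random subset, independent of the
    scaffold — the exchangeable null.
``ligand_scaffold_coverage``
    the fraction of binding-site native ligands that borrow a random
    indication's scaffold (plus the same noise); the rest are random.
    With coverage 0 the proteome carries no indication information.

Compounds not mapped to any indication get a random base set of the
same size as a scaffold, so drugs and decoys are statistically
indistinguishable at full noise and fingerprint sizes stay comparable
across signal levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .benchmark import IndicationMapping, benchmark_all
from .chem import Compound, Fingerprint
from .controls import hypergeometric_control
from .scoring import SCHEMES, BindingSite, Protein, build_interaction_matrix
from .signatures import all_ranked_lists, compound_similarity_matrix

__all__ = ["ScenarioParams", "Scenario", "generate_scenario", "signal_sweep"]


@dataclass(frozen=True)
class ScenarioParams:
    """Knobs of the synthetic benchmark scenario.

    Defaults describe a desk-scale library with a moderate planted
    signal: 60 compounds against 40 proteins, ten indications of 2-4
    drugs each, 24-bit scaffolds in a 512-bit universe, 10% bit noise
    and half of the site ligands scaffold-bearing.
    """

    n_compounds: int = 60
    n_proteins: int = 40
    sites_per_protein: Tuple[int, int] = (1, 3)
    n_indications: int = 10
    drugs_per_indication: Tuple[int, int] = (2, 4)
    fingerprint_universe: int = 512
    scaffold_bits: int = 24
    noise_flip_prob: float = 0.1
    bsscore_distribution: object = "uniform01"  # or ("beta", alpha, beta)
    ligand_scaffold_coverage: float = 0.5
    seed: int = 0
    emit_smiles: bool = False

    def validate(self) -> None:
        if min(self.n_compounds, self.n_proteins, self.n_indications) < 1:
            raise ValueError("all counts must be >= 1")
        lo, hi = self.sites_per_protein
        if not (0 <= lo <= hi):
            raise ValueError("sites_per_protein must be a non-negative range")
        dlo, dhi = self.drugs_per_indication
        if not (1 <= dlo <= dhi):
            raise ValueError("drugs_per_indication must be a positive range")
        if self.n_indications * dlo > self.n_compounds:
            raise ValueError(
                "infeasible: n_indications × min drugs exceeds n_compounds"
            )
        if not 0.0 <= self.noise_flip_prob <= 1.0:
            raise ValueError("noise_flip_prob must be in [0, 1]")
        if not 0.0 <= self.ligand_scaffold_coverage <= 1.0:
            raise ValueError("ligand_scaffold_coverage must be in [0, 1]")
        if self.scaffold_bits > self.fingerprint_universe:
            raise ValueError("scaffold_bits cannot exceed fingerprint_universe")
        dist = self.bsscore_distribution
        if dist != "uniform01" and not (
            isinstance(dist, (tuple, list)) and len(dist) == 3 and dist[0] == "beta"
        ):
            raise ValueError(
                "bsscore_distribution must be 'uniform01' or ('beta', a, b)"
            )


@dataclass
class Scenario:
    compounds: List[Compound]
    proteins: List[Protein]
    mapping: IndicationMapping
    scaffolds: Dict[str, Fingerprint] = field(default_factory=dict)


def _flip_noise(base: frozenset, universe: int, p: float, rng) -> Fingerprint:
    """Flip every universe bit independently with probability p."""
    member = np.zeros(universe, dtype=bool)
    member[list(base)] = True
    if p > 0:
        member ^= rng.random(universe) < p
    return Fingerprint(frozenset(np.flatnonzero(member).tolist()))


def _draw_bsscore(dist, rng) -> float:
    if dist == "uniform01":
        return float(rng.uniform())
    _, a, b = dist
    return float(rng.beta(a, b))


_SMILES_ATOMS = ("C", "N", "O")


def _random_smiles(rng) -> str:
    # simple unbranched single-bond heavy-atom chain: always valence-valid
    n = int(rng.integers(3, 13))
    return "".join(rng.choice(_SMILES_ATOMS) for _ in range(n))


def generate_scenario(params: ScenarioParams) -> Scenario:
    """Generate (compound library, site table, indication mapping).

    Fully reproducible from ``params.seed``.  Every mapped drug exists in
    the library; indications get disjoint drug sets.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    U = params.fingerprint_universe

    # indication scaffolds
    ind_ids = [f"ind{i:03d}" for i in range(params.n_indications)]
    scaffolds = {
        ind: Fingerprint(
            frozenset(rng.choice(U, size=params.scaffold_bits, replace=False).tolist())
        )
        for ind in ind_ids
    }

    # assign disjoint drug sets
    dlo, dhi = params.drugs_per_indication
    sizes = rng.integers(dlo, dhi + 1, size=params.n_indications)
    while int(sizes.sum()) > params.n_compounds:  # shrink greedily if unlucky
        sizes[int(np.argmax(sizes))] -= 1
    if np.any(sizes < 2) and dlo >= 2:
        sizes = np.maximum(sizes, 2)
    if int(sizes.sum()) > params.n_compounds:
        raise ValueError("infeasible: more mapped drugs than compounds")
    comp_ids = [f"c{i:04d}" for i in range(params.n_compounds)]
    order = rng.permutation(params.n_compounds)
    mapping = IndicationMapping()
    base_sets: Dict[str, frozenset] = {}
    cursor = 0
    for ind, size in zip(ind_ids, sizes):
        for _ in range(int(size)):
            cid = comp_ids[order[cursor]]
            cursor += 1
            mapping.add(ind, cid)
            base_sets[cid] = scaffolds[ind].bits
    for i in range(cursor, params.n_compounds):  # decoys: random base of scaffold size
        cid = comp_ids[order[i]]
        base_sets[cid] = frozenset(
            rng.choice(U, size=params.scaffold_bits, replace=False).tolist()
        )

    compounds = [
        Compound(
            id=cid,
            name=f"compound {cid}",
            smiles=_random_smiles(rng) if params.emit_smiles else None,
            fingerprint=_flip_noise(base_sets[cid], U, params.noise_flip_prob, rng),
        )
        for cid in comp_ids
    ]

    # binding sites: a coverage fraction of ligands borrow indication scaffolds
    slo, shi = params.sites_per_protein
    proteins = []
    for j in range(params.n_proteins):
        n_sites = int(rng.integers(slo, shi + 1))
        sites = []
        for s in range(n_sites):
            if rng.random() < params.ligand_scaffold_coverage:
                base = scaffolds[ind_ids[int(rng.integers(params.n_indications))]].bits
            else:
                base = frozenset(
                    rng.choice(U, size=params.scaffold_bits, replace=False).tolist()
                )
            sites.append(
                BindingSite(
                    site_id=f"s{s}",
                    bsscore=_draw_bsscore(params.bsscore_distribution, rng),
                    ligand=_flip_noise(base, U, params.noise_flip_prob, rng),
                )
            )
        proteins.append(Protein(id=f"p{j:04d}", sites=sites))

    return Scenario(
        compounds=compounds, proteins=proteins, mapping=mapping, scaffolds=scaffolds
    )


def signal_sweep(
    params: ScenarioParams,
    signal_grid: Sequence[float],
    replicates: int,
    cutoffs: Sequence[int],
    schemes: Sequence[str] = SCHEMES,
) -> pd.DataFrame:
    """Benchmark every scheme across a grid of noise levels.

    For each noise level and replicate, generates a scenario, builds the
    interaction matrix under each scheme, ranks, benchmarks, and returns
    replicate-averaged metrics alongside the matched closed-form null.
    One row per (noise level, scheme, cutoff).
    """
    if len(signal_grid) == 0:
        raise ValueError("signal grid must be non-empty")
    rng = np.random.default_rng(params.seed)
    rows = []
    for noise in signal_grid:
        per_scheme = {
            s: {k: [] for k in cutoffs} for s in schemes
        }
        per_scheme_pw = {s: {k: [] for k in cutoffs} for s in schemes}
        per_scheme_cov = {s: {k: [] for k in cutoffs} for s in schemes}
        null = None
        for _ in range(replicates):
            rep_params = replace(
                params,
                noise_flip_prob=float(noise),
                seed=int(rng.integers(2**31)),
            )
            scen = generate_scenario(rep_params)
            if null is None:
                null = hypergeometric_control(
                    scen.mapping, params.n_compounds, cutoffs
                )
            for scheme in schemes:
                m = build_interaction_matrix(scen.compounds, scen.proteins, scheme)
                lists = all_ranked_lists(compound_similarity_matrix(m))
                rep = benchmark_all(lists, scen.mapping, cutoffs)
                for k in cutoffs:
                    per_scheme[scheme][k].append(rep.average_indication_accuracy[k])
                    per_scheme_pw[scheme][k].append(rep.pairwise_accuracy[k])
                    per_scheme_cov[scheme][k].append(rep.indication_coverage[k])
        for scheme in schemes:
            for k in cutoffs:
                rows.append(
                    {
                        "noise_flip_prob": float(noise),
                        "scheme": scheme,
                        "cutoff": int(k),
                        "average_indication_accuracy": float(
                            np.mean(per_scheme[scheme][k])
                        ),
                        "pairwise_accuracy": float(np.mean(per_scheme_pw[scheme][k])),
                        "indication_coverage": float(
                            np.mean(per_scheme_cov[scheme][k])
                        ),
                        "null_average_indication_accuracy": null.average_indication_accuracy[k],
                    }
                )
    return pd.DataFrame(rows)
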