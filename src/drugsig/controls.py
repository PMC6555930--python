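"""Random controls for the leave-one-out benchmark.

Two null models estimate what the benchmark metrics look like when
signature similarity carries no information about indications:

* the **uniform-random control** fills the interaction matrix with
  i.i.d. uniform(0, 1) scores, runs the full similarity → rank →
  benchmark pipeline, and averages over replicates (default 100);
* the **hypergeometric control** notes that under a random matrix the
  ranked list of a left-out drug is an exchangeable ordering of the
  other N−1 compounds, so the probability that at least one of its d−1
  associates lands in the top k is the closed form
  1 − C(N−d, k)/C(N−1, k).

The two converge as replicates grow; the Monte-Carlo control reports
standard errors so the agreement is testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Dict, Optional, Sequence

import numpy as np

from .benchmark import IndicationMapping, benchmark_all
from .scoring import InteractionMatrix
from .signatures import all_ranked_lists, compound_similarity_matrix

__all__ = [
    "ControlReport",
    "hypergeometric_capture_probability",
    "hypergeometric_control",
    "uniform_random_control",
]


@dataclass
class ControlReport:
    """Expected benchmark metrics under a null model.

    Coverage is an expectation (a real number) here, unlike the integer
    count in an observed benchmark.  Standard errors are Monte-Carlo
    only; the closed-form control leaves them None.
    """

    method: str
    cutoffs: list
    n_indications: int
    average_indication_accuracy: Dict[int, float]
    pairwise_accuracy: Dict[int, float]
    coverage: Dict[int, float]
    replicates: Optional[int] = None
    se_average_indication_accuracy: Optional[Dict[int, float]] = None
    se_pairwise_accuracy: Optional[Dict[int, float]] = None
    se_coverage: Optional[Dict[int, float]] = None

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "cutoffs": list(self.cutoffs),
            "n_indications": self.n_indications,
            "average_indication_accuracy": {
                str(k): v for k, v in self.average_indication_accuracy.items()
            },
            "pairwise_accuracy": {str(k): v for k, v in self.pairwise_accuracy.items()},
            "coverage": {str(k): v for k, v in self.coverage.items()},
        }
        if self.replicates is not None:
            out["replicates"] = self.replicates
            out["se_average_indication_accuracy"] = {
                str(k): v for k, v in self.se_average_indication_accuracy.items()
            }
            out["se_pairwise_accuracy"] = {
                str(k): v for k, v in self.se_pairwise_accuracy.items()
            }
            out["se_coverage"] = {str(k): v for k, v in self.se_coverage.items()}
        return out


def hypergeometric_capture_probability(N: int, d: int, k: int) -> float:
    """P(≥1 same-indication associate in a random top-k) for one left-out drug.

    A uniformly random ranking of the N−1 non-self compounds places the
    d−1 associates by sampling without replacement, so the count of
    associates in the top k is hypergeometric and

        P(capture) = 1 − C(N−d, k) / C(N−1, k),

    which is 1 whenever k > N−d (the non-associates cannot fill the
    cutoff).  Computed with exact integer binomials.
    """
    if N < 2:
        raise ValueError("need N >= 2 compounds")
    if not 2 <= d <= N:
        raise ValueError(f"need 2 <= d <= N, got d={d}, N={N}")
    if not 1 <= k <= N - 1:
        raise ValueError(f"need 1 <= k <= N-1, got k={k}, N={N}")
    if k > N - d:
        return 1.0
    total = comb(N - 1, k)
    return (total - comb(N - d, k)) / total


def hypergeometric_control(
    mapping: IndicationMapping, N: int, cutoffs: Sequence[int]
) -> ControlReport:
    """Closed-form expected benchmark metrics under exchangeable rankings.

    Each left-out drug of a d-drug indication captures with the same
    probability p(N, d, k), so E[100·c/d] = 100·p.  The three summaries
    aggregate exactly as in the observed benchmark.  Expected coverage
    treats the d capture events as independent (an approximation — the
    lists share one random matrix), giving Σ_I [1 − (1−p_I)^{d_I}].
    """
    bench = mapping.benchmarkable()
    if not bench:
        raise ValueError("no indication with >= 2 drugs")
    max_d = max(len(v) for v in bench.values())
    if N < max_d:
        raise ValueError(f"library size N={N} smaller than largest indication ({max_d})")
    cutoffs = [int(k) for k in cutoffs]
    counts = {ind: len(v) for ind, v in bench.items()}
    total_drugs = sum(counts.values())
    avg: Dict[int, float] = {}
    pairwise: Dict[int, float] = {}
    coverage: Dict[int, float] = {}
    for k in cutoffs:
        p = {ind: hypergeometric_capture_probability(N, d, k) for ind, d in counts.items()}
        accs = {ind: 100.0 * p[ind] for ind in p}
        avg[k] = float(np.mean(list(accs.values())))
        pairwise[k] = sum(accs[ind] * counts[ind] for ind in accs) / total_drugs
        coverage[k] = float(
            sum(1.0 - (1.0 - p[ind]) ** counts[ind] for ind in p)
        )
    return ControlReport(
        method="hypergeometric",
        cutoffs=cutoffs,
        n_indications=len(bench),
        average_indication_accuracy=avg,
        pairwise_accuracy=pairwise,
        coverage=coverage,
    )


def _control_compound_ids(
    n_compounds: int, mapping: IndicationMapping, compound_ids
) -> list:
    mapped = sorted(mapping.all_compounds())
    if compound_ids is not None:
        compound_ids = list(compound_ids)
        unknown = sorted(set(mapped) - set(compound_ids))
        if unknown:
            raise ValueError(f"mapping references unknown compounds: {unknown}")
        if len(compound_ids) != n_compounds:
            raise ValueError("compound_ids length must equal n_compounds")
        return compound_ids
    if len(mapped) > n_compounds:
        raise ValueError(
            f"mapping references {len(mapped)} compounds but n_compounds={n_compounds}"
        )
    fillers = [f"rnd{i:05d}" for i in range(n_compounds - len(mapped))]
    return mapped + fillers


def uniform_random_control(
    n_compounds: int,
    n_proteins: int,
    mapping: IndicationMapping,
    cutoffs: Sequence[int],
    replicates: int = 100,
    seed: int = 0,
    compound_ids: Optional[Sequence[str]] = None,
) -> ControlReport:
    """Monte-Carlo null: benchmark averaged over random interaction matrices.

    Each replicate fills an n_compounds × n_proteins matrix with
    independent uniform(0, 1) scores and runs similarity → rank →
    benchmark; metrics are averaged over replicates with standard errors
    of the mean.  Reproducible for a fixed seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ids = _control_compound_ids(n_compounds, mapping, compound_ids)
    cutoffs = [int(k) for k in cutoffs]
    rng = np.random.default_rng(seed)
    acc = {k: [] for k in cutoffs}
    pw = {k: [] for k in cutoffs}
    cov = {k: [] for k in cutoffs}
    n_ind = len(mapping.benchmarkable())
    for _ in range(replicates):
        matrix = InteractionMatrix(
            compound_ids=ids,
            protein_ids=[f"p{j:05d}" for j in range(n_proteins)],
            scores=rng.uniform(0.0, 1.0, size=(n_compounds, n_proteins)),
            scheme="external",
        )
        lists = all_ranked_lists(compound_similarity_matrix(matrix))
        report = benchmark_all(lists, mapping, cutoffs)
        for k in cutoffs:
            acc[k].append(report.average_indication_accuracy[k])
            pw[k].append(report.pairwise_accuracy[k])
            cov[k].append(report.indication_coverage[k])

    def mean(d):
        return {k: float(np.mean(v)) for k, v in d.items()}

    def sem(d):
        if replicates == 1:
            return {k: 0.0 for k in d}
        return {
            k: float(np.std(v, ddof=1) / np.sqrt(replicates)) for k, v in d.items()
        }

    return ControlReport(
        method="uniform_random",
        cutoffs=cutoffs,
        n_indications=n_ind,
        average_indication_accuracy=mean(acc),
        pairwise_accuracy=mean(pw),
        coverage=mean(cov),
        replicates=replicates,
        se_average_indication_accuracy=sem(acc),
        se_pairwise_accuracy=sem(pw),
        se_coverage=sem(cov),
    )
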