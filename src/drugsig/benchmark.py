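"""Leave-one-out indication-recovery benchmarking.

Every drug approved for an indication is left out in turn; it is
*captured* at cutoff k when at least one other drug of the same
indication sits within the top k of the left-out drug's ranked
similarity list.  With c captures among the indication's d drugs, the
indication accuracy is 100·c/d.  Three summaries aggregate over all
benchmarkable indications (those with ≥ 2 drugs):

average indication accuracy
    unweighted mean of per-indication accuracies;
pairwise accuracy
    drug-count-weighted mean, Σ(acc_I·d_I)/Σ(d_I);
indication coverage
    number of indications with non-zero accuracy.

Accuracy distributions from two pipelines are compared with the
two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, NamedTuple, Sequence, Set

import numpy as np
import pandas as pd

from .signatures import RankedList

__all__ = [
    "IndicationMapping",
    "BenchmarkReport",
    "KSResult",
    "indication_accuracy",
    "benchmark_all",
    "nonzero_accuracy_values",
    "ks_two_sample",
]


@dataclass
class IndicationMapping:
    """indication id → set of approved compound ids."""

    drugs_by_indication: Dict[str, Set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.drugs_by_indication = {
            ind: set(drugs) for ind, drugs in self.drugs_by_indication.items()
        }

    def add(self, indication_id: str, compound_id: str) -> None:
        self.drugs_by_indication.setdefault(indication_id, set()).add(compound_id)

    def benchmarkable(self) -> Dict[str, Set[str]]:
        """Indications with at least two approved drugs."""
        return {
            ind: drugs
            for ind, drugs in self.drugs_by_indication.items()
            if len(drugs) >= 2
        }

    def all_compounds(self) -> Set[str]:
        out: Set[str] = set()
        for drugs in self.drugs_by_indication.values():
            out |= drugs
        return out

    def __len__(self) -> int:
        return len(self.drugs_by_indication)


def indication_accuracy(
    lists: Mapping[str, RankedList], drugs: Set[str], k: int
) -> float:
    """100·c/d for one indication at cutoff k.

    c counts drugs whose ranked list contains another drug of the same
    indication at rank ≤ k; d = |drugs|.  The left-out drug is always the
    query; its associates are targets.
    """
    if len(drugs) < 2:
        raise ValueError("indication accuracy requires at least 2 drugs")
    if k < 1:
        raise ValueError("cutoff must be >= 1")
    missing = sorted(d for d in drugs if d not in lists)
    if missing:
        raise KeyError(f"drugs absent from ranked lists: {missing}")
    captured = 0
    for drug in drugs:
        associates = drugs - {drug}
        if any(e.compound_id in associates for e in lists[drug].top(k)):
            captured += 1
    return 100.0 * captured / len(drugs)


@dataclass
class BenchmarkReport:
    """Per-cutoff, per-indication accuracies plus the three summary metrics."""

    cutoffs: list
    per_indication_accuracy: Dict[int, Dict[str, float]]
    average_indication_accuracy: Dict[int, float]
    pairwise_accuracy: Dict[int, float]
    indication_coverage: Dict[int, int]
    n_benchmarked_indications: int
    drug_counts: Dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        """Long-form per-indication table: indication, n_drugs, cutoff, accuracy."""
        rows = [
            {
                "indication_id": ind,
                "n_drugs": self.drug_counts[ind],
                "cutoff": k,
                "accuracy": acc,
            }
            for k in self.cutoffs
            for ind, acc in sorted(self.per_indication_accuracy[k].items())
        ]
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "average_indication_accuracy": [
                    self.average_indication_accuracy[k] for k in self.cutoffs
                ],
                "pairwise_accuracy": [self.pairwise_accuracy[k] for k in self.cutoffs],
                "indication_coverage": [
                    self.indication_coverage[k] for k in self.cutoffs
                ],
            }
        )

    def to_dict(self) -> dict:
        return {
            "cutoffs": list(self.cutoffs),
            "n_benchmarked_indications": self.n_benchmarked_indications,
            "average_indication_accuracy": {
                str(k): v for k, v in self.average_indication_accuracy.items()
            },
            "pairwise_accuracy": {str(k): v for k, v in self.pairwise_accuracy.items()},
            "indication_coverage": {
                str(k): v for k, v in self.indication_coverage.items()
            },
            "per_indication_accuracy": {
                str(k): dict(sorted(self.per_indication_accuracy[k].items()))
                for k in self.cutoffs
            },
            "drug_counts": dict(sorted(self.drug_counts.items())),
        }


def benchmark_all(
    lists: Mapping[str, RankedList],
    mapping: IndicationMapping,
    cutoffs: Sequence[int],
) -> BenchmarkReport:
    """Run the leave-one-out benchmark at every cutoff.

    Only indications with ≥ 2 drugs are evaluated.  Drugs present in the
    mapping but absent from the ranked lists raise — silently shrinking d
    would corrupt the metric.
    """
    bench = mapping.benchmarkable()
    if not bench:
        raise ValueError("no indication with >= 2 drugs to benchmark")
    cutoffs = [int(k) for k in cutoffs]
    if any(k < 1 for k in cutoffs):
        raise ValueError("cutoffs must be positive")
    per: Dict[int, Dict[str, float]] = {}
    avg: Dict[int, float] = {}
    pairwise: Dict[int, float] = {}
    coverage: Dict[int, int] = {}
    counts = {ind: len(drugs) for ind, drugs in bench.items()}
    for k in cutoffs:
        accs = {
            ind: indication_accuracy(lists, drugs, k) for ind, drugs in bench.items()
        }
        per[k] = accs
        avg[k] = float(np.mean(list(accs.values())))
        total_drugs = sum(counts.values())
        pairwise[k] = sum(accs[ind] * counts[ind] for ind in accs) / total_drugs
        coverage[k] = sum(1 for a in accs.values() if a > 0)
    return BenchmarkReport(
        cutoffs=cutoffs,
        per_indication_accuracy=per,
        average_indication_accuracy=avg,
        pairwise_accuracy=pairwise,
        indication_coverage=coverage,
        n_benchmarked_indications=len(bench),
        drug_counts=counts,
    )


def nonzero_accuracy_values(report: BenchmarkReport, k: int) -> list:
    """Per-indication accuracies > 0 at cutoff k (unordered); length == coverage."""
    if k not in report.per_indication_accuracy:
        raise KeyError(f"cutoff {k} not in report (has {report.cutoffs})")
    return [a for a in report.per_indication_accuracy[k].values() if a > 0]


class KSResult(NamedTuple):
    statistic: float
    pvalue: float


def ks_two_sample(x: Iterable[float], y: Iterable[float]) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum over the pooled sample points of the absolute ECDF
    difference.  The p-value uses the asymptotic survival function
    Q(λ) = 2 Σ_{j≥1} (−1)^{j−1} e^{−2j²λ²} with the small-sample
    correction λ = (√n_e + 0.12 + 0.11/√n_e)·D, n_e = nm/(n+m).
    """
    x = np.sort(np.asarray(list(x), dtype=float))
    y = np.sort(np.asarray(list(y), dtype=float))
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / x.size
    cdf_y = np.searchsorted(y, grid, side="right") / y.size
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    n_e = x.size * y.size / (x.size + y.size)
    lam = (math.sqrt(n_e) + 0.12 + 0.11 / math.sqrt(n_e)) * d
    if lam <= 0:
        p = 1.0
    else:
        terms = [
            2.0 * (-1.0) ** (j - 1) * math.exp(-2.0 * j * j * lam * lam)
            for j in range(1, 101)
        ]
        p = min(1.0, max(0.0, math.fsum(terms)))
    return KSResult(statistic=d, pvalue=p)
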