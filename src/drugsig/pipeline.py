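"""End-to-end pipeline orchestration: matrix → similarity → rank → benchmark.

A :class:`PipelineConfig` fully determines a run; ``run_pipeline``
executes the stages, writes all artifacts plus a JSON manifest (config
echo, library sizes, all-zero-signature diagnostics, seed), and is
deterministic given (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

from . import io as dio
from .benchmark import benchmark_all
from .controls import hypergeometric_control, uniform_random_control
from .scoring import SCHEMES, build_interaction_matrix, count_all_zero_signatures
from .signatures import all_ranked_lists, compound_similarity_matrix

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

DEFAULT_CUTOFFS = (10, 25, 50, 100)


@dataclass
class PipelineConfig:
    compounds: str = ""
    sites: str = ""
    indications: str = ""
    out_dir: str = "drugsig_run"
    scheme: str = "best_ob"
    cutoffs: Tuple[int, ...] = DEFAULT_CUTOFFS
    normalize_bsscore: bool = True
    fingerprint_backend: str = "morgan"
    control: Optional[str] = None  # None | 'uniform' | 'hypergeom'
    replicates: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")
        ks = [int(k) for k in self.cutoffs]
        if ks != sorted(set(ks)) or any(k < 1 for k in ks):
            raise ValueError("cutoffs must be strictly increasing positive integers")
        if self.control not in (None, "uniform", "hypergeom"):
            raise ValueError("control must be 'uniform', 'hypergeom', or absent")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open(encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.cutoffs = tuple(int(k) for k in cfg.cutoffs)
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute build-matrix → similarity → rank → benchmark (→ control).

    Returns the manifest dictionary; all artifacts land in
    ``config.out_dir``.  Any stage failure raises with a stage-labelled
    message.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    compounds = stage(
        "load-compounds", dio.read_compound_library, config.compounds,
        smiles_scheme=config.fingerprint_backend,
    )
    proteins = stage(
        "load-sites", dio.read_site_table, config.sites,
        smiles_scheme=config.fingerprint_backend,
    )
    mapping = stage(
        "load-indications", dio.read_indication_mapping, config.indications,
        known_compounds=[c.id for c in compounds],
    )
    n = len(compounds)
    if any(k >= n for k in config.cutoffs):
        raise ValueError(
            f"cutoffs {config.cutoffs} must be < n_compounds ({n})"
        )
    excluded = sorted(
        ind for ind, drugs in mapping.drugs_by_indication.items() if len(drugs) < 2
    )
    log.info(
        "loaded %d compounds, %d proteins, %d indications (%d excluded, <2 drugs)",
        n, len(proteins), len(mapping), len(excluded),
    )

    matrix = stage(
        "build-matrix", build_interaction_matrix, compounds, proteins,
        config.scheme, normalize_bsscore=config.normalize_bsscore,
    )
    n_zero, zero_ids = count_all_zero_signatures(matrix)
    if n_zero:
        log.info("%d compounds have all-zero interaction signatures: %s", n_zero, zero_ids)
    dio.write_matrix(matrix, out / "matrix.tsv")

    sim = stage("similarity", compound_similarity_matrix, matrix)
    lists = stage("rank", all_ranked_lists, sim)
    dio.write_ranked_lists(lists, out / "ranked_lists.tsv")

    report = stage("benchmark", benchmark_all, lists, mapping, config.cutoffs)
    dio.write_report(report, out / "benchmark")

    control_dict = None
    if config.control == "uniform":
        ctrl = stage(
            "control", uniform_random_control, n, len(proteins), mapping,
            config.cutoffs, replicates=config.replicates, seed=config.seed,
            compound_ids=[c.id for c in compounds],
        )
        dio.write_control_report(ctrl, out / "control.json")
        control_dict = ctrl.to_dict()
    elif config.control == "hypergeom":
        ctrl = stage("control", hypergeometric_control, mapping, n, config.cutoffs)
        dio.write_control_report(ctrl, out / "control.json")
        control_dict = ctrl.to_dict()

    manifest = {
        "config": asdict(config),
        "n_compounds": n,
        "n_proteins": len(proteins),
        "n_indications": len(mapping),
        "n_benchmarked_indications": report.n_benchmarked_indications,
        "excluded_indications": excluded,
        "all_zero_signatures": {"count": n_zero, "compound_ids": zero_ids},
        "seed": config.seed,
        "summary": {
            "average_indication_accuracy": {
                str(k): report.average_indication_accuracy[k] for k in report.cutoffs
            },
            "pairwise_accuracy": {
                str(k): report.pairwise_accuracy[k] for k in report.cutoffs
            },
            "indication_coverage": {
                str(k): report.indication_coverage[k] for k in report.cutoffs
            },
        },
        "control": control_dict,
    }
    with (out / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
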