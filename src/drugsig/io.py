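"""Readers and writers for the tabular interchange formats.

All tables are UTF-8, tab-separated, header row, Unix newlines.  Floats
are serialized with repr-faithful precision so matrices round-trip to at
least 6 significant digits.  Loaders validate schema and referential
integrity and report offending records with line numbers.

Formats:

* compound library: ``compound_id  name  smiles  fingerprint`` — at
  least one of smiles / fingerprint per row; fingerprints are sorted
  comma-separated integer lists;
* binding sites: ``protein_id  site_id  bsscore  ligand_smiles
  ligand_fingerprint``;
* indication mapping: ``indication_id  compound_id``, one association
  per row;
* interaction matrix: leading ``compound_id`` column then one column per
  protein;
* ranked lists: ``query_id  rank  candidate_id  rmsd``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .benchmark import BenchmarkReport, IndicationMapping
from .chem import Compound, Fingerprint, FingerprintError, fingerprint_from_smiles
from .scoring import BindingSite, InteractionMatrix, Protein
from .signatures import RankedList, RankEntry

__all__ = [
    "read_compound_library",
    "write_compound_library",
    "read_site_table",
    "write_site_table",
    "read_indication_mapping",
    "write_indication_mapping",
    "read_matrix",
    "write_matrix",
    "read_ranked_lists",
    "write_ranked_lists",
    "write_report",
    "write_control_report",
    "plot_benchmark",
]

COMPOUND_COLUMNS = ["compound_id", "name", "smiles", "fingerprint"]
SITE_COLUMNS = ["protein_id", "site_id", "bsscore", "ligand_smiles", "ligand_fingerprint"]
MAPPING_COLUMNS = ["indication_id", "compound_id"]
RANKED_COLUMNS = ["query_id", "rank", "candidate_id", "rmsd"]


class FormatError(ValueError):
    """Schema or referential-integrity violation in an input file."""


def _read_rows(path, columns) -> List[dict]:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or list(reader.fieldnames) != columns:
            raise FormatError(
                f"{path}: expected header {columns}, got {reader.fieldnames}"
            )
        return list(reader)


def read_compound_library(
    path,
    smiles_scheme: str = "morgan",
    on_smiles_error: str = "raise",
) -> List[Compound]:
    """Load and validate a compound library.

    Rows missing a precomputed fingerprint get one computed from SMILES
    with the configured backend.  ``on_smiles_error`` is 'raise' or
    'skip' (skip drops the record with a warning via logging).
    """
    import logging

    log = logging.getLogger(__name__)
    rows = _read_rows(path, COMPOUND_COLUMNS)
    compounds: List[Compound] = []
    seen = set()
    for lineno, row in enumerate(rows, start=2):
        cid = row["compound_id"].strip()
        if not cid:
            raise FormatError(f"{path}:{lineno}: empty compound_id")
        if cid in seen:
            raise FormatError(f"{path}:{lineno}: duplicate compound_id {cid!r}")
        seen.add(cid)
        smiles = row["smiles"].strip() or None
        fp_text = row["fingerprint"].strip()
        if not smiles and not fp_text:
            raise FormatError(
                f"{path}:{lineno}: compound {cid!r} needs smiles or fingerprint"
            )
        if fp_text:
            try:
                fp = Fingerprint.from_string(fp_text)
            except FingerprintError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
        else:
            try:
                fp = fingerprint_from_smiles(smiles, smiles_scheme)
            except FingerprintError as exc:
                if on_smiles_error == "skip":
                    log.warning("%s:%d: skipping %s: %s", path, lineno, cid, exc)
                    continue
                raise FormatError(f"{path}:{lineno}: {exc}") from None
        compounds.append(
            Compound(id=cid, name=row["name"].strip(), smiles=smiles, fingerprint=fp)
        )
    return compounds


def write_compound_library(compounds: Sequence[Compound], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(COMPOUND_COLUMNS)
        for c in compounds:
            w.writerow(
                [c.id, c.name, c.smiles or "", c.fingerprint.to_string() if c.fingerprint else ""]
            )


def read_site_table(path, smiles_scheme: str = "morgan") -> List[Protein]:
    """Load the binding-site table, grouping sites by protein in file order."""
    rows = _read_rows(path, SITE_COLUMNS)
    proteins: Dict[str, Protein] = {}
    for lineno, row in enumerate(rows, start=2):
        pid = row["protein_id"].strip()
        sid = row["site_id"].strip()
        if not pid or not sid:
            raise FormatError(f"{path}:{lineno}: empty protein_id or site_id")
        try:
            bsscore = float(row["bsscore"])
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: malformed bsscore {row['bsscore']!r}"
            ) from None
        fp_text = row["ligand_fingerprint"].strip()
        smiles = row["ligand_smiles"].strip() or None
        if fp_text:
            try:
                ligand = Fingerprint.from_string(fp_text)
            except FingerprintError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
        elif smiles:
            try:
                ligand = fingerprint_from_smiles(smiles, smiles_scheme)
            except FingerprintError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
        else:
            raise FormatError(
                f"{path}:{lineno}: site {pid}/{sid} needs ligand_smiles or ligand_fingerprint"
            )
        prot = proteins.setdefault(pid, Protein(id=pid, sites=[]))
        if any(s.site_id == sid for s in prot.sites):
            raise FormatError(f"{path}:{lineno}: duplicate site {sid!r} in {pid!r}")
        try:
            site = BindingSite(site_id=sid, bsscore=bsscore, ligand=ligand)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        prot.sites.append(site)
    return list(proteins.values())


def write_site_table(proteins: Sequence[Protein], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SITE_COLUMNS)
        for p in proteins:
            for s in p.sites:
                w.writerow([p.id, s.site_id, repr(s.bsscore), "", s.ligand.to_string()])


def read_indication_mapping(
    path, known_compounds: Optional[Sequence[str]] = None
) -> IndicationMapping:
    """Load drug-indication associations; optionally check referential integrity."""
    rows = _read_rows(path, MAPPING_COLUMNS)
    known = set(known_compounds) if known_compounds is not None else None
    mapping = IndicationMapping()
    for lineno, row in enumerate(rows, start=2):
        ind = row["indication_id"].strip()
        cid = row["compound_id"].strip()
        if not ind or not cid:
            raise FormatError(f"{path}:{lineno}: empty indication_id or compound_id")
        if known is not None and cid not in known:
            raise FormatError(
                f"{path}:{lineno}: compound {cid!r} not in compound library"
            )
        mapping.add(ind, cid)
    return mapping


def write_indication_mapping(mapping: IndicationMapping, path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(MAPPING_COLUMNS)
        for ind in sorted(mapping.drugs_by_indication):
            for cid in sorted(mapping.drugs_by_indication[ind]):
                w.writerow([ind, cid])


def write_matrix(matrix: InteractionMatrix, path) -> None:
    df = matrix.to_frame()
    # str() of a float is repr-faithful in py3: full round-trip precision
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_matrix(path, scheme: str = "external") -> InteractionMatrix:
    df = pd.read_csv(
        path, sep="\t", index_col="compound_id", float_precision="round_trip"
    )
    return InteractionMatrix(
        compound_ids=[str(c) for c in df.index],
        protein_ids=[str(p) for p in df.columns],
        scores=df.to_numpy(dtype=float),
        scheme=scheme,
    )


def write_ranked_lists(lists: Dict[str, RankedList], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(RANKED_COLUMNS)
        for qid in sorted(lists):
            for e in lists[qid].entries:
                w.writerow([qid, e.rank, e.compound_id, repr(e.rmsd)])


def read_ranked_lists(path) -> Dict[str, RankedList]:
    rows = _read_rows(path, RANKED_COLUMNS)
    out: Dict[str, List[RankEntry]] = {}
    for lineno, row in enumerate(rows, start=2):
        try:
            entry = RankEntry(int(row["rank"]), row["candidate_id"], float(row["rmsd"]))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        out.setdefault(row["query_id"], []).append(entry)
    lists = {}
    for qid, entries in out.items():
        entries.sort(key=lambda e: e.rank)
        if [e.rank for e in entries] != list(range(1, len(entries) + 1)):
            raise FormatError(f"{path}: ranks for query {qid!r} are not 1..N-1")
        lists[qid] = RankedList(query_compound_id=qid, entries=entries)
    return lists


def write_report(report: BenchmarkReport, prefix) -> None:
    """Write <prefix>.tsv (per-indication + summary block) and <prefix>.json."""
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    with tsv.open("w", encoding="utf-8") as fh:
        report.to_frame().to_csv(fh, sep="\t", index=False, lineterminator="\n")
        fh.write("\n# summary\n")
        report.summary_frame().to_csv(fh, sep="\t", index=False, lineterminator="\n")
    with prefix.with_suffix(".json").open("w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")


def write_control_report(report, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")


def plot_benchmark(reports: Dict[str, BenchmarkReport], path) -> None:
    """Scatter of average vs pairwise accuracy per cutoff, one colour per pipeline."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    markers = ["^", "P", "s", "X", "o", "D"]
    for label, rep in reports.items():
        xs = [rep.average_indication_accuracy[k] for k in rep.cutoffs]
        ys = [rep.pairwise_accuracy[k] for k in rep.cutoffs]
        line = ax.plot(xs, ys, alpha=0.4)[0]
        for i, k in enumerate(rep.cutoffs):
            ax.scatter(
                xs[i], ys[i], marker=markers[i % len(markers)],
                color=line.get_color(),
                label=f"{label} top{k}" if i == 0 else None,
            )
    ax.set_xlabel("average indication accuracy (%)")
    ax.set_ylabel("pairwise accuracy (%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
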