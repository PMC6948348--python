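"""Normalisation and merging of compound-target interaction tables.

Target prediction itself (ensemble similarity / random-forest+SVM models)
happens upstream; this module consumes its outputs as plain tables, maps
protein identifiers onto canonical UniProt accessions, and unions the edge
sets of several predictors into one deduplicated interaction list.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TargetRecord",
    "InteractionRecord",
    "UNIPROT_ACCESSION_RE",
    "normalize_targets",
    "merge_interactions",
    "read_target_table",
    "read_interaction_table",
    "write_interaction_table",
]

#: UniProt accession grammar (6-character classic and 10-character forms).
UNIPROT_ACCESSION_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)


@dataclass(frozen=True)
class TargetRecord:
    """One protein target: UniProt accession, protein name, gene symbol.

    Raw (pre-normalisation) records may carry an alias in ``uniprot_id``;
    :func:`normalize_targets` guarantees the accession grammar on its output.
    """

    uniprot_id: str
    protein_name: str
    gene_symbol: str

    def __post_init__(self) -> None:
        if not self.uniprot_id:
            raise ValueError("uniprot_id must be non-empty")
        if not self.gene_symbol:
            raise ValueError(f"{self.uniprot_id}: gene_symbol must be non-empty")

    @property
    def is_canonical(self) -> bool:
        return bool(UNIPROT_ACCESSION_RE.match(self.uniprot_id))


@dataclass(frozen=True)
class InteractionRecord:
    """One compound→target edge with a provenance tag (which predictor produced it)."""

    mol_id: str
    uniprot_id: str
    source: str = "unknown"


def normalize_targets(
    raw: Sequence[TargetRecord],
    synonym_map: Mapping[str, str] | None = None,
    strict: bool = True,
) -> list[TargetRecord]:
    """Map aliases to canonical accessions and collapse duplicates.

    ``synonym_map`` sends non-canonical identifiers (e.g. ``PPARG_HUMAN``) to
    accessions. Records whose accession resolves to the same canonical id are
    collapsed to the first occurrence; the collapse count is logged. In strict
    mode an alias missing from the map *and* failing the accession grammar is
    an error listing all offenders; lenient mode drops such records with a
    warning.

    Idempotent: normalising an already-normalised list is the identity.
    """
    synonym_map = synonym_map or {}
    seen: dict[str, TargetRecord] = {}
    unresolved: list[str] = []
    collapsed = 0
    for rec in raw:
        acc = synonym_map.get(rec.uniprot_id, rec.uniprot_id)
        if not UNIPROT_ACCESSION_RE.match(acc):
            unresolved.append(rec.uniprot_id)
            continue
        if acc in seen:
            collapsed += 1
            logger.warning(
                "accession %s duplicated (gene %s collapsed into %s)",
                acc, rec.gene_symbol, seen[acc].gene_symbol,
            )
            continue
        if acc != rec.uniprot_id:
            rec = TargetRecord(acc, rec.protein_name, rec.gene_symbol)
        seen[acc] = rec
    if unresolved:
        if strict:
            raise ValueError(f"unresolvable target identifiers: {sorted(set(unresolved))}")
        logger.warning("dropped %d unresolvable target identifiers", len(unresolved))
    if collapsed:
        logger.info("normalize_targets: collapsed %d duplicate records", collapsed)
    return sorted(seen.values(), key=lambda r: r.uniprot_id)


def merge_interactions(
    tables: Iterable[Sequence[InteractionRecord]],
    combine: str = "union",
) -> list[InteractionRecord]:
    """Combine interaction tables from several predictors into one edge list.

    ``union`` (default) accumulates every (mol_id, uniprot_id) pair seen in
    any table — using several predictors to broaden target coverage;
    ``intersection`` keeps only pairs present in every table, for
    sensitivity analysis. The source field concatenates the contributing
    provenance tags with ``+``. Output is sorted by (mol_id, uniprot_id),
    making the operation commutative, associative and idempotent at the
    edge-set level.
    """
    if combine not in ("union", "intersection"):
        raise ValueError(f"combine must be 'union' or 'intersection', got {combine!r}")
    tables = [list(t) for t in tables]
    merged: dict[tuple[str, str], list[str]] = {}
    per_table_keys = []
    for table in tables:
        keys = set()
        for rec in table:
            key = (rec.mol_id, rec.uniprot_id)
            keys.add(key)
            sources = merged.setdefault(key, [])
            if rec.source not in sources:
                sources.append(rec.source)
        per_table_keys.append(keys)
    if combine == "intersection" and per_table_keys:
        keep = set.intersection(*per_table_keys)
        merged = {k: v for k, v in merged.items() if k in keep}
    return [
        InteractionRecord(mol_id, uniprot_id, "+".join(sorted(merged[(mol_id, uniprot_id)])))
        for mol_id, uniprot_id in sorted(merged)
    ]


def predict_targets_nn(
    query,
    annotated,
    known: Mapping[str, Iterable[str]],
) -> list[InteractionRecord]:
    """Nearest-neighbour baseline predictor (invented — artifact plumbing).

    For each query compound, copies the target list of the most
    Tanimoto-similar annotated compound (by descriptor vectors). This is
    deliberately naive plumbing so the pipeline can run when no external
    predictor output is available; it carries its provenance in the source
    tag and makes no accuracy claim.
    """
    from .adme import tanimoto_dl

    annotated = [c for c in annotated if c.mol_id in known and c.descriptors is not None]
    if not annotated:
        raise ValueError("no annotated compounds with descriptors to match against")
    out = []
    for cmpd in query:
        if cmpd.descriptors is None:
            raise ValueError(f"{cmpd.mol_id}: descriptors required for NN prediction")
        best = max(
            annotated,
            key=lambda a: (tanimoto_dl(cmpd.descriptors, a.descriptors), a.mol_id),
        )
        out.extend(
            InteractionRecord(cmpd.mol_id, t, "nn-baseline (invented plumbing)")
            for t in sorted(known[best.mol_id])
        )
    return out


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def read_target_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a target table (uniprot_id, protein_name, gene_symbol[, degree])."""
    df = pd.read_csv(path, sep=sep)
    required = {"uniprot_id", "protein_name", "gene_symbol"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"target table missing columns: {sorted(missing)}")
    return df


def read_interaction_table(path, sep: str = "\t") -> list[InteractionRecord]:
    """Read a three-column interaction table (mol_id, uniprot_id, source)."""
    df = pd.read_csv(path, sep=sep)
    missing = {"mol_id", "uniprot_id"} - set(df.columns)
    if missing:
        raise ValueError(f"interaction table missing columns: {sorted(missing)}")
    if "source" not in df.columns:
        df["source"] = "unknown"
    return [
        InteractionRecord(str(r.mol_id), str(r.uniprot_id), str(r.source))
        for r in df.itertuples()
    ]


def write_interaction_table(records: Iterable[InteractionRecord], path, sep: str = "\t") -> None:
    pd.DataFrame(
        [{"mol_id": r.mol_id, "uniprot_id": r.uniprot_id, "source": r.source} for r in records]
    ).to_csv(path, sep=sep, index=False)
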