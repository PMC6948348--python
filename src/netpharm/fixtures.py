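"""Packaged reference tables and deterministic stand-ins derived from them.

Two small TSVs ship with the package, transcribed from the published
three-herb formula study this pipeline operationalises:

* ``table1_targets.tsv`` — the 116 predicted protein targets of the 37
  screened compounds, with the degree of each target in the compound-target
  network (degrees sum to the network's 950 edges). One accession (P04798)
  is printed twice under two gene symbols (CYP19A1 and CYP1A1); the table
  keeps both rows, so rows are unique by gene symbol, not by accession.
* ``table2_pathways.tsv`` — the 25 enriched KEGG pathways (p <= 0.05, >= 8
  targets) with their target counts. The study's published target-pathway
  network covers 24 of them: it omits the generic catch-all hsa05200
  ("Pathways in cancer"), whose 28 targets account exactly for the
  difference between the table's degree sum (260) and the network's 232
  edges.

The compound library, interaction table and enrichment results returned by
the ``make_*`` helpers are *synthetic reconstructions*: the published
supplementary compound list and per-pathway hit lists are not machine
readable, so degrees are realised deterministically (round-robin) over
generic identifiers, keeping every printed count exact while inventing no
biology.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .adme import CompoundRecord
from .enrichment import EnrichmentResult
from .targets import InteractionRecord

__all__ = [
    "load_table1",
    "load_table2",
    "GENERIC_PATHWAYS",
    "make_fixture_compounds",
    "make_fixture_interactions",
    "make_fixture_enrichment",
]

#: Catch-all pathway excluded from the published target-pathway network.
GENERIC_PATHWAYS = ("hsa05200",)


def _data(name: str):
    return resources.files("netpharm.data").joinpath(name)


def load_table1() -> pd.DataFrame:
    """The 116-row target table (uniprot_id, protein_name, gene_symbol, degree)."""
    with resources.as_file(_data("table1_targets.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_table2() -> pd.DataFrame:
    """The 25-row enriched-pathway table (set_id, name, degree)."""
    with resources.as_file(_data("table2_pathways.tsv")) as p:
        return pd.read_csv(p, sep="\t")


#: The six screen-passing compounds shared by >= 2 herbs, with printed OB/DL
#: where the study states them. Ursolic acid is cited under two ids (MOL074
#: in the screening text, MOL047 in the network analysis); both are kept as
#: aliases and MOL047 — the id used in the network — is the canonical one
#: here. OB/DL marked (synthetic) are plausible screen-passing placeholders,
#: not published values.
_SHARED = [
    # mol_id, name, herbs, OB, DL
    ("MOL004", "beta-sitosterol", ("SMK", "CIL", "HDW"), 36.91, 0.75),
    ("MOL009", "apigenin", ("SMK", "CIL"), 45.09, 0.21),
    ("MOL022", "luteolin", ("CIL", "HDW"), 36.16, 0.25),  # OB/DL synthetic
    ("MOL023", "kaempferol", ("SMK", "CIL"), 41.88, 0.24),  # OB/DL synthetic
    ("MOL047", "ursolic acid", ("CIL", "HDW"), 37.73, 0.75),
    ("MOL101", "sitogluside_qt", ("SMK", "HDW"), 35.00, 0.62),  # OB/DL synthetic
]

URSOLIC_ACID_ALIASES = ("MOL047", "MOL074")


def make_fixture_compounds() -> list[CompoundRecord]:
    """A 37-compound screened library: the six shared compounds + 31 fillers.

    Filler compounds (synthetic) occupy single herbs with unremarkable
    passing OB/DL values; together with the shared six they form the
    compound side of the fixture network.
    """
    records = [
        CompoundRecord(m, n, frozenset(h), ob, dl) for m, n, h, ob, dl in _SHARED
    ]
    herbs = ("SMK", "CIL", "HDW")
    used = {r.mol_id for r in records}
    i = 0
    while len(records) < 37:
        i += 1
        mol_id = f"MOL{200 + i:03d}"
        if mol_id in used:
            continue
        records.append(
            CompoundRecord(
                mol_id,
                f"filler-compound-{i:02d}",
                frozenset([herbs[i % 3]]),
                ob_percent=28.0 + i,
                dl=0.30,
            )
        )
    return records


def make_fixture_interactions() -> list[InteractionRecord]:
    """Deterministic interaction table realising Table 1's target degrees.

    For each of the 116 target rows (keyed by gene symbol, which is unique;
    see module docstring on the P04798 collision) the printed degree d is
    realised by linking the target to d consecutive compounds of the
    37-compound fixture library in round-robin order. Target-side degrees —
    the published quantities — are exact; compound-side degrees are an even
    ~950/37 split, since per-compound target lists were not published.
    """
    compounds = [c.mol_id for c in make_fixture_compounds()]
    t1 = load_table1()
    edges = []
    offset = 0
    for row in t1.itertuples():
        for j in range(int(row.degree)):
            edges.append(
                InteractionRecord(compounds[(offset + j) % len(compounds)],
                                  str(row.gene_symbol), "fixture")
            )
        offset += int(row.degree)
    return edges


def make_fixture_enrichment() -> list[EnrichmentResult]:
    """Enrichment-result stand-ins realising Table 2's pathway degrees.

    Hit lists assign each pathway its printed number of targets by
    round-robin over the 116 Table-1 gene symbols (synthetic assignment —
    the published per-pathway memberships are not machine readable).
    P-values are a nominal 0.01: the table prints only pre-filtered rows
    (all p <= 0.05), so only the degree and the pass/fail status are
    faithful, which is exactly what the target-pathway network construction
    consumes.
    """
    genes = [str(g) for g in load_table1()["gene_symbol"]]
    results = []
    offset = 0
    t2 = load_table2()
    for row in t2.itertuples():
        d = int(row.degree)
        hits = tuple(genes[(offset + j) % len(genes)] for j in range(d))
        results.append(
            EnrichmentResult(
                set_id=str(row.set_id),
                name=str(row.name),
                hits=d,
                set_size=d,
                query_size=116,
                background_size=2000,
                p_value=0.01,
                fdr=0.01,  # BH over equal p-values is the identity
                hit_list=hits,
            )
        )
        offset += d
    return results
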