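"""ADME screening: oral bioavailability and Tanimoto drug-likeness filters.

A multi-herb compound library is screened for candidate bioactive molecules
on two precomputed pharmacokinetic axes:

* **OB** (oral bioavailability, percent) — the fraction of an orally
  administered dose reaching systemic circulation, supplied per compound by
  an upstream predictor.
* **DL** (drug-likeness, unitless in [0, 1]) — the Tanimoto coefficient
  between a compound's molecular-descriptor vector and the average
  descriptor vector of a reference drug library,

  ``T(A, B) = A·B / (|A|^2 + |B|^2 - A·B)``.

The default screening standard retains compounds with OB >= 25 % and
DL >= 0.18 (the drug-library average). Glycosides are conventionally listed
in deglycosylated (aglycone) form under a ``_qt`` name suffix, since the
sugar is cleaved in the gut before absorption; the suffix is metadata, not a
transformation applied here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "ReferenceProfile",
    "ScreenCriteria",
    "tanimoto_dl",
    "assign_dl",
    "apply_screen",
    "shared_compounds",
    "read_compound_table",
    "write_compound_table",
]

#: Herb codes of the three-herb formula the default fixtures describe.
HERB_CODES = ("SMK", "CIL", "HDW")


@dataclass(frozen=True)
class CompoundRecord:
    """One herbal compound with its screening properties.

    ``herb_sources`` is the set of herbs the compound occurs in; a compound
    shared by several herbs is still a single record (and later a single
    network node). ``is_deglycosylated`` is derived from the ``_qt`` naming
    convention for aglycones and never set directly.
    """

    mol_id: str
    name: str
    herb_sources: frozenset[str]
    ob_percent: float
    dl: float | None = None
    descriptors: tuple[float, ...] | None = None
    is_deglycosylated: bool = field(init=False)

    def __post_init__(self) -> None:
        if not self.herb_sources:
            raise ValueError(f"{self.mol_id}: herb_sources must be non-empty")
        if self.ob_percent < 0:
            raise ValueError(f"{self.mol_id}: ob_percent must be >= 0")
        if self.dl is not None and not 0.0 <= self.dl <= 1.0:
            raise ValueError(f"{self.mol_id}: dl must lie in [0, 1], got {self.dl}")
        object.__setattr__(
            self, "is_deglycosylated", self.name.endswith("_qt") or self.name.endswith("-qt")
        )


@dataclass(frozen=True)
class ReferenceProfile:
    """Average molecular-descriptor vector of a reference drug library.

    Plays the role of *B* in the drug-likeness Tanimoto formula; the
    provenance label records which library the average came from.
    """

    descriptors: tuple[float, ...]
    provenance: str = "mean of drug library"

    def __post_init__(self) -> None:
        if not any(self.descriptors):
            raise ValueError("reference profile must not be all-zero")


@dataclass(frozen=True)
class ScreenCriteria:
    """OB/DL screening thresholds.

    Defaults implement the standard OB >= 25 %, DL >= 0.18; ``inclusive``
    switches >= to > for sensitivity checks.
    """

    ob_min: float = 25.0
    dl_min: float = 0.18
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.ob_min < 0:
            raise ValueError("ob_min must be >= 0")
        if not 0.0 <= self.dl_min <= 1.0:
            raise ValueError("dl_min must lie in [0, 1]")


def tanimoto_dl(a: Sequence[float], b: Sequence[float]) -> float:
    """Tanimoto coefficient ``A·B / (|A|^2 + |B|^2 - A·B)`` of two descriptor vectors.

    Symmetric; equals 1 for identical non-zero vectors and 0 for orthogonal
    ones. For non-negative descriptor vectors the value lies in [0, 1].

    Raises
    ------
    ValueError
        If the vectors differ in length, are empty, or are both all-zero
        (the coefficient is then 0/0).
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.ndim != 1 or bv.ndim != 1:
        raise ValueError("descriptor vectors must be one-dimensional")
    if av.size != bv.size:
        raise ValueError(f"dimension mismatch: {av.size} vs {bv.size}")
    if av.size == 0:
        raise ValueError("descriptor vectors must have length >= 1")
    dot = float(av @ bv)
    denom = float(av @ av) + float(bv @ bv) - dot
    if denom == 0.0:
        if dot == 0.0:
            raise ValueError("Tanimoto undefined for two all-zero vectors")
        return 1.0  # identical vectors: numerator equals |A|^2 = |B|^2
    return dot / denom


def assign_dl(
    library: Iterable[CompoundRecord], reference: ReferenceProfile
) -> list[CompoundRecord]:
    """Fill in drug-likeness from descriptors where it is not already supplied.

    A record carrying both a supplied ``dl`` and descriptors keeps the
    supplied value (a warning is logged), since curated tables take
    precedence over recomputation against a possibly different reference
    library.
    """
    out = []
    for rec in library:
        if rec.dl is not None:
            if rec.descriptors is not None:
                logger.warning(
                    "%s: supplied DL %.3f kept; descriptors ignored", rec.mol_id, rec.dl
                )
            out.append(rec)
        elif rec.descriptors is not None:
            out.append(replace(rec, dl=tanimoto_dl(rec.descriptors, reference.descriptors)))
        else:
            raise ValueError(f"{rec.mol_id}: neither dl nor descriptors available")
    return out


def apply_screen(
    library: Sequence[CompoundRecord], criteria: ScreenCriteria = ScreenCriteria()
) -> list[CompoundRecord]:
    """Retain compounds meeting the OB/DL screening standard.

    Input order is preserved and the input list is left unmodified. Records
    missing DL are a hard error (screening counts must stay auditable).
    """
    retained = []
    for rec in library:
        if rec.dl is None:
            raise ValueError(f"{rec.mol_id}: dl unset; run assign_dl or supply dl")
        if criteria.inclusive:
            ok = rec.ob_percent >= criteria.ob_min and rec.dl >= criteria.dl_min
        else:
            ok = rec.ob_percent > criteria.ob_min and rec.dl > criteria.dl_min
        if ok:
            retained.append(rec)
    logger.info(
        "ADME screen (OB %s %.4g, DL %s %.4g): %d in / %d retained",
        ">=" if criteria.inclusive else ">", criteria.ob_min,
        ">=" if criteria.inclusive else ">", criteria.dl_min,
        len(library), len(retained),
    )
    return retained


def shared_compounds(
    screened: Sequence[CompoundRecord], min_herbs: int = 2
) -> list[CompoundRecord]:
    """Screened compounds occurring in at least ``min_herbs`` herbs, sorted by mol_id.

    Shared compounds are of particular interest in a multi-herb formula:
    ingredients contributed by more than one herb are candidates for
    synergistic activity.
    """
    if min_herbs < 1:
        raise ValueError("min_herbs must be >= 1")
    return sorted(
        (rec for rec in screened if len(rec.herb_sources) >= min_herbs),
        key=lambda r: r.mol_id,
    )


# ---------------------------------------------------------------------------
# Table I/O — one row per compound-herb pair, merged to records on load.
# ---------------------------------------------------------------------------

def read_compound_table(path, sep: str = "\t") -> list[CompoundRecord]:
    """Read a compound table (columns mol_id, name, herb, ob, dl[, d0, d1, ...]).

    Rows sharing a mol_id are merged into one record whose herb_sources is
    the union of the rows' herbs; their ob/dl/descriptor values must agree.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"mol_id", "name", "herb", "ob"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"compound table missing columns: {sorted(missing)}")
    desc_cols = [c for c in df.columns if c.startswith("d") and c[1:].isdigit()]
    records = []
    for mol_id, grp in df.groupby("mol_id", sort=False):
        first = grp.iloc[0]
        dl = None
        if "dl" in grp.columns and not pd.isna(first["dl"]):
            dl = float(first["dl"])
        desc = None
        if desc_cols and not grp[desc_cols].isna().any().any():
            desc = tuple(float(first[c]) for c in desc_cols)
        records.append(
            CompoundRecord(
                mol_id=str(mol_id),
                name=str(first["name"]),
                herb_sources=frozenset(str(h) for h in grp["herb"]),
                ob_percent=float(first["ob"]),
                dl=dl,
                descriptors=desc,
            )
        )
    return records


def write_compound_table(records: Iterable[CompoundRecord], path, sep: str = "\t") -> None:
    """Write records back out, one row per compound-herb pair."""
    rows = []
    for rec in records:
        for herb in sorted(rec.herb_sources):
            row = {
                "mol_id": rec.mol_id,
                "name": rec.name,
                "herb": herb,
                "ob": rec.ob_percent,
                "dl": rec.dl,
            }
            if rec.descriptors is not None:
                row.update({f"d{i}": v for i, v in enumerate(rec.descriptors)})
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
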