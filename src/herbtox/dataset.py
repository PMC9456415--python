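"""Compound table ingestion, ADME active-compound screening, and dataset persistence.

The input is a delimited table of candidate compounds per herb (name, isomeric
SMILES, oral-bioavailability and drug-likeness scores).  Screening keeps rows
passing both ADME thresholds, drops rows with missing scores or unparseable
SMILES, and merges duplicate compound names across herbs into single records
with unioned herb membership.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from typing import Iterable, Optional

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# RDKit is chatty about bad SMILES on stderr; we log rejections ourselves.
RDLogger.DisableLog("rdApp.error")

DEFAULT_OB_MIN = 0.3
DEFAULT_DL_MIN = 0.18

#: Canonical output column order for persisted datasets.
DATASET_COLUMNS = ["Molecule Name", "smiles", "OB", "DL", "Herb"]

# Accepted header spellings (lower-cased) -> canonical field.
_COLUMN_ALIASES = {
    "molecule name": "name",
    "molecule_name": "name",
    "name": "name",
    "isomeric_smiles": "smiles",
    "smiles": "smiles",
    "ob": "ob",
    "oral bioavailability": "ob",
    "dl": "dl",
    "drug-likeness": "dl",
    "drug_likeness": "dl",
    "herb": "herb",
}


def normalize_name(name: str) -> str:
    """Lowercase, trim, and collapse internal whitespace for duplicate detection."""
    return re.sub(r"\s+", " ", str(name).strip()).lower()


@dataclasses.dataclass(frozen=True)
class Compound:
    """An active compound of one or more herbs.

    ``id`` is the normalized compound name, which is unique within a dataset
    after duplicate merging.  ``ob`` and ``dl`` are the unitless
    oral-bioavailability and drug-likeness scores.
    """

    id: str
    name: str
    smiles: str
    ob: float
    dl: float
    herbs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (self.ob >= 0 and self.dl >= 0):
            raise ValueError(
                f"ob/dl must be finite non-negative, got ob={self.ob}, dl={self.dl}"
            )


@dataclasses.dataclass
class HerbDataset:
    """A collection of active compounds drawn from a set of herbs.

    ``n_total`` counts source records before duplicate merging (so that
    total-vs-distinct can be reported); ``len(compounds)`` is the distinct
    count.
    """

    herbs: list[str]
    compounds: list[Compound]
    provenance: str = ""
    n_total: int = 0

    def __post_init__(self) -> None:
        herb_set = set(self.herbs)
        for c in self.compounds:
            if not set(c.herbs) <= herb_set:
                raise ValueError(
                    f"compound {c.id!r} references herbs outside the dataset: "
                    f"{set(c.herbs) - herb_set}"
                )
        ids = [c.id for c in self.compounds]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate compound ids in dataset")
        if self.n_total == 0:
            self.n_total = len(self.compounds)

    @property
    def n_distinct(self) -> int:
        return len(self.compounds)

    def herb_counts(self) -> dict[str, int]:
        """Number of compounds per herb (a compound counts for each herb it belongs to)."""
        counts: dict[str, int] = {h: 0 for h in self.herbs}
        for c in self.compounds:
            for h in c.herbs:
                counts[h] += 1
        return counts


def _resolve_columns(df: pd.DataFrame) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for col in df.columns:
        canon = _COLUMN_ALIASES.get(str(col).strip().lower())
        if canon is not None and canon not in mapping:
            mapping[canon] = col
    missing = {"name", "smiles", "ob", "dl"} - set(mapping)
    if missing:
        raise ValueError(f"compound table is missing required columns: {sorted(missing)}")
    return mapping


def read_compound_table(path) -> pd.DataFrame:
    """Read a raw delimited compound table (comma-separated, with header)."""
    return pd.read_csv(path)


def screen_active_compounds(
    table: pd.DataFrame,
    ob_min: float = DEFAULT_OB_MIN,
    dl_min: float = DEFAULT_DL_MIN,
    provenance: str = "",
) -> HerbDataset:
    """Apply the ADME screen and build a deduplicated :class:`HerbDataset`.

    A row survives iff ``ob >= ob_min`` and ``dl >= dl_min`` (boundaries
    inclusive).  Rows with missing scores or SMILES that fail to parse are
    rejected with a logged warning rather than aborting the batch.
    """
    cols = _resolve_columns(table)
    survivors: list[Compound] = []
    herbs: list[str] = []
    for idx, row in table.iterrows():
        name = row[cols["name"]]
        smiles = row[cols["smiles"]]
        ob = pd.to_numeric(row[cols["ob"]], errors="coerce")
        dl = pd.to_numeric(row[cols["dl"]], errors="coerce")
        if pd.isna(name) or pd.isna(smiles):
            logger.warning("row %s: missing name or SMILES, rejected", idx)
            continue
        if pd.isna(ob) or pd.isna(dl):
            logger.warning("row %s (%s): missing OB/DL score, rejected", idx, name)
            continue
        if not (ob >= ob_min and dl >= dl_min):
            continue
        if Chem.MolFromSmiles(str(smiles)) is None:
            logger.warning("row %s (%s): unparseable SMILES %r, rejected", idx, name, smiles)
            continue
        herb = ""
        if "herb" in cols and not pd.isna(row[cols["herb"]]):
            herb = str(row[cols["herb"]]).strip()
        if herb and herb not in herbs:
            herbs.append(herb)
        survivors.append(
            Compound(
                id=normalize_name(str(name)),
                name=str(name).strip(),
                smiles=str(smiles).strip(),
                ob=float(ob),
                dl=float(dl),
                herbs=frozenset([herb]) if herb else frozenset(),
            )
        )
    # Pre-merge records can share an id; build the dataset through the merge path.
    merged = _merge_compound_records(survivors)
    dataset = HerbDataset(
        herbs=sorted(herbs),
        compounds=merged,
        provenance=provenance,
        n_total=len(survivors),
    )
    logger.info(
        "ADME screen (ob>=%s, dl>=%s): %d/%d rows retained, %d distinct compounds",
        ob_min, dl_min, len(survivors), len(table), dataset.n_distinct,
    )
    for herb, n in dataset.herb_counts().items():
        logger.info("  %s: %d active compounds", herb, n)
    return dataset


def _merge_compound_records(records: Iterable[Compound]) -> list[Compound]:
    merged: dict[str, Compound] = {}
    for c in records:
        key = normalize_name(c.name)
        if key not in merged:
            merged[key] = dataclasses.replace(c, id=key)
            continue
        prev = merged[key]
        if prev.smiles != c.smiles:
            logger.warning(
                "name conflict for %r: structures differ (%r vs %r); keeping first",
                c.name, prev.smiles, c.smiles,
            )
        merged[key] = dataclasses.replace(prev, herbs=prev.herbs | c.herbs)
    return list(merged.values())


def merge_duplicates(dataset: HerbDataset) -> HerbDataset:
    """Collapse duplicate compound names (case/whitespace-insensitive) into one
    record each, unioning herb memberships.  Idempotent."""
    merged = _merge_compound_records(dataset.compounds)
    out = HerbDataset(
        herbs=list(dataset.herbs),
        compounds=merged,
        provenance=dataset.provenance,
        n_total=dataset.n_total or len(dataset.compounds),
    )
    logger.info("merge_duplicates: %d total -> %d distinct", out.n_total, out.n_distinct)
    return out


def write_dataset(dataset: HerbDataset, path) -> None:
    """Persist a dataset as comma-separated text, one row per compound.

    Herb membership is serialized as a ``;``-joined sorted list in the Herb
    column so that write/read round-trips reproduce the dataset exactly.
    """
    rows = []
    for c in sorted(dataset.compounds, key=lambda c: c.id):
        rows.append(
            {
                "Molecule Name": c.name,
                "smiles": c.smiles,
                "OB": c.ob,
                "DL": c.dl,
                "Herb": ";".join(sorted(c.herbs)),
            }
        )
    pd.DataFrame(rows, columns=DATASET_COLUMNS).to_csv(path, index=False)


def read_dataset(path, provenance: Optional[str] = None) -> HerbDataset:
    """Read a dataset previously written by :func:`write_dataset`."""
    df = pd.read_csv(path, keep_default_na=False)
    compounds = []
    herbs: set[str] = set()
    for _, row in df.iterrows():
        herb_field = str(row["Herb"]) if "Herb" in df.columns else ""
        herb_set = frozenset(h for h in herb_field.split(";") if h)
        herbs |= herb_set
        compounds.append(
            Compound(
                id=normalize_name(str(row["Molecule Name"])),
                name=str(row["Molecule Name"]),
                smiles=str(row["smiles"]),
                ob=float(row["OB"]),
                dl=float(row["DL"]),
                herbs=herb_set,
            )
        )
    return HerbDataset(
        herbs=sorted(herbs),
        compounds=compounds,
        provenance=provenance or f"read from {path}",
    )
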