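"""Ligand-based virtual screening against an annotated reference library.

Each active compound is compared to every library compound using a convex
combination of two 2D fingerprint Tanimoto scores: a path-based fingerprint
and a circular radius-2 (ECFP4-like) fingerprint.  The combined score is a
declared, reproducible approximation of proprietary "combined" similarity
models; its weights are exposed in configuration.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .dataset import Compound, HerbDataset

logger = logging.getLogger(__name__)

SCHEME_PATH = "path"
SCHEME_CIRCULAR = "circular"
SCHEMES = (SCHEME_PATH, SCHEME_CIRCULAR)

#: Default per-scheme weights of the combined score.
DEFAULT_WEIGHTS: dict[str, float] = {SCHEME_PATH: 0.5, SCHEME_CIRCULAR: 0.5}

_FP_SIZE = 2048
_path_gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=_FP_SIZE)
_circular_gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=_FP_SIZE)


class SmilesParseError(ValueError):
    """Raised when a SMILES string does not parse to a molecule."""


@dataclasses.dataclass(frozen=True)
class LibraryCompound:
    """A reference-library compound identified by an external-style id."""

    cid: str
    smiles: str
    name: str = ""


@dataclasses.dataclass(frozen=True)
class SimilarityHit:
    """A scored query -> library-compound match; ``score`` lies in [0, 1]."""

    query_id: str
    cid: str
    score: float
    descriptor: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"similarity score out of [0,1]: {self.score}")


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    return mol


def fingerprint(smiles: str, scheme: str) -> frozenset[int]:
    """Bit set of the requested fingerprint scheme for a molecule.

    The molecule is canonicalized by the parser, so any SMILES spelling of
    the same structure yields the same bit set.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    mol = _mol_from_smiles(smiles)
    gen = _path_gen if scheme == SCHEME_PATH else _circular_gen
    return frozenset(gen.GetFingerprint(mol).GetOnBits())


def tanimoto(a: frozenset[int], b: frozenset[int]) -> float:
    """|a ∩ b| / |a ∪ b|.  Undefined (raises) when both sets are empty."""
    if not a and not b:
        raise ValueError("Tanimoto undefined for two empty bit sets")
    return len(a & b) / len(a | b)


def combined_score(
    query: Compound | str,
    hit: LibraryCompound | str,
    weights: Optional[Mapping[str, float]] = None,
) -> SimilarityHit:
    """Convex combination of per-scheme Tanimoto scores for a query/hit pair.

    ``weights`` maps scheme name to a nonnegative weight; weights must sum
    to 1 (default: equal weights over both schemes).
    """
    weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be nonnegative")
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    q_smiles = query.smiles if isinstance(query, Compound) else query
    h_smiles = hit.smiles if isinstance(hit, LibraryCompound) else hit
    score = 0.0
    for scheme, w in weights.items():
        if w == 0:
            continue
        score += w * tanimoto(fingerprint(q_smiles, scheme), fingerprint(h_smiles, scheme))
    label = "+".join(f"{s}:{weights[s]:g}" for s in sorted(weights))
    return SimilarityHit(
        query_id=query.id if isinstance(query, Compound) else "query",
        cid=hit.cid if isinstance(hit, LibraryCompound) else "hit",
        score=min(score, 1.0),
        descriptor=label,
    )


def screen_library(
    dataset: HerbDataset,
    library: Sequence[LibraryCompound],
    floor: float = 0.0,
    weights: Optional[Mapping[str, float]] = None,
) -> list[SimilarityHit]:
    """Score every dataset compound against every library compound.

    Hits with score >= ``floor`` are returned sorted per query by descending
    score, ties broken by ascending cid, so output is deterministic.
    """
    if not 0.0 <= floor <= 1.0:
        raise ValueError(f"floor must be in [0,1], got {floor}")
    if not library:
        logger.warning("screen_library called with an empty library")
        return []
    # Pre-compute library fingerprints once.
    weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
    lib_fps: dict[str, dict[str, frozenset[int]]] = {}
    for lc in library:
        lib_fps[lc.cid] = {s: fingerprint(lc.smiles, s) for s in weights if weights[s] > 0}
    hits: list[SimilarityHit] = []
    label = "+".join(f"{s}:{weights[s]:g}" for s in sorted(weights))
    for comp in dataset.compounds:
        q_fps = {s: fingerprint(comp.smiles, s) for s in weights if weights[s] > 0}
        per_query: list[SimilarityHit] = []
        for lc in library:
            score = sum(
                weights[s] * tanimoto(q_fps[s], lib_fps[lc.cid][s]) for s in q_fps
            )
            score = min(score, 1.0)
            if score >= floor:
                per_query.append(
                    SimilarityHit(query_id=comp.id, cid=lc.cid, score=score, descriptor=label)
                )
        per_query.sort(key=lambda h: (-h.score, h.cid))
        hits.extend(per_query)
    return hits


def read_library(path) -> list[LibraryCompound]:
    """Read a reference library from delimited text with cid, smiles[, name]."""
    df = pd.read_csv(path, dtype={"cid": str})
    out = []
    for _, row in df.iterrows():
        out.append(
            LibraryCompound(
                cid=str(row["cid"]),
                smiles=str(row["smiles"]),
                name=str(row["name"]) if "name" in df.columns and not pd.isna(row["name"]) else "",
            )
        )
    cids = [c.cid for c in out]
    if len(cids) != len(set(cids)):
        raise ValueError("duplicate cid in library")
    return out


def write_hits(hits: Iterable[SimilarityHit], path) -> None:
    pd.DataFrame(
        [(h.query_id, h.cid, h.score, h.descriptor) for h in hits],
        columns=["query_id", "cid", "score", "descriptor"],
    ).to_csv(path, index=False)


def read_hits(path) -> list[SimilarityHit]:
    df = pd.read_csv(path, dtype={"cid": str, "query_id": str})
    return [
        SimilarityHit(
            query_id=str(r.query_id), cid=str(r.cid), score=float(r.score),
            descriptor=str(r.descriptor),
        )
        for r in df.itertuples()
    ]
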