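"""Verdict aggregation above the similarity threshold, interaction-text
classification, and interaction-network construction/export."""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .calibration import (
    AMBIGUOUS,
    DEFAULT_THRESHOLD,
    NA,
    NONTOXIC,
    TOXIC,
    AnnotationRecord,
    Verdict,
)
from .simscreen import SimilarityHit

logger = logging.getLogger(__name__)

VERDICT_LABELS = {TOXIC: "TOXIC", AMBIGUOUS: "AMBIGUOUS", NONTOXIC: "NONTOXIC", NA: "NA"}

# The seven interaction activity categories.
ENHANCED_RADIOTHERAPY = "Enhanced radiotherapy"
METASTASIS_INHIBITION = "Metastasis inhibition"
CARCINOGENESIS_INHIBITION = "Carcinogenesis inhibition"
ENHANCED_CHEMOTHERAPY = "Enhanced chemotherapy"
ENHANCED_GENOTOXICITY = "Enhanced genotoxicity"
ENHANCED_BIOAVAILABILITY = "Enhanced bioavailability"
WEAKENED_TARGET_THERAPY = "Weakened target therapy"
CATEGORIES = (
    ENHANCED_RADIOTHERAPY,
    METASTASIS_INHIBITION,
    CARCINOGENESIS_INHIBITION,
    ENHANCED_CHEMOTHERAPY,
    ENHANCED_GENOTOXICITY,
    ENHANCED_BIOAVAILABILITY,
    WEAKENED_TARGET_THERAPY,
)

SYNERGISTIC = "synergistic"
ANTAGONISTIC = "antagonistic"


@dataclasses.dataclass
class EndpointPrediction:
    """Aggregated toxicity prediction for one compound/endpoint pair.

    ``indicators`` are the (cid, score, verdict) triples with score strictly
    above the threshold and an informative verdict.
    """

    query_id: str
    endpoint: str
    verdict: Verdict
    indicators: list[tuple[str, float, Verdict]]
    threshold: float

    @property
    def verdict_label(self) -> str:
        return VERDICT_LABELS[self.verdict]


@dataclasses.dataclass(frozen=True)
class InteractionEdge:
    """A predicted interaction between an active compound and a partner agent."""

    compound: str
    partner: str
    category: str
    direction: str
    evidence_cid: str = ""
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown interaction category: {self.category!r}")
        if self.direction not in (SYNERGISTIC, ANTAGONISTIC):
            raise ValueError(f"unknown direction: {self.direction!r}")


def predict_endpoint(
    query_id: str,
    endpoint: str,
    hits: Sequence[SimilarityHit],
    annotations: Iterable[AnnotationRecord],
    threshold: float = DEFAULT_THRESHOLD,
) -> EndpointPrediction:
    """Aggregate indicator verdicts into a per-compound endpoint prediction.

    Indicators are hits for ``query_id`` with score strictly above the
    threshold, joined to informative annotations for ``endpoint``.  The
    aggregate is toxic on a strict majority of +1 verdicts over all others,
    non-toxic when every indicator is -1, ambiguous on any other mix, and NA
    with no indicators at all.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0,1], got {threshold}")
    verdict_by_cid: dict[str, Verdict] = {}
    for rec in annotations:
        if rec.endpoint == endpoint and rec.verdict is not NA:
            verdict_by_cid[rec.cid] = rec.verdict
    indicators = [
        (h.cid, h.score, verdict_by_cid[h.cid])
        for h in hits
        if h.query_id == query_id and h.score > threshold and h.cid in verdict_by_cid
    ]
    verdicts = [v for _, _, v in indicators]
    if not verdicts:
        verdict: Verdict = NA
    elif verdicts.count(TOXIC) > len(verdicts) - verdicts.count(TOXIC):
        verdict = TOXIC
    elif all(v == NONTOXIC for v in verdicts):
        verdict = NONTOXIC
    else:
        verdict = AMBIGUOUS
    return EndpointPrediction(
        query_id=query_id,
        endpoint=endpoint,
        verdict=verdict,
        indicators=indicators,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# Interaction text handling

# Dotted abbreviations that must not terminate a sentence during splitting.
_ABBREVIATIONS = (
    "e.g.", "i.e.", "et al.", "vs.", "cf.", "ca.", "approx.", "fig.", "Fig.",
    "no.", "No.", "i.p.", "p.o.", "i.v.", "spp.", "sp.", "wt.",
)
_SENTINEL = "\x00"


def split_interactions(payload: str, separator: Optional[str] = None) -> list[str]:
    """Split a free-text interactions payload into single-interaction rows.

    With an explicit ``separator`` the payload is split on it verbatim;
    otherwise sentence boundaries (., !, ? or ; followed by whitespace) are
    used, with common dotted abbreviations protected.  Original statement
    order is preserved; empty fragments are dropped.
    """
    if not payload or not payload.strip():
        return []
    if separator is not None:
        parts = payload.split(separator)
    else:
        protected = payload
        for abbr in _ABBREVIATIONS:
            protected = protected.replace(abbr, abbr.replace(".", _SENTINEL))
        parts = re.split(r"(?<=[.!?;])\s+", protected)
        parts = [p.replace(_SENTINEL, ".") for p in parts]
    return [p.strip() for p in parts if p.strip()]


#: Default keyword lexicon: first matching rule assigns (category, direction).
#: Patterns are case-insensitive regexes; order matters (more specific first).
#: Edit or replace via ``load_lexicon`` — nothing here is learned or hidden.
DEFAULT_LEXICON: list[dict[str, object]] = [
    {
        "pattern": r"(weaken\w*|attenuat\w*|reduc\w*|antagoni\w*)[^.;]*target(ed)? therap|target(ed)? therap\w*[^.;]*(weaken\w*|attenuat\w*)",
        "category": WEAKENED_TARGET_THERAPY,
        "direction": ANTAGONISTIC,
        "alert": False,
    },
    {
        "pattern": r"genotoxic",
        "category": ENHANCED_GENOTOXICITY,
        "direction": SYNERGISTIC,
        "alert": True,
    },
    {
        "pattern": r"ionizing radiation|radiotherap|radiosensiti|radiation therap",
        "category": ENHANCED_RADIOTHERAPY,
        "direction": SYNERGISTIC,
        "alert": False,
    },
    {
        "pattern": r"(inhibit\w*|suppress\w*|prevent\w*|reduc\w*)[^.;]*metastas|metastas\w*[^.;]*(inhibit\w*|suppress\w*)|anti-?metastatic",
        "category": METASTASIS_INHIBITION,
        "direction": SYNERGISTIC,
        "alert": False,
    },
    {
        "pattern": r"(inhibit\w*|suppress\w*|prevent\w*|protect\w*)[^.;]*(carcinogen\w*|tumorigen\w*|tumor induction)|(carcinogen\w*|tumorigen\w*)[^.;]*(inhibit\w*|suppress\w*)",
        "category": CARCINOGENESIS_INHIBITION,
        "direction": SYNERGISTIC,
        "alert": False,
    },
    {
        "pattern": r"bioavailab",
        "category": ENHANCED_BIOAVAILABILITY,
        "direction": SYNERGISTIC,
        "alert": False,
    },
    {
        "pattern": r"chemotherap|chemosensiti|(synergi\w*|potentiat\w*|enhanc\w*|sensitiz\w*)[^.;]*(cytotoxic|anticancer|anti-cancer|antitumor|anti-tumor)",
        "category": ENHANCED_CHEMOTHERAPY,
        "direction": SYNERGISTIC,
        "alert": False,
    },
]


def load_lexicon(path) -> list[dict[str, object]]:
    """Load a classification lexicon from a JSON file (list of rule objects
    with pattern/category/direction and optional alert flag)."""
    with open(path) as fh:
        rules = json.load(fh)
    for rule in rules:
        if rule["category"] not in CATEGORIES:
            raise ValueError(f"lexicon rule has unknown category: {rule['category']!r}")
    return rules


@dataclasses.dataclass(frozen=True)
class Classification:
    category: str
    direction: str
    alert: bool = False


def classify_interaction(
    row: str, lexicon: Optional[list[dict[str, object]]] = None
) -> Optional[Classification]:
    """Assign (category, direction) by the first matching lexicon rule.

    Returns None for rows matching no rule; callers must surface these for
    manual review rather than dropping them.
    """
    rules = DEFAULT_LEXICON if lexicon is None else lexicon
    for rule in rules:
        if re.search(str(rule["pattern"]), row, flags=re.IGNORECASE):
            return Classification(
                category=str(rule["category"]),
                direction=str(rule["direction"]),
                alert=bool(rule.get("alert", False)),
            )
    return None


def classify_interaction_rows(
    rows: Sequence[str], lexicon: Optional[list[dict[str, object]]] = None
) -> tuple[list[tuple[str, Classification]], list[str]]:
    """Classify many rows; returns (classified, unclassified) partitions whose
    sizes always sum to ``len(rows)``."""
    classified, unclassified = [], []
    for row in rows:
        c = classify_interaction(row, lexicon)
        if c is None:
            unclassified.append(row)
        else:
            classified.append((row, c))
    if unclassified:
        logger.info("%d interaction rows left unclassified for manual review", len(unclassified))
    return classified, unclassified


# ---------------------------------------------------------------------------
# Network construction

def build_interaction_network(edges: Sequence[InteractionEdge]) -> nx.MultiGraph:
    """Build a bipartite compound/partner graph from interaction edges.

    Exact duplicate edges (same compound, partner, category, direction) are
    collapsed into one edge with a ``multiplicity`` attribute.
    """
    g = nx.MultiGraph()
    for e in edges:
        g.add_node(e.compound, kind="compound")
        g.add_node(e.partner, kind="partner")
        key = f"{e.category}|{e.direction}"
        if g.has_edge(e.compound, e.partner, key=key):
            g[e.compound][e.partner][key]["multiplicity"] += 1
        else:
            g.add_edge(
                e.compound,
                e.partner,
                key=key,
                category=e.category,
                direction=e.direction,
                evidence_cid=e.evidence_cid,
                score=e.score,
                multiplicity=1,
            )
    logger.info(
        "interaction network: %d nodes, %d unique edges", g.number_of_nodes(), g.number_of_edges()
    )
    return g


def _sorted_edges(g: nx.MultiGraph):
    return sorted(g.edges(keys=True, data=True), key=lambda e: (e[0], e[1], e[2]))


def write_sif(g: nx.MultiGraph, path) -> None:
    """Cytoscape SIF export: source <tab> relation <tab> target, sorted."""
    with open(path, "w") as fh:
        for u, v, key, data in _sorted_edges(g):
            relation = f"{data['category']} ({data['direction']})".replace("\t", " ")
            src, dst = (u, v) if g.nodes[u].get("kind") == "compound" else (v, u)
            fh.write(f"{src}\t{relation}\t{dst}\n")
        # isolated nodes still need a line to appear in Cytoscape
        for n in sorted(g.nodes):
            if g.degree(n) == 0:
                fh.write(f"{n}\n")


def write_graphml(g: nx.MultiGraph, path) -> None:
    # GraphML writers need a deterministic node order for regression tests.
    h = nx.MultiGraph()
    h.add_nodes_from(sorted(g.nodes(data=True)))
    for u, v, key, data in _sorted_edges(g):
        h.add_edge(u, v, key=key, **data)
    nx.write_graphml(h, path)


def write_node_table(g: nx.MultiGraph, path) -> None:
    rows = [
        {"node": n, "kind": g.nodes[n].get("kind", ""), "degree": g.degree(n)}
        for n in sorted(g.nodes)
    ]
    pd.DataFrame(rows, columns=["node", "kind", "degree"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# File interfaces

def write_predictions(predictions: Iterable[EndpointPrediction], path) -> None:
    rows = [
        {
            "query_id": p.query_id,
            "endpoint": p.endpoint,
            "verdict": p.verdict_label,
            "n_indicators": len(p.indicators),
            "threshold": p.threshold,
        }
        for p in predictions
    ]
    pd.DataFrame(
        rows, columns=["query_id", "endpoint", "verdict", "n_indicators", "threshold"]
    ).to_csv(path, index=False)


def read_annotations(path) -> list[AnnotationRecord]:
    """Read (cid, endpoint, verdict[, text, source]) annotation rows."""
    from .calibration import parse_verdict

    df = pd.read_csv(path, dtype={"cid": str}, keep_default_na=False)
    return [
        AnnotationRecord(
            cid=str(r.cid),
            endpoint=str(r.endpoint),
            verdict=parse_verdict(r.verdict),
            text=str(getattr(r, "text", "")),
            source=str(getattr(r, "source", "")),
        )
        for r in df.itertuples()
    ]


def read_interaction_edges(path) -> list[InteractionEdge]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        InteractionEdge(
            compound=r.compound,
            partner=r.partner,
            category=r.category,
            direction=r.direction,
            evidence_cid=getattr(r, "evidence_cid", ""),
            score=float(getattr(r, "score", 1.0) or 1.0),
        )
        for r in df.itertuples()
    ]
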