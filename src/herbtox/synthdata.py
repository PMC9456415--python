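"""Deterministic synthetic fixtures for every pipeline stage.

All generators are pure functions of their parameters and seed: compound
sets built from a validated SMILES template pool, annotation retrieve
sequences with planted first-elusive/first-contrast structure, interaction
text payloads, and two-drug dose-response matrices generated from Hill
margins with a planted ZIP deviation field.
"""

from __future__ import annotations

import dataclasses
import functools
import itertools
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem

from .calibration import AMBIGUOUS, NA, NONTOXIC, TOXIC, RetrieveSequence, Verdict
from .dataset import Compound, HerbDataset, normalize_name
from .simscreen import LibraryCompound
from .synergy import DoseResponseMatrix

_SUBSTITUENTS = [
    "C", "CC", "CCC", "CCCC", "O", "OC", "OCC", "N", "NC", "Cl", "Br", "F",
    "C(=O)O", "C(=O)N", "C(=O)C", "C=C", "S", "SC", "OC(=O)C", "C(C)C",
]
_ONE_SLOT = ["{a}c1ccccc1", "{a}c1ccc2ccccc2c1", "{a}C1CCCCC1", "{a}c1ccncc1",
             "{a}c1ccco1", "{a}c1cccs1"]
_TWO_SLOT = ["{a}c1ccc({b})cc1", "{a}c1cccc({b})c1", "{a}c1ccc({b})nc1",
             "{a}C1CCC({b})CC1"]


@functools.lru_cache(maxsize=1)
def smiles_pool() -> tuple[str, ...]:
    """Sorted pool of distinct, valid template SMILES (validated once)."""
    seen: set[str] = set()
    candidates = [t.format(a=a) for t in _ONE_SLOT for a in _SUBSTITUENTS]
    candidates += [
        t.format(a=a, b=b)
        for t in _TWO_SLOT
        for a, b in itertools.product(_SUBSTITUENTS, repeat=2)
    ]
    for smi in candidates:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon not in seen:
            seen.add(canon)
    return tuple(sorted(seen))


_HERB_NAMES = ["herb-A", "herb-B", "herb-C", "herb-D", "herb-E"]


def gen_compound_set(n: int, seed: int) -> tuple[HerbDataset, list[LibraryCompound]]:
    """Deterministic-for-seed herb dataset of ``n`` compounds plus a reference
    library that contains the first dataset structure verbatim and one exact
    duplicate structure pair (two cids, same SMILES)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = smiles_pool()
    if n > len(pool):
        raise ValueError(f"n={n} exceeds template pool size {len(pool)}")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n, replace=False)
    compounds = []
    herbs_used: set[str] = set()
    for i, idx in enumerate(chosen):
        name = f"compound-{i:04d}"
        herb_ids = rng.choice(len(_HERB_NAMES), size=int(rng.integers(1, 3)), replace=False)
        herbs = frozenset(_HERB_NAMES[j] for j in herb_ids)
        herbs_used |= herbs
        compounds.append(
            Compound(
                id=normalize_name(name),
                name=name,
                smiles=pool[idx],
                ob=float(rng.uniform(0.3, 1.0)),
                dl=float(rng.uniform(0.18, 0.9)),
                herbs=herbs,
            )
        )
    dataset = HerbDataset(herbs=sorted(herbs_used), compounds=compounds,
                          provenance=f"synthetic seed={seed}")
    # Library: a random slice of the pool; guarantee one structure identical
    # to the first query and an exact duplicate pair inside the library.
    m = max(10, n // 5)
    lib_idx = rng.choice(len(pool), size=min(m, len(pool)), replace=False)
    lib_smiles = [compounds[0].smiles] + [pool[i] for i in lib_idx]
    lib_smiles.append(lib_smiles[1])  # duplicate structure pair
    library = [
        LibraryCompound(cid=str(900000 + i), smiles=smi, name=f"lib-{i:04d}")
        for i, smi in enumerate(lib_smiles)
    ]
    return dataset, library


@dataclasses.dataclass(frozen=True)
class AnnotationScenario:
    """Parameters of a planted retrieve sequence.

    ``elusive_depth``/``contrast_depth`` are record indices (>= 1; index 0 is
    the anchor) at which the planted equivocal/contradicting verdicts sit.
    ``contrast_depth`` requires a definite anchor.
    """

    anchor_verdict: int
    elusive_depth: Optional[int] = None
    contrast_depth: Optional[int] = None
    n_records: int = 5
    score_range: tuple[float, float] = (0.05, 0.99)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.anchor_verdict not in (TOXIC, AMBIGUOUS, NONTOXIC):
            raise ValueError("anchor_verdict must be +1, 0 or -1")
        for depth in (self.elusive_depth, self.contrast_depth):
            if depth is not None and not 1 <= depth < self.n_records:
                raise ValueError(f"depth {depth} out of range [1, {self.n_records})")
        if self.contrast_depth is not None and self.anchor_verdict == AMBIGUOUS:
            raise ValueError("contrast is undefined under an ambiguous anchor")
        if (
            self.elusive_depth is not None
            and self.contrast_depth is not None
            and self.elusive_depth == self.contrast_depth
        ):
            raise ValueError("elusive and contrast depths must differ")


@dataclasses.dataclass
class PlantedTruth:
    fep_ss: Optional[float]
    fcp_ss: Optional[float]


def gen_annotation_sequence(scenario: AnnotationScenario) -> tuple[RetrieveSequence, PlantedTruth]:
    """Build a retrieve sequence realizing the scenario and return it with the
    ground-truth first-elusive/first-contrast scores."""
    rng = np.random.default_rng(scenario.seed)
    low, high = scenario.score_range
    scores = np.sort(rng.uniform(low, high, size=scenario.n_records))[::-1]
    while len(np.unique(scores)) < scenario.n_records:  # pragma: no cover
        scores = np.sort(rng.uniform(low, high, size=scenario.n_records))[::-1]
    verdicts: list[Verdict] = [scenario.anchor_verdict] * scenario.n_records
    fep = fcp = None
    if scenario.elusive_depth is not None:
        if scenario.anchor_verdict == AMBIGUOUS:
            verdicts[scenario.elusive_depth] = int(rng.choice([TOXIC, NONTOXIC]))
        else:
            verdicts[scenario.elusive_depth] = AMBIGUOUS
        fep = float(scores[scenario.elusive_depth])
    if scenario.contrast_depth is not None:
        verdicts[scenario.contrast_depth] = -scenario.anchor_verdict
        fcp = float(scores[scenario.contrast_depth])
    seq = RetrieveSequence(
        query_id=f"synthetic-{scenario.seed}",
        endpoint="synthetic-endpoint",
        records=[(float(s), v) for s, v in zip(scores, verdicts)],
    )
    return seq, PlantedTruth(fep_ss=fep, fcp_ss=fcp)


def random_scenario(rng: np.random.Generator) -> AnnotationScenario:
    """Draw a random valid scenario (used by the recovery property tests)."""
    anchor = int(rng.choice([TOXIC, AMBIGUOUS, NONTOXIC]))
    n = int(rng.integers(3, 12))
    depths = list(rng.permutation(np.arange(1, n)))
    elusive = int(depths.pop()) if rng.random() < 0.7 else None
    contrast = None
    if anchor != AMBIGUOUS and depths and rng.random() < 0.7:
        contrast = int(depths.pop())
    return AnnotationScenario(
        anchor_verdict=anchor,
        elusive_depth=elusive,
        contrast_depth=contrast,
        n_records=n,
        seed=int(rng.integers(0, 2**31)),
    )


def gen_library_annotations(
    library: Sequence[LibraryCompound],
    endpoints: Sequence[str],
    seed: int,
    p_na: float = 0.25,
):
    """Random per-(cid, endpoint) verdicts for prediction-stage fixtures."""
    from .calibration import AnnotationRecord

    rng = np.random.default_rng(seed)
    records = []
    codes: list[Verdict] = [TOXIC, AMBIGUOUS, NONTOXIC, NA]
    p_each = (1.0 - p_na) / 3.0
    probs = [p_each, p_each, p_each, p_na]
    for lc in library:
        for ep in endpoints:
            v = codes[int(rng.choice(4, p=probs))]
            records.append(AnnotationRecord(cid=lc.cid, endpoint=ep, verdict=v,
                                            source="synthetic"))
    return records


# ---------------------------------------------------------------------------
# Interaction texts

_INTERACTION_TEMPLATES: list[tuple[str, Optional[str]]] = [
    ("Co-treatment may potentiate the sensitivity of cancer cells to ionizing radiation.",
     "Enhanced radiotherapy"),
    ("The compound inhibited lung metastasis of implanted tumor cells in mice.",
     "Metastasis inhibition"),
    ("Pretreatment suppressed carcinogenesis induced by azoxymethane in the colon.",
     "Carcinogenesis inhibition"),
    ("It enhanced the cytotoxic activity of docetaxel in chemotherapy regimens.",
     "Enhanced chemotherapy"),
    ("Combination exposure led to enhanced genotoxicity, e.g. increased micronuclei.",
     "Enhanced genotoxicity"),
    ("Co-administration increased the oral bioavailability of the partner drug.",
     "Enhanced bioavailability"),
    ("A weakened target therapy of bortezomib may occur with concurrent dosing.",
     "Weakened target therapy"),
    ("The compound is a crystalline solid at room temperature.", None),
    ("Stored samples were kept at 4 degrees (cf. the handling notes).", None),
]


def gen_interaction_payload(n_statements: int, seed: int) -> tuple[str, list[Optional[str]]]:
    """A sentence-delimited payload of ``n_statements`` drawn from templates,
    returned with the expected category per statement (None = unclassifiable)."""
    rng = np.random.default_rng(seed)
    picks = [int(rng.integers(0, len(_INTERACTION_TEMPLATES))) for _ in range(n_statements)]
    texts = [_INTERACTION_TEMPLATES[i][0] for i in picks]
    expected = [_INTERACTION_TEMPLATES[i][1] for i in picks]
    return " ".join(texts), expected


# ---------------------------------------------------------------------------
# Dose-response matrices

@dataclasses.dataclass(frozen=True)
class HillCurve:
    """Monotherapy inhibition curve: y(d) = top * d^slope / (d^slope + ic50^slope)."""

    ic50: float
    slope: float = 1.0
    top: float = 1.0

    def inhibition(self, dose):
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            y = self.top * dose**self.slope / (dose**self.slope + self.ic50**self.slope)
        return np.where(dose > 0, y, 0.0)


def gen_zip_matrix(
    hill1: HillCurve,
    hill2: HillCurve,
    delta_field: Optional[np.ndarray] = None,
    sigma: float = 0.0,
    seed: int = 0,
    n_row: int = 6,
    n_col: int = 6,
    row_doses: Optional[np.ndarray] = None,
    col_doses: Optional[np.ndarray] = None,
) -> tuple[DoseResponseMatrix, np.ndarray]:
    """Dose-response matrix whose margins follow the two Hill curves and whose
    combination cells equal the zero-interaction surface plus a planted
    per-cell delta field (inhibition fractions) and Gaussian noise.

    Values are clipped to [0, 1] after noise/delta addition, which can
    attenuate planted deltas near saturation.  Returns the matrix and the
    requested delta field (ground truth, fractions).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    if row_doses is None:
        row_doses = np.geomspace(hill1.ic50 / 8.0, 3.0 * hill1.ic50, n_row)
    if col_doses is None:
        col_doses = np.geomspace(hill2.ic50 / 8.0, 3.0 * hill2.ic50, n_col)
    row_doses = np.asarray(row_doses, dtype=float)
    col_doses = np.asarray(col_doses, dtype=float)
    if delta_field is None:
        delta_field = np.zeros((len(row_doses), len(col_doses)))
    delta_field = np.asarray(delta_field, dtype=float)
    if delta_field.shape != (len(row_doses), len(col_doses)):
        raise ValueError("delta_field shape must match the combination block")
    y1 = hill1.inhibition(row_doses)
    y2 = hill2.inhibition(col_doses)
    grid = np.zeros((len(row_doses) + 1, len(col_doses) + 1))
    grid[1:, 0] = y1
    grid[0, 1:] = y2
    null = y1[:, None] + y2[None, :] - y1[:, None] * y2[None, :]
    grid[1:, 1:] = null + delta_field
    if sigma > 0:
        grid += rng.normal(0.0, sigma, size=grid.shape)
        grid[0, 0] = 0.0
    grid = np.clip(grid, 0.0, 1.0)
    matrix = DoseResponseMatrix(
        row_doses=np.concatenate([[0.0], row_doses]),
        col_doses=np.concatenate([[0.0], col_doses]),
        inhibition=grid,
    )
    return matrix, delta_field


# ---------------------------------------------------------------------------
# Demo fixture writer

def make_fixtures(outdir, seed: int = 0) -> None:
    """Write the full demo dataset (compound table, library, retrieves,
    interaction payload, dose-response matrix) used by the tutorial."""
    import pathlib

    import pandas as pd

    from . import calibration, dataset as dataset_io, synergy as synergy_io

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    ds, library = gen_compound_set(30, seed)
    rows = []
    for c in ds.compounds:
        for herb in sorted(c.herbs):
            rows.append({"Molecule Name": c.name, "isomeric_smiles": c.smiles,
                         "OB": round(c.ob, 4), "DL": round(c.dl, 4), "Herb": herb})
    # a few rows that must fail the ADME screen or SMILES validation
    rows.append({"Molecule Name": "inactive-low-ob", "isomeric_smiles": "CCO",
                 "OB": 0.05, "DL": 0.5, "Herb": "herb-A"})
    rows.append({"Molecule Name": "broken-smiles", "isomeric_smiles": "not_a_smiles",
                 "OB": 0.9, "DL": 0.9, "Herb": "herb-A"})
    pd.DataFrame(rows).to_csv(outdir / "compounds.csv", index=False)
    pd.DataFrame(
        [{"cid": lc.cid, "smiles": lc.smiles, "name": lc.name} for lc in library]
    ).to_csv(outdir / "library.csv", index=False)

    retrieve_rows = []
    for i in range(20):
        scenario = random_scenario(rng)
        seq, _ = gen_annotation_sequence(scenario)
        for score, verdict in seq.records:
            retrieve_rows.append({
                "query_id": f"compound-{i:04d}",
                "cid": str(900000 + i),
                "score": round(score, 4),
                "endpoint": "Hepatotoxicity",
                "verdict": "N.A." if verdict is NA else verdict,
            })
    pd.DataFrame(retrieve_rows).to_csv(outdir / "retrieves.csv", index=False)

    payload, _ = gen_interaction_payload(7, seed)
    (outdir / "interactions.txt").write_text(payload + "\n")

    matrix, _ = gen_zip_matrix(HillCurve(ic50=1.0), HillCurve(ic50=10.0),
                               sigma=0.02, seed=seed)
    synergy_io.write_matrix(matrix, outdir / "matrix.csv")
    dataset_io.write_dataset(ds, outdir / "dataset.csv")
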