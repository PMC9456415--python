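"""Similarity-threshold calibration from annotation retrieve sequences.

For each (active compound, toxicity endpoint) pair the annotated similar
compounds form a retrieve sequence ordered by descending similarity score.
Relative to the verdict of the highest-scoring informative record (the
*anchor*), two statistics are computed:

* the first-elusive score: the largest similarity at which a retrieve becomes
  equivocal relative to the anchor verdict (an ambiguous record under a
  definite anchor, or a definite record under an ambiguous anchor);
* the first-contrast score: the largest similarity at which a retrieve
  directly contradicts a definite anchor verdict.

Both are independent descending scans, not nested ones, so the first-elusive
score may legitimately be smaller than the first-contrast score.  Summary
statistics over many pairs (after excluding low values attributable to sparse
annotation) yield the global similarity-score threshold used by prediction.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Verdict codes.  None encodes "not applicable" (no information).
TOXIC = 1
AMBIGUOUS = 0
NONTOXIC = -1
NA = None

Verdict = Optional[int]

#: Summary exclusion cutoff: values <= cutoff are dropped from summaries only.
DEFAULT_CUTOFF = 0.3

#: Default global threshold shipped with the package (mean first-contrast
#: score over a 20-herb calibration corpus; see package docs).
DEFAULT_THRESHOLD = 0.6171

_VERDICT_STRINGS = {
    "1": TOXIC, "+1": TOXIC, "toxic": TOXIC,
    "0": AMBIGUOUS, "ambiguous": AMBIGUOUS,
    "-1": NONTOXIC, "−1": NONTOXIC, "nontoxic": NONTOXIC, "non-toxic": NONTOXIC,
    "n.a.": NA, "na": NA, "nan": NA, "": NA,
}


def parse_verdict(value: Union[str, int, float, None]) -> Verdict:
    """Parse a verdict cell: 1/0/-1 (ASCII or Unicode minus) or N.A. variants."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return NA
    if isinstance(value, (int, float)):
        iv = int(value)
        if iv in (TOXIC, AMBIGUOUS, NONTOXIC):
            return iv
        raise ValueError(f"invalid verdict code: {value!r}")
    key = str(value).strip().lower()
    if key in _VERDICT_STRINGS:
        return _VERDICT_STRINGS[key]
    raise ValueError(f"invalid verdict: {value!r}")


@dataclasses.dataclass
class AnnotationRecord:
    """A per-endpoint trichotomous verdict on one library compound."""

    cid: str
    endpoint: str
    verdict: Verdict
    text: str = ""
    source: str = ""


@dataclasses.dataclass
class RetrieveSequence:
    """Similarity-ordered (score, verdict) pairs for one compound/endpoint pair.

    Scores must lie in [0, 1]; records are stored sorted by non-increasing
    score.  NA-verdict pairs are permitted and skipped by the statistics.
    """

    query_id: str
    endpoint: str
    records: list[tuple[float, Verdict]]

    def __post_init__(self) -> None:
        for s, _ in self.records:
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"similarity score out of [0,1]: {s}")
        self.records = sorted(self.records, key=lambda r: -r[0])

    def deduplicated(self) -> list[tuple[float, Verdict]]:
        """Records with exact (score, verdict) duplicates removed, order kept."""
        seen: set[tuple[float, Verdict]] = set()
        out = []
        for rec in self.records:
            if rec not in seen:
                seen.add(rec)
                out.append(rec)
        return out


def anchor_verdict(seq: RetrieveSequence) -> Verdict:
    """Verdict of the highest-scoring record with an informative verdict.

    At a tied top score with conflicting verdicts, definite verdicts take
    precedence over ambiguous ones, and toxic over non-toxic, so that the
    downstream contrast scan flags the disagreement at that score.
    """
    informative = [(s, v) for s, v in seq.deduplicated() if v is not NA]
    if not informative:
        return NA
    top = max(s for s, _ in informative)
    at_top = [v for s, v in informative if s == top]
    return max(at_top, key=lambda v: (abs(v), v))


def compute_fep_ss(seq: RetrieveSequence) -> Optional[float]:
    """First-elusive score: the largest similarity of an equivocal retrieve.

    Under a definite anchor (+1/-1) an ambiguous (0) record is elusive; under
    an ambiguous anchor (0) any definite record is elusive.  Returns None
    when the anchor is NA or no qualifying record exists.
    """
    v0 = anchor_verdict(seq)
    if v0 is NA:
        return None
    if v0 in (TOXIC, NONTOXIC):
        qualifying = {AMBIGUOUS}
    else:
        qualifying = {TOXIC, NONTOXIC}
    scores = [s for s, v in seq.deduplicated() if v in qualifying]
    return max(scores) if scores else None


def compute_fcp_ss(seq: RetrieveSequence) -> Optional[float]:
    """First-contrast score: the largest similarity of a retrieve whose
    definite verdict opposes a definite anchor.  None when the anchor is
    ambiguous/NA or no opposite-verdict record exists."""
    v0 = anchor_verdict(seq)
    if v0 is NA or v0 == AMBIGUOUS:
        return None
    scores = [s for s, v in seq.deduplicated() if v == -v0]
    return max(scores) if scores else None


@dataclasses.dataclass
class CalibrationResult:
    """Per-pair first-elusive/first-contrast scores plus global summary."""

    per_pair: dict[tuple[str, str], dict[str, Optional[float]]]
    exclusion_cutoff: float
    summary: dict[str, Optional[float]]
    chosen_threshold: Optional[float]


def calibrate_threshold(
    results: Union[Iterable[RetrieveSequence], dict[tuple[str, str], dict[str, Optional[float]]]],
    cutoff: float = DEFAULT_CUTOFF,
) -> CalibrationResult:
    """Summarize per-pair statistics and derive the global threshold.

    ``results`` is either an iterable of retrieve sequences (statistics are
    computed here) or a pre-computed per-pair mapping.  Values <= ``cutoff``
    are excluded from the summary only — per-pair values are reported in
    full.  The chosen threshold is the mean surviving first-contrast score;
    the third quartile (linear interpolation between order statistics) is
    reported alongside.
    """
    if isinstance(results, dict):
        per_pair = results
    else:
        per_pair = {}
        for seq in results:
            per_pair[(seq.query_id, seq.endpoint)] = {
                "fep_ss": compute_fep_ss(seq),
                "fcp_ss": compute_fcp_ss(seq),
            }
    fcp = [v["fcp_ss"] for v in per_pair.values() if v["fcp_ss"] is not None and v["fcp_ss"] > cutoff]
    fep = [v["fep_ss"] for v in per_pair.values() if v["fep_ss"] is not None and v["fep_ss"] > cutoff]
    summary: dict[str, Optional[float]] = {
        "mean_fcp": float(np.mean(fcp)) if fcp else None,
        "mean_fep": float(np.mean(fep)) if fep else None,
        "q3_fcp": float(np.percentile(fcp, 75)) if fcp else None,
        "n_fcp": len(fcp),
        "n_fep": len(fep),
    }
    if not fcp:
        logger.warning("no first-contrast values above cutoff %.3g; threshold undefined", cutoff)
    return CalibrationResult(
        per_pair=per_pair,
        exclusion_cutoff=cutoff,
        summary=summary,
        chosen_threshold=summary["mean_fcp"],
    )


# ---------------------------------------------------------------------------
# File interfaces

def read_retrieves(path) -> list[RetrieveSequence]:
    """Read (query_id, cid, score, endpoint, verdict) rows and group them into
    retrieve sequences keyed by (query_id, endpoint)."""
    df = pd.read_csv(path, dtype={"query_id": str, "cid": str}, keep_default_na=False)
    grouped: dict[tuple[str, str], list[tuple[float, Verdict]]] = {}
    for r in df.itertuples():
        key = (str(r.query_id), str(r.endpoint))
        grouped.setdefault(key, []).append((float(r.score), parse_verdict(r.verdict)))
    return [
        RetrieveSequence(query_id=q, endpoint=e, records=recs)
        for (q, e), recs in grouped.items()
    ]


def write_calibration(result: CalibrationResult, outdir) -> None:
    """Write the per-pair table and a key:value summary block under outdir."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "query_id": q,
            "endpoint": e,
            "fep_ss": "" if v["fep_ss"] is None else v["fep_ss"],
            "fcp_ss": "" if v["fcp_ss"] is None else v["fcp_ss"],
        }
        for (q, e), v in sorted(result.per_pair.items())
    ]
    pd.DataFrame(rows, columns=["query_id", "endpoint", "fep_ss", "fcp_ss"]).to_csv(
        outdir / "per_pair.csv", index=False
    )
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(f"exclusion_cutoff: {result.exclusion_cutoff}\n")
        for k, v in result.summary.items():
            fh.write(f"{k}: {'NA' if v is None else v}\n")
        fh.write(
            f"chosen_threshold: {'NA' if result.chosen_threshold is None else result.chosen_threshold}\n"
        )
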