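"""Dose-response synergy quantification.

Three pieces: four-parameter logistic (4PL) curve fitting for single-agent
IC50s, the Combination Index for a two-drug combination, and zero-interaction
potency (ZIP) delta scoring of full dose-response matrices with detection of
the most synergistic 3x3 dose window.

Conventions: the math core works on *inhibition* fractions in [0, 1]
(viability data are converted once at ingest via ``inhibition = 1 -
viability``); a positive Hill slope means response increases with dose.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

MSA_WINDOW = 3  # most-synergistic-area window edge (dose steps)


class FitError(RuntimeError):
    """Raised when a dose-response fit cannot be produced honestly."""


@dataclasses.dataclass
class DoseResponseCurve:
    """Single-agent dose-response data.

    ``orientation`` is ``"inhibition"`` (response rises with dose) or
    ``"viability"`` (response falls); viability input is converted to
    inhibition at construction so the math core sees one orientation.
    """

    doses: np.ndarray
    responses: np.ndarray
    orientation: str = "inhibition"
    dose_unit: str = ""

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must have equal length")
        if np.any(self.doses <= 0):
            raise ValueError("doses must be strictly positive (log-dose model)")
        if self.orientation not in ("inhibition", "viability"):
            raise ValueError(f"unknown orientation: {self.orientation!r}")
        if self.orientation == "viability":
            self.responses = 1.0 - self.responses
            self.orientation = "inhibition"


@dataclasses.dataclass
class FourPLFit:
    """Fitted 4PL parameters.  ``ic50 = 10**log_ic50``; ``in_range`` flags
    whether the IC50 falls inside the tested dose range."""

    bottom: float
    top: float
    log_ic50: float
    hill: float
    r_squared: float
    in_range: bool

    @property
    def ic50(self) -> float:
        return float(10.0 ** self.log_ic50)


def four_pl(dose: np.ndarray, bottom: float, top: float, log_ic50: float, hill: float) -> np.ndarray:
    """response = bottom + (top - bottom) / (1 + 10**((log_ic50 - log10 dose) * hill))"""
    log_d = np.log10(dose)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - log_d) * hill))


def fit_4pl(curve: DoseResponseCurve) -> FourPLFit:
    """Least-squares 4PL fit with a deterministic initialization rule.

    Initialization: bottom/top from the response extremes, log IC50 at the
    log-dose midpoint, Hill slope +1 or -1 by the response trend.  Flat data
    and optimizer failures raise :class:`FitError` instead of returning a
    spurious IC50.
    """
    doses, resp = curve.doses, curve.responses
    if len(np.unique(doses)) < 4:
        raise FitError("4PL fit needs >= 4 distinct doses")
    if np.ptp(resp) < 1e-6:
        raise FitError("degenerate flat response data; no IC50 exists")
    log_d = np.log10(doses)
    trend = np.polyfit(log_d, resp, 1)[0]
    p0 = [float(resp.min()), float(resp.max()), float((log_d.min() + log_d.max()) / 2.0),
          1.0 if trend >= 0 else -1.0]
    try:
        popt, _ = curve_fit(four_pl, doses, resp, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    bottom, top, log_ic50, hill = (float(x) for x in popt)
    if bottom > top:
        # canonical form: bottom <= top, compensated by the slope sign
        bottom, top, hill = top, bottom, -hill
    pred = four_pl(doses, bottom, top, log_ic50, hill)
    ss_res = float(np.sum((resp - pred) ** 2))
    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    ic50 = 10.0 ** log_ic50
    in_range = bool(doses.min() <= ic50 <= doses.max())
    if not in_range:
        logger.warning("fitted IC50 %.4g outside tested dose range [%.4g, %.4g]",
                       ic50, doses.min(), doses.max())
    return FourPLFit(bottom=bottom, top=top, log_ic50=log_ic50, hill=hill,
                     r_squared=r2, in_range=in_range)


@dataclasses.dataclass(frozen=True)
class CombinationIndexResult:
    ci: float

    @property
    def call(self) -> str:
        if self.ci < 1.0:
            return "synergistic"
        if self.ci == 1.0:
            return "additive"
        return "antagonistic"


def combination_index(
    dx1: float,
    dx2: float,
    d1: float,
    d2: float,
    unit1: Optional[tuple[str, str]] = None,
    unit2: Optional[tuple[str, str]] = None,
) -> CombinationIndexResult:
    """CI = d1/dx1 + d2/dx2 for an iso-effective combination.

    ``dx1``/``dx2`` are the single-agent doses of drugs 1 and 2 reaching the
    reference effect; ``d1``/``d2`` the combination doses reaching the same
    effect.  CI < 1 is synergistic, = 1 additive, > 1 antagonistic.  Optional
    ``unit1``/``unit2`` are (single-agent, combination) unit-label pairs; a
    mismatch within a drug raises.
    """
    for unit, drug in ((unit1, 1), (unit2, 2)):
        if unit is not None and unit[0] != unit[1]:
            raise ValueError(f"unit mismatch for drug {drug}: {unit[0]!r} vs {unit[1]!r}")
    if dx1 <= 0 or dx2 <= 0 or d1 < 0 or d2 < 0:
        raise ValueError("reference doses must be positive, combination doses non-negative")
    return CombinationIndexResult(ci=d1 / dx1 + d2 / dx2)


@dataclasses.dataclass
class DoseResponseMatrix:
    """Two-drug inhibition grid.  The first row and column (dose 0 of the
    partner drug) are the monotherapy margins."""

    row_doses: np.ndarray  # drug 1 doses, row_doses[0] == 0
    col_doses: np.ndarray  # drug 2 doses, col_doses[0] == 0
    inhibition: np.ndarray  # fractions in [0, 1], shape (len(row_doses), len(col_doses))
    row_unit: str = ""
    col_unit: str = ""

    def __post_init__(self) -> None:
        self.row_doses = np.asarray(self.row_doses, dtype=float)
        self.col_doses = np.asarray(self.col_doses, dtype=float)
        self.inhibition = np.asarray(self.inhibition, dtype=float)
        if self.inhibition.shape != (len(self.row_doses), len(self.col_doses)):
            raise ValueError("inhibition shape must be (n_row_doses, n_col_doses)")
        if self.row_doses[0] != 0 or self.col_doses[0] != 0:
            raise ValueError("first row/column dose must be 0 (monotherapy margins)")
        if np.any(self.row_doses[1:] <= 0) or np.any(self.col_doses[1:] <= 0):
            raise ValueError("non-margin doses must be strictly positive")
        if np.any(self.inhibition < -1e-9) or np.any(self.inhibition > 1 + 1e-9):
            raise ValueError("inhibition values must lie in [0, 1]")


@dataclasses.dataclass
class SynergyResult:
    """ZIP scoring of a dose-response matrix.

    ``zip_delta`` is the per-cell observed-minus-expected matrix over the
    combination block (both doses > 0), in percentage points; ``msa`` is the
    maximum window-mean delta and ``msa_window`` its top-left cell index
    within the combination block.
    """

    zip_delta: np.ndarray
    zip_mean: float
    msa: float
    msa_window: tuple[int, int]
    msa_window_shape: tuple[int, int]
    ci: Optional[float] = None


def _fit_margin(doses: np.ndarray, inhibition: np.ndarray) -> np.ndarray:
    curve = DoseResponseCurve(doses=doses, responses=inhibition)
    fit = fit_4pl(curve)
    return four_pl(doses, fit.bottom, fit.top, fit.log_ic50, fit.hill)


def zip_delta(matrix: DoseResponseMatrix, smooth: bool = False) -> SynergyResult:
    """Score a two-drug matrix against the zero-interaction expectation.

    For combination cell (i, j) the expected inhibition is
    ``y1 + y2 - y1*y2`` where y1, y2 are the monotherapy inhibitions of each
    drug at the cell's doses.  With ``smooth=False`` (the testable default)
    y1/y2 are the observed margins; ``smooth=True`` replaces them with 4PL
    fits along each margin.  Delta is reported in percentage points.
    """
    obs = matrix.inhibition
    y1 = obs[:, 0].copy()  # drug 1 margin over row doses
    y2 = obs[0, :].copy()  # drug 2 margin over col doses
    if smooth:
        y1[1:] = _fit_margin(matrix.row_doses[1:], obs[1:, 0])
        y2[1:] = _fit_margin(matrix.col_doses[1:], obs[0, 1:])
    expected = y1[1:, None] + y2[None, 1:] - y1[1:, None] * y2[None, 1:]
    delta = (obs[1:, 1:] - expected) * 100.0
    n_r, n_c = delta.shape
    win_r, win_c = min(MSA_WINDOW, n_r), min(MSA_WINDOW, n_c)
    if (win_r, win_c) != (MSA_WINDOW, MSA_WINDOW):
        logger.warning(
            "combination block %dx%d smaller than %dx%d; most-synergistic area "
            "computed over the largest available %dx%d window",
            n_r, n_c, MSA_WINDOW, MSA_WINDOW, win_r, win_c,
        )
    best, best_loc = -np.inf, (0, 0)
    for i in range(n_r - win_r + 1):
        for j in range(n_c - win_c + 1):
            m = float(delta[i : i + win_r, j : j + win_c].mean())
            if m > best:
                best, best_loc = m, (i, j)
    return SynergyResult(
        zip_delta=delta,
        zip_mean=float(delta.mean()),
        msa=best,
        msa_window=best_loc,
        msa_window_shape=(win_r, win_c),
    )


# ---------------------------------------------------------------------------
# File interfaces

def read_matrix(path) -> DoseResponseMatrix:
    """Read a dose-response matrix from delimited text.

    Layout: first cell names the units as ``row_unit/col_unit`` (optional),
    the rest of the header row holds drug-2 doses (starting at 0), the first
    column drug-1 doses (starting at 0), and the body inhibition fractions.
    """
    import csv

    with open(path) as fh:
        rows = [r for r in csv.reader(fh) if r and any(c.strip() for c in r)]
    header = rows[0]
    units = header[0].split("/") if header[0].strip() else ["", ""]
    col_doses = np.array([float(x) for x in header[1:]])
    row_doses = np.array([float(r[0]) for r in rows[1:]])
    inhibition = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
    return DoseResponseMatrix(
        row_doses=row_doses,
        col_doses=col_doses,
        inhibition=inhibition,
        row_unit=units[0].strip(),
        col_unit=units[1].strip() if len(units) > 1 else "",
    )


def write_matrix(matrix: DoseResponseMatrix, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([f"{matrix.row_unit}/{matrix.col_unit}"] + [repr(float(d)) for d in matrix.col_doses])
        for dose, row in zip(matrix.row_doses, matrix.inhibition):
            w.writerow([repr(float(dose))] + [repr(float(x)) for x in row])


def write_zip_report(result: SynergyResult, outdir) -> None:
    """Write the delta matrix (CSV) and a key:value summary block."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "zip_delta.csv", result.zip_delta, delimiter=",", fmt="%.6f")
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(f"zip_mean: {result.zip_mean:.6f}\n")
        fh.write(f"msa: {result.msa:.6f}\n")
        fh.write(f"msa_window_row: {result.msa_window[0]}\n")
        fh.write(f"msa_window_col: {result.msa_window[1]}\n")
        fh.write(f"msa_window_shape: {result.msa_window_shape[0]}x{result.msa_window_shape[1]}\n")
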