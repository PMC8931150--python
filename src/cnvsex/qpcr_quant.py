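"""Real-time PCR quantification: standard curves, efficiency, and
calibrator-relative copy number (Pfaffl / REST).

A dilution series of known DNA input fits Ct against log10(input); the
slope gives the per-cycle amplification factor E = 10^(−1/slope) and the
percent efficiency (E − 1)·100.  When the target and reference curves have
slopes within ±0.1 of each other (the Larionov rule) raw Ct values can be
compared directly and the copy number of the target gene relative to a
single-copy male calibrator is

    CNV = E_target^ΔCt_target / E_reference^ΔCt_reference

with ΔCt = (calibrator mean Ct) − (sample mean Ct) per gene, each mean
taken over technical replicates.  Because the calibrator male carries one
copy of the X-linked target, the ratio is directly the absolute target
copy number: ≈1 in males, ≈2 in females.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .ddpcr_quant import CnvResult, IncompleteSpecimenError

__all__ = [
    "CtRecord",
    "StandardCurve",
    "DeltaCtPair",
    "CnvResult",
    "fit_standard_curve",
    "efficiency_from_slope",
    "validate_slope_difference",
    "mean_ct",
    "select_calibrator",
    "pfaffl_cnv",
    "qpcr_pipeline",
    "NoAmplificationError",
    "NoCalibratorError",
    "SlopeRuleError",
    "TOTAL_CYCLES",
    "SLOPE_DIFFERENCE_LIMIT",
    "REPLICATE_SD_LIMIT",
]

logger = logging.getLogger(__name__)

TOTAL_CYCLES = 40
SLOPE_DIFFERENCE_LIMIT = 0.1
#: Technical replicates more dispersed than this (in cycles) flag the mean.
REPLICATE_SD_LIMIT = 0.5


class NoAmplificationError(ValueError):
    """Every technical replicate of a specimen × gene failed to amplify."""


class NoCalibratorError(ValueError):
    """No male available to serve as calibrator in a run."""


class SlopeRuleError(ValueError):
    """Standard-curve slopes differ by more than the raw-Ct limit."""


@dataclass(frozen=True)
class CtRecord:
    """One technical replicate's cycle-threshold measurement.

    ``ct`` is ``None`` when the well never crossed threshold
    (no amplification).
    """

    specimen_id: str
    gene_role: str  # "target" | "reference"
    biological_replicate: int
    technical_replicate: int
    ct: Optional[float]
    run_id: str = ""

    def __post_init__(self) -> None:
        if self.ct is not None and not (0 < self.ct <= TOTAL_CYCLES):
            raise ValueError(
                f"Ct {self.ct} outside (0, {TOTAL_CYCLES}] for "
                f"{self.specimen_id}/{self.gene_role}"
            )
        if self.biological_replicate < 1 or self.technical_replicate < 1:
            raise ValueError("replicate indices are 1-based")


@dataclass(frozen=True)
class StandardCurve:
    """Dilution-series fit of Ct on log10(input DNA mass)."""

    slope: float
    y_intercept: float
    r_squared: float
    efficiency_percent: float
    amplification_factor: float


@dataclass(frozen=True)
class DeltaCtPair:
    """Per-gene (calibrator mean Ct − sample mean Ct)."""

    delta_ct_target: float
    delta_ct_reference: float


def efficiency_from_slope(slope: float) -> tuple[float, float]:
    """Amplification factor E = 10^(−1/slope) and percent efficiency.

    A slope of −1/log10(2) ≈ −3.3219 corresponds to perfect doubling
    (E = 2, 100%).  Raises ``ValueError`` for non-negative slopes: Ct must
    decrease with input.
    """
    if slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    factor = 10.0 ** (-1.0 / slope)
    return factor, (factor - 1.0) * 100.0


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of Ct on log10(input ng).

    ``points`` are (input_ng, ct) pairs, e.g. a 20 → 1.25 ng two-fold
    dilution series.  Requires at least two distinct positive masses.
    """
    if any(m <= 0 for m, _ in points):
        raise ValueError("input masses must be positive")
    masses = [m for m, _ in points]
    if len(set(masses)) < 2:
        raise ValueError("standard curve needs >= 2 distinct input masses")
    x = np.log10(masses)
    y = np.array([ct for _, ct in points], dtype=float)
    fit = stats.linregress(x, y)
    r_squared = float(fit.rvalue**2)
    factor, eff = efficiency_from_slope(float(fit.slope))
    return StandardCurve(
        slope=float(fit.slope),
        y_intercept=float(fit.intercept),
        r_squared=r_squared,
        efficiency_percent=eff,
        amplification_factor=factor,
    )


def validate_slope_difference(
    curve_target: StandardCurve, curve_reference: StandardCurve
) -> tuple[float, bool]:
    """Larionov rule: raw-Ct quantification is valid when the two
    standard-curve slopes differ by at most 0.1 in absolute value.

    Returns ``(|slope difference| rounded to 3 d.p., pass flag)``.
    """
    diff = round(abs(curve_target.slope - curve_reference.slope), 3)
    return diff, diff <= SLOPE_DIFFERENCE_LIMIT


def mean_ct(replicates: Sequence[Optional[float]],
            specimen: str = "?", gene: str = "?") -> tuple[float, float, bool]:
    """Aggregate technical replicates: (mean, sample SD, outlier flag).

    Missing replicates (no amplification) are dropped; the flag is set
    when any replicate is missing or the SD exceeds 0.5 cycles.  With all
    replicates missing there is nothing to quantify and
    :class:`NoAmplificationError` is raised.
    """
    present = [c for c in replicates if c is not None]
    if not present:
        raise NoAmplificationError(
            f"no amplification in any technical replicate of {specimen}/{gene}"
        )
    mean = float(np.mean(present))
    sd = float(np.std(present, ddof=1)) if len(present) > 1 else 0.0
    flagged = sd > REPLICATE_SD_LIMIT or len(present) < len(replicates)
    return mean, sd, flagged


def select_calibrator(
    mean_cts: Mapping[str, tuple[float, float]],
    known_sexes: Optional[Mapping[str, str]] = None,
    seed: int = 0,
) -> str:
    """Choose the run's calibrator specimen.

    ``mean_cts`` maps specimen_id -> (mean Ct target, mean Ct reference)
    for one run.  With known sexes, a male is drawn uniformly at random
    with the given seed (the study protocol: one random male per run).
    Without sexes, the putative male is the specimen maximising
    Ct_target − Ct_reference: a single-copy target amplifies about one
    cycle later than in a two-copy female, so the largest gap marks the
    most probable male.  Ties break to the lexicographically smallest id,
    keeping the choice deterministic.
    """
    if not mean_cts:
        raise NoCalibratorError("empty run: no specimens to calibrate against")
    if known_sexes is not None:
        males = sorted(s for s in mean_cts if known_sexes.get(s) == "M")
        if not males:
            raise NoCalibratorError("no male in run to serve as calibrator")
        rng = np.random.default_rng(seed)
        return males[int(rng.integers(len(males)))]
    return max(sorted(mean_cts), key=lambda s: mean_cts[s][0] - mean_cts[s][1])


def pfaffl_cnv(
    e_target: float, e_reference: float, deltas: DeltaCtPair
) -> float:
    """Efficiency-corrected relative quantification.

    ``e_target``/``e_reference`` are amplification factors (the ~2 base of
    exponential amplification, not percentages).  With a true single-copy
    male as calibrator the returned ratio is the absolute target-gene copy
    number.
    """
    if e_target <= 1 or e_reference <= 1:
        raise ValueError(
            f"amplification factors must exceed 1, got {e_target}, {e_reference}"
        )
    return (e_target ** deltas.delta_ct_target) / (
        e_reference ** deltas.delta_ct_reference
    )


def _group_mean_cts(
    records: Iterable[CtRecord],
) -> dict[tuple[str, str, int], tuple[float, float, bool]]:
    """(specimen, run, bio_rep) × gene -> aggregated mean Ct."""
    raw: dict[tuple[str, str, int, str], list[Optional[float]]] = {}
    for rec in records:
        key = (rec.specimen_id, rec.run_id, rec.biological_replicate, rec.gene_role)
        raw.setdefault(key, []).append(rec.ct)
    out: dict[tuple, tuple[float, float, bool]] = {}
    for (spec, run, rep, gene), cts in raw.items():
        out[(spec, run, rep, gene)] = mean_ct(cts, specimen=spec, gene=gene)
    return out


def qpcr_pipeline(
    records: Sequence[CtRecord],
    curve_target: StandardCurve,
    curve_reference: StandardCurve,
    calibrator: str = "auto",
    known_sexes: Optional[Mapping[str, str]] = None,
    seed: int = 0,
    override_slope_rule: bool = False,
) -> list[CnvResult]:
    """Calibrator-relative CNV for every specimen × biological replicate.

    Runs are processed independently: each run gets its own calibrator
    (``calibrator='auto'`` selects one per run via
    :func:`select_calibrator`; a specimen id pins it explicitly).  The
    calibrator's own CNV is exactly 1.0 by construction.  Raw-Ct
    quantification requires the Larionov slope rule to pass, unless
    explicitly overridden (logged).
    """
    diff, ok = validate_slope_difference(curve_target, curve_reference)
    if not ok:
        if not override_slope_rule:
            raise SlopeRuleError(
                f"slope difference {diff} exceeds ±{SLOPE_DIFFERENCE_LIMIT}; "
                "raw-Ct quantification not validated"
            )
        logger.warning(
            "slope rule overridden: difference %.3f exceeds ±%.1f",
            diff, SLOPE_DIFFERENCE_LIMIT,
        )

    e_t = curve_target.amplification_factor
    e_r = curve_reference.amplification_factor

    means = _group_mean_cts(records)
    runs: dict[str, list[tuple[str, int]]] = {}
    for spec, run, rep, gene in means:
        if (spec, rep) not in runs.setdefault(run, []):
            runs[run].append((spec, rep))

    results: list[CnvResult] = []
    for run_id in runs:
        members = runs[run_id]
        # per-specimen means averaged over bio reps, used only for selection
        per_spec: dict[str, tuple[float, float]] = {}
        for spec, rep in members:
            kt = (spec, run_id, rep, "target")
            kr = (spec, run_id, rep, "reference")
            if kt not in means or kr not in means:
                missing = "target" if kt not in means else "reference"
                raise IncompleteSpecimenError(
                    f"specimen {spec} (run {run_id}, replicate {rep}) has no "
                    f"{missing}-gene measurements"
                )
            t_mean, r_mean = means[kt][0], means[kr][0]
            if spec in per_spec:
                per_spec[spec] = (
                    (per_spec[spec][0] + t_mean) / 2,
                    (per_spec[spec][1] + r_mean) / 2,
                )
            else:
                per_spec[spec] = (t_mean, r_mean)

        if calibrator == "auto":
            cal_id = select_calibrator(per_spec, known_sexes=known_sexes, seed=seed)
        else:
            if calibrator not in per_spec:
                raise NoCalibratorError(
                    f"calibrator {calibrator!r} not present in run {run_id}"
                )
            cal_id = calibrator

        for spec, rep in members:
            if spec == cal_id:
                cnv = 1.0
            else:
                cal_t = means[(cal_id, run_id, rep, "target")][0]
                cal_r = means[(cal_id, run_id, rep, "reference")][0]
                deltas = DeltaCtPair(
                    delta_ct_target=cal_t - means[(spec, run_id, rep, "target")][0],
                    delta_ct_reference=cal_r - means[(spec, run_id, rep, "reference")][0],
                )
                cnv = pfaffl_cnv(e_t, e_r, deltas)
            results.append(
                CnvResult(
                    specimen_id=spec,
                    method="qPCR",
                    biological_replicate=rep,
                    cnv=cnv,
                    calibrator_id=cal_id,
                    run_id=run_id,
                )
            )
    return results
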