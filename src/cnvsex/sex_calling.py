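"""Sex calls from copy-number values.

An X-linked target gene is present in one copy in X0 males and two in XX
females, so estimated CNVs cluster at 1 and 2.  The decision boundary is
the midpoint 1.5; calls whose CNV falls outside ±0.5 of the expected mode
are still made but flagged out-of-band.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .ddpcr_quant import CnvResult

__all__ = ["SexCall", "call_sex", "call_cohort", "DEFAULT_THRESHOLD",
           "DEFAULT_BAND_HALFWIDTH"]

DEFAULT_THRESHOLD = 1.5
DEFAULT_BAND_HALFWIDTH = 0.5


@dataclass(frozen=True)
class SexCall:
    specimen_id: str
    predicted_sex: str  # "F" | "M" | "ambiguous"
    cnv: float
    in_band: bool
    method: str
    flags: tuple[str, ...] = ()


def call_sex(
    cnv: float,
    threshold: float = DEFAULT_THRESHOLD,
    band_halfwidth: float = DEFAULT_BAND_HALFWIDTH,
    specimen_id: str = "",
    method: str = "",
) -> SexCall:
    """Classify one CNV: above threshold → F, below → M, exactly at →
    ambiguous.  ``in_band`` records whether the value lies within
    ``band_halfwidth`` of the expected mode (2 for F, 1 for M)."""
    if cnv < 0:
        raise ValueError(f"copy number cannot be negative, got {cnv}")
    if cnv > threshold:
        sex, mode = "F", 2.0
    elif cnv < threshold:
        sex, mode = "M", 1.0
    else:
        return SexCall(specimen_id, "ambiguous", cnv, False, method,
                       flags=("at_threshold",))
    in_band = abs(cnv - mode) <= band_halfwidth
    flags = () if in_band else ("out_of_band",)
    return SexCall(specimen_id, sex, cnv, in_band, method, flags=flags)


def call_cohort(
    results: Sequence[CnvResult],
    threshold: float = DEFAULT_THRESHOLD,
    band_halfwidth: float = DEFAULT_BAND_HALFWIDTH,
) -> tuple[list[SexCall], Counter]:
    """One call per specimen, requiring biological replicates to agree.

    Replicates calling different sexes yield an ambiguous call with a
    conflict flag rather than a vote — silent majority votes are unsafe
    when the call decides a specimen's fate.  Returns the calls and the
    Counter of predicted sexes.
    """
    if not results:
        raise ValueError("no CNV results to call")
    by_spec: dict[tuple[str, str], list[CnvResult]] = {}
    order: list[tuple[str, str]] = []
    for r in results:
        key = (r.specimen_id, r.method)
        if key not in by_spec:
            by_spec[key] = []
            order.append(key)
        by_spec[key].append(r)

    calls: list[SexCall] = []
    for key in order:
        spec, method = key
        reps = by_spec[key]
        rep_calls = [
            call_sex(r.cnv, threshold, band_halfwidth, spec, method) for r in reps
        ]
        sexes = {c.predicted_sex for c in rep_calls}
        mean_cnv = sum(r.cnv for r in reps) / len(reps)
        if len(sexes) > 1:
            calls.append(
                SexCall(spec, "ambiguous", mean_cnv, False, method,
                        flags=("replicate_conflict",))
            )
        else:
            calls.append(call_sex(mean_cnv, threshold, band_halfwidth, spec, method))
    counts = Counter(c.predicted_sex for c in calls)
    return calls, counts
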