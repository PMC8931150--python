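"""Droplet digital PCR quantification: Poisson inversion and copy number.

In ddPCR the reaction is partitioned into ~20,000 droplets; after
endpoint amplification each droplet is scored positive (contains template)
or negative.  Under random partitioning the number of template molecules
per droplet is Poisson(λ), so the negative fraction estimates exp(−λ):

    λ = −ln(n_negative / (n_positive + n_negative))
    c [copies/µL] = λ / droplet volume [µL]

The target-gene copy number per diploid genome is then

    CNV = 2 · c_target / c_reference

since the autosomal reference is present in exactly two copies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "DdpcrWell",
    "Concentration",
    "CnvResult",
    "poisson_concentration",
    "cnv_ddpcr",
    "ddpcr_pipeline",
    "SaturationError",
    "EmptyWellError",
    "IncompleteSpecimenError",
    "ZeroReferenceError",
    "DEFAULT_DROPLET_VOLUME_NL",
    "DEFAULT_MIN_ACCEPTED_DROPLETS",
]

logger = logging.getLogger(__name__)

#: Droplet volume in nanolitres. A common vendor constant; configurable
#: because instruments differ and absolute concentrations scale with it
#: (CNV, a ratio, does not).
DEFAULT_DROPLET_VOLUME_NL = 0.85

#: Wells with fewer accepted droplets are excluded from CNV estimation.
#: Well-run assays accept ~17,000–18,000 droplets per well.
DEFAULT_MIN_ACCEPTED_DROPLETS = 10_000


class SaturationError(ValueError):
    """All droplets positive: concentration not estimable."""


class EmptyWellError(ValueError):
    """Well has zero accepted droplets."""


class IncompleteSpecimenError(ValueError):
    """A specimen lacks wells for one of the two genes."""


class ZeroReferenceError(ZeroDivisionError):
    """Reference-gene concentration is zero; CNV undefined."""


@dataclass(frozen=True)
class DdpcrWell:
    """One well's thresholded droplet counts for one specimen and gene."""

    specimen_id: str
    gene_role: str  # "target" | "reference"
    n_positive: int
    n_negative: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    biological_replicate: int = 1

    def __post_init__(self) -> None:
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("droplet counts must be non-negative")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet volume must be positive")

    @property
    def n_total(self) -> int:
        return self.n_positive + self.n_negative


@dataclass(frozen=True)
class Concentration:
    """Template concentration with its Poisson occupancy."""

    copies_per_ul: float
    lam: float  # mean template copies per droplet


@dataclass(frozen=True)
class CnvResult:
    """A specimen's estimated target-gene copy number."""

    specimen_id: str
    method: str  # "ddPCR" | "qPCR"
    biological_replicate: int
    cnv: float
    calibrator_id: str | None = None
    run_id: str = ""


def poisson_concentration(well: DdpcrWell) -> Concentration:
    """Invert droplet occupancy to a template concentration.

    Raises :class:`EmptyWellError` when the well has no droplets and
    :class:`SaturationError` when every droplet is positive (the negative
    fraction is zero and λ diverges).
    """
    total = well.n_total
    if total == 0:
        raise EmptyWellError(f"well for {well.specimen_id}/{well.gene_role} is empty")
    if well.n_negative == 0:
        raise SaturationError(
            f"all {total} droplets positive for {well.specimen_id}/{well.gene_role}; "
            "concentration not estimable — dilute the sample"
        )
    lam = -math.log(well.n_negative / total)
    volume_ul = well.droplet_volume_nl * 1e-3
    return Concentration(copies_per_ul=lam / volume_ul, lam=lam)


def cnv_ddpcr(c_target: Concentration, c_reference: Concentration,
              reference_gene: str = "reference") -> float:
    """Copy number of the target gene: 2 · c_target / c_reference."""
    if c_reference.copies_per_ul <= 0:
        raise ZeroReferenceError(
            f"{reference_gene} concentration is zero; copy number undefined"
        )
    return 2.0 * c_target.copies_per_ul / c_reference.copies_per_ul


def _pool_wells(wells: list[DdpcrWell]) -> Concentration:
    """Merge replicate wells of one specimen × gene by summing droplets."""
    n_pos = sum(w.n_positive for w in wells)
    n_neg = sum(w.n_negative for w in wells)
    merged = DdpcrWell(
        specimen_id=wells[0].specimen_id,
        gene_role=wells[0].gene_role,
        n_positive=n_pos,
        n_negative=n_neg,
        droplet_volume_nl=wells[0].droplet_volume_nl,
        biological_replicate=wells[0].biological_replicate,
    )
    return poisson_concentration(merged)


def ddpcr_pipeline(
    wells: Iterable[DdpcrWell],
    min_accepted_droplets: int = DEFAULT_MIN_ACCEPTED_DROPLETS,
) -> list[CnvResult]:
    """Estimate one CNV per specimen per biological replicate.

    Wells below the accepted-droplet QC threshold are excluded and logged.
    Multiple passing wells for the same specimen × gene × replicate are
    pooled by summing droplet counts before Poisson inversion.

    Raises :class:`IncompleteSpecimenError` when a specimen (replicate) has
    passing wells for only one of the two genes.
    """
    groups: dict[tuple[str, int], dict[str, list[DdpcrWell]]] = {}
    order: list[tuple[str, int]] = []
    for well in wells:
        if well.n_total < min_accepted_droplets:
            logger.warning(
                "excluding well %s/%s (replicate %d): %d accepted droplets < %d",
                well.specimen_id, well.gene_role, well.biological_replicate,
                well.n_total, min_accepted_droplets,
            )
            continue
        key = (well.specimen_id, well.biological_replicate)
        if key not in groups:
            groups[key] = {}
            order.append(key)
        groups[key].setdefault(well.gene_role, []).append(well)

    results: list[CnvResult] = []
    for key in order:
        specimen_id, bio_rep = key
        by_gene = groups[key]
        missing = {"target", "reference"} - set(by_gene)
        if missing:
            raise IncompleteSpecimenError(
                f"specimen {specimen_id} (replicate {bio_rep}) lacks "
                f"{'/'.join(sorted(missing))} wells passing QC"
            )
        c_t = _pool_wells(by_gene["target"])
        c_r = _pool_wells(by_gene["reference"])
        results.append(
            CnvResult(
                specimen_id=specimen_id,
                method="ddPCR",
                biological_replicate=bio_rep,
                cnv=cnv_ddpcr(c_t, c_r),
            )
        )
    return results
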