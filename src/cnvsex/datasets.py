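"""Bundled reference dataset.

``collection_a`` is the optimisation cohort of the published Colorado
potato beetle assay: 10 morphologically sexed females (F1–F10) and 10
males (M1–M10), each measured in two biological replicates (head vs
thorax DNA extractions) by both ddPCR and qPCR — 80 CNV values in all.
It is the primary surface for validating the statistics battery and the
sex caller.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .ddpcr_quant import CnvResult

__all__ = ["collection_a", "collection_a_results"]


def collection_a() -> pd.DataFrame:
    """The bundled 20-adult validation cohort as a tidy DataFrame.

    Columns: specimen_id, true_sex, method, biological_replicate, cnv.
    """
    ref = resources.files("cnvsex.data").joinpath("collection_a_cnv.csv")
    with ref.open("rb") as fh:
        return pd.read_csv(fh)


def collection_a_results(method: str | None = None) -> list[CnvResult]:
    """The same cohort as :class:`CnvResult` records, optionally filtered
    to one method ("ddPCR" or "qPCR")."""
    df = collection_a()
    if method is not None:
        df = df[df["method"] == method]
    return [
        CnvResult(
            specimen_id=r.specimen_id,
            method=r.method,
            biological_replicate=int(r.biological_replicate),
            cnv=float(r.cnv),
            calibrator_id="M1" if r.method == "qPCR" else None,
        )
        for r in df.itertuples()
    ]
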