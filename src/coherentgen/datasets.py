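"""Packaged reference tables.

Ships the composition summary of the TCGA pan-cancer cohort the
framework was designed around: per-cancer-type sample totals and
per-modality availability counts, plus the train/validation/test split
sizes used with it.  These are bookkeeping inputs for consistency
checks and for configuring realistic synthetic cohorts — no patient-level
data is included.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_cohort_summary", "SPLIT_SIZES"]

#: train / validation / test sizes of the stratified cohort split
SPLIT_SIZES = (8305, 443, 1350)


def load_cohort_summary() -> pd.DataFrame:
    """Per-cancer-type cohort composition table.

    Columns: ``total_samples`` and the per-modality availability counts
    (``cna``, ``rnaseq``, ``rppa``, ``wsi``) plus ``complete`` /
    ``incomplete`` sample counts; indexed by cancer-type code.
    """
    ref = resources.files("coherentgen.data") / "tcga_pancancer_summary.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="cancer_type")
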