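"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import conception_theta


@dataclass
class MethylationMatrix:
    """Beta values (samples x CpGs) plus CpG genomic coordinates.

    ``betas`` rows are samples, columns are CpG ids; values lie in
    [0, 1] or are missing (e.g. after outlier masking). ``cpg_info`` is
    indexed by CpG id with ``chrom`` and 1-based ``pos`` columns.
    """

    betas: pd.DataFrame
    cpg_info: pd.DataFrame

    def __post_init__(self):
        vals = self.betas.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if np.any((vals[finite] < 0) | (vals[finite] > 1)):
            raise ValueError("beta values must lie in [0, 1] or be missing")
        if self.betas.columns.duplicated().any():
            raise ValueError("CpG ids must be unique")
        if (self.cpg_info["pos"] < 1).any():
            raise ValueError("CpG positions are 1-based and must be >= 1")

    @property
    def cpg_ids(self):
        return list(self.betas.columns)

    @property
    def n_samples(self) -> int:
        return self.betas.shape[0]


class SampleMetadata:
    """Per-sample phenotype and design information.

    Wraps a DataFrame (one row per sample) carrying at least a
    ``conception_date`` column; ``theta`` (the conception angle over the
    year) is derived on construction and kept consistent with the dates.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if "conception_date" not in frame.columns:
            raise ValueError("metadata requires a conception_date column")
        frame["theta"] = [conception_theta(pd.Timestamp(d).date())
                          for d in frame["conception_date"]]
        if "cell_fractions" in frame.columns:
            for cf in frame["cell_fractions"].dropna():
                if not np.isclose(np.sum(cf), 1.0):
                    raise ValueError("cell fractions must sum to 1")
        self.frame = frame

    @property
    def index(self):
        return self.frame.index

    def __getitem__(self, key):
        return self.frame[key]

    def __len__(self):
        return len(self.frame)
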