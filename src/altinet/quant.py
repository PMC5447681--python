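"""Expression quantification: RPKM and the log2 transform.

RPKM (reads per kilobase of feature per million mapped reads) for gene g in
sample s is

    rpkm(g, s) = count(g, s) / [ (length_bp(g) / 1e3) * (library_size(s) / 1e6) ]

Library sizes default to the column sums of the supplied count matrix when
no external mapped-read totals are provided. Downstream feature-space and
correlation analyses operate on log2(RPKM + 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CountMatrix


def rpkm(
    counts: CountMatrix, library_sizes: pd.Series | None = None
) -> pd.DataFrame:
    """Reads-per-kilobase-per-million normalization of a count matrix.

    Parameters
    ----------
    counts : CountMatrix
    library_sizes : Series, optional
        Mapped-read totals per sample. Derived from column sums when omitted.
    """
    if library_sizes is None:
        library_sizes = counts.library_sizes()
    else:
        library_sizes = pd.Series(library_sizes).reindex(counts.sample_ids)
        if library_sizes.isna().any():
            raise ValueError("library sizes missing for some samples")
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    kb = counts.lengths.to_numpy(dtype=float) / 1e3
    millions = library_sizes.to_numpy(dtype=float) / 1e6
    values = counts.counts.to_numpy(dtype=float) / kb[:, None] / millions[None, :]
    return pd.DataFrame(values, index=counts.counts.index, columns=counts.counts.columns)


def log_transform(expr: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(x + pseudocount), elementwise; shape preserved."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    return pd.DataFrame(
        np.log2(values + pseudocount), index=expr.index, columns=expr.columns
    )
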