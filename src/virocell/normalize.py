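"""Per-cell count normalization shared by the analysis stages.

Two denominators are meaningful in a hybrid host+virus matrix:

* ``"total"`` — counts-per-10k of all transcripts (the ordinary
  single-cell convention; used for annotation and for viral genes);
* ``"host"`` — counts-per-10k of host transcripts only. Used for
  host-gene analyses against viral load: with a total-count denominator
  every host gene would inherit a spurious negative coupling to the
  per-cell viral fraction v (its share of the library is scaled by 1-v),
  so correlations would no longer reflect gene-specific regulation.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from virocell.datatypes import ExpressionMatrix
from virocell.errors import ConfigurationError


def cp10k_log1p(
    matrix: ExpressionMatrix,
    genes: str = "host",
    denominator: str = "host",
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Counts-per-10k + log1p transform.

    Parameters
    ----------
    genes
        Which gene columns to return: ``"host"``, ``"viral"`` or ``"all"``.
    denominator
        Which counts form the per-cell library size: ``"host"`` or
        ``"total"``.

    Returns
    -------
    values, gene_index
        Sparse cells x selected-genes matrix of log1p(CP10K) values and
        the integer indices of the selected gene columns. Cells whose
        denominator is zero get all-zero rows.
    """
    if genes == "host":
        gmask = matrix.host_mask
    elif genes == "viral":
        gmask = matrix.viral_mask
    elif genes == "all":
        gmask = np.ones(matrix.n_genes, dtype=bool)
    else:
        raise ConfigurationError(f"unknown gene selection {genes!r}")
    if denominator == "host":
        dmask = matrix.host_mask
    elif denominator == "total":
        dmask = np.ones(matrix.n_genes, dtype=bool)
    else:
        raise ConfigurationError(f"unknown denominator {denominator!r}")

    totals = np.asarray(matrix.counts[:, dmask].sum(axis=1)).ravel().astype(float)
    scale = np.divide(1e4, totals, out=np.zeros_like(totals), where=totals > 0)
    sub = matrix.counts[:, gmask].tocsr().astype(float)
    values = sp.diags(scale) @ sub
    values = values.tocsr()
    np.log1p(values.data, out=values.data)
    return values, np.flatnonzero(gmask)
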