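"""Reference-based cell-composition estimation (Houseman-style projection).

Each blood sample's beta profile is modelled as a convex mixture of
reference cell-type profiles; the mixing weights — the estimated cell-type
proportions used as EWAS covariates — solve

    min_w || b_i - R^T w ||^2   s.t.  w >= 0,  sum(w) = 1

over the probes shared between the sample matrix and the reference panel.
The simplex constraint is enforced by augmenting the least-squares system
with a heavily weighted sum-to-one row and solving by non-negative least
squares, then renormalising; the solution is deterministic given inputs
and exact on noiseless mixtures.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .simulate import CellReference, MethylationMatrix

#: weight on the sum-to-one constraint row (residual sum deviation < 1e-9
#: at this weight on unit-scale problems)
_SUM_WEIGHT = 1000.0


def estimate_cell_proportions(
    beta: MethylationMatrix | pd.DataFrame,
    reference: CellReference,
    probe_subset: list[str] | None = None,
    top_variance: int | None = None,
) -> pd.DataFrame:
    """Estimate per-sample cell-type proportions.

    Parameters
    ----------
    beta
        Sample beta matrix (samples x probes); NaNs are allowed and are
        masked per sample.
    reference
        Mean beta profile per cell type.
    probe_subset
        Optional explicit probe list to project on.
    top_variance
        If given, restrict to the ``top_variance`` most variable probes
        across reference cell types (signature-probe style selection).

    Returns
    -------
    DataFrame (samples x cell types) of non-negative proportions summing
    to one per row.
    """
    df = beta.beta if isinstance(beta, MethylationMatrix) else beta
    ref = reference.mean_beta
    shared = [p for p in df.columns if p in set(ref.columns)]
    if probe_subset is not None:
        subset = set(probe_subset)
        shared = [p for p in shared if p in subset]
    if top_variance is not None and top_variance < len(shared):
        var = ref[shared].var(axis=0)
        shared = list(var.sort_values(ascending=False).index[:top_variance])
        shared.sort()  # order-invariance of the result
    k = ref.shape[0]
    if k < 2:
        raise ValueError("need >= 2 reference cell types for deconvolution")
    if len(shared) < k:
        raise ValueError(
            f"only {len(shared)} shared probes for {k} cell types; "
            "deconvolution is unidentifiable"
        )
    A = ref[shared].to_numpy().T  # probes x cell types
    if np.linalg.matrix_rank(A) < k:
        warnings.warn(
            "reference is rank-deficient on the probe intersection; "
            "falling back to pseudo-inverse projection"
        )
        W = np.clip(df[shared].to_numpy() @ np.linalg.pinv(A).T, 0.0, None)
        W /= W.sum(axis=1, keepdims=True)
        return pd.DataFrame(W, index=df.index, columns=ref.index)

    B = df[shared].to_numpy()
    ones = np.ones((1, k)) * _SUM_WEIGHT
    out = np.empty((len(df), k))
    for i in range(len(df)):
        b = B[i]
        mask = np.isfinite(b)
        if mask.sum() < k:
            raise ValueError(f"sample {df.index[i]} has < {k} finite shared probes")
        A_aug = np.vstack([A[mask], ones])
        b_aug = np.append(b[mask], _SUM_WEIGHT)
        w, _ = nnls(A_aug, b_aug)
        s = w.sum()
        if s == 0:
            raise RuntimeError(f"degenerate deconvolution for {df.index[i]}")
        out[i] = w / s
    return pd.DataFrame(out, index=df.index, columns=ref.index)
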