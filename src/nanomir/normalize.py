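"""Background correction and two-stage normalization.

The pipeline follows the nSolver order of operations: per-sample background
subtraction (geometric mean of that sample's negative controls, floored at
zero), positive-control normalization (geometric mean of the six positive
titration probes), then codeset-content normalization against the 100
endogenous probes with the highest mean expression. Each stage scales a
sample by mean(g)/g_s, where g_s is the sample's control geometric mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import geomean, log2p
from .rcc_io import CodeClass, CountMatrix

#: Factors outside these bounds are flagged (not excluded) as outliers.
FACTOR_BOUNDS = (0.3, 3.0)


@dataclass
class NormalizationFactors:
    """Per-sample scale factors and the content probe set used."""

    pos_factor: pd.Series
    content_factor: pd.Series
    top100_probes: list[str] = field(default_factory=list)
    out_of_range: pd.Series | None = None  # bool per sample


def background_subtract(matrix: CountMatrix) -> CountMatrix:
    """Subtract each sample's negative-control geometric mean, flooring at 0.

    Negative-control rows are retained unmodified for audit.
    """
    if matrix.stage != "raw":
        raise ValueError("background subtraction applies to raw counts")
    neg = matrix.class_view(CodeClass.NEGATIVE)
    if neg.shape[0] == 0:
        raise ValueError("matrix contains no Negative-class probes")
    out = matrix.counts.astype(float).copy()
    neg_rows = matrix.counts.index.isin(neg.index)
    for s in matrix.samples:
        bg = geomean(neg[s].to_numpy(), zero_replace=1.0)
        out.loc[~neg_rows, s] = np.maximum(out.loc[~neg_rows, s] - bg, 0.0)
    return matrix.with_counts(out, stage="background_subtracted")


def positive_control_factors(matrix: CountMatrix) -> pd.Series:
    """Per-sample positive-control factor: mean over samples of g / g_s."""
    pos = matrix.class_view(CodeClass.POSITIVE)
    if pos.shape[0] == 0:
        raise ValueError("matrix contains no Positive-class probes")
    g = {}
    for s in matrix.samples:
        g_s = geomean(pos[s].to_numpy(), zero_replace=None)
        if g_s == 0:
            raise ValueError(f"sample {s!r}: positive-control geometric mean is zero")
        g[s] = g_s
    g = pd.Series(g)
    return g.mean() / g


def content_factors(
    matrix: CountMatrix, n_top: int = 100
) -> tuple[list[str], pd.Series]:
    """Top-``n_top`` content normalization factors.

    The content set is the ``n_top`` endogenous probes with the highest mean
    count across all samples (ties broken by probe name ascending); factors
    are mean(h)/h_s on the geometric mean h_s of that set, with zeros
    replaced by 1 inside the geometric mean (a probe can rank into the top
    set on its mean yet be absent from individual samples). With fewer than
    ``n_top`` endogenous probes all of them are used, with a warning.
    """
    endo = matrix.endogenous()
    if endo.shape[0] == 0:
        raise ValueError("matrix contains no endogenous probes")
    if endo.shape[0] < n_top:
        warnings.warn(
            f"only {endo.shape[0]} endogenous probes available; "
            f"using all of them as the content set",
            stacklevel=2,
        )
    order = (
        endo.mean(axis=1)
        .to_frame("mean")
        .assign(name=endo.index)
        .sort_values(["mean", "name"], ascending=[False, True])
    )
    top = list(order.index[: min(n_top, endo.shape[0])])
    h = {}
    for s in matrix.samples:
        h_s = geomean(endo.loc[top, s].to_numpy(), zero_replace=1.0)
        if h_s == 0:
            raise ValueError(f"sample {s!r}: content geometric mean is zero")
        h[s] = h_s
    h = pd.Series(h)
    return top, h.mean() / h


def apply_normalization(
    matrix: CountMatrix, factors: NormalizationFactors
) -> CountMatrix:
    """Scale each sample by pos_factor x content_factor; stage becomes normalized."""
    missing = [
        s
        for s in matrix.samples
        if s not in factors.pos_factor.index or s not in factors.content_factor.index
    ]
    if missing:
        raise ValueError(f"normalization factors missing for samples: {missing}")
    scale = (factors.pos_factor * factors.content_factor)[matrix.samples]
    if np.any(scale.to_numpy() <= 0):
        raise ValueError("normalization factors must be positive")
    out = matrix.counts.astype(float) * scale
    return matrix.with_counts(out, stage="normalized")


def normalize_pipeline(
    matrix: CountMatrix,
    skip_content: bool = False,
    n_top: int = 100,
    factor_bounds: tuple[float, float] = FACTOR_BOUNDS,
) -> tuple[CountMatrix, NormalizationFactors]:
    """background subtraction -> positive-control -> top-100 content normalization.

    Content factors are computed on the positive-normalized counts, using the
    whole analysis set (never per group). Out-of-range factors are flagged,
    never excluded.
    """
    bs = background_subtract(matrix)
    pos = positive_control_factors(bs)
    pos_applied = bs.with_counts(bs.counts * pos[bs.samples], stage="background_subtracted")
    if skip_content:
        top, content = [], pd.Series(1.0, index=pos.index)
    else:
        top, content = content_factors(pos_applied, n_top=n_top)
    lo, hi = factor_bounds
    total = pos * content
    flags = (total < lo) | (total > hi)
    factors = NormalizationFactors(
        pos_factor=pos, content_factor=content, top100_probes=top, out_of_range=flags
    )
    return apply_normalization(bs, factors), factors


def fold_change(
    matrix: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-probe log2 ratio: mean log2(count+1) in A minus mean in B."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    la = log2p(matrix.counts[list(group_a)].to_numpy(), pseudocount).mean(axis=1)
    lb = log2p(matrix.counts[list(group_b)].to_numpy(), pseudocount).mean(axis=1)
    return pd.Series(la - lb, index=matrix.counts.index, name="log2fc")
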