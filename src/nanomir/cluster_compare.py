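"""Ward clustering of differential miRNAs and isolation-method concordance.

Clustering operates on row-wise z-scores of log2(normalized count + 1) and
uses Ward's agglomerative criterion in the ward.D2 convention (Euclidean
input distances, squared inside the objective), applied independently to
probes and to samples. The exported contract is the ordered scaled matrix
plus the two linkage tables; heatmap rendering is left to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from ._utils import log2p
from .detect import DetectionCalls
from .rcc_io import CountMatrix, SampleMeta


@dataclass
class ClusterResult:
    """Ordered, scaled matrix plus sample/probe linkage tables."""

    scaled_matrix: pd.DataFrame  # probes x samples z-scores
    probe_order: list[str]
    sample_order: list[str]
    probe_linkage: np.ndarray
    sample_linkage: np.ndarray
    constant_probes: list[str] = field(default_factory=list)

    def ordered_matrix(self) -> pd.DataFrame:
        return self.scaled_matrix.loc[self.probe_order, self.sample_order]


@dataclass
class MethodConcordance:
    """Per-pair detection overlap between manual and automated isolation."""

    per_pair: pd.DataFrame  # index pair label; columns common, manual_only, auto_only
    summary: pd.DataFrame  # mean / sd rows
    higher_in: pd.Series | None = None  # per-probe: manual | automated | tie


def zscore_rows(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row z-scores (ddof=1); constant rows become all-zero and are flagged."""
    mu = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    constant = list(X.index[sd == 0])
    sd_safe = sd.replace(0, 1.0)
    Z = X.sub(mu, axis=0).div(sd_safe, axis=0)
    return Z, constant


def ward_cluster(
    matrix: CountMatrix,
    probes: Sequence[str],
    pseudocount: float = 1.0,
) -> ClusterResult:
    """Ward (ward.D2) clustering of the given probes and of the samples.

    Deterministic for fixed input; equal-height merges are broken by the
    lowest pair index, scipy's convention.
    """
    probes = list(probes)
    if len(probes) < 2 or len(matrix.samples) < 2:
        raise ValueError("need at least 2 probes and 2 samples to cluster")
    X = pd.DataFrame(
        log2p(matrix.counts.loc[probes].to_numpy(), pseudocount),
        index=probes,
        columns=matrix.samples,
    )
    Z, constant = zscore_rows(X)
    probe_linkage = hierarchy.linkage(Z.to_numpy(), method="ward")
    sample_linkage = hierarchy.linkage(Z.to_numpy().T, method="ward")
    probe_order = [probes[i] for i in hierarchy.leaves_list(probe_linkage)]
    sample_order = [matrix.samples[i] for i in hierarchy.leaves_list(sample_linkage)]
    return ClusterResult(
        scaled_matrix=Z,
        probe_order=probe_order,
        sample_order=sample_order,
        probe_linkage=probe_linkage,
        sample_linkage=sample_linkage,
        constant_probes=constant,
    )


def cut_clusters(linkage: np.ndarray, k: int) -> np.ndarray:
    """Flat cluster labels from a linkage table (1..k)."""
    return hierarchy.fcluster(linkage, t=k, criterion="maxclust")


def method_concordance(
    calls_manual: DetectionCalls,
    calls_auto: DetectionCalls,
    pairing: Mapping[str, tuple[str, str]] | Sequence[tuple[str, str]],
    norm_manual: CountMatrix | None = None,
    norm_auto: CountMatrix | None = None,
) -> MethodConcordance:
    """Per-patient detection overlap between the two isolation methods.

    For each complete pair: counts of probes detected in both lanes, in the
    manual lane only, and in the automated lane only, summarized as
    mean +/- SD (n-1) across pairs (SD absent with a single pair). When
    normalized matrices are supplied, each probe is additionally labeled by
    which method shows the higher mean normalized count across pairs.
    """
    pairs = list(pairing.values()) if isinstance(pairing, Mapping) else list(pairing)
    pairs = [
        (m, a)
        for m, a in pairs
        if m in calls_manual.calls.columns and a in calls_auto.calls.columns
    ]
    if not pairs:
        raise ValueError("no complete pairs")
    rows = []
    for man, auto in pairs:
        cm = calls_manual.calls[man]
        ca = calls_auto.calls[auto].reindex(cm.index, fill_value=False)
        rows.append(
            {
                "pair": f"{man}|{auto}",
                "common": int((cm & ca).sum()),
                "manual_only": int((cm & ~ca).sum()),
                "auto_only": int((~cm & ca).sum()),
            }
        )
    per_pair = pd.DataFrame(rows).set_index("pair")
    summary = pd.DataFrame(
        {
            "mean": per_pair.mean(),
            "sd": per_pair.std(ddof=1) if len(per_pair) > 1 else np.nan,
        }
    )
    higher = None
    if norm_manual is not None and norm_auto is not None:
        man_ids = [m for m, _ in pairs]
        auto_ids = [a for _, a in pairs]
        mean_m = norm_manual.counts[man_ids].mean(axis=1)
        mean_a = norm_auto.counts[auto_ids].reindex(mean_m.index).mean(axis=1)
        higher = pd.Series(
            np.where(mean_m > mean_a, "manual", np.where(mean_m < mean_a, "automated", "tie")),
            index=mean_m.index,
            name="higher_in",
        )
    return MethodConcordance(per_pair=per_pair, summary=summary, higher_in=higher)


def age_correlation(
    matrix: CountMatrix,
    meta: Sequence[SampleMeta],
    probes: Sequence[str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Pearson r2 and two-sided p of log2(count+1) against age, per probe.

    Constant probes yield NaN with a ``constant`` flag.
    """
    by_id = {m.sample_id: m for m in meta}
    samples = [s for s in matrix.samples if s in by_id]
    if len(samples) < 3:
        raise ValueError("need at least 3 samples with age metadata")
    age = np.array([by_id[s].age for s in samples], dtype=float)
    if np.std(age) == 0:
        raise ValueError("age has zero variance")
    rows = []
    for probe in probes:
        y = log2p(matrix.counts.loc[probe, samples].to_numpy(), pseudocount)
        if np.std(y) == 0:
            rows.append({"probe": probe, "r2": np.nan, "p": np.nan, "constant": True})
            continue
        r, p = stats.pearsonr(age, y)
        rows.append({"probe": probe, "r2": float(r * r), "p": float(p), "constant": False})
    return pd.DataFrame(rows).set_index("probe")
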