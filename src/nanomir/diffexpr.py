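"""Differential expression between sample groups and related contrasts.

The group test is a two-sided Welch t-test on log2(normalized count + 1),
with the fold change defined as the difference of group means on that log2
scale and Benjamini-Hochberg adjusted p-values reported alongside the raw
ones. Volcano classification uses the raw p-value and a symmetric log2
fold-change threshold (up: log2FC > theta and p < alpha; down: mirrored).

An optional light-weight variance moderation shrinks each group's per-probe
variance toward the across-probe mean variance with a prior weight of
``n_mod`` pseudo-degrees of freedom - a simple stabilizer for small groups,
not an empirical-Bayes fit.

Also here: the three-stratum enzyme-replacement-therapy (ERT) contrast and
the patient-paired isolation-method test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import log2p
from .normalize import fold_change
from .rcc_io import CountMatrix, SampleMeta

logger = logging.getLogger(__name__)

DEFAULT_THETA = 1.5
DEFAULT_ALPHA = 0.05


@dataclass
class DeResult:
    """Per-probe differential-expression table plus the test's context."""

    table: pd.DataFrame  # columns: log2fc, p_value, p_adj, volcano_class, zero_variance
    n_a: int
    n_b: int
    theta: float
    alpha: float
    moderation: bool

    def counts(self) -> dict[str, int]:
        vc = self.table["volcano_class"].value_counts()
        return {k: int(vc.get(k, 0)) for k in ("up", "down", "ns")}


def _welch_arrays(
    xa: np.ndarray, xb: np.ndarray, moderation: bool, n_mod: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t-test over probe rows; returns (t, p)."""
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    dfa, dfb = float(na - 1), float(nb - 1)
    if moderation:
        va = (dfa * va + n_mod * va.mean()) / (dfa + n_mod)
        vb = (dfb * vb + n_mod * vb.mean()) / (dfb + n_mod)
        dfa, dfb = dfa + n_mod, dfb + n_mod
    sa, sb = va / na, vb / nb
    se2 = sa + sb
    t = np.zeros_like(ma)
    p = np.ones_like(ma)
    ok = se2 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t[ok] = (ma[ok] - mb[ok]) / np.sqrt(se2[ok])
        df = se2[ok] ** 2 / (sa[ok] ** 2 / dfa + sb[ok] ** 2 / dfb)
    p[ok] = 2 * stats.t.sf(np.abs(t[ok]), df)
    return t, p


def de_test(
    matrix: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    probes: Sequence[str] | None = None,
    moderation: bool = False,
    n_mod: float = 4.0,
    theta: float = DEFAULT_THETA,
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = 1.0,
) -> DeResult:
    """Welch t-test of group A vs group B on log2(count + pseudocount).

    ``probes`` restricts the test (typically to the prevalence-filtered set).
    Probes with zero variance in both groups (moderation off) get p = 1 and a
    ``zero_variance`` flag.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    sub = matrix.counts if probes is None else matrix.counts.loc[list(probes)]
    xa = log2p(sub[list(group_a)].to_numpy(), pseudocount)
    xb = log2p(sub[list(group_b)].to_numpy(), pseudocount)
    t, p = _welch_arrays(xa, xb, moderation, n_mod)
    zero_var = (xa.var(axis=1, ddof=1) + xb.var(axis=1, ddof=1)) == 0
    if np.any(zero_var) and not moderation:
        logger.warning("%d probes with zero within-group variance; p set to 1", int(zero_var.sum()))
    fc = fold_change(matrix, group_a, group_b, pseudocount=pseudocount)
    table = pd.DataFrame(
        {
            "log2fc": fc.loc[sub.index],
            "t": t,
            "p_value": p,
            "p_adj": multipletests(p, method="fdr_bh")[1],
            "zero_variance": zero_var,
        },
        index=sub.index,
    )
    result = DeResult(
        table=table,
        n_a=len(group_a),
        n_b=len(group_b),
        theta=theta,
        alpha=alpha,
        moderation=moderation,
    )
    return classify_volcano(result, theta, alpha)


def classify_volcano(de: DeResult, theta: float, alpha: float) -> DeResult:
    """Label probes up/down/ns at |log2FC| > theta and raw p < alpha."""
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    t = de.table.copy()
    sig = t["p_value"] < alpha
    t["volcano_class"] = "ns"
    t.loc[sig & (t["log2fc"] > theta), "volcano_class"] = "up"
    t.loc[sig & (t["log2fc"] < -theta), "volcano_class"] = "down"
    return DeResult(
        table=t,
        n_a=de.n_a,
        n_b=de.n_b,
        theta=theta,
        alpha=alpha,
        moderation=de.moderation,
    )


def _mwu(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value; degenerate all-tied input gives 1."""
    if np.all(x == x[0]) and np.all(y == x[0]):
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def ert_contrast(
    matrix: CountMatrix,
    meta: Sequence[SampleMeta],
    theta: float = DEFAULT_THETA,
    alpha: float = DEFAULT_ALPHA,
    probes: Sequence[str] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Three-stratum treatment contrast for differential probes.

    Stage 1 selects probes differential between healthy and untreated Fabry
    samples (|log2FC| > theta, Welch p < alpha). Stage 2 compares the
    ERT-treated stratum against both others with the two-sided Mann-Whitney
    U test. A probe is flagged ``recovered`` when the treated stratum differs
    significantly from the untreated one *toward* the healthy mean,
    ``unchanged`` when it does not differ from the untreated stratum, and
    ``other`` otherwise.
    """
    by_stratum: dict[str, list[str]] = {"healthy": [], "fabry_no_ert": [], "fabry_ert": []}
    in_matrix = set(matrix.samples)
    for m in meta:
        if m.sample_id in in_matrix:
            by_stratum[m.stratum].append(m.sample_id)
    for name, ids in by_stratum.items():
        if not ids:
            raise ValueError(f"stratum {name!r} is empty")

    stage1 = de_test(
        matrix,
        by_stratum["fabry_no_ert"],
        by_stratum["healthy"],
        probes=probes,
        theta=theta,
        alpha=alpha,
        pseudocount=pseudocount,
    )
    selected = stage1.table[stage1.table["volcano_class"] != "ns"].index

    X = pd.DataFrame(
        log2p(matrix.counts.to_numpy(), pseudocount),
        index=matrix.counts.index,
        columns=matrix.counts.columns,
    )
    rows = []
    for probe in selected:
        h = X.loc[probe, by_stratum["healthy"]].to_numpy()
        f0 = X.loc[probe, by_stratum["fabry_no_ert"]].to_numpy()
        f1 = X.loc[probe, by_stratum["fabry_ert"]].to_numpy()
        p_ert_vs_no = _mwu(f1, f0)
        p_ert_vs_h = _mwu(f1, h)
        toward_healthy = np.sign(f1.mean() - f0.mean()) == np.sign(h.mean() - f0.mean())
        if p_ert_vs_no >= alpha:
            flag = "unchanged"
        elif toward_healthy:
            flag = "recovered"
        else:
            flag = "other"
        rows.append(
            {
                "probe": probe,
                "mean_healthy": h.mean(),
                "mean_fabry_no_ert": f0.mean(),
                "mean_fabry_ert": f1.mean(),
                "log2fc_no_ert_vs_healthy": float(stage1.table.loc[probe, "log2fc"]),
                "p_no_ert_vs_healthy": float(stage1.table.loc[probe, "p_value"]),
                "p_ert_vs_no_ert": p_ert_vs_no,
                "p_ert_vs_healthy": p_ert_vs_h,
                "recovery_flag": flag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "probe",
            "mean_healthy",
            "mean_fabry_no_ert",
            "mean_fabry_ert",
            "log2fc_no_ert_vs_healthy",
            "p_no_ert_vs_healthy",
            "p_ert_vs_no_ert",
            "p_ert_vs_healthy",
            "recovery_flag",
        ],
    ).set_index("probe")


def paired_method_test(
    matrix_manual: CountMatrix,
    matrix_auto: CountMatrix,
    pairing: Mapping[str, tuple[str, str]] | Sequence[tuple[str, str]],
    probes: Sequence[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Patient-paired t-test of manual vs automated isolation, per probe.

    ``pairing`` maps patients to (manual sample id, automated sample id), or
    is a sequence of such pairs. Pairs with a missing sample in either matrix
    are excluded (logged); at least 3 complete pairs are required. The test
    is a two-sided paired t on per-patient differences of log2(count+1);
    ``direction`` is the sign of the mean difference.
    """
    pairs = list(pairing.values()) if isinstance(pairing, Mapping) else list(pairing)
    complete = []
    for man, auto in pairs:
        if man in matrix_manual.counts.columns and auto in matrix_auto.counts.columns:
            complete.append((man, auto))
        else:
            logger.warning("pair (%s, %s) incomplete; excluded", man, auto)
    if len(complete) < 3:
        raise ValueError(f"need >=3 complete pairs, have {len(complete)}")

    idx = matrix_manual.counts.index
    if probes is not None:
        idx = idx[idx.isin(set(probes))]
    man_ids = [m for m, _ in complete]
    auto_ids = [a for _, a in complete]
    xm = log2p(matrix_manual.counts.loc[idx, man_ids].to_numpy(), pseudocount)
    xa = log2p(matrix_auto.counts.loc[idx, auto_ids].to_numpy(), pseudocount)
    d = xm - xa
    n = d.shape[1]
    mean_d = d.mean(axis=1)
    sd_d = d.std(axis=1, ddof=1)
    t = np.zeros_like(mean_d)
    p = np.ones_like(mean_d)
    ok = sd_d > 0
    t[ok] = mean_d[ok] / (sd_d[ok] / np.sqrt(n))
    p[ok] = 2 * stats.t.sf(np.abs(t[ok]), n - 1)
    direction = np.where(mean_d > 0, "manual", np.where(mean_d < 0, "automated", "tie"))
    return pd.DataFrame(
        {
            "mean_log2_diff": mean_d,
            "t": t,
            "p_value": p,
            "p_adj": multipletests(p, method="fdr_bh")[1],
            "direction": direction,
            "significant": p < alpha,
            "n_pairs": n,
        },
        index=idx,
    )
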