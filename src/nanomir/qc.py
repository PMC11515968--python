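"""Assay quality control: limits of detection and the control battery.

The three-tier limit of detection (LOD) is derived from the negative
controls pooled over probes and samples:

* Low LOD    = geometric mean of all negative-control counts,
* Medium LOD = Low LOD + 2 x sample standard deviation of the same counts,
* High LOD   = 2 x Medium LOD.

Zeros are replaced by 1 inside the geometric mean (so log2(1) = 0 enters the
mean); the standard deviation is the arithmetic n-1 SD of the raw counts on
the linear scale. The remaining checks are positive-control titration
linearity, ligation-control exceedance against the LOD tiers, lane scan
metrics (FOV, binding density) and the input-concentration/total-count
correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import geomean, log2p
from .rcc_io import CodeClass, CountMatrix, LaneAttributes, SampleMeta

#: Platform-convention defaults, not study-reported values.
BINDING_DENSITY_RANGE = (0.1, 2.25)
FOV_RATIO_THRESHOLD = 0.75

#: Default positive-control titration, a 4-fold geometric series in fM.
DEFAULT_POSITIVE_CONCS = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)


@dataclass(frozen=True)
class LodThresholds:
    """The Low/Medium/High detection triplet."""

    low: float
    medium: float
    high: float
    scope: str = "per_dataset"

    def __post_init__(self):
        if self.high != 2 * self.medium:
            raise ValueError("High LOD must equal exactly 2 x Medium LOD")
        if self.medium < self.low:
            raise ValueError("Medium LOD cannot be below Low LOD")

    @classmethod
    def from_low_medium(
        cls, low: float, medium: float, scope: str = "per_dataset"
    ) -> "LodThresholds":
        """Apply the High-LOD doubling rule to a given Low/Medium pair."""
        return cls(low=low, medium=medium, high=2 * medium, scope=scope)

    @classmethod
    def from_negative_counts(
        cls, counts, scope: str = "per_dataset"
    ) -> "LodThresholds":
        """Derive the triplet from pooled negative-control counts."""
        v = np.asarray(counts, dtype=float).ravel()
        if v.size == 0:
            raise ValueError("no negative-control counts")
        if np.all(v == 0):
            raise ValueError("background undefined: all negative-control counts are zero")
        low = geomean(v, zero_replace=1.0)
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        return cls.from_low_medium(low, low + 2 * sd, scope=scope)


def compute_lod(matrix: CountMatrix, scope: str = "per_dataset"):
    """Three-tier LOD from the matrix's negative controls.

    ``scope="per_dataset"`` (default) pools negatives over probes and samples
    and returns one :class:`LodThresholds`; ``scope="per_sample"`` returns a
    ``{sample_id: LodThresholds}`` mapping.
    """
    if matrix.stage != "raw":
        raise ValueError("LOD is defined on raw counts")
    neg = matrix.class_view(CodeClass.NEGATIVE)
    if neg.shape[0] == 0:
        raise ValueError("matrix contains no Negative-class probes")
    if scope == "per_dataset":
        return LodThresholds.from_negative_counts(neg.to_numpy())
    if scope == "per_sample":
        return {
            s: LodThresholds.from_negative_counts(neg[s].to_numpy(), scope="per_sample")
            for s in matrix.samples
        }
    raise ValueError(f"unknown LOD scope {scope!r}")


def positive_control_linearity(
    matrix: CountMatrix,
    nominal_concs: Mapping[str, float] | None = None,
    r2_pass: float = 0.95,
) -> pd.DataFrame:
    """Per-sample titration linearity of the positive controls.

    Ordinary least squares of log2(count+1) on log2(nominal fM); the reported
    r2 is the squared Pearson correlation of the two vectors. Pass at
    r2 >= ``r2_pass`` (the platform acceptance bound).
    """
    pos = matrix.class_view(CodeClass.POSITIVE)
    if nominal_concs is None:
        nominal_concs = {
            p.name: p.nominal_conc_fM
            for p in matrix.codeset.probes_of(CodeClass.POSITIVE)
            if p.nominal_conc_fM is not None
        }
    probes = [p for p in pos.index if p in nominal_concs]
    concs = np.array([nominal_concs[p] for p in probes], dtype=float)
    if len(set(concs)) < 3:
        raise ValueError("need >=3 positive probes with distinct nominal concentrations")
    x = np.log2(concs)
    rows = []
    for s in matrix.samples:
        y = log2p(pos.loc[probes, s].to_numpy())
        if np.all(y == y[0]):
            r2, slope = 0.0, 0.0
        else:
            slope, _ = np.polyfit(x, y, 1)
            r = np.corrcoef(x, y)[0, 1]
            r2 = float(r * r)
        rows.append(
            {
                "sample_id": s,
                "pos_linearity_r2": r2,
                "pos_linearity_slope": float(slope),
                "pos_linearity_pass": bool(r2 >= r2_pass),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def _ligation_probes(matrix: CountMatrix) -> tuple[list[str], list[str]]:
    lig = matrix.codeset.probes_of(CodeClass.LIGATION)
    pos = [p.name for p in lig if "POS" in p.name.upper()]
    neg = [p.name for p in lig if "NEG" in p.name.upper()]
    if not pos or not neg:
        raise ValueError("matrix lacks ligation-positive and/or ligation-negative probes")
    return pos, neg


def ligation_qc(matrix: CountMatrix, lod: LodThresholds) -> pd.DataFrame:
    """Ligation-control exceedance flags per sample.

    Ligation negatives should stay below the Medium LOD; ligation positives
    should exceed all three tiers. The sample summary passes when every
    negative is below Medium and every positive is above Low.
    """
    pos_names, neg_names = _ligation_probes(matrix)
    counts = matrix.class_view(CodeClass.LIGATION)
    rows = []
    for s in matrix.samples:
        neg = counts.loc[neg_names, s].to_numpy(dtype=float)
        pos = counts.loc[pos_names, s].to_numpy(dtype=float)
        row = {
            "sample_id": s,
            "neg_below_low": bool(np.all(neg < lod.low)),
            "neg_below_medium": bool(np.all(neg < lod.medium)),
            "pos_above_low": bool(np.all(pos > lod.low)),
            "pos_above_medium": bool(np.all(pos > lod.medium)),
            "pos_above_high": bool(np.all(pos > lod.high)),
        }
        row["ligation_pass"] = row["neg_below_medium"] and row["pos_above_low"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def lane_scan_qc(
    lane_attrs: Mapping[str, LaneAttributes],
    binding_density_range: tuple[float, float] = BINDING_DENSITY_RANGE,
    fov_ratio_threshold: float = FOV_RATIO_THRESHOLD,
) -> pd.DataFrame:
    """Imaging QC from lane attributes: FOV counted ratio and binding density."""
    lo, hi = binding_density_range
    rows = []
    for s, a in lane_attrs.items():
        if a.fov_count == 0:
            raise ValueError(f"sample {s}: fov_count is zero")
        ratio = a.fov_counted / a.fov_count
        rows.append(
            {
                "sample_id": s,
                "fov_ratio": ratio,
                "fov_pass": bool(ratio >= fov_ratio_threshold),
                "binding_density": a.binding_density,
                "binding_density_pass": bool(lo <= a.binding_density <= hi),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def input_count_correlation(
    meta: Sequence[SampleMeta],
    matrix: CountMatrix,
    uncorrelated_below: float = 0.3,
) -> pd.DataFrame:
    """Pearson correlation of RNA input concentration vs total endogenous counts.

    Computed for the whole dataset and within each isolation method; a
    stratum with r2 below ``uncorrelated_below`` is flagged uncorrelated
    (input amount does not drive the counts). Empty strata are skipped;
    a nonempty stratum needs >= 3 samples.
    """
    totals = matrix.endogenous().sum(axis=0)
    by_id = {m.sample_id: m for m in meta}
    missing = [s for s in matrix.samples if s not in by_id]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    strata = {
        "all": list(matrix.samples),
        "manual": [s for s in matrix.samples if by_id[s].method == "manual"],
        "automated": [s for s in matrix.samples if by_id[s].method == "automated"],
    }
    rows = []
    for name, samples in strata.items():
        if not samples:
            continue
        if len(samples) < 3:
            raise ValueError(f"stratum {name!r} has fewer than 3 samples")
        x = np.array([by_id[s].input_conc_ng_per_uL for s in samples])
        y = totals[samples].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"stratum {name!r}: r2 undefined (zero variance)")
        r, p = stats.pearsonr(x, y)
        slope, _ = np.polyfit(x, y, 1)
        rows.append(
            {
                "stratum": name,
                "n": len(samples),
                "r2": float(r * r),
                "p": float(p),
                "slope": float(slope),
                "uncorrelated": bool(r * r < uncorrelated_below),
            }
        )
    return pd.DataFrame(rows).set_index("stratum")


@dataclass
class QcReport:
    """The assembled QC battery for a dataset."""

    lod: LodThresholds
    per_sample: pd.DataFrame  # linearity + ligation + lane scan columns
    input_correlation: pd.DataFrame | None = None

    def to_tsv(self, path) -> None:
        self.per_sample.to_csv(path, sep="\t")

    def to_json(self, path) -> None:
        payload = {
            "lod": asdict(self.lod),
            "per_sample": json.loads(self.per_sample.to_json(orient="index")),
            "input_correlation": None
            if self.input_correlation is None
            else json.loads(self.input_correlation.to_json(orient="index")),
            "thresholds": {
                "binding_density_range": list(BINDING_DENSITY_RANGE),
                "fov_ratio_threshold": FOV_RATIO_THRESHOLD,
                "note": "binding-density and FOV bounds are platform conventions",
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def qc_report(
    matrix: CountMatrix,
    meta: Sequence[SampleMeta] | None = None,
    r2_pass: float = 0.95,
    lod_scope: str = "per_dataset",
) -> QcReport:
    """Run the full QC battery on a raw count matrix."""
    lod = compute_lod(matrix, scope="per_dataset")
    parts = [
        positive_control_linearity(matrix, r2_pass=r2_pass),
        ligation_qc(matrix, lod),
        lane_scan_qc(matrix.lane_attrs),
    ]
    per_sample = pd.concat(parts, axis=1)
    corr = None
    if meta is not None:
        corr = input_count_correlation(meta, matrix)
    if lod_scope == "per_sample":
        per_lod = compute_lod(matrix, scope="per_sample")
        per_sample["lod_low"] = [per_lod[s].low for s in per_sample.index]
        per_sample["lod_medium"] = [per_lod[s].medium for s in per_sample.index]
        per_sample["lod_high"] = [per_lod[s].high for s in per_sample.index]
    return QcReport(lod=lod, per_sample=per_sample, input_correlation=corr)
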