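import numpy as np
import pandas as pd
import pytest

from nanomir import (
    CodeClass,
    CodeSet,
    CountMatrix,
    LaneAttributes,
    ProbeRecord,
    SyntheticConfig,
)


def build_matrix(
    endo: dict[str, list[float]],
    negatives: dict[str, list[float]] | None = None,
    positives: dict[str, tuple[float, list[float]]] | None = None,
    ligation: dict[str, list[float]] | None = None,
    sample_ids: list[str] | None = None,
    stage: str = "raw",
) -> CountMatrix:
    """Assemble a CountMatrix from per-probe count rows.

    ``positives`` maps probe name -> (nominal fM, counts row). Lane
    attributes are filled with neutral values.
    """
    n = len(next(iter(endo.values())))
    samples = sample_ids or [f"S{i + 1:02d}" for i in range(n)]
    probes, rows = [], {}
    for name, counts in endo.items():
        probes.append(ProbeRecord(CodeClass.ENDOGENOUS, name))
        rows[name] = counts
    for name, (conc, counts) in (positives or {}).items():
        probes.append(ProbeRecord(CodeClass.POSITIVE, name, nominal_conc_fM=conc))
        rows[name] = counts
    for name, counts in (negatives or {}).items():
        probes.append(ProbeRecord(CodeClass.NEGATIVE, name))
        rows[name] = counts
    for name, counts in (ligation or {}).items():
        probes.append(ProbeRecord(CodeClass.LIGATION, name))
        rows[name] = counts
    codeset = CodeSet(probes=probes, panel_name="TEST")
    counts = pd.DataFrame(rows).T.loc[[p.name for p in probes]]
    counts.columns = samples
    lane_attrs = {
        s: LaneAttributes(
            sample_id=s, fov_count=555, fov_counted=550, binding_density=0.8
        )
        for s in samples
    }
    return CountMatrix(codeset=codeset, counts=counts, lane_attrs=lane_attrs, stage=stage)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_config():
    """A fast generator configuration for round-trip and pipeline tests."""
    return SyntheticConfig(
        n_endogenous=40,
        strata={
            "manual": {"healthy": 4, "fabry_no_ert": 3, "fabry_ert": 3},
            "automated": {"healthy": 4, "fabry_no_ert": 3, "fabry_ert": 3},
        },
        paired_per_stratum={"healthy": 2, "fabry_no_ert": 1, "fabry_ert": 1},
        seed=0,
    )
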