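"""End-to-end orchestration: simulate/load -> QC -> normalize -> detect ->
differential expression -> clustering -> method comparison, with a
machine-readable provenance manifest.

Stages communicate through on-disk TSV/JSON artifacts under the run
directory so every intermediate is inspectable and diffable. The analysis is
stratified by isolation method, mirroring a design where each method's lanes
form their own batch with their own LOD and normalization.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cluster_compare import method_concordance, ward_cluster
from .detect import call_detection, detection_partition, prevalence_filter
from .diffexpr import de_test, ert_contrast, paired_method_test
from .normalize import normalize_pipeline
from .qc import compute_lod, qc_report
from .rcc_io import CountMatrix, SampleMeta, assemble_matrix, read_rcc, read_sample_meta
from .synthetic_data import SyntheticConfig, emit_fixture_suite

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults are the study's stated thresholds."""

    out_dir: str = "nanomir_run"
    seed: int = 0
    simulate: dict | None = None  # SyntheticConfig overrides; None -> load inputs
    rcc_dir: str | None = None
    meta_csv: str | None = None

    prevalence: float = 0.15
    theta: float = 1.5
    heatmap_theta: float = 0.5
    alpha: float = 0.05
    r2_pass: float = 0.95
    lod_scope: str = "per_dataset"
    moderation: bool = False
    skip_content: bool = False

    gmt: str | None = None
    interactions: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.prevalence <= 1:
            raise ValueError("prevalence must be in (0, 1]")
        if self.theta < 0 or self.heatmap_theta < 0:
            raise ValueError("fold-change thresholds must be nonnegative")
        if not 0 < self.r2_pass <= 1:
            raise ValueError("r2_pass must be in (0, 1]")
        if self.simulate is None and (self.rcc_dir is None or self.meta_csv is None):
            raise ValueError("either a simulate block or rcc_dir + meta_csv is required")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_inputs(config: RunConfig, out: Path) -> tuple[CountMatrix, list[SampleMeta], list[Path]]:
    if config.simulate is not None:
        sim = SyntheticConfig(**{**config.simulate, "seed": config.seed})
        suite = emit_fixture_suite(sim, out / "fixtures")
        rcc_paths = list(suite["rcc"])
        meta = read_sample_meta(suite["metadata"])
        codeset = suite["matrix"].codeset
        inputs = rcc_paths + [suite["metadata"]]
    else:
        rcc_paths = sorted(Path(config.rcc_dir).glob("*.RCC"))
        if not rcc_paths:
            raise ValueError(f"no RCC files under {config.rcc_dir}")
        meta = read_sample_meta(config.meta_csv)
        codeset = None
        inputs = rcc_paths + [Path(config.meta_csv)]
    lanes = [read_rcc(p) for p in rcc_paths]
    if codeset is None:
        from .rcc_io import CodeSet

        codeset = CodeSet(probes=lanes[0].probes, panel_name=lanes[0].gene_rlf or "panel")
    matrix = assemble_matrix(lanes, codeset, meta)
    return matrix, meta, inputs


def _subset(matrix: CountMatrix, samples: list[str]) -> CountMatrix:
    return CountMatrix(
        codeset=matrix.codeset,
        counts=matrix.counts[samples],
        lane_attrs={s: matrix.lane_attrs[s] for s in samples},
        stage=matrix.stage,
    )


def run_pipeline(config: RunConfig) -> Path:
    """Run every applicable stage; returns the run directory.

    Stage outputs are written under ``<out_dir>``; ``manifest.json`` records
    package/library versions, the seed, all thresholds, the SHA-256 of every
    input file, and the list of outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, meta, inputs = _load_inputs(config, out)
    by_id = {m.sample_id: m for m in meta}
    outputs: list[str] = []

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        outputs.append(name)

    methods = sorted({m.method for m in meta})
    method_artifacts: dict[str, dict] = {}
    for method in methods:
        samples = [s for s in matrix.samples if by_id[s].method == method]
        sub = _subset(matrix, samples)
        sub_meta = [by_id[s] for s in samples]
        logger.info("stage=qc method=%s n=%d", method, len(samples))
        report = qc_report(sub, sub_meta, r2_pass=config.r2_pass, lod_scope=config.lod_scope)
        emit(f"qc_{method}.tsv", report.to_tsv)
        emit(f"qc_{method}.json", report.to_json)

        lod = compute_lod(sub)
        calls = call_detection(sub, lod, prevalence_threshold=config.prevalence)
        detected = prevalence_filter(calls)
        healthy = [s for s in samples if by_id[s].group == "healthy"]
        fabry = [s for s in samples if by_id[s].group == "fabry"]
        partition = None
        if healthy and fabry:
            partition = detection_partition(calls, fabry, healthy)
            emit(
                f"detection_partition_{method}.json",
                lambda p, part=partition: Path(p).write_text(
                    json.dumps(part.to_dict(), indent=2)
                ),
            )

        logger.info("stage=normalize method=%s", method)
        normalized, factors = normalize_pipeline(sub, skip_content=config.skip_content)
        emit(f"normalized_{method}.tsv", normalized.to_tsv)
        emit(
            f"factors_{method}.tsv",
            lambda p, f=factors: pd.DataFrame(
                {
                    "pos_factor": f.pos_factor,
                    "content_factor": f.content_factor,
                    "out_of_range": f.out_of_range,
                }
            ).to_csv(p, sep="\t", index_label="sample_id"),
        )
        out_of_range = (
            factors.out_of_range if factors.out_of_range is not None else pd.Series(dtype=bool)
        )
        for s, flag in out_of_range.items():
            if flag:
                logger.warning("stage=normalize method=%s sample=%s out-of-range factor", method, s)

        de = None
        endo_detected = [p for p in detected if p in set(normalized.endogenous().index)]
        if len(healthy) >= 2 and len(fabry) >= 2 and endo_detected:
            logger.info("stage=diffexpr method=%s probes=%d", method, len(endo_detected))
            de = de_test(
                normalized,
                fabry,
                healthy,
                probes=endo_detected,
                moderation=config.moderation,
                theta=config.theta,
                alpha=config.alpha,
            )
            emit(
                f"de_{method}.tsv",
                lambda p, d=de: d.table.to_csv(p, sep="\t", index_label="probe"),
            )
            heat = de.table[
                (de.table["log2fc"].abs() > config.heatmap_theta)
                & (de.table["p_value"] < config.alpha)
            ].index
            if len(heat) >= 2:
                cluster = ward_cluster(normalized, list(heat))
                emit(
                    f"cluster_{method}.json",
                    lambda p, c=cluster: Path(p).write_text(
                        json.dumps(
                            {
                                "probe_order": c.probe_order,
                                "sample_order": c.sample_order,
                                "probe_linkage": c.probe_linkage.tolist(),
                                "sample_linkage": c.sample_linkage.tolist(),
                                "constant_probes": c.constant_probes,
                            },
                            indent=2,
                        )
                    ),
                )
                emit(
                    f"cluster_{method}.tsv",
                    lambda p, c=cluster: c.ordered_matrix().to_csv(
                        p, sep="\t", index_label="probe"
                    ),
                )
        strata = {m.stratum for m in sub_meta}
        if {"healthy", "fabry_no_ert", "fabry_ert"} <= strata and de is not None:
            ert = ert_contrast(
                normalized,
                sub_meta,
                theta=config.theta,
                alpha=config.alpha,
                probes=endo_detected,
            )
            emit(
                f"ert_{method}.tsv",
                lambda p, e=ert: e.to_csv(p, sep="\t"),
            )
        method_artifacts[method] = {
            "matrix": sub,
            "normalized": normalized,
            "calls": calls,
            "detected": detected,
        }

    # cross-method comparison over dual-method patients
    if {"manual", "automated"} <= set(methods):
        pairs = _pairing(meta)
        if pairs:
            man, auto = method_artifacts["manual"], method_artifacts["automated"]
            conc = method_concordance(
                man["calls"], auto["calls"], pairs, man["normalized"], auto["normalized"]
            )
            emit(
                "method_concordance.tsv",
                lambda p, c=conc: c.per_pair.to_csv(p, sep="\t"),
            )
            emit(
                "method_concordance_summary.tsv",
                lambda p, c=conc: c.summary.to_csv(p, sep="\t"),
            )
            if len(pairs) >= 3:
                both = sorted(set(man["detected"]) & set(auto["detected"]))
                paired = paired_method_test(
                    man["normalized"], auto["normalized"], pairs, probes=both, alpha=config.alpha
                )
                emit(
                    "paired_method_test.tsv",
                    lambda p, t=paired: t.to_csv(p, sep="\t", index_label="probe"),
                )

    manifest = {
        "nanomir_version": __version__,
        "library_versions": _library_versions(),
        "seed": config.seed,
        "thresholds": {
            "prevalence": config.prevalence,
            "theta": config.theta,
            "heatmap_theta": config.heatmap_theta,
            "alpha": config.alpha,
            "r2_pass": config.r2_pass,
            "lod_scope": config.lod_scope,
            "moderation": config.moderation,
            "skip_content": config.skip_content,
        },
        "config": dataclasses.asdict(config),
        "inputs": {str(p.name): _sha256(Path(p)) for p in inputs},
        "outputs": sorted(outputs),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _pairing(meta: list[SampleMeta]) -> list[tuple[str, str]]:
    """Dual-method (manual, automated) sample pairs keyed by patient id."""
    by_patient: dict[str, dict[str, str]] = {}
    for m in meta:
        if m.patient_id:
            by_patient.setdefault(m.patient_id, {})[m.method] = m.sample_id
    return [
        (d["manual"], d["automated"])
        for pid, d in sorted(by_patient.items())
        if "manual" in d and "automated" in d
    ]


def _library_versions() -> dict[str, str]:
    import numpy
    import pandas
    import scipy
    import statsmodels

    return {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "statsmodels": statsmodels.__version__,
    }
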