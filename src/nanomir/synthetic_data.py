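"""Synthetic RCC fixture generation with a ground-truth ledger.

The generator emulates the statistical structure of a serum-miRNA nCounter
study: an 827-probe endogenous codeset with the standard control classes,
lognormal baseline abundances, Poisson negative-control background, a
geometric positive-control titration, per-lane scale factors, group
(disease) log2 fold-change effects, treatment-recovery effects, per-probe
isolation-method capture offsets, and optional detection dropout. All
log-scale parameters are base 2, the scale on which fold changes are
analyzed. A single seeded RNG stream makes every output byte-reproducible,
and the ledger records exactly which effects were injected.
"""

from __future__ import annotations

import dataclasses
import json
import math
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rcc_io import (
    CodeClass,
    CodeSet,
    CountMatrix,
    LaneAttributes,
    ProbeRecord,
    SampleMeta,
    write_rcc,
    write_sample_meta,
)

SPIKEIN_NAMES = ("ath-miR-159a", "cel-miR-248", "cel-miR-254", "osa-miR-414", "osa-miR-442")
HOUSEKEEPING_NAMES = ("RPL10", "ACTB", "B2M", "GAPDH", "RPL19")


def _default_strata() -> dict[str, dict[str, int]]:
    # 24 manual + 23 automated lanes, matching the study's cohort structure
    return {
        "manual": {"healthy": 10, "fabry_no_ert": 5, "fabry_ert": 9},
        "automated": {"healthy": 12, "fabry_no_ert": 4, "fabry_ert": 7},
    }


def _default_paired() -> dict[str, int]:
    # 8 dual-method subjects: 2 healthy, 6 patients
    return {"healthy": 2, "fabry_no_ert": 2, "fabry_ert": 4}


@dataclass
class SyntheticConfig:
    """Parameters of the fixture generator (defaults emulate the study design)."""

    n_endogenous: int = 827
    n_positive: int = 6
    n_negative: int = 8
    n_ligation: int = 6  # split evenly into positive/negative ligation controls
    n_spikein: int = 5
    n_housekeeping: int = 5
    strata: dict[str, dict[str, int]] = field(default_factory=_default_strata)
    paired_per_stratum: dict[str, int] = field(default_factory=_default_paired)

    # abundance model (log2-scale lognormals)
    baseline_meanlog2: float = math.log2(20.0)
    baseline_sdlog2: float = 2.2
    noise_sdlog2: float = 0.5
    lane_scale_sdlog2: float = 0.2
    negative_lambda: float = 16.0
    endogenous_background_lambda: float = 2.0

    # controls
    positive_concs: tuple[float, ...] = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)
    pos_slope_counts_per_fM: float = 250.0
    pos_noise_sdlog2: float = 0.07
    ligation_pos_mean: float = 600.0
    spikein_mean: float = 400.0
    housekeeping_mean: float = 1000.0

    # injected effects
    n_de_probes: int = 0
    de_log2fc: float = 2.0
    de_probes: dict[str, float] | None = None  # explicit {probe: log2fc} override
    de_min_abundance: float = 128.0
    ert_recovery_fraction: float = 0.7
    group_exclusive: dict[str, int] = field(default_factory=lambda: {"fabry": 0, "healthy": 0})
    exclusive_abundance: float = 150.0
    method_effect: dict[str, float] = field(default_factory=dict)
    dropout_rate: float = 0.0

    seed: int = 0

    def __post_init__(self):
        if self.n_positive != len(self.positive_concs):
            raise ValueError("n_positive must match the titration series length")
        if self.n_ligation % 2 != 0:
            raise ValueError("n_ligation must split evenly into positive/negative")
        if self.n_spikein > len(SPIKEIN_NAMES) or self.n_housekeeping > len(HOUSEKEEPING_NAMES):
            raise ValueError("not enough named spike-in/housekeeping probes")
        for f in ("baseline_sdlog2", "noise_sdlog2", "lane_scale_sdlog2"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")
        if self.negative_lambda <= 0:
            raise ValueError("negative_lambda must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0 <= self.ert_recovery_fraction <= 1:
            raise ValueError("ert_recovery_fraction must be in [0, 1]")

    def n_samples(self) -> int:
        return sum(n for per in self.strata.values() for n in per.values())


@dataclass
class GroundTruthLedger:
    """Record of every injected effect, for recovery tests."""

    seed: int
    config: dict
    true_log2fc: dict[str, float]  # fabry-vs-healthy effects, per planted probe
    recovering_probes: list[str]  # effects removed in the ERT stratum
    non_recovering_probes: list[str]
    group_exclusive: dict[str, list[str]]  # group -> probes present only there
    method_effect: dict[str, float]  # probe -> log2 capture offset (manual - automated)
    base_abundance: dict[str, float]  # per-probe baseline mean counts

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruthLedger":
        with open(path) as fh:
            return cls(**json.load(fh))


def generate_codeset(config: SyntheticConfig) -> CodeSet:
    """Deterministic synthetic codeset with the standard control classes."""
    letters = string.ascii_uppercase
    probes: list[ProbeRecord] = []
    for i in range(config.n_endogenous):
        probes.append(
            ProbeRecord(CodeClass.ENDOGENOUS, f"hsa-miR-synth-{i + 1:04d}", f"SYN{i + 1:06d}")
        )
    for i, conc in enumerate(config.positive_concs):
        probes.append(
            ProbeRecord(CodeClass.POSITIVE, f"POS_{letters[i]}({conc:g})", "ERCC", conc)
        )
    for i in range(config.n_negative):
        probes.append(ProbeRecord(CodeClass.NEGATIVE, f"NEG_{letters[i]}(0)", "ERCC"))
    half = config.n_ligation // 2
    lig_concs = [32.0, 8.0, 2.0]
    for i in range(half):
        conc = lig_concs[i % len(lig_concs)]
        probes.append(ProbeRecord(CodeClass.LIGATION, f"LIG_POS_{letters[i]}", "LIG", conc))
    for i in range(half):
        probes.append(ProbeRecord(CodeClass.LIGATION, f"LIG_NEG_{letters[i]}", "LIG"))
    for name in SPIKEIN_NAMES[: config.n_spikein]:
        probes.append(ProbeRecord(CodeClass.SPIKEIN, name, "SPIKE"))
    for name in HOUSEKEEPING_NAMES[: config.n_housekeeping]:
        probes.append(ProbeRecord(CodeClass.HOUSEKEEPING, name, "HK"))
    return CodeSet(probes=probes)


def _make_meta(config: SyntheticConfig, rng: np.random.Generator) -> list[SampleMeta]:
    prefixes = {"manual": "MAN", "automated": "AUTO"}
    codes = {"healthy": "H", "fabry_no_ert": "F", "fabry_ert": "FE"}
    # patient-level attributes are drawn once and shared across methods for
    # the dual-method subjects
    patients: dict[str, dict] = {}

    def patient(pid: str, group: str) -> dict:
        if pid not in patients:
            patients[pid] = {
                "age": float(rng.integers(25, 71)),
                "gender": "M" if rng.random() < 0.5 else "F",
                "group": group,
            }
        return patients[pid]

    meta: list[SampleMeta] = []
    next_pid = 1
    paired_ids: dict[tuple[str, int], str] = {}
    for method in config.strata:
        for stratum, n in config.strata[method].items():
            n_paired = min(config.paired_per_stratum.get(stratum, 0), n)
            for i in range(n):
                if i < n_paired:
                    key = (stratum, i)
                    if key not in paired_ids:
                        paired_ids[key] = f"P{next_pid:03d}"
                        next_pid += 1
                    pid = paired_ids[key]
                else:
                    pid = f"P{next_pid:03d}"
                    next_pid += 1
                group = "healthy" if stratum == "healthy" else "fabry"
                info = patient(pid, group)
                if method == "manual":
                    conc = float(np.round(2 ** rng.normal(math.log2(5.76), 1.0), 3))
                else:
                    conc = float(np.round(2 ** rng.normal(math.log2(0.47), 0.5), 3))
                meta.append(
                    SampleMeta(
                        sample_id=f"{prefixes.get(method, method.upper())}-{codes.get(stratum, stratum)}{i + 1:02d}",
                        group=info["group"],
                        gender=info["gender"],
                        age=info["age"],
                        ert=(stratum == "fabry_ert"),
                        method=method,
                        input_conc_ng_per_uL=conc,
                        input_mass_ng=float(np.round(conc * 5.0, 3)),
                        patient_id=pid,
                    )
                )
    return meta


def simulate_counts(
    config: SyntheticConfig, codeset: CodeSet | None = None
) -> tuple[CountMatrix, list[SampleMeta], GroundTruthLedger]:
    """Simulate a raw count matrix, sample metadata and the ground-truth ledger.

    Endogenous count model, per probe p and lane s::

        count = round(lane_scale_s * capture(p, method_s) * 2^effect(p, stratum_s)
                      * base_p * 2^N(0, noise_sdlog2)) + Poisson(bg_lambda)

    with ``base_p ~ 2^N(baseline_meanlog2, baseline_sdlog2)``. Negative
    controls are Poisson(negative_lambda); positive controls follow the
    titration ``slope * conc`` with small multiplicative noise; ligation
    positives sit well above background and ligation negatives at background.
    Dropout (when enabled) zeroes endogenous counts at the stated rate.
    """
    if codeset is None:
        codeset = generate_codeset(config)
    rng = np.random.default_rng(config.seed)
    endo_names = codeset.names_of(CodeClass.ENDOGENOUS)
    n_endo = len(endo_names)

    base = 2.0 ** rng.normal(config.baseline_meanlog2, config.baseline_sdlog2, n_endo)
    base_by_name = dict(zip(endo_names, base))

    # planted fabry-vs-healthy effects, on probes quantifiable above background
    if config.de_probes is not None:
        true_fc = dict(config.de_probes)
    else:
        eligible = [n for n, b in base_by_name.items() if b >= config.de_min_abundance]
        if config.n_de_probes > len(eligible):
            raise ValueError("not enough high-abundance probes to plant effects on")
        chosen = rng.choice(len(eligible), size=config.n_de_probes, replace=False)
        true_fc = {eligible[i]: config.de_log2fc for i in sorted(chosen)}
    unknown = set(true_fc) - set(endo_names)
    if unknown:
        raise ValueError(f"de_probes not in codeset: {sorted(unknown)}")

    de_names = list(true_fc)
    n_recover = int(round(config.ert_recovery_fraction * len(de_names)))
    rec_idx = rng.choice(len(de_names), size=n_recover, replace=False) if n_recover else []
    recovering = sorted(de_names[i] for i in rec_idx)
    non_recovering = sorted(set(de_names) - set(recovering))

    # group-exclusive probes: absent (background only) outside their group
    exclusive: dict[str, list[str]] = {}
    pool = [n for n in endo_names if n not in true_fc]
    for group, count in config.group_exclusive.items():
        if count == 0:
            exclusive[group] = []
            continue
        idx = rng.choice(len(pool), size=count, replace=False)
        exclusive[group] = sorted(pool[i] for i in sorted(idx))
        pool = [p for p in pool if p not in set(exclusive[group])]
        for p in exclusive[group]:
            base_by_name[p] = config.exclusive_abundance

    meta = _make_meta(config, rng)
    base_vec = np.array([base_by_name[n] for n in endo_names])
    fc_vec = np.array([true_fc.get(n, 0.0) for n in endo_names])
    rec_mask = np.array([n in set(recovering) for n in endo_names])
    method_off = np.array([config.method_effect.get(n, 0.0) for n in endo_names])
    excl_fabry = np.array([n in set(exclusive.get("fabry", [])) for n in endo_names])
    excl_healthy = np.array([n in set(exclusive.get("healthy", [])) for n in endo_names])

    columns: dict[str, np.ndarray] = {}
    lane_attrs: dict[str, LaneAttributes] = {}
    cartridges = {"manual": "CART-MAN-01", "automated": "CART-AUTO-01"}
    for m in meta:
        lane_scale = 2.0 ** rng.normal(0.0, config.lane_scale_sdlog2)
        effect = fc_vec.copy()
        if m.stratum == "healthy":
            effect[:] = 0.0
        elif m.stratum == "fabry_ert":
            effect[rec_mask] = 0.0  # recovered to healthy levels under treatment
        present = np.ones(n_endo, dtype=bool)
        if m.group == "fabry":
            present &= ~excl_healthy
        else:
            present &= ~excl_fabry
        capture = 2.0 ** method_off if m.method == "manual" else np.ones(n_endo)
        noise = 2.0 ** rng.normal(0.0, config.noise_sdlog2, n_endo)
        signal = np.where(present, base_vec * 2.0**effect * capture * lane_scale * noise, 0.0)
        counts_endo = np.round(signal) + rng.poisson(
            config.endogenous_background_lambda, n_endo
        )
        if config.dropout_rate > 0:
            counts_endo[rng.random(n_endo) < config.dropout_rate] = 0

        col: list[float] = list(counts_endo)
        # controls, in codeset order after the endogenous block
        pos = np.round(
            config.pos_slope_counts_per_fM
            * np.asarray(config.positive_concs)
            * lane_scale
            * 2.0 ** rng.normal(0.0, config.pos_noise_sdlog2, config.n_positive)
        )
        col += list(pos)
        col += list(rng.poisson(config.negative_lambda, config.n_negative))
        half = config.n_ligation // 2
        col += list(
            np.round(config.ligation_pos_mean * lane_scale * 2.0 ** rng.normal(0.0, 0.1, half))
        )
        col += list(rng.poisson(config.negative_lambda, half))
        col += list(
            np.round(
                config.spikein_mean * lane_scale * 2.0 ** rng.normal(0.0, config.noise_sdlog2, config.n_spikein)
            )
        )
        col += list(
            np.round(
                config.housekeeping_mean
                * lane_scale
                * 2.0 ** rng.normal(0.0, config.noise_sdlog2, config.n_housekeeping)
            )
        )
        columns[m.sample_id] = np.asarray(col, dtype=np.int64)
        lane_attrs[m.sample_id] = LaneAttributes(
            sample_id=m.sample_id,
            fov_count=555,
            fov_counted=int(rng.integers(530, 556)),
            binding_density=float(np.round(rng.uniform(0.3, 1.5), 4)),
            cartridge_id=cartridges.get(m.method, "CART-01"),
            date="2023-06-15",
        )

    counts = pd.DataFrame(columns, index=codeset.names())
    matrix = CountMatrix(codeset=codeset, counts=counts, lane_attrs=lane_attrs, stage="raw")
    ledger = GroundTruthLedger(
        seed=config.seed,
        config=dataclasses.asdict(config),
        true_log2fc={k: float(v) for k, v in true_fc.items()},
        recovering_probes=recovering,
        non_recovering_probes=non_recovering,
        group_exclusive=exclusive,
        method_effect={k: float(v) for k, v in config.method_effect.items()},
        base_abundance={n: float(b) for n, b in base_by_name.items()},
    )
    return matrix, meta, ledger


def emit_fixture_suite(config: SyntheticConfig, out_dir) -> dict[str, object]:
    """Write one RCC file per sample plus metadata CSV and ledger JSON.

    Layout: ``<out_dir>/rcc/<sample_id>.RCC``, ``<out_dir>/samples.csv``,
    ``<out_dir>/ground_truth.json``. Re-running with the same config and seed
    produces a byte-identical suite.
    """
    out_dir = Path(out_dir)
    rcc_dir = out_dir / "rcc"
    rcc_dir.mkdir(parents=True, exist_ok=True)
    matrix, meta, ledger = simulate_counts(config)
    rcc_paths = []
    for m in meta:
        path = rcc_dir / f"{m.sample_id}.RCC"
        write_rcc(
            matrix.lane_attrs[m.sample_id],
            matrix.counts[m.sample_id].to_numpy(),
            matrix.codeset,
            path,
        )
        rcc_paths.append(path)
    meta_path = out_dir / "samples.csv"
    write_sample_meta(meta, meta_path)
    ledger_path = out_dir / "ground_truth.json"
    ledger.to_json(ledger_path)
    return {
        "rcc": rcc_paths,
        "metadata": meta_path,
        "ledger": ledger_path,
        "matrix": matrix,
        "meta": meta,
        "ground_truth": ledger,
    }
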