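"""Reading and writing nCounter RCC lane files and sample metadata.

An RCC file is the per-lane text output of an nCounter run: plain-text
sections delimited by ``<Section>`` / ``</Section>`` tags with CSV bodies.
The sections used here are ``Header``, ``Sample_Attributes``,
``Lane_Attributes`` and ``Code_Summary`` (rows ``CodeClass,Name,Accession,
Count``). Unknown sections are preserved verbatim so that write -> read ->
write is byte-stable.
"""

from __future__ import annotations

import csv
import enum
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class RccFormatError(ValueError):
    """Raised when an RCC file violates the lane-file format."""


class CodeClass(str, enum.Enum):
    """Probe classes of an nCounter miRNA codeset."""

    ENDOGENOUS = "Endogenous"
    POSITIVE = "Positive"
    NEGATIVE = "Negative"
    LIGATION = "Ligation"
    SPIKEIN = "SpikeIn"
    HOUSEKEEPING = "Housekeeping"


@dataclass(frozen=True)
class ProbeRecord:
    """One barcode probe of the codeset.

    ``nominal_conc_fM`` is the spiked nominal concentration; it is present
    for positive controls (the titration series) and ligation-positive
    controls, and absent elsewhere.
    """

    code_class: CodeClass
    name: str
    accession: str = ""
    nominal_conc_fM: float | None = None

    def __post_init__(self):
        if self.nominal_conc_fM is not None and self.nominal_conc_fM < 0:
            raise ValueError(f"negative nominal concentration for {self.name}")


@dataclass
class CodeSet:
    """The probe panel of an assay: endogenous probes plus built-in controls."""

    probes: list[ProbeRecord]
    panel_name: str = "NS_H_MIR_V3"

    def __post_init__(self):
        names = [p.name for p in self.probes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate probe names in codeset: {dupes}")

    def __len__(self) -> int:
        return len(self.probes)

    def names(self) -> list[str]:
        return [p.name for p in self.probes]

    def probes_of(self, code_class: CodeClass) -> list[ProbeRecord]:
        return [p for p in self.probes if p.code_class is code_class]

    def names_of(self, code_class: CodeClass) -> list[str]:
        return [p.name for p in self.probes if p.code_class is code_class]

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in self.probes:
            out[p.code_class.value] = out.get(p.code_class.value, 0) + 1
        return out


@dataclass
class LaneAttributes:
    """Scanner lane attributes carried in the RCC file."""

    sample_id: str
    fov_count: int
    fov_counted: int
    binding_density: float
    cartridge_id: str = ""
    date: str = ""

    def __post_init__(self):
        if self.fov_count <= 0:
            raise ValueError(f"fov_count must be positive, got {self.fov_count}")
        if not 0 <= self.fov_counted <= self.fov_count:
            raise ValueError(
                f"fov_counted {self.fov_counted} outside [0, {self.fov_count}]"
            )
        if self.binding_density < 0:
            raise ValueError("binding_density must be nonnegative")


@dataclass
class RccLane:
    """A parsed RCC lane: attributes, probe rows and counts in file order."""

    attrs: LaneAttributes
    probes: list[ProbeRecord]
    counts: np.ndarray  # integer counts, aligned with probes
    gene_rlf: str = ""
    extra_sections: dict[str, str] = field(default_factory=dict)


@dataclass
class SampleMeta:
    """Per-sample clinical and processing metadata."""

    sample_id: str
    group: str  # "healthy" | "fabry"
    gender: str  # "M" | "F"
    age: float
    ert: bool
    method: str  # "manual" | "automated"
    input_conc_ng_per_uL: float
    input_mass_ng: float
    patient_id: str = ""

    def __post_init__(self):
        if self.group not in ("healthy", "fabry"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.method not in ("manual", "automated"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.gender not in ("M", "F"):
            raise ValueError(f"unknown gender {self.gender!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.input_conc_ng_per_uL < 0 or self.input_mass_ng < 0:
            raise ValueError("input amounts must be nonnegative")

    @property
    def stratum(self) -> str:
        if self.group == "healthy":
            return "healthy"
        return "fabry_ert" if self.ert else "fabry_no_ert"


_STAGES = ("raw", "background_subtracted", "normalized")


@dataclass
class CountMatrix:
    """Probes x samples counts with the codeset and per-lane attributes.

    At ``raw`` stage counts are nonnegative integers; after background
    subtraction or normalization they are nonnegative reals.
    """

    codeset: CodeSet
    counts: pd.DataFrame  # index: probe names, columns: sample ids
    lane_attrs: dict[str, LaneAttributes]
    stage: str = "raw"

    def __post_init__(self):
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if list(self.counts.index) != self.codeset.names():
            raise ValueError("count matrix rows do not match codeset probe order")
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ValueError("counts must be nonnegative")
        if self.stage == "raw" and not np.allclose(vals, np.round(vals)):
            raise ValueError("raw counts must be integers")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def class_view(self, code_class: CodeClass) -> pd.DataFrame:
        return self.counts.loc[self.codeset.names_of(code_class)]

    def endogenous(self) -> pd.DataFrame:
        return self.class_view(CodeClass.ENDOGENOUS)

    def with_counts(self, counts: pd.DataFrame, stage: str) -> "CountMatrix":
        return CountMatrix(self.codeset, counts, dict(self.lane_attrs), stage)

    def to_tsv(self, path) -> None:
        """Export as TSV, probes as rows, samples as columns."""
        df = self.counts.copy()
        df.insert(0, "CodeClass", [p.code_class.value for p in self.codeset.probes])
        df.to_csv(path, sep="\t", index_label="Probe")


# ---------------------------------------------------------------------------
# RCC parsing


def _split_sections(text: str, path) -> dict[str, str]:
    sections: dict[str, str] = {}
    current: str | None = None
    body: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith("</") and stripped.endswith(">"):
            name = stripped[2:-1]
            if current != name:
                raise RccFormatError(
                    f"{path}:{lineno}: closing tag </{name}> without opening"
                )
            sections[current] = "\n".join(body)
            current, body = None, []
        elif stripped.startswith("<") and stripped.endswith(">"):
            if current is not None:
                raise RccFormatError(
                    f"{path}:{lineno}: nested section <{stripped[1:-1]}>"
                )
            current = stripped[1:-1]
            if current in sections:
                raise RccFormatError(f"{path}: duplicate section {current}")
            body = []
        elif current is not None:
            body.append(line)
    if current is not None:
        raise RccFormatError(f"{path}: unterminated section <{current}>")
    return sections


def _kv(body: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for row in csv.reader(io.StringIO(body)):
        if not row:
            continue
        out[row[0]] = row[1] if len(row) > 1 else ""
    return out


def read_rcc(path) -> RccLane:
    """Parse one RCC lane file.

    Raises :class:`RccFormatError` for a missing section, a malformed
    Code_Summary, or duplicate probes, and ``ValueError`` for non-integer or
    negative counts (with the offending line number).
    """
    path = Path(path)
    sections = _split_sections(path.read_text(encoding="utf-8"), path)
    for required in ("Header", "Sample_Attributes", "Lane_Attributes", "Code_Summary"):
        if required not in sections:
            raise RccFormatError(f"{path}: missing section {required}")

    sample_attrs = _kv(sections["Sample_Attributes"])
    lane_kv = _kv(sections["Lane_Attributes"])
    try:
        attrs = LaneAttributes(
            sample_id=sample_attrs.get("ID", ""),
            fov_count=int(lane_kv["FovCount"]),
            fov_counted=int(lane_kv["FovCounted"]),
            binding_density=float(lane_kv["BindingDensity"]),
            cartridge_id=lane_kv.get("CartridgeID", ""),
            date=sample_attrs.get("Date", ""),
        )
    except KeyError as exc:
        raise RccFormatError(f"{path}: Lane_Attributes missing field {exc}") from exc

    lines = sections["Code_Summary"].splitlines()
    if not lines or [c.strip() for c in lines[0].split(",")] != [
        "CodeClass",
        "Name",
        "Accession",
        "Count",
    ]:
        raise RccFormatError(
            f"{path}: Code_Summary must begin with header CodeClass,Name,Accession,Count"
        )
    probes: list[ProbeRecord] = []
    counts: list[int] = []
    seen: set[str] = set()
    for offset, row in enumerate(csv.reader(lines[1:]), start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != 4:
            raise RccFormatError(
                f"{path}: Code_Summary line {offset}: expected 4 fields, got {len(row)}"
            )
        cls_label, name, accession, count_str = (c.strip() for c in row)
        try:
            code_class = CodeClass(cls_label)
        except ValueError as exc:
            raise RccFormatError(
                f"{path}: Code_Summary line {offset}: unknown CodeClass {cls_label!r}"
            ) from exc
        if name in seen:
            raise RccFormatError(
                f"{path}: Code_Summary line {offset}: duplicate probe {name!r}"
            )
        seen.add(name)
        try:
            count = int(count_str)
        except ValueError as exc:
            raise ValueError(
                f"{path}: Code_Summary line {offset}: non-integer count {count_str!r}"
            ) from exc
        if count < 0:
            raise ValueError(
                f"{path}: Code_Summary line {offset}: negative count {count}"
            )
        # positive controls encode their titration concentration in the
        # probe name, e.g. POS_A(128); recover it so QC can use it downstream
        conc = None
        if code_class is CodeClass.POSITIVE:
            m = re.search(r"\(([\d.]+)\)", name)
            if m:
                conc = float(m.group(1))
        probes.append(ProbeRecord(code_class, name, accession, conc))
        counts.append(count)

    extra = {
        k: v
        for k, v in sections.items()
        if k not in ("Header", "Sample_Attributes", "Lane_Attributes", "Code_Summary")
    }
    return RccLane(
        attrs=attrs,
        probes=probes,
        counts=np.asarray(counts, dtype=np.int64),
        gene_rlf=sample_attrs.get("GeneRLF", ""),
        extra_sections=extra,
    )


def write_rcc(
    attrs: LaneAttributes,
    counts: Sequence[int],
    codeset: CodeSet,
    path,
    extra_sections: Mapping[str, str] | None = None,
) -> None:
    """Write one RCC lane file re-readable by :func:`read_rcc` bit-identically."""
    if len(codeset) == 0:
        raise RccFormatError("cannot write an RCC file for an empty codeset")
    counts = np.asarray(counts)
    if counts.shape != (len(codeset),):
        raise ValueError(
            f"counts length {counts.shape} does not match codeset size {len(codeset)}"
        )
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("RCC counts must be nonnegative integers")

    buf = io.StringIO()
    buf.write("<Header>\nFileVersion,1.7\nSoftwareVersion,4.0.0.3\n</Header>\n")
    buf.write(
        "<Sample_Attributes>\n"
        f"ID,{attrs.sample_id}\n"
        "Owner,\nComments,\n"
        f"Date,{attrs.date}\n"
        f"GeneRLF,{codeset.panel_name}\n"
        "SystemAPF,n.a.\n"
        "</Sample_Attributes>\n"
    )
    buf.write(
        "<Lane_Attributes>\n"
        "ID,1\n"
        f"FovCount,{attrs.fov_count}\n"
        f"FovCounted,{attrs.fov_counted}\n"
        f"BindingDensity,{attrs.binding_density!r}\n"
        f"CartridgeID,{attrs.cartridge_id}\n"
        "</Lane_Attributes>\n"
    )
    buf.write("<Code_Summary>\nCodeClass,Name,Accession,Count\n")
    for probe, count in zip(codeset.probes, counts):
        buf.write(f"{probe.code_class.value},{probe.name},{probe.accession},{int(count)}\n")
    buf.write("</Code_Summary>\n")
    for name, body in (extra_sections or {}).items():
        buf.write(f"<{name}>\n")
        if body:
            buf.write(body if body.endswith("\n") else body + "\n")
        buf.write(f"</{name}>\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def assemble_matrix(
    lanes: Iterable[RccLane], codeset: CodeSet, meta: Sequence[SampleMeta]
) -> CountMatrix:
    """Assemble parsed lanes into a raw CountMatrix, columns in metadata order.

    Every lane's probe sequence (class, name) must match the codeset, and the
    lane sample ids must match the metadata one-to-one.
    """
    expected = [(p.code_class, p.name) for p in codeset.probes]
    by_sample: dict[str, RccLane] = {}
    for lane in lanes:
        got = [(p.code_class, p.name) for p in lane.probes]
        if got != expected:
            diverging = sorted(
                {n for _, n in set(got) ^ set(expected)}
            )
            raise ValueError(
                f"lane {lane.attrs.sample_id!r} probes diverge from codeset: {diverging}"
            )
        if lane.attrs.sample_id in by_sample:
            raise ValueError(f"duplicate lane for sample {lane.attrs.sample_id!r}")
        by_sample[lane.attrs.sample_id] = lane

    meta_ids = [m.sample_id for m in meta]
    missing = [s for s in meta_ids if s not in by_sample]
    orphans = [s for s in by_sample if s not in set(meta_ids)]
    if missing or orphans:
        raise ValueError(
            f"metadata/lane mismatch: lanes missing for {missing}, "
            f"lanes without metadata {orphans}"
        )
    data = {s: by_sample[s].counts for s in meta_ids}
    counts = pd.DataFrame(data, index=codeset.names())
    lane_attrs = {s: by_sample[s].attrs for s in meta_ids}
    return CountMatrix(codeset=codeset, counts=counts, lane_attrs=lane_attrs, stage="raw")


# ---------------------------------------------------------------------------
# Sample metadata CSV

_META_COLUMNS = [
    "sample_id",
    "group",
    "gender",
    "age",
    "ert",
    "method",
    "input_conc_ng_per_uL",
    "input_mass_ng",
    "patient_id",
]


def write_sample_meta(meta: Sequence[SampleMeta], path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "group": m.group,
            "gender": m.gender,
            "age": m.age,
            "ert": int(m.ert),
            "method": m.method,
            "input_conc_ng_per_uL": m.input_conc_ng_per_uL,
            "input_mass_ng": m.input_mass_ng,
            "patient_id": m.patient_id,
        }
        for m in meta
    ]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, index=False)


def read_sample_meta(path) -> list[SampleMeta]:
    df = pd.read_csv(path, dtype={"patient_id": str, "sample_id": str})
    missing = [c for c in _META_COLUMNS if c not in df.columns and c != "patient_id"]
    if missing:
        raise ValueError(f"metadata file missing columns: {missing}")
    out = []
    for _, r in df.iterrows():
        out.append(
            SampleMeta(
                sample_id=str(r["sample_id"]),
                group=str(r["group"]),
                gender=str(r["gender"]),
                age=float(r["age"]),
                ert=bool(int(r["ert"])),
                method=str(r["method"]),
                input_conc_ng_per_uL=float(r["input_conc_ng_per_uL"]),
                input_mass_ng=float(r["input_mass_ng"]),
                patient_id="" if "patient_id" not in df.columns or pd.isna(r["patient_id"]) else str(r["patient_id"]),
            )
        )
    return out
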