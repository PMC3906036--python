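"""Readers and writers for the package's on-disk text formats.

Everything is plain text: FASTA for transcripts (header dialect
``>transcript_id|gene_id``, configurable via regex), TSV for probe tables,
intensity/expression matrices and sample annotation, YAML for simulation
configuration.  Binary vendor formats (CEL/CDF) are deliberately
unsupported; adapters can populate the same in-memory objects.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cdf import Probe, Transcript
from .errors import ConfigurationError, ParseError, ValidationError
from .simulate import SimulationConfig

DEFAULT_HEADER_REGEX = r"^(?P<transcript_id>[^|\s]+)\|(?P<gene_id>\S+)"


def read_fasta(path, header_regex: str = DEFAULT_HEADER_REGEX) -> list[Transcript]:
    """Read transcripts from FASTA.

    The header must expose ``transcript_id`` and ``gene_id`` named groups
    through ``header_regex``.  Sequences are uppercased; duplicate
    transcript ids and empty sequences are rejected.
    """
    pattern = re.compile(header_regex)
    records: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description or rec.id
        m = pattern.match(header)
        if not m:
            raise ParseError(f"FASTA header {header!r} does not match the dialect", path=path)
        tid = m.group("transcript_id")
        gid = m.group("gene_id")
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"empty sequence for {tid!r}", path=path)
        if tid in seen:
            raise ParseError(f"duplicate transcript id {tid!r}", path=path)
        seen.add(tid)
        records.append(Transcript(gene_id=gid, transcript_id=tid, sequence=seq))
    return records


def write_fasta(transcripts: Iterable[Transcript], path, width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(t.sequence), id=f"{t.transcript_id}|{t.gene_id}", description="")
        for t in transcripts
    ]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def read_probe_table(path) -> list[Probe]:
    """Probe table TSV: probe_id, probeset_id, x, y, sequence ('NA' coords ok)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_id", "probeset_id", "sequence"}
    if not required <= set(df.columns):
        raise ParseError(f"probe table must have columns {sorted(required)}", path=path)
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ParseError(f"duplicate probe id {dup!r}", path=path)
    probes = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        x = getattr(row, "x", None)
        y = getattr(row, "y", None)
        try:
            probes.append(
                Probe(
                    probe_id=row.probe_id,
                    probeset_id=row.probeset_id,
                    sequence=row.sequence.upper(),
                    x=None if x in (None, "NA") or pd.isna(x) else int(x),
                    y=None if y in (None, "NA") or pd.isna(y) else int(y),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ParseError(str(exc), path=path, line=i)
    return probes


def write_probe_table(probes: Iterable[Probe], path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tprobeset_id\tx\ty\tsequence\n")
        for p in probes:
            x = "NA" if p.x is None else p.x
            y = "NA" if p.y is None else p.y
            fh.write(f"{p.probe_id}\t{p.probeset_id}\t{x}\t{y}\t{p.sequence}\n")


def _read_matrix(path, value_kind: str) -> pd.DataFrame:
    # pandas silently renames duplicated header fields; check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dups = {h for h in header if header.count(h) > 1}
    if dups:
        raise ParseError(f"duplicated sample id {sorted(dups)[0]!r}", path=path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"cannot read matrix: {exc}", path=path)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicated row id {dup!r}", path=path)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = df.index[coerced.isna().argmax()]
            raise ParseError(
                f"non-numeric value at row {row!r}, column {col!r}", path=path
            )
        df[col] = coerced
    if value_kind == "intensity":
        arr = df.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            bad_rc = np.argwhere(~(np.isfinite(arr) & (arr > 0)))[0]
            raise ParseError(
                f"non-positive intensity at row {df.index[bad_rc[0]]!r}, "
                f"column {df.columns[bad_rc[1]]!r}",
                path=path,
            )
    return df


def read_intensity_matrix(path) -> pd.DataFrame:
    """Probe x sample raw intensity TSV; strictly positive values enforced."""
    df = _read_matrix(path, "intensity")
    df.index.name = "probe_id"
    return df


def read_expression_matrix(path) -> pd.DataFrame:
    """Probeset x sample log2 expression TSV (values may be negative)."""
    df = _read_matrix(path, "expression")
    df.index.name = "probeset_id"
    return df


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a matrix TSV losslessly to 10 significant digits."""
    matrix.to_csv(path, sep="\t", float_format="%.10g")


write_intensity_matrix = write_matrix
write_expression_matrix = write_matrix


ANNOTATION_COLUMNS = ["sample_id", "subgroup", "preservation", "pair_id"]


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"annotation lacks columns {missing}", path=path)
    bad = ~df["preservation"].isin(["frozen", "ffpe"])
    if bad.any():
        raise ParseError(
            f"preservation must be frozen/ffpe, found {df.loc[bad, 'preservation'].iloc[0]!r}",
            path=path,
        )
    if df["sample_id"].duplicated().any():
        raise ParseError("duplicate sample ids in annotation", path=path)
    return df[ANNOTATION_COLUMNS]


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_simulation_config(path, seed: int | None = None) -> SimulationConfig:
    """Load a YAML simulation config; unknown keys are rejected.

    ``seed`` overrides the file's seed when given (CLI-level seeding).
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ParseError("simulation config must be a YAML mapping", path=path)
    valid = set(SimulationConfig.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ConfigurationError(f"unknown simulation-config keys: {sorted(unknown)}")
    data = dict(data)
    for key in ("transcript_length_range", "decay_scale_range"):
        if key in data:
            data[key] = tuple(data[key])
    if seed is not None:
        data["seed"] = seed
    cfg = SimulationConfig(**data)
    cfg.validate()
    return cfg
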