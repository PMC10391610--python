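"""Readers and writers for the package's on-disk formats.

Fixed dialects: CSV is comma-separated, UTF-8, ``.`` decimal, header
mandatory; array tables may be TSV.  Concentration units are explicit
column-name suffixes (``_nM``, ``_mM``).  All writes go through a temp-file
+ atomic-rename helper.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .atom_types import STANDARD_RESIDUES
from .bli import BLITrace
from .mst import MSTCapillary, normalize_trace
from .nmr import NMRTitrationSeries
from .peptide_array import ArrayMeasurement, Peptide
from .sampling import PosteriorSamples

logger = logging.getLogger("survbind")


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a multi-record FASTA; sequences upper-cased and validated."""
    path = Path(path)
    header_lines: dict[int, int] = {}  # record ordinal -> line number
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                header_lines[len(header_lines)] = lineno
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for i, rec in enumerate(records):
        line = header_lines.get(i, 0)
        if rec.id in seen:
            raise ValueError(f"{path}:{line}: duplicate record ID {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in STANDARD_RESIDUES:
                raise ValueError(
                    f"{path}:{line}: record {rec.id!r} has illegal residue "
                    f"{ch!r} at position {pos}"
                )
        out.append((rec.id, seq))
    return out


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    with os.fdopen(fd, "w") as fh:
        SeqIO.write(recs, fh, "fasta")
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# typed tables


def read_table(path: str | Path, schema: dict[str, type], sep: str | None = None) -> pd.DataFrame:
    """Read a delimited table, enforcing required columns and numeric types.

    ``schema`` maps required column names to types; extra columns are kept
    as-is.  The separator defaults by extension (.tsv -> tab, else comma).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col, typ in schema.items():
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
        if typ in (float, int):
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                row = int(bad.idxmax())
                raise ValueError(
                    f"{path}: malformed numeric value {df[col][row]!r} in "
                    f"column {col!r}, row {row + 2}"
                )
            df[col] = converted.astype(typ)
    return df


def write_table(df: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    atomic_write_text(path, df.to_csv(index=False, sep=sep))


# ---------------------------------------------------------------------------
# assay-specific formats


def read_array_table(path: str | Path) -> tuple[list[Peptide], list[ArrayMeasurement]]:
    """Array TSV: peptide_id, protein_id, start, sequence, fi_rep1, fi_rep2."""
    df = read_table(
        path,
        {
            "peptide_id": str,
            "protein_id": str,
            "start": int,
            "sequence": str,
            "fi_rep1": float,
            "fi_rep2": float,
        },
    )
    peptides = [
        Peptide(r.peptide_id, r.protein_id, int(r.start), r.sequence.upper())
        for r in df.itertuples()
    ]
    measurements = [
        ArrayMeasurement(r.peptide_id, float(r.fi_rep1), float(r.fi_rep2))
        for r in df.itertuples()
    ]
    return peptides, measurements


def write_array_table(
    peptides: list[Peptide], measurements: list[ArrayMeasurement], path: str | Path
) -> None:
    fi = {m.peptide_id: (m.fi_rep1, m.fi_rep2) for m in measurements}
    df = pd.DataFrame(
        {
            "peptide_id": [p.id for p in peptides],
            "protein_id": [p.protein_id for p in peptides],
            "start": [p.start for p in peptides],
            "sequence": [p.sequence for p in peptides],
            "fi_rep1": [fi[p.id][0] for p in peptides],
            "fi_rep2": [fi[p.id][1] for p in peptides],
        }
    )
    write_table(df, path)


def read_mst_csv(path: str | Path, renormalize: bool = False) -> list[MSTCapillary]:
    """Long-format MST CSV: capillary, c_total_nM, time_s, fluorescence."""
    df = read_table(
        path,
        {"capillary": int, "c_total_nM": float, "time_s": float, "fluorescence": float},
    )
    capillaries = []
    for idx, grp in df.groupby("capillary", sort=True):
        grp = grp.sort_values("time_s")
        y = grp["fluorescence"].to_numpy()
        t = grp["time_s"].to_numpy()
        if renormalize:
            y = normalize_trace(t, y)
        capillaries.append(
            MSTCapillary(
                index=int(idx),
                c_total=float(grp["c_total_nM"].iloc[0]),
                times=t,
                fluorescence=y,
            )
        )
    return capillaries


def write_mst_csv(capillaries: list[MSTCapillary], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "capillary": cap.index,
                "c_total_nM": cap.c_total,
                "time_s": cap.times,
                "fluorescence": cap.fluorescence,
            }
        )
        for cap in capillaries
    ]
    write_table(pd.concat(frames, ignore_index=True), path)


def read_bli_csv(path: str | Path) -> list[BLITrace]:
    """Long-format BLI CSV: trace_id, conc_nM, phase {assoc,dissoc}, time_s, shift_nm."""
    df = read_table(
        path,
        {"trace_id": str, "conc_nM": float, "phase": str, "time_s": float, "shift_nm": float},
    )
    traces = []
    for tid, grp in df.groupby("trace_id", sort=True):
        phases = {}
        for phase, sub in grp.groupby("phase"):
            sub = sub.sort_values("time_s")
            phases[phase] = (sub["time_s"].to_numpy(), sub["shift_nm"].to_numpy())
        if "assoc" not in phases or "dissoc" not in phases:
            raise ValueError(f"{path}: trace {tid!r} must have assoc and dissoc phases")
        traces.append(
            BLITrace(
                trace_id=str(tid),
                conc=float(grp["conc_nM"].iloc[0]) * 1e-9,
                t_assoc=phases["assoc"][0],
                y_assoc=phases["assoc"][1],
                t_dissoc=phases["dissoc"][0],
                y_dissoc=phases["dissoc"][1],
            )
        )
    return traces


def write_bli_csv(traces: list[BLITrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        for phase, t, y in (
            ("assoc", tr.t_assoc, tr.y_assoc),
            ("dissoc", tr.t_dissoc, tr.y_dissoc),
        ):
            frames.append(
                pd.DataFrame(
                    {
                        "trace_id": tr.trace_id,
                        "conc_nM": tr.conc * 1e9,
                        "phase": phase,
                        "time_s": t,
                        "shift_nm": y,
                    }
                )
            )
    write_table(pd.concat(frames, ignore_index=True), path)


def read_nmr_series(path: str | Path, peptide_id: str = "peptide") -> NMRTitrationSeries:
    """Series CSV: conc_mM, intensity (already normalized)."""
    df = read_table(path, {"conc_mM": float, "intensity": float})
    return NMRTitrationSeries(
        peptide_id, df["conc_mM"].to_numpy(), df["intensity"].to_numpy()
    )


def write_nmr_series(series: NMRTitrationSeries, path: str | Path) -> None:
    write_table(
        pd.DataFrame({"conc_mM": series.conc, "intensity": series.i_norm}), path
    )


def read_shift_table(path: str | Path) -> pd.DataFrame:
    """Shift CSV: residue_index, residue, delta_obs_ppm, delta_rc_ppm."""
    return read_table(
        path,
        {
            "residue_index": int,
            "residue": str,
            "delta_obs_ppm": float,
            "delta_rc_ppm": float,
        },
    )


# ---------------------------------------------------------------------------
# posterior outputs


def write_posterior(
    posterior: PosteriorSamples,
    csv_path: str | Path,
    summary_path: str | Path | None = None,
    extra_summary: dict | None = None,
) -> None:
    """Posterior draws as CSV plus a JSON summary (means, intervals, R-hat)."""
    atomic_write_text(csv_path, posterior.draws.to_csv(index=False))
    if summary_path is not None:
        payload = {
            "parameters": posterior.summary(),
            "diagnostics": posterior.diagnostics,
        }
        if extra_summary:
            payload.update(extra_summary)
        atomic_write_text(summary_path, json.dumps(payload, indent=1))


def log_run(config: dict, inputs: list[str | Path] = ()) -> None:
    """Record the effective configuration and input checksums."""
    from . import __version__

    checksums = {str(p): file_checksum(p) for p in inputs}
    logger.info(
        "run config: %s",
        json.dumps({"version": __version__, "config": config, "inputs": checksums}),
    )
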