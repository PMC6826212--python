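"""File formats: FASTA, MGF (reference spectrum dialect) and TSV tables.

FASTA reading accepts UniProt-style headers (``sp|ACC|NAME desc``) and
plain accessions; sequences are uppercased and wrap-agnostic.  MGF is
read through :mod:`pyteomics.mgf` and written by a fixed in-package
formatter so that outputs are byte-reproducible given a seed.  All
tables are tab-separated with a header row and locale-independent
number formatting.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml
from pyteomics import mgf as _pt_mgf

from .localization import Spectrum


def parse_accession(header: str) -> str:
    """Accession from a FASTA header line (without '>')."""
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in {"sp", "tr"}:
        return parts[1]
    return token


def read_fasta(path) -> dict[str, str]:
    """Accession -> uppercased sequence map; duplicate accessions are an error."""
    out: dict[str, str] = {}
    header = None
    chunks: list[str] = []
    n_line = 0

    def _flush(line_no):
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ValueError(f"{path}: record {header!r} has no sequence "
                             f"(near line {line_no})")
        acc = parse_accession(header)
        if acc in out:
            raise ValueError(f"{path}: duplicate accession {acc!r} (line {line_no})")
        out[acc] = seq

    with open(path) as fh:
        for n_line, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(n_line)
                header = line[1:]
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}: sequence before any header at line {n_line}")
                chunks.append(line)
        _flush(n_line)
    if not out:
        raise ValueError(f"{path}: no FASTA records found")
    return out


def write_fasta(records: Mapping[str, str], path, wrap: int = 60) -> None:
    with open(path, "w", newline="\n") as fh:
        for acc, seq in records.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")


def read_mgf(path) -> Iterator[Spectrum]:
    """Yield spectra from an MGF file (TITLE/PEPMASS/CHARGE dialect).

    RTINSECONDS and FRAGMENTATION are optional; a missing charge
    defaults to 1; empty peak blocks yield zero-peak spectra.
    """
    with _pt_mgf.read(str(path), convert_arrays=1, use_index=False) as reader:
        for entry in reader:
            params = entry["params"]
            charge = params.get("charge")
            charge = int(charge[0]) if charge else 1
            pepmass = params.get("pepmass", (0.0,))[0]
            rt = params.get("rtinseconds")
            yield Spectrum(
                scan_id=str(params.get("title", "")),
                precursor_mz=float(pepmass),
                precursor_charge=charge,
                fragmentation=str(params.get("fragmentation", "HCD")),
                mz=entry["m/z array"],
                intensity=entry["intensity array"],
                rt_seconds=float(rt) if rt is not None else None,
            )


def format_mgf(spectra: Sequence[Spectrum]) -> str:
    """Fixed-format MGF text (byte-reproducible)."""
    buf = _io.StringIO()
    for s in spectra:
        buf.write("BEGIN IONS\n")
        buf.write(f"TITLE={s.scan_id}\n")
        buf.write(f"PEPMASS={s.precursor_mz:.6f}\n")
        buf.write(f"CHARGE={s.precursor_charge}+\n")
        if s.rt_seconds is not None:
            buf.write(f"RTINSECONDS={s.rt_seconds:.2f}\n")
        buf.write(f"FRAGMENTATION={s.fragmentation}\n")
        for mz, inten in zip(s.mz, s.intensity):
            buf.write(f"{mz:.6f} {inten:.4f}\n")
        buf.write("END IONS\n")
    return buf.getvalue()


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(format_mgf(spectra))


def write_table(df: pd.DataFrame, path, *, index: bool = False) -> None:
    """Tab-separated output with a header row and fixed float formatting."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g", lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def save_config(cfg: Mapping, path) -> None:
    with open(path, "w", newline="\n") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
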