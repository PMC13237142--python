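"""Reading and writing quantification tables, gene sets, sequences, results.

The on-disk quantification format is a neutral wide table: one row per
protein, column 1 the protein accession, then one column per measured
channel named ``<probe>_<fraction>-<metal>_rep<r>_c<concentration>``.
Missing values are empty fields; intensities of exactly 0 are converted to
missing on ingest, mirroring how zero reporter intensities are treated in
TMT quantification. Delimiter is chosen from the file extension
(.tsv/.txt = tab, .csv = comma).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .design import TitrationDesign

log = logging.getLogger(__name__)

ROW_INDEX = ("protein_id", "probe", "fraction", "metal", "replicate")


class FormatError(ValueError):
    """Raised when an input file does not match the expected schema."""


@dataclass
class QuantTable:
    """Per-replicate protein x channel reporter abundances.

    ``data`` has a MultiIndex (protein_id, probe, fraction, metal, replicate)
    and one float column per design channel (0..n_channels-1); NaN = missing.
    ``ibaq`` is an optional per-protein abundance proxy.
    """

    design: TitrationDesign
    data: pd.DataFrame
    ibaq: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if list(self.data.index.names) != list(ROW_INDEX):
            raise ValueError(f"row index must be {ROW_INDEX}")
        expected = list(range(self.design.n_channels))
        if list(self.data.columns) != expected:
            raise ValueError("abundance columns must map 1:1 to design channels")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate (protein, probe, condition, replicate) row: {dup}")
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise ValueError("abundances must be non-negative")

    def zeros_to_missing(self) -> "QuantTable":
        data = self.data.mask(self.data == 0.0)
        return QuantTable(self.design, data, self.ibaq)


def _conc_token(c: float) -> str:
    return f"{c:.6g}"


def _delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


_COL_RE = re.compile(r"^(?P<probe>.+)_(?P<fraction>[^_-]+)-(?P<metal>[^_]+)_rep(?P<rep>\d+)_c(?P<conc>[0-9.eE+-]+)$")


def _parse_column(name: str, design: TitrationDesign) -> Tuple[str, str, str, int, int]:
    m = _COL_RE.match(name)
    if not m:
        raise FormatError(f"column {name!r} does not match <probe>_<fraction>-<metal>_rep<r>_c<conc>")
    conc = float(m.group("conc"))
    channel = None
    for i, c in enumerate(design.channel_concentrations):
        if math.isclose(conc, c, rel_tol=1e-3, abs_tol=1e-9):
            channel = i
            break
    if channel is None:
        raise FormatError(f"column {name!r}: concentration {conc} not in design")
    return (m.group("probe"), m.group("fraction"), m.group("metal"), int(m.group("rep")), channel)


def write_quant_table(table: QuantTable, path: str | Path) -> None:
    """Write the wide TSV/CSV layout; missing values become empty fields."""
    path = Path(path)
    wide = table.data.unstack(["probe", "fraction", "metal", "replicate"])
    # columns: (channel, probe, fraction, metal, replicate) -> flat names
    cols = []
    for channel, probe, fraction, metal, rep in wide.columns:
        conc = table.design.channel_concentrations[channel]
        cols.append((probe, fraction, metal, rep, channel,
                     f"{probe}_{fraction}-{metal}_rep{rep}_c{_conc_token(conc)}"))
    order = sorted(range(len(cols)), key=lambda i: cols[i][:5])
    wide = wide.iloc[:, order]
    wide.columns = [cols[i][5] for i in order]
    wide = wide.sort_index()
    if table.ibaq is not None:
        wide["iBAQ"] = table.ibaq.reindex(wide.index)
    wide.index.name = "protein_id"
    wide.to_csv(path, sep=_delimiter(path))


def read_quant_table(path: str | Path, design: TitrationDesign) -> QuantTable:
    """Parse a wide quantification table against a design.

    Zeros are converted to missing; non-numeric, non-empty cells raise a
    FormatError naming the offending row and column; each (probe, condition,
    replicate) must supply every design channel.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=_delimiter(path), dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty quantification table") from None
    if df.empty or df.shape[1] < 2:
        raise FormatError(f"{path}: empty or header-only quantification table")
    if df.columns[0] != "protein_id":
        raise FormatError(f"{path}: first column must be 'protein_id', got {df.columns[0]!r}")
    ibaq = None
    value_cols = [c for c in df.columns[1:] if c != "iBAQ"]
    parsed = {c: _parse_column(c, design) for c in value_cols}

    # every (probe, fraction, metal, rep) must cover all channels
    groups: Dict[Tuple[str, str, str, int], set] = {}
    for probe, fraction, metal, rep, channel in parsed.values():
        groups.setdefault((probe, fraction, metal, rep), set()).add(channel)
    for key, channels in groups.items():
        missing = set(range(design.n_channels)) - channels
        if missing:
            conc = design.channel_concentrations[sorted(missing)[0]]
            raise FormatError(
                f"{path}: header lacks channel c{_conc_token(conc)} for "
                f"{key[0]}_{key[1]}-{key[2]}_rep{key[3]}"
            )

    def _to_float(val: object, row: int, col: str) -> float:
        if val is None or (isinstance(val, float) and math.isnan(val)) or val == "":
            return math.nan
        try:
            return float(val)
        except ValueError:
            raise FormatError(
                f"{path}: malformed numeric field {val!r} at row {row + 2}, column {col!r}"
            ) from None

    pids = df["protein_id"].tolist()
    records = []
    for col in value_cols:
        probe, fraction, metal, rep, channel = parsed[col]
        for i, val in enumerate(df[col].tolist()):
            records.append(
                (pids[i], probe, fraction, metal, rep, channel, _to_float(val, i, col))
            )
    long = pd.DataFrame.from_records(
        records, columns=list(ROW_INDEX) + ["channel", "abundance"]
    )
    try:
        data = long.set_index(list(ROW_INDEX) + ["channel"])["abundance"].unstack("channel")
    except ValueError:
        raise FormatError(f"{path}: duplicate (protein, probe, condition, replicate) rows") from None
    data.columns = [int(c) for c in data.columns]
    data = data.reindex(columns=range(design.n_channels))
    if "iBAQ" in df.columns:
        ser = df.set_index("protein_id")["iBAQ"]
        ibaq = pd.to_numeric(ser, errors="raise").astype(float)
        ibaq.name = "iBAQ"
    table = QuantTable(design, data, ibaq)
    return table.zeros_to_missing()


# ---------------------------------------------------------------------------
# result tables

RESULT_SCHEMAS: Dict[str, List[str]] = {
    "fits": [
        "protein_id", "probe", "fraction", "metal", "n_replicates",
        "baseline", "plateau", "hill_slope", "kd_app_uM",
        "r_squared", "pearson_r", "pearson_tier", "f_stat", "f_pvalue",
        "log2fc_endpoints", "converged", "boundary",
        "pass_r2", "pass_f", "pass_fc", "pass_all", "affinity_class",
    ],
    "binders": [
        "protein_id", "probe", "fraction", "metal", "kd_app_uM", "affinity_class",
    ],
    "differential": [
        "protein_id", "contrast", "log2fc", "moderated_t", "p_value",
        "adj_p", "significant", "cutoff_mode",
    ],
    "anova": [
        "protein_id", "F_compound", "p_compound", "q_compound",
        "F_fraction", "p_fraction", "q_fraction",
        "F_treatment", "p_treatment", "q_treatment", "compound_specific",
    ],
    "enrichment": [
        "set_name", "universe_size", "set_size", "query_size", "overlap",
        "p_value", "adj_p", "overlap_ids",
    ],
    "candidates": [
        "protein_id", "n_motif_hits", "n_hits_in_disorder", "candidate",
        "hit_positions", "hit_motifs",
    ],
    "overlap": [
        "set_a", "set_b", "size_a", "size_b", "intersection",
        "frac_a_in_b", "defined",
    ],
}

_SORT_KEYS: Dict[str, List[str]] = {
    "fits": ["protein_id", "probe", "fraction", "metal"],
    "binders": ["protein_id", "probe", "fraction", "metal"],
    "differential": ["protein_id", "contrast"],
    "anova": ["protein_id"],
    "enrichment": ["adj_p", "p_value", "set_name"],
    "candidates": ["protein_id"],
    "overlap": ["set_a", "set_b"],
}


def write_results(records: pd.DataFrame, path: str | Path, kind: str) -> None:
    """Write a result table with a stable schema and deterministic row order."""
    if kind not in RESULT_SCHEMAS:
        raise ValueError(f"unknown result kind {kind!r}; one of {sorted(RESULT_SCHEMAS)}")
    cols = RESULT_SCHEMAS[kind]
    path = Path(path)
    df = pd.DataFrame(records, columns=cols) if len(records) else pd.DataFrame(columns=cols)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"records for kind {kind!r} lack columns {missing}")
    df = df[cols]
    if len(df):
        df = df.sort_values(_SORT_KEYS[kind], kind="mergesort")
    df.to_csv(path, sep=_delimiter(path), index=False, na_rep="")


# ---------------------------------------------------------------------------
# gene sets (GMT) and sequences (FASTA)

def write_gmt(gene_sets: Mapping[str, Tuple[str, Sequence[str]]], path: str | Path) -> None:
    """GMT: one set per line -- name, description, tab-separated member ids."""
    with open(path, "w") as fh:
        for name, (desc, members) in gene_sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path: str | Path) -> Dict[str, Tuple[str, List[str]]]:
    sets: Dict[str, Tuple[str, List[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 member")
            name, desc, members = parts[0], parts[1], [p for p in parts[2:] if p]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = (desc, members)
    return sets


def write_fasta(records: Sequence[Tuple[str, str]], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in records],
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> List[Tuple[str, str]]:
    from Bio.SeqIO import parse as seqio_parse

    return [(rec.id, str(rec.seq)) for rec in seqio_parse(str(path), "fasta")]
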