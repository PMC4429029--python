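"""Readers and writers for the pipeline's plain-text interchange formats.

Matrix TSV
    column 1 ``feature_id``; one column per sample named ``<pair>_T`` or
    ``<pair>_N``; tab-separated; ``NA`` marks a missing value.  Pair order is
    the order of first appearance in the header.

Annotation
    BED6 plus two extra columns (platform, gene_symbol), tab-separated, no
    header: chrom, start, end, probe_id, score, strand, platform, gene_symbol
    and an optional ninth column with a region class.

Report
    flat-key JSON; fractions are written with six decimal digits.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .datatypes import (
    ContributionReport,
    DifferentialRecord,
    GeneAggregate,
    PairedOmicsMatrix,
    ProbeAnnotation,
    ScnaCall,
    TruthRecord,
)
from .errors import FormatError, PairingError, ParseError

PathLike = Union[str, Path]

_SAMPLE_COL = re.compile(r"^(?P<pair>.+)_(?P<half>[TN])$")
#: values accepted as missing in matrix cells
_NA_TOKENS = {"NA", "NaN", "nan", ""}


def read_matrix(path: PathLike, platform: str) -> PairedOmicsMatrix:
    """Read a paired matrix TSV, aligning tumor and normal halves by pair id.

    Raises :class:`PairingError` when a pair has only one half and
    :class:`ParseError` (with the offending row and column) for a
    non-numeric cell.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] == 0 or df.columns[0] != "feature_id":
        raise FormatError(f"{path}: first column must be 'feature_id'")
    features = df["feature_id"].tolist()

    pairs: list[str] = []
    halves: dict[tuple[str, str], str] = {}
    for col in df.columns[1:]:
        m = _SAMPLE_COL.match(col)
        if m is None:
            raise FormatError(f"{path}: column {col!r} is not <pair>_T or <pair>_N")
        pair, half = m.group("pair"), m.group("half")
        if (pair, half) in halves:
            raise FormatError(f"{path}: duplicate column {col!r}")
        halves[(pair, half)] = col
        if pair not in pairs:
            pairs.append(pair)
    for pair in pairs:
        for half in ("T", "N"):
            if (pair, half) not in halves:
                raise PairingError(f"{path}: pair {pair!r} lacks its _{half} column")

    def _numeric(col: str) -> np.ndarray:
        raw = df[col]
        out = pd.to_numeric(raw.where(~raw.isin(_NA_TOKENS)), errors="coerce")
        bad = out.isna() & ~raw.isin(_NA_TOKENS)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {raw.iloc[row]!r} at row "
                f"{row + 2} (feature {features[row]!r}), column {col!r}"
            )
        return out.to_numpy(dtype=float)

    tumor = pd.DataFrame(
        {pair: _numeric(halves[(pair, "T")]) for pair in pairs}, index=features
    )
    normal = pd.DataFrame(
        {pair: _numeric(halves[(pair, "N")]) for pair in pairs}, index=features
    )
    return PairedOmicsMatrix(platform=platform, tumor=tumor, normal=normal)


def write_matrix(matrix: PairedOmicsMatrix, path: PathLike) -> None:
    """Write a paired matrix TSV; values printed at full double precision so
    ``read_matrix`` inverts this bit-exactly."""
    out = pd.DataFrame(index=matrix.tumor.index.copy())
    for pair in matrix.pair_ids:
        out[f"{pair}_T"] = matrix.tumor[pair]
        out[f"{pair}_N"] = matrix.normal[pair]
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.17g", na_rep="NA")


def read_annotation(path: PathLike) -> list[ProbeAnnotation]:
    """Read a BED6+2(+1) annotation file, preserving input order."""
    records: list[ProbeAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (8, 9):
                raise FormatError(
                    f"{path}:{lineno}: expected 8 or 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            chrom, start, end, probe_id, _score, strand, platform, gene = fields[:8]
            region = fields[8] if len(fields) == 9 and fields[8] else None
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            records.append(
                ProbeAnnotation(
                    probe_id=probe_id,
                    platform=platform,
                    chromosome=chrom,
                    start=start_i,
                    end=end_i,
                    strand=strand,
                    gene_symbol=gene,
                    region_class=region,
                )
            )
    return records


def write_annotation(records: Iterable[ProbeAnnotation], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fields = [
                r.chromosome,
                str(r.start),
                str(r.end),
                r.probe_id,
                "0",
                r.strand,
                r.platform,
                r.gene_symbol,
            ]
            if r.region_class is not None:
                fields.append(r.region_class)
            fh.write("\t".join(fields) + "\n")


_FRACTION_FIELDS = ("frac_meth", "frac_cn", "frac_union")


def write_report(report: ContributionReport, path: PathLike) -> None:
    """Serialize a contribution report to flat-key JSON.

    Fractions are printed with six decimal digits (trailing zeros kept) so
    the on-disk document always shows at least four decimals.
    """
    items = []
    for f in dataclasses.fields(report):
        value = getattr(report, f.name)
        if f.name in _FRACTION_FIELDS:
            items.append(f'  "{f.name}": {value:.6f}')
        else:
            items.append(f'  "{f.name}": {json.dumps(value)}')
    with open(path, "w") as fh:
        fh.write("{\n" + ",\n".join(items) + "\n}\n")


def read_report(path: PathLike) -> ContributionReport:
    with open(path) as fh:
        data = json.load(fh)
    names = {f.name for f in dataclasses.fields(ContributionReport)}
    return ContributionReport(**{k: v for k, v in data.items() if k in names})


# --- tabular serialization of per-record results (CLI interchange) ---------


def _records_to_frame(records: Sequence) -> pd.DataFrame:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = ",".join(v)
        rows.append(d)
    return pd.DataFrame(rows)


def write_records(records: Sequence, path: PathLike) -> None:
    """Write a list of result dataclasses (one row each) as a TSV."""
    _records_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_differential(path: PathLike) -> list[DifferentialRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    return [DifferentialRecord(**row) for row in df.to_dict(orient="records")]


def read_gene_aggregates(path: PathLike) -> list[GeneAggregate]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_symbol": str})
    out = []
    for row in df.to_dict(orient="records"):
        row["probe_ids"] = tuple(str(row["probe_ids"]).split(",")) if row.get("probe_ids") else ()
        out.append(GeneAggregate(**row))
    return out


def read_scna_calls(path: PathLike) -> list[ScnaCall]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_symbol": str})
    out = []
    for row in df.to_dict(orient="records"):
        row["run_probe_ids"] = tuple(str(row["run_probe_ids"]).split(","))
        out.append(ScnaCall(**row))
    return out


def write_truth(truth: Sequence[TruthRecord], path: PathLike) -> None:
    _records_to_frame(truth).to_csv(path, sep="\t", index=False)


def read_truth(path: PathLike) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [TruthRecord(**row) for row in df.to_dict(orient="records")]
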