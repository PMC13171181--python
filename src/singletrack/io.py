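"""Pair-file input/output.

Two input layouts:

* ``tsv``: one pair per line, ``query<TAB>target`` or
  ``id<TAB>query<TAB>target``.
* ``fasta-pair``: two FASTA files with equal record counts, paired by
  order (queries in the first file, targets in the second).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from Bio import SeqIO


class PairFormatError(ValueError):
    """Malformed pair input; the message carries the file location."""


@dataclass(frozen=True)
class PairFileRecord:
    query: str
    target: str
    id: Optional[str] = None


def _check_seq(seq: str, where: str, allow_empty: bool) -> str:
    if not allow_empty and seq == "":
        raise PairFormatError(f"{where}: empty sequence (pass allow_empty to permit)")
    if any(c.isspace() for c in seq):
        raise PairFormatError(f"{where}: whitespace inside sequence")
    return seq


def read_pairs(
    path: Union[str, Path],
    fmt: str = "tsv",
    *,
    target_path: Union[str, Path, None] = None,
    allow_empty: bool = False,
) -> Iterator[PairFileRecord]:
    """Stream pair records in input order.

    ``fmt="tsv"`` reads ``path``; ``fmt="fasta-pair"`` reads queries from
    ``path`` and targets from ``target_path``, paired by record order.
    """
    if fmt == "tsv":
        yield from _read_tsv(Path(path), allow_empty)
    elif fmt == "fasta-pair":
        if target_path is None:
            raise ValueError("fasta-pair format needs target_path")
        yield from _read_fasta_pair(Path(path), Path(target_path), allow_empty)
    else:
        raise ValueError(f"unknown pair format {fmt!r}")


def _read_tsv(path: Path, allow_empty: bool) -> Iterator[PairFileRecord]:
    with open(path) as fh:
        seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            where = f"{path}:{lineno}"
            if len(fields) == 2:
                ident, q, t = None, *fields
            elif len(fields) == 3:
                ident, q, t = fields
            else:
                raise PairFormatError(
                    f"{where}: expected 2 or 3 tab-separated fields, got {len(fields)}"
                )
            seen = True
            yield PairFileRecord(
                _check_seq(q, where, allow_empty),
                _check_seq(t, where, allow_empty),
                ident,
            )
        if not seen:
            raise PairFormatError(f"{path}: no pair records found")


def _read_fasta_pair(qpath: Path, tpath: Path, allow_empty: bool) -> Iterator[PairFileRecord]:
    try:
        queries = list(SeqIO.parse(str(qpath), "fasta"))
        targets = list(SeqIO.parse(str(tpath), "fasta"))
    except ValueError as exc:
        raise PairFormatError(f"malformed FASTA: {exc}") from exc
    if not queries:
        raise PairFormatError(f"{qpath}: no FASTA records found")
    if len(queries) != len(targets):
        longer = max(len(queries), len(targets))
        raise PairFormatError(
            f"ragged pairing: record {longer} present in only one of "
            f"{qpath} ({len(queries)} records) and {tpath} ({len(targets)} records)"
        )
    for idx, (qrec, trec) in enumerate(zip(queries, targets), start=1):
        where = f"{qpath}|{tpath}:record {idx}"
        yield PairFileRecord(
            _check_seq(str(qrec.seq), where, allow_empty),
            _check_seq(str(trec.seq), where, allow_empty),
            qrec.id,
        )


def write_pairs(records: Iterable[PairFileRecord], path: Union[str, Path]) -> None:
    """Write records as a TSV pair file (id column only when present)."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.id is not None:
                fh.write(f"{rec.id}\t{rec.query}\t{rec.target}\n")
            else:
                fh.write(f"{rec.query}\t{rec.target}\n")
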