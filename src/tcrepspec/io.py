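"""Reading, QC and writing of TCR beta clonotype tables.

Supported input dialects (tab-delimited, header row, gzip-transparent):

``mixcr``
    MiXCR clone export: ``aaSeqCDR3``, ``allVHitsWithScore``,
    ``allJHitsWithScore``, ``cloneCount``.
``airr``
    AIRR Rearrangement: ``junction_aa``, ``v_call``, ``j_call``,
    ``duplicate_count``.
``simple``
    This package's normalized output: ``cdr3_aa``, ``v_gene``, ``j_gene``,
    ``read_count`` plus optional ``donor_id`` and ``epitope``.

Parsing keeps raw gene strings; :func:`qc_clonotypes` applies the filter
cascade (anchor residues, amino-acid alphabet, orphon genes) together with
allele stripping and first-gene selection, and returns an audit report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .resources import AA_SET, DEFAULT_ORPHON_GENES

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A clonotype table does not conform to the declared dialect."""


@dataclass(frozen=True, order=True)
class Clonotype:
    """One TCR beta chain record.

    ``v_gene``/``j_gene`` hold raw strings straight after parsing (possibly
    with alleles/scores/multiple hits) and clean single-gene symbols after QC.
    """

    cdr3_aa: str
    v_gene: str
    j_gene: str
    read_count: int = 1
    donor_id: str = ""
    epitope: Optional[str] = None

    def replace(self, **kw) -> "Clonotype":
        return dataclasses.replace(self, **kw)


@dataclass
class ParseReport:
    """Per-table QC accounting; output + all rejections = input."""

    n_input: int = 0
    n_rejected_anchor: int = 0
    n_rejected_stop_or_nonaa: int = 0
    n_rejected_orphon: int = 0
    n_rejected_missing_gene: int = 0
    n_output: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


_DIALECT_COLUMNS = {
    "mixcr": {
        "cdr3_aa": "aaSeqCDR3",
        "v_gene": "allVHitsWithScore",
        "j_gene": "allJHitsWithScore",
        "read_count": "cloneCount",
    },
    "airr": {
        "cdr3_aa": "junction_aa",
        "v_gene": "v_call",
        "j_gene": "j_call",
        "read_count": "duplicate_count",
    },
    "simple": {
        "cdr3_aa": "cdr3_aa",
        "v_gene": "v_gene",
        "j_gene": "j_gene",
        "read_count": "read_count",
    },
}


def read_clonotype_table(
    path: str | Path,
    dialect: str = "simple",
    donor_id: str = "",
    epitope: Optional[str] = None,
) -> list[Clonotype]:
    """Read a clonotype table into pre-QC records (no filters applied).

    Missing or non-finite read counts default to 1. ``donor_id``/``epitope``
    given here are fallbacks; columns of the same name in a ``simple`` table
    win.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    cols = _DIALECT_COLUMNS[dialect]
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("empty clonotype table: %s", path)
        return []
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required {dialect} column(s): {', '.join(missing)}"
        )
    if df.empty:
        logger.warning("clonotype table has no data rows: %s", path)
        return []

    records = []
    for row in df.itertuples(index=False):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        count = _coerce_count(row.get(cols["read_count"]))
        records.append(
            Clonotype(
                cdr3_aa=str(row.get(cols["cdr3_aa"]) or ""),
                v_gene=str(row.get(cols["v_gene"]) or ""),
                j_gene=str(row.get(cols["j_gene"]) or ""),
                read_count=count,
                donor_id=str(_opt(row.get("donor_id"), donor_id))
                if dialect == "simple"
                else donor_id,
                epitope=_opt(row.get("epitope"), epitope)
                if dialect == "simple"
                else epitope,
            )
        )
    return records


def _opt(value, fallback):
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return fallback
    return value


def _coerce_count(value) -> int:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return 1
    try:
        count = int(round(float(value)))
    except (TypeError, ValueError):
        logger.warning("unparseable read count %r; defaulting to 1", value)
        return 1
    if count < 1:
        logger.warning("read count %r < 1; clamped to 1", value)
        return 1
    return count


def strip_allele_and_select_first(gene_field: str) -> str:
    """Reduce a raw V/J hit string to a single allele-free gene symbol.

    Splits on commas, keeps the first listed gene, drops any parenthesized
    alignment score and any ``*allele`` suffix. Returns ``""`` for blank
    input (caller rejects as missing-gene).
    """
    if gene_field is None:
        return ""
    first = str(gene_field).split(",")[0]
    first = re.sub(r"\(.*?\)", "", first)
    first = first.split("*")[0]
    return first.strip()


def normalize_gene_symbol(symbol: str) -> str:
    """Canonicalize zero-padded gene dialects: ``TRBV07-03`` -> ``TRBV7-3``."""
    return re.sub(r"0*(\d+)", lambda m: str(int(m.group(1))), symbol)


def qc_clonotypes(
    records: Sequence[Clonotype],
    orphon_genes: Iterable[str] = DEFAULT_ORPHON_GENES,
) -> tuple[list[Clonotype], ParseReport]:
    """Apply the QC cascade and gene-field normalization.

    A record is rejected at the first failing rule, in order:

    1. CDR3 not anchored by the conserved cysteine ... phenylalanine frame;
    2. CDR3 contains a stop codon or any other non-amino-acid character;
    3. the V or J gene is an orphon (membership on normalized symbols);
    4. the V or J field is blank (missing gene).

    Surviving records carry allele-free, first-hit gene symbols. Idempotent.
    """
    orphons = {normalize_gene_symbol(g) for g in orphon_genes}
    report = ParseReport(n_input=len(records))
    out: list[Clonotype] = []
    for rec in records:
        seq = rec.cdr3_aa
        if len(seq) < 2 or not seq.startswith("C") or not seq.endswith("F"):
            report.n_rejected_anchor += 1
            continue
        if not set(seq) <= AA_SET:
            report.n_rejected_stop_or_nonaa += 1
            continue
        v = strip_allele_and_select_first(rec.v_gene)
        j = strip_allele_and_select_first(rec.j_gene)
        if normalize_gene_symbol(v) in orphons or normalize_gene_symbol(j) in orphons:
            report.n_rejected_orphon += 1
            continue
        if not v or not j:
            report.n_rejected_missing_gene += 1
            continue
        out.append(rec.replace(v_gene=v, j_gene=j, read_count=max(1, rec.read_count)))
    report.n_output = len(out)
    return out, report


def to_frame(records: Sequence[Clonotype]) -> pd.DataFrame:
    """Records -> simple-dialect DataFrame."""
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in records],
        columns=["cdr3_aa", "v_gene", "j_gene", "read_count", "donor_id", "epitope"],
    )


def from_frame(df: pd.DataFrame) -> list[Clonotype]:
    full = df.reindex(
        columns=["cdr3_aa", "v_gene", "j_gene", "read_count", "donor_id", "epitope"]
    )
    return [
        Clonotype(
            cdr3_aa=str(r.cdr3_aa),
            v_gene=str(r.v_gene),
            j_gene=str(r.j_gene),
            read_count=1 if pd.isna(r.read_count) else int(r.read_count),
            donor_id="" if pd.isna(r.donor_id) else str(r.donor_id),
            epitope=None if pd.isna(r.epitope) else str(r.epitope),
        )
        for r in full.itertuples(index=False)
    ]


def write_clonotype_table(records: Sequence[Clonotype], path: str | Path) -> None:
    """Write records as a simple-dialect TSV (gzip-transparent by suffix)."""
    to_frame(records).to_csv(path, sep="\t", index=False)
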