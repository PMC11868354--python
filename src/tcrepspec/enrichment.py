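"""V/J gene and gene-family usage enrichment against a background repertoire.

Usage is counted over unique TCRs (unique CDR3 + V + J combinations), not
read counts. Each gene observed at least ``min_count`` times in the focal
set is tested with a two-sided Fisher exact test on the 2x2 table

    [[gene in focal, gene in background],
     [other in focal, other in background]]

and Benjamini-Hochberg correction is applied per gene class (V or J) and
epitope. Genes below ``min_count`` are reported untested (no p, no q).
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .epitope_db import dedup_cdr3  # noqa: F401  (re-export convenience)
from .io import Clonotype, normalize_gene_symbol, qc_clonotypes

logger = logging.getLogger(__name__)

MIN_FOCAL_COUNT = 2
ALPHA = 0.05


def build_background(
    tables: Iterable[Sequence[Clonotype]],
    orphon_genes: Iterable[str] | None = None,
) -> list[Clonotype]:
    """Pool clonotype tables into a QC-passed, deduplicated background set.

    Duplicates are removed on the (cdr3_aa, v_gene, j_gene) triple after QC.
    """
    pooled: list[Clonotype] = []
    for table in tables:
        if orphon_genes is None:
            passed, _ = qc_clonotypes(table)
        else:
            passed, _ = qc_clonotypes(table, orphon_genes)
        pooled.extend(passed)
    seen: dict[tuple, Clonotype] = {}
    for rec in pooled:
        seen.setdefault((rec.cdr3_aa, rec.v_gene, rec.j_gene), rec)
    if not seen:
        raise ValueError("background set is empty; enrichment tests impossible")
    return [seen[k] for k in sorted(seen)]


def gene_family(symbol: str) -> str:
    """IMGT subgroup: symbol truncated before the subfamily hyphen."""
    return symbol.split("-")[0]


def _usage_counts(records: Sequence[Clonotype], segment: str, level: str) -> Counter:
    attr = {"v": "v_gene", "j": "j_gene"}[segment]
    symbols = (getattr(r, attr) for r in records)
    if level == "family":
        symbols = (gene_family(s) for s in symbols)
    return Counter(symbols)


def gene_usage_table(
    focal: Sequence[Clonotype],
    background: Sequence[Clonotype],
    segment: str = "v",
    level: str = "gene",
) -> pd.DataFrame:
    """Per-symbol usage counts in focal vs background unique-TCR sets.

    Symbols are matched across zero-padded/non-padded dialects; the output
    spelling follows the focal set where the symbol occurs there.
    """
    focal_counts = _usage_counts(focal, segment, level)
    bg_counts = _usage_counts(background, segment, level)
    display: dict[str, str] = {}
    norm_focal: Counter = Counter()
    for sym, n in focal_counts.items():
        key = normalize_gene_symbol(sym)
        display.setdefault(key, sym)
        norm_focal[key] += n
    norm_bg: Counter = Counter()
    for sym, n in bg_counts.items():
        key = normalize_gene_symbol(sym)
        display.setdefault(key, sym)
        norm_bg[key] += n
    rows = [
        {
            "symbol": display[key],
            "focal_count": norm_focal.get(key, 0),
            "background_count": norm_bg.get(key, 0),
            "focal_total": len(focal),
            "background_total": len(background),
        }
        for key in sorted(set(norm_focal) | set(norm_bg))
    ]
    return pd.DataFrame(
        rows,
        columns=["symbol", "focal_count", "background_count",
                 "focal_total", "background_total"],
    )


def family_rollup(usage: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a gene-level usage table to IMGT subgroups (counts summed)."""
    df = usage.copy()
    df["symbol"] = df["symbol"].map(gene_family)
    rolled = (
        df.groupby("symbol", as_index=False)
        .agg(
            focal_count=("focal_count", "sum"),
            background_count=("background_count", "sum"),
            focal_total=("focal_total", "first"),
            background_total=("background_total", "first"),
        )
        .sort_values("symbol", ignore_index=True)
    )
    return rolled


def fisher_enrichment(row, min_count: int = MIN_FOCAL_COUNT) -> dict:
    """Two-sided Fisher exact test for one usage-table row.

    Odds ratio uses the sample convention (a*d)/(b*c), with ``inf`` when
    ``b*c == 0`` and ``a*d > 0``. Rows with focal count below ``min_count``
    are flagged untested and get no p-value.
    """
    a = int(row["focal_count"])
    b = int(row["background_count"])
    c = int(row["focal_total"]) - a
    d = int(row["background_total"]) - b
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in 2x2 table")
    if a * d == 0 and b * c == 0:
        odds = np.nan
    elif b * c == 0:
        odds = np.inf
    else:
        odds = (a * d) / (b * c)
    result = {"symbol": row["symbol"], "a": a, "b": b, "c": c, "d": d,
              "odds_ratio": odds, "tested": a >= min_count, "p": np.nan}
    if result["tested"]:
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        result["p"] = p
    return result


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone-enforced)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    focal: Sequence[Clonotype],
    background: Sequence[Clonotype],
    segment: str = "v",
    level: str = "gene",
    min_count: int = MIN_FOCAL_COUNT,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Full enrichment analysis for one segment class of one epitope set.

    Returns one row per symbol with the 2x2 cells, odds ratio, p, BH q
    (within the tested symbols of this segment class only), direction and
    significance at ``q < alpha``.
    """
    usage = gene_usage_table(focal, background, segment=segment, level=level)
    results = pd.DataFrame([fisher_enrichment(r, min_count) for _, r in usage.iterrows()])
    results["q"] = np.nan
    tested = results["tested"].to_numpy()
    if tested.any():
        results.loc[tested, "q"] = bh_adjust(results.loc[tested, "p"])
    results["direction"] = np.where(results["odds_ratio"] > 1, "enriched", "depleted")
    results["significant"] = results["q"] < alpha
    return results
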