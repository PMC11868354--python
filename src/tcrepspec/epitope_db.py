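"""Construction of the per-epitope TCR database and publicity analysis.

Sorted sequencing runs for several epitopes share material from the same
donors, so a CDR3 can surface under more than one sorting epitope (tetramer
spill-over / promiscuous clones). The database builder resolves these by the
read-count ratio rule: for each ambiguous CDR3 the highest read count per
epitope is compared between the two most abundant epitopes; a ratio of at
least ``ratio_threshold`` (default 100) assigns the CDR3 to the dominant
epitope, anything below removes the CDR3 entirely. Control-sort epitopes
(e.g. irrelevant-tetramer sorts) participate in disambiguation but never
enter the final database.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io import Clonotype

logger = logging.getLogger(__name__)

#: Default read-count ratio for cross-epitope disambiguation.
RATIO_THRESHOLD = 100.0


@dataclass
class EpitopeDB:
    """Per-epitope sets of QC-passed clonotypes with donor provenance.

    ``entries`` maps epitope -> records unique per (donor, cdr3, v, j), read
    counts summed over technical replicates. Each CDR3 is assigned to at most
    one epitope.
    """

    epitopes: list[str] = field(default_factory=list)
    entries: dict[str, list[Clonotype]] = field(default_factory=dict)

    def unique_cdr3s(self, epitope: str) -> set[str]:
        return {c.cdr3_aa for c in self.entries.get(epitope, [])}

    def unique_clonotypes(self, epitope: str) -> list[Clonotype]:
        """One record per (cdr3, v, j) triple, counts summed over donors."""
        acc: dict[tuple, int] = Counter()
        for c in self.entries.get(epitope, []):
            acc[(c.cdr3_aa, c.v_gene, c.j_gene)] += c.read_count
        return [
            Clonotype(cdr3_aa=k[0], v_gene=k[1], j_gene=k[2], read_count=n, epitope=epitope)
            for k, n in sorted(acc.items())
        ]

    def size(self, epitope: str) -> int:
        """Number of unique CDR3 beta sequences under an epitope."""
        return len(self.unique_cdr3s(epitope))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (e, c.cdr3_aa, c.v_gene, c.j_gene, c.read_count, c.donor_id)
            for e in self.epitopes
            for c in self.entries[e]
        ]
        return pd.DataFrame(
            rows, columns=["epitope", "cdr3_aa", "v_gene", "j_gene", "read_count", "donor_id"]
        )


def disambiguate_cross_epitope(
    per_epitope_max_counts: dict[str, int],
    ratio_threshold: float = RATIO_THRESHOLD,
) -> Optional[str]:
    """Assign a multi-epitope CDR3 to one epitope, or remove it.

    ``per_epitope_max_counts`` holds, per epitope, the highest read count
    observed for this CDR3. The ratio between the two most abundant epitopes
    decides: ``top/second >= ratio_threshold`` returns the top epitope,
    otherwise ``None`` (remove entirely). Ties give ratio 1 and removal.
    CDR3s seen under a single epitope should bypass this rule.
    """
    if len(per_epitope_max_counts) < 2:
        raise ValueError("disambiguation requires counts under >= 2 epitopes")
    # sort by (count desc, epitope asc) for a deterministic top
    ranked = sorted(per_epitope_max_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    (top_epitope, top), (_, second) = ranked[0], ranked[1]
    if top / second >= ratio_threshold:
        return top_epitope
    return None


def dedup_cdr3(entries: Sequence[Clonotype]) -> list[Clonotype]:
    """Collapse to one record per CDR3: keep the highest-read-count V/J pair.

    Ties are broken by lexicographically smallest (v_gene, j_gene) so the
    result is order-independent.
    """
    best: dict[str, Clonotype] = {}
    for rec in entries:
        cur = best.get(rec.cdr3_aa)
        if (
            cur is None
            or rec.read_count > cur.read_count
            or (
                rec.read_count == cur.read_count
                and (rec.v_gene, rec.j_gene) < (cur.v_gene, cur.j_gene)
            )
        ):
            best[rec.cdr3_aa] = rec
    return [best[k] for k in sorted(best)]


def build_epitope_db(
    per_donor_runs: Iterable[tuple[str, str, Sequence[Clonotype]]],
    ratio_threshold: float = RATIO_THRESHOLD,
    control_epitopes: Iterable[str] = (),
) -> EpitopeDB:
    """Merge QC-passed sorted runs into a per-epitope database.

    ``per_donor_runs`` yields ``(donor_id, epitope, clonotypes)``. Replicate
    runs for the same (donor, epitope) are merged with read counts summed
    (logged). Cross-epitope CDR3s go through the ratio rule; control-sort
    epitopes take part in disambiguation but are dropped from the result.
    """
    control = set(control_epitopes)
    # (epitope, donor, cdr3, v, j) -> summed count
    merged: Counter = Counter()
    seen_runs: set[tuple[str, str]] = set()
    for donor_id, epitope, clonotypes in per_donor_runs:
        if (donor_id, epitope) in seen_runs:
            logger.info("merging replicate run donor=%s epitope=%s (counts summed)",
                        donor_id, epitope)
        seen_runs.add((donor_id, epitope))
        for c in clonotypes:
            merged[(epitope, donor_id, c.cdr3_aa, c.v_gene, c.j_gene)] += c.read_count

    per_cdr3_epitope_max: dict[str, dict[str, int]] = defaultdict(dict)
    for (epitope, _donor, cdr3, _v, _j), n in merged.items():
        cur = per_cdr3_epitope_max[cdr3].get(epitope, 0)
        per_cdr3_epitope_max[cdr3][epitope] = max(cur, n)

    assignment: dict[str, Optional[str]] = {}
    for cdr3, by_epitope in per_cdr3_epitope_max.items():
        if len(by_epitope) == 1:
            assignment[cdr3] = next(iter(by_epitope))
        else:
            assignment[cdr3] = disambiguate_cross_epitope(by_epitope, ratio_threshold)

    db = EpitopeDB()
    entries: dict[str, list[Clonotype]] = defaultdict(list)
    for (epitope, donor, cdr3, v, j), n in sorted(merged.items()):
        if epitope in control or assignment[cdr3] != epitope:
            continue
        entries[epitope].append(
            Clonotype(cdr3_aa=cdr3, v_gene=v, j_gene=j, read_count=n,
                      donor_id=donor, epitope=epitope)
        )
    db.epitopes = sorted(entries)
    db.entries = dict(entries)
    for e in db.epitopes:
        logger.info("epitope %s: %d unique CDR3s", e, db.size(e))
    return db


def publicity(db: EpitopeDB, epitope: str) -> tuple[pd.DataFrame, dict[int, int]]:
    """Donor sharing of CDR3 beta sequences (V/J genes ignored).

    Returns a table with one row per unique CDR3 (``n_donors``, per-donor
    read counts, ``public`` flag meaning shared by >= 2 donors) and a
    histogram ``{n_donors: n_public_cdr3s}`` restricted to public sequences.
    """
    per_cdr3: dict[str, dict[str, int]] = defaultdict(Counter)
    for c in db.entries.get(epitope, []):
        per_cdr3[c.cdr3_aa][c.donor_id] += c.read_count
    rows = []
    for cdr3 in sorted(per_cdr3):
        donors = per_cdr3[cdr3]
        rows.append(
            {
                "cdr3_aa": cdr3,
                "epitope": epitope,
                "n_donors": len(donors),
                "donor_read_counts": dict(sorted(donors.items())),
                "public": len(donors) >= 2,
            }
        )
    table = pd.DataFrame(rows, columns=["cdr3_aa", "epitope", "n_donors",
                                        "donor_read_counts", "public"])
    hist = dict(Counter(r["n_donors"] for r in rows if r["public"]))
    return table, hist
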