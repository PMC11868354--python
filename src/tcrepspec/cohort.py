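"""Annotation of independent patient repertoires with epitope-specific TCRs.

Specific TCRs are identified two ways and the results unioned per CDR3:
exact look-up of the CDR3 against the epitope database (V/J ignored) and
model prediction at the BPR threshold. Per-individual summary tables report
repertoire size, specific-TCR counts and frequencies (percent of unique
clonotypes, 3 decimals). All individuals' repertoires are then jointly
clustered; clusters containing at least one identified specific TCR are
annotated and their clinical-group composition tested for association with
a Pearson chi-squared test (no continuity correction).
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ClusterGraph, hamming1_graph
from .epitope_db import EpitopeDB, dedup_cdr3
from .io import Clonotype
from .model import BPR_THRESHOLD, TcrSpecificityClassifier, predict_repertoire

logger = logging.getLogger(__name__)

KNOWN_GROUPS = ("healthy", "complete remission", "relapse")


@dataclass
class Repertoire:
    """One individual's merged TCR beta repertoire (unique CDR3s)."""

    individual_id: str
    group: str
    clonotypes: list[Clonotype] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.clonotypes)

    @property
    def cdr3_set(self) -> set[str]:
        return {c.cdr3_aa for c in self.clonotypes}

    @classmethod
    def from_samples(
        cls, individual_id: str, group: str,
        samples: Iterable[Sequence[Clonotype]],
    ) -> "Repertoire":
        """Merge multiple samples into a single repertoire.

        Read counts of identical triples are summed, then the repertoire is
        collapsed to unique CDR3s (highest-count V/J pair retained).
        """
        acc: dict[tuple, int] = defaultdict(int)
        for sample in samples:
            for c in sample:
                acc[(c.cdr3_aa, c.v_gene, c.j_gene)] += c.read_count
        merged = [
            Clonotype(cdr3_aa=k[0], v_gene=k[1], j_gene=k[2], read_count=n,
                      donor_id=individual_id)
            for k, n in acc.items()
        ]
        return cls(individual_id=individual_id, group=group,
                   clonotypes=dedup_cdr3(merged))


def specific_frequency(count: int, size: int) -> float:
    """Percent frequency of identified specific TCRs, 3-decimal rounding."""
    if size <= 0:
        raise ValueError("repertoire size must be positive")
    return round(100.0 * count / size, 3)


def lookup_specific(
    repertoire: Repertoire, db: EpitopeDB, epitope: str
) -> list[Clonotype]:
    """Exact CDR3 identity matches against the database (V/J ignored)."""
    known = db.unique_cdr3s(epitope)
    return [c for c in repertoire.clonotypes if c.cdr3_aa in known]


def annotate_cohort(
    repertoires: Sequence[Repertoire],
    db: EpitopeDB,
    models: Sequence[TcrSpecificityClassifier] = (),
    threshold: float = BPR_THRESHOLD,
) -> tuple[pd.DataFrame, dict[str, dict[str, set[str]]]]:
    """Identify epitope-specific TCRs per individual; Table-2-shaped summary.

    The identified set per epitope is the union (on CDR3) of exact look-up
    matches and BPR-passing model predictions. Returns the summary table and
    ``identified[epitope][individual_id] -> set of CDR3s``.
    """
    epitopes = list(db.epitopes)
    for m in models:
        if m.epitope not in epitopes:
            epitopes.append(m.epitope)
    identified: dict[str, dict[str, set[str]]] = {e: {} for e in epitopes}
    rows = []
    for rep in repertoires:
        if rep.group not in KNOWN_GROUPS:
            warnings.warn(f"unknown group label {rep.group!r} (retained)")
        row = {"individual_id": rep.individual_id, "group": rep.group,
               "repertoire_size": rep.size}
        by_model = {m.epitope: m for m in models}
        for epitope in epitopes:
            hits = {c.cdr3_aa for c in lookup_specific(rep, db, epitope)}
            model = by_model.get(epitope)
            if model is not None and rep.size:
                pred = predict_repertoire(model, rep.clonotypes, threshold)
                hits |= set(pred.loc[pred.passes, "cdr3_aa"])
            identified[epitope][rep.individual_id] = hits
            row[f"n_specific_{epitope}"] = len(hits)
            row[f"freq_specific_{epitope}"] = specific_frequency(len(hits), rep.size)
        rows.append(row)
    summary = pd.DataFrame(rows)
    # internal consistency: frequencies must recompute from their own counts
    for epitope in epitopes:
        recomputed = [
            specific_frequency(n, s)
            for n, s in zip(summary[f"n_specific_{epitope}"],
                            summary["repertoire_size"])
        ]
        assert list(summary[f"freq_specific_{epitope}"]) == recomputed
    return summary, identified


def joint_cluster_annotate(
    repertoires: Sequence[Repertoire],
    identified: Mapping[str, Mapping[str, set[str]]],
) -> tuple[ClusterGraph, pd.DataFrame, pd.DataFrame]:
    """Jointly cluster all repertoires and annotate specific clusters.

    All individuals' unique CDR3s are pooled and clustered at Hamming
    distance 1. Clusters containing at least one identified epitope-specific
    CDR3 (any epitope) form the annotated-cluster table: member-CDR3 counts
    per clinical group (a CDR3 occurring in several groups counts toward
    each) and identified-TCR counts per epitope. Also returns dot-plot data
    (cluster, individual, count, group).
    """
    meta: dict[str, dict] = defaultdict(lambda: {"donor_ids": set(), "groups": set()})
    for rep in repertoires:
        for c in rep.clonotypes:
            meta[c.cdr3_aa]["donor_ids"].add(rep.individual_id)
            meta[c.cdr3_aa]["groups"].add(rep.group)
    cg = hamming1_graph(meta.keys(), metadata=meta)

    specific_by_epitope = {
        e: set().union(*by_ind.values()) if by_ind else set()
        for e, by_ind in identified.items()
    }
    all_specific = set().union(*specific_by_epitope.values()) if specific_by_epitope else set()
    groups = sorted({r.group for r in repertoires})

    rows = []
    dot_rows = []
    for cid in sorted(cg.clusters):
        members = set(cg.clusters[cid])
        if not members & all_specific:
            continue
        row = {"cluster_id": cid, "size": len(members)}
        for g in groups:
            row[f"n_{g}"] = sum(1 for m in members
                                if g in cg.graph.nodes[m]["groups"])
        for e in sorted(specific_by_epitope):
            row[f"n_specific_{e}"] = len(members & specific_by_epitope[e])
        rows.append(row)
        for rep in repertoires:
            n = len(members & rep.cdr3_set)
            if n:
                dot_rows.append(
                    {"cluster_id": cid, "individual_id": rep.individual_id,
                     "count": n, "group": rep.group}
                )
    cols = ["cluster_id", "size"] + [f"n_{g}" for g in groups] + [
        f"n_specific_{e}" for e in sorted(specific_by_epitope)
    ]
    table = pd.DataFrame(rows, columns=cols)
    dots = pd.DataFrame(dot_rows, columns=["cluster_id", "individual_id",
                                           "count", "group"])
    return cg, table, dots


def group_cluster_association(
    table: pd.DataFrame,
    groups: tuple[str, str] = ("complete remission", "relapse"),
) -> tuple[float, int, float, np.ndarray]:
    """Pearson chi-squared test of group x annotated-cluster composition.

    Builds the 2 x K contingency of member-CDR3 counts for the two groups
    over the K annotated clusters (clusters empty in both groups dropped).
    No continuity correction. Returns (statistic, dof, p, expected counts);
    warns when any expected count is below 5.
    """
    cols = [f"n_{g}" for g in groups]
    for col, g in zip(cols, groups):
        if col not in table.columns:
            raise ValueError(f"group {g!r} absent from cluster table")
    counts = table[cols].to_numpy().T.astype(float)
    keep = counts.sum(axis=0) > 0
    counts = counts[:, keep]
    if counts.size == 0 or (counts.sum(axis=1) == 0).any():
        raise ValueError("a group has zero total count; association undefined")
    if counts.shape[1] < 2:
        raise ValueError("need at least two non-empty clusters")
    stat, p, dof, expected = stats.chi2_contingency(counts, correction=False)
    if (expected < 5).any():
        warnings.warn("chi-squared approximation: some expected counts < 5")
    return float(stat), int(dof), float(p), expected
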