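"""Synthetic TCR beta repertoire generator.

Emulates the statistical structure of the three data shapes the pipeline
consumes, without any download:

* per-donor epitope-sorted clonotype runs — motif-structured CDR3 sets with
  configurable per-position substitution (creating Hamming-1 neighbourhoods),
  cross-donor sharing (publicity) and cross-epitope contaminant clones with a
  configurable count-ratio law;
* bulk background pools — anchor-constrained random CDR3s over a realistic
  length distribution with weighted V/J usage and heavy-tailed (zipf) read
  counts;
* patient cohort repertoires — background clones mixed with planted
  database CDR3s (exact copies, for look-up) and near-motif variants (for
  model prediction), with group-dependent concentration of the planted
  clones into few or many Hamming-1 cluster families.

Ground-truth bookkeeping is returned alongside every data set so parameter-
recovery tests can check what the pipeline finds against what was planted.
All draws derive from ``numpy.random.default_rng`` seeded from the config.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .io import Clonotype
from .resources import AMINO_ACIDS, TRBJ_GENES, TRBV_GENES

#: CDR3 length law: support 8..20, mode at 13-15.
DEFAULT_LENGTH_DIST = {
    8: 0.01, 9: 0.03, 10: 0.05, 11: 0.08, 12: 0.12, 13: 0.17, 14: 0.17,
    15: 0.14, 16: 0.10, 17: 0.06, 18: 0.04, 19: 0.02, 20: 0.01,
}

#: Inner-position residue usage, loosely following bulk CDR3 composition
#: (glycine/serine-rich, tryptophan/cysteine-poor).
RESIDUE_WEIGHTS = {
    "A": 5.5, "C": 0.5, "D": 4.0, "E": 5.5, "F": 3.0, "G": 9.5, "H": 2.0,
    "I": 3.0, "K": 2.5, "L": 7.0, "M": 1.5, "N": 3.5, "P": 4.0, "Q": 5.5,
    "R": 5.5, "S": 12.0, "T": 7.0, "V": 4.5, "W": 1.0, "Y": 6.0,
}


@dataclass
class MotifSpec:
    """Epitope-specific CDR3 family: full-length consensus plus noise.

    ``substitution_rate`` is the per-inner-position probability of replacing
    the consensus residue (anchors stay fixed), which yields Hamming-1
    neighbourhoods around the consensus. ``preferred_v`` biases V usage of
    the family for enrichment testing.
    """

    consensus: str
    substitution_rate: float = 0.15
    preferred_v: Optional[str] = None
    preferred_v_prob: float = 0.0


DEFAULT_EPITOPES = {
    "EPI-A": MotifSpec("CASSLAGNTEAFF", 0.15, preferred_v="TRBV19",
                       preferred_v_prob=0.4),
    "EPI-B": MotifSpec("CASSIRSTDTQYF", 0.15, preferred_v="TRBV28",
                       preferred_v_prob=0.4),
}
#: Irrelevant-sort control used to absorb promiscuous clones.
DEFAULT_CONTROL_EPITOPE = "CTRL"


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic repertoires.

    Defaults mirror the shape of the emulated study: 12 donors sorted per
    epitope, ~150 clones per sorted run at 90% sort purity, ~15% cross-donor
    sharing of specific clones, 5% contamination with a lognormal count-ratio
    law (mostly below the disambiguation threshold), zipf(a=2) read counts,
    and a 3 healthy / 3 remission / 3 relapse cohort whose planted specific
    clones are concentrated in few cluster families for relapse and spread
    over many for remission.
    """

    seed: int = 0
    n_donors: int = 12
    clones_per_donor: int = 150
    sort_purity: float = 0.9
    families_per_epitope: int = 60
    length_dist: dict = field(default_factory=lambda: dict(DEFAULT_LENGTH_DIST))
    sharing_prob: float = 0.15
    contamination_rate: float = 0.05
    ratio_law: tuple = ("lognormal", 2.1, 1.2)  # median ~8, occasional >=100
    zipf_a: float = 2.0
    corrupt_fraction: float = 0.0
    cohort_groups: tuple = ("healthy", "complete remission", "relapse")
    cohort_sizes: dict = field(default_factory=lambda: {
        "healthy": [295, 1100, 931],
        "complete remission": [3099, 1451, 1021],
        "relapse": [503, 592, 617],
    })
    planted_exact_frequency: dict = field(default_factory=lambda: {
        "healthy": 0.001, "complete remission": 0.004, "relapse": 0.004,
    })
    planted_near_frequency: dict = field(default_factory=lambda: {
        "healthy": 0.001, "complete remission": 0.002, "relapse": 0.002,
    })
    cluster_concentration: dict = field(default_factory=lambda: {
        "healthy": 2, "complete remission": 7, "relapse": 1,
    })

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=str, indent=2)


_RES = list(RESIDUE_WEIGHTS)
_RES_P = np.array(list(RESIDUE_WEIGHTS.values()), float)
_RES_P /= _RES_P.sum()


def _gene_weights(genes: Sequence[str]) -> np.ndarray:
    # heavy-tailed usage: rank-based zipf-ish weights
    w = 1.0 / np.arange(1, len(genes) + 1) ** 0.8
    return w / w.sum()


def _draw_cdr3(rng: np.random.Generator, length_dist: dict) -> str:
    lengths = np.array(list(length_dist), int)
    probs = np.array(list(length_dist.values()), float)
    L = int(rng.choice(lengths, p=probs / probs.sum()))
    inner = rng.choice(_RES, size=L - 2, p=_RES_P)
    return "C" + "".join(inner) + "F"


def _draw_count(rng: np.random.Generator, a: float, scale: int = 1) -> int:
    return int(min(rng.zipf(a), 100_000)) * scale


def _corrupt(rng: np.random.Generator, seq: str) -> str:
    mode = rng.integers(3)
    if mode == 0:
        return seq[1:]  # lose the cysteine anchor
    if mode == 1:
        i = int(rng.integers(1, len(seq) - 1))
        return seq[:i] + "*" + seq[i + 1 :]  # stop codon
    return seq.lower()


def gen_background(
    config: GeneratorConfig,
    n: int,
    rng: Optional[np.random.Generator] = None,
    donor_id: str = "bg",
) -> list[Clonotype]:
    """Draw ``n`` unique background clonotypes (unique triples, QC-clean).

    With ``config.corrupt_fraction > 0`` a matching share of records is
    deliberately malformed (for QC testing) — those are appended after the
    clean draw and do not break triple uniqueness.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = config.rng() if rng is None else rng
    vw, jw = _gene_weights(TRBV_GENES), _gene_weights(TRBJ_GENES)
    seen: set[tuple] = set()
    out: list[Clonotype] = []
    while len(out) < n:
        seq = _draw_cdr3(rng, config.length_dist)
        v = str(rng.choice(TRBV_GENES, p=vw))
        j = str(rng.choice(TRBJ_GENES, p=jw))
        if (seq, v, j) in seen:
            continue
        seen.add((seq, v, j))
        out.append(Clonotype(seq, v, j, _draw_count(rng, config.zipf_a), donor_id))
    n_bad = int(round(config.corrupt_fraction * n))
    for _ in range(n_bad):
        seq = _corrupt(rng, _draw_cdr3(rng, config.length_dist))
        out.append(Clonotype(seq, str(rng.choice(TRBV_GENES, p=vw)),
                             str(rng.choice(TRBJ_GENES, p=jw)),
                             _draw_count(rng, config.zipf_a), donor_id))
    return out


def sample_motif_cdr3(spec: MotifSpec, rng: np.random.Generator) -> str:
    """One draw from a motif family: consensus with per-position noise."""
    inner = list(spec.consensus[1:-1])
    for i in range(len(inner)):
        if rng.random() < spec.substitution_rate:
            inner[i] = str(rng.choice(_RES, p=_RES_P))
    return "C" + "".join(inner) + "F"


def sample_motif_positives(
    spec: MotifSpec, n: int, rng: np.random.Generator
) -> list[str]:
    """``n`` unique CDR3s from a motif family (for training-set synthesis)."""
    out: set[str] = set()
    attempts = 0
    while len(out) < n:
        out.add(sample_motif_cdr3(spec, rng))
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("motif family too narrow for requested n")
    return sorted(out)[:n]


def _draw_ratio(rng: np.random.Generator, law: tuple) -> float:
    kind = law[0]
    if kind == "fixed":
        return float(law[1])
    if kind == "lognormal":
        return float(np.exp(rng.normal(law[1], law[2])))
    raise ValueError(f"unknown ratio law {law!r}")


def gen_sorted_runs(
    config: GeneratorConfig,
    epitopes: Optional[dict[str, MotifSpec]] = None,
    control_epitope: str = DEFAULT_CONTROL_EPITOPE,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[tuple[str, str, list[Clonotype]]], dict]:
    """Per-donor, per-epitope sorted clonotype runs plus ground truth.

    Each run holds mostly motif-family clones of its sorting epitope (at
    ``sort_purity``) and a background remainder. A ``sharing_prob`` fraction
    of specific clones is copied into another donor's run for the same
    epitope; a ``contamination_rate`` fraction also appears under a second
    epitope (or the control sort) with its read count divided by a draw from
    the ratio law.
    """
    epitopes = dict(DEFAULT_EPITOPES) if epitopes is None else epitopes
    rng = config.rng() if rng is None else rng
    vw, jw = _gene_weights(TRBV_GENES), _gene_weights(TRBJ_GENES)
    donors = [f"HD{i+1}" for i in range(config.n_donors)]
    runs: dict[tuple[str, str], list[Clonotype]] = {
        (d, e): [] for e in list(epitopes) + [control_epitope] for d in donors
    }
    truth = {"specific": {e: set() for e in epitopes},
             "shared": set(), "contaminant": set()}
    epitope_names = list(epitopes)
    for e, spec in epitopes.items():
        # an epitope-specific repertoire is a mixture of motif families
        # (convergent CDR3 neighbourhoods), not a single consensus: family 0
        # is the configured consensus, the rest are fresh anchored draws
        families = [spec]
        for _ in range(max(config.families_per_epitope, 1) - 1):
            length = len(spec.consensus) + int(rng.integers(-1, 2))
            consensus = _draw_cdr3(rng, {length: 1.0})
            families.append(MotifSpec(consensus, spec.substitution_rate,
                                      spec.preferred_v, spec.preferred_v_prob))
        fam_w = 1.0 / np.arange(1, len(families) + 1) ** 0.5
        fam_w /= fam_w.sum()
        for d in donors:
            n_specific = int(round(config.sort_purity * config.clones_per_donor))
            for _ in range(n_specific):
                family = families[int(rng.choice(len(families), p=fam_w))]
                seq = sample_motif_cdr3(family, rng)
                if spec.preferred_v and rng.random() < spec.preferred_v_prob:
                    v = spec.preferred_v
                else:
                    v = str(rng.choice(TRBV_GENES, p=vw))
                j = str(rng.choice(TRBJ_GENES, p=jw))
                count = _draw_count(rng, config.zipf_a, scale=200)
                runs[(d, e)].append(Clonotype(seq, v, j, count, d, e))
                truth["specific"][e].add(seq)
                if rng.random() < config.sharing_prob:
                    other = str(rng.choice([x for x in donors if x != d]))
                    runs[(other, e)].append(
                        Clonotype(seq, v, j, _draw_count(rng, config.zipf_a, 200),
                                  other, e)
                    )
                    truth["shared"].add(seq)
                if rng.random() < config.contamination_rate:
                    targets = [x for x in epitope_names if x != e] + [control_epitope]
                    target = str(rng.choice(targets))
                    ratio = max(1.0, _draw_ratio(rng, config.ratio_law))
                    leak = max(1, int(round(count / ratio)))
                    runs[(d, target)].append(Clonotype(seq, v, j, leak, d, target))
                    truth["contaminant"].add(seq)
            n_noise = config.clones_per_donor - n_specific
            for c in gen_background(config, max(n_noise, 1), rng, donor_id=d)[:n_noise]:
                runs[(d, e)].append(c.replace(epitope=e))
    run_list = [
        (d, e, clones) for (d, e), clones in sorted(runs.items()) if clones
    ]
    return run_list, truth


def mutate_one(seq: str, rng: np.random.Generator) -> str:
    """A Hamming-1 inner-position variant of ``seq`` (anchors preserved)."""
    i = int(rng.integers(1, len(seq) - 1))
    alt = str(rng.choice([a for a in AMINO_ACIDS if a != seq[i]]))
    return seq[:i] + alt + seq[i + 1 :]


def gen_cohort(
    config: GeneratorConfig,
    db,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list, dict]:
    """Cohort repertoires with group-dependent planted specific clones.

    Per group, ``cluster_concentration`` seed CDR3s are drawn from the
    database; every planted clone of that group descends from one of the
    seeds, so planted clones land in that many Hamming-1 cluster families —
    few for relapse (concentrated), many for remission (spread). Exact seed
    copies enable look-up identification, 1-mutation variants enable model
    identification. Returns ``(repertoires, truth)``.
    """
    from .cohort import Repertoire  # local import to avoid a cycle

    rng = config.rng() if rng is None else rng
    db_cdr3s = sorted(set().union(*(db.unique_cdr3s(e) for e in db.epitopes)))
    if not db_cdr3s:
        raise ValueError("database is empty; nothing to plant")
    truth: dict = {"planted": {}, "seeds": {}}
    repertoires = []
    vw, jw = _gene_weights(TRBV_GENES), _gene_weights(TRBJ_GENES)
    for group in config.cohort_groups:
        k = config.cluster_concentration[group]
        seeds = [str(s) for s in
                 rng.choice(db_cdr3s, size=min(k, len(db_cdr3s)), replace=False)]
        truth["seeds"][group] = seeds
        for idx, size in enumerate(config.cohort_sizes[group], start=1):
            ind = f"{group.replace(' ', '_').upper()}_{idx}"
            n_exact = int(round(config.planted_exact_frequency[group] * size))
            n_near = int(round(config.planted_near_frequency[group] * size))
            if config.planted_exact_frequency[group] > 0 and n_exact == 0:
                warnings.warn(
                    f"{ind}: planted frequency x size < 1; expect zero look-up hits"
                )
            exact: set[str] = set()
            near: set[str] = set()
            for _ in range(n_exact):
                exact.add(str(rng.choice(seeds)))
            for _ in range(n_near):
                near.add(mutate_one(str(rng.choice(seeds)), rng))
            planted = exact | near
            n_bg = max(size - len(planted), 1)
            clones = gen_background(config, n_bg, rng, donor_id=ind)
            clones = [c for c in clones if c.cdr3_aa not in planted]
            for seq in sorted(planted):
                clones.append(
                    Clonotype(seq, str(rng.choice(TRBV_GENES, p=vw)),
                              str(rng.choice(TRBJ_GENES, p=jw)),
                              _draw_count(rng, config.zipf_a), ind)
                )
            repertoires.append(
                Repertoire.from_samples(ind, group, [clones])
            )
            truth["planted"][ind] = {"exact": exact, "near": near}
    return repertoires, truth


def gen_cluster_composition(
    rng: np.random.Generator, k: int, total: int, n_active: int
) -> np.ndarray:
    """Member counts of one group over ``k`` clusters.

    The group's ``total`` planted clones are spread uniformly (multinomial)
    over ``n_active`` randomly chosen clusters; the remaining clusters get
    zero. ``n_active = 1`` is full concentration, ``n_active = k`` full
    spread.
    """
    if not 1 <= n_active <= k:
        raise ValueError("n_active must be in 1..k")
    active = rng.choice(k, size=n_active, replace=False)
    counts = np.zeros(k, dtype=int)
    counts[active] = rng.multinomial(total, np.full(n_active, 1.0 / n_active))
    return counts
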