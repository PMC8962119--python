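"""Likelihood-based maternity assignment with simulated confidence tiers.

For each offspring the log-likelihood ratio (LOD) that a candidate is its
mother versus an unrelated individual is accumulated over loci, and the
difference between the best and second-best candidate (the delta statistic)
is compared against critical values calibrated by Monte-Carlo simulation at
the requested confidence levels (strict / relaxed / low).

Error model
-----------
With per-genotype mistyping rate ``e``, an observed genotype is the true
genotype with probability ``1 - e`` and an independent random HWE genotype
with probability ``e`` (applied to parents and offspring alike). Under this
model the marginal distribution of an observed genotype stays HWE, and the
single-locus likelihood ratio reduces to::

    LR = (1 - e)^2 * T(g_o | g_m) / P_HWE(g_o) + e * (2 - e)

where ``T`` is the Mendelian transmission probability with the paternal
allele drawn from the population allele frequencies, and ``P_HWE`` the HWE
genotype probability. At ``e = 0`` a Mendelian-incompatible locus gives
``LR = 0`` and the total LOD is ``-inf``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Sequence

import numpy as np

from .genotypes import AlleleFrequencies, GenotypeTable, allele_frequencies

__all__ = [
    "ParentageConfig",
    "ParentageResult",
    "DeltaThresholds",
    "Pedigree",
    "transition_probability",
    "lod_score",
    "delta_statistic",
    "simulate_critical_delta",
    "assign_maternity",
    "results_to_csv",
]

TIERS = ("strict", "relaxed", "low", "unassigned")


@dataclass
class ParentageConfig:
    """Settings for maternity assignment and confidence simulation."""

    error_rate: float = 0.01
    n_sim: int = 10_000
    confidence_levels: tuple[float, float] = (0.95, 0.80)
    prop_candidates_sampled: float = 1.0
    prop_loci_typed: float | None = None  # None -> estimated from the data
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        strict, relaxed = self.confidence_levels
        if not (0 < relaxed < strict < 1):
            raise ValueError("confidence levels must satisfy 0 < relaxed < strict < 1")
        if not 0 < self.prop_candidates_sampled <= 1:
            raise ValueError("prop_candidates_sampled must be in (0, 1]")


@dataclass
class ParentageResult:
    offspring: str
    candidate: str | None
    lod: float
    delta: float
    n_mismatched_loci: int
    tier: str
    tied: bool = False
    reason: str | None = None


@dataclass
class DeltaThresholds:
    """Critical delta values per confidence level plus the simulated
    distributions retained for audit."""

    thresholds: dict[float, float]
    deltas: np.ndarray
    correct: np.ndarray

    def critical(self, level: float) -> float:
        return self.thresholds[level]


@dataclass
class Pedigree:
    """Maternal links: id -> (dam or None, sire or None). Sires are unknown
    throughout (open pollination)."""

    parents: dict[str, tuple[str | None, str | None]]
    generation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        graph: dict[str, list[str]] = {}
        for child, (dam, sire) in self.parents.items():
            graph[child] = [p for p in (dam, sire) if p is not None]
            for p in graph[child]:
                if p not in self.parents:
                    raise ValueError(f"parent {p!r} of {child!r} not in pedigree")
        try:
            self._topo_order = list(TopologicalSorter(graph).static_order())
        except CycleError as exc:
            raise ValueError(f"pedigree contains a cycle: {exc}") from exc

    @property
    def ids(self) -> list[str]:
        return list(self.parents)

    def topological_order(self) -> list[str]:
        """Ids with every dam/sire preceding its offspring."""
        return list(self._topo_order)

    def dam(self, individual: str) -> str | None:
        return self.parents[individual][0]

    def founders(self) -> list[str]:
        return [i for i, (d, s) in self.parents.items() if d is None and s is None]

    def progeny_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for child, (dam, _) in self.parents.items():
            if dam is not None:
                counts[dam] = counts.get(dam, 0) + 1
        return counts

    def to_csv(self, path, header_comment: str | None = None) -> None:
        with open(path, "w", newline="") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            w = csv.writer(fh)
            w.writerow(["id", "dam", "sire"])
            for child, (dam, sire) in self.parents.items():
                w.writerow([child, dam or "NA", sire or "NA"])

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        parents = {}
        with open(path, newline="") as fh:
            lines = [ln for ln in fh if not ln.startswith("#")]
        for row in csv.DictReader(lines):
            dam = None if row["dam"] in ("NA", "") else row["dam"]
            sire = None if row["sire"] in ("NA", "") else row["sire"]
            parents[row["id"]] = (dam, sire)
        return cls(parents)


# ---------------------------------------------------------------------------
# Per-locus genotype tables (vectorized machinery)
# ---------------------------------------------------------------------------


class _LocusTables:
    """Enumerated unordered genotypes at one locus with HWE probabilities,
    Mendelian transmission matrix and the error-adjusted LOD lookup."""

    def __init__(self, alleles: Sequence[int], p: Sequence[float], error_rate: float):
        self.alleles = list(alleles)
        self.index = {a: k for k, a in enumerate(self.alleles)}
        self.p = np.asarray(p, dtype=float)
        k = len(self.alleles)
        gi, gj = np.triu_indices(k)
        self.gi, self.gj = gi, gj
        self.n_genotypes = gi.size
        self.geno_index = {
            (self.alleles[i], self.alleles[j]): g for g, (i, j) in enumerate(zip(gi, gj))
        }
        hom = gi == gj
        self.p_hwe = np.where(hom, self.p[gi] ** 2, 2 * self.p[gi] * self.p[gj])
        # maternal-allele distribution per genotype: P(transmit allele a | g)
        mat = np.zeros((self.n_genotypes, k))
        mat[np.arange(self.n_genotypes), gi] += 0.5
        mat[np.arange(self.n_genotypes), gj] += 0.5
        # T[gm, go] = P(offspring genotype go | mother gm, pollen ~ p)
        t = mat[:, gi] * self.p[gj][None, :] + mat[:, gj] * self.p[gi][None, :]
        t[:, hom] = mat[:, gi[hom]] * self.p[gi[hom]][None, :]
        self.T = t
        e = error_rate
        lr = (1 - e) ** 2 * self.T / self.p_hwe[None, :] + e * (2 - e)
        with np.errstate(divide="ignore"):
            self.log_lr = np.log(lr)

    def genotype_of(self, call: tuple[int, int]) -> int:
        a1, a2 = min(call), max(call)
        if a1 not in self.index or a2 not in self.index:
            raise ValueError(
                f"allele(s) {call} absent from the frequency table for this locus"
            )
        return self.geno_index[(a1, a2)]

    def sample_hwe(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(self.n_genotypes, size=size, p=self.p_hwe / self.p_hwe.sum())

    def sample_offspring(self, rng: np.random.Generator, mothers: np.ndarray) -> np.ndarray:
        cum = np.cumsum(self.T[mothers], axis=1)
        u = rng.random(mothers.size)
        return (cum < u[:, None]).sum(axis=1).clip(max=self.n_genotypes - 1)


def _build_tables(freqs: AlleleFrequencies, error_rate: float) -> dict[str, _LocusTables]:
    return {
        locus: _LocusTables(freqs.alleles(locus), freqs.vector(locus), error_rate)
        for locus in freqs.loci
    }


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def transition_probability(
    offspring_call: tuple[int, int],
    parent_call: tuple[int, int],
    freqs_at_locus: dict[int, float],
    error_rate: float,
) -> float:
    """P(observed offspring genotype | observed parent genotype, parent is
    the dam), marginalized over true genotypes under the replacement error
    model: ``(1-e)^2 T(g_o|g_m) + e(2-e) P_HWE(g_o)``."""
    alleles = list(freqs_at_locus)
    tables = _LocusTables(alleles, [freqs_at_locus[a] for a in alleles], error_rate)
    go = tables.genotype_of(offspring_call)
    gm = tables.genotype_of(parent_call)
    e = error_rate
    return float((1 - e) ** 2 * tables.T[gm, go] + e * (2 - e) * tables.p_hwe[go])


def lod_score(
    offspring_id: str,
    candidate_id: str,
    table: GenotypeTable,
    freqs: AlleleFrequencies,
    error_rate: float,
) -> tuple[float, int]:
    """Total LOD over shared typed loci and the count of Mendelian-
    incompatible loci. With ``error_rate = 0`` an incompatible locus drives
    the LOD to ``-inf``."""
    tables = _build_tables(freqs, error_rate)
    total = 0.0
    mismatches = 0
    shared = 0
    for locus in freqs.loci:
        oc = table.call(offspring_id, locus)
        cc = table.call(candidate_id, locus)
        if oc is None or cc is None:
            continue
        shared += 1
        lt = tables[locus]
        go, gm = lt.genotype_of(oc), lt.genotype_of(cc)
        if lt.T[gm, go] == 0.0:
            mismatches += 1
        total += lt.log_lr[gm, go]
    if shared == 0:
        raise ValueError(
            f"{offspring_id!r} and {candidate_id!r} share no typed loci"
        )
    return float(total), mismatches


def delta_statistic(sorted_lods: Sequence[float]) -> float:
    """Delta: best minus second-best LOD when two or more candidates have
    positive LOD; the best LOD itself when exactly one is positive; 0 when
    no candidate has positive LOD."""
    lods = sorted(sorted_lods, reverse=True)
    if not lods:
        raise ValueError("need at least one candidate LOD")
    positive = [l for l in lods if l > 0]
    if len(positive) >= 2:
        return positive[0] - positive[1]
    if len(positive) == 1:
        return positive[0]
    return 0.0


# ---------------------------------------------------------------------------
# Confidence simulation
# ---------------------------------------------------------------------------


def _simulate_deltas(
    tables: dict[str, _LocusTables],
    n_candidates: int,
    config: ParentageConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate config.n_sim offspring and return (delta, correct) arrays."""
    n = config.n_sim
    e = config.error_rate
    loci = list(tables)
    p_typed = 1.0 if config.prop_loci_typed is None else config.prop_loci_typed
    lod = np.zeros((n, n_candidates))
    # candidate slot 0 holds the true mother when she is sampled
    mother_in = rng.random(n) < config.prop_candidates_sampled
    for locus in loci:
        lt = tables[locus]
        true_mother = lt.sample_hwe(rng, n)
        offspring = lt.sample_offspring(rng, true_mother)
        # observation errors: replacement by an independent HWE genotype
        if e > 0:
            err = rng.random(n) < e
            offspring[err] = lt.sample_hwe(rng, int(err.sum()))
            err_m = rng.random(n) < e
            true_mother[err_m] = lt.sample_hwe(rng, int(err_m.sum()))
        cand = lt.sample_hwe(rng, (n, n_candidates)).reshape(n, n_candidates)
        cand[mother_in, 0] = true_mother[mother_in]
        contrib = lt.log_lr[cand, offspring[:, None]]
        if p_typed < 1.0:
            typed = (rng.random(n) < p_typed)[:, None] & (
                rng.random((n, n_candidates)) < p_typed
            )
            contrib = np.where(typed, contrib, 0.0)
        lod += contrib
    order = np.argsort(-lod, axis=1, kind="stable")
    best = order[:, 0]
    best_lod = lod[np.arange(n), best]
    second_lod = lod[np.arange(n), order[:, 1]] if n_candidates > 1 else np.full(n, -np.inf)
    n_positive = (lod > 0).sum(axis=1)
    delta = np.where(
        n_positive >= 2,
        best_lod - np.maximum(second_lod, 0.0),
        np.where(n_positive == 1, np.maximum(best_lod, 0.0), 0.0),
    )
    # when >=2 positive, delta is best - second *positive*; second_lod may be
    # negative only if n_positive < 2, which the where() already excludes
    correct = mother_in & (best == 0)
    return delta, correct


def simulate_critical_delta(
    freqs: AlleleFrequencies,
    n_candidates: int,
    config: ParentageConfig,
) -> DeltaThresholds:
    """Calibrate critical delta values by Monte-Carlo simulation.

    Simulates ``config.n_sim`` offspring (HWE mothers, pollen from the
    population frequencies, observation errors, locus-typing masking),
    scores every candidate, and for each confidence level ``c`` returns the
    smallest delta* such that the proportion of correct assignments among
    simulated assignments with delta >= delta* is at least ``c``. The
    simulated delta distribution is retained for audit. Deterministic for a
    fixed ``config.seed``.
    """
    if config.n_sim < 100:
        raise ValueError("n_sim < 100 gives unstable thresholds")
    if n_candidates < 1:
        raise ValueError("need at least one candidate")
    tables = _build_tables(freqs, config.error_rate)
    rng = np.random.default_rng(config.seed)
    delta, correct = _simulate_deltas(tables, n_candidates, config, rng)
    order = np.argsort(-delta, kind="stable")
    d_sorted = delta[order]
    c_sorted = correct[order]
    precision = np.cumsum(c_sorted) / np.arange(1, delta.size + 1)
    thresholds: dict[float, float] = {}
    for level in config.confidence_levels:
        ok = np.nonzero(precision >= level)[0]
        if ok.size == 0:
            thresholds[level] = math.inf  # unattainable at this information level
        else:
            thresholds[level] = float(d_sorted[ok[-1]])
    return DeltaThresholds(thresholds=thresholds, deltas=delta, correct=correct)


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------


def assign_maternity(
    table: GenotypeTable,
    offspring_group: str,
    candidate_group: str,
    config: ParentageConfig,
    thresholds: DeltaThresholds | None = None,
    freqs: AlleleFrequencies | None = None,
) -> tuple[list[ParentageResult], Pedigree]:
    """Assign each offspring to its maximum-LOD candidate mother.

    Confidence tiers compare each offspring's delta with the simulated
    critical values (strict / relaxed / low). LOD ties are broken to the
    lexicographically first candidate id and flagged. Offspring without a
    single locus typed in common with any candidate are reported as
    unassigned. The returned pedigree links every assigned offspring to its
    best candidate (any tier) with an unknown sire; candidates are founders.
    """
    offspring_ids = table.ids_in_group(offspring_group)
    candidate_ids = table.ids_in_group(candidate_group)
    if not offspring_ids or not candidate_ids:
        raise ValueError("offspring and candidate groups must be nonempty")
    if freqs is None:
        freqs = allele_frequencies(table)
    cfg = config
    if cfg.prop_loci_typed is None:
        cfg = ParentageConfig(
            error_rate=config.error_rate,
            n_sim=config.n_sim,
            confidence_levels=config.confidence_levels,
            prop_candidates_sampled=config.prop_candidates_sampled,
            prop_loci_typed=table.typed_fraction(),
            seed=config.seed,
        )
    if thresholds is None:
        thresholds = simulate_critical_delta(freqs, len(candidate_ids), cfg)
    strict_level, relaxed_level = cfg.confidence_levels
    tables = _build_tables(freqs, cfg.error_rate)
    loci = freqs.loci

    # genotype-index matrices; -1 encodes missing
    def geno_matrix(ids: list[str]) -> np.ndarray:
        g = np.full((len(ids), len(loci)), -1, dtype=int)
        for i, ind in enumerate(ids):
            for j, locus in enumerate(loci):
                call = table.call(ind, locus)
                if call is not None:
                    g[i, j] = tables[locus].genotype_of(call)
        return g

    g_off = geno_matrix(offspring_ids)
    g_cand = geno_matrix(candidate_ids)
    cand_sorted = sorted(range(len(candidate_ids)), key=lambda k: candidate_ids[k])

    results: list[ParentageResult] = []
    parents: dict[str, tuple[str | None, str | None]] = {c: (None, None) for c in candidate_ids}
    generation = {c: "candidate" for c in candidate_ids}
    for i, off in enumerate(offspring_ids):
        lods = np.zeros(len(candidate_ids))
        mism = np.zeros(len(candidate_ids), dtype=int)
        shared = np.zeros(len(candidate_ids), dtype=int)
        for j, locus in enumerate(loci):
            go = g_off[i, j]
            if go < 0:
                continue
            lt = tables[locus]
            gc = g_cand[:, j]
            ok = gc >= 0
            shared += ok
            lods[ok] += lt.log_lr[gc[ok], go]
            mism[ok] += lt.T[gc[ok], go] == 0.0
        if not np.any(shared > 0):
            results.append(
                ParentageResult(
                    offspring=off,
                    candidate=None,
                    lod=float("nan"),
                    delta=0.0,
                    n_mismatched_loci=0,
                    tier="unassigned",
                    reason="no locus typed in common with any candidate",
                )
            )
            parents[off] = (None, None)
            generation[off] = "offspring"
            continue
        lods[shared == 0] = -np.inf
        best_lod = np.max(lods)
        top = [k for k in cand_sorted if lods[k] == best_lod]
        best = top[0]
        tied = len(top) > 1
        delta = delta_statistic(lods.tolist())
        if delta >= thresholds.critical(strict_level):
            tier = "strict"
        elif delta >= thresholds.critical(relaxed_level):
            tier = "relaxed"
        else:
            tier = "low"
        results.append(
            ParentageResult(
                offspring=off,
                candidate=candidate_ids[best],
                lod=float(best_lod),
                delta=float(delta),
                n_mismatched_loci=int(mism[best]),
                tier=tier,
                tied=tied,
            )
        )
        parents[off] = (candidate_ids[best], None)
        generation[off] = "offspring"
    pedigree = Pedigree(parents=parents, generation=generation)
    return results, pedigree


def results_to_csv(results: Sequence[ParentageResult], path, header_comment: str | None = None) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh)
        w.writerow(["offspring", "candidate", "LOD", "delta", "mismatches", "tier", "tied", "reason"])
        for r in results:
            w.writerow(
                [
                    r.offspring,
                    r.candidate or "NA",
                    f"{r.lod:.6g}",
                    f"{r.delta:.6g}",
                    r.n_mismatched_loci,
                    r.tier,
                    int(r.tied),
                    r.reason or "",
                ]
            )
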