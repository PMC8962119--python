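"""Codominant microsatellite genotype tables, I/O and diversity statistics.

The central object is :class:`GenotypeTable`: individuals x loci diploid
allele calls with group labels (e.g. mother trees vs. offspring cohorts).
On top of it sit allele frequencies, per-locus/per-group diversity summaries
(allele counts, effective alleles, observed/expected heterozygosity,
fixation index), marker informativeness (PIC) and non-exclusion
probabilities used by parentage analysis.

Two CSV dialects are supported:

``genalex_csv``
    Line 1: ``n_loci,n_individuals,n_groups,size_group1,...``
    Line 2: ``id,group,<locus1>,,<locus2>,,...`` (two columns per locus)
    Data:   ``id,group,a1,a2,b1,b2,...`` with ``0`` for a missing allele.

``long_csv``
    Header ``id,group,locus,allele1,allele2``, one row per call.

A missing call is written as ``0,0``; a half-missing cell is an error.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeParseError",
    "GenotypeTable",
    "AlleleFrequencies",
    "DiversitySummary",
    "LocusInformativeness",
    "read_genotype_table",
    "write_genotype_table",
    "allele_frequencies",
    "diversity_summary",
    "pic",
    "non_exclusion",
    "write_diversity_csv",
]

#: allele code reserved for a missing allele
MISSING = 0

Call = tuple[int, int]


class GenotypeParseError(ValueError):
    """Raised when a genotype file violates the dialect or table invariants."""


def _norm_call(a1: int, a2: int) -> Call | None:
    if a1 == MISSING and a2 == MISSING:
        return None
    if a1 <= 0 or a2 <= 0:
        raise ValueError(f"invalid allele pair ({a1}, {a2}): codes must be > 0")
    return (a1, a2) if a1 <= a2 else (a2, a1)


@dataclass
class GenotypeTable:
    """Diploid codominant genotypes for a set of individuals.

    Parameters
    ----------
    individuals
        Ordered unique individual ids.
    groups
        Mapping id -> group label.
    loci
        Ordered unique locus names.
    calls
        Mapping ``(id, locus)`` -> unordered allele pair, or ``None`` /
        absent for a missing call. Pairs are normalised to ``a1 <= a2``.
    """

    individuals: list[str]
    groups: dict[str, str]
    loci: list[str]
    calls: dict[tuple[str, str], Call | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus names")
        norm: dict[tuple[str, str], Call | None] = {}
        for key, call in self.calls.items():
            if call is None:
                norm[key] = None
            else:
                norm[key] = _norm_call(call[0], call[1])
        self.calls = norm

    # -- access helpers -------------------------------------------------

    def call(self, individual: str, locus: str) -> Call | None:
        return self.calls.get((individual, locus))

    def ids_in_group(self, group: str | None) -> list[str]:
        if group is None:
            return list(self.individuals)
        return [i for i in self.individuals if self.groups.get(i) == group]

    def group_names(self) -> list[str]:
        """Group labels in order of first appearance."""
        seen: list[str] = []
        for i in self.individuals:
            g = self.groups[i]
            if g not in seen:
                seen.append(g)
        return seen

    def subset(self, individuals: Iterable[str]) -> "GenotypeTable":
        keep = list(individuals)
        keepset = set(keep)
        return GenotypeTable(
            individuals=keep,
            groups={i: self.groups[i] for i in keep},
            loci=list(self.loci),
            calls={k: v for k, v in self.calls.items() if k[0] in keepset},
        )

    def n_typed(self, locus: str, group: str | None = None) -> int:
        return sum(1 for i in self.ids_in_group(group) if self.call(i, locus) is not None)

    def typed_fraction(self) -> float:
        """Fraction of (individual, locus) cells with a non-missing call."""
        total = len(self.individuals) * len(self.loci)
        typed = sum(
            1
            for i in self.individuals
            for l in self.loci
            if self.call(i, l) is not None
        )
        return typed / total if total else 0.0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

DIALECTS = ("genalex_csv", "long_csv")


def read_genotype_table(path, dialect: str = "genalex_csv") -> GenotypeTable:
    """Read a genotype table from ``path`` in the given CSV dialect.

    Missing calls are coded ``0,0``. Malformed rows (wrong cell count,
    half-missing calls, duplicated ids) raise :class:`GenotypeParseError`
    naming the offending line number.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if dialect == "genalex_csv":
        return _read_genalex(rows)
    return _read_long(rows)


def _read_genalex(rows: list[list[str]]) -> GenotypeTable:
    if len(rows) < 3:
        raise GenotypeParseError("genalex_csv needs 2 header lines plus data")
    try:
        n_loci = int(rows[0][0])
        n_ind = int(rows[0][1])
    except (ValueError, IndexError) as exc:
        raise GenotypeParseError(f"line 1: bad count header ({exc})") from exc
    header = rows[1]
    loci = []
    for i in range(n_loci):
        col = 2 + 2 * i
        if col >= len(header) or not header[col]:
            raise GenotypeParseError(f"line 2: expected locus name in column {col + 1}")
        loci.append(header[col])
    individuals: list[str] = []
    groups: dict[str, str] = {}
    calls: dict[tuple[str, str], Call | None] = {}
    for lineno, row in enumerate(rows[2:], start=3):
        if not row or not any(cell.strip() for cell in row):
            continue
        if len(row) < 2 + 2 * n_loci:
            raise GenotypeParseError(
                f"line {lineno}: expected {2 + 2 * n_loci} cells, got {len(row)}"
            )
        ind, group = row[0], row[1]
        if ind in groups:
            raise GenotypeParseError(f"line {lineno}: duplicated individual id {ind!r}")
        individuals.append(ind)
        groups[ind] = group
        for j, locus in enumerate(loci):
            a1s, a2s = row[2 + 2 * j], row[3 + 2 * j]
            try:
                a1, a2 = int(a1s), int(a2s)
                calls[(ind, locus)] = _norm_call(a1, a2)
            except ValueError as exc:
                raise GenotypeParseError(
                    f"line {lineno}: locus {locus!r}: {exc}"
                ) from exc
    if len(individuals) != n_ind:
        raise GenotypeParseError(
            f"header declares {n_ind} individuals but file has {len(individuals)}"
        )
    return GenotypeTable(individuals, groups, loci, calls)


def _read_long(rows: list[list[str]]) -> GenotypeTable:
    if not rows or [c.strip() for c in rows[0][:5]] != ["id", "group", "locus", "allele1", "allele2"]:
        raise GenotypeParseError("line 1: expected header id,group,locus,allele1,allele2")
    individuals: list[str] = []
    groups: dict[str, str] = {}
    loci: list[str] = []
    calls: dict[tuple[str, str], Call | None] = {}
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or not any(cell.strip() for cell in row):
            continue
        if len(row) < 5:
            raise GenotypeParseError(f"line {lineno}: expected 5 cells, got {len(row)}")
        ind, group, locus = row[0], row[1], row[2]
        if ind not in groups:
            individuals.append(ind)
            groups[ind] = group
        elif groups[ind] != group:
            raise GenotypeParseError(
                f"line {lineno}: individual {ind!r} listed with conflicting groups"
            )
        if locus not in loci:
            loci.append(locus)
        if (ind, locus) in calls:
            raise GenotypeParseError(
                f"line {lineno}: duplicated call for ({ind!r}, {locus!r})"
            )
        try:
            calls[(ind, locus)] = _norm_call(int(row[3]), int(row[4]))
        except ValueError as exc:
            raise GenotypeParseError(f"line {lineno}: {exc}") from exc
    return GenotypeTable(individuals, groups, loci, calls)


def write_genotype_table(table: GenotypeTable, path, dialect: str = "genalex_csv") -> None:
    """Write ``table`` to ``path`` in canonical form for the dialect."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    lines: list[str] = []
    if dialect == "genalex_csv":
        names = table.group_names()
        sizes = [str(len(table.ids_in_group(g))) for g in names]
        lines.append(
            ",".join([str(len(table.loci)), str(len(table.individuals)), str(len(names))] + sizes)
        )
        header = ["id", "group"]
        for locus in table.loci:
            header += [locus, ""]
        lines.append(",".join(header))
        for ind in table.individuals:
            row = [ind, table.groups[ind]]
            for locus in table.loci:
                call = table.call(ind, locus)
                a1, a2 = call if call is not None else (MISSING, MISSING)
                row += [str(a1), str(a2)]
            lines.append(",".join(row))
    else:
        lines.append("id,group,locus,allele1,allele2")
        for ind in table.individuals:
            for locus in table.loci:
                call = table.call(ind, locus)
                a1, a2 = call if call is not None else (MISSING, MISSING)
                lines.append(f"{ind},{table.groups[ind]},{locus},{a1},{a2}")
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Allele frequencies and diversity
# ---------------------------------------------------------------------------


@dataclass
class AlleleFrequencies:
    """Per-locus allele frequencies with the count of typed individuals.

    ``freqs[locus][allele] = p`` with all p > 0 summing to 1 per locus;
    ``n_typed[locus]`` is the number of individuals with a non-missing call
    (each contributes two allele observations).
    """

    freqs: dict[str, dict[int, float]]
    n_typed: dict[str, int]

    def __post_init__(self) -> None:
        for locus, ps in self.freqs.items():
            total = sum(ps.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"locus {locus!r}: frequencies sum to {total}, not 1")
            if any(p <= 0 for p in ps.values()):
                raise ValueError(f"locus {locus!r}: non-positive frequency")

    @property
    def loci(self) -> list[str]:
        return list(self.freqs)

    def vector(self, locus: str) -> np.ndarray:
        return np.array(list(self.freqs[locus].values()), dtype=float)

    def alleles(self, locus: str) -> list[int]:
        return list(self.freqs[locus])


def allele_frequencies(table: GenotypeTable, group: str | None = None) -> AlleleFrequencies:
    """Tally allele frequencies in ``group`` (all individuals if ``None``).

    Each non-missing diploid call contributes two allele observations;
    missing calls are dropped per locus (per-locus deletion). A locus with
    zero typed individuals raises ``ValueError`` naming the locus.
    """
    ids = table.ids_in_group(group)
    if not ids:
        raise ValueError(f"group {group!r} is empty")
    freqs: dict[str, dict[int, float]] = {}
    n_typed: dict[str, int] = {}
    for locus in table.loci:
        counts: dict[int, int] = {}
        typed = 0
        for ind in ids:
            call = table.call(ind, locus)
            if call is None:
                continue
            typed += 1
            for a in call:
                counts[a] = counts.get(a, 0) + 1
        if typed == 0:
            raise ValueError(f"locus {locus!r}: no typed individuals in group {group!r}")
        total = 2 * typed
        freqs[locus] = {a: c / total for a, c in sorted(counts.items())}
        n_typed[locus] = typed
    return AlleleFrequencies(freqs, n_typed)


@dataclass
class DiversitySummary:
    """Per-locus diversity statistics plus across-locus mean and SE.

    ``per_locus`` has columns locus, n_typed, N_A, N_E, H_O, H_E, F.
    ``means``/``ses`` map statistic name -> across-locus mean and standard
    error (sd / sqrt(L)); F is averaged over the loci where it is defined.
    """

    group: str | None
    per_locus: pd.DataFrame
    means: dict[str, float]
    ses: dict[str, float]


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    values = values[~np.isnan(values)]
    if values.size == 0:
        return float("nan"), float("nan")
    mean = float(np.mean(values))
    if values.size == 1:
        return mean, float("nan")
    se = float(np.std(values, ddof=1) / math.sqrt(values.size))
    return mean, se


def diversity_summary(
    table: GenotypeTable, group: str | None = None, unbiased: bool = False
) -> DiversitySummary:
    """Compute N_A, N_E, H_O, H_E and F per locus for one group.

    H_E is the uncorrected gene diversity ``1 - sum(p_i^2)`` so that the
    identity ``H_E = 1 - 1/N_E`` holds exactly; pass ``unbiased=True`` for
    the small-sample corrected variant ``2N/(2N-1) * (1 - sum p^2)`` (the
    N_E identity then no longer applies). F = 1 - H_O/H_E, reported as NaN
    at monomorphic loci (H_E = 0).
    """
    af = allele_frequencies(table, group)
    ids = table.ids_in_group(group)
    rows = []
    for locus in table.loci:
        p = af.vector(locus)
        s2 = float(np.sum(p**2))
        n_a = int(p.size)
        n_e = 1.0 / s2
        h_e = 1.0 - s2
        if unbiased:
            n = af.n_typed[locus]
            h_e *= (2 * n) / (2 * n - 1)
        het = 0
        typed = 0
        for ind in ids:
            call = table.call(ind, locus)
            if call is None:
                continue
            typed += 1
            if call[0] != call[1]:
                het += 1
        h_o = het / typed
        f = 1.0 - h_o / h_e if h_e > 0 else float("nan")
        rows.append(
            {
                "locus": locus,
                "n_typed": typed,
                "N_A": n_a,
                "N_E": n_e,
                "H_O": h_o,
                "H_E": h_e,
                "F": f,
            }
        )
    per_locus = pd.DataFrame(rows)
    means: dict[str, float] = {}
    ses: dict[str, float] = {}
    for stat in ("N_A", "N_E", "H_O", "H_E", "F"):
        means[stat], ses[stat] = _mean_se(per_locus[stat].to_numpy(dtype=float))
    return DiversitySummary(group=group, per_locus=per_locus, means=means, ses=ses)


def pic(p: Iterable[float] | Mapping[int, float]) -> float:
    """Polymorphic information content of one locus.

    PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2, computed via power sums
    (sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4).
    """
    if isinstance(p, Mapping):
        p = list(p.values())
    arr = np.asarray(list(p), dtype=float)
    if arr.size == 0 or np.any(arr < 0) or not math.isclose(float(arr.sum()), 1.0, abs_tol=1e-9):
        raise ValueError("pic() needs a frequency vector summing to 1")
    s2 = float(np.sum(arr**2))
    s4 = float(np.sum(arr**4))
    return 1.0 - s2 - (s2**2 - s4)


@dataclass
class LocusInformativeness:
    """Marker informativeness: PIC and non-exclusion probabilities.

    NE_1P is the probability that a random non-mother cannot be excluded
    as the single assessed parent of a random offspring (Jamieson & Taylor
    polynomial: ``NE_1P = 4 a2 - 2 a2^2 - 4 a3 + 3 a4`` with power sums
    ``a_k = sum p_i^k``). NE_I is the probability that two unrelated
    individuals share a multilocus genotype by chance,
    ``NE_I = 2 a2^2 - a4`` per locus. Combined values are the products of
    the per-locus values (independent loci).
    """

    per_locus: pd.DataFrame
    combined_ne_1p: float
    combined_ne_i: float
    mean_pic: float


def non_exclusion(freqs: AlleleFrequencies) -> LocusInformativeness:
    """Per-locus PIC, NE_1P and NE_I and their multilocus combinations."""
    if not freqs.loci:
        raise ValueError("need at least one locus")
    rows = []
    for locus in freqs.loci:
        p = freqs.vector(locus)
        a2 = float(np.sum(p**2))
        a3 = float(np.sum(p**3))
        a4 = float(np.sum(p**4))
        ne_1p = 4 * a2 - 2 * a2**2 - 4 * a3 + 3 * a4
        ne_i = 2 * a2**2 - a4
        rows.append({"locus": locus, "PIC": pic(p), "NE_1P": ne_1p, "NE_I": ne_i})
    per_locus = pd.DataFrame(rows)
    return LocusInformativeness(
        per_locus=per_locus,
        combined_ne_1p=float(np.prod(per_locus["NE_1P"])),
        combined_ne_i=float(np.prod(per_locus["NE_I"])),
        mean_pic=float(np.mean(per_locus["PIC"])),
    )


def write_diversity_csv(summaries: list[DiversitySummary], path, header_comment: str | None = None) -> None:
    """Emit a per-group diversity table (one row per group x locus, plus a
    Total row per group carrying the across-locus mean and SE)."""
    frames = []
    for s in summaries:
        df = s.per_locus.copy()
        df.insert(0, "group", s.group if s.group is not None else "all")
        frames.append(df)
        total = {"group": s.group if s.group is not None else "all", "locus": "Total"}
        for stat in ("N_A", "N_E", "H_O", "H_E", "F"):
            total[stat] = s.means[stat]
            total[f"{stat}_se"] = s.ses[stat]
        frames.append(pd.DataFrame([total]))
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, index=False, float_format="%.6g")
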