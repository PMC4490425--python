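"""Corpus- and gene-level codon usage statistics.

Implements the classic single-codon indices:

* raw codon counts and per-mille frequencies over all 64 codons;
* RSCU (relative synonymous codon usage): a codon's count divided by the
  mean count of its synonymous family, so 1 means no bias.  RSCU is defined
  for the 59 sense codons in degenerate families and, separately, for the
  3-codon stop family;
* SCUO (synonymous codon usage order): an entropy-based bias index in
  [0, 1], 0 for uniform synonymous usage and 1 for single-codon usage;
* positional GC content GC1/GC2/GC3 (and AU3), computed over the same
  codon set as the raw counts;
* high-frequency codon calls (RSCU > 1.5 or within-family share > 60%),
  abundant/rare top-k sets, and the NCG:NCC CpG-suppression ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .seqio import OrfRecord
from .tables import (
    ALL_CODONS,
    CODON_TO_AA,
    DEGENERACY,
    DEGENERATE_AMINO_ACIDS,
    FAMILY,
    SENSE_CODONS,
    to_rna,
)


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. zero denominator)."""


@dataclass
class GcPartition:
    gc: float
    gc1: float
    gc2: float
    gc3: float
    au3: float


@dataclass
class CodonUsageTable:
    """Codon counts and derived usage statistics for a corpus (or one gene).

    ``rscu`` covers the 59 degenerate sense codons plus the three stop
    codons (treated as their own family); Met and Trp have no RSCU.  ``q``
    maps (amino acid, codon) to the within-family codon share q_ij.
    """

    counts: dict[str, int]
    total_codons: int
    freq_permille: dict[str, float]
    rscu: dict[str, float]
    family: dict[str, tuple[str, ...]]
    q: dict[tuple[str, str], float]

    def family_share(self, codon: str) -> float:
        return self.q.get((CODON_TO_AA[codon], codon), 0.0)

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("codon\tcodon_rna\taa\tcount\tpermille\trscu\n")
            for codon in ALL_CODONS:
                rscu = self.rscu.get(codon)
                fh.write(
                    f"{codon}\t{to_rna(codon)}\t{CODON_TO_AA[codon]}\t"
                    f"{self.counts[codon]}\t{self.freq_permille[codon]:.4f}\t"
                    f"{'' if rscu is None else f'{rscu:.4f}'}\n"
                )


def iter_codons(
    corpus: Iterable[OrfRecord],
    include_start: bool = True,
    include_stop: bool = True,
) -> Iterable[str]:
    for rec in corpus:
        codons = rec.codons()
        lo = 0 if include_start else 1
        hi = len(codons) if include_stop else len(codons) - 1
        yield from codons[lo:hi]


def table_from_counts(counts: Mapping[str, int]) -> CodonUsageTable:
    """Build the derived usage fields from a raw codon-count mapping."""
    full = {c: int(counts.get(c, 0)) for c in ALL_CODONS}
    total = sum(full.values())
    if total == 0:
        raise UndefinedStatisticError("empty corpus: no codons counted")
    freq = {c: 1000.0 * n / total for c, n in full.items()}

    rscu: dict[str, float] = {}
    q: dict[tuple[str, str], float] = {}
    for aa, codons in FAMILY.items():
        fam_total = sum(full[c] for c in codons)
        if fam_total > 0:
            for c in codons:
                q[(aa, c)] = full[c] / fam_total
        if len(codons) > 1 and fam_total > 0:
            for c in codons:
                rscu[c] = full[c] * len(codons) / fam_total
    return CodonUsageTable(
        counts=full,
        total_codons=total,
        freq_permille=freq,
        rscu=rscu,
        family=dict(FAMILY),
        q=q,
    )


def count_codons(
    corpus: Sequence[OrfRecord],
    include_start: bool = True,
    include_stop: bool = True,
) -> CodonUsageTable:
    """Count every in-frame codon in the corpus and derive usage statistics."""
    if not corpus:
        raise ValueError("corpus is empty")
    counts: dict[str, int] = {}
    for codon in iter_codons(corpus, include_start, include_stop):
        counts[codon] = counts.get(codon, 0) + 1
    unknown = set(counts) - set(ALL_CODONS)
    if unknown:
        raise ValueError(f"non-ACGT codons in corpus: {sorted(unknown)[:5]}")
    return table_from_counts(counts)


def gc_partition(
    corpus: Sequence[OrfRecord],
    include_start: bool = True,
    include_stop: bool = True,
) -> GcPartition:
    """Per-codon-position GC fractions over all counted codons."""
    gc_pos = [0, 0, 0]
    at3 = 0
    n = 0
    for codon in iter_codons(corpus, include_start, include_stop):
        n += 1
        for i in range(3):
            if codon[i] in "GC":
                gc_pos[i] += 1
        if codon[2] in "AT":
            at3 += 1
    if n == 0:
        raise UndefinedStatisticError("no codons to partition")
    g1, g2, g3 = (g / n for g in gc_pos)
    return GcPartition(gc=(g1 + g2 + g3) / 3, gc1=g1, gc2=g2, gc3=g3, au3=at3 / n)


def scuo(source: CodonUsageTable | Mapping[str, int] | OrfRecord) -> float:
    """Synonymous codon usage order in [0, 1].

    For each degenerate family i with observed count n_i and within-family
    shares q_ij: H_i = -sum_j q_ij log2 q_ij, O_i = (log2 S_i - H_i)/log2 S_i,
    and SCUO = sum_i F_i O_i with F_i = n_i / sum over degenerate families.
    Families with zero count are omitted.
    """
    if isinstance(source, OrfRecord):
        counts: Mapping[str, int] = {}
        tmp: dict[str, int] = {}
        for codon in source.codons():
            tmp[codon] = tmp.get(codon, 0) + 1
        counts = tmp
    elif isinstance(source, CodonUsageTable):
        counts = source.counts
    else:
        counts = source

    weighted = 0.0
    total = 0
    for aa in DEGENERATE_AMINO_ACIDS:
        codons = FAMILY[aa]
        fam_counts = [counts.get(c, 0) for c in codons]
        fam_total = sum(fam_counts)
        if fam_total == 0:
            continue
        h = 0.0
        for n in fam_counts:
            if n > 0:
                p = n / fam_total
                h -= p * math.log2(p)
        s = DEGENERACY[aa]
        o = (math.log2(s) - h) / math.log2(s)
        weighted += fam_total * o
        total += fam_total
    if total == 0:
        raise UndefinedStatisticError("no degenerate amino acids observed")
    return weighted / total


def classify_high_frequency(table: CodonUsageTable) -> set[str]:
    """Codons with RSCU > 1.5 or a within-family share above 60%.

    Only degenerate sense families are considered (Met, Trp and stops have
    no synonymous competition).
    """
    out: set[str] = set()
    for aa in DEGENERATE_AMINO_ACIDS:
        for c in FAMILY[aa]:
            if table.rscu.get(c, 0.0) > 1.5 or table.q.get((aa, c), 0.0) > 0.60:
                out.add(c)
    return out


def abundant_rare_sets(
    table: CodonUsageTable, k: int = 15
) -> tuple[set[str], set[str]]:
    """Top-k and bottom-k sense codons by per-mille frequency.

    Stop codons are excluded; frequency ties are broken lexicographically
    (the alphabetically smaller codon wins a spot in either set).
    """
    if len(SENSE_CODONS) < 2 * k:
        raise ValueError(f"k={k} too large for {len(SENSE_CODONS)} sense codons")
    by_freq_desc = sorted(SENSE_CODONS, key=lambda c: (-table.freq_permille[c], c))
    by_freq_asc = sorted(SENSE_CODONS, key=lambda c: (table.freq_permille[c], c))
    return set(by_freq_desc[:k]), set(by_freq_asc[:k])


def ncg_ncc_ratio(table: CodonUsageTable) -> float:
    """NCG:NCC codon-count ratio, a standard proxy for CpG suppression."""
    ncg = sum(table.counts[n + "CG"] for n in "ACGT")
    ncc = sum(table.counts[n + "CC"] for n in "ACGT")
    if ncc == 0:
        raise UndefinedStatisticError("NCG:NCC undefined: no NCC codons")
    return ncg / ncc
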