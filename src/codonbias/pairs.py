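"""Codon-pair usage: counting, RSCPU, and preferred/avoided calling.

Pairs are ordered codon pairs (c_t, c_{t+1+d}) taken within the interior of
each gene (start and stop codons excluded), at junction distance d = number
of intervening codons (d = 0 are neighbours).  The pair universe is the
61 x 61 = 3721 sense-codon pairs.

RSCPU (relative synonymous codon pair usage) is the pair-level analogue of
RSCU: within each amino-acid-pair family the expected count of a codon pair
is the family total divided by the product of the two codon degeneracies,
and RSCPU is observed/expected.  The four pairs built only from Met and Trp
(ATGATG, ATGTGG, TGGATG, TGGTGG) have no synonymous competition and are
excluded from RSCPU, leaving 3717 synonymous pairs.

Preferred/avoided calling compares observed pair counts with the analytic
expectation (product of single-codon frequencies) using the Audic-Claverie
count test at p < 0.01 plus a |log2 obs/exp| >= 1.5 (about 3-fold) cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .seqio import OrfRecord
from .tables import CODON_TO_AA, DEGENERACY, SENSE_CODONS, SENSE_INDEX, to_rna

N_SENSE = len(SENSE_CODONS)

#: pairs whose two codons both come from single-codon families.
NONSYNONYMOUS_PAIRS = frozenset(
    {("ATG", "ATG"), ("ATG", "TGG"), ("TGG", "ATG"), ("TGG", "TGG")}
)


@dataclass
class PairTable:
    """Codon-pair counts and frequencies at one junction distance.

    ``counts`` is a 61 x 61 integer matrix indexed by
    (:data:`~codonbias.tables.SENSE_CODONS` order); ``exp_freq`` is the
    product of the two single-codon frequencies estimated from the same
    interior codons.
    """

    distance: int
    counts: np.ndarray
    total_pairs: int
    single_freq: np.ndarray  # 61-vector of interior single-codon frequencies

    @property
    def obs_freq(self) -> np.ndarray:
        if self.total_pairs == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.total_pairs

    @property
    def exp_freq(self) -> np.ndarray:
        return np.outer(self.single_freq, self.single_freq)

    def count(self, first: str, second: str) -> int:
        return int(self.counts[SENSE_INDEX[first], SENSE_INDEX[second]])


def count_pairs(corpus: Sequence[OrfRecord], distance: int = 0) -> PairTable:
    """Count ordered sense-codon pairs at the given junction distance.

    Pairs never span gene boundaries; for a gene with m interior codons the
    number of pairs contributed is max(0, m - 1 - distance).
    """
    if not 0 <= distance <= 5:
        raise ValueError("distance must be in [0, 5]")
    counts = np.zeros((N_SENSE, N_SENSE), dtype=np.int64)
    single = np.zeros(N_SENSE, dtype=np.int64)
    for rec in corpus:
        idx = np.fromiter(
            (SENSE_INDEX[c] for c in rec.interior_codons()), dtype=np.int64
        )
        if idx.size:
            np.add.at(single, idx, 1)
        if idx.size > 1 + distance:
            first = idx[: -(1 + distance)]
            second = idx[1 + distance :]
            np.add.at(counts, (first, second), 1)
    total = int(counts.sum())
    n_single = single.sum()
    freq = single / n_single if n_single else single.astype(float)
    return PairTable(
        distance=distance, counts=counts, total_pairs=total, single_freq=freq
    )


def rscpu(pair_table: PairTable) -> dict[tuple[str, str], float]:
    """RSCPU for every observed synonymous-pair family member.

    Expected count of pair (a, b) whose amino-acid pair family F has N(F)
    occurrences is N(F) / (S_a * S_b); RSCPU = observed / expected.  Pairs
    in families never observed are absent from the result, as are the four
    Met/Trp-only pairs.
    """
    if pair_table.distance != 0:
        raise ValueError("RSCPU is defined for neighbouring pairs (d=0)")
    fam_totals: dict[tuple[str, str], int] = {}
    c = pair_table.counts
    for i, a in enumerate(SENSE_CODONS):
        aa1 = CODON_TO_AA[a]
        for j, b in enumerate(SENSE_CODONS):
            key = (aa1, CODON_TO_AA[b])
            fam_totals[key] = fam_totals.get(key, 0) + int(c[i, j])
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            if (a, b) in NONSYNONYMOUS_PAIRS:
                continue
            fam = fam_totals[(CODON_TO_AA[a], CODON_TO_AA[b])]
            if fam == 0:
                continue
            expected = fam / (DEGENERACY[CODON_TO_AA[a]] * DEGENERACY[CODON_TO_AA[b]])
            out[(a, b)] = c[i, j] / expected
    return out


def pair_family_shares(pair_table: PairTable) -> dict[tuple[str, str], float]:
    """Within-amino-acid-pair-family share of each observed codon pair."""
    fam_totals: dict[tuple[str, str], int] = {}
    c = pair_table.counts
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            key = (CODON_TO_AA[a], CODON_TO_AA[b])
            fam_totals[key] = fam_totals.get(key, 0) + int(c[i, j])
    shares: dict[tuple[str, str], float] = {}
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            fam = fam_totals[(CODON_TO_AA[a], CODON_TO_AA[b])]
            if fam > 0:
                shares[(a, b)] = c[i, j] / fam
    return shares


def classify_high_frequency_pairs(
    rscpu_map: Mapping[tuple[str, str], float],
    family_shares: Mapping[tuple[str, str], float],
    rscpu_cutoff: float = 1.5,
    share_cutoff: float = 0.60,
) -> set[tuple[str, str]]:
    """Pairs with RSCPU above the cutoff or a within-family share above 60%."""
    out: set[tuple[str, str]] = set()
    for pair, value in rscpu_map.items():
        if value > rscpu_cutoff or family_shares.get(pair, 0.0) > share_cutoff:
            out.add(pair)
    return out


def audic_claverie_pmf(x: int, y: int, n1: float, n2: float) -> float:
    """Audic-Claverie posterior point probability p(y|x).

    Closed form (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^{x+y+1}); e.g.
    p(0|0) = 1/2 and p(0|5) = 1/64 for equal library sizes.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    return float(stats.nbinom.pmf(y, x + 1, n1 / (n1 + n2)))


def audic_claverie_p(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided Audic-Claverie tail probability for counts x and y.

    The posterior predictive of y given x for libraries of sizes N1, N2 is
    p(y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^{x+y+1}), which is the
    negative-binomial pmf NB(r = x+1, p = N1/(N1+N2)) evaluated at y.  The
    two-sided p-value doubles the smaller tail and is capped at 1.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    p = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, p)
    upper = stats.nbinom.sf(y - 1, x + 1, p)
    return float(min(1.0, 2.0 * min(lower, upper)))


def _ac_p_vector(x: np.ndarray, y: np.ndarray, n1: float, n2: float) -> np.ndarray:
    p = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, p)
    upper = stats.nbinom.sf(y - 1, x + 1, p)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


@dataclass
class BiasCall:
    """Observed-vs-expected verdict for one codon or codon pair."""

    item: str | tuple[str, str]
    x: int
    y: int
    n1: float
    n2: float
    log2_ratio: float
    p: float
    verdict: str  # preferred | avoided | unbiased


def call_bias(
    observed: Mapping,
    expected_freq: Mapping,
    n_total: int,
    p_thresh: float = 0.01,
    log2_cutoff: float = 1.5,
    floor: float = 1e-10,
) -> list[BiasCall]:
    """Call each item preferred/avoided/unbiased against analytic expectation.

    ``observed`` maps item -> count; ``expected_freq`` maps item -> expected
    frequency (must sum to ~1 over the item universe).  Expected counts are
    y = round(N * exp_freq) and both libraries have size N.  The log2 ratio
    uses a +0.5 continuity correction when either count is zero; reported
    p-values are floored at ``floor``.
    """
    items = list(expected_freq)
    x = np.array([int(observed.get(it, 0)) for it in items], dtype=np.int64)
    ef = np.array([expected_freq[it] for it in items], dtype=float)
    total_ef = ef.sum()
    if not math.isclose(total_ef, 1.0, rel_tol=0, abs_tol=1e-6):
        raise ValueError(f"expected frequencies sum to {total_ef}, not 1")
    y = np.rint(n_total * ef).astype(np.int64)
    pvals = _ac_p_vector(x, y, n_total, n_total)
    zero = (x == 0) | (y == 0)
    num = np.where(zero, x + 0.5, x).astype(float)
    den = np.where(zero, y + 0.5, y).astype(float)
    log2r = np.log2(num / den)

    calls: list[BiasCall] = []
    for i, item in enumerate(items):
        p_rep = max(float(pvals[i]), floor)
        if pvals[i] < p_thresh and abs(log2r[i]) >= log2_cutoff:
            verdict = "preferred" if log2r[i] > 0 else "avoided"
        else:
            verdict = "unbiased"
        calls.append(
            BiasCall(
                item=item,
                x=int(x[i]),
                y=int(y[i]),
                n1=n_total,
                n2=n_total,
                log2_ratio=float(log2r[i]),
                p=p_rep,
                verdict=verdict,
            )
        )
    return calls


def call_pair_bias(
    pair_table: PairTable,
    p_thresh: float = 0.01,
    log2_cutoff: float = 1.5,
    floor: float = 1e-10,
) -> list[BiasCall]:
    """Preferred/avoided calls over the full 61 x 61 pair universe."""
    observed = {
        (a, b): int(pair_table.counts[i, j])
        for i, a in enumerate(SENSE_CODONS)
        for j, b in enumerate(SENSE_CODONS)
    }
    ef = pair_table.exp_freq
    expected = {
        (a, b): float(ef[i, j])
        for i, a in enumerate(SENSE_CODONS)
        for j, b in enumerate(SENSE_CODONS)
    }
    return call_bias(
        observed, expected, pair_table.total_pairs, p_thresh, log2_cutoff, floor
    )


def junction_profile(pair_table: PairTable) -> dict[str, dict[str, float]]:
    """Obs/exp ratio summaries grouped by junction dinucleotide.

    For neighbouring pairs the junction dinucleotide is (3rd nt of the first
    codon, 1st nt of the second codon).  Returns, per dinucleotide group,
    the number of pairs with positive expectation and the median and
    quartiles of the obs/exp frequency ratio.
    """
    if pair_table.distance != 0:
        raise ValueError("junction profile is defined for d=0")
    obs = pair_table.obs_freq
    exp = pair_table.exp_freq
    groups: dict[str, list[float]] = {}
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            if exp[i, j] <= 0:
                continue
            groups.setdefault(a[2] + b[0], []).append(obs[i, j] / exp[i, j])
    out: dict[str, dict[str, float]] = {}
    for dinuc, ratios in sorted(groups.items()):
        arr = np.array(ratios)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        out[dinuc] = {
            "n_pairs": float(arr.size),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
        }
    return out


def pair_calls_to_tsv(
    calls: Iterable[BiasCall], path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("pair\tobs_count\texp_count\tlog2_ratio\tp\tverdict\n")
        for c in calls:
            name = (
                to_rna(c.item[0]) + to_rna(c.item[1])
                if isinstance(c.item, tuple)
                else to_rna(c.item)
            )
            fh.write(
                f"{name}\t{c.x}\t{c.y}\t{c.log2_ratio:.4f}\t{c.p:.3e}\t{c.verdict}\n"
            )
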