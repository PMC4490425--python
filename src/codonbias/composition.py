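"""Mono-, di- and tri-nucleotide composition and GC3 stratification.

Dinucleotide relative abundance follows the Karlin-style odds ratio
rho_CG = f_CG / (f_C f_G): values near 1 indicate independence of adjacent
nucleotides, values well below 1 CpG suppression.  The trinucleotide
analogue used here is

    rho_CWG = f_CWG f_C f_W f_G / (f_CW f_WG f_CNG),  W in {A, T}

with f_W = f_A + f_T, f_CW = f_CA + f_CT, f_WG = f_AG + f_TG,
f_CWG = f_CAG + f_CTG and f_CNG summed over all middle nucleotides.
All frequencies come from overlapping windows that never span sequence
boundaries, on the coding strand only.

GC3 stratification sorts genes by GC3 and splits them into near-equal
terciles (the middle group absorbs any remainder), feeding per-group
composition contrasts with gene-level bootstrap intervals and the
SCUO-vs-GC3 polynomial fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np

from .tables import NUCLEOTIDES
from .usage import UndefinedStatisticError

logger = logging.getLogger(__name__)

DINUCLEOTIDES = tuple(a + b for a, b in product(NUCLEOTIDES, NUCLEOTIDES))
TRINUCLEOTIDES = tuple(
    a + b + c for a, b, c in product(NUCLEOTIDES, NUCLEOTIDES, NUCLEOTIDES)
)
_NT_IDX = {n: i for i, n in enumerate(NUCLEOTIDES)}
_DI_IDX = {d: i for i, d in enumerate(DINUCLEOTIDES)}
_TRI_IDX = {t: i for i, t in enumerate(TRINUCLEOTIDES)}


@dataclass
class CompositionStats:
    f_nt: dict[str, float]
    f_di: dict[str, float]
    f_tri: dict[str, float]
    rho_cg: float
    _rho_cwg: float | None = None

    @property
    def rho_cwg(self) -> float:
        """Raises UndefinedStatisticError when no CWG/CNG context exists."""
        if self._rho_cwg is None:
            raise UndefinedStatisticError("rho_CWG undefined: zero denominator")
        return self._rho_cwg

    @property
    def has_rho_cwg(self) -> bool:
        return self._rho_cwg is not None


def count_kmers(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Overlapping 1/2/3-mer counts for one sequence (no boundary spanning)."""
    n1 = np.zeros(4, dtype=np.int64)
    n2 = np.zeros(16, dtype=np.int64)
    n3 = np.zeros(64, dtype=np.int64)
    for ch in seq:
        n1[_NT_IDX[ch]] += 1
    for i in range(len(seq) - 1):
        n2[_DI_IDX[seq[i : i + 2]]] += 1
    for i in range(len(seq) - 2):
        n3[_TRI_IDX[seq[i : i + 3]]] += 1
    return n1, n2, n3


def _stats_from_counts(
    n1: np.ndarray, n2: np.ndarray, n3: np.ndarray
) -> CompositionStats:
    if n1.sum() < 3:
        raise UndefinedStatisticError("need at least 3 nucleotides")
    f1 = n1 / n1.sum()
    f2 = n2 / n2.sum() if n2.sum() else np.zeros(16)
    f3 = n3 / n3.sum() if n3.sum() else np.zeros(64)

    f = {nt: float(f1[_NT_IDX[nt]]) for nt in NUCLEOTIDES}
    fd = {d: float(f2[_DI_IDX[d]]) for d in DINUCLEOTIDES}
    ft = {t: float(f3[_TRI_IDX[t]]) for t in TRINUCLEOTIDES}

    if f["C"] == 0 or f["G"] == 0:
        raise UndefinedStatisticError("rho_CG undefined: f_C or f_G is zero")
    rho_cg = fd["CG"] / (f["C"] * f["G"])

    f_w = f["A"] + f["T"]
    f_cw = fd["CA"] + fd["CT"]
    f_wg = fd["AG"] + fd["TG"]
    f_cwg = ft["CAG"] + ft["CTG"]
    f_cng = sum(ft["C" + n + "G"] for n in NUCLEOTIDES)
    denom = f_cw * f_wg * f_cng
    rho_cwg = None if denom == 0 else f_cwg * f["C"] * f_w * f["G"] / denom
    return CompositionStats(f_nt=f, f_di=fd, f_tri=ft, rho_cg=rho_cg, _rho_cwg=rho_cwg)


def relative_abundance(seqs: Sequence[str] | str) -> CompositionStats:
    """Composition statistics pooled over one or more sequences."""
    if isinstance(seqs, str):
        seqs = [seqs]
    n1 = np.zeros(4, dtype=np.int64)
    n2 = np.zeros(16, dtype=np.int64)
    n3 = np.zeros(64, dtype=np.int64)
    for s in seqs:
        a, b, c = count_kmers(s)
        n1 += a
        n2 += b
        n3 += c
    return _stats_from_counts(n1, n2, n3)


def gc3_strata(
    gc3_by_gene: Mapping[str, float], n_strata: int = 3
) -> list[list[str]]:
    """Split genes into near-equal GC3 strata (low -> high).

    Genes are sorted by (GC3, id) for determinism; every stratum gets
    floor(n / n_strata) genes and the middle stratum absorbs the remainder,
    so 646 genes split 215/216/215 and 10 genes split 3/4/3.
    """
    ids = sorted(gc3_by_gene, key=lambda g: (gc3_by_gene[g], g))
    n = len(ids)
    if n < n_strata:
        raise ValueError(f"need at least {n_strata} genes, got {n}")
    base = n // n_strata
    sizes = [base] * n_strata
    sizes[n_strata // 2] += n - base * n_strata
    groups: list[list[str]] = []
    start = 0
    for size in sizes:
        groups.append(ids[start : start + size])
        start += size
    return groups


@dataclass
class GroupComposition:
    stats: CompositionStats
    rho_cg_ci: tuple[float, float]
    rho_cwg_ci: tuple[float, float]


def strata_composition_contrast(
    groups: Sequence[Sequence[str]],
    n_boot: int = 1000,
    seed: int = 0,
) -> list[GroupComposition]:
    """Per-group composition with gene-level percentile bootstrap 95% CIs.

    ``groups`` holds the raw sequences of each stratum.  Single-gene groups
    give degenerate (point) intervals and a warning.
    """
    rng = np.random.default_rng(seed)
    out: list[GroupComposition] = []
    for group in groups:
        per_gene = [count_kmers(s) for s in group]
        n1 = np.array([g[0] for g in per_gene])
        n2 = np.array([g[1] for g in per_gene])
        n3 = np.array([g[2] for g in per_gene])
        stats = _stats_from_counts(n1.sum(0), n2.sum(0), n3.sum(0))
        if len(group) < 2:
            warnings.warn("single-gene group: degenerate bootstrap interval")
            out.append(
                GroupComposition(
                    stats=stats,
                    rho_cg_ci=(stats.rho_cg, stats.rho_cg),
                    rho_cwg_ci=(stats.rho_cwg, stats.rho_cwg),
                )
            )
            continue
        cg = np.empty(n_boot)
        cwg = np.empty(n_boot)
        m = len(group)
        for b in range(n_boot):
            idx = rng.integers(0, m, size=m)
            s = _stats_from_counts(n1[idx].sum(0), n2[idx].sum(0), n3[idx].sum(0))
            cg[b] = s.rho_cg
            cwg[b] = s.rho_cwg
        out.append(
            GroupComposition(
                stats=stats,
                rho_cg_ci=tuple(np.percentile(cg, [2.5, 97.5])),
                rho_cwg_ci=tuple(np.percentile(cwg, [2.5, 97.5])),
            )
        )
    return out


@dataclass
class PolyFit:
    coefficients: tuple[float, ...]  # ascending order: c0 + c1 x + c2 x^2 ...
    r_squared: float
    minimum: float | None  # x at the fitted interior minimum, if any


def scuo_gc3_fit(
    scuo_values: Sequence[float], gc3_values: Sequence[float], degree: int = 2
) -> PolyFit:
    """Least-squares polynomial fit of SCUO against GC3.

    The fitted minimum (where defined: positive leading curvature for the
    quadratic case, otherwise the grid minimum of the fitted curve inside
    the observed GC3 range) characterises the U-shaped relation.
    """
    y = np.asarray(scuo_values, dtype=float)
    x = np.asarray(gc3_values, dtype=float)
    if x.size != y.size:
        raise ValueError("SCUO and GC3 vectors differ in length")
    if x.size < degree + 2:
        raise ValueError("not enough genes for the requested degree")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: constant GC3")
    series = np.polynomial.Polynomial.fit(x, y, degree).convert()
    coeffs = tuple(float(c) for c in series.coef)
    resid = y - series(x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    minimum: float | None = None
    deriv = series.deriv()
    crit = [r.real for r in deriv.roots() if abs(r.imag) < 1e-12]
    interior = [c for c in crit if x.min() < c < x.max()]
    if interior:
        second = deriv.deriv()
        mins = [c for c in interior if second(c) > 0]
        if mins:
            minimum = float(min(mins, key=series))
    return PolyFit(coefficients=coeffs, r_squared=r2, minimum=minimum)
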