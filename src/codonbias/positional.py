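"""Position-dependent codon usage bias.

The central quantity is the binned Kullback-Leibler divergence

    KLD(k) = sum_i sum_j p_ij(k) ln( p_ij(k) / q_ij )

where q_ij is the corpus-wide within-family codon share and p_ij(k) the
same share computed from the codons falling into positional bin k (five
10-codon bins after the start codon, five before the stop codon).  Finite
bins bias KLD upward even under the null, so the profile is corrected by
subtracting the mean KLD of SSC-shuffled replicates (synonymous-codon
permutations that preserve every protein sequence and the corpus codon
counts, hence q) rebinned identically.

Also here: preferred/avoided calling for the codon following the start
codon (or internal ATGs), WebLogo-style information-content matrices for
18-nt start/stop context windows, and the AU3 profile of the first codons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pairs import BiasCall, call_bias
from .seqio import (
    BIN_SIZE,
    N_BINS,
    ContextWindow,
    OrfRecord,
    bin_labels,
    eligible_for_bins,
)
from .tables import (
    ALL_CODONS,
    CODON_INDEX,
    CODON_TO_AA,
    DEGENERATE_AMINO_ACIDS,
    FAMILY,
    NUCLEOTIDES,
    SENSE_CODONS,
    START_CODON,
)

logger = logging.getLogger(__name__)

_NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

#: (family row selector) per degenerate amino acid, as codon indices 0..63.
_FAMILY_IDX = {
    aa: np.array([CODON_INDEX[c] for c in FAMILY[aa]]) for aa in DEGENERATE_AMINO_ACIDS
}


@dataclass
class PositionalProfile:
    bins: list[str]
    p: dict[str, dict[tuple[str, str], float]]  # bin -> (aa, codon) -> share
    kld_raw: dict[str, float]
    kld_null_mean: dict[str, float]
    kld_null_sd: dict[str, float]

    @property
    def kld_corrected(self) -> dict[str, float]:
        return {b: self.kld_raw[b] - self.kld_null_mean[b] for b in self.bins}

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        corrected = self.kld_corrected
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("bin\tkld_raw\tkld_null_mean\tkld_null_sd\tkld_corrected\n")
            for b in self.bins:
                fh.write(
                    f"{b}\t{self.kld_raw[b]:.6f}\t{self.kld_null_mean[b]:.6f}\t"
                    f"{self.kld_null_sd[b]:.6f}\t{corrected[b]:.6f}\n"
                )


def _kld_from_counts(bin_counts: np.ndarray, q: np.ndarray) -> float:
    """KLD of one bin's 64-long codon-count vector against corpus shares q."""
    total = 0.0
    for aa in DEGENERATE_AMINO_ACIDS:
        idx = _FAMILY_IDX[aa]
        fam = bin_counts[idx].astype(float)
        n = fam.sum()
        if n == 0:
            continue
        p = fam / n
        qf = q[idx]
        mask = p > 0
        # q > 0 wherever p > 0 because q comes from a superset of the bin
        total += float(np.sum(p[mask] * np.log(p[mask] / qf[mask])))
    return total


def _within_family_shares(counts: np.ndarray) -> np.ndarray:
    """64-long share vector: counts normalised within each family (0 if empty)."""
    q = np.zeros(64)
    for aa, codons in FAMILY.items():
        idx = np.array([CODON_INDEX[c] for c in codons])
        n = counts[idx].sum()
        if n > 0:
            q[idx] = counts[idx] / n
    return q


def kld_profile(
    corpus: Sequence[OrfRecord],
    ssc_replicates: int = 100,
    seed: int = 0,
    bin_size: int = BIN_SIZE,
    n_bins: int = N_BINS,
) -> PositionalProfile:
    """Binned KLD profile with SSC null baseline.

    Only ORFs long enough for disjoint bins enter the binning; the
    background q is the corpus-wide within-family share over the same
    admitted genes (the SSC shuffle preserves it exactly, so raw and null
    profiles share one q).
    """
    admitted = [r for r in corpus if eligible_for_bins(r)]
    n_excluded = len(corpus) - len(admitted)
    if n_excluded:
        logger.info("kld_profile: %d ORFs too short for binning", n_excluded)
    if not admitted:
        raise ValueError("no ORFs long enough for positional binning")

    # flatten all codons of admitted genes; record flat positions per bin
    codes_list: list[np.ndarray] = []
    offsets = [0]
    for rec in admitted:
        codes_list.append(
            np.fromiter((CODON_INDEX[c] for c in rec.codons()), dtype=np.int64)
        )
        offsets.append(offsets[-1] + codes_list[-1].size)
    codes = np.concatenate(codes_list)

    labels = bin_labels(n_bins)
    bin_pos: dict[str, list[np.ndarray]] = {b: [] for b in labels}
    for gi, rec in enumerate(admitted):
        off = offsets[gi]
        total = rec.n_codons
        for k in range(1, n_bins + 1):
            lo = 1 + bin_size * (k - 1)
            bin_pos[f"bin_{k}"].append(np.arange(off + lo, off + lo + bin_size))
            hi = total - 1 - bin_size * (k - 1)
            bin_pos[f"bin_{-k}"].append(np.arange(off + hi - bin_size, off + hi))
    bin_idx = {b: np.concatenate(v) for b, v in bin_pos.items()}

    corpus_counts = np.bincount(codes, minlength=64).astype(float)
    q = _within_family_shares(corpus_counts)

    kld_raw: dict[str, float] = {}
    p_store: dict[str, dict[tuple[str, str], float]] = {}
    for b in labels:
        counts_b = np.bincount(codes[bin_idx[b]], minlength=64)
        kld_raw[b] = _kld_from_counts(counts_b, q)
        shares = _within_family_shares(counts_b.astype(float))
        p_store[b] = {
            (CODON_TO_AA[c], c): float(shares[CODON_INDEX[c]])
            for c in ALL_CODONS
            if shares[CODON_INDEX[c]] > 0
        }

    # SSC null: permute codes within amino-acid groups, rebin, recompute
    rng = np.random.default_rng(seed)
    aa_groups = [
        np.flatnonzero(np.isin(codes, _FAMILY_IDX[aa]))
        for aa in DEGENERATE_AMINO_ACIDS
    ]
    null_vals = {b: np.empty(ssc_replicates) for b in labels}
    shuffled = codes.copy()
    for rep in range(ssc_replicates):
        for grp in aa_groups:
            shuffled[grp] = shuffled[grp][rng.permutation(grp.size)]
        for b in labels:
            counts_b = np.bincount(shuffled[bin_idx[b]], minlength=64)
            null_vals[b][rep] = _kld_from_counts(counts_b, q)

    return PositionalProfile(
        bins=labels,
        p=p_store,
        kld_raw=kld_raw,
        kld_null_mean={b: float(null_vals[b].mean()) for b in labels},
        kld_null_sd={b: float(null_vals[b].std(ddof=1)) for b in labels},
    )


# ---------------------------------------------------------------------------
# post-start-codon bias

#: the 12 positional-nucleotide masks ("Ann" ... "nnT").
MASKS = tuple(
    f"{nt}nn" for nt in NUCLEOTIDES
) + tuple(f"n{nt}n" for nt in NUCLEOTIDES) + tuple(f"nn{nt}" for nt in NUCLEOTIDES)


def _mask_members(mask: str) -> list[str]:
    pos = next(i for i, ch in enumerate(mask) if ch != "n")
    return [c for c in SENSE_CODONS if c[pos] == mask[pos]]


def post_aug_bias(
    corpus: Sequence[OrfRecord],
    anchor: str = "start",
    p_thresh: float = 0.01,
    log2_cutoff: float = 1.5,
    floor: float = 1e-10,
) -> tuple[list[BiasCall], dict[str, float]]:
    """Bias of the codon following the start codon (or internal ATGs).

    Observed counts are the codons at the qualifying position(s); expected
    frequencies are the corpus-wide interior sense-codon frequencies.
    Returns per-codon calls plus the obs/exp ratio aggregated over the 12
    positional-nucleotide masks (e.g. "Gnn" = any codon starting with G).
    """
    if anchor not in ("start", "internal"):
        raise ValueError(f"unknown anchor {anchor!r}")
    interior_counts: dict[str, int] = {c: 0 for c in SENSE_CODONS}
    observed: dict[str, int] = {c: 0 for c in SENSE_CODONS}
    for rec in corpus:
        interior = rec.interior_codons()
        for c in interior:
            interior_counts[c] += 1
        if anchor == "start":
            if interior:
                observed[interior[0]] += 1
        else:
            # internal ATG: interior occurrences whose following codon is
            # also interior (i.e. not the stop codon)
            for t in range(len(interior) - 1):
                if interior[t] == START_CODON:
                    observed[interior[t + 1]] += 1
    n_interior = sum(interior_counts.values())
    n_obs = sum(observed.values())
    if n_obs == 0:
        raise ValueError(f"no qualifying positions for anchor={anchor!r}")
    expected_freq = {c: interior_counts[c] / n_interior for c in SENSE_CODONS}
    calls = call_bias(observed, expected_freq, n_obs, p_thresh, log2_cutoff, floor)

    mask_ratio: dict[str, float] = {}
    for mask in MASKS:
        members = _mask_members(mask)
        obs = sum(observed[c] for c in members)
        exp = n_obs * sum(expected_freq[c] for c in members)
        mask_ratio[mask] = obs / exp if exp > 0 else math.nan
    return calls, mask_ratio


# ---------------------------------------------------------------------------
# context logos

ANCHOR_POSITIONS = (10, 11, 12)  # 1-based positions of the anchor codon


@dataclass
class LogoMatrix:
    """WebLogo-style information content for 18-nt context windows.

    Positions are 1-based within the window; the anchor codon's positions
    (10-12) are dropped.  info_bits = max(0, 2 - H - e_n) with the
    small-sample correction e_n = 3 / (2 ln2 n); letter heights are the
    nucleotide frequencies scaled by info_bits.
    """

    positions: list[int]
    info_bits: dict[int, float]
    letter_heights: dict[int, dict[str, float]]

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("position\tA\tC\tG\tT\tinfo_bits\n")
            for pos in self.positions:
                h = self.letter_heights[pos]
                fh.write(
                    f"{pos}\t" + "\t".join(f"{h[n]:.5f}" for n in NUCLEOTIDES)
                    + f"\t{self.info_bits[pos]:.5f}\n"
                )


def logo_matrix(windows: Sequence[ContextWindow]) -> LogoMatrix:
    if not windows:
        raise ValueError("no context windows")
    anchors = {w.anchor for w in windows}
    if len(anchors) > 1:
        raise ValueError("windows mix start and stop anchors")
    n = len(windows)
    counts = np.zeros((18, 4))
    for w in windows:
        for i, nt in enumerate(w.nucleotides):
            counts[i, _NT_INDEX[nt]] += 1
    freqs = counts / n
    e_n = 3.0 / (2.0 * math.log(2) * n)
    positions = [p for p in range(1, 19) if p not in ANCHOR_POSITIONS]
    info: dict[int, float] = {}
    heights: dict[int, dict[str, float]] = {}
    for pos in positions:
        f = freqs[pos - 1]
        h = -sum(x * math.log2(x) for x in f if x > 0)
        r = max(0.0, 2.0 - h - e_n)
        info[pos] = r
        heights[pos] = {nt: float(f[_NT_INDEX[nt]] * r) for nt in NUCLEOTIDES}
    return LogoMatrix(positions=positions, info_bits=info, letter_heights=heights)


def au3_profile(
    corpus: Sequence[OrfRecord], first_k_codons: int = 10
) -> tuple[dict[int, float], float]:
    """AU3 fraction per codon index 2..k+1, with the corpus-wide baseline.

    Codon index is 1-based over the whole ORF (the start codon is index 1),
    so index 2 is the first codon translated after initiation.  The
    baseline is the AU3 fraction over all interior codons.
    """
    hits = np.zeros(first_k_codons)
    totals = np.zeros(first_k_codons)
    base_hits = 0
    base_total = 0
    for rec in corpus:
        interior = rec.interior_codons()
        for t, c in enumerate(interior):
            at = c[2] in "AT"
            base_hits += at
            base_total += 1
            if t < first_k_codons:
                hits[t] += at
                totals[t] += 1
    if base_total == 0:
        raise ValueError("corpus has no interior codons")
    profile = {
        idx + 2: float(hits[idx] / totals[idx]) if totals[idx] else math.nan
        for idx in range(first_k_codons)
    }
    return profile, base_hits / base_total
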