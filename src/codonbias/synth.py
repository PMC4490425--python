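"""Synthetic ORF corpora with known codon-usage structure, plus null shuffles.

The generator draws each gene as start codon + interior codons + stop
codon.  Interior codons come from a base distribution built as
P0(c) = P(aa(c)) * w(c | aa): amino acids uniform over the 20 by default,
within-family codon weights uniform by default.  Three kinds of structure
can be injected on top:

* ``pair_coupling``: a first-order Markov reweighting
  P(c_t | c_{t-1}) ∝ P0(c_t) * coupling(c_{t-1}, c_t), so a pair weight w
  on (a, b) enriches the neighbouring pair roughly w-fold while spaced
  pairs stay near independence;
* ``positional_overrides``: replacement within-family codon weights applied
  to the codons falling in a named positional bin (bin_1 ... bin_-1), which
  moves within-family shares (hence RSCU/KLD) only at those positions;
* flanking-context profiles: per-position nucleotide probabilities for the
  9-nt upstream and 6-nt downstream flanks, plus an optional first-letter
  bias for the codon right after the start codon (a Kozak-like +4 signal).

The SSC shuffle permutes codons among all corpus positions encoding the
same amino acid (protein sequences and corpus codon counts are preserved
exactly); the SC shuffle permutes all interior codons across the corpus
(gene lengths and codon counts preserved, protein sequences generally not).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .seqio import BIN_SIZE, N_BINS, OrfRecord
from .tables import (
    AMINO_ACIDS,
    CODON_TO_AA,
    DEGENERACY,
    FAMILY,
    NUCLEOTIDES,
    SENSE_CODONS,
    SENSE_INDEX,
    START_CODON,
    STOP_CODONS,
)

_AA_OF_SENSE = np.array([AMINO_ACIDS.index(CODON_TO_AA[c]) for c in SENSE_CODONS])
_FIRST_NT_OF_SENSE = np.array(
    [NUCLEOTIDES.index(c[0]) for c in SENSE_CODONS]
)

UPSTREAM_LEN = 9
DOWNSTREAM_LEN = 6


def _uniform_profile(n_positions: int) -> np.ndarray:
    return np.full((n_positions, 4), 0.25)


@dataclass
class GeneratorSpec:
    """Parameters of a synthetic ORF corpus.

    Lengths are total codons including start and stop.  The lognormal
    defaults give a mean length of about 214 codons per ORF over a corpus
    of 646 genes, with a floor of 102 codons so every gene is eligible for
    positional binning.
    """

    n_genes: int = 646
    min_codons: int = 102
    max_codons: int = 2000
    length_law: str = "lognormal"  # or "uniform"
    length_mu: float = 5.29  # lognormal: mean of log codon count
    length_sigma: float = 0.4
    aa_weights: dict[str, float] | None = None
    codon_weights: dict[str, Sequence[float]] = field(default_factory=dict)
    pair_coupling: dict[tuple[str, str], float] = field(default_factory=dict)
    positional_overrides: dict[str, dict[str, Sequence[float]]] = field(
        default_factory=dict
    )
    stop_weights: Sequence[float] | None = None  # over sorted STOP_CODONS
    upstream_profile: np.ndarray | None = None  # 9 x 4 over A,C,G,T
    downstream_profile: np.ndarray | None = None  # 6 x 4
    post_start_first_nt: Sequence[float] | None = None  # 4-vector
    seed: int = 0

    def validate(self) -> None:
        problems: list[str] = []
        if self.n_genes < 1:
            problems.append("n_genes must be >= 1")
        if not 2 < self.min_codons <= self.max_codons:
            problems.append("need 2 < min_codons <= max_codons")
        if self.length_law not in ("uniform", "lognormal"):
            problems.append(f"unknown length_law {self.length_law!r}")
        for aa, w in self.codon_weights.items():
            if aa not in FAMILY or aa == "*":
                problems.append(f"codon_weights: unknown family {aa!r}")
            elif len(w) != DEGENERACY[aa] or not math.isclose(sum(w), 1.0):
                problems.append(f"codon_weights[{aa!r}]: need {DEGENERACY[aa]} probs summing to 1")
            elif min(w) < 0:
                problems.append(f"codon_weights[{aa!r}]: negative probability")
        for pair, w in self.pair_coupling.items():
            if w <= 0:
                problems.append(f"pair_coupling[{pair}]: weight must be > 0")
            if pair[0] not in SENSE_INDEX or pair[1] not in SENSE_INDEX:
                problems.append(f"pair_coupling[{pair}]: not sense codons")
        valid_bins = {f"bin_{k}" for k in range(1, N_BINS + 1)} | {
            f"bin_{-k}" for k in range(1, N_BINS + 1)
        }
        for label in self.positional_overrides:
            if label not in valid_bins:
                problems.append(f"positional_overrides: unknown bin {label!r}")
        if self.stop_weights is not None and (
            len(self.stop_weights) != 3
            or not math.isclose(sum(self.stop_weights), 1.0)
        ):
            problems.append("stop_weights: need 3 probabilities summing to 1")
        for name, prof, rows in (
            ("upstream_profile", self.upstream_profile, UPSTREAM_LEN),
            ("downstream_profile", self.downstream_profile, DOWNSTREAM_LEN),
        ):
            if prof is not None:
                arr = np.asarray(prof)
                if arr.shape != (rows, 4) or not np.allclose(arr.sum(1), 1.0):
                    problems.append(f"{name}: need {rows} x 4 rows summing to 1")
        if problems:
            raise ValueError("invalid GeneratorSpec: " + "; ".join(problems))

    # -- derived distributions -------------------------------------------

    def family_weight_vector(
        self, overrides: Mapping[str, Sequence[float]] | None = None
    ) -> np.ndarray:
        """Within-family codon probability for each of the 61 sense codons."""
        w = np.empty(len(SENSE_CODONS))
        src = dict(self.codon_weights)
        if overrides:
            src.update(overrides)
        for aa in AMINO_ACIDS:
            fam = FAMILY[aa]
            probs = src.get(aa)
            probs = np.full(len(fam), 1.0 / len(fam)) if probs is None else np.asarray(probs, dtype=float)
            for c, p in zip(fam, probs):
                w[SENSE_INDEX[c]] = p
        return w

    def aa_probability_vector(self) -> np.ndarray:
        if self.aa_weights is None:
            p = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
        else:
            p = np.array([self.aa_weights.get(aa, 0.0) for aa in AMINO_ACIDS])
            p = p / p.sum()
        return p

    def base_codon_distribution(
        self, overrides: Mapping[str, Sequence[float]] | None = None
    ) -> np.ndarray:
        """Unconditional sense-codon distribution P0 (61-vector)."""
        p_aa = self.aa_probability_vector()
        p = p_aa[_AA_OF_SENSE] * self.family_weight_vector(overrides)
        return p / p.sum()

    def target_rscu(self) -> dict[str, float]:
        """RSCU implied by the family weights: S_i * w(c | aa)."""
        w = self.family_weight_vector()
        return {
            c: DEGENERACY[CODON_TO_AA[c]] * float(w[SENSE_INDEX[c]])
            for c in SENSE_CODONS
            if DEGENERACY[CODON_TO_AA[c]] > 1
        }

    def to_json(self) -> str:
        d = asdict(self)
        d["pair_coupling"] = {f"{a},{b}": w for (a, b), w in self.pair_coupling.items()}
        for key in ("upstream_profile", "downstream_profile"):
            if d[key] is not None:
                d[key] = np.asarray(d[key]).tolist()
        if d["post_start_first_nt"] is not None:
            d["post_start_first_nt"] = list(d["post_start_first_nt"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorSpec":
        d = json.loads(text)
        if "pair_coupling" in d:
            d["pair_coupling"] = {
                tuple(k.split(",")): v for k, v in d["pair_coupling"].items()
            }
        for key in ("upstream_profile", "downstream_profile"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


@dataclass
class GroundTruth:
    """What the generator actually injected, sufficient to score recovery."""

    spec: GeneratorSpec
    target_rscu: dict[str, float]
    injected_pairs: dict[tuple[str, str], float]
    overridden_bins: list[str]
    kozak_positions: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "spec": json.loads(self.spec.to_json()),
                "target_rscu": self.target_rscu,
                "injected_pairs": {
                    f"{a},{b}": w for (a, b), w in self.injected_pairs.items()
                },
                "overridden_bins": self.overridden_bins,
                "kozak_positions": self.kozak_positions,
            },
            indent=2,
        )


def _draw_lengths(spec: GeneratorSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.length_law == "uniform":
        return rng.integers(spec.min_codons, spec.max_codons + 1, size=spec.n_genes)
    raw = np.exp(rng.normal(spec.length_mu, spec.length_sigma, size=spec.n_genes))
    return np.clip(np.rint(raw).astype(int), spec.min_codons, spec.max_codons)


def _sample_from_rows(
    cum_rows: np.ndarray, row_idx: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample one category per row index from row-wise cumulative dists."""
    u = rng.random(row_idx.size)
    return (cum_rows[row_idx] < u[:, None]).sum(axis=1)


def _bin_label_for_position(t: int, interior_len: int) -> str | None:
    """Bin label of interior position t (0-based), or None outside the bins.

    Interior position t corresponds to codon index t+2 in 1-based whole-ORF
    coordinates, so t = 0..49 fall in bin_1..bin_5 and the last 50 interior
    positions in bin_-5..bin_-1.
    """
    if t < BIN_SIZE * N_BINS:
        return f"bin_{t // BIN_SIZE + 1}"
    from_end = interior_len - 1 - t  # 0 for the last interior codon
    if from_end < BIN_SIZE * N_BINS:
        return f"bin_{-(from_end // BIN_SIZE + 1)}"
    return None


def generate_corpus(
    spec: GeneratorSpec,
) -> tuple[list[OrfRecord], GroundTruth]:
    """Generate a validated ORF corpus (with flanks) and its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lengths = _draw_lengths(spec, rng)
    n = spec.n_genes

    # per-bin-label base distributions (None label = no override)
    p0 = spec.base_codon_distribution()
    label_dists: dict[str | None, np.ndarray] = {None: p0}
    for label, ow in spec.positional_overrides.items():
        label_dists[label] = spec.base_codon_distribution(ow)

    post_start_dist: dict[str | None, np.ndarray] = {}
    if spec.post_start_first_nt is not None:
        nt_w = np.asarray(spec.post_start_first_nt, dtype=float)
        for label, dist in label_dists.items():
            d = dist * nt_w[_FIRST_NT_OF_SENSE]
            post_start_dist[label] = d / d.sum()

    coupled = bool(spec.pair_coupling)
    if coupled:
        k = len(SENSE_CODONS)
        trans: dict[str | None, np.ndarray] = {}
        coupling = np.ones((k, k))
        for (a, b), w in spec.pair_coupling.items():
            coupling[SENSE_INDEX[a], SENSE_INDEX[b]] = w
        for label, dist in label_dists.items():
            t = coupling * dist[None, :]
            t /= t.sum(axis=1, keepdims=True)
            trans[label] = np.cumsum(t, axis=1)
        label_cum = {lb: np.cumsum(d) for lb, d in label_dists.items()}
        post_cum = {lb: np.cumsum(d) for lb, d in post_start_dist.items()}

        genes_codes: list[np.ndarray] = []
        for g in range(n):
            m = int(lengths[g]) - 2
            codes = np.empty(m, dtype=np.int64)
            for t in range(m):
                label = _bin_label_for_position(t, m)
                label = label if label in label_dists else None
                if t == 0:
                    cum = (
                        post_cum[label]
                        if label in post_cum
                        else label_cum[label]
                    )
                    codes[t] = (cum < rng.random()).sum()
                else:
                    row = trans[label][codes[t - 1]]
                    codes[t] = (row < rng.random()).sum()
            genes_codes.append(codes)
    elif not spec.positional_overrides and spec.post_start_first_nt is None:
        # fully i.i.d.: one vectorised draw for all interior codons
        m_total = int((lengths - 2).sum())
        flat = rng.choice(len(SENSE_CODONS), size=m_total, p=p0)
        genes_codes = list(np.split(flat, np.cumsum(lengths - 2)[:-1]))
    else:
        # vectorised: sample positions grouped by their bin label
        genes_codes = [
            np.empty(int(L) - 2, dtype=np.int64) for L in lengths
        ]
        buckets: dict[tuple[str | None, bool], list[tuple[int, int]]] = {}
        for g, codes in enumerate(genes_codes):
            m = codes.size
            for t in range(m):
                label = _bin_label_for_position(t, m)
                label = label if label in label_dists else None
                is_post_start = t == 0 and spec.post_start_first_nt is not None
                buckets.setdefault((label, is_post_start), []).append((g, t))
        for (label, is_post), positions in buckets.items():
            dist = post_start_dist[label] if is_post else label_dists[label]
            draws = rng.choice(len(SENSE_CODONS), size=len(positions), p=dist)
            for (g, t), d in zip(positions, draws):
                genes_codes[g][t] = d

    stop_p = (
        np.full(3, 1.0 / 3.0)
        if spec.stop_weights is None
        else np.asarray(spec.stop_weights, dtype=float)
    )
    stop_idx = rng.choice(3, size=n, p=stop_p)

    up_prof = (
        _uniform_profile(UPSTREAM_LEN)
        if spec.upstream_profile is None
        else np.asarray(spec.upstream_profile, dtype=float)
    )
    down_prof = (
        _uniform_profile(DOWNSTREAM_LEN)
        if spec.downstream_profile is None
        else np.asarray(spec.downstream_profile, dtype=float)
    )
    up_draws = np.stack(
        [rng.choice(4, size=n, p=up_prof[i]) for i in range(UPSTREAM_LEN)], axis=1
    )
    down_draws = np.stack(
        [rng.choice(4, size=n, p=down_prof[i]) for i in range(DOWNSTREAM_LEN)],
        axis=1,
    )

    records: list[OrfRecord] = []
    for g in range(n):
        body = "".join(SENSE_CODONS[i] for i in genes_codes[g])
        cds = START_CODON + body + STOP_CODONS[stop_idx[g]]
        up = "".join(NUCLEOTIDES[i] for i in up_draws[g])
        down = "".join(NUCLEOTIDES[i] for i in down_draws[g])
        records.append(
            OrfRecord(
                id=f"synth_{g:05d}",
                cds=cds,
                upstream_flank=up,
                downstream_flank=down,
            )
        )

    kozak: list[str] = []
    if spec.upstream_profile is not None:
        kozak.append("upstream")
    if spec.post_start_first_nt is not None:
        kozak.append("post_start")
    truth = GroundTruth(
        spec=spec,
        target_rscu=spec.target_rscu(),
        injected_pairs=dict(spec.pair_coupling),
        overridden_bins=sorted(spec.positional_overrides),
        kozak_positions=kozak,
    )
    return records, truth


# ---------------------------------------------------------------------------
# null-model shuffles


def ssc_shuffle(
    corpus: Sequence[OrfRecord], seed: int = 0
) -> list[OrfRecord]:
    """Shuffle synonymous codons across the corpus.

    Codons are permuted among all positions encoding the same amino acid
    (stop codons among stop positions), so every gene's protein sequence
    and the corpus-wide codon counts are preserved exactly.
    """
    rng = np.random.default_rng(seed)
    all_codons: list[str] = []
    boundaries = [0]
    for rec in corpus:
        all_codons.extend(rec.codons())
        boundaries.append(len(all_codons))
    aa_seq = [CODON_TO_AA[c] for c in all_codons]
    positions_by_aa: dict[str, list[int]] = {}
    for i, aa in enumerate(aa_seq):
        positions_by_aa.setdefault(aa, []).append(i)
    shuffled = list(all_codons)
    for aa, pos in positions_by_aa.items():
        pos_arr = np.array(pos)
        perm = pos_arr[rng.permutation(pos_arr.size)]
        for src, dst in zip(pos_arr, perm):
            shuffled[dst] = all_codons[src]
    out: list[OrfRecord] = []
    for gi, rec in enumerate(corpus):
        codons = shuffled[boundaries[gi] : boundaries[gi + 1]]
        out.append(
            OrfRecord(
                id=rec.id,
                cds="".join(codons),
                upstream_flank=rec.upstream_flank,
                downstream_flank=rec.downstream_flank,
            )
        )
    return out


def sc_shuffle(corpus: Sequence[OrfRecord], seed: int = 0) -> list[OrfRecord]:
    """Randomly permute all interior codons across the corpus.

    Start and stop codons stay in place, so gene lengths are preserved and
    every output record is still a structurally valid ORF (interior codons
    of validated ORFs are never stops).
    """
    rng = np.random.default_rng(seed)
    interiors: list[str] = []
    for rec in corpus:
        interiors.extend(rec.interior_codons())
    perm = rng.permutation(len(interiors))
    shuffled = [interiors[i] for i in perm]
    out: list[OrfRecord] = []
    cursor = 0
    for rec in corpus:
        m = rec.n_codons - 2
        body = "".join(shuffled[cursor : cursor + m])
        cursor += m
        out.append(
            OrfRecord(
                id=rec.id,
                cds=rec.cds[:3] + body + rec.cds[-3:],
                upstream_flank=rec.upstream_flank,
                downstream_flank=rec.downstream_flank,
            )
        )
    return out


def write_fasta(records: Sequence[OrfRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.cds}\n")


def write_flank_tsv(records: Sequence[OrfRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            up = rec.upstream_flank or "-"
            down = rec.downstream_flank or "-"
            fh.write(f"{rec.id}\t{up}\t{down}\n")
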