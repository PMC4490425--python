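"""Reading, validating and slicing ORF corpora.

An ORF is accepted when it is a structurally complete coding sequence:
starts with ATG, ends with a stop codon, has no internal in-frame stop and
no ambiguous base, and is strictly longer than a minimum length (300 bp by
default, so a 300 bp sequence is rejected).  An optional table of homolog
reference lengths reproduces a completeness filter: the ORF length must lie
within 95%-105% of its reference homolog's length.

The module also provides the positional slices used downstream: ten bins of
ten codons flanking the start and stop codons, and 18-nt context windows
(9 nt upstream + anchor codon + 6 nt downstream) around either anchor.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .tables import START_CODON, STOP_CODONS

logger = logging.getLogger(__name__)

#: rejection reason codes, in the order the rules are applied.
REASONS = (
    "not-multiple-of-3",
    "no-start",
    "no-stop",
    "internal-stop",
    "ambiguous-base",
    "too-short",
    "homolog-length-ratio",
)

_VALID_CHARS = frozenset("ACGT")

BIN_SIZE = 10
N_BINS = 5
#: start + 5*10 codons + 5*10 codons + stop
MIN_POSITIONAL_CODONS = 2 * BIN_SIZE * N_BINS + 2


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed."""


@dataclass(frozen=True)
class OrfRecord:
    """One coding sequence with optional flanking nucleotides.

    The cds is stored in the DNA alphabet, uppercase.  Flanks may be empty;
    ``upstream_flank`` abuts the start codon, ``downstream_flank`` follows
    the stop codon.
    """

    id: str
    cds: str
    upstream_flank: str = ""
    downstream_flank: str = ""

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def codons(self) -> list[str]:
        return [self.cds[i : i + 3] for i in range(0, len(self.cds), 3)]

    def interior_codons(self) -> list[str]:
        """Codons between (excluding) the start and stop codons."""
        return self.codons()[1:-1]


@dataclass
class FilterReport:
    kept: list[OrfRecord]
    rejected: list[tuple[str, str]]

    def to_tsv(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write("id\tverdict\treason\n")
            for rec in self.kept:
                fh.write(f"{rec.id}\tkept\t-\n")
            for rid, reason in self.rejected:
                fh.write(f"{rid}\trejected\t{reason}\n")


@dataclass(frozen=True)
class ContextWindow:
    """18-nt window around a start or stop codon.

    ``nucleotides`` holds 9 nt upstream of the anchor, the 3-nt anchor codon
    (positions 10-12), and 6 nt downstream.
    """

    gene_id: str
    anchor: str  # "start" or "stop"
    nucleotides: str

    def __post_init__(self) -> None:
        if len(self.nucleotides) != 18:
            raise ValueError("context window must be 18 nt")
        if self.anchor not in ("start", "stop"):
            raise ValueError(f"unknown anchor {self.anchor!r}")


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> list[OrfRecord]:
    """Read candidate ORFs from a (optionally gzipped) FASTA file.

    Sequences are uppercased and U is mapped to T; no validation is done
    here — that is :func:`filter_orfs`'s job.
    """
    records: list[OrfRecord] = []
    with _open_maybe_gzip(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise FastaParseError(
                f"{path}: not FASTA — first line does not start with '>'"
            )
        fh.seek(0)
        for entry in SeqIO.parse(fh, "fasta"):
            records.append(OrfRecord(id=entry.id, cds=_normalize(str(entry.seq))))
    if not records:
        logger.warning("no FASTA entries found in %s", path)
    return records


def read_flanks(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read flanking sequences keyed by gene id.

    Two layouts are accepted: a FASTA whose entry ids carry ``|up`` /
    ``|down`` suffixes, or a 3-column TSV ``id<TAB>upstream<TAB>downstream``
    (``-`` or empty for a missing flank).
    """
    path = Path(path)
    flanks: dict[str, tuple[str, str]] = {}
    with _open_maybe_gzip(path) as fh:
        head = fh.read(1)
        fh.seek(0)
        if head == ">":
            ups: dict[str, str] = {}
            downs: dict[str, str] = {}
            for entry in SeqIO.parse(fh, "fasta"):
                if entry.id.endswith("|up"):
                    ups[entry.id[:-3]] = _normalize(str(entry.seq))
                elif entry.id.endswith("|down"):
                    downs[entry.id[:-5]] = _normalize(str(entry.seq))
                else:
                    raise FastaParseError(
                        f"{path}: flank FASTA id {entry.id!r} lacks |up/|down suffix"
                    )
            for gid in set(ups) | set(downs):
                flanks[gid] = (ups.get(gid, ""), downs.get(gid, ""))
        else:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    raise FastaParseError(f"{path}:{ln}: expected 3 columns")
                gid, up, down = parts
                up = "" if up == "-" else _normalize(up)
                down = "" if down == "-" else _normalize(down)
                flanks[gid] = (up, down)
    return flanks


def attach_flanks(
    records: Iterable[OrfRecord], flanks: Mapping[str, tuple[str, str]]
) -> list[OrfRecord]:
    out = []
    for rec in records:
        up, down = flanks.get(rec.id, ("", ""))
        out.append(
            OrfRecord(rec.id, rec.cds, upstream_flank=up, downstream_flank=down)
        )
    return out


def read_homolog_lengths(path: str | Path) -> dict[str, int]:
    """Read a 2-column TSV of reference homolog lengths (id, length_bp)."""
    table: dict[str, int] = {}
    with _open_maybe_gzip(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FastaParseError(f"{path}:{ln}: expected 2 columns")
            table[parts[0]] = int(parts[1])
    return table


def validation_failure(
    record: OrfRecord,
    min_len_bp: int = 300,
    homolog_lengths: Mapping[str, int] | None = None,
    ratio_bounds: tuple[float, float] = (0.95, 1.05),
) -> str | None:
    """Return the first failing rule's reason code, or None if valid.

    Rules are applied in the fixed order of :data:`REASONS` so that a
    rejection reason is deterministic.
    """
    cds = record.cds
    if len(cds) == 0 or len(cds) % 3 != 0:
        return "not-multiple-of-3"
    if not cds.startswith(START_CODON):
        return "no-start"
    if cds[-3:] not in STOP_CODONS:
        return "no-stop"
    for i in range(3, len(cds) - 3, 3):
        if cds[i : i + 3] in STOP_CODONS:
            return "internal-stop"
    if not _VALID_CHARS.issuperset(cds):
        return "ambiguous-base"
    if len(cds) <= min_len_bp:
        return "too-short"
    if homolog_lengths is not None and record.id in homolog_lengths:
        ratio = len(cds) / homolog_lengths[record.id]
        if not (ratio_bounds[0] <= ratio <= ratio_bounds[1]):
            return "homolog-length-ratio"
    return None


def filter_orfs(
    records: Iterable[OrfRecord],
    min_len_bp: int = 300,
    homolog_lengths: Mapping[str, int] | None = None,
    ratio_bounds: tuple[float, float] = (0.95, 1.05),
) -> FilterReport:
    """Partition candidate records into kept ORFs and reasoned rejections."""
    kept: list[OrfRecord] = []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        reason = validation_failure(rec, min_len_bp, homolog_lengths, ratio_bounds)
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec.id, reason))
    logger.info("filter_orfs: kept %d, rejected %d", len(kept), len(rejected))
    return FilterReport(kept=kept, rejected=rejected)


def eligible_for_bins(record: OrfRecord) -> bool:
    """ORFs must carry >= 102 codons so the ten 10-codon bins are disjoint."""
    return record.n_codons >= MIN_POSITIONAL_CODONS


def bin_labels(n_bins: int = N_BINS) -> list[str]:
    return [f"bin_{k}" for k in range(1, n_bins + 1)] + [
        f"bin_{-k}" for k in range(n_bins, 0, -1)
    ]


def extract_bins(
    record: OrfRecord, bin_size: int = BIN_SIZE, n_bins: int = N_BINS
) -> dict[str, list[str]]:
    """Slice an ORF into 5' and 3' codon bins of ``bin_size`` codons.

    bin_k (k = 1..n_bins) covers codons 2+bin_size*(k-1) .. 1+bin_size*k in
    1-based codon coordinates (the start codon is codon 1 and is excluded);
    bin_-k covers the k-th block of ``bin_size`` codons counting backwards
    from the codon immediately before the stop codon.

    Raises ValueError for records too short to give disjoint bins.
    """
    need = 2 * bin_size * n_bins + 2
    total = record.n_codons
    if total < need:
        raise ValueError(
            f"{record.id}: {total} codons < {need} required for disjoint bins"
        )
    codons = record.codons()
    bins: dict[str, list[str]] = {}
    for k in range(1, n_bins + 1):
        lo = 1 + bin_size * (k - 1)  # 0-based index of first codon in bin
        bins[f"bin_{k}"] = codons[lo : lo + bin_size]
    for k in range(1, n_bins + 1):
        hi = total - 1 - bin_size * (k - 1)  # 0-based stop index minus offset
        bins[f"bin_{-k}"] = codons[hi - bin_size : hi]
    return bins


def extract_context(record: OrfRecord, anchor: str) -> ContextWindow | None:
    """Extract the 18-nt context window around the start or stop codon.

    Returns None when the record's flanks are too short (the caller is
    expected to count skips).
    """
    if anchor == "start":
        if len(record.upstream_flank) < 9 or len(record.cds) < 9:
            return None
        window = record.upstream_flank[-9:] + record.cds[:9]
    elif anchor == "stop":
        if len(record.downstream_flank) < 6 or len(record.cds) < 12:
            return None
        window = record.cds[-12:] + record.downstream_flank[:6]
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    return ContextWindow(gene_id=record.id, anchor=anchor, nucleotides=window)


def extract_contexts(
    records: Iterable[OrfRecord], anchor: str
) -> tuple[list[ContextWindow], int]:
    """Extract all available context windows; returns (windows, n_skipped)."""
    windows: list[ContextWindow] = []
    skipped = 0
    for rec in records:
        w = extract_context(rec, anchor)
        if w is None:
            skipped += 1
        else:
            windows.append(w)
    if skipped:
        logger.info("extract_contexts(%s): skipped %d records", anchor, skipped)
    return windows, skipped
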