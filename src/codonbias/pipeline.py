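"""End-to-end orchestration: filter -> usage -> pairs -> positional ->
composition (-> comparative), with a run manifest.

Every output file starts with comment headers recording the tool version,
a hash of the run configuration and the seed, so a bundle is traceable to
the exact run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

from . import __version__
from .comparative import (
    build_profiles,
    cluster_species_rscu,
    pca_rscu,
    species_context_tree,
)
from .composition import (
    gc3_strata,
    relative_abundance,
    scuo_gc3_fit,
    strata_composition_contrast,
)
from .pairs import (
    call_pair_bias,
    classify_high_frequency_pairs,
    count_pairs,
    junction_profile,
    pair_calls_to_tsv,
    pair_family_shares,
    rscpu,
)
from .positional import au3_profile, kld_profile, logo_matrix, post_aug_bias
from .seqio import (
    OrfRecord,
    attach_flanks,
    extract_contexts,
    filter_orfs,
    read_fasta,
    read_flanks,
    read_homolog_lengths,
)
from .tables import to_rna
from .usage import (
    UndefinedStatisticError,
    abundant_rare_sets,
    classify_high_frequency,
    count_codons,
    gc_partition,
    ncg_ncc_ratio,
    scuo,
)

logger = logging.getLogger(__name__)

ALL_STAGES = ("usage", "pairs", "positional", "composition", "comparative")


@dataclass
class RunConfig:
    fasta: str | None = None
    flanks: str | None = None
    homolog_lengths: str | None = None
    species_manifest: str | None = None  # TSV: name <TAB> fasta path
    out_dir: str = "codonbias_out"
    min_len_bp: int = 300
    ratio_bounds: tuple[float, float] = (0.95, 1.05)
    p_thresh: float = 0.01
    log2_cutoff: float = 1.5
    rscu_high: float = 1.5
    share_high: float = 0.60
    bin_size: int = 10
    n_bins: int = 5
    max_pair_distance: int = 5
    ssc_replicates: int = 100
    bootstrap_replicates: int = 1000
    seed: int = 0

    def validate(self) -> None:
        positive = {
            "min_len_bp": self.min_len_bp,
            "p_thresh": self.p_thresh,
            "log2_cutoff": self.log2_cutoff,
            "rscu_high": self.rscu_high,
            "share_high": self.share_high,
            "bin_size": self.bin_size,
            "n_bins": self.n_bins,
            "ssc_replicates": self.ssc_replicates,
            "bootstrap_replicates": self.bootstrap_replicates,
        }
        bad = [k for k, v in positive.items() if v <= 0]
        if bad:
            raise ValueError(f"config thresholds must be positive: {bad}")
        if not 0 <= self.max_pair_distance <= 5:
            raise ValueError("max_pair_distance must be in [0, 5]")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [
            f"codonbias {__version__}",
            f"config_hash={self.config_hash()}",
            f"seed={self.seed}",
        ]


def _write_json(path: Path, payload: dict, config: RunConfig) -> None:
    payload = {
        "_meta": {
            "tool": f"codonbias {__version__}",
            "config_hash": config.config_hash(),
            "seed": config.seed,
        },
        **payload,
    }
    path.write_text(json.dumps(payload, indent=2, default=str))


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


def _load_records(config: RunConfig) -> list[OrfRecord]:
    if config.fasta is None:
        raise ValueError("no input: provide fasta or records")
    records = read_fasta(config.fasta)
    if config.flanks:
        records = attach_flanks(records, read_flanks(config.flanks))
    return records


def _stage_filter(config, records, out, header, manifest):
    homologs = (
        read_homolog_lengths(config.homolog_lengths)
        if config.homolog_lengths
        else None
    )
    report = filter_orfs(
        records,
        min_len_bp=config.min_len_bp,
        homolog_lengths=homologs,
        ratio_bounds=config.ratio_bounds,
    )
    report.to_tsv(out / "filter_report.tsv", header)
    manifest["stages"]["filter"] = {
        "input": len(records),
        "kept": len(report.kept),
        "rejected": len(report.rejected),
    }
    if not report.kept:
        raise ValueError("no ORFs survive filtering")
    return report.kept


def _stage_usage(config, kept, out, header, manifest):
    table = count_codons(kept)
    table.to_tsv(out / "codon_usage.tsv", header)
    gc = gc_partition(kept)
    high = classify_high_frequency(table)
    abundant, rare = abundant_rare_sets(table)
    try:
        ncg_ncc = ncg_ncc_ratio(table)
    except UndefinedStatisticError:
        ncg_ncc = None
    _write_json(
        out / "usage_summary.json",
        {
            "n_orfs": len(kept),
            "n_codons": table.total_codons,
            "gc": asdict(gc),
            "scuo": scuo(table),
            "high_frequency_codons": sorted(to_rna(c) for c in high),
            "abundant_codons": sorted(to_rna(c) for c in abundant),
            "rare_codons": sorted(to_rna(c) for c in rare),
            "ncg_ncc_ratio": ncg_ncc,
        },
        config,
    )
    manifest["stages"]["usage"] = {"n_codons": table.total_codons}


def _stage_pairs(config, kept, out, header, manifest):
    pair_summary = {}
    d0_table = None
    for d in range(config.max_pair_distance + 1):
        pt = count_pairs(kept, distance=d)
        if d == 0:
            d0_table = pt
        calls = call_pair_bias(pt, config.p_thresh, config.log2_cutoff)
        pair_calls_to_tsv(calls, out / f"pairs_d{d}.tsv", header)
        pair_summary[f"d{d}"] = {
            "total_pairs": pt.total_pairs,
            "preferred": sum(c.verdict == "preferred" for c in calls),
            "avoided": sum(c.verdict == "avoided" for c in calls),
        }
    rscpu_map = rscpu(d0_table)
    shares = pair_family_shares(d0_table)
    high_pairs = classify_high_frequency_pairs(
        rscpu_map, shares, config.rscu_high, config.share_high
    )
    with open(out / "high_frequency_pairs.tsv", "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("pair\trscpu\tfamily_share\n")
        for a, b in sorted(high_pairs):
            fh.write(
                f"{to_rna(a)}{to_rna(b)}\t{rscpu_map[(a, b)]:.4f}\t"
                f"{shares[(a, b)]:.4f}\n"
            )
    _write_json(
        out / "pairs_summary.json",
        {
            "per_distance": pair_summary,
            "n_high_frequency_pairs": len(high_pairs),
            "junction_profile": junction_profile(d0_table),
        },
        config,
    )
    manifest["stages"]["pairs"] = pair_summary


def _stage_positional(config, kept, out, header, manifest):
    profile = kld_profile(
        kept,
        ssc_replicates=config.ssc_replicates,
        seed=config.seed,
        bin_size=config.bin_size,
        n_bins=config.n_bins,
    )
    profile.to_tsv(out / "kld_profile.tsv", header)
    start_calls, start_masks = post_aug_bias(
        kept, "start", config.p_thresh, config.log2_cutoff
    )
    internal_calls, internal_masks = post_aug_bias(
        kept, "internal", config.p_thresh, config.log2_cutoff
    )
    au3, au3_baseline = au3_profile(kept)
    pos_summary = {
        "kld_corrected": profile.kld_corrected,
        "post_start_preferred": sorted(
            to_rna(c.item) for c in start_calls if c.verdict == "preferred"
        ),
        "post_start_avoided": sorted(
            to_rna(c.item) for c in start_calls if c.verdict == "avoided"
        ),
        "post_internal_significant": sum(
            c.verdict != "unbiased" for c in internal_calls
        ),
        "post_start_masks": start_masks,
        "post_internal_masks": internal_masks,
        "au3_profile": au3,
        "au3_baseline": au3_baseline,
    }
    n_logos = {}
    for anchor in ("start", "stop"):
        windows, skipped = extract_contexts(kept, anchor)
        n_logos[anchor] = {"windows": len(windows), "skipped": skipped}
        if windows:
            logo_matrix(windows).to_tsv(out / f"logo_{anchor}.tsv", header)
    pos_summary["context_windows"] = n_logos
    _write_json(out / "positional_summary.json", pos_summary, config)
    manifest["stages"]["positional"] = n_logos


def _stage_composition(config, kept, out, header, manifest):
    comp = relative_abundance([r.cds for r in kept])
    gc3_by_gene = {r.id: gc_partition([r]).gc3 for r in kept}
    groups_ids = gc3_strata(gc3_by_gene)
    seqs_by_id = {r.id: r.cds for r in kept}
    group_stats = strata_composition_contrast(
        [[seqs_by_id[g] for g in grp] for grp in groups_ids],
        n_boot=config.bootstrap_replicates,
        seed=config.seed,
    )
    scuo_by_gene = {}
    for r in kept:
        try:
            scuo_by_gene[r.id] = scuo(r)
        except UndefinedStatisticError:
            pass
    ids = [g for g in gc3_by_gene if g in scuo_by_gene]
    fit = scuo_gc3_fit(
        [scuo_by_gene[g] for g in ids], [gc3_by_gene[g] for g in ids]
    )
    _write_json(
        out / "composition.json",
        {
            "rho_cg": comp.rho_cg,
            "rho_cwg": comp.rho_cwg,
            "gc3_strata_sizes": [len(g) for g in groups_ids],
            "groups": [
                {
                    "rho_cg": gs.stats.rho_cg,
                    "rho_cg_ci": list(gs.rho_cg_ci),
                    "rho_cwg": gs.stats.rho_cwg,
                    "rho_cwg_ci": list(gs.rho_cwg_ci),
                }
                for gs in group_stats
            ],
            "scuo_gc3_fit": {
                "coefficients": list(fit.coefficients),
                "r_squared": fit.r_squared,
                "minimum": fit.minimum,
            },
        },
        config,
    )
    manifest["stages"]["composition"] = {
        "strata_sizes": [len(g) for g in groups_ids]
    }


def _stage_comparative(config, out, manifest):
    corpora: dict[str, list[OrfRecord]] = {}
    with open(config.species_manifest) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            name, path = line.rstrip("\n").split("\t")
            corpora[name] = read_fasta(path)
    profiles = build_profiles(corpora, min_len_bp=config.min_len_bp)
    species_tree, codon_tree, heat = cluster_species_rscu(profiles)
    heat.to_csv(out / "rscu_heatmap.tsv", sep="\t")
    (out / "species_rscu.nwk").write_text(species_tree.newick + "\n")
    (out / "codon_rscu.nwk").write_text(codon_tree.newick + "\n")
    if len(profiles) >= 3:
        pca = pca_rscu(profiles)
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
    ctx_tree = species_context_tree(profiles)
    (out / "species_context.nwk").write_text(ctx_tree.newick + "\n")
    manifest["stages"]["comparative"] = {
        "n_species": len(profiles),
        "species": [p.name for p in profiles],
    }


def run_pipeline(
    config: RunConfig,
    records: Sequence[OrfRecord] | None = None,
    stages: Sequence[str] | None = None,
) -> dict:
    """Run the analysis pipeline and return the run manifest.

    ``stages`` selects analysis stages (filtering always runs); by default
    everything runs, with the comparative stage only when a species
    manifest is configured.  Any stage failure aborts with a StageError
    naming the stage.
    """
    config.validate()
    selected = set(ALL_STAGES if stages is None else stages)
    unknown = selected - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = config.header_lines()
    manifest: dict = {
        "tool": f"codonbias {__version__}",
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    runners = {
        "usage": lambda kept: _stage_usage(config, kept, out, header, manifest),
        "pairs": lambda kept: _stage_pairs(config, kept, out, header, manifest),
        "positional": lambda kept: _stage_positional(
            config, kept, out, header, manifest
        ),
        "composition": lambda kept: _stage_composition(
            config, kept, out, header, manifest
        ),
    }

    needs_corpus = selected & set(runners)
    kept: list[OrfRecord] = []
    if needs_corpus or records is not None or config.fasta:
        stage = "filter"
        try:
            if records is None:
                records = _load_records(config)
            kept = _stage_filter(config, records, out, header, manifest)
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc

    for stage in ("usage", "pairs", "positional", "composition"):
        if stage not in selected:
            continue
        try:
            runners[stage](kept)
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc

    if "comparative" in selected and config.species_manifest:
        stage = "comparative"
        try:
            _stage_comparative(config, out, manifest)
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )
    return manifest
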