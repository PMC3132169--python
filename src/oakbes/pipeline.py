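"""End-to-end orchestration of the synthetic BES analysis.

Runs simulate -> stats -> coverage -> selfmatch -> repeats -> ssr ->
genes -> synteny -> annotate-stats from a single flat configuration and
one global seed, writing per-stage outputs plus a consolidated JSON
report whose sections mirror the shapes of a BAC-library
characterisation study (library table, dataset table, repeat table,
SSR summary, gene estimate, synteny table).

Every number in the report is produced by one module operation; the
report assembles, it never recomputes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from oakbes import annotation_stats, gene_content, library_stats, repeat_analysis
from oakbes import ssr_finder, synteny_classifier
from oakbes.bes_io import dataset_stats, pair_reads, retention_rate, write_bes_fasta
from oakbes.match_engine import AlignmentHit, AlignParams, self_match_counts
from oakbes.synthetic_data import (
    GenomeSpec,
    LibrarySimSpec,
    RepeatFamilySpec,
    SsrPlantSpec,
    build_genome,
    sample_clones,
    simulate_bes_reads,
    simulate_marker_screen,
)

DEFAULTS: dict[str, object] = {
    "seed": 1,
    # synthetic genome
    "genome.length": 2_000_000,
    "genome.gc": 0.3533,
    "genome.n_repeat_families": 2,
    "genome.repeat_len": 150,
    "genome.repeat_copies": 200,
    "genome.repeat_divergence": 0.02,
    "genome.n_ssr_loci": 300,
    "genome.ssr_motif": "AG",
    "genome.ssr_copies": 12,
    "genome.n_genes": 15,
    "genome.gene_len": 2_000,
    "genome.cp_len": 150_000,
    # simulated library (study conditions)
    "library.n_clones": 150,
    "library.insert_mean": 135_000,
    "library.insert_sd": 30_000,
    "library.insert_min": 50_000,
    "library.insert_max": 205_000,
    "library.empty_rate": 0.07,
    "library.cp_rate": 0.022,
    "library.read_len": 599,
    "library.read_retention": 0.6696,
    # coverage / marker screen
    "coverage.n_markers": 60,
    # self-comparison + repeat calling
    "selfmatch.word_size": 11,
    "selfmatch.min_score": 28,
    "repeats.window": 100,
    "repeats.min_identity": 0.90,
    "repeats.alpha": 0.05,
    "repeats.min_matches": 6,
    # gene content
    "genes.min_overlap": 100,
    "genes.novel_fraction": 0.11,
    # synteny
    "synteny.min_span": 15_000,
    "synteny.max_span": 250_000,
}


class ConfigError(ValueError):
    """Invalid pipeline configuration (reported before any stage runs)."""


class StageError(RuntimeError):
    """A stage failed; the message names the stage."""


def load_config(path: str | Path) -> dict[str, object]:
    """Read a flat key = value config file; unknown keys are an error."""
    config = dict(DEFAULTS)
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in DEFAULTS:
            raise ConfigError(f"line {lineno}: unknown key {key!r}")
        default = DEFAULTS[key]
        config[key] = type(default)(value) if not isinstance(default, str) else value
    return config


def validate_config(config: dict[str, object]) -> None:
    unknown = set(config) - set(DEFAULTS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    merged = {**DEFAULTS, **config}
    if merged["synteny.min_span"] >= merged["synteny.max_span"]:
        raise ConfigError("synteny.min_span must be < synteny.max_span")
    if merged["library.insert_max"] > merged["genome.length"]:
        raise ConfigError("library.insert_max exceeds genome.length")
    if not 0 < float(merged["genome.gc"]) < 1:
        raise ConfigError("genome.gc must be in (0, 1)")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict[str, object] | None = None, out_dir: str | Path = "oakbes_run") -> dict:
    """Run every stage in dependency order and write the report bundle.

    Returns the consolidated report (also written as ``report.json``).
    Identical (config, seed) produce byte-identical payloads.  A stage
    failure halts the run, leaves a ``FAILED`` marker naming the stage,
    and re-raises as StageError.
    """
    cfg = {**DEFAULTS, **(config or {})}
    validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(4)]
    report: dict[str, object] = {"seed": seed}
    stage = "simulate"
    try:
        # --- simulate -------------------------------------------------
        gc = float(cfg["genome.gc"])
        at = (1.0 - gc) / 2.0
        gspec = GenomeSpec(
            genome_len=int(cfg["genome.length"]),
            base_freqs=(at, gc / 2.0, gc / 2.0, at),
            repeat_families=[
                RepeatFamilySpec(
                    f"FAM{i + 1}",
                    int(cfg["genome.repeat_len"]),
                    int(cfg["genome.repeat_copies"]),
                    float(cfg["genome.repeat_divergence"]),
                )
                for i in range(int(cfg["genome.n_repeat_families"]))
            ],
            ssr_plants=[
                SsrPlantSpec(
                    str(cfg["genome.ssr_motif"]),
                    int(cfg["genome.ssr_copies"]),
                    int(cfg["genome.n_ssr_loci"]),
                )
            ],
            n_genes=int(cfg["genome.n_genes"]),
            gene_len=int(cfg["genome.gene_len"]),
            cp_seq_len=int(cfg["genome.cp_len"]),
        )
        genome, truth = build_genome(gspec, seed=sub[0])
        lspec = LibrarySimSpec(
            n_clones=int(cfg["library.n_clones"]),
            insert_mean=int(cfg["library.insert_mean"]),
            insert_sd=int(cfg["library.insert_sd"]),
            insert_min=int(cfg["library.insert_min"]),
            insert_max=int(cfg["library.insert_max"]),
            empty_rate=float(cfg["library.empty_rate"]),
            cp_rate=float(cfg["library.cp_rate"]),
            read_len_mean=int(cfg["library.read_len"]),
            read_retention=float(cfg["library.read_retention"]),
            seed=sub[1],
        )
        clones = sample_clones(gspec.genome_len, lspec)
        reads, truth_map = simulate_bes_reads(clones, lspec, genome, truth.cp_sequence)
        if not reads:
            raise RuntimeError("simulation produced no reads; increase library.n_clones")
        with open(out / "reads.fasta", "w") as fh:
            write_bes_fasta(reads, fh)
        (out / "truth.bed").write_text(truth.to_bed())

        # --- stats ----------------------------------------------------
        stage = "stats"
        stats = dataset_stats(reads)
        mates = pair_reads(reads)
        n_attempted = sum(1 for c in clones if not c.is_empty)
        report["dataset"] = {
            "n_reads": stats.n_reads,
            "total_bp": stats.total_bp,
            "min_len": stats.min_len,
            "max_len": stats.max_len,
            "mean_len": round(stats.mean_len, 2),
            "gc_pct": round(100 * stats.gc_fraction, 2),
            "n_mate_pairs": len(mates.pairs),
            "paired_fraction_pct": round(100 * mates.paired_fraction, 2),
            "retention_pct": (
                None if n_attempted == 0 else retention_rate(n_attempted, stats.n_reads)
            ),
        }
        (out / "dataset_stats.json").write_text(json.dumps(report["dataset"], indent=2))

        # --- coverage -------------------------------------------------
        stage = "coverage"
        lp = library_stats.LibraryParams(
            n_clones=lspec.n_clones,
            insert_size=lspec.insert_mean,
            genome_size=gspec.genome_len,
            empty_fraction=lspec.empty_rate,
            organelle_fraction=lspec.cp_rate,
        )
        hits_per_marker = simulate_marker_screen(
            clones, int(cfg["coverage.n_markers"]), gspec.genome_len, seed=sub[2]
        )
        report["library"] = {
            "n_clones": lspec.n_clones,
            "insert_mean_bp": lspec.insert_mean,
            "empty_rate": lspec.empty_rate,
            "cp_rate": lspec.cp_rate,
            "coverage_depth": round(library_stats.coverage_depth(lp), 2),
            "recovery_probability": library_stats.recovery_probability(
                lp.n_clones * (1 - lp.empty_fraction) * (1 - lp.organelle_fraction),
                lp.insert_size,
                lp.genome_size,
            ),
            "marker_screen_mean_hits": round(float(np.mean(hits_per_marker)), 2),
            "marker_screen_n_markers": int(cfg["coverage.n_markers"]),
        }

        # --- selfmatch ------------------------------------------------
        stage = "selfmatch"
        params = AlignParams(
            word_size=int(cfg["selfmatch.word_size"]), min_score=int(cfg["selfmatch.min_score"])
        )
        counts, passing_hits = self_match_counts(
            reads,
            params,
            w=int(cfg["repeats.window"]),
            min_identity=float(cfg["repeats.min_identity"]),
            collect_hits=True,
        )
        base_freqs = _empirical_freqs(reads)
        model = repeat_analysis.NullModel(
            base_freqs=base_freqs,
            w=int(cfg["repeats.window"]),
            k=int(np.ceil(float(cfg["repeats.min_identity"]) * int(cfg["repeats.window"]))),
            n_trials=max(1, stats.n_reads - 1),
            alpha=float(cfg["repeats.alpha"]),
        )
        report["selfmatch"] = {
            "n_matching_reads": counts.total_matching,
            "redundancy_pct": round(100 * counts.total_matching / stats.n_reads, 2),
            "null_p0": model.p0,
            "repeat_call_threshold": model.threshold,
        }

        # --- repeats --------------------------------------------------
        stage = "repeats"
        candidates = repeat_analysis.candidate_repeats(
            counts, min_matches=int(cfg["repeats.min_matches"])
        )
        families = repeat_analysis.cluster_families(candidates, passing_hits)
        for fam in families:
            fam.genome_copy_estimate = repeat_analysis.extrapolate_copies(
                fam.bes_copy_count, gspec.genome_len, stats.total_bp
            )
        novel_bp = sum(f.covered_bp for f in families)
        novel_density = repeat_analysis.repeat_density(
            min(novel_bp, stats.total_bp), stats.total_bp
        )
        accounting = repeat_analysis.total_repeat_accounting(0.0, novel_density)
        report["repeats"] = {
            "n_candidate_reads": len(candidates),
            "n_families": len(families),
            "family_sizes": [f.bes_copy_count for f in families],
            "genome_copy_estimates": [f.genome_copy_estimate for f in families],
            "novel_repeat_bp": novel_bp,
            "novel_density_pct": accounting.novel_density,
            "known_density_pct": accounting.known_density,
            "total_density_pct": accounting.total_density,
        }
        (out / "repeat_families.tsv").write_text(repeat_analysis.families_tsv(families))

        # --- ssr ------------------------------------------------------
        stage = "ssr"
        loci = ssr_finder.find_ssrs_in_reads(reads)
        report["ssr"] = ssr_finder.ssr_summary(loci, stats.total_bp)
        (out / "ssr_loci.tsv").write_text(ssr_finder.loci_tsv(loci))

        # --- genes ----------------------------------------------------
        stage = "genes"
        min_ov = int(cfg["genes.min_overlap"])
        gene_hit_reads = _reads_overlapping(truth_map, truth.genes, min_ov)
        eff_gene_len = gspec.gene_len + lspec.read_len_mean - 2 * min_ov + 1
        gp = gene_content.GeneEstimateParams(
            n_hit_bes=len(gene_hit_reads),
            mean_bes_len=stats.mean_len,
            total_bes_bp=stats.total_bp,
            genome_size=gspec.genome_len,
            mean_gene_len=eff_gene_len,
            novel_fraction=float(cfg["genes.novel_fraction"]),
        )
        n_cp = sum(1 for v in truth_map.values() if v[2].startswith("cp"))
        estimate = gene_content.estimate_gene_number(gp)
        report["genes"] = {
            "n_hit_bes": gp.n_hit_bes,
            "planted_genes": gspec.n_genes,
            "gene_estimate": estimate,
            "gene_estimate_with_novel": gene_content.adjust_for_novel(
                estimate, gp.novel_fraction
            ),
            "cp_fraction_pct": gene_content.organelle_fraction(n_cp, stats.n_reads),
        }

        # --- synteny --------------------------------------------------
        stage = "synteny"
        sp = synteny_classifier.SyntenyParams(
            min_span=int(cfg["synteny.min_span"]), max_span=int(cfg["synteny.max_span"])
        )
        truth_hits = _truth_hits(truth_map)
        results, summary = synteny_classifier.classify_dataset(mates, truth_hits, sp)
        report["synteny"] = summary
        (out / "synteny.tsv").write_text(synteny_classifier.classifications_tsv(results))

        # --- annotate-stats ------------------------------------------
        stage = "annotate-stats"
        assignments, reference = _synthetic_go(gene_hit_reads, seed=sub[3])
        if assignments:
            tc = annotation_stats.count_terms(assignments)
            observed = {t: tc.per_term.get(t, 0) for t in reference}
            comparisons = annotation_stats.chi2_category_compare(observed, reference)
            report["annotation"] = {
                "n_annotated_reads": tc.n_annotated_reads,
                "n_assignments": tc.n_assignments,
                "n_significant_categories": sum(1 for c in comparisons if c.significant),
            }
            (out / "go_comparison.tsv").write_text(
                annotation_stats.comparison_tsv(comparisons)
            )
        else:
            report["annotation"] = {"n_annotated_reads": 0, "n_assignments": 0}
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    manifest = {
        "seed": seed,
        "config": {k: cfg[k] for k in sorted(cfg)},
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def _empirical_freqs(reads) -> tuple[float, float, float, float]:
    counts = {b: 0 for b in "ACGT"}
    for r in reads:
        for b in "ACGT":
            counts[b] += r.sequence.count(b)
    total = sum(counts.values())
    return tuple(counts[b] / total for b in "ACGT")  # type: ignore[return-value]


def _reads_overlapping(truth_map, intervals, min_overlap: int) -> set[str]:
    """Read ids whose true genomic footprint overlaps any interval by
    >= min_overlap bp (organelle reads never count)."""
    hit = set()
    for read_id, (s, e, strand) in truth_map.items():
        if strand.startswith("cp") or strand.startswith("mt"):
            continue
        for gs, ge, _label in intervals:
            if min(e, ge) - max(s, gs) + 1 >= min_overlap:
                hit.add(read_id)
                break
    return hit


def _truth_hits(truth_map) -> list[AlignmentHit]:
    """Exact self-genome hits from the simulation truth (the synthetic
    stand-in for an external whole-genome mapping)."""
    hits = []
    for read_id, (s, e, strand) in truth_map.items():
        if strand.startswith("cp") or strand.startswith("mt"):
            continue
        length = e - s + 1
        hits.append(
            AlignmentHit(
                query_id=read_id,
                subject_id="genome",
                q_start=1,
                q_end=length,
                s_start=s,
                s_end=e,
                subject_strand=strand,
                match_vector=np.ones(length, dtype=bool),
                evalue=0.0,
            )
        )
    return hits


_GO_CATEGORIES = (
    ("binding", 0.40),
    ("catalytic_activity", 0.30),
    ("transporter_activity", 0.10),
    ("structural_molecule", 0.10),
    ("molecular_transducer", 0.10),
)


def _synthetic_go(gene_hit_reads: set[str], seed: int):
    """Toy GO assignments for the annotation stage: gene-hit reads get one
    molecular-function term drawn from a skewed distribution; the
    reference is the generating distribution itself."""
    rng = np.random.default_rng(seed)
    terms = [t for t, _ in _GO_CATEGORIES]
    probs = np.array([p for _, p in _GO_CATEGORIES])
    assignments = [
        annotation_stats.GoAssignment(
            bes_id=rid,
            go_id=terms[rng.choice(len(terms), p=probs)],
            namespace="molecular_function",
            top_level_term=terms[0],
        )
        for rid in sorted(gene_hit_reads)
    ]
    reference = {t: p for t, p in _GO_CATEGORIES}
    return assignments, reference
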