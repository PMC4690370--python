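"""End-to-end orchestration: simulate -> diff -> effects -> methylome -> loci.

Each stage writes its machine-readable reports into the output directory;
logging goes to stderr with stage tags, and the effective configuration is
echoed into the run directory so any report bundle is reproducible from its
own record.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .diff import call_variants, variants_table, write_vcf
from .effects import classify, effects_table, flanking_repeat, write_summary_json
from .loci import intergenic_gaps, scan_0a_boxes, zero_a_box_table
from .methylome import context_mean_ipd, methylome_report, welch_t
from .records import write_fasta, write_gff3
from .synthetic import (
    DEFAULT_MOTIFS,
    KineticsModel,
    generate_reference,
    plant_variants,
    simulate_kinetics,
    table1_profile,
    write_truth_table,
    write_truth_vcf,
)

logger = logging.getLogger("straindelta")


@dataclass
class PipelineConfig:
    """Tunable parameters of a full pipeline run."""

    k: int = 31
    qv_call_threshold: float = 30.0
    overspec_min_count: int = 30
    zeroa_window: int = 300
    profile: str = "table1"
    seed: int = 42
    kinetics_seed: int = 7
    simulate_kinetics_track: bool = True
    version: str = field(default=__version__)

    def __post_init__(self) -> None:
        if min(self.k, self.zeroa_window, self.overspec_min_count) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.qv_call_threshold <= 0:
            raise ValueError("qv_call_threshold must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        known.pop("version", None)
        return cls(**known)


def _echo_config(config: PipelineConfig, outdir: Path) -> None:
    (outdir / "config.yaml").write_text(yaml.safe_dump(asdict(config)))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on the configured synthetic profile.

    Produces the variant VCF and report table, class-count and repeat
    JSONs, the per-motif methylome table, context-IPD/Welch JSON, 0A-box and
    intergenic-gap tables, and a human-readable summary.  Returns the
    summary dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _echo_config(config, outdir)
    summary: dict = {"version": config.version}

    logger.info("[simulate] generating profile %r (seed %d)", config.profile,
                config.seed)
    if config.profile != "table1":
        raise ValueError(f"unknown simulation profile {config.profile!r}")
    profile = table1_profile(seed=config.seed)
    genome, annotations = generate_reference(profile)
    reference, mutant, truths = plant_variants(genome, annotations, profile)
    write_fasta([reference], outdir / "reference.fasta")
    write_fasta([mutant], outdir / "mutant.fasta")
    write_gff3(annotations, reference.id, outdir / "reference.gff3")
    write_truth_vcf(truths, reference, outdir / "truth.vcf")
    write_truth_table(truths, outdir / "truth.tsv")
    summary["n_truth_variants"] = len(truths)

    logger.info("[diff] calling variants (k=%d)", config.k)
    calls = call_variants(reference, mutant, k=config.k)
    write_vcf(calls, reference, outdir / "variants.vcf")
    variants_table(calls).to_csv(outdir / "variants.tsv", sep="\t", index=False)
    summary["n_variants"] = len(calls)
    summary["n_substitutions"] = sum(
        1 for c in calls if c.var_type == "substitution"
    )

    logger.info("[effects] classifying %d calls", len(calls))
    effects = [classify(call, annotations, reference) for call in calls]
    effects_table(effects, annotations).to_csv(
        outdir / "effects.tsv", sep="\t", index=False
    )
    deletions = [c for c in calls if c.var_type == "deletion"]
    repeat = (
        flanking_repeat(reference, deletions[0], annotations) if deletions else None
    )
    write_summary_json(effects, outdir / "effects_summary.json", repeat)
    summary["class_counts"] = {
        cls: count
        for cls, count in json.loads(
            (outdir / "effects_summary.json").read_text()
        )["class_counts"].items()
        if count
    }
    if repeat is not None:
        summary["repeat_flanked_deletions"] = 1
        summary["repeat_length"] = repeat.repeat_length

    if config.simulate_kinetics_track:
        logger.info("[methylome] simulating kinetics (seed %d)",
                    config.kinetics_seed)
        track = simulate_kinetics(
            reference, KineticsModel(), DEFAULT_MOTIFS, seed=config.kinetics_seed
        )
        track.write_tsv(outdir / "kinetics.tsv")
        report = methylome_report(
            reference, DEFAULT_MOTIFS, track, config.qv_call_threshold
        )
        report.to_csv(outdir / "methylome.tsv", sep="\t", index=False)
        contexts = {}
        for context in ("C_other", "CG_firstC", "CGCG_firstC", "CGCG_secondC"):
            n, mean, sd = context_mean_ipd(reference, track, context)
            contexts[context] = {"n": n, "mean": mean, "sd": sd}
        welch = welch_t(
            (
                contexts["CGCG_firstC"]["n"],
                contexts["CGCG_firstC"]["mean"],
                contexts["CGCG_firstC"]["sd"],
            ),
            (
                contexts["C_other"]["n"],
                contexts["C_other"]["mean"],
                contexts["C_other"]["sd"],
            ),
        )
        (outdir / "context_ipd.json").write_text(
            json.dumps(
                {
                    "contexts": contexts,
                    "welch_CGCG_firstC_vs_C_other": {
                        "t": welch.t_statistic,
                        "df": welch.degrees_freedom,
                        "p_two_sided": welch.p_two_sided,
                    },
                },
                indent=2,
            )
            + "\n"
        )
        summary["welch_p_CGCG_vs_C"] = welch.p_two_sided
    else:
        logger.warning("[methylome] no kinetics track; stage skipped")

    logger.info("[loci] 0A-box scan (window %d) and gap report",
                config.zeroa_window)
    hits = scan_0a_boxes(reference, annotations, config.zeroa_window)
    zero_a_box_table(hits).to_csv(outdir / "zeroa_boxes.tsv", sep="\t", index=False)
    intergenic_gaps(annotations).to_csv(outdir / "gaps.tsv", sep="\t", index=False)
    summary["n_0a_box_hits"] = len(hits)

    lines = [f"straindelta {config.version} pipeline summary"]
    lines.append(f"truth variants planted: {summary['n_truth_variants']}")
    lines.append(
        f"variants called: {summary['n_variants']} "
        f"({summary['n_substitutions']} substitutions)"
    )
    lines.append(f"class counts: {summary['class_counts']}")
    if "repeat_length" in summary:
        lines.append(
            f"repeat-flanked deletion: repeat length {summary['repeat_length']}"
        )
    if "welch_p_CGCG_vs_C" in summary:
        lines.append(
            "Welch p (CGCG first C vs background C): "
            f"{summary['welch_p_CGCG_vs_C']:.3g}"
        )
    lines.append(f"0A-box hits within {config.zeroa_window} bp: {len(hits)}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    logger.info("[done] reports in %s", outdir)
    return summary
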