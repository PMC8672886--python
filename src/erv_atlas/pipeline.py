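"""End-to-end orchestration: simulate -> detect -> classify/name -> date ->
distribution stats -> protein annotation -> expression integration.

Stages are plain library calls executed in dependency order; every run
writes a manifest (config hash, seed, package version) so that a rerun
with identical config and inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dating, detect, distribution, expression, io, naming, proteins, simulate

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """All stage parameters with their published defaults inline.

    report_threshold 250 / high-confidence 300 (detector score floor and
    flag), dating filters min_score 300 and min_ltr 100 bp, substitution
    rate 1.46e-8 subs/site/yr, expression thresholds TPM > 100 and
    FPKM > 1, log2FC >= 1, cis window 10 kb, trans |R| > 0.85 at
    p < 0.01.
    """

    out_dir: str = "erv_run"
    seed: int = 0
    genome_fasta: str | None = None      # input genome; None -> simulate
    stages: tuple[str, ...] = ("simulate", "detect", "classify", "date", "stats")
    # simulation
    n_elements: int = 20
    genome_length: int = 10_000_000
    n_chroms: int = 2
    gc_fraction: float = 0.384
    max_age_mya: float = 2.0
    # detection
    min_identity: float = 0.85
    report_threshold: float = 250.0
    high_confidence_threshold: float = 300.0
    # dating
    rate: float = 1.46e-8
    dating_model: str = "p"
    dating_min_score: float = 300.0
    dating_min_ltr: int = 100
    # classification
    class_min_identity: float = 0.6
    # expression
    tpm_threshold: float = 100.0
    fpkm_threshold: float = 1.0
    min_log2fc: float = 1.0
    cis_window: int = 10_000
    trans_r_min: float = 0.85
    trans_p_max: float = 0.01


DEFAULT_STRUCTURES = (
    "LTR-gag-pol-env-LTR",
    "LTR-pol-LTR",
    "LTR-LTR",
    "LTR-gag-pol-LTR",
)


def default_benchmark_specs(
    n: int, max_age_mya: float, seed: int, min_ltr: int = 300
) -> list[simulate.ElementSpec]:
    """The default simulated benchmark cohort.

    Ages uniform in [0, max_age], LTRs 300-800 bp, a structure mix
    dominated by gene-bearing elements, classes cycled over the six
    groups, canonical Env/Gag motif payloads on complete elements.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        structure = DEFAULT_STRUCTURES[i % len(DEFAULT_STRUCTURES)]
        payload: tuple[str, ...] = ()
        if "env" in structure:
            payload = ("furin", "isd_q", "cxxc", "cx6cc", "tm")
        elif "gag" in structure:
            payload = ("zf_cchc",)
        specs.append(
            simulate.ElementSpec(
                structure_category=structure,
                age_mya=float(rng.uniform(0, max_age_mya)),
                ltr_length=int(rng.integers(min_ltr, 801)),
                internal_length=int(rng.integers(3000, 8001)),
                class_label=simulate.CLASS_LABELS[i % len(simulate.CLASS_LABELS)],
                motif_payload=payload,
                strand="+",
                tsd_length=4,
            )
        )
    return specs


def simulate_stage(cfg: RunConfig):
    chrom_len = cfg.genome_length // cfg.n_chroms
    genome = {
        f"chr{i + 1}": simulate.generate_background(
            chrom_len, cfg.gc_fraction, seed=cfg.seed * 97 + i
        )
        for i in range(cfg.n_chroms)
    }
    specs = default_benchmark_specs(cfg.n_elements, cfg.max_age_mya, seed=cfg.seed + 1)
    return simulate.plant_elements(genome, specs, min_gap=20_000, seed=cfg.seed + 2,
                                   rate=cfg.rate)


def match_calls_to_truth(elements, truth, min_overlap_frac: float = 0.5):
    """Greedy 1:1 matching of calls to truth by reciprocal overlap."""
    matches = []
    used = set()
    for el in elements:
        best, best_ov = None, 0.0
        for ti, rec in enumerate(truth):
            if ti in used or rec.chrom != el.chrom:
                continue
            ov = min(el.end, rec.end) - max(el.start, rec.start)
            frac = ov / max(min(el.end - el.start, rec.end - rec.start), 1)
            if ov > 0 and frac >= min_overlap_frac and frac > best_ov:
                best, best_ov = ti, frac
        if best is not None:
            used.add(best)
            matches.append((el, truth[best]))
    tp = len(matches)
    recall = tp / len(truth) if truth else float("nan")
    precision = tp / len(elements) if elements else float("nan")
    return matches, recall, precision


def run_characterization(config: RunConfig) -> dict:
    """Execute the enabled stages and return the run report.

    A failing stage aborts with the stage named; partial outputs written
    before the failure are retained in the output directory.
    """
    out = io.ensure_dir(config.out_dir)
    report: dict = {"config": asdict(config), "version": __version__}
    cfg_hash = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    report["config_hash"] = cfg_hash

    genome: dict[str, str] = {}
    truth: list[simulate.TruthRecord] = []
    elements: list[detect.ErvElement] = []

    stage = "init"
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            genome, truth = simulate_stage(config)
            io.write_fasta(genome, out / "genome.fasta")
            io.write_truth_bed(truth, out / "truth.bed")
            io.write_truth_table(truth, out / "truth.tsv")
            report["simulate"] = {"n_planted": len(truth),
                                  "genome_bp": sum(map(len, genome.values()))}
        elif config.genome_fasta:
            genome = io.read_fasta(config.genome_fasta)

        if "detect" in config.stages:
            stage = "detect"
            if not genome or not any(genome.values()):
                raise ValueError("empty genome")
            params = detect.DetectorParams(min_identity=config.min_identity)
            for chrom in sorted(genome):
                elements.extend(
                    detect.detect_elements(
                        genome[chrom], chrom=chrom, params=params,
                        report_threshold=config.report_threshold,
                    )
                )
            report["detect"] = {"n_elements": len(elements),
                                "n_high_confidence": sum(e.high_confidence for e in elements)}
            if truth:
                _, recall, precision = match_calls_to_truth(elements, truth)
                report["detect"]["recall"] = recall
                report["detect"]["precision"] = precision

        if "classify" in config.stages:
            stage = "classify"
            for el in elements:
                if "pol" in el.genes:
                    a, b = el.genes["pol"]
                    label, ident = naming.assign_class_by_reference(
                        genome[el.chrom][a:b], simulate.REFERENCE_RT_PANEL,
                        min_identity=config.class_min_identity,
                    )
                    el.class_label = label
            naming.assign_names(elements)
            census = naming.structure_census(elements) if elements else None
            if census is not None:
                census.to_csv(out / "structure_census.tsv", sep="\t", index=False)
                report["classify"] = {
                    "census": census.to_dict("records"),
                    "both_ltr_fraction": census.attrs.get("both_ltr_fraction"),
                }
            io.write_bed(elements, out / "elements.bed")
            io.write_gff3(elements, out / "elements.gff3")
            io.write_score_sidecar(elements, out / "elements_scores.tsv")

        if "date" in config.stages:
            stage = "date"
            def ltr_seqs(el):
                return (
                    genome[el.chrom][el.ltr5[0]:el.ltr5[1]] if el.ltr5 else "",
                    genome[el.chrom][el.ltr3[0]:el.ltr3[1]] if el.ltr3 else "",
                )
            table, summary = dating.dating_cohort(
                elements, seq_by_element=ltr_seqs, rate=config.rate,
                model=config.dating_model, min_score=config.dating_min_score,
                min_ltr=config.dating_min_ltr,
            )
            table.to_csv(out / "dating.tsv", sep="\t", index=False)
            report["date"] = summary

        if "stats" in config.stages:
            stage = "stats"
            counts = {c: sum(e.chrom == c for e in elements) for c in genome}
            lengths = {c: len(s) / 1e6 for c, s in genome.items()}
            gc = {
                c: 100.0 * (s.count("G") + s.count("C")) / max(len(s), 1)
                for c, s in genome.items()
            }
            tbl = distribution.chromosome_table(counts, lengths, gc)
            tbl.to_csv(out / "chrom_stats.tsv", sep="\t", index=False)
            report["stats"] = {"n_chroms": len(tbl),
                               "n_enriched": int((tbl.direction == "enriched").sum())}

        if "protein" in config.stages:
            stage = "protein"
            annos = []
            for el in elements:
                if "env" not in el.genes:
                    continue
                a, b = el.genes["env"]
                orfs = proteins.find_orfs(genome[el.chrom][a:b], min_len_aa=100)
                if not orfs:
                    continue
                ann = proteins.annotate_env(orfs[0].protein)
                annos.append({"element_id": el.element_id,
                              "architecture_valid": ann.architecture_valid,
                              "furin": ann.furin_site,
                              "isd_suppressive": None if ann.isd is None else ann.isd.suppressive})
            report["protein"] = {"n_env_annotated": len(annos), "annotations": annos}

        if "express" in config.stages:
            stage = "express"
            ids = [e.element_id for e in elements] or [f"e{i}" for i in range(10)]
            genes_ids = [f"gene{i}" for i in range(20)]
            conditions = ("bud", "28hpf", "2dpf", "5dpf")
            spec_map = {
                eid: (conditions[i % len(conditions)],)
                for i, eid in enumerate(ids[: max(4, len(ids) // 2)])
            }
            trans = [
                (eid, genes_ids[i], 0.99)
                for i, eid in enumerate(ids[len(spec_map):][: len(genes_ids)])
            ]
            design = simulate.ExpressionDesign(
                conditions=conditions, specificity_map=spec_map,
                trans_pairs=trans, seed=config.seed + 5, corr_amplitude=1.5,
            )
            lengths = {eid: 1000 for eid in ids + genes_ids}
            counts, sheet, lens = simulate.simulate_expression(
                ids, genes_ids, lengths, design
            )
            counts.to_csv(out / "expression_counts.tsv", sep="\t")
            sheet.to_csv(out / "expression_samples.tsv", sep="\t", index=False)
            lens.to_csv(out / "expression_lengths.tsv", sep="\t")
            tpm = expression.normalize_counts(counts, lens, "TPM")
            sets = expression.expressed_set(tpm, sheet, threshold=config.tpm_threshold)
            specific, overlap = expression.specificity_and_overlap(sets)
            overlap.to_csv(out / "expression_overlap.tsv", sep="\t", index=False)
            recovered = sum(
                eid in specific.get(cs[0], set()) for eid, cs in spec_map.items()
            )
            log = np.log2(counts + 1)
            trans_table = expression.trans_partners(
                log.loc[ids], log.loc[genes_ids],
                r_min=config.trans_r_min, p_max=config.trans_p_max,
            )
            trans_table.to_csv(out / "trans_partners.tsv", sep="\t", index=False)
            called = set(zip(trans_table[trans_table.trans].element_id,
                             trans_table[trans_table.trans].gene_id))
            planted_trans = {(e, g) for e, g, _ in trans}
            report["express"] = {
                "specificity_recall": recovered / len(spec_map) if spec_map else None,
                "trans_recall": (
                    len(called & planted_trans) / len(planted_trans)
                    if planted_trans else None
                ),
                "n_trans_called": len(called),
            }
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {"version": __version__, "config_hash": cfg_hash, "seed": config.seed,
                "stages": list(config.stages)}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return report


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig(**data)
    if "stages" in data:
        cfg.stages = tuple(data["stages"])
    return cfg
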