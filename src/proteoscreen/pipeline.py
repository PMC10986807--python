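"""End-to-end orchestration: simulate -> preprocess -> score -> DE ->
screen -> replicate -> enrich -> network, from a single config.

Every stage writes its artifact into the output directory; a manifest
JSON records the config, master seed, per-stage counts (the analysis
funnel: measured -> DE-retained -> stage-1 -> stage-2 -> replicated ->
module) and a content hash per artifact, so a re-run with the same
config and seed is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import subseed
from .association import (CONFOUNDERS, final_hits, replicate,
                          replicated_hits, results_to_frame, run_screen,
                          technical_correlation, write_results)
from .clinical import derive_scores, read_clinical, write_clinical
from .diamond import grid_search, write_module
from .diffexpr import prioritize, write_results as write_de_results, write_retained
from .enrichment import (GeneSetLibrary, enrich, read_gmt, rows_to_frame,
                         write_gmt, write_rows)
from .matrix import ProteinMatrix
from .preprocess import preprocess
from .simulate import (CRP_PROTEIN, SimConfig, generate_gene_sets,
                       generate_interactome, generate_study,
                       read_interactome, write_interactome)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one analysis run needs, from inputs to grids."""

    out_dir: str = "run_output"
    rng_seed: int = 0
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    # real-input paths (used when simulate is False)
    discovery_matrix: str | None = None
    validation_matrix: str | None = None
    discovery_clinical: str | None = None
    validation_clinical: str | None = None
    interactome: str | None = None
    gene_sets: str | None = None
    # stage parameters
    de_alpha: float = 0.05
    screen_alpha: float = 0.05
    stage1_adjusted: bool = False
    imputation_method: str = "knn"
    imputation_k: int = 5
    max_missing: float = 0.5
    enrichment_alpha: float = 0.05
    n_grid: list[int] = field(default_factory=lambda: list(range(25, 201, 25)))
    alpha_grid: list[int] = field(default_factory=lambda: list(range(1, 11)))
    # simulated-interactome shape
    interactome_nodes: int = 1500
    interactome_attachment: int = 3
    neighbourhood_size: int = 25
    n_gene_sets: int = 50
    gene_set_size: tuple[int, int] = (10, 80)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        cfg = cls(sim=sim, **raw)
        if "rng_seed" in raw:
            cfg.sim.rng_seed = cfg.rng_seed
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gene_set_size"] = list(self.gene_set_size)
        return d


def validate_inputs(matrix: ProteinMatrix, clinical: pd.DataFrame) -> list[dict]:
    """Consistency diagnostics; exclusion is applied downstream, not here.

    Checks duplicate ids, matrix/clinical patient agreement, timepoint
    completeness (cases need serum at baseline and month 3 and outcomes
    at baseline, 3 and 6 months) and clinical component ranges.
    """
    diags: list[dict] = []
    if clinical.index.duplicated().any():
        dup = sorted(set(clinical.index[clinical.index.duplicated()]))
        diags.append({"level": "fatal", "code": "duplicate_patient_id",
                      "items": dup})
    meta = matrix.sample_meta
    case_meta = meta[meta["role"] == "case"]
    mat_patients = set(case_meta["patient_id"])
    clin_patients = set(clinical.index)
    only_matrix = sorted(mat_patients - clin_patients)
    if only_matrix:
        diags.append({"level": "warning", "code": "no_clinical_record",
                      "items": only_matrix})
    only_clin = sorted(clin_patients - mat_patients)
    if only_clin:
        diags.append({"level": "exclude", "code": "no_serum_samples",
                      "items": only_clin})

    by_tp = case_meta.groupby("patient_id")["timepoint"].agg(set)
    incomplete_serum = sorted(
        p for p in (mat_patients & clin_patients)
        if by_tp.get(p, set()) != {"baseline", "month3"})
    if incomplete_serum:
        diags.append({"level": "exclude", "code": "missing_serum_timepoint",
                      "items": incomplete_serum})

    needed = [f"{c}_{tp}" for tp in ("baseline", "month3", "month6")
              for c in ("tjc28", "sjc28", "vas_gh", "hscrp")]
    have = [c for c in needed if c in clinical.columns]
    absent_cols = sorted(set(needed) - set(have))
    if absent_cols:
        diags.append({"level": "fatal", "code": "missing_outcome_columns",
                      "items": absent_cols})
    elif len(clinical):
        incomplete = clinical[have].isna().any(axis=1)
        if incomplete.any():
            diags.append({"level": "exclude",
                          "code": "incomplete_outcome_measures",
                          "items": sorted(clinical.index[incomplete])})
        bad_range = []
        for tp in ("baseline", "month3", "month6"):
            sub = clinical.dropna(subset=[f"tjc28_{tp}", f"hscrp_{tp}"])
            bad = ((sub[f"tjc28_{tp}"] < 0) | (sub[f"tjc28_{tp}"] > 28)
                   | (sub[f"sjc28_{tp}"] < 0) | (sub[f"sjc28_{tp}"] > 28)
                   | (sub[f"vas_gh_{tp}"] < 0) | (sub[f"vas_gh_{tp}"] > 100)
                   | (sub[f"hscrp_{tp}"] <= 0))
            bad_range.extend(sub.index[bad])
        if bad_range:
            diags.append({"level": "fatal", "code": "component_out_of_range",
                          "items": sorted(set(bad_range))})
    return diags


def _excluded_patients(diags: list[dict]) -> set[str]:
    out: set[str] = set()
    for d in diags:
        if d["level"] == "exclude":
            out.update(d["items"])
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Any stage failure raises with the stage name; artifacts written by
    earlier stages are preserved in the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "seed": config.rng_seed,
        "stages": {},
        "artifacts": {},
    }
    stage = "configure"
    try:
        # ---- inputs ----------------------------------------------------
        stage = "simulate" if config.simulate else "load_inputs"
        if config.simulate:
            config.sim.rng_seed = config.rng_seed
            study = generate_study(config.sim)
            dmat, dclin = study.discovery_matrix, study.discovery_clinical
            vmat, vclin = study.validation_matrix, study.validation_clinical
            truth = study.truth
            seeds_for_graph = sorted({e.protein_id for e in truth.effects})
            graph = generate_interactome(
                config.interactome_nodes, config.interactome_attachment,
                seeds_for_graph, rng_seed=subseed(config.rng_seed, "interactome"),
                protein_ids=truth.protein_ids,
                neighbourhood_size=config.neighbourhood_size)
            enriched_nodes = (graph.graph["planted_seeds"]
                              + graph.graph["planted_neighbourhood"])
            library = GeneSetLibrary(
                sets={k: set(v) for k, v in generate_gene_sets(
                    graph, config.n_gene_sets, tuple(config.gene_set_size),
                    enriched_nodes,
                    rng_seed=subseed(config.rng_seed, "genesets")).items()},
                source_tag="synthetic")
            dmat.to_tsv(out / "discovery_matrix.tsv")
            vmat.to_tsv(out / "validation_matrix.tsv")
            write_clinical(dclin, out / "discovery_clinical.tsv")
            write_clinical(vclin, out / "validation_clinical.tsv")
            write_interactome(graph, out / "interactome.tsv")
            write_gmt(library, out / "gene_sets.gmt")
            truth.to_json(out / "truth.json")
        else:
            for name in ("discovery_matrix", "validation_matrix",
                         "discovery_clinical", "validation_clinical",
                         "interactome", "gene_sets"):
                p = getattr(config, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(
                        f"simulation disabled and input {name!r} missing: {p}")
            dmat = ProteinMatrix.from_tsv(config.discovery_matrix)
            vmat = ProteinMatrix.from_tsv(config.validation_matrix)
            dclin = read_clinical(config.discovery_clinical)
            vclin = read_clinical(config.validation_clinical)
            graph = read_interactome(config.interactome)
            library = read_gmt(config.gene_sets)

        # ---- preprocess (cohorts processed independently) --------------
        stage = "preprocess"
        dmat, dsum = preprocess(dmat, config.imputation_method,
                                config.imputation_k, config.max_missing)
        vmat, vsum = preprocess(vmat, config.imputation_method,
                                config.imputation_k, config.max_missing)
        dmat.to_tsv(out / "discovery_matrix_proc.tsv")
        vmat.to_tsv(out / "validation_matrix_proc.tsv")
        manifest["stages"]["preprocess"] = {"discovery": dsum,
                                            "validation": vsum}

        # ---- clinical scoring and validation ---------------------------
        stage = "score"
        dclin = derive_scores(dclin)
        vclin = derive_scores(vclin)
        diags_d = validate_inputs(dmat, dclin)
        diags_v = validate_inputs(vmat, vclin)
        fatal = [d for d in diags_d + diags_v if d["level"] == "fatal"]
        if fatal:
            raise ValueError(f"fatal input diagnostics: {fatal}")
        dclin = dclin.drop(index=sorted(_excluded_patients(diags_d)))
        vclin = vclin.drop(index=sorted(_excluded_patients(diags_v)))
        write_clinical(dclin, out / "discovery_clinical_scored.tsv")
        write_clinical(vclin, out / "validation_clinical_scored.tsv")
        manifest["stages"]["validate_inputs"] = {
            "discovery": diags_d, "validation": diags_v,
            "n_discovery_patients": int(len(dclin)),
            "n_validation_patients": int(len(vclin))}

        # ---- differential expression -----------------------------------
        stage = "diff_expression"
        retained, de_results, n_up, n_down = prioritize(dmat, config.de_alpha)
        write_de_results(de_results, out / "de_results.tsv")
        write_retained(retained, out / "de_retained.txt")
        manifest["stages"]["diff_expression"] = {
            "n_proteins": dmat.n_proteins, "n_retained": len(retained),
            "n_up": n_up, "n_down": n_down, "alpha": config.de_alpha}

        # ---- two-stage screen ------------------------------------------
        stage = "screen"
        results = run_screen(dmat, dclin, retained,
                             alpha=config.screen_alpha,
                             stage1_adjusted=config.stage1_adjusted)
        write_results(results, out / "associations.tsv")
        hits = final_hits(results, config.screen_alpha)
        stage1_hits = {(r.protein_id, r.family) for r in results
                       if r.stage == "univariate" and r.ok
                       and np.isfinite(r.p_adj)
                       and r.p_adj < config.screen_alpha}
        manifest["stages"]["screen"] = {
            "n_models_stage1": sum(1 for r in results
                                   if r.stage == "univariate"),
            "n_stage1_hits": len(stage1_hits),
            "n_stage2_hits": len(hits),
            "hit_proteins": sorted({r.protein_id for r in hits})}

        # ---- replication ------------------------------------------------
        stage = "replicate"
        rep_rows = replicate(hits, vmat, vclin)
        write_results(rep_rows, out / "replication.tsv")
        reps = replicated_hits(rep_rows)
        manifest["stages"]["replicate"] = {
            "n_tested": len(rep_rows),
            "n_replicated": len(reps),
            "replicated_proteins": sorted({r.protein_id for r in reps})}

        # ---- technical correlation of CRP -------------------------------
        stage = "technical_correlation"
        tech = {}
        if CRP_PROTEIN in dmat.protein_ids:
            for tp, label in (("baseline", "baseline"), ("month3", "month3")):
                sel = ((dmat.sample_meta["role"] == "case")
                       & (dmat.sample_meta["timepoint"] == tp))
                pats = dmat.sample_meta.loc[sel, "patient_id"]
                keep = pats.isin(dclin.index).to_numpy()
                swath = dmat.values.loc[sel, CRP_PROTEIN].to_numpy()[keep]
                elisa = dclin.loc[pats[keep], f"hscrp_{tp}"].to_numpy(float)
                r, ci, p = technical_correlation(swath, elisa)
                tech[label] = {"r": r, "ci": list(ci), "p": p,
                               "n": int(keep.sum())}
        manifest["stages"]["technical_correlation"] = tech

        # ---- enrichment --------------------------------------------------
        stage = "enrichment"
        background = set(graph.nodes)
        query = sorted({r.protein_id for r in hits} & background)
        dropped_seeds = sorted({r.protein_id for r in hits} - background)
        if dropped_seeds:
            log.warning("hit proteins absent from interactome dropped: %s",
                        dropped_seeds)
        enr_rows = []
        validation_genes: set[str] = set()
        if query:
            enr_rows = enrich(set(query), library, background)
            write_rows(enr_rows, out / "enrichment.tsv")
            sig = [r for r in enr_rows if r.p_adj < config.enrichment_alpha]
            top = sig if sig else enr_rows[:1]
            for row in top:
                validation_genes |= ({g.upper() for g in
                                      library.sets[row.set_name]} & background)
            (out / "validation_genes.txt").write_text(
                "".join(f"{g}\n" for g in sorted(validation_genes)))
        manifest["stages"]["enrichment"] = {
            "n_query": len(query), "n_sets": len(library),
            "dropped_seeds": dropped_seeds,
            "n_significant_sets": sum(
                1 for r in enr_rows if r.p_adj < config.enrichment_alpha),
            "n_validation_genes": len(validation_genes)}

        # ---- subnetwork --------------------------------------------------
        stage = "diamond_network"
        net = {}
        if query and validation_genes:
            best, table = grid_search(graph, set(query), config.n_grid,
                                      config.alpha_grid, validation_genes,
                                      background)
            write_module(best, out / "module.tsv")
            table.to_csv(out / "grid_table.tsv", sep="\t", index=False,
                         float_format="%.6g")
            hubs = best.hub_ranking(graph)
            hubs.to_csv(out / "module_hubs.tsv", sep="\t", index=False)
            net = {"best_n": int(best.n_requested),
                   "best_alpha": int(best.alpha),
                   "validation_p": float(best.validation_p),
                   "module_size": len(best.nodes),
                   "top_hub": str(hubs.iloc[0]["node"]) if len(hubs) else None}
        manifest["stages"]["diamond_network"] = net

        # ---- summary report ---------------------------------------------
        stage = "report"
        _write_summary(hits, rep_rows, out / "summary.tsv")
        for p in sorted(out.iterdir()):
            if p.is_file() and p.name != "manifest.json":
                manifest["artifacts"][p.name] = _sha256(p)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    return manifest


def _write_summary(hits, rep_rows, path: Path) -> None:
    """Human-readable hit table: effect (95% CI) and adjusted p per hit."""
    rep_by_key = {(r.protein_id, r.outcome, r.protein_timepoint,
                   r.outcome_timepoint): r for r in rep_rows}
    rows = []
    for h in hits:
        rep = rep_by_key.get((h.protein_id, h.outcome, h.protein_timepoint,
                              h.outcome_timepoint))
        rows.append({
            "protein": h.protein_id,
            "outcome": h.outcome,
            "model": h.model,
            "protein_timepoint": h.protein_timepoint,
            "outcome_timepoint": h.outcome_timepoint,
            "effect_95ci": f"{h.effect:.2f} ({h.ci_low:.2f}, {h.ci_high:.2f})",
            "p_adj": f"{h.p_adj:.3g}",
            "replication": (rep.note if rep is not None and rep.ok
                            else "untestable" if rep is not None else ""),
        })
    pd.DataFrame(rows, columns=["protein", "outcome", "model",
                                "protein_timepoint", "outcome_timepoint",
                                "effect_95ci", "p_adj",
                                "replication"]).to_csv(path, sep="\t",
                                                       index=False)


__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]
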