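"""End-to-end orchestration of the comparative-gland study.

``run_study`` executes the whole analysis on an in-memory synthetic study and
returns a report; ``run_pipeline`` is the file-based variant driven by a
config mapping (paths, stage toggles, seeds) that writes every stage's output
with a provenance JSON.  ``validate_inputs`` checks the file dialects up
front with line-numbered diagnostics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from . import coexpr, diffsim, isa as isa_mod, normalize, orthology, preservation, semsim, specificity
from .io import load_study_dir, write_expression, write_study
from .synthdata import SynthConfig, SynthStudy, generate_study
from .types import CrossExprError, ExpressionMatrix

log = logging.getLogger("crossexpr")


# ---------------------------------------------------------------------------
# in-memory pipeline
# ---------------------------------------------------------------------------


@dataclass
class StudyReport:
    """Collected outputs of a full in-memory run."""

    ortholog_matrix: ExpressionMatrix
    normalized: ExpressionMatrix
    network: coexpr.CoexpressionNetwork
    soft_threshold: coexpr.SoftThresholdReport
    preservation: dict[str, list[preservation.PreservationResult]]
    core_module: int
    si_reports: dict[str, diffsim.SimilarityReport]
    si_tests: pd.DataFrame
    specificity: pd.DataFrame
    semsim: dict[str, semsim.SemSimResult]
    isa_modules: list
    extras: dict = field(default_factory=dict)


def normalized_ortholog_matrix(study: SynthStudy) -> tuple[ExpressionMatrix, dict]:
    """Orthology -> TPM -> log2/QN -> batch-free matrix from raw study files."""
    anchor = study.config.anchor_species
    species = list(study.config.species)
    rbh = {}
    for sp in species:
        if sp == anchor:
            continue
        ab = orthology.HitTable(study.hits[(anchor, sp)], anchor, sp)
        ba = orthology.HitTable(study.hits[(sp, anchor)], sp, anchor)
        rbh[sp] = orthology.reciprocal_best_hits(ab, ba)
    oset = orthology.anchor_one_to_one(rbh, anchor)
    tpms = {
        sp: normalize.compute_tpm(study.counts[sp], study.lengths[sp])
        for sp in species
    }
    matrix_tpm = orthology.build_ortholog_matrix(oset, tpms)
    logqn = normalize.log_quantile(matrix_tpm)
    batchfree = normalize.batch_correct(logqn)
    return batchfree, {"ortholog_set": oset, "tpm_matrices": tpms, "matrix_tpm": matrix_tpm}


def run_study(
    study: SynthStudy,
    n_perm_preservation: int = 100,
    si_reps: int = 100,
    ss_perm: int = 1000,
    top_k: int = 500,
    seed: int = 0,
) -> StudyReport:
    """The full analysis on a generated study (see module docstring).

    The reference co-expression network is built from venom-gland samples of
    the ortholog matrix; preservation is evaluated in silk and salivary
    samples; SI compares venom vs silk and venom vs salivary across two
    species; semantic similarity compares the tissues' enriched-term sets.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(8)]
    matrix, extras = normalized_ortholog_matrix(study)
    species = list(study.config.species)

    # --- reference network on venom samples --------------------------------
    venom = matrix.subset_samples(matrix.sample_ids_where(tissue="venom_gland"))
    sd = venom.values.std(axis=1)
    venom = venom.subset_genes(list(venom.values.index[sd > 0]))
    # candidate powers start at the standard unsigned-network recommendation
    # for this sample-size regime; smaller powers under-separate modules
    sft = coexpr.pick_soft_threshold(venom, powers=[6, 7, 8, 9, 10, 12])
    net = coexpr.adjacency_tom(venom, beta=sft.chosen_power)
    labels = coexpr.detect_modules(net, venom)
    net.module_labels = labels
    net.eigengenes, net.kme = coexpr.eigengenes_kme(venom, labels)

    # the "core" module: the one best covering the venom+silk shared program
    core_truth = set(study.truth.programs["venom_silk_core"]["anchor_genes"])
    overlap = {
        mod: len(core_truth & set(labels.index[labels == mod]))
        for mod in sorted(set(labels) - {0})
    }
    core_module = max(overlap, key=lambda k: (overlap[k], -k)) if overlap else 0

    pres: dict[str, list[preservation.PreservationResult]] = {}
    for tissue in ("silk_gland", "salivary_gland"):
        test = matrix.subset_samples(matrix.sample_ids_where(tissue=tissue))
        pres[tissue] = preservation.module_preservation(
            net, venom, test, n_perm=n_perm_preservation, seed=seeds[0]
        )

    # --- similarity index ---------------------------------------------------
    # each tissue-pair group pools several species pairs, as the violin-plot
    # grouping does; both sides of a pair rotate over species so one species'
    # idiosyncrasies cannot dominate a group
    n_pairs = min(4, max(1, len(species) - 1))
    pairs = [
        (species[k % len(species)], species[(k + 1) % len(species)])
        for k in range(n_pairs)
    ]
    si_reports = {}
    for name, tissue_b in (
        ("venom_vs_silk", "silk_gland"),
        ("venom_vs_salivary", "salivary_gland"),
    ):
        reps_per_pair = max(1, si_reps // len(pairs))
        values: list[float] = []
        for k, (sp_a, sp_b) in enumerate(pairs):
            sub_a = matrix.subset_samples(matrix.sample_ids_where(species=sp_a))
            sub_b = matrix.subset_samples(matrix.sample_ids_where(species=sp_b))
            rep = diffsim.si_resample(
                sub_a,
                "venom_gland",
                sub_b,
                tissue_b,
                n_reps=reps_per_pair,
                seed=seeds[1] + k,
                pair_name=("venom_gland", tissue_b),
            )
            values.extend(rep.si_values)
        si_reports[name] = diffsim.SimilarityReport(
            pair=("venom_gland", tissue_b), si_values=values
        )
    si_tests = diffsim.compare_si_groups(
        {k: v.si_values for k, v in si_reports.items()}
    )

    # --- tissue specificity (focal species, raw TPM) ------------------------
    focal_tpm = extras["tpm_matrices"][species[0]]
    spec = specificity.assign_specific_genes(focal_tpm)

    # --- semantic similarity -------------------------------------------------
    ann = study.annotations
    background = sorted(ann)
    sim = semsim.WangSimilarity(study.dag)
    enriched = {}
    for tissue in ("venom_gland", "silk_gland", "salivary_gland"):
        top = semsim.top_expressed_genes(matrix, tissue, k=min(top_k, matrix.n_genes))
        table = semsim.enrich_terms(
            [g for g in top if g in ann], ann, background, study.dag
        )
        enriched[tissue] = list(table.loc[table["enriched"], "term"])
    sems = {}
    for name, t2 in (("venom_vs_silk", "silk_gland"), ("venom_vs_salivary", "salivary_gland")):
        if enriched["venom_gland"] and enriched[t2]:
            sems[name] = semsim.ss_permutation_test(
                enriched["venom_gland"],
                enriched[t2],
                study.dag.terms,
                study.dag,
                n_perm=ss_perm,
                seed=seeds[2],
                sim=sim,
            )

    # --- ISA ------------------------------------------------------------------
    modules = isa_mod.run_isa(matrix, n_seeds=100, seed=seeds[3])

    report = StudyReport(
        ortholog_matrix=matrix,
        normalized=matrix,
        network=net,
        soft_threshold=sft,
        preservation=pres,
        core_module=core_module,
        si_reports=si_reports,
        si_tests=si_tests,
        specificity=spec,
        semsim=sems,
        isa_modules=modules,
        extras={**extras, "enriched_terms": enriched, "module_labels": labels},
    )
    return report


# ---------------------------------------------------------------------------
# file-based pipeline
# ---------------------------------------------------------------------------


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _provenance(outdir: Path, stage: str, inputs: list[Path], params: Mapping) -> None:
    payload = {
        "stage": stage,
        "version": __version__,
        "inputs": {str(p): _checksum(p) for p in inputs if p.exists()},
        "params": {k: v for k, v in params.items()},
    }
    (outdir / f"{stage}.provenance.json").write_text(json.dumps(payload, indent=1, default=str))


def run_pipeline(config: Mapping) -> dict:
    """File-based pipeline: simulate (optional) then analyse, with provenance.

    ``config`` keys: ``outdir`` (required), ``seed``, ``simulate`` (bool or a
    mapping of SynthConfig overrides), ``study_dir`` (input directory when not
    simulating), and stage parameter blocks ``preservation``, ``si``,
    ``semsim``, ``isa``.  Missing input paths fail before any stage runs.
    """
    if "outdir" not in config:
        raise CrossExprError("config missing 'outdir'")
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    if config.get("simulate", True):
        overrides = config.get("simulate") if isinstance(config.get("simulate"), Mapping) else {}
        cfg = SynthConfig.from_dict({**overrides, "seed": seed})
        study = generate_study(cfg)
        study_dir = outdir / "study"
        write_study(study, study_dir)
        _provenance(outdir, "simulate", [], {"seed": seed})
    else:
        study_dir = Path(config.get("study_dir", ""))
        if not study_dir.is_dir():
            raise CrossExprError(f"study_dir {study_dir} does not exist")
        study = load_study_dir(study_dir)

    report = run_study(
        study,
        n_perm_preservation=int(config.get("preservation", {}).get("n_perm", 100)),
        si_reps=int(config.get("si", {}).get("n_reps", 50)),
        ss_perm=int(config.get("semsim", {}).get("n_perm", 1000)),
        seed=seed,
    )

    # write the headline outputs
    write_expression(report.ortholog_matrix, outdir / "ortholog_matrix.tsv")
    preservation.preservation_table(
        [r for rs in report.preservation.values() for r in rs]
    ).to_csv(outdir / "preservation.tsv", sep="\t", index=False)
    si_rows = []
    for name, rep in report.si_reports.items():
        for i, v in enumerate(rep.si_values):
            si_rows.append({"pair": name, "replicate": i, "si": v})
    pd.DataFrame(si_rows).to_csv(outdir / "si_values.tsv", sep="\t", index=False)
    report.si_tests.to_csv(outdir / "si_tests.tsv", sep="\t", index=False)
    report.specificity.to_csv(outdir / "specificity.tsv", sep="\t", index=False)
    summary = summarize_report(report)
    (outdir / "report.json").write_text(json.dumps(summary, indent=1, default=float))
    _provenance(outdir, "analyse", [study_dir / "metadata.tsv"], {"seed": seed})
    return summary


def summarize_report(report: StudyReport) -> dict:
    """Headline numbers of a run, JSON-serializable."""
    core = report.core_module
    pres = {}
    for tissue, results in report.preservation.items():
        for r in results:
            if r.module == core:
                pres[tissue] = {
                    "z_summary": r.z_summary,
                    "class": preservation.classify_preservation(r.z_summary)
                    if np.isfinite(r.z_summary)
                    else "undefined",
                }
    return {
        "soft_threshold": report.soft_threshold.chosen_power,
        "n_modules": int(len(set(report.network.module_labels) - {0})),
        "core_module": int(core),
        "core_preservation": pres,
        "median_si": {k: v.median_si for k, v in report.si_reports.items()},
        "si_tests": report.si_tests.to_dict(orient="records"),
        "semsim": {
            k: {"observed": v.observed_ss, "p95": v.p95, "significant": v.significant}
            for k, v in report.semsim.items()
        },
        "n_isa_modules": len(report.isa_modules),
    }


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_inputs(paths: Mapping[str, str | Path]) -> list[str]:
    """Schema checks for every declared input file; returns diagnostics.

    Keys select the dialect: ``expression``, ``metadata``, ``lengths``,
    ``hits`` (a file or directory), ``obo``, ``annotations``.  The report is
    a list of human-readable problems with line numbers; empty means clean.
    """
    diags: list[str] = []

    def check_tsv_header(path: Path, expected_first: str) -> None:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != expected_first:
            diags.append(f"{path}:1: first column must be '{expected_first}'")

    for kind, raw in paths.items():
        path = Path(raw)
        if not path.exists():
            diags.append(f"{path}: does not exist")
            continue
        if kind == "expression":
            check_tsv_header(path, "gene_id")
            df = pd.read_csv(path, sep="\t")
            if df.columns[0] == "gene_id" and df["gene_id"].duplicated().any():
                dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
                line = int(df.index[df["gene_id"] == dup][1]) + 2
                diags.append(f"{path}:{line}: duplicate gene id {dup}")
        elif kind == "metadata":
            check_tsv_header(path, "sample_id")
            df = pd.read_csv(path, sep="\t")
            for col in ("species", "tissue", "batch"):
                if col not in df.columns:
                    diags.append(f"{path}:1: missing column '{col}'")
        elif kind == "lengths":
            check_tsv_header(path, "gene_id")
        elif kind == "hits":
            files = sorted(path.glob("*.tsv")) if path.is_dir() else [path]
            for f in files:
                with open(f) as fh:
                    for i, line in enumerate(fh, start=1):
                        n = len(line.rstrip("\n").split("\t"))
                        if n != 12:
                            diags.append(f"{f}:{i}: expected 12 columns, found {n}")
                            break
        elif kind == "obo":
            text = path.read_text()
            if "[Term]" not in text:
                diags.append(f"{path}:1: no [Term] blocks found")
        elif kind == "annotations":
            check_tsv_header(path, "gene_id")
        else:
            diags.append(f"{path}: unknown input kind '{kind}'")
    return diags
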