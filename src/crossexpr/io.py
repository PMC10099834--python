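"""Readers and writers for the package's plain-text formats.

Formats: expression TSV (first column ``gene_id``, one column per sample)
with a sidecar JSON recording the value scale; sample metadata TSV; gene
length TSV; 12-column tab-delimited hit tables (BLAST outfmt-6 dialect);
minimal OBO for the ontology; two-column gene->term annotation TSV; truth
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import networkx as nx
import obonet
import pandas as pd

from .orthology import HitTable
from .synthdata import GoDag, SynthStudy, HIT_COLUMNS
from .types import CrossExprError, ExpressionMatrix


# -- expression matrices ----------------------------------------------------


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    out = m.values.copy()
    out.insert(0, "gene_id", out.index)
    out.to_csv(path, sep="\t", index=False)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"scale": m.scale}))


def read_expression(
    path: str | Path, metadata: pd.DataFrame, scale: str | None = None
) -> ExpressionMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t")
    if values.columns[0] != "gene_id":
        raise CrossExprError(f"{path}: first column must be 'gene_id'")
    values = values.set_index("gene_id")
    if scale is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            scale = json.loads(sidecar.read_text())["scale"]
        else:
            scale = "counts"
    samples = metadata.loc[list(values.columns)]
    return ExpressionMatrix(values=values, samples=samples, scale=scale)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    need = {"sample_id", "species", "tissue", "batch"}
    missing = need - set(meta.columns)
    if missing:
        raise CrossExprError(f"{path}: missing columns {sorted(missing)}")
    return meta.set_index("sample_id")


def write_lengths(lengths: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({"gene_id": lengths.index, "length_bp": lengths.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


def read_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["gene_id", "length_bp"]:
        raise CrossExprError(f"{path}: expected columns gene_id, length_bp")
    return df.set_index("gene_id")["length_bp"]


# -- hit tables -------------------------------------------------------------


def write_hit_table(rows: pd.DataFrame, path: str | Path) -> None:
    rows[list(HIT_COLUMNS)].to_csv(path, sep="\t", index=False, header=False)


def read_hit_table(path: str | Path, query_species: str, subject_species: str) -> HitTable:
    rows = pd.read_csv(path, sep="\t", header=None)
    if rows.shape[1] != len(HIT_COLUMNS):
        raise CrossExprError(
            f"{path}: expected {len(HIT_COLUMNS)} columns, found {rows.shape[1]}"
        )
    rows.columns = list(HIT_COLUMNS)
    return HitTable(rows=rows, query_species=query_species, subject_species=subject_species)


# -- ontology and annotations -----------------------------------------------


def write_obo(dag: GoDag, path: str | Path) -> None:
    """Minimal OBO: [Term] blocks with id, name, is_a and part_of lines."""
    lines = ["format-version: 1.2", ""]
    for term in sorted(dag.graph.nodes):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {dag.name(term)}")
        for parent, rel in sorted(dag.parents(term)):
            if rel == "is_a":
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: part_of {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_obo(path: str | Path) -> GoDag:
    graph = obonet.read_obo(str(path))
    multi = nx.MultiDiGraph()
    for node, data in graph.nodes(data=True):
        multi.add_node(node, name=data.get("name", node))
    for child, parent, key in graph.edges(keys=True):
        multi.add_edge(child, parent, key=key)
    roots = [n for n in multi.nodes if multi.out_degree(n) == 0]
    if len(roots) != 1:
        raise CrossExprError(f"{path}: expected a single root, found {len(roots)}")
    return GoDag(graph=multi, root=roots[0])


def write_annotations(ann: Mapping[str, set[str]], path: str | Path) -> None:
    rows = [(g, t) for g in sorted(ann) for t in sorted(ann[g])]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["gene_id", "term_id"]:
        raise CrossExprError(f"{path}: expected columns gene_id, term_id")
    out: dict[str, set[str]] = {}
    for g, t in zip(df["gene_id"], df["term_id"]):
        out.setdefault(str(g), set()).add(str(t))
    return out


# -- whole studies ----------------------------------------------------------


def write_study(study: SynthStudy, outdir: str | Path) -> None:
    """Write a generated study to a directory of plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_metadata(study.metadata, outdir / "metadata.tsv")
    for sp, m in study.counts.items():
        write_expression(m, outdir / f"counts_{sp}.tsv")
        write_lengths(study.lengths[sp], outdir / f"lengths_{sp}.tsv")
    hitdir = outdir / "hits"
    hitdir.mkdir(exist_ok=True)
    for (a, b), rows in study.hits.items():
        write_hit_table(rows, hitdir / f"{a}__{b}.tsv")
    write_obo(study.dag, outdir / "ontology.obo")
    write_annotations(study.annotations, outdir / "annotations.tsv")
    (outdir / "truth.json").write_text(study.truth.to_json())
    (outdir / "config.json").write_text(json.dumps(study.config.to_dict(), indent=1))


def load_study_dir(indir: str | Path) -> SynthStudy:
    """Rebuild a :class:`SynthStudy` from the files written by write_study."""
    from .synthdata import SynthConfig, TruthRecord

    indir = Path(indir)
    config = SynthConfig.from_dict(json.loads((indir / "config.json").read_text()))
    metadata = read_metadata(indir / "metadata.tsv")
    counts, lengths = {}, {}
    for f in sorted(indir.glob("counts_*.tsv")):
        sp = f.stem.replace("counts_", "")
        counts[sp] = read_expression(f, metadata, scale="counts")
        lengths[sp] = read_lengths(indir / f"lengths_{sp}.tsv")
    hits = {}
    for f in sorted((indir / "hits").glob("*.tsv")):
        a, b = f.stem.split("__")
        hits[(a, b)] = read_hit_table(f, a, b).rows
    dag = read_obo(indir / "ontology.obo")
    annotations = read_annotations(indir / "annotations.tsv")
    raw = json.loads((indir / "truth.json").read_text())
    truth = TruthRecord(
        programs=raw["programs"],
        specific_tissue=raw["specific_tissue"],
        orthogroups=raw["orthogroups"],
        one2one=raw["one2one"],
        batches=raw["batches"],
        similarity_ordering=[tuple(p) for p in raw["similarity_ordering"]],
        latent_factors={k: pd.Series(v) for k, v in raw["latent_factors"].items()},
        program_themes=raw["program_themes"],
    )
    return SynthStudy(
        config=config,
        counts=counts,
        lengths=lengths,
        metadata=metadata,
        hits=hits,
        dag=dag,
        annotations=annotations,
        truth=truth,
    )
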