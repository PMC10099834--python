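"""Synthetic multi-species gland-transcriptome studies with recorded ground truth.

The generator emits everything the comparative pipeline consumes: per-species
count matrices with negative-binomial noise, gene lengths, sample metadata,
pairwise similarity-hit tables from which orthology can be re-derived, a small
GO-style ontology with gene annotations, and a :class:`TruthRecord` describing
the planted structure.

Structure planted by the default configuration
----------------------------------------------
* ~10 species, each with the same seven tissue classes and 6 replicate
  libraries per tissue (downstream resampling draws 3 at a time).
* A set of one-to-one ortholog slots shared by all species, plus multi-gene
  orthogroups whose paralogs can diverge toward different tissues, plus
  species-specific genes.
* Expression "programs": gene sets elevated (``effect_size`` log2 units) in a
  set of active tissues and coupled through a per-sample latent factor whose
  loading is controlled by ``correlation_strength``.  The defaults plant a
  shared glandular secretion program, a venom+silk core program absent from
  salivary tissue, and single-tissue programs for venom, silk and salivary
  glands - so the true tissue-similarity ordering is venom~silk > venom~saliva.
* Additive per-(gene, batch) offsets on the log2 scale, applied before counts
  are drawn.

Identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    GLAND_TISSUES,
    TISSUES,
    CrossExprError,
)

HIT_COLUMNS = (
    "query",
    "subject",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


class SynthConfigError(CrossExprError):
    """Raised when a :class:`SynthConfig` field is invalid; names the field."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedProgram:
    """A co-regulated gene program active in a set of tissues.

    ``effect_size`` is the log2-scale mean elevation of member genes in the
    active tissues; ``correlation_strength`` in [0, 1] scales the loading on a
    per-sample latent factor shared by all members, which is what makes the
    program detectable as a co-expression module.
    """

    id: str
    n_genes: int
    active_tissues: tuple[str, ...]
    effect_size: float
    correlation_strength: float
    member_genes: tuple[str, ...] = ()

    def validate(self) -> None:
        if self.effect_size < 0:
            raise SynthConfigError(f"programs[{self.id}].effect_size must be >= 0")
        if not 0.0 <= self.correlation_strength <= 1.0:
            raise SynthConfigError(
                f"programs[{self.id}].correlation_strength must be in [0, 1]"
            )
        if self.n_genes <= 0:
            raise SynthConfigError(f"programs[{self.id}].n_genes must be positive")
        unknown = set(self.active_tissues) - set(TISSUES)
        if unknown:
            raise SynthConfigError(
                f"programs[{self.id}].active_tissues unknown: {sorted(unknown)}"
            )


def default_programs() -> tuple[PlantedProgram, ...]:
    """The default planted scenario (see module docstring)."""
    return (
        PlantedProgram("secretion", 150, GLAND_TISSUES, 1.5, 0.5),
        PlantedProgram("venom_silk_core", 300, ("venom_gland", "silk_gland"), 2.0, 0.8),
        PlantedProgram("venom_specific", 100, ("venom_gland",), 4.5, 0.8),
        PlantedProgram("silk_specific", 100, ("silk_gland",), 4.5, 0.8),
        PlantedProgram("salivary_specific", 150, ("salivary_gland",), 4.5, 0.6),
    )


def _default_size_dist() -> dict[int, float]:
    return {1: 0.35, 2: 0.25, 3: 0.15, 4: 0.10, 5: 0.06, 6: 0.04, 7: 0.03, 8: 0.02}


def _default_species() -> dict[str, int]:
    return {f"sp{i:02d}": 150 for i in range(1, 11)}


def _default_tissues() -> dict[str, int]:
    return {t: 6 for t in TISSUES}


@dataclass
class SynthConfig:
    """Full description of a synthetic study.

    Fields mirror the study design: ``species`` maps species id to its count
    of species-specific (unshared) genes, ``tissues`` maps tissue class to
    replicate library count, ``one2one_count`` is the number of ortholog slots
    present in every species, and ``orthogroup_size_dist`` is a categorical
    distribution over paralog-family sizes 1..8 (paralogs per species).
    """

    seed: int = 0
    species: Mapping[str, int] = field(default_factory=_default_species)
    anchor_species: str = "sp01"
    tissues: Mapping[str, int] = field(default_factory=_default_tissues)
    one2one_count: int = 2000
    n_orthogroups: int = 150
    orthogroup_size_dist: Mapping[int, float] = field(default_factory=_default_size_dist)
    programs: tuple[PlantedProgram, ...] = field(default_factory=default_programs)
    # paralog divergence: probability a paralog is assigned its own specific
    # glandular tissue, and the log2 elevation it then receives there
    paralog_specific_prob: float = 0.5
    paralog_effect_size: float = 5.0
    # batch -> (offset mean, offset sd) on the log2 scale
    batch_offsets: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"b1": (-0.25, 0.1), "b2": (0.25, 0.1)}
    )
    nb_dispersion: float = 0.3
    baseline_logmean_range: tuple[float, float] = (0.0, 8.0)
    # program members are drawn from the expressed upper part of the baseline
    # range: co-regulated secretory machinery is not low-expressed
    program_baseline_range: tuple[float, float] = (4.0, 8.0)
    gene_length_range: tuple[int, int] = (500, 10000)
    depth_scale: float = 3.0
    depth_log_sd: float = 0.1
    # latent-factor loading is correlation_strength * latent_amplitude (log2 units)
    latent_amplitude: float = 1.5
    go_terms: int = 500
    go_max_depth: int = 10
    terms_per_gene: tuple[int, int] = (3, 6)
    theme_size: int = 20

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["programs"] = [asdict(p) for p in self.programs]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SynthConfig":
        d = dict(d)
        progs = []
        for p in d.get("programs", []):
            p = dict(p)
            p["active_tissues"] = tuple(p["active_tissues"])
            p["member_genes"] = tuple(p.get("member_genes", ()))
            progs.append(PlantedProgram(**p))
        if progs:
            d["programs"] = tuple(progs)
        d["orthogroup_size_dist"] = {
            int(k): float(v) for k, v in d.get("orthogroup_size_dist", {}).items()
        } or _default_size_dist()
        d["batch_offsets"] = {
            k: tuple(v) for k, v in d.get("batch_offsets", {}).items()
        } or {"b1": (-0.25, 0.1), "b2": (0.25, 0.1)}
        for key in ("baseline_logmean_range", "program_baseline_range", "gene_length_range", "terms_per_gene"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def validate(self) -> None:
        if not self.species:
            raise SynthConfigError("species must be nonempty")
        for sp, n in self.species.items():
            if n < 0:
                raise SynthConfigError(f"species[{sp}] specific-gene count must be >= 0")
        if self.anchor_species not in self.species:
            raise SynthConfigError("anchor_species must be one of species")
        if not self.tissues:
            raise SynthConfigError("tissues must be nonempty")
        for t, reps in self.tissues.items():
            if t not in TISSUES:
                raise SynthConfigError(f"tissues[{t}] is not a known tissue class")
            if reps < 2:
                raise SynthConfigError(f"tissues[{t}] must have >= 2 replicate libraries")
        if self.one2one_count <= 0:
            raise SynthConfigError("one2one_count must be positive")
        if self.n_orthogroups < 0:
            raise SynthConfigError("n_orthogroups must be >= 0")
        sizes = sorted(self.orthogroup_size_dist)
        if not sizes or sizes[0] < 1 or sizes[-1] > 8:
            raise SynthConfigError("orthogroup_size_dist sizes must lie in 1..8")
        total_p = float(sum(self.orthogroup_size_dist.values()))
        if abs(total_p - 1.0) > 1e-8:
            raise SynthConfigError("orthogroup_size_dist probabilities must sum to 1")
        for p in self.programs:
            p.validate()
        n_program_genes = sum(p.n_genes for p in self.programs if not p.member_genes)
        if n_program_genes > self.one2one_count:
            raise SynthConfigError(
                "programs request more genes than one2one_count provides"
            )
        if not 0.0 <= self.paralog_specific_prob <= 1.0:
            raise SynthConfigError("paralog_specific_prob must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise SynthConfigError("nb_dispersion must be >= 0")
        lo, hi = self.baseline_logmean_range
        if hi < lo:
            raise SynthConfigError("baseline_logmean_range must be a valid interval")
        if self.gene_length_range[0] <= 0 or self.gene_length_range[1] < self.gene_length_range[0]:
            raise SynthConfigError("gene_length_range must be a positive interval")
        if self.go_terms < 2:
            raise SynthConfigError("go_terms must be >= 2")
        if self.go_max_depth < 1:
            raise SynthConfigError("go_max_depth must be >= 1")
        if not self.batch_offsets:
            raise SynthConfigError("batch_offsets must be nonempty")


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------


@dataclass
class GoDag:
    """A single-rooted acyclic ontology with typed (is_a / part_of) edges.

    ``graph`` is a networkx MultiDiGraph with child -> parent edges keyed by
    relation, the orientation obonet uses when reading OBO files.
    """

    graph: nx.MultiDiGraph
    root: str

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def parents(self, term: str) -> list[tuple[str, str]]:
        """(parent, relation) pairs of a term."""
        out = []
        for _, parent, rel in self.graph.out_edges(term, keys=True):
            out.append((parent, rel))
        return out


@dataclass
class TruthRecord:
    """Ground truth of a generated study, for evaluating recovery."""

    programs: dict[str, dict]  # program id -> {members, active_tissues, ...}
    specific_tissue: dict[str, str]  # per-species gene id -> tissue
    orthogroups: dict[str, dict[str, list[str]]]  # family id -> species -> genes
    one2one: list[dict[str, str]]  # one tuple per slot: species -> gene id
    batches: dict[str, str]  # sample id -> batch id
    similarity_ordering: list[tuple[str, str]]  # most-similar-first tissue pairs
    latent_factors: dict[str, pd.Series]  # program id -> per-sample factor
    program_themes: dict[str, list[str]]  # program id -> GO theme terms

    def to_json(self) -> str:
        payload = {
            "programs": self.programs,
            "specific_tissue": self.specific_tissue,
            "orthogroups": self.orthogroups,
            "one2one": self.one2one,
            "batches": self.batches,
            "similarity_ordering": [list(p) for p in self.similarity_ordering],
            "latent_factors": {k: v.to_dict() for k, v in self.latent_factors.items()},
            "program_themes": self.program_themes,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SynthStudy:
    """Everything :func:`generate_study` emits, in memory."""

    config: SynthConfig
    counts: dict[str, ExpressionMatrix]  # species -> counts matrix
    lengths: dict[str, pd.Series]  # species -> gene length (bp)
    metadata: pd.DataFrame  # all samples: species, tissue, batch
    hits: dict[tuple[str, str], pd.DataFrame]  # (query sp, subject sp) -> table
    dag: GoDag
    annotations: dict[str, set[str]]  # anchor gene id -> GO term ids
    truth: TruthRecord


# ---------------------------------------------------------------------------
# GO DAG generation
# ---------------------------------------------------------------------------


def generate_go_dag(n_terms: int, max_depth: int = 8, seed: int = 0) -> GoDag:
    """Random single-rooted DAG of ``n_terms`` terms with typed edges.

    Every non-root term gets one or two parents among already-created terms of
    depth < ``max_depth``; 80% of edges are ``is_a``, the rest ``part_of``.
    Acyclicity holds by construction (edges always point to earlier terms).
    """
    if n_terms < 2:
        raise SynthConfigError("go_terms: need n_terms >= 2")
    rng = np.random.default_rng(seed)
    g = nx.MultiDiGraph()
    root = "GO:0000001"
    g.add_node(root, name="biological_process", depth=0)
    depths = {root: 0}
    ids = [root]
    for i in range(2, n_terms + 1):
        term = f"GO:{i:07d}"
        eligible = [t for t in ids if depths[t] < max_depth - 1]
        if not eligible:
            eligible = [root]
        n_parents = 1 if (len(ids) < 3 or rng.random() < 0.7) else 2
        parents = rng.choice(len(eligible), size=min(n_parents, len(eligible)), replace=False)
        depth = 0
        for j, pi in enumerate(parents):
            parent = eligible[int(pi)]
            rel = "is_a" if (j == 0 or rng.random() < 0.8) else "part_of"
            g.add_edge(term, parent, key=rel)
            depth = max(depth, depths[parent] + 1)
        g.nodes[term]["name"] = f"process {i}"
        g.nodes[term]["depth"] = depth
        depths[term] = depth
        ids.append(term)
    return GoDag(graph=g, root=root)


def _descendants(dag: GoDag, term: str) -> set[str]:
    # edges run child -> parent, so descendants are graph-ancestors
    return set(nx.ancestors(dag.graph, term)) | {term}


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------


def _gene_universe(cfg: SynthConfig, rng: np.random.Generator):
    """Lay out gene ids, ortholog slots, orthogroups and program membership."""
    species = list(cfg.species)
    slots = [f"o{i:04d}" for i in range(cfg.one2one_count)]
    one2one = [{sp: f"{sp}_{slot}" for sp in species} for slot in slots]

    # assign program members to leading slots, in declared order
    programs: list[PlantedProgram] = []
    cursor = 0
    for prog in cfg.programs:
        if prog.member_genes:
            members = tuple(prog.member_genes)
        else:
            members = tuple(slots[cursor : cursor + prog.n_genes])
            cursor += prog.n_genes
        programs.append(
            PlantedProgram(
                prog.id,
                len(members),
                tuple(prog.active_tissues),
                prog.effect_size,
                prog.correlation_strength,
                members,
            )
        )

    sizes = np.array(sorted(cfg.orthogroup_size_dist))
    probs = np.array([cfg.orthogroup_size_dist[int(s)] for s in sizes], dtype=float)
    fam_sizes = rng.choice(sizes, size=cfg.n_orthogroups, p=probs / probs.sum())

    orthogroups: dict[str, dict[str, list[str]]] = {}
    for i, slot in enumerate(slots):
        orthogroups[f"OO{i:04d}"] = {sp: [f"{sp}_{slot}"] for sp in species}
    for f, k in enumerate(fam_sizes):
        fam = f"OG{f:04d}"
        orthogroups[fam] = {
            sp: [f"{sp}_f{f:03d}p{j}" for j in range(int(k))] for sp in species
        }
    specific_genes: dict[str, list[str]] = {}
    for sp in species:
        specific_genes[sp] = [f"{sp}_x{i:04d}" for i in range(cfg.species[sp])]
        for gid in specific_genes[sp]:
            orthogroups[f"SG_{gid}"] = {sp: [gid]}

    per_species_genes = {
        sp: [f"{sp}_{slot}" for slot in slots]
        + [g for f in range(cfg.n_orthogroups) for g in orthogroups[f"OG{f:04d}"][sp]]
        + specific_genes[sp]
        for sp in species
    }
    return slots, one2one, programs, orthogroups, per_species_genes, [int(k) for k in fam_sizes]


def generate_study(config: SynthConfig) -> SynthStudy:
    """Generate a complete study from ``config`` (deterministic in the seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    species = list(config.species)
    anchor = config.anchor_species

    slots, one2one, programs, orthogroups, per_species_genes, fam_sizes = _gene_universe(
        config, rng
    )
    slot_index = {slot: i for i, slot in enumerate(slots)}

    # -- samples ------------------------------------------------------------
    batches = list(config.batch_offsets)
    sample_rows = []
    for sp in species:
        for tissue, reps in config.tissues.items():
            for r in range(reps):
                sid = f"{sp}_{tissue}_r{r + 1}"
                sample_rows.append((sid, sp, tissue, batches[r % len(batches)]))
    metadata = pd.DataFrame(
        sample_rows, columns=["sample_id", "species", "tissue", "batch"]
    ).set_index("sample_id")

    # -- latent factors (per program, per active sample, shared across genes).
    # Centered within each species x tissue cell so the factor carries only
    # sample-level co-variation: the tissue-level elevation is exactly
    # effect_size, never masked or inflated by the factor's cell mean.
    latent: dict[str, pd.Series] = {}
    for prog in programs:
        active = metadata.index[metadata["tissue"].isin(prog.active_tissues)]
        fac = pd.Series(
            rng.normal(0.0, 1.0, size=len(active)), index=active, name=prog.id
        )
        cells = metadata.loc[active, ["species", "tissue"]]
        fac = fac - fac.groupby([cells["species"], cells["tissue"]]).transform("mean")
        latent[prog.id] = fac

    # per-gene loading multipliers: members load on the factor with different
    # strengths (hub structure), identically in every species, so intramodular
    # connectivity has preserved structure across datasets
    loading_mult: dict[str, np.ndarray] = {
        prog.id: rng.uniform(0.5, 1.5, size=len(prog.member_genes))
        for prog in programs
    }

    # -- baselines, lengths, paralog divergence -----------------------------
    lo, hi = config.baseline_logmean_range
    slot_base = rng.uniform(lo, hi, size=len(slots))
    plo, phi = config.program_baseline_range
    program_slots = {s for p in programs for s in p.member_genes}
    for i, slot in enumerate(slots):
        if slot in program_slots:
            slot_base[i] = rng.uniform(plo, phi)

    lengths: dict[str, pd.Series] = {}
    base_log: dict[str, pd.Series] = {}
    specific_tissue: dict[str, str] = {}
    for sp in species:
        genes = per_species_genes[sp]
        llo, lhi = np.log(config.gene_length_range[0]), np.log(config.gene_length_range[1])
        lengths[sp] = pd.Series(
            np.exp(rng.uniform(llo, lhi, size=len(genes))).round().astype(int),
            index=genes,
            name="length_bp",
        )
        vals = np.empty(len(genes))
        for i, g in enumerate(genes):
            tail = g.split("_", 1)[1]
            if tail.startswith("o"):
                vals[i] = slot_base[slot_index[tail]]
            else:
                vals[i] = rng.uniform(lo, hi)
        base_log[sp] = pd.Series(vals, index=genes)

    # single-tissue program members are tissue-specific by construction
    single_tissue = {p.id: p.active_tissues[0] for p in programs if len(p.active_tissues) == 1}
    for prog in programs:
        if prog.id not in single_tissue:
            continue
        for slot in prog.member_genes:
            for sp in species:
                specific_tissue[f"{sp}_{slot}"] = single_tissue[prog.id]

    # paralog divergence: each orthogroup paralog may pick its own gland
    paralog_effect: dict[str, tuple[str, float]] = {}
    for f in range(config.n_orthogroups):
        fam = f"OG{f:04d}"
        for j in range(fam_sizes[f]):
            for sp in species:
                gid = f"{sp}_f{f:03d}p{j}"
                if rng.random() < config.paralog_specific_prob:
                    tissue = GLAND_TISSUES[int(rng.integers(len(GLAND_TISSUES)))]
                    paralog_effect[gid] = (tissue, config.paralog_effect_size)
                    specific_tissue[gid] = tissue

    # batch offsets: one additive log2 draw per (gene, batch), per species
    batch_delta: dict[str, pd.DataFrame] = {}
    for sp in species:
        cols = {}
        for b, (mu, sd) in config.batch_offsets.items():
            cols[b] = rng.normal(mu, sd, size=len(per_species_genes[sp]))
        batch_delta[sp] = pd.DataFrame(cols, index=per_species_genes[sp])

    # -- counts -------------------------------------------------------------
    counts: dict[str, ExpressionMatrix] = {}
    prog_by_slotgene: dict[str, list[PlantedProgram]] = {}
    for prog in programs:
        for slot in prog.member_genes:
            for sp in species:
                prog_by_slotgene.setdefault(f"{sp}_{slot}", []).append(prog)

    for sp in species:
        genes = per_species_genes[sp]
        meta = metadata[metadata["species"] == sp]
        n_g, n_s = len(genes), len(meta)
        logmu = np.tile(base_log[sp].to_numpy()[:, None], (1, n_s))
        tissue_of = meta["tissue"].to_numpy()
        batch_of = meta["batch"].to_numpy()
        sample_ids = list(meta.index)
        gene_pos = {g: i for i, g in enumerate(genes)}

        for prog in programs:
            amp = prog.correlation_strength * config.latent_amplitude
            fac = latent[prog.id]
            rows = [gene_pos[f"{sp}_{slot}"] for slot in prog.member_genes]
            active_cols = [
                j for j, sid in enumerate(sample_ids) if tissue_of[j] in prog.active_tissues
            ]
            if not rows or not active_cols:
                continue
            fvals = np.array([fac[sample_ids[j]] for j in active_cols])
            mult = loading_mult[prog.id]
            logmu[np.ix_(rows, active_cols)] += (
                prog.effect_size + (amp * mult)[:, None] * fvals[None, :]
            )

        for gid, (tissue, eff) in paralog_effect.items():
            if not gid.startswith(sp + "_"):
                continue
            cols = [j for j in range(n_s) if tissue_of[j] == tissue]
            if cols:
                logmu[gene_pos[gid], cols] += eff

        for j in range(n_s):
            logmu[:, j] += batch_delta[sp].loc[genes, batch_of[j]].to_numpy()

        depth = config.depth_scale * np.exp(
            rng.normal(0.0, config.depth_log_sd, size=n_s)
        )
        len_kb = lengths[sp].to_numpy() / 1000.0
        mean = (2.0 ** logmu) * len_kb[:, None] * depth[None, :]
        phi = config.nb_dispersion
        if phi > 0:
            n_param = 1.0 / phi
            p_param = n_param / (n_param + mean)
            mat = rng.negative_binomial(n_param, p_param)
        else:
            mat = rng.poisson(mean)
        values = pd.DataFrame(mat, index=genes, columns=sample_ids)
        counts[sp] = ExpressionMatrix(
            values=values, samples=meta[["species", "tissue", "batch"]], scale="counts"
        )

    # -- hit tables ----------------------------------------------------------
    hits = generate_hit_tables(
        orthogroups, score_noise_sd=5.0, seed=int(rng.integers(2**31 - 1)),
        lengths=lengths,
    )

    # -- ontology + annotations ----------------------------------------------
    dag = generate_go_dag(config.go_terms, config.go_max_depth, seed=int(rng.integers(2**31 - 1)))
    themes = _pick_themes(dag, [p.id for p in programs], config.theme_size, rng)
    pool = dag.terms
    tlo, thi = config.terms_per_gene
    annotations: dict[str, set[str]] = {}
    anchor_of_slot = {slot: f"{anchor}_{slot}" for slot in slots}
    theme_of_slot: dict[str, list[str]] = {}
    for prog in programs:
        for slot in prog.member_genes:
            theme_of_slot.setdefault(slot, []).extend(themes[prog.id])
    for slot in slots:
        gid = anchor_of_slot[slot]
        k = int(rng.integers(tlo, thi + 1))
        source = theme_of_slot.get(slot)
        if source:
            idx = rng.choice(len(source), size=min(k, len(source)), replace=False)
            terms = {source[int(i)] for i in idx}
        else:
            idx = rng.choice(len(pool), size=k, replace=False)
            terms = {pool[int(i)] for i in idx}
        annotations[gid] = terms

    truth = TruthRecord(
        programs={
            p.id: {
                "members": list(p.member_genes),
                "anchor_genes": [anchor_of_slot[s] for s in p.member_genes],
                "active_tissues": list(p.active_tissues),
                "effect_size": p.effect_size,
                "correlation_strength": p.correlation_strength,
            }
            for p in programs
        },
        specific_tissue=specific_tissue,
        orthogroups=orthogroups,
        one2one=one2one,
        batches=metadata["batch"].to_dict(),
        similarity_ordering=[
            ("venom_gland", "silk_gland"),
            ("venom_gland", "salivary_gland"),
        ],
        latent_factors=latent,
        program_themes=themes,
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


def _pick_themes(
    dag: GoDag, program_ids: Sequence[str], theme_size: int, rng: np.random.Generator
) -> dict[str, list[str]]:
    """Choose a disjoint subtree ('theme') of terms for each program.

    Annotating a program's genes with terms from one subtree makes the
    program's enrichment signal semantically coherent, so related programs
    yield related enriched-term sets.
    """
    candidates = []
    for t in dag.terms:
        if t == dag.root:
            continue
        desc = _descendants(dag, t)
        # closed subtrees only: every descendant belongs to the theme, so
        # theme terms are not ancestors of unrelated annotation terms
        if 8 <= len(desc) <= theme_size:
            candidates.append((t, desc))
    order = rng.permutation(len(candidates))
    themes: dict[str, list[str]] = {}
    used: set[str] = set()
    ci = 0
    for pid in program_ids:
        chosen = None
        while ci < len(order):
            t, desc = candidates[int(order[ci])]
            ci += 1
            if not (desc & used):
                chosen = sorted(desc)
                used |= set(chosen)
                break
        if chosen is None:  # fall back to random leftover terms
            leftovers = [t for t in dag.terms if t not in used and t != dag.root]
            idx = rng.choice(len(leftovers), size=min(theme_size, len(leftovers)), replace=False)
            chosen = sorted(leftovers[int(i)] for i in idx)
            used |= set(chosen)
        themes[pid] = chosen
    return themes


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------


def _evalue_from_bitscore(bitscore: np.ndarray) -> np.ndarray:
    # monotone decreasing in bitscore; values far below typical thresholds
    return np.power(10.0, -np.asarray(bitscore, dtype=float) / 10.0)


def generate_hit_tables(
    orthogroups: Mapping[str, Mapping[str, Sequence[str]]],
    score_noise_sd: float = 5.0,
    seed: int = 0,
    lengths: Mapping[str, pd.Series] | None = None,
    n_decoys: int = 200,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Similarity-hit tables (12-column, BLAST outfmt-6 dialect) from truth.

    True ortholog pairs (matching paralog indexes across species) get the top
    bitscores with noise well below the separation margin, so reciprocal best
    hits recover the truth exactly; within-family and decoy hits score lower.
    E-values are a monotone decreasing function of bitscore.
    """
    if not orthogroups:
        raise SynthConfigError("orthogroup truth must be nonempty")
    if score_noise_sd < 0:
        raise SynthConfigError("score_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    species: list[str] = sorted({sp for fam in orthogroups.values() for sp in fam})
    genes_by_sp: dict[str, list[str]] = {sp: [] for sp in species}
    for fam in orthogroups.values():
        for sp, genes in fam.items():
            genes_by_sp[sp].extend(genes)

    TRUE, PARALOG, WITHIN, DECOY = 400.0, 250.0, 300.0, 90.0
    tables: dict[tuple[str, str], list[tuple[str, str, float]]] = {}

    def add(a: str, b: str, q: str, s: str, score: float) -> None:
        tables.setdefault((a, b), []).append((q, s, score))

    for fam in orthogroups.values():
        present = [sp for sp in species if fam.get(sp)]
        for a in present:
            for b in present:
                if a == b:
                    ga = fam[a]
                    for i, q in enumerate(ga):
                        for j, s in enumerate(ga):
                            if i != j:
                                add(a, a, q, s, WITHIN + rng.normal(0, score_noise_sd))
                    continue
                ga, gb = list(fam[a]), list(fam[b])
                for i, q in enumerate(ga):
                    for j, s in enumerate(gb):
                        base = TRUE if i == j else PARALOG
                        add(a, b, q, s, base + rng.normal(0, score_noise_sd))

    # low-scoring decoy hits between random unrelated genes
    for a in species:
        for b in species:
            if a == b or not genes_by_sp[a] or not genes_by_sp[b]:
                continue
            k = min(n_decoys, len(genes_by_sp[a]))
            qi = rng.choice(len(genes_by_sp[a]), size=k, replace=False)
            sj = rng.integers(0, len(genes_by_sp[b]), size=k)
            for i, j in zip(qi, sj):
                add(a, b, genes_by_sp[a][int(i)], genes_by_sp[b][int(j)],
                    DECOY + rng.normal(0, score_noise_sd))

    out: dict[tuple[str, str], pd.DataFrame] = {}
    for key in sorted(tables):
        rows = tables[key]
        q, s, score = zip(*rows)
        score = np.maximum(np.asarray(score, dtype=float), 25.0)
        n = len(rows)
        if lengths is not None:
            alen = np.array([int(lengths[key[0]].get(g, 900)) // 3 for g in q])
        else:
            alen = rng.integers(100, 600, size=n)
        df = pd.DataFrame(
            {
                "query": q,
                "subject": s,
                "pident": np.round(rng.uniform(55, 99, size=n), 1),
                "length": alen,
                "mismatch": rng.integers(0, 50, size=n),
                "gapopen": rng.integers(0, 5, size=n),
                "qstart": 1,
                "qend": alen,
                "sstart": 1,
                "send": alen,
                "evalue": _evalue_from_bitscore(score),
                "bitscore": np.round(score, 1),
            }
        )
        out[key] = df
    return out
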