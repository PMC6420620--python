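"""Synthetic multi-omics inputs with a known ground truth.

The generator emulates the study design the pipeline was built for:
three cell populations (a target progenitor population and two reference
populations) with three donors each, profiled by

* bulk RNA-seq counts (negative-binomial, gene-wise log-normal baseline
  means, planted group offsets on a fraction of genes),
* two-channel isobaric-label ratio experiments (target vs. each
  reference) with additive Gaussian noise in log2 space at the protein,
  peptide and spectrum levels,
* per-population label-free presence lists for whole extracts and for
  enriched membrane fractions,
* a subcellular compartment map and a GMT-style category database.

A configurable number of "planted surface markers" are constructed to
carry convergent evidence in every layer: membrane-localized,
upregulated in the target population in both transcriptome comparisons,
shifted in both isobaric-label comparisons, and present only in the
target population's label-free lists.  Every planted effect is recorded
in a :class:`TruthTable` so downstream stages can be scored.

Determinism: a single master seed is expanded into independent child
streams (plan / counts / isobaric / annotations), so identical
configurations produce byte-identical outputs and the three ``simulate_*``
operations agree on the same planted truth.
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

from .dea import CountMatrix
from .errors import ConfigError
from .wspp import CategoryDB

log = logging.getLogger(__name__)

PLASMA_MEMBRANE = "plasma membrane"
#: non-membrane compartment labels with draw weights shaped like a whole-cell
#: proteome (cytosol-heavy, then nuclear, secreted and a residual class)
_NONMEMBRANE = (("cytoplasm", 0.391), ("nucleus", 0.219), ("extracellular", 0.056), ("other", 0.207))


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the simulated study, with the study design as default."""

    n_genes: int = 2400
    groups: tuple[tuple[str, int], ...] = (("CPC", 3), ("MSC", 3), ("HDF", 3))
    frac_deg: float = 0.10
    lfc_scale: float = 2.0
    dispersion: float = 0.1
    base_mean_log: tuple[float, float] = (4.0, 1.2)
    n_proteins: int = 1800
    peptides_per_protein: tuple[int, int] = (1, 8)
    spectra_per_peptide: tuple[int, int] = (1, 4)
    sigma_spectrum: float = 0.25
    sigma_peptide: float = 0.10
    sigma_protein: float = 0.15
    frac_shifted_proteins: float = 0.10
    shift_scale: float = 1.0
    n_categories: int = 200
    category_size_range: tuple[int, int] = (5, 50)
    n_shifted_categories: int = 10
    category_shift: float = 0.5
    frac_membrane: float = 0.127
    n_planted_surface: int = 50
    seed: int = 0
    # share of the protein universe that also appears in the transcriptome
    frac_protein_in_transcriptome: float = 0.755
    # share of planted surface markers detectable in whole extracts (the
    # rest are recovered only from the enriched membrane fraction)
    frac_surface_whole_extract: float = 0.8

    def __post_init__(self) -> None:
        for name in (
            "frac_deg",
            "frac_shifted_proteins",
            "frac_membrane",
            "frac_protein_in_transcriptome",
            "frac_surface_whole_extract",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("sigma_spectrum", "sigma_peptide", "sigma_protein"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("n_genes", "n_proteins", "n_categories", "n_shifted_categories", "n_planted_surface"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.lfc_scale < 0 or self.shift_scale < 0:
            raise ConfigError("lfc_scale and shift_scale must be >= 0")
        if len(self.groups) < 2:
            raise ConfigError("groups must list at least two cell types")
        for label, reps in self.groups:
            if reps < 1:
                raise ConfigError(f"groups: {label!r} needs at least one replicate")
        for name in ("peptides_per_protein", "spectra_per_peptide", "category_size_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ConfigError(f"{name} must be a non-decreasing non-negative range, got ({lo}, {hi})")
        if self.peptides_per_protein[0] < 1:
            raise ConfigError("peptides_per_protein minimum must be >= 1")
        if self.category_size_range[1] > self.n_proteins:
            raise ConfigError(
                f"category_size_range max {self.category_size_range[1]} exceeds n_proteins {self.n_proteins}"
            )
        if self.n_shifted_categories > self.n_categories:
            raise ConfigError("n_shifted_categories exceeds n_categories")
        n_shared = round(self.frac_protein_in_transcriptome * self.n_proteins)
        if self.n_planted_surface > min(n_shared, self.n_genes):
            raise ConfigError(
                "n_planted_surface exceeds the number of entities shared between both omics layers"
            )

    @property
    def target_group(self) -> str:
        return self.groups[0][0]

    @property
    def comparisons(self) -> list[tuple[str, str]]:
        first = self.groups[0][0]
        return [(first, g) for g, _ in self.groups[1:]]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["groups"] = tuple((str(g), int(n)) for g, n in d["groups"])
        for name in ("base_mean_log", "peptides_per_protein", "spectra_per_peptide", "category_size_range"):
            d[name] = tuple(d[name])
        return cls(**d)


@dataclass
class TruthTable:
    """Planted ground truth: per-entity effects and per-category shifts."""

    entities: pd.DataFrame
    categories: pd.DataFrame

    @property
    def planted_surface(self) -> set:
        return set(self.entities.index[self.entities["is_planted_surface"]])

    def differential_genes(self, comparison: str) -> set:
        col = f"lfc_{comparison}"
        return set(self.entities.index[self.entities[col] != 0.0])


@dataclass
class AnnotationBundle:
    """Compartment map, category database and label-free presence lists."""

    compartments: pd.Series  # entity -> compartment label
    categories: CategoryDB
    whole_extract: dict[str, frozenset]
    membrane_fraction: dict[str, frozenset]


@dataclass
class _Plan:
    gene_ids: np.ndarray
    protein_ids: np.ndarray
    base_log_mean: np.ndarray  # per gene, natural-log scale
    offset_group: np.ndarray  # per gene: group index carrying the offset, -1 if none
    offset_lfc: np.ndarray  # per gene: signed log2 offset
    protein_shift: np.ndarray  # per protein: signed log2 ratio (target vs reference)
    compartment: pd.Series
    categories: dict[str, frozenset]
    shifted_categories: set
    planted: np.ndarray
    planted_we: np.ndarray  # planted markers detectable in whole extracts


def _streams(cfg: SimConfig) -> dict[str, np.random.Generator]:
    kids = np.random.SeedSequence(cfg.seed).spawn(4)
    names = ("plan", "counts", "itraq", "annotations")
    return {n: np.random.default_rng(k) for n, k in zip(names, kids)}


def _plan(cfg: SimConfig) -> _Plan:
    rng = _streams(cfg)["plan"]
    gene_ids = np.array([f"G{i:05d}" for i in range(cfg.n_genes)])
    n_shared = round(cfg.frac_protein_in_transcriptome * cfg.n_proteins)
    n_shared = min(n_shared, cfg.n_genes)
    shared = np.sort(rng.choice(cfg.n_genes, size=n_shared, replace=False))
    protein_only = np.array([f"P{i:05d}" for i in range(cfg.n_proteins - n_shared)])
    protein_ids = np.concatenate([gene_ids[shared], protein_only])

    base_log_mean = rng.normal(cfg.base_mean_log[0], cfg.base_mean_log[1], cfg.n_genes)

    # planted surface markers live in both omics layers
    planted = rng.choice(gene_ids[shared], size=cfg.n_planted_surface, replace=False)
    planted = np.sort(planted)
    n_we = round(cfg.frac_surface_whole_extract * cfg.n_planted_surface)
    planted_we = np.sort(rng.choice(planted, size=n_we, replace=False)) if len(planted) else planted

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    planted_gene_idx = np.array([gene_index[g] for g in planted], dtype=int)

    # ordinary differential genes: one group carries a signed offset
    offset_group = np.full(cfg.n_genes, -1, dtype=int)
    offset_lfc = np.zeros(cfg.n_genes)
    candidates = np.setdiff1d(np.arange(cfg.n_genes), planted_gene_idx)
    n_deg = min(round(cfg.frac_deg * cfg.n_genes), len(candidates))
    deg_idx = rng.choice(candidates, size=n_deg, replace=False)
    offset_group[deg_idx] = rng.integers(0, len(cfg.groups), size=n_deg)
    offset_lfc[deg_idx] = rng.choice([-1.0, 1.0], size=n_deg) * cfg.lfc_scale
    # planted markers: up in the target group
    offset_group[planted_gene_idx] = 0
    offset_lfc[planted_gene_idx] = cfg.lfc_scale

    # protein-level true ratios (target vs. either reference)
    prot_index = {p: i for i, p in enumerate(protein_ids)}
    protein_shift = np.zeros(cfg.n_proteins)
    planted_prot_idx = np.array([prot_index[p] for p in planted], dtype=int)
    protein_shift[planted_prot_idx] = cfg.shift_scale
    free = np.setdiff1d(np.arange(cfg.n_proteins), planted_prot_idx)
    n_shift = min(round(cfg.frac_shifted_proteins * cfg.n_proteins), len(free))
    shift_idx = rng.choice(free, size=n_shift, replace=False)
    protein_shift[shift_idx] = rng.choice([-1.0, 1.0], size=n_shift) * cfg.shift_scale

    # categories; shifted ones are built predominantly from a dedicated pool
    # of proteins raised by the category shift
    lo, hi = cfg.category_size_range
    sizes = rng.integers(lo, hi + 1, size=cfg.n_categories)
    names = [f"C{i:04d}" for i in range(cfg.n_categories)]
    shifted_pos = set(rng.choice(cfg.n_categories, size=cfg.n_shifted_categories, replace=False).tolist())
    pool = np.setdiff1d(free, shift_idx)
    rng.shuffle(pool)
    pool_cursor = 0
    categories: dict[str, frozenset] = {}
    for i, (name, size) in enumerate(zip(names, sizes)):
        if i in shifted_pos:
            n_core = max(int(np.ceil(0.8 * size)), 1)
            take_new = min(n_core, len(pool) - pool_cursor)
            core = pool[pool_cursor : pool_cursor + take_new]
            pool_cursor += take_new
            if len(core) < n_core:
                # small universes: reuse already-shifted pool proteins so the
                # planted categories stay predominantly shifted
                reuse = pool[:pool_cursor]
                if len(reuse) == 0:
                    raise ConfigError(
                        "no unshifted proteins left to build the planted categories; "
                        "reduce n_shifted_categories or category_size_range"
                    )
                extra = rng.choice(reuse, size=n_core - len(core), replace=True)
                core = np.unique(np.concatenate([core, extra]))
            protein_shift[core] = cfg.category_shift
            others = np.setdiff1d(np.arange(cfg.n_proteins), core)
            n_rest = min(size - len(core), len(others))
            rest = rng.choice(others, size=n_rest, replace=False)
            members = np.concatenate([core, rest])
        else:
            members = rng.choice(cfg.n_proteins, size=size, replace=False)
        categories[name] = frozenset(protein_ids[members])
    shifted_names = {names[i] for i in shifted_pos}

    # compartments over the union of both universes
    entities = np.concatenate([gene_ids, protein_only])
    is_planted = np.isin(entities, planted)
    comp = np.empty(len(entities), dtype=object)
    if cfg.frac_membrane >= 1.0:
        comp[:] = PLASMA_MEMBRANE
    else:
        labels = [l for l, _ in _NONMEMBRANE]
        weights = np.array([w for _, w in _NONMEMBRANE])
        weights = weights / weights.sum()
        nonmem = rng.choice(labels, size=len(entities), p=weights)
        mem = rng.random(len(entities)) < cfg.frac_membrane
        comp[:] = np.where(mem, PLASMA_MEMBRANE, nonmem)
        # unplanted differential genes stay off the membrane so the planted
        # surface truth is the unique membrane+differential evidence set
        diff_gene = np.zeros(len(entities), dtype=bool)
        diff_gene[: cfg.n_genes] = offset_lfc != 0.0
        comp[diff_gene & ~is_planted & (comp == PLASMA_MEMBRANE)] = "cytoplasm"
    comp[is_planted] = PLASMA_MEMBRANE
    compartment = pd.Series(comp, index=entities, name="compartment")

    return _Plan(
        gene_ids=gene_ids,
        protein_ids=protein_ids,
        base_log_mean=base_log_mean,
        offset_group=offset_group,
        offset_lfc=offset_lfc,
        protein_shift=protein_shift,
        compartment=compartment,
        categories=categories,
        shifted_categories=shifted_names,
        planted=planted,
        planted_we=planted_we,
    )


def _truth(cfg: SimConfig, plan: _Plan) -> TruthTable:
    entities = plan.compartment.index.to_numpy()
    is_gene = np.isin(entities, plan.gene_ids)
    is_protein = np.isin(entities, plan.protein_ids)
    df = pd.DataFrame(index=pd.Index(entities, name="entity"))
    df["is_gene"] = is_gene
    df["is_protein"] = is_protein
    df["compartment"] = plan.compartment
    df["is_planted_surface"] = np.isin(entities, plan.planted)
    df["in_whole_extract"] = np.where(
        df["is_planted_surface"], np.isin(entities, plan.planted_we), is_protein
    )
    base = pd.Series(np.nan, index=df.index)
    base.loc[plan.gene_ids] = np.exp(plan.base_log_mean)
    df["base_mean"] = base

    gene_pos = pd.Series(np.arange(len(plan.gene_ids)), index=plan.gene_ids)
    for g0, gk in cfg.comparisons:
        k = [g for g, _ in cfg.groups].index(gk)
        lfc = np.zeros(len(entities))
        og = plan.offset_group[gene_pos.reindex(entities).fillna(-1).astype(int)]
        ol = plan.offset_lfc[gene_pos.reindex(entities).fillna(-1).astype(int)]
        lfc = np.where(is_gene & (og == 0), ol, 0.0) - np.where(is_gene & (og == k), ol, 0.0)
        df[f"lfc_{g0}_vs_{gk}"] = lfc
        shift = np.zeros(len(entities))
        prot_pos = pd.Series(np.arange(len(plan.protein_ids)), index=plan.protein_ids)
        pp = prot_pos.reindex(entities)
        has = pp.notna().to_numpy()
        shift[has] = plan.protein_shift[pp[has].astype(int).to_numpy()]
        df[f"shift_{g0}_vs_{gk}"] = shift
    lfc_cols = [c for c in df.columns if c.startswith("lfc_")]
    df["is_differential"] = (df[lfc_cols] != 0.0).any(axis=1)
    shift_cols = [c for c in df.columns if c.startswith("shift_")]
    df["is_shifted_protein"] = (df[shift_cols] != 0.0).any(axis=1)

    cats = pd.DataFrame(
        {
            "category": sorted(plan.categories),
            "size": [len(plan.categories[c]) for c in sorted(plan.categories)],
            "is_shifted": [c in plan.shifted_categories for c in sorted(plan.categories)],
            "true_shift": [
                cfg.category_shift if c in plan.shifted_categories else 0.0
                for c in sorted(plan.categories)
            ],
        }
    ).set_index("category")
    return TruthTable(entities=df, categories=cats)


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, TruthTable]:
    """Negative-binomial gene x sample counts under the planted design."""
    if len(cfg.groups) < 2 or any(n < 2 for _, n in cfg.groups):
        raise ConfigError("groups: counts need >= 2 groups with >= 2 replicates each")
    plan = _plan(cfg)
    rng = _streams(cfg)["counts"]
    samples, labels = [], []
    for label, reps in cfg.groups:
        for r in range(reps):
            samples.append(f"{label}{r + 1}")
            labels.append(label)
    design = pd.Series(labels, index=pd.Index(samples, name="sample"), name="group")

    group_of = np.array([[g for g, _ in cfg.groups].index(l) for l in labels])
    mu_base = np.exp(plan.base_log_mean)[:, None]
    offset = np.where(
        plan.offset_group[:, None] == group_of[None, :], plan.offset_lfc[:, None], 0.0
    )
    mu = mu_base * 2.0**offset
    if cfg.dispersion > 0:
        lam = rng.gamma(1.0 / cfg.dispersion, mu * cfg.dispersion)
    else:
        lam = mu
    counts = rng.poisson(lam)
    cm = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(plan.gene_ids, name="gene"), columns=samples),
        design,
    )
    return cm, _truth(cfg, plan)


def simulate_itraq(cfg: SimConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Spectrum-level ratio table for each pairwise comparison.

    Hierarchical draw per comparison: protein true ratio plus a protein
    deviation ``N(0, sigma_protein^2)``, peptide deviation
    ``N(0, sigma_peptide^2)`` and spectrum deviation
    ``N(0, sigma_spectrum^2)``.  Weights encode ``1/sigma_spectrum^2``.
    Proteins that end up with zero spectra are omitted and recorded as
    unobserved in the truth table.
    """
    plan = _plan(cfg)
    rng = _streams(cfg)["itraq"]
    truth = _truth(cfg, plan)
    weight = 1.0 / cfg.sigma_spectrum**2 if cfg.sigma_spectrum > 0 else 1e12

    frames = []
    for g0, gk in cfg.comparisons:
        cmp_label = f"{g0}_vs_{gk}"
        plo, phi = cfg.peptides_per_protein
        n_pep = rng.integers(plo, phi + 1, size=cfg.n_proteins)
        prot_of_pep = np.repeat(np.arange(cfg.n_proteins), n_pep)
        pep_within = np.concatenate([np.arange(k) for k in n_pep]) if n_pep.sum() else np.empty(0, int)
        slo, shi = cfg.spectra_per_peptide
        n_spec = rng.integers(slo, shi + 1, size=len(prot_of_pep))
        pep_of_spec = np.repeat(np.arange(len(prot_of_pep)), n_spec)
        spec_within = (
            np.concatenate([np.arange(k) for k in n_spec]) if n_spec.sum() else np.empty(0, int)
        )

        dev_prot = rng.normal(0.0, cfg.sigma_protein, cfg.n_proteins)
        dev_pep = rng.normal(0.0, cfg.sigma_peptide, len(prot_of_pep))
        dev_spec = rng.normal(0.0, cfg.sigma_spectrum, len(pep_of_spec))
        prot_of_spec = prot_of_pep[pep_of_spec]
        xs = plan.protein_shift[prot_of_spec] + dev_prot[prot_of_spec] + dev_pep[pep_of_spec] + dev_spec

        prot_names = plan.protein_ids[prot_of_spec]
        pep_names = [
            f"{p}.p{j}" for p, j in zip(plan.protein_ids[prot_of_pep[pep_of_spec]], pep_within[pep_of_spec])
        ]
        spec_names = [f"{pep}.s{k}|{cmp_label}" for pep, k in zip(pep_names, spec_within)]
        frames.append(
            pd.DataFrame(
                {
                    "spectrum_id": spec_names,
                    "peptide_id": pep_names,
                    "protein_id": prot_names,
                    "log2_ratio": xs,
                    "weight": weight,
                    "comparison": cmp_label,
                }
            )
        )
        observed = np.zeros(cfg.n_proteins, dtype=bool)
        observed[np.unique(prot_of_spec)] = True
        col = pd.Series(False, index=truth.entities.index)
        col.loc[plan.protein_ids] = observed
        truth.entities[f"observed_{cmp_label}"] = col
        n_missing = int((~observed).sum())
        if n_missing:
            log.info("%s: %d proteins yielded no spectra and were omitted", cmp_label, n_missing)

    return pd.concat(frames, ignore_index=True), truth


def simulate_annotations(cfg: SimConfig) -> tuple[AnnotationBundle, TruthTable]:
    """Compartment map, category database and label-free presence lists.

    Every non-planted protein is detected in all populations' whole
    extracts; planted surface markers appear only in the target
    population's lists (a configurable fraction of them only in the
    enriched membrane fraction).  Membrane-fraction lists contain the
    membrane-localized proteins of each population.
    """
    plan = _plan(cfg)
    truth = _truth(cfg, plan)
    planted = set(plan.planted)
    planted_we = set(plan.planted_we)
    all_prot = set(plan.protein_ids)
    membrane_prot = {p for p in plan.protein_ids if plan.compartment[p] == PLASMA_MEMBRANE}

    whole_extract: dict[str, frozenset] = {}
    membrane_fraction: dict[str, frozenset] = {}
    for gi, (label, _) in enumerate(cfg.groups):
        if gi == 0:
            whole_extract[label] = frozenset((all_prot - planted) | planted_we)
            membrane_fraction[label] = frozenset(membrane_prot)
        else:
            whole_extract[label] = frozenset(all_prot - planted)
            membrane_fraction[label] = frozenset(membrane_prot - planted)

    bundle = AnnotationBundle(
        compartments=plan.compartment,
        categories=CategoryDB(dict(plan.categories), {n: "simulated category" for n in plan.categories}),
        whole_extract=whole_extract,
        membrane_fraction=membrane_fraction,
    )
    return bundle, truth


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_bundle(cfg: SimConfig, outdir: str | Path) -> dict:
    """Serialize every pipeline input plus truth tables and a manifest.

    Returns the manifest (config, seed, per-file sha256 checksums); the
    same manifest is written to ``manifest.json``.
    """
    from . import __version__
    from .io import write_compartments, write_counts, write_gmt, write_presence, write_spectra

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, truth = simulate_counts(cfg)
    spectra, truth = simulate_itraq(cfg)
    ann, _ = simulate_annotations(cfg)

    files: dict[str, str] = {}

    def _record(rel: str) -> None:
        files[rel] = sha256_file(outdir / rel)

    write_counts(cm, outdir / "counts.tsv", outdir / "design.tsv")
    _record("counts.tsv")
    _record("design.tsv")
    write_spectra(spectra, outdir / "spectra.tsv")
    _record("spectra.tsv")
    write_gmt(ann.categories, outdir / "categories.gmt")
    _record("categories.gmt")
    write_compartments(ann.compartments, outdir / "compartments.tsv")
    _record("compartments.tsv")
    (outdir / "presence").mkdir(exist_ok=True)
    for label in ann.whole_extract:
        rel = f"presence/whole_extract_{label}.txt"
        write_presence(ann.whole_extract[label], outdir / rel)
        _record(rel)
        rel = f"presence/membrane_fraction_{label}.txt"
        write_presence(ann.membrane_fraction[label], outdir / rel)
        _record(rel)
    truth.entities.to_csv(outdir / "truth_entities.tsv", sep="\t", float_format="%.10g")
    _record("truth_entities.tsv")
    truth.categories.to_csv(outdir / "truth_categories.tsv", sep="\t", float_format="%.10g")
    _record("truth_categories.tsv")

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "files": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def verify_bundle(outdir: str | Path) -> list[str]:
    """Re-checksum a written bundle; return the paths that mismatch."""
    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    bad = []
    for rel, digest in manifest["files"].items():
        path = outdir / rel
        if not path.exists() or sha256_file(path) != digest:
            bad.append(rel)
    return bad
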