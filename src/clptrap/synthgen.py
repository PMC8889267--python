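"""Synthetic inputs with the statistical structure each pipeline stage assumes.

Three generators emulate the shapes of the study data without any download:

* :func:`simulate_psm_dataset` — a two-genotype (TRAP/WT), three-bioreplicate,
  three-technical-replicate spectral-count experiment with shared peptides
  inside planted homolog families and a planted set of bait-enriched
  proteins.
* :func:`simulate_gene_trees` — gene trees over a fixed species tree whose
  terminal branch lengths follow a multiplicative species x gene rate model,
  with planted coevolving pairs sharing a latent per-species rate
  multiplier, plus an optional duplicate-and-diverge mode that inserts a
  logged gene duplication.
* :func:`simulate_coexpression` — latent-factor expression profiles with
  planted modules, turned into mutual ranks and a logit score (LS) per gene
  pair, emitted as per-bait ranked lists.

Every generator is a pure function of its :class:`SimConfig` (the seed is
mandatory), so identical configs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import io

import dendropy
import numpy as np
import pandas as pd
from scipy import stats as _stats

from .coexnet import CoexprList
from .quantify import PSMTable, make_roster

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_psm_dataset",
    "simulate_gene_trees",
    "simulate_coexpression",
    "load_species_tree",
    "load_table1_fixture",
    "table1_annotations",
]

_TABLE1_SHA256 = "0af65962e5c453d3f109223c52c535a1dbe3c866a1c8bf5dfb573c7161fe3363"

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Parameters for all three generators; only the relevant block is read.

    Spectral-count block: protein abundances are log-normal with median
    ``exp(abundance_mu)`` expected spectra per protein per run; enriched
    proteins are multiplied by ``effect_size`` in TRAP; per-bioreplicate
    biological noise has coefficient of variation ``bio_cv``; counts are
    negative binomial with ``dispersion`` (variance mu + dispersion*mu^2) or
    Poisson.
    """

    seed: int
    # spectral counting
    n_proteins: int = 2000
    n_enriched: int = 40
    effect_size: float = 5.0
    shared_peptide_fraction: float = 0.2
    family_size: int = 3
    min_peptides: int = 3
    max_peptides: int = 30
    genotypes: tuple = ("TRAP", "WT")
    n_bioreps: int = 3
    n_techreps: int = 3
    count_model: str = "negative_binomial"
    dispersion: float = 0.1
    abundance_mu: float = float(np.log(15.0))
    abundance_sigma: float = 1.2
    detectability_sigma: float = 0.5
    bio_cv: float = 0.2
    # gene trees / ERC
    n_species: int = 20
    n_genes: int = 100
    n_coevolving_pairs: int = 0
    coevolution_strength: float = 0.8
    coevolution_scale: float = 0.6   # log-sd of the shared multiplier at strength 1
    rate_noise_sigma: float = 0.15
    gene_rate_sigma: float = 0.5
    species_dropout: float = 0.0
    duplication_prob: float = 0.0
    # coexpression
    n_baits: int = 42
    n_background_genes: int = 4000
    n_modules: int = 7
    module_background_genes: int = 4
    module_rho: float = 0.8
    n_expression_samples: int = 200

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for field in ("n_proteins", "n_bioreps", "n_techreps", "n_species",
                      "n_genes", "n_baits"):
            if getattr(self, field) < 1:
                raise ValueError(f"{field} must be positive")
        if not (0 <= self.shared_peptide_fraction < 1):
            raise ValueError("shared_peptide_fraction must be in [0, 1)")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if self.count_model not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown count model {self.count_model!r}")
        if self.shared_peptide_fraction > 0 and self.family_size < 2:
            raise ValueError("shared peptides require family_size >= 2")


@dataclasses.dataclass
class GroundTruth:
    """What was planted: abundances, enriched set, coevolving pairs, modules."""

    abundance: pd.DataFrame | None = None     # protein x genotype expectations
    enriched: tuple = ()
    coevolving_pairs: tuple = ()
    duplications: dict = dataclasses.field(default_factory=dict)
    modules: dict = dataclasses.field(default_factory=dict)


def _nb_counts(rng, mu, dispersion):
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def _random_peptide(rng, length=12):
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length))


def simulate_psm_dataset(cfg: SimConfig) -> tuple:
    """Simulate a PSM count table with planted enrichment and shared peptides."""
    rng = np.random.default_rng(cfg.seed)
    roster = make_roster(cfg.genotypes, cfg.n_bioreps, cfg.n_techreps)
    proteins = [f"P{i:05d}" for i in range(cfg.n_proteins)]
    enriched = set(rng.choice(cfg.n_proteins, size=cfg.n_enriched,
                              replace=False).tolist())

    base = np.exp(rng.normal(cfg.abundance_mu, cfg.abundance_sigma,
                             size=cfg.n_proteins))
    mult = {g: np.ones(cfg.n_proteins) for g in cfg.genotypes}
    if "TRAP" in mult:
        for i in enriched:
            mult["TRAP"][i] = cfg.effect_size

    # consecutive proteins form homolog families eligible to share peptides
    family_of = np.arange(cfg.n_proteins) // max(cfg.family_size, 1)

    peptides, acc_sets, pep_protein, pep_detect = [], [], [], []
    seen = set()
    for i in range(cfg.n_proteins):
        n_pep = int(rng.integers(cfg.min_peptides, cfg.max_peptides + 1))
        fam = np.flatnonzero(family_of == family_of[i])
        partners = fam[fam != i]
        for _ in range(n_pep):
            while True:
                pep = _random_peptide(rng)
                if pep not in seen:
                    seen.add(pep)
                    break
            accs = {proteins[i]}
            if partners.size and rng.random() < cfg.shared_peptide_fraction:
                accs.add(proteins[int(rng.choice(partners))])
            peptides.append(pep)
            acc_sets.append(frozenset(accs))
            pep_protein.append(i)
            pep_detect.append(np.exp(rng.normal(0.0, cfg.detectability_sigma)))
    pep_protein = np.asarray(pep_protein)
    pep_detect = np.asarray(pep_detect)
    npep_of = np.bincount(pep_protein, minlength=cfg.n_proteins)

    # per-peptide expected counts: protein abundance spread over its peptides
    counts = np.zeros((len(peptides), len(roster)), dtype=np.int64)
    bio_sigma = np.sqrt(np.log1p(cfg.bio_cv ** 2))
    for col, key in enumerate(roster):
        bio = np.exp(rng.normal(0.0, bio_sigma, size=cfg.n_proteins)
                     - 0.5 * bio_sigma ** 2)
        prot_mean = base * mult[key.genotype] * bio
        mu = prot_mean[pep_protein] * pep_detect / npep_of[pep_protein]
        if cfg.count_model == "poisson":
            counts[:, col] = rng.poisson(mu)
        else:
            counts[:, col] = _nb_counts(rng, mu, cfg.dispersion)

    psm = PSMTable(tuple(peptides), tuple(acc_sets), counts, roster)
    truth = GroundTruth(
        abundance=pd.DataFrame(
            {g: base * mult[g] for g in cfg.genotypes}, index=proteins),
        enriched=tuple(sorted(proteins[i] for i in enriched)))
    return psm, truth


def load_species_tree() -> dendropy.Tree:
    """Packaged synthetic 20-taxon species tree (tips S01..S20)."""
    ref = importlib.resources.files("clptrap") / "data" / "species_tree_20taxa.nwk"
    return dendropy.Tree.get(data=ref.read_text(), schema="newick")


def _subtree_newick(node, tip_len, scale, suffix=""):
    if node.is_leaf():
        name = node.taxon.label + suffix
        return f"{name}:{tip_len(node.taxon.label):.6g}"
    parts = ",".join(_subtree_newick(c, tip_len, scale, suffix)
                     for c in node.child_nodes())
    length = (node.edge.length or 0.0) * scale
    return f"({parts}):{length:.6g}"


def simulate_gene_trees(species_tree: dendropy.Tree | None,
                        cfg: SimConfig) -> tuple:
    """Simulate gene trees with planted rate coevolution and/or duplications.

    Terminal branch lengths follow ``L_s * r_g * exp(strength * scale * z_s
    + sigma * eps)`` where ``L_s`` is the species' terminal branch length,
    ``r_g`` a log-normal gene rate, and ``z_s`` a standard-normal latent
    multiplier shared within each planted coevolving pair
    (``scale`` = ``coevolution_scale`` bounds the shared log-dispersion). With
    ``duplication_prob`` > 0, a random node is replaced by two diverged
    copies of its subtree (tips suffixed ``|1``/``|2``) and the planted
    duplication is logged by the tip set under the inserted node.
    """
    if species_tree is None:
        species_tree = load_species_tree()
    rng = np.random.default_rng(cfg.seed)
    leaves = [lf for lf in species_tree.leaf_node_iter()]
    species = [lf.taxon.label for lf in leaves]
    base_len = {lf.taxon.label: float(lf.edge.length) for lf in leaves}
    if any(v <= 0 for v in base_len.values()):
        raise ValueError("species tree must have positive branch lengths")

    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    pairs = []
    latent = {}
    for p in range(cfg.n_coevolving_pairs):
        g1, g2 = genes[2 * p], genes[2 * p + 1]
        pairs.append((g1, g2))
        z = rng.normal(0.0, 1.0, size=len(species))
        latent[g1] = z
        latent[g2] = z
    if 2 * cfg.n_coevolving_pairs > cfg.n_genes:
        raise ValueError("not enough genes for the requested coevolving pairs")

    trees = {}
    duplications = {}
    for gene in genes:
        r_g = float(np.exp(rng.normal(0.0, cfg.gene_rate_sigma)))
        z = latent.get(gene)
        eps = rng.normal(0.0, 1.0, size=len(species))
        logmult = cfg.rate_noise_sigma * eps
        if z is not None:
            logmult = (cfg.coevolution_strength * cfg.coevolution_scale * z
                       + logmult)
        tip_rate = {s: base_len[s] * r_g * float(np.exp(m))
                    for s, m in zip(species, logmult)}

        keep = set(species)
        if cfg.species_dropout > 0:
            drop = rng.random(len(species)) < cfg.species_dropout
            keep = {s for s, d in zip(species, drop) if not d}
            if len(keep) < 4:
                keep = set(species)

        tree = species_tree.clone(depth=1)
        if len(keep) < len(species):
            tree.retain_taxa_with_labels(sorted(keep))

        dup_node = None
        if cfg.duplication_prob > 0 and rng.random() < cfg.duplication_prob:
            candidates = [nd for nd in tree.preorder_node_iter()
                          if nd.parent_node is not None]
            dup_node = candidates[int(rng.integers(len(candidates)))]

        def render(node):
            if node is dup_node:
                jit = rng.uniform(0.5, 1.5, size=2)
                half = (node.edge.length or 0.0) * r_g * 0.5
                c1 = _subtree_newick(node, tip_rate.__getitem__, r_g * jit[0],
                                     suffix="|1")
                c2 = _subtree_newick(node, tip_rate.__getitem__, r_g * jit[1],
                                     suffix="|2")
                return f"({c1},{c2}):{half:.6g}"
            if node.is_leaf():
                return f"{node.taxon.label}:{tip_rate[node.taxon.label]:.6g}"
            parts = ",".join(render(c) for c in node.child_nodes())
            return f"({parts}):{(node.edge.length or 0.0) * r_g:.6g}"

        root = tree.seed_node
        nwk = "(" + ",".join(render(c) for c in root.child_nodes()) + ");"
        trees[gene] = dendropy.Tree.get(data=nwk, schema="newick")
        if dup_node is not None:
            tips = sorted(lf.taxon.label for lf in dup_node.leaf_iter())
            duplications[gene] = frozenset(
                t + suf for t in tips for suf in ("|1", "|2"))
    truth = GroundTruth(coevolving_pairs=tuple(pairs),
                        duplications=duplications)
    return trees, truth


def simulate_coexpression(cfg: SimConfig) -> tuple:
    """Simulate per-bait ranked logit-score lists with planted modules.

    Genes in a module load on a shared latent factor with correlation
    ``module_rho``; all other pairs are independent. Pairwise Pearson
    correlations below a Bonferroni-calibrated noise floor are assigned the
    bottom rank, so the mutual rank (geometric mean of the two directed
    ranks) separates planted from null pairs. The logit score is
    ``LS = log((1 - q) / q)`` with ``q = MR / (N + 1)``, clipped to [-10, 10].
    """
    rng = np.random.default_rng(cfg.seed)
    baits = [f"B{i:03d}" for i in range(cfg.n_baits)]
    background = [f"G{i:05d}" for i in range(cfg.n_background_genes)]
    genes = baits + background
    n = len(genes)

    modules: dict = {}
    bait_order = rng.permutation(cfg.n_baits)
    bg_pool = list(rng.permutation(cfg.n_background_genes))
    per_module = int(np.ceil(cfg.n_baits / cfg.n_modules))
    for m in range(cfg.n_modules):
        members = [baits[i] for i in bait_order[m * per_module:(m + 1) * per_module]]
        extra = [background[bg_pool.pop()] for _ in
                 range(min(cfg.module_background_genes, len(bg_pool)))]
        if members:
            modules[m] = tuple(members + extra)

    ns = cfg.n_expression_samples
    expr = rng.normal(0.0, 1.0, size=(n, ns))
    gene_idx = {g: i for i, g in enumerate(genes)}
    rho = cfg.module_rho
    for m, members in modules.items():
        factor = rng.normal(0.0, 1.0, size=ns)
        for g in members:
            i = gene_idx[g]
            expr[i] = np.sqrt(rho) * factor + np.sqrt(1 - rho) * expr[i]

    corr = np.corrcoef(expr)
    np.fill_diagonal(corr, -np.inf)
    # noise floor: Bonferroni-corrected two-sided correlation threshold
    n_pairs = n * (n - 1) / 2
    z_crit = _stats.norm.isf(0.025 / n_pairs)
    r_crit = float(np.tanh(z_crit / np.sqrt(max(ns - 3, 1))))

    order = np.argsort(-corr, axis=1, kind="stable")
    ranks = np.empty((n, n), dtype=np.int32)
    row = np.arange(n, dtype=np.int32)
    np.put_along_axis(ranks, order, np.broadcast_to(row, (n, n)).copy(), axis=1)
    ranks += 1                         # 1-based directed ranks
    mr_raw = np.sqrt(ranks.astype(float) * ranks.T.astype(float))
    # pairs whose similarity clears the noise floor get the logit of the
    # complementary mutual-rank percentile; sub-floor pairs sit strictly
    # below them on a compressed scale so ranked lists stay tie-free
    above = (corr >= r_crit) & (corr.T >= r_crit)
    q = np.minimum(mr_raw, n) / (n + 1.0)
    ls_above = np.clip(np.log((1.0 - q) / q), -9.0, 10.0)
    ls_below = -10.0 + 0.9 * (1.0 - q)
    ls = np.where(above, ls_above, ls_below)

    lists = {}
    for b in baits:
        i = gene_idx[b]
        pairs = [(genes[j], float(ls[i, j])) for j in range(n) if j != i]
        pairs.sort(key=lambda kv: (-kv[1], kv[0]))
        lists[b] = CoexprList.build(b, pairs[:200])

    module_of = {g: m for m, members in modules.items() for g in members}
    annotations = pd.DataFrame({
        "location": ["plastid" if g in module_of else "other" for g in genes],
        "class": ["bait" if g in set(baits) else "coexpressor" for g in genes],
    }, index=pd.Index(genes, name="accession"))
    truth = GroundTruth(modules={m: tuple(v) for m, v in modules.items()})
    return lists, annotations, truth


def load_table1_fixture() -> pd.DataFrame:
    """Packaged machine-readable table of the 59 trap-enriched proteins.

    Columns follow the published enrichment-table layout (per-protein
    observation counts, adjusted spectral counts, average TRAP/WT ratio on
    NadjSPC with a 1e-5 zero floor, and resampling p-value). All 59 proteins
    are plastid-localised and were identified with at least three distinct
    peptides, so ``location`` and ``n_peptides`` are filled accordingly.
    """
    ref = importlib.resources.files("clptrap") / "data" / "table1_enriched_proteins.tsv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE1_SHA256:
        raise ValueError("packaged enrichment table is corrupted "
                         f"(sha256 {digest})")
    df = pd.read_csv(io.StringIO(raw.decode()), sep="\t").set_index("accession")
    df["location"] = "plastid"
    df["n_peptides"] = 3           # published minimum; exact counts not listed
    # printed p of 0.00000 means below print precision; floor at the
    # resampling test's smallest attainable p (20,000 iterations)
    df["p_value"] = df["p_value"].clip(lower=1.0 / 20001.0)
    return df


def table1_annotations() -> pd.DataFrame:
    """Annotation frame (location, function, name) for the packaged table."""
    df = load_table1_fixture()
    return df[["location", "function", "name"]].copy()
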