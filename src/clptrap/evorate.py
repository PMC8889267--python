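"""Evolutionary rate covariation (ERC) and gene-duplication calling.

ERC asks whether two gene families show correlated lineage-specific
evolutionary rates across a shared set of species — a signature of
coevolution or shared selective pressure. Here a gene's rate in a species
is its terminal branch length in the gene tree; rates are normalised twice
(per species across genes, then per gene across species) to remove species
effects and gene-wide rate differences before Pearson correlation.

Duplication calling uses the species-overlap rule on a rooted gene tree: an
internal node is a duplication if the species sets of its child subtrees
intersect.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from collections.abc import Callable, Mapping, Sequence

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_gene_trees",
    "tip_rate_matrix",
    "normalize_rates",
    "erc_pair",
    "ERCPair",
    "erc_all_fdr",
    "erc_network",
    "DuplicationCall",
    "call_duplications",
    "write_erc_table",
]


def read_gene_trees(path, schema: str = "newick") -> dict:
    """Read one newick tree per line from a file of ``gene<TAB>newick`` rows,
    or a plain newick file (trees named ``gene_1``, ``gene_2``, ...)."""
    trees: dict = {}
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    for i, line in enumerate(lines, 1):
        if "\t" in line:
            name, nwk = line.split("\t", 1)
        else:
            name, nwk = f"gene_{i}", line
        trees[name] = dendropy.Tree.get(data=nwk, schema=schema)
    return trees


def _species_of(leaf, species_of_tip, delimiter):
    label = leaf.taxon.label if leaf.taxon is not None else str(leaf)
    if species_of_tip is not None:
        return species_of_tip(label)
    return label.split(delimiter)[0] if delimiter in label else label


def tip_rate_matrix(gene_trees: Mapping[str, dendropy.Tree],
                    species_of_tip: Callable[[str], str] | None = None,
                    delimiter: str = "|") -> pd.DataFrame:
    """Genes x species matrix of terminal branch lengths (NaN where absent)."""
    rows = {}
    for gene, tree in gene_trees.items():
        seen: dict = {}
        for leaf in tree.leaf_node_iter():
            sp = _species_of(leaf, species_of_tip, delimiter)
            if sp in seen:
                raise ValueError(
                    f"gene {gene!r}: duplicate species tip {sp!r}; resolve "
                    "paralogs before rate extraction")
            length = leaf.edge.length
            seen[sp] = float(length) if length is not None else np.nan
        rows[gene] = seen
    rm = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
    if (rm.fillna(0) < 0).any().any():
        raise ValueError("negative branch lengths")
    return rm


def normalize_rates(rm: pd.DataFrame, min_genes_per_species: int = 3,
                    floor: float = 1e-12) -> pd.DataFrame:
    """Remove species and gene rate effects by double mean-normalisation.

    Columns (species) observed in fewer than ``min_genes_per_species`` genes
    are dropped with a warning. Each surviving column is divided by its
    across-gene mean, then each row by its own mean over observed species.
    """
    observed = rm.notna().sum(axis=0)
    thin = observed.index[observed < min_genes_per_species]
    if len(thin):
        warnings.warn(f"dropping species observed in < {min_genes_per_species} "
                      f"genes: {', '.join(map(str, thin))}")
        rm = rm.drop(columns=thin)
    col_mean = rm.mean(axis=0, skipna=True).clip(lower=floor)
    out = rm.div(col_mean, axis=1)
    row_mean = out.mean(axis=1, skipna=True).clip(lower=floor)
    return out.div(row_mean, axis=0)


@dataclasses.dataclass(frozen=True)
class ERCPair:
    gene1: str
    gene2: str
    n_shared: int
    r: float
    p_raw: float
    p_adj: float = np.nan

    @property
    def valid(self) -> bool:
        return np.isfinite(self.r)


def erc_pair(rm: pd.DataFrame, g1: str, g2: str,
             min_overlap: int = 8) -> ERCPair:
    """Pearson correlation of two genes' rates over shared species.

    Returns an invalid (NaN) result when the species overlap is below
    ``min_overlap`` or either vector has zero variance.
    """
    a, b = rm.loc[g1], rm.loc[g2]
    mask = a.notna() & b.notna()
    n = int(mask.sum())
    if n < min_overlap:
        return ERCPair(g1, g2, n, np.nan, np.nan)
    x, y = a[mask].to_numpy(), b[mask].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ERCPair(g1, g2, n, np.nan, np.nan)
    r, p = stats.pearsonr(x, y)
    return ERCPair(g1, g2, n, float(r), float(p))


def erc_all_fdr(rm: pd.DataFrame, gene_set: Sequence[str] | None = None,
                min_overlap: int = 8) -> list:
    """All unordered pairs with Benjamini-Hochberg adjusted p-values.

    Invalid pairs (insufficient overlap or zero variance) are reported with
    NaN statistics and excluded from the FDR adjustment.
    """
    genes = list(gene_set) if gene_set is not None else list(rm.index)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    sub = rm.loc[genes]
    if not sub.isna().any().any() and sub.shape[1] >= min_overlap:
        pairs = _erc_all_complete(sub, genes)
    else:
        pairs = [erc_pair(rm, g1, g2, min_overlap=min_overlap)
                 for g1, g2 in itertools.combinations(genes, 2)]
    valid = [i for i, p in enumerate(pairs) if p.valid]
    if valid:
        _, p_adj, _, _ = multipletests([pairs[i].p_raw for i in valid],
                                       method="fdr_bh")
        for i, pa in zip(valid, p_adj):
            pairs[i] = dataclasses.replace(pairs[i], p_adj=float(pa))
    return pairs


def _erc_all_complete(sub: pd.DataFrame, genes: Sequence[str]) -> list:
    """All-pairs Pearson r and two-sided t-test p on a complete matrix."""
    x = sub.to_numpy(dtype=float)
    n = x.shape[1]
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    pairs = []
    for i, j in itertools.combinations(range(len(genes)), 2):
        if sd[i] == 0 or sd[j] == 0:
            pairs.append(ERCPair(genes[i], genes[j], n, np.nan, np.nan))
            continue
        r = float(np.clip(corr[i, j], -1.0, 1.0))
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), n - 2))
        pairs.append(ERCPair(genes[i], genes[j], n, r, p))
    return pairs


def erc_network(results: Sequence[ERCPair], alpha: float = 0.05,
                level: str = "adjusted") -> nx.Graph:
    """Graph of genes linked by significant rate covariation."""
    if level not in ("raw", "adjusted"):
        raise ValueError("level must be 'raw' or 'adjusted'")
    g = nx.Graph()
    for pair in results:
        p = pair.p_raw if level == "raw" else pair.p_adj
        if pair.valid and np.isfinite(p) and p < alpha:
            g.add_edge(pair.gene1, pair.gene2, r=pair.r, p=p)
    return g


@dataclasses.dataclass(frozen=True)
class DuplicationCall:
    node_id: int
    child_species_sets: tuple
    is_duplication: bool
    tip_labels: tuple


def call_duplications(gene_tree: dendropy.Tree,
                      species_of_tip: Callable[[str], str] | None = None,
                      delimiter: str = "|") -> list:
    """Species-overlap duplication calls on a rooted gene tree.

    Internal nodes are numbered in postorder. A node is a duplication iff
    any two of its child subtrees contain an overlapping species set.
    Multifurcating roots are rejected as unrooted.
    """
    root = gene_tree.seed_node
    if len(root.child_nodes()) > 2:
        raise ValueError("gene tree appears unrooted (multifurcating root); "
                         "provide a rooted tree")
    calls = []
    species_below: dict = {}
    node_idx = 0
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            species_below[node] = frozenset(
                [_species_of(node, species_of_tip, delimiter)])
            continue
        children = node.child_nodes()
        child_sets = tuple(species_below[c] for c in children)
        species_below[node] = frozenset().union(*child_sets)
        dup = any(a & b for a, b in itertools.combinations(child_sets, 2))
        tips = tuple(sorted(
            leaf.taxon.label for leaf in node.leaf_iter() if leaf.taxon))
        calls.append(DuplicationCall(node_idx, child_sets, dup, tips))
        node_idx += 1
    return calls


def write_erc_table(results: Sequence[ERCPair], path) -> None:
    """TSV of gene1, gene2, n, r, p_raw, p_adj."""
    pd.DataFrame([dataclasses.asdict(p) for p in results]).to_csv(
        path, sep="\t", index=False)
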