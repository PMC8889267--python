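"""Bait-enrichment statistics for TRAP-vs-WT affinity experiments.

The quantities of interest are per-bioreplicate TRAP/WT abundance ratios on
normalised adjusted spectral counts (NadjSPC), a resampling significance
test whose null standard deviation comes from a cubic fit of log10(sd)
against log10(mean) over adaptively binned protein abundances, and a
stringent candidate filter combining fold-change, reproducibility, and
spectral support.

Technical replicates are summed to the bioreplicate level before any ratio
is formed, so each genotype contributes one NadjSPC value per bioreplicate.
Zero denominators (and zero numerators) are floored at a small pseudo-value
so ratios stay finite.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import QuantMatrix

__all__ = [
    "LOCATIONS",
    "FUNCTION_BINS",
    "GleeFit",
    "load_annotations",
    "bioreplicate_nadjspc",
    "enrichment_ratio",
    "glee_fit",
    "glee_test",
    "glee_test_many",
    "prefilter_min_total",
    "apply_trap_filter",
    "volcano_table",
    "summarize_categories",
    "run_enrichment",
]

LOCATIONS = ("plastid", "mitochondria", "peroxisome", "other", "unknown")
FUNCTION_BINS = ("DNA-RNA", "metabolism", "proteostasis", "unknown", "other")


def load_annotations(path) -> pd.DataFrame:
    """Read an annotation TSV (accession, location, function[, name])."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("accession")
    if df.index.duplicated().any():
        raise ValueError("duplicate accessions in annotation table")
    return df


def bioreplicate_nadjspc(qm: QuantMatrix) -> pd.DataFrame:
    """Collapse technical runs and normalise: one NadjSPC per bioreplicate.

    Returns a frame indexed by accession with one column per
    (genotype, bioreplicate); each column sums adjSPC over that biorep's
    technical runs and divides by the biorep total over retained proteins.
    """
    adj = qm.adjspc.loc[qm.retained()]
    groups: dict = {}
    for key in qm.roster:
        groups.setdefault((key.genotype, key.bioreplicate), []).append(key.label)
    out = {}
    for (g, b), cols in sorted(groups.items()):
        total = adj[cols].to_numpy().sum()
        summed = adj[cols].sum(axis=1)
        out[(g, b)] = summed / total if total > 0 else summed * 0.0
    frame = pd.DataFrame(out)
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["genotype", "bioreplicate"])
    return frame


def bioreplicate_adjspc(qm: QuantMatrix) -> pd.DataFrame:
    """As :func:`bioreplicate_nadjspc` but without normalisation."""
    adj = qm.adjspc.loc[qm.retained()]
    groups: dict = {}
    for key in qm.roster:
        groups.setdefault((key.genotype, key.bioreplicate), []).append(key.label)
    frame = pd.DataFrame({gb: adj[cols].sum(axis=1)
                          for gb, cols in sorted(groups.items())})
    frame.columns = pd.MultiIndex.from_tuples(frame.columns,
                                              names=["genotype", "bioreplicate"])
    return frame


def enrichment_ratio(qm: QuantMatrix, zero_floor: float = 1e-5,
                     trap: str = "TRAP", wt: str = "WT") -> pd.DataFrame:
    """Per-bioreplicate TRAP/WT NadjSPC ratios and their mean.

    ``ratio_b = max(TRAP_b, floor) / max(WT_b, floor)``; the average is taken
    over bioreplicates in which the protein was observed in either genotype.
    """
    nadj = bioreplicate_nadjspc(qm)
    trap_cols = [c for c in nadj.columns if c[0] == trap]
    wt_cols = [c for c in nadj.columns if c[0] == wt]
    bioreps = sorted({c[1] for c in trap_cols} & {c[1] for c in wt_cols})
    if not bioreps:
        raise ValueError("no paired TRAP/WT bioreplicates in the design")

    t = nadj[[(trap, b) for b in bioreps]].to_numpy()
    w = nadj[[(wt, b) for b in bioreps]].to_numpy()
    ratios = np.maximum(t, zero_floor) / np.maximum(w, zero_floor)
    observed = (t > 0) | (w > 0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg = np.where(observed.any(axis=1),
                       np.nansum(np.where(observed, ratios, np.nan), axis=1)
                       / observed.sum(axis=1).clip(min=1),
                       np.nan)
    out = pd.DataFrame(
        {f"ratio_b{b}": ratios[:, i] for i, b in enumerate(bioreps)},
        index=nadj.index)
    out["avg_ratio"] = avg
    out["n_bioreps_trap_observed"] = (t > 0).sum(axis=1)
    return out


@dataclasses.dataclass(frozen=True)
class GleeFit:
    """Cubic log10(sd)-vs-log10(mean) variance model with an sd floor."""

    coefficients: np.ndarray        # highest power first, degree 3
    bin_log_means: np.ndarray
    bin_log_sds: np.ndarray
    sd_floor: float
    log_mean_range: tuple
    n_iterations: int = 20_000

    def predict_sd(self, mean: np.ndarray) -> np.ndarray:
        """Predicted sd at an abundance; clamped to the fitted range and floor."""
        m = np.maximum(np.asarray(mean, dtype=float), 10.0 ** self.log_mean_range[0])
        logm = np.clip(np.log10(m), *self.log_mean_range)
        sd = 10.0 ** np.polyval(self.coefficients, logm)
        return np.maximum(sd, self.sd_floor)


def glee_fit(condition_values: Sequence[pd.DataFrame] | pd.DataFrame,
             degree: int = 3, n_iterations: int = 20_000) -> GleeFit:
    """Fit the variance-vs-mean trend over adaptively binned abundances.

    ``condition_values`` is one frame per condition (proteins x replicate
    columns). Per protein and condition, the replicate mean and sample sd
    are computed; pairs with positive mean are sorted by log10 mean and cut
    into equal-count bins (bin count = clip(n/20, 5, 30)); a cubic is fit
    through per-bin medians of log10 mean and log10 sd. Zero sds are floored
    at one tenth of the smallest nonzero sd.
    """
    if isinstance(condition_values, pd.DataFrame):
        condition_values = [condition_values]
    means, sds = [], []
    for frame in condition_values:
        vals = frame.to_numpy(dtype=float)
        if vals.shape[1] < 2:
            raise ValueError("need >= 2 replicates per condition")
        # the sample sd of k replicates has median sigma*sqrt(chi2_median/df);
        # divide it out so the fitted trend is median-unbiased for sigma
        df = vals.shape[1] - 1
        debias = np.sqrt(stats.chi2.median(df) / df)
        means.append(vals.mean(axis=1))
        sds.append(vals.std(axis=1, ddof=1) / debias)
    mean = np.concatenate(means)
    sd = np.concatenate(sds)
    keep = mean > 0
    mean, sd = mean[keep], sd[keep]
    if mean.size < 25:
        raise ValueError("fewer than 25 proteins with nonzero mean; "
                         "provide more data")
    nonzero_sd = sd[sd > 0]
    if nonzero_sd.size == 0:
        raise ValueError("all replicate sets are identical; variance trend "
                         "is undefined")
    sd_floor = nonzero_sd.min() / 10.0
    sd = np.maximum(sd, sd_floor)

    order = np.argsort(np.log10(mean), kind="stable")
    n_bins = int(np.clip(mean.size // 20, 5, 30))
    chunks = np.array_split(order, n_bins)
    chunks = [c for c in chunks if c.size]
    if len(chunks) < 5:
        raise ValueError("fewer than 5 usable bins; provide more data")
    bin_logm = np.array([np.median(np.log10(mean[c])) for c in chunks])
    bin_logs = np.array([np.median(np.log10(sd[c])) for c in chunks])
    coeffs = np.polyfit(bin_logm, bin_logs, deg=degree)
    logm = np.log10(mean)
    return GleeFit(coefficients=coeffs, bin_log_means=bin_logm,
                   bin_log_sds=bin_logs, sd_floor=sd_floor,
                   log_mean_range=(float(logm.min()), float(logm.max())),
                   n_iterations=n_iterations)


def glee_test(fit: GleeFit, wt_values, trap_values,
              n_iterations: int | None = None, seed: int = 0) -> float:
    """Two-sided resampling p-value for a difference of condition means.

    Both conditions are resampled from a common Gaussian null whose mean is
    the pooled mean and whose sd comes from the fitted variance trend;
    ``p = (1 + #{|d*| >= |d|}) / (n_iterations + 1)``.
    """
    p = glee_test_many(fit, np.atleast_2d(np.asarray(wt_values, dtype=float)),
                       np.atleast_2d(np.asarray(trap_values, dtype=float)),
                       n_iterations=n_iterations, seed=seed)
    return float(p[0])


def glee_test_many(fit: GleeFit, wt: np.ndarray, trap: np.ndarray,
                   n_iterations: int | None = None, seed: int = 0,
                   chunk: int = 256) -> np.ndarray:
    """Vectorised :func:`glee_test` over rows of two replicate matrices."""
    wt = np.asarray(wt, dtype=float)
    trap = np.asarray(trap, dtype=float)
    if not (np.isfinite(wt).all() and np.isfinite(trap).all()):
        raise ValueError("non-finite abundance values")
    if n_iterations is None:
        n_iterations = fit.n_iterations
    n_prot, kw = wt.shape
    kt = trap.shape[1]
    d_obs = trap.mean(axis=1) - wt.mean(axis=1)
    m0 = (wt.sum(axis=1) + trap.sum(axis=1)) / (kw + kt)
    sigma0 = fit.predict_sd(m0)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_prot, dtype=np.int64)
    for start in range(0, n_prot, chunk):
        sl = slice(start, min(start + chunk, n_prot))
        n = sl.stop - sl.start
        mu = m0[sl][:, None, None]
        sig = sigma0[sl][:, None, None]
        wt_star = rng.normal(mu, sig, size=(n, n_iterations, kw)).mean(axis=2)
        trap_star = rng.normal(mu, sig, size=(n, n_iterations, kt)).mean(axis=2)
        d_star = trap_star - wt_star
        exceed[sl] = (np.abs(d_star) >= np.abs(d_obs[sl])[:, None]).sum(axis=1)
    return (1.0 + exceed) / (n_iterations + 1.0)


def prefilter_min_total(records: pd.DataFrame, min_total: float = 18,
                        location: str = "plastid") -> pd.DataFrame:
    """Keep proteins of the stated location with enough total spectral support."""
    mask = records["total_adjspc_all"] >= min_total
    if location is not None and "location" in records.columns:
        mask &= records["location"] == location
    records = records.copy()
    records["pass_prefilter"] = mask
    return records[mask]


def apply_trap_filter(records: pd.DataFrame, min_ratio: float = 3,
                      min_bioreps: int = 2, min_trap_spc: float = 18,
                      min_peptides: int = 3) -> pd.DataFrame:
    """Stringent candidate filter: fold-change, reproducibility, support.

    Requires avg TRAP/WT ratio >= ``min_ratio``, observation in at least
    ``min_bioreps`` TRAP bioreplicates, at least ``min_trap_spc`` adjSPC in
    the TRAP samples, and at least ``min_peptides`` distinct peptides.
    """
    mask = ((records["avg_ratio"] >= min_ratio)
            & (records["n_bioreps_trap_observed"] >= min_bioreps)
            & (records["total_adjspc_trap"] >= min_trap_spc)
            & (records["n_peptides"] >= min_peptides))
    out = records.copy()
    out["pass_enrichment"] = mask
    return out[mask]


def volcano_table(records: pd.DataFrame, ratio_floor: float = 1e-5,
                  p_floor: float = 5e-5) -> pd.DataFrame:
    """log2 fold-change vs -log10 p with significance/effect flags."""
    ratio = records["avg_ratio"].clip(lower=ratio_floor)
    p = records["p_value"].clip(lower=p_floor)
    out = pd.DataFrame({
        "log2_ratio": np.log2(ratio),
        "neg_log10_p": -np.log10(p),
    }, index=records.index)
    out["sig_p05"] = p < 0.05
    out["sig_p01"] = p < 0.01
    out["enriched_3fold"] = np.abs(out["log2_ratio"]) >= np.log2(3)
    return out


def summarize_categories(candidates: pd.DataFrame,
                         annotations: pd.DataFrame | None = None) -> pd.Series:
    """Count candidates per function bin (plus a 'total' entry)."""
    if "function" in candidates.columns:
        funcs = candidates["function"]
    elif annotations is not None:
        funcs = candidates.index.to_series().map(annotations["function"])
    else:
        raise ValueError("no function annotation available")
    missing = funcs.isna() | ~funcs.isin(FUNCTION_BINS)
    if missing.any():
        warnings.warn(f"{int(missing.sum())} candidates without a function "
                      "annotation counted as 'other'")
        funcs = funcs.where(~missing, "other")
    counts = funcs.value_counts().reindex(FUNCTION_BINS, fill_value=0)
    counts["total"] = int(counts.sum())
    return counts


def run_enrichment(qm: QuantMatrix, annotations: pd.DataFrame | None = None,
                   *, zero_floor: float = 1e-5, iterations: int = 20_000,
                   seed: int = 0, bait_accessions: Sequence[str] | None = None,
                   trap: str = "TRAP", wt: str = "WT") -> pd.DataFrame:
    """Full per-protein enrichment table from a quantified dataset.

    Ratios use total-normalised NadjSPC; the significance test runs on
    bait-normalised abundances when ``bait_accessions`` is given, otherwise
    on the same total-normalised values.
    """
    ratios = enrichment_ratio(qm, zero_floor=zero_floor, trap=trap, wt=wt)

    adj = bioreplicate_adjspc(qm)
    trap_cols = [c for c in adj.columns if c[0] == trap]
    wt_cols = [c for c in adj.columns if c[0] == wt]
    records = pd.DataFrame({
        "avg_ratio": ratios["avg_ratio"],
        "n_bioreps_trap_observed": ratios["n_bioreps_trap_observed"],
        "total_adjspc_all": adj.sum(axis=1),
        "total_adjspc_trap": adj[trap_cols].sum(axis=1),
        "total_adjspc_wt": adj[wt_cols].sum(axis=1),
        "n_peptides": qm.n_peptides.loc[ratios.index],
    })

    nadj = bioreplicate_nadjspc(qm)
    if bait_accessions:
        baits = [b for b in bait_accessions if b in adj.index]
        if not baits:
            raise ValueError("no bait accession present in the data")
        denom = adj.loc[baits].sum(axis=0)
        if (denom == 0).any():
            bad = denom.index[denom == 0][0]
            raise ValueError(f"bait adjSPC total is zero in bioreplicate {bad!r}")
        test_vals = adj / denom
    else:
        test_vals = nadj
    fit = glee_fit([test_vals[trap_cols], test_vals[wt_cols]],
                   n_iterations=iterations)
    records["p_value"] = glee_test_many(
        fit, test_vals[wt_cols].to_numpy(), test_vals[trap_cols].to_numpy(),
        n_iterations=iterations, seed=seed)

    if annotations is not None:
        records = records.join(annotations[["location", "function"]], how="left")
    records["pass_prefilter"] = False
    records["pass_enrichment"] = False
    return records
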