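"""CN-state / expression association engine.

Negative-binomial GLM testing of RNA-seq counts against per-region CN
state, with trimmed-mean normalization factors, expression and group-size
filters, an ANOVA-like likelihood-ratio test of all deviating CN groups
against the diploid reference, per-state log2 fold changes, dosage
direction calls, region/gene adjacency summaries and a synergy statistic
for pairs of regulator regions.

Filtering defaults follow the two analysis modes: local tests (genes
overlapping the region) use r = 3 cpm / s = 4 samples at a nominal 0.05;
genome-wide distal tests use r = 25 cpm / s = 10 samples with
Benjamini-Hochberg control at 0.01 jointly over all tested pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._utils import bh_adjust, overlap_len
from .nbglm import DispersionModel, estimate_dispersion, fit_oneway

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.5   # for all log-scale descriptive statistics
_DIR_TOL = 0.1      # log2 units: states disagreeing in sign beyond this -> mixed


@dataclass
class AssocThresholds:
    r_cpm: float
    s_min: int
    alpha: float
    mode: str = "local"      # local | distal
    mtc: str = "none"        # none | BH

    def __post_init__(self):
        if self.r_cpm <= 0 or self.s_min < 1 or not 0 < self.alpha < 1:
            raise ValueError("invalid association thresholds")

    @classmethod
    def local(cls) -> "AssocThresholds":
        return cls(r_cpm=3.0, s_min=4, alpha=0.05, mode="local", mtc="none")

    @classmethod
    def distal(cls) -> "AssocThresholds":
        return cls(r_cpm=25.0, s_min=10, alpha=0.01, mode="distal", mtc="BH")


@dataclass
class CountMatrix:
    """Genes x samples raw counts with library sizes and norm factors."""

    counts: pd.DataFrame
    lib_size: pd.Series
    norm_factors: pd.Series

    @classmethod
    def from_frame(cls, counts: pd.DataFrame, lib_size: pd.Series | None = None) -> "CountMatrix":
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if lib_size is None:
            lib_size = counts.sum(axis=0).astype(float)
        lib_size = lib_size.reindex(counts.columns).astype(float)
        nf = pd.Series(1.0, index=counts.columns)
        return cls(counts=counts, lib_size=lib_size, norm_factors=nf)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def effective_lib(self) -> pd.Series:
        return self.lib_size * self.norm_factors

    def cpm(self) -> pd.DataFrame:
        eff = self.effective_lib()
        if (eff <= 0).any():
            raise ValueError("non-positive effective library size")
        return self.counts * 1e6 / eff

    def subset_samples(self, samples) -> "CountMatrix":
        return CountMatrix(self.counts[list(samples)],
                           self.lib_size.loc[list(samples)],
                           self.norm_factors.loc[list(samples)])


def cpm(cm: CountMatrix, gene: str, sample: str) -> float:
    """Counts per million effective library reads for one cell."""
    eff = float(cm.lib_size[sample] * cm.norm_factors[sample])
    if eff <= 0:
        raise ValueError("non-positive effective library size")
    return float(cm.counts.at[gene, sample]) * 1e6 / eff


# ---------------------------------------------------------------------------
# Trimmed-mean-of-log-ratios normalization
# ---------------------------------------------------------------------------

def _tmm_factor(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
                trim_m: float, trim_a: float) -> float:
    keep = (obs > 0) & (ref > 0)
    if keep.sum() == 0:
        return 1.0
    po, pr = obs[keep] / lib_obs, ref[keep] / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    n = m.size
    lo_m, hi_m = int(np.floor(n * trim_m)), n - int(np.floor(n * trim_m))
    lo_a, hi_a = int(np.floor(n * trim_a)), n - int(np.floor(n * trim_a))
    rank_m = m.argsort().argsort()
    rank_a = a.argsort().argsort()
    sel = (rank_m >= lo_m) & (rank_m < hi_m) & (rank_a >= lo_a) & (rank_a < hi_a)
    if sel.sum() == 0:
        return 1.0
    return float(2.0 ** np.mean(m[sel]))


def compute_norm_factors(cm: CountMatrix, trim_m: float = 0.30,
                         trim_a: float = 0.05) -> CountMatrix:
    """Trimmed-mean-of-log-ratios scaling factors.

    The reference sample is the column whose upper quartile of count rates
    is closest to the mean upper quartile; per-sample factors are the
    doubly-trimmed (30% on log-ratios M, 5% on average log-abundance A)
    mean M against the reference, geometrically centered to product 1.
    """
    Y = cm.counts.to_numpy(dtype=float)
    if Y.shape[1] < 2:
        raise ValueError("need at least two samples")
    zero_cols = np.flatnonzero(Y.sum(axis=0) == 0)
    if zero_cols.size:
        raise ValueError(f"all-zero sample column: {cm.samples[zero_cols[0]]}")
    lib = cm.lib_size.to_numpy(dtype=float)
    uq = np.array([np.quantile(Y[:, j] / lib[j], 0.75) for j in range(Y.shape[1])])
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array([
        _tmm_factor(Y[:, j], Y[:, ref_j], lib[j], lib[ref_j], trim_m, trim_a)
        for j in range(Y.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    out = CountMatrix(cm.counts, cm.lib_size.copy(),
                      pd.Series(factors, index=cm.counts.columns))
    return out


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass
class RegionDesign:
    """Surviving CN groups of a region after the sample-size filter."""

    region_id: str
    states: list[int]             # deviating states with >= s_min samples
    groups: dict[int, list[str]]  # state (incl. 2) -> sample ids
    kept_genes: list[str] = field(default_factory=list)


def filter_genes_regions(
    cm: CountMatrix,
    matrix: pd.DataFrame,
    th: AssocThresholds,
    genes: list[str] | None = None,
) -> dict[str, RegionDesign]:
    """Apply the expression and group-size filters.

    Per region, deviating CN states with fewer than ``s_min`` samples are
    dropped; regions with no surviving deviating state are excluded. Per
    (region, gene), the gene is kept iff the maximum over the region's CN
    groups of the group mean cpm reaches ``r_cpm``.
    """
    shared = [s for s in matrix.columns if s in set(cm.samples)]
    if not shared:
        raise ValueError("no samples shared between counts and genotype matrix")
    if genes is None:
        genes = cm.genes
    cpm_df = cm.cpm()[shared]
    designs: dict[str, RegionDesign] = {}
    for rid in matrix.index:
        row = matrix.loc[rid, shared]
        groups: dict[int, list[str]] = {}
        for s in sorted(row.unique()):
            members = row.index[row == s].tolist()
            if s == 2:
                groups[2] = members
            elif len(members) >= th.s_min:
                groups[int(s)] = members
        dev = [s for s in groups if s != 2]
        if not dev or 2 not in groups:
            continue
        grp_mean = pd.concat(
            {s: cpm_df.loc[genes, m].mean(axis=1) for s, m in groups.items()}, axis=1
        )
        kept = grp_mean.max(axis=1) >= th.r_cpm
        designs[rid] = RegionDesign(region_id=rid, states=dev, groups=groups,
                                    kept_genes=list(kept.index[kept]))
    return designs


# ---------------------------------------------------------------------------
# Testing
# ---------------------------------------------------------------------------

def fit_dispersion(
    cm: CountMatrix,
    groups: pd.Series | None = None,
    genes: list[str] | None = None,
    prior_obs: float = 10.0,
    genewise: bool = True,
) -> DispersionModel:
    """Estimate common + shrunken gene-wise dispersions.

    ``groups`` maps sample id to a factor level (e.g. the CN state of a
    region of interest); ``None`` fits an intercept-only design. Genes with
    zero total count are excluded from estimation.
    """
    genes = genes if genes is not None else cm.genes
    Y = cm.counts.loc[genes].to_numpy(dtype=float)
    nz = Y.sum(axis=1) > 0
    if not nz.any():
        raise ValueError("all counts are zero")
    genes_nz = [g for g, keep in zip(genes, nz) if keep]
    lib = cm.effective_lib().to_numpy(dtype=float)
    if groups is None:
        group_cols = [np.arange(Y.shape[1])]
    else:
        groups = groups.reindex(cm.samples)
        group_cols = [np.flatnonzero((groups == lev).to_numpy())
                      for lev in pd.unique(groups.dropna())]
    model = estimate_dispersion(Y[nz], lib, group_cols, gene_ids=genes_nz,
                                prior_obs=prior_obs, genewise=genewise)
    return model


def _region_block_test(
    Y: np.ndarray,
    lib_eff: np.ndarray,
    cn: np.ndarray,
    states: list[int],
    alpha: np.ndarray,
):
    """Vectorized LRT for one region over a block of genes.

    Samples in deviating states that were filtered out are excluded
    entirely. Returns per-gene stat, p, log2fc (G x len(states)), and a
    convergence flag.
    """
    group_cols = [np.flatnonzero(cn == 2)] + [np.flatnonzero(cn == s) for s in states]
    if group_cols[0].size == 0:
        raise ValueError("empty 2n reference group")
    full = fit_oneway(Y, lib_eff, group_cols, alpha)
    all_cols = np.concatenate(group_cols)
    null = fit_oneway(Y, lib_eff, [all_cols], alpha)
    stat = np.maximum(2.0 * (full.loglik - null.loglik), 0.0)
    df = len(states)
    p = chi2.sf(stat, df)
    ref = np.maximum(full.rates[:, 0], 1e-12)
    log2fc = np.log2(np.maximum(full.rates[:, 1:], 1e-12) / ref[:, None])
    ok = full.converged & null.converged
    sizes = np.array([c.size for c in group_cols])
    return stat, p, log2fc, ok, sizes


def _dosage_direction(states: list[int], log2fc: np.ndarray, sizes: np.ndarray) -> tuple[str, float]:
    """Direction of expression with copy-number gain.

    Weighted least-squares slope of per-state log2FC (reference 0 at CN=2)
    on CN, weights = group sizes; 'mixed' when states imply conflicting
    directions beyond a 0.1 log2 tolerance.
    """
    cn_vals = np.array([2] + list(states), dtype=float)
    fc = np.concatenate([[0.0], log2fc])
    w = sizes.astype(float)
    x = cn_vals - np.average(cn_vals, weights=w)
    denom = np.sum(w * x * x)
    slope = float(np.sum(w * x * fc) / denom) if denom > 0 else 0.0
    dirs = set()
    for s, f in zip(states, log2fc):
        if abs(f) <= _DIR_TOL:
            continue
        dirs.add(np.sign(f) * np.sign(s - 2))
    if len(dirs) > 1:
        return "mixed", slope
    if slope > 0:
        return "up_with_gain", slope
    if slope < 0:
        return "down_with_gain", slope
    return "mixed", slope


def _records_for_designs(
    cm: CountMatrix,
    matrix: pd.DataFrame,
    designs: dict[str, RegionDesign],
    disp: DispersionModel,
    genes_for_region,
) -> pd.DataFrame:
    lib_all = cm.effective_lib()
    rows = []
    for rid, des in designs.items():
        genes = genes_for_region(rid, des)
        if not genes:
            continue
        samples = [s for members in des.groups.values() for s in members]
        Y = cm.counts.loc[genes, samples].to_numpy(dtype=float)
        lib = lib_all.loc[samples].to_numpy(dtype=float)
        cn = matrix.loc[rid, samples].to_numpy(dtype=int)
        alpha = disp.for_genes(genes)
        stat, p, log2fc, ok, sizes = _region_block_test(Y, lib, cn, des.states, alpha)
        for i, g in enumerate(genes):
            direction, slope = _dosage_direction(des.states, log2fc[i], sizes)
            rows.append({
                "region_id": rid, "gene_id": g,
                "states": ",".join(map(str, des.states)),
                "log2fc": {s: float(log2fc[i, j]) for j, s in enumerate(des.states)},
                "stat": float(stat[i]) if ok[i] else np.nan,
                "df": len(des.states),
                "p": float(p[i]) if ok[i] else np.nan,
                "slope": slope,
                "dosage_direction": direction,
                "converged": bool(ok[i]),
            })
    rec = pd.DataFrame(rows)
    if rec.empty:
        return pd.DataFrame(columns=["region_id", "gene_id", "states", "log2fc", "stat",
                                     "df", "p", "fdr", "slope", "dosage_direction",
                                     "converged", "significant"])
    return rec


def test_association(
    cm: CountMatrix,
    matrix: pd.DataFrame,
    region_id: str,
    gene_id: str,
    disp: DispersionModel,
    states: list[int] | None = None,
) -> pd.Series:
    """Single (region, gene) NB-GLM ANOVA-like test vs the 2n reference.

    ``states`` restricts testing to the given deviating CN states (samples
    in other deviating states are excluded); default tests every deviating
    state present.
    """
    row = matrix.loc[region_id, cm.samples]
    if states is None:
        states = sorted(int(s) for s in row.unique() if s != 2)
    if not states:
        raise ValueError(f"region {region_id}: no deviating CN state to test")
    if (row == 2).sum() == 0:
        raise ValueError(f"region {region_id}: empty 2n reference group")
    des = RegionDesign(region_id=region_id, states=states,
                       groups={s: row.index[row == s].tolist() for s in [2] + states})
    rec = _records_for_designs(cm, matrix, {region_id: des}, disp,
                               lambda rid, d: [gene_id])
    return rec.iloc[0]


def run_local(
    cm: CountMatrix,
    matrix: pd.DataFrame,
    regions: pd.DataFrame,
    annotation: pd.DataFrame,
    th: AssocThresholds | None = None,
    disp: DispersionModel | None = None,
) -> pd.DataFrame:
    """Test CNV-containing genes (>= 1 bp overlap with the region) for local
    dosage effects at the nominal level; no multiple-testing correction."""
    th = th or AssocThresholds.local()
    disp = disp or fit_dispersion(cm)
    designs = filter_genes_regions(cm, matrix, th)
    ann = annotation.set_index("gene_id")
    coords = regions.set_index("region_id")

    def genes_for(rid: str, des: RegionDesign) -> list[str]:
        r = coords.loc[rid]
        out = []
        for g in des.kept_genes:
            if g not in ann.index:
                continue
            a = ann.loc[g]
            if a["chrom"] == r["chrom"] and overlap_len(
                    int(a["start"]), int(a["end"]), int(r["start"]), int(r["end"])) > 0:
                out.append(g)
        return out

    rec = _records_for_designs(cm, matrix, designs, disp, genes_for)
    if not rec.empty:
        rec["fdr"] = np.nan
        rec["significant"] = rec["p"] <= th.alpha
    return rec


def run_distal(
    cm: CountMatrix,
    matrix: pd.DataFrame,
    th: AssocThresholds | None = None,
    disp: DispersionModel | None = None,
) -> pd.DataFrame:
    """Test every surviving (region, gene) pair genome-wide; BH adjustment
    jointly over all tested pairs, significant = fdr <= alpha."""
    th = th or AssocThresholds.distal()
    disp = disp or fit_dispersion(cm)
    designs = filter_genes_regions(cm, matrix, th)
    rec = _records_for_designs(cm, matrix, designs, disp,
                               lambda rid, des: des.kept_genes)
    if not rec.empty:
        rec["fdr"] = bh_adjust(rec["p"].to_numpy())
        rec["significant"] = rec["fdr"] <= th.alpha
    return rec


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_directions(records: pd.DataFrame, min_genes_flag: int = 10) -> pd.DataFrame:
    """Per-region counts of significant genes going up/down with CN gain."""
    if records.empty:
        return pd.DataFrame(columns=["region_id", "n_up", "n_down", "n_mixed",
                                     "n_significant", "high_impact"])
    sig = records[records["significant"].fillna(False)]
    rows = []
    for rid in records["region_id"].unique():
        sub = sig[sig["region_id"] == rid]
        n_up = int((sub["dosage_direction"] == "up_with_gain").sum())
        n_down = int((sub["dosage_direction"] == "down_with_gain").sum())
        n_mixed = int((sub["dosage_direction"] == "mixed").sum())
        rows.append({"region_id": rid, "n_up": n_up, "n_down": n_down,
                     "n_mixed": n_mixed, "n_significant": len(sub),
                     "high_impact": len(sub) >= min_genes_flag})
    return pd.DataFrame(rows)


def adjacency(records: pd.DataFrame, min_regions: int = 3) -> pd.DataFrame:
    """Binary region x gene adjacency over significant pairs, restricted to
    genes associated with >= min_regions regions; gene rows ordered by
    marginal (number of associated regions) descending."""
    if min_regions < 1:
        raise ValueError("min_regions must be >= 1")
    sig = records[records["significant"].fillna(False)]
    if sig.empty:
        return pd.DataFrame()
    adj = (pd.crosstab(sig["gene_id"], sig["region_id"]) > 0).astype(int)
    marg = adj.sum(axis=1)
    adj = adj.loc[marg[marg >= min_regions].sort_values(ascending=False).index]
    return adj


@dataclass
class SynergyResult:
    gene_id: str
    score: float
    group_means: dict[str, float]
    group_sizes: dict[str, int]
    p: float | None     # None when any cell has < 3 samples (descriptive only)


def synergy_score(
    cm: CountMatrix,
    matrix: pd.DataFrame,
    region_a: str, state_a: int,
    region_b: str, state_b: int,
    gene: str,
) -> SynergyResult:
    """Excess of the double-carrier group over the additive expectation.

    On the log2(cpm + 0.5) scale:
        score = mean(both) - [mean(onlyA) + mean(onlyB) - mean(neither)].
    A two-way OLS interaction p-value is attached only when every cell has
    at least 3 samples; otherwise the result is descriptive.
    """
    samples = cm.samples
    in_a = matrix.loc[region_a, samples] == state_a
    in_b = matrix.loc[region_b, samples] == state_b
    logx = np.log2(cm.cpm().loc[gene, samples] + PSEUDOCOUNT)
    cells = {
        "both": logx[in_a & in_b],
        "only_a": logx[in_a & ~in_b],
        "only_b": logx[~in_a & in_b],
        "neither": logx[~in_a & ~in_b],
    }
    if len(cells["neither"]) == 0:
        raise ValueError("empty 'neither' group; synergy undefined")
    for name in ("both", "only_a", "only_b"):
        if len(cells[name]) == 0:
            raise ValueError(f"empty '{name}' group; both effect states must be observed")
    means = {k: float(v.mean()) for k, v in cells.items()}
    sizes = {k: int(len(v)) for k, v in cells.items()}
    score = means["both"] - (means["only_a"] + means["only_b"] - means["neither"])
    p = None
    if all(n >= 3 for n in sizes.values()):
        import statsmodels.api as sm
        a = (in_a.to_numpy()).astype(float)
        b = (in_b.to_numpy()).astype(float)
        X = sm.add_constant(np.column_stack([a, b, a * b]))
        fit = sm.OLS(logx.to_numpy(), X).fit()
        p = float(fit.pvalues[3])
    return SynergyResult(gene_id=gene, score=float(score), group_means=means,
                         group_sizes=sizes, p=p)


def records_to_table(records: pd.DataFrame) -> pd.DataFrame:
    """Flatten the per-state log2fc dict for TSV output."""
    if records.empty:
        return records
    out = records.copy()
    out["log2fc"] = out["log2fc"].map(
        lambda d: ";".join(f"{s}:{v:.4f}" for s, v in d.items())
    )
    return out
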