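"""Region and gene-set enrichment.

Three flavours:

* permutation enrichment of a weighted genomic feature track within a CNV
  region, against same-length regions placed uniformly on the same
  chromosome (rejection-sampled against an exclusion list);
* Fisher's exact enrichment of transcription-factor binding sites in
  strand-aware promoter windows of a query gene set vs a background;
* generic Fisher over-representation of user-supplied gene sets (GMT).

Fisher tests are two-sided; families are BH-adjusted (conventional FDR
cutoff 0.1 downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from ._utils import bh_adjust, overlap_len

DEFAULT_PROMOTER = (-2000, 500)   # relative to TSS, strand-aware


@dataclass
class RegionEnrichment:
    region_id: str
    feature_label: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p_perm: float
    n_perm: int
    tail: str


def _label_arrays(track: pd.DataFrame, chrom: str, labels: list[str]):
    """Per-label (starts, ends, weights) numpy views for one chromosome."""
    sub = track[track["chrom"] == chrom]
    out = {}
    for lab in labels:
        ls = sub[sub["label"] == lab]
        out[lab] = (ls["start"].to_numpy(dtype=float),
                    ls["end"].to_numpy(dtype=float),
                    ls["weight"].to_numpy(dtype=float))
    return out


def _weighted_overlap_arrays(arrays, labels: list[str], start: int, end: int) -> np.ndarray:
    obs = np.zeros(len(labels))
    for j, lab in enumerate(labels):
        s, e, w = arrays[lab]
        obs[j] = w[(s < end) & (e > start)].sum()
    return obs


def region_feature_enrichment(
    region: tuple[str, str, int, int],
    track: pd.DataFrame,
    genome: dict[str, int],
    n_perm: int = 1000,
    exclusions: pd.DataFrame | None = None,
    seed: int = 0,
    tail: str = "enrichment",
) -> pd.DataFrame:
    """Permutation enrichment of track features in one region.

    ``region`` is (region_id, chrom, start, end). The observed statistic per
    feature label is the summed weight of overlapping intervals; the null
    places ``n_perm`` same-length regions uniformly on the same chromosome,
    rejecting placements that touch an exclusion interval.

    p = (1 + #{null >= observed}) / (n_perm + 1) for the enrichment tail
    (<= for depletion); z is reported from the null mean/sd and is NaN when
    the null is degenerate.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if tail not in ("enrichment", "depletion"):
        raise ValueError("tail must be 'enrichment' or 'depletion'")
    rid, chrom, start, end = region
    if chrom not in genome:
        raise ValueError(f"chromosome {chrom} not in genome")
    length = end - start
    if length <= 0 or length > genome[chrom]:
        raise ValueError("region longer than usable chromosome span")
    rng = np.random.default_rng(seed)
    excl = []
    if exclusions is not None:
        excl = [(int(r["start"]), int(r["end"]))
                for _, r in exclusions[exclusions["chrom"] == chrom].iterrows()]

    labels = sorted(track["label"].unique())
    arrays = _label_arrays(track, chrom, labels)
    obs = _weighted_overlap_arrays(arrays, labels, start, end)

    max_start = genome[chrom] - length
    null = np.zeros((n_perm, len(labels)))
    placed = 0
    attempts = 0
    while placed < n_perm:
        attempts += 1
        if attempts > 100 * n_perm:
            raise RuntimeError("rejection sampling failed; exclusions too dense")
        s = int(rng.integers(0, max_start + 1))
        e = s + length
        if any(overlap_len(s, e, xs, xe) > 0 for xs, xe in excl):
            continue
        null[placed] = _weighted_overlap_arrays(arrays, labels, s, e)
        placed += 1

    rows = []
    for j, lab in enumerate(labels):
        o = float(obs[j])
        nm, nsd = float(null[:, j].mean()), float(null[:, j].std(ddof=1))
        if tail == "enrichment":
            p = (1 + int((null[:, j] >= o).sum())) / (n_perm + 1)
        else:
            p = (1 + int((null[:, j] <= o).sum())) / (n_perm + 1)
        z = (o - nm) / nsd if nsd > 0 else np.nan
        rows.append(RegionEnrichment(region_id=rid, feature_label=lab, observed=o,
                                     null_mean=nm, null_sd=nsd, z=z, p_perm=p,
                                     n_perm=n_perm, tail=tail))
    out = pd.DataFrame([r.__dict__ for r in rows])
    if not out.empty:
        out["fdr"] = bh_adjust(out["p_perm"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Fisher-based set enrichment
# ---------------------------------------------------------------------------

def _fisher_table(k: int, K: int, m: int, N: int):
    """2x2 table [[k, K-k], [m-k, N-K-(m-k)]] and two-sided Fisher."""
    table = np.array([[k, K - k], [m - k, (N - K) - (m - k)]])
    if (table < 0).any():
        raise ValueError("inconsistent 2x2 counts")
    odds, p = fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def promoter_windows(annotation: pd.DataFrame,
                     window: tuple[int, int] = DEFAULT_PROMOTER) -> pd.DataFrame:
    """Strand-aware promoter interval per gene: TSS+window on +, mirrored on -."""
    up, down = window
    rows = []
    for _, g in annotation.iterrows():
        if g["strand"] == "+":
            tss = int(g["start"])
            s, e = tss + up, tss + down
        else:
            tss = int(g["end"])
            s, e = tss - down, tss - up
        rows.append((g["gene_id"], g["chrom"], max(0, s), max(0, e)))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def promoter_tfbs_enrichment(
    query_genes: list[str],
    background_genes: list[str],
    tfbs: pd.DataFrame,
    annotation: pd.DataFrame,
    window: tuple[int, int] = DEFAULT_PROMOTER,
) -> pd.DataFrame:
    """Per-TF Fisher enrichment of promoter binding in query vs background.

    A gene is 'bound' by a TF iff at least one TFBS interval of that TF
    overlaps its promoter window. Genes missing from the annotation are
    dropped with a warning.
    """
    import logging
    log = logging.getLogger(__name__)
    ann_ids = set(annotation["gene_id"])
    missing = [g for g in set(query_genes) | set(background_genes) if g not in ann_ids]
    if missing:
        log.warning("%d gene(s) missing from annotation; dropped", len(missing))
    query = [g for g in dict.fromkeys(query_genes) if g in ann_ids]
    background = [g for g in dict.fromkeys(background_genes) if g in ann_ids]
    if not set(query) <= set(background):
        raise ValueError("query genes must be a subset of the background")
    if not query:
        raise ValueError("empty query gene set")

    prom = promoter_windows(annotation[annotation["gene_id"].isin(background)], window)
    bound: dict[str, set[str]] = {}
    for tf, sub in tfbs.groupby("label"):
        hits = set()
        for _, p in prom.iterrows():
            psub = sub[sub["chrom"] == p["chrom"]]
            if ((psub["start"] < p["end"]) & (psub["end"] > p["start"])).any():
                hits.add(p["gene_id"])
        bound[tf] = hits

    qset, N, K = set(query), len(background), len(query)
    rows = []
    for tf, hits in sorted(bound.items()):
        m = len(hits)
        k = len(hits & qset)
        odds, p = _fisher_table(k, K, m, N)
        rows.append({"set_id": tf, "k": k, "K": K, "m": m, "N": N,
                     "odds_ratio": odds, "p_fisher": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = bh_adjust(out["p_fisher"].to_numpy())
    return out


def gene_set_ora(
    query_genes: list[str],
    background_genes: list[str],
    gene_sets: dict[str, list[str]],
) -> pd.DataFrame:
    """Fisher over-representation of each gene set in the query vs background."""
    query = list(dict.fromkeys(query_genes))
    background = list(dict.fromkeys(background_genes))
    if not query:
        raise ValueError("empty query gene set")
    if not set(query) <= set(background):
        raise ValueError("query genes must be a subset of the background")
    qset, bset = set(query), set(background)
    N, K = len(background), len(query)
    rows = []
    for sid, members in gene_sets.items():
        mem = set(members) & bset
        m = len(mem)
        k = len(mem & qset)
        odds, p = _fisher_table(k, K, m, N)
        rows.append({"set_id": sid, "k": k, "K": K, "m": m, "N": N,
                     "odds_ratio": odds, "p_fisher": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = bh_adjust(out["p_fisher"].to_numpy())
    return out
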