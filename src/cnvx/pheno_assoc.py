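"""Association between per-region CN state and breeding-value phenotypes.

Two statistics per (region, trait) pair:

* additive model — OLS regression of the GEBV on CN dosage (slope and
  t-test p), the natural test when effects scale with allele count;
* genotypic model — one-way ANOVA across CN groups, sensitive to
  non-additive (e.g. tri-allelic) patterns.

Deviating CN states with fewer than ``s_min`` phenotyped samples are
excluded (their samples dropped), missing phenotypes are dropped pairwise
per trait, and BH adjustment runs across all (region, trait) pairs per
model.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import bh_adjust

logger = logging.getLogger(__name__)


def cn_phenotype_association(
    matrix: pd.DataFrame,
    pheno: pd.DataFrame,
    s_min: int = 10,
    fdr_level: float = 0.1,
) -> pd.DataFrame:
    """Test every (region, trait) pair; returns one record per pair.

    ``pheno`` is samples x traits (NaN = not phenotyped). Traits with zero
    variance among analyzed samples are flagged and skipped.
    """
    shared = [s for s in matrix.columns if s in pheno.index]
    if not shared:
        raise ValueError("no samples shared between genotype matrix and phenotypes")
    rows = []
    for rid in matrix.index:
        cn_all = matrix.loc[rid, shared]
        for trait in pheno.columns:
            y_all = pheno.loc[shared, trait]
            ok = y_all.notna()
            cn, y = cn_all[ok], y_all[ok]
            counts = cn.value_counts()
            states = [int(s) for s in counts.index
                      if s == 2 or counts[s] >= s_min]
            if 2 not in states or len(states) < 2:
                continue
            keep = cn.isin(states)
            cn, y = cn[keep].astype(float), y[keep].astype(float)
            rec = {"region_id": rid, "trait_id": trait,
                   "states": ",".join(map(str, sorted(set(cn.astype(int))))),
                   "n": int(len(y))}
            if y.std(ddof=0) == 0:
                rec.update({"flag": "zero_variance", "slope": np.nan, "p_add": np.nan,
                            "F": np.nan, "p_geno": np.nan})
                logger.warning("trait %s has zero variance for region %s", trait, rid)
                rows.append(rec)
                continue
            res = stats.linregress(cn.to_numpy(), y.to_numpy())
            groups = [y[cn == s].to_numpy() for s in sorted(set(cn))]
            F, p_geno = stats.f_oneway(*groups)
            means = {int(s): float(y[cn == s].mean()) for s in sorted(set(cn))}
            medians = {int(s): float(y[cn == s].median()) for s in sorted(set(cn))}
            rec.update({"flag": "", "slope": float(res.slope),
                        "p_add": float(res.pvalue), "F": float(F),
                        "p_geno": float(p_geno), "group_means": means,
                        "group_medians": medians})
            rows.append(rec)
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr_add"] = bh_adjust(out["p_add"].to_numpy())
        out["fdr_geno"] = bh_adjust(out["p_geno"].to_numpy())
        out["significant_add"] = out["fdr_add"] <= fdr_level
        out["significant_geno"] = out["fdr_geno"] <= fdr_level
    return out
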