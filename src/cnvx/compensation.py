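"""Dosage-compensation analysis for one-copy losses.

For genes carried by a substantial 1n group, the compensation statistic is
the ratio of the median cpm in the 1n group to the median cpm in the 2n
group: 0.5 under strict dosage (expression proportional to copy number),
1 under full compensation. Percentile bootstrap confidence intervals are
obtained by resampling samples with replacement within each group, and the
gene is classified by CI membership:

    compensated  CI contains 1
    dosage       CI contains 0.5 (and not 1)
    inverse      ratio > 1 and CI excludes 1
    partial      otherwise
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expr_assoc import CountMatrix


@dataclass
class CompensationResult:
    gene_id: str
    region_id: str
    ratio: float
    ci_low: float
    ci_high: float
    n_1n: int
    n_2n: int
    cls: str
    flag: str = ""


def _classify(ratio: float, lo: float, hi: float) -> str:
    if lo <= 1.0 <= hi:
        return "compensated"
    if lo <= 0.5 <= hi:
        return "dosage"
    if ratio > 1.0 and lo > 1.0:
        return "inverse"
    return "partial"


def compensation_analysis(
    cm: CountMatrix,
    matrix: pd.DataFrame,
    pairs: list[tuple[str, str]],
    n_boot: int = 10_000,
    ci_level: float = 0.95,
    seed: int = 0,
    s_min: int = 4,
) -> pd.DataFrame:
    """Median-ratio + bootstrap CI for each (gene, region) pair.

    ``pairs`` lists (gene_id, region_id) with an observed 1n group. Pairs
    with fewer than ``s_min`` 1n samples are flagged and skipped; a zero 2n
    median makes the ratio undefined (flagged record, NaN ratio).
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0,1)")
    rng = np.random.default_rng(seed)
    cpm_df = cm.cpm()
    qlo, qhi = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    rows = []
    for gene, region in pairs:
        states = matrix.loc[region, cm.samples]
        x1 = cpm_df.loc[gene, states.index[states == 1]].to_numpy(dtype=float)
        x2 = cpm_df.loc[gene, states.index[states == 2]].to_numpy(dtype=float)
        res = CompensationResult(gene_id=gene, region_id=region, ratio=np.nan,
                                 ci_low=np.nan, ci_high=np.nan,
                                 n_1n=len(x1), n_2n=len(x2), cls="")
        if len(x1) < s_min:
            res.flag = "insufficient_1n"
            rows.append(res)
            continue
        med2 = float(np.median(x2))
        if med2 == 0:
            res.flag = "undefined_ratio"
            rows.append(res)
            continue
        res.ratio = float(np.median(x1)) / med2
        idx1 = rng.integers(0, len(x1), size=(n_boot, len(x1)))
        idx2 = rng.integers(0, len(x2), size=(n_boot, len(x2)))
        m1 = np.median(x1[idx1], axis=1)
        m2 = np.median(x2[idx2], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            boots = m1 / m2
        boots = boots[np.isfinite(boots)]
        res.ci_low = float(np.quantile(boots, qlo))
        res.ci_high = float(np.quantile(boots, qhi))
        res.cls = _classify(res.ratio, res.ci_low, res.ci_high)
        rows.append(res)
    return pd.DataFrame([r.__dict__ for r in rows]).rename(columns={"cls": "class"})
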