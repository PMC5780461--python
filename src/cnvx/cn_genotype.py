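"""Collapse per-sample CNV calls onto CNV regions into a CN-state matrix.

The CN genotype matrix (regions x samples, diploid default 2) is the
stratification variable of every downstream association stage. Calls are
deviations only (CN != 2); a sample is genotyped with a call's state when
the call covers at least ``min_overlap_frac`` of the region. Conflicting
overlapping calls are resolved by largest covered fraction, then by the
state nearest diploid, then by the lower state.
"""

from __future__ import annotations

import logging

import pandas as pd

from ._utils import overlap_len

logger = logging.getLogger(__name__)

VALID_STATES = (0, 1, 2, 3, 4)


def assign_cn_states(
    calls: pd.DataFrame,
    regions: pd.DataFrame,
    samples: list[str],
    min_overlap_frac: float = 0.5,
    known_chroms: set[str] | None = None,
) -> pd.DataFrame:
    """Build the regions x samples CN genotype matrix.

    ``calls`` needs columns sample, chrom, start, end, cn; ``regions`` needs
    region_id, chrom, start, end. Samples absent from ``samples`` are
    skipped with a warning; a call on a chromosome outside ``known_chroms``
    (when given) is a hard error.
    """
    if not 0 < min_overlap_frac <= 1:
        raise ValueError("min_overlap_frac must be in (0, 1]")
    sample_set = set(samples)
    region_ids = regions["region_id"].tolist()
    mat = pd.DataFrame(2, index=region_ids, columns=list(samples), dtype=int)

    if known_chroms is not None:
        bad = set(calls["chrom"]) - set(known_chroms)
        if bad:
            raise ValueError(f"calls on unknown chromosome(s): {sorted(bad)}")

    # candidates per (region, sample): (fraction, cn)
    best: dict[tuple[str, str], tuple[float, int]] = {}
    reg_by_chrom: dict[str, list[tuple[str, int, int]]] = {}
    for _, r in regions.iterrows():
        if r["start"] >= r["end"]:
            raise ValueError(f"region {r['region_id']}: start >= end")
        reg_by_chrom.setdefault(r["chrom"], []).append(
            (r["region_id"], int(r["start"]), int(r["end"]))
        )

    for _, c in calls.iterrows():
        if c["sample"] not in sample_set:
            logger.warning("call sample %s not in cohort; skipped", c["sample"])
            continue
        cn = int(c["cn"])
        if cn not in VALID_STATES:
            raise ValueError(f"CN state {cn} outside 0..4")
        for rid, rs, re_ in reg_by_chrom.get(c["chrom"], []):
            frac = overlap_len(int(c["start"]), int(c["end"]), rs, re_) / (re_ - rs)
            if frac < min_overlap_frac:
                continue
            key = (rid, c["sample"])
            prev = best.get(key)
            if prev is None:
                best[key] = (frac, cn)
            elif frac > prev[0] + 1e-12:
                best[key] = (frac, cn)
            elif abs(frac - prev[0]) <= 1e-12 and cn != prev[1]:
                # exact tie: prefer the state nearest diploid, then the lower one
                keep = min(prev[1], cn, key=lambda s: (abs(s - 2), s))
                if keep != prev[1]:
                    logger.info("conflict at %s/%s: %s over %s", rid, key[1], keep, prev[1])
                best[key] = (frac, keep)

    for (rid, sample), (_, cn) in best.items():
        mat.at[rid, sample] = cn
    return mat


def tabulate_states(matrix: pd.DataFrame, region_id: str) -> dict[int, int]:
    """Exhaustive per-state sample counts (states 0..4) for one region."""
    if region_id not in matrix.index:
        raise KeyError(f"unknown region {region_id!r}")
    row = matrix.loc[region_id]
    counts = {s: int((row == s).sum()) for s in VALID_STATES}
    assert sum(counts.values()) == matrix.shape[1]
    return counts


def implied_calls(matrix: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Calls implied by a genotype matrix: one region-spanning call per
    deviating entry. Re-assigning these reproduces the matrix (idempotence)."""
    coords = regions.set_index("region_id")
    rows = []
    for rid in matrix.index:
        r = coords.loc[rid]
        for sample, cn in matrix.loc[rid].items():
            if cn != 2:
                rows.append((sample, r["chrom"], int(r["start"]), int(r["end"]),
                             int(cn), "snp", float("nan"), float("nan")))
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "cn", "source", "quality", "q0"]
    )
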