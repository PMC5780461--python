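"""CNV breakpoint fine-mapping and SNP-vs-sequencing concordance.

Fine-mapping piles up, per genomic bin and per deviating CN state, the
number of distinct samples whose calls cover the bin; consensus breakpoints
show up as the maximal-count run of bins, and inheritance is checked by
comparing offspring and sire pileups. Sequencing-based calls pass through
length/quality/q0/exclusion filters before being compared, in base pairs,
against SNP-array calls per founder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import intersect_len, merge_intervals, overlap_len, total_len

logger = logging.getLogger(__name__)

PILEUP_STATES = (0, 1, 3, 4)


@dataclass
class PileupTrack:
    chrom: str
    start: int
    end: int
    bin_width: int
    cohort: str
    cohort_size: int
    counts: pd.DataFrame = field(repr=False)   # bins x states, index = bin starts

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def bin_edges(self) -> np.ndarray:
        edges = np.arange(self.start, self.end + self.bin_width, self.bin_width)
        edges[-1] = min(edges[-1], self.end)
        return edges


def pileup(
    calls: pd.DataFrame,
    window: tuple[str, int, int],
    bin_width: int,
    cohort: str,
    cohort_size: int | None = None,
    genome: dict[str, int] | None = None,
) -> PileupTrack:
    """Per-bin, per-state counts of distinct samples with covering calls.

    A sample is counted at most once per (bin, state) however many of its
    calls overlap the bin. The last bin may be short.
    """
    chrom, start, end = window
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if start >= end:
        raise ValueError("empty window")
    if genome is not None:
        if chrom not in genome or start < 0 or end > genome[chrom]:
            raise ValueError("window outside genome")
    n_bins = int(np.ceil((end - start) / bin_width))
    bin_starts = start + bin_width * np.arange(n_bins)
    counts = {s: np.zeros(n_bins, dtype=int) for s in PILEUP_STATES}
    sub = calls[(calls["chrom"] == chrom)
                & (calls["start"] < end) & (calls["end"] > start)]
    for (sample, cn), grp in sub.groupby(["sample", "cn"]):
        cn = int(cn)
        if cn not in PILEUP_STATES:
            continue
        covered = np.zeros(n_bins, dtype=bool)
        for _, c in grp.iterrows():
            b0 = max(0, (int(c["start"]) - start) // bin_width)
            b1 = min(n_bins, -(-(int(c["end"]) - start) // bin_width))
            covered[b0:b1] = True
        counts[cn] += covered
    df = pd.DataFrame(counts, index=bin_starts)
    if cohort_size is None:
        cohort_size = calls["sample"].nunique()
    return PileupTrack(chrom=chrom, start=start, end=end, bin_width=bin_width,
                       cohort=cohort, cohort_size=cohort_size, counts=df)


@dataclass
class PeakInterval:
    start: int
    end: int
    count: int
    tied: bool


def peak_interval(track: PileupTrack, state: int) -> PeakInterval | None:
    """Genomic interval of the maximal-count contiguous bin run for a state.

    Returns None on an all-zero track. Separate runs attaining the maximum
    tie-break to the leftmost run and are flagged.
    """
    vec = track.counts[state].to_numpy()
    if vec.max() == 0:
        return None
    peak = vec.max()
    at_max = vec == peak
    # contiguous runs of at_max
    runs = []
    i = 0
    while i < len(vec):
        if at_max[i]:
            j = i
            while j + 1 < len(vec) and at_max[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    i0, j0 = runs[0]
    tied = len(runs) > 1
    if tied:
        logger.info("tied peak runs for state %d; using leftmost", state)
    gstart = track.start + i0 * track.bin_width
    gend = min(track.start + (j0 + 1) * track.bin_width, track.end)
    return PeakInterval(start=int(gstart), end=int(gend), count=int(peak), tied=tied)


# ---------------------------------------------------------------------------
# Sequencing-call filtering
# ---------------------------------------------------------------------------

@dataclass
class SeqCallFilterConfig:
    min_len: int = 1_000
    max_len: int = 1_000_000
    max_q0: float = 0.5
    min_quality: float = 10.0
    exclusions: pd.DataFrame | None = None   # chrom/start/end
    max_exclusion_overlap: float = 0.5

    def __post_init__(self):
        if self.min_len >= self.max_len:
            raise ValueError("min_len must be < max_len")


def filter_seq_calls(calls: pd.DataFrame,
                     cfg: SeqCallFilterConfig) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply length/q0/quality/exclusion filters to sequencing-based calls.

    Calls shorter than ``min_len`` or longer than ``max_len``, with q0 above
    ``max_q0``, quality below ``min_quality``, or overlapping an exclusion
    interval by >= 50% of their length are dropped. Per-rule drop counts are
    returned (a call tripping several rules is counted under each); missing
    quality/q0 columns skip the corresponding rule with a warning. The rules
    are applied independently, so their order is immaterial.
    """
    drops = {"len_short": 0, "len_long": 0, "q0": 0, "qual": 0, "excl": 0}
    length = (calls["end"] - calls["start"]).to_numpy()
    drop = np.zeros(len(calls), dtype=bool)

    short = length < cfg.min_len
    long_ = length > cfg.max_len
    drops["len_short"] = int(short.sum())
    drops["len_long"] = int(long_.sum())
    drop |= short | long_

    if "q0" in calls.columns and calls["q0"].notna().any():
        bad = calls["q0"].to_numpy(dtype=float) > cfg.max_q0   # NaN compares False
        drops["q0"] = int(bad.sum())
        drop |= bad
    else:
        logger.warning("no q0 values; q0 filter skipped")

    if "quality" in calls.columns and calls["quality"].notna().any():
        qual = calls["quality"].to_numpy(dtype=float)
        bad = np.where(np.isnan(qual), False, qual < cfg.min_quality)
        drops["qual"] = int(bad.sum())
        drop |= bad
    else:
        logger.warning("no quality values; quality filter skipped")

    if cfg.exclusions is not None and len(cfg.exclusions):
        for i, (_, c) in enumerate(calls.iterrows()):
            exc = cfg.exclusions[cfg.exclusions["chrom"] == c["chrom"]]
            ov = sum(overlap_len(int(c["start"]), int(c["end"]), int(e["start"]), int(e["end"]))
                     for _, e in exc.iterrows())
            if ov >= cfg.max_exclusion_overlap * (c["end"] - c["start"]):
                drops["excl"] += 1
                drop[i] = True
    return calls.loc[~drop].reset_index(drop=True), drops


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def _intervals(df: pd.DataFrame, chrom: str) -> list[tuple[int, int]]:
    sub = df[df["chrom"] == chrom]
    return list(zip(sub["start"].astype(int), sub["end"].astype(int)))


def _per_sire_concordance(snp: pd.DataFrame, seq: pd.DataFrame, mode: str) -> float | None:
    """Fraction of SNP-call bp corroborated by sequencing calls, one sire."""
    if mode == "deletions_only":
        snp = snp[snp["cn"] < 2]
        seq = seq[seq["cn"] < 2]
    denom = 0
    numer = 0
    for chrom in snp["chrom"].unique():
        snp_iv = merge_intervals(_intervals(snp, chrom))
        denom += total_len(snp_iv)
        if mode == "type_match":
            for side in ("loss", "gain"):
                snp_s = snp[(snp["chrom"] == chrom)
                            & ((snp["cn"] < 2) if side == "loss" else (snp["cn"] > 2))]
                seq_s = seq[(seq["chrom"] == chrom)
                            & ((seq["cn"] < 2) if side == "loss" else (seq["cn"] > 2))]
                numer += intersect_len(
                    list(zip(snp_s["start"], snp_s["end"])),
                    list(zip(seq_s["start"], seq_s["end"])),
                )
        else:
            numer += intersect_len(snp_iv, _intervals(seq, chrom))
    if denom == 0:
        return None
    return numer / denom


def concordance(
    snp_calls: pd.DataFrame,
    seq_calls: pd.DataFrame,
    mode: str = "any",
) -> pd.DataFrame:
    """Per-sire SNP-vs-seq concordance fractions plus the cohort median.

    Modes: ``any`` (bp of SNP calls covered by any seq call), ``type_match``
    (coverage must come from a seq call on the same side of diploid) and
    ``deletions_only`` (both call sets restricted to CN < 2 first). Sires
    with zero SNP-call bp under the mode are excluded from the median with
    a warning. The returned frame has one row per sire and a ``median``
    attribute in ``.attrs``.
    """
    if mode not in ("any", "type_match", "deletions_only"):
        raise ValueError(f"unknown mode {mode!r}")
    sires = sorted(set(snp_calls["sample"]))
    rows = []
    for sire in sires:
        frac = _per_sire_concordance(
            snp_calls[snp_calls["sample"] == sire],
            seq_calls[seq_calls["sample"] == sire],
            mode,
        )
        if frac is None:
            logger.warning("sire %s has zero SNP-call bp in mode %s; excluded", sire, mode)
            continue
        rows.append({"sample": sire, "mode": mode, "fraction": frac})
    out = pd.DataFrame(rows)
    out.attrs["median"] = float(out["fraction"].median()) if len(out) else np.nan
    return out


def concordance_report(snp_calls: pd.DataFrame, seq_calls: pd.DataFrame) -> dict:
    """All three concordance modes, as cohort medians on the percent scale."""
    out = {}
    for mode in ("any", "type_match", "deletions_only"):
        df = concordance(snp_calls, seq_calls, mode)
        out[mode] = {"median_pct": 100.0 * df.attrs["median"],
                     "per_sire": df}
    return out


def inheritance_check(offspring_track: PileupTrack, sire_track: PileupTrack,
                      state: int) -> dict:
    """Do offspring and sire pileups localize the same breakpoint region?

    Returns peak-interval overlap (bool) and the cosine similarity of the
    two per-cohort-size-normalized bin profiles.
    """
    same = (offspring_track.chrom == sire_track.chrom
            and offspring_track.start == sire_track.start
            and offspring_track.end == sire_track.end
            and offspring_track.bin_width == sire_track.bin_width)
    if not same:
        raise ValueError("mismatched windows/binning between tracks")
    po = peak_interval(offspring_track, state)
    ps = peak_interval(sire_track, state)
    overlap = bool(po and ps and overlap_len(po.start, po.end, ps.start, ps.end) > 0)
    a = offspring_track.counts[state].to_numpy(dtype=float) / offspring_track.cohort_size
    b = sire_track.counts[state].to_numpy(dtype=float) / sire_track.cohort_size
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    sim = float(a @ b / (na * nb)) if na > 0 and nb > 0 else 0.0
    return {"peak_overlap": overlap, "cosine_similarity": sim,
            "offspring_peak": po, "sire_peak": ps}
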