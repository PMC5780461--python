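"""Synthetic half-sib cohort generator.

Emulates the data structure of a CNV/expression/phenotype study in a
half-sib livestock design: founding sires crossed to unrelated dams,
Mendelian transmission of CNV alleles, copy-number calls with imprecise
(SNP-inference-like) borders, negative-binomial RNA-seq counts carrying
local dosage effects (with tunable compensation) and distal regulator
effects (consistent direction, shared targets, synergy), and breeding-value
phenotypes linear in copy number.

All randomness flows from ``SimConfig.seed`` through named substreams, so a
given configuration is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._utils import derive_seed, overlap_len

CN_MIN, CN_MAX = 0, 4


@dataclass
class CNVLocusSpec:
    """One simulated CNV locus (deletion or duplication allele)."""

    locus_id: str
    chrom: str
    start: int
    end: int
    allele_type: str = "deletion"          # deletion | duplication
    sire_carrier_freq: float = 0.0         # P(a sire is a het carrier)
    dam_allele_freq: float = 0.0           # variant allele frequency in dams
    local_genes: dict[str, float] = field(default_factory=dict)   # gene -> compensation c in [0,1]
    distal_targets: dict[str, float] = field(default_factory=dict)  # gene -> log2 effect beta
    synergy_partner: str | None = None
    synergy_log2: float = 0.0
    nested: bool = False

    def validate(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.locus_id}: start must be < end")
        if self.allele_type not in ("deletion", "duplication"):
            raise ValueError(f"{self.locus_id}: bad allele_type {self.allele_type!r}")
        for f in (self.sire_carrier_freq, self.dam_allele_freq):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.locus_id}: frequency {f} outside [0,1]")
        for g, c in self.local_genes.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"{self.locus_id}/{g}: compensation {c} outside [0,1]")

    @property
    def sign(self) -> int:
        return -1 if self.allele_type == "deletion" else +1


@dataclass
class TraitSpec:
    """Additive CN effects of loci on a breeding-value trait."""

    trait_id: str
    effects: dict[str, float] = field(default_factory=dict)  # locus_id -> per-copy effect
    residual_sd: float = 1.0

    def validate(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError(f"{self.trait_id}: residual sd must be > 0")


@dataclass
class SimConfig:
    n_sires: int = 9
    offspring_per_sire: int = 20
    genome: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 50_000_000), ("chr2", 40_000_000), ("chr3", 30_000_000)]
    )
    loci: list[CNVLocusSpec] = field(default_factory=list)
    n_genes: int = 1000
    baseline_log_mean_range: tuple[float, float] = (1.0, 8.0)   # log2 cpm of generic genes
    effect_gene_log_mean_range: tuple[float, float] = (5.0, 8.0)  # log2 cpm of local/distal target genes
    nb_dispersion: float = 0.2
    library_size_range: tuple[float, float] = (15e6, 25e6)
    border_jitter_sd: float = 5000.0
    traits: list[TraitSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_sires <= 0 or self.offspring_per_sire <= 0 or self.n_genes <= 0:
            raise ValueError("counts must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not (0 < self.library_size_range[0] <= self.library_size_range[1]):
            raise ValueError("bad library_size_range")
        sizes = dict(self.genome)
        for loc in self.loci:
            loc.validate()
            if loc.chrom not in sizes:
                raise ValueError(f"{loc.locus_id}: chromosome {loc.chrom} not in genome")
            if not (0 <= loc.start and loc.end <= sizes[loc.chrom]):
                raise ValueError(f"{loc.locus_id}: interval outside chromosome")
        # overlapping loci on a chromosome make CN ambiguous unless flagged nested
        by_chrom: dict[str, list[CNVLocusSpec]] = {}
        for loc in self.loci:
            by_chrom.setdefault(loc.chrom, []).append(loc)
        for locs in by_chrom.values():
            locs = sorted(locs, key=lambda l: l.start)
            for a, b in zip(locs, locs[1:]):
                if overlap_len(a.start, a.end, b.start, b.end) > 0 and not (a.nested or b.nested):
                    raise ValueError(f"loci {a.locus_id} and {b.locus_id} overlap; "
                                     "flag nested=True if intentional")
        for t in self.traits:
            t.validate()
            for lid in t.effects:
                if lid not in {l.locus_id for l in self.loci}:
                    raise ValueError(f"{t.trait_id}: unknown locus {lid}")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(derive_seed(self.seed, "simdata", stage))


@dataclass
class Cohort:
    """Pedigree genotypes: per-locus variant-allele dosages and CN states."""

    sires: list[str]
    offspring: list[str]
    sire_of: pd.Series                  # offspring -> sire
    sire_dosage: pd.DataFrame           # loci x sires, variant allele count 0..2
    offspring_dosage: pd.DataFrame      # loci x offspring
    sire_cn: pd.DataFrame               # loci x sires, CN state 0..4
    offspring_cn: pd.DataFrame          # loci x offspring

    @property
    def samples(self) -> list[str]:
        return list(self.offspring)


def _dosage_to_cn(dosage: pd.DataFrame, loci: list[CNVLocusSpec]) -> pd.DataFrame:
    signs = pd.Series({l.locus_id: l.sign for l in loci})
    cn = 2 + dosage.mul(signs.loc[dosage.index], axis=0)
    return cn.clip(CN_MIN, CN_MAX).astype(int)


def simulate_pedigree_genotypes(cfg: SimConfig) -> Cohort:
    """Draw sire genotypes and Mendelian offspring genotypes at every locus.

    A carrier sire is heterozygous (one variant allele) and transmits it to
    each offspring with probability 1/2; the maternal allele is an
    independent Bernoulli draw at ``dam_allele_freq`` (dams are unrelated
    commercial females, one offspring each).
    """
    cfg.validate()
    rng = cfg.rng("pedigree")
    sires = [f"SIRE{j + 1:02d}" for j in range(cfg.n_sires)]
    offspring = [f"S{j + 1:02d}_O{i + 1:03d}"
                 for j in range(cfg.n_sires) for i in range(cfg.offspring_per_sire)]
    sire_of = pd.Series({o: sires[int(o[1:3]) - 1] for o in offspring})

    locus_ids = [l.locus_id for l in cfg.loci]
    n_off = len(offspring)
    sire_dos = np.zeros((len(locus_ids), cfg.n_sires), dtype=int)
    off_dos = np.zeros((len(locus_ids), n_off), dtype=int)
    sire_idx = np.repeat(np.arange(cfg.n_sires), cfg.offspring_per_sire)

    for r, loc in enumerate(cfg.loci):
        carriers = rng.random(cfg.n_sires) < loc.sire_carrier_freq
        sire_dos[r] = carriers.astype(int)          # het carriers: one variant allele
        paternal = np.where(
            carriers[sire_idx], (rng.random(n_off) < 0.5).astype(int), 0
        )
        maternal = (rng.random(n_off) < loc.dam_allele_freq).astype(int)
        off_dos[r] = paternal + maternal

    sire_dosage = pd.DataFrame(sire_dos, index=locus_ids, columns=sires)
    offspring_dosage = pd.DataFrame(off_dos, index=locus_ids, columns=offspring)
    return Cohort(
        sires=sires,
        offspring=offspring,
        sire_of=sire_of,
        sire_dosage=sire_dosage,
        offspring_dosage=offspring_dosage,
        sire_cn=_dosage_to_cn(sire_dosage, cfg.loci),
        offspring_cn=_dosage_to_cn(offspring_dosage, cfg.loci),
    )


def emit_cnv_calls(
    cohort: Cohort,
    cfg: SimConfig,
    subinterval_fraction: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Emit per-sample CNV calls for every sample-locus with CN != 2.

    Offspring calls carry source ``snp`` with Gaussian border jitter
    (sd = ``border_jitter_sd``, truncated at the locus midpoint so
    start < end always holds). Sires are emitted twice: a jittered ``snp``
    call and an exact ``seq`` call, mirroring array- and sequencing-based
    calling of the founders. ``subinterval_fraction`` optionally replaces a
    locus's true interval by a random sub-interval covering that fraction of
    its length (an intersecting rather than full-spanning variant).
    """
    rng = cfg.rng("calls")
    sizes = dict(cfg.genome)
    sub = dict(subinterval_fraction or {})
    rows: list[tuple] = []

    def true_interval(loc: CNVLocusSpec) -> tuple[int, int]:
        if loc.locus_id in sub:
            frac = float(sub[loc.locus_id])
            if not 0 < frac <= 1:
                raise ValueError(f"subinterval fraction {frac} outside (0,1]")
            length = max(1, int(round(frac * (loc.end - loc.start))))
            off = int(rng.integers(0, loc.end - loc.start - length + 1))
            return loc.start + off, loc.start + off + length
        return loc.start, loc.end

    def jittered(s: int, e: int, chrom: str) -> tuple[int, int]:
        if cfg.border_jitter_sd == 0:
            return s, e
        mid = (s + e) // 2
        js = int(round(s + rng.normal(0, cfg.border_jitter_sd)))
        je = int(round(e + rng.normal(0, cfg.border_jitter_sd)))
        js = int(np.clip(js, 0, mid - 1))
        je = int(np.clip(je, mid + 1, sizes[chrom]))
        return js, je

    for loc in cfg.loci:
        s0, e0 = true_interval(loc)
        for sample in cohort.offspring:
            cn = int(cohort.offspring_cn.at[loc.locus_id, sample])
            if cn != 2:
                js, je = jittered(s0, e0, loc.chrom)
                rows.append((sample, loc.chrom, js, je, cn, "snp", np.nan, np.nan))
        for sire in cohort.sires:
            cn = int(cohort.sire_cn.at[loc.locus_id, sire])
            if cn != 2:
                js, je = jittered(s0, e0, loc.chrom)
                rows.append((sire, loc.chrom, js, je, cn, "snp", np.nan, np.nan))
                rows.append((sire, loc.chrom, s0, e0, cn, "seq", np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "cn", "source", "quality", "q0"]
    )


def build_gene_annotation(cfg: SimConfig) -> pd.DataFrame:
    """Place genes on the genome: generic genes G0001.. plus all gene ids
    referenced by loci. Local genes are placed inside their locus; all other
    genes avoid every CNV locus so 'local' and 'distal' stay disjoint."""
    rng = cfg.rng("annotation")
    sizes = dict(cfg.genome)
    chroms = list(sizes)
    lens = np.array([sizes[c] for c in chroms], dtype=float)

    special_local: dict[str, CNVLocusSpec] = {}
    referenced: list[str] = []
    for loc in cfg.loci:
        for g in loc.local_genes:
            special_local[g] = loc
            referenced.append(g)
        for g in loc.distal_targets:
            if g not in referenced:
                referenced.append(g)

    generic = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    gene_ids = generic + [g for g in referenced if g not in generic]

    loci_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for loc in cfg.loci:
        loci_by_chrom.setdefault(loc.chrom, []).append((loc.start, loc.end))

    rows = []
    for g in gene_ids:
        length = int(rng.integers(2_000, 30_000))
        if g in special_local:
            loc = special_local[g]
            span = loc.end - loc.start
            glen = min(length, span)
            start = loc.start + int(rng.integers(0, span - glen + 1))
            chrom = loc.chrom
            end = start + glen
        else:
            for _ in range(200):
                ci = int(rng.choice(len(chroms), p=lens / lens.sum()))
                chrom = chroms[ci]
                start = int(rng.integers(0, sizes[chrom] - length))
                end = start + length
                hits = loci_by_chrom.get(chrom, [])
                if all(overlap_len(start, end, s, e) == 0 for s, e in hits):
                    break
            else:  # pragma: no cover - genome essentially full of loci
                raise RuntimeError("could not place gene outside CNV loci")
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((g, chrom, start, end, strand))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def _local_factor(cn: np.ndarray, c: float) -> np.ndarray:
    """Dosage response with compensation c: f = c + (1-c) * CN/2."""
    return c + (1.0 - c) * cn / 2.0


def simulate_counts(
    cohort: Cohort,
    cfg: SimConfig,
    annotation: pd.DataFrame | None = None,
):
    """Simulate the gene x sample RNA-seq count matrix for the offspring.

    Mean model per gene g and sample i: mu = L_i * q_g * f_local * f_distal
    with q_g the baseline library fraction, f_local = c + (1-c)*CN/2 for a
    gene inside a CNV locus with compensation c, and f_distal multiplying
    2^beta for every regulator locus targeting g at which sample i deviates
    from 2n (plus 2^synergy when both partner loci deviate). Counts are
    gamma-Poisson draws, i.e. NB2 with the configured dispersion.

    Returns ``(CountMatrix, annotation)``.
    """
    from .expr_assoc import CountMatrix

    if annotation is None:
        annotation = build_gene_annotation(cfg)
    rng = cfg.rng("counts")
    genes = annotation["gene_id"].tolist()
    samples = cohort.offspring
    G, N = len(genes), len(samples)
    gidx = {g: i for i, g in enumerate(genes)}

    special = set()
    for loc in cfg.loci:
        special.update(loc.local_genes)
        special.update(loc.distal_targets)
    lo, hi = cfg.baseline_log_mean_range
    log2cpm = rng.uniform(lo, hi, size=G)
    elo, ehi = cfg.effect_gene_log_mean_range
    for g in special:
        log2cpm[gidx[g]] = rng.uniform(elo, ehi)
    q = np.power(2.0, log2cpm) / 1e6   # library fraction per gene

    llo, lhi = np.log(cfg.library_size_range[0]), np.log(cfg.library_size_range[1])
    lib = np.exp(rng.uniform(llo, lhi, size=N))

    factor = np.ones((G, N))
    cn = cohort.offspring_cn
    deviating = {loc.locus_id: (cn.loc[loc.locus_id].to_numpy() != 2) for loc in cfg.loci}
    for loc in cfg.loci:
        cn_vec = cn.loc[loc.locus_id].to_numpy()
        for g, c in loc.local_genes.items():
            factor[gidx[g]] *= _local_factor(cn_vec, c)
        for g, beta in loc.distal_targets.items():
            factor[gidx[g]] *= np.power(2.0, beta * deviating[loc.locus_id])
        if loc.synergy_partner is not None and loc.synergy_log2 != 0.0:
            both = deviating[loc.locus_id] & deviating[loc.synergy_partner]
            partner = next(l for l in cfg.loci if l.locus_id == loc.synergy_partner)
            shared = set(loc.distal_targets) & set(partner.distal_targets)
            for g in shared:
                factor[gidx[g]] *= np.power(2.0, loc.synergy_log2 * both)

    mu = q[:, None] * lib[None, :] * factor
    a = cfg.nb_dispersion
    if a == 0:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=1.0 / a, scale=mu * a)
        counts = rng.poisson(lam)
    df = pd.DataFrame(counts, index=genes, columns=samples)
    cm = CountMatrix.from_frame(df, lib_size=pd.Series(lib, index=samples))
    return cm, annotation


def simulate_gebvs(cohort: Cohort, cfg: SimConfig) -> pd.DataFrame:
    """Breeding values: GEBV = sum over loci effect * (CN - 2) + N(0, sd)."""
    rng = cfg.rng("gebvs")
    samples = cohort.offspring
    out = {}
    for trait in cfg.traits:
        val = np.zeros(len(samples))
        for lid, eff in trait.effects.items():
            val += eff * (cohort.offspring_cn.loc[lid].to_numpy() - 2)
        val += rng.normal(0.0, trait.residual_sd, size=len(samples))
        out[trait.trait_id] = val
    return pd.DataFrame(out, index=samples)


def simulate_tfbs_track(
    annotation: pd.DataFrame,
    tf_labels: list[str],
    planted_tf: str | None = None,
    planted_genes: list[str] | None = None,
    background_rate: float = 0.1,
    planted_rate: float = 0.9,
    promoter_window: tuple[int, int] = (-2000, 500),
    seed: int = 0,
) -> pd.DataFrame:
    """Random promoter TFBS track with an optionally planted motif.

    Every TF hits each promoter independently at ``background_rate``; the
    planted TF additionally hits the promoters of ``planted_genes`` at
    ``planted_rate``. Returns a feature BED-like frame (chrom, start, end,
    label, weight)."""
    rng = np.random.default_rng(seed)
    up, down = promoter_window
    rows = []
    planted_set = set(planted_genes or [])
    for _, g in annotation.iterrows():
        tss = g["start"] if g["strand"] == "+" else g["end"]
        sgn = 1 if g["strand"] == "+" else -1
        pstart = tss + (up if sgn == 1 else -down)
        pend = tss + (down if sgn == 1 else -up)
        pstart, pend = max(0, min(pstart, pend)), max(pstart, pend)
        for tf in tf_labels:
            rate = background_rate
            if tf == planted_tf and g["gene_id"] in planted_set:
                rate = planted_rate
            if rng.random() < rate:
                pos = int(rng.integers(pstart, max(pend - 10, pstart + 1)))
                rows.append((g["chrom"], pos, pos + 10, tf, 1.0))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "weight"])


def default_config(seed: int = 0, n_genes: int = 1000) -> SimConfig:
    """The default synthetic cohort.

    Shape mirrors a half-sib beef-cattle expression cohort at desk scale:
    9 sires x 20 offspring (180 transcriptomed animals), two distal
    regulator loci each driving 20 well-expressed targets at |log2FC| = 1
    (one copy-loss region with positive targets, one copy-gain region with
    negative targets), 5 shared targets with a synergistic term, one local
    locus carrying genes across the compensation spectrum (c = 0, 0.5, 1),
    and a shear-force-like trait loaded on the first regulator locus.
    """
    local = CNVLocusSpec(
        locus_id="L_MHC", chrom="chr3", start=10_000_000, end=10_100_000,
        allele_type="deletion", sire_carrier_freq=0.5, dam_allele_freq=0.30,
        local_genes={"LOC_DOSAGE": 0.0, "LOC_PARTIAL": 0.5, "LOC_COMP": 1.0},
    )
    targets_a = {f"TGT_A{i:02d}": 1.0 for i in range(1, 16)}
    targets_b = {f"TGT_B{i:02d}": -1.0 for i in range(1, 16)}
    shared = {f"TGT_S{i:02d}": 1.0 for i in range(1, 6)}
    reg_a = CNVLocusSpec(
        locus_id="R727", chrom="chr1", start=20_000_000, end=20_150_000,
        allele_type="deletion", sire_carrier_freq=0.5, dam_allele_freq=0.15,
        distal_targets={**targets_a, **shared},
        synergy_partner="R2440", synergy_log2=1.0,
    )
    reg_b = CNVLocusSpec(
        locus_id="R2440", chrom="chr2", start=15_000_000, end=15_120_000,
        allele_type="duplication", sire_carrier_freq=0.5, dam_allele_freq=0.15,
        distal_targets={**targets_b, **{g: 1.0 for g in shared}},
    )
    trait = TraitSpec(trait_id="shear_force", effects={"R727": -0.8}, residual_sd=1.0)
    return SimConfig(
        n_sires=9, offspring_per_sire=20, n_genes=n_genes,
        loci=[local, reg_a, reg_b], traits=[trait], seed=seed,
    )


@dataclass
class SimResult:
    cohort: Cohort
    annotation: pd.DataFrame
    calls: pd.DataFrame
    counts: "object"            # CountMatrix
    gebvs: pd.DataFrame
    regions: pd.DataFrame       # truth: locus intervals as region definitions


def simulate_cohort(cfg: SimConfig) -> SimResult:
    """Run the full generator: pedigree, calls, counts, GEBVs, truth regions."""
    cohort = simulate_pedigree_genotypes(cfg)
    calls = emit_cnv_calls(cohort, cfg)
    counts, annotation = simulate_counts(cohort, cfg)
    gebvs = simulate_gebvs(cohort, cfg)
    regions = pd.DataFrame(
        [(l.locus_id, l.chrom, l.start, l.end) for l in cfg.loci],
        columns=["region_id", "chrom", "start", "end"],
    )
    return SimResult(cohort=cohort, annotation=annotation, calls=calls,
                     counts=counts, gebvs=gebvs, regions=regions)
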