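"""Synthetic tumor-cohort generator with planted ground truth.

Emulates the statistical structure a tumor/normal short-read pipeline sees once
alignment and pileup are done: per-site ref/alt read counts whose allele fractions
follow tumor purity and local copy number, 100-bp read-depth bins scaled by planted
copy-number segments, germline heterozygous SNPs, somatic SNVs/indels drawn either
from a seven-category background process (optionally with elevated-rate driver genes)
or from trinucleotide-context mutational signatures, and multi-region tumors with
exact trunk/shared/private splits.  Everything is deterministic given the seed.

The expected tumor allele fraction of a mutation on m of M tumor copies at purity
rho is rho*m / (rho*M + 2*(1-rho)); mutated copies default to m = 1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import channels as ch

# effect distribution of coding SNVs (synonymous, missense, nonsense, splice)
_SNV_EFFECTS = ("synonymous", "missense", "nonsense", "splice")
_SNV_EFFECT_P = (0.25, 0.68, 0.05, 0.02)

DEFAULT_BACKGROUND_RATES = {
    # per available base per sample; CpG transitions strongly elevated, total ~2/Mb
    "AT_transition": 1.0e-6,
    "AT_transversion": 5.0e-7,
    "CpG_transition": 1.0e-5,
    "CpG_transversion": 1.0e-6,
    "CG_transition": 1.5e-6,
    "CG_transversion": 1.0e-6,
    "indel": 2.0e-7,
}


@dataclass
class GeneSpec:
    """A gene footprint with its composition over the three site classes."""

    gene: str
    chrom: str
    start: int  # 0-based, half-open
    end: int
    class_fractions: tuple[float, float, float] = (0.50, 0.05, 0.45)  # AT, CpG, CG

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene}: end <= start")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9 or min(self.class_fractions) < 0:
            raise ValueError(f"gene {self.gene}: class fractions must be a distribution")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CnaSpec:
    """A recurrent copy-number event planted at a cohort frequency."""

    chrom: str
    start: int
    end: int
    copies: int  # total tumor copy number (0 = homozygous deletion)
    frequency: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("CNA interval end <= start")
        if self.copies < 0:
            raise ValueError("negative copy number")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("CNA frequency outside [0,1]")


@dataclass
class SignatureSpec:
    """A 96-channel mutational signature and its expected per-sample burden."""

    probabilities: np.ndarray
    weight: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (96,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("signature must be a 96-vector summing to 1 within 1e-9")
        if self.weight < 0:
            raise ValueError("negative signature weight")
        self.probabilities = p


def default_genes(
    n_genes: int = 50,
    gene_length: int = 3000,
    spacing: int = 20000,
    chroms: tuple[str, ...] = ("chr1", "chr12"),
) -> list[GeneSpec]:
    """A regular lattice of gene footprints across the simulated chromosomes."""
    genes = []
    per_chrom = -(-n_genes // len(chroms))
    i = 0
    for chrom in chroms:
        for j in range(per_chrom):
            if i >= n_genes:
                break
            start = 10000 + j * spacing
            genes.append(GeneSpec(f"G{i:04d}", chrom, start, start + gene_length))
            i += 1
    return genes


@dataclass
class SimConfig:
    """Full specification of a synthetic cohort."""

    n_samples: int = 12
    genome: tuple[tuple[str, int], ...] = (("chr1", 2_000_000), ("chr12", 2_000_000))
    genes: list[GeneSpec] = field(default_factory=default_genes)
    purity: float = 0.7
    mean_depth: float = 100.0
    background_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_RATES)
    )
    driver_spec: dict[str, float] = field(default_factory=dict)
    cna_spec: list[CnaSpec] = field(default_factory=list)
    signature_spec: list[SignatureSpec] = field(default_factory=list)
    germline_het_rate: float = 5e-4
    sequencing_error: float = 1e-3
    # per-sample signature proportions ~ Dirichlet(concentration * relative weights);
    # tumors vary in signature activity, and that variation is what makes the
    # factorization identifiable
    exposure_concentration: float = 1.0
    n_noise_sites: int = 0
    bin_size: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        sizes = dict(self.genome)
        if any(l <= 0 for l in sizes.values()):
            raise ValueError("chromosome lengths must be positive")
        for cat, rate in self.background_rates.items():
            if cat not in ch.CATEGORIES:
                raise ValueError(f"unknown mutation category {cat!r}")
            if rate < 0:
                raise ValueError(f"negative rate for {cat}")
        if self.germline_het_rate < 0 or self.sequencing_error < 0:
            raise ValueError("rates must be >= 0")
        for g in self.genes:
            if g.chrom not in sizes or g.end > sizes[g.chrom]:
                raise ValueError(f"gene {g.gene} outside the simulated genome")
        for c in self.cna_spec:
            if c.chrom not in sizes or c.end > sizes[c.chrom]:
                raise ValueError("CNA interval outside the simulated genome")
        for gene, mult in self.driver_spec.items():
            if mult < 0:
                raise ValueError(f"negative driver multiplier for {gene}")
        # expected mutations per gene per sample must fit in the gene footprint
        for g in self.genes:
            lam = self._gene_lambda(g) * self.driver_spec.get(g.gene, 1.0)
            if lam > g.length:
                raise ValueError(
                    f"expected mutation count {lam:.1f} for gene {g.gene} exceeds "
                    f"its footprint of {g.length} bases"
                )

    def _gene_lambda(self, g: GeneSpec) -> float:
        """Expected background mutations per sample in one gene (all categories)."""
        bases = gene_category_bases(g)
        return sum(self.background_rates.get(c, 0.0) * bases[c] for c in ch.CATEGORIES)


def gene_category_bases(g: GeneSpec) -> dict[str, float]:
    """Available bases per category for one gene (indel sees the whole footprint)."""
    f_at, f_cpg, f_cg = g.class_fractions
    class_bases = {"AT": f_at * g.length, "CpG": f_cpg * g.length, "CG": f_cg * g.length}
    bases = {cat: class_bases[cls] for cat, cls in ch.CATEGORY_TO_CLASS.items()}
    bases["indel"] = float(g.length)
    return bases


def footprint_table(genes: list[GeneSpec]) -> pd.DataFrame:
    """Per-gene available bases per category, as consumed by driver discovery."""
    rows = []
    for g in genes:
        bases = gene_category_bases(g)
        rows.append({"gene": g.gene, "chrom": g.chrom, "length": g.length, **bases})
    return pd.DataFrame(rows)


@dataclass
class TruthSet:
    """Planted ground truth accompanying a simulated cohort."""

    somatic: pd.DataFrame  # sample, chrom, pos, ref, alt, context, gene, effect, category, channel
    germline: pd.DataFrame  # sample, chrom, pos, ref, alt, context
    cna_segments: pd.DataFrame  # sample, chrom, start, end, copies, mean_log2
    exposures: pd.DataFrame  # sample, signature, count
    region_assignment: pd.DataFrame | None = None  # chrom,pos,ref,alt + one bool col/region

    def validate(self, genome: tuple[tuple[str, int], ...]) -> None:
        sizes = dict(genome)
        for df in (self.somatic, self.germline):
            if len(df):
                ok = df.apply(lambda r: r["chrom"] in sizes and 1 <= r["pos"] <= sizes[r["chrom"]], axis=1)
                if not ok.all():
                    raise ValueError("truth mutation outside the simulated genome")
        if self.region_assignment is not None and len(self.region_assignment):
            regions = [c for c in self.region_assignment.columns if c.startswith("T")]
            if not self.region_assignment[regions].any(axis=1).all():
                raise ValueError("mutation with empty region assignment")


@dataclass
class CohortData:
    """simulate_cohort output bundle."""

    site_tables: dict[str, pd.DataFrame]
    depth_tables: dict[str, pd.DataFrame]
    truth: TruthSet
    footprint: pd.DataFrame
    config: SimConfig


def _stage_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _copy_adjusted_fraction(purity: float, copies: int, mutated: int = 1) -> float:
    denom = purity * copies + 2.0 * (1.0 - purity)
    if denom <= 0:
        return 0.0
    return purity * mutated / denom


def _sample_segments(cfg: SimConfig, rng: np.random.Generator) -> list[dict]:
    segs = []
    for c in cfg.cna_spec:
        if rng.random() < c.frequency:
            ratio = (cfg.purity * c.copies + 2 * (1 - cfg.purity)) / 2.0
            segs.append(
                {
                    "chrom": c.chrom,
                    "start": c.start,
                    "end": c.end,
                    "copies": c.copies,
                    "mean_log2": np.log2(ratio) if ratio > 0 else -np.inf,
                }
            )
    return segs


def _copies_at(segs: list[dict], chrom: str, pos0: int) -> int:
    for s in segs:
        if s["chrom"] == chrom and s["start"] <= pos0 < s["end"]:
            return int(s["copies"])
    return 2


def _draw_context_for_category(category: str, rng: np.random.Generator) -> tuple[str, str, str]:
    """(ref, alt, context) on the pyrimidine strand for a background-category draw."""
    if category.startswith("AT"):
        ref = "T"
        alt = "C" if category.endswith("transition") else rng.choice(["A", "G"])
        five, three = rng.choice(ch.BASES, size=2)
        return ref, str(alt), f"{five}{ref}{three}"
    ref = "C"
    alt = "T" if category.endswith("transition") else rng.choice(["A", "G"])
    five = rng.choice(ch.BASES)
    if category.startswith("CpG"):
        three = "G"
    else:
        three = rng.choice(["A", "C", "T"])
    return ref, str(alt), f"{five}{ref}{three}"


def _maybe_flip_strand(
    ref: str, alt: str, context: str, rng: np.random.Generator
) -> tuple[str, str, str]:
    """Store half of the substitutions as observed on the purine strand."""
    if rng.random() < 0.5:
        return ch.COMPLEMENT[ref], ch.COMPLEMENT[alt], ch.revcomp(context)
    return ref, alt, context


def _draw_indel(rng: np.random.Generator) -> tuple[str, str, str]:
    base = rng.choice(ch.BASES)
    ins = rng.choice(ch.BASES)
    if rng.random() < 0.5:
        return str(base), f"{base}{ins}", "NNN"  # insertion
    return f"{base}{ins}", str(base), "NNN"  # deletion


def _read_counts(
    rng: np.random.Generator,
    n: int,
    mean_depth: float,
    fraction: np.ndarray,
    error: float,
) -> tuple[np.ndarray, np.ndarray]:
    depth = rng.poisson(mean_depth, size=n)
    p = fraction * (1 - error) + (1 - fraction) * error
    alt = rng.binomial(depth, np.clip(p, 0.0, 1.0))
    return depth, alt


def _draw_somatic_events(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[dict], np.ndarray]:
    """Planted somatic events for one sample; returns rows and signature counts."""
    rows: list[dict] = []
    sig_counts = np.zeros(max(len(cfg.signature_spec), 1), dtype=int)
    if cfg.signature_spec:
        # signature mode: burden ~ Poisson(sum of weights), channels from the mixture
        weights = np.array([s.weight for s in cfg.signature_spec], dtype=float)
        if weights.sum() == 0:
            return rows, sig_counts
        n_mut = rng.poisson(weights.sum())
        if n_mut == 0 or not cfg.genes:
            return rows, sig_counts
        lens = np.array([g.length * cfg.driver_spec.get(g.gene, 1.0) for g in cfg.genes])
        gene_idx = rng.choice(len(cfg.genes), size=n_mut, p=lens / lens.sum())
        if len(weights) > 1 and cfg.exposure_concentration > 0:
            alpha = cfg.exposure_concentration * weights / weights.mean()
            props = rng.dirichlet(alpha)
        else:
            props = weights / weights.sum()
        which_sig = rng.choice(len(weights), size=n_mut, p=props)
        for gi, si in zip(gene_idx, which_sig):
            sig_counts[si] += 1
            chan = rng.choice(96, p=cfg.signature_spec[si].probabilities)
            ref, alt, context = ch.channel_parts(int(chan))
            rows.append(
                _somatic_row(cfg, rng, cfg.genes[gi], ref, alt, context,
                             ch.categorize(ref, alt, context), int(chan))
            )
    else:
        # category mode: per gene x category Poisson counts at the planted rates
        for g in cfg.genes:
            mult = cfg.driver_spec.get(g.gene, 1.0)
            bases = gene_category_bases(g)
            for cat in ch.CATEGORIES:
                lam = cfg.background_rates.get(cat, 0.0) * bases[cat] * mult
                for _ in range(rng.poisson(lam)):
                    if cat == "indel":
                        ref, alt, context = _draw_indel(rng)
                        chan = -1
                    else:
                        ref, alt, context = _draw_context_for_category(cat, rng)
                        chan = ch.channel_index(ref, alt, context)
                        ref, alt, context = _maybe_flip_strand(ref, alt, context, rng)
                    rows.append(_somatic_row(cfg, rng, g, ref, alt, context, cat, chan))
    return rows, sig_counts


def _somatic_row(
    cfg: SimConfig,
    rng: np.random.Generator,
    gene: GeneSpec,
    ref: str,
    alt: str,
    context: str,
    category: str,
    channel: int,
) -> dict:
    pos0 = int(rng.integers(gene.start, gene.end))
    if category == "indel":
        effect = "frameshift"
    else:
        effect = str(rng.choice(_SNV_EFFECTS, p=_SNV_EFFECT_P))
        # signature-mode draws arrive on the pyrimidine strand; store half of them
        # as observed on the opposite strand (the channel in truth is unaffected)
        if cfg.signature_spec:
            ref, alt, context = _maybe_flip_strand(ref, alt, context, rng)
    return {
        "chrom": gene.chrom,
        "pos": pos0 + 1,  # 1-based in all emitted records
        "ref": ref,
        "alt": alt,
        "context": context,
        "gene": gene.gene,
        "effect": effect,
        "category": category,
        "channel": channel,
    }


def _dedupe_positions(rows: list[dict]) -> list[dict]:
    seen = set()
    out = []
    for r in rows:
        key = (r["chrom"], r["pos"])
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out


def _germline_rows(cfg: SimConfig, rng: np.random.Generator) -> list[dict]:
    rows = []
    for chrom, length in cfg.genome:
        n = rng.poisson(cfg.germline_het_rate * length)
        if n == 0:
            continue
        pos = np.unique(rng.integers(0, length, size=n))
        for p in pos:
            five, ref, three = rng.choice(ch.BASES, size=3)
            alt = rng.choice([b for b in ch.BASES if b != ref])
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(p) + 1,
                    "ref": str(ref),
                    "alt": str(alt),
                    "context": f"{five}{ref}{three}",
                }
            )
    return rows


def _noise_rows(cfg: SimConfig, rng: np.random.Generator) -> list[dict]:
    if cfg.n_noise_sites <= 0:
        return []
    lengths = np.array([l for _, l in cfg.genome], dtype=float)
    which = rng.choice(len(cfg.genome), size=cfg.n_noise_sites, p=lengths / lengths.sum())
    pos = np.array([rng.integers(0, cfg.genome[ci][1]) for ci in which])
    bases = np.array(ch.BASES)
    five = bases[rng.integers(0, 4, cfg.n_noise_sites)]
    ref_i = rng.integers(0, 4, cfg.n_noise_sites)
    ref = bases[ref_i]
    alt = bases[(ref_i + rng.integers(1, 4, cfg.n_noise_sites)) % 4]
    three = bases[rng.integers(0, 4, cfg.n_noise_sites)]
    return [
        {
            "chrom": cfg.genome[ci][0],
            "pos": int(p) + 1,
            "ref": str(r),
            "alt": str(a),
            "context": f"{f}{r}{t}",
        }
        for ci, p, f, r, a, t in zip(which, pos, five, ref, alt, three)
    ]


_SITE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "t_ref", "t_alt", "n_ref", "n_alt",
    "context", "gene", "effect", "mapq_pass_fraction", "mismatch_pass_fraction",
]


def _assemble_sites(
    cfg: SimConfig,
    rng: np.random.Generator,
    somatic: list[dict],
    germline: list[dict],
    noise: list[dict],
    segs: list[dict],
) -> pd.DataFrame:
    rows = list(somatic)
    t_frac = [
        _copy_adjusted_fraction(cfg.purity, _copies_at(segs, r["chrom"], r["pos"] - 1))
        for r in somatic
    ]
    t_scale = [
        (cfg.purity * _copies_at(segs, r["chrom"], r["pos"] - 1) + 2 * (1 - cfg.purity)) / 2.0
        for r in somatic
    ]
    n_frac = [0.0] * len(somatic)
    for r in germline:
        rows.append({**r, "gene": r.get("gene", ""), "effect": r.get("effect", "other")})
        t_frac.append(0.5)
        t_scale.append(1.0)
        n_frac.append(0.5)
    for r in noise:
        rows.append({**r, "gene": r.get("gene", ""), "effect": r.get("effect", "missense")})
        t_frac.append(0.0)
        t_scale.append(1.0)
        n_frac.append(0.0)
    n = len(rows)
    t_frac = np.asarray(t_frac)
    n_frac = np.asarray(n_frac)
    t_depth = rng.poisson(cfg.mean_depth * np.asarray(t_scale))
    e = cfg.sequencing_error
    t_alt = rng.binomial(t_depth, np.clip(t_frac * (1 - e) + (1 - t_frac) * e, 0, 1))
    n_depth = rng.poisson(cfg.mean_depth, size=n)
    n_alt = rng.binomial(n_depth, np.clip(n_frac * (1 - e) + (1 - n_frac) * e, 0, 1))
    df = pd.DataFrame(
        {
            "chrom": [r["chrom"] for r in rows],
            "pos": [r["pos"] for r in rows],
            "ref": [r["ref"] for r in rows],
            "alt": [r["alt"] for r in rows],
            "t_ref": t_depth - t_alt,
            "t_alt": t_alt,
            "n_ref": n_depth - n_alt,
            "n_alt": n_alt,
            "context": [r["context"] for r in rows],
            "gene": [r.get("gene", "") for r in rows],
            "effect": [r.get("effect", "other") for r in rows],
            "mapq_pass_fraction": 1.0,
            "mismatch_pass_fraction": 1.0,
        },
        columns=_SITE_COLUMNS,
    )
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def _depth_table(cfg: SimConfig, rng: np.random.Generator, segs: list[dict]) -> pd.DataFrame:
    frames = []
    for chrom, length in cfg.genome:
        starts = np.arange(0, length, cfg.bin_size)
        scale = np.ones(len(starts))
        for s in segs:
            if s["chrom"] != chrom:
                continue
            mask = (starts >= s["start"]) & (starts < s["end"])
            scale[mask] = (cfg.purity * s["copies"] + 2 * (1 - cfg.purity)) / 2.0
        t_depth = rng.poisson(cfg.mean_depth * scale)
        n_depth = rng.poisson(cfg.mean_depth, size=len(starts))
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "bin_start": starts, "t_depth": t_depth, "n_depth": n_depth}
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_cohort(config: SimConfig) -> CohortData:
    """Generate a full synthetic cohort with planted ground truth.

    Returns per-sample site-count tables, per-sample 100-bp depth tables, the
    :class:`TruthSet`, and the gene coverage footprint table.
    """
    config.validate()
    site_tables: dict[str, pd.DataFrame] = {}
    depth_tables: dict[str, pd.DataFrame] = {}
    som_all, germ_all, seg_all, expo_all = [], [], [], []
    for i in range(config.n_samples):
        sample = f"S{i:03d}"
        rng = _stage_rng(config.seed, 1, i)
        segs = _sample_segments(config, rng)
        somatic, sig_counts = _draw_somatic_events(config, rng)
        somatic = _dedupe_positions(somatic)
        germline = _germline_rows(config, rng)
        # germline/noise must not collide with somatic positions
        taken = {(r["chrom"], r["pos"]) for r in somatic}
        germline = [r for r in germline if (r["chrom"], r["pos"]) not in taken]
        taken |= {(r["chrom"], r["pos"]) for r in germline}
        noise = [r for r in _noise_rows(config, rng) if (r["chrom"], r["pos"]) not in taken]
        site_tables[sample] = _assemble_sites(config, rng, somatic, germline, noise, segs)
        depth_tables[sample] = _depth_table(config, rng, segs)
        for r in somatic:
            som_all.append({"sample": sample, **r})
        for r in germline:
            germ_all.append({"sample": sample, **r})
        for s in segs:
            seg_all.append({"sample": sample, **s})
        for k, c in enumerate(sig_counts):
            if config.signature_spec:
                expo_all.append({"sample": sample, "signature": k, "count": int(c)})
    truth = TruthSet(
        somatic=pd.DataFrame(
            som_all,
            columns=["sample", "chrom", "pos", "ref", "alt", "context", "gene",
                     "effect", "category", "channel"],
        ),
        germline=pd.DataFrame(
            germ_all, columns=["sample", "chrom", "pos", "ref", "alt", "context"]
        ),
        cna_segments=pd.DataFrame(
            seg_all, columns=["sample", "chrom", "start", "end", "copies", "mean_log2"]
        ),
        exposures=pd.DataFrame(expo_all, columns=["sample", "signature", "count"]),
    )
    truth.validate(config.genome)
    return CohortData(site_tables, depth_tables, truth, footprint_table(config.genes), config)


def simulate_multiregion(
    config: SimConfig,
    n_regions: int,
    trunk: int,
    shared: int | dict[tuple[int, ...], int] = 0,
    private: tuple[int, ...] = (),
) -> tuple[dict[str, pd.DataFrame], TruthSet]:
    """Simulate one tumor sampled in ``n_regions`` regions with an exact split.

    ``trunk`` mutations are present in every region; ``shared`` mutations occupy
    proper subsets of size >= 2 (an int places them all in the first region pair;
    a dict maps region-index tuples to counts); ``private[i]`` mutations are
    exclusive to region i.  Counts are exact, not sampled.
    """
    config.validate()
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if trunk < 0 or any(p < 0 for p in private):
        raise ValueError("counts must be >= 0")
    if private and len(private) != n_regions:
        raise ValueError("private counts must list one count per region")
    private = tuple(private) if private else tuple(0 for _ in range(n_regions))
    if isinstance(shared, int):
        if shared < 0:
            raise ValueError("counts must be >= 0")
        shared_map = {(0, 1): shared} if shared else {}
    else:
        shared_map = {tuple(sorted(k)): v for k, v in shared.items() if v}
    for subset, count in shared_map.items():
        if count < 0:
            raise ValueError("counts must be >= 0")
        if len(subset) < 2 or len(subset) >= n_regions or len(set(subset)) != len(subset):
            raise ValueError(
                f"shared subset {subset} is not a proper subset of size >= 2 of "
                f"{n_regions} regions"
            )
        if any(i < 0 or i >= n_regions for i in subset):
            raise ValueError(f"region index out of range in subset {subset}")
    regions = [f"T{i + 1}" for i in range(n_regions)]
    rng = _stage_rng(config.seed, 2)
    assignments: list[tuple[int, ...]] = []
    assignments += [tuple(range(n_regions))] * trunk
    for subset, count in sorted(shared_map.items()):
        assignments += [subset] * count
    for i, cnt in enumerate(private):
        assignments += [(i,)] * cnt

    # draw mutation identities with the cohort machinery (single pseudo-sample)
    muts: list[dict] = []
    genes = config.genes or default_genes()
    lens = np.array([g.length for g in genes], dtype=float)
    taken: set[tuple[str, int]] = set()
    for _ in assignments:
        while True:
            gi = int(rng.choice(len(genes), p=lens / lens.sum()))
            if config.signature_spec:
                weights = np.array([s.weight for s in config.signature_spec])
                si = int(rng.choice(len(weights), p=weights / weights.sum()))
                chan = int(rng.choice(96, p=config.signature_spec[si].probabilities))
                ref, alt, context = ch.channel_parts(chan)
                cat = ch.categorize(ref, alt, context)
            else:
                cats = [c for c in ch.CATEGORIES if c != "indel"]
                rates = np.array([config.background_rates.get(c, 0.0) for c in cats])
                if rates.sum() == 0:
                    rates = np.ones(len(cats))
                cat = str(rng.choice(cats, p=rates / rates.sum()))
                ref, alt, context = _draw_context_for_category(cat, rng)
                chan = ch.channel_index(ref, alt, context)
            row = _somatic_row(config, rng, genes[gi], ref, alt, context, cat, chan)
            if (row["chrom"], row["pos"]) not in taken:
                taken.add((row["chrom"], row["pos"]))
                muts.append(row)
                break

    pres_rows = []
    site_tables: dict[str, pd.DataFrame] = {r: None for r in regions}
    per_region_rows: dict[str, list] = {r: [] for r in regions}
    f_present = _copy_adjusted_fraction(config.purity, 2)
    for row, subset in zip(muts, assignments):
        pres = {"chrom": row["chrom"], "pos": row["pos"], "ref": row["ref"], "alt": row["alt"]}
        for i, rname in enumerate(regions):
            present = i in subset
            pres[rname] = bool(present)
            frac = f_present if present else 0.0
            td, ta = _read_counts(rng, 1, config.mean_depth, np.array([frac]), config.sequencing_error)
            nd, na = _read_counts(rng, 1, config.mean_depth, np.array([0.0]), config.sequencing_error)
            per_region_rows[rname].append(
                {
                    **{k: row[k] for k in ("chrom", "pos", "ref", "alt", "context", "gene", "effect")},
                    "t_ref": int(td[0] - ta[0]),
                    "t_alt": int(ta[0]),
                    "n_ref": int(nd[0] - na[0]),
                    "n_alt": int(na[0]),
                    "mapq_pass_fraction": 1.0,
                    "mismatch_pass_fraction": 1.0,
                }
            )
        pres_rows.append(pres)
    for rname in regions:
        df = pd.DataFrame(per_region_rows[rname], columns=_SITE_COLUMNS)
        site_tables[rname] = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    truth = TruthSet(
        somatic=pd.DataFrame(
            [{"sample": "tumor", **m} for m in muts],
            columns=["sample", "chrom", "pos", "ref", "alt", "context", "gene",
                     "effect", "category", "channel"],
        ),
        germline=pd.DataFrame(columns=["sample", "chrom", "pos", "ref", "alt", "context"]),
        cna_segments=pd.DataFrame(columns=["sample", "chrom", "start", "end", "copies", "mean_log2"]),
        exposures=pd.DataFrame(columns=["sample", "signature", "count"]),
        region_assignment=pd.DataFrame(pres_rows, columns=["chrom", "pos", "ref", "alt", *regions]),
    )
    truth.validate(config.genome)
    return site_tables, truth
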